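"""Exception hierarchy for cyanoflux."""


class CyanofluxError(Exception):
    """Base class for all package errors."""


class StructuralError(CyanofluxError):
    """The model violates a structural invariant (dangling references, bad bounds)."""


class InfeasibleProblem(CyanofluxError):
    """A linear program has no feasible solution under the given constraints."""


class UnboundedProblem(CyanofluxError):
    """A linear program is unbounded in the optimization direction."""


class UnknownProductError(CyanofluxError):
    """Requested product id is not in the pathway registry."""


class ScenarioError(CyanofluxError):
    """Invalid scenario configuration."""


class AugmentationError(CyanofluxError):
    """Model augmentation with a product pathway failed."""


class ProductUnreachableError(CyanofluxError):
    """The product export flux is zero at the optimum; synthesis is blocked."""

    def __init__(self, product_id, blocked_steps=()):
        self.product_id = product_id
        self.blocked_steps = list(blocked_steps)
        msg = f"product {product_id!r} unreachable"
        if self.blocked_steps:
            msg += "; blocked pathway steps: " + ", ".join(self.blocked_steps)
        super().__init__(msg)
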