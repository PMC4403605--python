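"""Pathway library for the twelve cyanobacterial bioproducts.

Each :class:`ProductDefinition` bundles the heterologous synthesis pathway
(reaction ids Bi0001–Bi0019 plus the native steps they rely on), the product's
elemental formula and lower heating value (LHV), an export reaction, and any
route constraints (native reactions that must be silenced so the optimizer
uses the intended route — e.g. ethanol synthesis is enforced through pyruvate
decarboxylase rather than the acetyl-CoA/acetaldehyde side route).

The propane and 1-butanol definitions share the crotonase/TER/PDUP trunk; it
is stored once and referenced by both.  Precursor metabolism upstream of the
heterologous steps (thiolase, acetolactate synthase, the MEP pathway,
acyl-ACP synthesis) is host metabolism and lives in the corenet extension
packs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corenet import make_metabolite
from .exceptions import AugmentationError, UnknownProductError
from .io import parse_equation
from .model import MetabolicModel, Reaction, parse_formula

_INF = 1000.0


def _rxn(rid: str, name: str, equation: str, subsystem: str = "product pathway",
         lb: float = 0.0, ub: float = _INF, pseudo: bool = False) -> Reaction:
    stoich, reversible = parse_equation(equation)
    return Reaction(id=rid, name=name, stoichiometry=stoich,
                    lower_bound=-_INF if reversible else lb, upper_bound=ub,
                    subsystem=subsystem, pseudo=pseudo,
                    is_exchange=rid.startswith("EX_"))


@dataclass(frozen=True)
class ProductDefinition:
    """A bioproduct: synthesis pathway, energetics and export."""

    product_id: str
    name: str
    formula: dict[str, int]
    lhv: float                       # lower heating value, kJ/mol
    metabolite_id: str               # cytosolic species excreted
    pathway: tuple[Reaction, ...]    # heterologous steps (may be empty)
    route_constraints: tuple[str, ...] = ()   # reaction ids forced to zero
    required_extensions: tuple[str, ...] = ()

    def __post_init__(self):
        if self.lhv <= 0:
            raise ValueError("LHV must be positive")

    @property
    def export_reaction(self) -> Reaction:
        met = self.metabolite_id
        ext = met[:-2] + "_e"
        return _rxn(f"T_{met[:-2]}", f"{self.name} export", f"{met} => {ext}",
                    subsystem="transport")

    @property
    def exchange_id(self) -> str:
        return f"EX_{self.metabolite_id[:-2]}"

    @property
    def degree_of_reduction(self) -> int:
        """Available electrons per molecule: 4C + H - 2O (+5N if N were reduced;
        the products here are CHO compounds, nitrogen-free)."""
        f = self.formula
        return 4 * f.get("C", 0) + f.get("H", 0) - 2 * f.get("O", 0)


# shared crotonase / trans-enoyl-CoA reductase / aldehyde-forming trunk of the
# propane and 1-butanol pathways (single source of truth)
_BUTANOL_TRUNK = (
    _rxn("Bi0006", "crotonase", "hbcoa_c => b2coa_c + h2o_c"),
    _rxn("Bi0007", "trans-enoyl-CoA reductase",
         "b2coa_c + nadh_c + h_c => btcoa_c + nad_c"),
    _rxn("Bi0008", "CoA-acylating butyraldehyde dehydrogenase",
         "btcoa_c + nadh_c + h_c => btal_c + coa_c + nad_c"),
)

_DEFS: dict[str, ProductDefinition] = {}


def _register(product: ProductDefinition) -> None:
    _DEFS[product.product_id] = product


_register(ProductDefinition(
    "ethanol", "ethanol", parse_formula("C2H6O"), 1370.0, "etoh_c",
    pathway=(
        _rxn("Bi0001", "pyruvate decarboxylase", "pyr_c + h_c => acald_c + co2_c"),
        _rxn("ADH_etoh", "alcohol dehydrogenase (NADPH)",
             "acald_c + nadph_c + h_c => etoh_c + nadp_c"),
    ),
    # enforce synthesis via PDC: silence the CoA-acylating acetaldehyde route
    route_constraints=("ACALDDH",),
))

_register(ProductDefinition(
    "ethylene", "ethylene", parse_formula("C2H4"), 1410.0, "ethl_c",
    pathway=(
        _rxn("Bi0005", "ethylene-forming enzyme",
             "3 akg_c + arg_c + 3 o2_c + 2 h_c => "
             "2 ethl_c + 7 co2_c + succ_c + gdn_c + p5c_c + 3 h2o_c"),
    ),
    required_extensions=("arginine_tca",),
))

_register(ProductDefinition(
    "lactate", "lactate", parse_formula("C3H6O3"), 1362.0, "lac_c",
    pathway=(
        _rxn("LDH_het", "lactate dehydrogenase (heterologous)",
             "pyr_c + nadh_c + h_c => lac_c + nad_c"),
    ),
))

_register(ProductDefinition(
    "propane", "propane", parse_formula("C3H8"), 2220.0, "prop_c",
    pathway=_BUTANOL_TRUNK + (
        _rxn("Bi0009", "aldehyde deformylating oxygenase (butyraldehyde)",
             "btal_c + o2_c + 4 fd_red_c + 3 h_c => "
             "prop_c + for_c + h2o_c + 4 fd_ox_c"),
    ),
    required_extensions=("fermentative",),
))

_register(ProductDefinition(
    "1-butanol", "1-butanol", parse_formula("C4H10O"), 2670.0, "btoh_c",
    pathway=_BUTANOL_TRUNK + (
        _rxn("Bi0010", "alcohol dehydrogenase (NADPH)",
             "btal_c + nadph_c + h_c => btoh_c + nadp_c"),
    ),
    required_extensions=("fermentative",),
))

_register(ProductDefinition(
    "isoprene", "isoprene", parse_formula("C5H8"), 3190.0, "iprn_c",
    pathway=(
        _rxn("Bi0011", "isoprene synthase", "dmapp_c => iprn_c + ppi_c"),
    ),
    required_extensions=("isoprenoid_mep",),
))

_register(ProductDefinition(
    "1-octadecanol", "1-octadecanol", parse_formula("C18H38O"), 11820.0, "ocdcol_c",
    pathway=(
        _rxn("Bi0012", "acyl-ACP reductase (C18)",
             "acp18_c + nadph_c + h_c => ocdcal_c + acp_c + nadp_c"),
        _rxn("Bi0014", "alcohol dehydrogenase (NADPH)",
             "ocdcal_c + nadph_c + h_c => ocdcol_c + nadp_c"),
    ),
    required_extensions=("fatty_acid",),
))

_register(ProductDefinition(
    "heptadecane", "heptadecane", parse_formula("C17H36"), 11350.0, "hpdcn_c",
    pathway=(
        _rxn("Bi0012", "acyl-ACP reductase (C18)",
             "acp18_c + nadph_c + h_c => ocdcal_c + acp_c + nadp_c"),
        _rxn("Bi0016", "aldehyde deformylating oxygenase (octadecanal)",
             "ocdcal_c + o2_c + 4 fd_red_c + 3 h_c => "
             "hpdcn_c + for_c + h2o_c + 4 fd_ox_c"),
    ),
    required_extensions=("fatty_acid",),
))

_register(ProductDefinition(
    "pentadecane", "pentadecane", parse_formula("C15H32"), 10050.0, "pntdcn_c",
    pathway=(
        _rxn("Bi0013", "acyl-ACP reductase (C16)",
             "acp16_c + nadph_c + h_c => hdcal_c + acp_c + nadp_c"),
        _rxn("Bi0017", "aldehyde deformylating oxygenase (hexadecanal)",
             "hdcal_c + o2_c + 4 fd_red_c + 3 h_c => "
             "pntdcn_c + for_c + h2o_c + 4 fd_ox_c"),
    ),
    required_extensions=("fatty_acid",),
))

_register(ProductDefinition(
    "butane-2,3-diol", "butane-2,3-diol", parse_formula("C4H10O2"), 2460.0, "btd_c",
    pathway=(
        _rxn("Bi0018", "2-acetolactate decarboxylase",
             "alac_c + h_c => actn_c + co2_c"),
        _rxn("Bi0019", "alcohol dehydrogenase (NADH)",
             "actn_c + nadh_c + h_c => btd_c + nad_c"),
    ),
    required_extensions=("fermentative",),
))

_register(ProductDefinition(
    "isobutyraldehyde", "isobutyraldehyde", parse_formula("C4H8O"), 2470.0, "ibal_c",
    pathway=(
        _rxn("Bi0002", "2-ketoacid decarboxylase",
             "mob_c + h_c => ibal_c + co2_c"),
    ),
    required_extensions=("fermentative",),
))

_register(ProductDefinition(
    "isobutanol", "isobutanol", parse_formula("C4H10O"), 2670.0, "ibtoh_c",
    pathway=(
        _rxn("Bi0002", "2-ketoacid decarboxylase",
             "mob_c + h_c => ibal_c + co2_c"),
        _rxn("Bi0003", "alcohol dehydrogenase (NADH)",
             "ibal_c + nadh_c + h_c => ibtoh_c + nad_c"),
    ),
    required_extensions=("fermentative",),
))

PRODUCT_IDS = tuple(_DEFS)


def get_product(product_id: str) -> ProductDefinition:
    """Look up a product definition by id."""
    try:
        return _DEFS[product_id]
    except KeyError:
        raise UnknownProductError(
            f"unknown product {product_id!r}; valid ids: {', '.join(PRODUCT_IDS)}"
        ) from None


# guanidine handling for the ethylene variants
_GDN_EXPORT = (
    _rxn("GEx", "guanidine export", "gdn_c => gdn_e", subsystem="transport"),
    _rxn("EX_gdn", "guanidine exchange", "gdn_e =>", subsystem="exchange",
         pseudo=True),
)
# guanidine decomposition: CH5N3 + H2O -> CH4N2O + NH3; ammonia is carried as
# ammonium (H4N), so an explicit proton keeps the reaction H-balanced
_GDN_REINTEGRATION = (
    _rxn("GDNDC", "guanidine decomposition (non-enzymatic)",
         "gdn_c + h2o_c + h_c => urea_c + nh4_c", subsystem="nitrogen"),
    _rxn("UREASE", "urease", "urea_c + h2o_c + 2 h_c => co2_c + 2 nh4_c",
         subsystem="nitrogen"),
)


def augment_with_product(model: MetabolicModel, product: ProductDefinition | str,
                         variant: str = "default") -> MetabolicModel:
    """Return a copy of ``model`` extended with a product pathway and export.

    ``variant`` applies to ethylene only: ``"default"`` exports the guanidine
    by-product, ``"guanidine_reintegration"`` instead adds non-enzymatic
    guanidine decomposition to urea + ammonium and urea hydrolysis, returning
    the nitrogen to metabolism.

    Pathway reactions already present in the model (e.g. a genome-scale input
    that ships its own Bi-reactions) are kept as they are; only missing
    reactions are added.  Route constraints are applied in either case.
    Augmenting twice with the same product is an error.
    """
    if isinstance(product, str):
        product = get_product(product)
    if variant not in ("default", "guanidine_reintegration"):
        raise AugmentationError(f"unknown variant {variant!r}")
    if variant == "guanidine_reintegration" and product.product_id != "ethylene":
        raise AugmentationError(
            "guanidine_reintegration only applies to ethylene")
    export = product.export_reaction
    if model.has_reaction(export.id) or model.has_reaction(product.exchange_id):
        raise AugmentationError(
            f"model already augmented with {product.product_id!r}")

    out = model.copy()
    new_reactions = list(product.pathway) + [
        export,
        _rxn(product.exchange_id, f"{product.name} exchange",
             f"{product.metabolite_id[:-2]}_e =>", subsystem="exchange", pseudo=True),
    ]
    if product.product_id == "ethylene":
        new_reactions += list(_GDN_EXPORT if variant == "default"
                              else _GDN_REINTEGRATION)
    # species produced by the new reactions may be introduced from the
    # catalog; species only consumed must already exist in the host model
    added = [rxn for rxn in new_reactions if not model.has_reaction(rxn.id)]
    produced = {met_id for rxn in added
                for met_id, coeff in rxn.stoichiometry.items() if coeff > 0}
    missing_substrates = sorted(
        {met_id for rxn in added for met_id, coeff in rxn.stoichiometry.items()
         if coeff < 0 and met_id not in produced
         and not out.has_metabolite(met_id)})
    if missing_substrates:
        raise AugmentationError(
            f"pathway substrates missing from model for {product.product_id!r}: "
            + ", ".join(missing_substrates))
    for rxn in added:
        for met_id in rxn.stoichiometry:
            if not out.has_metabolite(met_id):
                out.add_metabolite(make_metabolite(met_id))
    for rxn in new_reactions:
        if not out.has_reaction(rxn.id):
            out.add_reaction(rxn.copy())
    for rid in product.route_constraints:
        if out.has_reaction(rid):
            out.set_bounds(rid, 0.0, 0.0)
    out.objective = {product.exchange_id: 1.0}
    out.annotations["product"] = product.product_id
    out.annotations["variant"] = variant
    return out


def energetic_yield(flux: float, product: ProductDefinition) -> float:
    """Energetic yield in J gDW^-1 h^-1 for a product flux in umol gDW^-1 h^-1.

    The LHV in kJ/mol equals J/mmol, i.e. 1e-3 J/umol: a 1370 kJ/mol fuel
    yields 1.37 J per umol.
    """
    if flux < 0:
        raise ValueError("flux must be non-negative")
    return flux * product.lhv * 1e-3
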