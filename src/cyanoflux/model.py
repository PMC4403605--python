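"""In-memory representation of a stoichiometric metabolic network.

A :class:`MetabolicModel` holds metabolites, reactions with signed rational
stoichiometric coefficients, flux bounds and a linear objective.  The model is
the common currency of the package: the synthetic core network, tabular and
SBML inputs all produce one, and the LP machinery consumes one.

Coefficients are stored as exact :class:`fractions.Fraction` values (e.g. the
14/3 H+ per ATP of the thylakoid ATP synthase) and are converted to floating
point only when the stoichiometric matrix is assembled for a solver.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from .exceptions import StructuralError

#: elements tracked by the balance checker
ELEMENTS = ("C", "H", "N", "O", "P", "S")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string like ``"C2H6O"`` into a count map.

    An empty string yields an empty map, which is a *known* composition with
    zero atoms of every element (used for electron carriers such as ferredoxin
    whose redox pair is elementally identical).
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, num = match.groups()
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Inverse of :func:`parse_formula` (Hill-ish ordering: C, H, then others)."""
    order = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{el}{counts[el] if counts[el] != 1 else ''}"
                   for el in order if counts[el])


@dataclass
class Metabolite:
    """A metabolic species in a single compartment.

    ``formula`` is an elemental count map; ``None`` means unknown (the species
    cannot be balance-checked), while an empty dict means "no atoms tracked"
    (pool carriers).  Pseudo-species such as photons or biomass carry
    ``formula=None``.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None
    charge: int | None = None

    def __post_init__(self):
        if not self.id:
            raise StructuralError("metabolite id must be non-empty")
        if self.formula is not None:
            for el, n in self.formula.items():
                if not isinstance(n, int) or n < 0:
                    raise StructuralError(
                        f"metabolite {self.id}: element count {el}={n} must be a "
                        "non-negative integer")


def _as_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, float):
        return Fraction(x).limit_denominator(10**9)
    return Fraction(x)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite ids to signed rational coefficients
    (negative = consumed).  ``pseudo`` marks reactions that are unbalanced by
    design (photon capture, biomass drain, exchanges) and are skipped by the
    elemental balance check.
    """

    id: str
    stoichiometry: dict[str, Fraction] = field(default_factory=dict)
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    subsystem: str = ""
    isoenzyme_group: str | None = None
    is_exchange: bool = False
    pseudo: bool = False

    def __post_init__(self):
        if not self.id:
            raise StructuralError("reaction id must be non-empty")
        self.stoichiometry = {m: _as_fraction(c) for m, c in self.stoichiometry.items()}
        if not self.stoichiometry:
            raise StructuralError(f"reaction {self.id}: empty stoichiometry")
        if any(c == 0 for c in self.stoichiometry.values()):
            raise StructuralError(f"reaction {self.id}: zero coefficient")
        if self.lower_bound > self.upper_bound:
            raise StructuralError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds upper "
                f"bound {self.upper_bound}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


class MetabolicModel:
    """A stoichiometric network: metabolites, reactions, objective."""

    def __init__(self, model_id: str = "model",
                 metabolites: Iterable[Metabolite] = (),
                 reactions: Iterable[Reaction] = (),
                 objective: Mapping[str, float] | None = None,
                 annotations: Mapping[str, str] | None = None):
        self.id = model_id
        self.metabolites: list[Metabolite] = []
        self.reactions: list[Reaction] = []
        self._met_index: dict[str, int] = {}
        self._rxn_index: dict[str, int] = {}
        self.objective: dict[str, float] = dict(objective or {})
        self.annotations: dict[str, str] = dict(annotations or {})
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self._met_index:
            raise StructuralError(f"duplicate metabolite id {met.id!r}")
        self._met_index[met.id] = len(self.metabolites)
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self._rxn_index:
            raise StructuralError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self._met_index:
                raise StructuralError(
                    f"reaction {rxn.id} references unknown metabolite {met_id!r}")
        self._rxn_index[rxn.id] = len(self.reactions)
        self.reactions.append(rxn)

    def remove_reaction(self, rxn_id: str) -> None:
        idx = self._rxn_index.pop(rxn_id)
        del self.reactions[idx]
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self.objective.pop(rxn_id, None)

    # -- lookup -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def set_bounds(self, rxn_id: str, lower: float, upper: float) -> None:
        rxn = self.reaction(rxn_id)
        if lower > upper:
            raise StructuralError(f"{rxn_id}: lower bound {lower} > upper {upper}")
        rxn.lower_bound = lower
        rxn.upper_bound = upper

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            self.id,
            [replace(m, formula=None if m.formula is None else dict(m.formula))
             for m in self.metabolites],
            [r.copy() for r in self.reactions],
            self.objective, self.annotations)

    def validate(self) -> None:
        """Raise :class:`StructuralError` on any violated model invariant."""
        for rxn_id in self.objective:
            if rxn_id not in self._rxn_index:
                raise StructuralError(f"objective references unknown reaction {rxn_id!r}")
        build_stoich_matrix(self)

    def __repr__(self):
        return (f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions>")


def build_stoich_matrix(model: MetabolicModel, exact: bool = False):
    """Assemble the stoichiometric matrix S (metabolites x reactions).

    With ``exact=False`` (default) a float ``scipy.sparse.csr_matrix`` suitable
    for LP assembly is returned; with ``exact=True`` a dense object-dtype array
    of ``Fraction`` entries preserving the rational coefficients (scipy sparse
    containers do not carry exact rationals).

    Entry (i, j) is the coefficient of metabolite i in reaction j; columns
    follow the model's reaction order.
    """
    n_met, n_rxn = len(model.metabolites), len(model.reactions)
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            try:
                i = met_index[met_id]
            except KeyError:
                raise StructuralError(
                    f"reaction {rxn.id} references unknown metabolite {met_id!r}"
                ) from None
            rows.append(i)
            cols.append(j)
            data.append(coeff if exact else float(coeff))
    if exact:
        mat = np.full((n_met, n_rxn), Fraction(0), dtype=object)
        for i, j, coeff in zip(rows, cols, data):
            mat[i, j] += coeff
        return mat
    return sparse.csr_matrix(
        (np.array(data, dtype=float),
         (np.array(rows, dtype=np.int32), np.array(cols, dtype=np.int32))),
        shape=(n_met, n_rxn))


@dataclass(frozen=True)
class BalanceIssue:
    """One elemental imbalance (or an uncheckable reaction)."""

    reaction_id: str
    element: str            # element symbol, or "uncheckable"
    imbalance: Fraction     # products minus substrates atom count (0 if uncheckable)


def check_elemental_balance(model: MetabolicModel,
                            elements: tuple[str, ...] = ELEMENTS,
                            include_pseudo: bool = False) -> list[BalanceIssue]:
    """Check conservation of atoms across every non-pseudo, non-exchange reaction.

    Returns one :class:`BalanceIssue` per (reaction, element) with a non-zero
    net atom count.  Reactions involving a species without a formula are
    reported with ``element="uncheckable"`` rather than as imbalanced.
    A fully balanced model yields an empty list.
    """
    issues: list[BalanceIssue] = []
    for rxn in model.reactions:
        if rxn.is_exchange or (rxn.pseudo and not include_pseudo):
            continue
        formulas = {}
        uncheckable = False
        for met_id in rxn.stoichiometry:
            f = model.metabolite(met_id).formula
            if f is None:
                uncheckable = True
                break
            formulas[met_id] = f
        if uncheckable:
            issues.append(BalanceIssue(rxn.id, "uncheckable", Fraction(0)))
            continue
        for el in elements:
            net = sum((coeff * formulas[met_id].get(el, 0)
                       for met_id, coeff in rxn.stoichiometry.items()),
                      Fraction(0))
            if net != 0:
                issues.append(BalanceIssue(rxn.id, el, net))
    return issues


def _normalized_stoich(rxn: Reaction) -> tuple:
    """Stoichiometry normalized to the first (sorted) coefficient = 1.

    Used to detect isoreactions: duplicates up to positive scaling share a key.
    """
    items = sorted(rxn.stoichiometry.items())
    scale = abs(items[0][1])
    return tuple((m, c / scale) for m, c in items)


def auto_group_isoenzymes(model: MetabolicModel) -> MetabolicModel:
    """Assign ``isoenzyme_group`` keys to reactions with identical stoichiometry.

    Reactions whose stoichiometries agree up to a positive scale factor are
    considered isoreactions (parallel enzymes catalysing the same conversion).
    Existing group assignments are kept.  Returns a modified copy.
    """
    out = model.copy()
    seen: dict[tuple, list[Reaction]] = {}
    for rxn in out.reactions:
        if rxn.is_exchange:
            continue
        seen.setdefault(_normalized_stoich(rxn), []).append(rxn)
    n = 0
    for key, members in seen.items():
        if len(members) > 1 and all(r.isoenzyme_group is None for r in members):
            n += 1
            for r in members:
                r.isoenzyme_group = f"auto{n:03d}"
    return out


def collapse_isoenzymes(model: MetabolicModel) -> MetabolicModel:
    """Merge reactions sharing an ``isoenzyme_group`` into one representative.

    The representative (the group's first reaction in model order) carries the
    summed flux bounds of all members.  Members must have identical
    stoichiometry up to a positive scale factor; the representative's scaling
    is kept and other members' bounds are rescaled before summation.
    Idempotent: a model without multi-member groups is returned unchanged
    (as a copy).
    """
    groups: dict[str, list[Reaction]] = {}
    for rxn in model.reactions:
        if rxn.isoenzyme_group is not None:
            groups.setdefault(rxn.isoenzyme_group, []).append(rxn)

    out = MetabolicModel(model.id, annotations=model.annotations)
    for m in model.metabolites:
        out.add_metabolite(replace(m, formula=None if m.formula is None else dict(m.formula)))
    dropped: dict[str, str] = {}
    for rxn in model.reactions:
        grp = rxn.isoenzyme_group
        if grp is None or len(groups[grp]) == 1 or rxn is groups[grp][0]:
            out.add_reaction(rxn.copy())
            continue
        rep = groups[grp][0]
        rep_key = _normalized_stoich(rep)
        if _normalized_stoich(rxn) != rep_key:
            raise StructuralError(
                f"isoenzyme group {grp!r}: members {rep.id} and {rxn.id} have "
                "conflicting stoichiometry")
        # rescale member bounds into the representative's flux units
        scale = float(abs(sorted(rxn.stoichiometry.items())[0][1])
                      / abs(sorted(rep.stoichiometry.items())[0][1]))
        merged = out.reaction(rep.id)
        merged.lower_bound += rxn.lower_bound * scale
        merged.upper_bound += rxn.upper_bound * scale
        dropped[rxn.id] = rep.id

    objective = {}
    for rid, w in model.objective.items():
        objective[dropped.get(rid, rid)] = objective.get(dropped.get(rid, rid), 0.0) + w
    out.objective = objective
    return out
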