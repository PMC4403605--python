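"""Model and scenario serialization.

Three dialects are supported:

* SBML (Level 2 with note-encoded bounds, or Level 3 with the flux-balance
  constraints extension), read and written through cobrapy/libsbml;
* a tab-separated tabular dialect (a reactions table with human-readable
  equation strings plus a metabolites table);
* flat key/value scenario files (one ``key value`` pair per line, ``#``
  comments), which are bit-exact and diff-able.

Equation strings use ``=>`` for irreversible and ``<=>`` for reversible
reactions; coefficients may be integers, decimals, or exact rationals such as
``14/3``.  Metabolite tokens are opaque ids (compartments are part of the id,
conventionally a ``_c``/``_l``/``_e`` suffix).
"""

from __future__ import annotations

import csv
import io as _stdio
from fractions import Fraction
from pathlib import Path

from .exceptions import ScenarioError, StructuralError
from .model import (MetabolicModel, Metabolite, Reaction, format_formula,
                    parse_formula)

DEFAULT_BOUND = 1000.0

# ---------------------------------------------------------------------------
# equation strings
# ---------------------------------------------------------------------------


def _parse_coefficient(token: str) -> Fraction:
    try:
        return Fraction(token)
    except ValueError:
        raise ValueError(f"bad stoichiometric coefficient {token!r}") from None


def parse_equation(text: str) -> tuple[dict[str, Fraction], bool]:
    """Parse ``"2 A + B => C"`` into ``({A: -2, B: -1, C: 1}, reversible)``.

    A one-sided equation (``"A =>"`` or ``"=> A"``) denotes an exchange with
    the environment.
    """
    if "<=>" in text:
        arrow, reversible = "<=>", True
    elif "=>" in text:
        arrow, reversible = "=>", False
    else:
        raise ValueError(f"equation {text!r} has no '=>' or '<=>' arrow")
    left, right = text.split(arrow)
    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            parts = term.split()
            if not parts:
                raise ValueError(f"empty term in equation {text!r}")
            if len(parts) == 1:
                coeff, met = Fraction(1), parts[0]
            elif len(parts) == 2:
                coeff, met = _parse_coefficient(parts[0]), parts[1]
            else:
                raise ValueError(f"cannot parse term {term.strip()!r} in {text!r}")
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff

    add_side(left, -1)
    add_side(right, +1)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise ValueError(f"equation {text!r} reduces to nothing")
    return stoich, reversible


def format_equation(rxn: Reaction) -> str:
    """Render a reaction's stoichiometry as an equation string."""
    subs, prods = [], []
    for met, coeff in sorted(rxn.stoichiometry.items()):
        target = prods if coeff > 0 else subs
        mag = abs(coeff)
        target.append(met if mag == 1 else f"{mag} {met}")
    arrow = "<=>" if rxn.reversible else "=>"
    return f"{' + '.join(subs)} {arrow} {' + '.join(prods)}".strip()


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

_RXN_COLUMNS = ["id", "name", "equation", "lower_bound", "upper_bound",
                "subsystem", "isoenzyme_group", "is_exchange", "pseudo"]
_MET_COLUMNS = ["id", "name", "compartment", "formula", "charge"]


def write_tabular_model(model: MetabolicModel, reactions_path, metabolites_path) -> None:
    """Write the model as two UTF-8 tab-separated tables."""
    with open(metabolites_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MET_COLUMNS)
        for met in model.metabolites:
            writer.writerow([
                met.id, met.name, met.compartment,
                "-" if met.formula is None else format_formula(met.formula),
                "" if met.charge is None else met.charge,
            ])
    with open(reactions_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_RXN_COLUMNS + ["objective"])
        for rxn in model.reactions:
            writer.writerow([
                rxn.id, rxn.name, format_equation(rxn),
                repr(rxn.lower_bound), repr(rxn.upper_bound), rxn.subsystem,
                rxn.isoenzyme_group or "", int(rxn.is_exchange), int(rxn.pseudo),
                model.objective.get(rxn.id, ""),
            ])


def read_tabular_model(reactions_path, metabolites_path,
                       model_id: str | None = None) -> MetabolicModel:
    """Read a model from the tabular dialect written by :func:`write_tabular_model`."""
    model = MetabolicModel(model_id or Path(reactions_path).stem)
    with open(metabolites_path, encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter="\t")):
            if row.get("id") is None:
                raise StructuralError(f"metabolite table row {i + 2}: missing id column")
            raw_formula = (row.get("formula") or "").strip()
            formula = None if raw_formula == "-" else parse_formula(raw_formula)
            charge = row.get("charge") or ""
            model.add_metabolite(Metabolite(
                id=row["id"], name=row.get("name") or "",
                compartment=row.get("compartment") or "c",
                formula=formula,
                charge=int(charge) if charge.strip() else None))
    with open(reactions_path, encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter="\t")):
            rid = row.get("id")
            if not rid:
                raise StructuralError(f"reaction table row {i + 2}: missing id")
            try:
                stoich, reversible = parse_equation(row["equation"])
            except (KeyError, ValueError) as exc:
                raise StructuralError(
                    f"reaction table row {i + 2} ({rid}): {exc}") from None
            for met in stoich:
                if not model.has_metabolite(met):
                    raise StructuralError(
                        f"reaction table row {i + 2} ({rid}): unknown metabolite {met!r}")
            lb = row.get("lower_bound") or ""
            ub = row.get("upper_bound") or ""
            lower = float(lb) if lb.strip() else (-DEFAULT_BOUND if reversible else 0.0)
            upper = float(ub) if ub.strip() else DEFAULT_BOUND
            model.add_reaction(Reaction(
                id=rid, name=row.get("name") or "", stoichiometry=stoich,
                lower_bound=lower, upper_bound=upper,
                subsystem=row.get("subsystem") or "",
                isoenzyme_group=row.get("isoenzyme_group") or None,
                is_exchange=bool(int(row.get("is_exchange") or 0)),
                pseudo=bool(int(row.get("pseudo") or 0))))
            obj = (row.get("objective") or "").strip()
            if obj:
                model.objective[rid] = float(obj)
    return model


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for met in model.metabolites:
        m = cobra.Metabolite(
            met.id, name=met.name, compartment=met.compartment or "c",
            formula=None if met.formula is None else format_formula(met.formula),
            charge=met.charge)
        mets[met.id] = m
    cm.add_metabolites(list(mets.values()))
    for rxn in model.reactions:
        r = cobra.Reaction(rxn.id, name=rxn.name,
                           lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound)
        r.subsystem = rxn.subsystem
        cm.add_reactions([r])
        r.add_metabolites({mets[m]: float(c) for m, c in rxn.stoichiometry.items()})
        notes = {}
        if rxn.isoenzyme_group:
            notes["isoenzyme_group"] = rxn.isoenzyme_group
        if rxn.pseudo:
            notes["pseudo"] = "true"
        if rxn.is_exchange:
            notes["exchange"] = "true"
        if notes:
            r.notes = notes
    if model.objective:
        cm.objective = {cm.reactions.get_by_id(rid): w
                        for rid, w in model.objective.items()}
    return cm


def _from_cobra(cm) -> MetabolicModel:
    model = MetabolicModel(cm.id or "sbml_model")
    for met in cm.metabolites:
        formula = None
        if met.formula:
            try:
                formula = parse_formula(met.formula)
            except ValueError:
                formula = None
        model.add_metabolite(Metabolite(
            id=met.id, name=met.name or "", compartment=met.compartment or "c",
            formula=formula, charge=met.charge))
    from cobra.util.solver import linear_reaction_coefficients

    objective = linear_reaction_coefficients(cm)
    for rxn in cm.reactions:
        if not rxn.metabolites:
            continue  # pure bookkeeping reactions carry no stoichiometry
        notes = rxn.notes or {}
        model.add_reaction(Reaction(
            id=rxn.id, name=rxn.name or "",
            stoichiometry={m.id: Fraction(c).limit_denominator(10**9)
                           for m, c in rxn.metabolites.items()},
            lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
            subsystem=rxn.subsystem or "",
            isoenzyme_group=notes.get("isoenzyme_group") or None,
            is_exchange=rxn.boundary or str(notes.get("exchange")).lower() == "true",
            pseudo=str(notes.get("pseudo")).lower() == "true"))
    model.objective = {r.id: float(w) for r, w in objective.items()}
    return model


def read_sbml_model(path) -> MetabolicModel:
    """Read an SBML file (L2 with notes, or L3-FBC; the level is sniffed)."""
    from cobra.io import read_sbml_model as _read

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        cm = _read(str(path))
    except Exception as exc:  # libsbml reports line context in its message
        raise StructuralError(f"cannot parse SBML file {path}: {exc}") from None
    return _from_cobra(cm)


def write_sbml_model(model: MetabolicModel, path) -> None:
    """Write the model as SBML Level 3 with flux-balance constraints."""
    from cobra.io import write_sbml_model as _write

    _write(_to_cobra(model), str(path))


# ---------------------------------------------------------------------------
# scenario key/value files
# ---------------------------------------------------------------------------


def read_keyvalue(path_or_text) -> dict[str, str]:
    """Parse a flat key/value file: one ``key value`` pair per line, ``#`` comments."""
    if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text(encoding="utf-8")
    else:
        text = str(path_or_text)
    pairs: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ScenarioError(f"line {lineno}: expected 'key value', got {raw!r}")
        pairs[parts[0]] = parts[1].strip()
    return pairs


def read_scenario_config(path):
    """Read a scenario preset from a key/value file (see :mod:`cyanoflux.scenarios`)."""
    from .scenarios import Scenario

    return Scenario.from_mapping(read_keyvalue(path))


def write_scenario_config(scenario, path) -> None:
    Path(path).write_text(scenario.to_keyvalue(), encoding="utf-8")
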