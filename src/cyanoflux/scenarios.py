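"""Constraint presets for the two simulation regimes.

``yield_scenario`` reproduces the maximal-stoichiometric-yield conditions:
no maintenance demand, no respiration, Mehler-like or ROS side reactions,
Rubisco carboxylase and oxygenase decoupled, bicarbonate importable through
the cost-free Na+-dependent route, and a fixed photon influx of 15.57
flux units.

``transition_scenario`` reproduces the wild-type-state preset used for the
transition experiments: the oxygenase carries 3% of total Rubisco flux,
basal respiration and the Mehler-like reaction each consume 10% of the PSII
oxygen evolution, ROS formation diverts 0.5% of the electrons converted at
each photosystem, the basal maintenance ATP demand is at least 0.6312
flux units, and the photon influx is 18.0.

Couplings are installed as extra LP rows tied dynamically to the PSII flux
("dynamic" mode); a "fixed" mode (freeze the side fluxes at their initial
wild-type values) is available as a configuration switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .exceptions import ScenarioError, StructuralError
from .lp import LinearConstraint
from .model import MetabolicModel

#: photon influx reproducing the yield-mode light input (umol gDW^-1 h^-1)
YIELD_PHOTON_INFLUX = 15.57
#: photon influx of the transition experiments (supports ~24 h doubling time
#: on the genome-scale network once side-reaction couplings apply)
TRANSITION_PHOTON_INFLUX = 18.0
#: basal maintenance ATP demand of the wild-type state (mmol gDW^-1 h^-1)
TRANSITION_MAINTENANCE = 0.6312


@dataclass(frozen=True)
class CouplingConstraint:
    """A linear relation ``sum(coeffs[r] * v_r) = 0`` between named fluxes."""

    coeffs: dict[str, float]

    def __post_init__(self):
        if len(self.coeffs) < 2:
            raise ScenarioError("coupling needs at least two terms")
        if any(c == 0 for c in self.coeffs.values()):
            raise ScenarioError("coupling coefficients must be non-zero")

    def as_linear_constraint(self) -> LinearConstraint:
        return LinearConstraint(self.coeffs, "==", 0.0)


_SCENARIO_KEYS = {
    "name": str,
    "photon_influx": float,
    "maintenance_atp": float,
    "rubisco_coupled": lambda s: str(s).strip().lower() in ("1", "true", "yes"),
    "oxygenase_fraction": float,
    "respiration_fraction": float,
    "mehler_fraction": float,
    "ros_fraction": float,
    "nitrogen_source": str,
    "coupling_mode": str,
}


@dataclass(frozen=True)
class Scenario:
    """A named constraint preset."""

    name: str = "yield_mode"
    photon_influx: float = YIELD_PHOTON_INFLUX
    maintenance_atp: float = 0.0
    rubisco_coupled: bool = False
    oxygenase_fraction: float = 0.0   # share of total Rubisco flux
    respiration_fraction: float = 0.0  # share of PSII O2 evolution
    mehler_fraction: float = 0.0       # share of PSII O2 evolution
    ros_fraction: float = 0.0          # share of electrons per photosystem
    nitrogen_source: str = "nitrate"
    coupling_mode: str = "dynamic"     # dynamic | fixed
    couplings: tuple[CouplingConstraint, ...] = ()

    def __post_init__(self):
        if self.photon_influx <= 0:
            raise ScenarioError("photon_influx must be positive")
        if self.maintenance_atp < 0:
            raise ScenarioError("maintenance_atp must be non-negative")
        for frac_name in ("oxygenase_fraction", "respiration_fraction",
                          "mehler_fraction", "ros_fraction"):
            value = getattr(self, frac_name)
            if not 0.0 <= value < 1.0:
                raise ScenarioError(f"{frac_name} must lie in [0, 1)")
        if self.nitrogen_source not in ("nitrate", "ammonium"):
            raise ScenarioError(
                f"nitrogen_source must be 'nitrate' or 'ammonium', "
                f"got {self.nitrogen_source!r}")
        if self.coupling_mode not in ("dynamic", "fixed"):
            raise ScenarioError("coupling_mode must be 'dynamic' or 'fixed'")

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_mapping(cls, pairs: dict[str, str]) -> "Scenario":
        unknown = sorted(set(pairs) - set(_SCENARIO_KEYS))
        if unknown:
            raise ScenarioError(
                f"unknown scenario keys: {', '.join(unknown)}; "
                f"valid keys: {', '.join(sorted(_SCENARIO_KEYS))}")
        kwargs = {}
        for key, raw in pairs.items():
            try:
                kwargs[key] = _SCENARIO_KEYS[key](raw)
            except ValueError:
                raise ScenarioError(f"cannot parse value {raw!r} for key {key!r}")
        name = kwargs.get("name")
        if name == "transition_mode" or (
                name is None and ("maintenance_atp" in kwargs
                                  or "oxygenase_fraction" in kwargs)):
            base = transition_scenario()
        else:
            base = yield_scenario()
        return replace(base, **kwargs)

    def to_keyvalue(self) -> str:
        lines = [f"name {self.name}",
                 f"photon_influx {self.photon_influx!r}",
                 f"maintenance_atp {self.maintenance_atp!r}",
                 f"rubisco_coupled {str(self.rubisco_coupled).lower()}",
                 f"oxygenase_fraction {self.oxygenase_fraction!r}",
                 f"respiration_fraction {self.respiration_fraction!r}",
                 f"mehler_fraction {self.mehler_fraction!r}",
                 f"ros_fraction {self.ros_fraction!r}",
                 f"nitrogen_source {self.nitrogen_source}",
                 f"coupling_mode {self.coupling_mode}"]
        return "\n".join(lines) + "\n"


def yield_scenario(photon_influx: float = YIELD_PHOTON_INFLUX,
                   nitrogen_source: str = "nitrate") -> Scenario:
    """Maximal-stoichiometric-yield preset (no energy-consuming side reactions)."""
    return Scenario(name="yield_mode", photon_influx=photon_influx,
                    nitrogen_source=nitrogen_source)


def transition_scenario(photon_influx: float = TRANSITION_PHOTON_INFLUX,
                        maintenance_atp: float = TRANSITION_MAINTENANCE,
                        coupling_mode: str = "dynamic",
                        nitrogen_source: str = "nitrate") -> Scenario:
    """Wild-type-state preset used by trade-off scans and transition experiments."""
    return Scenario(name="transition_mode", photon_influx=photon_influx,
                    maintenance_atp=maintenance_atp, rubisco_coupled=True,
                    oxygenase_fraction=0.03, respiration_fraction=0.10,
                    mehler_fraction=0.10, ros_fraction=0.005,
                    coupling_mode=coupling_mode, nitrogen_source=nitrogen_source)


# electrons moved per unit flux of the core light reactions (used to translate
# the percentage rules into coupling rows)
_PSII_ELECTRONS_PER_UNIT = 2.0    # PSII is written per 2 electrons
_PSII_O2_PER_UNIT = 0.5
_PSI_ELECTRONS_PER_UNIT = 1.0     # PSI is written per electron
_ROS_ELECTRONS_PER_UNIT = 2.0     # both lumped ROS sinks consume 2 electrons
_RESP_O2_PER_UNIT = 1.0
_MEHLER_O2_PER_UNIT = 1.0


def scenario_couplings(scenario: Scenario, ids) -> list[CouplingConstraint]:
    """Build the coupling rows of a scenario for a model with accounting ids.

    ``ids`` maps accounting roles ("psii", "respiration", ...) to reaction ids
    (see :data:`cyanoflux.corenet.CORE_ACCOUNTING_IDS`).
    """
    rows: list[CouplingConstraint] = list(scenario.couplings)
    if scenario.rubisco_coupled and scenario.oxygenase_fraction > 0:
        f = scenario.oxygenase_fraction
        # v_oxy = f * (v_carb + v_oxy)  <=>  (1 - f) v_oxy - f v_carb = 0
        rows.append(CouplingConstraint({
            ids["rubisco_oxygenase"]: 1.0 - f,
            ids["rubisco_carboxylase"]: -f}))
    if scenario.respiration_fraction > 0:
        rows.append(CouplingConstraint({
            ids["respiration"]: _RESP_O2_PER_UNIT,
            ids["psii"]: -scenario.respiration_fraction * _PSII_O2_PER_UNIT}))
    if scenario.mehler_fraction > 0:
        rows.append(CouplingConstraint({
            ids["mehler"]: _MEHLER_O2_PER_UNIT,
            ids["psii"]: -scenario.mehler_fraction * _PSII_O2_PER_UNIT}))
    if scenario.ros_fraction > 0:
        rows.append(CouplingConstraint({
            ids["ros_psii"]: _ROS_ELECTRONS_PER_UNIT,
            ids["psii"]: -scenario.ros_fraction * _PSII_ELECTRONS_PER_UNIT}))
        rows.append(CouplingConstraint({
            ids["ros_psi"]: _ROS_ELECTRONS_PER_UNIT,
            ids["psi"]: -scenario.ros_fraction * _PSI_ELECTRONS_PER_UNIT}))
    return rows


def apply_scenario(model: MetabolicModel, scenario: Scenario,
                   ids=None) -> tuple[MetabolicModel, list[LinearConstraint]]:
    """Install a scenario's bounds on a copy of the model; return coupling rows.

    The original model is left unmodified.  Missing referenced reactions raise
    :class:`StructuralError` naming the reaction.
    """
    from .corenet import CORE_ACCOUNTING_IDS

    ids = dict(CORE_ACCOUNTING_IDS if ids is None else ids)
    out = model.copy()

    def require(role: str) -> str:
        rid = ids.get(role)
        if rid is None or not out.has_reaction(rid):
            raise StructuralError(
                f"scenario {scenario.name!r} references missing reaction "
                f"{rid or role!r}")
        return rid

    out.set_bounds(require("photon_exchange"), -scenario.photon_influx, 0.0)
    side = ("respiration", "mehler", "ros_psii", "ros_psi")
    if scenario.name == "yield_mode" or (
            scenario.maintenance_atp == 0 and scenario.respiration_fraction == 0
            and scenario.mehler_fraction == 0 and scenario.ros_fraction == 0):
        # side reactions not considered at maximal stoichiometric yield
        for role in side:
            if ids.get(role) and out.has_reaction(ids[role]):
                out.set_bounds(ids[role], 0.0, 0.0)
        if ids.get("maintenance") and out.has_reaction(ids["maintenance"]):
            out.set_bounds(ids["maintenance"], scenario.maintenance_atp,
                           scenario.maintenance_atp if scenario.maintenance_atp == 0
                           else 1000.0)
    else:
        for role in side:
            require(role)
        # the basal maintenance demand is a floor; the optimizer may hydrolyze
        # more ATP (ATP-wasting is part of the production phenotype)
        out.set_bounds(require("maintenance"), scenario.maintenance_atp, 1000.0)

    # nitrogen source selection
    ex_no3, ex_nh4 = "EX_no3", "EX_nh4"
    if out.has_reaction(ex_no3) and out.has_reaction(ex_nh4):
        if scenario.nitrogen_source == "nitrate":
            out.set_bounds(ex_no3, -1000.0, 1000.0)
            out.set_bounds(ex_nh4, 0.0, 1000.0)
        else:
            out.set_bounds(ex_no3, 0.0, 1000.0)
            out.set_bounds(ex_nh4, -1000.0, 1000.0)

    couplings = scenario_couplings(scenario, ids)
    for row in couplings:
        for rid in row.coeffs:
            if not out.has_reaction(rid):
                raise StructuralError(
                    f"coupling references missing reaction {rid!r}")
    return out, [row.as_linear_constraint() for row in couplings]
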