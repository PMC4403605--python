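"""Growth-to-production trade-off scans and transition experiments.

A transition experiment mimics the metabolic changes required when a cell
moves from a growth-only phenotype to a production-only phenotype: starting
from the maximal growth rate under constant light, the minimally required
growth rate is stepwise reduced from 100% to 0% of the maximum while product
synthesis is maximized, and at every step the variability (FVA interval) of
every reaction flux is recorded with the product flux pinned at the step
optimum.

Each reaction's trajectory is then classified by comparing the interval
midpoints at the two endpoints (for an interval, the median and the mean of
the flux range coincide at the midpoint):

* ``below_focus`` — midpoint magnitude at most 1e-6 at 100% growth *and* at
  most 1e-4 at 100% product synthesis (flux units, mmol gDW^-1 h^-1);
* ``sign_change`` — the product of the two endpoint interval minima, or of
  the two maxima, is negative;
* ``no_change`` — relative midpoint change below 5%;
* ``increase_from_zero`` / ``increase_from_flux`` — magnitude grows, from a
  zero or non-zero growth-phenotype flux;
* ``decrease_to_zero`` / ``decrease_to_flux`` — magnitude shrinks, to a zero
  or non-zero production-phenotype flux.

The classification is endpoint-determined, so the density of the growth-
fraction grid affects only the recorded trajectories, not the category
counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corenet import CORE_ACCOUNTING_IDS
from .exceptions import InfeasibleProblem, ScenarioError, StructuralError
from .lp import FIX_SLACK, FluxRange, LinearConstraint, run_fva, solve_fba
from .model import MetabolicModel
from .products import ProductDefinition, get_product
from .scenarios import Scenario, apply_scenario, transition_scenario

CATEGORIES = ("sign_change", "increase_from_flux", "increase_from_zero",
              "decrease_to_flux", "decrease_to_zero", "no_change")


@dataclass(frozen=True)
class ClassificationRules:
    """Thresholds of the trajectory classification."""

    focus_threshold_biomass: float = 1e-6   # midpoint floor at 100% growth
    focus_threshold_product: float = 1e-4   # midpoint floor at 100% product
    relative_change_cutoff: float = 0.05

    def __post_init__(self):
        if self.focus_threshold_biomass <= 0 or self.focus_threshold_product <= 0:
            raise ValueError("focus thresholds must be positive")
        if not 0 < self.relative_change_cutoff < 1:
            raise ValueError("relative change cutoff must lie in (0, 1)")


@dataclass
class TransitionTrajectory:
    """Per-reaction flux-range series over the growth-fraction grid."""

    reaction_id: str
    growth_fractions: tuple[float, ...]   # strictly decreasing, 1 -> 0
    ranges: tuple[FluxRange, ...]
    category: str | None = None

    def __post_init__(self):
        fracs = self.growth_fractions
        if len(fracs) != len(self.ranges):
            raise ValueError("one flux range per grid point required")
        if len(fracs) < 2 or any(b >= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("growth fractions must strictly decrease from 1 to 0")

    @property
    def growth_range(self) -> FluxRange:
        return self.ranges[0]

    @property
    def production_range(self) -> FluxRange:
        return self.ranges[-1]


def classify_trajectory(trajectory: TransitionTrajectory,
                        rules: ClassificationRules | None = None) -> str:
    """Assign exactly one category label to a trajectory (total function)."""
    rules = rules or ClassificationRules()
    growth, production = trajectory.growth_range, trajectory.production_range
    a, b = growth.midpoint, production.midpoint
    if (abs(a) <= rules.focus_threshold_biomass
            and abs(b) <= rules.focus_threshold_product):
        return "below_focus"
    if growth.min * production.min < 0 or growth.max * production.max < 0:
        return "sign_change"
    if abs(b - a) / max(abs(a), abs(b)) < rules.relative_change_cutoff:
        return "no_change"
    if abs(b) > abs(a):
        return ("increase_from_zero" if abs(a) <= rules.focus_threshold_biomass
                else "increase_from_flux")
    return ("decrease_to_zero" if abs(b) <= rules.focus_threshold_product
            else "decrease_to_flux")


@dataclass(frozen=True)
class CategoryCounts:
    """Tally of trajectory categories (focus reactions only)."""

    sign_change: int = 0
    increase_from_flux: int = 0
    increase_from_zero: int = 0
    decrease_to_flux: int = 0
    decrease_to_zero: int = 0
    no_change: int = 0

    @property
    def total(self) -> int:
        return sum(getattr(self, c) for c in CATEGORIES)

    def as_row(self) -> dict:
        return {"sign_change": self.sign_change,
                "increase_from_flux": self.increase_from_flux,
                "increase_from_zero": self.increase_from_zero,
                "decrease_to_flux": self.decrease_to_flux,
                "decrease_to_zero": self.decrease_to_zero,
                "no_change": self.no_change}


def category_counts(trajectories) -> CategoryCounts:
    """Tally classified trajectories, excluding below-focus reactions."""
    tally = Counter()
    for traj in trajectories:
        cat = traj.category or classify_trajectory(traj)
        if cat == "below_focus":
            continue
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r} for {traj.reaction_id}")
        tally[cat] += 1
    return CategoryCounts(**{c: tally.get(c, 0) for c in CATEGORIES})


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def _growth_setup(model: MetabolicModel, product: ProductDefinition | str,
                  scenario: Scenario | None, ids):
    if isinstance(product, str):
        product = get_product(product)
    scenario = scenario or transition_scenario()
    ids = dict(CORE_ACCOUNTING_IDS if ids is None else ids)
    biomass_id = ids.get("biomass", "BIOMASS")
    if not model.has_reaction(biomass_id):
        raise StructuralError(
            f"model lacks a growth objective reaction {biomass_id!r}")
    if not model.has_reaction(product.exchange_id):
        raise StructuralError(
            f"model not augmented with {product.product_id!r} "
            f"(no {product.exchange_id})")
    constrained, extra = apply_scenario(model, scenario, ids)
    if scenario.coupling_mode == "fixed":
        # freeze side fluxes at their initial (100% growth) wild-type values
        wt = solve_fba(constrained, biomass_id, "max", extra_constraints=extra)
        for role in ("respiration", "mehler", "ros_psii", "ros_psi"):
            rid = ids[role]
            constrained.set_bounds(rid, wt[rid], wt[rid])
        extra = [c for c in extra
                 if not set(c.coeffs) & {ids[r] for r in
                                         ("respiration", "mehler",
                                          "ros_psii", "ros_psi")}]
    mu_max = solve_fba(constrained, biomass_id, "max",
                       extra_constraints=extra).objective_value
    return product, scenario, ids, biomass_id, constrained, extra, mu_max


def tradeoff_scan(model: MetabolicModel, product: ProductDefinition | str,
                  scenario: Scenario | None = None, n_steps: int = 101,
                  ids=None) -> list[tuple[float, float]]:
    """Maximal product flux along the growth-fraction grid (the trade-off frontier).

    For each fraction f of the maximal growth rate, product export is
    maximized subject to growth >= f * mu_max.  Returns (fraction, flux)
    pairs with fractions decreasing from 1 to 0.
    """
    if n_steps < 2:
        raise ScenarioError("n_steps must be at least 2 (both endpoints)")
    product, scenario, ids, biomass_id, constrained, extra, mu_max = \
        _growth_setup(model, product, scenario, ids)
    frontier = []
    for f in np.linspace(1.0, 0.0, n_steps):
        step = constrained.copy()
        # growth enters as a lower bound (an inequality, not an equality)
        step.set_bounds(biomass_id, f * mu_max - FIX_SLACK,
                        step.reaction(biomass_id).upper_bound)
        sol = solve_fba(step, product.exchange_id, "max", extra_constraints=extra)
        frontier.append((float(f), sol.objective_value))
    return frontier


def transition_experiment(model: MetabolicModel,
                          product: ProductDefinition | str,
                          scenario: Scenario | None = None,
                          rules: ClassificationRules | None = None,
                          n_steps: int = 101,
                          targets=None,
                          ids=None) -> list[TransitionTrajectory]:
    """Run the full transition experiment and classify every reaction.

    At each grid point the product flux is maximized and the flux variability
    of every target reaction is determined with the product flux fixed at the
    step optimum and growth held at its lower bound.  Isoreactions should be
    collapsed beforehand.  An infeasible step aborts with its index.
    """
    if n_steps < 2:
        raise ScenarioError("n_steps must be at least 2 (both endpoints)")
    rules = rules or ClassificationRules()
    product, scenario, ids, biomass_id, constrained, extra, mu_max = \
        _growth_setup(model, product, scenario, ids)
    if targets is None:
        targets = [r.id for r in constrained.reactions]
    fractions = tuple(float(f) for f in np.linspace(1.0, 0.0, n_steps))
    series: dict[str, list[FluxRange]] = {rid: [] for rid in targets}
    for step_index, f in enumerate(fractions):
        step = constrained.copy()
        step.set_bounds(biomass_id, f * mu_max - FIX_SLACK,
                        step.reaction(biomass_id).upper_bound)
        try:
            sol = solve_fba(step, product.exchange_id, "max",
                            extra_constraints=extra)
            ranges = run_fva(step, fixed=[(product.exchange_id,
                                           sol.objective_value)],
                             targets=targets, extra_constraints=extra)
        except InfeasibleProblem as exc:
            raise InfeasibleProblem(
                f"transition step {step_index} (growth fraction {f:.3f}) "
                f"infeasible: {exc}") from None
        for rid in targets:
            series[rid].append(ranges[rid])
    trajectories = []
    for rid in targets:
        traj = TransitionTrajectory(rid, fractions, tuple(series[rid]))
        traj.category = classify_trajectory(traj, rules)
        trajectories.append(traj)
    return trajectories


def trajectories_frame(trajectories) -> pd.DataFrame:
    """Long-format table: reaction, growth fraction, flux min/max/midpoint."""
    records = []
    for traj in trajectories:
        for f, rng in zip(traj.growth_fractions, traj.ranges):
            records.append({"reaction_id": traj.reaction_id,
                            "growth_fraction": f,
                            "flux_min": rng.min, "flux_max": rng.max,
                            "midpoint": rng.midpoint,
                            "category": traj.category})
    return pd.DataFrame(records)
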