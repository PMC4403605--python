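"""Shared fixtures: core networks, augmented product models, tiny toy models."""

from __future__ import annotations

import pytest

from cyanoflux import (CoreNetworkSpec, MetabolicModel, Metabolite, Reaction,
                       build_product_model, generate_core_network,
                       stoichiometric_summary)
from cyanoflux.corenet import EXTENSIONS


@pytest.fixture(scope="session")
def core_base():
    """Base core network (no extensions, no biomass)."""
    return generate_core_network()


@pytest.fixture(scope="session")
def core_full():
    """Core network with every extension pack and the toy biomass objective."""
    return generate_core_network(CoreNetworkSpec(
        extensions=EXTENSIONS, include_toy_biomass=True))


@pytest.fixture(scope="session")
def ethanol_model():
    """Core + ethanol pathway (no biomass), yield-mode analyses."""
    return build_product_model("ethanol")


@pytest.fixture(scope="session")
def ethanol_growth_model():
    """Core + ethanol pathway + toy biomass, for transition analyses."""
    return build_product_model("ethanol", with_biomass=True)


@pytest.fixture(scope="session")
def all_summaries():
    """Yield-mode stoichiometric summaries for all twelve products."""
    from cyanoflux import PRODUCT_IDS

    out = {}
    for pid in PRODUCT_IDS:
        model = build_product_model(pid)
        out[pid] = stoichiometric_summary(model, pid)
    return out


def chain_model(n_steps: int = 3, uptake: float = 5.0) -> MetabolicModel:
    """A linear chain EX_s -> m1 -> ... -> mN -> EX_p with bounded uptake."""
    m = MetabolicModel("chain")
    mets = [Metabolite(f"m{i}_c", formula={}) for i in range(n_steps + 1)]
    for met in mets:
        m.add_metabolite(met)
    m.add_reaction(Reaction("EX_s", stoichiometry={"m0_c": -1},
                            lower_bound=-uptake, upper_bound=0.0,
                            is_exchange=True, pseudo=True))
    for i in range(n_steps):
        m.add_reaction(Reaction(f"R{i + 1}", stoichiometry={
            f"m{i}_c": -1, f"m{i + 1}_c": 1}))
    m.add_reaction(Reaction("EX_p", stoichiometry={f"m{n_steps}_c": -1},
                            lower_bound=0.0, upper_bound=1000.0,
                            is_exchange=True, pseudo=True))
    return m


@pytest.fixture
def toy_chain():
    return chain_model()
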