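"""Shared fixtures: small hand-checkable webs and random web builders."""

from __future__ import annotations

import numpy as np
import pytest

from fwb import (
    CONSUMER,
    DETRITUS,
    PRODUCER,
    DietMatrix,
    FunctionalGroup,
    ModelDefinition,
)


def make_w3(carn_qb: float = 5.0) -> ModelDefinition:
    """Detritus + phytoplankton + herbivore + carnivore chain.

    With the default carnivore Q/B the hand-solved ecotrophic efficiencies
    are 0.10 (phyto), 0.25 (herbivore), 0 (carnivore).
    """
    groups = [
        FunctionalGroup("detritus", DETRITUS, B=100.0),
        FunctionalGroup("phyto", PRODUCER, B=20.0, PB=50.0),
        FunctionalGroup("herb", CONSUMER, B=10.0, PB=2.0, QB=10.0, UC=0.2),
        FunctionalGroup("carn", CONSUMER, B=1.0, PB=1.0, QB=carn_qb, UC=0.2),
    ]
    diet = DietMatrix.empty([g.name for g in groups], ["herb", "carn"])
    diet.DC.loc["phyto", "herb"] = 1.0
    diet.DC.loc["herb", "carn"] = 1.0
    return ModelDefinition(groups, diet, {"site": "W3"})


@pytest.fixture
def w3() -> ModelDefinition:
    return make_w3()


def make_truncated_web() -> ModelDefinition:
    """Web whose top consumer sits at fractional TL 3.2 with no predators.

    producer/detritus (TL 1) -> grazer (TL 2) -> specialist (TL 3), plus a
    mixed-diet consumer (80% grazer, 20% specialist => TL 3.2) that nobody
    eats or catches: discrete level IV receives inflow but passes nothing up.
    """
    groups = [
        FunctionalGroup("detritus", DETRITUS, B=10.0),
        FunctionalGroup("producer", PRODUCER, B=50.0, PB=30.0),
        FunctionalGroup("grazer", CONSUMER, B=8.0, PB=4.0, QB=20.0, UC=0.3),
        FunctionalGroup("specialist", CONSUMER, B=1.2, PB=2.0, QB=10.0, UC=0.2),
        FunctionalGroup("mixed_top", CONSUMER, B=0.3, PB=1.5, QB=7.0, UC=0.2),
    ]
    diet = DietMatrix.empty(
        [g.name for g in groups], ["grazer", "specialist", "mixed_top"]
    )
    diet.DC.loc["producer", "grazer"] = 0.6
    diet.DC.loc["detritus", "grazer"] = 0.4
    diet.DC.loc["grazer", "specialist"] = 1.0
    diet.DC.loc["grazer", "mixed_top"] = 0.8
    diet.DC.loc["specialist", "mixed_top"] = 0.2
    return ModelDefinition(groups, diet)


@pytest.fixture
def truncated_web() -> ModelDefinition:
    return make_truncated_web()


def make_mc_web() -> ModelDefinition:
    """Chain tuned for the Monte Carlo closed-form oracle.

    The herbivore's EE is exactly 0.95 (predation 19 over production 20) and
    the carnivore's gross efficiency exactly 0.2, so perturbing only the
    carnivore's Q/B moves herbivore EE linearly and the acceptance region is
    a normal-tail expression in closed form.
    """
    groups = [
        FunctionalGroup("detritus", DETRITUS, B=10.0),
        FunctionalGroup("producer", PRODUCER, B=20.0, PB=50.0),
        FunctionalGroup("herb", CONSUMER, B=10.0, PB=2.0, QB=10.0, UC=0.2),
        FunctionalGroup("carn", CONSUMER, B=1.9, PB=2.0, QB=10.0, UC=0.2),
    ]
    diet = DietMatrix.empty([g.name for g in groups], ["herb", "carn"])
    diet.DC.loc["producer", "herb"] = 1.0
    diet.DC.loc["herb", "carn"] = 1.0
    return ModelDefinition(groups, diet)


@pytest.fixture
def mc_web() -> ModelDefinition:
    return make_mc_web()


def random_web(
    rng: np.random.Generator, n_groups: int = 8, import_fraction: float = 0.5
) -> ModelDefinition:
    """Random acyclic web (<= n_groups) with mixed diets for oracle tests.

    Consumers draw up to 4 prey from strictly earlier groups, so trophic
    cycles only run through detritus; a substantial diet-import fraction
    keeps the direct-impact couplings moderate (Neumann-convergent webs).
    """
    n = int(rng.integers(5, n_groups + 1))
    groups = [
        FunctionalGroup("det", DETRITUS, B=10.0),
        FunctionalGroup("prod_a", PRODUCER, B=float(rng.uniform(5, 30)),
                        PB=float(rng.uniform(20, 80))),
        FunctionalGroup("prod_b", PRODUCER, B=float(rng.uniform(5, 30)),
                        PB=float(rng.uniform(20, 80))),
    ]
    for k in range(n - 3):
        pb = float(rng.uniform(1, 6))
        groups.append(
            FunctionalGroup(
                f"cons_{k}", CONSUMER, B=float(rng.uniform(0.2, 3.0)), PB=pb,
                QB=pb / float(rng.uniform(0.12, 0.28)), UC=float(rng.uniform(0.2, 0.4)),
            )
        )
    names = [g.name for g in groups]
    consumers = [g.name for g in groups if g.group_type == CONSUMER]
    diet = DietMatrix.empty(names, consumers)
    for j, cname in enumerate(consumers):
        pool = names[: 3 + j]  # strictly earlier groups (incl. detritus)
        k = min(len(pool), int(rng.integers(3, 5)))
        prey = rng.choice(pool, size=k, replace=False)
        w = rng.dirichlet(np.ones(k)) * (1.0 - import_fraction)
        for p, frac in zip(prey, w):
            diet.DC.loc[p, cname] = float(frac)
        diet.import_fraction[cname] = import_fraction
    return ModelDefinition(groups, diet)
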