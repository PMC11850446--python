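"""Synthetic river food webs with known ground truth, plus degradation scenarios.

The generator emulates the structure of subtropical-river trophic models: a
detritus pool, three producer compartments (phytoplankton, periphyton,
macrophytes), invertebrate and fish feeding guilds stacked over 2-5 trophic
levels with a biomass pyramid, gross efficiencies inside the plausible
(0.1, 0.3) interval, and Dirichlet-drawn diet columns restricted to lower
guild levels.  Consumption demand on every living prey is capped at 90% of
its production during generation, so the constructed web balances with all
ecotrophic efficiencies known in advance and strictly below 1 — the ground
truth every solver test recovers.

Degradation scenarios mirror the three disturbance modes of lowland rivers:
"industrial" (pollution removes the upper food web and favours tolerant
detritivores), "overfishing" (catch proportional to production on the
highest trophic levels), and "invasion" (a high-biomass exotic detritivore
whose production nobody utilizes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model_io import (
    CONSUMER,
    DETRITUS,
    PRODUCER,
    DietMatrix,
    FunctionalGroup,
    ModelDefinition,
)
from .trophic_analysis import fractional_trophic_levels

__all__ = ["GuildSpec", "WebRecipe", "generate_web", "degrade_web", "SCENARIOS"]

SCENARIOS = ("industrial", "overfishing", "invasion")

#: fraction of a prey's production that consumer demand may claim
DEMAND_CAP = 0.9


@dataclass(frozen=True)
class GuildSpec:
    """One functional guild: trophic position, permitted prey, P/B range (/yr).

    ``b_range`` (g/m^2) is used for producers, whose standing stock is set
    directly; consumer biomass follows the recipe's pyramid instead.
    """

    name: str
    group_type: str
    level: int
    prey: tuple[str, ...]
    pb_range: tuple[float, float]
    b_range: tuple[float, float] | None = None


# Default roster: 16 groups spanning detritus, producers, invertebrate guilds,
# fish feeding guilds and an apex soft-shelled reptile.
DEFAULT_ROSTER: tuple[GuildSpec, ...] = (
    GuildSpec("detritus", DETRITUS, 1, (), (0.0, 0.0)),
    GuildSpec("phytoplankton", PRODUCER, 1, (), (150.0, 250.0), b_range=(1.5, 4.0)),
    GuildSpec("periphyton", PRODUCER, 1, (), (40.0, 80.0), b_range=(3.0, 8.0)),
    GuildSpec("macrophytes", PRODUCER, 1, (), (4.0, 10.0), b_range=(12.0, 25.0)),
    GuildSpec("rotifers", CONSUMER, 2, ("phytoplankton", "detritus"), (25.0, 40.0)),
    GuildSpec("copepods", CONSUMER, 2, ("phytoplankton", "detritus"), (15.0, 30.0)),
    GuildSpec("gastropods", CONSUMER, 2,
              ("periphyton", "macrophytes", "detritus"), (3.0, 8.0)),
    GuildSpec("bivalves", CONSUMER, 2, ("phytoplankton", "detritus"), (2.0, 6.0)),
    GuildSpec("shrimp", CONSUMER, 2, ("detritus", "periphyton"), (4.0, 9.0)),
    GuildSpec("annelids", CONSUMER, 2, ("detritus",), (3.0, 7.0)),
    GuildSpec("detritivorous_fish", CONSUMER, 2, ("detritus",), (1.5, 3.0)),
    GuildSpec("phytoplanktivorous_fish", CONSUMER, 2, ("phytoplankton",), (1.2, 2.5)),
    GuildSpec("omnivorous_fish", CONSUMER, 3,
              ("gastropods", "bivalves", "phytoplankton", "detritus"), (1.0, 2.0)),
    GuildSpec("molluscivorous_fish", CONSUMER, 3,
              ("gastropods", "bivalves", "annelids"), (0.8, 1.8)),
    GuildSpec("benthic_carnivorous_fish", CONSUMER, 3,
              ("shrimp", "annelids", "detritivorous_fish", "phytoplanktivorous_fish"),
              (0.7, 1.5)),
    GuildSpec("softshell_turtle", CONSUMER, 4,
              ("benthic_carnivorous_fish", "molluscivorous_fish",
               "omnivorous_fish", "shrimp"), (0.3, 0.8)),
)


@dataclass
class WebRecipe:
    """Parameters of the generator; the defaults are the study conditions."""

    n_levels: int = 4
    roster: tuple[GuildSpec, ...] = DEFAULT_ROSTER
    consumer_biomass: float = 25.0        # total level-II consumer B, g/m^2
    biomass_decay: float = 0.25           # multiplicative B decline per level
    ge_range: tuple[float, float] = (0.1, 0.3)
    uc_low_level: float = 0.4             # detritivores / herbivores (level 2)
    uc_high_level: float = 0.2            # carnivores / omnivores (level >= 3)
    diet_concentration: float = 1.0       # Dirichlet concentration
    seed: int = 0

    def validate(self) -> None:
        if not (2 <= self.n_levels <= 5):
            raise ValueError("n_levels must be in 2..5")
        if not (0 < self.biomass_decay < 1):
            raise ValueError("biomass_decay must be in (0, 1)")
        lo, hi = self.ge_range
        if not (0 < lo < hi < 1):
            raise ValueError("ge_range must be inside (0, 1)")


def generate_web(recipe: WebRecipe) -> tuple[ModelDefinition, pd.Series]:
    """Build a balanced web; returns (model with EE unset, ground-truth EEs).

    The truth Series covers living groups; solving the returned model must
    recover exactly these ecotrophic efficiencies.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    roster = [g for g in recipe.roster if g.level <= recipe.n_levels]
    names = [g.name for g in roster]
    by_name = {g.name: g for g in roster}
    det_names = [g.name for g in roster if g.group_type == DETRITUS]
    if not det_names:
        raise ValueError("roster must include a detritus pool")

    groups: list[FunctionalGroup] = []
    # biomasses: producers are low-standing-stock/high-turnover pools drawn
    # from their guild ranges; consumer biomass is dominated by level II and
    # declines by the decay pyramid, split with a Dirichlet jitter per level
    producers = [g for g in roster if g.group_type == PRODUCER]
    consumers = [g for g in roster if g.group_type == CONSUMER]
    B: dict[str, float] = {}
    for g in producers:
        lo, hi = g.b_range or (1.0, 5.0)
        B[g.name] = float(rng.uniform(lo, hi))
    for level in range(2, recipe.n_levels + 1):
        at = [g for g in consumers if g.level == level]
        if not at:
            continue
        total = recipe.consumer_biomass * recipe.biomass_decay ** (level - 2)
        shares = rng.dirichlet(np.full(len(at), 4.0))
        for g, share in zip(at, shares):
            B[g.name] = total * float(share)

    PB: dict[str, float] = {}
    QB: dict[str, float] = {}
    for g in roster:
        if g.group_type == DETRITUS:
            continue
        PB[g.name] = float(rng.uniform(*g.pb_range))
        if g.group_type == CONSUMER:
            ge = float(rng.uniform(*recipe.ge_range))
            QB[g.name] = PB[g.name] / ge

    # diet columns: Dirichlet over the permitted (strictly lower level) prey
    diet = DietMatrix.empty(names, [g.name for g in consumers])
    for g in consumers:
        prey = [p for p in g.prey if p in by_name and by_name[p].level < g.level]
        if not prey:
            raise ValueError(
                f"guild {g.name!r} has no permitted prey in this recipe; "
                "lower its level or extend the roster"
            )
        w = rng.dirichlet(np.full(len(prey), recipe.diet_concentration))
        for p, frac in zip(prey, w):
            diet.DC.loc[p, g.name] = float(frac)

    # demand capping: no living prey may be asked for more than 90% of its
    # production; excess diet fractions are rerouted to detritus
    Q = {g.name: B[g.name] * QB[g.name] for g in consumers}
    P = {n: B[n] * PB[n] for n in B}
    for prey_g in roster:
        if prey_g.group_type == DETRITUS:
            continue
        prey = prey_g.name
        demand = sum(Q[c.name] * diet.DC.loc[prey, c.name] for c in consumers)
        cap = DEMAND_CAP * P[prey]
        if demand > cap:
            if cap <= 0:
                scale = 0.0
            else:
                scale = cap / demand
            for c in consumers:
                old = float(diet.DC.loc[prey, c.name])
                if old > 0:
                    new = old * scale
                    diet.DC.loc[prey, c.name] = new
                    diet.DC.loc[det_names[0], c.name] += old - new

    # ground truth
    truth = {}
    for g in roster:
        if g.group_type == DETRITUS:
            continue
        demand = sum(Q[c.name] * float(diet.DC.loc[g.name, c.name]) for c in consumers)
        truth[g.name] = demand / P[g.name] if P[g.name] > 0 else 0.0

    # detritus budget: top up external import so the pool is not over-drawn
    uc = {
        g.name: (recipe.uc_low_level if g.level <= 2 else recipe.uc_high_level)
        for g in consumers
    }
    det_in = sum(uc[c.name] * Q[c.name] for c in consumers)
    det_in += sum((1.0 - truth[n]) * P[n] for n in truth)
    det_out = sum(
        Q[c.name] * float(diet.DC.loc[d, c.name])
        for c in consumers for d in det_names
    )
    det_import = 0.0
    if det_in <= 0 or det_out / max(det_in, 1e-300) > DEMAND_CAP:
        det_import = det_out / 0.85 - det_in

    for g in roster:
        if g.group_type == DETRITUS:
            groups.append(
                FunctionalGroup(g.name, DETRITUS, B=10.0,
                                detritus_import=det_import if g.name == det_names[0] else 0.0)
            )
        elif g.group_type == PRODUCER:
            groups.append(FunctionalGroup(g.name, PRODUCER, B=B[g.name], PB=PB[g.name]))
        else:
            groups.append(
                FunctionalGroup(
                    g.name, CONSUMER, B=B[g.name], PB=PB[g.name],
                    QB=QB[g.name], UC=uc[g.name],
                )
            )
    model = ModelDefinition(
        groups, diet,
        {"recipe_seed": recipe.seed, "n_levels": recipe.n_levels},
    )
    return model, pd.Series(truth, name="EE")


# ---------------------------------------------------------------------------
# degradation scenarios
# ---------------------------------------------------------------------------

def _renormalize_columns(model: ModelDefinition, det_name: str | None) -> None:
    dc = model.diet.DC
    for g in model.consumers:
        imp = float(model.diet.import_fraction.get(g.name, 0.0))
        internal = float(dc[g.name].sum())
        if internal <= 0 and imp <= 0:
            if det_name is not None:
                dc.loc[det_name, g.name] = 1.0
        elif internal > 0 and abs(internal + imp - 1.0) > 1e-12:
            dc[g.name] *= (1.0 - imp) / internal


def degrade_web(
    model: ModelDefinition, scenario: str, intensity: float
) -> ModelDefinition:
    """Apply a disturbance scenario at the given intensity in [0, 1].

    industrial: removes consumers with fractional TL > 2 + intensity and
    scales detritivore biomass up by (1 + 4*intensity); overfishing: adds
    catch Y = intensity * P to the top TL quartile; invasion: inserts a
    high-biomass exotic detritivore with no predators.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if not (0.0 <= intensity <= 1.0):
        raise ValueError("intensity must be in [0, 1]")
    if intensity == 0.0:
        return model.copy()

    out = model.copy()
    det_names = [g.name for g in out.detritus_groups]
    det0 = det_names[0] if det_names else None
    tl = fractional_trophic_levels(out)

    if scenario == "industrial":
        doomed = [
            g.name for g in out.consumers if tl[g.name] > 2.0 + intensity
        ]
        survivors = [g for g in out.groups if g.name not in doomed]
        if not any(g.is_consumer for g in survivors):
            raise ValueError("industrial scenario would remove every consumer")
        out.groups = survivors
        keep = [g.name for g in survivors]
        out.diet.DC = out.diet.DC.loc[keep, [c for c in out.diet.DC.columns if c in keep]]
        out.diet.import_fraction = out.diet.import_fraction[
            [c for c in out.diet.import_fraction.index if c in keep]
        ]
        _renormalize_columns(out, det0)
        for g in out.consumers:
            # tolerant detritivores thrive in the polluted reach
            if det0 and float(out.diet.DC.loc[det0, g.name]) >= 0.5:
                g.B = (g.B or 0.0) * (1.0 + 4.0 * intensity)
    elif scenario == "overfishing":
        cons = [g for g in out.consumers]
        if not cons:
            raise ValueError("no consumers to fish")
        cut = np.quantile([tl[g.name] for g in cons], 0.75)
        for g in cons:
            if tl[g.name] >= cut:
                if g.B is None or g.PB is None:
                    raise ValueError(f"group {g.name} lacks B/PB for catch scaling")
                g.Y = intensity * g.B * g.PB
    else:  # invasion
        if det0 is None:
            raise ValueError("invasion scenario needs a detritus pool")
        total_consumer_b = sum(g.B or 0.0 for g in out.consumers)
        inv = FunctionalGroup(
            "invasive_detritivore", CONSUMER,
            B=intensity * total_consumer_b,
            PB=5.0, QB=25.0, UC=0.4,
        )
        out.groups.append(inv)
        out.diet.DC.loc[inv.name] = 0.0
        out.diet.DC[inv.name] = 0.0
        out.diet.DC.loc[det0, inv.name] = 1.0
        out.diet.import_fraction[inv.name] = 0.0
    out.metadata = dict(out.metadata, scenario=scenario, intensity=intensity)
    return out
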