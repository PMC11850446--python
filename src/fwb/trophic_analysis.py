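"""Fractional trophic levels, omnivory, and the Lindeman spine.

Fractional trophic level is 1 for producers and detritus and, for a consumer,
one plus the diet-weighted mean trophic level of its prey — a linear system
that handles diet cycles and cannibalism.  The Lindeman spine re-expresses
the flow network on discrete trophic levels I, II, III, ... by apportioning
each consumer's intake over integer path lengths back to the level-I sources
(primary producers or detritus); per-level transfer efficiency is the share
of a level's inflow passed upward as predation plus export and catch.

Producer-origin and detritus-origin chains are propagated separately through
the same recursion and also reported combined, as in classical trophic
aggregation diagrams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mass_balance import BalancedModel
from .model_io import ModelDefinition

__all__ = [
    "TrophicProfile",
    "LindemanSpine",
    "fractional_trophic_levels",
    "omnivory",
    "lindeman_spine",
    "transfer_efficiencies",
]

ORIGINS = ("producer", "detritus")
DEFAULT_LEVEL_CAP = 8
ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI", 7: "VII", 8: "VIII"}


@dataclass
class TrophicProfile:
    """Per-group fractional trophic level and omnivory index."""

    TL: pd.Series
    OI: pd.Series | None = None
    SOI: float | None = None


def fractional_trophic_levels(model: ModelDefinition) -> pd.Series:
    """Solve TL_j = 1 + sum_i DC_ij TL_i (producers and detritus at TL 1).

    Diet imports contribute prey material at TL 1.
    """
    names = model.names
    n = len(names)
    A = np.eye(n)
    b = np.ones(n)
    dc = model.diet.DC
    for j, g in enumerate(model.groups):
        if not g.is_consumer or g.name not in dc.columns:
            continue
        col = dc[g.name].reindex(names).fillna(0.0).to_numpy()
        A[j, :] -= col
        imp = float(model.diet.import_fraction.get(g.name, 0.0))
        b[j] = 1.0 + imp  # imported diet counts as TL-1 prey
    try:
        tl = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        # identify rows with no external trophic anchor (e.g. a pure cannibal)
        bad = [
            names[j]
            for j in range(n)
            if model.groups[j].is_consumer and abs(A[j, j]) < 1e-12
        ]
        raise ValueError(
            f"trophic-level system is singular (self-referential diet): {bad or names}"
        ) from None
    return pd.Series(tl, index=pd.Index(names, name="group"), name="TL")


def omnivory(
    profile: TrophicProfile | pd.Series,
    model: ModelDefinition,
    Q: pd.Series | None = None,
) -> tuple[pd.Series, float]:
    """Per-consumer omnivory index and the system omnivory index (SOI).

    OI_j is the diet-weighted variance of prey trophic levels around
    TL_j - 1; SOI is the mean OI weighted by the logarithm of each
    consumer's consumption (consumers with Q <= 1 are excluded from the
    weighting, following the convention that log-weights must be positive).
    """
    tl = profile.TL if isinstance(profile, TrophicProfile) else profile
    names = model.names
    oi = {}
    for g in model.consumers:
        col = model.diet.DC[g.name].reindex(names).fillna(0.0)
        imp = float(model.diet.import_fraction.get(g.name, 0.0))
        center = tl[g.name] - 1.0
        var = float(((tl.reindex(names) - center) ** 2 * col).sum())
        var += imp * (1.0 - center) ** 2
        oi[g.name] = var
    oi = pd.Series(oi, name="OI", dtype=float)

    if Q is None:
        qvals = {}
        for g in model.consumers:
            if g.B is None or g.QB is None:
                raise ValueError("SOI weighting needs consumption: solve first "
                                 "or pass Q explicitly")
            qvals[g.name] = g.B * g.QB
        Q = pd.Series(qvals, dtype=float)
    num = den = 0.0
    for name, o in oi.items():
        q = float(Q.get(name, 0.0))
        if q > 1.0:
            w = math.log(q)
            num += o * w
            den += w
    soi = num / den if den > 0 else 0.0
    return oi, soi


# ---------------------------------------------------------------------------
# Lindeman spine
# ---------------------------------------------------------------------------

@dataclass
class LindemanSpine:
    """Flows aggregated on discrete trophic levels, split by origin.

    Each table is indexed by discrete level 1..cap with columns
    ('producer', 'detritus', 'combined'); TE is in percent (nan where the
    level receives no inflow).  ``remainder`` is consumption mass not
    apportioned within the level cap (nonzero only for deep diet cycles).
    """

    inflow: pd.DataFrame
    flow_up: pd.DataFrame          # flow from level k to k+1
    export_catch: pd.DataFrame     # catch + net migration + accumulation
    respiration: pd.DataFrame
    to_detritus: pd.DataFrame
    TE: pd.DataFrame
    remainder: float
    level_fractions: pd.DataFrame  # group x level, combined origins

    @property
    def levels(self) -> list[int]:
        return list(self.inflow.index)


def _level_fractions(
    balanced: BalancedModel, cap: int
) -> dict[str, np.ndarray]:
    """a[origin][g, k]: fraction of group g's intake at discrete level k+1."""
    m = balanced.model
    names = m.names
    n = len(names)
    dc = np.zeros((n, n))
    imp = np.zeros(n)
    for j, g in enumerate(m.groups):
        if g.is_consumer and g.name in m.diet.DC.columns:
            dc[:, j] = m.diet.DC[g.name].reindex(names).fillna(0.0).to_numpy()
            imp[j] = float(m.diet.import_fraction.get(g.name, 0.0))
    a = {o: np.zeros((n, cap)) for o in ORIGINS}
    for i, g in enumerate(m.groups):
        if g.group_type == "producer":
            a["producer"][i, 0] = 1.0
        elif g.group_type == "detritus":
            a["detritus"][i, 0] = 1.0
    for k in range(1, cap):
        for o in ORIGINS:
            prev = a[o][:, k - 1]
            nxt = dc.T @ prev
            if k == 1 and o == "producer":
                nxt = nxt + imp  # diet imports enter as TL-1 producer-origin
            for i, g in enumerate(m.groups):
                if g.is_consumer:
                    a[o][i, k] = nxt[i]
    return a


def lindeman_spine(
    balanced: BalancedModel,
    profile: TrophicProfile | None = None,
    cap: int = DEFAULT_LEVEL_CAP,
) -> LindemanSpine:
    """Aggregate the solved flow network onto discrete trophic levels."""
    m = balanced.model
    names = m.names
    n = len(names)
    frac = _level_fractions(balanced, cap)

    Q = balanced.Q.to_numpy()
    P = balanced.P.to_numpy()
    R = balanced.R.to_numpy()
    pred = balanced.predation.to_numpy()
    todet = balanced.flow_to_detritus.to_numpy()
    exports = (balanced.flows.exports
               + pd.Series([g.BA for g in m.groups], index=balanced.flows.exports.index)
               ).to_numpy()
    diet_import_total = float(
        sum(
            float(m.diet.import_fraction.get(g.name, 0.0)) * balanced.Q[g.name]
            for g in m.consumers
        )
    )
    det_inflow = {g.name: 0.0 for g in m.detritus_groups}
    nd = len(det_inflow)
    if nd:
        total_td = float(balanced.flow_to_detritus.sum())
        for g in m.detritus_groups:
            det_inflow[g.name] = total_td / nd + (g.detritus_import or 0.0)

    cols = list(ORIGINS)
    idx = pd.Index(range(1, cap + 1), name="level")
    zero = lambda: pd.DataFrame(0.0, index=idx, columns=cols)
    inflow, flow_up, exp_c, resp, to_det = (zero() for _ in range(5))

    is_prod = np.array([g.group_type == "producer" for g in m.groups])
    is_det = np.array([g.group_type == "detritus" for g in m.groups])
    is_cons = np.array([g.is_consumer for g in m.groups])

    # --- level I: producers, detritus pools and diet-import sources -------
    prod_P = float(P[is_prod].sum())
    inflow.loc[1, "producer"] = prod_P + diet_import_total
    inflow.loc[1, "detritus"] = float(sum(det_inflow.values()))
    flow_up.loc[1, "producer"] = float(pred[is_prod].sum()) + diet_import_total
    flow_up.loc[1, "detritus"] = float(pred[is_det].sum())
    exp_c.loc[1, "producer"] = float(exports[is_prod].sum())
    # detritus surplus (inflow - consumption - export) accumulates/sediments;
    # book it with export so each level's inflow decomposes exactly
    det_surplus = float(sum(det_inflow.values())) - float(pred[is_det].sum()) \
        - float(exports[is_det].sum())
    exp_c.loc[1, "detritus"] = float(exports[is_det].sum()) + max(det_surplus, 0.0)
    resp.loc[1, "producer"] = float(R[is_prod].sum())
    to_det.loc[1, "producer"] = float(todet[is_prod].sum())

    # --- levels II..cap: consumers apportioned by diet path length --------
    for o in ORIGINS:
        A = frac[o]
        for k in range(2, cap + 1):
            ak = A[:, k - 1] * is_cons
            inflow.loc[k, o] += float((Q * ak).sum())
            flow_up.loc[k, o] += float((pred * ak).sum())
            exp_c.loc[k, o] += float((exports * ak).sum())
            resp.loc[k, o] += float((R * ak).sum())
            to_det.loc[k, o] += float((todet * ak).sum())

    for df in (inflow, flow_up, exp_c, resp, to_det):
        df["combined"] = df[list(ORIGINS)].sum(axis=1)

    TE = pd.DataFrame(np.nan, index=idx, columns=inflow.columns)
    for c in TE.columns:
        with np.errstate(invalid="ignore", divide="ignore"):
            te = 100.0 * (flow_up[c] + exp_c[c]) / inflow[c]
        TE[c] = te.where(inflow[c] > 0)
    # accumulation booked at level I is not an upward transfer; report raw TE
    # there from predation + true exports only
    for c in TE.columns:
        if inflow.loc[1, c] > 0:
            true_exp = exp_c.loc[1, c] - (max(det_surplus, 0.0) if c != "producer" else 0.0)
            TE.loc[1, c] = 100.0 * (flow_up.loc[1, c] + max(true_exp, 0.0)) / inflow.loc[1, c]

    comb = frac["producer"] + frac["detritus"]
    apportioned = (Q[:, None] * comb * is_cons[:, None]).sum()
    remainder = float((Q * is_cons).sum() - apportioned)
    level_fractions = pd.DataFrame(
        comb, index=pd.Index(names, name="group"), columns=idx
    )
    return LindemanSpine(
        inflow=inflow,
        flow_up=flow_up,
        export_catch=exp_c,
        respiration=resp,
        to_detritus=to_det,
        TE=TE,
        remainder=remainder,
        level_fractions=level_fractions,
    )


def transfer_efficiencies(
    spine: LindemanSpine,
    levels: tuple[int, ...] = (2, 3, 4),
    method: str = "geometric",
) -> pd.DataFrame:
    """Per-level TE (%) plus the mean over ``levels`` for each origin chain.

    Levels with undefined TE (no inflow) are excluded from the mean; for the
    geometric mean zero-TE levels (a top level nobody preys on or harvests)
    are excluded too, since a single structural zero would erase the signal
    of the levels that do transfer.  If every level is excluded the mean is
    nan.  ``method`` is 'geometric' (the EwE convention) or 'arithmetic'.
    """
    te = spine.TE.copy()
    means = {}
    for c in te.columns:
        vals = te.loc[[l for l in levels if l in te.index], c].dropna()
        if method == "geometric":
            vals = vals[vals > 0]
        if vals.empty:
            means[c] = math.nan
        elif method == "geometric":
            means[c] = float(math.exp(np.log(vals).mean()))
        elif method == "arithmetic":
            means[c] = float(vals.mean())
        else:
            raise ValueError(f"unknown mean method {method!r}")
    out = te.copy()
    out.loc["mean"] = pd.Series(means)
    return out
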