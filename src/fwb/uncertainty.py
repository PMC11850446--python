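"""Input pedigree scoring and Monte Carlo uncertainty propagation.

The pedigree index is the unweighted mean of the per-parameter confidence
scores attached to living groups, a standard summary of input data quality.

The Monte Carlo resampler perturbs every scored basic parameter with a
normal relative error, re-solves the mass balance, accepts runs that balance
(all EE <= 1) and respect the physiological screening constraints, and keeps
the accepted runs closest to the base inputs (smallest sum of squared
standardized deviations).  Parameter means and standard deviations, and the
distributions of the derived indices, are summarized over the kept set.
Every random draw flows from a single integer seed, with per-run substreams
derived from the run index, so results are reproducible bit for bit and
independent of evaluation order.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import system_indices
from .mass_balance import (
    GE_BOUNDS,
    SolverError,
    _as_arrays,
    _solve_arrays,
    solve_balance,
)
from .model_io import ModelDefinition
from .trophic_analysis import fractional_trophic_levels

__all__ = [
    "pedigree_table",
    "pedigree_index",
    "EnsembleResult",
    "monte_carlo",
]

#: default per-parameter-class pedigree confidence when a score is missing
PEDIGREE_DEFAULTS = {"B": 0.7, "PB": 0.6, "QB": 0.6, "DC": 0.6, "Y": 0.7}

#: constraints checked for run acceptance
DEFAULT_CONSTRAINTS = ("ee", "ge", "ra", "pr")


def pedigree_table(model: ModelDefinition, fill_defaults: bool = False) -> pd.DataFrame:
    """Group x parameter table of confidence scores for living groups."""
    rows = {}
    for g in model.living:
        row = {}
        for p in PEDIGREE_DEFAULTS:
            if p in g.pedigree_scores:
                row[p] = g.pedigree_scores[p]
            elif fill_defaults:
                row[p] = PEDIGREE_DEFAULTS[p]
            else:
                row[p] = math.nan
        rows[g.name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def pedigree_index(table: pd.DataFrame | ModelDefinition) -> float:
    """Unweighted mean of all scored entries over living groups."""
    if isinstance(table, ModelDefinition):
        table = pedigree_table(table)
    vals = table.to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("pedigree table has no scored entries")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    n_total: int
    n_accepted: int
    n_keep: int
    seed: int
    kept_runs: list[int]
    acceptance_rate: float
    rejection_tally: dict[str, int]
    param_mean: pd.DataFrame       # group x parameter, over kept runs
    param_sd: pd.DataFrame
    index_stats: dict[str, pd.DataFrame | pd.Series] = field(default_factory=dict)


def _normalize_cv(cv_table, names) -> dict[str, np.ndarray | float]:
    """cv per parameter class (percent), optionally per group via a DataFrame."""
    out: dict[str, np.ndarray | float] = {}
    if isinstance(cv_table, pd.DataFrame):
        for p in cv_table.columns:
            out[p] = cv_table[p].reindex(names).fillna(0.0).to_numpy() / 100.0
    else:
        for p, v in dict(cv_table).items():
            out[p] = float(v) / 100.0
    return out


def _draw_positive(rng, base: np.ndarray, sd: np.ndarray, max_draws: int = 100):
    """Normal(base, sd) truncated to positive values (resample, then clamp)."""
    x = rng.normal(base, sd)
    bad = (x <= 0) & (sd > 0) & (base > 0)
    draws = 1
    while bad.any() and draws < max_draws:
        x[bad] = rng.normal(base[bad], sd[bad])
        bad = (x <= 0) & (sd > 0) & (base > 0)
        draws += 1
    x[bad] = 0.0
    return x


def monte_carlo(
    model: ModelDefinition,
    cv_table,
    n_total: int = 10_000,
    n_keep: int = 200,
    seed: int = 0,
    constraints: tuple[str, ...] = DEFAULT_CONSTRAINTS,
    index_funcs: bool = True,
) -> EnsembleResult:
    """Ecoranger-style resampling with constraint-based acceptance.

    ``cv_table`` gives the relative error (%) per parameter class among
    {B, PB, QB, DC, Y}, either as a mapping or as a group x parameter
    DataFrame.  Only parameters that are set in the base model are perturbed;
    unknowns stay unknown.  Diet columns are clipped to [0, 1] and
    renormalized after perturbation.
    """
    base = _as_arrays(model)
    names = base.names
    n = len(names)
    cv = _normalize_cv(cv_table, names)
    living = base.living
    consumer = base.consumer

    def sd_for(p: str, vals: np.ndarray) -> np.ndarray:
        c = cv.get(p, 0.0)
        c = c if isinstance(c, np.ndarray) else np.full(n, c)
        return np.where(np.isnan(vals), 0.0, np.abs(vals)) * c

    base_B = np.nan_to_num(base.B)
    base_PB = np.nan_to_num(base.PB)
    base_QB = np.nan_to_num(base.QB)
    base_Y = base.Y
    sd_B = sd_for("B", base.B) * living
    sd_PB = sd_for("PB", base.PB) * living
    sd_QB = sd_for("QB", base.QB) * consumer
    sd_Y = sd_for("Y", base.Y) * living
    cv_dc = cv.get("DC", 0.0)
    cv_dc_vec = cv_dc if isinstance(cv_dc, np.ndarray) else np.full(n, cv_dc)
    internal_target = 1.0 - base.import_frac  # diet columns renormalize to this

    tally = {"solver": 0, "ee": 0, "ge": 0, "ra": 0, "pr": 0}
    accepted: list[tuple[float, int]] = []
    draws_cache: dict[int, tuple] = {}

    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_total)

    for r in range(n_total):
        rng = np.random.default_rng(streams[r])
        B = _draw_positive(rng, base_B, sd_B)
        PB = _draw_positive(rng, base_PB, sd_PB)
        QB = _draw_positive(rng, base_QB, sd_QB)
        Y = rng.normal(base_Y, sd_Y)
        np.clip(Y, 0.0, None, out=Y)
        DC = base.DC
        score = 0.0
        if (cv_dc_vec > 0).any() and base.DC.any():
            noise = rng.normal(1.0, cv_dc_vec[np.newaxis, :], size=base.DC.shape)
            DC = np.clip(base.DC * noise, 0.0, 1.0)
            colsum = DC.sum(axis=0)
            scale = np.where(colsum > 0, internal_target / np.where(colsum > 0, colsum, 1.0), 1.0)
            DC = DC * scale[np.newaxis, :]

        a = dataclasses.replace(
            base,
            B=np.where(np.isnan(base.B), np.nan, B),
            PB=np.where(np.isnan(base.PB), np.nan, PB),
            QB=np.where(np.isnan(base.QB), np.nan, QB),
            Y=Y,
            DC=DC,
        )
        try:
            B_sol, EE = _solve_arrays(a)
        except SolverError:
            tally["solver"] += 1
            continue

        ok = True
        if "ee" in constraints:
            if np.any(EE[living] > 1.0 + 1e-12):
                tally["ee"] += 1
                ok = False
        if ok and consumer.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                GE = np.where(a.QB > 0, a.PB / np.where(a.QB > 0, a.QB, 1.0), np.nan)
            ge_c = GE[consumer]
            uc_c = a.UC[consumer]
            if "ge" in constraints and np.any(
                ~((ge_c > GE_BOUNDS[0]) & (ge_c < GE_BOUNDS[1]))
            ):
                tally["ge"] += 1
                ok = False
            elif "ra" in constraints and np.any(~(ge_c < 1.0 - uc_c)):
                tally["ra"] += 1  # RA >= 1 iff P >= assimilation
                ok = False
            elif "pr" in constraints and np.any(~(ge_c < (1.0 - uc_c) / 2.0)):
                tally["pr"] += 1  # P/R >= 1 iff GE >= (1-UC)/2
                ok = False
        if not ok:
            continue

        # standardized squared deviation from base inputs
        for x, b, s in ((B, base_B, sd_B), (PB, base_PB, sd_PB),
                        (QB, base_QB, sd_QB), (Y, base_Y, sd_Y)):
            mask = s > 0
            if mask.any():
                score += float((((x - b)[mask] / s[mask]) ** 2).sum())
        if DC is not base.DC:
            sd_dc = base.DC * cv_dc_vec[np.newaxis, :]
            mask = sd_dc > 0
            if mask.any():
                score += float((((DC - base.DC)[mask] / sd_dc[mask]) ** 2).sum())

        accepted.append((score, r))
        draws_cache[r] = (B, PB, QB, Y, DC, B_sol, EE)

    if not accepted:
        raise RuntimeError(f"no accepted runs out of {n_total}; rejections: {tally}")

    accepted.sort()
    kept = [r for _, r in accepted[:n_keep]]
    kept_sorted = sorted(kept)

    params = ("B", "PB", "QB", "Y")
    stacks = {p: [] for p in params}
    ee_rows, tl_rows, tst_vals, fci_vals = [], [], [], []
    for r in kept_sorted:
        B, PB, QB, Y, DC, B_sol, EE = draws_cache[r]
        stacks["B"].append(B_sol)
        stacks["PB"].append(PB)
        stacks["QB"].append(QB)
        stacks["Y"].append(Y)
        if index_funcs:
            pert = model.copy()
            for i, g in enumerate(pert.groups):
                if g.B is not None:
                    g.B = float(B[i])
                if g.PB is not None:
                    g.PB = float(PB[i])
                if g.QB is not None:
                    g.QB = float(QB[i])
                g.Y = float(Y[i])
            for j, g in enumerate(pert.groups):
                if g.is_consumer:
                    pert.diet.DC[g.name] = DC[:, j]
            bal = solve_balance(pert)
            ee_rows.append(bal.EE.to_numpy())
            tl_rows.append(fractional_trophic_levels(pert).to_numpy())
            stats = system_indices.summary_statistics(bal)
            fin = system_indices.finn_analysis(bal.flows, pert)
            tst_vals.append(stats.TST)
            fci_vals.append(fin.FCI)

    idx = pd.Index(names, name="group")
    mean = pd.DataFrame({p: np.mean(stacks[p], axis=0) for p in params}, index=idx)
    sd = pd.DataFrame({p: np.std(stacks[p], axis=0, ddof=0) for p in params}, index=idx)

    index_stats: dict = {}
    if index_funcs:
        runs = pd.Index(kept_sorted, name="run")
        index_stats["EE"] = pd.DataFrame(ee_rows, index=runs, columns=idx)
        index_stats["TL"] = pd.DataFrame(tl_rows, index=runs, columns=idx)
        index_stats["TST"] = pd.Series(tst_vals, index=runs, name="TST")
        index_stats["FCI"] = pd.Series(fci_vals, index=runs, name="FCI")

    return EnsembleResult(
        n_total=n_total,
        n_accepted=len(accepted),
        n_keep=len(kept_sorted),
        seed=seed,
        kept_runs=kept_sorted,
        acceptance_rate=len(accepted) / n_total,
        rejection_tally=tally,
        param_mean=mean,
        param_sd=sd,
        index_stats=index_stats,
    )
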