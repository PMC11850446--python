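"""Linear mass-balance solver and per-group energy budgets.

Every living group must satisfy the production balance

    P/B_i * B_i * EE_i = Y_i + sum_j B_j * Q/B_j * DC_ij + NM_i + BA_i

(production routed to catch, predation, migration and accumulation; the
remaining fraction ``1 - EE`` is other mortality flowing to detritus), and
every consumer the energy balance

    Q_i = P_i + R_i + UC_i * Q_i.

With exactly one unknown per living group among {B, EE} the first equation is
linear: the rows whose biomass is unknown form a square system in those
biomasses; every remaining row then yields its EE directly.  Detritus EE is
derived from the detritus budget (consumption of detritus over inflow).

EE > 1 is a *flagged* state, never an exception — the balancing workflow
inspects the diagnostics and optionally calls :func:`auto_adjust_diet`, which
mimics the manual practice of trimming the diet fractions of over-consumed
prey until all EE <= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .model_io import (
    CONSUMER,
    DETRITUS,
    PRODUCER,
    DietMatrix,
    ModelDefinition,
)

__all__ = [
    "SolverError",
    "BalancedModel",
    "FlowMatrix",
    "Budget",
    "DetritusBudget",
    "DiagnosticsReport",
    "AdjustmentResult",
    "solve_balance",
    "compute_budget",
    "detritus_budget",
    "diagnose",
    "auto_adjust_diet",
]

#: gross-efficiency interval considered physiologically plausible
GE_BOUNDS = (0.1, 0.3)


class SolverError(RuntimeError):
    """The linear system cannot be solved (singular, infeasible, negative B)."""


class Budget(NamedTuple):
    """Consumer energy budget derived from Q = P + R + UC*Q."""

    R: float    # respiration
    GE: float   # gross efficiency P/Q
    RA: float   # respiration / assimilation
    PR: float   # production / respiration (nan when R == 0)


@dataclass
class FlowMatrix:
    """Inter-group consumption flows plus boundary vectors (all g/m^2/yr).

    ``T.loc[i, j]`` is consumption of prey ``i`` by predator ``j``.  Imports
    hold external detritus inflow and diet imports; exports hold catch plus
    net migration; ``to_detritus`` is each group's unassimilated consumption
    plus unutilized production.
    """

    T: pd.DataFrame
    imports: pd.Series
    exports: pd.Series
    respiration: pd.Series
    to_detritus: pd.Series

    @property
    def names(self) -> list[str]:
        return list(self.T.index)

    def total_system_throughput(self) -> float:
        return float(
            self.T.to_numpy().sum()
            + self.exports.sum()
            + self.respiration.sum()
            + self.to_detritus.sum()
        )


@dataclass
class BalancedModel:
    """A solved model: all parameters set plus per-group flow accounts."""

    model: ModelDefinition
    flows: FlowMatrix
    Q: pd.Series
    P: pd.Series
    R: pd.Series
    EE: pd.Series
    B: pd.Series
    predation: pd.Series
    flow_to_detritus: pd.Series
    P_unutilized: pd.Series

    @property
    def names(self) -> list[str]:
        return self.model.names

    def budget_table(self) -> pd.DataFrame:
        """Per-group budget in the layout of a standard basic-estimates table."""
        return pd.DataFrame(
            {
                "B": self.B,
                "P": self.P,
                "Q": self.Q,
                "R": self.R,
                "EE": self.EE,
                "predation": self.predation,
                "P_unutilized": self.P_unutilized,
                "flow_to_detritus": self.flow_to_detritus,
            }
        )


@dataclass
class DetritusBudget:
    unassimilated: float      # sum UC_i * Q_i over consumers
    unutilized: float         # sum (1 - EE_i) * P_i over living groups
    external_import: float    # detritus_import
    outflow: float            # consumption of detritus by detritivores
    EE: float

    @property
    def inflow(self) -> float:
        return self.unassimilated + self.unutilized + self.external_import


@dataclass
class DiagnosticsReport:
    """Per-group physiological/thermodynamic constraint flags.

    The classical screening rules are 0.1 < GE < 0.3, GE < net efficiency,
    R/assimilation < 1 and P/R < 1, checked for consumers, plus EE <= 1 for
    every group.  P/R < 1 is applied to consumers only: producer-dominated
    systems violate it trivially.
    """

    table: pd.DataFrame

    @property
    def ok(self) -> bool:
        flag_cols = [c for c in self.table.columns if c.startswith("flag_")]
        return not self.table[flag_cols].any().any()

    def flagged(self) -> pd.DataFrame:
        flag_cols = [c for c in self.table.columns if c.startswith("flag_")]
        return self.table[self.table[flag_cols].any(axis=1)]


# ---------------------------------------------------------------------------
# array core (shared with the Monte Carlo machinery)
# ---------------------------------------------------------------------------

@dataclass
class _Arrays:
    """Dense views of a model, in group order."""

    names: list[str]
    types: list[str]
    B: np.ndarray
    PB: np.ndarray
    QB: np.ndarray
    EE: np.ndarray        # nan = unknown
    UC: np.ndarray
    Y: np.ndarray
    NM: np.ndarray
    BA: np.ndarray
    R_input: np.ndarray   # nan = not supplied
    det_import: np.ndarray
    DC: np.ndarray        # prey x predator, full square
    import_frac: np.ndarray
    living: np.ndarray    # bool
    consumer: np.ndarray  # bool


def _as_arrays(model: ModelDefinition) -> _Arrays:
    n = len(model.groups)
    names = model.names
    get = lambda attr: np.array(
        [np.nan if getattr(g, attr) is None else float(getattr(g, attr))
         for g in model.groups]
    )
    types = [g.group_type for g in model.groups]
    living = np.array([t != DETRITUS for t in types])
    consumer = np.array([t == CONSUMER for t in types])
    DC = np.zeros((n, n))
    import_frac = np.zeros(n)
    for j, g in enumerate(model.groups):
        if g.is_consumer and g.name in model.diet.DC.columns:
            DC[:, j] = model.diet.DC[g.name].reindex(names).fillna(0.0).to_numpy()
            import_frac[j] = float(model.diet.import_fraction.get(g.name, 0.0))
    arr = _Arrays(
        names=names, types=types,
        B=get("B"), PB=get("PB"), QB=get("QB"), EE=get("EE"),
        UC=np.nan_to_num(get("UC")), Y=np.nan_to_num(get("Y")),
        NM=np.nan_to_num(get("NM")), BA=np.nan_to_num(get("BA")),
        R_input=get("R"), det_import=np.nan_to_num(get("detritus_import")),
        DC=DC, import_frac=import_frac, living=living, consumer=consumer,
    )
    arr.QB = np.where(consumer, arr.QB, 0.0)
    arr.PB = np.where(living, arr.PB, 0.0)
    return arr


def _solve_arrays(a: _Arrays) -> tuple[np.ndarray, np.ndarray]:
    """Solve for the unknown B/EE values; returns (B, EE) for living groups.

    Detritus entries of EE are left nan here (filled from the detritus
    budget later); detritus B defaults to 0 when unset.
    """
    n = len(a.names)
    B = a.B.copy()
    EE = a.EE.copy()

    b_unknown = a.living & np.isnan(B)
    ee_unknown = a.living & np.isnan(EE)
    both = b_unknown & ee_unknown
    if both.any():
        bad = [a.names[i] for i in np.flatnonzero(both)]
        raise SolverError(f"groups with both B and EE unknown: {bad}")
    neither = a.living & ~b_unknown & ~ee_unknown
    if neither.any():
        bad = [a.names[i] for i in np.flatnonzero(neither)]
        raise SolverError(f"groups with neither B nor EE unknown (over-determined): {bad}")
    if np.isnan(a.PB[a.living]).any():
        bad = [a.names[i] for i in np.flatnonzero(a.living & np.isnan(a.PB))]
        raise SolverError(f"living groups missing P/B: {bad}")
    if np.isnan(a.QB[a.consumer]).any():
        bad = [a.names[i] for i in np.flatnonzero(a.consumer & np.isnan(a.QB))]
        raise SolverError(f"consumers missing Q/B: {bad}")

    # demand coefficients: predation on i = sum_j M[i, j] * B_j
    M = a.DC * a.QB[np.newaxis, :]

    ub = np.flatnonzero(b_unknown)
    if ub.size:
        kb = np.flatnonzero(~np.isnan(B))
        known_pred = M[:, kb] @ B[kb] if kb.size else np.zeros(n)
        A = -M[np.ix_(ub, ub)]
        A[np.diag_indices_from(A)] += a.PB[ub] * EE[ub]
        rhs = (a.Y + a.NM + a.BA)[ub] + known_pred[ub]
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            raise SolverError(
                f"singular mass-balance system for groups {[a.names[i] for i in ub]}"
            ) from None
        if not np.all(np.isfinite(sol)):
            raise SolverError("non-finite solved biomass")
        neg = sol < 0
        if neg.any():
            bad = [a.names[ub[i]] for i in np.flatnonzero(neg)]
            raise SolverError(f"negative solved biomass for {bad}")
        B[ub] = sol

    B = np.where(np.isnan(B), 0.0, B)  # unset detritus biomass
    predation = M @ B
    ue = np.flatnonzero(ee_unknown)
    if ue.size:
        P = B[ue] * a.PB[ue]
        sinks = (a.Y + a.NM + a.BA)[ue] + predation[ue]
        with np.errstate(divide="ignore", invalid="ignore"):
            ee = np.where(P > 0, sinks / np.where(P > 0, P, 1.0),
                          np.where(np.abs(sinks) < 1e-300, 0.0, np.inf))
        EE[ue] = ee
    return B, EE


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def compute_budget(Q: float, UC: float, P: float) -> Budget:
    """Energy budget of a consumer: R = Q(1-UC) - P, GE = P/Q, RA, PR.

    A negative R is returned as-is and reported by :func:`diagnose`; PR is
    nan when R == 0.
    """
    if Q <= 0:
        raise ValueError("compute_budget requires consumption Q > 0")
    assim = Q * (1.0 - UC)
    R = assim - P
    GE = P / Q
    RA = R / assim if assim > 0 else math.nan
    PR = P / R if R != 0 else math.nan
    return Budget(R=R, GE=GE, RA=RA, PR=PR)


def _detritus_split(a: _Arrays) -> np.ndarray:
    """Fraction of system flow-to-detritus routed to each detritus group.

    A single detritus pool receives everything; multiple pools split equally.
    """
    det = ~a.living
    nd = int(det.sum())
    w = np.zeros(len(a.names))
    if nd:
        w[det] = 1.0 / nd
    return w


def solve_balance(model: ModelDefinition) -> BalancedModel:
    """Solve the production balance and assemble all per-group flow accounts."""
    a = _as_arrays(model)
    B, EE = _solve_arrays(a)
    names = a.names
    n = len(names)

    QB = np.nan_to_num(a.QB)
    Q = np.where(a.consumer, B * QB, 0.0)
    P = np.where(a.living, B * a.PB, 0.0)
    # consumers: R from the energy balance; producers: measured R or 0
    R = np.where(
        a.consumer,
        Q * (1.0 - a.UC) - P,
        np.where(np.isnan(a.R_input), 0.0, np.nan_to_num(a.R_input)),
    )
    R = np.where(a.living, R, 0.0)

    T = a.DC * (QB * B)[np.newaxis, :]           # T[i, j] = B_j QB_j DC_ij
    predation = T.sum(axis=1)
    unassimilated = a.UC * Q
    with np.errstate(invalid="ignore"):
        unutilized = np.where(a.living, (1.0 - EE) * P, 0.0)
    unutilized = np.nan_to_num(unutilized)        # detritus EE still nan here
    flow_to_det = np.where(a.living, unassimilated + unutilized, 0.0)

    # detritus budget -> detritus EE
    split = _detritus_split(a)
    det_idx = np.flatnonzero(~a.living)
    det_inflow = split * flow_to_det.sum() + a.det_import
    for d in det_idx:
        outflow = predation[d]
        inflow = det_inflow[d]
        if inflow > 0:
            EE[d] = outflow / inflow
        else:
            EE[d] = 0.0 if outflow == 0 else np.inf

    diet_imports = a.import_frac * Q
    imports = a.det_import + diet_imports
    exports = a.Y + a.NM

    idx = pd.Index(names, name="group")
    flows = FlowMatrix(
        T=pd.DataFrame(T, index=idx, columns=idx),
        imports=pd.Series(imports, index=idx),
        exports=pd.Series(exports, index=idx),
        respiration=pd.Series(R, index=idx),
        to_detritus=pd.Series(flow_to_det, index=idx),
    )

    solved = model.copy()
    for i, g in enumerate(solved.groups):
        g.B = float(B[i])
        g.EE = float(EE[i])

    return BalancedModel(
        model=solved,
        flows=flows,
        Q=pd.Series(Q, index=idx),
        P=pd.Series(P, index=idx),
        R=pd.Series(R, index=idx),
        EE=pd.Series(EE, index=idx),
        B=pd.Series(B, index=idx),
        predation=pd.Series(predation, index=idx),
        flow_to_detritus=pd.Series(flow_to_det, index=idx),
        P_unutilized=pd.Series(np.where(a.living, unutilized, 0.0), index=idx),
    )


def detritus_budget(balanced: BalancedModel) -> DetritusBudget:
    """Aggregate detritus inflow components, outflow and detritus EE."""
    m = balanced.model
    unassim = sum(
        (g.UC or 0.0) * balanced.Q[g.name] for g in m.consumers
    )
    unutil = sum(balanced.P_unutilized[g.name] for g in m.living)
    ext = sum(g.detritus_import or 0.0 for g in m.detritus_groups)
    outflow = sum(balanced.predation[g.name] for g in m.detritus_groups)
    inflow = unassim + unutil + ext
    if inflow == 0 and outflow > 0:
        raise SolverError("detritus outflow with zero inflow: web is imbalanced")
    ee = outflow / inflow if inflow > 0 else 0.0
    return DetritusBudget(
        unassimilated=float(unassim),
        unutilized=float(unutil),
        external_import=float(ext),
        outflow=float(outflow),
        EE=float(ee),
    )


def diagnose(balanced: BalancedModel) -> DiagnosticsReport:
    """Screen a solved model against the classical balance constraints."""
    rows = []
    for g in balanced.model.groups:
        name = g.name
        row: dict = {
            "group": name,
            "group_type": g.group_type,
            "EE": balanced.EE[name],
            "GE": math.nan,
            "RA": math.nan,
            "PR": math.nan,
            "flag_ee_gt_1": bool(balanced.EE[name] > 1.0 + 1e-12),
            "flag_ge_range": False,
            "flag_ge_vs_ne": False,
            "flag_ra_ge_1": False,
            "flag_pr_ge_1": False,
            "flag_negative_R": False,
        }
        if g.is_consumer and balanced.Q[name] > 0:
            b = compute_budget(balanced.Q[name], g.UC or 0.0, balanced.P[name])
            ne = b.GE / (1.0 - (g.UC or 0.0))  # net efficiency P/(Q(1-UC))
            row.update(GE=b.GE, RA=b.RA, PR=b.PR)
            row["flag_ge_range"] = not (GE_BOUNDS[0] < b.GE < GE_BOUNDS[1])
            row["flag_ge_vs_ne"] = not (b.GE < ne) if ne == ne else True
            row["flag_ra_ge_1"] = not (b.RA < 1.0)
            row["flag_pr_ge_1"] = (b.PR == b.PR) and not (b.PR < 1.0)
            row["flag_negative_R"] = b.R < 0
        rows.append(row)
    return DiagnosticsReport(pd.DataFrame(rows).set_index("group"))


# ---------------------------------------------------------------------------
# diet auto-adjustment
# ---------------------------------------------------------------------------

@dataclass
class AdjustmentResult:
    model: ModelDefinition
    log: list[dict] = field(default_factory=list)
    balanced: bool = True
    iterations: int = 0


def auto_adjust_diet(
    model: ModelDefinition,
    max_iter: int = 100,
    step: float = 0.1,
    ee_tol: float = 1e-3,
) -> AdjustmentResult:
    """Iteratively trim diet fractions of over-consumed prey until EE <= 1.

    Each iteration, for every living prey ``i`` with EE_i > 1, every diet
    entry DC[i, j] > 0 is multiplied by ``1 - step * overshoot_i`` where
    ``overshoot_i = min(1, (EE_i - 1)/EE_i)``; the freed diet fraction is
    redistributed proportionally among predator ``j``'s other prey that are
    not themselves over-consumed, or to detritus if it has none.  Mimics the
    manual practice of reducing the insufficient supply of prey within diet
    uncertainty.

    The multiplicative update approaches EE = 1 geometrically from above
    (excess shrinks by roughly ``1 - step`` per iteration), so convergence
    is declared at EE <= 1 + ``ee_tol``.
    """
    work = model.copy()
    log: list[dict] = []
    det_names = [g.name for g in work.detritus_groups]
    it = 0
    for it in range(1, max_iter + 1):
        balanced = solve_balance(work)
        over = [
            g.name
            for g in work.living
            if balanced.EE[g.name] > 1.0 + ee_tol
        ]
        if not over:
            return AdjustmentResult(work, log, balanced=True, iterations=it - 1)
        dc = work.diet.DC
        for prey in over:
            ee = float(balanced.EE[prey])
            overshoot = min(1.0, (ee - 1.0) / ee)
            factor = 1.0 - step * overshoot
            for pred in dc.columns:
                old = float(dc.loc[prey, pred])
                if old <= 0:
                    continue
                new = old * factor
                freed = old - new
                dc.loc[prey, pred] = new
                others = [
                    k for k in dc.index
                    if k != prey and k not in over and dc.loc[k, pred] > 0
                ]
                if others:
                    weights = dc.loc[others, pred]
                    dc.loc[others, pred] += freed * weights / weights.sum()
                    target = "proportional"
                elif det_names:
                    dc.loc[det_names[0], pred] += freed
                    target = det_names[0]
                else:
                    # no sink available: give the fraction back as diet import
                    work.diet.import_fraction[pred] += freed
                    target = "import"
                log.append(
                    {
                        "iteration": it,
                        "prey": prey,
                        "predator": pred,
                        "old": old,
                        "new": new,
                        "redistributed_to": target,
                        "EE": ee,
                    }
                )
    balanced = solve_balance(work)
    still_over = any(
        balanced.EE[g.name] > 1.0 + ee_tol for g in work.living
    )
    return AdjustmentResult(work, log, balanced=not still_over, iterations=it)
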