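"""System-level flow statistics and ecological network indices.

Implements the classical maturity/health index suite for a solved web: total
system throughput and its components, primary-production ratios, Finn's
cycling and path-length measures from the Leontief input structure,
connectance, biomass diversity, and the Ulanowicz information indices
(ascendency and development capacity, reported in "flowbits", i.e. log2).

Cycling is analyzed on the compartment network that includes detritus pools
(flows to detritus are genuine inter-compartment transfers); the "excluding
detritus" variants delete detritus nodes and their incident flows first, so
they capture predator-mediated cycling only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mass_balance import BalancedModel, FlowMatrix
from .model_io import DETRITUS, ModelDefinition
from .trophic_analysis import TrophicProfile, fractional_trophic_levels, omnivory

__all__ = [
    "SystemStatistics",
    "CycleAnalysis",
    "flow_accounts",
    "summary_statistics",
    "connectance",
    "finn_analysis",
    "shannon_diversity",
    "information_indices",
    "full_statistics",
]


@dataclass
class SystemStatistics:
    """The full summary-statistics row set for one model (nan = not computed)."""

    sum_consumption: float = math.nan
    sum_respiration: float = math.nan      # TR
    sum_to_detritus: float = math.nan
    sum_exports: float = math.nan
    TST: float = math.nan
    sum_production: float = math.nan
    TPP: float = math.nan
    NSP: float = math.nan                  # TPP - TR
    TB: float = math.nan                   # excluding detritus
    TPP_TR: float = math.nan
    TPP_TB: float = math.nan
    TB_TST: float = math.nan
    throughput_cycled_excl: float = math.nan
    throughput_cycled_incl: float = math.nan
    predator_cycling_index: float = math.nan
    FCI: float = math.nan
    FML: float = math.nan
    straight_path_excl: float = math.nan
    straight_path_incl: float = math.nan
    CI: float = math.nan
    SOI: float = math.nan
    shannon_diversity: float = math.nan
    capacity: float = math.nan             # C, flowbits
    ascendency: float = math.nan           # A, flowbits
    AC_pct: float = math.nan               # 100 * A / C
    name: str = ""

    def as_series(self) -> pd.Series:
        d = {k: v for k, v in self.__dict__.items() if k != "name"}
        return pd.Series(d, name=self.name or None)


@dataclass
class CycleAnalysis:
    """Leontief structure of the flow network used for Finn's indices."""

    G: pd.DataFrame          # G[i, j] = flow i->j / total inflow of j
    L: pd.DataFrame          # (I - G)^-1
    inflow: pd.Series        # per-compartment total inflow (throughput)
    cycled: pd.Series        # inflow_i * (L_ii - 1) / L_ii

    @property
    def total_cycled(self) -> float:
        return float(self.cycled.sum())


def flow_accounts(balanced: BalancedModel) -> FlowMatrix:
    """The inter-group flow matrix with boundary vectors (built at solve time)."""
    return balanced.flows


# ---------------------------------------------------------------------------
# flow sums and ratios
# ---------------------------------------------------------------------------

def summary_statistics(
    balanced: BalancedModel, flows: FlowMatrix | None = None
) -> SystemStatistics:
    """Throughput sums and maturity ratios (the flow part of the index table)."""
    flows = flows or balanced.flows
    m = balanced.model
    s = SystemStatistics()
    s.sum_consumption = float(balanced.Q.sum())
    s.sum_respiration = float(flows.respiration.sum())
    s.sum_to_detritus = float(flows.to_detritus.sum())
    s.sum_exports = float(flows.exports.sum())
    s.TST = s.sum_consumption + s.sum_exports + s.sum_respiration + s.sum_to_detritus
    s.sum_production = float(balanced.P.sum())
    s.TPP = float(sum(balanced.P[g.name] for g in m.producers))
    s.NSP = s.TPP - s.sum_respiration
    s.TB = float(sum(balanced.B[g.name] for g in m.living))
    s.TPP_TR = s.TPP / s.sum_respiration if s.sum_respiration > 0 else math.nan
    s.TPP_TB = s.TPP / s.TB if s.TB > 0 else math.nan
    s.TB_TST = s.TB / s.TST if s.TST > 0 else math.nan
    return s


def connectance(model: ModelDefinition) -> float:
    """Realized fraction of possible links: links / (N_living * (N_living - 1)).

    Links are nonzero diet entries of living consumers on living prey plus
    detritus-feeding links; N_living counts non-detritus groups.
    """
    n_living = len(model.living)
    if n_living < 2:
        return math.nan
    links = 0
    for g in model.consumers:
        if g.name not in model.diet.DC.columns:
            continue
        col = model.diet.DC[g.name]
        for prey, v in col.items():
            if v > 0:
                links += 1
    return links / (n_living * (n_living - 1))


# ---------------------------------------------------------------------------
# Finn cycling / path lengths
# ---------------------------------------------------------------------------

def _compartment_flows(
    flows: FlowMatrix, model: ModelDefinition, include_detritus: bool
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(F, imports, names): inter-compartment flow matrix and boundary inflow.

    F includes predation flows and (when detritus is kept) each group's flow
    to detritus, split equally among detritus pools.
    """
    names = model.names
    det = [g.name for g in model.detritus_groups]
    F = flows.T.to_numpy().copy()
    imports = flows.imports.to_numpy().copy()
    if include_detritus and det:
        didx = [names.index(d) for d in det]
        td = flows.to_detritus.to_numpy()
        for i in range(len(names)):
            for d in didx:
                F[i, d] += td[i] / len(didx)
        return F, imports, names
    keep = [i for i, g in enumerate(model.groups) if g.group_type != DETRITUS]
    kept_names = [names[i] for i in keep]
    Fk = F[np.ix_(keep, keep)]
    # flows formerly received from detritus become boundary imports
    if det:
        didx = [names.index(d) for d in det]
        from_det = F[didx, :].sum(axis=0)
        imports = imports + from_det
    return Fk, imports[keep], kept_names


def _leontief(F: np.ndarray, imports: np.ndarray, names: list[str]) -> CycleAnalysis:
    inflow = F.sum(axis=0) + imports
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.where(inflow[np.newaxis, :] > 0, F / np.where(inflow > 0, inflow, 1.0), 0.0)
    try:
        L = np.linalg.inv(np.eye(len(names)) - G)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate webs
        raise RuntimeError(f"Leontief inverse undefined: {exc}") from None
    diag = np.diag(L)
    cycled = np.where(diag > 0, inflow * (diag - 1.0) / np.where(diag > 0, diag, 1.0), 0.0)
    idx = pd.Index(names, name="group")
    return CycleAnalysis(
        G=pd.DataFrame(G, index=idx, columns=idx),
        L=pd.DataFrame(L, index=idx, columns=idx),
        inflow=pd.Series(inflow, index=idx),
        cycled=pd.Series(cycled, index=idx),
    )


@dataclass
class FinnResult:
    analysis: CycleAnalysis                 # including detritus
    analysis_excl: CycleAnalysis            # detritus nodes deleted
    FCI: float                              # %, cycled/TST incl detritus
    throughput_cycled_incl: float
    throughput_cycled_excl: float
    predator_cycling_index: float           # %, cycled/TST excl detritus
    FML: float                              # TST / (exports + respiration)
    straight_path_incl: float
    straight_path_excl: float


def finn_analysis(flows: FlowMatrix, model: ModelDefinition) -> FinnResult:
    """Finn's cycling index, mean path length and straight-through paths."""
    ca = _leontief(*_compartment_flows(flows, model, include_detritus=True))
    ca_x = _leontief(*_compartment_flows(flows, model, include_detritus=False))

    TST = flows.total_system_throughput()
    det = [g.name for g in model.detritus_groups]
    living = [g.name for g in model.living]
    det_import = float(sum(g.detritus_import or 0.0 for g in model.detritus_groups))
    # TST without detritus pools: drop flows into detritus and their imports
    TST_x = (
        float(flows.T.to_numpy().sum())
        + float(flows.exports[living].sum())
        + float(flows.respiration[living].sum())
    )

    cyc_in = ca.total_cycled
    cyc_x = ca_x.total_cycled
    outflux = float(flows.exports.sum() + flows.respiration.sum())
    fci = 100.0 * cyc_in / TST if TST > 0 else math.nan
    pci = 100.0 * cyc_x / TST_x if TST_x > 0 else math.nan
    fml = TST / outflux if outflux > 0 else math.nan
    sp_in = (TST - cyc_in) / outflux if outflux > 0 else math.nan
    sp_x = (TST_x - cyc_x) / outflux if outflux > 0 else math.nan
    return FinnResult(
        analysis=ca,
        analysis_excl=ca_x,
        FCI=fci,
        throughput_cycled_incl=cyc_in,
        throughput_cycled_excl=cyc_x,
        predator_cycling_index=pci,
        FML=fml,
        straight_path_incl=sp_in,
        straight_path_excl=sp_x,
    )


# ---------------------------------------------------------------------------
# diversity and information indices
# ---------------------------------------------------------------------------

def shannon_diversity(balanced: BalancedModel, flow_based: bool = False) -> float:
    """Shannon entropy of living-group biomass shares (or inflow shares)."""
    m = balanced.model
    if flow_based:
        vals = np.array(
            [balanced.Q[g.name] + balanced.P[g.name] for g in m.living]
        )
    else:
        vals = np.array([balanced.B[g.name] for g in m.living])
    vals = vals[vals > 0]
    if vals.size == 0:
        return math.nan
    p = vals / vals.sum()
    return float(-(p * np.log(p)).sum())


def information_indices(
    flows: FlowMatrix, model: ModelDefinition
) -> tuple[float, float, float]:
    """(capacity C, ascendency A, A/C in %) over the extended flow network.

    The network is extended with boundary compartments for imports, exports
    and respiration; logarithms are base 2 so C and A are in flowbits.
    Zero flows contribute nothing (0 log 0 := 0).
    """
    F, imports, names = _compartment_flows(flows, model, include_detritus=True)
    n = len(names)
    # extended matrix: rows/cols [groups..., import, export, respiration]
    X = np.zeros((n + 3, n + 3))
    X[:n, :n] = F
    X[n, :n] = imports
    exports = flows.exports.reindex(names).fillna(0.0).to_numpy()
    resp = flows.respiration.reindex(names).fillna(0.0).to_numpy()
    X[:n, n + 1] = exports
    X[:n, n + 2] = resp
    total = X.sum()
    if total <= 0:
        return math.nan, math.nan, math.nan
    rows = X.sum(axis=1)
    cols = X.sum(axis=0)
    nz = X > 0
    t = X[nz]
    ri = np.broadcast_to(rows[:, None], X.shape)[nz]
    cj = np.broadcast_to(cols[None, :], X.shape)[nz]
    A = float((t * np.log2(t * total / (ri * cj))).sum())
    C = float(-(t * np.log2(t / total)).sum())
    ac = 100.0 * A / C if C > 0 else math.nan
    return C, A, ac


# ---------------------------------------------------------------------------
# one-call assembly
# ---------------------------------------------------------------------------

def full_statistics(balanced: BalancedModel, name: str = "") -> SystemStatistics:
    """Compute the complete index suite for one solved model."""
    m = balanced.model
    flows = balanced.flows
    s = summary_statistics(balanced, flows)
    s.name = name
    s.CI = connectance(m)
    tl = fractional_trophic_levels(m)
    _, s.SOI = omnivory(TrophicProfile(TL=tl), m, Q=balanced.Q)
    fin = finn_analysis(flows, m)
    s.FCI = fin.FCI
    s.FML = fin.FML
    s.throughput_cycled_incl = fin.throughput_cycled_incl
    s.throughput_cycled_excl = fin.throughput_cycled_excl
    s.predator_cycling_index = fin.predator_cycling_index
    s.straight_path_incl = fin.straight_path_incl
    s.straight_path_excl = fin.straight_path_excl
    s.shannon_diversity = shannon_diversity(balanced)
    s.capacity, s.ascendency, s.AC_pct = information_indices(flows, m)
    return s
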