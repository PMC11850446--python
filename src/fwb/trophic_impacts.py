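"""Mixed trophic impacts and keystoneness.

The direct-impact matrix q scores, for each ordered pair (i, j), the benefit
i provides as food to j (i's share of j's diet) minus the harm i causes as a
predator of j (i's share of the total predation on j).  Total impacts over
all direct and indirect pathways are M = (I - q)^-1 - I, the closed form of
the Neumann path sum q + q^2 + ...  Keystoneness combines the overall impact
magnitude of a group with its (low) biomass share, flagging groups whose
influence is disproportionate to their standing stock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mass_balance import BalancedModel

__all__ = [
    "ImpactMatrices",
    "direct_impacts",
    "mixed_trophic_impacts",
    "keystoneness",
    "impact_analysis",
]


@dataclass
class ImpactMatrices:
    q: pd.DataFrame                    # direct impacts, row = impacting
    M: pd.DataFrame                    # mixed (total) impacts
    epsilon: pd.Series                 # overall effect, living groups
    relative_total_impact: pd.Series   # epsilon / max epsilon, in [0, 1]
    p: pd.Series                       # biomass proportion (detritus excluded)
    KS: pd.Series                      # keystoneness, log10(eps * (1 - p))


def direct_impacts(balanced: BalancedModel) -> pd.DataFrame:
    """q[i, j]: net direct impact of group i on group j in [-1, 1].

    The positive term is prey-i's share of predator-j's diet; for a detritus
    column the "diet" is the normalized inflow to that detritus pool.  The
    negative term is predator-i's share of the total predation on j (zero for
    prey nobody eats).
    """
    m = balanced.model
    names = m.names
    n = len(names)
    T = balanced.flows.T.to_numpy()

    # diet share of prey i in consumer j (DC), detritus columns from inflows
    D = np.zeros((n, n))
    for j, g in enumerate(m.groups):
        if g.is_consumer and g.name in m.diet.DC.columns:
            D[:, j] = m.diet.DC[g.name].reindex(names).fillna(0.0).to_numpy()
        elif g.group_type == "detritus":
            contrib = balanced.flow_to_detritus.to_numpy().astype(float).copy()
            nd = max(len(m.detritus_groups), 1)
            contrib = contrib / nd
            total = contrib.sum() + (g.detritus_import or 0.0)
            if total > 0:
                D[:, j] = contrib / total

    # predation share: F[i, j] = predator-i's share of total predation on j
    pred_tot = T.sum(axis=1)  # total predation on each prey
    # include detritus "predation" = consumption of detritus
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(
            pred_tot[np.newaxis, :] > 0,
            T.T / np.where(pred_tot > 0, pred_tot, 1.0)[np.newaxis, :],
            0.0,
        )  # share[i, j] = T[j, i] / pred_tot[j]
    q = D - share
    idx = pd.Index(names, name="group")
    return pd.DataFrame(q, index=idx, columns=idx)


def mixed_trophic_impacts(q: pd.DataFrame) -> pd.DataFrame:
    """Total impacts M = (I - q)^-1 - I (sum over all impact pathways).

    When the spectral radius of q is below 1 this equals the convergent
    Neumann path sum q + q^2 + ...; the closed form extends it to webs of
    strong pairwise couplings (radius up to and beyond 1) where the series
    only sums in the averaged sense.  A singular (I - q) means impact
    propagation genuinely fails to resolve and raises.
    """
    qa = q.to_numpy()
    eye = np.eye(len(q))
    try:
        M = np.linalg.inv(eye - qa) - eye
    except np.linalg.LinAlgError:
        raise ValueError("non-convergent impact propagation: (I - q) is singular") from None
    return pd.DataFrame(M, index=q.index, columns=q.columns)


def keystoneness(
    M: pd.DataFrame,
    biomasses: pd.Series,
    living: list[str] | None = None,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """(epsilon, relative total impact, KS) for living groups.

    epsilon_i = sqrt(sum_{j != i} m_ij^2) over living impacted groups;
    KS_i = log10(epsilon_i * (1 - p_i)) with p the biomass proportion of
    living groups (detritus carries no biomass share).  Groups with zero
    impact get KS = nan.
    """
    if living is None:
        living = [g for g in M.index if g in biomasses.index]
    eps = {}
    for i in living:
        others = [j for j in living if j != i]
        eps[i] = math.sqrt(float((M.loc[i, others] ** 2).sum()))
    eps = pd.Series(eps, name="epsilon")
    mx = float(eps.max())
    rel = eps / mx if mx > 0 else eps * math.nan
    tb = float(biomasses[living].sum())
    p = biomasses[living] / tb if tb > 0 else biomasses[living] * math.nan
    ks = pd.Series(
        {
            i: math.log10(eps[i] * (1.0 - p[i])) if eps[i] * (1.0 - p[i]) > 0 else math.nan
            for i in living
        },
        name="KS",
    )
    return eps, rel, ks


def impact_analysis(balanced: BalancedModel) -> ImpactMatrices:
    """Run the full impact chain: q -> M -> keystoneness."""
    q = direct_impacts(balanced)
    M = mixed_trophic_impacts(q)
    living = [g.name for g in balanced.model.living]
    eps, rel, ks = keystoneness(M, balanced.B, living)
    tb = float(balanced.B[living].sum())
    p = balanced.B[living] / tb if tb > 0 else balanced.B[living] * math.nan
    return ImpactMatrices(q=q, M=M, epsilon=eps, relative_total_impact=rel, p=p, KS=ks)
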