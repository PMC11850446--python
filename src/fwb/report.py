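"""Report rendering, model comparison and the batch pipeline.

Renders the summary-statistics table (one column per model, the classical
flow/cycling/information row set), a text Lindeman spine, per-group budget
tables, a graph exchange export of the flow network, and a maturity
comparison that ranks models per index and by a configurable weighted
composite.  Numbers are formatted by precision class (flows as integers,
ratios to 2-4 decimals) so printed ratios reproduce exactly from their
printed components.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .mass_balance import AdjustmentResult, BalancedModel, auto_adjust_diet, solve_balance
from .model_io import ModelDefinition, load_model
from .system_indices import SystemStatistics, full_statistics
from .trophic_analysis import LindemanSpine, lindeman_spine, transfer_efficiencies
from .trophic_impacts import impact_analysis
from .uncertainty import monte_carlo

__all__ = [
    "STAT_ROWS",
    "format_value",
    "render_stats_table",
    "render_spine_text",
    "render_budget_table",
    "export_flow_network",
    "ComparisonReport",
    "compare_models",
    "run_pipeline",
    "StageError",
]

# (label, SystemStatistics attribute, unit, precision class)
STAT_ROWS: tuple[tuple[str, str, str, str], ...] = (
    ("Sum of all consumption", "sum_consumption", "g/m^2/year", "flow"),
    ("Sum of all respiration (TR)", "sum_respiration", "g/m^2/year", "flow"),
    ("Sum of all back flows to detritus", "sum_to_detritus", "g/m^2/year", "flow"),
    ("Total system throughput (TST)", "TST", "g/m^2/year", "flow"),
    ("Sum of all production", "sum_production", "g/m^2/year", "flow"),
    ("Total net primary production (TPP)", "TPP", "g/m^2/year", "flow"),
    ("Net system production (TPP-TR)", "NSP", "g/m^2/year", "flow"),
    ("Total biomass (TB, excluding detritus)", "TB", "g/m^2", "sig3"),
    ("Total primary production/total respiration (TPP/TR)", "TPP_TR", "", "dec2"),
    ("Total primary production/total biomass (TPP/TB)", "TPP_TB", "", "sig3"),
    ("Total biomass/Total system throughput (TB/TST)", "TB_TST", "", "dec4"),
    ("Throughput cycled (excluding detritus)", "throughput_cycled_excl",
     "g/m^2/year", "sig3"),
    ("Throughput cycled (including detritus)", "throughput_cycled_incl",
     "g/m^2/year", "flow"),
    ("Predator cycling index", "predator_cycling_index", "%", "sig3"),
    ("Finn's cycling index (FCI)", "FCI", "%", "sig3"),
    ("Finn's mean path length (FML)", "FML", "", "sig3"),
    ("Finn's straight-through path length (excluding detritus)",
     "straight_path_excl", "", "sig3"),
    ("Finn's straight-through path length (including detritus)",
     "straight_path_incl", "", "sig3"),
    ("Connectance Index (CI)", "CI", "", "dec3"),
    ("System Omnivory Index (SOI)", "SOI", "", "dec3"),
    ("Shannon diversity index", "shannon_diversity", "", "dec3"),
    ("Capacity (C)", "capacity", "Flowbits", "flow"),
    ("Ascendency (A)", "ascendency", "Flowbits", "flow"),
    ("Ascendency/Capacity (A/C)", "AC_pct", "%", "dec1"),
)


def format_value(value: float, kind: str) -> str:
    """Format one statistic to its printed precision class ('-' if undefined)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "-"
    if kind == "flow":
        return f"{value:.0f}" if abs(value) >= 100 else f"{value:.3g}"
    if kind == "sig3":
        return f"{value:.3g}"
    if kind.startswith("dec"):
        return f"{value:.{int(kind[3:])}f}"
    raise ValueError(f"unknown precision class {kind!r}")


def render_stats_table(stats_list: list[SystemStatistics], fmt: str = "csv") -> str:
    """The summary-statistics table, one column per model."""
    cols = {}
    for i, s in enumerate(stats_list):
        name = s.name or f"model_{i + 1}"
        cols[name] = [format_value(getattr(s, attr), kind)
                      for _, attr, _, kind in STAT_ROWS]
    df = pd.DataFrame(cols, index=pd.Index([r[0] for r in STAT_ROWS], name="Parameter"))
    df.insert(0, "Unit", [r[2] for r in STAT_ROWS])
    if fmt == "csv":
        return df.to_csv()
    if fmt == "markdown":
        return df.to_markdown()
    raise ValueError(f"unknown format {fmt!r}")


ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]


def render_spine_text(spine: LindemanSpine, origin: str = "combined") -> str:
    """Text diagram of the Lindeman spine, one box per discrete level."""
    lines = []
    for k in spine.levels:
        inflow = spine.inflow.loc[k, origin]
        if inflow <= 0:
            lines.append(f"TL {ROMAN[k - 1]:>4}: -")
            continue
        te = spine.TE.loc[k, origin]
        te_s = "-" if math.isnan(te) else f"{te:.3g}%"
        lines.append(
            f"TL {ROMAN[k - 1]:>4}: inflow {inflow:10.4g}  TE {te_s}\n"
            f"         -> up {spine.flow_up.loc[k, origin]:.4g}"
            f" | export+catch {spine.export_catch.loc[k, origin]:.4g}"
            f" | resp {spine.respiration.loc[k, origin]:.4g}"
            f" | to detritus {spine.to_detritus.loc[k, origin]:.4g}"
        )
    if spine.remainder > 1e-9:
        lines.append(f"(unapportioned consumption beyond level cap: {spine.remainder:.4g})")
    return "\n".join(lines)


def render_budget_table(balanced: BalancedModel) -> str:
    """Per-group budget CSV (B, P, Q, R, EE, predation, unutilized production)."""
    return balanced.budget_table().to_csv(float_format="%.6g")


def export_flow_network(balanced: BalancedModel, tl: pd.Series | None = None) -> str:
    """Flow network in GML text (nodes carry B and TL, edges carry flow)."""
    from .trophic_analysis import fractional_trophic_levels

    if tl is None:
        tl = fractional_trophic_levels(balanced.model)
    names = balanced.names
    out = ["graph ["]
    out.append("  directed 1")
    for i, n in enumerate(names):
        out.append(
            f'  node [ id {i} label "{n}" biomass {balanced.B[n]:.6g} tl {tl[n]:.4f} ]'
        )
    T = balanced.flows.T
    for i, src in enumerate(names):
        for j, dst in enumerate(names):
            w = float(T.iloc[i, j])
            if w > 0:
                out.append(f"  edge [ source {i} target {j} flow {w:.6g} ]")
    out.append("]")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

#: index -> orientation used for maturity ranking; "high" = larger is more
#: mature, "unit" = closer to 1 is more mature
DEFAULT_MATURITY_INDICES: dict[str, str] = {
    "FCI": "high",
    "FML": "high",
    "SOI": "high",
    "CI": "high",
    "shannon_diversity": "high",
    "TST": "high",
    "TPP_TR": "unit",
}


@dataclass
class ComparisonReport:
    models: list[str]
    ranks: pd.DataFrame          # model x index, 1 = most mature
    composite: pd.Series         # weighted Borda points, higher = more mature
    ties: list[tuple[str, str, str]] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def ordering(self) -> list[str]:
        return list(self.composite.sort_values(ascending=False).index)


def compare_models(
    stats_list: list[SystemStatistics],
    weights: dict[str, float] | None = None,
) -> ComparisonReport:
    """Rank models per maturity index and by a weighted Borda composite."""
    if len(stats_list) < 2:
        raise ValueError("need at least two models to compare")
    names = []
    for i, s in enumerate(stats_list):
        names.append(s.name or f"model_{i + 1}")
    indices = dict(DEFAULT_MATURITY_INDICES)
    w = {k: 1.0 for k in indices}
    if weights:
        w.update(weights)

    ranks = {}
    ties: list[tuple[str, str, str]] = []
    skipped: list[str] = []
    for idx, orientation in indices.items():
        vals = []
        for s in stats_list:
            v = getattr(s, idx, math.nan)
            if orientation == "unit" and not math.isnan(v) and v > 0:
                v = -abs(math.log(v))
            vals.append(v)
        if any(math.isnan(v) for v in vals):
            skipped.append(idx)
            continue
        ser = pd.Series(vals, index=names)
        # higher value -> better rank (1); ties broken by model name order
        order = sorted(names, key=lambda n: (-ser[n], names.index(n)))
        r = pd.Series({n: i + 1 for i, n in enumerate(order)})
        for a in names:
            for b in names:
                if a < b and ser[a] == ser[b]:
                    ties.append((idx, a, b))
        ranks[idx] = r
    rank_df = pd.DataFrame(ranks).reindex(names)
    n = len(names)
    # Borda points use average ranks so tied models score identically even
    # though the rank table breaks ties by model name order
    composite = pd.Series(0.0, index=names)
    for idx, orientation in indices.items():
        if idx not in rank_df.columns:
            continue
        vals = []
        for s in stats_list:
            v = getattr(s, idx, math.nan)
            if orientation == "unit" and not math.isnan(v) and v > 0:
                v = -abs(math.log(v))
            vals.append(v)
        avg_rank = pd.Series(vals, index=names).rank(ascending=False, method="average")
        composite += w.get(idx, 1.0) * (n - avg_rank)
    return ComparisonReport(
        models=names, ranks=rank_df, composite=composite, ties=ties, skipped=skipped
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_STAGES = ("solve", "stats", "spine", "impacts")


def run_pipeline(model_paths: list[str], config: dict) -> dict:
    """Run the configured stages for each model; returns the run manifest.

    Config keys: ``out_dir`` (required), ``stages`` (subset of solve, stats,
    spine, impacts, ensemble), ``seed``, ``auto_balance``, ``ensemble``
    (options for the Monte Carlo stage).  Artifacts are written per model;
    a failure in one stage aborts with a stage-labelled error and leaves
    artifacts of completed stages on disk.
    """
    out_dir = config.get("out_dir", "fwb_out")
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    seed = int(config.get("seed", 0))
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "stages": list(stages),
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "models": {},
        "artifacts": [],
    }

    def write(name: str, text: str) -> None:
        path = os.path.join(out_dir, name)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        manifest["artifacts"].append(name)

    stats_all: list[SystemStatistics] = []
    for path in model_paths:
        label = os.path.splitext(os.path.basename(str(path).rstrip("/")))[0]
        try:
            model = path if isinstance(path, ModelDefinition) else load_model(path)
        except Exception as exc:
            raise StageError("load", exc) from exc
        try:
            if config.get("auto_balance"):
                adj: AdjustmentResult = auto_adjust_diet(
                    model, max_iter=int(config.get("max_iter", 100))
                )
                model = adj.model
            balanced = solve_balance(model)
        except Exception as exc:
            raise StageError("solve", exc) from exc
        if "solve" in stages:
            write(f"{label}_budget.csv", render_budget_table(balanced))
            write(f"{label}_network.gml", export_flow_network(balanced))
        if "stats" in stages:
            try:
                stats = full_statistics(balanced, name=label)
            except Exception as exc:
                raise StageError("stats", exc) from exc
            stats_all.append(stats)
        if "spine" in stages:
            try:
                spine = lindeman_spine(balanced)
                te = transfer_efficiencies(spine)
            except Exception as exc:
                raise StageError("spine", exc) from exc
            write(f"{label}_spine.txt", render_spine_text(spine))
            write(f"{label}_te.csv", te.to_csv(float_format="%.6g"))
        if "impacts" in stages:
            try:
                imp = impact_analysis(balanced)
            except Exception as exc:
                raise StageError("impacts", exc) from exc
            write(f"{label}_mti.csv", imp.M.to_csv(float_format="%.6g"))
            ks = pd.DataFrame(
                {
                    "epsilon": imp.epsilon,
                    "relative_total_impact": imp.relative_total_impact,
                    "KS": imp.KS,
                }
            )
            write(f"{label}_ks.csv", ks.to_csv(float_format="%.6g"))
        if "ensemble" in stages:
            opts = dict(config.get("ensemble", {}))
            cv = opts.pop("cv", {"B": 10, "PB": 10, "QB": 10})
            try:
                ens = monte_carlo(
                    model, cv,
                    n_total=int(opts.pop("n_total", 1000)),
                    n_keep=int(opts.pop("n_keep", 50)),
                    seed=seed,
                )
            except Exception as exc:
                raise StageError("ensemble", exc) from exc
            doc = {
                "n_total": ens.n_total,
                "n_accepted": ens.n_accepted,
                "n_keep": ens.n_keep,
                "seed": ens.seed,
                "acceptance_rate": ens.acceptance_rate,
                "param_mean": ens.param_mean.to_dict(),
                "param_sd": ens.param_sd.to_dict(),
            }
            write(f"{label}_ensemble.json", json.dumps(doc, indent=1, sort_keys=True))
        manifest["models"][label] = str(path)

    if "stats" in stages and stats_all:
        write("stats.csv", render_stats_table(stats_all))
        if len(stats_all) >= 2:
            cmp_ = compare_models(stats_all)
            write(
                "comparison.csv",
                cmp_.ranks.assign(composite=cmp_.composite).to_csv(),
            )
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
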