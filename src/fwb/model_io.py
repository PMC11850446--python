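"""Canonical data model and I/O for mass-balance food-web definitions.

A model is a list of functional groups (producers, consumers, detritus) with
their rate parameters, plus a diet-composition matrix ``DC`` whose entry
``DC[prey, predator]`` is the fraction of the predator's diet taken from that
prey.  Two on-disk representations are supported:

* a CSV pair (``groups.csv`` + ``diet.csv``) — diet oriented prey-rows ×
  predator-columns, matching the conventional DC_ij subscript order;
* a single structured JSON or YAML document.

Unset parameters (the quantities the solver is asked for) are stored as
``None`` in memory and serialized as an empty cell or ``NA`` — never 0, which
is a legal measured value.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CONSUMER",
    "PRODUCER",
    "DETRITUS",
    "FunctionalGroup",
    "DietMatrix",
    "ModelDefinition",
    "Violation",
    "ValidationReport",
    "ModelIOError",
    "load_model",
    "save_model",
    "validate_model",
]

CONSUMER = "consumer"
PRODUCER = "producer"
DETRITUS = "detritus"
GROUP_TYPES = (CONSUMER, PRODUCER, DETRITUS)

#: numeric per-group parameter columns, in canonical file order
PARAM_COLUMNS = ("B", "PB", "QB", "EE", "UC", "Y", "NM", "BA", "R", "detritus_import")
#: parameter classes that can carry pedigree confidence scores
PEDIGREE_PARAMS = ("B", "PB", "QB", "DC", "Y")

#: diet columns whose sum is off by at most this much are silently accepted
DIET_SUM_TOL = 1e-6
#: ... and off by at most this much are renormalized with a warning
DIET_RENORM_TOL = 1e-3

IMPORT_ROW = "import"


class ModelIOError(ValueError):
    """Structural problem while reading or writing a model."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FunctionalGroup:
    """One biomass compartment of the web.

    Units: B in g/m^2 (wet weight); PB (production/biomass) and QB
    (consumption/biomass) in /yr; Y (catch), NM (net migration), BA (biomass
    accumulation) and detritus_import in g/m^2/yr; EE and UC dimensionless.
    ``None`` means unset (e.g. EE left for the solver).
    """

    name: str
    group_type: str = CONSUMER
    B: float | None = None
    PB: float | None = None
    QB: float | None = None
    EE: float | None = None
    UC: float | None = None
    Y: float = 0.0
    NM: float = 0.0
    BA: float = 0.0
    R: float | None = None          # optional measured respiration (producers)
    detritus_import: float = 0.0    # external detritus inflow (detritus groups)
    pedigree_scores: dict[str, float] = field(default_factory=dict)

    @property
    def is_living(self) -> bool:
        return self.group_type != DETRITUS

    @property
    def is_consumer(self) -> bool:
        return self.group_type == CONSUMER

    def copy(self) -> "FunctionalGroup":
        return replace(self, pedigree_scores=dict(self.pedigree_scores))


@dataclass
class DietMatrix:
    """Diet composition DC (prey rows × predator columns) plus diet imports.

    ``DC.loc[i, j]`` is the proportion of prey ``i`` in predator ``j``'s diet;
    each consumer column plus its import fraction sums to 1.
    """

    DC: pd.DataFrame
    import_fraction: pd.Series

    @classmethod
    def empty(cls, prey_names: list[str], predator_names: list[str]) -> "DietMatrix":
        dc = pd.DataFrame(0.0, index=list(prey_names), columns=list(predator_names))
        imp = pd.Series(0.0, index=list(predator_names))
        return cls(dc, imp)

    def copy(self) -> "DietMatrix":
        return DietMatrix(self.DC.copy(), self.import_fraction.copy())

    def column_sum(self, predator: str) -> float:
        return float(self.DC[predator].sum() + self.import_fraction[predator])


@dataclass
class ModelDefinition:
    """An unsolved model: groups, diet matrix and free-form metadata."""

    groups: list[FunctionalGroup]
    diet: DietMatrix
    metadata: dict = field(default_factory=dict)

    # -- conveniences -------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    def __getitem__(self, name: str) -> FunctionalGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def by_type(self, group_type: str) -> list[FunctionalGroup]:
        return [g for g in self.groups if g.group_type == group_type]

    @property
    def consumers(self) -> list[FunctionalGroup]:
        return self.by_type(CONSUMER)

    @property
    def producers(self) -> list[FunctionalGroup]:
        return self.by_type(PRODUCER)

    @property
    def detritus_groups(self) -> list[FunctionalGroup]:
        return self.by_type(DETRITUS)

    @property
    def living(self) -> list[FunctionalGroup]:
        return [g for g in self.groups if g.is_living]

    def copy(self) -> "ModelDefinition":
        return ModelDefinition(
            [g.copy() for g in self.groups], self.diet.copy(), dict(self.metadata)
        )


@dataclass
class Violation:
    severity: str          # "error" | "warning"
    group: str | None
    field: str
    observed: object
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"{self.group}.{self.field}" if self.group else self.field
        return f"[{self.severity}] {where} = {self.observed!r}: {self.rule}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(v.severity == "error" for v in self.violations)

    def __bool__(self) -> bool:
        return self.ok

    def __len__(self) -> int:
        return len(self.violations)

    def __iter__(self):
        return iter(self.violations)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _is_set(x) -> bool:
    return x is not None and not (isinstance(x, float) and math.isnan(x))


def validate_model(model: ModelDefinition) -> ValidationReport:
    """Check every type invariant; returns a report, never raises on content."""
    out: list[Violation] = []

    def err(group, field_, observed, rule):
        out.append(Violation("error", group, field_, observed, rule))

    names = model.names
    seen = set()
    for n in names:
        if n in seen:
            err(n, "name", n, "duplicate group name")
        seen.add(n)
    if not model.groups:
        err(None, "groups", 0, "model has no groups")

    for g in model.groups:
        if g.group_type not in GROUP_TYPES:
            err(g.name, "group_type", g.group_type, "unknown group type")
        for f_ in ("B", "PB", "QB"):
            v = getattr(g, f_)
            if _is_set(v) and v < 0:
                err(g.name, f_, v, f"{f_} must be >= 0")
        if _is_set(g.EE) and g.EE < 0:
            err(g.name, "EE", g.EE, "EE must be unset or >= 0")
        if _is_set(g.UC) and not (0 <= g.UC < 1):
            err(g.name, "UC", g.UC, "UC outside [0,1)")
        if g.group_type in (PRODUCER, DETRITUS):
            if _is_set(g.QB) and g.QB != 0:
                err(g.name, "QB", g.QB, "non-consumers have no QB")
            if _is_set(g.UC) and g.UC != 0:
                err(g.name, "UC", g.UC, "non-consumers have no UC")
        if g.group_type == DETRITUS and _is_set(g.PB) and g.PB != 0:
            err(g.name, "PB", g.PB, "detritus has no PB")
        if g.group_type != DETRITUS and g.detritus_import:
            err(g.name, "detritus_import", g.detritus_import,
                "detritus import only on detritus groups")
        for p, s in g.pedigree_scores.items():
            if not (0 <= s <= 1):
                err(g.name, f"pedigree[{p}]", s, "pedigree score outside [0,1]")

    # diet matrix
    dc = model.diet.DC
    if list(dc.index) != names:
        err(None, "diet", list(dc.index), "diet rows must match group order")
    consumer_names = [g.name for g in model.consumers]
    extra = [c for c in dc.columns if c not in names]
    if extra:
        err(None, "diet", extra, "diet column references unknown group")
    for g in model.groups:
        col = dc[g.name] if g.name in dc.columns else None
        if g.is_consumer:
            if col is None:
                err(g.name, "diet", None, "consumer missing diet column")
                continue
            if (col < -1e-12).any() or (col > 1 + 1e-12).any():
                err(g.name, "diet", col[(col < 0) | (col > 1)].to_dict(),
                    "diet entries outside [0,1]")
            imp = float(model.diet.import_fraction.get(g.name, 0.0))
            if not (0 <= imp <= 1 + 1e-12):
                err(g.name, "import_fraction", imp, "import fraction outside [0,1]")
            total = float(col.sum()) + imp
            if abs(total - 1.0) > DIET_SUM_TOL:
                err(g.name, "diet", total, "diet column not normalized")
        else:
            if col is not None and (col != 0).any():
                err(g.name, "diet", float(col.sum()),
                    "producer/detritus columns must be absent or all-zero")
    return ValidationReport(out)


def renormalize_diet(model: ModelDefinition, tol: float = DIET_RENORM_TOL) -> None:
    """Renormalize consumer diet columns off by at most ``tol`` (in place).

    Field tables are usually hand-rounded; columns farther off than ``tol``
    are left alone for :func:`validate_model` to flag.
    """
    for g in model.consumers:
        if g.name not in model.diet.DC.columns:
            continue
        total = model.diet.column_sum(g.name)
        if total > 0 and DIET_SUM_TOL < abs(total - 1.0) <= tol:
            warnings.warn(
                f"diet column {g.name!r} sums to {total:.6f}; renormalized",
                stacklevel=2,
            )
            model.diet.DC[g.name] /= total
            model.diet.import_fraction[g.name] /= total


# ---------------------------------------------------------------------------
# CSV pair
# ---------------------------------------------------------------------------

def _cell(v) -> str:
    return "" if not _is_set(v) else repr(float(v))


def _groups_frame(model: ModelDefinition) -> pd.DataFrame:
    rows = []
    for g in model.groups:
        row = {"name": g.name, "group_type": g.group_type}
        for c in PARAM_COLUMNS:
            row[c] = getattr(g, c)
        for p in PEDIGREE_PARAMS:
            if p in g.pedigree_scores:
                row[f"ped_{p}"] = g.pedigree_scores[p]
        rows.append(row)
    return pd.DataFrame(rows)


def _save_csv_pair(model: ModelDefinition, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    gf = _groups_frame(model)
    # repr round-trips doubles exactly; empty string is the unset sentinel
    num_cols = [c for c in gf.columns if c not in ("name", "group_type")]
    for c in num_cols:
        gf[c] = gf[c].map(_cell)
    gf.to_csv(os.path.join(path, "groups.csv"), index=False)

    dc = model.diet.DC.copy()
    consumer_names = [g.name for g in model.consumers]
    dc = dc[consumer_names] if consumer_names else dc.iloc[:, :0]
    dc.loc[IMPORT_ROW] = model.diet.import_fraction.reindex(consumer_names).fillna(0.0)
    dc = dc.map(lambda v: repr(float(v)))
    dc.to_csv(os.path.join(path, "diet.csv"), index_label="prey")


def _parse_number(v, where: str) -> float | None:
    if v is None:
        return None
    s = str(v).strip()
    if s == "" or s.upper() in ("NA", "NAN"):
        return None
    try:
        return float(s)
    except ValueError:
        raise ModelIOError(f"non-numeric cell at {where}: {v!r}") from None


def _load_csv_pair(path: str) -> ModelDefinition:
    gpath = os.path.join(path, "groups.csv")
    dpath = os.path.join(path, "diet.csv")
    if not os.path.exists(gpath):
        raise ModelIOError(f"missing groups table {gpath}")
    gf = pd.read_csv(gpath, dtype=str, keep_default_na=False)
    if "name" not in gf.columns or "group_type" not in gf.columns:
        raise ModelIOError("groups.csv must have 'name' and 'group_type' columns")

    groups: list[FunctionalGroup] = []
    for _, row in gf.iterrows():
        name = str(row["name"]).strip()
        if not name:
            raise ModelIOError("empty group name in groups.csv")
        g = FunctionalGroup(name=name, group_type=str(row["group_type"]).strip())
        for c in PARAM_COLUMNS:
            if c in gf.columns:
                v = _parse_number(row[c], f"groups.csv[{name}][{c}]")
                if v is not None:
                    setattr(g, c, v)
        for p in PEDIGREE_PARAMS:
            col = f"ped_{p}"
            if col in gf.columns:
                v = _parse_number(row[col], f"groups.csv[{name}][{col}]")
                if v is not None:
                    g.pedigree_scores[p] = v
        # absent Y/NM/BA columns mean 0 (defaults), but absent B/PB/... mean unset
        groups.append(g)

    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ModelIOError(f"duplicate group names: {dupes}")

    consumer_names = [g.name for g in groups if g.group_type == CONSUMER]
    diet = DietMatrix.empty(names, consumer_names)
    if os.path.exists(dpath):
        df = pd.read_csv(dpath, index_col=0)
        for c in df.columns:
            if c not in names:
                raise ModelIOError(f"diet column references unknown group {c!r}")
        for r in df.index:
            if r != IMPORT_ROW and r not in names:
                raise ModelIOError(f"diet row references unknown group {r!r}")
        for c in df.columns:
            for r in df.index:
                v = _parse_number(df.loc[r, c], f"diet.csv[{r}][{c}]") or 0.0
                if r == IMPORT_ROW:
                    diet.import_fraction[c] = v
                else:
                    diet.DC.loc[r, c] = v
    model = ModelDefinition(groups, diet, {"source": os.path.abspath(path)})
    renormalize_diet(model)
    return model


# ---------------------------------------------------------------------------
# structured JSON/YAML
# ---------------------------------------------------------------------------

def _to_document(model: ModelDefinition) -> dict:
    doc: dict = {"metadata": {k: v for k, v in model.metadata.items() if k != "source"}}
    doc["groups"] = []
    for g in model.groups:
        entry: dict = {"name": g.name, "group_type": g.group_type}
        for c in PARAM_COLUMNS:
            v = getattr(g, c)
            if _is_set(v):
                entry[c] = float(v)
        if g.pedigree_scores:
            entry["pedigree_scores"] = dict(g.pedigree_scores)
        doc["groups"].append(entry)
    diet: dict = {}
    for g in model.consumers:
        col = {
            prey: float(v)
            for prey, v in model.diet.DC[g.name].items()
            if v != 0
        }
        imp = float(model.diet.import_fraction.get(g.name, 0.0))
        if imp:
            col[IMPORT_ROW] = imp
        diet[g.name] = col
    doc["diet"] = diet
    return doc


def _from_document(doc: dict, source: str) -> ModelDefinition:
    if not isinstance(doc, dict) or "groups" not in doc:
        raise ModelIOError(f"{source}: document must contain a 'groups' list")
    groups = []
    for entry in doc["groups"]:
        if "name" not in entry:
            raise ModelIOError(f"{source}: group without a name")
        g = FunctionalGroup(
            name=str(entry["name"]),
            group_type=str(entry.get("group_type", CONSUMER)),
        )
        for c in PARAM_COLUMNS:
            if c in entry and entry[c] is not None:
                v = entry[c]
                if not isinstance(v, (int, float)):
                    raise ModelIOError(f"{source}: non-numeric {c} for {g.name}: {v!r}")
                setattr(g, c, float(v))
        g.pedigree_scores = {
            str(k): float(v) for k, v in entry.get("pedigree_scores", {}).items()
        }
        groups.append(g)
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ModelIOError("duplicate group names")
    consumer_names = [g.name for g in groups if g.group_type == CONSUMER]
    diet = DietMatrix.empty(names, consumer_names)
    for pred, col in (doc.get("diet") or {}).items():
        if pred not in consumer_names:
            raise ModelIOError(f"diet column references unknown consumer {pred!r}")
        for prey, v in (col or {}).items():
            if prey == IMPORT_ROW:
                diet.import_fraction[pred] = float(v)
            elif prey in names:
                diet.DC.loc[prey, pred] = float(v)
            else:
                raise ModelIOError(f"diet for {pred!r} references unknown prey {prey!r}")
    model = ModelDefinition(groups, diet, dict(doc.get("metadata") or {}))
    renormalize_diet(model)
    return model


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _infer_format(path: str) -> str:
    if os.path.isdir(path):
        return "csv-pair"
    ext = os.path.splitext(path)[1].lower()
    if ext in (".json", ".yaml", ".yml"):
        return "structured"
    raise ModelIOError(f"cannot infer model format from {path!r}")


def load_model(path: str, format: str | None = None) -> ModelDefinition:
    """Read a model from a CSV pair directory or a JSON/YAML document."""
    fmt = format or _infer_format(path)
    if fmt == "csv-pair":
        return _load_csv_pair(path)
    if fmt == "structured":
        if not os.path.exists(path):
            raise ModelIOError(f"no such file: {path}")
        with open(path, encoding="utf-8") as fh:
            if path.lower().endswith(".json"):
                doc = json.load(fh)
            else:
                doc = yaml.safe_load(fh)
        return _from_document(doc, path)
    raise ModelIOError(f"unknown format {fmt!r}")


def save_model(model: ModelDefinition, path: str, format: str | None = None) -> None:
    """Write a model so that :func:`load_model` inverts it exactly."""
    if not model.groups:
        raise ModelIOError("refusing to save a model with no groups")
    fmt = format
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = "structured" if ext in (".json", ".yaml", ".yml") else "csv-pair"
    if fmt == "csv-pair":
        _save_csv_pair(model, path)
    elif fmt == "structured":
        doc = _to_document(model)
        with open(path, "w", encoding="utf-8") as fh:
            if path.lower().endswith(".json"):
                json.dump(doc, fh, indent=1)
            else:
                yaml.safe_dump(doc, fh, sort_keys=False)
    else:
        raise ModelIOError(f"unknown format {fmt!r}")
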