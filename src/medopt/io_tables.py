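"""Delimited-text readers/writers for component tables and datasets.

The on-disk dataset format is a wide CSV/TSV: one row per medium, the id
column, one fold column per component in design-space order, per-timepoint
replicate and mean A450 columns, then ``round`` and ``mode`` metadata.  A
*dialect* config (YAML-able mapping) absorbs foreign layouts — renamed
component columns, absolute concentrations instead of folds, different
timepoint column patterns — so externally produced tables (e.g. exports of
published supplementary spreadsheets) can be loaded against a declared
design space without editing the files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .dataset import CultureObservation, Dataset
from .design import DesignSpace, MediumCombination, canonical_fold

__all__ = [
    "Dialect",
    "LoadReport",
    "read_component_table",
    "write_component_table",
    "read_dataset",
    "write_dataset",
    "save_oracle",
    "load_oracle",
]

_REP_RE = re.compile(r"^A450_(?P<t>[0-9.]+)h_rep(?P<rep>\d+)$")
_MEAN_RE = re.compile(r"^A450_(?P<t>[0-9.]+)h_mean$")


@dataclass
class Dialect:
    """Column-name mapping between a file and the in-memory model.

    component_columns maps file column -> component name (identity by
    default); values are ``"fold"`` or ``"absolute"`` (absolute
    concentrations are divided by the component baselines on load).
    """

    id_column: str = "id"
    round_column: str = "round"
    mode_column: str = "mode"
    values: str = "fold"
    component_columns: Dict[str, str] = field(default_factory=dict)
    sep: str = ","

    def __post_init__(self):
        if self.values not in ("fold", "absolute"):
            raise ValueError("values must be 'fold' or 'absolute'")

    @classmethod
    def from_yaml(cls, path) -> "Dialect":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class LoadReport:
    warnings: list[str] = field(default_factory=list)
    bad_rows: list[tuple[str, str]] = field(default_factory=list)  # (row id, reason)

    @property
    def ok(self) -> bool:
        return not self.bad_rows


def read_component_table(path, sep: str = ",") -> pd.DataFrame:
    """Component-spec table: name, baseline, unit, levels (';'-separated), fixed, role."""
    return pd.read_csv(path, sep=sep)


def write_component_table(table: pd.DataFrame, path, sep: str = ",") -> None:
    table.to_csv(path, sep=sep, index=False)


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_dataset(dataset: Dataset, path, dialect: Optional[Dialect] = None) -> None:
    """Write a dataset as delimited text with a deterministic column order.

    Columns: id, components in space order (folds, 12 significant digits),
    per-timepoint replicate then mean A450 columns ascending in time, then
    round and mode.  Missing replicate cells are left empty.  Two writes of
    the same dataset are byte-identical.
    """
    dialect = dialect or Dialect()
    names = dataset.space.names
    timepoints = dataset.timepoints
    max_reps = max((dataset.observation(i).n_replicates for i in dataset.ids), default=0)

    cols = [dialect.id_column] + list(names)
    for t in timepoints:
        cols += [f"A450_{t:g}h_rep{r}" for r in range(1, max_reps + 1)]
        cols.append(f"A450_{t:g}h_mean")
    cols += [dialect.round_column, dialect.mode_column]

    rows = []
    for i in dataset.ids:
        combo = dataset.combination(i)
        obs = dataset.observation(i)
        row: dict = {dialect.id_column: i}
        for name, fold in zip(names, combo.folds):
            row[name] = _fmt(canonical_fold(fold))
        for t in timepoints:
            if t in obs.blanked:
                for r, v in enumerate(obs.blanked[t], start=1):
                    row[f"A450_{t:g}h_rep{r}"] = _fmt(float(v))
                row[f"A450_{t:g}h_mean"] = _fmt(float(obs.mean[t]))
        row[dialect.round_column] = dataset.round_label(i)
        row[dialect.mode_column] = dataset.mode(i)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=cols)
    frame.to_csv(path, sep=dialect.sep, index=False)


def read_dataset(
    path, space: DesignSpace, dialect: Optional[Dialect] = None
) -> tuple[Dataset, LoadReport]:
    """Load a dataset table against a design space.

    Unknown columns are reported as warnings; rows that fail validation are
    collected into the report (with reasons) rather than silently dropped.
    Raises if a component of the space has no column in the file, or if no
    A450 column can be mapped at all.
    """
    dialect = dialect or Dialect()
    frame = pd.read_csv(path, sep=dialect.sep)
    report = LoadReport()

    colmap = dict(dialect.component_columns)  # file column -> component
    for name in space.names:
        if name not in colmap.values() and name in frame.columns:
            colmap[name] = name
    mapped = set(colmap.values())
    missing = [n for n in space.names if n not in mapped]
    if missing:
        raise ValueError(f"unmappable component columns: {missing}")
    by_component = {comp: col for col, comp in colmap.items()}

    rep_cols: dict[float, list[str]] = {}
    mean_cols: dict[float, str] = {}
    known = {dialect.id_column, dialect.round_column, dialect.mode_column} | set(colmap)
    for col in frame.columns:
        if col in known:
            continue
        m = _REP_RE.match(col)
        if m:
            rep_cols.setdefault(float(m.group("t")), []).append(col)
            continue
        m = _MEAN_RE.match(col)
        if m:
            mean_cols[float(m.group("t"))] = col
            continue
        report.warnings.append(f"unmapped column {col!r} ignored")
    if not rep_cols and not mean_cols and len(frame) > 0:
        raise ValueError("no A450 columns found (missing timepoint data)")

    dataset = Dataset(space)
    baselines = {c.name: c.baseline for c in space.components}
    for idx, row in frame.iterrows():
        rid = str(row[dialect.id_column]) if dialect.id_column in frame.columns else f"row{idx}"
        try:
            folds = []
            for name in space.names:
                v = float(row[by_component[name]])
                if dialect.values == "absolute":
                    v = v / baselines[name]
                folds.append(v)
            combo = MediumCombination(folds=tuple(folds), id=rid)
            raw: dict = {}
            blanked: dict = {}
            mean: dict = {}
            n_reps = 0
            for t in sorted(set(rep_cols) | set(mean_cols)):
                vals = []
                for col in sorted(rep_cols.get(t, [])):
                    v = row[col]
                    if pd.notna(v) and str(v).strip() != "":
                        vals.append(float(v))
                if vals:
                    blanked[t] = np.array(vals)
                    raw[t] = np.array(vals)  # raw plate values are not stored on disk
                    mean[t] = float(np.mean(vals))
                    n_reps = max(n_reps, len(vals))
                elif t in mean_cols and pd.notna(row[mean_cols[t]]):
                    m = float(row[mean_cols[t]])
                    blanked[t] = np.array([m])
                    raw[t] = np.array([m])
                    mean[t] = m
                    n_reps = max(n_reps, 1)
            if not mean:
                raise ValueError("row has no A450 observation")
            # pad ragged timepoints so replicate counts are consistent per row
            for t in blanked:
                if len(blanked[t]) < n_reps:
                    pad = np.full(n_reps - len(blanked[t]), np.nan)
                    blanked[t] = np.concatenate([blanked[t], pad])
                    raw[t] = np.concatenate([raw[t], pad])
                    mean[t] = float(np.nanmean(blanked[t]))
            obs = CultureObservation(
                combination_id=rid, raw=raw, blanked=blanked, mean=mean, n_replicates=n_reps
            )
            rnd = str(row.get(dialect.round_column, "initial"))
            mode = str(row.get(dialect.mode_column, "regular"))
            dataset.add(combo, obs, round_label=rnd, mode=mode)
        except (ValueError, KeyError) as exc:
            report.bad_rows.append((rid, str(exc)))
    return dataset, report


# ---------------------------------------------------------------------------
# Oracle (de)serialization
# ---------------------------------------------------------------------------

def save_oracle(oracle, path) -> None:
    """Round-trippable YAML serialization of oracle parameters."""
    from dataclasses import asdict as _asdict

    from .culture_sim import OracleParams

    assert isinstance(oracle, OracleParams)
    payload = {
        "r0": oracle.r0,
        "K0": oracle.K0,
        "n0": oracle.n0,
        "osmo_weights": dict(oracle.osmo_weights),
        "osmo_threshold": oracle.osmo_threshold,
        "osmo_alpha": oracle.osmo_alpha,
        "nadph_modifiers": dict(oracle.nadph_modifiers),
        "assay_scale": oracle.assay_scale,
        "blank_a450": oracle.blank_a450,
        "noise_sd_mult": oracle.noise_sd_mult,
        "noise_sd_add": oracle.noise_sd_add,
        "timepoints": list(oracle.timepoints),
        "multiplier_cap": oracle.multiplier_cap,
        "rng_seed": oracle.rng_seed,
        "effects": {k: _asdict(v) for k, v in oracle.effects.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_oracle(path, space: DesignSpace):
    from .culture_sim import ComponentEffect, OracleParams

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    effects = {k: ComponentEffect(**v) for k, v in raw.pop("effects", {}).items()}
    raw["timepoints"] = tuple(raw.get("timepoints", (48.0, 96.0, 144.0, 168.0)))
    return OracleParams(space=space, effects=effects, **raw)
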