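"""Configuration, CSV dataset I/O and JSON report serialization.

Tabular data is plain CSV with a header row (RFC-4180, "." decimal): the
method operates on already-extracted plot/cell tables, so no raster or
point-cloud formats are involved.  Unit columns are omitted on disk and
re-added on load.  Dataset schemas by role:

    s_i.csv   : y, x   (field response + field covariate)
    s_ii.csv  : x, z   (field covariate + intermediate RS covariate)
    s_iii.csv : z, p   (intermediate + final-phase covariate)
    p_u.csv   : p      (final-phase covariate, wall-to-wall or sample)

Reports are emitted as JSON with a full configuration echo so that every
run is replayable from its own report.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .superpop import SuperpopulationSpec
from .datagen import FixedDesigns, HierarchicalDatasets

__all__ = [
    "RunSettings",
    "RunConfig",
    "load_config",
    "load_datasets",
    "write_datasets",
    "emit_report",
    "render_validation_table",
]

_SCHEMAS = {"s_i": ("y", "x"), "s_ii": ("x", "z"), "s_iii": ("z", "p"), "p_u": ("p",)}


@dataclass(frozen=True)
class RunSettings:
    n_reps: int = 10_000
    seed: int = 0
    modes: tuple = ("3phmb", "3phhy")
    include_traces: bool = True
    output: str | None = None


@dataclass(frozen=True)
class RunConfig:
    """Parsed run configuration: a superpopulation block or an io block, plus run settings."""

    spec: SuperpopulationSpec | None
    dataset_paths: dict | None
    run: RunSettings
    population_size: int | None = None  # N for hybrid runs on user data
    source: str | None = None


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Exactly one of the ``superpopulation`` and ``io`` blocks must be
    present; unknown keys are rejected at every level.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - {"superpopulation", "run", "io"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys: {sorted(unknown)}")
    has_spec = "superpopulation" in raw
    has_io = "io" in raw
    if has_spec == has_io:
        raise ValueError(
            f"{path}: exactly one of the 'superpopulation' and 'io' blocks must drive a run"
        )

    spec = SuperpopulationSpec.from_dict(raw["superpopulation"]) if has_spec else None

    run_raw = dict(raw.get("run") or {})
    unknown = set(run_raw) - {"n_reps", "seed", "modes", "include_traces", "output"}
    if unknown:
        raise ValueError(f"{path}: unknown run keys: {sorted(unknown)}")
    if "modes" in run_raw:
        run_raw["modes"] = tuple(run_raw["modes"])
    run = RunSettings(**run_raw)

    paths = None
    pop_size = None
    if has_io:
        io_raw = dict(raw["io"])
        unknown = set(io_raw) - set(_SCHEMAS) - {"N"}
        if unknown:
            raise ValueError(f"{path}: unknown io keys: {sorted(unknown)}")
        missing = set(_SCHEMAS) - set(io_raw)
        if missing:
            raise ValueError(f"{path}: missing io dataset paths: {sorted(missing)}")
        pop_size = int(io_raw.pop("N")) if "N" in io_raw else None
        paths = {k: str((path.parent / v) if not Path(v).is_absolute() else v)
                 for k, v in io_raw.items()}

    return RunConfig(spec=spec, dataset_paths=paths, run=run,
                     population_size=pop_size, source=str(path))


def _read_table(path, role: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{role} dataset not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty {role} dataset") from exc
    if df.empty:
        raise ValueError(f"{path}: empty {role} dataset")
    for col in _SCHEMAS[role]:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}' required for {role}")
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            line = int(numeric.isna().idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: non-numeric value in column '{col}' near line {line}")
        df[col] = numeric.astype(float)
    return df


def load_datasets(paths: dict) -> tuple[HierarchicalDatasets, FixedDesigns]:
    """Read the four CSV datasets and rebuild designs and responses.

    Unit columns are re-added; generating moments are recorded as the
    empirical column moments (the true ones are unknown for user data).
    """
    frames = {role: _read_table(paths[role], role) for role in _SCHEMAS}

    def with_unit(col: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(len(col)), col])

    designs = FixedDesigns(
        X_I=with_unit(frames["s_i"]["x"].to_numpy()),
        Z_II=with_unit(frames["s_ii"]["z"].to_numpy()),
        P_III=with_unit(frames["s_iii"]["p"].to_numpy()),
        P_U=with_unit(frames["p_u"]["p"].to_numpy()),
        generating_moments={
            name: (float(frames[role][name].mean()), float(frames[role][name].std(ddof=1)))
            for role, name in (("s_i", "x"), ("s_ii", "z"), ("p_u", "p"))
        },
    )
    data = HierarchicalDatasets(
        y_I=frames["s_i"]["y"].to_numpy(),
        X_II=with_unit(frames["s_ii"]["x"].to_numpy()),
        Z_III=with_unit(frames["s_iii"]["z"].to_numpy()),
        iteration_seed=None,
    )
    return data, designs


def write_datasets(
    designs: FixedDesigns, data: HierarchicalDatasets, outdir, spec: SuperpopulationSpec | None = None
) -> dict:
    """Write the four datasets as CSV (plus the config used, if given)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "s_i": pd.DataFrame({"y": data.y_I, "x": designs.X_I[:, 1]}),
        "s_ii": pd.DataFrame({"x": data.X_II[:, 1], "z": designs.Z_II[:, 1]}),
        "s_iii": pd.DataFrame({"z": data.Z_III[:, 1], "p": designs.P_III[:, 1]}),
        "p_u": pd.DataFrame({"p": designs.P_U[:, 1]}),
    }
    paths = {}
    for role, df in tables.items():
        p = outdir / f"{role}.csv"
        df.to_csv(p, index=False)
        paths[role] = str(p)
    if spec is not None:
        cfg = outdir / "config.yaml"
        with open(cfg, "w") as fh:
            yaml.safe_dump({"superpopulation": spec.as_dict()}, fh, sort_keys=False)
        paths["config"] = str(cfg)
    return paths


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "as_dict"):
        return _jsonable(obj.as_dict())
    return obj


def emit_report(report, path, extra: dict | None = None) -> dict:
    """Serialize a report (anything with ``as_dict``, or a dict) to JSON.

    The payload carries the package version and a timestamp; two runs with
    the same seed differ only in the timestamp field.
    """
    from . import __version__

    payload = _jsonable(report)
    if not isinstance(payload, dict):
        payload = {"report": payload}
    if extra:
        payload.update(_jsonable(extra))
    payload["triphase_version"] = __version__
    payload["written_at"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    return payload


def render_validation_table(report) -> str:
    """Text table mirroring the validation layout: V, V_MC, V_hat per mode,
    followed by the trace-contribution lines."""
    d = report.as_dict() if hasattr(report, "as_dict") else report
    modes = d["config"]["modes"]
    header = f"{'predictor':>10} {'V (analytic)':>14} {'V_MC (empirical)':>18} {'V_hat (mean est.)':>18}"
    lines = [header, "-" * len(header)]
    label = {"3phmb": "3pHMB", "3phhy": "3pHHY"}
    for m in modes:
        lines.append(
            f"{label.get(m, m):>10} {d['analytic_variance'][m]:>14.4f} "
            f"{d['empirical_variance'][m]:>18.4f} {d['mean_estimated_variance'][m]:>18.4f}"
        )
    lines.append("")
    lines.append(f"{'predictor':>10} {'top-level trace %':>18} {'all traces %':>14}")
    lines.append("-" * 46)
    for m in modes:
        lines.append(
            f"{label.get(m, m):>10} {d['trace_relative_contribution'][m]:>17.4e}% "
            f"{d['trace_relative_contribution_all'][m]:>13.4e}%"
        )
    return "\n".join(lines)
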