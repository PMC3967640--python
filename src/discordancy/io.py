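"""File formats: results tables, configuration files, plain data arrays.

Results are stored long-form, one row per (n, contamination parameter,
test, quantity), with a ``#``-prefixed metadata header carrying
everything needed to reproduce the run (M, E, confidence, base seed,
software version).  Numbers are written at full double precision with a
locale-independent decimal point, so a write/read round trip is
bit-exact.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .contamination import ContaminationKind, ContaminationSpec
from .runner import CellSummary, ExperimentGrid
from .stats import TestId

__all__ = [
    "ResultsTable",
    "summaries_to_table",
    "write_results",
    "read_results",
    "load_config",
    "read_data_array",
    "comparison_table",
]

_COLUMNS = ["n", "kind", "parameter", "test", "quantity", "mean", "u99"]
_FLOAT_FORMAT = "%.17g"


class ResultsFormatError(ValueError):
    """Malformed results file."""


@dataclass
class ResultsTable:
    """Long-form simulation results plus run metadata."""

    frame: pd.DataFrame
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ResultsFormatError(f"results frame missing columns {sorted(missing)}")


def summaries_to_table(
    summaries: Sequence[CellSummary], grid: ExperimentGrid
) -> ResultsTable:
    rows = []
    for s in summaries:
        for q in s.quantities:
            rows.append(
                {
                    "n": s.n,
                    "kind": s.spec.kind.value,
                    "parameter": s.spec.parameter,
                    "test": s.test.value,
                    "quantity": q,
                    "mean": s.means[q],
                    "u99": s.u99[q],
                }
            )
    meta = {
        "M": grid.M,
        "E": grid.E,
        "confidence": grid.confidence,
        "base_seed": grid.base_seed,
        "version": __version__,
    }
    return ResultsTable(frame=pd.DataFrame(rows, columns=_COLUMNS), metadata=meta)


def write_results(table: ResultsTable, path) -> Path:
    path = Path(path)
    buf = _io.StringIO()
    for key, value in table.metadata.items():
        buf.write(f"# {key} = {value}\n")
    table.frame.to_csv(buf, index=False, float_format=_FLOAT_FORMAT)
    path.write_text(buf.getvalue())
    return path


def read_results(path) -> ResultsTable:
    path = Path(path)
    metadata: dict[str, object] = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        try:
            key, value = line.lstrip("# ").split(" = ", 1)
        except ValueError:
            raise ResultsFormatError(f"{path}:{i + 1}: malformed metadata line {line!r}")
        metadata[key] = _parse_scalar(value)
    else:
        raise ResultsFormatError(f"{path}: no table body found")
    body = lines[body_start:]
    if not body or body[0].split(",") != _COLUMNS:
        raise ResultsFormatError(
            f"{path}:{body_start + 1}: expected header {','.join(_COLUMNS)!r}"
        )
    frame = pd.read_csv(
        _io.StringIO("\n".join(body)),
        float_precision="round_trip",
        dtype={"n": int, "parameter": float, "mean": float, "u99": float},
    )
    return ResultsTable(frame=frame, metadata=metadata)


def _parse_scalar(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


_CONFIG_KEYS = {
    "n_values",
    "kind",
    "parameter_values",
    "tests",
    "M",
    "E",
    "confidence",
    "base_seed",
}
_CONFIG_DEFAULTS = {
    "tests": ["N2", "N8", "N14", "N15"],
    "M": 1_000_000,
    "E": 10,
    "confidence": 0.99,
    "base_seed": 0,
}


def load_config(path) -> ExperimentGrid:
    """Parse a flat key-value (YAML) config into a validated grid.

    Required keys: ``n_values``, ``kind`` (location | scale) and
    ``parameter_values`` (delta or epsilon values; 0 and +/-1 denote the
    uncontaminated model).  Optional keys with defaults: ``tests`` (all
    four), ``M`` (10^6), ``E`` (10), ``confidence`` (0.99),
    ``base_seed`` (0).  Unknown keys are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path}: expected a flat key-value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
    for key in ("n_values", "kind", "parameter_values"):
        if key not in raw:
            raise ValueError(f"config {path}: missing required key {key!r}")
    cfg = {**_CONFIG_DEFAULTS, **raw}
    kind = ContaminationKind(cfg["kind"])
    n_values = cfg["n_values"]
    if not isinstance(n_values, (list, tuple)):
        n_values = [n_values]
    params = cfg["parameter_values"]
    if not isinstance(params, (list, tuple)):
        params = [params]
    specs = tuple(ContaminationSpec.from_parameter(kind, v) for v in params)
    return ExperimentGrid(
        n_values=tuple(n_values),
        contamination_specs=specs,
        tests=tuple(TestId(t) for t in cfg["tests"]),
        M=int(cfg["M"]),
        E=int(cfg["E"]),
        confidence=float(cfg["confidence"]),
        base_seed=int(cfg["base_seed"]),
    )


def read_data_array(path) -> list[float]:
    """Read a plain-text data array, one number per line; '#' comments allowed."""
    values = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        try:
            values.append(float(text))
        except ValueError:
            raise ValueError(f"{path}:{i}: not a number: {text!r}")
    return values


def comparison_table(table: ResultsTable, quantity: str) -> pd.DataFrame:
    """Pivot a long-form results table into a wide comparison table.

    One row per (n, parameter); per-test mean and u99 columns plus
    percent-difference columns relative to the reference test N2 (when
    N2 is present in the results).
    """
    sub = table.frame[table.frame["quantity"] == quantity]
    if sub.empty:
        raise ValueError(f"no rows for quantity {quantity!r}")
    wide = sub.pivot_table(
        index=["n", "kind", "parameter"],
        columns="test",
        values=["mean", "u99"],
    )
    out = pd.DataFrame(index=wide.index)
    tests = [t.value for t in TestId if ("mean", t.value) in wide.columns]
    for t in tests:
        out[f"mean_{t}"] = wide[("mean", t)]
        out[f"u99_{t}"] = wide[("u99", t)]
    if "N2" in tests:
        for t in tests:
            if t == "N2":
                continue
            # NaN where the reference mean is zero (empty cell at tiny M)
            out[f"delta_pct_{t}"] = [
                (mj - m2) / m2 * 100.0 if m2 else float("nan")
                for mj, m2 in zip(out[f"mean_{t}"], out["mean_N2"])
            ]
    return out.reset_index()
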