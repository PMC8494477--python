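"""Tabular readers and JSON writers used by the command-line interface.

Input conventions: comma-separated UTF-8 CSV with a header row.  Binary
outcome tables carry one row per unit with a ``significant`` column of
0/1 values; effect tables carry a numeric ``effect`` column.  Summaries
are written as JSON with a fixed schema so that any run can be reproduced
from its own output (inputs + seed are echoed verbatim).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .core import PosteriorSummary, TestResultCounts
from .differences import DifferenceSummary

__all__ = [
    "RunConfig",
    "read_binary_outcomes",
    "read_effects",
    "write_summary",
    "summary_to_dict",
]

SUMMARY_SCHEMA_FIELDS = ("command", "inputs", "seed", "samples", "map", "hpdi", "hpdi_mass")


@dataclass(frozen=True)
class RunConfig:
    """Provenance record for one analysis run."""

    command: str
    parameters: Mapping[str, Any] = field(default_factory=dict)
    seed: int | None = None
    samples: int | None = None
    hpdi_mass: float = 0.96
    output_path: str | None = None


class ParseError(ValueError):
    """A CSV input failed validation."""


def read_binary_outcomes(path: str | Path, alpha: float) -> TestResultCounts:
    """Read per-unit binary test outcomes and reduce to (k, n, alpha).

    Expects a CSV with a ``significant`` column of 0/1 values, one row per
    unit; ``alpha`` (the within-unit false positive rate) is supplied by
    the caller since it is a property of the test, not of the data.
    """
    df = _read_csv(path)
    if "significant" not in df.columns:
        raise ParseError(f"{path}: missing required column 'significant'")
    col = df["significant"]
    numeric = pd.to_numeric(col, errors="coerce")
    bad = numeric.isna() | ~numeric.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{path}: row {row + 2} has non-binary 'significant' value {col.iloc[row]!r}"
        )
    return TestResultCounts(k=int(numeric.sum()), n=len(df), alpha=alpha)


def read_effects(path: str | Path) -> np.ndarray:
    """Read a per-unit ``effect`` column, preserving row order."""
    df = _read_csv(path)
    if "effect" not in df.columns:
        raise ParseError(f"{path}: missing required column 'effect'")
    values = pd.to_numeric(df["effect"], errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ParseError(
            f"{path}: row {row + 2} has non-finite 'effect' value "
            f"{df['effect'].iloc[row]!r}"
        )
    return values


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")
    return df


def summary_to_dict(
    summary: PosteriorSummary | DifferenceSummary, config: RunConfig
) -> dict[str, Any]:
    """Serialise a summary plus its provenance into the fixed JSON schema."""
    extras: dict[str, Any] = {}
    if isinstance(summary, PosteriorSummary):
        extras["lower_bounds"] = {str(k): v for k, v in summary.lower_bounds.items()}
    else:
        extras["n_samples"] = summary.n_samples
    doc = {
        "command": config.command,
        "inputs": dict(config.parameters),
        "seed": config.seed,
        "samples": config.samples,
        "map": summary.map,
        "hpdi": [summary.hpdi_lo, summary.hpdi_hi],
        "hpdi_mass": summary.hpdi_mass,
        "extras": extras,
    }
    return doc


def write_summary(
    summary: PosteriorSummary | DifferenceSummary,
    config: RunConfig,
    path: str | Path,
) -> None:
    """Write the JSON summary document to ``path`` at full float precision."""
    doc = summary_to_dict(summary, config)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def validate_summary_dict(doc: Mapping[str, Any]) -> None:
    """Check a summary document against the fixed schema; raise on failure."""
    missing = [f for f in SUMMARY_SCHEMA_FIELDS if f not in doc]
    if missing:
        raise ParseError(f"summary document missing fields: {missing}")
    hpdi = doc["hpdi"]
    if not (isinstance(hpdi, (list, tuple)) and len(hpdi) == 2):
        raise ParseError("summary field 'hpdi' must be a [lo, hi] pair")
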