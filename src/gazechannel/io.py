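"""Fixation-table I/O and measure-table output.

The fixation CSV dialect is a plain comma-separated, UTF-8, dot-decimal
table with the header columns

    observer_id, stimulus_id, onset_s, duration_ms, x_px, y_px

one row per fixation, modelled on typical eye-tracker fixation exports.
Stimulus pixel dimensions are supplied separately through a manifest
mapping ``stimulus_id -> [width, height]`` (a dict or a JSON file).
"""

from __future__ import annotations

import json
import logging
import math
import sys
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .channel import MEASURE_COLUMNS
from .types import Fixation, ScanPath

logger = logging.getLogger("gazechannel")
if not logger.handlers:  # per-stage info lines go to stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("gazechannel: %(message)s"))
    logger.addHandler(_h)

REQUIRED_COLUMNS = ["observer_id", "stimulus_id", "onset_s", "duration_ms", "x_px", "y_px"]
_NUMERIC = ["onset_s", "duration_ms", "x_px", "y_px"]

SUMMARY_LABELS = ("Average Value", "Standard Deviation")


def load_manifest(source: str | Path | Mapping) -> dict[str, tuple[int, int]]:
    """Normalize a stimulus-dimension manifest (dict or JSON file path)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = json.load(fh)
    return {str(k): (int(v[0]), int(v[1])) for k, v in source.items()}


def _parse_numeric(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in _NUMERIC:
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() & out[col].notna()
        if bad.any():
            # +2: one for the header row, one for 1-based line numbers
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"unparseable value {out[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {line}"
            )
        out[col] = parsed
    return out


def scanpaths_from_frame(
    df: pd.DataFrame, width: int, height: int
) -> list[ScanPath]:
    """Group a fixation table with uniform stimulus size into scanpaths."""
    manifest = {sid: (width, height) for sid in df["stimulus_id"].astype(str).unique()}
    return _group_paths(df, manifest)


def _group_paths(df: pd.DataFrame, manifest: dict[str, tuple[int, int]]) -> list[ScanPath]:
    paths = []
    for (obs, stim), grp in df.groupby(["observer_id", "stimulus_id"], sort=True):
        stim = str(stim)
        if stim not in manifest:
            raise ValueError(f"unknown stimulus dimensions for {stim!r}; add it to the manifest")
        w, h = manifest[stim]
        grp = grp.sort_values("onset_s", kind="stable")
        fixations = [
            Fixation(
                onset=float(r.onset_s),
                duration=float(r.duration_ms),
                x=float(r.x_px),
                y=float(r.y_px),
                observer_id=str(obs),
                stimulus_id=stim,
            )
            for r in grp.itertuples()
        ]
        paths.append(ScanPath(fixations=fixations, stimulus_width=w, stimulus_height=h))
    return paths


def read_fixations(
    path: str | Path, manifest: str | Path | Mapping
) -> list[ScanPath]:
    """Read a fixation CSV into scanpaths, one per (observer, stimulus).

    Rows are sorted by onset within each group. Missing columns,
    unparseable numeric fields (reported with their line number) and
    unknown stimulus dimensions raise ``ValueError``; an empty file
    yields an empty list with a warning.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fixation table is missing column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("fixation file %s has a header but no rows", path)
        return []
    df = _parse_numeric(df)
    paths = _group_paths(df, load_manifest(manifest))
    logger.info("read %d fixations into %d scanpaths from %s",
                len(df), len(paths), path)
    return paths


def write_fixations(paths: list[ScanPath], path: str | Path) -> None:
    """Write scanpaths back to the fixation CSV dialect."""
    rows = [
        {
            "observer_id": f.observer_id,
            "stimulus_id": f.stimulus_id,
            "onset_s": f.onset,
            "duration_ms": f.duration,
            "x_px": f.x,
            "y_px": f.y,
        }
        for p in paths
        for f in p.fixations
    ]
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)


def summarize_measures(df: pd.DataFrame) -> pd.DataFrame:
    """Append 'Average Value' and 'Standard Deviation' rows.

    The SD is the population standard deviation (divisor n), matching how
    summary rows of clustered gaze-measure tables are conventionally
    reported alongside small fixed sets of stimuli or observers.
    """
    numeric = df.select_dtypes(include=[np.number]).columns
    mean_row = {c: df[c].mean() for c in numeric}
    sd_row = {c: df[c].std(ddof=0) for c in numeric}
    label_col = df.columns[0]
    mean_row[label_col], sd_row[label_col] = SUMMARY_LABELS
    return pd.concat([df, pd.DataFrame([mean_row, sd_row])], ignore_index=True)


def ordered_measure_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Reorder columns: id columns, canonical measure columns, extras."""
    ids = [c for c in df.columns if c not in MEASURE_COLUMNS and df[c].dtype == object]
    core = [c for c in MEASURE_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ids and c not in core]
    return df[ids + core + extra]


def write_measures(
    df: pd.DataFrame,
    path: str | Path,
    format: str = "csv",
    summary: bool = False,
) -> None:
    """Write a measure table as CSV or JSON records.

    Column order is deterministic — H(X), H(X|Y), H(X,Y), I(X;Y),
    normalized MI, then any aesthetics columns — and ``summary=True``
    appends mean and population-SD rows. Values survive a CSV round
    trip to at least 12 significant digits.
    """
    if df.empty:
        raise ValueError("refusing to write an empty measure table")
    out = ordered_measure_frame(df)
    if summary:
        out = summarize_measures(out)
    if format == "csv":
        out.to_csv(path, index=False, float_format="%.12g")
    elif format == "json":
        records = out.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump({"columns": list(out.columns), "rows": records}, fh, indent=2)
    else:
        raise ValueError(f"unknown format {format!r}: use 'csv' or 'json'")
    logger.info("wrote %d rows to %s", len(out), path)


def validate_measures_json(path: str | Path) -> dict:
    """Validate the JSON layout produced by :func:`write_measures`.

    Checks the {"columns": [...], "rows": [...]} envelope, that every row
    holds exactly the declared columns, and that measure fields are
    numbers (NaN allowed). Returns the parsed document.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if set(doc) != {"columns", "rows"}:
        raise ValueError("measure JSON must have exactly 'columns' and 'rows'")
    cols = doc["columns"]
    if not isinstance(cols, list) or not all(isinstance(c, str) for c in cols):
        raise ValueError("'columns' must be a list of strings")
    for k, row in enumerate(doc["rows"]):
        if set(row) != set(cols):
            raise ValueError(f"row {k} fields do not match the declared columns")
        for c in cols:
            v = row[c]
            if c in MEASURE_COLUMNS and not (
                isinstance(v, (int, float)) or v is None
            ):
                raise ValueError(f"row {k} column {c!r} is not numeric")
            if isinstance(v, float) and math.isinf(v):
                raise ValueError(f"row {k} column {c!r} is infinite")
    return doc
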