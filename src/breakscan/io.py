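"""Readers and writers for every table the pipeline touches.

Formats are deliberately plain: delimited text for probe signal, BED-like
TSV for segments, CSV for cohorts, YAML for configuration.  All loaders
validate their invariants up front and either reject offending rows with a
logged message or raise, so that downstream numerics never see malformed
input.

Coordinate conventions
----------------------
Probe indices are 1-based inclusive internally.  Segment output follows the
BED contract: 0-based half-open base-pair intervals, so a segment spanning
probes at bp 100..500 is written as start 99, end 500.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

PROBE_COLUMNS = ("tumor_id", "chrom", "pos", "signal")
SEGMENT_COLUMNS = ("chrom", "start", "end", "tumor_id", "mean_signal", "n_probes")
COHORT_COLUMNS = (
    "patient_id",
    "breakpoint_count",
    "ki67_fraction",
    "ggi",
    "grade",
    "er10",
    "pr10",
    "dfi_time",
    "mfi_time",
    "dfi_event",
    "mfi_event",
)

#: Canonical within-tumor chromosome ordering: 1..22, X, Y.
CHROMOSOME_ORDER = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


class SchemaError(ValueError):
    """A required column is missing or a file is structurally unreadable."""


def chromosome_sort_key(label: str) -> tuple[int, str]:
    """Sort key implementing the 1..22, X, Y ordering (chr prefix tolerated)."""
    name = str(label)
    if name.lower().startswith("chr"):
        name = name[3:]
    try:
        return (CHROMOSOME_ORDER.index(name), name)
    except ValueError:
        return (len(CHROMOSOME_ORDER), name)


@dataclass(frozen=True)
class ProbeTrack:
    """Ordered probe positions and log-scale signal for one tumor chromosome.

    Invariants: ``positions`` strictly increasing, ``signal`` finite, and at
    least two probes (shorter tracks are not segmentable and are dropped at
    load time with a warning).
    """

    tumor_id: str
    chromosome: str
    positions: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=np.int64)
        signal = np.asarray(self.signal, dtype=np.float64)
        if positions.ndim != 1 or signal.ndim != 1 or len(positions) != len(signal):
            raise ValueError("positions and signal must be 1-D and equally long")
        if np.any(np.diff(positions) <= 0):
            raise ValueError("probe positions must be strictly increasing")
        if not np.all(np.isfinite(signal)):
            raise ValueError("probe signal must be finite")
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "signal", signal)

    @property
    def n_probes(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SegmentRecord:
    """One constant-mean segment; probe indices 1-based inclusive."""

    chromosome: str
    start_probe_index: int
    end_probe_index: int
    start_bp: int
    end_bp: int
    mean_signal: float

    @property
    def n_probes(self) -> int:
        return self.end_probe_index - self.start_probe_index + 1


def read_probe_table(path, dialect: dict | None = None) -> list[ProbeTrack]:
    """Read a per-probe signal table into one ProbeTrack per (tumor, chromosome).

    The file must contain the columns ``tumor_id, chrom, pos, signal``
    (TSV or CSV; the delimiter is sniffed unless ``dialect`` sets ``sep``).
    Rows are re-sorted by position, duplicate positions are collapsed to
    their mean with a logged warning, non-finite signal rows are dropped
    with a warning, and non-numeric signal entries raise with their line
    numbers.  Tumor order follows first appearance in the file; chromosomes
    within a tumor follow the canonical 1..22, X, Y ordering.
    """
    dialect = dict(dialect or {})
    sep = dialect.pop("sep", None)
    try:
        df = pd.read_csv(path, sep=sep, engine="python", dtype=str, **dialect)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: header-only probe table, no tracks loaded", path)
        return []

    signal = pd.to_numeric(df["signal"], errors="coerce")
    bad = signal.isna() & df["signal"].notna() & (df["signal"].str.strip() != "")
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header line + 1-based
        raise ValueError(f"{path}: non-numeric signal at line(s) {lines}")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    if pos.isna().any():
        lines = (df.index[pos.isna()] + 2).tolist()
        raise ValueError(f"{path}: non-numeric position at line(s) {lines}")
    df = df.assign(pos=pos.astype(np.int64), signal=signal.astype(float))

    nonfinite = ~np.isfinite(df["signal"])
    if nonfinite.any():
        logger.warning(
            "%s: dropped %d row(s) with non-finite signal", path, int(nonfinite.sum())
        )
        df = df[~nonfinite]

    tracks: list[ProbeTrack] = []
    tumor_order = df["tumor_id"].drop_duplicates().tolist()
    for tumor in tumor_order:
        sub = df[df["tumor_id"] == tumor]
        chroms = sorted(sub["chrom"].unique(), key=chromosome_sort_key)
        for chrom in chroms:
            grp = sub[sub["chrom"] == chrom].sort_values("pos")
            if grp["pos"].duplicated().any():
                n_dup = int(grp["pos"].duplicated().sum())
                logger.warning(
                    "%s: tumor %s chrom %s: averaged %d duplicated position(s)",
                    path,
                    tumor,
                    chrom,
                    n_dup,
                )
                grp = grp.groupby("pos", as_index=False)["signal"].mean()
            if len(grp) < 2:
                logger.warning(
                    "%s: tumor %s chrom %s: <2 probes, chromosome dropped",
                    path,
                    tumor,
                    chrom,
                )
                continue
            tracks.append(
                ProbeTrack(
                    tumor_id=str(tumor),
                    chromosome=str(chrom),
                    positions=grp["pos"].to_numpy(np.int64),
                    signal=grp["signal"].to_numpy(float),
                )
            )
    return tracks


def write_segments(profiles: Iterable, path) -> None:
    """Write segmented profiles as BED-like TSV (0-based half-open intervals).

    Columns: ``chrom, start, end, tumor_id, mean_signal, n_probes``.  Means
    are written with 17 significant digits so that a round-trip through
    :func:`read_segments` reproduces boundaries and means exactly.
    """
    rows = []
    for profile in profiles:
        for seg in profile.segments:
            rows.append(
                {
                    "chrom": seg.chromosome,
                    "start": seg.start_bp - 1,
                    "end": seg.end_bp,
                    "tumor_id": profile.tumor_id,
                    "mean_signal": seg.mean_signal,
                    "n_probes": seg.n_probes,
                }
            )
    out = pd.DataFrame(rows, columns=list(SEGMENT_COLUMNS))
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_segments(path) -> pd.DataFrame:
    """Read a BED-like segment table written by :func:`write_segments`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing segment column(s) {missing}")
    return df


def _validate_cohort_row(row: pd.Series) -> str | None:
    """Return a rejection reason for one cohort row, or None if valid."""
    if pd.isna(row["breakpoint_count"]) or row["breakpoint_count"] < 0:
        return "breakpoint_count missing or negative"
    if row["breakpoint_count"] != int(row["breakpoint_count"]):
        return "breakpoint_count not an integer"
    if not pd.isna(row["ki67_fraction"]) and not 0.0 <= row["ki67_fraction"] <= 1.0:
        return "ki67_fraction outside [0, 1]"
    if not pd.isna(row["grade"]) and row["grade"] not in (1, 2, 3):
        return "unknown grade level"
    for col in ("er10", "pr10"):
        if not pd.isna(row[col]) and not (0 <= row[col] <= 10 and row[col] == int(row[col])):
            return f"{col} outside 0-10"
    for col in ("dfi_time", "mfi_time"):
        if pd.isna(row[col]) or row[col] <= 0:
            return f"{col} missing or non-positive"
    for col in ("dfi_event", "mfi_event"):
        if row[col] not in (0, 1):
            return f"{col} not binary"
    return None


def read_cohort(path, on_invalid: str = "drop") -> pd.DataFrame:
    """Read and validate a per-patient cohort CSV.

    Each row carries the breakpoint count, proliferation covariates
    (``ki67_fraction`` in [0, 1], ``ggi``, ``grade`` in {1, 2, 3}, semi-
    quantitative ``er10``/``pr10`` in 0-10) and the two survival endpoints
    (disease-free and metastasis-free times in years with binary event
    flags).  Missing covariates stay as NaN and are never imputed.  Rows
    violating an invariant are dropped with a logged per-row message
    (``on_invalid='raise'`` raises instead).
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing cohort column(s) {missing}")
    for col in COHORT_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    reasons = df.apply(_validate_cohort_row, axis=1)
    bad = reasons.notna()
    if bad.any():
        for idx in df.index[bad]:
            msg = f"{path}: row {idx + 2} (patient {df.at[idx, 'patient_id']}): {reasons[idx]}"
            if on_invalid == "raise":
                raise ValueError(msg)
            logger.warning("rejected %s", msg)
        df = df[~bad]
    df = df.reset_index(drop=True)
    df["breakpoint_count"] = df["breakpoint_count"].astype(int)
    df["dfi_event"] = df["dfi_event"].astype(int)
    df["mfi_event"] = df["mfi_event"].astype(int)
    return df


@dataclass
class PipelineConfig:
    """Tunable parameters shared by the CLI commands."""

    k_max_cap: int = 60
    k_max_frac: float = 0.25
    threshold: int = 34
    ki67_rescale: float = 1.0
    seed: int = 0
    extra: dict = field(default_factory=dict)


def load_config(path) -> PipelineConfig:
    """Load a YAML config file into a :class:`PipelineConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {k: raw.pop(k) for k in list(raw) if k in PipelineConfig.__dataclass_fields__}
    cfg = PipelineConfig(**known)
    cfg.extra = raw
    return cfg
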