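"""File formats: evidence tables, MS1 point lists, result tables.

Evidence tables are tab-separated files patterned on search-engine output
(one row per identified precursor).  A declarative column-name map per
dialect translates foreign headers to the minimal internal schema; MaxQuant
evidence.txt names are supported out of the box and unknown extra columns
are ignored.

MS1 data are exchanged as a portable point list (frame_id, scan_time_min,
mz, inv_k0, intensity) in TSV or Parquet, one row per detected ion-mobility
resolved peak.  Vendor raw formats are out of scope; converting them to the
point list is the adapter's job.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("swaps")

#: Internal evidence schema -> accepted foreign (MaxQuant-dialect) headers.
#: The first match present in the file wins; the internal name itself is
#: always accepted.
EVIDENCE_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "modified_sequence": ("Modified sequence",),
    "charge": ("Charge",),
    "rt_obs": ("Calibrated retention time", "Retention time"),
    "rt_start": ("Calibrated retention time start",),
    "rt_end": ("Calibrated retention time finish",),
    "im_center": ("1/K0",),
    "im_length": ("1/K0 length",),
    "intensity": ("Intensity",),
    "species": ("Species", "Proteins"),
}

MANDATORY_EVIDENCE_COLUMNS = (
    "modified_sequence", "charge", "rt_obs", "rt_start", "rt_end",
    "im_center", "im_length", "intensity",
)


@dataclass
class EvidenceRecord:
    """One identified precursor from a search-engine evidence table."""

    modified_sequence: str
    charge: int
    rt_obs: float          # minutes
    rt_start: float        # minutes
    rt_end: float          # minutes
    im_center: float       # 1/K0, V*s/cm^2
    im_length: float       # 1/K0 units
    intensity: float
    species: str | None = None
    source: str = "experiment"  # "experiment" | "reference"

    def is_valid(self) -> bool:
        return (
            self.charge >= 1
            and self.im_length >= 0
            and self.intensity >= 0
            and self.rt_start <= self.rt_obs <= self.rt_end
        )


@dataclass
class Ms1Frame:
    """One MS1 scan: all ion-mobility resolved peaks of a complete ramp.

    ``points`` is an (n, 3) float array with columns (mz, 1/K0, intensity).
    """

    frame_id: int
    scan_time: float  # minutes
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) and (self.points[:, 0] <= 0).any():
            raise ValueError("all m/z values must be positive")


class SchemaError(ValueError):
    """An input table is missing a mandatory column."""


def _resolve_columns(header: Sequence[str]) -> dict[str, str]:
    resolved: dict[str, str] = {}
    for internal, aliases in EVIDENCE_COLUMN_MAP.items():
        for name in (internal, *aliases):
            if name in header:
                resolved[internal] = name
                break
    return resolved


def read_evidence_table(path: str | Path, source_tag: str = "experiment") -> list[EvidenceRecord]:
    """Parse an evidence TSV into records, dropping rows that violate the
    schema invariants (rt_start <= rt_obs <= rt_end, charge >= 1, ...).

    Raises :class:`SchemaError` naming the first missing mandatory column.
    """
    df = pd.read_csv(path, sep="\t")
    colmap = _resolve_columns(df.columns)
    for name in MANDATORY_EVIDENCE_COLUMNS:
        if name not in colmap:
            raise SchemaError(f"evidence table {path} is missing column {name!r}")
    records: list[EvidenceRecord] = []
    n_dropped = 0
    df = df.rename(columns={v: k for k, v in colmap.items()})
    species_col = "species" if "species" in colmap else None
    for row in df.to_dict(orient="records"):
        get = lambda k: row[k]  # noqa: E731
        try:
            rec = EvidenceRecord(
                modified_sequence=str(get("modified_sequence")),
                charge=int(get("charge")),
                rt_obs=float(get("rt_obs")),
                rt_start=float(get("rt_start")),
                rt_end=float(get("rt_end")),
                im_center=float(get("im_center")),
                im_length=float(get("im_length")),
                intensity=float(get("intensity")),
                species=None if species_col is None else str(row[species_col]),
                source=source_tag,
            )
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if not rec.is_valid() or any(
            not math.isfinite(v) for v in (rec.rt_obs, rec.rt_start, rec.rt_end,
                                           rec.im_center, rec.im_length, rec.intensity)
        ):
            n_dropped += 1
            continue
        records.append(rec)
    logger.info("stage=read_evidence path=%s in=%d out=%d dropped=%d",
                path, len(df), len(records), n_dropped)
    return records


def write_evidence_table(records: Iterable[EvidenceRecord], path: str | Path) -> None:
    rows = [
        {k: getattr(r, k) for k in ("modified_sequence", "charge", "rt_obs", "rt_start",
                                    "rt_end", "im_center", "im_length", "intensity", "species")}
        for r in records
    ]
    pd.DataFrame(rows, columns=["modified_sequence", "charge", "rt_obs", "rt_start",
                                "rt_end", "im_center", "im_length", "intensity",
                                "species"]).to_csv(path, sep="\t", index=False)


FRAME_COLUMNS = ("frame_id", "scan_time_min", "mz", "inv_k0", "intensity")


def read_frames(path: str | Path) -> list[Ms1Frame]:
    """Read an MS1 point list, grouping points into frames ordered by scan
    time.  Frame ids must be strictly increasing with scan time."""
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, sep="\t")
    missing = set(FRAME_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"point list {path} is missing columns {sorted(missing)}")
    if df.empty:
        return []
    per_frame = df.groupby("frame_id", sort=True)["scan_time_min"].first()
    if not per_frame.is_monotonic_increasing or per_frame.index.has_duplicates:
        raise ValueError("scan_time_min must increase strictly with frame_id")
    if df.groupby("frame_id")["scan_time_min"].nunique().max() > 1:
        raise ValueError("a frame_id maps to more than one scan_time_min")
    frames = [
        Ms1Frame(int(fid), float(sub["scan_time_min"].iloc[0]),
                 sub[["mz", "inv_k0", "intensity"]].to_numpy(dtype=float))
        for fid, sub in df.groupby("frame_id", sort=True)
    ]
    logger.info("stage=read_frames path=%s frames=%d points=%d", path, len(frames), len(df))
    return frames


def write_frames(frames: Iterable[Ms1Frame], path: str | Path) -> None:
    parts = []
    for f in frames:
        sub = pd.DataFrame(f.points, columns=["mz", "inv_k0", "intensity"])
        sub.insert(0, "scan_time_min", f.scan_time)
        sub.insert(0, "frame_id", f.frame_id)
        parts.append(sub)
    df = (pd.concat(parts, ignore_index=True) if parts
          else pd.DataFrame(columns=list(FRAME_COLUMNS)))
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, sep="\t", index=False)


RESULT_COLUMNS = (
    "sequence", "charge", "is_decoy", "inferred_intensity", "confidence",
    "passed_intensity_filter", "passed_tdc", "passed_signal_competition",
    "fdr_at_score",
)


def write_results(scored, fdr_table, path: str | Path) -> None:
    """Write the per-candidate report and the threshold/FDR table.

    ``path`` is a basename; two files are produced, ``<path>.candidates.tsv``
    and ``<path>.fdr.tsv``.  Floats are written with 6 significant digits so
    re-reading reproduces the values to that precision.
    """
    path = Path(path)
    rows = [
        {
            "sequence": c.modified_sequence,
            "charge": c.charge,
            "is_decoy": c.is_decoy,
            "inferred_intensity": c.inferred_intensity,
            "confidence": c.confidence,
            "passed_intensity_filter": c.passed_intensity_filter,
            "passed_tdc": c.passed_tdc,
            "passed_signal_competition": c.passed_signal_competition,
            "fdr_at_score": c.fdr_at_score,
        }
        for c in scored
    ]
    cand_path = Path(str(path) + ".candidates.tsv")
    fdr_path = Path(str(path) + ".fdr.tsv")
    pd.DataFrame(rows, columns=list(RESULT_COLUMNS)).to_csv(
        cand_path, sep="\t", index=False, float_format="%.6g")
    fdr_df = fdr_table.to_frame() if hasattr(fdr_table, "to_frame") else pd.DataFrame(fdr_table)
    fdr_df.to_csv(fdr_path, sep="\t", index=False, float_format="%.6g")
    logger.info("stage=write_results candidates=%d fdr_rows=%d out=%s",
                len(rows), len(fdr_df), path)


def read_results(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-read the two tables produced by :func:`write_results`."""
    return (
        pd.read_csv(str(path) + ".candidates.tsv", sep="\t"),
        pd.read_csv(str(path) + ".fdr.tsv", sep="\t"),
    )
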