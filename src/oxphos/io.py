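"""Readers and writers for the delimited formats the pipeline touches.

Segment files are tab-separated with columns ``chrom start end total_cn
major_cn`` and 1-based inclusive coordinates (SEG convention); internally
segments are 0-based half-open.  Abundance matrices are tab-separated with
``sample_id``, ``run``, then one column per protein; empty cells are
missing.  Images load as single-channel float arrays rescaled to [0, 1].
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .lst import CopyNumberProfile, SegmentRecord
from .prep import ProteinMatrix

SEGMENT_COLUMNS = ["chrom", "start", "end", "total_cn", "major_cn"]


def read_segments(path: str | Path) -> CopyNumberProfile:
    """Parse a SEG-style table into an internally 0-based half-open profile."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"segment file {path} lacks columns: {missing}")
    if df[["total_cn", "major_cn"]].isna().any().any():
        raise ValueError("segments with missing copy-number values are rejected")
    segments: dict[str, list[SegmentRecord]] = {}
    for row in df.itertuples(index=True):
        chrom = str(row.chrom)
        try:
            seg = SegmentRecord(
                chromosome=chrom,
                start=int(row.start) - 1,  # 1-based inclusive -> 0-based half-open
                end=int(row.end),
                total_cn=int(row.total_cn),
                major_cn=int(row.major_cn),
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {row.Index}: {exc}") from exc
        segments.setdefault(chrom, []).append(seg)
    try:
        return CopyNumberProfile(segments)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_segments(profile: CopyNumberProfile, path: str | Path) -> None:
    """Write a profile back to 1-based inclusive SEG-style text."""
    rows = [
        {
            "chrom": s.chromosome,
            "start": s.start + 1,
            "end": s.end,
            "total_cn": s.total_cn,
            "major_cn": s.major_cn,
        }
        for s in profile.all_segments()
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path) -> ProteinMatrix:
    """Read a samples x proteins abundance table with run labels."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "run": str})
    for col in ("sample_id", "run"):
        if col not in df.columns:
            raise ValueError(f"matrix file {path} lacks a '{col}' column")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")
    df = df.set_index("sample_id")
    runs = df.pop("run")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric abundance in {path}: {exc}") from exc
    return ProteinMatrix(values, runs)


def write_matrix(m: ProteinMatrix, path: str | Path, float_format: str = "%.10g") -> None:
    out = m.values.copy()
    out.insert(0, "run", m.runs)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=float_format)


def read_image(path: str | Path) -> np.ndarray:
    """Load a single-channel image as float64 rescaled to [0, 1]."""
    raw = np.asarray(iio.imread(path))
    img = raw
    if img.ndim == 3:
        if img.shape[2] not in (1, 3, 4):
            raise ValueError(f"unexpected image shape {img.shape}")
        img = img[..., 0] if img.shape[2] == 1 else img[..., :3].mean(axis=2)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    img = img.astype(float)
    if np.issubdtype(raw.dtype, np.integer):
        img = img / np.iinfo(raw.dtype).max
    return np.clip(img, 0.0, 1.0)
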