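"""Reading, writing and QC of per-cell fluorescence tables.

The measurement unit throughout is the AGV (average grey value): the mean
pixel fluorescence intensity of one segmented cell, in arbitrary camera
units.  Input is delimited text in one of two dialects:

* ``single-column`` — one numeric AGV per line, optional header; all cells
  are assigned to a synthetic image ``img1``.
* ``long-table`` — comma- or tab-separated columns including an image label,
  an optional cell label and the AGV (column names matched
  case-insensitively against {image, image_id}, {cell, cell_id},
  {agv, value, intensity}).

Because whole-image acquisition mistakes (wrong exposure, focus drift)
shift every cell in that image, the QC step summarizes each image by its
median and Tukey hinges and flags images whose median is a robust outlier
among the per-image medians.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .splitters import tukey_hinges

__all__ = [
    "CellRecord",
    "FluorescenceDataset",
    "ImageSummary",
    "read_agv_table",
    "write_agv_table",
    "summarize_by_image",
    "flag_biased_images",
    "qc_report",
]

logger = logging.getLogger(__name__)

_IMAGE_ALIASES = {"image", "image_id"}
_CELL_ALIASES = {"cell", "cell_id"}
_AGV_ALIASES = {"agv", "value", "intensity"}


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: image label, cell label, AGV."""

    image_id: str
    cell_id: str
    agv: float


@dataclass
class FluorescenceDataset:
    """Ordered per-cell AGV records, grouped by source image."""

    records: List[CellRecord]
    condition_label: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("no records")
        agv = np.array([r.agv for r in self.records], dtype=float)
        if not np.all(np.isfinite(agv)):
            raise ValueError("AGV values must be finite")
        if any(not r.image_id for r in self.records):
            raise ValueError("image_id must be non-empty")

    def __len__(self) -> int:
        return len(self.records)

    def agv_values(self) -> np.ndarray:
        """All AGVs in record order; splitters/descriptors consume this."""
        return np.array([r.agv for r in self.records], dtype=float)

    def image_ids(self) -> List[str]:
        """Distinct image labels, in order of first appearance."""
        seen: dict = {}
        for r in self.records:
            seen.setdefault(r.image_id, None)
        return list(seen)

    def by_image(self) -> dict:
        """Map image_id -> AGV array (record order preserved within image)."""
        groups: dict = {}
        for r in self.records:
            groups.setdefault(r.image_id, []).append(r.agv)
        return {k: np.array(v, dtype=float) for k, v in groups.items()}

    def subset_images(self, keep: Sequence[str]) -> "FluorescenceDataset":
        keep_set = set(keep)
        recs = [r for r in self.records if r.image_id in keep_set]
        return FluorescenceDataset(records=recs, condition_label=self.condition_label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": [r.image_id for r in self.records],
                "cell_id": [r.cell_id for r in self.records],
                "agv": [r.agv for r in self.records],
            }
        )


@dataclass
class ImageSummary:
    image_id: str
    n_cells: int
    median_agv: float
    hinge_lower: float
    hinge_upper: float
    flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "n_cells": self.n_cells,
            "median_agv": self.median_agv,
            "hinge_lower": self.hinge_lower,
            "hinge_upper": self.hinge_upper,
            "flagged": self.flagged,
        }


def _sniff_dialect(text: str) -> str:
    for line in text.splitlines():
        if line.strip():
            return "long-table" if ("," in line or "\t" in line) else "single-column"
    return "single-column"


def _parse_single_column(text: str, condition_label: str) -> FluorescenceDataset:
    records: List[CellRecord] = []
    cell_no = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        try:
            agv = float(line)
        except ValueError:
            if lineno == 1 and cell_no == 0:
                continue  # header line
            raise ValueError(f"non-numeric AGV at line {lineno}: {line!r}") from None
        cell_no += 1
        records.append(CellRecord(image_id="img1", cell_id=f"c{cell_no}", agv=agv))
    if not records:
        raise ValueError("no records")
    return FluorescenceDataset(records=records, condition_label=condition_label)


def _resolve_column(columns, aliases) -> Union[str, None]:
    for col in columns:
        if str(col).strip().lower() in aliases:
            return col
    return None


def _parse_long_table(text: str, condition_label: str) -> FluorescenceDataset:
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    img_col = _resolve_column(df.columns, _IMAGE_ALIASES)
    agv_col = _resolve_column(df.columns, _AGV_ALIASES)
    cell_col = _resolve_column(df.columns, _CELL_ALIASES)
    if agv_col is None:
        raise ValueError(
            f"missing AGV column; found columns {list(df.columns)} "
            f"(expected one of {sorted(_AGV_ALIASES)})"
        )
    if img_col is None:
        raise ValueError(
            f"missing image column; found columns {list(df.columns)} "
            f"(expected one of {sorted(_IMAGE_ALIASES)})"
        )
    records: List[CellRecord] = []
    images = df[img_col].astype(str).tolist()
    raws = df[agv_col].tolist()
    cells = df[cell_col].astype(str).tolist() if cell_col is not None else None
    for idx, raw in enumerate(raws):
        line_no = idx + 2  # +1 for header, +1 for 1-based lines
        if pd.isna(raw):
            raise ValueError(f"non-numeric AGV at line {line_no}: missing value")
        try:
            agv = float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric AGV at line {line_no}: {raw!r}") from None
        cell = cells[idx] if cells is not None else f"c{idx + 1}"
        records.append(CellRecord(image_id=images[idx], cell_id=cell, agv=agv))
    if not records:
        raise ValueError("no records")
    return FluorescenceDataset(records=records, condition_label=condition_label)


def read_agv_table(
    path: Union[str, Path],
    dialect: str = "auto",
    condition_label: str = "",
) -> FluorescenceDataset:
    """Read a per-cell AGV table.

    ``dialect`` is ``single-column``, ``long-table`` or ``auto`` (sniffed
    from the first non-empty line: any comma/tab means long-table).
    Raises ``ValueError`` for an empty file, a non-numeric AGV cell (the
    message names the offending line), or a long table lacking an AGV
    column (the message lists the columns found).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError("no records")
    if dialect == "auto":
        dialect = _sniff_dialect(text)
    if dialect == "single-column":
        return _parse_single_column(text, condition_label)
    if dialect == "long-table":
        return _parse_long_table(text, condition_label)
    raise ValueError(f"unknown dialect {dialect!r}; use 'single-column', 'long-table' or 'auto'")


def write_agv_table(ds: FluorescenceDataset, path: Union[str, Path]) -> None:
    """Write the long-table CSV dialect (image_id, cell_id, agv)."""
    ds.to_frame().to_csv(path, index=False)


def summarize_by_image(ds: FluorescenceDataset) -> List[ImageSummary]:
    """One median/Tukey-hinge summary per distinct image, in first-appearance order."""
    out: List[ImageSummary] = []
    for image_id, agv in ds.by_image().items():
        fns = tukey_hinges(agv)
        out.append(
            ImageSummary(
                image_id=image_id,
                n_cells=int(agv.size),
                median_agv=fns.median,
                hinge_lower=fns.hinge_lower,
                hinge_upper=fns.hinge_upper,
            )
        )
    return out


def flag_biased_images(
    ds: FluorescenceDataset, k: float = 3.0
) -> Tuple[FluorescenceDataset, List[ImageSummary]]:
    """Flag and drop images whose median AGV is a robust outlier.

    An image is flagged iff ``|median_i - grand_median| > k * MAD``, where
    the grand median and the MAD (median absolute deviation, scaled by
    1.4826 for consistency with the normal SD) are taken over the per-image
    medians.  With fewer than two images the check is a no-op.  Raises if
    every image would be flagged.

    Returns ``(filtered dataset, summaries of all images with flags set)``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    summaries = summarize_by_image(ds)
    if len(summaries) < 2:
        warnings.warn("fewer than 2 images; bias QC skipped", stacklevel=2)
        return ds, summaries

    medians = np.array([s.median_agv for s in summaries])
    grand = np.median(medians)
    # scipy's median_abs_deviation(scale='normal') equivalent, kept inline
    mad = 1.4826022185056018 * np.median(np.abs(medians - grand))
    for s in summaries:
        s.flagged = bool(abs(s.median_agv - grand) > k * mad)

    flagged = [s for s in summaries if s.flagged]
    if len(flagged) == len(summaries):
        raise ValueError("QC removed all data; lower k or inspect the per-image medians")
    logger.info(
        "image bias QC: %d/%d images flagged (k=%g, MAD=%g)",
        len(flagged), len(summaries), k, mad,
    )
    if not flagged:
        return ds, summaries
    keep = [s.image_id for s in summaries if not s.flagged]
    return ds.subset_images(keep), summaries


def qc_report(summaries: Sequence[ImageSummary], k: float, path: Union[str, Path, None] = None) -> dict:
    """Assemble (and optionally write) the per-image QC report as JSON."""
    report = {
        "k": k,
        "n_images": len(summaries),
        "n_flagged": sum(s.flagged for s in summaries),
        "images": [s.to_dict() for s in summaries],
    }
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report
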