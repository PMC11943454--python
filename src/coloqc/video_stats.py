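"""Per-frame pixel statistics, validity filtering, per-segment aggregation.

Each labeled frame is reduced to the percentage of its pixels in every
region.  A frame is *valid* when its artifact percentage is strictly below a
threshold (default 34%; 25% and 40% are the alternative scenarios).  Class
percentages per scope (whole video and the three colon segments) pool pixel
counts over valid frames only; the indicator counts — frames with more than
75% mucosa (well-visualised) and frames with more than 50% residues (poor
preparation) — are taken over all frames.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .color_features import RegionClass

DEFAULT_VALIDITY_THRESHOLD = 34.0
SCENARIO_THRESHOLDS = (25.0, 40.0, 34.0)
MUCOSA_EXCEEDANCE = 75.0
RESIDUE_EXCEEDANCE = 50.0

_CLASSES = list(RegionClass)


@dataclass
class FrameStats:
    """Class percentages over one frame's pixels and the validity flag."""

    pct: dict
    n_pixels: int
    valid: bool


@dataclass
class SegmentBoundaries:
    """1-based frame indices where segment 2 and segment 3 begin.

    Frames with index < ``cut_1_2`` belong to segment 1, indices in
    [cut_1_2, cut_2_3) to segment 2, and >= ``cut_2_3`` to segment 3.
    """

    cut_1_2: int
    cut_2_3: int

    def __post_init__(self) -> None:
        if not 1 < self.cut_1_2 < self.cut_2_3:
            raise ValueError("require 1 < cut_1_2 < cut_2_3")

    def segment_of(self, frame_index: int) -> int:
        if frame_index < self.cut_1_2:
            return 1
        if frame_index < self.cut_2_3:
            return 2
        return 3


@dataclass
class SegmentReport:
    total_frames: int
    valid_frames: int
    pct: dict  # pooled class percentages over valid frames
    n_frames_mucosa_over_75: int
    n_frames_residue_over_50: int


@dataclass
class VideoReport:
    overall: SegmentReport
    segments: list  # three SegmentReport
    validity_threshold: float


def frame_stats(
    labels: np.ndarray, threshold: float = DEFAULT_VALIDITY_THRESHOLD
) -> FrameStats:
    """Pixel percentages of one label map; valid iff artifact % < threshold."""
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("empty label map")
    n = arr.size
    counts = np.bincount(arr.ravel(), minlength=len(_CLASSES))
    pct = {c: 100.0 * counts[int(c)] / n for c in _CLASSES}
    return FrameStats(pct=pct, n_pixels=n, valid=pct[RegionClass.ARTIFACT] < threshold)


def _summarize(stats: Sequence[FrameStats]) -> SegmentReport:
    total = len(stats)
    valid = [s for s in stats if s.valid]
    pix = {c: 0.0 for c in _CLASSES}
    npix = 0
    for s in valid:
        for c in _CLASSES:
            pix[c] += s.pct[c] * s.n_pixels / 100.0
        npix += s.n_pixels
    pct = {c: (100.0 * pix[c] / npix if npix else float("nan")) for c in _CLASSES}
    return SegmentReport(
        total_frames=total,
        valid_frames=len(valid),
        pct=pct,
        n_frames_mucosa_over_75=sum(
            1 for s in stats if s.pct[RegionClass.MUCOSA] > MUCOSA_EXCEEDANCE
        ),
        n_frames_residue_over_50=sum(
            1 for s in stats if s.pct[RegionClass.RESIDUE] > RESIDUE_EXCEEDANCE
        ),
    )


def aggregate(
    stats: Sequence[FrameStats],
    bounds: SegmentBoundaries,
    validity_threshold: float = DEFAULT_VALIDITY_THRESHOLD,
) -> VideoReport:
    """Aggregate ordered per-frame statistics into whole-video and
    per-segment reports.  ``stats`` is ordered by 1-based frame index."""
    if not stats:
        raise ValueError("no frame statistics supplied")
    if not bounds.cut_2_3 <= len(stats):
        raise ValueError("segment boundaries fall outside the frame range")
    per_seg = {1: [], 2: [], 3: []}
    for i, s in enumerate(stats, start=1):
        per_seg[bounds.segment_of(i)].append(s)
    return VideoReport(
        overall=_summarize(stats),
        segments=[_summarize(per_seg[k]) for k in (1, 2, 3)],
        validity_threshold=validity_threshold,
    )


def _report_row(scope: str, r: SegmentReport) -> dict:
    row = {
        "scope": scope,
        "total_frames": r.total_frames,
        "valid_frames": r.valid_frames,
        "frames_mucosa_over_75": r.n_frames_mucosa_over_75,
        "frames_residue_over_50": r.n_frames_residue_over_50,
    }
    for c in _CLASSES:
        row[f"pct_{c.name.lower()}"] = r.pct[c]
    return row


def export_report(report: VideoReport, path: str | Path) -> None:
    """Write a report as CSV (one row per scope) plus a JSON summary."""
    path = Path(path)
    rows = [_report_row("overall", report.overall)] + [
        _report_row(f"segment_{i}", seg)
        for i, seg in enumerate(report.segments, start=1)
    ]
    with open(path.with_suffix(".csv"), "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(
            {"validity_threshold": report.validity_threshold, "scopes": rows},
            fh,
            indent=2,
        )


def read_report_csv(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        rows = []
        for row in csv.DictReader(fh):
            parsed = {"scope": row["scope"]}
            for k, v in row.items():
                if k == "scope":
                    continue
                parsed[k] = float(v) if k.startswith("pct_") else int(v)
            rows.append(parsed)
        return rows
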