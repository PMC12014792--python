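"""Blob texture analysis of grayscale frames.

Pipeline: pool the ROI pixels of the healthy group and take percentile
reference thresholds (95th/99th, linear interpolation between order
statistics) -> binarize each frame at each threshold (``>=`` keeps ties
as bright) -> label maximal connected components (8-connectivity by
default) -> per-frame metrics (count, total size in pixels and mm^2,
per-mm^2 normalisations, echointensity) -> per-subject arithmetic mean
over the three frames -> cohort table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import RoiMask, SubjectScan, UltrasoundFrame

PERCENTILE_LEVELS = (95, 99)
MIN_POOLED_PIXELS = 100

#: metrics.csv column order (per-frame and per-subject alike)
METRIC_COLUMNS = ["echointensity"] + [
    f"{name}_p{lvl}"
    for lvl in PERCENTILE_LEVELS
    for name in (
        "blob_count",
        "total_blob_size_px",
        "total_blob_size_mm2",
        "blob_count_per_mm2",
        "total_blob_size_per_mm2",
    )
]

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass(frozen=True)
class ThresholdSet:
    """Reference grayscale thresholds from the pooled healthy pixel distribution."""

    t95: float
    t99: float
    source_n_pixels: int
    percentile_definition: str = "linear interpolation between order statistics"

    def __post_init__(self) -> None:
        if not (0 <= self.t95 <= self.t99 <= 255):
            raise ValueError("thresholds must satisfy 0 <= t95 <= t99 <= 255")
        if self.source_n_pixels < MIN_POOLED_PIXELS:
            raise ValueError(
                f"pooled reference distribution too small ({self.source_n_pixels} < {MIN_POOLED_PIXELS})"
            )

    def by_level(self, level: int) -> float:
        return {95: self.t95, 99: self.t99}[level]


@dataclass(frozen=True)
class Blob:
    label: int
    size_px: int
    size_mm2: float
    centroid: tuple[float, float]


@dataclass
class FrameBlobReport:
    frame_id: str
    echointensity: float
    roi_area_mm2: float
    metrics: dict[str, float] = field(default_factory=dict)


def compute_echointensity(frame: UltrasoundFrame, roi: RoiMask) -> float:
    """Mean grayscale value over the ROI pixels."""
    _check_congruent(frame, roi)
    return float(frame.pixels[roi.mask].mean())


def pooled_roi_pixels(scans: list[SubjectScan]) -> np.ndarray:
    """Concatenate the ROI pixel values of every frame of every scan."""
    chunks = [frame.pixels[roi.mask] for scan in scans for frame, roi in scan.frames]
    if not chunks:
        return np.empty(0, dtype=np.uint8)
    return np.concatenate(chunks)


def reference_thresholds(
    healthy_scans: list[SubjectScan],
    percentiles: tuple[float, float] = PERCENTILE_LEVELS,
) -> ThresholdSet:
    """Percentile thresholds of the pooled healthy ROI grayscale distribution.

    The pooled definition makes the result invariant to subject order and
    to how pixels are split across frames.
    """
    if not healthy_scans:
        raise ValueError("no healthy subjects to derive reference thresholds from")
    non_healthy = [s.subject_id for s in healthy_scans if s.group != "healthy"]
    if non_healthy:
        raise ValueError(f"reference thresholds require healthy scans; got non-healthy: {non_healthy}")
    pooled = pooled_roi_pixels(healthy_scans)
    if pooled.size < MIN_POOLED_PIXELS:
        raise ValueError(f"pooled healthy ROI pixels below floor ({pooled.size} < {MIN_POOLED_PIXELS})")
    lo, hi = sorted(percentiles)
    t_lo, t_hi = np.percentile(pooled, [lo, hi])  # linear interpolation
    return ThresholdSet(t95=float(t_lo), t99=float(t_hi), source_n_pixels=int(pooled.size))


def binarize(frame: UltrasoundFrame, roi: RoiMask, threshold: float) -> np.ndarray:
    """1 where the pixel is in the ROI and its grayscale is >= threshold, else 0."""
    _check_congruent(frame, roi)
    return ((frame.pixels >= threshold) & roi.mask).astype(np.uint8)


def label_blobs(binary: np.ndarray, connectivity: int = 8) -> list[Blob]:
    """Partition 1-pixels into maximal connected components.

    Labels are 1..N in raster order of each component's first pixel.
    ``size_mm2`` is left at pixel units times 1.0 here; callers that know
    the spacing use :func:`frame_report`.
    """
    return _label_blobs(np.asarray(binary) != 0, connectivity, pixel_area_mm2=1.0)


def label_map(binary: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Labeled matrix (0 = background) with labels 1..N in raster order."""
    labels, sizes, order = _label_fast(np.asarray(binary) != 0, connectivity)
    if labels is None:
        return np.zeros(np.asarray(binary).shape, dtype=np.int32)
    remap = np.zeros(sizes.size + 1, dtype=np.int32)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return remap[labels]


def _label_blobs(binary: np.ndarray, connectivity: int, pixel_area_mm2: float) -> list[Blob]:
    labels, sizes, order = _label_fast(binary, connectivity)
    if labels is None:
        return []
    blobs: list[Blob] = []
    rows, cols = np.nonzero(labels)
    lab_of_px = labels[rows, cols]
    r_sum = np.bincount(lab_of_px, weights=rows, minlength=sizes.size + 1)
    c_sum = np.bincount(lab_of_px, weights=cols, minlength=sizes.size + 1)
    for new_label, old in enumerate(order, start=1):
        n = int(sizes[old - 1])
        blobs.append(
            Blob(
                label=new_label,
                size_px=n,
                size_mm2=n * pixel_area_mm2,
                centroid=(r_sum[old] / n, c_sum[old] / n),
            )
        )
    return blobs


def _label_fast(binary: np.ndarray, connectivity: int):
    """scipy labeling + sizes; ``order`` maps raster rank -> scipy label."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    binary = np.asarray(binary) != 0
    labels, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    if n == 0:
        return None, np.empty(0, dtype=int), []
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    # raster order of first occurrence: scipy assigns labels in scan order,
    # but we derive the order explicitly so the contract is self-enforced
    flat = labels.ravel()
    first_idx = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.nonzero(flat)[0]
    np.minimum.at(first_idx, flat[nz], nz)
    order = list(np.argsort(first_idx[1:], kind="stable") + 1)
    return labels, sizes, order


def frame_report(
    frame: UltrasoundFrame,
    roi: RoiMask,
    thresholds: ThresholdSet,
    connectivity: int = 8,
    min_blob_px: int = 1,
) -> FrameBlobReport:
    """Blob metrics at both percentile levels plus echointensity, one frame."""
    _check_congruent(frame, roi)
    report = FrameBlobReport(
        frame_id=frame.frame_id,
        echointensity=compute_echointensity(frame, roi),
        roi_area_mm2=roi.area_mm2,
    )
    px_area = frame.pixel_area_mm2
    for level in PERCENTILE_LEVELS:
        binary = (frame.pixels >= thresholds.by_level(level)) & roi.mask
        _, sizes, _ = _label_fast(binary, connectivity)
        if min_blob_px > 1:
            sizes = sizes[sizes >= min_blob_px]
        count = int(sizes.size)
        total_px = int(sizes.sum())
        report.metrics[f"blob_count_p{level}"] = float(count)
        report.metrics[f"total_blob_size_px_p{level}"] = float(total_px)
        report.metrics[f"total_blob_size_mm2_p{level}"] = total_px * px_area
        report.metrics[f"blob_count_per_mm2_p{level}"] = count / roi.area_mm2
        report.metrics[f"total_blob_size_per_mm2_p{level}"] = total_px / roi.area_mm2
    return report


def band_map(frame: UltrasoundFrame, roi: RoiMask, thresholds: ThresholdSet) -> np.ndarray:
    """Exploration map: 1 where t95 <= g < t99 inside the ROI."""
    g = frame.pixels
    return ((g >= thresholds.t95) & (g < thresholds.t99) & roi.mask).astype(np.uint8)


def subject_report(
    scan: SubjectScan,
    thresholds: ThresholdSet,
    connectivity: int = 8,
    aggregation: str = "mean",
    min_blob_px: int = 1,
) -> dict[str, float]:
    """Aggregate the three frame reports of one subject (arithmetic mean by default)."""
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be 'mean' or 'median'")
    agg = np.mean if aggregation == "mean" else np.median
    frames = [
        frame_report(frame, roi, thresholds, connectivity, min_blob_px) for frame, roi in scan.frames
    ]
    out = {"echointensity": float(agg([r.echointensity for r in frames]))}
    for key in METRIC_COLUMNS[1:]:
        out[key] = float(agg([r.metrics[key] for r in frames]))
    out["roi_area_mm2"] = float(agg([r.roi_area_mm2 for r in frames]))
    return out


def cohort_metrics(
    scans: list[SubjectScan],
    thresholds: ThresholdSet,
    connectivity: int = 8,
    covariates: pd.DataFrame | None = None,
    aggregation: str = "mean",
) -> pd.DataFrame:
    """One row per subject: group, subject-level blob metrics, joined covariates."""
    if not scans:
        raise ValueError("empty cohort")
    rows = []
    for scan in scans:
        row = {"subject_id": scan.subject_id, "group": scan.group}
        row.update(subject_report(scan, thresholds, connectivity, aggregation))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("subject_id").sort_index()
    if covariates is not None:
        cov = covariates.drop(columns=[c for c in ("group",) if c in covariates.columns])
        missing = table.index.difference(cov.index)
        if len(missing):
            raise ValueError(f"covariate join failed for subjects: {list(missing)}")
        table = table.join(cov, how="left")
    return table


def _check_congruent(frame: UltrasoundFrame, roi: RoiMask) -> None:
    if frame.shape != roi.mask.shape:
        raise ValueError(
            f"frame {frame.frame_id!r} shape {frame.shape} does not match ROI shape {roi.mask.shape}"
        )
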