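"""Core data model shared by every stage of the pipeline.

Conventions: pixels are 8-bit grayscale (0 = darkest, 255 = brightest),
row 0 is the shallowest tissue, indices are 0-based (row, col).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROUPS = ("healthy", "fm")


@dataclass(frozen=True)
class UltrasoundFrame:
    """A single 8-bit grayscale B-mode frame with physical pixel spacing.

    Parameters
    ----------
    pixels
        2-D integer array, values in [0, 255].
    spacing_axial
        Millimetres per pixel row (depth direction), > 0.
    spacing_lateral
        Millimetres per pixel column, > 0.
    frame_id
        Free-text identifier used in error messages and reports.
    """

    pixels: np.ndarray
    spacing_axial: float
    spacing_lateral: float
    frame_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"frame {self.frame_id!r}: pixels must be a non-empty 2-D array")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError(f"frame {self.frame_id!r}: pixels must be integers on the 0-255 scale")
        if px.min() < 0 or px.max() > 255:
            raise ValueError(f"frame {self.frame_id!r}: pixel values outside [0, 255]")
        if not (self.spacing_axial > 0 and self.spacing_lateral > 0):
            raise ValueError(f"frame {self.frame_id!r}: pixel spacings must be > 0")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.spacing_axial * self.spacing_lateral)


@dataclass(frozen=True)
class RoiMask:
    """Binary region-of-interest mask congruent with its frame.

    ``area_mm2`` is ``n_pixels * spacing_axial * spacing_lateral`` of the
    frame the mask was built against.
    """

    mask: np.ndarray
    n_pixels: int
    area_mm2: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        n = int(m.sum())
        if n < 1:
            raise ValueError("empty ROI: mask includes no pixels")
        if n != self.n_pixels:
            raise ValueError("n_pixels inconsistent with mask")
        if not self.area_mm2 > 0:
            raise ValueError("ROI area must be > 0")
        object.__setattr__(self, "mask", m)

    @classmethod
    def from_array(cls, mask: np.ndarray, frame: UltrasoundFrame) -> "RoiMask":
        m = np.asarray(mask, dtype=bool)
        if m.shape != frame.shape:
            raise ValueError(
                f"mask shape {m.shape} does not match frame {frame.frame_id!r} shape {frame.shape}"
            )
        n = int(m.sum())
        if n < 1:
            raise ValueError(f"empty ROI for frame {frame.frame_id!r}")
        return cls(mask=m, n_pixels=n, area_mm2=n * frame.pixel_area_mm2)


@dataclass
class SubjectScan:
    """One subject's scan: exactly three (frame, ROI) pairs and a group label."""

    subject_id: str
    group: str
    frames: list[tuple[UltrasoundFrame, RoiMask]] = field(default_factory=list)

    N_FRAMES = 3

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"subject {self.subject_id!r}: group must be one of {GROUPS}")
        if len(self.frames) != self.N_FRAMES:
            raise ValueError(
                f"subject {self.subject_id!r}: expected {self.N_FRAMES} frames, got {len(self.frames)}"
            )
        spacings = {(f.spacing_axial, f.spacing_lateral) for f, _ in self.frames}
        if len(spacings) > 1:
            raise ValueError(f"subject {self.subject_id!r}: frames disagree on pixel spacing")
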