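"""Reading and writing frames, ROI masks and cohort manifests.

Frames and masks are single-channel 8-bit PNG/TIFF.  Non-8-bit input is
rejected rather than rescaled because all thresholds live on the 0-255
scale.  The manifest is a CSV with columns ``subject_id, group,
frame1..frame3, mask1..mask3, spacing_axial_mm, spacing_lateral_mm`` plus
arbitrary covariate columns.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .types import GROUPS, RoiMask, SubjectScan, UltrasoundFrame

FRAME_COLUMNS = ["frame1", "frame2", "frame3"]
MASK_COLUMNS = ["mask1", "mask2", "mask3"]
REQUIRED_MANIFEST_COLUMNS = (
    ["subject_id", "group"] + FRAME_COLUMNS + MASK_COLUMNS + ["spacing_axial_mm", "spacing_lateral_mm"]
)


class ManifestError(ValueError):
    """Raised when a cohort manifest or a referenced file is invalid."""


def _read_gray8(path: str | os.PathLike) -> np.ndarray:
    """Read an image and return a 2-D uint8 array, or raise."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    img = iio.imread(path)
    if img.dtype != np.uint8:
        raise ValueError(f"{path}: bit depth not 8; rescale explicitly")
    if img.ndim == 3:
        # accept multi-channel only when all channels agree (gray stored as RGB)
        chans = img.reshape(img.shape[0], img.shape[1], -1)
        if not np.all(chans == chans[..., :1]):
            raise ValueError(f"{path}: multi-channel image without unambiguous grayscale conversion")
        img = chans[..., 0]
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D single-channel image, got shape {img.shape}")
    return img


def read_frame(
    path: str | os.PathLike,
    spacing_axial: float,
    spacing_lateral: float,
    frame_id: str | None = None,
) -> UltrasoundFrame:
    """Load an 8-bit grayscale frame from PNG/TIFF and attach pixel spacing."""
    px = _read_gray8(path)
    return UltrasoundFrame(
        pixels=px,
        spacing_axial=spacing_axial,
        spacing_lateral=spacing_lateral,
        frame_id=frame_id if frame_id is not None else Path(path).stem,
    )


def write_frame(frame: UltrasoundFrame, path: str | os.PathLike) -> None:
    """Write a frame losslessly as single-channel 8-bit PNG/TIFF."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), frame.pixels)


def read_mask(path: str | os.PathLike, frame: UltrasoundFrame) -> RoiMask:
    """Load a binary ROI mask (0 = excluded, nonzero = included) for ``frame``."""
    img = _read_gray8(path)
    if img.shape != frame.shape:
        raise ValueError(
            f"{path}: mask shape {img.shape} does not match frame {frame.frame_id!r} shape {frame.shape}"
        )
    values = np.unique(img)
    if len(values) > 2:
        raise ValueError(f"{path}: mask must be binary, found {len(values)} distinct values")
    if len(values) == 1 and values[0] == 0:
        raise ValueError(f"{path}: empty ROI")
    return RoiMask.from_array(img != 0, frame)


def write_mask(mask: RoiMask, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))


def read_dicom_frame(path: str | os.PathLike, frame_id: str | None = None) -> UltrasoundFrame:
    """Optional DICOM reader; extracts PixelSpacing when present.

    Requires ``pydicom`` which is an optional dependency.
    """
    try:
        import pydicom  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError("DICOM support requires the optional dependency 'pydicom'") from exc
    ds = pydicom.dcmread(str(path))
    px = ds.pixel_array
    if px.dtype != np.uint8:
        raise ValueError(f"{path}: bit depth not 8; rescale explicitly")
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise ValueError(f"{path}: DICOM lacks PixelSpacing; supply spacings via the manifest")
    return UltrasoundFrame(
        pixels=px,
        spacing_axial=float(spacing[0]),
        spacing_lateral=float(spacing[1]),
        frame_id=frame_id if frame_id is not None else Path(path).stem,
    )


def read_manifest(manifest_path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate the manifest CSV (structure only, not the files)."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, comment="#")
    missing = [c for c in REQUIRED_MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {manifest_path} missing required columns: {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ManifestError(f"duplicate subject_id in manifest: {sorted(set(dup.astype(str)))}")
    bad_group = df.loc[~df["group"].isin(GROUPS), "subject_id"]
    if len(bad_group):
        raise ManifestError(
            f"group must be one of {GROUPS}; offending subjects: {list(bad_group.astype(str))}"
        )
    return df


def load_cohort(manifest_path: str | os.PathLike) -> tuple[list[SubjectScan], pd.DataFrame]:
    """Load every subject listed in a manifest.

    Returns the scans plus a covariate table indexed by ``subject_id``
    (all manifest columns that are not file paths or spacings).
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    root = manifest_path.parent
    scans: list[SubjectScan] = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        frame_paths = [row[c] for c in FRAME_COLUMNS]
        mask_paths = [row[c] for c in MASK_COLUMNS]
        if any(pd.isna(p) for p in frame_paths + mask_paths):
            raise ManifestError(f"subject {sid!r}: expected 3 frames and 3 masks, found missing entries")
        pairs = []
        for fpath, mpath in zip(frame_paths, mask_paths):
            fpath, mpath = _resolve(root, fpath), _resolve(root, mpath)
            try:
                frame = read_frame(
                    fpath,
                    float(row["spacing_axial_mm"]),
                    float(row["spacing_lateral_mm"]),
                    frame_id=f"{sid}/{Path(fpath).stem}",
                )
                mask = read_mask(mpath, frame)
            except (OSError, ValueError) as exc:
                raise ManifestError(f"subject {sid!r}: {exc}") from exc
            pairs.append((frame, mask))
        scans.append(SubjectScan(subject_id=sid, group=str(row["group"]), frames=pairs))
    covariates = (
        df.drop(columns=FRAME_COLUMNS + MASK_COLUMNS)
        .astype({"subject_id": str})
        .set_index("subject_id")
        .sort_index()
    )
    return scans, covariates


def _resolve(root: Path, p: str) -> Path:
    p = Path(p)
    return p if p.is_absolute() else root / p
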