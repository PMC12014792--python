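"""Seeded synthetic B-mode-like cohort generator.

Frame model: Rayleigh speckle amplitude field, Poisson-placed elongated
elliptical inclusions that multiply the amplitude, logarithmic
compression onto the 0-255 grayscale, clipping.  The ROI is a horizontal
band excluding top/bottom margins (fascia stand-in).

The compression g = clip(C * ln(A) + B) makes the mean grayscale an
affine function of ln(sigma), so each subject's Rayleigh scale is solved
analytically from its target echointensity:

    E[g] ~= C * (ln(sigma) + (ln 2 - gamma)/2) + B.

A single master seed expands into per-subject / per-frame substreams, so
cohorts are reproducible and stable under subject-count changes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import RoiMask, SubjectScan, UltrasoundFrame

# log-compression constants (grayscale = LOG_CONTRAST * ln(amplitude) + LOG_OFFSET).
# LOG_OFFSET absorbs the ~+1.5 gray mean bias of clipping the left tail at 0,
# so a unit Rayleigh scale still lands near 72 mean gray.
LOG_CONTRAST = 60.0
LOG_OFFSET = 65.55
_E_LN_RAYLEIGH1 = 0.5 * (np.log(2.0) - np.euler_gamma)  # E[ln X], X ~ Rayleigh(1)

ROI_ROW_MARGIN = 0.10  # excluded band at top and bottom (fascia stand-in)
ROI_COL_MARGIN = 0.02


@dataclass(frozen=True)
class GroupParams:
    """Image-generation parameters of one cohort group."""

    mean_echointensity_target: float
    speckle_scale: float = 1.0
    inclusion_rate: float = 0.0  # expected bright bands per cm^2 of ROI
    inclusion_length_mm: float = 6.0  # lateral (fiber-aligned) full length
    inclusion_width_mm: float = 1.2  # axial full width
    inclusion_brightness_gain: float = 2.5
    between_subject_sd: float = 10.0
    psf_blur_sigma_px: float = 0.0  # optional Gaussian PSF stand-in, off by default

    def __post_init__(self) -> None:
        if min(self.mean_echointensity_target, self.speckle_scale,
               self.inclusion_length_mm, self.inclusion_width_mm,
               self.inclusion_brightness_gain, self.between_subject_sd) <= 0:
            raise ValueError("GroupParams fields must be positive")
        if self.inclusion_rate < 0:
            raise ValueError("inclusion_rate must be >= 0")
        if not self.inclusion_width_mm < self.inclusion_length_mm:
            raise ValueError("inclusions must be elongated: width < length")


@dataclass(frozen=True)
class CovariateSpec:
    """One generated covariate: mean, total SD, latent-severity loading, range."""

    mean: float
    sd: float
    load: float  # covariate units per unit latent severity (|load| <= sd)
    lo: float
    hi: float


@dataclass(frozen=True)
class CovariateModel:
    """Latent-severity model for clinical covariates.

    FM covariates load on a standard-normal per-subject severity; the same
    severity multiplies the inclusion rate (exp(coeff * severity)) and adds
    to the echointensity target, so blob metrics carry a recoverable
    correlation with symptom scores.
    """

    fm: dict[str, CovariateSpec]
    healthy: dict[str, CovariateSpec]
    severity_inclusion_coeff: float = 0.4
    severity_echo_coeff: float = 3.0
    drug_classes: tuple[str, ...] = ("none",)
    drug_probs: tuple[float, ...] = (1.0,)


def compressed_mean_gray(sigma: float) -> float:
    """Exact mean of clip(round(C*ln(A) + B), 0, 255) for A ~ Rayleigh(sigma).

    Sums the probability mass of every integer gray level, so clipping and
    rounding are accounted for analytically.
    """
    grays = np.arange(256)
    upper_amp = np.exp((grays + 0.5 - LOG_OFFSET) / LOG_CONTRAST)
    lower_amp = np.concatenate([[0.0], upper_amp[:-1]])
    upper_amp[-1] = np.inf
    surv_lo = np.exp(-lower_amp**2 / (2 * sigma**2))
    surv_hi = np.where(np.isinf(upper_amp), 0.0, np.exp(-upper_amp**2 / (2 * sigma**2)))
    return float(np.sum(grays * (surv_lo - surv_hi)))


def subject_sigma(params: GroupParams, subject_effect: float) -> float:
    """Rayleigh scale whose compressed mean grayscale hits the subject target.

    Solved by bisection on the exact clipped/rounded compressed mean, seeded
    from the clip-free closed form E[g] = C*(ln sigma + (ln2 - gamma)/2) + B.
    """
    from scipy.optimize import brentq

    target = float(np.clip(params.mean_echointensity_target + subject_effect, 1.0, 254.0))
    guess = np.exp((target - LOG_OFFSET) / LOG_CONTRAST - _E_LN_RAYLEIGH1)
    lo, hi = guess * np.exp(-3), guess * np.exp(3)
    sigma = brentq(lambda s: compressed_mean_gray(s) - target, lo, hi, xtol=1e-10)
    return params.speckle_scale * float(sigma)


def roi_band(size: tuple[int, int]) -> np.ndarray:
    rows, cols = size
    mask = np.zeros(size, dtype=bool)
    r0, r1 = int(round(ROI_ROW_MARGIN * rows)), int(round((1 - ROI_ROW_MARGIN) * rows))
    c0, c1 = int(round(ROI_COL_MARGIN * cols)), int(round((1 - ROI_COL_MARGIN) * cols))
    mask[r0:r1, c0:c1] = True
    return mask


def simulate_frame(
    params: GroupParams,
    subject_effect: float,
    size: tuple[int, int] = (128, 256),
    spacing: tuple[float, float] = (0.4, 0.4),
    seed: int | np.random.Generator = 0,
    frame_id: str = "synthetic",
) -> tuple[UltrasoundFrame, RoiMask]:
    """One synthetic frame plus its band ROI mask.

    ``subject_effect`` shifts the subject's mean echointensity (grayscale
    units); inclusion geometry and count are drawn from ``params``.
    """
    rows, cols = size
    if rows < 64 or cols < 64:
        raise ValueError(f"degenerate frame size {size}; need at least 64x64")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = subject_sigma(params, subject_effect)
    amplitude = rng.rayleigh(scale=sigma, size=size)

    mask = roi_band(size)
    n_roi = int(mask.sum())
    roi_area_cm2 = n_roi * spacing[0] * spacing[1] / 100.0
    n_inc = rng.poisson(params.inclusion_rate * roi_area_cm2)
    if n_inc:
        rr = np.nonzero(mask.any(axis=1))[0]
        cc = np.nonzero(mask.any(axis=0))[0]
        half_len_px = 0.5 * params.inclusion_length_mm / spacing[1]
        half_wid_px = 0.5 * params.inclusion_width_mm / spacing[0]
        for _ in range(n_inc):
            r0 = rng.uniform(rr[0], rr[-1])
            c0 = rng.uniform(cc[0], cc[-1])
            jit = rng.lognormal(mean=0.0, sigma=0.25, size=2)
            a_px = max(half_wid_px * jit[0], 0.6)  # axial half-axis
            b_px = max(half_len_px * jit[1], 0.6)  # lateral half-axis
            rlo, rhi = int(max(0, r0 - a_px - 1)), int(min(rows, r0 + a_px + 2))
            clo, chi = int(max(0, c0 - b_px - 1)), int(min(cols, c0 + b_px + 2))
            rr_loc = np.arange(rlo, rhi)[:, None]
            cc_loc = np.arange(clo, chi)[None, :]
            inside = ((rr_loc - r0) / a_px) ** 2 + ((cc_loc - c0) / b_px) ** 2 <= 1.0
            amplitude[rlo:rhi, clo:chi][inside] *= params.inclusion_brightness_gain
    if params.psf_blur_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        amplitude = gaussian_filter(amplitude, params.psf_blur_sigma_px)

    gray = LOG_CONTRAST * np.log(np.maximum(amplitude, 1e-12)) + LOG_OFFSET
    pixels = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    frame = UltrasoundFrame(
        pixels=pixels, spacing_axial=spacing[0], spacing_lateral=spacing[1], frame_id=frame_id
    )
    return frame, RoiMask.from_array(mask, frame)


def _draw_covariates(
    specs: dict[str, CovariateSpec], severity: float, rng: np.random.Generator
) -> dict[str, float]:
    out: dict[str, float] = {}
    for name, sp in specs.items():
        noise_sd = float(np.sqrt(max(sp.sd**2 - sp.load**2, 0.0)))
        value = sp.mean + sp.load * severity + noise_sd * rng.standard_normal()
        out[name] = float(np.clip(value, sp.lo, sp.hi))
    return out


def draw_covariate_table(
    specs: dict[str, CovariateSpec], n: int, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Subject-level covariate rows only (no images), one latent severity per row."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        severity = float(rng.standard_normal())
        row = _draw_covariates(specs, severity, rng)
        row["latent_severity"] = severity
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SyntheticSubject:
    scan: SubjectScan
    covariates: dict[str, float]
    severity: float
    inclusion_rate: float


def simulate_subject(
    subject_id: str,
    group: str,
    params: GroupParams,
    covmodel: CovariateModel,
    seed: int,
    index: int,
    size: tuple[int, int],
    spacing: tuple[float, float],
    frames_per_subject: int = 3,
) -> SyntheticSubject:
    group_code = 0 if group == "healthy" else 1
    rng = np.random.default_rng([seed, group_code, index])
    severity = float(rng.standard_normal()) if group == "fm" else 0.0
    subject_effect = params.between_subject_sd * float(rng.standard_normal())
    specs = covmodel.fm if group == "fm" else covmodel.healthy
    covs = _draw_covariates(specs, severity, rng)
    if group == "fm":
        subject_effect += covmodel.severity_echo_coeff * severity
        rate = params.inclusion_rate * float(np.exp(covmodel.severity_inclusion_coeff * severity))
        covs["drug"] = str(rng.choice(covmodel.drug_classes, p=covmodel.drug_probs))
    else:
        rate = params.inclusion_rate
        covs["drug"] = "none"
    subj_params = dataclasses.replace(params, inclusion_rate=rate)
    pairs = []
    for k in range(frames_per_subject):
        frame_rng = np.random.default_rng([seed, group_code, index, k])
        pairs.append(
            simulate_frame(
                subj_params, subject_effect, size, spacing, frame_rng,
                frame_id=f"{subject_id}_f{k + 1}",
            )
        )
    return SyntheticSubject(
        scan=SubjectScan(subject_id=subject_id, group=group, frames=pairs),
        covariates=covs,
        severity=severity,
        inclusion_rate=rate,
    )


def simulate_cohort_in_memory(
    healthy: GroupParams,
    fm: GroupParams,
    covmodel: CovariateModel,
    n_per_group: int,
    seed: int,
    size: tuple[int, int] = (128, 256),
    spacing: tuple[float, float] = (0.4, 0.4),
    frames_per_subject: int = 3,
) -> tuple[list[SubjectScan], pd.DataFrame]:
    """Generate a full cohort without touching disk.

    Returns the scans and a covariate table indexed by subject_id (with
    ``group``, generated covariates, and the realised latent severity and
    inclusion rate for oracle tests).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    scans: list[SubjectScan] = []
    rows = []
    for group, params in (("healthy", healthy), ("fm", fm)):
        for i in range(n_per_group):
            sid = f"{group}{i + 1:03d}"
            subj = simulate_subject(
                sid, group, params, covmodel, seed, i, size, spacing, frames_per_subject
            )
            scans.append(subj.scan)
            rows.append(
                {
                    "subject_id": sid, "group": group,
                    "spacing_axial_mm": spacing[0], "spacing_lateral_mm": spacing[1],
                    **subj.covariates,
                    "latent_severity": subj.severity,
                    "realized_inclusion_rate": subj.inclusion_rate,
                }
            )
    covariates = pd.DataFrame(rows).set_index("subject_id").sort_index()
    return scans, covariates


def simulate_cohort(
    healthy: GroupParams,
    fm: GroupParams,
    covmodel: CovariateModel,
    n_per_group: int,
    out_dir: str | Path,
    seed: int,
    size: tuple[int, int] = (128, 256),
    spacing: tuple[float, float] = (0.4, 0.4),
    frames_per_subject: int = 3,
) -> Path:
    """Write frames, masks and a manifest CSV consumable by ``echoblob.io``.

    Returns the manifest path.
    """
    from . import io as eio

    out_dir = Path(out_dir)
    (out_dir / "frames").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    scans, covariates = simulate_cohort_in_memory(
        healthy, fm, covmodel, n_per_group, seed, size, spacing, frames_per_subject
    )
    records = []
    for scan in scans:
        rec: dict[str, object] = {"subject_id": scan.subject_id, "group": scan.group}
        for k, (frame, mask) in enumerate(scan.frames, start=1):
            fpath = f"frames/{frame.frame_id}.png"
            mpath = f"masks/{frame.frame_id}_mask.png"
            eio.write_frame(frame, out_dir / fpath)
            eio.write_mask(mask, out_dir / mpath)
            rec[f"frame{k}"] = fpath
            rec[f"mask{k}"] = mpath
        rec["spacing_axial_mm"] = spacing[0]
        rec["spacing_lateral_mm"] = spacing[1]
        cov = covariates.loc[scan.subject_id].drop(
            ["group", "spacing_axial_mm", "spacing_lateral_mm", "latent_severity",
             "realized_inclusion_rate"]
        )
        rec.update(cov.to_dict())
        records.append(rec)
    manifest = pd.DataFrame(records)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
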