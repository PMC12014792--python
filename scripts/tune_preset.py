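"""One-off tuning study for the frozen 'paper' preset.

Runs seeded cohorts through the real pipeline and reports the quantities
the preset is calibrated against: group means/SDs of the subject-level
metrics, the Mann-Whitney significance rate for total blob size, the
within-FM Spearman rate for blob size vs CSI, and the pooled-pixel tail
fraction at t95.  Preset constants in echoblob/presets.py were frozen
from this script's output; rerun after any generator change.

Usage: python scripts/tune_preset.py [n_cohorts] [size_rows size_cols]
"""

import sys
import time

import numpy as np
from scipy.stats import mannwhitneyu, spearmanr

from echoblob.blob import cohort_metrics, pooled_roi_pixels, reference_thresholds
from echoblob.presets import PAPER_PRESET
from echoblob.synth import simulate_cohort_in_memory


def main() -> None:
    n_cohorts = int(sys.argv[1]) if len(sys.argv) > 1 else 100
    size = (int(sys.argv[2]), int(sys.argv[3])) if len(sys.argv) > 3 else (128, 256)
    t0 = time.time()
    sig = pos = corr_pos = corr_sig = 0
    stats = {k: [] for k in ("h_echo", "f_echo", "h_size", "f_size", "h_cnt", "f_cnt", "tail")}
    for seed in range(n_cohorts):
        scans, cov = simulate_cohort_in_memory(
            PAPER_PRESET["healthy"], PAPER_PRESET["fm"], PAPER_PRESET["covariates"],
            n_per_group=34, seed=seed, size=size,
        )
        healthy = [s for s in scans if s.group == "healthy"]
        thr = reference_thresholds(healthy)
        tab = cohort_metrics(scans, thr, covariates=cov)
        h = tab[tab.group == "healthy"]
        f = tab[tab.group == "fm"]
        a, b = h.total_blob_size_px_p95, f.total_blob_size_px_p95
        p = mannwhitneyu(a, b, alternative="two-sided").pvalue
        sig += p < 0.05
        pos += b.mean() > a.mean()
        rho, rp = spearmanr(f.total_blob_size_px_p95, f.csi_total)
        corr_pos += rho > 0
        corr_sig += (rho > 0) and (rp < 0.05)
        stats["h_echo"].append(h.echointensity.mean())
        stats["f_echo"].append(f.echointensity.mean())
        stats["h_size"].append(a.mean())
        stats["f_size"].append(b.mean())
        stats["h_cnt"].append(h.blob_count_p95.mean())
        stats["f_cnt"].append(f.blob_count_p95.mean())
        stats["tail"].append(float(np.mean(pooled_roi_pixels(healthy) >= thr.t95)))
    print(f"{n_cohorts} cohorts at {size}, {time.time() - t0:.0f}s")
    print(f"MW p<0.05 rate: {sig}/{n_cohorts}   FM>healthy mean rate: {pos}/{n_cohorts}")
    print(f"spearman>0 rate: {corr_pos}/{n_cohorts}   (also p<0.05: {corr_sig}/{n_cohorts})")
    for k, v in stats.items():
        print(f"{k}: {np.mean(v):.2f} ± {np.std(v):.2f}")


if __name__ == "__main__":
    main()
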