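"""Cohort statistics: normality-gated two-group tests, categorical tests,
correlations, backward-elimination OLS with diagnostics, and
Benjamini-Hochberg FDR adjustment.

Routing follows the analysis plan the pipeline reproduces: Shapiro-Wilk
at alpha = 0.05 gates Student t vs Mann-Whitney U and Pearson vs
Spearman; Fisher's exact test (Freeman-Halton for 2xC) replaces the
chi-square when any expected cell is below 5; FDR is applied as one
family over every reported p-value by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson

GATE_ALPHA = 0.05
EXACT_MW_MAX_N = 8
STRENGTH_BANDS = {"weak": 0.3, "moderate": 0.6}  # |r| < 0.3 weak, < 0.6 moderate, else strong


# ---------------------------------------------------------------------------
# result containers


@dataclass
class TestResult:
    test_name: str  # student_t | mann_whitney_u | chi_square | fisher_exact
    statistic: float
    p_raw: float
    p_fdr: float | None = None
    summary_a: str = ""
    summary_b: str = ""
    gate: str = ""


@dataclass
class CorrelationResult:
    method: str  # pearson | spearman
    r: float
    p_raw: float
    p_fdr: float | None = None
    n: int = 0

    @property
    def strength(self) -> str:
        return strength_label(self.r)


@dataclass
class RegressionResult:
    response: str
    params: pd.DataFrame  # index: predictor; columns: beta, se, beta_std, p_raw, vif
    model_p: float
    r_squared: float
    durbin_watson: float
    n: int
    eliminated: list[str] = field(default_factory=list)


def strength_label(r: float, bands: dict[str, float] = STRENGTH_BANDS) -> str:
    a = abs(r)
    if a < bands["weak"]:
        return "weak"
    if a < bands["moderate"]:
        return "moderate"
    return "strong"


# ---------------------------------------------------------------------------
# normality gate


def normality_gate(sample, alpha: float = GATE_ALPHA) -> str:
    """Shapiro-Wilk route decision: 'normal' or 'non_normal'.

    Degenerate (constant) samples take the conservative non-parametric route.
    """
    x = _clean(sample)
    if x.size < 3:
        raise ValueError(f"normality gate needs n >= 3, got {x.size}")
    if np.ptp(x) == 0:
        return "non_normal"
    return "normal" if sps.shapiro(x).pvalue >= alpha else "non_normal"


# ---------------------------------------------------------------------------
# two-group comparison


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U by full enumeration of group assignments.

    Ties are handled exactly (mid-rank U over all C(n_a+n_b, n_a) splits).
    p = min(1, 2 * one-sided tail containing the observed U).
    """
    a, b = _clean(a), _clean(b)
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    u_obs = _u_statistic(a, b)
    mu = na * b.size / 2.0
    us = np.array(
        [
            _u_statistic(pooled[list(idx)], np.delete(pooled, list(idx)))
            for idx in itertools.combinations(range(n), na)
        ]
    )
    eps = 1e-9
    if u_obs <= mu:
        tail = np.mean(us <= u_obs + eps)
    else:
        tail = np.mean(us >= u_obs - eps)
    return float(u_obs), float(min(1.0, 2.0 * tail))


def mann_whitney_approx(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U, tie-corrected continuity-corrected normal
    approximation (the large-sample route of :func:`compare_groups`)."""
    res = sps.mannwhitneyu(_clean(a), _clean(b), alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample a: number of (a_i, b_j) pairs with a_i > b_j, ties 1/2."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def compare_groups(a, b, force_route: str | None = None) -> TestResult:
    """Two-sided two-group comparison routed by the normality gate.

    Both samples normal -> Student t (equal variances); otherwise
    Mann-Whitney U (exact enumeration when both n <= 8, else tie-corrected
    continuity-corrected normal approximation).
    """
    a, b = _clean(a), _clean(b)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    if force_route is None:
        gates = (normality_gate(a), normality_gate(b))
        route = "t" if gates == ("normal", "normal") else "mw"
        gate = "+".join(gates)
    else:
        route, gate = force_route, f"forced:{force_route}"
    if route == "t":
        t = sps.ttest_ind(a, b, equal_var=True)
        return TestResult(
            "student_t", float(t.statistic), float(t.pvalue),
            summary_a=_mean_sd(a), summary_b=_mean_sd(b), gate=gate,
        )
    if a.size <= EXACT_MW_MAX_N and b.size <= EXACT_MW_MAX_N:
        u, p = mann_whitney_exact(a, b)
    else:
        u, p = mann_whitney_approx(a, b)
    return TestResult(
        "mann_whitney_u", u, p,
        summary_a=_median_range(a), summary_b=_median_range(b), gate=gate,
    )


# ---------------------------------------------------------------------------
# categorical tests


def fisher_exact_2xc(table: np.ndarray) -> float:
    """Freeman-Halton exact test for a 2xC table.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.
    """
    table = np.asarray(table, dtype=np.int64)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = int(table.sum())
    lf = [math.lgamma(k + 1) for k in range(n + 1)]
    const = sum(lf[r] for r in row) + sum(lf[c] for c in col) - lf[n]

    def logp(first_row) -> float:
        cells = list(first_row) + [c - f for c, f in zip(col, first_row)]
        return const - sum(lf[x] for x in cells)

    lp_obs = logp(table[0])
    total = 0.0
    ranges = [range(min(row[0], c) + 1) for c in col[:-1]]
    for partial in itertools.product(*ranges):
        last = row[0] - sum(partial)
        if last < 0 or last > col[-1]:
            continue
        lp = logp(partial + (last,))
        if lp <= lp_obs + 1e-9:
            total += math.exp(lp)
    return float(min(1.0, total))


def categorical_test(table) -> TestResult:
    """Pearson chi-square, or Fisher's exact when any expected cell < 5."""
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2xC contingency table with C >= 2")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero-margin contingency table")
    chi2, p_chi2, _, expected = sps.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        if table.shape[1] == 2:
            p = float(sps.fisher_exact(table)[1])
        else:
            p = fisher_exact_2xc(table)
        return TestResult("fisher_exact", float(chi2), p, gate="expected<5")
    return TestResult("chi_square", float(chi2), float(p_chi2), gate="expected>=5")


# ---------------------------------------------------------------------------
# correlation


def correlate(x, y, bands: dict[str, float] = STRENGTH_BANDS) -> CorrelationResult:
    """Pearson if both variables pass the gate, else Spearman."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size != y.size or x.size < 4:
        raise ValueError("correlation needs >= 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a correlation variable")
    if normality_gate(x) == "normal" and normality_gate(y) == "normal":
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(method=method, r=float(r), p_raw=float(p), n=int(x.size))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR


def bh_fdr(p_values) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order.

    adjusted_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = m * p[order] / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# backward-elimination OLS


def backward_ols(
    response,
    predictors: pd.DataFrame,
    p_remove: float = 0.05,
    response_name: str = "response",
) -> RegressionResult:
    """OLS with backward elimination at ``p_remove``.

    Iteratively drops the predictor with the largest p >= p_remove and
    refits until every retained predictor has p < p_remove.  Reports
    unstandardized and standardized coefficients, VIF per retained
    predictor, the Durbin-Watson statistic and the elimination trace.
    """
    y = np.asarray(response, dtype=float)
    X = predictors.astype(float).copy()
    if y.size != len(X):
        raise ValueError("response and predictors disagree on n")
    if y.size <= X.shape[1] + 2:
        raise ValueError(f"n={y.size} too small for {X.shape[1]} predictors")
    constant = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
    if constant:
        raise ValueError(f"constant predictor column(s): {constant}")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear predictor columns)")

    eliminated: list[str] = []
    while True:
        model = sm.OLS(y, sm.add_constant(X)).fit()
        pvals = model.pvalues.drop("const")
        if len(pvals) == 0 or pvals.max() < p_remove:
            break
        worst = pvals.idxmax()
        eliminated.append(worst)
        X = X.drop(columns=[worst])

    design = sm.add_constant(X)
    sd_y = y.std(ddof=1)
    rows = []
    for i, name in enumerate(X.columns):
        beta = model.params[name]
        rows.append(
            {
                "predictor": name,
                "beta": float(beta),
                "se": float(model.bse[name]),
                "beta_std": float(beta * X[name].std(ddof=1) / sd_y),
                "p_raw": float(model.pvalues[name]),
                "vif": float(variance_inflation_factor(design.to_numpy(), i + 1))
                if X.shape[1] > 1
                else 1.0,
            }
        )
    params = pd.DataFrame(rows).set_index("predictor") if rows else pd.DataFrame(
        columns=["beta", "se", "beta_std", "p_raw", "vif"]
    )
    return RegressionResult(
        response=response_name,
        params=params,
        model_p=float(model.f_pvalue) if len(rows) else float("nan"),
        r_squared=float(model.rsquared),
        durbin_watson=float(durbin_watson(model.resid)),
        n=int(y.size),
        eliminated=eliminated,
    )


# ---------------------------------------------------------------------------
# full cohort analysis


DEFAULT_RESPONSES = ("blob_count_p95", "total_blob_size_per_mm2_p95", "echointensity")


@dataclass
class AnalysisBundle:
    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    regressions: pd.DataFrame
    fdr_family: pd.DataFrame
    descriptives: pd.DataFrame
    regression_models: dict[str, RegressionResult] = field(default_factory=dict)


def run_full_analysis(
    cohort: pd.DataFrame,
    endpoints: list[str] | None = None,
    covariates: list[str] | None = None,
    responses: tuple[str, ...] = DEFAULT_RESPONSES,
    fdr_mode: str = "global",
    p_remove: float = 0.05,
) -> AnalysisBundle:
    """Descriptives, group comparisons, correlations, three backward
    regressions, and FDR over the configured family.

    ``cohort`` is a subject-level table with a ``group`` column, blob-metric
    columns and covariate columns (missing values allowed in covariates).
    """
    if set(cohort["group"].unique()) != {"healthy", "fm"}:
        raise ValueError("cohort must contain both groups 'healthy' and 'fm'")
    from .blob import METRIC_COLUMNS  # local import to avoid cycle

    numeric = cohort.select_dtypes(include=[np.number]).columns
    if endpoints is None:
        endpoints = [c for c in METRIC_COLUMNS if c in cohort.columns]
    if covariates is None:
        covariates = [c for c in numeric if c not in endpoints and c != "roi_area_mm2"]

    healthy = cohort[cohort["group"] == "healthy"]
    fm = cohort[cohort["group"] == "fm"]

    desc_rows = []
    for col in endpoints + covariates:
        for gname, g in (("healthy", healthy), ("fm", fm)):
            x = g[col].dropna().to_numpy(dtype=float)
            if x.size == 0:
                continue
            desc_rows.append(
                {
                    "variable": col, "group": gname, "n": x.size,
                    "mean": x.mean(), "sd": x.std(ddof=1) if x.size > 1 else np.nan,
                    "median": np.median(x), "min": x.min(), "max": x.max(),
                }
            )
    descriptives = pd.DataFrame(desc_rows)

    comp_rows = []
    for col in endpoints + covariates:
        a = healthy[col].dropna().to_numpy(dtype=float)
        b = fm[col].dropna().to_numpy(dtype=float)
        if a.size < 3 or b.size < 3:
            continue  # one-group covariate (e.g. disease-specific scale)
        res = compare_groups(a, b)
        comp_rows.append(
            {
                "variable": col, "test": res.test_name, "statistic": res.statistic,
                "p_raw": res.p_raw, "healthy": res.summary_a, "fm": res.summary_b,
                "gate": res.gate,
            }
        )
    comparisons = pd.DataFrame(comp_rows)

    corr_rows = []
    for endpoint in endpoints:
        for cov in covariates:
            pair = cohort[[endpoint, cov]].dropna()
            if len(pair) < 4:
                continue
            try:
                res = correlate(pair[endpoint], pair[cov])
            except ValueError:
                continue
            corr_rows.append(
                {
                    "endpoint": endpoint, "covariate": cov, "method": res.method,
                    "r": res.r, "strength": res.strength, "p_raw": res.p_raw, "n": res.n,
                }
            )
    correlations = pd.DataFrame(corr_rows)

    reg_rows = []
    models: dict[str, RegressionResult] = {}
    for response in responses:
        if response not in cohort.columns:
            continue
        sig = correlations[
            (correlations["endpoint"] == response) & (correlations["p_raw"] < 0.05)
        ]["covariate"].tolist()
        if not sig:
            continue
        data = cohort[[response] + sig].dropna()
        # keep the model identifiable on the available rows
        while sig and len(data) <= len(sig) + 2:
            sig = sig[:-1]
            data = cohort[[response] + sig].dropna()
        if not sig:
            continue
        try:
            res = backward_ols(
                data[response], data[sig], p_remove=p_remove, response_name=response
            )
        except ValueError:
            continue
        models[response] = res
        for pred, row in res.params.iterrows():
            reg_rows.append(
                {
                    "response": response, "predictor": pred, "beta": row["beta"],
                    "se": row["se"], "beta_std": row["beta_std"], "p_raw": row["p_raw"],
                    "vif": row["vif"], "model_p": res.model_p,
                    "durbin_watson": res.durbin_watson, "n": res.n,
                }
            )
    regressions = pd.DataFrame(reg_rows)

    family_rows = []
    for _, r in comparisons.iterrows():
        family_rows.append({"source": "comparison", "label": r["variable"], "p_raw": r["p_raw"]})
    for _, r in correlations.iterrows():
        family_rows.append(
            {"source": "correlation", "label": f"{r['endpoint']}~{r['covariate']}", "p_raw": r["p_raw"]}
        )
    for _, r in regressions.iterrows():
        family_rows.append(
            {"source": "regression", "label": f"{r['response']}~{r['predictor']}", "p_raw": r["p_raw"]}
        )
    fdr_family = pd.DataFrame(family_rows)
    if len(fdr_family):
        fdr_family["p_raw"] = fdr_family["p_raw"].clip(lower=np.nextafter(0, 1))
        if fdr_mode == "global":
            fdr_family["p_fdr"] = bh_fdr(fdr_family["p_raw"].to_numpy())
        elif fdr_mode == "per_table":
            fdr_family["p_fdr"] = np.nan
            for src, idx in fdr_family.groupby("source").groups.items():
                fdr_family.loc[idx, "p_fdr"] = bh_fdr(fdr_family.loc[idx, "p_raw"].to_numpy())
        else:
            raise ValueError("fdr_mode must be 'global' or 'per_table'")
        lut = dict(zip(fdr_family["label"], fdr_family["p_fdr"]))
        if len(comparisons):
            comparisons["p_fdr"] = comparisons["variable"].map(lut)
        if len(correlations):
            correlations["p_fdr"] = (
                correlations["endpoint"] + "~" + correlations["covariate"]
            ).map(lut)
        if len(regressions):
            regressions["p_fdr"] = (regressions["response"] + "~" + regressions["predictor"]).map(lut)
    return AnalysisBundle(
        comparisons=comparisons,
        correlations=correlations,
        regressions=regressions,
        fdr_family=fdr_family,
        descriptives=descriptives,
        regression_models=models,
    )


# ---------------------------------------------------------------------------
# helpers


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[~np.isnan(x)]


def _mean_sd(x: np.ndarray) -> str:
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"


def _median_range(x: np.ndarray) -> str:
    return f"{np.median(x):.2f} ({x.min():.2f}–{x.max():.2f})"
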