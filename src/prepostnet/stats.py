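"""Inference layer: covariate adjustment, paired sign-flip permutation
tests, Benjamini–Hochberg FDR, brain–behavior correlations and the
classical behavioral tests (two-sample t, Levene, two-way ANOVA).

The permutation scheme is the paired one: the statistic is the mean
pre-to-post difference of a metric AUC and the null is generated by
independent random sign flips of each subject's difference, with the
add-one p estimator p = (1 + #{|null| >= |obs|}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "CorrelationResult",
    "residualize_covariates",
    "adjust_for_covariates",
    "paired_permutation_test",
    "paired_permutation_test_matrix",
    "bh_fdr",
    "metric_cognition_correlation",
    "correlation_table",
    "effect_size_from_r",
    "two_sample_t",
    "two_sample_t_from_data",
    "levene_test",
    "two_way_anova",
    "classify_significance",
]


@dataclass
class PermutationResult:
    metric: str
    node: str
    observed_stat: float  # mean pre->post AUC difference
    p_raw: float
    p_adjusted: float
    n_permutations: int
    seed: int


@dataclass
class CorrelationResult:
    metric: str
    node: str
    scale: str
    r: float
    p_raw: float
    p_adjusted: float
    effect_size_d: float
    n: int
    significance: str = "none"


# ---------------------------------------------------------------------------
# covariate adjustment
# ---------------------------------------------------------------------------

def _design(age, sex) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    sex01 = np.asarray([1.0 if s in ("M", "m", 1, True) else 0.0
                        for s in np.asarray(sex).ravel()])
    if age.shape != sex01.shape:
        raise ValueError("age and sex must have equal length")
    return np.column_stack([np.ones_like(age), age, sex01])


def residualize_covariates(values, age, sex) -> np.ndarray:
    """Full least-squares residuals of ``values`` on
    [intercept, age, sex]; residuals sum to zero."""
    values = np.asarray(values, dtype=float)
    x = _design(age, sex)
    if values.shape[0] < 4:
        raise ValueError("need at least 4 observations")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient covariate design (constant age "
                         "and/or single-sex sample)")
    beta, *_ = np.linalg.lstsq(x, values, rcond=None)
    return values - x @ beta


def adjust_for_covariates(values, age, sex) -> np.ndarray:
    """Remove only the age/sex contributions (covariates centered,
    intercept retained), preserving the mean of ``values``.

    This is the adjustment applied to paired pre-to-post differences
    before the sign-flip test: a full residualization would also remove
    the mean difference, i.e. the effect under test.
    """
    values = np.asarray(values, dtype=float)
    x = _design(age, sex)
    xc = x.copy()
    xc[:, 1:] -= xc[:, 1:].mean(axis=0)
    if np.linalg.matrix_rank(xc) < xc.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(xc, values, rcond=None)
    return values - xc[:, 1:] @ beta[1:]


# ---------------------------------------------------------------------------
# permutation testing
# ---------------------------------------------------------------------------

def paired_permutation_test_matrix(diffs: np.ndarray, n_perm: int,
                                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Sign-flip test on each column of an (n_subjects x n_tests) matrix
    of paired differences; the same flip draws are shared across columns.

    Returns ``(observed, p_raw)`` vectors.  Columns of all-zero
    differences get p = 1 by convention.
    """
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n, m = diffs.shape
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = diffs.mean(axis=0)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    null = (signs @ diffs) / n                       # (n_perm x m)
    exceed = (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    degenerate = np.all(diffs == 0, axis=0)
    p[degenerate] = 1.0
    return observed, p


def paired_permutation_test(pre, post, n_perm: int = 10_000,
                            seed: int = 0) -> tuple[float, float]:
    """Paired sign-flip permutation test of mean(post - pre) = 0."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    obs, p = paired_permutation_test_matrix((post - pre)[:, None],
                                            n_perm, seed)
    return float(obs[0]), float(p[0])


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order:
    sort ascending, adj_(i) = min_{j>=i} (p_(j) * m / j), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# brain-behavior correlations
# ---------------------------------------------------------------------------

def effect_size_from_r(r: float) -> float:
    """Cohen's d from a Pearson correlation: d = 2|r| / sqrt(1 - r^2)."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1")
    return 2.0 * abs(r) / np.sqrt(1.0 - r * r)


def metric_cognition_correlation(delta_metric, delta_score,
                                 metric: str = "", node: str = "",
                                 scale: str = "") -> CorrelationResult:
    """Pearson correlation between a nodal-metric change and a cognitive
    score change; two-sided p from t = r sqrt(n-2)/sqrt(1-r^2), Cohen's d
    attached.  FDR adjustment/labels are assigned at the family level
    (see :func:`correlation_table`)."""
    x = np.asarray(delta_metric, dtype=float)
    y = np.asarray(delta_score, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input vector")
    r, p = sps.pearsonr(x, y)
    r = float(r)
    d = float("inf") if abs(r) >= 1.0 else effect_size_from_r(r)
    return CorrelationResult(metric, node, scale, r, float(p), float(p),
                             d, n)


def correlation_table(results: list[CorrelationResult],
                      alpha_significant: float = 0.05,
                      alpha_marginal: float = 0.1) -> pd.DataFrame:
    """FDR-adjust a family of correlation tests together and label each
    as significant / marginal / none."""
    if not results:
        return pd.DataFrame(columns=["metric", "node", "scale", "r",
                                     "p_raw", "p_adjusted",
                                     "effect_size_d", "n", "significance"])
    adj = bh_fdr([cr.p_raw for cr in results])
    rows = []
    for cr, pa in zip(results, adj):
        cr.p_adjusted = float(pa)
        cr.significance = classify_significance(pa, alpha_significant,
                                                alpha_marginal)
        rows.append(vars(cr).copy())
    return pd.DataFrame(rows)


def classify_significance(p_adjusted: float,
                          alpha_significant: float = 0.05,
                          alpha_marginal: float = 0.1) -> str:
    """significant if p < 0.05, marginal if 0.05 <= p < 0.1, else none
    (strict inequalities; p = 0.05 is marginal)."""
    if not 0 <= p_adjusted <= 1:
        raise ValueError("p_adjusted must lie in [0, 1]")
    if alpha_marginal <= alpha_significant:
        raise ValueError("alpha_marginal must exceed alpha_significant")
    if p_adjusted < alpha_significant:
        return "significant"
    if p_adjusted < alpha_marginal:
        return "marginal"
    return "none"


# ---------------------------------------------------------------------------
# classical behavioral tests
# ---------------------------------------------------------------------------

def two_sample_t(mean1: float, sd1: float, n1: int,
                 mean2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Pooled-variance independent-samples t-test from group summaries;
    df = n1 + n2 - 2, two-sided p."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def two_sample_t_from_data(x1, x2) -> tuple[float, float]:
    """Raw-data form; equals the summary form when the summaries are
    computed from the same data."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return two_sample_t(x1.mean(), x1.std(ddof=1), x1.size,
                        x2.mean(), x2.std(ddof=1), x2.size)


def levene_test(group1, group2) -> tuple[float, float]:
    """Levene's test for equality of variances on absolute deviations
    from the group means (the classic mean-centered form)."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("need n >= 2 per group")
    f, p = sps.levene(g1, g2, center="mean")
    return float(f), float(p)


def two_way_anova(scores, factor_treatment, factor_time) -> pd.DataFrame:
    """2x2 between-cells ANOVA with interaction, type-II sums of squares.

    Returns a table with F and p for Treatment, Time and
    Treatment x Time.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    df = pd.DataFrame({
        "score": np.asarray(scores, dtype=float),
        "treatment": list(factor_treatment),
        "time": list(factor_time),
    })
    counts = df.groupby(["treatment", "time"]).size()
    if len(counts) < 4 or (counts < 2).any():
        raise ValueError("need at least 2 observations in each of the "
                         "4 treatment x time cells")
    model = smf.ols("score ~ C(treatment) * C(time)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = table.rename(index={
        "C(treatment)": "Treatment",
        "C(time)": "Time",
        "C(treatment):C(time)": "Treatment x Time",
    })
    return out[["F", "PR(>F)"]].rename(columns={"PR(>F)": "p"}).iloc[:3]
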