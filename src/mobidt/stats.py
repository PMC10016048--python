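"""Scalar statistics: normality-gated tests, mixed ANOVA, improver
classification, and the combined two-stage FDR.

Conventions follow standard reporting practice: paired t with Cohen's
d = t / sqrt(n); Wilcoxon signed rank with the normal approximation z and
Cohen's r = |z| / sqrt(N) where N counts observations across both
conditions (2n); independent t with pooled-SD Cohen's d; 2x2 mixed ANOVA
with classical eta-squared (effect SS over total SS).  The improver
criterion compares each participant's walking-minus-sitting d' change with
the 95% band of a zero-mean normal whose SD is that of the whole cohort's
change distribution; only positive exceedance counts as improvement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateSetError, EmptySampleError, InvalidConfigError

__all__ = [
    "TestResult",
    "normality_gate",
    "paired_t",
    "wilcoxon_signed_rank",
    "independent_t",
    "anova_2x2_mixed",
    "classify_improver",
    "classify_cohort",
    "bky_fdr",
    "aggregate_pvalues_for_fdr",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p_value: float
    effect_size: float
    effect_name: str  # cohen_d | cohen_r | eta_squared
    tails: int = 2

    def as_row(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p_value,
            self.effect_name: self.effect_size,
        }


def normality_gate(differences: np.ndarray, alpha: float = 0.05) -> str:
    """Route to 'parametric' or 'nonparametric' via a Shapiro-Wilk test."""
    d = np.asarray(differences, dtype=float)
    if len(d) < 3:
        raise InvalidConfigError("Shapiro-Wilk needs n >= 3")
    if np.ptp(d) == 0:
        warnings.warn("constant sample: routing to the nonparametric branch", stacklevel=2)
        return "nonparametric"
    _, p = sps.shapiro(d)
    return "parametric" if p >= alpha else "nonparametric"


def paired_t(x: np.ndarray, y: np.ndarray, name: str = "paired_t") -> TestResult:
    """Two-tailed paired t-test with Cohen's d = mean(diff) / SD(diff)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise InvalidConfigError("paired samples must be equal-length 1D, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateSetError("zero-variance differences")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(name, float(t), n - 1, float(p), float(t / np.sqrt(n)), "cohen_d")


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, name: str = "wilcoxon", method: str = "approx"
) -> TestResult:
    """Wilcoxon signed rank test; effect size Cohen's r = |z| / sqrt(2n).

    ``method='approx'`` uses the tie- and continuity-corrected normal
    approximation to obtain z (the reporting convention the effect size is
    defined on); ``method='exact'`` uses the exact signed-rank distribution
    for the p-value while z is still taken from the approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 5:
        raise InvalidConfigError("need equal-length 1D samples, n >= 5")
    d = x - y
    if np.all(d == 0):
        raise DegenerateSetError("all paired differences are zero")
    approx = sps.wilcoxon(x, y, correction=True, method="approx")
    nz = d[d != 0]
    ranks = sps.rankdata(np.abs(nz))
    direction = np.sign(ranks[nz > 0].sum() - ranks[nz < 0].sum())
    z = float(direction * abs(approx.zstatistic))  # z carries the sign of x - y
    if method == "exact":
        res = sps.wilcoxon(x, y, method="exact")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p = float(approx.statistic), float(approx.pvalue)
    n = len(d)
    r = abs(z) / np.sqrt(2 * n)
    out = TestResult(name, stat, np.nan, p, float(r), "cohen_r")
    out.z = z  # attach the normal-approximation statistic for reporting
    return out


def independent_t(a: np.ndarray, b: np.ndarray, name: str = "independent_t") -> TestResult:
    """Pooled-variance two-sample t with pooled-SD Cohen's d."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.ndim != 1 or b.ndim != 1 or len(a) < 2 or len(b) < 2:
        raise InvalidConfigError("each group needs n >= 2")
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise DegenerateSetError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * sps.t.sf(abs(t), df=df)
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    return TestResult(name, float(t), df, float(p), float(d), "cohen_d")


def anova_2x2_mixed(
    groups: np.ndarray,
    y: np.ndarray,
    name: str = "anova",
) -> tuple[dict[str, TestResult], pd.DataFrame]:
    """2 (between group) x 2 (within condition) mixed-design ANOVA.

    ``groups`` labels each subject; ``y`` is subjects x 2 repeated measures.
    Classical univariate decomposition: the group effect is tested against
    subjects-within-groups error, the within factor and the interaction
    against the subject x condition error.  Eta-squared is classical
    (effect SS / total SS); the SS table conserves SS_total exactly.
    """
    groups = np.asarray(groups)
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2 or len(groups) != len(y):
        raise InvalidConfigError("y must be subjects x 2 with one group label per subject")
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise InvalidConfigError("exactly 2 groups required")
    ns = {g: int((groups == g).sum()) for g in labels}
    if min(ns.values()) < 2:
        raise InvalidConfigError("each group needs n >= 2 subjects")

    n_subj = len(y)
    gm = y.mean()
    ss_total = ((y - gm) ** 2).sum()
    subj_means = y.mean(axis=1)
    ss_between_subj = 2 * ((subj_means - gm) ** 2).sum()
    group_means = {g: y[groups == g].mean() for g in labels}
    ss_group = 2 * sum(ns[g] * (group_means[g] - gm) ** 2 for g in labels)
    ss_subj_within = ss_between_subj - ss_group

    cond_means = y.mean(axis=0)
    ss_cond = n_subj * ((cond_means - gm) ** 2).sum()
    ss_cells = sum(
        ns[g] * ((y[groups == g].mean(axis=0) - gm) ** 2).sum() for g in labels
    )
    ss_inter = ss_cells - ss_group - ss_cond
    ss_within_subj = ss_total - ss_between_subj
    ss_err_within = ss_within_subj - ss_cond - ss_inter

    df_group, df_err_b = 1, n_subj - 2
    df_cond = df_inter = 1
    df_err_w = n_subj - 2

    def _f(ss_eff, df_eff, ss_err, df_err):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err == 0:
            f = 0.0 if ms_eff == 0 else np.inf
        else:
            f = ms_eff / ms_err
        p = float(sps.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
        return float(f), p

    f_g, p_g = _f(ss_group, df_group, ss_subj_within, df_err_b)
    f_c, p_c = _f(ss_cond, df_cond, ss_err_within, df_err_w)
    f_i, p_i = _f(ss_inter, df_inter, ss_err_within, df_err_w)

    def _eta(ss_eff):
        return float(ss_eff / ss_total) if ss_total > 0 else 0.0

    results = {
        "group": TestResult(f"{name}_group", f_g, df_err_b, p_g,
                            _eta(ss_group), "eta_squared"),
        "condition": TestResult(f"{name}_condition", f_c, df_err_w, p_c,
                                _eta(ss_cond), "eta_squared"),
        "interaction": TestResult(f"{name}_interaction", f_i, df_err_w, p_i,
                                  _eta(ss_inter), "eta_squared"),
    }
    table = pd.DataFrame(
        {
            "source": ["group", "subjects_within_groups", "condition",
                       "interaction", "condition_x_subjects", "total"],
            "ss": [ss_group, ss_subj_within, ss_cond, ss_inter, ss_err_within, ss_total],
            "df": [df_group, df_err_b, df_cond, df_inter, df_err_w, 2 * n_subj - 1],
        }
    )
    return results, table


def classify_improver(
    delta_dprime: float, cohort_deltas: np.ndarray, alpha: float = 0.05
) -> tuple[str, float]:
    """Label one participant IMP/nIMP against the cohort-null 95% band.

    The null is a zero-mean normal with SD equal to the sample SD (n-1
    denominator) of the whole cohort's walking-minus-sitting d' changes,
    including the candidate.  Only positive exceedance of the two-sided
    band maps to IMP; decline and no-change are both nIMP.
    """
    deltas = np.asarray(cohort_deltas, dtype=float)
    if len(deltas) < 3:
        raise InvalidConfigError("cohort must have >= 3 participants")
    sigma = deltas.std(ddof=1)
    if sigma == 0:
        raise DegenerateSetError("degenerate cohort: zero spread of d' changes")
    threshold = float(sps.norm.ppf(1 - alpha / 2.0) * sigma)
    return ("IMP" if delta_dprime > threshold else "nIMP"), threshold


def classify_cohort(cohort_deltas: np.ndarray, alpha: float = 0.05) -> tuple[list[str], float]:
    """Classify every participant of a cohort; returns (labels, threshold)."""
    deltas = np.asarray(cohort_deltas, dtype=float)
    labels = []
    threshold = np.nan
    for d in deltas:
        lab, threshold = classify_improver(float(d), deltas, alpha)
        labels.append(lab)
    return labels, threshold


def bky_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Two-stage step-up FDR control (Benjamini-Krieger-Yekutieli).

    Stage 1 runs Benjamini-Hochberg at q' = q/(1+q) to estimate the number
    of true nulls; stage 2 reruns the step-up pass at the adjusted level.
    Returns the rejection mask and the critical p (largest rejected
    p-value; NaN when nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.nan
    if np.any((p <= 0) | (p > 1)):
        raise InvalidConfigError("p-values must lie in (0, 1]")
    mask = multipletests(p, alpha=q, method="fdr_tsbky")[0]
    crit = float(p[mask].max()) if mask.any() else np.nan
    return mask, crit


def aggregate_pvalues_for_fdr(
    scalar_results: list[TestResult],
    cluster_results: dict[str, "ClusterResult"] | None = None,  # noqa: F821
) -> pd.DataFrame:
    """Assemble the combined p-value set entering the FDR correction.

    One p-value per scalar test (a 2x2 ANOVA contributes its three), plus
    the minimum cluster p-value of each EEG comparison; comparisons that
    formed no cluster contribute nothing.  The order of entries is recorded
    for audit.
    """
    rows = [{"label": r.name, "p": r.p_value, "kind": "scalar"} for r in scalar_results]
    for label, cres in (cluster_results or {}).items():
        mp = cres.min_p()
        if np.isfinite(mp):
            rows.append({"label": f"{label}_min_cluster", "p": mp, "kind": "cluster"})
    return pd.DataFrame(rows, columns=["label", "p", "kind"])
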