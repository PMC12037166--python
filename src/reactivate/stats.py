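"""Cohort-level reactivation statistics.

Implements the group analyses applied to the task-fraction results: the
2 x 2 mixed-design ANOVA (one within-subject factor with two levels, e.g.
pre/post rest; one between-subject factor, e.g. hand group), paired and
one-sample t-tests with Cohen's d, Pearson correlation, Bonferroni
correction, and the behavioral improvement score.

The mixed ANOVA uses the classical sums-of-squares decomposition.  For a
two-level within factor this is computed exactly through the equivalent
split into difference scores (session and interaction effects) and subject
means (group effect); with unbalanced groups the single-degree-of-freedom
effects follow the Type-III / unweighted-means convention, which is what
standard neuroimaging statistics packages report.  All tests are
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

__all__ = [
    "EffectResult",
    "AnovaTable",
    "TTestResult",
    "CorrelationResult",
    "SubjectResult",
    "fraction_difference",
    "mixed_anova_2x2",
    "paired_t",
    "one_sample_t",
    "pearson_corr",
    "bonferroni",
    "behavior_improvement",
]


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA effect: F(df1, df2), p, and partial eta squared."""

    F: float
    df1: int
    df2: int
    p: float
    eta_p_sq: float


@dataclass(frozen=True)
class AnovaTable:
    """Effects of the 2x2 mixed design (group terms absent for one group)."""

    session: EffectResult
    group: EffectResult | None = None
    interaction: EffectResult | None = None

    def to_dict(self) -> dict:
        out = {}
        for name in ("session", "group", "interaction"):
            eff = getattr(self, name)
            if eff is not None:
                out[name] = vars(eff).copy()
        return out


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    cohen_d: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class SubjectResult:
    """Per-subject analysis outcome: the cohort-level unit of data.

    ``fractions`` maps ``(method, roi, hemisphere, rest_session)`` to a
    task-fraction percentage, with ``rest_session`` in {"pre", "post"}.
    """

    subject_id: str
    group: str
    fractions: dict = field(default_factory=dict)
    behavior_improvement: float = 0.0

    def __post_init__(self) -> None:
        for key, value in self.fractions.items():
            if not (0.0 <= value <= 100.0):
                raise ValueError(f"fraction {key}={value} outside [0, 100]")


def fraction_difference(result: SubjectResult, cell: tuple) -> float:
    """Post-minus-pre task fraction (percentage points) for one cell.

    ``cell`` is ``(method, roi, hemisphere)``; both rest sessions must be
    present.
    """
    method, roi, hemisphere = cell
    try:
        post = result.fractions[(method, roi, hemisphere, "post")]
        pre = result.fractions[(method, roi, hemisphere, "pre")]
    except KeyError as exc:
        raise ValueError(f"missing rest session {exc} for cell {cell}") from exc
    return post - pre


def _effect_coded_ols(y: np.ndarray, x: np.ndarray) -> tuple:
    """OLS of y on [1, x] with x in {+1,-1}; returns per-coefficient Type-III
    SS, residual SS and df."""
    X = np.column_stack([np.ones_like(y), x])
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    rss = float(np.sum((y - X @ beta) ** 2))
    ss = beta**2 / np.diag(xtx_inv)
    return ss, rss, y.size - 2


def _f_effect(ss_eff: float, ss_err: float, df1: int, df2: int) -> EffectResult:
    if ss_err <= 0.0 and ss_eff <= 0.0:
        return EffectResult(0.0, df1, df2, 1.0, 0.0)
    ms_err = ss_err / df2
    F = float((ss_eff / df1) / ms_err) if ms_err > 0 else float("inf")
    p = float(_stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    eta = float(ss_eff / (ss_eff + ss_err)) if (ss_eff + ss_err) > 0 else 0.0
    return EffectResult(F, df1, df2, p, eta)


def mixed_anova_2x2(pre, post, groups=None) -> AnovaTable:
    """Classical mixed-design ANOVA: 2-level within factor x 2 groups.

    Parameters
    ----------
    pre, post
        Within-factor measurements, one complete pair per subject.
    groups
        Between-subject labels (exactly two distinct values), or None for a
        single-group design, in which case only the within effect is
        computed and its F equals the squared paired t statistic.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D arrays of equal length")
    n = pre.size
    diff = post - pre
    subj_mean = 0.5 * (pre + post)

    if groups is None or len(set(map(str, groups))) == 1:
        if n < 2:
            raise ValueError("need at least 2 subjects")
        # session effect == one-sample t on difference scores
        mean_d = diff.mean()
        ss_session = n * mean_d**2
        rss = float(np.sum((diff - mean_d) ** 2))
        return AnovaTable(session=_f_effect(ss_session, rss, 1, n - 1))

    labels = np.asarray([str(g) for g in groups])
    if labels.shape != (n,):
        raise ValueError("groups must have one label per subject")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {uniq}")
    counts = {u: int((labels == u).sum()) for u in uniq}
    if min(counts.values()) < 2:
        raise ValueError(f"each group needs >= 2 subjects, got {counts}")
    x = np.where(labels == uniq[0], 1.0, -1.0)

    # within-subject part: difference scores
    (ss_session, ss_inter), rss_d, df_w = _effect_coded_ols(diff, x)
    # between-subject part: subject means
    (_, ss_group), rss_m, df_b = _effect_coded_ols(subj_mean, x)

    # Scale to the classical y-scale decomposition: each subject contributes
    # two observations, so difference-based SS carry a factor 1/2 and
    # mean-based SS a factor 2.  F and eta_p^2 are scale-invariant; the
    # scaling keeps reported SS comparable across the two strata.
    return AnovaTable(
        session=_f_effect(ss_session / 2.0, rss_d / 2.0, 1, df_w),
        group=_f_effect(2.0 * ss_group, 2.0 * rss_m, 1, df_b),
        interaction=_f_effect(ss_inter / 2.0, rss_d / 2.0, 1, df_w),
    )


def paired_t(x, y) -> TTestResult:
    """Paired t-test on ``d = x - y`` with Cohen's d = mean(d)/sd(d)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired_t needs two equal-length vectors with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance differences: paired t undefined")
    n = d.size
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = 2.0 * float(_stats.t.sf(abs(t), n - 1))
    return TTestResult(t, n - 1, p, float(d.mean() / sd))


def one_sample_t(values, mu0: float) -> TTestResult:
    """One-sample t-test against ``mu0`` with Cohen's d = (mean-mu0)/sd."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("one_sample_t needs a vector with n >= 2")
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance sample: t undefined")
    n = v.size
    t = float((v.mean() - mu0) / (sd / np.sqrt(n)))
    p = 2.0 * float(_stats.t.sf(abs(t), n - 1))
    return TTestResult(t, n - 1, p, float((v.mean() - mu0) / sd))


def pearson_corr(x, y) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-based p (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson_corr needs two equal-length vectors with n >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("constant input: correlation undefined")
    res = _stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), x.size)


def bonferroni(p_values, m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) with explicit family size ``m``."""
    p = np.asarray(p_values, dtype=float)
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than the {p.size} tests")
    return np.minimum(1.0, p * m)


def behavior_improvement(errors) -> float:
    """Tracking-error decrease: mean of sessions 1-3 minus session 4."""
    e = np.asarray(errors, dtype=float)
    if e.shape != (4,):
        raise ValueError(f"expected 4 session errors, got shape {e.shape}")
    return float(e[:3].mean() - e[3])
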