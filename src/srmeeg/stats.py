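"""Behavioral scores and the statistical battery for group comparisons.

Covers the recognition / self-referential-memory (SRM) bias scores, the
two-way mixed-design ANOVA (group between subjects, task condition
within subjects), pooled-variance independent t-tests, Pearson
correlation, simple linear regression, and Bonferroni correction.

The mixed ANOVA is computed from classical split-plot sums of squares
with no sphericity correction:

    F_group = MS_group / MS_subjects(group),   df (g-1, N-g)
    F_cond  = MS_cond  / MS_error,             df (c-1, (c-1)(N-g))
    F_inter = MS_inter / MS_error,             df ((g-1)(c-1), (c-1)(N-g))

With two groups and a single condition the group F collapses to the
square of the pooled-variance t statistic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

__all__ = [
    "BehavioralRecord",
    "StatResult",
    "recognition_score",
    "srm_bias",
    "mixed_anova",
    "ttest_ind",
    "pearson",
    "linreg",
    "bonferroni",
]


@dataclass
class StatResult:
    """A single test statistic with its degrees of freedom and p-value."""

    statistic: float
    df: tuple | float
    p: float
    effect: dict = field(default_factory=dict)
    flag: str | None = None  # e.g. "zero-error-SS" when F is undefined


def recognition_score(hits: int, n_old: int, false_alarms: int,
                      n_new: int) -> float:
    """Proportion of hits minus proportion of false alarms.

    ``hits`` out of ``n_old`` previously studied items; ``false_alarms``
    out of ``n_new`` unstudied lures. Ranges over [-1, 1]; 0 is chance.
    """
    if n_old <= 0 or n_new <= 0:
        raise ValueError("n_old and n_new must be positive")
    if not (0 <= hits <= n_old) or not (0 <= false_alarms <= n_new):
        raise ValueError("counts out of range")
    return hits / n_old - false_alarms / n_new


def srm_bias(rec_self: float, rec_other: float) -> float:
    """Self-referential memory bias: recognition(self) - recognition(other).

    Positive values indicate a self-referential memory advantage.
    """
    if not (np.isfinite(rec_self) and np.isfinite(rec_other)):
        raise ValueError("recognition scores must be finite")
    return rec_self - rec_other


@dataclass
class BehavioralRecord:
    """Per-condition recognition behaviour for one subject.

    ``conditions`` maps each task condition to a dict with keys
    ``n_old, n_new, hits, false_alarms, hit_rate, fa_rate, recognition,
    mean_rt``. The SRM bias is derived from the self and other
    conditions.
    """

    subject_id: str
    group: str
    conditions: dict = field(default_factory=dict)

    @classmethod
    def from_counts(cls, subject_id: str, group: str,
                    counts: dict) -> "BehavioralRecord":
        """Build from ``{condition: (hits, n_old, fa, n_new, mean_rt)}``."""
        conds = {}
        for cond, (hits, n_old, fa, n_new, rt) in counts.items():
            conds[cond] = dict(
                n_old=int(n_old), n_new=int(n_new), hits=int(hits),
                false_alarms=int(fa),
                hit_rate=hits / n_old, fa_rate=fa / n_new,
                recognition=recognition_score(hits, n_old, fa, n_new),
                mean_rt=float(rt),
            )
        return cls(subject_id, group, conds)

    def recognition(self, condition: str) -> float:
        return self.conditions[condition]["recognition"]

    @property
    def srm_bias(self) -> float:
        return srm_bias(self.recognition("self"), self.recognition("other"))


def mixed_anova(values: np.ndarray, groups: np.ndarray) -> dict[str, StatResult]:
    """Two-way mixed-design ANOVA (group between, condition within).

    Parameters
    ----------
    values
        ``(n_subjects, n_conditions)`` table; every subject has a value
        in every condition (balanced within-subject design).
    groups
        Per-subject group labels (any hashable; two or more levels).

    Returns
    -------
    dict with keys ``"group"``, and — when there is more than one
    condition — ``"condition"`` and ``"interaction"``; values are
    :class:`StatResult` with classical df and no sphericity correction.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("values must be (n_subjects, n_conditions)")
    if np.isnan(x).any():
        raise ValueError("missing cells in the within-subject design")
    groups = np.asarray(groups)
    if groups.shape[0] != x.shape[0]:
        raise ValueError("groups length != n_subjects")
    levels, g_idx = np.unique(groups, return_inverse=True)
    g = levels.size
    N, C = x.shape
    if g < 2 or np.bincount(g_idx).min() < 2:
        raise ValueError("need >= 2 subjects in each of >= 2 groups")

    gm = x.mean()
    subj_means = x.mean(axis=1)
    group_means = np.array([x[g_idx == k].mean() for k in range(g)])
    n_per = np.bincount(g_idx)

    ss_total = ((x - gm) ** 2).sum()
    ss_between_subj = C * ((subj_means - gm) ** 2).sum()
    ss_group = C * (n_per * (group_means - gm) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    df_group, df_subj = g - 1, N - g

    out: dict[str, StatResult] = {}

    def _f(ss_num, df_num, ss_den, df_den) -> StatResult:
        if ss_den <= 0 or df_den <= 0:
            return StatResult(np.nan, (df_num, df_den), np.nan,
                              flag="zero-error-SS")
        f = (ss_num / df_num) / (ss_den / df_den)
        p = float(spstats.f.sf(f, df_num, df_den))
        return StatResult(float(f), (df_num, df_den), p)

    out["group"] = _f(ss_group, df_group, ss_subj_within, df_subj)

    if C > 1:
        cond_means = x.mean(axis=0)
        cell_means = np.array([x[g_idx == k].mean(axis=0) for k in range(g)])
        ss_within_subj = ss_total - ss_between_subj
        ss_cond = N * ((cond_means - gm) ** 2).sum()
        ss_cells = (n_per[:, None] * (cell_means - gm) ** 2).sum()
        ss_inter = ss_cells - ss_group - ss_cond
        ss_err = ss_within_subj - ss_cond - ss_inter
        df_cond = C - 1
        df_inter = (g - 1) * (C - 1)
        df_err = (C - 1) * (N - g)
        out["condition"] = _f(ss_cond, df_cond, ss_err, df_err)
        out["interaction"] = _f(max(ss_inter, 0.0), df_inter, ss_err, df_err)
    return out


def ttest_ind(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Two-tailed pooled-variance (Student) independent t-test.

    Pooled variance is used, so df = n_a + n_b - 2 (the convention that
    yields df = 34 for two groups of 18).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return StatResult(0.0, a.size + b.size - 2, 1.0,
                              effect={"mean_diff": 0.0})
        raise ValueError("zero pooled variance")
    t, p = spstats.ttest_ind(a, b, equal_var=True)
    return StatResult(float(t), a.size + b.size - 2, float(p),
                      effect={"mean_diff": float(a.mean() - b.mean())})


def pearson(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Two-tailed Pearson correlation with t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r, p = spstats.pearsonr(x, y)
    return StatResult(float(r), x.size - 2, float(p),
                      effect={"r_squared": float(r ** 2)})


def linreg(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Simple least-squares regression of y on x, with an F-test.

    Returns the F statistic (df = (1, n - 2)), with slope, intercept
    and R-squared (= Pearson r squared, exactly) in ``effect``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched samples of length >= 3")
    if x.std() == 0:
        raise ValueError("constant regressor")
    res = spstats.linregress(x, y)
    f = float(res.rvalue ** 2 / (1 - res.rvalue ** 2) * (x.size - 2)) \
        if abs(res.rvalue) < 1 else np.inf
    return StatResult(f, (1, x.size - 2), float(res.pvalue),
                      effect={"slope": float(res.slope),
                              "intercept": float(res.intercept),
                              "r_squared": float(res.rvalue ** 2)})


def bonferroni(pvals: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, p * m)`` (m defaults to len(p))."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else int(m)
    return np.minimum(1.0, p * m)
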