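"""Normality-gated pairwise comparisons with Bonferroni correction.

The comparison branch follows the data distribution: Shapiro-Wilk is run
on each sample (on the paired differences for paired designs) at alpha =
0.05; when normality is not rejected a t-test is used (paired, or Welch
two-sample by default), otherwise the Wilcoxon alternative (signed-rank or
rank-sum). Raw p-values are Bonferroni-corrected within their feature
group: p_bonf = min(1, m * p_raw). Hedges' g (small-sample-corrected
standardized mean difference) accompanies parametric comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as st

__all__ = ["PairwiseResult", "gated_pairwise", "hedges_g", "bonferroni"]


@dataclass
class PairwiseResult:
    """Outcome of one gated pairwise comparison."""

    label: str
    test: str  # "t" or "wilcoxon"
    statistic: float
    p_raw: float
    p_bonferroni: float
    hedges_g: float  # NaN for the non-parametric branch
    n: tuple[int, int]
    normal: bool  # whether the normality gate passed
    note: str = ""


def bonferroni(p_raw: float, m_comparisons: int) -> float:
    """Bonferroni-corrected p within a feature group: min(1, m * p)."""
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    return float(min(1.0, m_comparisons * p_raw))


def hedges_g(a: np.ndarray, b: np.ndarray) -> float:
    """Small-sample-corrected standardized mean difference.

    g = J * (mean_a - mean_b) / s_pooled with the correction factor
    J = 1 - 3 / (4 (n_a + n_b - 2) - 1); |g| is always below the
    uncorrected Cohen's d.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("hedges_g needs at least 2 observations per sample")
    s_pooled_sq = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if s_pooled_sq == 0:
        raise ZeroDivisionError("zero pooled variance; effect size undefined")
    j = 1.0 - 3.0 / (4.0 * (na + nb - 2) - 1.0)
    return float(j * (a.mean() - b.mean()) / np.sqrt(s_pooled_sq))


def gated_pairwise(
    a: np.ndarray,
    b: np.ndarray,
    paired: bool = False,
    m_comparisons: int = 1,
    *,
    label: str = "",
    normality_alpha: float = 0.05,
    welch: bool = True,
) -> PairwiseResult:
    """Compare two samples, choosing the test by a Shapiro-Wilk gate.

    Parametric branch: paired t-test, or two-sample t (Welch by default;
    ``welch=False`` selects the pooled-variance form). Non-parametric
    branch: Wilcoxon signed-rank (paired) or rank-sum (independent).
    Hedges' g is attached on the parametric branch. ``m_comparisons`` is
    the size of the Bonferroni feature group this comparison belongs to.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if paired and a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if min(a.size, b.size) < 3:
        raise ValueError("need n >= 3 per sample for the normality gate")

    note = ""
    if paired:
        diffs = a - b
        if np.ptp(diffs) == 0:
            normal = True  # constant differences: Shapiro undefined, t-test handles it
            note = "constant paired differences"
        else:
            normal = st.shapiro(diffs).pvalue > normality_alpha
    else:
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            normal = True  # constant sample: Shapiro undefined, t-test handles it
            note = "constant sample"
        else:
            normal = (
                st.shapiro(a).pvalue > normality_alpha
                and st.shapiro(b).pvalue > normality_alpha
            )

    if normal:
        if paired:
            if np.ptp(a - b) == 0 and np.all(a == b):
                stat, p = 0.0, 1.0
            else:
                res = st.ttest_rel(a, b)
                stat, p = float(res.statistic), float(res.pvalue)
                if not np.isfinite(stat):  # zero-variance nonzero difference
                    stat, p = np.inf * np.sign((a - b).mean()), 0.0
        else:
            res = st.ttest_ind(a, b, equal_var=not welch)
            stat, p = float(res.statistic), float(res.pvalue)
        try:
            g = hedges_g(a, b)
        except ZeroDivisionError:
            g = np.nan
            note = (note + "; " if note else "") + "zero pooled variance"
        test = "t"
    else:
        if paired:
            diffs = a - b
            if np.all(diffs == 0):
                stat, p = 0.0, 1.0
                note = "all-tied paired data"
            else:
                res = st.wilcoxon(a, b, zero_method="wilcox")
                stat, p = float(res.statistic), float(res.pvalue)
        else:
            res = st.ranksums(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
        g = np.nan
        test = "wilcoxon"

    return PairwiseResult(
        label=label,
        test=test,
        statistic=stat,
        p_raw=p,
        p_bonferroni=bonferroni(p, m_comparisons),
        hedges_g=g,
        n=(int(a.size), int(b.size)),
        normal=bool(normal),
        note=note,
    )
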