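"""Paired statistical comparison protocol.

One-tailed paired Wilcoxon signed-rank tests for metric comparisons
(exact null distribution up to n = 15, normal approximation with tie
correction beyond), and an assumption-checked paired t-test with Wilcoxon
fallback for mean-thickness bias testing (Anderson-Darling normality and
variance-ratio F-test, both at alpha = 0.05).

Zero differences are dropped before ranking (Wilcoxon's original rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

EXACT_N_MAX = 15


@dataclass
class PairedComparison:
    sample_a: np.ndarray
    sample_b: np.ndarray
    test_used: str  # "t" | "wilcoxon"
    tail: str  # "one" | "two"
    statistic: float
    p_value: float
    alpha: float
    reject: bool
    assumption_report: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _signed_ranks(diffs: np.ndarray) -> np.ndarray:
    """Mid-ranks of |d| (zeros already removed)."""
    return sps.rankdata(np.abs(diffs))


def _exact_sf_table(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Distribution of W+ = sum of ranks with positive sign under the null.

    Ranks may be mid-ranks (ties give .5 steps); doubling makes them
    integers.  Returns (counts over doubled-sum values 0..max, scale 2).
    Built by dynamic programming over the generating function
    prod_i (1 + x^{2 r_i}); each of the 2^n sign vectors contributes one
    count, without enumerating them."""
    doubled = np.round(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled:  # r >= 2 always (smallest mid-rank is 1)
        counts[r:] = counts[r:] + counts[:-r]  # RHS evaluated to a temp first
    return counts, 2


def wilcoxon_signed_rank(a, b=None, tail: str = "two",
                         alternative: str = "greater") -> tuple[float, float, dict]:
    """Paired Wilcoxon signed-rank test.

    ``a`` and ``b`` are paired samples (or ``a`` the differences when ``b``
    is None).  ``alternative='greater'`` tests a > b one-tailed.  Returns
    (W+ statistic, p-value, info dict).  All-zero differences give the
    degenerate p = 1.
    """
    a = np.asarray(a, dtype=np.float64)
    diffs = a if b is None else a - np.asarray(b, dtype=np.float64)
    info: dict = {"n_pairs": int(diffs.size)}
    nonzero = diffs[diffs != 0]
    info["n_zero_dropped"] = int(diffs.size - nonzero.size)
    if nonzero.size == 0:
        info["degenerate"] = True
        return 0.0, 1.0, info
    if nonzero.size < 3:
        raise ValueError(f"need >= 3 nonzero differences, got {nonzero.size}")
    n = nonzero.size
    ranks = _signed_ranks(nonzero)
    w_plus = float(ranks[nonzero > 0].sum())
    w_total = n * (n + 1) / 2.0

    if n <= EXACT_N_MAX:
        counts, scale = _exact_sf_table(ranks)
        total = counts.sum()  # == 2^n
        wd = int(round(scale * w_plus))
        p_ge = counts[wd:].sum() / total
        p_le = counts[:wd + 1].sum() / total
        info["method"] = "exact"
    else:
        # normal approximation with tie correction and continuity correction
        _, tie_counts = np.unique(np.abs(nonzero), return_counts=True)
        tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
        mu = n * (n + 1) / 4.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0)
        p_ge = sps.norm.sf((w_plus - 0.5 - mu) / sigma)
        p_le = sps.norm.cdf((w_plus + 0.5 - mu) / sigma)
        info["method"] = "normal_approx"

    if tail == "one":
        p = p_ge if alternative == "greater" else p_le
    elif tail == "two":
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        raise ValueError(f"tail must be 'one' or 'two', got {tail!r}")
    info["w_total"] = w_total
    return w_plus, float(min(p, 1.0)), info


# Stephens' approximation for the Anderson-Darling normality p-value
# (mean and variance estimated from the data).
def anderson_darling_normal(x: np.ndarray) -> tuple[float, float]:
    """A^2 statistic and approximate p-value for composite normality."""
    x = np.sort(np.asarray(x, dtype=np.float64))
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for the Anderson-Darling test")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return np.inf, 0.0
    z = sps.norm.cdf((x - mu) / sd)
    z = np.clip(z, 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1])))
    a2s = a2 * (1.0 + 0.75 / n + 2.25 / n ** 2)
    if a2s >= 0.6:
        p = np.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s ** 2)
    elif a2s > 0.34:
        p = np.exp(0.9177 - 4.279 * a2s - 1.38 * a2s ** 2)
    elif a2s > 0.2:
        p = 1 - np.exp(-8.318 + 42.796 * a2s - 59.938 * a2s ** 2)
    else:
        p = 1 - np.exp(-13.436 + 101.14 * a2s - 223.73 * a2s ** 2)
    return float(a2), float(np.clip(p, 0.0, 1.0))


def variance_ratio_f_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test of equal variances (variance ratio of the samples)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0 and va == 0:
        return 1.0, 1.0
    if vb == 0 or va == 0:
        return np.inf, 0.0
    f = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p_one = sps.f.sf(f, dfa, dfb) if f >= 1 else sps.f.cdf(f, dfa, dfb)
    return float(f), float(min(1.0, 2.0 * p_one))


def thickness_bias_test(est_means, true_means, alpha_normality: float = 0.05,
                        alpha_test: float = 0.01) -> PairedComparison:
    """Test for bias between estimated and reference mean thicknesses.

    Paired t-test at ``alpha_test`` when the paired differences pass
    Anderson-Darling normality and the two samples pass a variance-ratio
    F-test (both at ``alpha_normality``); otherwise a paired Wilcoxon
    signed-rank test.  Two-tailed throughout (a bias has no preferred sign).
    """
    est = np.asarray(est_means, dtype=np.float64)
    true = np.asarray(true_means, dtype=np.float64)
    if est.shape != true.shape or est.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if est.size < 3:
        raise ValueError(f"need n >= 3 pairs, got {est.size}")
    diffs = est - true
    notes = []

    if np.all(diffs == 0):
        return PairedComparison(est, true, "t", "two", 0.0, 1.0, alpha_test,
                                False, {"degenerate": True},
                                ["all differences zero; no bias detectable"])

    a2, p_normal = anderson_darling_normal(diffs)
    f_stat, p_var = variance_ratio_f_test(est, true)
    report = {"ad_statistic": a2, "ad_p": p_normal,
              "f_statistic": f_stat, "f_p": p_var}
    notes.append(
        "variance-ratio F-test applied to paired samples as specified by the "
        "protocol; note it ignores pairing"
    )

    if p_normal > alpha_normality and p_var > alpha_normality:
        t_stat, p = sps.ttest_rel(est, true)
        comp = PairedComparison(est, true, "t", "two", float(t_stat), float(p),
                                alpha_test, bool(p < alpha_test), report, notes)
    else:
        w, p, info = wilcoxon_signed_rank(est, true, tail="two")
        report["wilcoxon"] = info
        comp = PairedComparison(est, true, "wilcoxon", "two", w, p, alpha_test,
                                bool(p < alpha_test), report, notes)
    return comp


def compare_metrics(a, b, alpha: float = 0.05,
                    alternative: str = "greater") -> PairedComparison:
    """One-tailed paired Wilcoxon comparison of two paired metric samples
    (e.g. per-volume Dice of the ensemble vs a member model)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    w, p, info = wilcoxon_signed_rank(a, b, tail="one", alternative=alternative)
    return PairedComparison(a, b, "wilcoxon", "one", w, p, alpha,
                            bool(p < alpha), info)
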