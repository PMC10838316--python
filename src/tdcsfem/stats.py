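"""Nonparametric statistical battery for the cohort comparisons.

Small-sample routines use exact null distributions: the Wilcoxon
signed-rank null is built by a shift-convolution over signed-rank sums
(valid with tied absolute differences via average ranks), Mann-Whitney and
Spearman fall back to scipy's exact enumeration / full rank-permutation
where feasible.  Larger samples use the usual tie-corrected normal or t
approximations.  Spearman confidence intervals use the Fisher z transform
with SE = 1/sqrt(n - 3).

No multiple-testing correction is applied anywhere; reports carry the raw
two-sided p-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import scipy.stats as sps

from .exceptions import DegenerateDataError

#: Largest n for which the Wilcoxon null is enumerated exactly.
WILCOXON_EXACT_N = 25
#: Largest min-group size for the exact Mann-Whitney null (tie-free data).
MANN_WHITNEY_EXACT_N = 8
#: Largest n for the exact Spearman permutation p.
SPEARMAN_EXACT_N = 9


@dataclass
class StatsReport:
    """One test result: statistic, two-sided p, optional effect and CI."""

    name: str
    statistic: float
    p_value: float
    n: int
    effect: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    note: str = ""

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise DegenerateDataError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _signed_rank_null_cdf(ranks2: np.ndarray) -> np.ndarray:
    """Null pmf of W+ over half-unit-scaled ranks (ints), by convolution.

    ``ranks2`` are 2x the signed ranks so average ranks stay integral.
    Returns counts over W+ * 2 = 0..sum(ranks2).
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        r = int(r)
        nxt = pmf.copy()
        nxt[r:] += pmf[: total + 1 - r]
        pmf = nxt
    return pmf


def wilcoxon_signed_rank(paired_a, paired_b,
                         name: str = "wilcoxon") -> StatsReport:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Exact enumeration of the 2^n sign-flip null for n <= 25 (handles ties
    in |differences| through average ranks); tie-corrected normal
    approximation above.  Zero differences are dropped (Wilcoxon rule).
    """
    a = np.asarray(paired_a, float)
    b = np.asarray(paired_b, float)
    if a.shape != b.shape:
        raise DegenerateDataError("paired samples must have equal length")
    d = b - a
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    if n < 5:
        raise DegenerateDataError(
            f"need >= 5 nonzero differences, got {n}")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)
    if n <= WILCOXON_EXACT_N:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        pmf = _signed_rank_null_cdf(ranks2)
        total = pmf.sum()
        w2 = int(round(2.0 * w_plus))
        lo = pmf[: w2 + 1].sum() / total
        hi = pmf[w2:].sum() / total
        p = min(1.0, 2.0 * min(lo, hi))
        note = "exact sign-flip null"
    else:
        mean = n * (n + 1) / 4.0
        tie_term = _tie_correction_signed(ranks)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
        note = "normal approximation with tie correction"
    return StatsReport(name, stat, float(min(p, 1.0)), n, note=note)


def _tie_correction_signed(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float((counts**3 - counts).sum()) / 48.0


def mann_whitney_u(group_a, group_b, name: str = "mann-whitney"
                   ) -> StatsReport:
    """Two-sided Mann-Whitney U test on independent groups."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateDataError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    exact = (min(len(a), len(b)) <= MANN_WHITNEY_EXACT_N) and not has_ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    note = ("exact enumeration" if exact
            else "tie-corrected normal approximation")
    return StatsReport(name, float(res.statistic), float(res.pvalue),
                       len(a) + len(b), note=note)


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman_ci(x, y, alpha: float = 0.05, name: str = "spearman"
                ) -> StatsReport:
    """Spearman rho with Fisher-z CI and two-sided p.

    p is exact (all n! rank permutations) for n <= 9, else from the
    t approximation t = rho sqrt((n-2)/(1-rho^2)).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y) or n < 4:
        raise DegenerateDataError("need paired samples with n >= 4")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateDataError("constant sample in correlation")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _spearman_rho(rx, ry)
    if n <= SPEARMAN_EXACT_N:
        count = 0
        total = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_spearman_rho(rx, np.asarray(perm))) >= target:
                count += 1
        p = count / total
        note = "exact permutation null"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), n - 2)
        note = "t approximation"
    if n > 3 and abs(rho) < 1.0:
        z = math.atanh(rho)
        se = 1.0 / math.sqrt(n - 3)
        zc = sps.norm.ppf(1.0 - alpha / 2.0)
        ci_low, ci_high = math.tanh(z - zc * se), math.tanh(z + zc * se)
    else:
        ci_low = ci_high = rho
        note += "; degenerate CI at |rho| = 1"
    return StatsReport(name, rho, float(min(p, 1.0)), n, effect=rho,
                       ci_low=ci_low, ci_high=ci_high, note=note)


def ks_normality(sample, name: str = "ks-normality") -> StatsReport:
    """One-sample KS statistic against N(mean, sd) fitted from the sample.

    Parameters are estimated from the data (Lilliefors situation), so the
    returned p-value is approximate and conservative; noted in the report.
    """
    x = np.asarray(sample, float)
    if len(x) < 3:
        raise DegenerateDataError("need n >= 3 for the KS normality check")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("constant sample")
    res = sps.kstest(x, "norm", args=(x.mean(), sd))
    return StatsReport(
        name, float(res.statistic), float(res.pvalue), len(x),
        note="parameters estimated from sample (Lilliefors); p approximate")
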