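"""Protocol comparability statistics: Wilcoxon signed-rank test (exact for
small n) and Bland-Altman percentage analysis.

Two motion-compensation protocols are declared comparable when both
criteria hold: the WSRT p-value exceeds the Bonferroni-adjusted alpha, and
the 95% confidence interval of the mean percentage difference (Bland-Altman)
contains zero.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)

EXACT_N_MAX = 25


@dataclass
class BlandAltman:
    mean_pct: float
    sd_pct: float
    loa: tuple[float, float]
    ci_mean: tuple[float, float]
    n: int

    @property
    def comparable(self) -> bool:
        return self.ci_mean[0] <= 0.0 <= self.ci_mean[1]


@dataclass
class ComparisonResult:
    protocol_a: str
    protocol_b: str
    n_pairs: int
    wsrt_p: float
    alpha_adjusted: float
    ba_mean_pct: float
    ba_sd_pct: float
    ba_loa: tuple[float, float]
    ba_ci_mean: tuple[float, float]
    comparable_wsrt: bool
    comparable_ba: bool

    @property
    def comparable(self) -> bool:
        return self.comparable_wsrt and self.comparable_ba


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return w_plus, ranks


def _exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p by dynamic programming over the 2^n equally likely
    sign assignments; tie-averaged ranks are doubled so sums stay integral."""
    r2 = np.rint(ranks * 2).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w_plus * 2))
    p_low = dist[: w2 + 1].sum()
    p_high = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def _normal_approx_p(w_plus: float, ranks: np.ndarray) -> float:
    n = len(ranks)
    mn = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts ** 3 - counts).sum() / 48.0
    if var <= 0:
        return 1.0
    diff = w_plus - mn
    if diff == 0:
        return 1.0
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired series.

    Zero differences are dropped before ranking (Wilcoxon's convention);
    ties receive average ranks.  The null distribution is enumerated
    exactly for n <= 25 and approximated normally (continuity and tie
    corrected) above.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; p = 1.0", stacklevel=2)
        return 1.0
    if len(d) < 3:
        raise ValueError("need at least 3 non-zero differences")
    w_plus, ranks = _signed_rank_statistic(d)
    if len(d) <= EXACT_N_MAX:
        return _exact_p(w_plus, ranks)
    return _normal_approx_p(w_plus, ranks)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Adjusted significance level alpha/m for m comparisons."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def bland_altman_pct(a, b, ci_level: float = 0.95) -> BlandAltman:
    """Bland-Altman percentage analysis of paired series.

    Each difference is expressed as a percentage of the pair mean:
    d_i = 100 (a_i - b_i) / ((a_i + b_i) / 2).  Limits of agreement are
    mean +- 1.96 SD; the CI of the mean uses the t distribution (n is
    small in this application).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    pair_mean = (a + b) / 2.0
    bad = np.flatnonzero(pair_mean == 0)
    if len(bad):
        raise ValueError(f"pair mean is zero at index {bad[0]}: percentage undefined")
    d = 100.0 * (a - b) / pair_mean
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    t_crit = float(sps.t.ppf((1 + ci_level) / 2.0, n - 1))
    half = t_crit * sd / np.sqrt(n)
    return BlandAltman(
        mean_pct=mean,
        sd_pct=sd,
        loa=(mean - 1.96 * sd, mean + 1.96 * sd),
        ci_mean=(mean - half, mean + half),
        n=n,
    )


def compare_protocols(
    records,
    protocol_a: str,
    protocol_b: str,
    alpha: float = 0.05,
    m: int = 1,
    ci_level: float = 0.95,
) -> ComparisonResult:
    """Pair RC records of two protocols by (analysis, pattern, target), pool
    across analyses, and run both comparability tests.

    Unpaired targets are dropped with a log message.  Comparability requires
    both the WSRT (p > alpha/m) and the Bland-Altman CI-comprises-zero
    criterion.
    """
    keyed_a = {
        (r.analysis, r.pattern_id, r.target_id): r.rc
        for r in records
        if r.protocol_id == protocol_a
    }
    keyed_b = {
        (r.analysis, r.pattern_id, r.target_id): r.rc
        for r in records
        if r.protocol_id == protocol_b
    }
    common = sorted(set(keyed_a) & set(keyed_b))
    dropped = (set(keyed_a) | set(keyed_b)) - set(common)
    if dropped:
        log.warning(
            "compare %s vs %s: dropping %d unpaired target(s): %s",
            protocol_a, protocol_b, len(dropped), sorted(dropped),
        )
    if len(common) < 3:
        raise ValueError(
            f"need at least 3 paired targets, got {len(common)} "
            f"for {protocol_a} vs {protocol_b}"
        )
    a = np.array([keyed_a[k] for k in common])
    b = np.array([keyed_b[k] for k in common])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = wilcoxon_signed_rank(a, b)
    alpha_adj = bonferroni_alpha(alpha, m)
    ba = bland_altman_pct(a, b, ci_level=ci_level)
    return ComparisonResult(
        protocol_a=protocol_a,
        protocol_b=protocol_b,
        n_pairs=len(common),
        wsrt_p=p,
        alpha_adjusted=alpha_adj,
        ba_mean_pct=ba.mean_pct,
        ba_sd_pct=ba.sd_pct,
        ba_loa=ba.loa,
        ba_ci_mean=ba.ci_mean,
        comparable_wsrt=p > alpha_adj,
        comparable_ba=ba.comparable,
    )
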