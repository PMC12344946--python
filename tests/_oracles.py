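"""Independent high-precision oracles used by the tests.

The Mittag-Leffler oracle is computed with mpmath at 40+ significant
digits: by the defining power series where it converges within the term
budget, otherwise by fixed-Talbot numerical inversion of the Laplace
transform L[E_a(-x t^a)](s) = s^(a-1)/(s^a + x) at t=1 — a method entirely
independent of the package's series/integral/asymptotic evaluator.
"""

import mpmath as mp
import numpy as np


def ml_series_highprec(x: float, alpha: float, max_terms: int = 400):
    """Power series at high precision; None if not converged in budget."""
    with mp.workdps(60):
        xm, am = mp.mpf(x), mp.mpf(alpha)
        total = mp.mpf(0)
        term_mags = []
        for k in range(max_terms):
            term = (-xm) ** k / mp.gamma(am * k + 1)
            total += term
            term_mags.append(abs(term))
            if k > 5 and abs(term) < mp.mpf(10) ** -30 \
                    and term_mags[-1] < term_mags[-2]:
                return float(total)
    return None


def ml_talbot(x: float, alpha: float) -> float:
    """Fixed-Talbot Laplace inversion of s^(a-1)/(s^a + x) at t=1."""
    with mp.workdps(40):
        xm, am = mp.mpf(x), mp.mpf(alpha)
        return float(mp.invertlaplace(
            lambda s: s ** (am - 1) / (s ** am + xm), 1.0, method="talbot"))


def mittag_leffler_oracle(x: float, alpha: float) -> float:
    """E_alpha(-x) by the series where feasible, else Talbot inversion."""
    if x == 0:
        return 1.0
    if alpha == 1.0:
        return float(np.exp(-x))
    val = ml_series_highprec(x, alpha)
    if val is not None:
        return val
    return ml_talbot(x, alpha)


def rank_sum_auc(pos, neg) -> float:
    """Brute-force pair-counting AUC oracle."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))


def youden_oracle(values, is_pos, higher_positive: bool):
    """Exhaustive Youden scan over all observed thresholds.

    Returns (best_j, best_threshold) with ties toward the smaller
    threshold, matching the package's documented tie-break.
    """
    values = np.asarray(values, float)
    is_pos = np.asarray(is_pos, bool)
    best = (-np.inf, np.nan)
    for t in np.unique(values):
        pred = values >= t if higher_positive else values <= t
        sens = np.mean(pred[is_pos])
        spec = np.mean(~pred[~is_pos])
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, float(t))
    return best
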