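"""Maximum-likelihood mate-choice probabilities with Edwards support limits.

For a female taxon with mating counts ``y_1..y_k`` (n = sum y_i) the
log-likelihood is ``sum_i y_i * ln(P_i)`` over the probability simplex.  The
MLE is the closed form ``P_i = y_i / n``.  Support limits for each ``P_i``
are the extreme values whose *profile* log-likelihood (maximizing over the
remaining coordinates) stays within two units of the maximum.

Profiling has a closed inner solution: with ``P_i = p`` fixed, the remaining
mass ``1 - p`` is distributed proportionally to the remaining counts, giving

    profile_ll(p) = y_i ln p + (n - y_i) ln(1 - p) + sum_{j != i} y_j ln(y_j / (n - y_i))

which is unimodal in ``p``; the limits are found by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2

from .core import EstimationError, MatingCountTable

SUPPORT_DROP = 2.0  # log-likelihood units defining the support interval
_TOL = 1e-6


def multinomial_loglik(counts, probabilities) -> float:
    """``sum_i y_i * ln(P_i)`` with the convention ``0 * ln(0) = 0``.

    Returns ``-inf`` (not an exception) when some ``y_i > 0`` has ``P_i = 0``.
    """
    y = np.asarray(counts, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("counts and probabilities must have the same length")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    if (p < 0).any() or p.sum() > 1 + 1e-9:
        raise ValueError("probabilities must be >= 0 and sum to <= 1")
    if ((y > 0) & (p == 0)).any():
        return float("-inf")
    return float(xlogy(y, p, where=p > 0, out=np.zeros_like(p)).sum())


def profile_loglik(p: float, y_i: float, n: float, rest_term: float) -> float:
    """Profile log-likelihood of one coordinate at value ``p``."""
    if p == 0.0:
        return float("-inf") if y_i > 0 else rest_term
    if p == 1.0:
        return float("-inf") if n > y_i else 0.0
    return float(xlogy(y_i, p) + xlogy(n - y_i, 1.0 - p) + rest_term)


def _rest_term(y: np.ndarray, i: int) -> float:
    """``sum_{j != i} y_j ln(y_j / (n - y_i))`` (0 when no other matings)."""
    rest = np.delete(y, i)
    s = rest.sum()
    if s == 0:
        return 0.0
    return float(xlogy(rest, rest / s, where=rest > 0, out=np.zeros_like(rest)).sum())


def support_limits(y: np.ndarray, i: int, drop: float = SUPPORT_DROP) -> tuple[float, float]:
    """Edwards support interval for coordinate ``i`` of the count vector."""
    y = np.asarray(y, dtype=float)
    n = y.sum()
    if n <= 0:
        raise EstimationError("no matings observed")
    y_i = y[i]
    mle = y_i / n
    rest = _rest_term(y, i)
    ll_max = profile_loglik(mle, y_i, n, rest)
    target = ll_max - drop

    def f(p: float) -> float:
        return profile_loglik(p, y_i, n, rest) - target

    lower = 0.0 if f(0.0) >= 0 else _bisect(f, 0.0, mle, increasing=True)
    upper = 1.0 if f(1.0) >= 0 else _bisect(f, mle, 1.0, increasing=False)
    return lower, upper


def _bisect(f, lo: float, hi: float, increasing: bool, tol: float = _TOL) -> float:
    """Root of ``f`` on [lo, hi] where f(lo) and f(hi) have opposite signs.

    ``increasing`` marks the sign pattern: f < 0 at lo and f >= 0 at hi when
    True (the lower limb of the unimodal profile), and vice versa.
    """
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if (val < 0) == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class MatingMLE:
    female_taxon: str
    taxa: tuple[str, ...]
    probabilities: np.ndarray  # MLE P_i = y_i / n
    support: list[tuple[float, float]]  # per-coordinate (lower, upper)
    loglik: float
    n: int
    k: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "female_taxon": self.female_taxon,
                "male_taxon": list(self.taxa),
                "estimate": self.probabilities,
                "support_lower": [s[0] for s in self.support],
                "support_upper": [s[1] for s in self.support],
            }
        )


def fit_mating_mle(table: MatingCountTable, female_taxon: str) -> MatingMLE:
    """Closed-form MLE and profile support limits for one female taxon."""
    y = table.row(female_taxon).astype(float)
    n = y.sum()
    if n < 1:
        raise EstimationError(f"no matings observed for {female_taxon!r} females")
    p_hat = y / n
    limits = [support_limits(y, i) for i in range(len(y))]
    return MatingMLE(
        female_taxon=female_taxon,
        taxa=table.taxa,
        probabilities=p_hat,
        support=limits,
        loglik=multinomial_loglik(y, p_hat),
        n=int(n),
        k=len(y),
    )


def pooling_lrt(
    table_3male: MatingCountTable,
    table_15male: MatingCountTable,
    female_taxon: str,
) -> tuple[float, int, float]:
    """LRT of separate vs pooled mating probabilities across group sizes.

    Separate fits spend ``2(k - 1)`` parameters against ``k - 1`` pooled, so
    the statistic is referred to a chi-square with ``k - 1`` df.
    """
    if table_3male.taxa != table_15male.taxa:
        raise ValueError("tables must share the same taxon set")
    y3 = table_3male.row(female_taxon).astype(float)
    y15 = table_15male.row(female_taxon).astype(float)
    if y3.sum() == 0 or y15.sum() == 0:
        raise EstimationError(
            f"one experiment has no matings for {female_taxon!r} females; "
            "pooling test undefined"
        )
    pooled = y3 + y15
    ll_sep = (
        multinomial_loglik(y3, y3 / y3.sum())
        + multinomial_loglik(y15, y15 / y15.sum())
    )
    ll_pool = (
        multinomial_loglik(y3, pooled / pooled.sum())
        + multinomial_loglik(y15, pooled / pooled.sum())
    )
    stat = 2.0 * (ll_sep - ll_pool)
    df = len(pooled) - 1
    p = float(chi2.sf(stat, df))
    return float(stat), df, p


def mating_x(table: MatingCountTable, pair: tuple[str, str]) -> float:
    """Heterospecific share of the pair's matings: ``x = H / (H + C)``."""
    sub = table.pair_counts(pair).to_numpy()
    conspecific = sub[0, 0] + sub[1, 1]
    heterospecific = sub[0, 1] + sub[1, 0]
    total = conspecific + heterospecific
    if total == 0:
        raise EstimationError(f"no matings within pair {pair}; x undefined")
    return float(heterospecific / total)
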