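"""Forced-choice discrimination statistics: guessing model and Thurstonian d'.

For a 2-AFC panel of N assessors with k correct "fattier" choices the
module computes:

* the one-sided exact binomial p value against the chance rate,
* the guessing-model proportion of discriminators
  pd = (pc - guess) / (1 - guess), with pc = k/N,
* the Thurstonian sensory distance d' via the 2-AFC identity
  pc = Phi(d' / sqrt(2)),
* exact-binomial post-hoc power at the observed proportion, and
* the sample size needed for a target power at a given pd.

Forced-choice tests are one-sided by construction (performance can only be
pulled above chance by real discrimination).  Power uses the exact binomial
critical value rather than a normal approximation; a normal-approximation
mode is kept for cross-checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairDiscrimination",
    "exact_binomial_tail",
    "proportion_discriminators",
    "dprime_2afc",
    "pc_from_dprime",
    "critical_value",
    "posthoc_power",
    "sample_size",
    "analyze_panel",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class PairDiscrimination:
    """One paired comparison: k of N assessors chose the fattier sample."""

    pair_label: str
    n_total: int
    n_correct: int
    guess_rate: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_total:
            raise ValueError("need 0 <= n_correct <= n_total")
        if not math.isclose(self.guess_rate, 0.5) and not math.isclose(
            self.guess_rate, 1.0 / 3.0
        ):
            raise ValueError("guess_rate must be 1/2 (2-AFC) or 1/3 (3-AFC)")

    @property
    def pc(self) -> float:
        return self.n_correct / self.n_total


def exact_binomial_tail(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0) — the one-sided guessing-model p value."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    return float(stats.binom.sf(k - 1, n, p0))


def proportion_discriminators(k: int, n: int, guess_rate: float, *, floor_at_zero: bool = False) -> float:
    """Guessing-model proportion of true discriminators, (pc - g)/(1 - g).

    May be negative when performance falls below chance; pass
    ``floor_at_zero=True`` for a display-style clamp.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < guess_rate < 1:
        raise ValueError("guess_rate must be in (0, 1)")
    pd_ = (k / n - guess_rate) / (1.0 - guess_rate)
    return max(pd_, 0.0) if floor_at_zero else pd_


def dprime_2afc(pc: float) -> float:
    """Thurstonian d' for 2-AFC: d' = sqrt(2) * Phi^-1(pc).

    Strictly increasing in pc and zero at chance (pc = 1/2).  pc of exactly
    0 or 1 signals an unmeasurably extreme sensitivity and maps to -inf/+inf.
    """
    if not 0 <= pc <= 1:
        raise ValueError(f"pc must lie in [0, 1], got {pc}")
    if pc == 0.0:
        return -math.inf
    if pc == 1.0:
        return math.inf
    return float(_SQRT2 * stats.norm.ppf(pc))


def pc_from_dprime(d: float) -> float:
    """Inverse of :func:`dprime_2afc`: proportion correct implied by d'."""
    return float(stats.norm.cdf(d / _SQRT2))


def critical_value(n: int, p0: float, alpha: float) -> int | None:
    """Smallest correct count c with P(X >= c | n, p0) <= alpha, or None."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    # sf(c-1) is decreasing in c; binary search would also do, n is small
    tails = stats.binom.sf(np.arange(n + 1) - 1, n, p0)
    hits = np.nonzero(tails <= alpha)[0]
    return int(hits[0]) if hits.size else None


def posthoc_power(k: int, n: int, alpha: float = 0.05, p0: float = 0.5, *, method: str = "exact") -> float:
    """Power of the exact one-sided binomial test if the true pc equals k/n.

    ``exact``: P(X >= c | n, k/n) at the exact critical value c.
    ``normal``: normal-approximation cross-check with continuity correction.
    Returns 0 when no critical value exists (alpha unattainably small for n).
    """
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    c = critical_value(n, p0, alpha)
    if c is None:
        return 0.0
    pc = k / n
    if method == "exact":
        if pc == 0.0:
            return 0.0 if c > 0 else 1.0
        return float(stats.binom.sf(c - 1, n, pc))
    if method == "normal":
        if pc in (0.0, 1.0):
            return float(pc if c <= n * pc else 1.0 - pc) if pc in (0.0, 1.0) else 0.0
        mu = n * pc
        sd = math.sqrt(n * pc * (1 - pc))
        return float(stats.norm.sf((c - 0.5 - mu) / sd))
    raise ValueError(f"unknown power method {method!r}")


def sample_size(
    alpha: float,
    target_power: float,
    pd_alt: float,
    guess_rate: float = 0.5,
    n_max: int = 10000,
) -> int:
    """Smallest panel size reaching ``target_power`` for a given effect.

    The alternative is expressed as a proportion of discriminators
    ``pd_alt``; the implied proportion correct is
    pc = guess_rate + pd_alt * (1 - guess_rate).  Exact binomial power is
    scanned over n (it is sawtoothed, so the first n reaching the target is
    returned).
    """
    if not 0 < pd_alt < 1:
        raise ValueError("pd_alt must be in (0, 1)")
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0, 1)")
    pc_alt = guess_rate + pd_alt * (1.0 - guess_rate)
    for n in range(2, n_max + 1):
        c = critical_value(n, guess_rate, alpha)
        if c is None:
            continue
        if float(stats.binom.sf(c - 1, n, pc_alt)) >= target_power:
            return n
    raise ValueError(f"target power not attainable with n <= {n_max}")


def analyze_panel(pairs: list[PairDiscrimination], alpha: float = 0.05) -> pd.DataFrame:
    """Discrimination-test summary table, one row per paired comparison.

    Columns mirror the conventional sensory report: correct count, percent
    discriminators, one-sided exact p value, post-hoc power and d' (2-AFC
    pairs only).  ``similarity_underpowered`` flags non-significant pairs
    whose power falls short of 80% — they cannot be claimed similar.
    """
    if not pairs:
        raise ValueError("empty panel")
    rows = []
    for pair in pairs:
        pd_hat = proportion_discriminators(pair.n_correct, pair.n_total, pair.guess_rate)
        p_val = exact_binomial_tail(pair.n_correct, pair.n_total, pair.guess_rate)
        power = posthoc_power(pair.n_correct, pair.n_total, alpha=alpha, p0=pair.guess_rate)
        d = dprime_2afc(pair.pc) if math.isclose(pair.guess_rate, 0.5) else math.nan
        rows.append(
            {
                "pair_label": pair.pair_label,
                "n_total": pair.n_total,
                "n_correct": pair.n_correct,
                "guess_rate": pair.guess_rate,
                "pc": pair.pc,
                "pd": pd_hat,
                "pct_discriminators": 100.0 * pd_hat,
                "p_value": p_val,
                "power": power,
                "d_prime": d,
                "significant": p_val <= alpha,
                "similarity_underpowered": (p_val > alpha) and (power < 0.80),
            }
        )
    return pd.DataFrame(rows)
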