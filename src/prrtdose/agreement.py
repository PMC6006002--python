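"""Protocol-agreement statistics.

Quantifies how well two dosimetry protocols agree on paired per-patient (or
per-cycle) dose values: Bland-Altman relative differences with 95% limits of
agreement, Pearson correlation, management-decision concordance, and the
exact power of a one-sided binomial test for detecting discordant
management.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, InputError

__all__ = [
    "PairedSeries",
    "BlandAltmanSummary",
    "bland_altman",
    "pearson",
    "binomial_power",
    "concordance",
]


@dataclass(frozen=True)
class PairedSeries:
    """Values of the same quantity measured by two protocols, paired by label."""

    labels: tuple[str, ...]
    a: tuple[float, ...]
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.a) == len(self.b)):
            raise InputError("labels, a and b must have equal length")

    @classmethod
    def from_arrays(cls, a, b, labels=None) -> "PairedSeries":
        a = tuple(float(x) for x in a)
        b = tuple(float(x) for x in b)
        if labels is None:
            labels = tuple(str(i) for i in range(len(a)))
        return cls(labels=tuple(labels), a=a, b=b)

    def __len__(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Per-pair relative differences (%) and their limits of agreement."""

    differences_pct: tuple[float, ...]
    mean_pct: float
    sd_pct: float
    loa_low_pct: float
    loa_high_pct: float
    signed: bool


def bland_altman(pairs: PairedSeries, signed: bool = True) -> BlandAltmanSummary:
    """Bland-Altman summary of relative differences between two protocols.

    Each pair contributes d_i = (a_i - b_i) / ((a_i + b_i)/2) * 100, the
    difference as a percentage of the pair mean; with ``signed=False`` the
    absolute value is taken.  The summary is the mean, sample SD (n-1
    denominator) and the 95% limits of agreement mean +/- 1.96*SD.
    """
    a = np.asarray(pairs.a, dtype=float)
    b = np.asarray(pairs.b, dtype=float)
    means = (a + b) / 2.0
    if np.any(means == 0):
        raise DomainError("pair mean of 0 makes the relative difference undefined")
    if len(pairs) < 2:
        raise DomainError("need >= 2 pairs for an SD-based summary")
    d = (a - b) / means * 100.0
    if not signed:
        d = np.abs(d)
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanSummary(
        differences_pct=tuple(float(x) for x in d),
        mean_pct=mean, sd_pct=sd,
        loa_low_pct=mean - 1.96 * sd, loa_high_pct=mean + 1.96 * sd,
        signed=signed)


def pearson(pairs: PairedSeries) -> tuple[float, float]:
    """Pearson product-moment r and two-sided p (Student t with n-2 df)."""
    a = np.asarray(pairs.a, dtype=float)
    b = np.asarray(pairs.b, dtype=float)
    if len(a) < 3:
        raise DomainError("Pearson correlation needs >= 3 pairs")
    if np.var(a) == 0 or np.var(b) == 0:
        raise DomainError("zero variance in one series; correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def binomial_power(n: int, p_alt: float, alpha: float = 0.05,
                   p_null: float = 0.0) -> float:
    """Exact power of the one-sided binomial test of H0: p = p_null.

    The rejection region is {X >= k*} with k* the smallest integer such that
    P(X >= k* | p_null) <= alpha (exact upper tail, so the achieved size
    never exceeds alpha); the power is P(X >= k* | p_alt).  For the
    degenerate null p_null = 0 the region is {X >= 1} and the power reduces
    to 1 - (1 - p_alt)^n: the chance of observing at least one discordant
    case when the true discordance rate is p_alt.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    if not (0.0 <= p_null <= p_alt <= 1.0):
        raise DomainError(
            f"need 0 <= p_null <= p_alt <= 1, got p_null={p_null}, p_alt={p_alt}")
    # smallest k with upper tail <= alpha; sf(k-1) = P(X >= k)
    tails = stats.binom.sf(np.arange(-1, n + 1), n, p_null)  # P(X >= 0..n+1)
    k_star = int(np.argmax(tails <= alpha))  # first k with P(X >= k) <= alpha
    if p_alt == 0.0:
        return 0.0
    return float(stats.binom.sf(k_star - 1, n, p_alt))


def concordance(decisions_a: list[str], decisions_b: list[str],
                ) -> tuple[int, float]:
    """Count and proportion of paired management decisions that differ."""
    if len(decisions_a) != len(decisions_b):
        raise InputError("decision lists must have equal length")
    if not decisions_a:
        raise InputError("decision lists must be non-empty")
    discordant = sum(1 for x, y in zip(decisions_a, decisions_b) if x != y)
    return discordant, discordant / len(decisions_a)
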