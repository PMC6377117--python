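"""Statistical gates for gene acceptance.

IGIS+ compares the k per-fold accuracy vectors before and after a candidate
gene addition with Cohen's d,

    d = (mu_t - mu_c) / s_pooled,
    s_pooled = sqrt( ((n_t - 1) s_t^2 + (n_c - 1) s_c^2) / (n_t + n_c) ),

and accepts a gene only if d >= 0.40 (medium effect) on the training rates
and d >= 0.15 (small effect) on the validation rates; both thresholds are
inclusive. Note the pooled-SD denominator is n_t + n_c, not the textbook
n_t + n_c - 2; the algorithm is defined with the former, and
``pooled_sd(..., denominator="textbook")`` exposes the alternative.

The original IGIS instead used Student's paired t-tests at the 0.1 level
(right-tailed on training rates for acceptance, left-tailed on validation
rates for early stopping); those live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "EffectThresholds",
    "pooled_sd",
    "cohens_d",
    "passes_gate",
    "paired_t_test",
]


@dataclass(frozen=True)
class EffectThresholds:
    """Cohen's effect-size conventions: small / medium / large."""

    small: float = 0.15
    medium: float = 0.40
    large: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.small < self.medium < self.large:
            raise ValueError("thresholds must satisfy 0 < small < medium < large")

    def threshold(self, level: str) -> float:
        try:
            return float(getattr(self, level))
        except AttributeError:
            raise ValueError(f"unknown effect level {level!r}") from None


def _as_vector(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError(f"{name} must be a 1-D vector of length >= 2")
    return v


def pooled_sd(
    t: np.ndarray, c: np.ndarray, *, denominator: str = "as_defined"
) -> float:
    """Pooled standard deviation of two accuracy vectors.

    ``denominator="as_defined"`` divides by n_t + n_c (the convention the
    selection gates use); ``"textbook"`` divides by n_t + n_c - 2.
    """
    t = _as_vector(t, "t")
    c = _as_vector(c, "c")
    nt, nc = t.size, c.size
    num = (nt - 1) * t.var(ddof=1) + (nc - 1) * c.var(ddof=1)
    if denominator == "as_defined":
        den = nt + nc
    elif denominator == "textbook":
        den = nt + nc - 2
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    return math.sqrt(num / den)


def cohens_d(t: np.ndarray, c: np.ndarray, **kwargs) -> float:
    """Signed standardized mean difference between two accuracy vectors.

    Returns ``(mean(t) - mean(c)) / pooled_sd(t, c)``. When the pooled SD is
    zero the effect is 0 for equal means and signed infinity otherwise (an
    all-perfect improvement must count as significant).
    """
    t = _as_vector(t, "t")
    c = _as_vector(c, "c")
    diff = t.mean() - c.mean()
    s = pooled_sd(t, c, **kwargs)
    if s == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / s


def passes_gate(
    t: np.ndarray,
    c: np.ndarray,
    level: str,
    thresholds: EffectThresholds = EffectThresholds(),
) -> bool:
    """True iff Cohen's d of t over c reaches the given effect level (inclusive)."""
    return cohens_d(t, c) >= thresholds.threshold(level)


def paired_t_test(a: np.ndarray, b: np.ndarray, tail: str) -> float:
    """One-sided Student's paired t-test p-value on fold-aligned accuracies.

    ``tail="right"`` tests mean(a - b) > 0; ``tail="left"`` tests
    mean(a - b) < 0. All-zero differences give p = 0.5 (t = 0, not
    significant); zero-variance nonzero differences give a degenerate
    t of +/- infinity.
    """
    a = _as_vector(a, "a")
    b = _as_vector(b, "b")
    if a.size != b.size:
        raise ValueError("paired test requires equal-length, fold-aligned vectors")
    if tail not in ("right", "left"):
        raise ValueError(f"tail must be 'right' or 'left', got {tail!r}")
    d = a - b
    k = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.5
        t_stat = math.copysign(math.inf, d.mean())
    else:
        t_stat = d.mean() / (sd / math.sqrt(k))
    if tail == "right":
        return float(sps.t.sf(t_stat, df=k - 1))
    return float(sps.t.cdf(t_stat, df=k - 1))
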