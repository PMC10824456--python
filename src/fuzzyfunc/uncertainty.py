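"""Significant-digit uncertainty quantification across MCA repetitions.

Given n perturbed samples X_1..X_n of a quantity and its unperturbed
reference x_IEEE, a bit position k is *significant* if every deviation
Z_i = X_i - x_IEEE satisfies |Z_i| < 2^-k.  The number of significant bits
is the largest such k up to the working-precision cap (24 bits for
single-precision quantities, 53 for double), and converts to decimal
digits as k * log10(2) — hence at most 15.95 digits for double precision
and 7.23 for single.

By default deviations are taken *relative* to the reference
(Z_i = (X_i - x_IEEE) / x_IEEE): the cap is a mantissa-length bound and
only makes sense for mantissa-relative error.  Absolute mode (the
deviation as printed above, without normalisation) is retained for
completeness and is the fallback when the reference is exactly zero.

The estimate is non-parametric.  The companion sample-size rule gives the
smallest n for which, with confidence c, at least a fraction p of future
samples shares the estimated significant bits: the smallest n with
p^n <= 1 - c.  n = 10 corresponds to confidence 0.80 at probability 0.85.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleSet",
    "significant_bits",
    "significant_bits_array",
    "to_digits",
    "min_sample_size",
    "summarize",
]

LOG10_2 = math.log10(2.0)


@dataclass
class SampleSet:
    """Perturbed samples of one quantity plus its unperturbed reference.

    ``cap`` is the working-precision ceiling on significant bits: 24 for
    single-precision quantities, 53 for double.
    """

    quantity: str
    reference: float
    samples: np.ndarray
    cap: int = 53

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.size == 0:
            raise ValueError(f"empty sample set for quantity {self.quantity!r}")
        if self.cap not in (24, 53):
            raise ValueError("cap must be 24 (single) or 53 (double)")


def _max_deviation(reference: float, samples: np.ndarray, mode: str) -> float:
    z = samples - reference
    if mode == "relative":
        if reference != 0.0:
            z = z / reference
        # reference exactly zero: fall back to absolute deviations
    elif mode != "absolute":
        raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    if not np.isfinite(z).all():
        return math.inf
    return float(np.max(np.abs(z)))


def significant_bits(s: SampleSet, mode: str = "relative") -> int:
    """Largest k in 1..cap with |Z_i| < 2^-k for every sample; 0 if none.

    Non-finite samples carry no information and yield 0.
    """
    zmax = _max_deviation(s.reference, s.samples, mode)
    if zmax == 0.0:
        return s.cap
    if not math.isfinite(zmax):
        return 0
    # largest integer k with zmax < 2^-k, clamped to [0, cap]; start from a
    # log2 estimate and correct with exact power-of-two comparisons
    k = min(s.cap, max(0, math.floor(-math.log2(zmax))))
    while k > 0 and zmax >= math.ldexp(1.0, -k):
        k -= 1
    while k < s.cap and zmax < math.ldexp(1.0, -(k + 1)):
        k += 1
    return k


def significant_bits_array(
    reference: np.ndarray, samples: np.ndarray, cap: int, mode: str = "relative"
) -> np.ndarray:
    """Vectorised :func:`significant_bits`: ``samples`` has shape
    ``(n_repetitions,) + reference.shape``; returns an int array shaped
    like ``reference``."""
    reference = np.asarray(reference, dtype=np.float64)
    samples = np.asarray(samples, dtype=np.float64)
    z = samples - reference
    if mode == "relative":
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(reference != 0.0, z / reference, z)
    elif mode != "absolute":
        raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    bad = ~np.isfinite(z).all(axis=0)
    zmax = np.max(np.abs(z), axis=0)
    with np.errstate(divide="ignore"):
        k = np.floor(-np.log2(zmax, where=zmax > 0, out=np.full(zmax.shape, np.inf)))
    k = np.clip(k, 0, cap).astype(np.int64)
    # exact correction: need zmax < 2^-k strictly
    for _ in range(2):
        too_high = (k > 0) & (zmax >= np.ldexp(1.0, -k))
        k[too_high] -= 1
        too_low = (k < cap) & (zmax < np.ldexp(1.0, -(k + 1)))
        k[too_low] += 1
    k[zmax == 0.0] = cap
    k[bad] = 0
    return k


def to_digits(bits) -> float:
    """Convert significant bits to significant decimal digits
    (bits * log10 2): 53 bits -> 15.95 digits, 24 -> 7.23."""
    b = np.asarray(bits, dtype=np.float64)
    if (b < 0).any():
        raise ValueError("bits must be >= 0")
    out = b * LOG10_2
    return float(out) if out.ndim == 0 else out


def min_sample_size(probability: float, confidence: float) -> int:
    """Smallest sample size n with probability^n <= 1 - confidence.

    This is the one-sided non-parametric tolerance bound: with confidence
    ``confidence``, a fraction ``probability`` of the distribution lies
    below the sample maximum.
    """
    if not 0.0 < probability < 1.0:
        raise ValueError(f"probability must be in (0, 1), got {probability}")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    n = max(1, math.ceil(math.log(1.0 - confidence) / math.log(probability)))
    while probability**n > 1.0 - confidence:  # guard against log round-off
        n += 1
    while n > 1 and probability ** (n - 1) <= 1.0 - confidence:
        n -= 1
    return n


def summarize(
    sets: Sequence[SampleSet],
    mode: str = "relative",
    probability: float = 0.85,
) -> pd.DataFrame:
    """One report row per quantity: mean, population standard deviation,
    significant bits and digits, sample size and the confidence of the
    non-parametric estimate at ``probability``.

    All sample sets must share the same n.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("no sample sets to summarise")
    ns = {s.samples.size for s in sets}
    if len(ns) > 1:
        raise ValueError(f"mismatched sample sizes across quantities: {sorted(ns)}")
    n = ns.pop()
    rows = []
    for s in sets:
        sb = significant_bits(s, mode=mode)
        rows.append(
            {
                "quantity": s.quantity,
                "mean": float(np.mean(s.samples)),
                "std": float(np.std(s.samples)),  # population std
                "significant_bits": sb,
                "significant_digits": to_digits(sb),
                "n": n,
                "probability": probability,
                "confidence": 1.0 - probability**n,
            }
        )
    return pd.DataFrame(rows)
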