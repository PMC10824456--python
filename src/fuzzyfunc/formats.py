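"""Custom floating-point formats and the rounding operator that emulates them.

A :class:`FloatFormat` is described by its mantissa precision (number of
explicitly stored significand bits, the implicit leading 1 excluded) and the
width of its exponent field.  :func:`round_to_format` maps an arbitrary
double-precision value onto the nearest value representable in such a format,
using round-to-nearest, ties-to-even — the IEEE-754 default.  Computing an
operation in double precision and rounding its result (or its operands) with
this operator emulates what hardware with the reduced format would produce,
up to innocuous double rounding.

Semantics at the edges:

* magnitudes above the format's largest finite value overflow to signed
  infinity (not saturation), so that overflow is observable downstream;
* the format's subnormal range is emulated (gradual underflow); magnitudes
  below half of the smallest subnormal flush to signed zero;
* infinities pass through, any NaN becomes the canonical quiet NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FloatFormat", "preset", "parse_format", "round_to_format", "PRESET_NAMES"]


@dataclass(frozen=True)
class FloatFormat:
    """A binary floating-point format: sign + exponent field + significand.

    Parameters
    ----------
    name
        Human-readable label, used in configs and CLI flags.
    precision_bits
        Number of stored significand bits, excluding the implicit leading 1.
        IEEE double stores 52, single 23.
    exponent_bits
        Width of the exponent field; determines the dynamic range.
    """

    name: str
    precision_bits: int
    exponent_bits: int

    def __post_init__(self) -> None:
        if not 1 <= self.precision_bits <= 52:
            raise ValueError(
                f"precision_bits must be in [1, 52], got {self.precision_bits}"
            )
        if not 2 <= self.exponent_bits <= 11:
            raise ValueError(
                f"exponent_bits must be in [2, 11], got {self.exponent_bits}"
            )

    @property
    def exponent_bias(self) -> int:
        return 2 ** (self.exponent_bits - 1) - 1

    @property
    def max_unbiased_exponent(self) -> int:
        # the all-ones exponent encodes inf/NaN, so the largest normal
        # exponent is bias (biased code 2^w - 2)
        return self.exponent_bias

    @property
    def min_unbiased_exponent(self) -> int:
        return 1 - self.exponent_bias

    @property
    def max_finite(self) -> float:
        p = self.precision_bits
        return float((2.0 - 2.0 ** -p) * 2.0 ** self.max_unbiased_exponent)

    @property
    def smallest_subnormal(self) -> float:
        return float(2.0 ** (self.min_unbiased_exponent - self.precision_bits))

    @property
    def smallest_normal(self) -> float:
        return float(2.0 ** self.min_unbiased_exponent)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name}(p{self.precision_bits}e{self.exponent_bits})"


#: Preset formats.  float64/float32/float16 are the IEEE-754 binary formats,
#: bfloat16 the truncated-single "brain" float, bfloat8 a 2-bit-mantissa
#: 5-bit-exponent 8-bit format, and tf32 NVIDIA's TensorFloat-32 (10-bit
#: precision, 8-bit exponent).
_PRESETS = {
    "float64": FloatFormat("float64", 52, 11),
    "float32": FloatFormat("float32", 23, 8),
    "float16": FloatFormat("float16", 10, 5),
    "bfloat16": FloatFormat("bfloat16", 7, 8),
    "bfloat8": FloatFormat("bfloat8", 2, 5),
    "tf32": FloatFormat("tf32", 10, 8),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> FloatFormat:
    """Return a preset format by name.

    Raises
    ------
    ValueError
        If ``name`` is not a known preset; the message lists valid names.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown format preset {name!r}; valid presets are: "
            + ", ".join(_PRESETS)
        ) from None


def parse_format(spec: str) -> FloatFormat:
    """Parse a format given either as a preset name or a ``p<bits>e<bits>``
    string, e.g. ``"p9e6"`` for 9 precision bits and a 6-bit exponent."""
    if spec in _PRESETS:
        return _PRESETS[spec]
    if spec.startswith("p") and "e" in spec:
        body = spec[1:]
        p_str, _, e_str = body.partition("e")
        try:
            return FloatFormat(spec, int(p_str), int(e_str))
        except ValueError as exc:
            raise ValueError(f"invalid format spec {spec!r}: {exc}") from None
    raise ValueError(
        f"invalid format spec {spec!r}; use a preset name "
        f"({', '.join(_PRESETS)}) or 'p<bits>e<bits>'"
    )


def round_to_format(x, fmt: FloatFormat):
    """Round value(s) to the nearest representable value in ``fmt``.

    Round-to-nearest, ties-to-even on the format's grid; overflow maps to
    signed infinity, underflow flushes gradually through the format's
    subnormal range down to signed zero.  NaN maps to the canonical quiet
    NaN, infinities pass through.  The result is always representable in
    ``fmt`` (the operator is idempotent) and is returned as float64.

    Accepts scalars or arrays; scalars come back as Python floats.
    """
    arr = np.asarray(x, dtype=np.float64)
    scalar = arr.ndim == 0
    a = np.atleast_1d(arr)

    with np.errstate(invalid="ignore", over="ignore", under="ignore"):
        # unbiased exponent: frexp gives x = m * 2^e with m in [0.5, 1),
        # so floor(log2|x|) = e - 1 (exact, also for subnormal doubles)
        _, e = np.frexp(a)
        eu = e - 1
        # grid spacing is 2^(eu - p) in the normal range and fixed at
        # 2^(emin - p) in the subnormal range
        q = np.maximum(eu, fmt.min_unbiased_exponent) - fmt.precision_bits
        scaled = np.ldexp(a, -q)          # |scaled| <= 2^(p+1), exact
        r = np.rint(scaled)               # ties to even
        y = np.ldexp(r, q)
        y = np.where(np.abs(y) > fmt.max_finite, np.copysign(np.inf, a), y)
        y = np.where(np.isfinite(a), y, np.where(np.isnan(a), np.nan, a))

    if scalar:
        return float(y[0])
    return y.reshape(arr.shape)
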