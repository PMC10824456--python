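"""Monte Carlo Arithmetic in Random Rounding (RR) mode.

Random Rounding simulates floating-point roundoff by adding, to the exact
result of every operation, a uniform random perturbation at a chosen
*virtual precision* t:

    inexact(x) = x + 2^(e_x - t) * xi,      xi ~ U(-1/2, 1/2)

where ``e_x = floor(log2 |x|)`` is the unbiased binary exponent of x.  The
perturbed result is then rounded to the working format the value is stored
in.  At t = 24 the injected relative noise is of order 2^-24 ~ 1e-8
(single-precision roundoff); at t = 53 it is 2^-53 ~ 1e-16 (double).

Only RR is implemented.  Precision Bounding and full MCA, which additionally
perturb operation inputs, are deliberately rejected: they are far more
invasive and routinely abort the very computations one is trying to study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats import FloatFormat, preset, round_to_format

__all__ = [
    "VirtualPrecision",
    "VP_SINGLE",
    "VP_DOUBLE",
    "inexact",
    "rr_op",
    "reject_unsupported_mode",
    "RR_OPS",
]


@dataclass(frozen=True)
class VirtualPrecision:
    """Virtual precision for MCA noise plus the format results are stored in.

    The conventional pairings are t=24 with float32 storage for
    single-precision-class values and t=53 with float64 storage for
    double-precision-class values.
    """

    t: int
    working_format: FloatFormat

    def __post_init__(self) -> None:
        if not 1 <= self.t <= 53:
            raise ValueError(f"virtual precision t must be in [1, 53], got {self.t}")


VP_SINGLE = VirtualPrecision(24, preset("float32"))
VP_DOUBLE = VirtualPrecision(53, preset("float64"))


def _t_of(vp) -> int:
    return vp.t if isinstance(vp, VirtualPrecision) else int(vp)


def inexact(x, vp, rng: np.random.Generator):
    """Perturb value(s) with uniform noise at virtual precision ``vp``.

    Exact zeros are never perturbed (zero has no binary exponent, and
    perturbing it would inject *absolute* rather than relative noise);
    NaN and infinities pass through unchanged.  ``vp`` may be a
    :class:`VirtualPrecision` or a bare integer t.

    The arithmetic honours the input's resolution: float64 input is
    perturbed in float64, extended-precision (``np.longdouble``) input in
    extended precision.  The latter matters at t close to 53, where the
    injected noise sits below the double-precision ulp and would otherwise
    be annihilated by the storage rounding of the sum.
    """
    t = _t_of(vp)
    arr = np.asarray(x)
    if arr.dtype != np.longdouble:
        arr = arr.astype(np.float64)
    scalar = arr.ndim == 0
    a = np.atleast_1d(arr)

    xi = (rng.random(a.shape) - 0.5).astype(a.dtype)
    with np.errstate(invalid="ignore", over="ignore", under="ignore"):
        _, e = np.frexp(a)  # a = m * 2^e, m in [0.5, 1) -> floor(log2|a|) = e - 1
        pert = a + np.ldexp(xi, e - 1 - t)
        out = np.where((a != 0) & np.isfinite(a), pert, a)

    if scalar:
        return float(out[0]) if out.dtype == np.float64 else out[0]
    return out.reshape(arr.shape)


def _exact_extended(op: str, operands):
    """The operation evaluated in extended precision (80-bit on x86), so
    that the subsequent perturbation acts on the effectively exact result
    *before* the rounding to the working format — the defining order of
    Random Rounding."""
    a = [np.asarray(o, dtype=np.float64).astype(np.longdouble) for o in operands]
    with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
        if op == "add":
            return a[0] + a[1]
        if op == "sub":
            return a[0] - a[1]
        if op == "mul":
            return a[0] * a[1]
        if op == "div":
            return a[0] / a[1]
        if op == "fma":
            # single rounding: the extended-precision product is exact for
            # double operands, so the final sum is rounded only once
            return a[0] * a[1] + a[2]
        if op == "exp":
            return np.exp(a[0])
        if op == "max":
            return np.maximum(a[0], a[1])
    raise ValueError(f"unknown operation {op!r}; valid: {sorted(RR_OPS)}")


RR_OPS = frozenset({"add", "sub", "mul", "div", "fma", "exp", "max"})


def rr_op(op: str, *operands, vp: VirtualPrecision = VP_DOUBLE, rng: np.random.Generator):
    """Random-Rounding operation: exact double result, one `inexact`
    perturbation at ``vp.t``, then rounding to ``vp.working_format``.

    ``max`` is a comparison, not an arithmetic operation: it is evaluated on
    unperturbed operands and returned unperturbed (comparisons have a
    regularising effect and injecting noise into them would change control
    flow, not roundoff).  ``fma`` is perturbed once, mirroring a fused
    hardware multiply-add with a single rounding.  Division by exact zero
    follows IEEE semantics and the resulting infinity passes through
    unperturbed.
    """
    if op not in RR_OPS:
        raise ValueError(f"unknown operation {op!r}; valid: {sorted(RR_OPS)}")
    z = _exact_extended(op, operands)
    if op == "max":
        z = z.astype(np.float64)
        return z if z.ndim else float(z)
    z = inexact(z, vp, rng)  # extended precision: noise survives at t = 53
    z = np.asarray(z).astype(np.float64)
    if vp.working_format.name != "float64":
        z = round_to_format(z, vp.working_format)
    return z if np.ndim(z) else float(z)


def reject_unsupported_mode(mode: str) -> None:
    """Raise for MCA modes other than RR, with an explanation."""
    if mode in {"pb", "full_mca", "mca"}:
        raise ValueError(
            f"MCA mode {mode!r} is not supported: Precision Bounding and full "
            "MCA perturb operation inputs as well as outputs, which is far "
            "more invasive and is known to crash the instrumented model; "
            "only Random Rounding ('rr') is implemented"
        )
    if mode != "rr":
        raise ValueError(f"unknown MCA mode {mode!r}; only 'rr' is supported")
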