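"""Arithmetic backends: the contract every scalar operation of the CNN
forward pass flows through.

Four backends are available:

``ieee``
    Plain double-precision arithmetic; the unperturbed reference.
``mca_rr``
    Monte Carlo Arithmetic, Random Rounding mode: every operation result is
    perturbed at the virtual precision of its precision class and rounded to
    that class's working format.
``vprec_outbound``
    Reduced-precision emulation: operations are computed in double and every
    *result* is rounded to the custom format assigned to its class.
``vprec_inbound``
    Operations are computed at full double precision but the *input values*
    of each model stage — the sequence encoding, the weights, and the
    stored activations entering the stage — are first rounded to the custom
    format of their class.  Intermediate results inside a stage (partial
    sums of an accumulation) stay at full precision: inbound reduces what
    the computation reads, not how it calculates.

Values in the model belong to one of two precision classes, ``"single"`` or
``"double"``, assigned per model stage (see :mod:`fuzzyfunc.model`).  The
backends operate elementwise on NumPy arrays so that the instrumented
forward pass stays vectorised; every array element corresponds to one scalar
operation, and per-stage operation counters record exactly how many were
executed.

Comparison-based operations (ReLU, max-pooling) are evaluated on unperturbed
operands and never rounded: their result is one of the operands, already
representable, and perturbing order decisions would change control flow
rather than simulate roundoff.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .formats import FloatFormat, preset, round_to_format
from .mca import VirtualPrecision, VP_SINGLE, VP_DOUBLE, inexact, reject_unsupported_mode

__all__ = [
    "ArithmeticBackend",
    "IEEEBackend",
    "MCABackend",
    "VprecBackend",
    "BackendSpec",
    "make_backend",
    "BACKEND_MODES",
]

BACKEND_MODES = ("ieee", "mca_rr", "vprec_inbound", "vprec_outbound")

_F32 = preset("float32")
_F64 = preset("float64")


class ArithmeticBackend:
    """Base backend: plain IEEE double-precision arithmetic.

    Subclasses hook ``_prep`` (operand transform) and ``_finish`` (result
    transform).  ``op_counts`` maps ``(stage, kind)`` to the number of scalar
    operations executed; ``overflow_stages`` records stages where a finite
    input produced a non-finite value (the crash signal for reduced
    formats).
    """

    name = "ieee"

    def __init__(self) -> None:
        self.op_counts: Counter = Counter()
        self.overflow_stages: dict[str, str] = {}

    # -- hooks ---------------------------------------------------------
    def _prep(self, x, cls: str, stage: str):
        return x

    def _cast_in(self, x, cls: str):
        return x

    def _finish(self, z, cls: str, stage: str):
        return z

    def prep_weights(self, w: np.ndarray, cls: str) -> np.ndarray:
        """Transform weights at load time (reduced formats round them)."""
        return np.asarray(w, dtype=np.float64)

    def prep_stage_input(self, x, cls: str, stage: str):
        """Transform a value entering a model stage (inbound rounding)."""
        return x

    # -- arithmetic ops ------------------------------------------------
    def _binop(self, ufunc, kind, x, y, cls, stage):
        x = self._cast_in(self._prep(x, cls, stage), cls)
        y = self._cast_in(self._prep(y, cls, stage), cls)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore", under="ignore"):
            z = ufunc(x, y)
        self.op_counts[(stage, kind)] += z.size
        return self._finish(z, cls, stage)

    def add(self, x, y, cls, stage):
        return self._binop(np.add, "add", x, y, cls, stage)

    def sub(self, x, y, cls, stage):
        return self._binop(np.subtract, "sub", x, y, cls, stage)

    def mul(self, x, y, cls, stage):
        return self._binop(np.multiply, "mul", x, y, cls, stage)

    def div(self, x, y, cls, stage):
        return self._binop(np.divide, "div", x, y, cls, stage)

    def exp(self, x, cls, stage):
        x = self._cast_in(self._prep(x, cls, stage), cls)
        with np.errstate(over="ignore", under="ignore"):
            z = np.exp(x)
        self.op_counts[(stage, "exp")] += z.size
        if np.isinf(z).any() and np.isfinite(np.asarray(x)).all():
            self.overflow_stages.setdefault(stage, "exp overflow")
        return self._finish(z, cls, stage)

    # -- comparison ops (never perturbed, never rounded) ---------------
    def relu(self, x):
        return np.maximum(x, 0.0)

    def maxpool(self, x, axis):
        return np.max(x, axis=axis)

    def conv_branch_mul_count(self, stage: str) -> int:
        return self.op_counts[(stage, "mul")]


class IEEEBackend(ArithmeticBackend):
    """Unperturbed double-precision reference."""


class MCABackend(ArithmeticBackend):
    """Monte Carlo Arithmetic, Random Rounding mode.

    Each operation result is perturbed with uniform noise at the virtual
    precision of its class and then rounded to that class's working format
    (float32 for single-class, float64 for double-class by default).  The
    backend owns one seeded RNG stream: fixing the seed makes any sequence
    of operations bit-reproducible.
    """

    name = "mca_rr"

    def __init__(
        self,
        seed: int,
        vp_single: VirtualPrecision = VP_SINGLE,
        vp_double: VirtualPrecision = VP_DOUBLE,
    ) -> None:
        super().__init__()
        self.vp_single = vp_single
        self.vp_double = vp_double
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)

    def _vp(self, cls: str) -> VirtualPrecision:
        return self.vp_single if cls == "single" else self.vp_double

    def _cast_in(self, x, cls):
        # double-class operations run in extended precision so that t=53
        # noise acts on the pre-rounding result and dithers the final
        # rounding instead of being annihilated by the double-precision ulp;
        # for single-class (t ~ 24) the double result is already exact
        # relative to the injected noise scale
        if cls == "double" and self._vp(cls).t > 49:
            return np.asarray(x).astype(np.longdouble)
        return x

    def _finish(self, z, cls, stage):
        vp = self._vp(cls)
        z = inexact(z, vp.t, self.rng)
        z = np.asarray(z).astype(np.float64)
        wf = vp.working_format
        if wf.name == "float64":
            return z
        if wf.name == "float32":
            # fast path, bit-identical to round_to_format for this preset
            with np.errstate(over="ignore", under="ignore"):
                return z.astype(np.float32).astype(np.float64)
        return round_to_format(z, wf)


class VprecBackend(ArithmeticBackend):
    """Reduced-precision emulation of custom floating-point formats.

    ``outbound`` rounds every operation result to the class's format;
    ``inbound`` rounds the values entering each stage (weights, encoded
    input, stored activations) and computes the stage at full double
    precision.  Overflow to infinity introduced by the rounding (or by the
    operation itself) is recorded per stage so that runs can be flagged as
    crashed instead of silently propagating non-finite values.
    """

    def __init__(self, mode: str, fmt_single: FloatFormat, fmt_double: FloatFormat) -> None:
        if mode not in ("inbound", "outbound"):
            raise ValueError(f"vprec mode must be 'inbound' or 'outbound', got {mode!r}")
        super().__init__()
        self.mode = mode
        self.name = f"vprec_{mode}"
        self.fmt_single = fmt_single
        self.fmt_double = fmt_double

    def _fmt(self, cls: str) -> FloatFormat:
        return self.fmt_single if cls == "single" else self.fmt_double

    def _round(self, x, cls, stage):
        fmt = self._fmt(cls)
        if fmt.name == "float64":
            return np.asarray(x, dtype=np.float64)
        y = round_to_format(x, fmt)
        ya = np.asarray(y)
        if np.isinf(ya).any() and np.isfinite(np.asarray(x, dtype=np.float64)).all():
            self.overflow_stages.setdefault(stage, f"overflow rounding to {fmt.name}")
        return y

    def _finish(self, z, cls, stage):
        if self.mode == "outbound":
            return self._round(z, cls, stage)
        return z

    def prep_stage_input(self, x, cls, stage):
        if self.mode == "inbound":
            return self._round(x, cls, stage)
        return x

    def prep_weights(self, w, cls):
        return np.asarray(self._round(np.asarray(w, dtype=np.float64), cls, "weights"))


@dataclass(frozen=True)
class BackendSpec:
    """Declarative description of an arithmetic backend.

    Exactly one mode is active; fields irrelevant to the mode are ignored
    (``ieee`` uses none of them).  ``seed`` is required for ``mca_rr``.
    ``class_assignment`` optionally overrides the model's default mapping
    of stages to precision classes (see :mod:`fuzzyfunc.model`).
    """

    mode: str = "ieee"
    fmt_double: FloatFormat = _F64
    fmt_single: FloatFormat = _F32
    vp_single: VirtualPrecision = VP_SINGLE
    vp_double: VirtualPrecision = VP_DOUBLE
    seed: Optional[int] = None
    class_assignment: Optional[tuple] = None  # ((stage, class), ...) pairs

    def __post_init__(self) -> None:
        if self.mode not in BACKEND_MODES:
            if self.mode in {"pb", "full_mca", "mca"}:
                reject_unsupported_mode(self.mode)
            raise ValueError(
                f"unknown backend mode {self.mode!r}; valid: {BACKEND_MODES}"
            )


def make_backend(spec: BackendSpec) -> ArithmeticBackend:
    """Instantiate the backend described by ``spec``."""
    if spec.mode == "ieee":
        return IEEEBackend()
    if spec.mode == "mca_rr":
        if spec.seed is None:
            raise ValueError("mca_rr backend requires an explicit seed")
        return MCABackend(spec.seed, spec.vp_single, spec.vp_double)
    mode = spec.mode.split("_", 1)[1]  # inbound | outbound
    return VprecBackend(mode, spec.fmt_single, spec.fmt_double)
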