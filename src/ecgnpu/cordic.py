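"""CORDIC evaluation of tanh and sigmoid for the activation unit.

Two cascaded CORDIC stages reproduce the activation unit:

1. *Hyperbolic rotation mode* computes (sinh θ, cosh θ) by shift-and-add
   micro-rotations with step angles atanh(2^-k).  Hyperbolic CORDIC only
   converges if iterations k = 4, 13, 40, ... are executed twice; with the
   standard schedule (k = 1..n plus those repeats) the reachable angle is
   Σ atanh(2^-k) ≈ 1.1182.  To reach larger arguments the index set is
   extended to k = -m..0 with step angles atanh(1 - 2^(k-2)), which raises
   the bound to ≈5.16 at the default three extension terms (k = -2..0) —
   enough for sigmoid over
   |x| ≤ 8 (which needs |θ| ≤ 4 after the x/2 identity).
2. *Linear vectoring mode* divides sinh/cosh; its own constraint |y/x| ≤ 1
   is always met because |tanh| < 1.

tanh(x) = sinh(x)/cosh(x); sigmoid(x) = (tanh(x/2) + 1)/2, the same
identity as tanh(x) = 2·sigmoid(2x) − 1.  Inputs beyond the configured
convergence bound saturate to the asymptote (exact in binary16 anyway for
|x| ≳ 6).  Iterations run in float64; binary16 rounding is applied only at
the module boundary, so algorithmic error can be separated from
quantisation error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .fp16 import HalfWord, f16_encode

__all__ = [
    "CordicConfig",
    "CordicDomainError",
    "max_rotation_angle",
    "rotate_hyperbolic",
    "divide_linear",
    "tanh_cordic",
    "sigmoid_cordic",
]

#: hyperbolic iterations that must run twice for convergence
_REPEAT_INDICES = (4, 13, 40, 121)


class CordicDomainError(ValueError):
    """Argument outside the convergence domain of a CORDIC mode."""


def _positive_schedule(n_pos: int) -> list[int]:
    sched: list[int] = []
    for k in range(1, n_pos + 1):
        sched.append(k)
        if k in _REPEAT_INDICES:
            sched.append(k)
    return sched


def _extension_schedule(m_neg: int) -> list[int]:
    # m_neg is a count: m_neg iterations k = -(m_neg-1) .. 0, executed
    # before the positive iterations; 0 means no extension at all
    if m_neg <= 0:
        return []
    return list(range(1 - m_neg, 1))


def _step_angle(k: int) -> float:
    if k >= 1:
        return math.atanh(2.0 ** -k)
    return math.atanh(1.0 - 2.0 ** (k - 2))


def _step_tangent(k: int) -> float:
    if k >= 1:
        return 2.0 ** -k
    return 1.0 - 2.0 ** (k - 2)


@dataclass
class CordicConfig:
    """Iteration schedule of the hyperbolic stage.

    Parameters
    ----------
    n_pos:
        Number of standard iterations k = 1..n_pos; indices 4 and 13 (and
        40, ...) are automatically executed twice when present.  16 gives
        ≈2^-15 angular resolution, comfortably below the binary16 ulp.
    m_neg:
        Count of range-extension iterations k = -(m_neg-1)..0 (0 disables
        the extension).  The default 3 is the smallest count whose
        convergence bound covers |θ| ≤ 4.2 (it reaches ≈5.16; 2 reaches
        only ≈3.38).
    """

    n_pos: int = 16
    m_neg: int = 3
    gain: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.m_neg < 0:
            raise ValueError("n_pos and m_neg must be non-negative")
        g = 1.0
        for k in self.schedule():
            t = _step_tangent(k)
            g *= math.sqrt(1.0 - t * t)
        self.gain = g

    def schedule(self) -> list[int]:
        """Executed iteration indices, extension terms first."""
        return _extension_schedule(self.m_neg) + _positive_schedule(self.n_pos)

    @property
    def resolution(self) -> float:
        """Guaranteed absolute accuracy of the rotation, 2^(1-n_pos)."""
        return 2.0 ** (1 - self.n_pos)


def max_rotation_angle(cfg: CordicConfig) -> float:
    """Largest |θ| the hyperbolic rotation can reach: Σ step angles.

    With the standard positive schedule alone (n_pos = 30, m_neg = 0) this
    is the classic bound 1.1182.
    """
    if cfg.n_pos == 0 and cfg.m_neg == 0:
        return 0.0
    return sum(_step_angle(k) for k in cfg.schedule())


def rotate_hyperbolic(theta: float, cfg: CordicConfig) -> tuple[float, float]:
    """Gain-compensated (sinh θ, cosh θ) via hyperbolic micro-rotations."""
    bound = max_rotation_angle(cfg)
    if abs(theta) > bound:
        raise CordicDomainError(
            f"|theta|={abs(theta):.4f} exceeds convergence bound {bound:.4f}"
        )
    if theta == 0.0:
        # the d = sign(z) choice is asymmetric at zero; the zero angle is
        # exact by odd symmetry
        return 0.0, 1.0
    x = 1.0 / cfg.gain  # pre-scale so the shrinking gain cancels
    y = 0.0
    z = theta
    for k in cfg.schedule():
        t = _step_tangent(k)
        d = 1.0 if z >= 0.0 else -1.0
        x, y = x + d * t * y, y + d * t * x
        z -= d * _step_angle(k)
    return y, x


def divide_linear(y: float, x: float, cfg: CordicConfig) -> float:
    """y/x via linear-mode vectoring; requires x ≠ 0 and |y/x| ≤ 1."""
    if x == 0.0:
        raise ZeroDivisionError("divide_linear: x = 0")
    if abs(y) > abs(x):
        raise CordicDomainError("divide_linear requires |y/x| <= 1")
    if y == 0.0:
        return 0.0  # d = sign(y·x) is asymmetric at zero; 0/x is exact
    z = 0.0
    yy = y
    for k in range(1, cfg.n_pos + 1):
        t = 2.0 ** -k
        d = 1.0 if (yy >= 0.0) == (x >= 0.0) else -1.0
        yy -= d * t * x
        z += d * t
    return z


def _tanh_core(xv: float, cfg: CordicConfig) -> float:
    """tanh via the two CORDIC stages, in float64, with saturation."""
    bound = max_rotation_angle(cfg)
    if abs(xv) > bound:
        return math.copysign(1.0, xv)
    s, c = rotate_hyperbolic(xv, cfg)
    return divide_linear(s, c, cfg)


def tanh_cordic(x: HalfWord | float, cfg: CordicConfig) -> HalfWord:
    """tanh(x) through hyperbolic rotation + linear division, in binary16."""
    xv = x.value if isinstance(x, HalfWord) else float(x)
    return f16_encode(_tanh_core(xv, cfg))


def sigmoid_cordic(x: HalfWord | float, cfg: CordicConfig) -> HalfWord:
    """sigmoid(x) = (tanh(x/2) + 1)/2, sharing the tanh datapath."""
    xv = x.value if isinstance(x, HalfWord) else float(x)
    return f16_encode((_tanh_core(xv / 2.0, cfg) + 1.0) / 2.0)
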