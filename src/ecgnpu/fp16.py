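"""IEEE-754 binary16 datapath emulation.

The processor computes everything in half precision (1 sign bit, 5 exponent
bits, 10 mantissa bits).  This module is the software model of that datapath:
encode/decode between reals and 16-bit patterns, multiply, add, and the
two-step multiply-accumulate, each with sticky overflow/underflow/invalid
flags mirroring the MAC unit's error signal.

Semantics
---------
* Rounding is round-to-nearest-even at every operation boundary.
* Overflow saturates to +/-65504 (the largest finite half) and sets the
  overflow flag; the datapath never emits infinities from finite operands.
* Underflow is gradual (subnormals are kept); the flag is set whenever a
  nonzero exact result rounds to a subnormal or to zero.
* The MAC rounds the product to binary16 *before* adding it to the
  accumulator (separate multiplier and adder blocks, not a fused unit).

Every scalar operation is defined as the exact float64 computation rounded
to binary16 — exact because any product or sum of two binary16 values is
representable in float64.  Vectorised helpers with identical semantics are
provided for the convolution engine, which represents feature maps as
float64 arrays whose every element is an exact binary16 value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "F16_MAX",
    "F16_MIN_NORMAL",
    "Flags",
    "HalfWord",
    "f16_encode",
    "f16_decode",
    "f16_add",
    "f16_mul",
    "f16_mac",
    "round_f16",
    "vround_f16",
    "bits_to_float",
    "float_to_bits",
    "image_to_floats",
    "floats_to_image",
    "write_hex_image",
    "read_hex_image",
]

F16_MAX = 65504.0            # largest finite binary16
F16_MIN_NORMAL = 2.0 ** -14  # smallest positive normal binary16

_POS_SAT_BITS = 0x7BFF
_NEG_SAT_BITS = 0xFBFF
_CANONICAL_NAN = 0x7E00


@dataclass
class Flags:
    """Sticky status flags of one accumulation chain."""

    overflow: bool = False
    underflow: bool = False
    invalid: bool = False

    def reset(self) -> None:
        self.overflow = self.underflow = self.invalid = False

    def any(self) -> bool:
        return self.overflow or self.underflow or self.invalid

    def merge(self, other: "Flags") -> None:
        self.overflow |= other.overflow
        self.underflow |= other.underflow
        self.invalid |= other.invalid


@dataclass
class HalfWord:
    """A 16-bit binary16 pattern plus the sticky flags that produced it.

    ``bits`` is the ground truth; ``value`` is the decoded float64 view.
    Decode→encode round-trips every pattern (including NaN payloads) because
    ``bits`` is carried, never reconstructed from the float.
    """

    bits: int
    flags: Flags = field(default_factory=Flags)

    def __post_init__(self) -> None:
        self.bits = int(self.bits) & 0xFFFF

    @property
    def value(self) -> float:
        return bits_to_float(self.bits)

    def is_nan(self) -> bool:
        return (self.bits & 0x7C00) == 0x7C00 and (self.bits & 0x03FF) != 0

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"HalfWord(0x{self.bits:04X} = {self.value!r})"


def bits_to_float(bits: int) -> float:
    """Decode a 16-bit pattern to the float64 it denotes."""
    return float(np.uint16(bits).view(np.float16))


def float_to_bits(x: float) -> int:
    """Round a float64 to binary16 (RNE, inf on overflow) and return bits."""
    with np.errstate(over="ignore"):
        return int(np.float64(x).astype(np.float16).view(np.uint16))


def f16_encode(x: float) -> HalfWord:
    """Encode a real (or +/-inf, NaN) as a HalfWord with status flags.

    Finite values that round beyond the binary16 range saturate to +/-65504
    with the overflow flag; nonzero values that round to a subnormal or to
    zero set the underflow flag.  Exact infinities encode as infinities
    (they are representable); NaN encodes as the canonical quiet NaN with
    the invalid flag.
    """
    flags = Flags()
    xf = float(x)
    if xf != xf:  # NaN: keep the truncated payload when one survives
        flags.invalid = True
        bits = float_to_bits(xf)
        if (bits & 0x03FF) == 0:  # payload lost entirely -> canonical qNaN
            bits = _CANONICAL_NAN
        return HalfWord(bits, flags)
    bits = float_to_bits(xf)
    exp_field = bits & 0x7C00
    if exp_field == 0x7C00:  # rounded to +/-inf
        if xf == float("inf"):
            return HalfWord(0x7C00, flags)
        if xf == float("-inf"):
            return HalfWord(0xFC00, flags)
        flags.overflow = True
        bits = _POS_SAT_BITS if xf > 0 else _NEG_SAT_BITS
    elif xf != 0.0 and exp_field == 0:  # nonzero rounded to subnormal/zero
        flags.underflow = True
    return HalfWord(bits, flags)


def f16_decode(bits: int) -> HalfWord:
    """Wrap a raw 16-bit pattern as a HalfWord (no flags)."""
    return HalfWord(int(bits) & 0xFFFF)


def _combine(result: float, a: HalfWord, b: HalfWord, *extra: HalfWord) -> HalfWord:
    out = f16_encode(result)
    for operand in (a, b, *extra):
        out.flags.merge(operand.flags)
    return out


def f16_mul(a: HalfWord, b: HalfWord) -> HalfWord:
    """Correctly rounded binary16 product with sticky flags."""
    av, bv = a.value, b.value
    if a.is_nan() or b.is_nan() or (abs(av) == float("inf") and bv == 0.0) or (
        abs(bv) == float("inf") and av == 0.0
    ):
        flags = Flags(invalid=True)
        flags.merge(a.flags)
        flags.merge(b.flags)
        return HalfWord(_CANONICAL_NAN, flags)
    return _combine(av * bv, a, b)  # exact in float64


def f16_add(a: HalfWord, b: HalfWord) -> HalfWord:
    """Correctly rounded binary16 sum with sticky flags."""
    av, bv = a.value, b.value
    if a.is_nan() or b.is_nan() or (
        abs(av) == float("inf") and abs(bv) == float("inf") and av != bv
    ):
        flags = Flags(invalid=True)
        flags.merge(a.flags)
        flags.merge(b.flags)
        return HalfWord(_CANONICAL_NAN, flags)
    return _combine(av + bv, a, b)  # exact in float64


def f16_mac(acc: HalfWord, a: HalfWord, b: HalfWord) -> HalfWord:
    """acc + a*b with the product rounded to binary16 before the add.

    Two rounding steps, matching a separate multiplier feeding an adder;
    flags are sticky across both steps and across the chain through acc.
    """
    return f16_add(acc, f16_mul(a, b))


# ---------------------------------------------------------------------------
# Vectorised kernels (engine-internal).  Arrays hold float64 values each of
# which is exactly a binary16 value; rounding happens through the float16
# cast, saturating instead of producing infinities.
# ---------------------------------------------------------------------------


def vround_f16(x: np.ndarray, flags: Flags | None = None) -> np.ndarray:
    """Round a float64 array elementwise to binary16 values (as float64).

    Finite inputs that overflow saturate to +/-F16_MAX; if ``flags`` is
    given, overflow/underflow are accumulated stickily.
    """
    x = np.asarray(x, dtype=np.float64)
    with np.errstate(over="ignore"):
        r = x.astype(np.float16).astype(np.float64)
    finite_in = np.isfinite(x)
    over = finite_in & ~np.isfinite(r)
    if over.any():
        r = np.where(over, np.copysign(F16_MAX, x), r)
    if flags is not None:
        if over.any():
            flags.overflow = True
        under = finite_in & (x != 0.0) & (np.abs(r) < F16_MIN_NORMAL)
        if under.any():
            flags.underflow = True
        if np.isnan(r).any():
            flags.invalid = True
    return r


def round_f16(x: float, flags: Flags | None = None) -> float:
    """Scalar counterpart of :func:`vround_f16`."""
    return float(vround_f16(np.asarray([x]), flags)[0])


# ---------------------------------------------------------------------------
# Weight/data images: flat little-endian 16-bit words, plus a plain-text hex
# dump (one 4-hex-digit word per line) used for fixtures.
# ---------------------------------------------------------------------------


def image_to_floats(image: np.ndarray) -> np.ndarray:
    """View a uint16 word image as the float64 values it encodes."""
    return np.asarray(image, dtype=np.uint16).view(np.float16).astype(np.float64)


def floats_to_image(values: np.ndarray, flags: Flags | None = None) -> np.ndarray:
    """Quantise float64 values to a uint16 binary16 word image."""
    r = vround_f16(np.asarray(values, dtype=np.float64), flags)
    return r.astype(np.float16).view(np.uint16)


def write_hex_image(path, image: np.ndarray) -> None:
    words = np.asarray(image, dtype=np.uint16)
    with open(path, "w") as fh:
        for w in words:
            fh.write(f"{int(w):04X}\n")


def read_hex_image(path) -> np.ndarray:
    with open(path) as fh:
        words = [int(line.strip(), 16) for line in fh if line.strip()]
    return np.asarray(words, dtype=np.uint16)
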