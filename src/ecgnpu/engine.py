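"""PE-array execution engine: convolution, activation, pooling, FIR mode.

The compute fabric is a 4x4 grid: four MAC groups, four MAC units (lanes)
per group.  During a "wave" each group produces one output position, so
four consecutive output positions are computed per wave (inter-kernel
parallelism); within a group the four lanes supply products for four
consecutive taps of the multiply-accumulate sequence (intra-kernel
parallelism), feeding a single accumulator in tap order.

binary16 addition is not associative, so one accumulation order must be
law.  The canonical order — input channel ascending, then tap ascending,
each MAC being the two-step rounded product-then-add — is defined by the
sequential loop-nest reference (:func:`run_conv_reference`); the PE-array
path schedules work in waves and lanes but feeds its accumulators in the
same canonical order, and is therefore bit-identical to the reference by
construction.  That equivalence is a tested contract, not an accident.

Feature maps are float64 arrays whose elements are exact binary16 values
(shape ``[channels, length]``); SRAM images are flat uint16 word arrays
with channel-major layout.  Both paths saturate to ±65504 on overflow and
record sticky flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .cordic import CordicConfig, sigmoid_cordic, tanh_cordic
from .fp16 import Flags, floats_to_image, image_to_floats, vround_f16
from .isa import Activation, Instruction, PoolType

__all__ = [
    "EngineError",
    "LayerTrace",
    "run_conv_reference",
    "run_conv_pe_array",
    "run_fc",
    "apply_activation",
    "apply_pooling",
    "execute_stream",
    "fir_filter",
    "design_bandpass",
    "MAC_GROUPS",
    "LANES_PER_GROUP",
]

MAC_GROUPS = 4        # output positions per wave
LANES_PER_GROUP = 4   # taps per group per cycle


class EngineError(ValueError):
    """Shape mismatch, address fault, or invalid engine request."""


def _check_conv_shapes(x: np.ndarray, w: np.ndarray, stride: int) -> int:
    if x.ndim != 2 or w.ndim != 3:
        raise EngineError(
            f"expected input [C,L] and weights [O,C,K], got {x.shape} / {w.shape}")
    if w.shape[1] != x.shape[0]:
        raise EngineError(
            f"weight in_channels {w.shape[1]} != input channels {x.shape[0]}")
    if stride not in (1, 2, 3):
        raise EngineError(f"stride must be 1..3, got {stride}")
    out_len = (x.shape[1] - w.shape[2]) // stride + 1
    if x.shape[1] < w.shape[2] or out_len <= 0:
        raise EngineError(
            f"kernel {w.shape[2]} does not fit input length {x.shape[1]}")
    return out_len


def run_conv_reference(x: np.ndarray, w: np.ndarray, stride: int = 1,
                       flags: Flags | None = None) -> np.ndarray:
    """Sequential loop-nest valid convolution in binary16.

    This is the engine's bit-exactness oracle: for every (out_channel,
    position) the accumulator starts at zero and receives the rounded
    products in canonical order — input channel ascending, tap ascending —
    each add itself rounded (two-step MAC).
    """
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    out_len = _check_conv_shapes(x, w, stride)
    n_out, n_in, k = w.shape
    base = np.arange(out_len) * stride
    acc = np.zeros((n_out, out_len))
    for c in range(n_in):
        xc = x[c]
        for t in range(k):
            prod = vround_f16(w[:, c, t][:, None] * xc[base + t][None, :], flags)
            acc = vround_f16(acc + prod, flags)
    return acc


def run_conv_pe_array(x: np.ndarray, w: np.ndarray, stride: int = 1,
                      flags: Flags | None = None
                      ) -> tuple[np.ndarray, int]:
    """Wave-scheduled PE-array convolution; returns (output, wave_count).

    Output positions are issued in waves of MAC_GROUPS consecutive
    positions; inside each wave the (channel, tap) MAC sequence is walked
    in chunks of LANES_PER_GROUP lane products, which the group accumulator
    absorbs in lane order.  The resulting per-output addition sequence is
    exactly the canonical one, so the result is bit-identical to
    :func:`run_conv_reference`.
    """
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    out_len = _check_conv_shapes(x, w, stride)
    n_out, n_in, k = w.shape
    taps = [(c, t) for c in range(n_in) for t in range(k)]  # canonical order
    out = np.zeros((n_out, out_len))
    n_waves = math.ceil(out_len / MAC_GROUPS)
    for wave in range(n_waves):
        pos = np.arange(wave * MAC_GROUPS,
                        min((wave + 1) * MAC_GROUPS, out_len))
        base = pos * stride
        acc = np.zeros((n_out, len(pos)))
        for chunk_start in range(0, len(taps), LANES_PER_GROUP):
            chunk = taps[chunk_start:chunk_start + LANES_PER_GROUP]
            # all lanes multiply concurrently ...
            lane_products = [
                vround_f16(w[:, c, t][:, None] * x[c, base + t][None, :], flags)
                for (c, t) in chunk
            ]
            # ... and the group accumulator drains them in lane order
            for prod in lane_products:
                acc = vround_f16(acc + prod, flags)
        out[:, pos] = acc
    return out, n_waves


def run_fc(x_flat: np.ndarray, w: np.ndarray,
           flags: Flags | None = None) -> np.ndarray:
    """Fully connected layer: out[o] = sum_j w[o,j]*x[j] in binary16.

    The flattened input is walked in storage (channel-major) order, each
    product rounded then accumulated — the same MAC semantics as conv.
    """
    x_flat = np.asarray(x_flat, dtype=np.float64).ravel()
    w = np.asarray(w, dtype=np.float64)
    if w.ndim != 2 or w.shape[1] != x_flat.size:
        raise EngineError(
            f"FC weights {w.shape} do not match input length {x_flat.size}")
    acc = np.zeros(w.shape[0])
    for j in range(x_flat.size):
        prod = vround_f16(w[:, j] * x_flat[j], flags)
        acc = vround_f16(acc + prod, flags)
    return acc


# ---------------------------------------------------------------------------
# Activation dispatch
# ---------------------------------------------------------------------------

_act_cache: dict[tuple, dict[float, float]] = {}


def apply_activation(x: np.ndarray, code: Activation,
                     cfg: CordicConfig | None = None) -> np.ndarray:
    """Elementwise bypass / ReLU / CORDIC sigmoid / CORDIC tanh."""
    x = np.asarray(x, dtype=np.float64)
    code = Activation(code)
    if code == Activation.BYPASS:
        return x.copy()
    if code == Activation.RELU:
        return np.maximum(x, 0.0)
    if cfg is None:
        cfg = CordicConfig()
    fn = tanh_cordic if code == Activation.TANH else sigmoid_cordic
    # only 2^16 distinct binary16 inputs exist; memoise per configuration
    key = (code, cfg.n_pos, cfg.m_neg)
    cache = _act_cache.setdefault(key, {})
    flat = x.ravel()
    out = np.empty_like(flat)
    for i, v in enumerate(flat):
        fv = float(v)
        r = cache.get(fv)
        if r is None:
            r = cache[fv] = fn(fv, cfg).value
        out[i] = r
    return out.reshape(x.shape)


# ---------------------------------------------------------------------------
# Pooling unit
# ---------------------------------------------------------------------------


def apply_pooling(x: np.ndarray, pool_type: PoolType, pool_size: int,
                  flags: Flags | None = None) -> np.ndarray:
    """Non-overlapping pooling with the trailing remainder dropped.

    Max pooling is a comparator pass over NaN-free binary16 values.  Average
    pooling accumulates the window in index order with binary16 rounding,
    then divides by the power-of-two window via an exponent decrement.
    """
    x = np.asarray(x, dtype=np.float64)
    pool_type = PoolType(pool_type)
    if pool_type == PoolType.BYPASS:
        return x.copy()
    if pool_size < 1:
        raise EngineError(f"pool_size must be >= 1, got {pool_size}")
    n_ch, length = x.shape
    n_win = length // pool_size
    if n_win == 0:
        raise EngineError(
            f"pool_size {pool_size} empties a length-{length} feature map")
    windows = x[:, :n_win * pool_size].reshape(n_ch, n_win, pool_size)
    if pool_type == PoolType.MAX:
        return windows.max(axis=2)
    if pool_size & (pool_size - 1):
        raise EngineError(
            f"avg pooling needs a power-of-two size, got {pool_size}")
    acc = np.zeros((n_ch, n_win))
    for j in range(pool_size):  # binary16 sum in index order
        acc = vround_f16(acc + windows[:, :, j], flags)
    return vround_f16(acc / pool_size, flags)  # exact exponent shift


# ---------------------------------------------------------------------------
# Instruction-stream execution over SRAM images
# ---------------------------------------------------------------------------


@dataclass
class LayerTrace:
    """Per-instruction execution record (the Fig-8 output-mux tag lives in
    ``stream``: 'conv', 'fc' or 'fir')."""

    index: int
    stream: str
    in_shape: tuple
    conv_len: int
    out_shape: tuple
    waves: int
    flags: Flags = field(default_factory=Flags)

    def as_dict(self) -> dict:
        return {"index": self.index, "stream": self.stream,
                "in_shape": list(self.in_shape), "conv_len": self.conv_len,
                "out_shape": list(self.out_shape), "waves": self.waves,
                "overflow": self.flags.overflow,
                "underflow": self.flags.underflow,
                "invalid": self.flags.invalid}


def execute_stream(instructions, weight_image, data_image,
                   cordic_cfg: CordicConfig | None = None,
                   fir_tag: bool = False
                   ) -> tuple[np.ndarray, list[LayerTrace]]:
    """Run a compiled instruction stream over SRAM images.

    ``weight_image`` and ``data_image`` are flat uint16 word arrays; feature
    maps are stored channel-major at the instruction's addresses.  Each
    instruction runs conv/FC → activation → pooling fused, writing its
    result at ``output_addr``.  Returns the final feature map ``[C, L]``
    and a per-layer trace.  An empty stream returns the data image's
    untouched words as a 1-channel map.
    """
    weights = image_to_floats(np.asarray(weight_image, dtype=np.uint16))
    data = image_to_floats(np.asarray(data_image, dtype=np.uint16))
    instructions = list(instructions)
    if not instructions:
        return data[None, :].copy(), []
    trace: list[LayerTrace] = []
    out = None
    for idx, inst in enumerate(instructions):
        n_ch, length = inst.input_channel, inst.input_row
        in_words = n_ch * length
        if inst.input_addr + in_words > data.size:
            raise EngineError(
                f"instruction {idx}: input region [{inst.input_addr}, "
                f"{inst.input_addr + in_words}) exceeds data SRAM "
                f"({data.size} words)")
        x = data[inst.input_addr:inst.input_addr + in_words].reshape(n_ch, length)
        flags = Flags()
        if inst.layer_type == 0:
            n_w = inst.output_channel * n_ch * inst.kernel_row
            if inst.weight_addr + n_w > weights.size:
                raise EngineError(
                    f"instruction {idx}: weight region exceeds image "
                    f"({weights.size} words)")
            w = weights[inst.weight_addr:inst.weight_addr + n_w].reshape(
                inst.output_channel, n_ch, inst.kernel_row)
            conv, waves = run_conv_pe_array(x, w, inst.stride, flags)
            stream_tag = "fir" if fir_tag else "conv"
        else:
            if n_ch != 1:
                raise EngineError(
                    f"instruction {idx}: FC expects input_channel=1")
            n_w = inst.output_channel * length
            if inst.weight_addr + n_w > weights.size:
                raise EngineError(
                    f"instruction {idx}: weight region exceeds image "
                    f"({weights.size} words)")
            w = weights[inst.weight_addr:inst.weight_addr + n_w].reshape(
                inst.output_channel, length)
            conv = run_fc(x[0], w, flags)[:, None]
            waves = math.ceil(inst.output_channel / MAC_GROUPS)
            stream_tag = "fc"
        act = apply_activation(conv, inst.activation, cordic_cfg)
        out = apply_pooling(act, inst.pool_type, inst.pool_size, flags)
        out_words = out.size
        if inst.output_addr + out_words > data.size:
            raise EngineError(
                f"instruction {idx}: output region [{inst.output_addr}, "
                f"{inst.output_addr + out_words}) exceeds data SRAM")
        data[inst.output_addr:inst.output_addr + out_words] = out.ravel()
        trace.append(LayerTrace(
            index=idx, stream=stream_tag, in_shape=(n_ch, length),
            conv_len=conv.shape[1], out_shape=out.shape, waves=waves,
            flags=flags))
    return out, trace


# ---------------------------------------------------------------------------
# FIR mode: band-pass denoising on the CNN fabric
# ---------------------------------------------------------------------------


def design_bandpass(fs: float, low: float = 0.5, high: float = 40.0,
                    n_taps: int = 64) -> np.ndarray:
    """Hamming-windowed sinc band-pass taps, quantised to binary16.

    The default 0.5–40 Hz band removes baseline wander and high-frequency
    noise while keeping the QRS energy.  Any coefficient set may be
    substituted.
    """
    if not 0 < low < high < fs / 2:
        raise EngineError(
            f"band edges must satisfy 0 < {low} < {high} < fs/2 ({fs / 2})")
    taps = scipy.signal.firwin(n_taps, [low, high], pass_zero=False, fs=fs,
                               window="hamming")
    return image_to_floats(floats_to_image(taps))


def fir_filter(x: np.ndarray, coeffs: np.ndarray,
               cordic_cfg: CordicConfig | None = None
               ) -> tuple[np.ndarray, list[LayerTrace]]:
    """Valid FIR convolution executed on the CNN engine.

    A tap vector short enough for the 5-bit kernel-length field (≤31 taps)
    runs as a plain 1-in/1-out-channel conv instruction with bypass
    activation and bypass pooling.  Longer tap vectors are split into
    contiguous 16-tap blocks laid across input channels, channel ``c``
    holding the input delayed by ``16·c`` samples: channel-ascending /
    tap-ascending accumulation then walks the taps in exactly canonical
    order, so the output of the multi-channel instruction is bit-identical
    to a single valid convolution (and hence to
    :func:`run_conv_reference` on the original taps).

    Records longer than the 10-bit input-row field are processed in
    overlapping tiles whose concatenated outputs equal one valid
    convolution of the whole stream.
    """
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.size == 0:
        raise EngineError("FIR needs at least one coefficient")
    k = coeffs.size
    x = np.asarray(x, dtype=np.float64)
    if x.size < k:
        raise EngineError(f"input of {x.size} samples shorter than {k} taps")
    block = k if k <= 31 else 16
    n_ch = -(-k // block)
    if n_ch > 255:
        raise EngineError(f"{k} taps exceed the engine's FIR capacity")
    padded_taps = np.zeros(n_ch * block)
    padded_taps[:k] = coeffs
    weight_image = floats_to_image(padded_taps)  # [1, n_ch, block] layout

    # largest per-tile output run honouring the input-row (10-bit) and
    # output-address (12-bit) fields
    l_out_max = min(1023, 4095 // n_ch) - (block - 1)
    if l_out_max < 1:
        raise EngineError(f"{k} taps leave no room for output samples")
    n_out_total = x.size - k + 1
    pad = n_ch * block - k  # trailing zeros matched by the zero taps
    x_padded = np.concatenate([x, np.zeros(pad)]) if pad else x

    outputs = []
    trace: list[LayerTrace] = []
    for start in range(0, n_out_total, l_out_max):
        l_out = min(l_out_max, n_out_total - start)
        l_row = l_out + block - 1
        # channel c = input delayed by c*block samples
        chans = np.stack([x_padded[start + c * block:
                                   start + c * block + l_row]
                          for c in range(n_ch)])
        out_addr = n_ch * l_row
        inst = Instruction(
            layer_type=0, input_row=l_row, input_channel=n_ch,
            input_addr=0, kernel_row=block, output_channel=1,
            weight_addr=0, stride=1, activation=Activation.BYPASS,
            pool_type=PoolType.BYPASS, pool_size=1, output_addr=out_addr)
        data = np.zeros(out_addr + l_out, dtype=np.uint16)
        data[:n_ch * l_row] = floats_to_image(chans.ravel())
        out, tile_trace = execute_stream([inst], weight_image, data,
                                         cordic_cfg, fir_tag=True)
        outputs.append(out[0])
        trace.extend(tile_trace)
    return np.concatenate(outputs), trace
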