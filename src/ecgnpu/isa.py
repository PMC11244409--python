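"""Instruction set and model compiler.

One instruction describes one convolutional or fully connected layer,
including its fused activation and pooling stage.  The instruction SRAM is
16 bits wide and the control FSM fetches six words per instruction, so an
encoded instruction is a 96-bit image: the 78 payload bits packed MSB-first
in field order, zero-padded.

Field layout (width in bits)::

    layer_type      1   0: conv, 1: fc
    input_row      10   input feature length
    input_channel   8
    input_addr     12   data-SRAM word address
    kernel_row      5   kernel length (1 for fc)
    output_channel  8
    weight_addr    13   weight-SRAM word address
    stride          2   1..3 (0 reserved-invalid)
    activation      2   00 bypass, 01 relu, 10 sigmoid, 11 tanh
    pool_type       2   00 max, 01 avg, 10 bypass
    pool_size       3   1..7; avg restricted to {2, 4} (shift-implementable)
    output_addr    12   data-SRAM word address

Shape rules: convolution is padding-free ("valid"), out = (L-K)//s + 1;
pooling is non-overlapping with the trailing remainder dropped,
out = L//p; the flattened length before the FC layer is out_len*out_ch of
the last conv stage.  These are the only conventions consistent with both
built-in model descriptions (flatten 480 and 448).

The compiler turns an ordered layer list (:class:`ModelSpec`) into one
instruction per layer plus a memory map: weight offsets cumulative in layer
order, data buffers alternating between a ping and a pong half of the data
SRAM.  Capacity limits are enforced only when explicitly supplied; large
models may legitimately compile to instructions whose cumulative weight
offsets exceed the 13-bit address field, in which case encoding (not
compilation or execution) reports the overflow.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "Activation",
    "PoolType",
    "Instruction",
    "ConvLayer",
    "FCLayer",
    "ModelSpec",
    "MemoryMap",
    "Capacities",
    "FieldOverflowError",
    "MalformedInstructionError",
    "CapacityError",
    "ShapeError",
    "WORDS_PER_INSTRUCTION",
    "encode_instruction",
    "decode_instruction",
    "encode_stream",
    "decode_stream",
    "propagate_shapes",
    "compile_model",
    "five_class_model",
    "two_class_model",
    "load_model_spec",
    "save_model_spec",
]

WORDS_PER_INSTRUCTION = 6
_IMAGE_BITS = 16 * WORDS_PER_INSTRUCTION  # 96


class Activation(enum.IntEnum):
    BYPASS = 0
    RELU = 1
    SIGMOID = 2
    TANH = 3


class PoolType(enum.IntEnum):
    MAX = 0
    AVG = 1
    BYPASS = 2


class FieldOverflowError(ValueError):
    """An instruction field value does not fit its declared bit width."""


class MalformedInstructionError(ValueError):
    """A word image violates the instruction format."""


class CapacityError(ValueError):
    """A compiled region exceeds an SRAM capacity limit."""


class ShapeError(ValueError):
    """A layer chain produces an empty or inconsistent feature shape."""


# (name, width) in packing order
_FIELDS = (
    ("layer_type", 1),
    ("input_row", 10),
    ("input_channel", 8),
    ("input_addr", 12),
    ("kernel_row", 5),
    ("output_channel", 8),
    ("weight_addr", 13),
    ("stride", 2),
    ("activation", 2),
    ("pool_type", 2),
    ("pool_size", 3),
    ("output_addr", 12),
)
_PAYLOAD_BITS = sum(w for _, w in _FIELDS)  # 78


@dataclass(frozen=True)
class Instruction:
    """Decoded description of one conv/FC layer with fused act + pool."""

    layer_type: int          # 0 conv, 1 fc
    input_row: int
    input_channel: int
    input_addr: int
    kernel_row: int
    output_channel: int
    weight_addr: int
    stride: int
    activation: Activation
    pool_type: PoolType
    pool_size: int
    output_addr: int

    def validate(self, *, check_addr_width: bool = True) -> None:
        for name, width in _FIELDS:
            v = int(getattr(self, name))
            if v < 0:
                raise FieldOverflowError(f"{name} is negative ({v})")
            if not check_addr_width and name in ("weight_addr", "input_addr",
                                                 "output_addr"):
                continue
            if v >= 1 << width:
                raise FieldOverflowError(
                    f"{name}={v} does not fit {width} bits (max {(1 << width) - 1})"
                )
        if self.stride not in (1, 2, 3):
            raise FieldOverflowError(f"stride must be 1..3, got {self.stride}")
        if not 1 <= self.pool_size <= 7:
            raise FieldOverflowError(
                f"pool_size must be 1..7, got {self.pool_size}")
        if self.pool_type == PoolType.AVG and self.pool_size not in (2, 4):
            raise FieldOverflowError(
                "avg pooling requires pool_size in {2, 4} "
                f"(shift-implementable), got {self.pool_size}"
            )


def encode_instruction(inst: Instruction) -> list[int]:
    """Pack an instruction into six 16-bit words (MSB-first, zero padded)."""
    inst.validate()
    image = 0
    for name, width in _FIELDS:
        image = (image << width) | (int(getattr(inst, name)) & ((1 << width) - 1))
    image <<= _IMAGE_BITS - _PAYLOAD_BITS  # zero padding on the right
    return [(image >> (16 * (WORDS_PER_INSTRUCTION - 1 - i))) & 0xFFFF
            for i in range(WORDS_PER_INSTRUCTION)]


def decode_instruction(words) -> Instruction:
    """Inverse of :func:`encode_instruction`; rejects malformed images."""
    words = list(words)
    if len(words) != WORDS_PER_INSTRUCTION:
        raise MalformedInstructionError(
            f"expected {WORDS_PER_INSTRUCTION} words, got {len(words)}")
    image = 0
    for w in words:
        w = int(w)
        if not 0 <= w <= 0xFFFF:
            raise MalformedInstructionError(f"word 0x{w:X} is not 16-bit")
        image = (image << 16) | w
    pad = image & ((1 << (_IMAGE_BITS - _PAYLOAD_BITS)) - 1)
    if pad != 0:
        raise MalformedInstructionError("nonzero padding bits")
    payload = image >> (_IMAGE_BITS - _PAYLOAD_BITS)
    values: dict[str, int] = {}
    shift = _PAYLOAD_BITS
    for name, width in _FIELDS:
        shift -= width
        values[name] = (payload >> shift) & ((1 << width) - 1)
    if values["pool_type"] > 2:
        raise MalformedInstructionError(
            f"invalid pool_type code {values['pool_type']}")
    inst = Instruction(
        layer_type=values["layer_type"],
        input_row=values["input_row"],
        input_channel=values["input_channel"],
        input_addr=values["input_addr"],
        kernel_row=values["kernel_row"],
        output_channel=values["output_channel"],
        weight_addr=values["weight_addr"],
        stride=values["stride"],
        activation=Activation(values["activation"]),
        pool_type=PoolType(values["pool_type"]),
        pool_size=values["pool_size"],
        output_addr=values["output_addr"],
    )
    inst.validate()
    return inst


def encode_stream(instructions) -> list[int]:
    words: list[int] = []
    for inst in instructions:
        words.extend(encode_instruction(inst))
    return words


def decode_stream(words) -> list[Instruction]:
    words = list(words)
    if len(words) % WORDS_PER_INSTRUCTION:
        raise MalformedInstructionError(
            f"stream length {len(words)} is not a multiple of "
            f"{WORDS_PER_INSTRUCTION}")
    return [decode_instruction(words[i:i + WORDS_PER_INSTRUCTION])
            for i in range(0, len(words), WORDS_PER_INSTRUCTION)]


# ---------------------------------------------------------------------------
# Model description and shape propagation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConvLayer:
    in_channels: int
    out_channels: int
    kernel_len: int
    stride: int = 1
    activation: Activation = Activation.BYPASS
    pool_type: PoolType = PoolType.BYPASS
    pool_size: int = 1

    kind = "conv"

    @property
    def weight_count(self) -> int:
        return self.out_channels * self.in_channels * self.kernel_len


@dataclass(frozen=True)
class FCLayer:
    fc_in: int
    fc_out: int
    activation: Activation = Activation.BYPASS

    kind = "fc"

    @property
    def weight_count(self) -> int:
        return self.fc_out * self.fc_in


@dataclass(frozen=True)
class ModelSpec:
    """Ordered layer list plus the input length, e.g. a 300-sample beat."""

    input_len: int
    layers: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))


def propagate_shapes(spec: ModelSpec) -> list[tuple[int, int, int]]:
    """Shape chain: per layer, (layer_index, out_len, out_channels).

    For conv layers the reported length is *after* the fused pooling stage.
    Raises :class:`ShapeError` on empty intermediates or an FC whose fc_in
    does not equal the flattened length feeding it.
    """
    shapes: list[tuple[int, int, int]] = []
    length = spec.input_len
    channels = 1
    for i, layer in enumerate(spec.layers):
        if layer.kind == "conv":
            if layer.in_channels != channels:
                raise ShapeError(
                    f"layer {i}: in_channels={layer.in_channels} but the "
                    f"incoming feature map has {channels} channels")
            conv_len = (length - layer.kernel_len) // layer.stride + 1
            if length < layer.kernel_len or conv_len <= 0:
                raise ShapeError(
                    f"layer {i}: kernel {layer.kernel_len} does not fit "
                    f"input length {length}")
            if layer.pool_type == PoolType.BYPASS:
                out_len = conv_len
            else:
                out_len = conv_len // layer.pool_size
                if out_len <= 0:
                    raise ShapeError(
                        f"layer {i}: pooling {layer.pool_size} empties a "
                        f"length-{conv_len} feature map")
            length, channels = out_len, layer.out_channels
        elif layer.kind == "fc":
            flat = length * channels
            if layer.fc_in != flat:
                raise ShapeError(
                    f"layer {i}: fc_in={layer.fc_in} but the flattened "
                    f"input is {flat} ({channels} ch x {length})")
            length, channels = 1, layer.fc_out
        else:  # pragma: no cover - defensive
            raise ShapeError(f"layer {i}: unknown kind {layer.kind!r}")
        shapes.append((i, length, channels))
    return shapes


# ---------------------------------------------------------------------------
# Memory map and compiler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Capacities:
    """SRAM sizes in 16-bit words.

    Defaults mirror a 12.5 KB on-chip budget: 4 KB data (2048 words),
    8 KB weights (4096 words), 0.5 KB instructions (256 words).
    """

    data_words: int = 2048
    weight_words: int = 4096
    inst_words: int = 256


@dataclass
class MemoryMap:
    weight_regions: list = field(default_factory=list)   # (name, offset, length)
    data_regions: list = field(default_factory=list)     # (name, offset, length)
    inst_region: tuple = ("instructions", 0, 0)
    data_ping: int = 0
    data_pong: int = 2048

    def manifest(self) -> str:
        lines = ["# region  offset  length"]
        name, off, ln = self.inst_region
        lines.append(f"inst:{name} {off} {ln}")
        for name, off, ln in self.weight_regions:
            lines.append(f"weight:{name} {off} {ln}")
        for name, off, ln in self.data_regions:
            lines.append(f"data:{name} {off} {ln}")
        return "\n".join(lines) + "\n"


def compile_model(spec: ModelSpec, capacities: Capacities | None = None,
                  data_ping: int = 0, data_pong: int | None = None
                  ) -> tuple[list[Instruction], MemoryMap]:
    """Compile a ModelSpec into an instruction stream and a memory map.

    Weight offsets are cumulative in layer order.  Data buffers alternate
    ping/pong between layers; ``data_pong`` defaults to half the data SRAM.
    Capacity limits are checked only when ``capacities`` is given.
    """
    shapes = propagate_shapes(spec)
    if data_pong is None:
        data_pong = (capacities.data_words // 2) if capacities else 2048
    mmap = MemoryMap(data_ping=data_ping, data_pong=data_pong)
    instructions: list[Instruction] = []
    weight_off = 0
    length, channels = spec.input_len, 1
    in_addr, out_addr = data_ping, data_pong
    for i, layer in enumerate(spec.layers):
        if layer.kind == "conv":
            inst = Instruction(
                layer_type=0,
                input_row=length,
                input_channel=channels,
                input_addr=in_addr,
                kernel_row=layer.kernel_len,
                output_channel=layer.out_channels,
                weight_addr=weight_off,
                stride=layer.stride,
                activation=layer.activation,
                pool_type=layer.pool_type,
                pool_size=max(1, layer.pool_size),
                output_addr=out_addr,
            )
        else:
            inst = Instruction(
                layer_type=1,
                input_row=layer.fc_in,
                input_channel=1,
                input_addr=in_addr,
                kernel_row=1,
                output_channel=layer.fc_out,
                weight_addr=weight_off,
                stride=1,
                activation=layer.activation,
                pool_type=PoolType.BYPASS,
                pool_size=1,
                output_addr=out_addr,
            )
        inst.validate(check_addr_width=False)
        instructions.append(inst)
        mmap.weight_regions.append((f"layer{i}", weight_off, layer.weight_count))
        in_words = length * channels
        mmap.data_regions.append((f"layer{i}_in", in_addr, in_words))
        weight_off += layer.weight_count
        _, length, channels = shapes[i]
        in_addr, out_addr = out_addr, in_addr
    if spec.layers:
        mmap.data_regions.append(("output", in_addr, length * channels))
    n_inst_words = len(instructions) * WORDS_PER_INSTRUCTION
    mmap.inst_region = ("instructions", 0, n_inst_words)
    if capacities is not None:
        if weight_off > capacities.weight_words:
            first = next(
                (name, off, ln) for name, off, ln in mmap.weight_regions
                if off + ln > capacities.weight_words)
            raise CapacityError(
                f"weight region {first[0]} (offset {first[1]}, length "
                f"{first[2]}) exceeds weight SRAM of "
                f"{capacities.weight_words} words")
        for name, off, ln in mmap.data_regions:
            half = (capacities.data_words - data_pong if off >= data_pong
                    else data_pong - data_ping)
            if ln > half or off + ln > capacities.data_words:
                raise CapacityError(
                    f"data region {name} (offset {off}, length {ln}) exceeds "
                    f"its data-SRAM buffer")
        if n_inst_words > capacities.inst_words:
            raise CapacityError(
                f"instruction stream of {n_inst_words} words exceeds "
                f"instruction SRAM of {capacities.inst_words} words")
    return instructions, mmap


# ---------------------------------------------------------------------------
# Built-in model descriptions
# ---------------------------------------------------------------------------


def five_class_model(input_len: int = 300, n_classes: int = 5) -> ModelSpec:
    """Three ReLU conv stages with max pooling and a 448-way FC head.

    Chain at input 300: conv12→289, pool4→72, conv8→65, pool2→32,
    conv4→29, pool2→14; flatten 14x32 = 448.
    """
    return ModelSpec(input_len=input_len, layers=(
        ConvLayer(1, 16, 12, activation=Activation.RELU,
                  pool_type=PoolType.MAX, pool_size=4),
        ConvLayer(16, 32, 8, activation=Activation.RELU,
                  pool_type=PoolType.MAX, pool_size=2),
        ConvLayer(32, 32, 4, activation=Activation.RELU,
                  pool_type=PoolType.MAX, pool_size=2),
        FCLayer(448, n_classes),
    ))


def two_class_model(input_len: int = 300, n_classes: int = 2) -> ModelSpec:
    """Two Tanh conv stages with max pooling and a 480-way FC head.

    Chain at input 300: conv12→289, pool4→72, conv12→61, pool4→15;
    flatten 15x32 = 480.  The head width defaults to 2 (normal/abnormal).
    """
    return ModelSpec(input_len=input_len, layers=(
        ConvLayer(1, 16, 12, activation=Activation.TANH,
                  pool_type=PoolType.MAX, pool_size=4),
        ConvLayer(16, 32, 12, activation=Activation.TANH,
                  pool_type=PoolType.MAX, pool_size=4),
        FCLayer(480, n_classes),
    ))


# ---------------------------------------------------------------------------
# ModelSpec (de)serialisation: YAML/JSON config files
# ---------------------------------------------------------------------------


def _layer_to_dict(layer) -> dict:
    if layer.kind == "conv":
        return {"kind": "conv", "in_channels": layer.in_channels,
                "out_channels": layer.out_channels,
                "kernel_len": layer.kernel_len, "stride": layer.stride,
                "activation": layer.activation.name.lower(),
                "pool_type": layer.pool_type.name.lower(),
                "pool_size": layer.pool_size}
    return {"kind": "fc", "fc_in": layer.fc_in, "fc_out": layer.fc_out,
            "activation": layer.activation.name.lower()}


def _layer_from_dict(d: dict):
    kind = d.get("kind")
    act = Activation[d.get("activation", "bypass").upper()]
    if kind == "conv":
        return ConvLayer(
            in_channels=int(d["in_channels"]),
            out_channels=int(d["out_channels"]),
            kernel_len=int(d["kernel_len"]),
            stride=int(d.get("stride", 1)),
            activation=act,
            pool_type=PoolType[d.get("pool_type", "bypass").upper()],
            pool_size=int(d.get("pool_size", 1)),
        )
    if kind == "fc":
        return FCLayer(fc_in=int(d["fc_in"]), fc_out=int(d["fc_out"]),
                       activation=act)
    raise ValueError(f"unknown layer kind {kind!r}")


def save_model_spec(spec: ModelSpec, path) -> None:
    doc = {"input_len": spec.input_len,
           "layers": [_layer_to_dict(l) for l in spec.layers]}
    text = (json.dumps(doc, indent=2) if str(path).endswith(".json")
            else yaml.safe_dump(doc, sort_keys=False))
    with open(path, "w") as fh:
        fh.write(text)


def load_model_spec(path) -> ModelSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)  # YAML is a JSON superset
    return ModelSpec(input_len=int(doc["input_len"]),
                     layers=tuple(_layer_from_dict(d) for d in doc["layers"]))
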