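"""Instruction packing, shape propagation, and the model compiler."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgnpu.isa import (Activation, Capacities, CapacityError, ConvLayer,
                        FCLayer, FieldOverflowError, Instruction,
                        MalformedInstructionError, ModelSpec, PoolType,
                        ShapeError, WORDS_PER_INSTRUCTION, compile_model,
                        decode_instruction, decode_stream, encode_instruction,
                        encode_stream, five_class_model, load_model_spec,
                        propagate_shapes, save_model_spec, two_class_model)


def _pool_strategy():
    return st.one_of(
        st.tuples(st.just(PoolType.BYPASS), st.integers(1, 7)),
        st.tuples(st.just(PoolType.MAX), st.integers(1, 7)),
        st.tuples(st.just(PoolType.AVG), st.sampled_from([2, 4])),
    )


valid_instructions = st.builds(
    lambda lt, row, ch, ia, kr, oc, wa, s, act, pool, oa: Instruction(
        layer_type=lt, input_row=row, input_channel=ch, input_addr=ia,
        kernel_row=kr, output_channel=oc, weight_addr=wa, stride=s,
        activation=act, pool_type=pool[0], pool_size=pool[1], output_addr=oa),
    st.integers(0, 1), st.integers(0, 1023), st.integers(0, 255),
    st.integers(0, 4095), st.integers(0, 31), st.integers(0, 255),
    st.integers(0, 8191), st.integers(1, 3),
    st.sampled_from(list(Activation)), _pool_strategy(),
    st.integers(0, 4095))


@given(valid_instructions)
@settings(max_examples=500, derandomize=True)
def test_encode_decode_roundtrip(inst):
    words = encode_instruction(inst)
    assert len(words) == WORDS_PER_INSTRUCTION
    assert all(0 <= w <= 0xFFFF for w in words)
    assert decode_instruction(words) == inst


def test_field_overflow_names_offending_field():
    inst = Instruction(0, 1024, 1, 0, 3, 1, 0, 1, Activation.BYPASS,
                       PoolType.BYPASS, 1, 0)
    with pytest.raises(FieldOverflowError, match="input_row"):
        encode_instruction(inst)


def test_stride_and_pool_constraints():
    base = dict(layer_type=0, input_row=10, input_channel=1, input_addr=0,
                kernel_row=3, output_channel=1, weight_addr=0,
                activation=Activation.BYPASS, output_addr=0)
    with pytest.raises(FieldOverflowError, match="stride"):
        encode_instruction(Instruction(stride=0, pool_type=PoolType.BYPASS,
                                       pool_size=1, **base))
    with pytest.raises(FieldOverflowError, match="avg"):
        encode_instruction(Instruction(stride=1, pool_type=PoolType.AVG,
                                       pool_size=3, **base))


def test_decode_rejects_nonzero_padding():
    inst = Instruction(0, 300, 1, 0, 12, 16, 0, 1, Activation.RELU,
                       PoolType.MAX, 4, 2048)
    words = encode_instruction(inst)
    words[-1] |= 1  # poke a padding bit
    with pytest.raises(MalformedInstructionError, match="padding"):
        decode_instruction(words)


def test_decode_rejects_invalid_pool_code():
    inst = Instruction(0, 300, 1, 0, 12, 16, 0, 1, Activation.RELU,
                       PoolType.MAX, 4, 2048)
    words = encode_instruction(inst)
    image = 0
    for w in words:
        image = (image << 16) | w
    # pool_type field sits above pool_size(3) + output_addr(12) + padding(18)
    image |= 0b11 << (18 + 12 + 3)
    bad = [(image >> (16 * (5 - i))) & 0xFFFF for i in range(6)]
    with pytest.raises(MalformedInstructionError, match="pool_type"):
        decode_instruction(bad)


def test_activation_code_10_is_sigmoid():
    inst = Instruction(0, 8, 1, 0, 1, 1, 0, 1, Activation.SIGMOID,
                       PoolType.BYPASS, 1, 0)
    decoded = decode_instruction(encode_instruction(inst))
    assert decoded.activation == Activation.SIGMOID == 2


def test_five_class_shape_chain():
    shapes = propagate_shapes(five_class_model())
    assert shapes == [(0, 72, 16), (1, 32, 32), (2, 14, 32), (3, 1, 5)]
    assert shapes[2][1] * shapes[2][2] == 448  # flatten feeding the FC


def test_two_class_shape_chain():
    shapes = propagate_shapes(two_class_model())
    assert shapes == [(0, 72, 16), (1, 15, 32), (2, 1, 2)]
    assert shapes[1][1] * shapes[1][2] == 480


def test_kernel_equal_to_input_gives_length_one():
    spec = ModelSpec(input_len=17, layers=(ConvLayer(1, 3, 17),))
    assert propagate_shapes(spec) == [(0, 1, 3)]


def test_shape_error_on_empty_intermediate():
    spec = ModelSpec(input_len=5, layers=(ConvLayer(1, 1, 8),))
    with pytest.raises(ShapeError):
        propagate_shapes(spec)


def test_shape_error_on_fc_mismatch():
    spec = ModelSpec(input_len=300, layers=(
        ConvLayer(1, 16, 12, pool_type=PoolType.MAX, pool_size=4),
        FCLayer(100, 5)))
    with pytest.raises(ShapeError, match="fc_in"):
        propagate_shapes(spec)


def test_compile_emits_one_instruction_per_layer():
    i5, _ = compile_model(five_class_model())
    i2, _ = compile_model(two_class_model())
    i0, m0 = compile_model(ModelSpec(input_len=10))
    assert len(i5) == 4 and len(i2) == 3
    assert i0 == [] and m0.weight_regions == []


def test_compile_weight_offsets_cumulative():
    insts, mmap = compile_model(five_class_model())
    lengths = [1 * 16 * 12, 16 * 32 * 8, 32 * 32 * 4, 448 * 5]
    offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    assert [i.weight_addr for i in insts] == list(offsets)
    assert [ln for _, _, ln in mmap.weight_regions] == lengths


def test_compile_ping_pong_alternation():
    insts, _ = compile_model(five_class_model(), data_pong=2048)
    addrs = [(i.input_addr, i.output_addr) for i in insts]
    assert addrs == [(0, 2048), (2048, 0), (0, 2048), (2048, 0)]


def test_compile_deterministic_bit_identical_image():
    a = encode_stream(compile_model(two_class_model())[0])
    b = encode_stream(compile_model(two_class_model())[0])
    assert a == b
    assert decode_stream(a) == compile_model(two_class_model())[0]


def test_compile_capacity_error_reports_region():
    with pytest.raises(CapacityError, match="layer"):
        compile_model(five_class_model(),
                      Capacities(weight_words=1024, data_words=4096,
                                 inst_words=256))


def test_model_spec_yaml_roundtrip(tmp_path):
    for spec in (five_class_model(), two_class_model()):
        path = tmp_path / "model.yaml"
        save_model_spec(spec, path)
        assert load_model_spec(path) == spec
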