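"""PE-array engine: conv bit-exactness, activation, pooling, streams, FIR."""

import math

import numpy as np
import pytest

from conftest import quantize, random_layer
from ecgnpu.cordic import CordicConfig, tanh_cordic
from ecgnpu.engine import (EngineError, apply_activation, apply_pooling,
                           design_bandpass, execute_stream, fir_filter,
                           run_conv_pe_array, run_conv_reference, run_fc)
from ecgnpu.fp16 import Flags, floats_to_image, image_to_floats
from ecgnpu.isa import (Activation, ConvLayer, FCLayer, ModelSpec, PoolType,
                        compile_model, five_class_model)
from ecgnpu.synth import gen_fixture_weights


def test_identity_kernel_passes_input_through(rng):
    x = quantize(rng.normal(size=(1, 40)))
    out = run_conv_reference(x, np.array([[[1.0]]]), 1)
    assert np.array_equal(out, x)


def test_valid_conv_output_length():
    x = np.zeros((1, 300))
    w = np.zeros((16, 1, 12))
    assert run_conv_reference(x, w, 1).shape == (16, 289)


def test_zero_weights_zero_output_no_flags(rng):
    x = quantize(rng.normal(size=(4, 30)))
    flags = Flags()
    out = run_conv_reference(x, np.zeros((3, 4, 5)), 1, flags)
    assert not out.any() and not flags.any()


def test_pe_array_bit_identical_to_reference(rng):
    for _ in range(30):
        x, w, stride = random_layer(rng)
        ref = run_conv_reference(x, w, stride)
        pe, waves = run_conv_pe_array(x, w, stride)
        assert np.array_equal(ref, pe)
        assert waves == math.ceil(ref.shape[1] / 4)


def test_wave_counts():
    x = np.zeros((1, 300))
    w = np.zeros((1, 1, 12))
    _, waves = run_conv_pe_array(x, w, 1)
    assert waves == 73  # ceil(289 / 4)
    _, waves = run_conv_pe_array(np.zeros((1, 4)), np.zeros((1, 1, 1)), 1)
    assert waves == 1


def test_shape_mismatch_raises():
    with pytest.raises(EngineError):
        run_conv_reference(np.zeros((2, 10)), np.zeros((1, 3, 3)), 1)
    with pytest.raises(EngineError):
        run_conv_reference(np.zeros((1, 4)), np.zeros((1, 1, 8)), 1)


def test_fc_matches_manual_mac_chain(rng):
    x = quantize(rng.normal(size=12))
    w = quantize(rng.normal(scale=0.3, size=(3, 12)))
    out = run_fc(x, w)
    # manual canonical chain in float64-with-rounding
    from ecgnpu.fp16 import round_f16
    for o in range(3):
        acc = 0.0
        for j in range(12):
            acc = round_f16(acc + round_f16(w[o, j] * x[j]))
        assert out[o] == acc


def test_activation_bypass_and_relu(rng):
    x = quantize(rng.normal(size=(2, 9)))
    assert np.array_equal(apply_activation(x, Activation.BYPASS), x)
    relu = apply_activation(x, Activation.RELU)
    assert np.array_equal(relu, np.maximum(x, 0.0))
    assert apply_activation(np.array([[-1.0]]), Activation.RELU)[0, 0] == 0.0


def test_activation_tanh_matches_cordic_module():
    cfg = CordicConfig()
    out = apply_activation(np.array([[0.5]]), Activation.TANH, cfg)
    assert out[0, 0] == tanh_cordic(0.5, cfg).value


@pytest.mark.parametrize("values, pool, size, expect", [
    ([1, 3, 2, 4], PoolType.MAX, 4, [4.0]),
    ([1, 2, 3, 4], PoolType.AVG, 4, [2.5]),
    ([5, 1, 2, 6, 0, 3], PoolType.MAX, 2, [5.0, 6.0, 3.0]),
])
def test_pooling_values(values, pool, size, expect):
    out = apply_pooling(np.asarray([values], dtype=float), pool, size)
    assert out.tolist() == [expect]


def test_pooling_drops_trailing_remainder():
    out = apply_pooling(np.zeros((3, 65)), PoolType.MAX, 2)
    assert out.shape == (3, 32)


def test_avg_pooling_rejects_non_power_of_two():
    with pytest.raises(EngineError, match="power-of-two"):
        apply_pooling(np.zeros((1, 9)), PoolType.AVG, 3)


def test_execute_stream_matches_manual_composition(rng):
    spec = ModelSpec(input_len=40, layers=(
        ConvLayer(1, 4, 5, activation=Activation.RELU,
                  pool_type=PoolType.MAX, pool_size=2),
        ConvLayer(4, 3, 3, activation=Activation.TANH,
                  pool_type=PoolType.AVG, pool_size=2),
    ))
    weights = gen_fixture_weights(spec, seed=11)
    insts, _ = compile_model(spec)
    x = quantize(rng.normal(size=40))
    data = np.zeros(4096, dtype=np.uint16)
    data[:40] = floats_to_image(x)
    cfg = CordicConfig()
    out, trace = execute_stream(insts, weights, data, cfg)

    wf = image_to_floats(weights)
    w1 = wf[:4 * 1 * 5].reshape(4, 1, 5)
    w2 = wf[4 * 5:4 * 5 + 3 * 4 * 3].reshape(3, 4, 3)
    step1 = apply_pooling(apply_activation(
        run_conv_reference(x[None, :], w1, 1), Activation.RELU, cfg),
        PoolType.MAX, 2)
    step2 = apply_pooling(apply_activation(
        run_conv_reference(step1, w2, 1), Activation.TANH, cfg),
        PoolType.AVG, 2)
    assert np.array_equal(out, step2)
    assert [t.stream for t in trace] == ["conv", "conv"]
    assert trace[0].out_shape == (4, 18) and trace[1].out_shape == (3, 8)


def test_execute_stream_relocation_invariance(rng):
    spec = ModelSpec(input_len=30, layers=(
        ConvLayer(1, 2, 3, pool_type=PoolType.MAX, pool_size=2),
        FCLayer(28, 4)))
    weights = gen_fixture_weights(spec, seed=5)
    x = floats_to_image(rng.normal(size=30))
    outs = []
    for ping, pong in ((0, 2048), (123, 1500), (700, 3000)):
        insts, _ = compile_model(spec, data_ping=ping, data_pong=pong)
        data = np.zeros(4096, dtype=np.uint16)
        data[ping:ping + 30] = x
        out, _ = execute_stream(insts, weights, data)
        outs.append(out)
    assert np.array_equal(outs[0], outs[1])
    assert np.array_equal(outs[0], outs[2])


def test_execute_stream_empty_is_passthrough():
    data = floats_to_image(np.arange(8.0))
    out, trace = execute_stream([], np.zeros(0, dtype=np.uint16), data)
    assert np.array_equal(out.ravel(), np.arange(8.0))
    assert trace == []


def test_execute_stream_address_fault():
    spec = ModelSpec(input_len=30, layers=(ConvLayer(1, 2, 3),))
    insts, _ = compile_model(spec)
    with pytest.raises(EngineError, match="data SRAM"):
        execute_stream(insts, gen_fixture_weights(spec, seed=0),
                       np.zeros(16, dtype=np.uint16))


def test_overflow_flag_propagates_to_trace():
    # 200*200 products accumulate past 65504 and must flag the layer
    spec = ModelSpec(input_len=8, layers=(ConvLayer(1, 1, 4),))
    insts, _ = compile_model(spec)
    weights = floats_to_image(np.full(4, 200.0))
    data = np.zeros(4096, dtype=np.uint16)
    data[:8] = floats_to_image(np.full(8, 200.0))
    out, trace = execute_stream(insts, weights, data)
    assert trace[0].flags.overflow
    assert np.all(out == 65504.0)


def test_five_class_stream_emits_five_scores(rng):
    spec = five_class_model()
    insts, _ = compile_model(spec)
    weights = gen_fixture_weights(spec, seed=2)
    data = np.zeros(4096, dtype=np.uint16)
    data[:300] = floats_to_image(rng.normal(scale=0.5, size=300))
    out, trace = execute_stream(insts, weights, data)
    assert out.shape == (5, 1)
    assert [t.stream for t in trace] == ["conv", "conv", "conv", "fc"]
    assert not any(t.flags.overflow for t in trace)


@pytest.mark.parametrize("coeffs, x, expect", [
    ([1.0], [3.0, -1.0, 2.0], [3.0, -1.0, 2.0]),
    ([0.5, 0.5], [1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
])
def test_fir_small_cases(coeffs, x, expect):
    out, trace = fir_filter(np.asarray(x), np.asarray(coeffs))
    assert out.tolist() == expect
    assert all(t.stream == "fir" for t in trace)


def test_fir_bit_exact_to_reference_including_tiling(rng):
    x = quantize(rng.normal(size=2500))
    taps = design_bandpass(360.0)  # 64 taps: exercises the multi-channel split
    out, trace = fir_filter(x, taps)
    ref = run_conv_reference(x[None, :], quantize(taps)[None, None, :], 1)[0]
    assert np.array_equal(out, ref)
    assert len(trace) > 1  # tiled
    assert out.size == x.size - taps.size + 1


def test_design_bandpass_validates_edges():
    with pytest.raises(EngineError):
        design_bandpass(360.0, low=50.0, high=40.0)
    with pytest.raises(EngineError):
        design_bandpass(60.0, low=0.5, high=40.0)
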