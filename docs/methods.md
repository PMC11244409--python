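# Methods

`ecgnpu` is a bit-accurate functional reference model of an
instruction-driven half-precision 1-D CNN processor for on-device ECG beat
classification.  "Functional reference" means: given the same inputs
(samples, weights, instructions), the model produces, value for value, the
numbers the datapath would produce — without modelling clock cycles, SRAM
port timing, or power.  This note records the model, its parameters, the
numerical conventions, and the design choices made where the hardware
description left the behaviour open.

## The binary16 datapath (`fp16`)

Every number inside the CNN engine is an IEEE-754 binary16 value (1 sign,
5 exponent, 10 mantissa bits).  Each scalar operation is defined as the
exact float64 computation rounded to binary16 — exact because any product
or sum of two binary16 values is representable in float64 — with
round-to-nearest-even at every operation boundary.  Conventions the format
alone does not fix:

* **Overflow saturates** to ±65504 and sets a sticky overflow flag; the
  datapath never emits infinities from finite operands.  Saturation makes
  downstream comparisons (max pooling) total and keeps error handling
  deterministic, matching an error-flagging fixed-width MAC.
* **Underflow is gradual** (subnormals kept); the flag is set when a
  nonzero exact result rounds to a subnormal or to zero.
* **The MAC is two-step**: the product is rounded to binary16 *before*
  the add, which is itself rounded.  The hardware has a separate
  multiplier and adder, not a fused unit, and the two-step result differs
  from fused rounding in the last place often enough to matter for
  bit-exactness.

## Canonical accumulation order (`engine`)

binary16 addition is not associative, so a convolution's value depends on
the order its partial products are summed.  The model fixes one order as
law: **input channel ascending, then tap ascending**, accumulator per
(output channel, output position).  The sequential loop-nest
`run_conv_reference` embodies this order and serves as the oracle.

The PE-array path (`run_conv_pe_array`) models the 4×4 fabric: waves of
four consecutive output positions across the four MAC groups
(inter-kernel parallelism), and four lanes per group supplying products
for four consecutive entries of the (channel, tap) sequence (intra-kernel
parallelism).  The lanes multiply concurrently but the group accumulator
drains them in lane order, so the per-output addition sequence is exactly
the canonical one and the result is bit-identical to the reference.  This
equivalence is enforced by a 200-random-layer test covering strides 1–3,
channels 1–32 and kernels 1–12.

Fully connected layers walk the flattened (channel-major) input in
storage order with the same MAC semantics.  Average pooling sums each
non-overlapping window in index order and divides by the power-of-two
window length (an exact exponent decrement); max pooling is a comparator
pass, safe because saturation keeps the data NaN-free.

## CORDIC activations (`cordic`)

Tanh and sigmoid are evaluated with two cascaded CORDIC stages: hyperbolic
rotation (sinh, cosh; step angles atanh 2^-k, with the convergence repeats
at k = 4 and 13) followed by linear vectoring (the division sinh/cosh,
whose own |y/x| ≤ 1 constraint tanh always satisfies).  Sigmoid shares the
tanh datapath through sigmoid(x) = (tanh(x/2)+1)/2, equivalent to
tanh(x) = 2·sigmoid(2x) − 1.

The standard positive schedule reaches |θ| ≤ Σ atanh(2^-k) ≈ 1.1182.  The
index set is extended by m_neg iterations k = −(m_neg−1)..0 with step
angles atanh(1 − 2^(k−2)).  Defaults, with reasons:

| parameter | default | why |
|---|---|---|
| `n_pos` | 16 | 2^(1−n) ≈ 3·10⁻⁵ angular resolution, far below the binary16 ulp of the outputs |
| `m_neg` | 3 | smallest count whose bound (≈5.16) covers θ ≤ 4.2, i.e. sigmoid over x ≤ 8.4 via the x/2 identity (m_neg = 2 reaches only ≈3.38) |
| internal precision | float64 | the word width of the iterations is a free choice; keeping them in float64 and rounding to binary16 only at the module boundary separates algorithmic error from quantisation error in tests |

Inputs beyond the configured bound saturate to the asymptote — already
exact in binary16 for |x| ≳ 6, and within 7·10⁻⁵ of the true tanh at the
default bound.  θ = 0 (and y = 0 in the division) are returned exactly:
the d = sign(z) iteration choice is asymmetric at zero and would otherwise
leave a ±2^(−n) residual on a value that plain symmetry fixes.  Measured
on the grid x ∈ [−8, 8], step 1/64, the worst pre-rounding error of both
functions at n_pos = 16 is below 2^−10.

## Instruction set and compiler (`isa`)

An instruction is 78 payload bits — layer type (1), input row (10), input
channel (8), input address (12), kernel row (5), output channel (8),
weight address (13), stride (2), activation (2), pool type (2), pool size
(3), output address (12) — packed MSB-first in that order and zero-padded
to six 16-bit words, matching the six-cycle fetch of the control FSM
(the payload would fit five words; six is the architected count).  The
pool-type field is 2 bits here: a 1-bit field cannot hold the three
documented encodings (max / avg / bypass).  Stride stores its literal
value, code 0 reserved-invalid; average pooling only accepts sizes 2 and
4 (shift-implementable).

Convolution is padding-free ("valid", out = (L−K)//s + 1) and pooling is
non-overlapping with the trailing remainder dropped (out = L//p) — the
only pair of conventions under which both built-in models reach their
printed flatten widths (two-class: 300→289→72→61→15, 15×32 = 480;
five-class: 300→289→72→65→32→29→14, 14×32 = 448).

The compiler emits one instruction per layer, assigns weight offsets
cumulatively in layer order, and alternates feature-map buffers between a
ping and a pong region of the data SRAM.  FC layers reuse the input-row
field as the flattened length with kernel row 1 (the flattened length
exceeds the 5-bit kernel field).

**Known inconsistency.**  The five-class model's cumulative weight
footprint (192 + 4096 + 4096 + 2240 = 10 624 words) overflows both the
13-bit weight-address field and a 12.5 KB SRAM budget.  The model
description is internally inconsistent on this point, so capacity checks
are opt-in: compilation and execution (which run on decoded instruction
objects and arbitrarily long images) always succeed, while *encoding* an
instruction whose address cannot fit its field raises a field-overflow
error.  The two-class model encodes fully; the five-class FC instruction
does not.

## FIR mode (`engine.fir_filter`)

The band-pass denoiser reuses the CNN fabric: a conv instruction with
bypass activation and bypass pooling.  Default taps are a 64-tap
Hamming-windowed sinc band-pass, 0.5–40 Hz at the record's sampling rate,
quantised to binary16; any coefficient file may be substituted.  Two field
widths constrain the mapping, and both are handled bit-exactly:

* 64 taps exceed the 5-bit kernel field, so tap vectors longer than 31
  are split into contiguous 16-tap blocks laid across input channels,
  channel c holding the input delayed by 16·c samples.  Channel-ascending
  / tap-ascending accumulation then walks the taps in exactly canonical
  order, so the multi-channel instruction is bit-identical to a single
  valid convolution.
* Records longer than the 10-bit input-row field run in overlapping tiles
  whose concatenated outputs equal one valid convolution of the whole
  stream.

## R-peak detection (`rpeak`)

The chain is the classical cascade: low-pass
y(n) = 2y(n−1) − y(n−2) + x(n) − 2x(n−6) + x(n−12); high-pass
y(n) = x(n−16) − x(n−17) + y(n−1) − [x(n) − x(n−32)]/32; five-point
derivative [2x(n) + x(n−1) − x(n−3) − 2x(n−4)]/8; squaring; 32-tap moving
average.  The filters run with these coefficients at whatever sampling
rate the record declares.  The stated single-stage delays (12 and 32
samples) disagree with the group delays the equations imply (5 and 16);
the equations are taken as authoritative and the implied delays (total 38
samples to the averaged signal) are what the detector compensates and
reports in its trace.  Integer mode implements every division as an
arithmetic right shift (flooring), real mode divides exactly.

The FSM: thresholds initialise from the first 2 s of the averaged signal
(SPK = max, NPK = mean); every local maximum updates SPK (if accepted as
signal) or NPK (if below threshold) through 0.125/0.875 exponential
averages, with threshold = NPK + 0.25·(SPK − NPK).  A suprathreshold
maximum outside the 200 ms refractory window becomes a candidate; the
reported index is the raw-stream argmax within ±25 samples of the
delay-compensated candidate, earliest index on ties; reported peaks are
re-checked so consecutive R indices are ≥ round(0.2·fs) apart.  Searchback
and T-wave slope discrimination are deliberately absent — refractory plus
refinement only.  Because initialisation and updates are homogeneous in
the input scale, detection is invariant to power-of-two amplitude scaling
(exact in floating point).

Each accepted peak yields the 300 samples r−100 … r+199 (the R sample
itself plus 100 before and 199 after); beats without full context are
counted as edge drops, not errors.

## Synthetic records (`synth`)

Records are a quasi-periodic train of beats, each the sum of five Gaussian
bumps (P, Q, R, S, T) with per-class amplitude/offset/width parameters;
five caricature classes (N, S, V, F, Q — e.g. a widened, P-free QRS for
the VEB-like class) exist to exercise a five-way head, not to claim
clinical realism.  Defaults: 100 beats, fs = 360 Hz, 60 bpm with 30 ms RR
jitter, first R peak 1 s into the record so the detector's initialisation
window sees QRS energy (records start mid-rhythm, as real recordings do).
Noise: sinusoidal baseline wander, sinusoidal powerline interference, and
white Gaussian noise whose sigma can be solved from a target SNR (the
measured SNR is recorded alongside).  Layers are bias-free; fixture
weights are uniform on [−0.5, 0.5], which keeps the built-in models'
forward passes clear of binary16 saturation.

What the generator does *not* emulate: real QRS morphology variation,
ectopic timing, muscle artefact, electrode motion, or MIT-BIH class
statistics.  Detector and pipeline results on these records demonstrate
correctness of the mechanism (filters, FSM, windows, datapath), not
clinical performance; classification accuracy on real databases requires
trained weights and is out of scope.

## Pipeline (`pipeline`)

Stages run in the processor's order: FIR denoise (on the CNN fabric) →
detection → segmentation → per-beat CNN inference.  Detection coordinates
live in the denoised stream; the valid convolution delays it by
(taps−1)//2 samples, and both the stream index and the mapped raw index
are reported per beat.  Class = argmax of the FC scores, lowest index on
ties.  Given a config and an input stream the output is byte-identical
across runs.  `evaluate_detection` matches detections to truth greedily,
one-to-one, within a ±tolerance window (default 5 samples) and reports
sensitivity, positive predictivity and mean offset.

## Problem sizes used in the checked examples

The test suite and the acceptance script use desk-scale inputs chosen to
exercise every code path while keeping runs short: 200 random layers (up
to 32 channels, kernel 12, stride 3) for the bit-exactness contract;
a 1025-point grid over [−8, 8] for CORDIC accuracy; ten 100-beat records
at 20 dB SNR for detector quality; 10–40-beat records for the pipeline;
and the full 65 536-pattern space for the binary16 round-trip.
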