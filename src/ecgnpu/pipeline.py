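"""End-to-end orchestration: denoise → detect → segment → classify.

The stages run in the processor's order: the FIR band-pass executes on the
CNN fabric in bypass mode, the Pan-Tompkins engine locates R peaks in the
denoised stream, each peak yields a 300-sample beat (100 before, the peak,
199 after), and the compiled instruction stream classifies every beat,
emitting a score vector and an argmax class (lowest index on ties).

Detected indices live in the denoised stream's coordinates; the valid FIR
convolution shortens the record by ``taps - 1`` samples and delays it by
``(taps - 1) // 2``, so ``r_raw = r + (taps - 1) // 2`` maps a peak back
onto the raw record.  Both coordinates are reported.

Everything is deterministic: a config plus an input stream fixes every
byte of the output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cordic import CordicConfig
from .engine import design_bandpass, execute_stream, fir_filter
from .fp16 import Flags, floats_to_image, image_to_floats, vround_f16
from .isa import ModelSpec, compile_model, five_class_model, propagate_shapes
from .rpeak import DetectionResult, detect

__all__ = [
    "PipelineConfig",
    "BeatRecord",
    "PipelineResult",
    "run_pipeline",
    "evaluate_detection",
]


@dataclass
class PipelineConfig:
    fs: float = 360.0
    fir_enabled: bool = True
    fir_low: float = 0.5
    fir_high: float = 40.0
    fir_taps: int = 64
    detector_mode: str = "real"
    model: ModelSpec = field(default_factory=five_class_model)
    weight_image: np.ndarray | None = None
    cordic: CordicConfig = field(default_factory=CordicConfig)
    data_words: int = 4096
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fir_enabled and not (0 < self.fir_low < self.fir_high
                                     < self.fs / 2):
            raise ValueError(
                f"band edges must satisfy 0 < low < high < fs/2, got "
                f"({self.fir_low}, {self.fir_high}) at fs={self.fs}")


@dataclass
class BeatRecord:
    r_index: int        # in the detection (denoised) stream
    r_index_raw: int    # mapped back to the raw record
    class_index: int
    scores: np.ndarray

    def as_dict(self) -> dict:
        return {"r_index": self.r_index, "r_index_raw": self.r_index_raw,
                "class_index": self.class_index,
                "scores": [float(s) for s in self.scores]}


@dataclass
class PipelineResult:
    beats: list
    detection: DetectionResult
    trace: dict

    def __len__(self) -> int:
        return len(self.beats)

    def report(self) -> str:
        return json.dumps(self.trace, indent=2)


def run_pipeline(cfg: PipelineConfig, samples: np.ndarray) -> PipelineResult:
    """Run the full chain on a raw sample stream."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("input stream is empty")
    trace: dict = {"stages": []}

    # stage 1: FIR band-pass on the CNN fabric (bypass = pass-through)
    quantised = image_to_floats(floats_to_image(samples))
    if cfg.fir_enabled:
        taps = design_bandpass(cfg.fs, cfg.fir_low, cfg.fir_high, cfg.fir_taps)
        denoised, fir_trace = fir_filter(quantised, taps, cfg.cordic)
        raw_offset = (cfg.fir_taps - 1) // 2
        fir_flags = Flags()
        for entry in fir_trace:
            fir_flags.merge(entry.flags)
        trace["stages"].append({
            "stage": "fir", "taps": int(cfg.fir_taps),
            "band_hz": [cfg.fir_low, cfg.fir_high],
            "in_samples": int(samples.size),
            "out_samples": int(denoised.size),
            "tiles": len(fir_trace),
            "overflow": fir_flags.overflow, "underflow": fir_flags.underflow})
    else:
        denoised, raw_offset = quantised, 0
        trace["stages"].append({"stage": "fir", "bypassed": True,
                                "in_samples": int(samples.size),
                                "out_samples": int(denoised.size)})

    # stage 2+3: R-peak detection and beat segmentation
    detection = detect(denoised, cfg.fs, mode=cfg.detector_mode)
    trace["stages"].append({
        "stage": "detect", "mode": cfg.detector_mode,
        "peaks": int(len(detection.r_indices)),
        "segments": int(detection.segments.shape[0]),
        "dropped_edge_peaks": int(detection.dropped_edge_peaks),
        "refractory_samples": detection.trace["refractory_samples"]})

    # stage 4: instruction-driven CNN inference per beat
    if cfg.model.input_len != detection.segments.shape[1]:
        raise ValueError(
            f"model expects {cfg.model.input_len}-sample beats, segmentation "
            f"produced {detection.segments.shape[1]}")
    weight_image = cfg.weight_image
    if weight_image is None:
        from .synth import gen_fixture_weights
        weight_image = gen_fixture_weights(cfg.model, seed=cfg.seed)
    instructions, mmap = compile_model(cfg.model, data_pong=cfg.data_words // 2)
    n_classes = propagate_shapes(cfg.model)[-1][2] if cfg.model.layers else 0

    beats: list[BeatRecord] = []
    cnn_flags = Flags()
    for seg, r in zip(detection.segments, detection.segment_peaks):
        data = np.zeros(cfg.data_words, dtype=np.uint16)
        seg_words = floats_to_image(seg)
        data[instructions[0].input_addr:
             instructions[0].input_addr + seg_words.size] = seg_words
        out, layer_trace = execute_stream(instructions, weight_image, data,
                                          cfg.cordic)
        for entry in layer_trace:
            cnn_flags.merge(entry.flags)
        scores = out.ravel()
        beats.append(BeatRecord(
            r_index=int(r), r_index_raw=int(r) + raw_offset,
            class_index=int(np.argmax(scores)),  # lowest index on ties
            scores=scores))
    trace["stages"].append({
        "stage": "cnn", "beats": len(beats), "classes": int(n_classes),
        "instructions": len(instructions),
        "overflow": cnn_flags.overflow, "underflow": cnn_flags.underflow,
        "invalid": cnn_flags.invalid})
    trace["raw_offset"] = raw_offset
    return PipelineResult(beats=beats, detection=detection, trace=trace)


def evaluate_detection(detected, truth, tolerance: int = 5) -> dict:
    """Greedy one-to-one matching of detections to ground truth.

    ``detected`` may be a DetectionResult or an index array.  Detections
    and truths are walked in time order; each truth matches the first
    unmatched detection within ±tolerance samples.  Returns sensitivity
    TP/(TP+FN), positive predictivity TP/(TP+FP), and the mean signed
    offset (detected − truth) over matches.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if isinstance(detected, DetectionResult):
        detected = detected.r_indices
    det = np.sort(np.asarray(detected, dtype=int))
    tru = np.sort(np.asarray(truth, dtype=int))
    i = j = tp = 0
    offsets = []
    while i < det.size and j < tru.size:
        d = int(det[i]) - int(tru[j])
        if abs(d) <= tolerance:
            tp += 1
            offsets.append(d)
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    fp = det.size - tp
    fn = tru.size - tp
    return {
        "tp": tp, "fp": int(fp), "fn": int(fn),
        "sensitivity": tp / (tp + fn) if (tp + fn) else 1.0,
        "ppv": tp / (tp + fp) if (tp + fp) else 1.0,
        "mean_offset": float(np.mean(offsets)) if offsets else 0.0,
    }
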