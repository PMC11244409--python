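"""Seeded synthetic ECG records and fixture images.

Records emulate single-lead ECG as a quasi-periodic train of P-QRS-T beats:
each beat is the sum of five Gaussian bumps whose amplitude, offset from
the R peak, and width are per-class morphology parameters.  Three noise
components can be added — sinusoidal baseline wander, sinusoidal powerline
interference, and white Gaussian noise (either a fixed sigma or a sigma
solved from a target SNR).  Ground-truth R indices and per-beat class
labels are emitted alongside the samples, so detection, segmentation and
classification are all testable without external data.

Class morphologies are deliberate caricatures (a widened QRS for the
VEB-like class, a diminished P wave for the SVEB-like class, ...): they
exercise a five-way classifier head, they do not claim clinical realism.

Everything is driven by ``numpy.random.default_rng(seed)``; the same seed
and parameters regenerate a bit-identical record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fp16 import floats_to_image
from .isa import ModelSpec

__all__ = [
    "BEAT_CLASSES",
    "MORPHOLOGIES",
    "SyntheticRecord",
    "gen_record",
    "gaussian_pulse_train",
    "gen_fixture_weights",
]

BEAT_CLASSES = ("N", "S", "V", "F", "Q")

# per class: wave -> (amplitude [mV-ish], offset from R [s], width sigma [s])
MORPHOLOGIES: dict[str, dict[str, tuple[float, float, float]]] = {
    "N": {"P": (0.12, -0.200, 0.025), "Q": (-0.15, -0.030, 0.010),
          "R": (1.00, 0.000, 0.012), "S": (-0.20, 0.030, 0.010),
          "T": (0.30, 0.220, 0.045)},
    # SVEB-like: diminished/absent P wave, slightly smaller R
    "S": {"P": (0.03, -0.160, 0.020), "Q": (-0.12, -0.030, 0.010),
          "R": (0.90, 0.000, 0.012), "S": (-0.18, 0.030, 0.010),
          "T": (0.28, 0.210, 0.045)},
    # VEB-like: widened, tall QRS, no P, discordant T
    "V": {"P": (0.00, -0.200, 0.025), "Q": (-0.10, -0.060, 0.020),
          "R": (1.10, 0.000, 0.035), "S": (-0.45, 0.070, 0.030),
          "T": (-0.35, 0.260, 0.060)},
    # fusion-like: intermediate width and amplitude
    "F": {"P": (0.06, -0.190, 0.025), "Q": (-0.12, -0.045, 0.015),
          "R": (0.80, 0.000, 0.022), "S": (-0.30, 0.050, 0.020),
          "T": (0.20, 0.240, 0.050)},
    # unknown/paced-like: blunt, low-slope complex
    "Q": {"P": (0.05, -0.210, 0.030), "Q": (-0.08, -0.050, 0.020),
          "R": (0.70, 0.000, 0.028), "S": (-0.15, 0.060, 0.025),
          "T": (0.25, 0.250, 0.055)},
}


@dataclass
class SyntheticRecord:
    """Generated samples plus the ground truth that produced them."""

    samples: np.ndarray
    fs: float
    r_truth: np.ndarray          # strictly increasing sample indices
    labels: tuple                # one class tag per r_truth entry
    seed: int
    snr_db: float | None = None  # measured SNR when any noise was added
    clean: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.r_truth) > 0), "r_truth must increase"
        assert len(self.labels) == len(self.r_truth)


def _beat(t: np.ndarray, r_time: float, label: str) -> np.ndarray:
    out = np.zeros_like(t)
    for amp, mu, sigma in MORPHOLOGIES[label].values():
        if amp != 0.0:
            out += amp * np.exp(-0.5 * ((t - r_time - mu) / sigma) ** 2)
    return out


def gen_record(n_beats: int = 100, fs: float = 360.0, rate_bpm: float = 60.0,
               rr_jitter: float = 0.03, labels=None, class_probs=None,
               baseline_amp: float = 0.0, baseline_freq: float = 0.25,
               powerline_amp: float = 0.0, powerline_freq: float = 50.0,
               white_sigma: float = 0.0, snr_db: float | None = None,
               lead_in_s: float = 1.0, lead_out_s: float = 1.0,
               seed: int = 0) -> SyntheticRecord:
    """Generate a labelled quasi-periodic ECG-like record.

    Parameters
    ----------
    rate_bpm, rr_jitter:
        Mean heart rate and the RR-interval jitter (standard deviation in
        seconds, clipped so intervals stay >= 0.35 s).
    labels, class_probs:
        Explicit per-beat labels, or sampling probabilities over
        :data:`BEAT_CLASSES`; default is all-normal beats.
    baseline_*, powerline_*, white_sigma, snr_db:
        Noise model: sinusoidal baseline wander, sinusoidal mains
        interference, and white Gaussian noise.  When ``snr_db`` is given
        the white-noise sigma is solved so the total noise power hits the
        requested signal-to-noise ratio.
    lead_in_s:
        Interval before the first R peak.  The default 1.0 s starts the
        record mid-rhythm, so a detector initialising its thresholds from
        the opening seconds sees real QRS energy rather than a flat line.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if fs <= 0 or rate_bpm <= 0:
        raise ValueError("fs and rate_bpm must be positive")
    if rr_jitter < 0 or white_sigma < 0:
        raise ValueError("rr_jitter and white_sigma must be non-negative")
    rng = np.random.default_rng(seed)

    if labels is not None:
        labels = tuple(labels)
        if len(labels) != n_beats:
            raise ValueError("labels length must equal n_beats")
    elif class_probs is not None:
        p = np.asarray([class_probs.get(c, 0.0) for c in BEAT_CLASSES], float)
        if p.sum() <= 0:
            raise ValueError("class_probs must have positive mass")
        labels = tuple(rng.choice(BEAT_CLASSES, size=n_beats, p=p / p.sum()))
    else:
        labels = ("N",) * n_beats
    unknown = set(labels) - set(BEAT_CLASSES)
    if unknown:
        raise ValueError(f"unknown beat classes: {sorted(unknown)}")

    rr_mean = 60.0 / rate_bpm
    rr = rr_mean + rr_jitter * rng.standard_normal(n_beats - 1)
    rr = np.clip(rr, 0.35, None)
    r_times = lead_in_s + np.concatenate([[0.0], np.cumsum(rr)])
    duration = r_times[-1] + lead_out_s
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    clean = np.zeros(n)
    for r_time, label in zip(r_times, labels):
        lo = max(int((r_time - 0.4) * fs), 0)
        hi = min(int((r_time + 0.45) * fs), n)
        clean[lo:hi] += _beat(t[lo:hi], r_time, label)
    r_truth = np.round(r_times * fs).astype(int)

    structured = np.zeros(n)
    if baseline_amp:
        structured += baseline_amp * np.sin(
            2 * np.pi * baseline_freq * t + rng.uniform(0, 2 * np.pi))
    if powerline_amp:
        structured += powerline_amp * np.sin(
            2 * np.pi * powerline_freq * t + rng.uniform(0, 2 * np.pi))

    sigma = white_sigma
    if snr_db is not None:
        p_signal = float(np.mean(clean ** 2))
        p_target = p_signal / 10.0 ** (snr_db / 10.0)
        p_structured = float(np.mean(structured ** 2))
        if p_target <= p_structured:
            raise ValueError(
                "structured noise alone already exceeds the requested SNR")
        sigma = float(np.sqrt(p_target - p_structured))
    white = sigma * rng.standard_normal(n) if sigma > 0 else np.zeros(n)

    noise = structured + white
    samples = clean + noise
    p_noise = float(np.mean(noise ** 2))
    measured = (10.0 * np.log10(np.mean(clean ** 2) / p_noise)
                if p_noise > 0 else None)
    return SyntheticRecord(
        samples=samples, fs=fs, r_truth=r_truth, labels=labels, seed=seed,
        snr_db=measured, clean=clean,
        params={"n_beats": n_beats, "rate_bpm": rate_bpm,
                "rr_jitter": rr_jitter, "baseline_amp": baseline_amp,
                "powerline_amp": powerline_amp, "white_sigma": sigma,
                "requested_snr_db": snr_db})


def gaussian_pulse_train(positions, n: int, fs: float = 360.0,
                         amp: float = 1.0, width_s: float = 0.02
                         ) -> np.ndarray:
    """Bare QRS-like Gaussian pulses at the given sample positions.

    A minimal stimulus for exercising the detector FSM (refractory sweeps,
    threshold behaviour) without full beat morphology.
    """
    t = np.arange(n) / fs
    out = np.zeros(n)
    for pos in positions:
        out += amp * np.exp(-0.5 * ((t - pos / fs) / width_s) ** 2)
    return out


def gen_fixture_weights(spec: ModelSpec, seed: int = 0, scale: float = 0.5
                        ) -> np.ndarray:
    """Random bounded binary16 weight image for a model description.

    Weights are uniform on [-scale, scale] (|w| <= 0.5 by default keeps a
    five-class forward pass well clear of binary16 saturation), laid out
    cumulatively in layer order — the layout ``compile_model`` assumes.
    ``scale=0`` yields an all-zero image.
    """
    rng = np.random.default_rng(seed)
    chunks = []
    for layer in spec.layers:
        chunks.append(rng.uniform(-scale, scale, size=layer.weight_count)
                      if scale else np.zeros(layer.weight_count))
    flat = np.concatenate(chunks) if chunks else np.zeros(0)
    return floats_to_image(flat)
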