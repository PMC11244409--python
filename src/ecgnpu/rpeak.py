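"""Pan-Tompkins R-peak detection and beat segmentation.

Processing chain (per sample)::

    raw -> LPF -> HPF -> 5-point derivative -> squaring -> 32-tap moving
    average -> adaptive-threshold FSM -> ±25-sample refinement -> 300-sample
    beat segmentation

Difference equations (the hardware uses only shift registers, shifters and
adders; ``>>`` denotes an arithmetic right shift, i.e. floor division):

* LPF:  y(n) = 2y(n-1) - y(n-2) + x(n) - 2x(n-6) + x(n-12)
  — transfer function ((1 - z^-6)/(1 - z^-1))^2, DC gain 36, group delay 5.
* HPF:  y(n) = x(n-16) - x(n-17) + y(n-1) - [x(n) - x(n-32)]/32
  — DC-free, group delay 16.
* Derivative:  y(n) = [2x(n) + x(n-1) - x(n-3) - 2x(n-4)]/8 (delay 2).
* Moving-window integrator: mean of the last 32 samples (delay 15.5);
  the /32 is a shift by 5.

The stated single-stage delays of 12 (LPF) and 32 (HPF) samples differ
from the group delays the printed equations imply (5 and 16); the
equations are authoritative here and the implied delays are what the
detector compensates and reports in its trace.

Detection FSM: the running signal-peak (SPK) and noise-peak (NPK)
estimates follow the classical exponential updates SPK ← 0.125·peak +
0.875·SPK (for accepted peaks), NPK ← 0.125·peak + 0.875·NPK (for
sub-threshold peaks), with threshold = NPK + 0.25·(SPK − NPK),
initialised from the first two seconds of the averaged signal (SPK = max,
NPK = mean).  A local maximum of the averaged signal above threshold fires
a candidate unless it falls inside the 200 ms refractory window after the
previous accepted peak; the reported index is the raw-signal argmax within
±25 samples of the delay-compensated candidate (earliest index on ties).
The original algorithm's searchback and T-wave slope discrimination are
intentionally absent: refractory plus refinement only.

Both a real-arithmetic mode and an integer shift-add mode (truncating
toward negative infinity, as arithmetic shifts do) are provided; the
filter steps are exposed individually for streaming use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

__all__ = [
    "REFINE_HALF_WINDOW",
    "REFRACTORY_S",
    "SEG_BEFORE",
    "SEG_AFTER",
    "CHAIN_DELAY",
    "FilterState",
    "lpf_step",
    "hpf_step",
    "derivative_step",
    "square_step",
    "mwi_step",
    "preprocess",
    "refine_peak",
    "refractory_samples",
    "detect",
    "segment",
    "DetectionResult",
]

REFINE_HALF_WINDOW = 25   # samples searched either side of a candidate
REFRACTORY_S = 0.2        # post-detection suppression, seconds
SEG_BEFORE = 100          # samples kept before the R peak
SEG_AFTER = 199           # samples kept after the R peak
MWI_ORDER = 32

# group delays implied by the printed equations: LPF 5 + HPF 16 +
# derivative 2 + MWI 15.5, rounded down
CHAIN_DELAY = 38

# filter coefficient vectors (b, a) for the real-mode vectorised path
_LPF_B = np.array([1, 0, 0, 0, 0, 0, -2, 0, 0, 0, 0, 0, 1], dtype=float)
_LPF_A = np.array([1, -2, 1], dtype=float)
_HPF_B = np.zeros(33); _HPF_B[0] = -1 / 32; _HPF_B[16] = 1.0
_HPF_B[17] = -1.0; _HPF_B[32] = 1 / 32
_HPF_A = np.array([1, -1], dtype=float)
_DERIV_B = np.array([2, 1, 0, -1, -2], dtype=float) / 8


@dataclass
class FilterState:
    """Delay lines for the streaming per-sample filter steps."""

    mode: str = "real"              # "real" | "int"
    lpf_x: list = field(default_factory=lambda: [0] * 13)
    lpf_y: list = field(default_factory=lambda: [0] * 2)
    hpf_x: list = field(default_factory=lambda: [0] * 33)
    hpf_y: int = 0
    der_x: list = field(default_factory=lambda: [0] * 5)
    mwi_x: list = field(default_factory=lambda: [0] * MWI_ORDER)
    mwi_sum: float = 0

    def _div(self, value, shift: int):
        if self.mode == "int":
            return int(value) >> shift  # arithmetic shift: floor division
        return value / (1 << shift)


def lpf_step(x_n, state: FilterState):
    """y(n) = 2y(n-1) - y(n-2) + x(n) - 2x(n-6) + x(n-12)."""
    xs, ys = state.lpf_x, state.lpf_y
    xs.insert(0, x_n)
    xs.pop()
    y = 2 * ys[0] - ys[1] + xs[0] - 2 * xs[6] + xs[12]
    ys.insert(0, y)
    ys.pop()
    return y


def hpf_step(x_n, state: FilterState):
    """y(n) = x(n-16) - x(n-17) + y(n-1) - [x(n) - x(n-32)]/32."""
    xs = state.hpf_x
    xs.insert(0, x_n)
    xs.pop()
    y = xs[16] - xs[17] + state.hpf_y - state._div(xs[0] - xs[32], 5)
    state.hpf_y = y
    return y


def derivative_step(x_n, state: FilterState):
    """y(n) = [2x(n) + x(n-1) - x(n-3) - 2x(n-4)]/8."""
    xs = state.der_x
    xs.insert(0, x_n)
    xs.pop()
    return state._div(2 * xs[0] + xs[1] - xs[3] - 2 * xs[4], 3)


def square_step(x_n):
    """Point-by-point squaring; emphasises QRS slope energy."""
    return x_n * x_n


def mwi_step(x_n, state: FilterState):
    """Mean of the last 32 samples; the /32 is a shift by 5."""
    xs = state.mwi_x
    state.mwi_sum += x_n - xs[-1]
    xs.insert(0, x_n)
    xs.pop()
    return state._div(state.mwi_sum, 5)


def preprocess(x: np.ndarray, mode: str = "real") -> np.ndarray:
    """Run the full chain raw → averaged signal.

    Real mode evaluates the same difference equations vectorised
    (scipy.signal.lfilter); integer mode streams through the shift-add
    steps sample by sample.
    """
    x = np.asarray(x)
    if mode == "real":
        y = scipy.signal.lfilter(_LPF_B, _LPF_A, x.astype(float))
        y = scipy.signal.lfilter(_HPF_B, _HPF_A, y)
        y = scipy.signal.lfilter(_DERIV_B, [1.0], y)
        y = y * y
        return scipy.signal.lfilter(np.full(MWI_ORDER, 1 / MWI_ORDER), [1.0], y)
    if mode == "int":
        state = FilterState(mode="int")
        out = np.empty(x.size, dtype=float)
        for i, v in enumerate(np.rint(x).astype(int)):
            s = mwi_step(
                square_step(
                    derivative_step(hpf_step(lpf_step(int(v), state), state),
                                    state)),
                state)
            out[i] = s
        return out
    raise ValueError(f"mode must be 'real' or 'int', got {mode!r}")


def refractory_samples(fs: float) -> int:
    """200 ms refractory period expressed in samples."""
    return round(REFRACTORY_S * fs)


def refine_peak(stream: np.ndarray, provisional: int,
                half_window: int = REFINE_HALF_WINDOW) -> int:
    """Raw-signal argmax within ±half_window of a provisional candidate.

    Earliest index wins on ties; the window is clipped at the record edges.
    """
    stream = np.asarray(stream)
    lo = max(provisional - half_window, 0)
    hi = min(provisional + half_window + 1, stream.size)
    if lo >= hi:
        raise ValueError("provisional index outside the record")
    return lo + int(np.argmax(stream[lo:hi]))


@dataclass
class DetectionResult:
    """Ordered R-peak indices, their 300-sample beats, and the FSM trace."""

    r_indices: np.ndarray
    segments: np.ndarray            # [n_kept, 300]
    segment_peaks: np.ndarray       # r_indices that produced the segments
    dropped_edge_peaks: int
    trace: dict

    def __len__(self) -> int:
        return len(self.r_indices)


def segment(stream: np.ndarray, r_index: int) -> np.ndarray | None:
    """300 raw samples r−100 … r+199, or None when the edge context is
    missing (the beat is dropped, not an error)."""
    stream = np.asarray(stream)
    if r_index - SEG_BEFORE < 0 or r_index + SEG_AFTER >= stream.size:
        return None
    return stream[r_index - SEG_BEFORE:r_index + SEG_AFTER + 1]


def _local_maxima(m: np.ndarray) -> np.ndarray:
    """Indices i with m[i-1] < m[i] >= m[i+1] (left edge of plateaus)."""
    rising = m[1:-1] > m[:-2]
    not_falling = m[1:-1] >= m[2:]
    return np.nonzero(rising & not_falling)[0] + 1


def detect(stream: np.ndarray, fs: float, mode: str = "real",
           init_window_s: float = 2.0) -> DetectionResult:
    """Full Pan-Tompkins detection over a sample stream.

    The adaptive threshold is initialised from the first ``init_window_s``
    seconds of the averaged signal (SPK = max, NPK = mean) and then updated
    at every local maximum of the averaged signal.  Candidates inside the
    refractory window are suppressed; accepted candidates are mapped back
    to the raw stream (chain delay compensated) and refined to the raw
    argmax within ±25 samples.  Reported peaks are guaranteed to be at
    least one refractory period apart.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    stream = np.asarray(stream, dtype=float)
    mwi = preprocess(stream, mode=mode)
    refractory = refractory_samples(fs)
    n_init = min(int(round(init_window_s * fs)), mwi.size)
    spk = float(mwi[:n_init].max()) if n_init else 0.0
    npk = float(mwi[:n_init].mean()) if n_init else 0.0
    thr = npk + 0.25 * (spk - npk)

    r_indices: list[int] = []
    events: list[dict] = []
    last_cand = None
    for cand in _local_maxima(mwi):
        peak = mwi[cand]
        if peak > thr:
            if last_cand is not None and cand - last_cand < refractory:
                events.append({"mwi_index": int(cand), "state": "refractory",
                               "threshold": thr})
                continue
            provisional = max(int(cand) - CHAIN_DELAY, 0)
            refined = refine_peak(stream, provisional)
            if r_indices and refined - r_indices[-1] < refractory:
                events.append({"mwi_index": int(cand), "state": "refractory",
                               "threshold": thr})
                continue
            spk = 0.125 * peak + 0.875 * spk
            last_cand = cand
            r_indices.append(refined)
            events.append({"mwi_index": int(cand), "r_index": int(refined),
                           "state": "signal", "threshold": thr,
                           "spk": spk, "npk": npk})
        else:
            npk = 0.125 * peak + 0.875 * npk
            events.append({"mwi_index": int(cand), "state": "noise",
                           "threshold": thr, "npk": npk})
        thr = npk + 0.25 * (spk - npk)

    segments, kept_peaks = [], []
    dropped = 0
    for r in r_indices:
        seg = segment(stream, r)
        if seg is None:
            dropped += 1
        else:
            segments.append(seg)
            kept_peaks.append(r)
    seg_arr = (np.vstack(segments) if segments
               else np.empty((0, SEG_BEFORE + SEG_AFTER + 1)))
    trace = {
        "mode": mode,
        "chain_delay": CHAIN_DELAY,
        "stage_delays": {"lpf": 5, "hpf": 16, "derivative": 2, "mwi": 15.5},
        "refractory_samples": refractory,
        "init": {"spk": float(mwi[:n_init].max()) if n_init else 0.0,
                 "npk": float(mwi[:n_init].mean()) if n_init else 0.0},
        "final": {"spk": spk, "npk": npk, "threshold": thr},
        "events": events,
    }
    return DetectionResult(
        r_indices=np.asarray(r_indices, dtype=int),
        segments=seg_arr,
        segment_peaks=np.asarray(kept_peaks, dtype=int),
        dropped_edge_peaks=dropped,
        trace=trace,
    )
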