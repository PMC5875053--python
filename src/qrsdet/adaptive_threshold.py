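"""Adaptive-threshold QRS classification with RR-based search-back.

Candidate peaks are traversed left to right against a running decision
level THRESHOLD = 0.25*SPK + 0.75*NPK, where SPK and NPK are
exponentially smoothed estimates of the signal-peak and noise-peak
amplitude in the integrated signal.  The state is seeded from the maximum
of the first 300 samples: SPK = 0.13*M, NPK = 0.1*SPK.

A 10-slot FIFO of the most recent RR intervals yields AVE_RR.  Whenever
no QRS has been accepted for more than max(400 samples, 1.5*AVE_RR), SPK
is halved and the candidates rejected since the last accepted QRS are
re-examined under the lowered threshold (search-back); the first
candidate exceeding it is accepted and flagged.  Halving repeats while
the gap persists and a pending candidate could still cross the threshold
floor.  The same check runs once more at the end of the signal so that a
trailing missed beat can be recovered.

Accepted fiducials live in integrated-signal coordinates; they are mapped
back to raw-signal coordinates by subtracting the cascade's total group
delay and optionally snapping to the band-passed signal's local extremum.
"""
from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

from .config import DetectorConfig
from .peak_finder import CandidatePeak
from .preprocessing import PreprocessedSignal

__all__ = [
    "ThresholdState",
    "Detection",
    "DetectionResult",
    "init_state",
    "update_ave_rr",
    "detect",
    "to_raw_fiducials",
]


@dataclass
class ThresholdState:
    """SPK/NPK/THRESHOLD plus the RR buffer driving the timeout."""

    spk: float
    npk: float
    threshold: float
    rr_buffer: deque = field(default_factory=lambda: deque(maxlen=10))
    ave_rr: float = 0.0
    last_qrs_index: int | None = None

    def recompute_threshold(self, config: DetectorConfig) -> None:
        self.threshold = (config.thr_spk_w * self.spk
                          + config.thr_npk_w * self.npk)


@dataclass(frozen=True)
class Detection:
    """One accepted QRS fiducial."""

    integrated_index: int
    raw_index: int
    amplitude: float
    via_searchback: bool = False


@dataclass
class DetectionResult:
    """Ordered detections, their RR intervals, and an optional state trace.

    ``state_trace`` rows are (peak_index, spk, npk, threshold, accepted)
    recorded after every decision, suitable for threshold-vs-time plots.
    """

    detections: list[Detection]
    rr_intervals: np.ndarray
    state_trace: list[tuple[int, float, float, float, bool]] | None = None

    @property
    def integrated_indices(self) -> np.ndarray:
        return np.asarray([d.integrated_index for d in self.detections],
                          dtype=np.int64)

    @property
    def raw_indices(self) -> np.ndarray:
        return np.asarray([d.raw_index for d in self.detections],
                          dtype=np.int64)


def init_state(integrated, fs: float,
               config: DetectorConfig | None = None) -> ThresholdState:
    """Seed the threshold state from the first 300 samples (scaled to fs).

    M = max of the initialisation window; SPK = 0.13*M, NPK = 0.1*SPK,
    THRESHOLD = 0.25*SPK + 0.75*NPK.  Shorter signals use all samples.
    """
    config = config or DetectorConfig()
    x = np.asarray(integrated, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("integrated signal must be a non-empty 1-D array")
    init_n = config.scaled(config.init_n, fs)
    m_val = float(np.max(x[:init_n]))
    spk = config.spk_init_frac * m_val
    npk = config.npk_frac * spk
    state = ThresholdState(
        spk=spk, npk=npk, threshold=0.0,
        rr_buffer=deque(maxlen=config.rr_buffer_len))
    state.recompute_threshold(config)
    return state


def update_ave_rr(state: ThresholdState, new_rr: float) -> ThresholdState:
    """Push an RR interval (samples) into the FIFO and refresh AVE_RR."""
    if new_rr <= 0:
        raise ValueError("RR intervals must be positive")
    state.rr_buffer.append(float(new_rr))
    state.ave_rr = float(np.mean(state.rr_buffer))
    return state


def _timeout(state: ThresholdState, timeout_n: int,
             config: DetectorConfig) -> float:
    if state.rr_buffer:
        return max(timeout_n, config.rr_gap_factor * state.ave_rr)
    return float(timeout_n)


def detect(peaks: list[CandidatePeak], integrated, fs: float,
           state: ThresholdState | None = None,
           config: DetectorConfig | None = None,
           trace: bool = False) -> DetectionResult:
    """Classify candidate peaks as QRS or noise.

    Parameters
    ----------
    peaks:
        Sorted candidate peaks from :func:`qrsdet.peak_finder.find_peaks`.
    integrated:
        The integrated signal the peaks were found on (used for state
        initialisation and the end-of-signal search-back).
    state:
        Pre-initialised threshold state; created from ``integrated`` when
        omitted.
    trace:
        Record per-decision (index, spk, npk, threshold, accepted) rows.

    Returns
    -------
    DetectionResult
        ``raw_index`` equals ``integrated_index`` until
        :func:`to_raw_fiducials` applies the delay correction.
    """
    config = config or DetectorConfig()
    x = np.asarray(integrated, dtype=float)
    if any(peaks[i].index >= peaks[i + 1].index for i in range(len(peaks) - 1)):
        raise ValueError("candidate peaks must be strictly increasing")
    if state is None:
        state = init_state(x, fs, config)

    timeout_n = config.scaled(config.timeout_n, fs)
    detections: list[Detection] = []
    pending: list[CandidatePeak] = []   # rejected since the last accepted QRS
    trace_rows: list[tuple[int, float, float, float, bool]] = []

    def accept(p: CandidatePeak, via_searchback: bool) -> None:
        if state.last_qrs_index is not None:
            rr = p.index - state.last_qrs_index
            if rr > 0:
                update_ave_rr(state, rr)
        sf = config.smoothing_factor
        state.spk = sf * p.amplitude + (1 - sf) * state.spk
        state.recompute_threshold(config)
        state.last_qrs_index = p.index
        detections.append(Detection(p.index, p.index, p.amplitude,
                                    via_searchback))

    def searchback(gap_end: int) -> None:
        # halve SPK and re-examine pending candidates while the gap since
        # the last accepted QRS persists and some pending candidate can
        # still cross the threshold floor (thr_npk_w * NPK)
        while (state.last_qrs_index is not None
               and gap_end - state.last_qrs_index > _timeout(state, timeout_n,
                                                             config)
               and any(p.amplitude > config.thr_npk_w * state.npk
                       for p in pending)):
            state.spk *= config.searchback_halving
            state.recompute_threshold(config)
            hit = next((p for p in pending
                        if p.amplitude > state.threshold), None)
            if hit is not None:
                accept(hit, via_searchback=True)
                pending[:] = [p for p in pending if p.index > hit.index]

    for pk in peaks:
        searchback(pk.index)
        if pk.amplitude > state.threshold:
            accept(pk, via_searchback=False)
            pending.clear()
        else:
            sf = config.smoothing_factor
            state.npk = sf * pk.amplitude + (1 - sf) * state.npk
            state.recompute_threshold(config)
            pending.append(pk)
        if trace:
            trace_rows.append((pk.index, state.spk, state.npk,
                               state.threshold,
                               state.last_qrs_index == pk.index))

    if len(x):
        searchback(len(x) - 1)

    detections.sort(key=lambda d: d.integrated_index)
    rr = np.diff([d.integrated_index for d in detections]).astype(np.int64) \
        if len(detections) > 1 else np.empty(0, dtype=np.int64)
    return DetectionResult(detections, rr, trace_rows if trace else None)


def to_raw_fiducials(result: DetectionResult, pre: PreprocessedSignal,
                     refine_window: int | None = None,
                     config: DetectorConfig | None = None) -> DetectionResult:
    """Map integrated-signal fiducials back to raw-signal coordinates.

    ``raw_index = integrated_index - round(total_delay)``, then (for a
    positive refinement window) snapped to the largest absolute
    band-passed sample within ±``refine_window``, compensating the
    band-pass group delay.  Ordering is preserved; indices are clamped to
    the signal bounds.
    """
    config = config or DetectorConfig()
    if refine_window is None:
        refine_window = round(config.refine_window_ms * pre.fs / 1000.0)
    n = len(pre.raw)
    delay = round(pre.total_delay)
    bp_delay = round(pre.stage_delays["lowpass"] + pre.stage_delays["highpass"])
    out: list[Detection] = []
    prev = -1
    for d in result.detections:
        r = min(max(d.integrated_index - delay, 0), n - 1)
        if refine_window > 0:
            lo = max(0, r - refine_window + bp_delay)
            hi = min(n, r + refine_window + bp_delay + 1)
            if hi > lo:
                r = lo + int(np.argmax(np.abs(pre.bandpassed[lo:hi]))) - bp_delay
                r = min(max(r, 0), n - 1)
        if r <= prev:  # keep strict ordering if refinement collides
            r = prev + 1
        prev = r
        out.append(replace(d, raw_index=r))
    rr = np.diff([d.raw_index for d in out]).astype(np.int64) \
        if len(out) > 1 else np.empty(0, dtype=np.int64)
    return DetectionResult(out, rr, result.state_trace)
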