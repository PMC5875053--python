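"""Candidate-peak extraction from the integrated signal.

A single left-to-right scan keeps the running maximum since the last
emitted peak.  A peak is emitted at the running maximum's position once
the signal drops below half that maximum (the half-drop rule); if nothing
was emitted for 300 samples the local maximum of the unemitted stretch is
forced out and flagged.  Candidates closer than 80 samples (222 ms at
360 Hz) are then merged, keeping the larger amplitude.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DetectorConfig

__all__ = ["CandidatePeak", "find_peaks"]


@dataclass(frozen=True)
class CandidatePeak:
    """A candidate QRS position in integrated-signal coordinates."""

    index: int
    amplitude: float
    forced: bool = False


def _scan(x: np.ndarray, forced_n: int) -> list[CandidatePeak]:
    peaks: list[CandidatePeak] = []
    run_max = x[0]
    run_arg = 0
    last_emit = -1
    for i in range(len(x)):
        v = x[i]
        if v > run_max:
            run_max = v
            run_arg = i
        if run_max > 0 and v < 0.5 * run_max:
            peaks.append(CandidatePeak(run_arg, run_max, False))
            run_max = v
            run_arg = i
            last_emit = i
        elif i - last_emit >= forced_n:
            peaks.append(CandidatePeak(run_arg, run_max, True))
            run_max = v
            run_arg = i
            last_emit = i
    return peaks


def _merge(peaks: list[CandidatePeak], merge_n: int) -> list[CandidatePeak]:
    # stack-based greedy merge; equal amplitudes keep the earlier peak
    out: list[CandidatePeak] = []
    for p in peaks:
        keep = True
        while out and p.index - out[-1].index < merge_n:
            if p.amplitude > out[-1].amplitude:
                out.pop()
            else:
                keep = False  # dominated by the surviving earlier peak
                break
        if keep:
            out.append(p)
    return out


def find_peaks(integrated, fs: float,
               config: DetectorConfig | None = None) -> list[CandidatePeak]:
    """Extract candidate peaks from a non-negative integrated signal.

    Returns peaks with strictly increasing indices separated by at least
    the merge distance (80 samples rescaled to ``fs``).  On flat/zero
    stretches only forced peaks are produced; rejecting those as noise is
    the threshold stage's job.
    """
    config = config or DetectorConfig()
    x = np.asarray(integrated, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D integrated signal")
    if len(x) == 0:
        return []
    if np.any(x < 0):
        raise ValueError("integrated signal must be elementwise >= 0")
    forced_n = config.scaled(config.forced_n, fs)
    merge_n = config.scaled(config.merge_n, fs)
    return _merge(_scan(x, forced_n), merge_n)
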