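"""Five-stage preprocessing cascade.

The raw ECG is low-pass filtered, high-pass filtered (together a ~5-15 Hz
band-pass that keeps the QRS energy while attenuating baseline drift,
powerline interference and T waves), differentiated to emphasise the steep
QRS slopes, squared, and smoothed with a moving-window integrator whose
output carries both slope and width information of the QRS complex.

All filters are realised as difference equations with zero initial state
(the startup transient is accepted).  The recursive low-pass is an FIR
filter in disguise — ((1-z^-6)/(1-z^-1))^2, a triangular impulse response
with DC gain 36 and exact group delay 5 samples.  The high-pass is the
all-pass-minus-running-sum construction y(n) = 32*x(n-16) - sum_{k<32}
x(n-k): an FIR with DC gain 0 whose dominant spike sits 16 samples in.
Because the derivative uses two future samples it is realised causally
with an extra 2-sample delay.  Per-stage group delays are tracked so that
fiducials found on the integrated signal can be mapped back to raw-signal
coordinates with a single subtraction.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .config import DetectorConfig, REFERENCE_FS
from .signal_io import EcgRecord

__all__ = [
    "PreprocessedSignal",
    "lowpass",
    "highpass",
    "derivative",
    "square",
    "integrate",
    "preprocess",
    "dump_stages",
    "LOWPASS_DELAY",
    "HIGHPASS_DELAY",
    "DERIVATIVE_DELAY",
]

# numerator/denominator of the recursive low-pass:
#   y(n) = 2y(n-1) - y(n-2) + x(n) - 2x(n-6) + x(n-12)
_LP_B = np.zeros(13)
_LP_B[[0, 6, 12]] = (1.0, -2.0, 1.0)
_LP_A = np.array([1.0, -2.0, 1.0])

# high-pass FIR: 32*delta(n-16) minus a 32-point running sum
_HP_B = -np.ones(32)
_HP_B[16] += 32.0

# causal five-point derivative (1/8)[-x(n-4) - 2x(n-3) + 2x(n-1) + x(n)]
_DERIV_B = np.array([1.0, 2.0, 0.0, -2.0, -1.0]) / 8.0

LOWPASS_DELAY = 5.0      # samples; symmetry center of the triangular FIR
HIGHPASS_DELAY = 16.0    # samples; position of the dominant spike
DERIVATIVE_DELAY = 2.0   # samples added by the causal realisation


@dataclass
class PreprocessedSignal:
    """All intermediate stage outputs plus per-stage delay bookkeeping."""

    fs: float
    raw: np.ndarray
    lowpassed: np.ndarray
    bandpassed: np.ndarray
    derivative: np.ndarray
    squared: np.ndarray
    integrated: np.ndarray
    stage_delays: dict[str, float]

    @property
    def total_delay(self) -> float:
        """Delay (samples) from a raw fiducial to the integrated signal."""
        return sum(self.stage_delays.values())


def _check_signal(signal, min_len: int = 1) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample sequence")
    if len(x) < min_len:
        raise ValueError(f"signal too short: need at least {min_len} samples")
    return x


def lowpass(signal) -> np.ndarray:
    """Recursive low-pass y(n) = 2y(n-1) - y(n-2) + x(n) - 2x(n-6) + x(n-12)."""
    return lfilter(_LP_B, _LP_A, _check_signal(signal))


def highpass(signal) -> np.ndarray:
    """High-pass y(n) = 32 x(n-16) - sum_{k=0}^{31} x(n-k) (DC gain 0)."""
    return lfilter(_HP_B, [1.0], _check_signal(signal))


def derivative(signal) -> np.ndarray:
    """Five-point derivative, causal with a 2-sample delay.

    Interior response to a unit ramp is exactly 1.
    """
    return lfilter(_DERIV_B, [1.0], _check_signal(signal, min_len=5))


def square(signal) -> np.ndarray:
    """Elementwise squaring."""
    x = np.asarray(signal, dtype=float)
    return x * x


def integrate(signal, window_n: int = 24) -> np.ndarray:
    """Moving-window mean y(n) = (1/N) sum_{k=0}^{N-1} x(n-k).

    The default N = 24 spans 66.7 ms at 360 Hz.
    """
    if window_n < 1:
        raise ValueError("window_n must be >= 1")
    x = _check_signal(signal)
    return lfilter(np.full(window_n, 1.0 / window_n), [1.0], x)


def preprocess(record: EcgRecord | np.ndarray,
               channel: int | str = 0,
               config: DetectorConfig | None = None,
               fs: float | None = None) -> PreprocessedSignal:
    """Run the full cascade on one channel of ``record``.

    ``record`` may also be a bare sample array, in which case ``fs`` must
    be given.  The integrator window is rescaled for sampling rates other
    than 360 Hz.
    """
    config = config or DetectorConfig()
    if isinstance(record, EcgRecord):
        raw = record.channel(channel)
        fs = record.fs
    else:
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
        raw = _check_signal(record)

    window_n = config.scaled(config.window_n, fs)
    lp = lowpass(raw)
    bp = highpass(lp)
    der = derivative(bp)
    sq = square(der)
    integ = integrate(sq, window_n)
    delays = {
        "lowpass": LOWPASS_DELAY * 1.0,
        "highpass": HIGHPASS_DELAY * 1.0,
        "derivative": DERIVATIVE_DELAY * 1.0,
        "square": 0.0,
        "integrate": (window_n - 1) / 2.0,
    }
    return PreprocessedSignal(fs=fs, raw=raw, lowpassed=lp, bandpassed=bp,
                              derivative=der, squared=sq, integrated=integ,
                              stage_delays=delays)


def dump_stages(pre: PreprocessedSignal, path: str | Path) -> Path:
    """Write all stage outputs to CSV (one column per stage)."""
    p = Path(path)
    header = "raw,lowpassed,bandpassed,derivative,squared,integrated"
    data = np.column_stack([pre.raw, pre.lowpassed, pre.bandpassed,
                            pre.derivative, pre.squared, pre.integrated])
    np.savetxt(p, data, delimiter=",", header=header, comments="")
    return p
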