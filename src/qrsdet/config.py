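"""Detector configuration.

Every numeric constant of the detector lives here, defined at the 360 Hz
reference sampling rate of the MIT-BIH Arrhythmia Database and rescaled
proportionally for other rates.
"""
from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

#: Sampling rate (Hz) at which the sample-count constants are defined.
REFERENCE_FS = 360.0


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the QRS detector.

    Sample-count parameters (``*_n``) are expressed at the 360 Hz reference
    rate and converted with :meth:`scaled` for records sampled at other
    rates.

    Attributes
    ----------
    window_n:
        Moving-window integrator width in samples (24 ≙ 66.7 ms at 360 Hz).
    init_n:
        Length of the initialisation window whose maximum seeds the
        threshold state (300 samples).
    merge_n:
        Minimum separation between candidate peaks; closer peaks are merged
        keeping the larger (80 samples ≙ 222 ms).
    forced_n:
        A candidate peak is forced out if none was emitted for this many
        samples (300).
    timeout_n:
        Search-back timeout: if no QRS was accepted within
        ``max(timeout_n, rr_gap_factor * AVE_RR)`` samples, the signal-peak
        estimate is halved and rejected candidates are re-examined
        (400 samples ≙ 1111 ms).
    spk_init_frac, npk_frac:
        Initial signal-peak estimate SPK = ``spk_init_frac`` × max of the
        init window; initial noise-peak estimate NPK = ``npk_frac`` × SPK.
    thr_spk_w, thr_npk_w:
        Decision threshold weights: THRESHOLD = ``thr_spk_w``·SPK +
        ``thr_npk_w``·NPK.  Must sum to 1.
    searchback_halving:
        Multiplier applied to SPK on a search-back trigger (0.5).
    rr_gap_factor:
        RR multiple that also triggers search-back (1.5 × AVE_RR).
    rr_buffer_len:
        Number of most recent RR intervals averaged into AVE_RR (10).
    abnormal_rr_ms:
        RR intervals strictly longer than this are reported as suspicious
        abnormal regions (1000 ms).
    smoothing_factor:
        Exponential smoothing weight for SPK/NPK refreshes (0.125).
    match_tolerance_ms:
        Beat-matching tolerance for evaluation (150 ms, the ANSI/AAMI EC57
        convention).
    refine_window_ms:
        Half-width of the window used to snap delay-corrected fiducials
        onto the band-passed signal's extremum (50 ms; 0 disables).
    channel:
        Channel index or name used for detection (first channel — MLII in
        most MIT-BIH records — by default).
    """

    window_n: int = 24
    init_n: int = 300
    merge_n: int = 80
    forced_n: int = 300
    timeout_n: int = 400
    spk_init_frac: float = 0.13
    npk_frac: float = 0.1
    thr_spk_w: float = 0.25
    thr_npk_w: float = 0.75
    searchback_halving: float = 0.5
    rr_gap_factor: float = 1.5
    rr_buffer_len: int = 10
    abnormal_rr_ms: float = 1000.0
    smoothing_factor: float = 0.125
    match_tolerance_ms: float = 150.0
    refine_window_ms: float = 50.0
    channel: int | str = 0

    def __post_init__(self) -> None:
        for name in ("window_n", "init_n", "merge_n", "forced_n",
                     "timeout_n", "rr_buffer_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive sample count")
        if abs(self.thr_spk_w + self.thr_npk_w - 1.0) > 1e-12:
            raise ValueError("threshold weights must sum to 1")
        for name in ("spk_init_frac", "npk_frac", "searchback_halving",
                     "smoothing_factor"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.rr_gap_factor <= 0:
            raise ValueError("rr_gap_factor must be positive")
        if self.match_tolerance_ms <= 0:
            raise ValueError("match_tolerance_ms must be positive")

    def scaled(self, n: int, fs: float) -> int:
        """Rescale a 360 Hz sample count ``n`` to sampling rate ``fs``."""
        return max(1, round(n * fs / REFERENCE_FS))

    def with_overrides(self, **kwargs) -> "DetectorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "DetectorConfig":
        """Load a config from a plain ``key = value`` file.

        Lines starting with ``#`` and blank lines are ignored.  Unknown
        keys raise ``ValueError``.
        """
        known = {f.name: f.type for f in fields(cls)}
        kwargs: dict[str, object] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            if key == "channel":
                kwargs[key] = int(value) if value.lstrip("-").isdigit() else value
            elif key.endswith("_n") or key == "rr_buffer_len":
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def dump(self) -> str:
        """Serialise as a ``key = value`` block readable by :meth:`from_file`."""
        return "\n".join(f"{f.name} = {getattr(self, f.name)}"
                         for f in fields(self)) + "\n"
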