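"""Convenience wrapper chaining all detector stages."""
from __future__ import annotations

from .adaptive_threshold import (DetectionResult, detect, init_state,
                                 to_raw_fiducials)
from .config import DetectorConfig
from .peak_finder import find_peaks
from .preprocessing import PreprocessedSignal, preprocess
from .signal_io import EcgRecord

__all__ = ["run_detector"]


def run_detector(record: EcgRecord, config: DetectorConfig | None = None,
                 trace: bool = False
                 ) -> tuple[PreprocessedSignal, DetectionResult]:
    """Preprocess, find peaks, threshold, and delay-correct one record.

    Returns the preprocessed stages and the detection result with raw
    fiducials already corrected for the cascade delay.
    """
    config = config or DetectorConfig()
    pre = preprocess(record, config.channel, config)
    peaks = find_peaks(pre.integrated, pre.fs, config)
    state = init_state(pre.integrated, pre.fs, config)
    result = detect(peaks, pre.integrated, pre.fs, state, config, trace=trace)
    return pre, to_raw_fiducials(result, pre, config=config)
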