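"""Beat-level evaluation against reference annotations.

Detections are matched one-to-one to reference beats within a ±150 ms
tolerance (the ANSI/AAMI EC57 convention) by greedy nearest pairing.
The reported statistics are

    sensitivity      Se = TP / (TP + FN)
    "specificity"    Sp = TP / (TP + FP)   (positive predictivity, P+)
    detection rate   DR = (actual - (FP + FN)) / actual
    error rate       Er = (FP + FN) / actual

Note Sp as used throughout this package is positive predictivity, kept
under its customary name in the QRS-detection literature.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import DetectorConfig
from .signal_io import BeatAnnotations, EcgRecord, read_record

__all__ = ["EvalResult", "match_beats", "score", "aggregate",
           "evaluate_record", "evaluate_database"]


@dataclass(frozen=True)
class EvalResult:
    """Per-record (or aggregate) beat-detection statistics."""

    record_id: str
    actual: int
    tp: int
    fp: int
    fn: int
    detection_rate: float
    se: float
    sp: float
    er: float


def match_beats(detections: Sequence[int], reference: BeatAnnotations,
                fs: float, tolerance_ms: float = 150.0
                ) -> tuple[int, int, int, list[tuple[int, int]]]:
    """Greedy one-to-one matching within ±``tolerance_ms``.

    Both lists are traversed in time order and each detection is paired
    with the earliest still-unmatched reference beat within tolerance (a
    two-pointer sweep).  For 1-D tolerance matching this greedy rule
    achieves the maximum possible number of pairs, so TP never
    undercounts.  Returns ``(tp, fp, fn, pairs)`` where ``pairs`` holds
    matched (detection_index, reference_index) sample positions; each
    detection and each reference beat is used at most once.
    """
    if tolerance_ms <= 0:
        raise ValueError("tolerance_ms must be positive")
    det = np.sort(np.asarray(detections, dtype=np.int64))
    ref = np.asarray(reference.indices, dtype=np.int64)
    tol = tolerance_ms * fs / 1000.0

    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < len(det) and j < len(ref):
        if det[i] < ref[j] - tol:
            i += 1
        elif ref[j] < det[i] - tol:
            j += 1
        else:
            pairs.append((int(det[i]), int(ref[j])))
            i += 1
            j += 1
    tp = len(pairs)
    return tp, len(det) - tp, len(ref) - tp, pairs


def score(tp: int, fp: int, fn: int, actual: int,
          record_id: str = "") -> EvalResult:
    """Fill all rates from the counts.

    ``actual`` must equal ``tp + fn``; "failed" beats are FP + FN.
    """
    if actual <= 0:
        raise ValueError("actual beat count must be positive")
    if tp + fn != actual:
        raise ValueError(f"inconsistent counts: tp+fn={tp + fn} != "
                         f"actual={actual}")
    failed = fp + fn
    return EvalResult(
        record_id=record_id, actual=actual, tp=tp, fp=fp, fn=fn,
        detection_rate=(actual - failed) / actual,
        se=tp / (tp + fn) if tp + fn else 0.0,
        sp=tp / (tp + fp) if tp + fp else 0.0,
        er=failed / actual,
    )


def aggregate(results: Iterable[EvalResult],
              record_id: str = "all") -> EvalResult:
    """Sum counts across records and recompute rates from the sums."""
    rs = list(results)
    if not rs:
        raise ValueError("nothing to aggregate")
    return score(sum(r.tp for r in rs), sum(r.fp for r in rs),
                 sum(r.fn for r in rs), sum(r.actual for r in rs),
                 record_id=record_id)


def evaluate_record(record: EcgRecord,
                    config: DetectorConfig | None = None) -> EvalResult:
    """Run the full detector on one annotated record and score it.

    Reference annotations are filtered to beat codes first; rhythm and
    quality annotations do not count as beats.
    """
    from .pipeline import run_detector  # local import avoids a cycle

    config = config or DetectorConfig()
    if record.annotations is None:
        raise ValueError(f"record {record.record_id} has no reference "
                         "annotations")
    beats = record.annotations.beats_only()
    _, result = run_detector(record, config)
    tp, fp, fn, _ = match_beats(result.raw_indices, beats, record.fs,
                                config.match_tolerance_ms)
    return score(tp, fp, fn, len(beats), record_id=record.record_id)


def evaluate_database(records: Iterable[EcgRecord | str | Path],
                      config: DetectorConfig | None = None,
                      out_csv: str | Path | None = None
                      ) -> tuple[list[EvalResult], EvalResult, pd.DataFrame]:
    """Evaluate a batch of records and tabulate per-record + aggregate rows.

    ``records`` may mix in-memory records and WFDB paths.  Per-record
    failures are collected into the table as NaN rows rather than aborting
    the batch.  The CSV columns mirror the customary benchmark layout:
    Num, Actual, TP, FP, FN, Det_Rate, plus Se, Sp, Er.
    """
    config = config or DetectorConfig()
    results: list[EvalResult] = []
    failures: list[tuple[str, str]] = []
    for item in records:
        rec = item if isinstance(item, EcgRecord) else \
            read_record(item, channel=None)
        try:
            results.append(evaluate_record(rec, config))
        except Exception as exc:  # noqa: BLE001 - batch robustness
            failures.append((rec.record_id, str(exc)))
    if not results:
        raise RuntimeError(f"no record evaluated successfully: {failures}")
    agg = aggregate(results)

    rows = [r.__dict__ for r in results] + [agg.__dict__]
    df = pd.DataFrame(rows).rename(columns={
        "record_id": "Num", "actual": "Actual", "tp": "TP", "fp": "FP",
        "fn": "FN", "detection_rate": "Det_Rate", "se": "Se", "sp": "Sp",
        "er": "Er"})
    for rid, msg in failures:
        df.loc[len(df)] = {"Num": rid, **{c: np.nan for c in df.columns
                                          if c != "Num"}}
    if out_csv is not None:
        df.to_csv(out_csv, index=False, float_format="%.5f")
    return results, agg, df
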