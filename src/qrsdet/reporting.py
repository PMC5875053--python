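"""Abnormal-region flagging and RR-Lorenz (Poincaré) output.

An RR interval strictly longer than 1000 ms means no QRS was found within
the physiological expectation and the stretch between the two detections
is reported as a suspicious abnormal region for a cardiologist to review.
The Lorenz plot scatters each RR interval against its successor,
RR(N+1) vs RR(N), giving a compact view of beat-to-beat variability.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)
import numpy as np

from .adaptive_threshold import DetectionResult
from .config import DetectorConfig
from .preprocessing import PreprocessedSignal
from .signal_io import EcgRecord

__all__ = ["AbnormalRegion", "LorenzPoints", "find_abnormal_regions",
           "lorenz", "render_reports"]


@dataclass(frozen=True)
class AbnormalRegion:
    """A long RR gap, bounded by the two neighbouring detections."""

    start_index: int
    end_index: int
    start_s: float
    end_s: float
    gap_ms: float


@dataclass(frozen=True)
class LorenzPoints:
    """Consecutive RR-interval pairs in ms: x = RR(N), y = RR(N+1)."""

    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.x)


def find_abnormal_regions(result: DetectionResult, fs: float,
                          config: DetectorConfig | None = None
                          ) -> list[AbnormalRegion]:
    """Return one region per consecutive detection pair with RR > 1000 ms.

    The comparison is strict: an RR of exactly 1000 ms is not abnormal.
    Fewer than two detections yield an empty list.
    """
    config = config or DetectorConfig()
    idx = result.raw_indices
    regions: list[AbnormalRegion] = []
    for a, b in zip(idx[:-1], idx[1:]):
        gap_ms = (b - a) / fs * 1000.0
        if gap_ms > config.abnormal_rr_ms:
            regions.append(AbnormalRegion(int(a), int(b), a / fs, b / fs,
                                          gap_ms))
    return regions


def lorenz(result: DetectionResult, fs: float) -> LorenzPoints:
    """RR(N) vs RR(N+1) pairs in ms; empty for fewer than 3 detections."""
    idx = result.raw_indices
    if len(idx) < 3:
        return LorenzPoints(np.empty(0), np.empty(0))
    rr_ms = np.diff(idx) / fs * 1000.0
    return LorenzPoints(rr_ms[:-1].copy(), rr_ms[1:].copy())


def _plot_region(record: EcgRecord, result: DetectionResult,
                 region: AbnormalRegion, pre: PreprocessedSignal | None,
                 channel: int | str, window_s: float, path: Path) -> None:
    fs = record.fs
    raw = record.channel(channel)
    lo = max(0, int((region.start_s - window_s) * fs))
    hi = min(len(raw), int((region.end_s + window_s) * fs))
    t = np.arange(lo, hi) / fs

    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    if pre is not None:
        ax0.plot(t, pre.integrated[lo:hi], lw=0.8, label="integrated")
        if result.state_trace:
            tr = np.asarray([(r[0], r[3]) for r in result.state_trace])
            m = (tr[:, 0] >= lo) & (tr[:, 0] < hi)
            ax0.step(tr[m, 0] / fs, tr[m, 1], where="post", color="r",
                     lw=0.8, label="threshold")
        ax0.legend(loc="upper right", fontsize=8)
    ax0.set_ylabel("integrated")

    ax1.plot(t, raw[lo:hi], lw=0.8)
    det = result.raw_indices
    m = (det >= lo) & (det < hi)
    ax1.plot(det[m] / fs, raw[det[m]], "rv", ms=6, label="QRS")
    for ax in (ax0, ax1):
        ax.axvspan(region.start_s, region.end_s, color="green", alpha=0.2)
    ax1.set_xlabel("time (s)")
    ax1.set_ylabel("ECG (mV)")
    ax1.legend(loc="upper right", fontsize=8)
    fig.suptitle(f"{record.record_id}: RR gap {region.gap_ms:.0f} ms")
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_reports(record: EcgRecord, result: DetectionResult,
                   regions: list[AbnormalRegion], points: LorenzPoints,
                   out_dir: str | Path,
                   pre: PreprocessedSignal | None = None,
                   channel: int | str = 0,
                   window_s: float = 5.0) -> list[Path]:
    """Write per-region plots, the Lorenz scatter, and a JSON summary.

    Returns the list of files written.  ``out_dir`` is created when
    missing; an unwritable location raises ``OSError``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for k, region in enumerate(regions):
        p = out / f"{record.record_id}_region_{k}.png"
        _plot_region(record, result, region, pre, channel, window_s, p)
        written.append(p)

    if len(points):
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.scatter(points.x, points.y, s=6, alpha=0.5)
        lim = (0, max(float(np.max(points.x)), float(np.max(points.y))) * 1.1)
        ax.plot(lim, lim, "k--", lw=0.5)
        ax.set_xlim(lim)
        ax.set_ylim(lim)
        ax.set_xlabel("RR(N) (ms)")
        ax.set_ylabel("RR(N+1) (ms)")
        ax.set_title(f"RR-Lorenz plot: {record.record_id}")
        p = out / f"{record.record_id}_lorenz.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        written.append(p)
        csv = out / f"{record.record_id}_lorenz.csv"
        np.savetxt(csv, np.column_stack([points.x, points.y]), delimiter=",",
                   header="x_ms,y_ms", comments="")
        written.append(csv)

    rr_ms = result.rr_intervals / record.fs * 1000.0
    summary = {
        "record_id": record.record_id,
        "fs": record.fs,
        "n_detections": len(result.detections),
        "n_searchback": sum(d.via_searchback for d in result.detections),
        "n_abnormal_regions": len(regions),
        "regions": [asdict(r) for r in regions],
        "rr_ms": {
            "n": int(len(rr_ms)),
            "mean": float(np.mean(rr_ms)) if len(rr_ms) else None,
            "sd": float(np.std(rr_ms)) if len(rr_ms) else None,
            "min": float(np.min(rr_ms)) if len(rr_ms) else None,
            "max": float(np.max(rr_ms)) if len(rr_ms) else None,
        },
    }
    p = out / f"{record.record_id}_summary.json"
    p.write_text(json.dumps(summary, indent=2))
    written.append(p)
    return written
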