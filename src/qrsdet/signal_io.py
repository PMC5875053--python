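"""ECG record I/O and synthetic signal generation.

Reads and writes records in the PhysioNet WFDB layout (``.hea`` header,
``.dat`` signal, ``.atr`` beat annotations) as used by the MIT-BIH
Arrhythmia Database, plus a plain CSV fallback, and generates seeded
synthetic ECG with ground-truth beat locations.

The WFDB support is deliberately minimal but faithful: signal formats 8,
16, 80 and 212 are read, format 16 is written, and annotation files use
the MIT annotation byte format (including SKIP/NUM/SUB/CHN/AUX pseudo
annotation handling).
"""
from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BeatAnnotations",
    "EcgRecord",
    "SyntheticSpec",
    "read_record",
    "read_annotations",
    "write_record",
    "write_annotations",
    "read_csv_record",
    "generate_synthetic",
    "ANNOTATION_SYMBOLS",
    "BEAT_SYMBOLS",
]

# MIT annotation code -> display symbol (beat and common non-beat codes).
ANNOTATION_SYMBOLS: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
_SYMBOL_CODES = {s: c for c, s in ANNOTATION_SYMBOLS.items()}

#: Symbols that denote an actual heartbeat (QRS complex) rather than a
#: rhythm change, artifact or other non-beat event.
BEAT_SYMBOLS: frozenset[str] = frozenset(
    "N L R a V F J A S E j / Q B e n f r".split()
)


class WfdbFormatError(ValueError):
    """Raised for malformed or unsupported WFDB header/signal content."""


@dataclass
class BeatAnnotations:
    """Reference beat annotations: 0-based sample indices plus type codes."""

    indices: np.ndarray
    codes: list[str]

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if len(self.indices) != len(self.codes):
            raise ValueError("indices and codes must have equal length")
        if len(self.indices) > 1 and not np.all(np.diff(self.indices) > 0):
            raise ValueError("annotation indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    def beats_only(self) -> "BeatAnnotations":
        """Return only annotations whose code is a beat code."""
        keep = [i for i, c in enumerate(self.codes) if c in BEAT_SYMBOLS]
        return BeatAnnotations(self.indices[keep],
                               [self.codes[i] for i in keep])


@dataclass
class EcgRecord:
    """A (possibly multi-channel) ECG time series with sampling rate.

    ``channels`` holds equal-length 1-D arrays in physical units (mV) when
    the source provides calibration, otherwise raw ADC counts.
    """

    record_id: str
    fs: float
    channels: list[np.ndarray]
    channel_names: list[str] = field(default_factory=list)
    annotations: BeatAnnotations | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.channels = [np.asarray(c, dtype=float) for c in self.channels]
        if not self.channels:
            raise ValueError("record must contain at least one channel")
        n = len(self.channels[0])
        if n < 1 or any(len(c) != n for c in self.channels):
            raise ValueError("all channels must share the same length >= 1")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(len(self.channels))]

    @property
    def n_samples(self) -> int:
        return len(self.channels[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, selector: int | str = 0) -> np.ndarray:
        """Return one channel by index or name."""
        if isinstance(selector, str):
            try:
                selector = self.channel_names.index(selector)
            except ValueError:
                raise KeyError(f"no channel named {selector!r}; "
                               f"have {self.channel_names}") from None
        return self.channels[selector]


# ---------------------------------------------------------------------------
# WFDB header / signal reading
# ---------------------------------------------------------------------------

def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise WfdbFormatError(f"{hea_path}: empty header")
    top = lines[0].split()
    if len(top) < 2:
        raise WfdbFormatError(f"{hea_path}: malformed record line {lines[0]!r}")
    record_name = top[0].split("/")[0]
    nsig = int(top[1])
    fs = float(top[2].split("/")[0]) if len(top) > 2 else 250.0
    nsamp = int(top[3]) if len(top) > 3 else 0
    if nsig < 1:
        raise WfdbFormatError(f"{hea_path}: record declares no signals")
    if len(lines) - 1 < nsig:
        raise WfdbFormatError(f"{hea_path}: header declares {nsig} signals "
                              f"but lists {len(lines) - 1}")
    sigs = []
    for ln in lines[1:1 + nsig]:
        tok = ln.split()
        if len(tok) < 2:
            raise WfdbFormatError(f"{hea_path}: malformed signal line {ln!r}")
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain_tok = tok[2] if len(tok) > 2 else "200"
        units = "mV"
        if "/" in gain_tok:
            gain_tok, units = gain_tok.split("/", 1)
        baseline = None
        if "(" in gain_tok:
            gain_tok, base_tok = gain_tok.split("(", 1)
            baseline = int(base_tok.rstrip(")"))
        gain = float(gain_tok) if gain_tok else 0.0
        if gain == 0.0:
            gain = 200.0  # WFDB default for uncalibrated signals
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(sigs)}"
        sigs.append({"file": tok[0], "fmt": fmt, "gain": gain,
                     "baseline": baseline, "units": units, "desc": desc})
    return record_name, nsig, fs, nsamp, sigs


def _decode_212(data: bytes, n_values: int) -> np.ndarray:
    """Decode WFDB format 212: two 12-bit two's-complement samples per 3 bytes."""
    b = np.frombuffer(data, dtype=np.uint8)
    n_triplets = len(b) // 3
    b = b[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(n_triplets * 2, dtype=np.int32)
    out[0::2] = s0
    out[1::2] = s1
    out[out > 2047] -= 4096
    return out[:n_values]


def _read_dat(path: Path, fmt: str, nsig: int, nsamp: int) -> np.ndarray:
    data = path.read_bytes()
    if fmt == "212":
        total = nsamp * nsig if nsamp else (len(data) // 3) * 2
        flat = _decode_212(data, total)
    elif fmt == "16":
        flat = np.frombuffer(data, dtype="<i2").astype(np.int32)
    elif fmt == "80":
        flat = np.frombuffer(data, dtype=np.uint8).astype(np.int32) - 128
    elif fmt == "8":
        # first differences, 8-bit signed
        flat = np.cumsum(np.frombuffer(data, dtype=np.int8).astype(np.int32))
    else:
        raise WfdbFormatError(f"unsupported WFDB signal format {fmt!r}")
    usable = (len(flat) // nsig) * nsig
    if nsamp:
        usable = min(usable, nsamp * nsig)
    if usable == 0:
        raise WfdbFormatError(f"{path}: no decodable samples")
    return flat[:usable].reshape(-1, nsig)


def read_record(path: str | Path, channel: int | str | None = None) -> EcgRecord:
    """Read a WFDB record (``.hea`` + ``.dat`` and, if present, ``.atr``).

    Parameters
    ----------
    path:
        Path to the header file or the record's base name (with or without
        the ``.hea`` extension).
    channel:
        If given, keep only this channel (by index or header description).

    Returns
    -------
    EcgRecord
        Samples converted to physical units using each signal's gain and
        baseline; every annotation in the ``.atr`` file is attached
        (beat/non-beat filtering is left to the evaluation stage).
    """
    base = Path(path)
    if base.suffix == ".hea":
        base = base.with_suffix("")
    hea = base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    record_name, nsig, fs, nsamp, sigs = _parse_header(hea)

    fmts = {s["fmt"] for s in sigs}
    files = {s["file"] for s in sigs}
    if len(fmts) > 1 or len(files) > 1:
        raise WfdbFormatError(f"{hea}: multiplexed multi-file/multi-format "
                              "records are not supported")
    dat = base.parent / sigs[0]["file"]
    if not dat.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat}")
    raw = _read_dat(dat, sigs[0]["fmt"], nsig, nsamp)

    channels = [(raw[:, i] - sigs[i]["baseline"]) / sigs[i]["gain"]
                for i in range(nsig)]
    names = [s["desc"] for s in sigs]

    annotations = None
    atr = base.with_suffix(".atr")
    if atr.exists():
        annotations = read_annotations(atr)

    rec = EcgRecord(record_name, fs, channels, names, annotations)
    if channel is not None:
        idx = (rec.channel_names.index(channel)
               if isinstance(channel, str) else channel)
        rec = EcgRecord(record_name, fs, [rec.channels[idx]],
                        [rec.channel_names[idx]], annotations)
    return rec


def read_annotations(path: str | Path) -> BeatAnnotations:
    """Read an MIT-format annotation file (e.g. ``.atr``).

    Returns every annotation (0-based sample indices) with its display
    symbol; pseudo-annotations (SKIP, NUM, SUB, CHN, AUX) are consumed but
    not emitted.
    """
    data = Path(path).read_bytes()
    indices: list[int] = []
    codes: list[str] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:  # end of file
            break
        if code == 59:  # SKIP: 4-byte interval follows (high word first)
            if interval == 0:
                if i + 3 >= len(data):
                    raise WfdbFormatError(f"{path}: truncated SKIP")
                high = data[i] | (data[i + 1] << 8)
                low = data[i + 2] | (data[i + 3] << 8)
                i += 4
                delta = (high << 16) | low
                if delta >= 1 << 31:
                    delta -= 1 << 32
                t += delta
            else:
                t += interval
        elif code in (60, 61, 62):  # NUM / SUB / CHN: value in interval
            continue
        elif code == 63:  # AUX: interval = byte count, padded to even
            i += interval + (interval & 1)
        else:
            t += interval
            indices.append(t)
            codes.append(ANNOTATION_SYMBOLS.get(code, "?"))
    return BeatAnnotations(np.asarray(indices, dtype=np.int64), codes)


# ---------------------------------------------------------------------------
# WFDB writing (fixtures, detector output)
# ---------------------------------------------------------------------------

def write_record(record: EcgRecord, base_path: str | Path,
                 gain: float = 200.0) -> Path:
    """Write ``record`` as a WFDB format-16 signal with matching header.

    Samples are quantised to ``round(value * gain)`` ADC counts (baseline
    0), so a round-trip read reproduces the signal to 1/gain precision.
    Annotations, when present, are written to a ``.atr`` file alongside.
    """
    base = Path(base_path)
    if base.suffix == ".hea":
        base = base.with_suffix("")
    base.parent.mkdir(parents=True, exist_ok=True)
    nsig = len(record.channels)
    n = record.n_samples
    counts = np.empty((n, nsig), dtype="<i2")
    for i, ch in enumerate(record.channels):
        q = np.clip(np.round(ch * gain), -32768, 32767)
        counts[:, i] = q.astype("<i2")
    dat_name = base.name + ".dat"
    lines = [f"{base.name} {nsig} {record.fs:g} {n}"]
    for i in range(nsig):
        lines.append(f"{dat_name} 16 {gain:g}(0)/mV 16 0 "
                     f"{counts[0, i]} 0 0 {record.channel_names[i]}")
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    base.with_suffix(".dat").write_bytes(counts.tobytes())
    if record.annotations is not None:
        write_annotations(record.annotations, base.with_suffix(".atr"))
    return base.with_suffix(".hea")


def write_annotations(ann: BeatAnnotations, path: str | Path) -> Path:
    """Write annotations in the MIT byte format readable by :func:`read_annotations`."""
    out = bytearray()
    prev = 0
    for idx, sym in zip(ann.indices, ann.codes):
        code = _SYMBOL_CODES.get(sym, 13)  # unknown symbols -> Q
        delta = int(idx) - prev
        if delta > 1023:
            out += struct.pack("<H", 59 << 10)
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
            prev = int(idx)
            out += struct.pack("<H", (code << 10) | 0)
        else:
            prev = int(idx)
            out += struct.pack("<H", (code << 10) | delta)
    out += struct.pack("<H", 0)
    p = Path(path)
    p.write_bytes(bytes(out))
    return p


def read_csv_record(path: str | Path, fs: float,
                    record_id: str | None = None) -> EcgRecord:
    """Read an ad-hoc ``sample_index,value[,value...]`` CSV signal.

    A header row is tolerated; ``fs`` must be supplied by the caller.
    """
    arr = np.genfromtxt(path, delimiter=",", skip_header=0)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    if np.isnan(arr[0]).any():  # header row
        arr = arr[1:]
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two CSV columns "
                         "(sample_index,value)")
    channels = [arr[:, j] for j in range(1, arr.shape[1])]
    return EcgRecord(record_id or Path(path).stem, fs, channels)


# ---------------------------------------------------------------------------
# Synthetic ECG generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic ECG record with ground-truth beats.

    The signal is a sum of per-beat Gaussian templates (a narrow QRS bump
    plus smaller, broader P and T waves), sinusoidal baseline drift,
    powerline interference and white noise.  The same (spec, seed) pair
    reproduces the identical signal bit for bit.
    """

    duration_s: float = 30.0
    fs: float = 360.0
    heart_rate_bpm: float = 75.0
    rr_jitter_frac: float = 0.05
    qrs_amp: float = 1.0
    p_amp: float = 0.15
    t_amp: float = 0.3
    drift_amp: float = 0.1
    drift_freq_hz: float = 0.3
    powerline_amp: float = 0.05
    powerline_freq_hz: float = 50.0
    noise_sd: float = 0.02
    dropped_beats: tuple[int, ...] = ()
    attenuated_beats: Mapping[int, float] = field(default_factory=dict)
    seed: int = 0

    # template shape constants (seconds)
    qrs_sigma_s: float = 0.025
    p_sigma_s: float = 0.035
    p_offset_s: float = -0.16
    t_sigma_s: float = 0.06
    t_offset_s: float = 0.25

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0 or self.heart_rate_bpm <= 0:
            raise ValueError("duration_s, fs and heart_rate_bpm must be positive")
        if 60.0 / self.heart_rate_bpm < 6 * self.qrs_sigma_s:
            raise ValueError("heart rate too high: QRS templates would overlap")
        if self.rr_jitter_frac < 0 or self.noise_sd < 0:
            raise ValueError("rr_jitter_frac and noise_sd must be non-negative")
        object.__setattr__(self, "dropped_beats", tuple(self.dropped_beats))
        object.__setattr__(self, "attenuated_beats",
                           dict(self.attenuated_beats))


def _add_gaussian(signal: np.ndarray, fs: float, center_s: float,
                  amp: float, sigma_s: float) -> None:
    # add a truncated (±5 sigma) Gaussian bump in place
    lo = max(0, int(np.floor((center_s - 5 * sigma_s) * fs)))
    hi = min(len(signal), int(np.ceil((center_s + 5 * sigma_s) * fs)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    signal[lo:hi] += amp * np.exp(-0.5 * ((t - center_s) / sigma_s) ** 2)


def generate_synthetic(spec: SyntheticSpec) -> EcgRecord:
    """Generate a synthetic single-channel ECG record from ``spec``.

    Beat centers are placed starting at half the nominal RR interval and
    advance by RR intervals jittered multiplicatively; dropped beats are
    removed *after* placement so the remaining rhythm keeps the RR gap,
    and attenuated beats scale only the QRS bump (P/T unchanged).  The
    ground-truth annotation indices are the QRS template centers.
    """
    rng = np.random.default_rng(spec.seed)
    mean_rr = 60.0 / spec.heart_rate_bpm
    centers: list[float] = []
    t = 0.5 * mean_rr
    while t < spec.duration_s:
        centers.append(t)
        step = mean_rr
        if spec.rr_jitter_frac > 0:
            step *= max(0.3, 1.0 + spec.rr_jitter_frac * rng.standard_normal())
        else:
            rng.standard_normal()  # keep the stream aligned across specs
        t += step

    n = int(round(spec.duration_s * spec.fs))
    sig = np.zeros(n)
    ann_indices: list[int] = []
    for k, c in enumerate(centers):
        if k in spec.dropped_beats:
            continue
        scale = float(spec.attenuated_beats.get(k, 1.0))
        _add_gaussian(sig, spec.fs, c, spec.qrs_amp * scale, spec.qrs_sigma_s)
        _add_gaussian(sig, spec.fs, c + spec.p_offset_s, spec.p_amp,
                      spec.p_sigma_s)
        _add_gaussian(sig, spec.fs, c + spec.t_offset_s, spec.t_amp,
                      spec.t_sigma_s)
        idx = int(round(c * spec.fs))
        if 0 <= idx < n:
            ann_indices.append(idx)

    tt = np.arange(n) / spec.fs
    if spec.drift_amp:
        sig += spec.drift_amp * np.sin(2 * np.pi * spec.drift_freq_hz * tt)
    if spec.powerline_amp:
        sig += spec.powerline_amp * np.sin(2 * np.pi * spec.powerline_freq_hz * tt)
    if spec.noise_sd:
        sig += spec.noise_sd * rng.standard_normal(n)

    ann = BeatAnnotations(np.asarray(ann_indices, dtype=np.int64),
                          ["N"] * len(ann_indices))
    return EcgRecord(f"synthetic-{spec.seed}", spec.fs, [sig], ["synth"], ann)
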