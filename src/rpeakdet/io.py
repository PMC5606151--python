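"""Reading and writing ECG records, beat annotations and detection files.

Supports PhysioNet WFDB single-segment records (``.hea`` + ``.dat``, signal
formats 16 and 212) and WFDB MIT-format annotation files, plus a plain CSV
dialect ``sample_index,amplitude_mV``.  All format handling lives here so the
algorithm modules only ever see :class:`EcgRecord`, :class:`BeatAnnotations`
and :class:`RPeakSet` containers holding physical units (mV) and 0-based
sample indices.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "EcgRecord",
    "BeatAnnotations",
    "RPeakSet",
    "read_record",
    "read_annotations",
    "write_record",
    "write_annotations",
    "write_detections",
    "read_detections",
    "BEAT_CODES",
    "SYMBOL_TO_CODE",
]


@dataclass(frozen=True)
class EcgRecord:
    """Uniformly sampled single-channel ECG in physical units (mV)."""

    record_id: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        bad = np.flatnonzero(~np.isfinite(samples))
        if bad.size:
            raise ValueError(
                f"record {self.record_id!r}: non-finite sample at index {bad[0]}"
            )

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class BeatAnnotations:
    """Sorted sample positions of reference heart beats with their symbols."""

    indices: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        indices = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", indices)
        if indices.size and np.any(np.diff(indices) <= 0):
            raise ValueError("beat indices must be strictly increasing")
        if indices.size and indices[0] < 0:
            raise ValueError("beat indices must be non-negative")
        if self.labels and len(self.labels) != indices.size:
            raise ValueError("labels must match indices in length")

    def __len__(self) -> int:
        return self.indices.size


@dataclass(frozen=True)
class RPeakSet:
    """Sorted sample positions of detected R-peaks."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        indices = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", indices)
        if indices.size and np.any(np.diff(indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if indices.size and indices[0] < 0:
            raise ValueError("peak indices must be non-negative")

    def __len__(self) -> int:
        return self.indices.size


# --------------------------------------------------------------------------
# WFDB annotation codes (MIT format).  Beat codes follow the standard WFDB
# annotation table; everything else (rhythm / signal-quality / wave marks)
# is a non-beat annotation and excluded from BeatAnnotations.
# --------------------------------------------------------------------------

_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

#: Annotation codes that mark a QRS complex (a beat).
BEAT_CODES = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38, 41})

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


# --------------------------------------------------------------------------
# Record reading
# --------------------------------------------------------------------------

def read_record(
    path: str | Path,
    channel: int = 0,
    fs: float | None = None,
    record_id: str | None = None,
) -> EcgRecord:
    """Read a WFDB record (header path or base name) or a CSV signal.

    Parameters
    ----------
    path
        Path to a WFDB ``.hea`` file (or record base name, extension
        optional) or to a ``.csv`` file with rows ``sample_index,amplitude``.
    channel
        Signal channel to extract; default 0 (the first channel).
    fs
        Sampling rate in Hz.  Required for CSV input, ignored for WFDB
        (taken from the header).
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        if fs is None:
            raise ValueError("fs must be given when reading a CSV signal")
        return _read_csv_record(path, fs, record_id)
    return _read_wfdb_record(path, channel, record_id)


def _read_csv_record(path: Path, fs: float, record_id: str | None) -> EcgRecord:
    if not path.exists():
        raise FileNotFoundError(path)
    data = np.genfromtxt(path, delimiter=",", skip_header=_csv_has_header(path))
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two CSV columns (sample_index, amplitude)")
    amplitudes = data[:, 1]
    return EcgRecord(record_id or path.stem, amplitudes, fs)


def _csv_has_header(path: Path) -> int:
    with open(path) as fh:
        first = fh.readline()
    try:
        float(first.split(",")[0])
        return 0
    except ValueError:
        return 1


def _read_wfdb_record(path: Path, channel: int, record_id: str | None) -> EcgRecord:
    header = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not header.exists():
        raise FileNotFoundError(header)
    lines = [
        ln.strip()
        for ln in header.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    name = rec_fields[0].split("/")[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
    n_samp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    if not 0 <= channel < n_sig:
        raise IndexError(f"channel {channel} out of range for {n_sig} signal(s)")

    sig_lines = lines[1 : 1 + n_sig]
    specs = [_parse_signal_line(ln) for ln in sig_lines]
    dat_name = specs[channel]["file"]
    fmt = specs[channel]["fmt"]
    if any(s["file"] != dat_name or s["fmt"] != fmt for s in specs):
        raise NotImplementedError("signals split across multiple .dat files")

    raw = (header.parent / dat_name).read_bytes()
    if fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2")
    elif fmt == 212:
        flat = _decode_212(raw)
    else:
        raise NotImplementedError(f"WFDB signal format {fmt} not supported")
    usable = (flat.size // n_sig) * n_sig
    adc = flat[:usable].reshape(-1, n_sig)[:, channel]
    if n_samp:
        adc = adc[:n_samp]

    gain = specs[channel]["gain"] or 200.0
    baseline = specs[channel]["baseline"]
    physical = (adc.astype(float) - baseline) / gain
    return EcgRecord(record_id or name, physical, fs)


def _parse_signal_line(line: str) -> dict:
    parts = line.split()
    fmt_field = parts[1]
    for sep in ("x", ":", "+"):
        fmt_field = fmt_field.split(sep)[0]
    gain, baseline, adczero = 200.0, None, 0
    if len(parts) > 2:
        gb = parts[2].split("/")[0]
        if "(" in gb:
            gain_s, base_s = gb.split("(")
            gain = float(gain_s)
            baseline = int(base_s.rstrip(")"))
        else:
            gain = float(gb)
    if len(parts) > 4:
        adczero = int(parts[4])
    if baseline is None:
        baseline = adczero
    return {"file": parts[0], "fmt": int(fmt_field), "gain": gain, "baseline": baseline}


def _decode_212(raw: bytes) -> np.ndarray:
    """Unpack WFDB format 212: two 12-bit samples per 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    b = b[: (b.size // 3) * 3].reshape(-1, 3).astype(np.int32)
    s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * b.shape[0], dtype=np.int32)
    out[0::2], out[1::2] = s1, s2
    out[out > 2047] -= 4096  # sign-extend 12 bits
    return out


# --------------------------------------------------------------------------
# Record writing (format 16 only; enough for fixtures and round-trips)
# --------------------------------------------------------------------------

def write_record(
    rec: EcgRecord,
    directory: str | Path,
    gain: float = 200.0,
    units: str = "mV",
) -> Path:
    """Write ``rec`` as a WFDB format-16 record pair; returns the header path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    adc = np.clip(np.rint(rec.samples * gain), -32768, 32767).astype("<i2")
    dat = directory / f"{rec.record_id}.dat"
    dat.write_bytes(adc.tobytes())
    fs_text = f"{rec.fs:g}"
    header = directory / f"{rec.record_id}.hea"
    header.write_text(
        f"{rec.record_id} 1 {fs_text} {len(rec)}\n"
        f"{rec.record_id}.dat 16 {gain:g}(0)/{units} 16 0 {adc[0]} 0 0 ECG\n"
    )
    return header


# --------------------------------------------------------------------------
# Annotations
# --------------------------------------------------------------------------

def read_annotations(path: str | Path, beats_only: bool = True) -> BeatAnnotations:
    """Read a WFDB MIT-format annotation file.

    Non-beat annotations (rhythm changes, quality marks, wave boundaries) are
    filtered out by default since beat-level evaluation counts QRS complexes
    only.  An annotation stream with no beat annotations yields an empty
    container and a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = path.read_bytes()
    indices: list[int] = []
    labels: list[str] = []
    time = 0
    i = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if code == 0 and interval == 0:  # EOF
            break
        if code == _SKIP:
            (high,) = struct.unpack_from("<H", raw, i)
            (low,) = struct.unpack_from("<H", raw, i + 2)
            i += 4
            time += (high << 16) | low
        elif code == _AUX:
            i += interval + (interval & 1)  # aux string, padded to even
        elif code in (_NUM, _SUB, _CHN):
            pass  # modifiers; no time advance
        else:
            time += interval
            if (not beats_only) or code in BEAT_CODES:
                indices.append(time)
                labels.append(_CODE_TO_SYMBOL.get(code, "Q"))
    if not indices:
        warnings.warn(f"{path}: no beat annotations found", stacklevel=2)
        return BeatAnnotations(np.empty(0, dtype=np.int64))
    return BeatAnnotations(np.asarray(indices), tuple(labels))


def write_annotations(
    ann: BeatAnnotations, path: str | Path, default_symbol: str = "N"
) -> Path:
    """Write beats as a WFDB MIT-format annotation file."""
    path = Path(path)
    out = bytearray()
    prev = 0
    labels = ann.labels or tuple(default_symbol for _ in range(len(ann)))
    for idx, sym in zip(ann.indices, labels):
        code = SYMBOL_TO_CODE.get(sym, 1)
        interval = int(idx) - prev
        if interval > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<HH", (interval >> 16) & 0xFFFF, interval & 0xFFFF)
            interval = 0
        out += struct.pack("<H", (code << 10) | interval)
        prev = int(idx)
    out += struct.pack("<H", 0)
    path.write_bytes(bytes(out))
    return path


# --------------------------------------------------------------------------
# Detections
# --------------------------------------------------------------------------

def write_detections(
    peaks: RPeakSet,
    path: str | Path,
    fs: float,
    format: str = "csv",
) -> Path:
    """Write detected peaks as CSV (``sample_index,time_s``) or WFDB annotations."""
    path = Path(path)
    if format == "csv":
        lines = ["sample_index,time_s"]
        lines += [f"{int(i)},{int(i) / fs:.6f}" for i in peaks.indices]
        path.write_text("\n".join(lines) + "\n")
        return path
    if format == "wfdb-annotation":
        ann = BeatAnnotations(peaks.indices, tuple("N" for _ in range(len(peaks))))
        return write_annotations(ann, path)
    raise ValueError(f"unknown detection format {format!r}")


def read_detections(path: str | Path) -> RPeakSet:
    """Read a detection CSV written by :func:`write_detections`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        rows = [ln.strip() for ln in fh if ln.strip()]
    indices = [int(r.split(",")[0]) for r in rows[1:]]
    return RPeakSet(np.asarray(indices, dtype=np.int64))
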