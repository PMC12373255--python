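"""Reading MIT-style ECG records and turning them into labelled beat windows.

Implements the subset of the WFDB conventions the arrhythmia corpus uses:
text headers (``.hea``), format-212 signal files (``.dat``, two 12-bit
samples packed in three bytes) and MIT annotation files (``.atr``).
Writers for all three exist primarily so tests can round-trip synthetic
records.

Coordinates are 0-based sample indices; beat windows are half-open and
centred on the annotation fiducial (floor(W/2) samples before it).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .synth import BeatSet

__all__ = [
    "EcgRecord", "read_record", "extract_beats", "save_beatset",
    "load_beatset", "write_wfdb_record", "MLII_RECORD_IDS", "BEAT_SYMBOLS",
]

# the arrhythmia-corpus records whose header names an MLII channel
MLII_RECORD_IDS = (
    "100", "101", "103", "105", "106", "107", "108", "109", "111", "112",
    "113", "114", "115", "116", "117", "119", "121", "122", "123", "124",
    "200", "201", "202", "203", "205", "208", "210", "212", "213", "214",
    "215", "217", "219", "220", "221", "222", "223", "228", "230", "231",
    "232", "233", "234",
)

BEAT_SYMBOLS = frozenset("NLRaVFJASEj/Q!exfQn")  # annotation symbols that mark beats

# MIT annotation code <-> symbol (subset of the standard table)
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "e", 33: "n", 34: "x",
    35: "f", 36: "(", 37: ")", 38: "r",
}
_SYMBOL_TO_CODE = {v: k for k, v in _CODE_TO_SYMBOL.items()}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


class RecordIOError(IOError):
    pass


@dataclass
class EcgRecord:
    record_id: str
    samples: np.ndarray          # mV
    fs: float
    channel_name: str
    ann_positions: np.ndarray    # sample indices, strictly increasing
    ann_symbols: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.ann_positions = np.asarray(self.ann_positions, dtype=np.int64)
        self.ann_symbols = np.asarray(self.ann_symbols, dtype=object)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.ann_positions) != len(self.ann_symbols):
            raise ValueError("annotation positions/symbols length mismatch")
        if len(self.ann_positions):
            if np.any(np.diff(self.ann_positions) <= 0):
                raise ValueError("annotation positions must be strictly increasing")
            if self.ann_positions[0] < 0 or \
                    self.ann_positions[-1] >= len(self.samples):
                raise ValueError("annotation positions outside the record")


# ---------------------------------------------------------------------------
# header
# ---------------------------------------------------------------------------

def _parse_header(path: Path):
    lines = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise RecordIOError(f"{path}: empty header")
    rec = lines[0].split()
    record_name = rec[0].split("/")[0]
    nsig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    nsamp = int(rec[3]) if len(rec) > 3 else None
    signals = []
    for ln in lines[1:1 + nsig]:
        f = ln.split()
        fmt = f[1].split("x")[0].split(":")[0].split("+")[0]
        gain_field = f[2] if len(f) > 2 else "200"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain = float(gain_part[:gain_part.index("(")])
            baseline = int(gain_part[gain_part.index("(") + 1:gain_part.index(")")])
        else:
            gain = float(gain_part)
            baseline = None
        adc_zero = int(f[4]) if len(f) > 4 else 0
        desc = " ".join(f[8:]) if len(f) > 8 else f"sig{len(signals)}"
        signals.append({
            "file": f[0], "fmt": fmt, "gain": gain if gain != 0 else 200.0,
            "baseline": baseline if baseline is not None else adc_zero,
            "desc": desc,
        })
    return record_name, nsig, fs, nsamp, signals


# ---------------------------------------------------------------------------
# format 212 signal payload
# ---------------------------------------------------------------------------

def _read_dat_212(path: Path, nsig: int, nsamp: int | None) -> np.ndarray:
    raw = np.frombuffer(path.read_bytes(), dtype=np.uint8)
    if len(raw) % 3:
        raw = raw[: 3 * (len(raw) // 3)]
    b0, b1, b2 = raw[0::3].astype(np.int64), raw[1::3].astype(np.int64), \
        raw[2::3].astype(np.int64)
    s0 = ((b1 & 0x0F) << 8) | b0
    s1 = ((b1 & 0xF0) << 4) | b2
    s0[s0 > 2047] -= 4096
    s1[s1 > 2047] -= 4096
    flat = np.empty(2 * len(s0), dtype=np.int64)
    flat[0::2], flat[1::2] = s0, s1
    total = (len(flat) // nsig) * nsig
    sig = flat[:total].reshape(-1, nsig)
    if nsamp is not None:
        if len(sig) < nsamp:
            raise RecordIOError(f"{path}: truncated format-212 payload "
                                f"({len(sig)} < {nsamp} samples)")
        sig = sig[:nsamp]
    return sig


def _write_dat_212(path: Path, adc: np.ndarray) -> None:
    flat = adc.reshape(-1).astype(np.int64)
    if len(flat) % 2:
        flat = np.concatenate([flat, [0]])
    u = np.where(flat < 0, flat + 4096, flat)
    s0, s1 = u[0::2], u[1::2]
    out = np.empty(3 * len(s0), dtype=np.uint8)
    out[0::3] = s0 & 0xFF
    out[1::3] = ((s0 >> 8) & 0x0F) | (((s1 >> 8) & 0x0F) << 4)
    out[2::3] = s1 & 0xFF
    path.write_bytes(out.tobytes())


# ---------------------------------------------------------------------------
# MIT annotation files
# ---------------------------------------------------------------------------

def _read_annotations(path: Path):
    raw = path.read_bytes()
    positions, symbols = [], []
    t = 0
    i = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code, interval = word >> 10, word & 0x3FF
        if code == 0 and interval == 0:      # EOF
            break
        if code == _SKIP and interval == 0:  # long interval in next 4 bytes
            hi = raw[i] | (raw[i + 1] << 8)
            lo = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            t += (hi << 16) | lo
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += interval + (interval & 1)   # aux string, padded to even
            continue
        t += interval
        positions.append(t)
        symbols.append(_CODE_TO_SYMBOL.get(code, "Q"))
    return np.array(positions, dtype=np.int64), np.array(symbols, dtype=object)


def _write_annotations(path: Path, positions, symbols) -> None:
    out = bytearray()
    prev = 0
    for pos, sym in zip(positions, symbols):
        delta = int(pos) - prev
        prev = int(pos)
        code = _SYMBOL_TO_CODE.get(str(sym))
        if code is None:
            raise ValueError(f"no annotation code for symbol {sym!r}")
        if delta >= 1024:
            out += (( _SKIP << 10) & 0xFFFF).to_bytes(2, "little")
            out += ((delta >> 16) & 0xFFFF).to_bytes(2, "little")
            out += (delta & 0xFFFF).to_bytes(2, "little")
            delta = 0
        out += (((code << 10) | delta) & 0xFFFF).to_bytes(2, "little")
    out += b"\x00\x00"
    path.write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def write_wfdb_record(directory, record_id: str, signals_mv: np.ndarray,
                      fs: float, channel_names, ann_positions, ann_symbols,
                      gain: float = 200.0, baseline: int = 0) -> Path:
    """Write a (header, format-212 dat, annotation) triplet; returns hea path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    signals_mv = np.atleast_2d(np.asarray(signals_mv, dtype=np.float64))
    if signals_mv.shape[0] < signals_mv.shape[1]:
        signals_mv = signals_mv.T  # (nsamp, nsig)
    nsamp, nsig = signals_mv.shape
    adc = np.clip(np.rint(signals_mv * gain + baseline), -2048, 2047).astype(np.int64)
    _write_dat_212(directory / f"{record_id}.dat", adc)
    lines = [f"{record_id} {nsig} {fs:g} {nsamp}"]
    for ch in range(nsig):
        lines.append(f"{record_id}.dat 212 {gain:g}({baseline})/mV 12 {baseline} "
                     f"{adc[0, ch]} 0 0 {channel_names[ch]}")
    (directory / f"{record_id}.hea").write_text("\n".join(lines) + "\n")
    _write_annotations(directory / f"{record_id}.atr", ann_positions, ann_symbols)
    return directory / f"{record_id}.hea"


def read_record(path, channel_preference: str = "MLII",
                strict: bool = True, beats_only: bool = True) -> EcgRecord:
    """Read one record (``path`` is the ``.hea`` file or its stem).

    Returns the requested channel in mV with its beat annotations.  With
    ``strict=True`` a missing preferred channel is an error; otherwise the
    first channel is used with a warning.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise RecordIOError(f"header not found: {hea}")
    record_name, nsig, fs, nsamp, signals = _parse_header(hea)
    descs = [s["desc"] for s in signals]
    if channel_preference in descs:
        ch = descs.index(channel_preference)
    elif strict:
        raise RecordIOError(
            f"record {record_name}: channel {channel_preference!r} not found "
            f"(has {descs})")
    else:
        ch = 0
        warnings.warn(f"record {record_name}: channel {channel_preference!r} "
                      f"absent, using {descs[0]!r}")
    fmt = signals[ch]["fmt"]
    if fmt != "212":
        raise RecordIOError(f"record {record_name}: unsupported format {fmt}")
    dat = hea.parent / signals[ch]["file"]
    if not dat.exists():
        raise RecordIOError(f"record {record_name}: signal file missing: {dat}")
    adc = _read_dat_212(dat, nsig, nsamp)
    mv = (adc[:, ch] - signals[ch]["baseline"]) / signals[ch]["gain"]
    atr = hea.with_suffix(".atr")
    if atr.exists():
        pos, sym = _read_annotations(atr)
    else:
        pos = np.array([], dtype=np.int64)
        sym = np.array([], dtype=object)
    if beats_only and len(pos):
        keep = np.array([s in BEAT_SYMBOLS for s in sym])
        pos, sym = pos[keep], sym[keep]
    inside = (pos >= 0) & (pos < len(mv))
    return EcgRecord(record_name, mv, fs, descs[ch], pos[inside], sym[inside])


def extract_beats(record: EcgRecord, window_len: int = 300,
                  keep_symbols=frozenset({"N", "A", "V", "L", "R"}),
                  patient_id: str | None = None) -> tuple[BeatSet, int]:
    """Windows centred on annotation fiducials; returns (BeatSet, dropped).

    A window spans [pos - floor(W/2), pos + W - floor(W/2)); annotations
    whose window would cross a record boundary are dropped and counted.
    """
    half = window_len // 2
    rows, labels = [], []
    dropped = 0
    n = len(record.samples)
    for pos, sym in zip(record.ann_positions, record.ann_symbols):
        if sym not in keep_symbols:
            continue
        lo, hi = pos - half, pos - half + window_len
        if lo < 0 or hi > n:
            dropped += 1
            continue
        rows.append(record.samples[lo:hi])
        labels.append(sym)
    pid = record.record_id if patient_id is None else patient_id
    X = np.array(rows) if rows else np.zeros((0, window_len))
    beatset = BeatSet(X, np.array(labels, dtype=object),
                      np.array([pid] * len(labels), dtype=object), fs=record.fs)
    return beatset, dropped


def save_beatset(beatset: BeatSet, path, extra_columns: dict | None = None) -> None:
    """CSV, one row per beat: label, patient_id[, extras], s0..s{W-1}."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    W = beatset.window_len
    extra_columns = extra_columns or {}
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "patient_id", *extra_columns,
                    *(f"s{i}" for i in range(W))])
        for i in range(len(beatset)):
            w.writerow([beatset.y[i], beatset.patient_ids[i],
                        *(extra_columns[k][i] for k in extra_columns),
                        *(repr(float(v)) for v in beatset.X[i])])


def load_beatset(path, fs: float = 360.0) -> BeatSet:
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh)
        header = next(reader)
        try:
            first_s = next(i for i, c in enumerate(header) if c == "s0")
        except StopIteration:
            raise RecordIOError(f"{path}: not a beat-set CSV (no s0 column)")
        W = len(header) - first_s
        rows, labels, pids = [], [], []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise RecordIOError(
                    f"{path}: row {lineno} has {len(row)} columns, "
                    f"expected {len(header)}")
            labels.append(row[0])
            pids.append(row[1])
            rows.append([float(v) for v in row[first_s:]])
    X = np.array(rows) if rows else np.zeros((0, W))
    return BeatSet(X, np.array(labels, dtype=object),
                   np.array(pids, dtype=object), fs=fs)


def load_cohort(directory, record_ids=None, window_len: int = 300,
                channel: str = "MLII") -> tuple[BeatSet, dict]:
    """Extract beats from a directory of records; returns (BeatSet, report)."""
    directory = Path(directory)
    if not directory.exists():
        raise RecordIOError(f"data directory not found: {directory}")
    if record_ids is None:
        record_ids = sorted(p.stem for p in directory.glob("*.hea"))
    parts, report = [], {"dropped": 0, "records": []}
    for rid in record_ids:
        rec = read_record(directory / rid, channel_preference=channel)
        bs, dropped = extract_beats(rec, window_len=window_len)
        parts.append(bs)
        report["dropped"] += dropped
        report["records"].append(rid)
    if not parts:
        return BeatSet(np.zeros((0, window_len)), np.array([], dtype=object),
                       np.array([], dtype=object)), report
    X = np.vstack([p.X for p in parts])
    y = np.concatenate([p.y for p in parts])
    pid = np.concatenate([p.patient_ids for p in parts])
    return BeatSet(X, y, pid, fs=parts[0].fs), report
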