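"""Minimal reader/writer for the WFDB (PhysioNet) record layout.

Supports exactly what this package needs: ``.hea`` headers, signal files in
format 212 (the MIT-BIH packing: two 12-bit samples per 3 bytes) and format
16 (little-endian int16), and the binary ``.atr`` beat annotation codec
(2-byte words with SKIP/NUM/SUB/CHN/AUX escapes).  Synthetic records are
written in format 16; MIT-BIH-layout records can be read directly.

This is a self-contained subset codec, not a full WFDB implementation:
multi-segment records, other signal formats, and calibration files are out
of scope.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .preprocessing import ECGRecord

__all__ = ["read_wfdb_record", "write_wfdb_record", "read_annotations",
           "write_annotations"]

#: standard annotation code <-> symbol table (beat and non-beat codes)
_CODE_TO_SYMBOL: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63

#: symbols that mark beats (vs rhythm changes, noise, comments)
BEAT_SYMBOLS = set("NLRaVFJASEj/Qfen!x") | {"r", "B"}

_PREFERRED_LEADS = ("MLII", "II")


def _parse_header(path: Path):
    lines = [
        ln.strip() for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    first = lines[0].split()
    record_name = first[0].split("/")[0]
    n_sig = int(first[1])
    fs = float(first[2].split("/")[0]) if len(first) > 2 else 250.0
    n_samples = int(first[3]) if len(first) > 3 else 0
    signals = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fname, fmt = tok[0], tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain_field = tok[2] if len(tok) > 2 else "200"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain = float(gain_part.split("(")[0])
            baseline = float(gain_part.split("(")[1].rstrip(")"))
        else:
            gain = float(gain_part)
            baseline = float(tok[4]) if len(tok) > 4 else 0.0  # adc zero
        if gain == 0:
            gain = 200.0
        description = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(signals)}"
        signals.append(
            {"file": fname, "format": int(fmt), "gain": gain,
             "baseline": baseline, "description": description}
        )
    return record_name, n_sig, fs, n_samples, signals


def _read_dat(path: Path, fmt: int, n_sig: int) -> np.ndarray:
    """All channels from one signal file, shape (n_samples, n_sig)."""
    raw = path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw, dtype="<i2")
        usable = (data.size // n_sig) * n_sig
        return data[:usable].reshape(-1, n_sig).astype(float)
    if fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (b.size // 3) * 3].reshape(-1, 3)
        s0 = ((b[:, 1].astype(np.int32) & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1].astype(np.int32) & 0xF0) << 4) | b[:, 2]
        pairs = np.empty(2 * b.shape[0], dtype=np.int32)
        pairs[0::2], pairs[1::2] = s0, s1
        pairs[pairs >= 2048] -= 4096  # 12-bit two's complement
        usable = (pairs.size // n_sig) * n_sig
        return pairs[:usable].reshape(-1, n_sig).astype(float)
    raise ValueError(f"unsupported signal format {fmt}")


def read_annotations(path: Path) -> list[tuple[int, str]]:
    """(sample_index, symbol) pairs from a binary MIT annotation file."""
    raw = path.read_bytes()
    out: list[tuple[int, str]] = []
    time = 0
    pos = 0
    pending_skip = 0
    while pos + 2 <= len(raw):
        (word,) = struct.unpack_from("<H", raw, pos)
        pos += 2
        if word == 0:
            break
        code, interval = word >> 10, word & 0x3FF
        if code == _SKIP:
            (hi,) = struct.unpack_from("<H", raw, pos)
            (lo,) = struct.unpack_from("<H", raw, pos + 2)
            pos += 4
            delta = (hi << 16) | lo
            if delta >= 1 << 31:
                delta -= 1 << 32
            pending_skip += delta
        elif code in (_NUM, _SUB, _CHN):
            continue
        elif code == _AUX:
            pos += interval + (interval & 1)
        else:
            time += interval + pending_skip
            pending_skip = 0
            out.append((time, _CODE_TO_SYMBOL.get(code, "Q")))
    return out


def write_annotations(path: Path, annotations: list[tuple[int, str]]) -> None:
    """Binary MIT annotation file; large gaps use the 4-byte SKIP escape."""
    buf = bytearray()
    prev = 0
    for sample, symbol in annotations:
        code = _SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise ValueError(f"no annotation code for symbol {symbol!r}")
        delta = sample - prev
        if delta < 0:
            raise ValueError("annotations must be in increasing sample order")
        if delta > 1023:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<H", (delta >> 16) & 0xFFFF)
            buf += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        buf += struct.pack("<H", (code << 10) | delta)
        prev = sample
    buf += struct.pack("<H", 0)
    path.write_bytes(bytes(buf))


def read_wfdb_record(directory, record_id: str,
                     annotator: str = "atr") -> ECGRecord:
    """One record from a WFDB-layout directory as a single-lead ECGRecord.

    Picks the first available of leads MLII / II, else the first channel.
    Signal values are converted to physical units via gain and baseline.
    Missing header, signal, or annotation files raise with the file named.
    """
    directory = Path(directory)
    hea = directory / f"{record_id}.hea"
    if not hea.exists():
        raise FileNotFoundError(f"missing header file: {hea}")
    _, n_sig, fs, _, signals = _parse_header(hea)

    chosen = 0
    for lead in _PREFERRED_LEADS:
        hits = [i for i, s in enumerate(signals) if s["description"] == lead]
        if hits:
            chosen = hits[0]
            break
    sig_meta = signals[chosen]
    dat = directory / sig_meta["file"]
    if not dat.exists():
        raise FileNotFoundError(f"missing signal file: {dat}")
    # channel position within the shared signal file
    file_channels = [i for i, s in enumerate(signals) if s["file"] == sig_meta["file"]]
    adc = _read_dat(dat, sig_meta["format"], len(file_channels))
    column = file_channels.index(chosen)
    physical = (adc[:, column] - sig_meta["baseline"]) / sig_meta["gain"]

    atr = directory / f"{record_id}.{annotator}"
    if not atr.exists():
        raise FileNotFoundError(f"missing annotation file: {atr}")
    ann = [(i, s) for i, s in read_annotations(atr)
           if s in BEAT_SYMBOLS and i < physical.size]
    return ECGRecord(
        record_id=record_id,
        signal=physical,
        fs=fs,
        beat_annotations=ann,
        lead_name=sig_meta["description"],
    )


def write_wfdb_record(directory, record_id: str, signal: np.ndarray, fs: float,
                      annotations: list[tuple[int, str]] | None = None,
                      lead_name: str = "MLII", gain: float = 200.0,
                      annotator: str = "atr") -> None:
    """Write a single-lead record as .hea + format-16 .dat (+ .atr)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    signal = np.asarray(signal, dtype=float)
    adc = np.clip(np.round(signal * gain), -32768, 32767).astype("<i2")
    dat_name = f"{record_id}.dat"
    (directory / dat_name).write_bytes(adc.tobytes())
    header = (
        f"{record_id} 1 {fs:g} {signal.size}\n"
        f"{dat_name} 16 {gain:g}(0)/mV 16 0 {adc[0] if adc.size else 0} 0 0 {lead_name}\n"
    )
    (directory / f"{record_id}.hea").write_text(header)
    if annotations is not None:
        write_annotations(directory / f"{record_id}.{annotator}", annotations)
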