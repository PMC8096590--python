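"""From annotated ECG recordings to the 5-class segment dataset.

Pipeline: map beat annotation symbols to the five AAMI classes, cut
10-second (M = 3600 sample) windows labeled by the majority class of the
beats they contain, Z-score each window, optionally augment minority
classes by translating window start points, split 70/10/20 stratified by
class, and (for robustness experiments) inject white noise at an exact
target SNR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AAMI_CLASSES",
    "ECGRecord",
    "Segment",
    "SegmentDataset",
    "map_to_aami",
    "segment_with_majority_label",
    "zscore_normalize",
    "augment_by_translation",
    "stratified_split",
    "add_white_noise",
]

AAMI_CLASSES: tuple[str, ...] = ("N", "S", "V", "F", "Q")

#: AAMI class per MIT-BIH mnemonic (the published mapping table)
_MNEMONIC_TO_AAMI: dict[str, str] = {
    # Normal: normal, nodal escape, atrial escape, left/right bundle branch block
    "NOR": "N", "NE": "N", "AE": "N", "LBBB": "N", "RBBB": "N",
    # Supraventricular ectopic: atrial premature (plain/aberrated), nodal and
    # supraventricular premature
    "AP": "S", "APB": "S", "APC": "S", "NP": "S", "SP": "S",
    # Ventricular ectopic: ventricular flutter wave, ventricular escape, PVC
    "VF": "V", "VE": "V", "PVC": "V",
    # Fusion of ventricular and normal
    "F": "F",
    # Unknown: unclassifiable, fusion of paced and normal, paced
    "UN": "Q", "FPN": "Q", "P": "Q",
}

#: standard single-character annotation symbols -> the mnemonics above
_CHAR_ALIASES: dict[str, str] = {
    "N": "NOR", "L": "LBBB", "R": "RBBB", "e": "AE", "j": "NE",
    "A": "AP", "a": "APC", "J": "NP", "S": "SP",
    "V": "PVC", "E": "VE", "!": "VF",
    "F": "F",
    "Q": "UN", "f": "FPN", "/": "P",
}

#: tie-break precedence for majority labeling: pathological classes beat N,
#: and among pathological classes V > S > F > Q (conservative toward disease)
_TIE_PRECEDENCE: dict[str, int] = {"V": 0, "S": 1, "F": 2, "Q": 3, "N": 4}

_warned_symbols: set[str] = set()


@dataclass
class ECGRecord:
    """One single-lead recording with beat annotations."""

    record_id: str
    signal: np.ndarray
    fs: float
    beat_annotations: list[tuple[int, str]] = field(default_factory=list)
    lead_name: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        idx = [i for i, _ in self.beat_annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotation indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= self.signal.size):
            raise ValueError("annotation index outside the signal")


@dataclass
class Segment:
    """One fixed-length window with its label and (optionally) CV."""

    samples: np.ndarray
    label: str
    cv: float | None = None
    record_id: str = ""
    start_index: int = 0


def map_to_aami(symbol: str) -> str | None:
    """AAMI class for one beat annotation symbol, or None if excluded.

    Accepts both table mnemonics ("PVC", "LBBB", ...) and the standard
    single-character symbols found in annotation files ("V", "L", ...).
    Unknown symbols (artifacts, rhythm changes, ...) are excluded with a
    one-time logged warning per symbol.
    """
    key = _CHAR_ALIASES.get(symbol, symbol)
    cls = _MNEMONIC_TO_AAMI.get(key)
    if cls is None and symbol not in _warned_symbols:
        _warned_symbols.add(symbol)
        logger.warning("annotation symbol %r not in the AAMI mapping; excluded", symbol)
    return cls


def _majority_label(classes: list[str]) -> str | None:
    if not classes:
        return None
    counts: dict[str, int] = {}
    for c in classes:
        counts[c] = counts.get(c, 0) + 1
    return min(counts, key=lambda c: (-counts[c], _TIE_PRECEDENCE[c]))


def segment_with_majority_label(
    record: ECGRecord, M: int = 3600, stride: int | None = None
) -> list[Segment]:
    """Cut sliding windows and label each by its majority AAMI beat class.

    Windows start at 0, stride, 2*stride, ...; the trailing partial window
    is dropped, and so is any window containing zero mapped beats (a
    majority label is undefined there).  Ties go to the pathological class
    (precedence V > S > F > Q over N).
    """
    stride = M if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = record.signal.size
    if n < M:
        return []
    ann = [(i, map_to_aami(s)) for i, s in record.beat_annotations]
    ann = [(i, c) for i, c in ann if c is not None]
    out: list[Segment] = []
    for start in range(0, n - M + 1, stride):
        inside = [c for i, c in ann if start <= i < start + M]
        label = _majority_label(inside)
        if label is None:
            continue
        out.append(
            Segment(
                samples=record.signal[start:start + M].copy(),
                label=label,
                record_id=record.record_id,
                start_index=start,
            )
        )
    return out


def zscore_normalize(x: np.ndarray) -> np.ndarray:
    """(x - mean) / sd; a constant window maps to the zero vector."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def augment_by_translation(
    segments_of_class: list[Segment],
    record_pool: dict[str, ECGRecord],
    target_count: int,
    seed: int,
    M: int = 3600,
    max_attempts_per_segment: int = 50,
) -> tuple[list[Segment], int]:
    """Grow a class to ``target_count`` by translating window start points.

    New windows are offset from existing ones by a uniform shift of
    magnitude in [M/8, M/2] samples (either direction), re-labeled by the
    majority rule and kept only when the label is preserved.  Returns the
    achieved list (originals first, unmodified) and a shortfall count
    (0 when the target was reached).
    """
    if target_count < len(segments_of_class):
        raise ValueError("target_count must be >= current count")
    if not segments_of_class:
        raise ValueError("no source segments for this class")
    out = list(segments_of_class)
    cls = segments_of_class[0].label
    rng = np.random.default_rng(seed)
    needed = target_count - len(out)
    attempts_left = max_attempts_per_segment * max(needed, 1)
    while len(out) < target_count and attempts_left > 0:
        attempts_left -= 1
        base = segments_of_class[rng.integers(len(segments_of_class))]
        record = record_pool[base.record_id]
        shift = int(rng.integers(M // 8, M // 2 + 1)) * (1 if rng.random() < 0.5 else -1)
        start = base.start_index + shift
        if start < 0 or start + M > record.signal.size:
            continue
        candidates = segment_with_majority_label(
            ECGRecord(
                record_id=record.record_id,
                signal=record.signal[start:start + M],
                fs=record.fs,
                beat_annotations=[
                    (i - start, s)
                    for i, s in record.beat_annotations
                    if start <= i < start + M
                ],
            ),
            M=M,
        )
        if not candidates or candidates[0].label != cls:
            continue
        seg = candidates[0]
        seg.record_id = record.record_id
        seg.start_index = start
        out.append(seg)
    shortfall = target_count - len(out)
    if shortfall:
        logger.warning("augmentation shortfall for class %s: %d missing", cls, shortfall)
    return out, shortfall


@dataclass
class SegmentDataset:
    """Array-of-segments container with per-segment split tags.

    ``segments`` holds the normalized windows (n, M); ``labels`` the AAMI
    classes; ``cv`` the rhythm feature; ``split`` one of
    {"train", "val", "test", ""}.
    """

    segments: np.ndarray
    labels: np.ndarray
    cv: np.ndarray
    split: np.ndarray
    record_ids: np.ndarray
    start_indices: np.ndarray

    def __post_init__(self) -> None:
        n = self.segments.shape[0]
        for name in ("labels", "cv", "split", "record_ids", "start_indices"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"field {name} length mismatch")

    def __len__(self) -> int:
        return int(self.segments.shape[0])

    def subset(self, split: str) -> "SegmentDataset":
        mask = self.split == split
        return SegmentDataset(
            segments=self.segments[mask],
            labels=self.labels[mask],
            cv=self.cv[mask],
            split=self.split[mask],
            record_ids=self.record_ids[mask],
            start_indices=self.start_indices[mask],
        )

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_id": np.arange(len(self)),
                "record_id": self.record_ids,
                "start_index": self.start_indices,
                "label": self.labels,
                "cv": self.cv,
                "split": self.split,
            }
        )

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    @classmethod
    def from_segments(cls, segments: list[Segment]) -> "SegmentDataset":
        return cls(
            segments=np.stack([np.asarray(s.samples, dtype=np.float32) for s in segments]),
            labels=np.asarray([s.label for s in segments], dtype=object),
            cv=np.asarray([0.0 if s.cv is None else s.cv for s in segments],
                          dtype=np.float32),
            split=np.asarray([""] * len(segments), dtype=object),
            record_ids=np.asarray([s.record_id for s in segments], dtype=object),
            start_indices=np.asarray([s.start_index for s in segments], dtype=int),
        )

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            segments=self.segments,
            labels=self.labels.astype(str),
            cv=self.cv,
            split=self.split.astype(str),
            record_ids=self.record_ids.astype(str),
            start_indices=self.start_indices,
        )

    @classmethod
    def load_npz(cls, path) -> "SegmentDataset":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                segments=z["segments"],
                labels=z["labels"].astype(object),
                cv=z["cv"],
                split=z["split"].astype(object),
                record_ids=z["record_ids"].astype(object),
                start_indices=z["start_indices"],
            )


def stratified_split(
    dataset: SegmentDataset,
    seed: int,
    test_fraction: float = 0.2,
    val_fraction_of_train: float = 0.125,
    min_per_class: int = 10,
) -> SegmentDataset:
    """Assign per-class train/val/test tags (net 70/10/20 by default).

    Each class is sampled separately: 20% of it becomes test, then 12.5% of
    the remaining 80% becomes validation.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    split = np.asarray([""] * len(dataset), dtype=object)
    for cls in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == cls)
        if idx.size < min_per_class:
            raise ValueError(
                f"class {cls!r} has only {idx.size} segments (< {min_per_class})"
            )
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        n_val = int(round(val_fraction_of_train * (idx.size - n_test)))
        split[idx[:n_test]] = "test"
        split[idx[n_test:n_test + n_val]] = "val"
        split[idx[n_test + n_val:]] = "train"
    return replace(dataset, split=split)


def add_white_noise(x: np.ndarray, snr_db: float, seed: int) -> np.ndarray:
    """Additive white Gaussian noise at an exact realized SNR.

    The drawn noise vector is rescaled to its own empirical power so that
    10*log10(P_signal / P_noise) equals ``snr_db`` to machine precision.
    ``snr_db = inf`` returns the signal unchanged.
    """
    x = np.asarray(x, dtype=float)
    p_signal = float(np.mean(x**2))
    if p_signal == 0.0:
        raise ValueError("zero-power signal: SNR undefined")
    if np.isinf(snr_db):
        return x.copy()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(x.shape)
    p_target = p_signal / 10.0 ** (snr_db / 10.0)
    noise *= np.sqrt(p_target / np.mean(noise**2))
    return x + noise
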