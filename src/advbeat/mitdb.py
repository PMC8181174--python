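"""MIT-BIH arrhythmia database handling: AAMI classes and the DS1/DS2 split.

The MIT-BIH arrhythmia database holds 48 half-hour two-lead ambulatory ECG
records sampled at 360 Hz from 47 patients (records 201 and 202 share a
patient). Beat annotations carry one-character symbols which the AAMI
EC57 practice groups into five superclasses: N (sinus-node origin),
S (supraventricular ectopic), V (ventricular ectopic), F (fusion) and
Q (unknown). The inter-patient evaluation protocol of de Chazal et al.
excludes the four paced records and splits the remaining 44 into a
training half (DS1) and a test half (DS2) with disjoint patients.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from . import wfdb_io

AAMI_CLASSES: tuple[str, ...] = ("N", "S", "V", "F", "Q")
N_CLASSES = 5

#: Beat-symbol -> AAMI superclass. Any symbol not listed here is not a
#: beat (rhythm/noise markers) or is excluded from the protocol.
SYMBOL_TO_AAMI: dict[str, str] = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "Q": "Q",
}

ALL_RECORDS: tuple[str, ...] = tuple(
    str(r) for r in (
        list(range(100, 110)) + list(range(111, 120)) + list(range(121, 125))
        + [200, 201, 202, 203, 205, 207, 208, 209, 210, 212, 213, 214, 215,
           217, 219, 220, 221, 222, 223, 228, 230, 231, 232, 233, 234]
    )
)

#: Paced records excluded by the AAMI-recommended practice.
PACED_RECORDS: frozenset[str] = frozenset({"102", "104", "107", "217"})

#: Test half of the de Chazal inter-patient protocol.
DS2_RECORDS: frozenset[str] = frozenset(
    str(r) for r in (100, 103, 105, 111, 113, 117, 121, 123, 200, 202, 210,
                     212, 213, 214, 219, 221, 222, 228, 231, 232, 233, 234)
)

#: Published per-symbol beat counts (DS1, DS2) of this split, used as
#: reference data for validating the mapping and the split accounting.
REFERENCE_SYMBOL_COUNTS: dict[str, tuple[int, int]] = {
    "N": (37951, 36304), "L": (3940, 4109), "R": (3760, 3456),
    "e": (16, 0), "j": (16, 213),
    "A": (810, 1730), "a": (100, 50), "J": (32, 51), "S": (2, 0),
    "V": (3673, 3207), "E": (105, 1),
    "F": (413, 388),
    "Q": (8, 7),
}


@dataclass(frozen=True)
class EcgRecord:
    """A two-lead ECG record at its native sampling rate."""

    record_id: str
    sampling_rate: float
    signal: np.ndarray  # T x 2, mV
    lead_names: tuple[str, str]

    def __post_init__(self) -> None:
        if self.signal.ndim != 2 or self.signal.shape[1] != 2:
            raise ValueError("EcgRecord requires a T x 2 signal")
        if self.sampling_rate <= 0 or self.signal.shape[0] == 0:
            raise ValueError("invalid sampling rate or empty signal")


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated R peak (0-based sample index) with its beat symbol."""

    sample_index: int
    symbol: str


@dataclass(frozen=True)
class DatasetSplit:
    ds1_records: frozenset[str]
    ds2_records: frozenset[str]
    excluded_paced: frozenset[str]


@dataclass(frozen=True)
class LabeledBeat:
    """A beat with its record, optional training subject ID and AAMI code."""

    record_id: str
    subject_id: int | None
    sample_index: int
    aami_class: int  # 0..4 indexing AAMI_CLASSES


def map_symbol_to_aami(symbol: str) -> int | None:
    """Map a one-character beat symbol to its AAMI class code (or None)."""
    cls = SYMBOL_TO_AAMI.get(symbol)
    return None if cls is None else AAMI_CLASSES.index(cls)


def read_record(path: str) -> EcgRecord:
    """Read a WFDB record (path with or without ``.hea``) at native rate."""
    hea = path if path.endswith(".hea") else path + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(hea)
    signal, fs, leads = wfdb_io.read_signals(hea)
    if signal.shape[1] != 2:
        raise wfdb_io.WfdbFormatError(
            f"expected 2 channels, found {signal.shape[1]}"
        )
    rid = os.path.basename(hea)[: -len(".hea")]
    return EcgRecord(rid, fs, signal, (leads[0], leads[1]))


def read_beat_annotations(path: str) -> list[BeatAnnotation]:
    """Read an ``.atr`` file keeping only mapped beat symbols, sorted."""
    atr = path if path.endswith(".atr") else path + ".atr"
    samples, symbols = wfdb_io.read_annotations(atr)
    beats = [
        BeatAnnotation(int(s), sym)
        for s, sym in zip(samples, symbols)
        if sym in SYMBOL_TO_AAMI
    ]
    beats.sort(key=lambda b: b.sample_index)
    return beats


def make_split() -> DatasetSplit:
    """The inter-patient DS1/DS2 partition of the 48 records."""
    ds2 = frozenset(DS2_RECORDS)
    paced = frozenset(PACED_RECORDS)
    ds1 = frozenset(ALL_RECORDS) - ds2 - paced
    return DatasetSplit(ds1, ds2, paced)


def assign_subject_ids(training_records: set[str] | frozenset[str]) -> dict[str, int]:
    """Distinct subject IDs 1..S in sorted-record-ID order (deterministic)."""
    if not training_records:
        raise ValueError("training_records must be nonempty")
    return {rid: i + 1 for i, rid in enumerate(sorted(training_records))}


def class_distribution(beats: list[LabeledBeat]) -> np.ndarray:
    """Integer beat counts per AAMI class (length 5)."""
    counts = np.zeros(N_CLASSES, dtype=np.int64)
    for b in beats:
        counts[b.aami_class] += 1
    return counts


def class_totals_from_symbol_counts(symbol_counts: dict[str, int]) -> dict[str, int]:
    """Aggregate per-symbol beat counts into AAMI-class totals.

    Symbols outside the beat mapping are ignored, mirroring how the
    annotation reader drops them.
    """
    totals = {c: 0 for c in AAMI_CLASSES}
    for sym, n in symbol_counts.items():
        cls = SYMBOL_TO_AAMI.get(sym)
        if cls is not None:
            totals[cls] += int(n)
    return totals


def label_beats(
    record_id: str,
    annotations: list[BeatAnnotation],
    subject_id: int | None = None,
) -> list[LabeledBeat]:
    """Attach AAMI codes (and optionally a subject ID) to beat annotations."""
    out = []
    for a in annotations:
        code = map_symbol_to_aami(a.symbol)
        if code is not None:
            out.append(LabeledBeat(record_id, subject_id, a.sample_index, code))
    return out


def scan_database(data_dir: str, records: list[str] | None = None) -> dict[str, dict[str, int]]:
    """Per-record beat-symbol counts for a local WFDB database copy."""
    records = list(records) if records is not None else list(ALL_RECORDS)
    out: dict[str, dict[str, int]] = {}
    for rid in records:
        anns = read_beat_annotations(os.path.join(data_dir, rid))
        counts: dict[str, int] = {}
        for a in anns:
            counts[a.symbol] = counts.get(a.symbol, 0) + 1
        out[rid] = counts
    return out


def write_split_manifest(path: str, split: DatasetSplit | None = None) -> None:
    """Emit the split + subject-ID assignment as a JSON manifest."""
    split = split or make_split()
    subj = assign_subject_ids(set(split.ds1_records))
    manifest = {
        rid: {
            "split": ("DS1" if rid in split.ds1_records
                      else "DS2" if rid in split.ds2_records else "excluded"),
            "subject_id": subj.get(rid),
        }
        for rid in ALL_RECORDS
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
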