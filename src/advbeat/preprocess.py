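"""Beat segmentation, resampling, baseline removal and RR-ratio features.

Each annotated heartbeat is cut from the record as the half-open sample
window ``[prev_R + 50, cur_R + 100)`` — anchoring the start to the
previous R peak keeps the full P-QRS-T complex inside the window across
changing heart rates, and gives the window-length identity
``L = RR + 50``. Windows are resampled to a fixed length of 128 samples
per channel, and each beat/channel is zero-meaned to suppress baseline
wander.

Rhythm is summarised by two unitless ratios of the current pre-RR
interval: against the record-wide mean pre-RR (normalising away each
subject's basal heart rate) and against the mean of the previous ten
pre-RR intervals (tracking slow heart-rate drift). Both are replicated
along the length axis and stacked with the beat into a 3 x 128 x 2 input
tensor (768 scalars).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .mitdb import BeatAnnotation, EcgRecord, LabeledBeat, map_symbol_to_aami

logger = logging.getLogger(__name__)

BEAT_LENGTH = 128
PRE_OFFSET = 50   # samples after the previous R peak
POST_OFFSET = 100  # samples after the current R peak
NEAR_WINDOW = 10  # pre-RR intervals in the local average


@dataclass(frozen=True)
class RawSegment:
    """A variable-length two-channel beat window (L = RR + 50)."""

    samples: np.ndarray  # L x 2
    prev_r: int
    cur_r: int
    record_id: str


@dataclass(frozen=True)
class RrRatios:
    pre_rr_ratio: float
    near_pre_rr_ratio: float


def segment_heartbeats(
    record: EcgRecord, annotations: list[BeatAnnotation]
) -> list[RawSegment]:
    """Cut one window per beat except the first (no previous R peak).

    Windows overrunning the record end are completed by edge-value
    replication; a window starting at or past the end is skipped with a
    warning.
    """
    if len(annotations) < 2:
        return []
    t = record.signal.shape[0]
    out: list[RawSegment] = []
    for prev, cur in zip(annotations, annotations[1:]):
        start = prev.sample_index + PRE_OFFSET
        stop = cur.sample_index + POST_OFFSET
        if start >= t:
            logger.warning(
                "record %s: beat at %d starts past record end, skipped",
                record.record_id, cur.sample_index,
            )
            continue
        window = record.signal[start:min(stop, t)]
        if stop > t:  # edge-replicate the tail
            pad = np.repeat(record.signal[-1:], stop - t, axis=0)
            window = np.concatenate([window, pad], axis=0)
        out.append(RawSegment(window, prev.sample_index, cur.sample_index,
                              record.record_id))
    return out


def resample_to_128(segment: RawSegment | np.ndarray) -> np.ndarray:
    """Linear-interpolation resampling of an L x 2 window to 128 x 2.

    Exact on affine signals and the identity when L = 128; endpoints are
    preserved.
    """
    samples = segment.samples if isinstance(segment, RawSegment) else np.asarray(segment)
    length = samples.shape[0]
    if length < 2:
        raise ValueError("segment must contain at least 2 samples")
    if length == BEAT_LENGTH:
        return samples.astype(np.float64, copy=True)
    grid = np.linspace(0.0, length - 1, BEAT_LENGTH)
    src = np.arange(length, dtype=np.float64)
    return np.stack(
        [np.interp(grid, src, samples[:, ch]) for ch in range(samples.shape[1])],
        axis=1,
    )


def remove_baseline(beats: np.ndarray, mode: str = "per_beat") -> np.ndarray:
    """Baseline removal on an (n, 128, 2) stack of resampled beats.

    ``per_beat`` (default) subtracts each beat/channel's own scalar mean,
    leaving every output beat exactly zero-mean. ``template`` subtracts
    the cross-beat mean waveform per channel instead (an alternative
    reading of averaging over heartbeat segments; it removes shared
    morphology rather than per-beat offsets, so it is not the default).
    """
    beats = np.asarray(beats, dtype=np.float64)
    if beats.ndim == 2:
        beats = beats[None]
    if beats.size == 0:
        raise ValueError("remove_baseline requires at least one beat")
    if mode == "per_beat":
        return beats - beats.mean(axis=1, keepdims=True)
    if mode == "template":
        return beats - beats.mean(axis=0, keepdims=True)
    raise ValueError(f"unknown baseline mode {mode!r}")


def compute_rr_ratios(
    annotations: list[BeatAnnotation],
    beat_index: int,
    sampling_rate: float | None = None,
) -> RrRatios:
    """Pre-RR ratio and near-pre-RR ratio for the beat at ``beat_index``.

    The pre-RR interval of beat i is ``R_i - R_{i-1}`` (samples; the
    ratios are unitless so the sampling rate is irrelevant and accepted
    only for interface symmetry). The first ratio divides by the mean of
    all pre-RR intervals in the record, the second by the mean of the
    previous ``min(10, available)`` pre-RR intervals, excluding the
    current one; with no previous interval the current interval itself is
    used (ratio 1.0).
    """
    del sampling_rate
    if beat_index < 1:
        raise ValueError("beat_index must be >= 1 (first beat has no pre-RR)")
    samples = np.asarray([a.sample_index for a in annotations], dtype=np.float64)
    intervals = np.diff(samples)
    cur = intervals[beat_index - 1]
    pre_ratio = cur / intervals.mean()
    prev = intervals[max(0, beat_index - 1 - NEAR_WINDOW): beat_index - 1]
    near_ratio = cur / prev.mean() if prev.size else 1.0
    return RrRatios(float(pre_ratio), float(near_ratio))


def assemble_input(beat: np.ndarray, ratios: RrRatios) -> np.ndarray:
    """Stack beat and replicated RR ratios into the 3 x 128 x 2 tensor."""
    beat = np.asarray(beat, dtype=np.float64)
    if beat.shape != (BEAT_LENGTH, 2):
        raise ValueError(f"beat must be {BEAT_LENGTH} x 2, got {beat.shape}")
    x = np.empty((3, BEAT_LENGTH, 2), dtype=np.float64)
    x[0] = beat
    x[1] = ratios.pre_rr_ratio
    x[2] = ratios.near_pre_rr_ratio
    return x


def preprocess_record(
    record: EcgRecord,
    annotations: list[BeatAnnotation],
    subject_id: int | None = None,
    baseline_mode: str = "per_beat",
) -> tuple[np.ndarray, list[LabeledBeat]]:
    """Full record pipeline -> (inputs (n, 3, 128, 2), labeled beats).

    Annotations whose symbol has no AAMI class are dropped before
    segmentation pairing, so RR intervals are measured between retained
    beats. The first retained beat yields no input (no previous R peak).
    """
    beats = [a for a in annotations if map_symbol_to_aami(a.symbol) is not None]
    segments = segment_heartbeats(record, beats)
    if not segments:
        return np.zeros((0, 3, BEAT_LENGTH, 2)), []
    resampled = np.stack([resample_to_128(s) for s in segments])
    fixed = remove_baseline(resampled, mode=baseline_mode)
    kept = {s.cur_r for s in segments}
    inputs, labeled = [], []
    j = 0
    for i, ann in enumerate(beats):
        if i == 0 or ann.sample_index not in kept:
            continue
        ratios = compute_rr_ratios(beats, i)
        inputs.append(assemble_input(fixed[j], ratios))
        labeled.append(
            LabeledBeat(record.record_id, subject_id, ann.sample_index,
                        map_symbol_to_aami(ann.symbol))
        )
        j += 1
    return np.stack(inputs), labeled


def flatten_for_encoder(x: np.ndarray) -> np.ndarray:
    """(n, 3, 128, 2) -> (n, 6, 128) channel layout for the 1-D encoder.

    The encoder's first 3x3 valid convolution spans the full 3-row axis,
    which is equivalent to a width-3 1-D convolution over 6 input
    channels ordered (row, lead).
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0]
    return x.transpose(0, 1, 3, 2).reshape(n, 6, BEAT_LENGTH)
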