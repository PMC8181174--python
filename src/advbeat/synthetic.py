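"""Synthetic multi-subject ECG records with controllable subject confounds.

Beats are rendered as sums of five Gaussian bumps (P, Q, R, S, T),
a transparent stand-in for real ECG morphology whose class and subject
effects can be dialled exactly. Each subject carries a basal RR interval
drawn uniformly from 0.6–1.1 s, per-wave amplitude jitter (±30%), width
jitter (±20%), per-lead gains, additive Gaussian noise and sinusoidal
baseline wander (~0.3 Hz) — the subject-specific morphology/rhythm
variability that makes inter-patient generalisation hard. A global
``confound_strength`` in [0, 1] scales all subject-specific deviations;
at 0 every subject is identical.

Class effects are stylised arrhythmia physiology: supraventricular
ectopic beats (S) arrive early (RR x 0.6) with an attenuated P wave;
ventricular ectopic beats (V) arrive early (RR x 0.55) with a widened
(x 2.2), taller (x 1.5) QRS, no P wave, and a compensatory pause
(RR x 1.4) on the following beat; normal beats carry ±5% RR jitter.
Ectopic prematurity is not fixed: each S/V beat's RR factor is jittered
±25% around its mean, reproducing the wide, overlapping pre-RR-ratio
spread real ectopic beats show, so rhythm alone does not give the class
away — S detection must lean on the (subject-confounded) P-wave
morphology, which is what makes the inter-patient problem non-trivial.
Records are 360 Hz, two-lead, and round-trip through the package's WFDB
writer/reader so the real-data ingestion path is exercised end to end.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from . import wfdb_io
from .mitdb import BeatAnnotation, EcgRecord, assign_subject_ids
from .preprocess import preprocess_record

FS = 360
WAVE_NAMES = ("P", "Q", "R", "S", "T")
# base bump heights (mV), widths (s), centres relative to the R peak (s)
BASE_AMPLITUDES = np.array([0.15, -0.10, 1.00, -0.15, 0.30])
BASE_WIDTHS = np.array([0.025, 0.010, 0.012, 0.010, 0.050])
BASE_CENTERS = np.array([-0.200, -0.035, 0.000, 0.035, 0.300])
BASE_LEAD_GAINS = np.array([1.0, 0.6])
MIN_RR_SAMPLES = 72  # 0.2 s at 360 Hz
CLASS_CODES = {"N": 0, "S": 1, "V": 2}


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: int
    base_rr: float  # seconds
    wave_amplitudes: np.ndarray  # 5, mV
    wave_widths: np.ndarray  # 5, seconds
    wave_centers: np.ndarray  # 5, seconds relative to R
    lead_gains: np.ndarray  # 2
    noise_sd: float  # mV
    wander_amplitude: float  # mV
    wander_freq: float  # Hz

    def __post_init__(self) -> None:
        if self.base_rr <= 0 or np.any(self.wave_widths <= 0) \
                or np.any(self.lead_gains <= 0):
            raise ValueError("invalid subject profile")


@dataclass(frozen=True)
class BeatClassEffect:
    label: str
    rr_factor: float
    rr_jitter: float  # fractional, applied multiplicatively
    next_rr_factor: float  # compensatory factor on the following beat
    p_wave_scale: float
    qrs_width_factor: float
    qrs_amp_factor: float


CLASS_EFFECTS: dict[str, BeatClassEffect] = {
    "N": BeatClassEffect("N", 1.00, 0.05, 1.0, 1.0, 1.0, 1.0),
    "S": BeatClassEffect("S", 0.60, 0.25, 1.0, 0.3, 1.0, 1.0),
    "V": BeatClassEffect("V", 0.55, 0.25, 1.4, 0.0, 2.2, 1.5),
}


@dataclass(frozen=True)
class SyntheticRecord:
    record_id: str
    subject_id: int
    signal: np.ndarray  # T x 2, mV
    ann_samples: np.ndarray  # strictly increasing R-peak indices
    labels: list[str]  # per beat, in {N, S, V}
    fs: int = FS

    def as_ecg_record(self) -> EcgRecord:
        return EcgRecord(self.record_id, float(self.fs), self.signal,
                         ("synthI", "synthII"))

    def beat_annotations(self) -> list[BeatAnnotation]:
        return [BeatAnnotation(int(s), sym)
                for s, sym in zip(self.ann_samples, self.labels)]


def sample_subject(seed: int, subject_id: int,
                   confound_strength: float = 1.0) -> SubjectProfile:
    """Deterministic subject draw from (seed, subject_id)."""
    if not 0 <= confound_strength <= 1:
        raise ValueError("confound_strength must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, subject_id)))
    c = confound_strength
    base_rr = 0.85 + c * (rng.uniform(0.6, 1.1) - 0.85)
    amps = BASE_AMPLITUDES * (1 + c * rng.uniform(-0.3, 0.3, size=5))
    widths = BASE_WIDTHS * (1 + c * rng.uniform(-0.2, 0.2, size=5))
    gains = BASE_LEAD_GAINS * (1 + c * rng.uniform(-0.3, 0.3, size=2))
    return SubjectProfile(
        subject_id=subject_id,
        base_rr=float(base_rr),
        wave_amplitudes=amps,
        wave_widths=widths,
        wave_centers=BASE_CENTERS.copy(),
        lead_gains=gains,
        noise_sd=0.08,
        wander_amplitude=0.15,
        wander_freq=float(0.3 * (1 + 0.1 * c * rng.uniform(-1, 1))),
    )


def _wave_params(profile: SubjectProfile, effect: BeatClassEffect
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    amps = profile.wave_amplitudes.copy()
    widths = profile.wave_widths.copy()
    amps[0] *= effect.p_wave_scale
    amps[1:4] *= effect.qrs_amp_factor  # Q, R, S complex
    widths[1:4] *= effect.qrs_width_factor
    return amps, widths, profile.wave_centers


def render_beat(profile: SubjectProfile, effect: BeatClassEffect,
                rr_samples: int) -> np.ndarray:
    """One beat as an (rr_samples, 2) waveform with the R peak at 35%.

    Deterministic (noise and wander belong to the record, not the beat).
    """
    if rr_samples < MIN_RR_SAMPLES:
        raise ValueError(f"rr_samples must be >= {MIN_RR_SAMPLES}")
    amps, widths, centers = _wave_params(profile, effect)
    t = (np.arange(rr_samples) - round(0.35 * rr_samples)) / FS
    bumps = (amps[None, :]
             * np.exp(-0.5 * ((t[:, None] - centers[None, :]) / widths[None, :]) ** 2))
    mono = bumps.sum(axis=1)
    return mono[:, None] * profile.lead_gains[None, :]


def generate_record(
    profile: SubjectProfile,
    n_beats: int,
    seed: int,
    class_sequence: list[str] | None = None,
    class_rates: tuple[float, float, float] = (0.8, 0.1, 0.1),
    record_id: str | None = None,
) -> SyntheticRecord:
    """Concatenate beats with class-dependent rhythm into a full record.

    RR intervals follow the class effects (with the compensatory pause
    after V beats), Gaussian noise and baseline wander are added, and
    each R-bump centre is annotated with its class label.
    """
    if n_beats < 2:
        raise ValueError("n_beats must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence((seed, profile.subject_id, 7)))
    if class_sequence is None:
        class_sequence = list(rng.choice(list("NSV"), size=n_beats,
                                         p=np.asarray(class_rates)))
    elif len(class_sequence) != n_beats:
        raise ValueError("class_sequence length must equal n_beats")

    # R-peak times: each beat's pre-RR is scaled by its own class factor
    # and by the compensatory factor of the preceding beat's class.
    r_times = [profile.base_rr]
    for i in range(1, n_beats):
        eff = CLASS_EFFECTS[class_sequence[i]]
        rr = profile.base_rr * eff.rr_factor
        if eff.rr_jitter:
            rr *= 1 + eff.rr_jitter * rng.uniform(-1, 1)
        rr *= CLASS_EFFECTS[class_sequence[i - 1]].next_rr_factor
        rr = max(rr, (MIN_RR_SAMPLES + 1) / FS)
        r_times.append(r_times[-1] + rr)
    r_times = np.asarray(r_times)

    duration = r_times[-1] + 0.6
    n_samples = int(np.ceil(duration * FS))
    t = np.arange(n_samples) / FS
    mono = np.zeros(n_samples)
    for r_t, label in zip(r_times, class_sequence):
        amps, widths, centers = _wave_params(profile, CLASS_EFFECTS[label])
        lo = max(int((r_t - 0.5) * FS), 0)
        hi = min(int((r_t + 0.6) * FS), n_samples)
        tl = t[lo:hi]
        mono[lo:hi] += (
            amps[None, :]
            * np.exp(-0.5 * ((tl[:, None] - r_t - centers[None, :])
                             / widths[None, :]) ** 2)
        ).sum(axis=1)
    signal = mono[:, None] * profile.lead_gains[None, :]
    phase = rng.uniform(0, 2 * np.pi)
    signal += (profile.wander_amplitude
               * np.sin(2 * np.pi * profile.wander_freq * t + phase))[:, None]
    signal += rng.normal(0.0, profile.noise_sd, size=signal.shape)

    ann = np.rint(r_times * FS).astype(np.int64)
    rid = record_id or f"syn{profile.subject_id:03d}"
    return SyntheticRecord(rid, profile.subject_id, signal, ann,
                           list(class_sequence))


@dataclass(frozen=True)
class Cohort:
    """Preprocessed inter-patient train/test datasets (disjoint subjects)."""

    train_x: np.ndarray  # (n, 3, 128, 2)
    train_y: np.ndarray  # AAMI codes
    train_s: np.ndarray  # subject IDs 1..S (training numbering)
    test_x: np.ndarray
    test_y: np.ndarray
    test_subject: np.ndarray  # original subject IDs of test beats
    train_subjects: tuple[int, ...]
    test_subjects: tuple[int, ...]


def generate_cohort(
    n_subjects: int = 8,
    beats_per_subject: int = 300,
    class_mix: tuple[float, float, float] = (0.8, 0.1, 0.1),
    confound_strength: float = 1.0,
    seed: int = 0,
    n_test_subjects: int | None = None,
) -> Cohort:
    """Generate, preprocess and split a cohort by subject.

    The last ``n_test_subjects`` (default: half) are held out entirely,
    mirroring the inter-patient protocol: no training beat shares a
    subject with a test beat.
    """
    if n_subjects < 4:
        raise ValueError("n_subjects must be >= 4 (>= 2 per split)")
    n_test = n_test_subjects or n_subjects // 2
    if not 2 <= n_test <= n_subjects - 2:
        raise ValueError("need >= 2 subjects on each side of the split")
    subjects = list(range(1, n_subjects + 1))
    train_subjects = tuple(subjects[: n_subjects - n_test])
    test_subjects = tuple(subjects[n_subjects - n_test:])
    sid_map = assign_subject_ids({str(s) for s in train_subjects})

    def build(sids, training: bool):
        xs, ys, ss = [], [], []
        for sid in sids:
            profile = sample_subject(seed, sid, confound_strength)
            rec = generate_record(profile, beats_per_subject, seed,
                                  class_rates=class_mix)
            x, beats = preprocess_record(rec.as_ecg_record(),
                                         rec.beat_annotations())
            xs.append(x)
            ys.append(np.array([b.aami_class for b in beats], dtype=np.int64))
            tag = sid_map[str(sid)] if training else sid
            ss.append(np.full(len(beats), tag, dtype=np.int64))
        return np.concatenate(xs), np.concatenate(ys), np.concatenate(ss)

    xt, yt, st = build(train_subjects, True)
    xe, ye, se = build(test_subjects, False)
    return Cohort(xt, yt, st, xe, ye, se, train_subjects, test_subjects)


def write_cohort_wfdb(
    directory: str,
    n_subjects: int,
    beats_per_subject: int,
    seed: int,
    class_mix: tuple[float, float, float] = (0.8, 0.1, 0.1),
    confound_strength: float = 1.0,
) -> dict:
    """Emit a cohort as WFDB records plus a JSON manifest; returns the
    manifest. The files are consumable by the standard reader path."""
    os.makedirs(directory, exist_ok=True)
    manifest: dict = {
        "fs": FS, "seed": seed, "n_subjects": n_subjects,
        "beats_per_subject": beats_per_subject,
        "confound_strength": confound_strength, "records": {},
    }
    for sid in range(1, n_subjects + 1):
        profile = sample_subject(seed, sid, confound_strength)
        rec = generate_record(profile, beats_per_subject, seed,
                              class_rates=class_mix)
        wfdb_io.write_record(directory, rec.record_id, rec.signal, FS,
                             ["synthI", "synthII"])
        wfdb_io.write_annotations(
            os.path.join(directory, f"{rec.record_id}.atr"),
            rec.ann_samples, rec.labels)
        manifest["records"][rec.record_id] = {
            "subject_id": sid, "n_beats": beats_per_subject,
        }
    with open(os.path.join(directory, "cohort.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
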