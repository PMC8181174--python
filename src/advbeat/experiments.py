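"""Canned inter-patient experiments on synthetic cohorts.

These drive the full pipeline — cohort generation, preprocessing,
adversarial training, held-out-subject evaluation, and subject-probe
analysis — at sizes small enough for routine runs, and back both the
lambda sweep command and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import confusion, per_class_metrics
from .synthetic import Cohort, generate_cohort
from .training import TrainConfig, evaluate_invariance_probe, train

LAMBDA_GRID = (0.001, 0.005, 0.01, 0.05, 0.1)


@dataclass(frozen=True)
class ExperimentResult:
    lambda_adv: float
    seed: int
    accuracy: float
    pat_f1: float
    sen: dict[str, float]
    pre: dict[str, float]
    probe_encoded: float
    probe_raw: float
    probe_train_encoded: float
    probe_train_raw: float
    n_test_beats: int


def run_invariance_experiment(
    lambda_adv: float,
    seed: int,
    cohort: Cohort | None = None,
    n_subjects: int = 8,
    beats_per_subject: int = 300,
    n_test_subjects: int = 4,
    max_epochs: int = 15,
    batch_size: int = 128,
    confound_strength: float = 1.0,
) -> ExperimentResult:
    """Train at one lambda and measure generalisation + invariance.

    Returns held-out-subject classification metrics together with
    subject-probe accuracies on the encoder features and on the raw
    inputs of the held-out subjects.
    """
    if cohort is None:
        cohort = generate_cohort(n_subjects, beats_per_subject,
                                 confound_strength=confound_strength,
                                 seed=seed, n_test_subjects=n_test_subjects)
    cfg = TrainConfig(lambda_adv=lambda_adv, seed=seed,
                      max_epochs=max_epochs, batch_size=batch_size)
    model, _ = train((cohort.train_x, cohort.train_y, cohort.train_s), cfg)
    pred = model.predict(cohort.test_x)
    rep = per_class_metrics(confusion(cohort.test_y, pred))
    feats = np.concatenate([
        model.encode(cohort.test_x[i:i + 512])
        for i in range(0, len(cohort.test_x), 512)
    ])
    probe_enc = evaluate_invariance_probe(feats, cohort.test_subject, seed=seed)
    probe_raw = evaluate_invariance_probe(
        cohort.test_x.reshape(len(cohort.test_x), -1),
        cohort.test_subject, seed=seed)
    # the adversary's own targets: how identifiable the *training* subjects
    # remain in the learned representation
    tfeats = np.concatenate([
        model.encode(cohort.train_x[i:i + 512])
        for i in range(0, len(cohort.train_x), 512)
    ])
    probe_tr_enc = evaluate_invariance_probe(tfeats, cohort.train_s, seed=seed)
    probe_tr_raw = evaluate_invariance_probe(
        cohort.train_x.reshape(len(cohort.train_x), -1),
        cohort.train_s, seed=seed)
    classes = ("N", "S", "V")
    return ExperimentResult(
        lambda_adv=lambda_adv, seed=seed,
        accuracy=rep.accuracy, pat_f1=rep.pat_f1,
        sen={c: rep.per_class[c].sensitivity for c in classes},
        pre={c: rep.per_class[c].precision for c in classes},
        probe_encoded=probe_enc, probe_raw=probe_raw,
        probe_train_encoded=probe_tr_enc, probe_train_raw=probe_tr_raw,
        n_test_beats=rep.n_beats,
    )


def sweep_lambda(
    lambdas: tuple[float, ...] = LAMBDA_GRID,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """One row per adversarial weight with Acc and per-class Sen/Pre."""
    cohort = generate_cohort(
        kwargs.pop("n_subjects", 8), kwargs.pop("beats_per_subject", 300),
        confound_strength=kwargs.pop("confound_strength", 1.0),
        seed=seed, n_test_subjects=kwargs.pop("n_test_subjects", 4))
    rows = []
    for lam in lambdas:
        r = run_invariance_experiment(lam, seed, cohort=cohort, **kwargs)
        rows.append({
            "lambda": lam, "acc": r.accuracy,
            "sen_N": r.sen["N"], "pre_N": r.pre["N"],
            "sen_S": r.sen["S"], "pre_S": r.pre["S"],
            "sen_V": r.sen["V"], "pre_V": r.pre["V"],
            "pat_f1": r.pat_f1, "probe_acc": r.probe_encoded,
        })
    return pd.DataFrame(rows)
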