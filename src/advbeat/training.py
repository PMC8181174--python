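"""Adversarial training: the min-max objective, schedule and probes.

The network is trained towards

    min_{theta_e, theta_c} max_{theta_a}  L = L_c - lambda * L_a,

where L_c is the classifier cross-entropy on beat classes and L_a the
adversary cross-entropy on training-subject IDs. The saddle point is
sought with single-loop gradient reversal: one joint Adam step per batch
in which the classifier head receives dL_c/dtheta_c, the adversary head
receives plain dL_a/dtheta_a (so the adversary keeps improving at
subject identification), and the encoder receives
dL_c/dtheta_e - lambda * dL_a/dtheta_e — the adversary branch's gradient
is sign-flipped and scaled on its way into the shared encoder. With
lambda = 0 this reduces exactly to an ordinary encoder+classifier CNN.
An alternating two-phase update (adversary step, then encoder+classifier
step) is available as a config option.

Schedule: Adam at 1e-3, batches of 128; 20% of the training beats are
held out as validation; when validation L_c has not improved for 10
epochs the learning rate drops once to 1e-4, and after 20 such epochs
training stops, returning the parameters with minimal validation L_c.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import nn
from .model import AdversarialModel, EncoderConfig

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12


@dataclass
class TrainConfig:
    lambda_adv: float = 0.005
    learning_rate: float = 1e-3
    reduced_learning_rate: float = 1e-4
    batch_size: int = 128
    lr_patience: int = 10
    stop_patience: int = 20
    val_fraction: float = 0.2
    max_epochs: int = 200
    seed: int = 0
    optimizer: str = "adam"
    update_scheme: str = "grl"  # "grl" | "alternating"

    def __post_init__(self) -> None:
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")
        if self.lr_patience <= 0 or self.stop_patience <= 0:
            raise ValueError("patiences must be positive")
        if self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("batch_size and max_epochs must be positive")
        if self.update_scheme not in ("grl", "alternating"):
            raise ValueError(f"unknown update scheme {self.update_scheme!r}")


@dataclass(frozen=True)
class LossBreakdown:
    """L_c, L_a and the combined objective L = L_c - lambda * L_a."""

    classifier_ce: float
    adversary_ce: float
    lambda_adv: float

    @property
    def total(self) -> float:
        return self.classifier_ce - self.lambda_adv * self.adversary_ce


@dataclass
class EpochRecord:
    epoch: int
    train_classifier_ce: float
    train_adversary_ce: float
    train_total: float
    val_classifier_ce: float | None
    val_adversary_ce: float | None
    learning_rate: float
    is_best: bool = False


@dataclass
class TrainHistory:
    epochs: list[EpochRecord] = field(default_factory=list)
    best_epoch: int | None = None
    stopped_early: bool = False

    def to_dict(self) -> dict:
        return {
            "best_epoch": self.best_epoch,
            "stopped_early": self.stopped_early,
            "epochs": [vars(e) for e in self.epochs],
        }


def adversarial_loss(
    class_probs: np.ndarray,
    subject_probs: np.ndarray,
    true_y: np.ndarray,
    true_s: np.ndarray,
    lambda_adv: float,
) -> LossBreakdown:
    """Batch-mean cross-entropies and the combined objective.

    Probabilities at the true label are clamped at 1e-12 before the log
    (with a debug note) so a saturated head cannot produce infinities.
    """
    class_probs = np.asarray(class_probs, dtype=np.float64)
    subject_probs = np.asarray(subject_probs, dtype=np.float64)
    true_y = np.asarray(true_y, dtype=np.int64)
    true_s = np.asarray(true_s, dtype=np.int64)
    p_y = class_probs[np.arange(len(true_y)), true_y]
    p_s = subject_probs[np.arange(len(true_s)), true_s]
    if np.any(p_y < PROB_FLOOR) or np.any(p_s < PROB_FLOOR):
        logger.debug("probability clamped at %g before log", PROB_FLOOR)
    lc = float(-np.log(np.maximum(p_y, PROB_FLOOR)).mean())
    la = float(-np.log(np.maximum(p_s, PROB_FLOOR)).mean())
    return LossBreakdown(lc, la, lambda_adv)


def split_validation(
    n_or_items, val_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Beat-level random split -> (train indices, validation indices).

    Disjoint, exhaustive and reproducible from the seed. A zero fraction
    yields an empty validation set (early stopping then has nothing to
    watch, which `train` warns about).
    """
    n = n_or_items if isinstance(n_or_items, (int, np.integer)) else len(n_or_items)
    if not 0 <= val_fraction < 1:
        raise ValueError("val_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = int(round(n * val_fraction))
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


class PlateauSchedule:
    """Validation-loss bookkeeping for the LR drop and early stop.

    The learning rate is reduced (once) after ``lr_patience`` consecutive
    epochs without a new minimum, and training stops after
    ``stop_patience`` such epochs.
    """

    def __init__(self, lr_patience: int, stop_patience: int):
        self.lr_patience = lr_patience
        self.stop_patience = stop_patience
        self.best = np.inf
        self.epochs_since_best = 0
        self.lr_dropped = False

    def step(self, val_loss: float) -> tuple[bool, bool, bool]:
        """-> (is_new_best, drop_lr_now, stop_now)."""
        if val_loss < self.best:
            self.best = val_loss
            self.epochs_since_best = 0
            is_best = True
        else:
            self.epochs_since_best += 1
            is_best = False
        drop = (not self.lr_dropped
                and self.epochs_since_best >= self.lr_patience)
        if drop:
            self.lr_dropped = True
        stop = self.epochs_since_best >= self.stop_patience
        return is_best, drop, stop


def _epoch_losses(model: AdversarialModel, x: np.ndarray, y: np.ndarray,
                  s: np.ndarray, lam: float, batch_size: int) -> LossBreakdown:
    """Eval-mode losses over a dataset (no parameter updates)."""
    model.set_training(False)
    lcs, las, ns = [], [], []
    for i in range(0, len(x), batch_size):
        xb, yb, sb = x[i:i + batch_size], y[i:i + batch_size], s[i:i + batch_size]
        h = model.encode(xb)
        b = adversarial_loss(model.classify(h), model.discriminate_subject(h),
                             yb, sb, lam)
        lcs.append(b.classifier_ce)
        las.append(b.adversary_ce)
        ns.append(len(xb))
    w = np.asarray(ns, dtype=np.float64)
    w /= w.sum()
    return LossBreakdown(float(np.dot(lcs, w)), float(np.dot(las, w)), lam)


def _grl_step(model: AdversarialModel, opt: nn.Adam, xb, yb, sb,
              lam: float) -> tuple[float, float]:
    opt.zero_grad()
    _, class_logits, adv_logits = model.forward(xb, lambda_adv=lam)
    lc = nn.softmax_cross_entropy(class_logits, yb)
    la = nn.softmax_cross_entropy(adv_logits, sb)
    # The reversal layer inside `forward` turns this sum into the saddle
    # gradient: heads descend their own CE, the encoder descends
    # L_c - lambda * L_a.
    (lc + la).backward()
    opt.step()
    return float(lc.data), float(la.data)


def _alternating_step(model: AdversarialModel, opt: nn.Adam, xb, yb, sb,
                      lam: float) -> tuple[float, float]:
    # phase 1: adversary only, encoder frozen
    opt.zero_grad()
    h, _, adv_logits = model.forward(xb, lambda_adv=0.0)
    la = nn.softmax_cross_entropy(adv_logits, sb)
    enc_params = set(map(id, model.encoder.parameters()))
    cls_params = set(map(id, model.classifier_head.parameters()))
    la.backward()
    for p in model.parameters():
        if id(p) in enc_params or id(p) in cls_params:
            p.grad = None
    opt.step()
    # phase 2: encoder + classifier against the updated adversary
    opt.zero_grad()
    _, class_logits, adv_logits = model.forward(xb, lambda_adv=lam)
    lc = nn.softmax_cross_entropy(class_logits, yb)
    la2 = nn.softmax_cross_entropy(adv_logits, sb)
    (lc + la2).backward()
    for p in model.adversary_head.parameters():
        p.grad = None
    opt.step()
    return float(lc.data), float(la2.data)


def train(
    dataset: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: TrainConfig,
    model: AdversarialModel | None = None,
    encoder_config: EncoderConfig | None = None,
) -> tuple[AdversarialModel, TrainHistory]:
    """Train on (inputs, class labels, subject IDs 1..S).

    Returns the model restored to the epoch of minimal validation L_c,
    together with the per-epoch history. All randomness (validation
    split, parameter init, epoch shuffling) derives from ``config.seed``.
    """
    x, y, s = dataset
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    s0 = np.asarray(s, dtype=np.int64) - 1  # subject IDs 1..S -> 0-based
    if len(x) == 0:
        raise ValueError("empty training dataset")
    if len(np.unique(y)) < 2:
        logger.warning("training labels are degenerate (single class)")
    n_subjects = int(s0.max()) + 1
    if model is None:
        model = AdversarialModel(n_subjects, encoder_config, seed=config.seed)
    train_idx, val_idx = split_validation(len(x), config.val_fraction,
                                          config.seed)
    if len(val_idx) == 0:
        logger.warning("empty validation set: early stopping disabled")
    xt, yt, st = x[train_idx], y[train_idx], s0[train_idx]
    xv, yv, sv = x[val_idx], y[val_idx], s0[val_idx]

    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    step = _grl_step if config.update_scheme == "grl" else _alternating_step

    history = TrainHistory()
    sched = PlateauSchedule(config.lr_patience, config.stop_patience)
    best_state = model.get_state()
    best_epoch = 0

    for epoch in range(1, config.max_epochs + 1):
        model.set_training(True)
        perm = shuffle_rng.permutation(len(xt))
        lcs, las = [], []
        for i in range(0, len(xt), config.batch_size):
            idx = perm[i:i + config.batch_size]
            lc, la = step(model, opt, xt[idx], yt[idx], st[idx],
                          config.lambda_adv)
            lcs.append(lc)
            las.append(la)
        train_lc, train_la = float(np.mean(lcs)), float(np.mean(las))
        rec = EpochRecord(
            epoch, train_lc, train_la,
            train_lc - config.lambda_adv * train_la,
            None, None, opt.lr,
        )
        if len(xv):
            vb = _epoch_losses(model, xv, yv, sv, config.lambda_adv,
                               config.batch_size)
            rec.val_classifier_ce = vb.classifier_ce
            rec.val_adversary_ce = vb.adversary_ce
            is_best, drop_lr, stop = sched.step(vb.classifier_ce)
            if is_best:
                best_state = model.get_state()
                best_epoch = epoch
                rec.is_best = True
            history.epochs.append(rec)
            if drop_lr:
                opt.lr = config.reduced_learning_rate
                logger.info("epoch %d: learning rate reduced to %g",
                            epoch, opt.lr)
            if stop:
                history.stopped_early = True
                logger.info("epoch %d: early stop (no improvement for %d "
                            "epochs)", epoch, config.stop_patience)
                break
        else:
            history.epochs.append(rec)

    if len(xv):
        model.set_state(best_state)
        history.best_epoch = best_epoch
    else:
        history.best_epoch = len(history.epochs)
    model.set_training(False)
    return model, history


def evaluate_invariance_probe(
    features: np.ndarray,
    subject_ids: np.ndarray,
    seed: int = 0,
    probe_fraction: float = 0.5,
) -> float:
    """Subject-identifiability of a representation.

    Fits a fresh affine+softmax probe (multinomial logistic regression)
    on one half of the beats and returns its subject-ID accuracy on the
    other half. High accuracy means the representation still encodes who
    the beat came from.
    """
    features = np.asarray(features, dtype=np.float64)
    features = features.reshape(len(features), -1)
    subject_ids = np.asarray(subject_ids, dtype=np.int64)
    if len(np.unique(subject_ids)) < 2:
        raise ValueError("probe requires at least 2 subjects")
    fit_idx, eval_idx = split_validation(len(features), probe_fraction, seed)
    probe = LogisticRegression(max_iter=2000, random_state=seed)
    probe.fit(features[fit_idx], subject_ids[fit_idx])
    return float(probe.score(features[eval_idx], subject_ids[eval_idx]))
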