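"""Two-scenario training protocol.

Both scenarios start with an unsupervised warmup on the whole dataset
(reconstruction, KLD for variational models, and the batch-effect loss
when one is configured).  Scenario 1 then freezes the autoencoder and
trains only the label classifier on the training split; scenario 2
alternates unsupervised epochs on all samples with supervised epochs
whose gradients flow through the encoder.  Early stopping monitors the
validation MCC with a configurable patience.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import autograd as ag
from . import metrics as met
from .autograd import Adam, Tensor, grad_scale, gradient_reversal
from .core_data import OmicsMatrix
from .networks import (
    CorrectionModel,
    clamped_adversarial_total,
    dann_batch_loss,
    inv_triplet_loss,
    kld_gaussian,
    normae_batch_loss,
    reconstruction_loss,
    rev_triplet_loss,
    smoothed_cross_entropy,
)
from .splitting import HoldoutSplit, materialize

logger = logging.getLogger(__name__)


@dataclass
class TrainerConfig:
    """Protocol-level knobs (model hyperparameters live in ModelConfig)."""

    batch_size: int = 32
    max_epochs: int = 1000
    patience: int = 100
    alternation: str = "epoch"  # or "minibatch"
    strict_unsupervised: bool = False  # exclude valid/test from unsupervised steps
    # adversarial stabilization: the batch discriminator is kept close to
    # optimal (extra detached updates, faster learning rate) but bounded in
    # confidence (weight decay, label smoothing), so the reversed gradient
    # reflects true separability instead of a cluster relabeling race
    disc_steps: int = 3
    disc_lr_scale: float = 5.0
    disc_weight_decay: float = 0.1
    disc_label_smoothing: float = 0.1

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 0 or self.patience < 1:
            raise ValueError("invalid trainer configuration")
        if self.alternation not in ("epoch", "minibatch"):
            raise ValueError("alternation must be 'epoch' or 'minibatch'")
        if self.disc_steps < 0 or self.disc_lr_scale <= 0:
            raise ValueError("invalid discriminator settings")


@dataclass
class TrainState:
    """Progress record for one training run."""

    epoch: int = 0
    best_valid_mcc: float = float("-inf")
    epochs_since_improvement: int = 0
    loss_history: list[dict] = field(default_factory=list)
    rng_seed: int = 0

    def record_validation(self, valid_mcc: float) -> bool:
        """Update the early-stopping bookkeeping; True on strict improvement."""
        if valid_mcc > self.best_valid_mcc:
            self.best_valid_mcc = valid_mcc
            self.epochs_since_improvement = 0
            return True
        self.epochs_since_improvement += 1
        return False


def class_weights(labels: Sequence) -> np.ndarray:
    """Per-sample weights 1 / count(class): expected sampled class
    frequencies become uniform under weighted draws with replacement."""
    labels = np.asarray(labels, dtype=object)
    uniq, counts = np.unique(labels.astype(str), return_counts=True)
    count_of = dict(zip(uniq, counts))
    return np.array([1.0 / count_of[str(l)] for l in labels], dtype=np.float64)


# ----------------------------------------------------------------------
# epoch runners
# ----------------------------------------------------------------------

def _batch_codes(model: CorrectionModel, m: OmicsMatrix) -> np.ndarray:
    """Integer batch codes aligned with the model's batch order."""
    order = {b: i for i, b in enumerate(model.batch_order)}
    return np.array([order[b] for b in m.batch_labels], dtype=np.int64)


def _minibatch_indices(
    n: int,
    batch_size: int,
    rng: np.random.Generator,
    weights: Optional[np.ndarray] = None,
):
    if weights is not None:
        p = weights / weights.sum()
        idx = rng.choice(n, size=n, replace=True, p=p)
    else:
        idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start : start + batch_size]


def _mine_triplets(
    batch_codes: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform same-batch positive and different-batch negative per anchor."""
    anchors, positives, negatives = [], [], []
    n = len(batch_codes)
    for i in range(n):
        same = np.flatnonzero(batch_codes == batch_codes[i])
        same = same[same != i]
        diff = np.flatnonzero(batch_codes != batch_codes[i])
        if len(same) == 0 or len(diff) == 0:
            continue
        anchors.append(i)
        positives.append(rng.choice(same))
        negatives.append(rng.choice(diff))
    return (
        np.asarray(anchors, dtype=np.int64),
        np.asarray(positives, dtype=np.int64),
        np.asarray(negatives, dtype=np.int64),
    )


def _unsupervised_step(
    model: CorrectionModel,
    xb: np.ndarray,
    codes_b: np.ndarray,
    opt: Adam,
    disc_opt: Optional[Adam],
    rng: np.random.Generator,
    tc: TrainerConfig,
) -> dict:
    """One minibatch of reconstruction (+ KLD + batch-effect) training."""
    cfg = model.cfg
    xt = Tensor(xb)
    record: dict = {}

    if disc_opt is not None:
        # keep the discriminator near-optimal on the detached bottleneck
        for _ in range(max(tc.disc_steps, 1)):
            z_d, _, _ = model.encode_t(xt, training=True, sample_noise=cfg.variational)
            d_loss = normae_batch_loss(
                model, z_d, codes_b, cfg.gamma, detach=True,
                smoothing=tc.disc_label_smoothing,
            ) if cfg.be_strategy == "batch_mapping_adversarial" else (
                smoothed_cross_entropy(
                    model.batch_logits_t(z_d.detach()),
                    codes_b,
                    cfg.n_batches,
                    tc.disc_label_smoothing,
                )
            )
            disc_opt.zero_grad()
            d_loss.backward()
            disc_opt.step()
        record["disc"] = float(d_loss)

    z, mu, sigma = model.encode_t(xt, training=True, sample_noise=cfg.variational)
    dec_codes = codes_b if cfg.be_strategy == "batch_mapping_adversarial" else None
    rec = reconstruction_loss(xt, model.decode_t(z, dec_codes))
    total = rec
    record["rec"] = float(rec)

    if cfg.variational:
        kld = kld_gaussian(mu, sigma)
        total = total + ag.mul(kld, cfg.beta)
        record["kld"] = float(kld)

    be = None
    if cfg.be_strategy == "dann":
        # gamma enters through the reversal factor: the discriminator head
        # minimizes the cross-entropy at full strength while the encoder
        # receives -gamma times its gradient
        be = dann_batch_loss(model, z, codes_b, cfg.gamma, smoothing=tc.disc_label_smoothing)
        total = total + be
    elif cfg.be_strategy in ("inv_triplet", "rev_triplet"):
        ia, ip, in_ = _mine_triplets(codes_b, rng)
        if len(ia) > 0:
            if cfg.be_strategy == "rev_triplet":
                zt = gradient_reversal(z, 1.0)
                fA, fP, fN = (ag.embedding(zt, i) for i in (ia, ip, in_))
                be = rev_triplet_loss(fA, fP, fN, cfg.margin)
            else:
                fA, fP, fN = (ag.embedding(z, i) for i in (ia, ip, in_))
                be = inv_triplet_loss(fA, fP, fN, cfg.margin)
            total = total + ag.mul(be, cfg.gamma)
    elif cfg.be_strategy == "batch_mapping_adversarial":
        be = normae_batch_loss(model, z, codes_b, cfg.gamma, detach=False)
        total = clamped_adversarial_total(total, be, cfg.gamma)

    if be is not None:
        record["be"] = float(be)
    record["total"] = float(total)
    opt.zero_grad()
    if disc_opt is not None:
        disc_opt.zero_grad()
    total.backward()
    opt.step()
    if disc_opt is not None and cfg.be_strategy == "dann":
        disc_opt.step()  # head grads from the (un-reversed) CE path
    return record


def _run_unsupervised_epoch(
    model: CorrectionModel,
    X: np.ndarray,
    codes: np.ndarray,
    tc: TrainerConfig,
    opt: Adam,
    disc_opt: Optional[Adam],
    rng: np.random.Generator,
) -> dict:
    records = []
    for idx in _minibatch_indices(X.shape[0], tc.batch_size, rng):
        records.append(
            _unsupervised_step(model, X[idx], codes[idx], opt, disc_opt, rng, tc)
        )
    keys = set().union(*(r.keys() for r in records))
    return {k: float(np.mean([r[k] for r in records if k in r])) for k in keys}


def _run_supervised_epoch(
    model: CorrectionModel,
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    tc: TrainerConfig,
    opt: Adam,
    rng: np.random.Generator,
    through_encoder: bool,
) -> dict:
    """One epoch of label-classifier training with weighted sampling.

    The classifier head always receives the full gradient; the encoder
    path is scaled by nu (and cut entirely when ``through_encoder`` is
    False), so nu=0 leaves everything but the head untouched.
    """
    cfg = model.cfg
    losses = []
    for idx in _minibatch_indices(X.shape[0], tc.batch_size, rng, weights):
        xt = Tensor(X[idx])
        z, _, _ = model.encode_t(xt, training=True, sample_noise=cfg.variational)
        if not through_encoder:
            z = z.detach()
        else:
            z = grad_scale(z, cfg.nu)
        logits = model.classify_t(z, training=True)
        loss = smoothed_cross_entropy(logits, y[idx], cfg.n_classes, cfg.label_smoothing)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss))
    return {"classif": float(np.mean(losses))}


# ----------------------------------------------------------------------
# protocol phases
# ----------------------------------------------------------------------

def warmup(
    model: CorrectionModel,
    full_data: OmicsMatrix,
    epochs: Optional[int] = None,
    tc: Optional[TrainerConfig] = None,
) -> TrainState:
    """Unsupervised pre-training on all samples; the label classifier is
    untouched."""
    tc = tc or TrainerConfig()
    if epochs is None:
        epochs = model.cfg.warmup_epochs
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    state = TrainState(rng_seed=model.cfg.seed)
    if model.batch_order is None:
        model.batch_order = full_data.batches
    if epochs == 0:
        return state
    X = full_data.values
    codes = _batch_codes(model, full_data)
    rng = np.random.default_rng(np.random.SeedSequence((model.cfg.seed, 1)))
    opt, disc_opt = _make_optimizers(model, tc)
    for epoch in range(epochs):
        rec = _run_unsupervised_epoch(model, X, codes, tc, opt, disc_opt, rng)
        rec.update(epoch=epoch, phase="warmup")
        state.loss_history.append(rec)
        state.epoch = epoch + 1
    return state


def _make_optimizers(
    model: CorrectionModel, tc: TrainerConfig
) -> tuple[Adam, Optional[Adam]]:
    """Main optimizer (encoder+decoder) and, for adversarial strategies, a
    faster, confidence-bounded discriminator optimizer."""
    cfg = model.cfg
    main_params = model.encoder_parameters() + model.decoder_parameters()
    disc_opt = None
    if cfg.be_strategy in ("dann", "batch_mapping_adversarial"):
        disc_opt = Adam(
            model.discriminator_parameters(),
            lr=cfg.learning_rate * tc.disc_lr_scale,
            weight_decay=tc.disc_weight_decay,
        )
    opt = Adam(main_params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    return opt, disc_opt


def _class_codes(class_order: list, m: OmicsMatrix) -> np.ndarray:
    """Class codes aligned with the full dataset's class order (QC rows -1)."""
    order = {c: i for i, c in enumerate(class_order)}
    return np.array([order.get(c, -1) for c in m.class_labels], dtype=np.int64)


def _validation_mcc(model: CorrectionModel, valid: OmicsMatrix, class_order: list) -> float:
    mask = ~valid.qc_flags
    if not mask.any():
        return float("nan")
    pred = model.predict_labels(valid.values[mask])
    return met.mcc(pred, _class_codes(class_order, valid)[mask])


def _snapshot(model: CorrectionModel) -> dict[str, np.ndarray]:
    return {n: t.data.copy() for n, t in model.params.items()}


def _restore(model: CorrectionModel, snap: dict[str, np.ndarray]) -> None:
    for n, data in snap.items():
        model.params[n].data = data.copy()


def train_scenario1(
    model: CorrectionModel,
    data: OmicsMatrix,
    split: HoldoutSplit,
    tc: Optional[TrainerConfig] = None,
) -> TrainState:
    """Frozen autoencoder; only the label classifier is trained."""
    tc = tc or TrainerConfig()
    train, valid, _ = materialize(split, data)
    return _train_classifier_phase(model, data, train, valid, tc, through_encoder=False)


def train_scenario2(
    model: CorrectionModel,
    data: OmicsMatrix,
    split: HoldoutSplit,
    tc: Optional[TrainerConfig] = None,
) -> TrainState:
    """Alternate unsupervised epochs on all samples with supervised epochs
    whose gradients flow through the encoder."""
    tc = tc or TrainerConfig()
    train, valid, _ = materialize(split, data)
    return _train_classifier_phase(model, data, train, valid, tc, through_encoder=True)


def _train_classifier_phase(
    model: CorrectionModel,
    full_data: OmicsMatrix,
    train: OmicsMatrix,
    valid: OmicsMatrix,
    tc: TrainerConfig,
    through_encoder: bool,
) -> TrainState:
    cfg = model.cfg
    if model.batch_order is None:
        model.batch_order = full_data.batches
    class_order = full_data.classes
    tr_mask = ~train.qc_flags
    if not tr_mask.any():
        raise ValueError("empty training split (no non-QC samples)")
    X_tr = train.values[tr_mask]
    y_tr = _class_codes(class_order, train)[tr_mask]
    if (y_tr < 0).any():
        raise ValueError("training split contains unlabeled samples")
    weights = class_weights(y_tr)

    unsup = full_data
    if tc.strict_unsupervised:
        unsup = train
    X_all = unsup.values
    codes_all = _batch_codes(model, unsup)

    state = TrainState(rng_seed=cfg.seed)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    cls_opt = Adam(
        model.classifier_parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay
    )
    if through_encoder:
        main_opt, disc_opt = _make_optimizers(model, tc)
        # supervised epochs in scenario 2 update encoder and head together
        sup_opt = Adam(
            model.classifier_parameters() + model.encoder_parameters(),
            lr=cfg.learning_rate,
            weight_decay=cfg.weight_decay,
        )
    else:
        main_opt = disc_opt = None
        sup_opt = cls_opt

    best = _snapshot(model)
    for epoch in range(tc.max_epochs):
        if through_encoder and epoch % 2 == 0:
            rec = _run_unsupervised_epoch(
                model, X_all, codes_all, tc, main_opt, disc_opt, rng
            )
            phase = "unsupervised"
        else:
            rec = _run_supervised_epoch(
                model, X_tr, y_tr, weights, tc, sup_opt, rng, through_encoder
            )
            phase = "supervised"
        valid_mcc = _validation_mcc(model, valid, class_order)
        rec.update(epoch=epoch, phase=phase, valid_mcc=valid_mcc)
        state.loss_history.append(rec)
        state.epoch = epoch + 1
        # ties update the snapshot (keep the most-trained equally-good model)
        # but only strict improvement resets the patience counter
        if valid_mcc >= state.best_valid_mcc:
            best = _snapshot(model)
        state.record_validation(valid_mcc)
        if state.epochs_since_improvement >= tc.patience:
            logger.info(
                "early stopping at epoch %d (best valid MCC %.4f)",
                epoch,
                state.best_valid_mcc,
            )
            break
    _restore(model, best)
    return state


def fit(
    model: CorrectionModel,
    data: OmicsMatrix,
    split: HoldoutSplit,
    scenario: int = 2,
    tc: Optional[TrainerConfig] = None,
    warmup_epochs: Optional[int] = None,
) -> TrainState:
    """Warmup then the chosen scenario; returns the combined TrainState."""
    tc = tc or TrainerConfig()
    unsup_data = data
    if tc.strict_unsupervised:
        unsup_data, _, _ = materialize(split, data)
        model.batch_order = data.batches
    w_state = warmup(model, unsup_data, epochs=warmup_epochs, tc=tc)
    if scenario == 1:
        state = train_scenario1(model, data, split, tc)
    elif scenario == 2:
        state = train_scenario2(model, data, split, tc)
    else:
        raise ValueError("scenario must be 1 or 2")
    state.loss_history = w_state.loss_history + state.loss_history
    return state
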