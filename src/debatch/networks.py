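"""The model zoo: single-hidden-layer (variational) autoencoders with
label/batch classifier heads and five batch-effect-removal strategies.

The cross-product {deterministic AE, variational AE} x {plain,
batch-mapping adversarial, DANN, inverse triplet, reverse triplet} gives
exactly ten model families.  All loss terms of the composite objective

    L_total = L_rec + nu * L_classif + beta * KLD + gamma * L_BE

are exposed as standalone operations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import autograd as ag
from .autograd import Tensor, as_tensor, gradient_reversal
from .core_data import NormalizationSpec

BE_STRATEGIES = ("none", "batch_mapping_adversarial", "dann", "inv_triplet", "rev_triplet")

_STRATEGY_TOKEN = {
    "none": "",
    "batch_mapping_adversarial": "bmadv",
    "dann": "dann",
    "inv_triplet": "invtriplet",
    "rev_triplet": "revtriplet",
}

#: family name -> (variational, be_strategy); exactly 10 entries
MODEL_FAMILIES: dict[str, tuple[bool, str]] = {
    (("vae" if var else "ae") + ("-" + tok if tok else "")): (var, strat)
    for var in (False, True)
    for strat, tok in _STRATEGY_TOKEN.items()
}


@dataclass
class ModelConfig:
    """Architecture and loss-weight hyperparameters for one zoo member."""

    n_features: int
    n_classes: int
    n_batches: int
    layer1: int = 128
    layer2: int = 32
    variational: bool = False
    be_strategy: str = "none"
    dropout: float = 0.0
    label_smoothing: float = 0.0
    margin: float = 1.0
    nu: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    warmup_epochs: int = 0
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.be_strategy not in BE_STRATEGIES:
            raise ValueError(
                f"unknown be_strategy {self.be_strategy!r}; expected one of {BE_STRATEGIES}"
            )
        for name in ("n_features", "n_classes", "n_batches", "layer1", "layer2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if not 0.0 <= self.label_smoothing < 0.5:
            raise ValueError("label_smoothing must lie in [0, 0.5)")
        for name in ("margin", "nu", "beta", "gamma", "weight_decay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.warmup_epochs < 0:
            raise ValueError("warmup_epochs must be >= 0")
        if isinstance(self.normalization, dict):
            self.normalization = NormalizationSpec(**self.normalization)

    @property
    def family(self) -> str:
        tok = _STRATEGY_TOKEN[self.be_strategy]
        base = "vae" if self.variational else "ae"
        return base + ("-" + tok if tok else "")

    @classmethod
    def for_family(cls, family: str, **kwargs) -> "ModelConfig":
        if family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown model family {family!r}; valid families: "
                f"{sorted(MODEL_FAMILIES)}"
            )
        variational, strategy = MODEL_FAMILIES[family]
        return cls(variational=variational, be_strategy=strategy, **kwargs)


@dataclass
class LatentRepresentation:
    """Per-sample bottleneck embeddings, with Gaussian parameters for VAEs."""

    z: np.ndarray
    mu: Optional[np.ndarray] = None
    sigma: Optional[np.ndarray] = None


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


class CorrectionModel:
    """One member of the model zoo, backed by the numpy autodiff engine."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.batch_order: Optional[list] = None
        init = np.random.default_rng(cfg.seed)
        p: dict[str, Tensor] = {}

        def param(name: str, data: np.ndarray) -> None:
            p[name] = Tensor(data, requires_grad=True, name=name)

        f, h, d = cfg.n_features, cfg.layer1, cfg.layer2
        param("enc_w1", _glorot(init, f, h))
        param("enc_b1", np.zeros(h))
        if cfg.variational:
            param("enc_wmu", _glorot(init, h, d))
            param("enc_bmu", np.zeros(d))
            param("enc_wlv", _glorot(init, h, d))
            param("enc_blv", np.zeros(d))
        else:
            param("enc_w2", _glorot(init, h, d))
            param("enc_b2", np.zeros(d))
        param("dec_w1", _glorot(init, d, h))
        param("dec_b1", np.zeros(h))
        param("dec_w2", _glorot(init, h, f))
        param("dec_b2", np.zeros(f))
        param("cls_w", _glorot(init, d, cfg.n_classes))
        param("cls_b", np.zeros(cfg.n_classes))
        if cfg.be_strategy in ("dann", "batch_mapping_adversarial"):
            param("disc_w", _glorot(init, d, cfg.n_batches))
            param("disc_b", np.zeros(cfg.n_batches))
        if cfg.be_strategy == "batch_mapping_adversarial":
            # zero-initialized so the batch mapping starts as the identity
            param("batch_emb", np.zeros((cfg.n_batches, d)))
        self.params = p

    # ------------------------------------------------------------------
    # parameter groups
    # ------------------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def encoder_parameters(self) -> list[Tensor]:
        return [t for n, t in self.params.items() if n.startswith("enc_")]

    def decoder_parameters(self) -> list[Tensor]:
        return [
            t
            for n, t in self.params.items()
            if n.startswith("dec_") or n == "batch_emb"
        ]

    def classifier_parameters(self) -> list[Tensor]:
        return [t for n, t in self.params.items() if n.startswith("cls_")]

    def discriminator_parameters(self) -> list[Tensor]:
        return [t for n, t in self.params.items() if n.startswith("disc_")]

    def reseed(self, seed: int) -> None:
        """Reset the stochastic state used for dropout and VAE noise."""
        self.rng = np.random.default_rng(seed)

    def state_hash(self, names: Optional[Sequence[str]] = None) -> str:
        import hashlib

        h = hashlib.sha256()
        for name in sorted(names if names is not None else self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name].data).tobytes())
        return h.hexdigest()

    # ------------------------------------------------------------------
    # forward passes (Tensor graph)
    # ------------------------------------------------------------------
    def encode_t(
        self, x: Tensor, training: bool = False, sample_noise: bool = False
    ) -> tuple[Tensor, Optional[Tensor], Optional[Tensor]]:
        cfg = self.cfg
        if x.shape[-1] != cfg.n_features:
            raise ValueError(
                f"input has {x.shape[-1]} features, model expects {cfg.n_features}"
            )
        h = ag.relu(x @ self.params["enc_w1"] + self.params["enc_b1"])
        h = ag.dropout(h, cfg.dropout, self.rng, training)
        if not cfg.variational:
            z = h @ self.params["enc_w2"] + self.params["enc_b2"]
            return z, None, None
        mu = h @ self.params["enc_wmu"] + self.params["enc_bmu"]
        logvar = h @ self.params["enc_wlv"] + self.params["enc_blv"]
        sigma = ag.exp(ag.mul(logvar, 0.5))
        if sample_noise:
            eps = self.rng.standard_normal(mu.shape)
            z = mu + sigma * Tensor(eps)
        else:
            z = mu + sigma * Tensor(np.zeros(mu.shape))
        return z, mu, sigma

    def decode_t(self, z: Tensor, batch_codes: Optional[np.ndarray] = None) -> Tensor:
        cfg = self.cfg
        if cfg.be_strategy == "batch_mapping_adversarial":
            if batch_codes is None:
                raise ValueError("batch labels are required for batch-mapping models")
            z = z + ag.embedding(self.params["batch_emb"], batch_codes)
        h = ag.relu(z @ self.params["dec_w1"] + self.params["dec_b1"])
        return h @ self.params["dec_w2"] + self.params["dec_b2"]

    def classify_t(self, z: Tensor, training: bool = False) -> Tensor:
        z = ag.dropout(z, self.cfg.dropout, self.rng, training)
        return z @ self.params["cls_w"] + self.params["cls_b"]

    def batch_logits_t(self, z: Tensor) -> Tensor:
        if "disc_w" not in self.params:
            raise ValueError(
                f"model family {self.cfg.family!r} has no batch classifier head"
            )
        return z @ self.params["disc_w"] + self.params["disc_b"]

    # ------------------------------------------------------------------
    # public numpy API
    # ------------------------------------------------------------------
    def encode(self, x: np.ndarray, sample_noise: bool = False) -> LatentRepresentation:
        z, mu, sigma = self.encode_t(as_tensor(x), training=False, sample_noise=sample_noise)
        return LatentRepresentation(
            z=z.data.copy(),
            mu=None if mu is None else mu.data.copy(),
            sigma=None if sigma is None else sigma.data.copy(),
        )

    def _codes_for(self, batch_labels: Sequence) -> np.ndarray:
        labels = np.asarray(batch_labels, dtype=object)
        if labels.dtype == object and self.batch_order is not None:
            order = {b: i for i, b in enumerate(self.batch_order)}
            codes = []
            for b in labels:
                if b not in order:
                    raise ValueError(f"unknown batch label at inference: {b!r}")
                codes.append(order[b])
            return np.asarray(codes, dtype=np.int64)
        codes = labels.astype(np.int64)
        if (codes < 0).any() or (codes >= self.cfg.n_batches).any():
            bad = codes[(codes < 0) | (codes >= self.cfg.n_batches)][0]
            raise ValueError(f"unknown batch label at inference: {bad!r}")
        return codes

    def decode(
        self,
        rep: Union[LatentRepresentation, np.ndarray],
        batch_labels: Optional[Sequence] = None,
    ) -> np.ndarray:
        z = rep.z if isinstance(rep, LatentRepresentation) else np.asarray(rep)
        codes = None
        if self.cfg.be_strategy == "batch_mapping_adversarial":
            if batch_labels is None:
                raise ValueError("batch labels are required for batch-mapping models")
            codes = self._codes_for(batch_labels)
        return self.decode_t(as_tensor(z), codes).data.copy()

    def predict_labels(self, x: np.ndarray) -> np.ndarray:
        z, _, _ = self.encode_t(as_tensor(x), training=False, sample_noise=False)
        logits = self.classify_t(z, training=False)
        return logits.data.argmax(axis=1)

    # ------------------------------------------------------------------
    # checkpointing (single-file JSON archive)
    # ------------------------------------------------------------------
    def save(self, path: Union[str, Path]) -> None:
        cfg = asdict(self.cfg)
        cfg["normalization"] = asdict(self.cfg.normalization)
        payload = {
            "config": cfg,
            "batch_order": self.batch_order,
            "params": {n: t.data.tolist() for n, t in self.params.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "CorrectionModel":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        cfg["normalization"] = NormalizationSpec(**cfg["normalization"])
        model = cls(ModelConfig(**cfg))
        model.batch_order = payload["batch_order"]
        for name, data in payload["params"].items():
            model.params[name].data = np.asarray(data, dtype=np.float64)
        return model


def build_model(cfg: ModelConfig) -> CorrectionModel:
    """Instantiate one zoo member; initialization is seeded from cfg.seed."""
    return CorrectionModel(cfg)


# ----------------------------------------------------------------------
# loss terms
# ----------------------------------------------------------------------

def _maybe_float(t: Tensor, *inputs) -> Union[Tensor, float]:
    """Return a Tensor when any input participates in a graph, else a float."""
    if any(isinstance(x, Tensor) and x.requires_grad for x in inputs):
        return t
    return float(t.data)


def reconstruction_loss(x, x_hat) -> Union[Tensor, float]:
    """Mean squared error over all matrix entries."""
    xt, ht = as_tensor(x), as_tensor(x_hat)
    if xt.shape != ht.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {ht.shape}")
    t = ((ht - xt) ** 2.0).mean()
    return _maybe_float(t, x, x_hat)


def kld_gaussian(mu, sigma) -> Union[Tensor, float]:
    """KL(N(mu, sigma^2) || N(0, I)): per-sample sum over dimensions,
    averaged over samples."""
    mt, st = as_tensor(mu), as_tensor(sigma)
    if (st.data <= 0).any():
        raise ValueError("sigma must be positive element-wise")
    per_elem = ag.mul(
        1.0 + ag.mul(ag.log(st), 2.0) - mt ** 2.0 - st ** 2.0, -0.5
    )
    axis = per_elem.ndim - 1
    t = per_elem.sum(axis=axis)
    if t.ndim > 0:
        t = t.mean()
    return _maybe_float(t, mu, sigma)


def smoothed_cross_entropy(
    logits: Tensor, targets: np.ndarray, n_classes: int, smoothing: float = 0.0
) -> Tensor:
    """Cross-entropy against label-smoothed targets.

    Mass ``1 - smoothing`` on the true class, ``smoothing / (C - 1)``
    spread uniformly over the others.
    """
    targets = np.asarray(targets, dtype=np.int64)
    if (targets < 0).any() or (targets >= n_classes).any():
        bad = targets[(targets < 0) | (targets >= n_classes)][0]
        raise ValueError(f"unknown class index {bad} (n_classes={n_classes})")
    T = np.full((len(targets), n_classes), 0.0)
    if n_classes > 1 and smoothing > 0:
        T += smoothing / (n_classes - 1)
    T[np.arange(len(targets)), targets] = 1.0 - smoothing if n_classes > 1 else 1.0
    ls = ag.log_softmax(logits)
    return ag.mul((as_tensor(T) * ls).sum(axis=1).mean(), -1.0)


def label_classification_loss(
    model: CorrectionModel, z, class_labels, smoothing: Optional[float] = None
) -> Union[Tensor, float]:
    """Smoothed cross-entropy of the label classifier head on z."""
    if smoothing is None:
        smoothing = model.cfg.label_smoothing
    zt = as_tensor(z)
    logits = model.classify_t(zt, training=False)
    t = smoothed_cross_entropy(logits, class_labels, model.cfg.n_classes, smoothing)
    return _maybe_float(t, z, *model.classifier_parameters())


def dann_batch_loss(
    model: CorrectionModel, z, batch_labels, gamma: float, smoothing: float = 0.0
) -> Union[Tensor, float]:
    """Batch cross-entropy behind a gradient reversal layer.

    The scalar is minimized by the discriminator head, whose own gradients
    are untouched, while the encoder receives its gradient multiplied by
    ``-gamma``.
    """
    if model.cfg.n_batches < 2:
        raise ValueError("adversarial batch loss requires >= 2 batches")
    zt = as_tensor(z)
    logits = model.batch_logits_t(gradient_reversal(zt, gamma))
    codes = np.asarray(batch_labels, dtype=np.int64)
    t = smoothed_cross_entropy(logits, codes, model.cfg.n_batches, smoothing)
    return _maybe_float(t, z, *model.discriminator_parameters())


def normae_batch_loss(
    model: CorrectionModel,
    z,
    batch_labels,
    gamma: float,
    detach: bool = False,
    smoothing: float = 0.0,
) -> Union[Tensor, float]:
    """Discriminator cross-entropy for the GRL-free min-max strategy.

    With ``detach=True`` the bottleneck is cut from the graph (the
    discriminator update step); the encoder/decoder step subtracts
    ``gamma`` times this loss from the composite objective, which is
    clamped at 0 from below (see :func:`clamped_adversarial_total`).
    """
    if model.cfg.be_strategy != "batch_mapping_adversarial":
        raise ValueError("normae_batch_loss requires be_strategy='batch_mapping_adversarial'")
    if model.cfg.n_batches < 2:
        raise ValueError("adversarial batch loss requires >= 2 batches")
    zt = as_tensor(z)
    if detach:
        zt = zt.detach()
    logits = model.batch_logits_t(zt)
    codes = np.asarray(batch_labels, dtype=np.int64)
    t = smoothed_cross_entropy(logits, codes, model.cfg.n_batches, smoothing)
    return _maybe_float(t, z, *model.discriminator_parameters())


def clamped_adversarial_total(other_losses: Tensor, disc_loss: Tensor, gamma: float) -> Tensor:
    """``max(other_losses - gamma * disc_loss, 0)``: the min-max composite
    objective is not allowed to become negative."""
    composite = other_losses - ag.mul(disc_loss, gamma)
    return ag.relu(composite)


def _pair_distance(a: Tensor, b: Tensor) -> Tensor:
    diff = a - b
    axis = diff.ndim - 1
    return ag.sqrt((diff ** 2.0).sum(axis=axis) + 1e-24)


def inv_triplet_loss(fA, fP, fN, alpha: float) -> Union[Tensor, float]:
    """max(||A - N|| - ||A - P|| + alpha, 0), averaged over triplets.

    Positive/negative roles are inverted relative to the standard triplet
    loss: different-batch samples are pulled together, same-batch samples
    pushed apart.
    """
    a, p, n = as_tensor(fA), as_tensor(fP), as_tensor(fN)
    if not (a.shape == p.shape == n.shape):
        raise ValueError("triplet embeddings must share the same shape")
    hinge = ag.relu(_pair_distance(a, n) - _pair_distance(a, p) + alpha)
    t = hinge.mean() if hinge.ndim > 0 else hinge
    return _maybe_float(t, fA, fP, fN)


def rev_triplet_loss(fA, fP, fN, alpha: float) -> Union[Tensor, float]:
    """Standard batch-triplet hinge max(||A - P|| - ||A - N|| + alpha, 0).

    During training the embeddings are passed through the gradient
    reversal layer first, so the encoder is driven toward batch mixing.
    """
    a, p, n = as_tensor(fA), as_tensor(fP), as_tensor(fN)
    if not (a.shape == p.shape == n.shape):
        raise ValueError("triplet embeddings must share the same shape")
    hinge = ag.relu(_pair_distance(a, p) - _pair_distance(a, n) + alpha)
    t = hinge.mean() if hinge.ndim > 0 else hinge
    return _maybe_float(t, fA, fP, fN)


def total_loss(
    rec,
    classif=None,
    kld=None,
    be=None,
    nu: float = 1.0,
    beta: float = 1.0,
    gamma: float = 1.0,
) -> Union[Tensor, float]:
    """Weighted composite  rec + nu*classif + beta*kld + gamma*be.

    Absent terms contribute 0.  Negative weights are rejected.
    """
    if nu < 0 or beta < 0 or gamma < 0:
        raise ValueError("loss weights must be >= 0")
    total = as_tensor(rec)
    if classif is not None:
        total = total + ag.mul(as_tensor(classif), nu)
    if kld is not None:
        total = total + ag.mul(as_tensor(kld), beta)
    if be is not None:
        total = total + ag.mul(as_tensor(be), gamma)
    return _maybe_float(total, rec, classif, kld, be)
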