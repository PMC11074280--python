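"""Sequential hyperparameter search maximizing mean validation MCC.

The sampler is a Gaussian-process surrogate (upper-confidence-bound
acquisition over random candidates) with a pure-random fallback; both are
fully seeded.  Conditional parameters (triplet margin, KLD beta, batch
gamma) are only sampled for families that use them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_data import NORMALIZATION_VARIANTS, NormalizationSpec, OmicsMatrix, preprocess
from .networks import MODEL_FAMILIES, ModelConfig, build_model
from .splitting import HoldoutSplit
from .training import TrainerConfig, fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchSpace:
    """Ranges/choices; pairs are (low, high), log-uniform where noted."""

    learning_rate: tuple = (1e-5, 1e-2)  # log-uniform
    weight_decay: tuple = (1e-8, 1e-2)  # log-uniform
    dropout: tuple = (0.0, 0.5)
    warmup_epochs: tuple = (10, 250)  # integer
    layer1: tuple = (32, 1024)  # integer; layer2 <= layer1 enforced
    layer2: tuple = (16, 256)  # integer
    label_smoothing: tuple = (0.0, 0.2)
    margin: tuple = (0.0, 10.0)  # triplet strategies only
    beta: tuple = (1e-4, 10.0)  # log-uniform; variational only
    gamma: tuple = (1e-4, 10.0)  # log-uniform; batch-effect strategies only
    normalization: tuple = NORMALIZATION_VARIANTS

    _LOG_PARAMS = ("learning_rate", "weight_decay", "beta", "gamma")
    _INT_PARAMS = ("warmup_epochs", "layer1", "layer2")

    def conditional_names(self, family: str) -> list[str]:
        variational, strategy = MODEL_FAMILIES[family]
        names = [
            "learning_rate",
            "weight_decay",
            "dropout",
            "warmup_epochs",
            "layer1",
            "layer2",
            "label_smoothing",
            "normalization",
        ]
        if strategy in ("inv_triplet", "rev_triplet"):
            names.append("margin")
        if variational:
            names.append("beta")
        if strategy != "none":
            names.append("gamma")
        return names

    def sample(self, rng: np.random.Generator, family: str) -> dict:
        params: dict = {}
        for name in self.conditional_names(family):
            bounds = getattr(self, name)
            if name == "normalization":
                params[name] = bounds[rng.integers(len(bounds))]
            elif name in self._LOG_PARAMS:
                lo, hi = np.log(bounds[0]), np.log(bounds[1])
                params[name] = float(np.exp(rng.uniform(lo, hi)))
            elif name in self._INT_PARAMS:
                params[name] = int(rng.integers(bounds[0], bounds[1] + 1))
            else:
                params[name] = float(rng.uniform(bounds[0], bounds[1]))
        if "layer2" in params and "layer1" in params:
            params["layer2"] = min(params["layer2"], params["layer1"])
        return params

    def encode(self, params: dict, family: str) -> np.ndarray:
        """Numeric encoding of a configuration for the GP surrogate."""
        vec = []
        for name in self.conditional_names(family):
            v = params[name]
            if name == "normalization":
                vec.append(float(self.normalization.index(v)))
            elif name in self._LOG_PARAMS:
                vec.append(float(np.log(v)))
            else:
                vec.append(float(v))
        return np.asarray(vec)


@dataclass
class Trial:
    index: int
    params: dict
    objective: float
    per_split: list[float] = field(default_factory=list)
    error: Optional[str] = None


def _propose(
    space: SearchSpace,
    family: str,
    rng: np.random.Generator,
    history: list[Trial],
    sampler: str,
    n_init: int = 5,
    n_candidates: int = 64,
) -> dict:
    done = [t for t in history if np.isfinite(t.objective)]
    if sampler != "gp" or len(done) < n_init:
        return space.sample(rng, family)
    try:
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import Matern

        X = np.vstack([space.encode(t.params, family) for t in done])
        y = np.array([t.objective for t in done])
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), normalize_y=True, alpha=1e-4, random_state=0
        )
        gp.fit(X / scale, y)
        candidates = [space.sample(rng, family) for _ in range(n_candidates)]
        Xc = np.vstack([space.encode(c, family) for c in candidates]) / scale
        mean, std = gp.predict(Xc, return_std=True)
        return candidates[int(np.argmax(mean + std))]  # UCB acquisition
    except Exception as err:  # pragma: no cover - surrogate is best-effort
        logger.warning("GP surrogate failed (%s); falling back to random", err)
        return space.sample(rng, family)


def search(
    space: SearchSpace,
    model_family: str,
    data: OmicsMatrix,
    splits: Sequence[HoldoutSplit],
    n_trials: int = 20,
    seed: int = 0,
    sampler: str = "gp",
    scenario: int = 2,
    tc: Optional[TrainerConfig] = None,
    warmup_epochs: Optional[int] = None,
) -> tuple[ModelConfig, list[Trial]]:
    """Run `n_trials` train+evaluate rounds and return the best ModelConfig.

    The objective is the unweighted mean of the best validation MCC over
    all splits.  Failed trials are recorded with objective -inf; if every
    trial fails, the first failure is re-raised.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if model_family not in MODEL_FAMILIES:
        raise ValueError(
            f"unknown model family {model_family!r}; valid families: "
            f"{sorted(MODEL_FAMILIES)}"
        )
    rng = np.random.default_rng(seed)
    history: list[Trial] = []
    first_error: Optional[BaseException] = None

    for t in range(n_trials):
        params = _propose(space, model_family, rng, history, sampler)
        try:
            per_split = _evaluate_params(
                params, model_family, data, splits, seed, t, scenario, tc, warmup_epochs
            )
            history.append(
                Trial(t, params, float(np.mean(per_split)), per_split=per_split)
            )
        except Exception as err:
            if first_error is None:
                first_error = err
            logger.warning("trial %d failed: %s", t, err)
            history.append(Trial(t, params, float("-inf"), error=str(err)))

    if not any(np.isfinite(t.objective) for t in history):
        raise RuntimeError("all hyperparameter trials failed") from first_error
    best = max(history, key=lambda t: t.objective)
    cfg = _config_from_params(best.params, model_family, data, seed)
    return cfg, history


def _config_from_params(
    params: dict, family: str, data: OmicsMatrix, seed: int
) -> ModelConfig:
    kwargs = dict(params)
    kwargs["normalization"] = NormalizationSpec.from_name(kwargs.pop("normalization"))
    return ModelConfig.for_family(
        family,
        n_features=data.n_features,
        n_classes=len(data.classes),
        n_batches=data.n_batches,
        seed=seed,
        **kwargs,
    )


def _evaluate_params(
    params: dict,
    family: str,
    data: OmicsMatrix,
    splits: Sequence[HoldoutSplit],
    seed: int,
    trial_index: int,
    scenario: int,
    tc: Optional[TrainerConfig],
    warmup_epochs: Optional[int],
) -> list[float]:
    cfg = _config_from_params(params, family, data, seed)
    pre = preprocess(data, cfg.normalization)
    scores = []
    for split in splits:
        run_cfg = ModelConfig(**{**cfg.__dict__, "seed": int(seed * 1000 + trial_index)})
        model = build_model(run_cfg)
        state = fit(model, pre, split, scenario=scenario, tc=tc, warmup_epochs=warmup_epochs)
        scores.append(state.best_valid_mcc)
    return scores
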