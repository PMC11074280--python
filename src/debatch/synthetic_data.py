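"""Multi-batch LC-MS-like data simulation with known ground truth.

Signal is composed on the log scale — log-normal baseline feature means,
class shifts on a random feature subset, per-batch additive offsets and
multiplicative factors, an optional monotone per-batch warp, Gaussian
noise — then exponentiated to the intensity scale, floored at 0, and
zero-coded at the requested missing rate.  Pooled-QC replicates are the
global mean profile plus the batch effect plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import OmicsMatrix

QC_CLASS = "QC"


@dataclass(frozen=True)
class SimulationSpec:
    n_batches: int = 6
    samples_per_batch: int = 40
    n_features: int = 200
    n_classes: int = 2
    class_effect_size: float = 1.0  # mean shift in noise-sd units
    class_effect_fraction: float = 0.1  # fraction of features carrying it
    batch_additive_sd: float = 1.0
    batch_multiplicative_sd: float = 0.0
    nonlinear_warp: bool = False
    missing_rate: float = 0.0
    qc_per_batch: int = 0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_batches, self.samples_per_batch, self.n_features, self.n_classes) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.class_effect_fraction <= 1.0:
            raise ValueError("class_effect_fraction must lie in [0, 1]")
        if self.qc_per_batch < 0:
            raise ValueError("qc_per_batch must be >= 0")
        if min(self.batch_additive_sd, self.batch_multiplicative_sd, self.noise_sd) < 0:
            raise ValueError("spread parameters must be >= 0")
        if self.class_effect_size < 0:
            raise ValueError("class_effect_size must be >= 0")


def generate(spec: SimulationSpec) -> tuple[OmicsMatrix, dict]:
    """Simulate an annotated intensity matrix plus its ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    F, B, C = spec.n_features, spec.n_batches, spec.n_classes

    # log-scale feature means (log-normal intensities); kept well above 0 so
    # zero-coded entries come from missing_rate, not from the intensity floor
    baseline = rng.normal(4.0, 1.0, size=F)
    n_effect = int(round(spec.class_effect_fraction * F))
    effect_features = rng.choice(F, size=n_effect, replace=False)
    class_shift = np.zeros((C, F))
    for c in range(C):
        signs = rng.choice([-1.0, 1.0], size=n_effect)
        class_shift[c, effect_features] = (
            c * spec.class_effect_size * spec.noise_sd * signs
        )

    batch_add = rng.normal(0.0, spec.batch_additive_sd, size=(B, F))
    batch_mul = np.exp(rng.normal(0.0, spec.batch_multiplicative_sd, size=(B, F)))
    warp_strength = (
        np.abs(rng.normal(0.0, 0.15, size=B)) if spec.nonlinear_warp else np.zeros(B)
    )

    rows, sample_ids, batch_labels, class_labels, qc_flags = [], [], [], [], []
    for b in range(B):
        for s in range(spec.samples_per_batch):
            c = (b * spec.samples_per_batch + s) % C  # balanced classes
            log_sig = baseline + class_shift[c] + rng.normal(0.0, spec.noise_sd, size=F)
            rows.append(_apply_batch(log_sig, b, batch_add, batch_mul, warp_strength, baseline))
            sample_ids.append(f"b{b}_s{s}")
            batch_labels.append(f"batch{b}")
            class_labels.append(f"class{c}")
            qc_flags.append(False)
        for q in range(spec.qc_per_batch):
            log_sig = baseline + rng.normal(0.0, spec.noise_sd, size=F)
            rows.append(_apply_batch(log_sig, b, batch_add, batch_mul, warp_strength, baseline))
            sample_ids.append(f"b{b}_qc{q}")
            batch_labels.append(f"batch{b}")
            class_labels.append(QC_CLASS)
            qc_flags.append(True)

    log_values = np.vstack(rows)
    values = np.maximum(np.expm1(np.maximum(log_values, 0.0)), 0.0)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values[mask] = 0.0

    matrix = OmicsMatrix(
        values=values,
        sample_ids=sample_ids,
        feature_ids=[f"feat{j}" for j in range(F)],
        batch_labels=np.asarray(batch_labels, dtype=object),
        class_labels=np.asarray(class_labels, dtype=object),
        qc_flags=np.asarray(qc_flags, dtype=bool),
    )
    truth = {
        "baseline_log_means": baseline,
        "effect_features": np.sort(effect_features),
        "class_shift": class_shift,
        "batch_additive": batch_add,
        "batch_multiplicative": batch_mul,
        "warp_strength": warp_strength,
        "seed": spec.seed,
    }
    return matrix, truth


def _apply_batch(
    log_sig: np.ndarray,
    b: int,
    batch_add: np.ndarray,
    batch_mul: np.ndarray,
    warp_strength: np.ndarray,
    baseline: np.ndarray,
) -> np.ndarray:
    y = log_sig * batch_mul[b] + batch_add[b]
    if warp_strength[b] > 0:
        # monotone cubic on centered log intensities: y + w * ((y - m)/s)^3 * s
        centered = (y - baseline) / 1.0
        y = y + warp_strength[b] * centered ** 3
    return y
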