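"""Annotated intensity matrices, file I/O, and the preprocessing pipeline.

An :class:`OmicsMatrix` holds a non-negative samples x features intensity
matrix together with per-sample batch labels, class labels and QC flags.
Missing values are zero-coded at load time.  Preprocessing is ``log1p``
followed by one of six normalization variants (minmax/standard/robust,
each optionally fitted per batch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NORMALIZATION_METHODS = ("minmax", "standard", "robust")

#: The six concrete normalization variants selectable as a hyperparameter.
NORMALIZATION_VARIANTS = (
    "minmax",
    "standard",
    "robust",
    "minmax_per_batch",
    "standard_per_batch",
    "robust_per_batch",
)


@dataclass(frozen=True)
class NormalizationSpec:
    """One of the six normalization variants, plus whether log1p was applied."""

    method: str = "standard"
    per_batch: bool = False
    log_applied: bool = True

    def __post_init__(self) -> None:
        if self.method not in NORMALIZATION_METHODS:
            raise ValueError(
                f"unknown normalization method {self.method!r}; "
                f"expected one of {NORMALIZATION_METHODS}"
            )

    @property
    def name(self) -> str:
        return self.method + ("_per_batch" if self.per_batch else "")

    @classmethod
    def from_name(cls, name: str, log_applied: bool = True) -> "NormalizationSpec":
        if name not in NORMALIZATION_VARIANTS:
            raise ValueError(
                f"unknown normalization {name!r}; expected one of {NORMALIZATION_VARIANTS}"
            )
        per_batch = name.endswith("_per_batch")
        method = name[: -len("_per_batch")] if per_batch else name
        return cls(method=method, per_batch=per_batch, log_applied=log_applied)


@dataclass
class OmicsMatrix:
    """Samples x features intensity matrix with per-sample annotations."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    batch_labels: np.ndarray
    class_labels: np.ndarray
    qc_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        n = self.values.shape[0]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.batch_labels = np.asarray(self.batch_labels, dtype=object)
        self.class_labels = np.asarray(self.class_labels, dtype=object)
        if self.qc_flags is None:
            self.qc_flags = np.zeros(n, dtype=bool)
        self.qc_flags = np.asarray(self.qc_flags, dtype=bool)
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match values")
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature_ids length does not match values")
        for name, arr in (
            ("batch_labels", self.batch_labels),
            ("class_labels", self.class_labels),
            ("qc_flags", self.qc_flags),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length does not match number of samples")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs")
        if np.isnan(self.values).any():
            raise ValueError("values contain NaN; missing entries must be zero-coded")
        # non-negativity of raw intensities is enforced at load/generation
        # time; normalized views may hold negative values

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def batches(self) -> list:
        """Distinct batch labels in sorted order."""
        return sorted(set(self.batch_labels.tolist()), key=str)

    @property
    def classes(self) -> list:
        """Distinct class labels of non-QC samples, sorted."""
        return sorted(set(self.class_labels[~self.qc_flags].tolist()), key=str)

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    def batch_indices(self) -> np.ndarray:
        """Integer batch codes aligned with :attr:`batches`."""
        order = {b: i for i, b in enumerate(self.batches)}
        return np.array([order[b] for b in self.batch_labels], dtype=np.int64)

    def class_indices(self) -> np.ndarray:
        """Integer class codes aligned with :attr:`classes` (QC rows get -1)."""
        order = {c: i for i, c in enumerate(self.classes)}
        return np.array(
            [order.get(c, -1) for c in self.class_labels], dtype=np.int64
        )

    def with_values(self, values: np.ndarray) -> "OmicsMatrix":
        return replace(self, values=np.asarray(values, dtype=np.float64))

    def subset(self, rows: Union[np.ndarray, Sequence[int]]) -> "OmicsMatrix":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return OmicsMatrix(
            values=self.values[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            feature_ids=list(self.feature_ids),
            batch_labels=self.batch_labels[rows],
            class_labels=self.class_labels[rows],
            qc_flags=self.qc_flags[rows],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OmicsMatrix):
            return NotImplemented
        return (
            np.array_equal(self.values, other.values)
            and self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.batch_labels, other.batch_labels)
            and np.array_equal(self.class_labels, other.class_labels)
            and np.array_equal(self.qc_flags, other.qc_flags)
        )


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a delimited text table; TSV by default, comma autodetected."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")


def load_matrix(
    path: Union[str, Path], annotation_path: Union[str, Path]
) -> OmicsMatrix:
    """Load an intensity matrix and its sample annotations.

    The matrix file has feature IDs in the first row and sample IDs in the
    first column.  The annotation file has columns ``sample_id``, ``batch``,
    ``label`` and ``is_qc``.  Empty cells become 0; negative or unparseable
    cells raise; samples missing from the annotation raise an error naming
    the sample.
    """
    df = _read_table(path)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in matrix file: {dupes}")
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as err:
        raise ValueError(f"unparseable cell in matrix file {path}: {err}") from err
    if (np.nan_to_num(values, nan=0.0) < 0).any():
        raise ValueError("matrix file contains negative intensities")
    values = np.nan_to_num(values, nan=0.0)  # empty cells -> 0

    ann = _read_table(annotation_path)
    ann.index = ann.index.map(str)
    required = {"batch", "label", "is_qc"}
    missing_cols = required - set(ann.columns)
    if missing_cols:
        raise ValueError(f"annotation file lacks columns: {sorted(missing_cols)}")

    sample_ids = [str(s) for s in df.index]
    missing = [s for s in sample_ids if s not in ann.index]
    if missing:
        raise ValueError(f"annotation missing for sample(s): {missing}")
    ann = ann.loc[sample_ids]
    return OmicsMatrix(
        values=values,
        sample_ids=sample_ids,
        feature_ids=[str(f) for f in df.columns],
        batch_labels=ann["batch"].to_numpy(dtype=object),
        class_labels=ann["label"].to_numpy(dtype=object),
        qc_flags=ann["is_qc"].to_numpy().astype(int).astype(bool),
    )


def save_matrix(
    m: OmicsMatrix, path: Union[str, Path], annotation_path: Union[str, Path]
) -> None:
    """Write the matrix and annotations as TSV (inverse of :func:`load_matrix`)."""
    df = pd.DataFrame(m.values, index=m.sample_ids, columns=m.feature_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")  # exact float round-trip
    ann = pd.DataFrame(
        {
            "batch": m.batch_labels,
            "label": m.class_labels,
            "is_qc": m.qc_flags.astype(int),
        },
        index=pd.Index(m.sample_ids, name="sample_id"),
    )
    ann.to_csv(annotation_path, sep="\t")


# ----------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------

def log1p_transform(m: OmicsMatrix) -> OmicsMatrix:
    """Apply ln(1 + v) entrywise; zeros stay zero."""
    if (m.values < 0).any():
        raise ValueError("log1p_transform requires non-negative values")
    return m.with_values(np.log1p(m.values))


def _fit_stats(method: str, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (center, scale) for one normalization method."""
    if method == "minmax":
        lo = x.min(axis=0)
        scale = x.max(axis=0) - lo
        return lo, scale
    if method == "standard":
        return x.mean(axis=0), x.std(axis=0)
    if method == "robust":
        q25, q50, q75 = np.percentile(x, [25, 50, 75], axis=0)
        return q50, q75 - q25
    raise ValueError(f"unknown normalization method {method!r}")


def _apply_stats(
    x: np.ndarray, center: np.ndarray, scale: np.ndarray
) -> np.ndarray:
    zero = scale <= 0
    if zero.any():
        logger.warning(
            "%d zero-variance/zero-range feature(s) set to 0 during normalization",
            int(zero.sum()),
        )
    safe = np.where(zero, 1.0, scale)
    out = (x - center) / safe
    out[:, zero] = 0.0
    return out


def normalize(
    m: OmicsMatrix,
    spec: NormalizationSpec,
    fit_on: Optional[np.ndarray] = None,
) -> OmicsMatrix:
    """Scale each feature according to `spec`.

    ``fit_on`` restricts the samples used to compute the statistics (a
    boolean mask); by default statistics are fitted on all samples,
    matching the transductive whole-dataset protocol.  With
    ``spec.per_batch`` the statistics are computed and applied within each
    batch independently.
    """
    if fit_on is None:
        fit_on = np.ones(m.n_samples, dtype=bool)
    fit_on = np.asarray(fit_on, dtype=bool)
    if fit_on.shape != (m.n_samples,):
        raise ValueError("fit_on mask must have one entry per sample")
    out = np.empty_like(m.values)
    if spec.per_batch:
        codes = m.batch_indices()
        for b in range(m.n_batches):
            rows = codes == b
            fit_rows = rows & fit_on
            if not fit_rows.any():
                fit_rows = rows  # fall back to the batch itself
            if spec.method in ("standard", "robust") and fit_rows.sum() < 2:
                raise ValueError(
                    f"per-batch {spec.method} normalization needs >= 2 samples "
                    f"per batch; batch {m.batches[b]!r} has {int(fit_rows.sum())}"
                )
            center, scale = _fit_stats(spec.method, m.values[fit_rows])
            out[rows] = _apply_stats(m.values[rows], center, scale)
    else:
        center, scale = _fit_stats(spec.method, m.values[fit_on])
        out = _apply_stats(m.values, center, scale)
    return m.with_values(out)


def preprocess(
    m: OmicsMatrix,
    spec: NormalizationSpec,
    fit_on: Optional[np.ndarray] = None,
) -> OmicsMatrix:
    """log1p (if ``spec.log_applied``) followed by :func:`normalize`."""
    if spec.log_applied:
        m = log1p_transform(m)
    return normalize(m, spec, fit_on=fit_on)
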