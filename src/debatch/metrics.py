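"""Evaluation metrics.

Batch-mixing metrics built on a 20-nearest-neighbour batch classifier
(normalized batch entropy, adjusted Rand index, adjusted mutual
information), pooled-QC reproducibility metrics (average pairwise Pearson
correlation and normalized median Euclidean distance), and classification
metrics (Matthews correlation coefficient, accuracy).

ARI, AMI and MCC are computed directly from the contingency/confusion
table rather than delegated to a library, so that the test suite can
check them against independent oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist
from scipy.special import gammaln
from sklearn.neighbors import NearestNeighbors

from .core_data import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BatchProbabilities:
    """Per-sample batch membership probabilities from the KNN classifier."""

    probs: np.ndarray  # (n_samples, K)
    batch_order: list

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != len(self.batch_order):
            raise ValueError("probs must be (n_samples, K) with K = len(batch_order)")
        if (p < 0).any() or (p > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each probability row must sum to 1")
        object.__setattr__(self, "probs", p)

    @property
    def n_batches(self) -> int:
        return len(self.batch_order)

    def predictions(self) -> np.ndarray:
        """Argmax batch per sample; ties broken by batch_order position."""
        idx = self.probs.argmax(axis=1)
        return np.asarray([self.batch_order[i] for i in idx], dtype=object)


@dataclass
class EvaluationReport:
    """All metrics for one representation of one dataset."""

    mcc: Optional[float] = None
    accuracy: Optional[float] = None
    nbe: Optional[float] = None
    ari: Optional[float] = None
    ami: Optional[float] = None
    qc_apcc: Optional[float] = None
    qc_nmed: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


# ----------------------------------------------------------------------
# KNN batch classifier
# ----------------------------------------------------------------------

def knn_batch_probabilities(
    embeddings: np.ndarray,
    batch_labels: Sequence,
    k: int = 20,
    include_self: bool = True,
) -> BatchProbabilities:
    """Relative batch frequencies among each sample's k nearest neighbours.

    Euclidean distance; by default the neighbourhood of a sample includes
    the sample itself (as when fitting and predicting a KNN classifier on
    the same data).  Set ``include_self=False`` for leave-self-out
    neighbourhoods.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("embeddings must be a 2-D (samples x d) array")
    labels = np.asarray(batch_labels, dtype=object)
    n = X.shape[0]
    if labels.shape[0] != n:
        raise ValueError("batch_labels must align with embeddings rows")
    if k < 1:
        raise ValueError("k must be a positive integer")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")

    batch_order = sorted(set(labels.tolist()), key=str)
    code = {b: i for i, b in enumerate(batch_order)}
    codes = np.array([code[b] for b in labels], dtype=np.int64)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = idx[:, :k] if include_self else idx[:, 1 : k + 1]

    counts = np.zeros((n, len(batch_order)), dtype=np.float64)
    for j, b in enumerate(batch_order):
        counts[:, j] = (codes[neigh] == j).sum(axis=1)
    return BatchProbabilities(probs=counts / k, batch_order=list(batch_order))


# ----------------------------------------------------------------------
# entropy-based batch mixing
# ----------------------------------------------------------------------

def batch_entropy(p: np.ndarray) -> float:
    """Shannon entropy H(p) = sum p_i ln(1/p_i) in nats, with 0 ln(1/0) := 0."""
    p = np.asarray(p, dtype=np.float64)
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def normalized_batch_entropy(bp: BatchProbabilities) -> float:
    """Mean over samples of (ln K - BE_i) / ln K; 0 = mixed, 1 = separated."""
    K = bp.n_batches
    if K < 2:
        raise ValueError("normalized batch entropy requires K >= 2 batches")
    max_ent = np.log(K)
    per_sample = [(max_ent - batch_entropy(row)) / max_ent for row in bp.probs]
    return float(np.mean(per_sample))


# ----------------------------------------------------------------------
# partition agreement
# ----------------------------------------------------------------------

def contingency_table(pred: Sequence, true: Sequence) -> np.ndarray:
    pred = np.asarray(pred, dtype=object)
    true = np.asarray(true, dtype=object)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal lengths")
    pu = sorted(set(pred.tolist()), key=str)
    tu = sorted(set(true.tolist()), key=str)
    table = np.zeros((len(pu), len(tu)), dtype=np.int64)
    pi = {v: i for i, v in enumerate(pu)}
    ti = {v: i for i, v in enumerate(tu)}
    for p, t in zip(pred, true):
        table[pi[p], ti[t]] += 1
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) / 2.0


def adjusted_rand_index(pred: Sequence, true: Sequence) -> float:
    """Chance-adjusted Rand index from the contingency table."""
    table = contingency_table(pred, true)
    n = table.sum()
    if n < 2:
        raise ValueError("adjusted_rand_index requires >= 2 samples")
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    sum_ij = _comb2(table.astype(np.float64)).sum()
    sum_a = _comb2(a.astype(np.float64)).sum()
    sum_b = _comb2(b.astype(np.float64)).sum()
    expected = sum_a * sum_b / _comb2(np.float64(n))
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(pred: Sequence, true: Sequence) -> float:
    """MI of the two partitions, in nats."""
    table = contingency_table(pred, true).astype(np.float64)
    n = table.sum()
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij > 0:
                mi += (nij / n) * np.log(n * nij / (a[i] * b[j]))
    return float(max(mi, 0.0))


def expected_mutual_information(a: np.ndarray, b: np.ndarray, n: int) -> float:
    """Hypergeometric expectation of MI given the two sets of marginals."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    emi = 0.0
    log_fact = gammaln(np.arange(n + 2) + 1.0)  # log(x!) lookup

    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                term1 = (nij / n) * np.log(n * nij / (ai * bj))
                log_term2 = (
                    log_fact[ai]
                    + log_fact[bj]
                    + log_fact[n - ai]
                    + log_fact[n - bj]
                    - log_fact[n]
                    - log_fact[nij]
                    - log_fact[ai - nij]
                    - log_fact[bj - nij]
                    - log_fact[n - ai - bj + nij]
                )
                emi += term1 * np.exp(log_term2)
    return float(emi)


def adjusted_mutual_information(pred: Sequence, true: Sequence) -> float:
    """AMI = (MI - E[MI]) / (mean(H(pred), H(true)) - E[MI])."""
    table = contingency_table(pred, true)
    n = int(table.sum())
    if n < 2:
        raise ValueError("adjusted_mutual_information requires >= 2 samples")
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    h_pred = _entropy_from_counts(a.astype(np.float64))
    h_true = _entropy_from_counts(b.astype(np.float64))
    mi = mutual_information(pred, true)
    emi = expected_mutual_information(a, b, n)
    normalizer = 0.5 * (h_pred + h_true)
    denom = normalizer - emi
    if abs(denom) < 1e-15:
        # both partitions trivial (or degenerate): MI == EMI == normalizer
        return 1.0 if abs(mi - emi) < 1e-15 and normalizer > 0 else 0.0
    return float((mi - emi) / denom)


# ----------------------------------------------------------------------
# classification
# ----------------------------------------------------------------------

def accuracy(pred: Sequence, true: Sequence) -> float:
    pred = np.asarray(pred, dtype=object)
    true = np.asarray(true, dtype=object)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal lengths")
    return float(np.mean(pred == true))


def mcc(pred: Sequence, true: Sequence) -> float:
    """Matthews correlation coefficient (generalized multiclass form).

    A degenerate denominator (e.g. all predictions in one class) yields 0.
    """
    pred = np.asarray(pred, dtype=object)
    true = np.asarray(true, dtype=object)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have equal lengths")
    # square confusion matrix over the union of labels
    labels = sorted(set(pred.tolist()) | set(true.tolist()), key=str)
    idx = {v: i for i, v in enumerate(labels)}
    C = np.zeros((len(labels), len(labels)), dtype=np.float64)
    for p, t in zip(pred, true):
        C[idx[t], idx[p]] += 1  # rows = true, cols = pred

    t_sum = C.sum(axis=1)  # per true class
    p_sum = C.sum(axis=0)  # per predicted class
    n = C.sum()
    correct = np.trace(C)
    cov_ytyp = correct * n - t_sum @ p_sum
    cov_ypyp = n * n - p_sum @ p_sum
    cov_ytyt = n * n - t_sum @ t_sum
    denom = np.sqrt(cov_ypyp * cov_ytyt)
    if denom == 0:
        logger.warning("MCC denominator degenerate; returning 0 by convention")
        return 0.0
    return float(cov_ytyp / denom)


# ----------------------------------------------------------------------
# QC metrics
# ----------------------------------------------------------------------

def _qc_values(m, qc_flags=None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(m, OmicsMatrix):
        return m.values, m.qc_flags
    if qc_flags is None:
        raise ValueError("qc_flags required when passing a plain array")
    return np.asarray(m, dtype=np.float64), np.asarray(qc_flags, dtype=bool)


def qc_apcc(m, qc_flags: Optional[np.ndarray] = None) -> Optional[float]:
    """Mean pairwise Pearson correlation (across features) of QC samples.

    Returns None when fewer than two QC samples are present.  Pairs
    involving a constant profile are excluded with a warning.
    """
    values, flags = _qc_values(m, qc_flags)
    qc = values[flags]
    if qc.shape[0] < 2:
        return None
    pccs = []
    skipped = 0
    for i in range(qc.shape[0]):
        for j in range(i + 1, qc.shape[0]):
            xi, xj = qc[i], qc[j]
            if xi.std() == 0 or xj.std() == 0:
                skipped += 1
                continue
            pccs.append(float(np.corrcoef(xi, xj)[0, 1]))
    if skipped:
        logger.warning("qc_apcc: %d pair(s) with constant profile excluded", skipped)
    if not pccs:
        return None
    return float(np.mean(pccs))


def qc_nmed(m, qc_flags: Optional[np.ndarray] = None) -> Optional[float]:
    """Median QC pairwise distance over median non-QC pairwise distance."""
    values, flags = _qc_values(m, qc_flags)
    qc = values[flags]
    non_qc = values[~flags]
    if qc.shape[0] < 2 or non_qc.shape[0] < 2:
        return None
    qc_med = float(np.median(pdist(qc)))
    ref_med = float(np.median(pdist(non_qc)))
    if ref_med == 0:
        raise ValueError("median non-QC distance is 0 (degenerate dataset)")
    return qc_med / ref_med


# ----------------------------------------------------------------------
# report assembly
# ----------------------------------------------------------------------

def evaluate_representation(
    embeddings: np.ndarray,
    m: OmicsMatrix,
    label_pred: Optional[Sequence] = None,
    k: int = 20,
) -> EvaluationReport:
    """Assemble classification, batch-mixing and QC metrics into one report.

    Batch metrics are computed on `embeddings`; QC metrics on the same
    representation.  Classification metrics compare ``label_pred`` with the
    class labels of non-QC samples and are omitted when no predictions are
    given.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    if X.shape[0] != m.n_samples:
        raise ValueError("embeddings must be row-aligned with the matrix")
    report = EvaluationReport()

    k_eff = min(k, m.n_samples - 1)
    bp = knn_batch_probabilities(X, m.batch_labels, k=k_eff)
    report.nbe = normalized_batch_entropy(bp)
    report.ari = adjusted_rand_index(bp.predictions(), m.batch_labels)
    report.ami = adjusted_mutual_information(bp.predictions(), m.batch_labels)

    if label_pred is not None:
        mask = ~m.qc_flags
        pred = np.asarray(label_pred, dtype=object)
        if pred.shape[0] == m.n_samples:
            pred = pred[mask]
        true = m.class_labels[mask]
        report.mcc = mcc(pred, true)
        report.accuracy = accuracy(pred, true)

    if int(m.qc_flags.sum()) >= 2:
        report.qc_apcc = qc_apcc(X, m.qc_flags)
        report.qc_nmed = qc_nmed(X, m.qc_flags)
    return report
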