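"""Cross-session subject identification from connectome similarity.

A subject's vectorized connectivity profile is treated as a fingerprint:
for each reference-session connectome, the Pearson similarity to every
target-session connectome is computed, and the predicted identity is
the target with the highest score.  Both directions (session 1 as
reference, then session 2) are evaluated and their accuracies pooled.
Significance is attached by permuting target identities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectomes import ConnMatrix, vectorize_edges

__all__ = ["IdentificationResult", "similarity_scores", "identify", "permutation_test"]


@dataclass
class IdentificationResult:
    """Identification outcome for one reference/target session pair."""

    similarity: np.ndarray  # reference subjects x target subjects, Pearson r
    predicted_ref_to_target: np.ndarray
    predicted_target_to_ref: np.ndarray
    accuracy_ref_to_target: float
    accuracy_target_to_ref: float
    accuracy: float  # pooled (mean of the two directions)
    permutation_p: float | None = None
    n_permutations: int = 0
    meta: dict = field(default_factory=dict)


def _edge_vectors(mats: list[ConnMatrix]) -> np.ndarray:
    labels = mats[0].parcel_labels
    vecs = []
    for i, m in enumerate(mats):
        if m.parcel_labels != labels:
            raise ValueError(f"matrix {i}: parcel labels differ from the first matrix")
        v, _ = vectorize_edges(m)
        if v.std() == 0:
            raise ValueError(f"matrix {i}: zero-variance edge vector; similarity undefined")
        vecs.append(v)
    return np.array(vecs)


def similarity_scores(reference: list[ConnMatrix], target: list[ConnMatrix]) -> np.ndarray:
    """N x N matrix of Pearson similarities between edge fingerprints.

    Entry (i, k) correlates the vectorized edges of reference subject i
    with those of target subject k.
    """
    if len(reference) < 2 or len(reference) != len(target):
        raise ValueError("need the same N >= 2 subjects in reference and target lists")
    r = _edge_vectors(reference)
    t = _edge_vectors(target)
    if reference[0].parcel_labels != target[0].parcel_labels:
        raise ValueError("reference and target parcel labels differ")
    rz = (r - r.mean(axis=1, keepdims=True)) / r.std(axis=1, keepdims=True)
    tz = (t - t.mean(axis=1, keepdims=True)) / t.std(axis=1, keepdims=True)
    return rz @ tz.T / r.shape[1]


def identify(scores: np.ndarray, true_ids: np.ndarray | None = None) -> IdentificationResult:
    """Predict identities by highest similarity, in both directions.

    Reference subject i is identified as the target with the maximal
    score in row i; the transposed matrix gives the reverse direction.
    Ties are broken toward the lowest index with a warning (exact ties
    are measure-zero for real-valued fingerprints).  ``true_ids`` maps
    row/column position to identity; default is position itself.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("score matrix must be square (same subjects in both sessions)")
    n = s.shape[0]
    ids = np.arange(n) if true_ids is None else np.asarray(true_ids)
    if np.any((s == s.max(axis=1, keepdims=True)).sum(axis=1) > 1) or \
       np.any((s == s.max(axis=0, keepdims=True)).sum(axis=0) > 1):
        warnings.warn("tied maximum similarity; breaking toward lowest index", stacklevel=2)
    pred_rt = np.argmax(s, axis=1)
    pred_tr = np.argmax(s.T, axis=1)
    acc_rt = float(np.mean(ids[pred_rt] == ids))
    acc_tr = float(np.mean(ids[pred_tr] == ids))
    return IdentificationResult(
        similarity=s,
        predicted_ref_to_target=pred_rt,
        predicted_target_to_ref=pred_tr,
        accuracy_ref_to_target=acc_rt,
        accuracy_target_to_ref=acc_tr,
        accuracy=(acc_rt + acc_tr) / 2.0,
    )


def permutation_test(scores: np.ndarray, true_ids: np.ndarray | None = None,
                     n_perm: int = 1000, seed: int | None = None,
                     rng: np.random.Generator | None = None) -> IdentificationResult:
    """Permutation p-value for the observed identification accuracy.

    The null distribution relabels target identities uniformly at
    random ``n_perm`` times and recomputes pooled accuracy under each
    relabeling; p = (1 + #{null >= observed}) / (n_perm + 1), the
    add-one estimator, so p is never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    res = identify(scores, true_ids)
    n = res.similarity.shape[0]
    if rng is None:
        rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    pred_rt, pred_tr = res.predicted_ref_to_target, res.predicted_target_to_ref
    for b in range(n_perm):
        perm = rng.permutation(n)  # permuted target identities
        acc_rt = np.mean(perm[pred_rt] == np.arange(n))
        acc_tr = np.mean(pred_tr == perm)
        null[b] = (acc_rt + acc_tr) / 2.0
    p = (1 + int(np.sum(null >= res.accuracy))) / (n_perm + 1)
    res.permutation_p = p
    res.n_permutations = n_perm
    res.meta["null_accuracy_mean"] = float(null.mean())
    return res
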