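"""CPM-style brain-behavior predictive modeling.

Connectome-based predictive modeling (CPM): correlate each edge with a
behavioral trait across subjects, keep edges past a p-value threshold
split by correlation sign, summarize each subject by the summed weight
over the kept edges ("network strength"), and fit a linear model from
strength to trait.  The whole procedure — edge statistics, selection,
fit — is repeated inside a leave-one-out cross-validation loop so that
the left-out subject never informs the model that predicts it.  The
predicted-vs-observed Pearson r is the headline statistic; families of
such models (traits x subnetworks x signs x edge-weight kinds) are
corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectomes import ConnMatrix, GroupingScheme, edge_index_map, vectorize_edges

__all__ = [
    "EdgeStats",
    "CpmResult",
    "edge_behavior_corr",
    "select_edges",
    "network_strength",
    "loocv_predict",
    "fdr_correct",
    "run_matrix_of_models",
    "edge_matrix_from_connmatrices",
    "subnetwork_edge_indices",
]

logger = logging.getLogger(__name__)

P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass
class EdgeStats:
    """Per-edge Pearson r and two-sided p against a trait."""

    r: np.ndarray
    p: np.ndarray
    n_used: int
    n_dropped: int = 0


@dataclass
class CpmResult:
    """One LOOCV brain-behavior model (one trait/subnetwork/sign cell)."""

    trait: str
    subnetwork: str
    weight_kind: str
    sign: str  # "positive" | "negative"
    predictions: np.ndarray
    observed: np.ndarray
    r_pred: float
    p_pred: float
    n_subjects: int
    edge_frequency: np.ndarray  # fraction of folds selecting each edge
    n_edges_mean: float
    empty_folds: int = 0
    fdr_significant: bool | None = None
    p_fdr: float | None = None
    meta: dict = field(default_factory=dict)


def _pearson_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of x against y (vectorized)."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = xc.T @ yc / (sx * sy)
    r = np.where(sx == 0, 0.0, r)  # constant edge: no linear association
    return np.clip(r, -1.0, 1.0)


def edge_behavior_corr(edge_matrix: np.ndarray, trait: np.ndarray) -> EdgeStats:
    """Correlate every edge with the trait across subjects.

    Subjects with a missing trait value are dropped pairwise (the count
    is logged, never imputed).  p-values are two-sided from the exact
    t-distribution with n - 2 degrees of freedom and floored at the
    smallest positive double so downstream -log and FDR stay finite.
    """
    x = np.asarray(edge_matrix, dtype=float)
    y = np.asarray(trait, dtype=float).ravel()
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("edge matrix must be subjects x edges aligned with the trait vector")
    keep = np.isfinite(y)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("edge_behavior_corr: dropped %d subjects with missing trait", n_dropped)
    x, y = x[keep], y[keep]
    n = y.shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 subjects with observed trait values, have {n}")
    if y.std() == 0:
        raise ValueError("trait is constant; correlation undefined")
    r = _pearson_columns(x, y)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
        t = np.where(np.abs(r) >= 1.0, np.sign(r) / np.zeros(1), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, P_FLOOR, 1.0)
    return EdgeStats(r=r, p=p, n_used=n, n_dropped=n_dropped)


def select_edges(edge_stats: EdgeStats, p_threshold: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Split edges passing the p threshold by correlation sign.

    Returns (positive indices, negative indices); the sets are disjoint
    and may be empty (an empty set propagates as a no-model downstream).
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must lie in (0, 1)")
    sig = edge_stats.p < p_threshold
    pos = np.nonzero(sig & (edge_stats.r > 0))[0]
    neg = np.nonzero(sig & (edge_stats.r < 0))[0]
    return pos, neg


def network_strength(edge_vector: np.ndarray, edge_set: np.ndarray) -> float:
    """Sum of a subject's edge weights over the selected edge set.

    The unweighted sum follows the original CPM protocol; an empty set
    yields 0.0 (callers flag that fold).
    """
    v = np.asarray(edge_vector, dtype=float)
    idx = np.asarray(edge_set, dtype=int)
    if idx.size == 0:
        return 0.0
    if idx.min(initial=0) < 0 or idx.max(initial=-1) >= v.shape[0]:
        raise IndexError("edge set index outside the edge vector range")
    return float(v[idx].sum())


def loocv_predict(edge_matrix: np.ndarray, trait: np.ndarray,
                  p_threshold: float = 0.01, sign: str = "positive",
                  trait_name: str = "trait", subnetwork: str = "whole-brain",
                  weight_kind: str = "FCz") -> CpmResult:
    """Leave-one-out CPM prediction of a trait from edge weights.

    For each left-out subject the edge statistics, edge selection and
    the ordinary least-squares fit trait ~ strength are recomputed on
    the remaining subjects only; folds whose selected edge set is empty
    predict the training-trait mean and are counted in ``empty_folds``.
    After the loop, r_pred/p_pred are the Pearson correlation of the
    LOOCV predictions with the observed trait (p from the t
    approximation; see the docs for the dependence caveat).

    When a majority of folds select no edges there is no stable model:
    the result is marked no-model with r_pred = 0 and p_pred = 1.
    Training-mean predictions anti-correlate with the left-out value by
    construction (a -1/(n-1) leverage artifact), so correlating them
    with the trait would manufacture spurious negative r_pred.
    """
    if sign not in ("positive", "negative", "combined"):
        raise ValueError("sign must be 'positive', 'negative' or 'combined'")
    x = np.asarray(edge_matrix, dtype=float)
    y = np.asarray(trait, dtype=float).ravel()
    keep = np.isfinite(y)
    x, y = x[keep], y[keep]
    n, n_edges = x.shape
    if n < 4:
        raise ValueError(f"need >= 4 subjects with observed trait values, have {n}")
    if n < 10:
        warnings.warn(f"only {n} subjects; LOOCV estimates will be unstable", stacklevel=2)
    preds = np.empty(n)
    freq = np.zeros(n_edges)
    n_sel = np.zeros(n)
    empty_folds = 0
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        y_tr = y[tr]
        if y_tr.std() == 0:
            raise ValueError(f"trait constant in training fold {i}; cannot fit")
        es = edge_behavior_corr(x[tr], y_tr)
        pos, neg = select_edges(es, p_threshold)
        if sign == "positive":
            strength_of = lambda v: network_strength(v, pos)
            sel = pos
        elif sign == "negative":
            strength_of = lambda v: network_strength(v, neg)
            sel = neg
        else:
            strength_of = lambda v: network_strength(v, pos) - network_strength(v, neg)
            sel = np.concatenate([pos, neg])
        n_sel[i] = sel.size
        if sel.size == 0:
            empty_folds += 1
            preds[i] = y_tr.mean()
            continue
        freq[sel] += 1
        s_tr = np.array([strength_of(v) for v in x[tr]])
        slope, intercept = np.polyfit(s_tr, y_tr, 1)
        preds[i] = slope * strength_of(x[i]) + intercept
    no_model = empty_folds > n / 2
    if no_model or preds.std() == 0 or y.std() == 0:
        r_pred, p_pred = 0.0, 1.0
    else:
        r_pred, p_pred = stats.pearsonr(preds, y)
    return CpmResult(
        trait=trait_name, subnetwork=subnetwork, weight_kind=weight_kind, sign=sign,
        predictions=preds, observed=y, r_pred=float(r_pred),
        p_pred=float(np.clip(p_pred, P_FLOOR, 1.0)), n_subjects=n,
        edge_frequency=freq / n, n_edges_mean=float(n_sel.mean()),
        empty_folds=empty_folds, meta={"no_model": bool(no_model)},
    )


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over a family of p-values.

    Returns (rejection flags, adjusted p); adjusted p is monotone
    nondecreasing in the raw p.
    """
    p = np.asarray(p_values, dtype=float)
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def loocv_permutation_p(edge_matrix: np.ndarray, trait: np.ndarray,
                        p_threshold: float = 0.01, sign: str = "positive",
                        n_perm: int = 100, seed: int | None = None) -> float:
    """Subject-level permutation p for the LOOCV r_pred.

    Shuffles the trait across subjects and reruns the full LOOCV loop
    each time; exact under exchangeability, unlike the t approximation
    which ignores the dependence between LOOCV folds.
    """
    rng = np.random.default_rng(seed)
    obs = loocv_predict(edge_matrix, trait, p_threshold, sign).r_pred
    null = np.empty(n_perm)
    y = np.asarray(trait, dtype=float).ravel()
    for b in range(n_perm):
        null[b] = loocv_predict(edge_matrix, rng.permutation(y),
                                p_threshold, sign).r_pred
    return (1 + int(np.sum(null >= obs))) / (n_perm + 1)


def edge_matrix_from_connmatrices(mats: list[ConnMatrix]) -> tuple[np.ndarray, list[str]]:
    """Stack per-subject matrices into a subjects x edges array."""
    vecs = []
    labels = mats[0].parcel_labels
    for i, m in enumerate(mats):
        if m.parcel_labels != labels:
            raise ValueError(f"matrix {i}: parcel labels differ from the first matrix")
        v, _ = vectorize_edges(m)
        vecs.append(v)
    return np.array(vecs), list(labels)


def subnetwork_edge_indices(parcel_labels: list[str], g: GroupingScheme,
                            group: str) -> np.ndarray:
    """Canonical edge indices with BOTH endpoints inside ``group``."""
    member = np.array([g.parcel_to_group.get(p) == group for p in parcel_labels])
    rows, cols = edge_index_map(len(parcel_labels))
    return np.nonzero(member[rows] & member[cols])[0]


def run_matrix_of_models(conn_sets: dict[str, list[ConnMatrix]],
                         grouping: GroupingScheme | None,
                         traits: pd.DataFrame,
                         p_threshold: float = 0.01, q: float = 0.05,
                         signs: tuple[str, ...] = ("positive", "negative"),
                         include_whole_brain: bool = True) -> pd.DataFrame:
    """Fit the full family of CPM models and FDR-correct it as one unit.

    ``conn_sets`` maps weight kind -> one ConnMatrix per subject (rows
    of ``traits``).  One model is fitted per trait x subnetwork x sign x
    weight kind, plus a whole-brain (ungrouped) row per combination;
    Benjamini-Hochberg runs once over every p_pred in the family.  The
    returned table carries trait, group, weight_kind, sign, n, r_pred,
    p_pred, p_fdr, significant, n_edges_mean, empty_folds.
    """
    rows = []
    results: list[CpmResult] = []
    for kind, mats in conn_sets.items():
        if len(mats) != len(traits):
            raise ValueError(f"{kind}: {len(mats)} matrices for {len(traits)} trait rows")
        x, labels = edge_matrix_from_connmatrices(mats)
        scopes: list[tuple[str, np.ndarray]] = []
        if include_whole_brain:
            scopes.append(("whole-brain", np.arange(x.shape[1])))
        if grouping is not None:
            for grp in grouping.group_labels:
                idx = subnetwork_edge_indices(labels, grouping, grp)
                scopes.append((grp, idx))
        for trait_name in traits.columns:
            y = traits[trait_name].to_numpy(dtype=float)
            for scope_name, idx in scopes:
                if idx.size == 0:
                    continue  # single-parcel subnetwork: no within-block edges
                for sign in signs:
                    res = loocv_predict(x[:, idx], y, p_threshold, sign,
                                        trait_name=trait_name, subnetwork=scope_name,
                                        weight_kind=kind)
                    results.append(res)
    if not results:
        return pd.DataFrame(columns=["trait", "group", "weight_kind", "sign", "n",
                                     "r_pred", "p_pred", "p_fdr", "significant",
                                     "n_edges_mean", "empty_folds"])
    reject, p_adj = fdr_correct(np.array([r.p_pred for r in results]), q=q)
    for res, rej, pa in zip(results, reject, p_adj):
        res.fdr_significant = bool(rej)
        res.p_fdr = float(pa)
        rows.append({
            "trait": res.trait, "group": res.subnetwork, "weight_kind": res.weight_kind,
            "sign": res.sign, "n": res.n_subjects, "r_pred": res.r_pred,
            "p_pred": res.p_pred, "p_fdr": res.p_fdr, "significant": res.fdr_significant,
            "n_edges_mean": res.n_edges_mean, "empty_folds": res.empty_folds,
        })
    return pd.DataFrame(rows)
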