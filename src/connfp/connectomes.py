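"""Connectivity-matrix construction and subnetwork bookkeeping.

Functional connectivity (FC) is the Fisher-z-transformed Pearson
correlation between parcel-mean BOLD time series.  Structural
connectivity (SC) aggregates tractography streamlines into three edge
weights per parcel pair: streamline count (NS), mean connecting
streamline length (ML), and mean quantitative anisotropy along the
connecting streamlines (QA).  Parcels may have soft (smooth-boundary)
membership weights; a streamline's contribution to edge (i, j) is the
product of its endpoint memberships, summed over both orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConnMatrix",
    "ParcelTimeSeries",
    "StreamlineSet",
    "GroupingScheme",
    "ParcelWeightField",
    "fc_matrix",
    "sc_matrices",
    "bundle_assign",
    "group_reduce",
    "vectorize_edges",
    "devectorize_edges",
    "edge_count",
    "edge_index_map",
]

#: Fisher z is undefined at |r| = 1; correlations are clipped to this bound.
R_CLIP = 1.0 - 1e-7

SYMMETRY_TOL = 1e-12
WEIGHT_KINDS = ("FCz", "NS", "ML", "QA")


@dataclass
class ParcelTimeSeries:
    """Parcel-mean BOLD signal for one subject/session.

    ``values`` is timepoints x parcels; units are arbitrary because
    Pearson correlation is affine-invariant.
    """

    values: np.ndarray
    parcel_labels: list[str]
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D timepoints x parcels array")
        if self.values.shape[1] != len(self.parcel_labels):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.parcel_labels)} parcel labels"
            )
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 timepoints to correlate parcels")

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnMatrix:
    """Symmetric parcel x parcel edge-weight matrix with labeled axes.

    ``weight_kind`` records what the edges measure: Fisher-z Pearson
    correlation (FCz) or one of the streamline aggregates (NS, ML, QA).
    The diagonal is zero by construction (self-connections carry no
    information in this framework).
    """

    weights: np.ndarray
    parcel_labels: list[str]
    weight_kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if w.shape[0] != len(self.parcel_labels):
            raise ValueError("parcel label count does not match matrix size")
        if self.weight_kind not in WEIGHT_KINDS:
            raise ValueError(f"weight_kind must be one of {WEIGHT_KINDS}, got {self.weight_kind!r}")
        if not np.all(np.isfinite(w)):
            raise ValueError("connectivity matrix contains non-finite entries")
        if np.max(np.abs(w - w.T), initial=0.0) > SYMMETRY_TOL:
            raise ValueError("connectivity matrix is asymmetric beyond tolerance")
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_parcels(self) -> int:
        return self.weights.shape[0]


@dataclass
class StreamlineSet:
    """Collection of 3-D polylines in physical coordinates.

    Each polyline has >= 2 points; ``qa`` optionally carries a per-point
    scalar channel (quantitative anisotropy, dimensionless).  Lengths
    (sum of segment Euclidean norms) are cached on construction.
    """

    polylines: list[np.ndarray]
    qa: list[np.ndarray] | None = None
    lengths: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        polys = []
        for i, p in enumerate(self.polylines):
            p = np.asarray(p, dtype=float)
            if p.ndim != 2 or p.shape[1] != 3:
                raise ValueError(f"streamline {i}: points must form an (n, 3) array")
            if p.shape[0] < 2:
                raise ValueError(f"streamline {i}: needs at least 2 points")
            polys.append(p)
        self.polylines = polys
        if self.qa is not None:
            if len(self.qa) != len(polys):
                raise ValueError("QA channel count does not match streamline count")
            self.qa = [np.asarray(q, dtype=float).ravel() for q in self.qa]
            for i, (p, q) in enumerate(zip(polys, self.qa)):
                if q.shape[0] != p.shape[0]:
                    raise ValueError(f"streamline {i}: QA channel length mismatch")
        self.lengths = np.array(
            [np.linalg.norm(np.diff(p, axis=0), axis=1).sum() for p in polys]
        )
        if len(polys) and np.any(self.lengths <= 0):
            bad = int(np.argmax(self.lengths <= 0))
            raise ValueError(f"streamline {bad}: zero length (degenerate polyline)")

    def __len__(self) -> int:
        return len(self.polylines)

    def mean_qa(self) -> np.ndarray:
        """Per-streamline mean of the QA channel."""
        if self.qa is None:
            raise ValueError("streamline set has no QA channel")
        return np.array([q.mean() for q in self.qa])


@dataclass
class GroupingScheme:
    """Assignment of parcels to subnetworks or bundle groups."""

    name: str
    parcel_to_group: dict[str, str]
    group_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.group_labels:
            seen: list[str] = []
            for g in self.parcel_to_group.values():
                if g not in seen:
                    seen.append(g)
            self.group_labels = seen
        missing = set(self.parcel_to_group.values()) - set(self.group_labels)
        if missing:
            raise ValueError(f"groups used but not in group_labels: {sorted(missing)}")
        for g in self.group_labels:
            if g not in set(self.parcel_to_group.values()):
                raise ValueError(f"group {g!r} is empty")

    def members(self, group: str) -> list[str]:
        return [p for p, g in self.parcel_to_group.items() if g == group]


class ParcelWeightField:
    """Soft parcel membership weights on a voxel grid.

    ``weights`` is (n_parcels, nx, ny, nz) with entries in [0, 1] and a
    per-voxel sum <= 1 (plus tolerance).  Physical coordinates map to
    voxels by division by ``voxel_size`` and rounding to nearest;
    out-of-volume points get zero membership everywhere.  Built from a
    hard integer label volume (label 0 = background) or given directly
    for smooth boundaries.
    """

    def __init__(self, weights: np.ndarray, voxel_size: float = 1.0,
                 parcel_labels: list[str] | None = None, *, allow_overlap: bool = False):
        w = np.asarray(weights, dtype=float)
        if w.ndim != 4:
            raise ValueError("weights must be (n_parcels, nx, ny, nz)")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("membership weights must lie in [0, 1]")
        if not allow_overlap and np.any(w.sum(axis=0) > 1 + 1e-6):
            raise ValueError("per-voxel membership weights sum above 1")
        self.weights = w
        self.voxel_size = float(voxel_size)
        self.parcel_labels = parcel_labels or [str(i + 1) for i in range(w.shape[0])]
        if len(self.parcel_labels) != w.shape[0]:
            raise ValueError("parcel label count does not match weight field")

    @property
    def n_parcels(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_labels(cls, labels: np.ndarray, voxel_size: float = 1.0,
                    parcel_labels: list[str] | None = None) -> "ParcelWeightField":
        labels = np.asarray(labels)
        n = int(labels.max())
        w = np.zeros((n,) + labels.shape)
        for k in range(1, n + 1):
            w[k - 1] = labels == k
        return cls(w, voxel_size=voxel_size, parcel_labels=parcel_labels)

    def weights_at(self, points: np.ndarray) -> np.ndarray:
        """Membership weights (n_points, n_parcels) at physical coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.rint(pts / self.voxel_size).astype(int)
        shape = np.array(self.weights.shape[1:])
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.zeros((pts.shape[0], self.n_parcels))
        if inside.any():
            ii = idx[inside]
            out[inside] = self.weights[:, ii[:, 0], ii[:, 1], ii[:, 2]].T
        return out


def fc_matrix(ts: ParcelTimeSeries) -> ConnMatrix:
    """Fisher-z Pearson FC matrix from parcel time series.

    Off-diagonal (i, j) is atanh of the Pearson correlation between
    parcel columns i and j, clipped away from +/-1 so the transform
    stays finite; the diagonal is zero.
    """
    x = ts.values
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = ts.parcel_labels[int(np.argmax(sd == 0))]
        raise ValueError(f"parcel {bad!r} has a constant time series; correlation undefined")
    r = np.corrcoef(x, rowvar=False)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnMatrix(z, list(ts.parcel_labels), "FCz",
                      meta={"subject_id": ts.subject_id, "session_id": ts.session_id})


def sc_matrices(streams: StreamlineSet, parcels: ParcelWeightField,
                *, normalized: bool = False, with_qa: bool = True) -> dict[str, ConnMatrix]:
    """NS / ML / QA structural connectivity triple from streamlines.

    Each streamline contributes to edge (i, j), i != j, with soft mass
    c = w_i(start) * w_j(end) + w_j(start) * w_i(end) from its endpoint
    parcel memberships.  NS sums c (divided by the streamline count when
    ``normalized``); ML is the c-weighted mean streamline length
    (divided by the whole-set mean length when ``normalized``); QA is
    the c-weighted mean of per-streamline mean QA.  Edges with zero mass
    are zero in all three outputs.  An empty streamline set yields
    all-zero matrices.
    """
    n = parcels.n_parcels
    labels = list(parcels.parcel_labels)
    ns = np.zeros((n, n))
    ml_num = np.zeros((n, n))
    qa_num = np.zeros((n, n))
    if with_qa and len(streams) and streams.qa is None:
        raise ValueError("streamline set has no QA channel; QA matrix cannot be built")
    if len(streams):
        starts = np.array([p[0] for p in streams.polylines])
        ends = np.array([p[-1] for p in streams.polylines])
        w_start = parcels.weights_at(starts)
        w_end = parcels.weights_at(ends)
        mean_qa = streams.mean_qa() if with_qa else np.zeros(len(streams))
        # c_ij per streamline, both orientations; vectorized over streamlines
        c = np.einsum("si,sj->ij", w_start, w_end)
        c = c + c.T
        lw = w_start * streams.lengths[:, None]
        cl = np.einsum("si,sj->ij", lw, w_end)
        ml_num = cl + cl.T
        qw = w_start * mean_qa[:, None]
        cq = np.einsum("si,sj->ij", qw, w_end)
        qa_num = cq + cq.T
        ns = c
    np.fill_diagonal(ns, 0.0)
    np.fill_diagonal(ml_num, 0.0)
    np.fill_diagonal(qa_num, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ml = np.where(ns > 0, ml_num / np.where(ns > 0, ns, 1.0), 0.0)
        qa = np.where(ns > 0, qa_num / np.where(ns > 0, ns, 1.0), 0.0)
    ns_out = ns.copy()
    if normalized:
        if len(streams):
            ns_out = ns_out / len(streams)
            ml = ml / streams.lengths.mean()
    meta = {"normalized": normalized, "n_streamlines": len(streams)}
    out = {
        "NS": ConnMatrix(ns_out, labels, "NS", meta=dict(meta)),
        "ML": ConnMatrix(ml, labels, "ML", meta=dict(meta)),
    }
    if with_qa:
        out["QA"] = ConnMatrix(qa, labels, "QA", meta=dict(meta))
    return out


def bundle_assign(streams: StreamlineSet, bundle_masks: ParcelWeightField,
                  tau: float = 0.5) -> list[set[str]]:
    """Assign each streamline to the bundle masks it traverses.

    A streamline belongs to bundle b when at least a fraction ``tau`` of
    its points have membership weight > 0.5 in b.  Membership is a set:
    a streamline crossing several bundle templates belongs to all of
    them, which is how intersecting bundles providing a physical path
    between two parcels enter the pair counts.
    """
    if not (0 < tau <= 1):
        raise ValueError("tau must lie in (0, 1]")
    memberships: list[set[str]] = []
    for poly in streams.polylines:
        w = bundle_masks.weights_at(poly)  # (n_points, n_bundles)
        frac = (w > 0.5).mean(axis=0)
        memberships.append(
            {bundle_masks.parcel_labels[b] for b in np.nonzero(frac >= tau)[0]}
        )
    return memberships


def group_reduce(m: ConnMatrix, g: GroupingScheme, stat: str = "mean"):
    """Reduce a parcel matrix to a group x group block summary.

    Block (A, B) applies ``stat`` (mean or sum) over all edges with one
    endpoint in A and the other in B; within-group blocks (the diagonal
    of the output) use unordered within-block edges with the parcel
    diagonal excluded.  Returns a symmetric groups x groups DataFrame —
    unlike a connectome, its diagonal is meaningful, so it is not a
    ConnMatrix.
    """
    if stat not in ("mean", "sum"):
        raise ValueError("stat must be 'mean' or 'sum'")
    for p in m.parcel_labels:
        if p not in g.parcel_to_group:
            raise ValueError(f"parcel {p!r} missing from grouping scheme {g.name!r}")
    groups = g.group_labels
    idx = {grp: [i for i, p in enumerate(m.parcel_labels) if g.parcel_to_group[p] == grp]
           for grp in groups}
    k = len(groups)
    out = np.zeros((k, k))
    w = m.weights
    for a in range(k):
        ia = idx[groups[a]]
        for b in range(a, k):
            ib = idx[groups[b]]
            if a == b:
                block = w[np.ix_(ia, ia)]
                iu = np.triu_indices(len(ia), k=1)
                vals = block[iu]
            else:
                vals = w[np.ix_(ia, ib)].ravel()
            if vals.size == 0:
                val = 0.0
            else:
                val = vals.sum() if stat == "sum" else vals.mean()
            out[a, b] = out[b, a] = val
    df = pd.DataFrame(out, index=list(groups), columns=list(groups))
    df.attrs.update({"weight_kind": m.weight_kind, "grouping": g.name, "stat": stat})
    return df


def edge_index_map(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the canonical upper-triangle edge order."""
    return np.triu_indices(n, k=1)


def vectorize_edges(m: ConnMatrix | np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Vectorize a symmetric matrix into canonical edge order.

    Edges are the upper triangle (i < j) in row-major order — the single
    edge-indexing convention used throughout the package.  Returns the
    length n(n-1)/2 vector and the (rows, cols) index map that inverts it.
    """
    w = m.weights if isinstance(m, ConnMatrix) else np.asarray(m, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("matrix must be square")
    if np.max(np.abs(w - w.T), initial=0.0) > 1e-9:
        raise ValueError("matrix is asymmetric beyond tolerance; cannot vectorize edges")
    iu = edge_index_map(w.shape[0])
    return w[iu], iu


def devectorize_edges(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`: rebuild the symmetric matrix."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape[0] != n * (n - 1) // 2:
        raise ValueError(f"edge vector length {vec.shape[0]} does not match n={n}")
    out = np.zeros((n, n))
    iu = edge_index_map(n)
    out[iu] = vec
    return out + out.T


def edge_count(n_parcels: int, convention: str = "unordered") -> int:
    """Number of connections among ``n_parcels`` parcels.

    ``unordered`` is the standard graph count n(n-1)/2.  ``ordered_halved``
    is the n^2/2 convention some reports use when quoting the size of a
    full connection matrix divided by two (e.g. a 52-parcel language
    network quoted as (52 x 52)/2 = 1352 connections).
    """
    if convention == "unordered":
        return n_parcels * (n_parcels - 1) // 2
    if convention == "ordered_halved":
        q, r = divmod(n_parcels * n_parcels, 2)
        return q + r  # exact only for even n; callers quoting odd n round up
    raise ValueError("convention must be 'unordered' or 'ordered_halved'")
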