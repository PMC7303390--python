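"""Synthetic cohorts with known ground truth.

The generator emulates the minimal statistical structure the analysis
stages exercise, not realistic neuroimaging data:

* two-session FC matrices whose edge vectors share a subject-specific
  fingerprint component (drawn once per subject) plus independent
  per-session noise — the substrate for cross-session identification;
* toy streamline geometry over a block-parcel label volume, with known
  endpoint parcels, lengths and a constant per-streamline QA channel —
  the substrate for NS/ML/QA aggregation;
* behavioral traits linearly driven by a planted subset of edges plus
  Gaussian noise — the substrate for CPM recovery and null calibration.

Every draw comes from one seedable generator per cohort; identical
config + seed reproduces identical output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectomes import ConnMatrix, StreamlineSet, devectorize_edges, edge_count

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_fc_cohort",
    "generate_streamlines",
    "generate_traits",
]

#: deterministic tractography commonly keeps fibers in this length window (mm)
LENGTH_MIN, LENGTH_MAX = 20.0, 500.0


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic two-session cohort.

    ``sigma_fingerprint`` is the std-dev of the per-subject, per-edge
    fingerprint component shared across sessions; ``sigma_session`` the
    std-dev of independent per-session noise.  ``effect_edges_pos`` /
    ``effect_edges_neg`` index (canonical edge order) the edges whose
    session-averaged weights drive the trait with slope ``beta`` (trait
    units per unit summed edge weight); ``sigma_trait`` is the trait
    noise std-dev.  ``mu`` is the baseline edge weight, a typical
    resting-state Fisher-z magnitude.
    """

    n_subjects: int = 144
    n_parcels: int = 268
    n_sessions: int = 2
    mu: float = 0.3
    sigma_fingerprint: float = 0.10
    sigma_session: float = 0.05
    effect_edges_pos: tuple[int, ...] = ()
    effect_edges_neg: tuple[int, ...] = ()
    beta: float = 0.0
    sigma_trait: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_parcels < 3:
            raise ValueError("n_parcels must be >= 3")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        for name in ("sigma_fingerprint", "sigma_session", "sigma_trait"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_edges = edge_count(self.n_parcels)
        for name in ("effect_edges_pos", "effect_edges_neg"):
            idx = getattr(self, name)
            object.__setattr__(self, name, tuple(int(i) for i in idx))
            if any(i < 0 or i >= n_edges for i in getattr(self, name)):
                raise ValueError(f"{name} contains an index outside [0, {n_edges})")

    @property
    def n_edges(self) -> int:
        return edge_count(self.n_parcels)


@dataclass
class SyntheticCohort:
    """Generated cohort plus the ground truth used to generate it."""

    config: CohortConfig
    fc_matrices: list[list[ConnMatrix]]  # [subject][session]
    subject_ids: list[str]
    streamlines: StreamlineSet | None = None
    label_volume: np.ndarray | None = None
    traits: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.fc_matrices)

    def session_matrices(self, session: int) -> list[ConnMatrix]:
        return [subj[session] for subj in self.fc_matrices]

    def edge_vectors(self, session: int | None = None) -> np.ndarray:
        """Subjects x edges array; session-averaged when session is None."""
        iu = np.triu_indices(self.config.n_parcels, k=1)
        if session is not None:
            return np.array([s[session].weights[iu] for s in self.fc_matrices])
        per = [np.array([m.weights[iu] for m in subj]).mean(axis=0)
               for subj in self.fc_matrices]
        return np.array(per)


def _cohort_rng(config: CohortConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def generate_fc_cohort(config: CohortConfig) -> SyntheticCohort:
    """Two-session FC matrices with a planted subject fingerprint.

    The edge vector of subject i, session s is mu + f_i + eps_{i,s} with
    f_i ~ N(0, sigma_fingerprint^2) i.i.d. per edge (shared across that
    subject's sessions) and eps ~ N(0, sigma_session^2) i.i.d.  Matrices
    are symmetric with zero diagonal; ``truth['fingerprints']`` stores
    the f_i array.
    """
    rng = _cohort_rng(config, 0)
    n, p, s = config.n_subjects, config.n_parcels, config.n_sessions
    n_edges = config.n_edges
    fingerprints = rng.normal(0.0, config.sigma_fingerprint, size=(n, n_edges))
    noise = rng.normal(0.0, config.sigma_session, size=(n, s, n_edges))
    labels = [f"P{i + 1:03d}" for i in range(p)]
    subject_ids = [f"S{i + 1:03d}" for i in range(n)]
    fc = []
    for i in range(n):
        per_session = []
        for k in range(s):
            vec = config.mu + fingerprints[i] + noise[i, k]
            m = ConnMatrix(devectorize_edges(vec, p), labels, "FCz",
                           meta={"subject_id": subject_ids[i], "session_id": f"sess{k + 1}"})
            per_session.append(m)
        fc.append(per_session)
    return SyntheticCohort(
        config=config, fc_matrices=fc, subject_ids=subject_ids,
        truth={"fingerprints": fingerprints},
    )


def generate_streamlines(n_parcels: int, n_streamlines: int,
                         label_volume_shape: tuple[int, int, int] = (48, 48, 48),
                         seed: int = 0, voxel_size: float = 2.0,
                         parcel_pairs: list[tuple[int, int]] | None = None,
                         qa_values: list[float] | None = None,
                         ) -> tuple[StreamlineSet, np.ndarray]:
    """Toy streamlines plus the integer label volume they terminate in.

    Parcels are 3x3x3-voxel blocks placed on a regular grid inside the
    volume (an error if it cannot hold them).  Each streamline is a
    3-point polyline whose endpoints sit at the centers of its two
    parcels, with the midpoint deflected so the physical length stays
    within the deterministic-tracking window [20, 500] mm.  The QA
    channel holds one known constant per streamline.  ``parcel_pairs``
    (1-based labels) plants endpoint parcels explicitly; otherwise pairs
    are drawn uniformly.
    """
    if n_parcels < 2:
        raise ValueError("n_parcels must be >= 2")
    rng = np.random.default_rng(seed)
    shape = tuple(int(v) for v in label_volume_shape)
    block = 3
    pitch = 8  # voxels between block corners; keeps parcels disjoint and separated
    per_axis = tuple(max((v - block) // pitch + 1, 0) for v in shape)
    capacity = per_axis[0] * per_axis[1] * per_axis[2]
    if capacity < n_parcels:
        raise ValueError(
            f"volume {shape} holds at most {capacity} parcels; {n_parcels} requested"
        )
    labels = np.zeros(shape, dtype=np.int32)
    centers = np.empty((n_parcels, 3))
    for k in range(n_parcels):
        gx, rem = divmod(k, per_axis[1] * per_axis[2])
        gy, gz = divmod(rem, per_axis[2])
        corner = np.array([gx, gy, gz]) * pitch
        sl = tuple(slice(c, c + block) for c in corner)
        labels[sl] = k + 1
        centers[k] = (corner + (block - 1) / 2.0) * voxel_size
    if parcel_pairs is None:
        pairs = [tuple(sorted(rng.choice(n_parcels, size=2, replace=False) + 1))
                 for _ in range(n_streamlines)]
    else:
        pairs = [tuple(p) for p in parcel_pairs]
        if len(pairs) != n_streamlines:
            raise ValueError("parcel_pairs length must equal n_streamlines")
        for a, b in pairs:
            if not (1 <= a <= n_parcels and 1 <= b <= n_parcels):
                raise ValueError(f"parcel pair ({a}, {b}) outside 1..{n_parcels}")
    if qa_values is None:
        qa_vals = rng.uniform(0.1, 0.8, size=n_streamlines)
    else:
        qa_vals = np.asarray(qa_values, dtype=float)
        if qa_vals.shape[0] != n_streamlines:
            raise ValueError("qa_values length must equal n_streamlines")
    polys, qa = [], []
    for (a, b), q in zip(pairs, qa_vals):
        start, end = centers[a - 1], centers[b - 1]
        d = float(np.linalg.norm(end - start))
        if d > LENGTH_MAX:
            raise ValueError(f"parcel pair ({a}, {b}) is {d:.1f} mm apart, above {LENGTH_MAX}")
        mid = (start + end) / 2.0
        if d < LENGTH_MIN:
            # deflect the midpoint perpendicular to the chord (or +x for loops)
            # so the two segments sum to at least the minimum length
            h = np.sqrt(max((LENGTH_MIN / 2.0) ** 2 - (d / 2.0) ** 2, 0.0)) * 1.0001
            if d > 0:
                chord = (end - start) / d
                perp = np.cross(chord, [0.0, 0.0, 1.0])
                if np.linalg.norm(perp) < 1e-9:
                    perp = np.cross(chord, [0.0, 1.0, 0.0])
                perp /= np.linalg.norm(perp)
            else:
                perp = np.array([1.0, 0.0, 0.0])
            mid = mid + h * perp
        polys.append(np.array([start, mid, end]))
        qa.append(np.full(3, q))
    streams = StreamlineSet(polys, qa) if polys else StreamlineSet([], [])
    return streams, labels


def generate_traits(cohort: SyntheticCohort, config: CohortConfig | None = None,
                    trait_name: str = "trait") -> pd.DataFrame:
    """Traits linearly driven by the planted effect edges.

    trait_i = beta * (sum of session-averaged weights over the positive
    effect edges - sum over the negative ones) + N(0, sigma_trait^2).
    The cohort's ``traits`` table and ``truth`` record are updated.
    """
    config = config or cohort.config
    if config.beta != 0 and not (config.effect_edges_pos or config.effect_edges_neg):
        raise ValueError("beta != 0 requires at least one planted effect edge")
    rng = _cohort_rng(config, 1)
    edges = cohort.edge_vectors(session=None)
    signal = np.zeros(cohort.n_subjects)
    if config.effect_edges_pos:
        signal += edges[:, list(config.effect_edges_pos)].sum(axis=1)
    if config.effect_edges_neg:
        signal -= edges[:, list(config.effect_edges_neg)].sum(axis=1)
    noise = rng.normal(0.0, config.sigma_trait, size=cohort.n_subjects)
    values = config.beta * signal + noise
    traits = pd.DataFrame({trait_name: values}, index=pd.Index(cohort.subject_ids, name="subject"))
    cohort.traits = traits
    cohort.truth.update({
        "effect_edges_pos": config.effect_edges_pos,
        "effect_edges_neg": config.effect_edges_neg,
        "beta": config.beta,
        "trait_signal": config.beta * signal,
    })
    return traits
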