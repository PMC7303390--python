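"""Replicate-level simulation studies over the synthetic cohorts.

These are the calibration and recovery experiments the package runs on
its own generator: chance-level identification when no fingerprint is
planted, perfect recovery when no session noise is present, CPM
recovery of a planted edge-behavior effect, and false-positive control
on null cohorts.  Each function returns plain floats/arrays so drivers
can tabulate them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import loocv_predict, run_matrix_of_models
from .connectomes import ConnMatrix, GroupingScheme
from .fingerprint import identify, permutation_test, similarity_scores
from .synthetic import CohortConfig, generate_fc_cohort, generate_traits

__all__ = [
    "identification_experiment",
    "chance_accuracy_study",
    "planted_effect_study",
    "null_cpm_study",
    "planted_cpm_config",
]


def identification_experiment(config: CohortConfig, n_perm: int = 1000,
                              seed: int | None = None):
    """Generate one cohort and run the full identification analysis."""
    cohort = generate_fc_cohort(config)
    scores = similarity_scores(cohort.session_matrices(0), cohort.session_matrices(1))
    return permutation_test(scores, n_perm=n_perm,
                            seed=config.seed if seed is None else seed)


def chance_accuracy_study(n_replicates: int = 1000, n_subjects: int = 20,
                          n_parcels: int = 20, seed: int = 0) -> np.ndarray:
    """Pooled identification accuracy on fingerprint-free cohorts.

    With sigma_fingerprint = 0 subjects are exchangeable, so accuracy
    should sit at the 1/n_subjects chance level on average.
    """
    accs = np.empty(n_replicates)
    for b in range(n_replicates):
        cfg = CohortConfig(n_subjects=n_subjects, n_parcels=n_parcels,
                           sigma_fingerprint=0.0, sigma_session=0.05,
                           seed=seed * n_replicates + b)
        cohort = generate_fc_cohort(cfg)
        scores = similarity_scores(cohort.session_matrices(0), cohort.session_matrices(1))
        accs[b] = identify(scores).accuracy
    return accs


def planted_cpm_config(n_subjects: int = 200, n_parcels: int = 10,
                       seed: int = 0) -> CohortConfig:
    """Cohort with one planted positive effect edge at signal:noise 1.

    The trait is beta * (session-averaged weight of one edge) + noise
    with the noise variance equal to the signal variance, so the
    population predicted-observed correlation is sqrt(1/2) ~ 0.707.
    """
    sigma_f, sigma_s = 0.10, 0.05
    signal_sd = np.sqrt(sigma_f ** 2 + sigma_s ** 2 / 2.0)  # session-averaged edge sd
    return CohortConfig(n_subjects=n_subjects, n_parcels=n_parcels,
                        sigma_fingerprint=sigma_f, sigma_session=sigma_s,
                        effect_edges_pos=(0,), beta=1.0,
                        sigma_trait=signal_sd, seed=seed)


def planted_effect_study(n_replicates: int = 500, n_subjects: int = 200,
                         n_parcels: int = 10, p_threshold: float = 0.01,
                         seed: int = 0) -> np.ndarray:
    """LOOCV r_pred across replicate cohorts with the planted effect."""
    r = np.empty(n_replicates)
    for b in range(n_replicates):
        cfg = planted_cpm_config(n_subjects, n_parcels, seed=seed * n_replicates + b)
        cohort = generate_fc_cohort(cfg)
        traits = generate_traits(cohort, cfg)
        res = loocv_predict(cohort.edge_vectors(), traits.iloc[:, 0].to_numpy(),
                            p_threshold=p_threshold, sign="positive")
        r[b] = res.r_pred
    return r


def _half_grouping(n_parcels: int) -> GroupingScheme:
    labels = [f"P{i + 1:03d}" for i in range(n_parcels)]
    half = n_parcels // 2
    return GroupingScheme("halves", {p: ("A" if i < half else "B")
                                     for i, p in enumerate(labels)})


def null_cpm_study(n_replicates: int = 200, n_subjects: int = 60,
                   n_parcels: int = 10, q: float = 0.05,
                   p_threshold: float = 0.01, seed: int = 0) -> pd.DataFrame:
    """CPM family on beta = 0 cohorts: false-positive calibration.

    Runs the full model family (whole-brain + two subnetworks, both
    signs) per replicate and records the mean r_pred and whether any row
    survives FDR at level q.
    """
    rows = []
    for b in range(n_replicates):
        cfg = CohortConfig(n_subjects=n_subjects, n_parcels=n_parcels,
                           beta=0.0, sigma_trait=1.0, seed=seed * n_replicates + b)
        cohort = generate_fc_cohort(cfg)
        traits = generate_traits(cohort, cfg)
        mats = [ConnMatrix(np.mean([m.weights for m in subj], axis=0),
                           subj[0].parcel_labels, "FCz")
                for subj in cohort.fc_matrices]
        table = run_matrix_of_models({"FCz": mats}, _half_grouping(n_parcels),
                                     traits, p_threshold=p_threshold, q=q)
        rows.append({
            "replicate": b,
            "mean_r_pred": table["r_pred"].mean(),
            "any_significant": bool(table["significant"].any()),
            "p_pred_min": table["p_pred"].min(),
        })
    return pd.DataFrame(rows)
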