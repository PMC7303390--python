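"""End-to-end driver: simulate -> connectomes -> identify -> CPM.

Given a run configuration the driver generates (or loads) a cohort,
runs the cross-session identification analysis and the CPM
brain-behavior family, and writes every product — matrices, the
identification report, the CPM results table, and a log echoing all
parameters plus a config hash — into one run directory.  With a fixed
seed the result files are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .behavior import run_matrix_of_models
from .connectomes import ConnMatrix, ParcelWeightField, sc_matrices
from .fingerprint import permutation_test, similarity_scores
from .synthetic import CohortConfig, generate_fc_cohort, generate_streamlines, generate_traits

__all__ = ["RunConfig", "pipeline_run"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    out_dir: str
    cohort: CohortConfig = field(default_factory=CohortConfig)
    grouping_path: str | None = None
    simulate_streamlines: bool = False
    n_streamlines: int = 200
    sc_normalized: bool = False
    tau: float = 0.5
    p_threshold: float = 0.01
    q: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")
        if not (0 < self.q < 1):
            raise ValueError("q must lie in (0, 1)")
        if not (0 < self.tau <= 1):
            raise ValueError("tau must lie in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.grouping_path is not None and not Path(self.grouping_path).exists():
            raise ValueError(f"grouping_path does not exist: {self.grouping_path}")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = cio.read_config_toml(path)
        cohort = CohortConfig(**raw.pop("cohort", {}))
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(cohort=cohort, **raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_id_report(out: Path, res, subject_ids) -> None:
    sim = pd.DataFrame(res.similarity, index=subject_ids, columns=subject_ids)
    sim.index.name = "reference"
    sim.to_csv(out / "similarity.csv", float_format=cio.FLOAT_FMT)
    report = {
        "similarity_csv": "similarity.csv",
        "accuracy_ref_to_target": res.accuracy_ref_to_target,
        "accuracy_target_to_ref": res.accuracy_target_to_ref,
        "accuracy": res.accuracy,
        "permutation_p": res.permutation_p,
        "n_permutations": res.n_permutations,
    }
    (out / "identification.json").write_text(json.dumps(report, indent=2, sort_keys=True))


def pipeline_run(config: RunConfig) -> Path:
    """Run the full synthetic pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("connfp")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    t0 = time.time()
    stage = "setup"
    try:
        logger.info("config digest %s seed %d", config.digest(), config.seed)
        for f in dataclasses.fields(config):
            logger.info("param %s = %r", f.name, getattr(config, f.name))

        stage = "simulate"
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        cohort = generate_fc_cohort(cohort_cfg)
        generate_traits(cohort, cohort_cfg)
        fc_dir = out / "fc"
        fc_dir.mkdir(exist_ok=True)
        for sid, per_session in zip(cohort.subject_ids, cohort.fc_matrices):
            for k, m in enumerate(per_session):
                cio.write_conn_csv(m, fc_dir / f"{sid}_sess{k + 1}.csv")
        cio.write_traits_csv(cohort.traits, out / "traits.csv")
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in cohort.truth.items()}
        (out / "truth.json").write_text(json.dumps(truth, sort_keys=True))

        # session-averaged FC feeds the behavior models (same convention as
        # the trait generator)
        conn_sets = {"FCz": [
            ConnMatrix(np.mean([m.weights for m in subj], axis=0),
                       subj[0].parcel_labels, "FCz")
            for subj in cohort.fc_matrices
        ]}
        if config.simulate_streamlines:
            stage = "sc"
            streams, labels = generate_streamlines(
                config.cohort.n_parcels, config.n_streamlines, seed=config.seed)
            cio.write_streamlines_tsv(streams, out / "streamlines.tsv")
            cio.write_label_volume(labels, out / "labels.nii.gz")
            field_ = ParcelWeightField.from_labels(labels, voxel_size=2.0)
            for kind, m in sc_matrices(streams, field_,
                                       normalized=config.sc_normalized).items():
                cio.write_conn_csv(m, out / f"sc_{kind}.csv")

        stage = "identify"
        if config.cohort.n_sessions >= 2:
            scores = similarity_scores(cohort.session_matrices(0), cohort.session_matrices(1))
            id_res = permutation_test(scores, n_perm=config.n_perm, seed=config.seed)
            _write_id_report(out, id_res, cohort.subject_ids)
            logger.info("identification accuracy %.4f p %.6f", id_res.accuracy,
                        id_res.permutation_p)

        stage = "cpm"
        grouping = None
        if config.grouping_path:
            grouping = cio.read_grouping_csv(config.grouping_path)
        results = run_matrix_of_models(conn_sets, grouping, cohort.traits,
                                       p_threshold=config.p_threshold, q=config.q)
        results.to_csv(out / "cpm_results.csv", index=False, float_format=cio.FLOAT_FMT)
        logger.info("pipeline finished in %.1f s", time.time() - t0)
        return out
    except Exception:
        logger.exception("pipeline aborted in stage %r", stage)
        (out / "FAILED_STAGE").write_text(stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
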