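"""Generate the reference synthetic cohort and write it to results/cohort/.

Two-session FC matrices for 40 subjects x 20 parcels with a planted
subject fingerprint, toy streamlines over a block-parcel label volume,
and a trait driven by one planted edge at signal:noise 1.  Prints where
everything went and the planted ground truth.
"""

import json
import sys
from pathlib import Path

import numpy as np

from connfp import io as cio
from connfp.experiments import planted_cpm_config
from connfp.synthetic import generate_fc_cohort, generate_streamlines, generate_traits

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main(seed: int = 7) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = planted_cpm_config(n_subjects=40, n_parcels=20, seed=seed)
    cohort = generate_fc_cohort(cfg)
    generate_traits(cohort, cfg)
    fc_dir = OUT / "fc"
    fc_dir.mkdir(exist_ok=True)
    for sid, per_session in zip(cohort.subject_ids, cohort.fc_matrices):
        for k, m in enumerate(per_session):
            cio.write_conn_csv(m, fc_dir / f"{sid}_sess{k + 1}.csv")
    streams, labels = generate_streamlines(cfg.n_parcels, 400, seed=seed)
    cio.write_streamlines_tsv(streams, OUT / "streamlines.tsv")
    cio.write_label_volume(labels, OUT / "labels.nii.gz")
    cio.write_traits_csv(cohort.traits, OUT / "traits.csv")
    truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in cohort.truth.items()}
    (OUT / "truth.json").write_text(json.dumps(truth, sort_keys=True, indent=2))
    print(f"cohort: {cfg.n_subjects} subjects, {cfg.n_parcels} parcels, "
          f"{len(streams)} streamlines -> {OUT}")
    print(f"planted effect edge {cfg.effect_edges_pos} with beta={cfg.beta}, "
          f"trait noise sd={cfg.sigma_trait:.4f} (signal:noise 1)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
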