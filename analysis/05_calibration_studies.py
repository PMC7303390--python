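"""Replicate-level calibration of the whole pipeline.

Four studies over replicate synthetic cohorts:

1. chance-level identification when no fingerprint is planted
   (expected pooled accuracy ~ 1/N);
2. perfect identification when session noise is absent;
3. LOOCV recovery of the planted edge effect at signal:noise 1
   (population predicted-observed correlation sqrt(1/2) ~ 0.707);
4. false-positive control of the FDR-corrected CPM family on null
   cohorts (expected <= ~q of replicates with any significant row).

Replicate counts are chosen so the whole script runs in a few minutes
on one core; pass a different seed as argv[1].
"""

import dataclasses
import json
import sys
import time
from pathlib import Path

import numpy as np

from connfp.experiments import (
    chance_accuracy_study,
    identification_experiment,
    null_cpm_study,
    planted_cpm_config,
    planted_effect_study,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "calibration"


def main(seed: int = 7) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    report = {}
    t0 = time.time()

    acc = chance_accuracy_study(n_replicates=1000, n_subjects=20, seed=seed)
    report["chance_accuracy"] = {"mean": float(acc.mean()), "expected": 0.05,
                                 "n_replicates": 1000}
    print(f"[1] fingerprint-free cohorts: mean accuracy {acc.mean():.4f} "
          f"(chance 1/20 = 0.05)")

    cfg = dataclasses.replace(planted_cpm_config(20, 20, seed=seed), sigma_session=0.0)
    res = identification_experiment(cfg, n_perm=1000)
    report["noise_free_identification"] = {"accuracy": res.accuracy,
                                           "permutation_p": res.permutation_p}
    print(f"[2] noise-free cohort: accuracy {res.accuracy:.3f}, "
          f"permutation p {res.permutation_p:.6f} (= 1/1001)")

    r = planted_effect_study(n_replicates=500, n_subjects=200, seed=seed)
    report["planted_effect_r_pred"] = {
        "mean": float(r.mean()), "sd": float(r.std()),
        "population_r": float(np.sqrt(0.5)), "n_replicates": 500,
    }
    print(f"[3] planted effect (500 replicates, n=200): LOOCV r_pred "
          f"{r.mean():.4f} +/- {r.std():.4f} (population sqrt(1/2) = 0.7071)")

    null = null_cpm_study(n_replicates=200, seed=seed)
    report["null_fdr"] = {
        "fraction_any_significant": float(null["any_significant"].mean()),
        "mean_r_pred": float(null["mean_r_pred"].mean()), "n_replicates": 200,
    }
    print(f"[4] null cohorts (200 replicates): {null['any_significant'].mean():.3f} "
          f"of replicates have any FDR-significant row (bound 0.10); "
          f"mean r_pred {null['mean_r_pred'].mean():+.4f}")

    report["runtime_s"] = time.time() - t0
    (OUT / "calibration.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    print(f"wrote {OUT / 'calibration.json'} in {report['runtime_s']:.0f}s")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
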