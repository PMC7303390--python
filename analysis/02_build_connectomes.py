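"""Build SC matrices (NS/ML/QA) from the simulated streamlines.

Reads the cohort written by 01_simulate_cohort.py, aggregates
streamlines into the three structural edge-weight matrices, reduces
them to a two-group block summary, and reports the densest edges.
"""

from pathlib import Path

import numpy as np

from connfp import io as cio
from connfp.connectomes import GroupingScheme, ParcelWeightField, group_reduce, sc_matrices

ROOT = Path(__file__).resolve().parents[1] / "results"
COHORT = ROOT / "cohort"
OUT = ROOT / "connectomes"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    streams = cio.read_streamlines_tsv(COHORT / "streamlines.tsv")
    labels, voxel_size = cio.read_label_volume(COHORT / "labels.nii.gz")
    field = ParcelWeightField.from_labels(labels, voxel_size=voxel_size)
    mats = sc_matrices(streams, field, normalized=False)
    for kind, m in mats.items():
        cio.write_conn_csv(m, OUT / f"sc_{kind}.csv")
    ns = mats["NS"].weights
    iu = np.triu_indices_from(ns, k=1)
    order = np.argsort(ns[iu])[::-1][:5]
    print(f"{len(streams)} streamlines over {field.n_parcels} parcels "
          f"-> {int(ns[iu].sum())} endpoint pairs counted")
    print("densest edges (parcel_i, parcel_j, NS, ML_mm, QA):")
    for k in order:
        i, j = iu[0][k], iu[1][k]
        print(f"  ({mats['NS'].parcel_labels[i]}, {mats['NS'].parcel_labels[j]}) "
              f"NS={ns[i, j]:.0f} ML={mats['ML'].weights[i, j]:.1f} "
              f"QA={mats['QA'].weights[i, j]:.3f}")
    half = field.n_parcels // 2
    grouping = GroupingScheme("halves", {
        p: ("A" if i < half else "B") for i, p in enumerate(mats["NS"].parcel_labels)})
    blocks = group_reduce(mats["NS"], grouping, stat="sum")
    blocks.to_csv(OUT / "sc_NS_blocks.csv")
    print(f"two-group NS block sums: within-A={blocks.iloc[0, 0]:.0f} "
          f"within-B={blocks.iloc[1, 1]:.0f} between={blocks.iloc[0, 1]:.0f}")


if __name__ == "__main__":
    main()
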