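# Methods

## Overview

`connfp` implements a connectome-fingerprinting analysis pipeline: it
builds functional (FC) and structural (SC) connectivity matrices over a
brain parcellation, identifies individual subjects across scan sessions
from the similarity of their connectivity profiles, and relates
connectivity to behavioral traits with connectome-based predictive
modeling (CPM) under leave-one-out cross-validation (LOOCV) and
Benjamini–Hochberg false-discovery-rate (FDR) control. Because the
neuroimaging cohorts this style of analysis is usually run on are
access-restricted, the package ships a synthetic cohort generator with
planted ground truth; every stage is validated against that ground
truth and against independent brute-force oracles.

## Connectivity matrices

**Functional connectivity.** For a parcel-mean BOLD time-series matrix
(timepoints × parcels), the FC matrix is the Pearson correlation
between every pair of parcel columns, passed through the Fisher
z-transform `z = atanh(r)`. Correlations are clipped to
`|r| ≤ 1 − 1e−7` so the transform stays finite; the diagonal is zero
and constant columns are rejected with the parcel named. FC is
invariant to positive-slope affine rescaling of any column (an
inherited Pearson property that the tests assert to 1e−10).

**Structural connectivity.** A tractography streamline contributes to
the edge between parcels *i* and *j* through its endpoint parcel
memberships. Memberships may be soft (smooth parcel boundaries): with
endpoint weight vectors `w(start)` and `w(end)`, the contribution mass
is `c = w_i(start)·w_j(end) + w_j(start)·w_i(end)`. Products of
endpoint weights (rather than min or max) are used because they are
mass-conserving and reduce to the hard-label tally when weights are
0/1. Three edge weights are aggregated:

- **NS** — summed streamline mass Σc; with the `normalized` flag it is
  divided by the total streamline count ("normalized number of
  streamlines").
- **ML** — the c-weighted mean streamline length in mm,
  `Σ(c·length)/Σc`; the `normalized` flag divides by the mean length
  over the whole streamline set. The normalization convention is not
  standardized in the literature, so both forms are available and the
  flag is recorded in the matrix metadata.
- **QA** — the c-weighted mean of per-streamline mean quantitative
  anisotropy. The per-streamline summary is the mean of the per-point
  QA channel (median would be a defensible alternative; mean is the
  simpler estimator and is what the tests pin down).

Streamline length is the sum of segment Euclidean norms over the
polyline as given (no resampling). Edges with zero mass are zero in
all three matrices, and an empty streamline set produces all-zero
matrices rather than an error.

**Bundle assignment.** A streamline belongs to a bundle template when
at least a fraction `tau` (default 0.5) of its points have membership
weight > 0.5 in that template's mask. Membership is a set — a
streamline crossing several templates belongs to all of them — which
is how intersecting bundles providing a physical path between two
parcels enter bundle-pair counts. Bundle masks may overlap, so the
per-voxel sum-to-one validation is relaxed for them
(`allow_overlap=True`).

**Grouping and edge vectorization.** A grouping scheme maps each
parcel to exactly one subnetwork/bundle group; `group_reduce`
summarizes a parcel matrix into group blocks (mean or sum over the
edges spanning two groups; within-group blocks use unordered
within-block edges, diagonal excluded, so `sum` conserves total edge
mass). The canonical edge order everywhere in the package is the
upper triangle (i < j), row-major; `vectorize_edges` /
`devectorize_edges` are exact inverses. For a 52-parcel network this
gives 52·51/2 = 1,326 unordered edges; some reports quote the
full-matrix-halved count (52×52)/2 = 1,352 instead, so
`edge_count(n, convention=...)` exposes both conventions explicitly.

## Cross-session identification

Each subject's fingerprint is the vectorized edge vector of one
session's matrix. The similarity score between reference subject *i*
and target subject *k* is the Pearson correlation of their edge
vectors; identification predicts, for each reference, the target with
the highest score. Both directions are computed (session 1 as
reference, then session 2, i.e. the transposed score matrix) and the
pooled accuracy is their mean; per-direction accuracies are also
reported. Ties at the argmax are broken toward the lowest index with
a warning — with real-valued scores exact ties have measure zero.

Significance comes from a permutation test: target identities are
relabeled uniformly at random `n_perm` times (default 1,000), the
pooled accuracy is recomputed under each relabeling, and
`p = (1 + #{null ≥ observed}) / (n_perm + 1)` — the add-one estimator,
so a perfectly identified cohort yields p = 1/(n_perm+1), never 0.

## CPM brain–behavior models

For a subjects × edges matrix and one trait:

1. **Edge statistics** — per-edge Pearson r against the trait with
   two-sided p from the t distribution (n−2 df). Subjects with a
   missing trait value are dropped pairwise (logged, never imputed);
   p-values are floored at the smallest positive double.
2. **Edge selection** — edges with p below the threshold (default
   0.01, the conventional CPM selection level; configurable), split
   into a positive set (r > 0) and a negative set (r < 0). The two
   sets are modeled separately by default; a combined pos−neg model
   is available behind `sign="combined"`.
3. **Network strength** — the unweighted sum of a subject's edge
   weights over the selected set (the original CPM convention; no
   r-weighting).
4. **LOOCV** — steps 1–3 plus an ordinary least-squares fit
   (trait ~ strength) are recomputed with each subject left out in
   turn, and the held-out subject is predicted from the training-fold
   model. `r_pred`/`p_pred` are the Pearson correlation of the LOOCV
   predictions with the observed trait.

**Empty selections and the no-model rule.** A fold whose selected edge
set is empty predicts the training-fold trait mean and is flagged.
Training-mean predictions are perfectly anti-correlated with the
left-out observation (`pred_i = c − y_i/(n−1)`), so a model dominated
by empty folds would report r_pred → −1 purely by construction. When
a majority of folds are empty the result is therefore declared
no-model: r_pred = 0, p_pred = 1, with the empty-fold count reported.
This keeps the null distribution of r_pred centered near zero (mean
≈ 0.004 over 200 null replicates) and the family-wide FDR calibrated
(8% of null replicates show any significant row at q = 0.05).

**p_pred caveat.** The t-approximation treats the n LOOCV predictions
as independent, which they are not; the null of LOOCV r is left-skewed.
`loocv_permutation_p` provides the exact alternative — shuffle the
trait, re-run the full LOOCV loop (default 100 permutations) — at
proportionally higher cost.

**Model family and FDR.** `run_matrix_of_models` fits one model per
trait × subnetwork × sign × edge-weight kind, plus a whole-brain row,
and applies Benjamini–Hochberg step-up once across the entire family
(the broadest defensible family; the alternative of per-weight-kind
families would be less conservative). A subnetwork's edge set is the
within-block set — both endpoints inside the subnetwork — matching the
submatrix view of a grouped connectome; single-parcel groups have no
within-block edges and are skipped. BH itself is delegated to
statsmodels and cross-checked in the tests against an independent
step-up implementation on 1,000 random p-vectors.

## Synthetic cohorts

The generator produces the minimal statistical structure the analysis
consumes, with known ground truth:

- **FC with fingerprints.** The edge vector of subject *i*, session
  *s* is `mu + f_i + eps_{i,s}` with `f_i ~ N(0, σ_f²)` per edge drawn
  once per subject and `eps ~ N(0, σ_s²)` per session. Defaults:
  `mu = 0.3` (a typical resting-state Fisher-z magnitude),
  `σ_f = 0.10`, `σ_s = 0.05` — identifiable but not trivially so; the
  within-subject across-session edge covariance equals σ_f² (asserted
  within 10% at n = 500). Default cohort dimensions are 144 subjects ×
  268 parcels × 2 sessions, the scale of the HCP-style cohorts this
  design emulates; the studies below use smaller dimensions, stated
  per study.
- **Streamlines.** Parcels are 3×3×3-voxel blocks on a regular grid
  (2 mm voxels); each streamline is a 3-point polyline between the
  centers of its two endpoint parcels, with the midpoint deflected so
  the length stays within the deterministic-tracking window
  [20, 500] mm. The QA channel is one known constant per streamline.
  Endpoint pairs and QA values can be planted exactly, which is what
  the hand-computed aggregation fixtures use.
- **Traits.** `trait_i = β·(Σ session-averaged weights over planted
  positive edges − Σ over negative edges) + N(0, σ_t²)`.
  Session-averaged (not single-session) edge weights drive the trait
  and the CPM models, the more common convention when two sessions are
  available. Trait variance decomposes as β²·Var(signal) + σ_t²
  (asserted within 10% at n = 4,000).

One seeded `numpy` Generator per cohort (no global RNG state), with
independent spawned streams per stage; identical config + seed is
bit-for-bit reproducible, which is also what makes the pipeline's
output files byte-identical across reruns.

**What the generator does not emulate:** BOLD time-series dynamics,
realistic white-matter geometry, head motion, scanner/site effects,
non-Gaussian trait distributions, or the empirical covariance
structure of real connectomes. Passing tests therefore demonstrate
the correctness and calibration of the *procedures*, not expected
effect sizes on real data — real identification accuracies and
brain–behavior correlations depend on variance structure the
generator deliberately idealizes.

## Calibration studies and their study sizes

The replicate studies in `connfp.experiments` (driven by
`analysis/05_calibration_studies.py` and recomputed by
`scripts/acceptance.py`) use sizes chosen to make Monte-Carlo error
small relative to the effects being checked:

- **Chance-level identification** — 1,000 fingerprint-free cohorts of
  20 subjects × 20 parcels: mean pooled accuracy ≈ 1/20 = 0.05.
- **Noise-free identification** — one 20-subject cohort with
  `σ_s = 0`: accuracy 1.0 and permutation p = 1/1001.
- **Planted-effect recovery** — 500 cohorts of 200 subjects × 10
  parcels with one planted positive edge and trait noise matched to
  the signal variance (signal:noise 1), so the population
  predicted-observed correlation is √½ ≈ 0.7071. The LOOCV estimate
  is attenuated by edge selection and finite-sample fitting: the
  500-replicate study gives mean r_pred 0.655 with sd 0.079, and the
  population value lies inside the Monte-Carlo band (mean ± 2 sd).
- **Null FDR calibration** — 200 cohorts of 60 subjects with β = 0,
  run through the full model family (whole-brain + two subnetworks ×
  two signs): ≈8% of replicates show any FDR-significant row at
  q = 0.05, and the mean null r_pred is ≈0.004.

## Numerical and design choices

- Correlation clip `1 − 1e−7`; symmetry tolerance 1e−12 on construction
  and 1e−9 on CSV read; p-value floor at the smallest positive double.
- OLS fits use `numpy.polyfit` degree 1 (two-parameter model; no
  regularization — ridge/elastic-net CPM variants are out of scope).
- CSV is the canonical matrix format, written at 17 significant digits
  and read back with round-trip float parsing, so write→read is exact.
  Labels are validated (row = column, no duplicates). NIfTI carries
  label volumes; TRK (via nibabel) or a one-point-per-line TSV dialect
  (`streamline_id x y z qa`) carries streamlines.
- Edge indices are 0-based in memory; file outputs use parcel labels
  rather than numeric indices.
- Missing traits: pairwise deletion per trait, counts logged.

## Known limitations

- The t-based `p_pred` is approximate under LOOCV dependence (see
  above); the permutation alternative is exact but ~100× slower.
- The no-model rule is a hard majority threshold; near the boundary
  (just under half the folds empty) the training-mean artifact still
  attenuates r_pred downward.
- Soft parcel memberships are looked up at the nearest voxel; no
  trilinear interpolation of membership fields.
- Identification supports exactly two sessions (reference/target);
  multi-session generalizations are out of scope.
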