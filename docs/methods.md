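# Methods

## Molecules, activities, conformers

Activities are IC50 values stored in µM; potency is expressed as
pIC50 = −log10(IC50 in mol/L). A sound quantitative training set contains at
least 16 molecules spanning at least four orders of magnitude in activity;
both checks can be overridden for toy inputs (`allow_small=True`).

Molecular flexibility is represented by a conformer ensemble generated with
distance-geometry embedding (RDKit ETKDGv3, seeded) followed by MMFF94
minimization. The ensemble is bounded by `max_conformers` (default 250) and
an `energy_window` (default 20 kcal/mol above the minimum-energy member);
near-duplicate geometries are removed greedily in energy order at a
heavy-atom RMSD threshold of 0.5 Å. The threshold is this package's
documented default for an operation whose upstream tools do not specify one.
Identical structure, settings and seed give bit-identical ensembles.

The rule-of-five filter flags MW > 500 Da, logP > 5, H-bond donors > 5, or
acceptors > 10 — strict inequalities, and a single violation rejects. logP
is the Crippen atom-contribution estimate. Donor/acceptor counts use the
same SMARTS dictionary as 3D feature perception (one count per donor or
acceptor heavy atom), so the filter and the pharmacophore engine agree on
chemistry. The filter itself is tested exclusively on synthetic descriptor
records, making its correctness independent of the estimator choices.

## Feature perception

The shipped SMARTS dictionary (`phorescreen/_smarts.py`) defines:

* **HBD** — O/N/S atoms bearing hydrogen, positioned on the heavy atom with
  the heavy-atom→H unit vector as direction;
* **HBA** — oxygens with a lone pair, pyridine-type aromatic N,
  nitrile/imine N, and H-free amines not conjugated or oxidized;
* **RingArom** — aromatic-ring centroids with the ring normal as direction;
* **HBic** — centroids of contiguous clusters of apolar carbons, thioether
  sulfurs and heavy halogens. Aromatic carbons are expressed through
  RingArom and excluded from hydrophobic clusters, so a bare benzene ring
  perceives as one RingArom feature, not one RingArom plus one hydrophobe.

Directionality is perceived but deliberately not scored: the fit model is
distance-only. This is the package's main simplification relative to
direction-aware engines and mainly affects donors and ring normals.

## Mapping and fit

A hypothesis holds at most five features, each a sphere with tolerance
(default 1.6 Å) and weight (default 1). Mapping a conformer enumerates
kind-compatible injective correspondences (optionally omitting up to
`max_omitted` features), pruned by pairwise-distance compatibility
(|d_model(i,j) − d_points(i,j)| ≤ tol_i + tol_j). Each surviving
correspondence is aligned by weighted Kabsch superposition (batched,
SVD-based, proper rotations only); it is feasible only if every mapped
displacement is within its tolerance — the hard location constraint. The
fit value is Σ w_f·(1 − (d_f/tol_f)²) over mapped features. Ties break on
lower weighted RMSD, then lexicographically on the correspondence, making
results total-ordered and deterministic. Correspondence groups whose total
mappable weight cannot strictly beat the best feasible fit already found are
skipped (a branch-and-bound shortcut that cannot change the result).

`best_fit` scans a conformer ensemble. `mode="fast"` scores stored
conformers under the least-squares alignment. `mode="best"` additionally
evaluates a fit-optimal re-alignment: inside the feasible region, maximizing
the fit equals minimizing Σ (w_f/tol_f²)·d_f², i.e. a second Kabsch pass
with rescaled weights; both alignments are checked and the better feasible
one kept. With uniform tolerances the two coincide.

The raw fit is always reported; no cap is applied. A cap tied to the fit
values of reference ligands can be imposed by callers that need one — the
capping rule used by proprietary tools is not publicly defined, so this
package treats the uncapped value as canonical.

## Hypothesis generation

* **Partition** — leads are within uncertainty² (default 9×) of the most
  potent IC50, inclusive; inactives are at least 10^3.5-fold weaker than the
  most potent compound, inclusive; the rest are moderates. Both thresholds
  follow published descriptions of activity-driven hypothesis generation and
  are configuration constants.
* **Constructive phase** — point subsets (sizes `min_features`..5, default
  3..5) of the lead with the fewest features seed candidates; a candidate
  survives only if every other lead maps all its features with zero
  omissions. Candidates are deduplicated by kind multiset plus a pairwise
  distance signature rounded to 0.1 Å. A minimum size of 3 is the package's
  choice: 1–2-point hypotheses are metrically degenerate as 3D queries.
* **Subtractive phase** — candidates fully mapped by more than 50% of the
  inactives are removed (strictly more: exactly half is retained).
* **Costs** — error cost uses k_e = 1/(2·ln2·σ²) with σ = 0.3 log units, so
  a residual of one σ beyond the uncertainty band costs ~1/(2 ln2) bits;
  weight cost is k_w·Σ(w_f−1)² with k_w = 1 bit; configuration cost is
  log2(n_configs) with n_configs the number of candidate configurations
  considered. The null cost is the error cost of the constant mean-activity
  predictor; fixed cost is the weight + configuration cost of a zero-error
  model; residual cost = null − total. The *identities* among these
  components are contractual; the absolute bit magnitudes are this package's
  own scale and are not comparable to proprietary implementations.
* **Optimization** — seeded simulated annealing perturbs one feature per
  step: center (Gaussian, σ 0.5 Å), tolerance (σ 0.1 Å, floor 0.5 Å) or
  weight (σ 0.1, floor 0). The start temperature is calibrated from a pilot
  phase (default 10 proposals) so that roughly half of uphill moves are
  accepted initially; cooling is geometric (0.93/step, default 30 steps).
  Only the `n_anneal` (default 3) lowest-cost candidates are annealed — at
  the 62-molecule study scale the constructive phase already proposes the
  correct topology and annealing is a polish, so spending steps on dominated
  candidates buys nothing. The best state ever visited is kept, hence the
  ranking never falls below the best unoptimized candidate. An optional
  kind-swap move exists but is disabled by default; topology changes are the
  constructive phase's job. At most ten hypotheses are returned, sorted by
  ascending total cost.
* Molecules that do not map contribute fit 0 to the regression rather than
  being dropped, which would bias the line toward the mapped subset.

## Validation

Retrieval statistics follow the standard definitions (%Y = 100·Ha/Ht,
%A = 100·Ha/A, E = (Ha/Ht)/(A/D), GH as in the README); GH ∈ [0,1] follows
from writing the first factor as (3·recall + precision)/4. Comparisons to
two-decimal published values round the full-precision result. Note the two
prose glosses of %Y and %A are sometimes swapped in the literature; this
package follows the bracketed formulas (%Y per hit list, %A per active
pool).

Fischer randomization permutes activities uniformly (seeded),
re-runs a builder per scramble — by default the constructive+subtractive
pipeline without annealing, for speed and determinism — and declares
significance iff the original statistic (train_r, with total cost as
tie-break; configurable) strictly beats every scramble. A training set on
which the original build fails is never significant. Supported confidence
levels are those for which 100/(100−c) is integral: 90, 95, 98, 99.

Test-set prediction reports the squared Pearson correlation between
estimated and observed pIC50, with unmapped molecules estimated at the
intercept.

## Screening funnel and consensus scoring

The funnel stages are: library → rule-of-five → conformers/feature points →
pharmacophore mapping (default `max_omitted=0`: a hit satisfies every
feature) → optional fit threshold. The drug-likeness stage rejects on a
single violation by default; `lipinski_max_violations` relaxes that for
protocols that tolerate one. Counts are non-increasing, unparseable
or unembeddable records are counted as rejected rather than dropped, and
hits are ranked by fit with ties broken by id for reproducibility.
Pseudo-ligands without descriptor records pass the drug-likeness stage
unchanged (the stage is about chemistry the abstract carriers do not have).

Consensus scoring replaces an unpublished aggregation function with a
transparent one: each scorer column is z-normalized over the calibration
molecules (orientation-corrected so higher is better), averaged with
non-negative weights summing to 1 (equal by default; zero-variance scorers
are excluded with a warning), and calibrated to pIC50 by least squares.
Predictions are invariant to positive affine rescaling of any single scorer
column (when the model is refit on the rescaled matrix) and to column order.
The packaged 9×11 pose-score matrix and companion activity file support the
workflow end to end; the package makes no claim of reproducing the
activities predicted by the original unpublished function.

## Synthetic data: what it emulates and what it does not

Pseudo-ligands are abstract typed feature-point sets, not molecules. This
isolates the mapping, generation and validation logic from conformer
embedding and feature perception, which are exercised separately on real
SMILES. Generators are deterministic under seed and serialize their
parameters.

* `make_pharmacophore` places feature centers with pairwise separation
  ≥ 2×tolerance inside a 10 Å box.
* Actives are jittered copies of the truth's features (default jitter sd
  0.4 Å) plus distractor points kept ≥ 2×tolerance away from every planted
  center — so a degraded ligand cannot accidentally recover an omitted
  feature — under a random rigid motion; each active is verified to map the
  truth in full with fit ≥ 70% of the total weight.
* Decoys are built exactly like actives of their *own* freshly drawn random
  arrangement (truth kinds shuffled), giving the same point count and
  spatial statistics; any decoy that fully maps the truth is resampled.
  Benchmark ligands carry 15 points (5 core + 10 distractors), a density at
  which an arbitrary five-feature query retrieves a few percent of the
  library — the order of magnitude of real decoy-matched screens.
* Simulated activities are pIC50 = slope·fit + intercept + N(0, noise_sd)
  with defaults slope 1.3, intercept 3.5, noise 0.3 log units, spanning
  more than four orders of magnitude over 62 ligands in a realistic 4.5–10
  pIC50 range.
* Training ligands come in feature-completeness classes (0–4 planted
  features removed; jitter 0.15 Å when complete, 0.3 Å otherwise),
  emulating a potency gradient in which weaker binders engage fewer
  pharmacophore sites — the structure–activity coupling a quantitative
  model presumes.

Passing tests on this data demonstrates correct recovery of planted signal
under the stated noise model. It does **not** demonstrate performance on
real chemistry: pseudo-ligands have no conformational strain, no feature
perception ambiguity, no activity cliffs, and decoy "property matching" is
defined on point-set statistics rather than physicochemical properties.

## Numerical choices and degenerate inputs

* Kabsch superposition restricts to proper rotations (det +1); mirror
  images of chiral point sets therefore retain positive RMSD. Rank-deficient
  cases (single points, collinear sets) resolve to a valid rotation via the
  SVD sign convention.
* Feasibility uses d ≤ tol + 1e-12; fit ties compare exactly, then RMSD,
  then the correspondence tuple.
* Zero-variance fit vectors (every molecule scores the same) are rejected
  as degenerate rather than fitted.
* A hypothesis ranking is valid only if sorted and of length ≤ 10; cost
  reports self-check their additive identities at 1e-6.
* Problem sizes in the test suite (62-molecule training sets, 20
  replicates, a 3606-molecule benchmark, exhaustive GH sweep to D = 60)
  were chosen to exercise the study-scale behavior of every stage on a
  single CPU.

## Known limitations

* No excluded-volume spheres, no field-based or shape scoring, no feature
  directionality in the score.
* No docking engine: external pose-score matrices are the integration
  boundary for structure-based rescoring.
* Cost magnitudes are on this package's own bit scale; only their
  identities and orderings are meaningful across implementations.
* The constructive phase anchors candidates on a single reference lead; a
  pathological lead set in which the reference lacks the common
  configuration (while all others share it) would miss it. Using the
  smallest lead as reference minimizes this risk.
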