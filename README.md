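# phorescreen

Ligand-based 3D pharmacophore modeling and virtual screening for small-molecule
drug discovery: quantitative hypothesis generation from activity-annotated
ligands, fit-value scoring, a rule-of-five + pharmacophore screening funnel,
retrieval statistics (Güner-Henry scoring, enrichment factors, Fischer
randomization), and consensus aggregation of external docking scores into
activity predictions.

## The science

A **pharmacophore** is the abstract 3D arrangement of chemical features —
hydrogen-bond donors (HBD), acceptors (HBA), hydrophobes (HBic), aromatic
rings (RingArom) — required for biological activity. A quantitative
hypothesis is a set of at most five toleranced, weighted feature spheres
together with a linear map from fit values to potency. A conformer *maps*
the hypothesis when a kind-compatible, injective assignment of its perceived
feature points exists such that, after optimal weighted rigid superposition
(Kabsch), every mapped point lies inside its tolerance sphere. Its fit value
is

```
fit = Σ_mapped  w_f · (1 − (d_f / tol_f)²)
```

where `d_f` is the post-alignment displacement; fit is bounded by the summed
weights and reaches the bound only for a perfect superposition. Predicted
potency is `pIC50 ≈ slope·fit + intercept`, with pIC50 the negative log10 of
the molar IC50.

Hypothesis generation proceeds through constructive (features common to the
most potent "leads"), subtractive (configurations matched by the least
active compounds are dropped) and annealing-optimization phases, ranked by a
total cost in bits:

```
total = error + weight + config
error = k_e · Σ_i max(0, |pIC50_i − est_i| − log10(uncertainty))²
```

Residuals inside the multiplicative uncertainty band (default ×3) cost
nothing. The *residual cost* — the cost of the no-relationship null model
minus the total cost — measures how unlikely the fit–activity correlation is
to arise by chance.

Screening performance on a labeled database (D molecules, A actives, Ht
hits, Ha active hits) is summarized by

```
%Y = 100·Ha/Ht    %A = 100·Ha/A    E = (Ha/Ht)/(A/D)
GH = (Ha(3A+Ht)/(4·Ht·A)) · (1 − (Ht−Ha)/(D−A))   ∈ [0, 1]
```

with GH = 1 the ideal screen. Statistical significance of a hypothesis is
assessed by Fischer randomization: re-deriving models on activity-scrambled
training sets (19 scrambles at the 95% level) and requiring the original to
beat every scramble.

Because real screening libraries and proprietary conformer generators are
not redistributable, the `synthdata` module provides seeded generators of
abstract *pseudo-ligands* — typed feature-point sets with a planted
ground-truth pharmacophore, simulated activities, and property-matched
decoys — so every pipeline stage is testable end to end.

## Worked example

```python
from phorescreen import synthdata, hypogen, screening, validation
from phorescreen.pharmacophore import FeatureKind

kinds = [FeatureKind.HBD] + [FeatureKind.HBIC] * 4
truth = synthdata.make_pharmacophore(5, kinds=kinds, seed=7)

# 62 training pseudo-ligands, activities linear in fit + noise (sd 0.3)
ts = synthdata.make_training_set(truth, n=62, seed=11)
ranking = hypogen.build_hypotheses(ts, seed=5)
best = ranking.best
print(best.hypothesis.kind_multiset(), round(best.train_r, 3))
# ('HBD', 'HBic', 'HBic', 'HBic', 'HBic') 0.97

# screen a planted benchmark (3606 molecules, 66 actives) with the truth
bench = synthdata.make_benchmark(3606, 66, truth, seed=42)
hits, funnel = screening.screen_library(
    bench.library, truth, screening.ScreeningConfig(mode="best", max_omitted=0, seed=1))
active_ids = {l.id for l in bench.actives}
rep = validation.enrichment_metrics(validation.EnrichmentCounts(
    D=3606, A=66, Ht=len(hits), Ha=sum(h.id in active_ids for h in hits)))
print(len(hits), round(rep.gh, 3), round(rep.enrichment, 1))
# 66 1.0 54.6
```

The first block recovers the planted donor + four-hydrophobes topology with
a training correlation of 0.97; the second retrieves all 66 planted actives
and nothing else (GH = 1, 55-fold enrichment over random retrieval).

The enrichment calculator is also exposed on the command line:

```
$ phorescreen gh --counts D=3606,A=66,Ht=75,Ha=53
yield_pct,ratio_pct,enrichment,gh,false_neg,false_pos
70.67,80.30,38.61,0.73,13,22
```

Other subcommands: `conformers`, `lipinski`, `build`, `fischer`, `screen`,
`consensus fit|predict`, `simulate benchmark`. A 9-molecule × 11-scorer
docking pose-score matrix ships as a packaged fixture
(`phorescreen.datasets.nsc_pose_scores()`) for the consensus-scoring workflow.

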