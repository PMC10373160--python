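# ksphos

Kinase-specific phosphorylation-site prediction with interpretable,
per-cluster sequence models.

Phosphoproteomics reliably tells you *which* serine, threonine or
tyrosine residues are phosphorylated, but rarely *which kinase* is
responsible. `ksphos` is a toolkit for building and applying
kinase-specific phosphosite classifiers: given curated kinase–substrate
site tables and substrate sequences, it trains one binary classifier per
kinase cluster (a kinome group, a family, or an individual kinase,
separately for S/T and Y substrates where warranted) and scores
candidate sites on new proteins. Every prediction can be explained with
position-grouped Shapley attributions and compared against sequence
logos of the training data.

## The model

For a candidate phosphosite at position *p* of a substrate, the input is
the 15-residue window *s*₋₇…*s*₊₇ centered on *p* (windows overlapping a
terminus are padded). Each residue is encoded as its 20-value row of the
BLOSUM62 substitution matrix, giving a position-major feature vector
**x** ∈ ℝ³⁰⁰ (15 × 20). A per-cluster classifier *f* (gradient-boosted
trees by default, or an RBF SVM with calibrated probabilities) maps
**x** to P(phosphosite | cluster); sites with *f*(**x**) ≥ 0.5 are
called phospho.

Training sets are built per cluster:

* **positives** — windows of the cluster's experimentally verified
  sites, deduplicated by window sequence; clusters with fewer than 15
  unique positives are rejected;
* **negatives** — every other same-type (S/T or Y) residue on the
  cluster's own substrate proteins, thinned so that no negative has
  ≥ 40 % ungapped identity to any positive, no two retained negatives
  share ≥ 40 % identity, and finally undersampled to at most five
  negatives per positive.

Evaluation uses the confusion-matrix suite — accuracy, recall = TP/(TP+FN),
precision = TP/(TP+FP), F1 = 2·P·R/(P+R) — their support-weighted
two-class variants, and the ROC AUC, under stratified 10-fold
cross-validation.

For interpretation, the Shapley value φᵢ of feature *i* is its average
marginal contribution to the model output over feature coalitions, with
the additivity property φ₀ + Σφᵢ = *f*(**x**). Because one window
position owns 20 encoding features, those are attributed jointly as a
feature group, yielding 15 per-position importances. Tree models are
explained exactly (closed-form interventional attribution per tree leaf,
averaged over a background set); SVMs with seeded permutation sampling.
Kinases lacking curated classification can inherit group/family labels
from a phylogenetic tree (first informative ancestor, unanimity rule).

## Worked example

A synthetic cluster with a planted motif (information-rich positions −5
and −3, concentration 0.9, 200 positive sites on 100 background
proteins) run through the full pipeline:

```python
from ksphos import synthetic, dataset, modeling
from ksphos.windowing import ResidueClass

motif = synthetic.make_motif([-5, -3], ResidueClass.ST, concentration=0.9, seed=1)
frag = synthetic.plant_sites(motif, n_proteins=100, protein_length=200,
                             sites_per_protein=2, seed=1)
cluster = dataset.assemble_cluster(frag.sites, frag.proteins, "PLANTED",
                                   "family", ResidueClass.ST,
                                   config=dataset.ReductionConfig(seed=1))
results = modeling.PhosphositeModel(cluster, modeling.ModelSpec(seed=1)).fit()
results.cross_validate(k=10, seed=1)
print(results.summary())
```

```
Phosphosite classifier results
==================================
cluster:        PLANTED (family)
residue class:  ST
algorithm:      gbtree
positives:      200
negatives:      1000
flank:          7 (window length 15)
features:       300
seed:           1

10-fold cross-validation (means)
----------------------------------
accuracy            0.951
recall              0.815
precision           0.884
f1                  0.845
weighted_accuracy   0.951
weighted_recall     0.951
weighted_precision  0.951
weighted_f1         0.950
auc                 0.983
```

The 1000 negatives are the five-fold cap on the 200 positives after
redundancy reduction. Position-grouped Shapley attribution recovers the
planted motif — the two informative positions dominate all thirteen
background positions:

```python
att = results.explain(windows=cluster.positives[:100], seed=0)
print(att.to_frame().sort_values("mean_abs_shap", ascending=False).head(4))
```

```
 position  mean_abs_shap
       -5       6.822461
       -3       6.118486
        7       0.546682
       -4       0.405459
```

The same workflow is available from the shell via the `ksphos` command
(`simulate`, `annotate`, `train`, `evaluate`, `predict` subcommands);
`ksphos predict` emits a TSV whose `source` column distinguishes
experimentally verified sites (`Exp.`) from purely predicted ones
(`Pred.`).

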