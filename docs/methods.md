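# Methods

## Problem and model

`ksphos` predicts, per kinase cluster, whether a serine/threonine or
tyrosine residue is a phosphosite of that cluster. The unit of
observation is the site-centered sequence window of length
2·flank + 1 (default flank 7 → 15-mers); nothing else about the
substrate (structure, disorder, domains) enters the model. Each window
position is encoded as the BLOSUM62 row of its residue in the canonical
residue order A R N D C Q E G H I L K M F P S T W Y V, giving a
position-major vector of 15 × 20 = 300 integer log-odds features. The
pad character `-` (used when a window overlaps a protein terminus) and
the ambiguity codes B, Z, X, U, O encode as all-zero blocks, so such
positions carry no signal and receive no attribution. Feature values
are the raw log-odds; an optional standardization step is deliberately
not applied by default, since tree ensembles are scale-invariant and
the SVM's RBF kernel operates on the bounded integer range (−4..11).

Two classifier families are supported, with the gradient-boosted tree
as the default for prediction:

* `gbtree` — xgboost, 300 trees, depth 6, learning rate 0.1,
  histogram split finding, single thread, seeded;
* `svm` — RBF kernel, C = 1, gamma = "scale", probability outputs via
  internal 5-fold sigmoid (Platt) calibration.

These hyperparameters are exposed in `ModelSpec` and recorded in model
metadata together with seed, flank, feature layout and training counts,
so a registry model refuses inputs with a mismatched layout. The
decision threshold is fixed at 0.5.

## Training-set construction

For one cluster (a kinome group, family, or individual kinase, filtered
to a residue class — ALL, ST or Y):

1. Positive windows are extracted at verified sites, deduplicated first
   by (substrate, position) and then by window sequence. Clusters with
   fewer than `min_positives = 15` unique positives are rejected — with
   fewer examples than that, per-cluster models are not built.
2. The negative pool is every same-class residue on the cluster's own
   substrate proteins that is not a positive coordinate, in
   deterministic (substrate, position) order. Negatives are never drawn
   from proteins outside the cluster's substrate set.
3. Inter-set reduction removes negatives with identity ≥ 0.4 to any
   positive. Identity between two equal-length windows is the fraction
   of positions with identical non-pad residues; pad-vs-pad counts as a
   mismatch so terminal windows cannot match through shared padding.
   This exact ungapped identity replaces the word-based similarity of
   greedy clustering tools: for fixed-length 15-mers an alignment-free
   identity is well defined, bit-reproducible and independent of word
   size heuristics, while the 0.4 threshold is kept.
4. Intra-set reduction greedily selects negative representatives so
   that no two retained negatives share identity ≥ 0.4. Visit order is
   lexicographic by (sequence, substrate, position) — a fixed total
   order that makes the greedy result reproducible (length ordering,
   the usual tie-break in clustering tools, is vacuous for constant
   length).
5. If negatives still outnumber positives more than five-fold, a
   seeded uniform undersample without replacement caps them at 5:1.

All thresholds, the ratio, the seed and the resulting counts are stored
in a JSON provenance sidecar when a cluster is serialized.

Cross-validation is stratified k-fold (default k = 10, configurable)
on the once-balanced training set; folds are split with a fixed seed
and the report carries both fold-level metrics and their means. The
balancing is not redone per fold, so fold class ratios match the
training ratio. Degenerate metric denominators follow the zero
convention (precision/recall = 0 when undefined, F1 = 0 when
precision + recall = 0). Support-weighted metrics treat each class in
turn as positive and weight by class prevalence; weighted recall then
telescopes to plain accuracy, which the tests assert as an identity.

## Taxonomy propagation

Kinases without curated classification inherit labels from a
phylogenetic tree whose leaves are kinase identifiers. The rule is
"first informative ancestor with unanimity": ascend from the
unannotated leaf; at the first ancestor whose clade contains at least
one annotated leaf, adopt the label if all annotated leaves in that
clade agree at the requested level, otherwise leave the leaf
unassigned. Seed annotations are never modified, and annotated
identifiers absent from the tree only produce a warning. This is a
deliberate formalization of neighborhood-based annotation; nearest
neighbor by branch length was rejected because it must guess in exactly
the ambiguous cases where unanimity abstains. Trees are consumed, not
inferred; unrooted newick input is treated as rooted at its notational
root.

## Shapley attribution

Explanations are additive feature attributions: base value φ₀ (the
expected model output over a background set) plus per-feature values φᵢ
reconstructing the model output. Three routes:

* **Exact enumeration** (≤ 12 features) evaluates the model on all 2^M
  coalitions, with absent features taking a single background row's
  values. It is the oracle the other routes are tested against.
* **Tree models** use an interventional tree-path attribution computed
  from the booster dump. For one tree, one instance and one background
  row, a leaf is reached by a coalition iff every path feature on which
  only the instance satisfies the splits is present and every feature
  on which only the background satisfies them is absent; the Shapley
  value of that indicator game has a closed form in the counts of the
  two feature sets. Summing over leaves and trees and averaging over
  background rows gives exact (non-sampled) values in margin
  (log-odds) space, where the ensemble is additive. Split comparisons
  are evaluated in float32 to mirror the booster's own inference, so
  hybrid points lying on a threshold take the same branch as the
  booster. Leaf-sum margins are accumulated in float64, making the
  additivity identity hold to machine precision (tolerance 1e-6 is
  enforced).
* **SVMs** use permutation sampling on the positive-class probability:
  marginal contributions along seeded random feature orderings. Each
  ordering's contributions telescope to f(x) − f(background), so
  additivity is exact by construction (tolerance 1e-3 enforced);
  individual values converge with the number of permutations (default
  20).

The default background is the cluster's training negatives — the
natural "unremarkable residue" reference — subsampled with the seed to
at most 16 rows to bound cost; both choices are configurable. Because
each window position owns a 20-feature block, attributions are reported
as 15 position groups: the signed group value is the sum of its member
φᵢ (conserving the total), and positions are ranked by mean absolute
group value across the explained instances.

## Logos

Sequence logos report per-position residue frequencies over non-pad
symbols and the information content log₂ 20 − H in bits (0 for a
uniform column, log₂ 20 ≈ 4.32 for perfect conservation); all-pad
positions are flagged rather than given frequencies. The differential
logo contrasts positives against negatives with a two-proportion
z-score using pooled variance per (position, residue); it is zero when
the proportions are equal and antisymmetric under swapping the inputs.
This standardized-difference statistic is a stated stand-in for
probability-based differential-logo tools; it preserves the sign and
ranking semantics those tools convey.

## Synthetic data

The generator emulates the structure the models are meant to exploit: a
positive 15-mer distribution with a fixed central residue class, a few
information-rich flanking positions (default −5 and −3 at concentration
0.9, i.e., 90 % of positives carry the chosen residue there), and
uninformative uniform flanks, embedded in background proteins drawn
uniformly over the 20 residues. Defaults produce 200 positive sites
(100 proteins × 2 sites, length 200), the scale at which training,
cross-validation and attribution all run in seconds. Planted windows
never overlap (one per protein segment), so planted positives cannot
collide with enumerated negatives. Labeled trees place each family in
its own clade with exactly one pre-annotated leaf.

What the generator does not emulate — and what passing tests therefore
do not show about real data: realistic amino-acid composition and
disorder context around phosphosites, overlapping kinase specificities,
correlated motif positions, homology between substrates beyond window
identity, and realistic kinome tree branch lengths. Results on
synthetic clusters validate the machinery (pipeline correctness,
attribution faithfulness, metric arithmetic), not biological
performance.

## Numerical and design notes

* Candidate positions are 1-based throughout, matching the convention
  of protein databases.
* Greedy reduction, undersampling, fold splitting, motif construction
  and attribution sampling are all driven by explicit seeds; identical
  seeds give bit-identical outputs.
* The registry stores boosters as JSON text and SVMs via joblib, with a
  versioned index; loading a mismatched version fails rather than
  guessing.
* `train` refuses single-class clusters; `cross_validate` refuses k < 2
  or classes too small to stratify; AUC refuses one-class inputs.
* Problem sizes in the test suite (clusters of 200 positives, 8–12
  feature oracle models, 10-seed attribution replicates) were chosen so
  the full pipeline stays interactive on a single CPU while keeping the
  planted-signal checks statistically unambiguous.

## Known limitations

* The identity filter is a proxy for word-based greedy clustering; at
  the same nominal threshold it can retain slightly different negative
  sets than those tools would.
* Cross-validation is performed on the balanced (≤ 5:1) sets, so
  reported precision reflects that ratio, not the proteome-wide base
  rate.
* SVM attribution values are sampled estimates; only their sum is
  exact. Increase `n_permutations` for tighter per-feature values.
* Label propagation abstains on conflicted clades by design; it will
  leave leaves unassigned in polyphyletic regions rather than guess.
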