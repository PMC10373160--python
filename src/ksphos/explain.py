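"""Shapley-value attribution of phosphosite predictions, grouped by
window position, plus sequence-logo summaries.

The Shapley value of feature i is its average marginal contribution to
the model output over all coalitions of the other features, weighted by
|z|! (M - |z| - 1)! / M!; absent features take the value of a background
reference.  The explanation is additive: the base value (expected model
output over the background) plus all per-feature values reconstructs the
model output for the instance.

Three computation routes are provided:

* :func:`exact_shapley` — direct enumeration of all 2^M coalitions for
  small M; the ground truth the other routes are validated against.
* tree-path attribution for gradient-boosted trees — an interventional
  TreeSHAP: per tree and background row the Shapley values have a closed
  form over each leaf's path conditions, so the result is exact (not
  sampled) and is averaged over the background set.  Attribution is in
  margin (log-odds) space, where the ensemble is additive.
* permutation sampling for SVMs — marginal contributions along random
  feature orderings; each ordering telescopes to f(x) - f(background),
  so additivity is preserved exactly while individual values converge
  with the number of permutations.

Since every residue is encoded as a 20-value substitution-matrix block,
the 20 features of one window position form a natural feature group;
:func:`group_by_position` sums member values into per-position signed
attributions and ranks positions by mean absolute group value.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import xgboost

from .encoding import RESIDUE_ORDER
from .modeling import TrainedModel
from .windowing import PAD, Window

EXACT_LIMIT = 12
_FACT = [math.factorial(i) for i in range(80)]
_FACT_ARR = np.array([float(f) for f in _FACT])


@dataclass
class ShapExplanation:
    """Additive feature attribution for one instance."""

    base_value: float
    values: np.ndarray  # (M,)
    model_output: float
    instance_index: int = 0

    @property
    def additivity_gap(self) -> float:
        return abs(self.base_value + float(self.values.sum()) - self.model_output)


@dataclass
class PositionAttribution:
    """Position-grouped Shapley summaries for a set of instances."""

    positions: list[int]  # offsets -flank..+flank
    group_values: np.ndarray  # (n_instances, n_positions), signed
    mean_abs: np.ndarray  # (n_positions,)

    def ranking(self) -> list[int]:
        """Position offsets ordered by decreasing mean absolute value."""
        order = np.argsort(-self.mean_abs, kind="stable")
        return [self.positions[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "mean_abs_shap": self.mean_abs}
        )


def exact_shapley(
    model_fn: Callable[[np.ndarray], np.ndarray],
    instance: np.ndarray,
    background: np.ndarray,
    max_features: int = EXACT_LIMIT,
) -> ShapExplanation:
    """Shapley values by direct enumeration of all feature coalitions.

    ``background`` is a single reference instance supplying the values of
    absent features.  Exponential in M; refuses M > ``max_features``.
    """
    x = np.asarray(instance, dtype=float).ravel()
    bg = np.asarray(background, dtype=float).ravel()
    M = x.size
    if bg.size != M:
        raise ValueError("instance and background differ in length")
    if M > max_features:
        raise ValueError(
            f"exact enumeration over {M} features is intractable (limit "
            f"{max_features}); use explain_instances instead"
        )
    # evaluate the model on every coalition once
    masks = np.array(list(itertools.product([0, 1], repeat=M)), dtype=bool)
    points = np.where(masks, x, bg)
    outputs = np.asarray(model_fn(points), dtype=float).ravel()
    value = {tuple(m): o for m, o in zip(masks, outputs)}

    phi = np.zeros(M)
    others = list(range(M))
    for i in range(M):
        rest = [j for j in others if j != i]
        for r in range(M):
            for subset in itertools.combinations(rest, r):
                m = np.zeros(M, dtype=bool)
                m[list(subset)] = True
                without = value[tuple(m)]
                m[i] = True
                with_i = value[tuple(m)]
                weight = _FACT[r] * _FACT[M - r - 1] / _FACT[M]
                phi[i] += weight * (with_i - without)
    base = float(value[tuple(np.zeros(M, dtype=bool))])
    out = float(value[tuple(np.ones(M, dtype=bool))])
    return ShapExplanation(base_value=base, values=phi, model_output=out)


# ---------------------------------------------------------------------------
# interventional tree-path attribution

def _parse_tree(node: dict, conditions: dict, leaves: list) -> None:
    if "leaf" in node:
        # freeze the per-feature condition lists for this leaf
        leaves.append(
            (float(node["leaf"]), {f: list(conds) for f, conds in conditions.items()})
        )
        return
    feat = int(node["split"].lstrip("f"))
    thr = float(node["split_condition"])
    children = {c["nodeid"]: c for c in node["children"]}
    for branch, sat in ((node["yes"], True), (node["no"], False)):
        conditions.setdefault(feat, []).append((thr, sat))
        _parse_tree(children[branch], conditions, leaves)
        conditions[feat].pop()
        if not conditions[feat]:
            del conditions[feat]


def _booster_leaves(booster: xgboost.Booster) -> list[list[tuple[float, dict]]]:
    """Per tree: list of (leaf value, {feature: [(thr, goes_yes), ...]})."""
    trees = []
    for dump in booster.get_dump(dump_format="json"):
        leaves: list = []
        _parse_tree(json.loads(dump), {}, leaves)
        trees.append(leaves)
    return trees


def _passes(values: np.ndarray, conds: list[tuple[float, bool]]) -> np.ndarray:
    # xgboost evaluates splits in float32; mirror that exactly so hybrid
    # points on a threshold take the same branch as the booster
    v = values.astype(np.float32)
    ok = np.ones(values.shape[0], dtype=bool)
    for thr, goes_yes in conds:
        side = v < np.float32(thr)
        ok &= side if goes_yes else ~side
    return ok


def tree_shap_interventional(
    booster: xgboost.Booster,
    X: np.ndarray,
    background: np.ndarray,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Exact interventional Shapley values for a tree ensemble.

    For one tree and one background row, a leaf is reached by coalition z
    iff every path feature where only the instance satisfies the splits
    is present and every feature where only the background satisfies them
    is absent; the Shapley value of such an indicator game has a closed
    form, summed over leaves and trees and averaged over background rows.

    Returns ``(phi, base_value, margins)`` where ``phi`` is (n, M) in
    margin space, ``base_value`` the mean background margin, and
    ``margins`` the instances' margin outputs.
    """
    X = np.asarray(X, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n, M = X.shape
    nbg = background.shape[0]
    phi = np.zeros((n, M))
    # float64 leaf-sum margins so that additivity holds to machine precision
    # (the booster's own predictions are float32)
    x_sum = np.zeros(n)
    bg_sum = np.zeros(nbg)
    all_trees = _booster_leaves(booster)
    for leaves in all_trees:
        for leaf_value, conds in leaves:
            reach_x = np.ones(n, dtype=bool)
            reach_bg = np.ones(nbg, dtype=bool)
            for f, cs in conds.items():
                reach_x &= _passes(X[:, f], cs)
                reach_bg &= _passes(background[:, f], cs)
            x_sum += leaf_value * reach_x
            bg_sum += leaf_value * reach_bg
    for leaves in all_trees:
        for leaf_value, conds in leaves:
            if not conds:
                continue  # constant leaf: cancels between instance and background
            feats = list(conds)
            k = len(feats)
            xp = np.stack([_passes(X[:, f], conds[f]) for f in feats], axis=1)
            bp = np.stack(
                [_passes(background[:, f], conds[f]) for f in feats], axis=1
            )
            xpb = xp[:, None, :]  # (n, 1, k)
            bpb = bp[None, :, :]  # (1, nbg, k)
            need_on = xpb & ~bpb  # feature must be in the coalition
            need_off = ~xpb & bpb  # feature must be out of the coalition
            dead = (~xpb & ~bpb).any(axis=2)  # (n, nbg)
            a = need_on.sum(axis=2)
            b = need_off.sum(axis=2)
            tot = a + b
            # phi for "need on" features: c * (a-1)! b! / (a+b)!
            coef_on = np.where(
                (a > 0) & ~dead,
                leaf_value * _FACT_ARR[np.maximum(a - 1, 0)] * _FACT_ARR[b] / _FACT_ARR[tot],
                0.0,
            )
            coef_off = np.where(
                (b > 0) & ~dead,
                -leaf_value * _FACT_ARR[a] * _FACT_ARR[np.maximum(b - 1, 0)] / _FACT_ARR[tot],
                0.0,
            )
            contrib = (
                need_on * coef_on[:, :, None] + need_off * coef_off[:, :, None]
            ).mean(axis=1)  # (n, k), averaged over background rows
            phi[:, feats] += contrib
    # intercept (base_score in margin space): constant offset shared by all
    # outputs, recovered once from a booster prediction
    probe = booster.predict(xgboost.DMatrix(X[:1]), output_margin=True)
    intercept = float(probe[0]) - x_sum[0]
    margins = x_sum + intercept
    bg_margin = float(bg_sum.mean()) + intercept
    return phi, bg_margin, margins


# ---------------------------------------------------------------------------
# permutation sampling (SVM and other black-box models)

def permutation_shapley(
    model_fn: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Sampled Shapley values along random feature orderings.

    The marginal contributions along one ordering telescope to
    f(x) - f(background), so the average over orderings (and background
    rows) satisfies additivity exactly; individual values are estimates.
    """
    X = np.asarray(X, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n, M = X.shape
    rng = np.random.default_rng(seed)
    phi = np.zeros((n, M))
    for _ in range(n_permutations):
        order = rng.permutation(M)
        for bg in background:
            for i in range(n):
                # chain of hybrids bg -> x: hybrid t carries order[:t] from x
                hybrids = np.tile(bg, (M + 1, 1))
                for t, f in enumerate(order):
                    hybrids[t + 1 :, f] = X[i, f]
                outputs = np.asarray(model_fn(hybrids), dtype=float).ravel()
                phi[i, order] += np.diff(outputs)
    phi /= n_permutations * background.shape[0]
    base = float(np.asarray(model_fn(background), dtype=float).mean())
    outputs = np.asarray(model_fn(X), dtype=float).ravel()
    return phi, base, outputs


# ---------------------------------------------------------------------------
# front end

def _subsample_background(
    background: np.ndarray, max_background: int, seed: int
) -> np.ndarray:
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] <= max_background:
        return background
    rng = np.random.default_rng(seed)
    idx = rng.choice(background.shape[0], size=max_background, replace=False)
    return background[np.sort(idx)]


def explain_instances(
    model: TrainedModel,
    instances: np.ndarray,
    background: np.ndarray,
    max_background: int = 16,
    n_permutations: int = 20,
    seed: int = 0,
) -> list[ShapExplanation]:
    """Shapley explanations for a batch of encoded windows.

    gbtree models use exact interventional tree-path attribution in
    margin space (additivity tolerance 1e-6); svm models use permutation
    sampling on the positive-class probability (tolerance 1e-3).
    """
    instances = np.atleast_2d(np.asarray(instances, dtype=float))
    if instances.shape[1] != model.n_features:
        raise ValueError(
            f"instances have {instances.shape[1]} features; model expects "
            f"{model.n_features}"
        )
    bg = _subsample_background(background, max_background, seed)
    if bg.shape[1] != model.n_features:
        raise ValueError("background feature layout does not match the model")
    if model.spec.algorithm == "gbtree":
        phi, base, outputs = tree_shap_interventional(
            model.estimator.get_booster(), instances, bg
        )
        tol = 1e-6
    else:
        def proba(points: np.ndarray) -> np.ndarray:
            return np.asarray(model.estimator.predict_proba(points))[:, 1]

        phi, base, outputs = permutation_shapley(
            proba, instances, bg, n_permutations=n_permutations, seed=seed
        )
        tol = 1e-3
    explanations = []
    for i in range(instances.shape[0]):
        exp = ShapExplanation(
            base_value=base,
            values=phi[i],
            model_output=float(outputs[i]),
            instance_index=i,
        )
        if exp.additivity_gap > tol:
            raise AssertionError(
                f"additivity violated for instance {i}: gap {exp.additivity_gap:.2e}"
            )
        explanations.append(exp)
    return explanations


def group_by_position(
    explanations: list[ShapExplanation],
    layout: Sequence[tuple[int, str]],
) -> PositionAttribution:
    """Sum per-feature values into the 20-feature groups of each window
    position and report the mean absolute group value across instances."""
    M = len(layout)
    if M % 20 != 0:
        raise ValueError(f"feature count {M} is not divisible by 20")
    n_positions = M // 20
    positions = [layout[20 * p][0] for p in range(n_positions)]
    values = np.stack([e.values for e in explanations])
    if values.shape[1] != M:
        raise ValueError("explanation width does not match the layout")
    grouped = values.reshape(len(explanations), n_positions, 20).sum(axis=2)
    return PositionAttribution(
        positions=positions,
        group_values=grouped,
        mean_abs=np.abs(grouped).mean(axis=0),
    )


def attribution_frame(
    attribution: PositionAttribution, instance_ids: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Long-format (instance, position, group value) table."""
    n, p = attribution.group_values.shape
    ids = list(instance_ids) if instance_ids is not None else list(range(n))
    rows = [
        (ids[i], attribution.positions[j], attribution.group_values[i, j])
        for i in range(n)
        for j in range(p)
    ]
    return pd.DataFrame(rows, columns=["instance", "position", "group_value"])


# ---------------------------------------------------------------------------
# sequence logos

@dataclass
class LogoMatrix:
    """Per-position residue frequencies and information content (bits)."""

    frequencies: pd.DataFrame  # index: position offsets; columns: residues
    information: pd.Series  # bits per position
    all_pad_positions: list[int] = field(default_factory=list)


@dataclass
class DifferentialLogo:
    """Standardized positive-vs-negative enrichment per (position, residue)."""

    scores: pd.DataFrame  # two-proportion z-scores
    n_positives: int
    n_negatives: int


def _position_counts(windows: list[Window]) -> tuple[np.ndarray, np.ndarray, int]:
    length = len(windows[0])
    counts = np.zeros((length, 20))
    res_index = {aa: i for i, aa in enumerate(RESIDUE_ORDER)}
    for w in windows:
        if len(w) != length:
            raise ValueError("windows of unequal length")
        for p, aa in enumerate(w.sequence):
            if aa in res_index:
                counts[p, res_index[aa]] += 1
    return counts, counts.sum(axis=1), length


def sequence_logo(windows: list[Window]) -> LogoMatrix:
    """Residue frequencies over non-pad symbols and the per-position
    information content log2(20) - H (bits)."""
    if not windows:
        raise ValueError("cannot build a logo from an empty window set")
    counts, totals, length = _position_counts(windows)
    flank = length // 2
    offsets = list(range(-flank, flank + 1))
    freqs = np.full((length, 20), np.nan)
    info = np.zeros(length)
    all_pad = []
    for p in range(length):
        if totals[p] == 0:
            all_pad.append(offsets[p])
            continue
        f = counts[p] / totals[p]
        freqs[p] = f
        nz = f[f > 0]
        info[p] = math.log2(20) + float((nz * np.log2(nz)).sum())
    return LogoMatrix(
        frequencies=pd.DataFrame(freqs, index=offsets, columns=list(RESIDUE_ORDER)),
        information=pd.Series(info, index=offsets, name="bits"),
        all_pad_positions=all_pad,
    )


def differential_logo(
    positives: list[Window], negatives: list[Window]
) -> DifferentialLogo:
    """Two-proportion z-score of residue usage, positives vs negatives,
    with pooled variance; zero where the two proportions are equal."""
    if not positives or not negatives:
        raise ValueError("both window sets must be non-empty")
    cp, tp_, length = _position_counts(positives)
    cn, tn_, length_n = _position_counts(negatives)
    if length != length_n:
        raise ValueError("positive and negative windows differ in length")
    flank = length // 2
    offsets = list(range(-flank, flank + 1))
    z = np.zeros((length, 20))
    for p in range(length):
        n1, n2 = tp_[p], tn_[p]
        if n1 == 0 or n2 == 0:
            continue
        p1 = cp[p] / n1
        p2 = cn[p] / n2
        pooled = (cp[p] + cn[p]) / (n1 + n2)
        var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
        with np.errstate(invalid="ignore", divide="ignore"):
            zz = np.where(var > 0, (p1 - p2) / np.sqrt(var), 0.0)
        z[p] = np.where(p1 == p2, 0.0, zz)
    return DifferentialLogo(
        scores=pd.DataFrame(z, index=offsets, columns=list(RESIDUE_ORDER)),
        n_positives=len(positives),
        n_negatives=len(negatives),
    )


def plot_group_importance(attribution: PositionAttribution, ax=None):
    """Bar chart of mean absolute group values per window position."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.bar([str(p) for p in attribution.positions], attribution.mean_abs)
    ax.set_xlabel("window position")
    ax.set_ylabel("mean |group Shapley value|")
    return ax


def plot_logo(logo: LogoMatrix, ax=None):
    """Stacked letter-height plot: per-position information content split
    by residue frequency (plain matplotlib rendering)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    for pos in logo.frequencies.index:
        freqs = logo.frequencies.loc[pos]
        if freqs.isna().all():
            continue
        bottom = 0.0
        total_bits = logo.information.loc[pos]
        for aa, f in freqs.sort_values().items():
            if f <= 0:
                continue
            h = f * total_bits
            ax.bar([str(pos)], [h], bottom=bottom, label="_")
            if h > 0.3:
                ax.text(str(pos), bottom + h / 2, aa, ha="center", va="center", fontsize=7)
            bottom += h
    ax.set_xlabel("window position")
    ax.set_ylabel("bits")
    return ax
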