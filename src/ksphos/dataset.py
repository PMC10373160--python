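"""Per-cluster training-set construction.

Positives are the windows around experimentally verified sites of a
cluster (a kinase group, family, or individual kinase).  Negatives are
every other same-type residue on the cluster's own substrate proteins.
The negative pool is then thinned in three stages mirroring common
redundancy-reduction practice:

1. inter-set reduction: drop any negative with >= 40% identity to a
   positive (CD-HIT-2D at its minimum threshold, emulated by exact
   ungapped identity on the fixed-length windows);
2. intra-set reduction: greedy representative selection so that no two
   retained negatives share >= 40% identity (CD-HIT emulation);
3. class balancing: random undersampling to at most five negatives per
   positive.

Clusters with fewer than 15 unique positive windows are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np

from .seqio import ProteinRecord, SiteRecord
from .windowing import (
    DEFAULT_FLANK,
    PAD,
    ResidueClass,
    Window,
    enumerate_candidates,
    extract_window,
)

MIN_POSITIVES = 15


@dataclass(frozen=True)
class ReductionConfig:
    """Thresholds and seed for negative-set reduction and balancing."""

    inter_threshold: float = 0.4
    intra_threshold: float = 0.4
    max_ratio: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("inter_threshold", "intra_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.max_ratio < 1:
            raise ValueError(f"max_ratio must be >= 1, got {self.max_ratio}")


@dataclass
class SiteCluster:
    """Training data for one (level, label, residue-class) model."""

    cluster_id: str
    level: str  # "group" | "family" | "kinase"
    residue_class: ResidueClass
    positives: list[Window]
    negatives: list[Window]
    substrate_ids: set[str]
    config: ReductionConfig = field(default_factory=ReductionConfig)
    flank: int = DEFAULT_FLANK

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)


@dataclass(frozen=True)
class ClusterRejection:
    """Returned when a cluster has too few positives to build a model."""

    cluster_id: str
    level: str
    residue_class: ResidueClass
    n_positives: int
    min_positives: int

    def __bool__(self) -> bool:
        return False


def _seq_matrix(windows: list[Window]) -> np.ndarray:
    """Window sequences as an (n, L) uint8 matrix for fast identity."""
    joined = "".join(w.sequence for w in windows)
    n = len(windows)
    length = len(windows[0]) if windows else 0
    return np.frombuffer(joined.encode("ascii"), dtype=np.uint8).reshape(n, length)


_PAD_BYTE = ord(PAD)


def window_identity(a: Window, b: Window) -> float:
    """Fraction of positions with identical non-pad residues.

    Pad-vs-anything (including pad-vs-pad) counts as a mismatch, so
    terminal windows cannot cluster merely by shared padding.
    """
    if len(a) != len(b):
        raise ValueError(f"window length mismatch: {len(a)} vs {len(b)}")
    matches = sum(
        1 for x, y in zip(a.sequence, b.sequence) if x == y and x != PAD
    )
    return matches / len(a)


def build_negative_pool(
    substrates: list[ProteinRecord],
    positive_sites: set[tuple[str, int]],
    residue_class: ResidueClass,
    flank: int = DEFAULT_FLANK,
) -> list[Window]:
    """All same-type residues on the substrates that are not positives.

    Output is deterministic: ordered by (substrate_id, position).
    """
    pool: list[Window] = []
    for protein in sorted(substrates, key=lambda p: p.id):
        for pos in enumerate_candidates(protein, residue_class):
            if (protein.id, pos) in positive_sites:
                continue
            pool.append(extract_window(protein, pos, flank=flank, label="negative"))
    return pool


def reduce_against_reference(
    negatives: list[Window],
    positives: list[Window],
    threshold: float = 0.4,
) -> list[Window]:
    """Keep only negatives whose identity to every positive is < threshold."""
    if not negatives or not positives:
        return list(negatives)
    neg = _seq_matrix(negatives)
    pos = _seq_matrix(positives)
    if neg.shape[1] != pos.shape[1]:
        raise ValueError("negative and positive windows differ in length")
    length = neg.shape[1]
    keep: list[Window] = []
    # chunk over negatives to bound the (chunk, n_pos, L) comparison tensor
    chunk = max(1, 10_000_000 // (pos.shape[0] * length + 1))
    for start in range(0, len(negatives), chunk):
        block = neg[start : start + chunk]
        eq = (block[:, None, :] == pos[None, :, :]) & (block[:, None, :] != _PAD_BYTE)
        max_ident = eq.sum(axis=2).max(axis=1) / length
        for offset in np.nonzero(max_ident < threshold)[0]:
            keep.append(negatives[start + offset])
    return keep


def _greedy_order(windows: list[Window]) -> list[int]:
    return sorted(
        range(len(windows)),
        key=lambda i: (windows[i].sequence, windows[i].substrate_id, windows[i].position),
    )


def reduce_within(windows: list[Window], threshold: float = 0.4) -> list[Window]:
    """Greedy representative selection at an identity threshold.

    Windows are visited in a deterministic order (lexicographic by
    sequence, then substrate id, then position); a window is retained iff
    its identity to every already-retained window is below the threshold.
    The result is returned in the original input order.
    """
    if not windows:
        return []
    mat = _seq_matrix(windows)
    length = mat.shape[1]
    kept_idx: list[int] = []
    kept_rows: list[np.ndarray] = []
    for i in _greedy_order(windows):
        row = mat[i]
        if kept_rows:
            ref = np.stack(kept_rows)
            ident = (((ref == row) & (row != _PAD_BYTE)).sum(axis=1)) / length
            if (ident >= threshold).any():
                continue
        kept_idx.append(i)
        kept_rows.append(row)
    kept_idx.sort()
    return [windows[i] for i in kept_idx]


def balance_classes(
    n_positives: int,
    negatives: list[Window],
    max_ratio: int = 5,
    seed: int = 0,
) -> list[Window]:
    """Random undersampling of negatives to at most max_ratio per positive."""
    if n_positives < 1:
        raise ValueError("n_positives must be >= 1")
    cap = max_ratio * n_positives
    if len(negatives) <= cap:
        return list(negatives)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negatives), size=cap, replace=False)
    idx.sort()
    return [negatives[i] for i in idx]


def assemble_cluster(
    sites: list[SiteRecord],
    substrates: list[ProteinRecord],
    cluster_id: str,
    level: str,
    residue_class: ResidueClass,
    config: Optional[ReductionConfig] = None,
    min_positives: int = MIN_POSITIVES,
    flank: int = DEFAULT_FLANK,
) -> Union[SiteCluster, ClusterRejection]:
    """Run the full training-set pipeline for one cluster.

    Steps: extract positive windows; deduplicate identical positive
    windows; enumerate the negative pool; inter-set reduction against the
    positives; intra-set greedy reduction; random undersampling to the
    class-ratio cap.  Clusters with fewer than ``min_positives`` unique
    positives are rejected with the observed count.
    """
    config = config or ReductionConfig()
    by_id = {p.id: p for p in substrates}
    residues = residue_class.residues

    pos_windows: list[Window] = []
    seen_coord: set[tuple[str, int]] = set()
    seen_seq: set[str] = set()
    for site in sorted(sites, key=lambda s: (s.substrate_id, s.position)):
        if site.residue not in residues:
            continue
        protein = by_id.get(site.substrate_id)
        if protein is None:
            raise ValueError(
                f"site references substrate {site.substrate_id!r} absent from "
                f"the supplied proteins"
            )
        if protein.sequence[site.position - 1] != site.residue:
            raise ValueError(
                f"site {site.substrate_id}:{site.position} claims residue "
                f"{site.residue} but the sequence has "
                f"{protein.sequence[site.position - 1]}"
            )
        coord = (site.substrate_id, site.position)
        if coord in seen_coord:
            continue
        seen_coord.add(coord)
        window = extract_window(protein, site.position, flank=flank, label="positive")
        if window.sequence in seen_seq:  # redundant site within the cluster
            continue
        seen_seq.add(window.sequence)
        pos_windows.append(window)

    if len(pos_windows) < min_positives:
        return ClusterRejection(
            cluster_id=cluster_id,
            level=level,
            residue_class=residue_class,
            n_positives=len(pos_windows),
            min_positives=min_positives,
        )

    pool = build_negative_pool(
        substrates, seen_coord, residue_class, flank=flank
    )
    reduced = reduce_against_reference(pool, pos_windows, config.inter_threshold)
    reduced = reduce_within(reduced, config.intra_threshold)
    balanced = balance_classes(
        len(pos_windows), reduced, config.max_ratio, config.seed
    )
    return SiteCluster(
        cluster_id=cluster_id,
        level=level,
        residue_class=residue_class,
        positives=pos_windows,
        negatives=balanced,
        substrate_ids={p.id for p in substrates},
        config=config,
        flank=flank,
    )


# ---------------------------------------------------------------------------
# serialization

def save_cluster(cluster: SiteCluster, directory: Union[str, Path]) -> None:
    """Write positives/negatives as window TSVs plus a JSON provenance sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, windows in (("positives", cluster.positives), ("negatives", cluster.negatives)):
        with open(directory / f"{name}.tsv", "w") as fh:
            fh.write("substrate_id\tposition\twindow\tlabel\n")
            for w in windows:
                fh.write(f"{w.substrate_id}\t{w.position}\t{w.sequence}\t{w.label}\n")
    provenance = {
        "cluster_id": cluster.cluster_id,
        "level": cluster.level,
        "residue_class": cluster.residue_class.name,
        "flank": cluster.flank,
        "inter_threshold": cluster.config.inter_threshold,
        "intra_threshold": cluster.config.intra_threshold,
        "max_ratio": cluster.config.max_ratio,
        "seed": cluster.config.seed,
        "n_pos": cluster.n_pos,
        "n_neg": cluster.n_neg,
        "substrate_ids": sorted(cluster.substrate_ids),
    }
    (directory / "provenance.json").write_text(json.dumps(provenance, indent=2))


def load_cluster(directory: Union[str, Path]) -> SiteCluster:
    directory = Path(directory)
    prov = json.loads((directory / "provenance.json").read_text())
    windows: dict[str, list[Window]] = {}
    for name in ("positives", "negatives"):
        rows: list[Window] = []
        lines = (directory / f"{name}.tsv").read_text().splitlines()
        for line in lines[1:]:
            substrate_id, position, seq, label = line.split("\t")
            rows.append(
                Window(
                    substrate_id=substrate_id,
                    position=int(position),
                    sequence=seq,
                    label=None if label == "None" else label,
                )
            )
        windows[name] = rows
    return SiteCluster(
        cluster_id=prov["cluster_id"],
        level=prov["level"],
        residue_class=ResidueClass[prov["residue_class"]],
        positives=windows["positives"],
        negatives=windows["negatives"],
        substrate_ids=set(prov["substrate_ids"]),
        config=ReductionConfig(
            inter_threshold=prov["inter_threshold"],
            intra_threshold=prov["intra_threshold"],
            max_ratio=prov["max_ratio"],
            seed=prov["seed"],
        ),
        flank=prov["flank"],
    )
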