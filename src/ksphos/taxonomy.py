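"""Kinase classification (group / family / subfamily) and tree-based
label propagation.

Kinases with curated classifications seed the taxonomy; kinases known
only from a phylogenetic tree inherit labels from their neighborhood:
for each unannotated leaf we ascend toward the root and, at the first
ancestor whose clade contains at least one annotated leaf, adopt the
clade's label if it is unanimous at the requested level.  Clades with
conflicting labels leave the leaf unassigned — propagation never
guesses and never alters a curated annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Union

import dendropy
import pandas as pd

from .seqio import SiteRecord
from .windowing import ResidueClass

LEVELS = ("group", "family", "subfamily")


@dataclass(frozen=True)
class KinaseAnnotation:
    """Hierarchical classification of one kinase; unassigned levels are None."""

    kinase_id: str
    group: Optional[str] = None
    family: Optional[str] = None
    subfamily: Optional[str] = None

    def __post_init__(self) -> None:
        if self.family is not None and self.group is None:
            raise ValueError(
                f"{self.kinase_id}: family assigned without a group"
            )
        if self.subfamily is not None and self.family is None:
            raise ValueError(
                f"{self.kinase_id}: subfamily assigned without a family"
            )

    def label(self, level: str) -> Optional[str]:
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
        return getattr(self, level)


@dataclass
class KinaseTaxonomy:
    """Mapping kinase id -> annotation, with level vocabularies derived
    from the data (e.g., the ten retained kinase groups)."""

    annotations: dict[str, KinaseAnnotation] = field(default_factory=dict)

    def add(self, annotation: KinaseAnnotation) -> None:
        self.annotations[annotation.kinase_id] = annotation

    def label(self, kinase_id: str, level: str) -> Optional[str]:
        ann = self.annotations.get(kinase_id)
        return None if ann is None else ann.label(level)

    def vocabulary(self, level: str) -> set[str]:
        return {
            lab
            for ann in self.annotations.values()
            if (lab := ann.label(level)) is not None
        }

    def __len__(self) -> int:
        return len(self.annotations)

    def __contains__(self, kinase_id: str) -> bool:
        return kinase_id in self.annotations


def propagate_labels(
    tree: dendropy.Tree,
    seed_annotations: KinaseTaxonomy,
    level: str = "family",
) -> KinaseTaxonomy:
    """Propagate annotations from labeled leaves to unlabeled ones.

    Rule: first informative ancestor + unanimity.  Seed annotations are
    never changed; annotated ids missing from the tree only produce a
    warning (they may simply not have a sequence in this tree).
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    leaf_by_name: dict[str, dendropy.Node] = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is not None:
            leaf_by_name[leaf.taxon.label] = leaf

    seeded = {
        kid: lab
        for kid in seed_annotations.annotations
        if (lab := seed_annotations.label(kid, level)) is not None
    }
    missing = [kid for kid in seeded if kid not in leaf_by_name]
    if missing:
        warnings.warn(
            f"{len(missing)} annotated kinase(s) not found among tree leaves: "
            f"{sorted(missing)[:5]}...",
            stacklevel=2,
        )

    # label of each annotated leaf, cached per node for clade scans
    leaf_label = {
        leaf_by_name[kid]: lab for kid, lab in seeded.items() if kid in leaf_by_name
    }

    def clade_labels(node: dendropy.Node) -> set[str]:
        return {
            leaf_label[lf] for lf in node.leaf_iter() if lf in leaf_label
        }

    result = KinaseTaxonomy()
    for ann in seed_annotations.annotations.values():
        result.add(ann)

    for name, leaf in leaf_by_name.items():
        if name in seeded:
            continue
        assigned: Optional[str] = None
        node = leaf.parent_node
        while node is not None:
            labels = clade_labels(node)
            if labels:
                if len(labels) == 1:
                    assigned = labels.pop()
                break  # first informative ancestor decides, unanimity or nothing
            node = node.parent_node
        if assigned is not None:
            existing = result.annotations.get(name)
            if existing is None:
                existing = KinaseAnnotation(kinase_id=name)
            result.add(_with_level(existing, level, assigned))
    return result


def _with_level(ann: KinaseAnnotation, level: str, label: str) -> KinaseAnnotation:
    # keep the hierarchy invariant: assigning a deep level fills shallower
    # ones with the same label only when they are empty and required
    fields = {"group": ann.group, "family": ann.family, "subfamily": ann.subfamily}
    fields[level] = label
    if level == "family" and fields["group"] is None:
        fields["group"] = label
    if level == "subfamily":
        if fields["family"] is None:
            fields["family"] = label
        if fields["group"] is None:
            fields["group"] = fields["family"]
    return KinaseAnnotation(kinase_id=ann.kinase_id, **fields)


def group_sites(
    sites: list[SiteRecord],
    taxonomy: KinaseTaxonomy,
    level: str,
    residue_class: ResidueClass,
) -> tuple[dict[str, list[SiteRecord]], int]:
    """Route sites to their kinase's cluster label at the given level.

    Sites whose kinase is unannotated at that level are dropped; the
    number dropped is returned alongside the buckets.
    """
    buckets: dict[str, list[SiteRecord]] = {}
    dropped = 0
    residues = residue_class.residues
    for site in sites:
        if site.residue not in residues:
            continue
        label = taxonomy.label(site.kinase_id, level)
        if label is None:
            dropped += 1
            continue
        buckets.setdefault(label, []).append(site)
    return buckets, dropped


# ---------------------------------------------------------------------------
# TSV interface: kinase_id, group, family, subfamily (empty = unassigned)

TAXONOMY_COLUMNS = ["kinase_id", "group", "family", "subfamily"]


def read_taxonomy_table(path: Union[str, Path]) -> KinaseTaxonomy:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"taxonomy table {path} lacks columns: {missing}")
    tax = KinaseTaxonomy()
    for row in df.itertuples(index=False):
        tax.add(
            KinaseAnnotation(
                kinase_id=row.kinase_id,
                group=row.group or None,
                family=row.family or None,
                subfamily=row.subfamily or None,
            )
        )
    return tax


def write_taxonomy_table(tax: KinaseTaxonomy, path: Union[str, Path]) -> None:
    rows = [
        (a.kinase_id, a.group or "", a.family or "", a.subfamily or "")
        for a in tax.annotations.values()
    ]
    pd.DataFrame(rows, columns=TAXONOMY_COLUMNS).to_csv(path, sep="\t", index=False)
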