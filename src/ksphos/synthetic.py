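"""Synthetic kinase-substrate data with known ground truth.

Positive 15-mers are drawn from a position weight matrix with a fixed
central S/T/Y and a few information-rich flanking positions, then
embedded in random background proteins.  Background residues are uniform
over the 20 standard amino acids by default, which makes closed-form
logo expectations exact.  Labeled phylogenies with one monophyletic
clade per family exercise the taxonomy-propagation rule.  Every
generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .encoding import RESIDUE_ORDER
from .seqio import ProteinRecord, SiteRecord
from .taxonomy import KinaseAnnotation, KinaseTaxonomy
from .windowing import DEFAULT_FLANK, ResidueClass
from . import seqio

_RES_INDEX = {aa: i for i, aa in enumerate(RESIDUE_ORDER)}


@dataclass
class MotifModel:
    """A position weight matrix over the window, with planted structure."""

    pwm: np.ndarray  # (window_length, 20), rows sum to 1
    center_class: ResidueClass
    informative_positions: list[int]  # offsets, 0 excluded
    chosen_residues: dict[int, str]  # offset -> enriched residue
    flank: int = DEFAULT_FLANK

    @property
    def window_length(self) -> int:
        return 2 * self.flank + 1

    def sample_window(self, rng: np.random.Generator) -> str:
        return "".join(
            RESIDUE_ORDER[rng.choice(20, p=row)] for row in self.pwm
        )


@dataclass
class SyntheticDataset:
    """Proteins + sites (+ optionally taxonomy and tree) with truth record."""

    proteins: list[ProteinRecord]
    sites: list[SiteRecord]
    taxonomy: Optional[KinaseTaxonomy] = None
    tree: Optional[object] = None  # dendropy.Tree
    truth: dict = field(default_factory=dict)


def make_motif(
    informative_positions: list[int],
    center_class: ResidueClass = ResidueClass.ST,
    concentration: float = 0.9,
    seed: int = 0,
    flank: int = DEFAULT_FLANK,
) -> MotifModel:
    """Build a motif PWM: uniform rows everywhere except the center (all
    mass on the central residue class) and the informative positions,
    which put ``concentration`` mass on one seeded residue choice."""
    if not 0 < concentration <= 1:
        raise ValueError(f"concentration must lie in (0, 1], got {concentration}")
    for p in informative_positions:
        if p == 0:
            raise ValueError("position 0 is the phosphosite itself; not plantable")
        if not -flank <= p <= flank:
            raise ValueError(f"informative position {p} outside -{flank}..+{flank}")
    rng = np.random.default_rng(seed)
    length = 2 * flank + 1
    pwm = np.full((length, 20), 1.0 / 20)
    chosen: dict[int, str] = {}
    for p in sorted(informative_positions):
        aa = RESIDUE_ORDER[rng.integers(20)]
        chosen[p] = aa
        row = np.full(20, (1 - concentration) / 19)
        row[_RES_INDEX[aa]] = concentration
        pwm[p + flank] = row
    center = np.zeros(20)
    residues = sorted(center_class.residues)
    for aa in residues:
        center[_RES_INDEX[aa]] = 1.0 / len(residues)
    pwm[flank] = center
    return MotifModel(
        pwm=pwm,
        center_class=center_class,
        informative_positions=sorted(informative_positions),
        chosen_residues=chosen,
        flank=flank,
    )


def plant_sites(
    motif: MotifModel,
    n_proteins: int = 100,
    protein_length: int = 200,
    sites_per_protein: int = 2,
    seed: int = 0,
    kinase_id: str = "KIN1",
    substrate_prefix: str = "prot",
) -> SyntheticDataset:
    """Embed motif samples in uniform background proteins.

    Each protein is split into ``sites_per_protein`` equal segments and
    one window is planted per segment, keeping planted windows fully
    inside the protein and non-overlapping.
    """
    length = motif.window_length
    segment = protein_length // sites_per_protein
    if segment < length + 2:
        raise ValueError(
            f"cannot place {sites_per_protein} non-overlapping {length}-mers "
            f"in a protein of length {protein_length}"
        )
    rng = np.random.default_rng(seed)
    proteins: list[ProteinRecord] = []
    sites: list[SiteRecord] = []
    planted: dict[str, list[int]] = {}
    for i in range(n_proteins):
        seq = list(
            RESIDUE_ORDER[j] for j in rng.integers(0, 20, size=protein_length)
        )
        pid = f"{substrate_prefix}{i:04d}"
        positions: list[int] = []
        for s in range(sites_per_protein):
            lo = s * segment + motif.flank + 1  # 1-based center bounds
            hi = (s + 1) * segment - motif.flank
            center = int(rng.integers(lo, hi + 1))
            sample = motif.sample_window(rng)
            start = center - 1 - motif.flank
            seq[start : start + length] = list(sample)
            positions.append(center)
        protein = ProteinRecord(id=pid, sequence="".join(seq))
        proteins.append(protein)
        planted[pid] = positions
        for center in positions:
            sites.append(
                SiteRecord(
                    kinase_id=kinase_id,
                    substrate_id=pid,
                    position=center,
                    residue=protein.sequence[center - 1],
                )
            )
    return SyntheticDataset(
        proteins=proteins,
        sites=sites,
        truth={
            "kinase_id": kinase_id,
            "informative_positions": motif.informative_positions,
            "chosen_residues": motif.chosen_residues,
            "planted_positions": planted,
            "seed": seed,
        },
    )


def make_labeled_tree(
    n_families: int,
    leaves_per_family: int,
    seed: int = 0,
    group_label: str = "G1",
):
    """A tree with one monophyletic clade per family and exactly one
    pre-annotated leaf per family.

    Returns ``(tree, seed_annotations, truth)`` where ``truth`` maps
    every leaf name to its family label.
    """
    if n_families < 1 or leaves_per_family < 1:
        raise ValueError("need at least one family and one leaf per family")
    rng = np.random.default_rng(seed)
    clades = []
    truth: dict[str, str] = {}
    seeds = KinaseTaxonomy()
    for f in range(n_families):
        family = f"FAM{f + 1}"
        names = [f"{family}_K{j + 1}" for j in range(leaves_per_family)]
        for name in names:
            truth[name] = family
        annotated = names[int(rng.integers(len(names)))]
        seeds.add(
            KinaseAnnotation(kinase_id=annotated, group=group_label, family=family)
        )
        if len(names) == 1:
            clades.append(f"{names[0]}:1")
        else:
            inner = ",".join(f"{n}:1" for n in names)
            clades.append(f"({inner}):1")
    newick = "(" + ",".join(clades) + ");" if len(clades) > 1 else clades[0].rsplit(":", 1)[0] + ";"
    tree = seqio.read_newick(newick)
    return tree, seeds, truth


def make_dataset(
    n_families: int = 2,
    kinases_per_family: int = 3,
    n_proteins_per_kinase: int = 10,
    protein_length: int = 200,
    sites_per_protein: int = 2,
    informative_positions: Optional[list[int]] = None,
    center_class: ResidueClass = ResidueClass.ST,
    concentration: float = 0.9,
    seed: int = 0,
) -> SyntheticDataset:
    """A complete synthetic study: one motif per family, substrates and
    planted sites per kinase, a labeled tree and a seed taxonomy."""
    informative_positions = informative_positions or [-5, -3]
    tree, seeds, truth_labels = make_labeled_tree(
        n_families, kinases_per_family, seed=seed
    )
    proteins: list[ProteinRecord] = []
    sites: list[SiteRecord] = []
    truth: dict = {"families": {}, "labels": truth_labels, "seed": seed}
    kin_index = 0
    for f in range(n_families):
        family = f"FAM{f + 1}"
        motif = make_motif(
            informative_positions,
            center_class=center_class,
            concentration=concentration,
            seed=seed + 1000 + f,
        )
        truth["families"][family] = {
            "informative_positions": motif.informative_positions,
            "chosen_residues": motif.chosen_residues,
        }
        for j in range(kinases_per_family):
            kinase = f"{family}_K{j + 1}"
            frag = plant_sites(
                motif,
                n_proteins=n_proteins_per_kinase,
                protein_length=protein_length,
                sites_per_protein=sites_per_protein,
                seed=seed + 7919 * kin_index + 1,
                kinase_id=kinase,
                substrate_prefix=f"sub_{kinase}_",
            )
            proteins.extend(frag.proteins)
            sites.extend(frag.sites)
            kin_index += 1
    return SyntheticDataset(
        proteins=proteins, sites=sites, taxonomy=seeds, tree=tree, truth=truth
    )
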