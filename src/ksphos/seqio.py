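"""Readers and writers for the formats the toolkit touches.

FASTA protein collections, tab-separated site and taxonomy tables, and
newick trees.  Parsing of the underlying formats is delegated to
Biopython (FASTA) and DendroPy (newick); this module adds the domain
types and the validation the rest of the toolkit relies on.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import dendropy
import pandas as pd
from Bio import SeqIO

PathLike = Union[str, Path]

#: residues accepted in protein sequences: the 20 standard letters plus
#: common ambiguity/rare codes.
TOLERATED_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "BZXUO")

PHOSPHO_RESIDUES = frozenset("STY")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession and free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - TOLERATED_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r} contains unsupported symbols: "
                f"{''.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteRecord:
    """A kinase-substrate phosphosite: 1-based position on the substrate."""

    kinase_id: str
    substrate_id: str
    position: int
    residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"site position must be 1-based (>=1), got {self.position}"
            )
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(
                f"site residue must be one of S/T/Y, got {self.residue!r}"
            )


def read_fasta(path: PathLike) -> list[ProteinRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Sequences are uppercased; the record id is the header token up to the
    first whitespace and the remainder is kept as the description.
    """
    text = Path(path).read_text()
    stripped = text.strip()
    if not stripped:
        raise ValueError(f"FASTA file {path} is empty")
    if not stripped.startswith(">"):
        raise ValueError(f"FASTA file {path}: sequence data before first header")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has no sequence data")
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


SITE_COLUMNS = ["kinase_id", "substrate_id", "position", "residue"]


def read_site_table(path: PathLike) -> list[SiteRecord]:
    """Read a TSV of kinase-substrate sites (header: kinase_id, substrate_id,
    position, residue).  Positions are 1-based integers."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table {path} lacks columns: {missing}")
    records: list[SiteRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = int(row.position)
        except (TypeError, ValueError):
            raise ValueError(
                f"site table {path} row {i}: non-integer position {row.position!r}"
            ) from None
        try:
            records.append(
                SiteRecord(
                    kinase_id=str(row.kinase_id),
                    substrate_id=str(row.substrate_id),
                    position=pos,
                    residue=str(row.residue),
                )
            )
        except ValueError as exc:
            raise ValueError(f"site table {path} row {i}: {exc}") from None
    return records


def write_site_table(sites: Iterable[SiteRecord], path: PathLike) -> None:
    df = pd.DataFrame(
        [(s.kinase_id, s.substrate_id, s.position, s.residue) for s in sites],
        columns=SITE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_newick(source: Union[PathLike, str]) -> dendropy.Tree:
    """Parse a newick tree from a string or a file path.

    Leaf names are preserved; malformed newick raises ``ValueError``.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    if ";" not in text:
        raise ValueError("newick parse error: missing terminating ';'")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"newick parse error: {exc}") from exc
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(leaves) != len(set(leaves)):
        raise ValueError("newick tree has duplicate leaf names")
    if not leaves:
        raise ValueError("newick tree has no named leaves")
    return tree


def write_newick(tree: dendropy.Tree, path: PathLike) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
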