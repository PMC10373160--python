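"""Candidate-site enumeration and fixed-length window extraction.

Models operate on the peptide spanning positions -flank..+flank around a
candidate serine, threonine or tyrosine (15 residues at the default
flank of 7).  Windows overlapping a protein terminus are padded with
``-``; pads later encode to zero feature blocks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .seqio import ProteinRecord, PHOSPHO_RESIDUES

PAD = "-"
DEFAULT_FLANK = 7


class ResidueClass(enum.Enum):
    """Which central residues a model covers: S/T, Y, or both."""

    ALL = frozenset("STY")
    ST = frozenset("ST")
    Y = frozenset("Y")

    @property
    def residues(self) -> frozenset[str]:
        return self.value

    @classmethod
    def from_string(cls, name: str) -> "ResidueClass":
        try:
            return cls[name.upper().replace("/", "")]
        except KeyError:
            raise ValueError(
                f"unknown residue class {name!r}; expected one of ALL, ST, Y"
            ) from None


@dataclass(frozen=True)
class Window:
    """A site-centered peptide of length ``2*flank + 1``.

    ``position`` is the 1-based index of the center residue on the
    substrate; pad characters may appear only as a contiguous prefix
    and/or suffix.
    """

    substrate_id: str
    position: int
    sequence: str
    label: Optional[str] = None  # "positive" | "negative" | None

    @property
    def center_residue(self) -> str:
        return self.sequence[len(self.sequence) // 2]

    @property
    def flank(self) -> int:
        return len(self.sequence) // 2

    def __len__(self) -> int:
        return len(self.sequence)


def enumerate_candidates(
    protein: ProteinRecord, residue_class: ResidueClass
) -> list[int]:
    """1-based positions of every residue of ``residue_class``, ascending."""
    residues = residue_class.residues
    return [i + 1 for i, aa in enumerate(protein.sequence) if aa in residues]


def extract_window(
    protein: ProteinRecord,
    position: int,
    flank: int = DEFAULT_FLANK,
    pad: str = PAD,
    label: Optional[str] = None,
) -> Window:
    """Extract the ``2*flank+1``-mer centered on a 1-based position.

    Positions within ``flank`` of a terminus are padded so every window
    has the same length and its center stays at the middle index.
    """
    n = len(protein.sequence)
    if not 1 <= position <= n:
        raise ValueError(
            f"position {position} out of range 1..{n} on protein {protein.id!r}"
        )
    center = protein.sequence[position - 1]
    if center not in PHOSPHO_RESIDUES:
        raise ValueError(
            f"residue at {protein.id!r}:{position} is {center!r}, not S/T/Y"
        )
    lo = position - 1 - flank
    hi = position + flank  # exclusive, 0-based
    left_pad = max(0, -lo)
    right_pad = max(0, hi - n)
    core = protein.sequence[max(lo, 0) : min(hi, n)]
    seq = pad * left_pad + core + pad * right_pad
    return Window(substrate_id=protein.id, position=position, sequence=seq, label=label)
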