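"""BLOSUM62 feature encoding of site-centered windows.

Each residue is represented by its 20-value row of the BLOSUM62
substitution matrix, in the canonical residue order
A R N D C Q E G H I L K M F P S T W Y V.  A window of length 15 thus
becomes a position-major vector of 15 x 20 = 300 integer log-odds
values.  Pad characters and ambiguity codes without a matrix row encode
as all-zero blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

from .windowing import Window

#: canonical residue order of the NCBI matrix files.
RESIDUE_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: symbols that encode as a zero block (pad + ambiguity/rare codes).
ZERO_SYMBOLS = frozenset("-BZXUO")


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 integer log-odds table in canonical residue order."""

    name: str
    values: np.ndarray  # (20, 20) float array, symmetric

    def __post_init__(self) -> None:
        if self.values.shape != (20, 20):
            raise ValueError("substitution matrix must be 20x20")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("substitution matrix must be symmetric")

    def row(self, residue: str) -> np.ndarray:
        """The 20-value row for a residue; zero symbols give a zero block."""
        if residue in ZERO_SYMBOLS:
            return np.zeros(20)
        idx = RESIDUE_ORDER.find(residue)
        if idx < 0:
            raise KeyError(f"no matrix row for symbol {residue!r}")
        return self.values[idx]

    def entry(self, a: str, b: str) -> float:
        return self.values[RESIDUE_ORDER.index(a), RESIDUE_ORDER.index(b)]


def load_blosum62() -> SubstitutionMatrix:
    """Load the packaged BLOSUM62 matrix (NCBI plain-text asset)."""
    ref = resources.files("ksphos.data").joinpath("blosum62.txt")
    with resources.as_file(ref) as path:
        arr = substitution_matrices.read(str(path))
    values = np.empty((20, 20))
    for i, a in enumerate(RESIDUE_ORDER):
        for j, b in enumerate(RESIDUE_ORDER):
            values[i, j] = arr[a, b]
    return SubstitutionMatrix(name="BLOSUM62", values=values)


def encode_window(window: Window, matrix: SubstitutionMatrix) -> np.ndarray:
    """Encode one window as a position-major vector of length len*20."""
    blocks = [matrix.row(aa) for aa in window.sequence]
    return np.concatenate(blocks)


def encode_batch(windows: list[Window], matrix: SubstitutionMatrix) -> np.ndarray:
    """Encode windows into an (n, len*20) feature table, order preserved.

    All windows must share one flank.  Ambiguity codes are tolerated and
    reported once per batch.
    """
    if not windows:
        return np.empty((0, 300))
    lengths = {len(w) for w in windows}
    if len(lengths) > 1:
        raise ValueError(f"windows of mixed lengths in one batch: {sorted(lengths)}")
    ambiguous = {aa for w in windows for aa in w.sequence if aa in ZERO_SYMBOLS - {"-"}}
    if ambiguous:
        warnings.warn(
            f"ambiguity codes {''.join(sorted(ambiguous))} encoded as zero blocks",
            stacklevel=2,
        )
    return np.stack([encode_window(w, matrix) for w in windows])


def feature_layout(flank: int = 7) -> list[tuple[int, str]]:
    """(position offset, residue) per feature index, position-major.

    Offsets run -flank..+flank; each contributes the 20 residues in
    canonical order.  Recorded in model metadata so that feature index
    <-> (position, residue) stays stable across save/load.
    """
    return [
        (offset, aa)
        for offset in range(-flank, flank + 1)
        for aa in RESIDUE_ORDER
    ]
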