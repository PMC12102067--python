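"""The 20-letter canonical amino-acid alphabet and sequence validation."""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA: int = len(AMINO_ACIDS)


class NonCanonicalResidueError(ValueError):
    """A sequence contains a character outside the 20 canonical amino acids."""

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position  # 1-based
        super().__init__(
            f"non-canonical residue {residue!r} at position {position} "
            f"(allowed: {AMINO_ACIDS})"
        )


def encode_sequence(seq: str) -> np.ndarray:
    """Map a protein sequence to integer indices, rejecting non-canonical residues.

    Raises
    ------
    ValueError
        If ``seq`` is empty.
    NonCanonicalResidueError
        Naming the first offending character and its 1-based position.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    out = np.empty(len(seq), dtype=np.intp)
    for i, ch in enumerate(seq):
        idx = AA_INDEX.get(ch)
        if idx is None:
            raise NonCanonicalResidueError(ch, i + 1)
        out[i] = idx
    return out
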