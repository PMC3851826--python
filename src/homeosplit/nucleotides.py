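"""Nucleotide indexing conventions shared across the package.

Nucleotides are indexed 1-based, A=1, C=2, G=3, T=4, matching the ALR
count-field order A/C/G/T.  Index 0 is the missing marker (no nucleotide
observed).  Array axes holding the four counts are 0-based internally.
"""

from __future__ import annotations

import numpy as np

NUCLEOTIDES = "ACGT"

#: 1-based index for each base character.
BASE_TO_INDEX = {base: i + 1 for i, base in enumerate(NUCLEOTIDES)}

#: Missing marker for nucleotide indices.
MISSING = 0

#: OTHER_INDICES[i] lists the three 0-based indices != i, ascending.
OTHER_INDICES = np.array([[j for j in range(4) if j != i] for i in range(4)])


def index_to_base(index: int) -> str:
    """Return the base character for a 1-based nucleotide index (0 -> 'N')."""
    if index == MISSING:
        return "N"
    return NUCLEOTIDES[index - 1]


def seq_to_indices(seq: str) -> np.ndarray:
    """Convert an A/C/G/T string to a 0-based integer array (N -> -1)."""
    table = np.full(256, -1, dtype=np.int64)
    for i, base in enumerate(NUCLEOTIDES):
        table[ord(base)] = i
        table[ord(base.lower())] = i
    arr = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    return arr


def indices_to_seq(indices: np.ndarray) -> str:
    """Convert a 0-based integer array to an A/C/G/T string (-1 -> 'N')."""
    lookup = np.array(list(NUCLEOTIDES + "N"))
    return "".join(lookup[np.asarray(indices, dtype=np.int64)])
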