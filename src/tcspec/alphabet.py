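"""Sequence alphabets for Potts-model encoding.

The standard alphabet used throughout two-component-system scoring has
q = 21 states: the 20 canonical amino acids plus the alignment gap. Any
non-canonical residue letter (B, Z, X, U, O, J) is collapsed onto the gap
state, which keeps the state space fixed and mirrors common DCA practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EncodingError

#: Canonical amino acids in the conventional alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Gap character used in all serialized output.
GAP_CHAR = "-"


@dataclass(frozen=True)
class Alphabet:
    """Ordered set of sequence states.

    Parameters
    ----------
    symbols
        One character per state; must contain the gap character exactly once.
    """

    symbols: str = AMINO_ACIDS + GAP_CHAR
    _index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise EncodingError("alphabet symbols must be unique")
        if GAP_CHAR not in self.symbols:
            raise EncodingError("alphabet must contain the gap symbol '-'")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.symbols)})

    @property
    def q(self) -> int:
        """Number of states."""
        return len(self.symbols)

    @property
    def gap_index(self) -> int:
        """State index reserved for the gap (and for unknown residue letters)."""
        return self._index[GAP_CHAR]

    def encode_char(self, c: str) -> int:
        """Map one character to a state; unknown letters map to the gap state.

        Lowercase canonical letters encode like their uppercase form; '.'
        (insert-state gap) encodes as the gap.
        """
        c = c.upper()
        if c == ".":
            return self.gap_index
        return self._index.get(c, self.gap_index)

    def encode(self, row: str) -> np.ndarray:
        """Encode a character row into integer states (total function)."""
        return np.fromiter((self.encode_char(c) for c in row), dtype=np.int64, count=len(row))

    def decode(self, states) -> str:
        """Decode integer states back into characters."""
        states = np.asarray(states)
        if states.size and (states.min() < 0 or states.max() >= self.q):
            raise EncodingError(f"state out of range for q={self.q}")
        return "".join(self.symbols[s] for s in states)


#: The q=21 alphabet used for HisKA/REC scoring.
PROTEIN_ALPHABET = Alphabet()
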