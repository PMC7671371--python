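"""Residue alphabet and sequence normalization.

The engine works on the 22 proteinogenic amino acids: the 20 standard
residues plus pyrrolysine (O) and selenocysteine (U).  Sequences are held
lowercase internally; ambiguity codes (B, J, X, Z), the stop symbol '*' and
gap characters are rejected so that downstream mass/pI estimates are never
silently wrong.
"""

from __future__ import annotations

RESIDUES: frozenset[str] = frozenset("acdefghiklmnopqrstuvwy")


class AlphabetError(ValueError):
    """A sequence contains a character outside the 22-residue alphabet."""

    def __init__(self, char: str, position: int, record_id: str | None = None):
        self.char = char
        self.position = position  # 0-based
        self.record_id = record_id
        where = f" in record '{record_id}'" if record_id else ""
        super().__init__(
            f"illegal residue {char!r} at position {position + 1}{where}: "
            "expected one of ACDEFGHIKLMNOPQRSTUVWY"
        )


def normalize(sequence: str, record_id: str | None = None) -> str:
    """Lowercase *sequence* and verify every character is a valid residue.

    Whitespace is not tolerated here: callers strip line structure before
    normalizing.  Raises :class:`AlphabetError` on the first offending
    character, reporting its 1-based position.
    """
    seq = sequence.lower()
    for i, ch in enumerate(seq):
        if ch not in RESIDUES:
            raise AlphabetError(ch, i, record_id)
    return seq
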