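"""Residue alphabet shared by every encoder.

The working alphabet is the 20 standard amino acids in alphabetical
one-letter order followed by ``X``, the padding symbol used when a
window overhangs a protein terminus. All count/probability matrices and
feature vectors index residues in this fixed order so that feature
columns are auditable.
"""

from __future__ import annotations

AA20: str = "ACDEFGHIKLMNPQRSTVWY"
PAD: str = "X"
ALPHABET: str = AA20 + PAD

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

# residues that occur in real-world FASTA but are outside the model alphabet
NONSTANDARD: frozenset[str] = frozenset("BJOUZ*")


def validate_residue(residue: str) -> int:
    """Return the alphabet index of *residue* or raise ``ValueError``."""
    try:
        return AA_INDEX[residue]
    except KeyError:
        raise ValueError(
            f"residue {residue!r} is not in the 21-letter alphabet {ALPHABET}"
        ) from None
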