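"""Residue-composition utility for splice-insert peptides.

Cassette exons in neuroligin genes encode short surface loops whose charge
composition drives their biochemistry; the NLGN1 A1 insert is a 20-residue
peptide nearly half of whose residues are arginine or lysine, giving it a
strongly basic character.  This module provides the small composition
summary used to report that property.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PeptideComposition", "peptide_composition", "SYNTHETIC_NLGN1_A1_INSERT"]

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")
_BASIC = set("RK")
_ACIDIC = set("DE")

#: Synthetic stand-in for the human NLGN1 A1 splice-insert peptide,
#: constructed to match its published composition: 20 residues, 9 of them
#: arginine or lysine, with two internal cysteines (disulfide pair) and a
#: net positive charge.  It is NOT the genuine sequence.
SYNTHETIC_NLGN1_A1_INSERT = "HKRGCKRSKIDGRCKTRYKP"


@dataclass(frozen=True)
class PeptideComposition:
    """Charge-relevant composition of a peptide."""

    length: int
    n_basic: int  # R + K
    n_acidic: int  # D + E

    @property
    def net_charge_proxy(self) -> int:
        """Basic minus acidic residue count (ignores H and termini)."""
        return self.n_basic - self.n_acidic


def peptide_composition(peptide: str) -> PeptideComposition:
    """Count basic (R/K) and acidic (D/E) residues of a one-letter-code peptide.

    Case-insensitive; only the 20 standard amino-acid codes are accepted.

    Raises
    ------
    ValueError
        If a non-standard character is present; the message lists its
        1-based position.
    """
    seq = peptide.upper()
    bad = [(i + 1, ch) for i, ch in enumerate(seq) if ch not in _STANDARD]
    if bad:
        pos, ch = bad[0]
        raise ValueError(f"non-standard residue {ch!r} at position {pos}")
    return PeptideComposition(
        length=len(seq),
        n_basic=sum(ch in _BASIC for ch in seq),
        n_acidic=sum(ch in _ACIDIC for ch in seq),
    )
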