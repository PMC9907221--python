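"""Amino-acid alphabet and sequence validation shared by every module.

The canonical alphabet order ``ACDEFGHIKLMNPQRSTVWY`` is the single source of
truth for every residue-indexed object in the package: one-hot encodings, PWM
rows, and the 20-way residue action head all use this order, so no silent
row/column permutation can occur between modules.
"""

from __future__ import annotations

from dataclasses import dataclass

#: The 20 canonical amino acids in fixed alphabetical one-letter order.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: residue -> integer index 0..19
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

N_RESIDUES: int = 20

#: Peptide lengths handled by the mutation environment and motif pipeline.
MIN_PEPTIDE_LEN: int = 8
MAX_PEPTIDE_LEN: int = 15

#: Fixed length of an MHC class I pseudo sequence (peptide-contacting residues).
PSEUDO_SEQ_LEN: int = 34


class SequenceError(ValueError):
    """Raised for sequences violating the alphabet or length contracts."""


def validate_residue(residue: str) -> str:
    if len(residue) != 1 or residue not in AA_INDEX:
        raise SequenceError(f"unknown residue {residue!r}: not one of the 20 canonical amino acids")
    return residue


def validate_peptide(seq: str, min_len: int = MIN_PEPTIDE_LEN, max_len: int = MAX_PEPTIDE_LEN) -> str:
    """Validate a peptide: canonical residues only, length within [min_len, max_len].

    Non-canonical codes (X, B, Z, U, ...) are rejected rather than imputed:
    the mutation action space and all PWMs are defined over exactly 20 types.
    """
    for ch in seq:
        if ch not in AA_INDEX:
            raise SequenceError(f"unknown residue {ch!r} in peptide {seq!r}")
    if not (min_len <= len(seq) <= max_len):
        raise SequenceError(
            f"peptide length {len(seq)} outside allowed range [{min_len}, {max_len}]: {seq!r}"
        )
    return seq


@dataclass(frozen=True)
class MHCPseudoSeq:
    """An MHC class I allele represented by its 34-residue pseudo sequence.

    The pseudo sequence covers the residues in potential contact with a bound
    peptide; distinct alleles may share a pseudo sequence, in which case the
    whole pipeline treats them identically.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != PSEUDO_SEQ_LEN:
            raise SequenceError(
                f"pseudo sequence for {self.name!r} has length {len(self.sequence)}, "
                f"expected {PSEUDO_SEQ_LEN}"
            )
        for ch in self.sequence:
            if ch not in AA_INDEX:
                raise SequenceError(f"unknown residue {ch!r} in pseudo sequence for {self.name!r}")


def peptide_to_indices(seq: str) -> list[int]:
    return [AA_INDEX[ch] for ch in seq]


def indices_to_peptide(idx) -> str:
    return "".join(ALPHABET[i] for i in idx)
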