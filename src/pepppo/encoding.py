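"""Residue, peptide and MHC encodings.

Each residue is encoded as the concatenation ``e = e_B + e_O + e_D`` (in that
fixed order) of a scaled BLOSUM62 row, a one-hot vector, and a row of a
learnable embedding table.  The learnable table is owned by the policy module
and passed in, so this module stays parameter-free; when ``learned_dim`` is 0
no table is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .sequences import (
    AA_INDEX,
    ALPHABET,
    N_RESIDUES,
    PSEUDO_SEQ_LEN,
    MHCPseudoSeq,
    SequenceError,
    validate_peptide,
)


@lru_cache(maxsize=None)
def blosum62_matrix() -> np.ndarray:
    """Raw integer BLOSUM62 scores as a 20x20 array in canonical alphabet order."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    out = np.empty((N_RESIDUES, N_RESIDUES), dtype=np.float64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = m[a, b]
    return out


@dataclass(frozen=True)
class EncodingConfig:
    """Which residue encoding blocks to use and how wide each is.

    blosum_scale multiplies the raw integer BLOSUM62 scores (range roughly
    -4..11) so inputs stay O(1) for the network; 0.1 by default.  Whether the
    rows should instead be standardized is left as configuration — scaling is
    the default because it preserves the matrix's symmetry exactly.
    """

    use_blosum: bool = True
    use_onehot: bool = True
    learned_dim: int = 16
    blosum_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.learned_dim < 0:
            raise ValueError("learned_dim must be >= 0")
        if self.d <= 0:
            raise ValueError("encoding width d must be positive: enable at least one block")

    @property
    def d(self) -> int:
        """Per-residue encoding width."""
        return 20 * self.use_blosum + 20 * self.use_onehot + self.learned_dim

    @property
    def fixed_dim(self) -> int:
        """Width of the non-learned (BLOSUM + one-hot) prefix."""
        return 20 * self.use_blosum + 20 * self.use_onehot


def fixed_encoding_table(cfg: EncodingConfig) -> np.ndarray:
    """20 x fixed_dim table of the constant (BLOSUM + one-hot) encoding blocks."""
    blocks = []
    if cfg.use_blosum:
        blocks.append(blosum62_matrix() * cfg.blosum_scale)
    if cfg.use_onehot:
        blocks.append(np.eye(N_RESIDUES))
    if not blocks:
        return np.zeros((N_RESIDUES, 0))
    return np.concatenate(blocks, axis=1)


def _learned_rows(cfg: EncodingConfig, learned_table: np.ndarray | None, idx: np.ndarray) -> np.ndarray:
    if cfg.learned_dim == 0:
        return np.zeros((len(idx), 0))
    if learned_table is None:
        raise ValueError("learned_dim > 0 requires a learned_table")
    learned_table = np.asarray(learned_table, dtype=np.float64)
    if learned_table.shape != (N_RESIDUES, cfg.learned_dim):
        raise ValueError(
            f"learned_table shape {learned_table.shape} != ({N_RESIDUES}, {cfg.learned_dim})"
        )
    return learned_table[idx]


def encode_residue(residue: str, cfg: EncodingConfig, learned_table: np.ndarray | None = None) -> np.ndarray:
    """Encode one residue as the width-d concatenation [BLOSUM | one-hot | learned]."""
    if residue not in AA_INDEX:
        raise SequenceError(f"unknown residue {residue!r}")
    idx = np.array([AA_INDEX[residue]])
    fixed = fixed_encoding_table(cfg)[idx]
    return np.concatenate([fixed, _learned_rows(cfg, learned_table, idx)], axis=1)[0]


def encode_peptide(peptide: str, cfg: EncodingConfig, learned_table: np.ndarray | None = None) -> np.ndarray:
    """Encode a peptide as an l x d matrix, one row per residue in sequence order."""
    validate_peptide(peptide)
    idx = np.array([AA_INDEX[ch] for ch in peptide])
    fixed = fixed_encoding_table(cfg)[idx]
    return np.concatenate([fixed, _learned_rows(cfg, learned_table, idx)], axis=1)


def encode_mhc(mhc: MHCPseudoSeq, cfg: EncodingConfig, learned_table: np.ndarray | None = None) -> np.ndarray:
    """Encode a 34-residue pseudo sequence as a 34 x d matrix (same residue encoder)."""
    if len(mhc.sequence) != PSEUDO_SEQ_LEN:  # MHCPseudoSeq enforces this; re-check for raw ducks
        raise SequenceError(f"pseudo sequence length {len(mhc.sequence)}, expected {PSEUDO_SEQ_LEN}")
    idx = np.array([AA_INDEX[ch] for ch in mhc.sequence])
    fixed = fixed_encoding_table(cfg)[idx]
    return np.concatenate([fixed, _learned_rows(cfg, learned_table, idx)], axis=1)
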