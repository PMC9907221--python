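"""PWM motif construction and Hellinger-distance comparison.

A motif is a 20 x L position weight matrix (rows in canonical alphabet order,
columns summing to 1) built from equal-length qualified peptides.  Two motifs
of the same length are compared by averaging per-column Hellinger distances
H(p, q) = (1/sqrt(2)) * ||sqrt(p) - sqrt(q)||_2; similarity is one minus the
distance.  Motifs of different lengths are never compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .sequences import AA_INDEX, ALPHABET, N_RESIDUES

_COLSUM_TOL = 1e-6


@dataclass(frozen=True)
class PWM:
    """Per-position residue probabilities (20 x L) with supporting peptide count."""

    matrix: np.ndarray
    n_peptides: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != N_RESIDUES:
            raise ValueError(f"PWM must be 20 x L, got shape {m.shape}")
        if np.any(m < 0):
            raise ValueError("PWM entries must be nonnegative")
        if np.any(np.abs(m.sum(axis=0) - 1.0) > _COLSUM_TOL):
            raise ValueError("every PWM column must sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=0))

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits, log2(20) minus Shannon entropy."""
        p = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=0)
        return np.log2(N_RESIDUES) - ent


def logo_matrix(pwm: PWM) -> pd.DataFrame:
    """Sequence-logo heights: probabilities scaled by per-column information content.

    Rows are 1-based positions, columns residues — the layout logo-plotting
    libraries expect; plotting itself is left to the caller.
    """
    heights = pwm.matrix * pwm.information_content()
    return pd.DataFrame(heights.T, index=range(1, pwm.length + 1), columns=list(ALPHABET))


def filter_qualified(peptides, scores, threshold: float = 0.75):
    """Drop peptides whose score falls below the threshold (score == threshold stays)."""
    peptides = list(peptides)
    scores = np.asarray(scores, dtype=float)
    if len(peptides) != len(scores):
        raise ValueError(f"{len(peptides)} peptides vs {len(scores)} scores")
    return [p for p, s in zip(peptides, scores) if s >= threshold]


def build_pwm(peptides, pseudocount: float = 0.0) -> PWM:
    """Column-wise residue frequencies of equal-length peptides.

    column_j = (counts_j + pseudocount) / (n + 20 * pseudocount).  Pseudocount
    defaults to 0: motifs are reported as pure empirical frequencies.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("cannot build a PWM from an empty peptide list")
    length = len(peptides[0])
    if any(len(p) != length for p in peptides):
        raise ValueError("all peptides must have the same length")
    counts = np.zeros((N_RESIDUES, length))
    for pep in peptides:
        for j, ch in enumerate(pep):
            counts[AA_INDEX[ch], j] += 1
    matrix = (counts + pseudocount) / (len(peptides) + N_RESIDUES * pseudocount)
    return PWM(matrix, n_peptides=len(peptides))


def hellinger_column(p: np.ndarray, q: np.ndarray) -> float:
    """Hellinger distance (1/sqrt 2)*||sqrt p - sqrt q|| between probability vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > _COLSUM_TOL or np.any(v < 0):
            raise ValueError(f"{name} is not a probability vector (sum {v.sum():.6g})")
    return float(np.sqrt(0.5) * np.linalg.norm(np.sqrt(p) - np.sqrt(q)))


def motif_distance(a: PWM, b: PWM, columns=None) -> float:
    """Mean per-column Hellinger distance between equal-length PWMs.

    `columns` optionally restricts the average to a subset of positions
    (e.g. anchor columns).
    """
    if a.length != b.length:
        raise ValueError(f"cannot compare motifs of lengths {a.length} and {b.length}")
    cols = range(a.length) if columns is None else columns
    return float(np.mean([hellinger_column(a.matrix[:, j], b.matrix[:, j]) for j in cols]))


def motif_similarity(a: PWM, b: PWM, columns=None) -> float:
    """1 - motif_distance."""
    return 1.0 - motif_distance(a, b, columns)


def pairwise_distance_matrix(pwms: list[PWM]) -> np.ndarray:
    """Symmetric zero-diagonal matrix of motif distances."""
    n = len(pwms)
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        out[i, j] = out[j, i] = motif_distance(pwms[i], pwms[j])
    return out


def robustness_protocol(
    generate_fn,
    alleles: list[str],
    runs: int = 5,
    n_peptides: int = 1000,
    threshold: float = 0.75,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Repeat generation with distinct seeds and report pairwise motif similarities.

    `generate_fn(allele, n, seed)` must return a DataFrame with columns
    peptide and score.  For each allele, `runs` repertoires are generated,
    each reduced to the PWM of its qualified peptides, and all C(runs, 2)
    pairwise similarities reported.  Alleles with a run yielding zero
    qualified peptides are flagged and excluded.
    Columns: allele, run_a, run_b, similarity, flagged.
    """
    rows = []
    for allele in alleles:
        pwms = []
        failed = False
        for r in range(runs):
            df = generate_fn(allele, n_peptides, base_seed + r)
            kept = filter_qualified(df["peptide"], df["score"], threshold)
            if not kept:
                failed = True
                break
            pwms.append(build_pwm(kept))
        if failed:
            rows.append({"allele": allele, "run_a": -1, "run_b": -1,
                         "similarity": np.nan, "flagged": True})
            continue
        for i, j in combinations(range(runs), 2):
            rows.append({"allele": allele, "run_a": i, "run_b": j,
                         "similarity": motif_similarity(pwms[i], pwms[j]), "flagged": False})
    return pd.DataFrame(rows, columns=["allele", "run_a", "run_b", "similarity", "flagged"])
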