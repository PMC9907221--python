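"""Generation baselines: sPWM sampling and uniform-random peptides.

Both are evaluated by the same scorer and metrics as the learned policy:
percentage of qualified peptides (score strictly above the threshold), mean
and maximum presentation score over the generated set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .env import RewardScorer
from .expert import AlleleProfile, ExpertPolicyTable, nearest_allele
from .sequences import ALPHABET, MAX_PEPTIDE_LEN, MIN_PEPTIDE_LEN, N_RESIDUES, MHCPseudoSeq


def spwm_generate(
    profile: AlleleProfile,
    length: int,
    n: int,
    rng: np.random.Generator,
) -> list[str]:
    """Sample peptides position-independently from the profile's distributions."""
    if not profile.has_length(length):
        raise KeyError(f"profile for {profile.allele!r} has no length {length}")
    dist = profile.profiles[length]
    cols = np.stack(
        [rng.choice(N_RESIDUES, size=n, p=dist[:, j] / dist[:, j].sum()) for j in range(length)],
        axis=1,
    )
    return ["".join(ALPHABET[i] for i in row) for row in cols]


def spwm_generate_for_allele(
    mhc: MHCPseudoSeq,
    table: ExpertPolicyTable,
    length: int,
    n: int,
    rng: np.random.Generator,
) -> list[str]:
    """sPWM with nearest-allele fallback for alleles lacking a profile."""
    prof = table.profiles.get(mhc.name)
    if prof is None or not prof.has_length(length):
        prof = table.profiles[nearest_allele(mhc, table, required_length=length)]
    return spwm_generate(prof, length, n, rng)


def random_generate(
    n: int,
    rng: np.random.Generator,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> list[str]:
    """Uniform-random peptides: length uniform over [min_len, max_len], residues uniform."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lengths = rng.integers(min_len, max_len + 1, size=n)
    return ["".join(rng.choice(list(ALPHABET), size=int(l))) for l in lengths]


def evaluate_generation(
    peptides: list[str],
    allele: str,
    scorer: RewardScorer,
    threshold: float = 0.75,
) -> dict:
    """Qualified percentage (score > threshold, strict), mean and max score."""
    if not peptides:
        raise ValueError("cannot evaluate an empty peptide list")
    scores = np.asarray(scorer.score_batch(peptides, [allele] * len(peptides)), dtype=float)
    return {
        "allele": allele,
        "n": len(peptides),
        "qualified_pct": float(100.0 * (scores > threshold).mean()),
        "mean_score": float(scores.mean()),
        "max_score": float(scores.max()),
    }


def generation_report(rows: list[dict]) -> pd.DataFrame:
    """Table-shaped report: method x allele x {percentage, avg, max}."""
    return pd.DataFrame(rows, columns=["method", "allele", "n", "qualified_pct", "mean_score", "max_score"])
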