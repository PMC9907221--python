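"""Data-derived expert mutation policy.

For each allele with enough qualifying binding data, per-length per-position
amino-acid distributions p_i(o | m) are tabulated from the positive peptides.
The expert mutates a peptide by picking the position with the largest gap
between the most popular residue's probability and the current residue's
probability, then sampling the replacement from that position's distribution
(current residue excluded).  Alleles without data fall back to the
distributions of the nearest allele under position-summed BLOSUM62 similarity
of pseudo sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import blosum62_matrix
from .sequences import AA_INDEX, ALPHABET, N_RESIDUES, MHCPseudoSeq


@dataclass
class AlleleProfile:
    """Per-length position-wise residue distributions for one allele.

    profiles[l] is a 20 x l matrix (canonical residue order down the rows);
    counts[l] is the number of supporting peptides.  Only lengths with at
    least `min_count` qualifying peptides are present.
    """

    allele: str
    profiles: dict[int, np.ndarray] = field(default_factory=dict)
    counts: dict[int, int] = field(default_factory=dict)

    def has_length(self, length: int) -> bool:
        return length in self.profiles


class MissingLengthError(KeyError):
    """Signals the caller to fall back to the nearest data-bearing allele."""


@dataclass
class ExpertPolicyTable:
    """allele -> AlleleProfile, plus a pseudo-sequence registry for fallback."""

    profiles: dict[str, AlleleProfile]
    registry: dict[str, MHCPseudoSeq] = field(default_factory=dict)

    def resolve(self, mhc: MHCPseudoSeq, length: int) -> AlleleProfile:
        """The allele's own profile if it covers `length`, else the nearest allele's."""
        prof = self.profiles.get(mhc.name)
        if prof is not None and prof.has_length(length):
            return prof
        name = nearest_allele(mhc, self, required_length=length)
        return self.profiles[name]


def qualify_records(df: pd.DataFrame, affinity_threshold_nm: float = 500.0) -> pd.DataFrame:
    """Default qualification rule for binding records.

    A record qualifies if its measurement column is a binary positive label
    (1/True/"positive") or a quantitative affinity below `affinity_threshold_nm`
    nanomolar.
    """
    meas = df["measurement"]
    if meas.dtype == object:
        mask = meas.astype(str).str.lower().isin({"1", "true", "positive", "pos"})
    else:
        vals = meas.astype(float)
        if set(np.unique(vals)) <= {0.0, 1.0}:
            mask = vals == 1.0
        else:
            mask = vals < affinity_threshold_nm
    return df[mask]


def build_profiles(
    dataset: pd.DataFrame,
    registry: dict[str, MHCPseudoSeq] | None = None,
    min_count: int = 50,
    pseudocount: float = 1.0,
    affinity_threshold_nm: float = 500.0,
) -> ExpertPolicyTable:
    """Tabulate Laplace-smoothed per-allele per-length residue distributions.

    `dataset` has columns allele, peptide, measurement.  Raises if no
    (allele, length) group passes `min_count`.
    """
    qualified = qualify_records(dataset, affinity_threshold_nm)
    profiles: dict[str, AlleleProfile] = {}
    for (allele, length), group in qualified.groupby(
        [qualified["allele"], qualified["peptide"].str.len()]
    ):
        n = len(group)
        if n < min_count:
            continue
        counts = np.zeros((N_RESIDUES, int(length)))
        for pep in group["peptide"]:
            for j, ch in enumerate(pep):
                counts[AA_INDEX[ch], j] += 1
        dist = (counts + pseudocount) / (n + N_RESIDUES * pseudocount)
        prof = profiles.setdefault(allele, AlleleProfile(allele))
        prof.profiles[int(length)] = dist
        prof.counts[int(length)] = n
    if not profiles:
        raise ValueError("no (allele, length) group passes the min_count qualification rule")
    return ExpertPolicyTable(profiles=profiles, registry=dict(registry or {}))


def expert_select_position(peptide: str, profile: AlleleProfile) -> int:
    """Position with the largest gap max_o p_i(o) - p_i(current residue).

    Ties break to the lowest index.  Raises MissingLengthError if the profile
    does not cover the peptide's length.
    """
    length = len(peptide)
    if not profile.has_length(length):
        raise MissingLengthError(f"profile for {profile.allele!r} has no length {length}")
    dist = profile.profiles[length]
    idx = np.array([AA_INDEX[ch] for ch in peptide])
    gaps = dist.max(axis=0) - dist[idx, np.arange(length)]
    return int(np.argmax(gaps))  # argmax takes the first maximum: lowest index wins ties


def expert_sample_residue(
    position: int,
    profile_matrix: np.ndarray,
    current_residue: str,
    rng: np.random.Generator,
) -> str:
    """Sample the replacement from p_i(o) with the current residue masked out."""
    p = profile_matrix[:, position].astype(float).copy()
    p[AA_INDEX[current_residue]] = 0.0
    total = p.sum()
    if total <= 0:
        raise ValueError("distribution degenerate: all mass on the current residue")
    return ALPHABET[int(rng.choice(N_RESIDUES, p=p / total))]


def pseudo_similarity(a: str, b: str) -> float:
    """Position-summed BLOSUM62 similarity between two pseudo sequences."""
    m = blosum62_matrix()
    return float(sum(m[AA_INDEX[x], AA_INDEX[y]] for x, y in zip(a, b)))


def nearest_allele(
    query: MHCPseudoSeq,
    table: ExpertPolicyTable,
    required_length: int | None = None,
    return_similarity: bool = False,
):
    """Data-bearing allele whose pseudo sequence is most BLOSUM62-similar.

    Raw similarities over the candidate set are min-max normalized to [0, 1];
    ties break lexicographically by allele name.  If `required_length` is
    given, only alleles whose profile covers that length are candidates.
    """
    candidates = []
    for name, prof in table.profiles.items():
        if required_length is not None and not prof.has_length(required_length):
            continue
        seq = table.registry[name].sequence if name in table.registry else None
        if seq is None:
            continue
        candidates.append((name, seq))
    if not candidates:
        raise ValueError("empty registry: no data-bearing allele with a pseudo sequence")
    sims = np.array([pseudo_similarity(query.sequence, seq) for _, seq in candidates])
    span = sims.max() - sims.min()
    norm = np.ones_like(sims) if span == 0 else (sims - sims.min()) / span
    order = sorted(range(len(candidates)), key=lambda i: (-norm[i], candidates[i][0]))
    best = order[0]
    if return_similarity:
        return candidates[best][0], float(norm[best])
    return candidates[best][0]


def expert_action(
    peptide: str,
    mhc: MHCPseudoSeq,
    table: ExpertPolicyTable,
    rng: np.random.Generator,
) -> tuple[int, str]:
    """Full expert move: resolve profile (with fallback), pick position, sample residue."""
    profile = table.resolve(mhc, len(peptide))
    pos = expert_select_position(peptide, profile)
    res = expert_sample_residue(pos, profile.profiles[len(peptide)], peptide[pos], rng)
    return pos, res


def save_profiles(table: ExpertPolicyTable, directory) -> None:
    """Write every (allele, length) profile as a PWM TSV for inspection."""
    from pathlib import Path

    from .io import write_pwm
    from .motifs import PWM

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, prof in table.profiles.items():
        for length, mat in prof.profiles.items():
            write_pwm(PWM(mat, n_peptides=prof.counts[length]),
                      directory / f"{name}.L{length}.pwm.tsv")


def profile_consensus(profile: AlleleProfile, length: int) -> str:
    """Per-position argmax peptide of the profile at the given length."""
    dist = profile.profiles[length]
    return "".join(ALPHABET[i] for i in dist.argmax(axis=0))
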