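"""Synthetic test world: hidden-motif presentation oracle, binding datasets,
and mutation cohorts.

The oracle assigns each allele a hidden PWM per supported length, with a few
near-point-mass anchor columns (probability kappa on one residue) and
near-uniform columns elsewhere.  A peptide's presentation score is its
min-max-normalized PWM matching score passed through a fixed monotone
squashing, calibrated so uniform-random peptides essentially never exceed the
0.75 qualification threshold while the consensus peptide scores exactly 1.
Because the oracle's ground truth IS a PWM, motif-recovery experiments are
well-posed: the pipeline's recovered motif can be compared to the hidden one.

Everything here is seeded and emits the same file formats the production
pipelines read, so the fixtures double as integration tests of the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import AA_INDEX, ALPHABET, N_RESIDUES, PSEUDO_SEQ_LEN, MHCPseudoSeq

#: Frozen squashing constants: a logistic in normalized-matching-score space,
#: rescaled so g(0) = 0 and g(1) = 1 exactly.  The midpoint sits between the
#: normalized scores of "all but one anchor correct" (~0.75 at kappa 0.9 with
#: 4 anchors) and the consensus (1.0), so a peptide qualifies only when every
#: anchor is matched.  This keeps motif recovery well-posed: if one missing
#: anchor still qualified, episodes would always terminate with that anchor
#: unmatched and no generator could ever reproduce the full hidden motif.
_SQUASH_MID = 0.85
_SQUASH_STEEP = 14.0


def _squash(x: np.ndarray) -> np.ndarray:
    lo = 1.0 / (1.0 + np.exp(_SQUASH_STEEP * _SQUASH_MID))
    hi = 1.0 / (1.0 + np.exp(-_SQUASH_STEEP * (1.0 - _SQUASH_MID)))
    y = 1.0 / (1.0 + np.exp(-_SQUASH_STEEP * (np.asarray(x, dtype=float) - _SQUASH_MID)))
    return (y - lo) / (hi - lo)


@dataclass
class HiddenMotifOracle:
    """Deterministic presentation scorer backed by hidden per-allele PWMs.

    Satisfies the RewardScorer contract: score(peptide, allele) in [0, 1].
    """

    alleles: dict[str, MHCPseudoSeq]
    pwms: dict[tuple[str, int], np.ndarray]
    anchors: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    kappa: float = 0.9

    def supported_lengths(self, allele: str) -> list[int]:
        return sorted(l for (a, l) in self.pwms if a == allele)

    def consensus(self, allele: str, length: int) -> str:
        pwm = self.pwms[(allele, length)]
        return "".join(ALPHABET[i] for i in pwm.argmax(axis=0))

    def _normalized_match(self, peptides: list[str], allele: str, length: int) -> np.ndarray:
        pwm = self.pwms[(allele, length)]
        idx = np.array([[AA_INDEX[ch] for ch in p] for p in peptides])
        raw = pwm[idx, np.arange(length)].sum(axis=1)
        smin = pwm.min(axis=0).sum()
        smax = pwm.max(axis=0).sum()
        return (raw - smin) / (smax - smin)

    def score(self, peptide: str, allele: str) -> float:
        return float(self.score_batch([peptide], [allele])[0])

    def score_batch(self, peptides, alleles) -> np.ndarray:
        peptides = list(peptides)
        alleles = list(alleles)
        out = np.zeros(len(peptides))
        order = {}
        for i, (p, a) in enumerate(zip(peptides, alleles)):
            key = (a, len(p))
            if key not in self.pwms:
                raise KeyError(f"oracle has no hidden motif for allele {a!r} at length {len(p)}")
            order.setdefault(key, []).append(i)
        for (a, l), idxs in order.items():
            s = self._normalized_match([peptides[i] for i in idxs], a, l)
            out[idxs] = _squash(s)
        return out


def make_hidden_oracle(
    n_alleles: int = 3,
    lengths: tuple[int, ...] = (9,),
    n_anchors: int = 4,
    kappa: float = 0.9,
    seed: int = 0,
    uniform_concentration: float = 100.0,
) -> HiddenMotifOracle:
    """Build an oracle with `n_alleles` alleles, one hidden PWM per length.

    Anchor columns put probability kappa on one residue and spread the rest
    uniformly; non-anchor columns are a mild Dirichlet jitter around uniform
    (concentration `uniform_concentration` per residue).
    """
    if not (0.05 < kappa <= 1.0):
        raise ValueError(f"kappa must lie in (0.05, 1], got {kappa}")
    if n_anchors >= min(lengths):
        raise ValueError("n_anchors must be smaller than the shortest peptide length")
    rng = np.random.default_rng(seed)
    alleles: dict[str, MHCPseudoSeq] = {}
    pwms: dict[tuple[str, int], np.ndarray] = {}
    anchors: dict[tuple[str, int], np.ndarray] = {}
    for k in range(n_alleles):
        name = f"SYN-{k + 1:02d}"
        pseudo = "".join(rng.choice(list(ALPHABET), size=PSEUDO_SEQ_LEN))
        alleles[name] = MHCPseudoSeq(name, pseudo)
        for length in lengths:
            pwm = rng.dirichlet([uniform_concentration] * N_RESIDUES, size=length).T
            anchor_pos = np.sort(rng.choice(length, size=n_anchors, replace=False))
            for j in anchor_pos:
                col = np.full(N_RESIDUES, (1.0 - kappa) / (N_RESIDUES - 1))
                col[rng.integers(N_RESIDUES)] = kappa
                pwm[:, j] = col
            pwms[(name, length)] = pwm
            anchors[(name, length)] = anchor_pos
    return HiddenMotifOracle(alleles=alleles, pwms=pwms, anchors=anchors, kappa=kappa)


def synth_binding_dataset(
    oracle: HiddenMotifOracle,
    n_per_allele: int = 200,
    threshold: float = 0.75,
    seed: int = 0,
    max_attempts: int = 200,
    n_negatives: int | None = None,
) -> pd.DataFrame:
    """Synthetic binding records with exactly `n_per_allele` positives per allele.

    Positives are rejection-sampled from each hidden PWM until `n_per_allele`
    peptides exceed `threshold` (emulating experimentally confirmed binders);
    an equal number of uniform-random negatives is added unless overridden.
    Columns: allele, peptide, measurement (1 positive / 0 negative).
    """
    rng = np.random.default_rng(seed)
    if n_negatives is None:
        n_negatives = n_per_allele
    rows: list[tuple[str, str, int]] = []
    for allele in oracle.alleles:
        for length in oracle.supported_lengths(allele):
            pwm = oracle.pwms[(allele, length)]
            kept: list[str] = []
            for attempt in range(max_attempts):
                draw = np.stack(
                    [rng.choice(N_RESIDUES, size=n_per_allele, p=pwm[:, j]) for j in range(length)],
                    axis=1,
                )
                peps = ["".join(ALPHABET[i] for i in row) for row in draw]
                scores = oracle.score_batch(peps, [allele] * len(peps))
                kept.extend(p for p, s in zip(peps, scores) if s > threshold)
                if len(kept) >= n_per_allele:
                    break
            else:
                raise RuntimeError(
                    f"could not collect {n_per_allele} qualified peptides for {allele} "
                    f"length {length} in {max_attempts} attempts"
                )
            rows.extend((allele, p, 1) for p in kept[:n_per_allele])
            neg = np.stack(
                [rng.integers(N_RESIDUES, size=n_negatives) for _ in range(length)], axis=1
            )
            rows.extend(
                (allele, "".join(ALPHABET[i] for i in row), 0) for row in neg
            )
    return pd.DataFrame(rows, columns=["allele", "peptide", "measurement"])


@dataclass
class SyntheticCohort:
    proteins: dict[str, str]
    mutations: pd.DataFrame  # protein_id, position (1-based), ref, alt, sample
    alleles: list[str]


def synth_cohort(
    oracle: HiddenMotifOracle,
    n_proteins: int = 20,
    protein_length: int = 120,
    n_mutations: int = 60,
    planted_fraction: float = 0.3,
    length: int = 9,
    seed: int = 0,
) -> SyntheticCohort:
    """Random proteins plus point-mutation records, some planted as neoantigens.

    A planted mutation rewrites a window of its protein to an allele's hidden
    consensus, then reverts the mutated site to a different residue so that the
    reference residue mismatches the consensus and the *mutant* window matches
    it — a true neoantigen by construction.
    """
    rng = np.random.default_rng(seed)
    proteins = {
        f"PROT{i + 1:03d}": "".join(rng.choice(list(ALPHABET), size=protein_length))
        for i in range(n_proteins)
    }
    allele_names = list(oracle.alleles)
    rows = []
    n_planted = int(round(planted_fraction * n_mutations))
    if n_planted > n_proteins:
        raise ValueError(
            f"{n_planted} planted mutations need at least as many proteins (have {n_proteins})"
        )
    prot_ids = list(proteins)
    # each planted mutation rewrites its own protein so no record goes stale
    planted_pids = list(rng.choice(prot_ids, size=n_planted, replace=False))
    for j in range(n_mutations):
        planted = j < n_planted
        pid = planted_pids[j] if planted else prot_ids[int(rng.integers(n_proteins))]
        seq = list(proteins[pid])
        if planted:
            allele = allele_names[int(rng.integers(len(allele_names)))]
            consensus = oracle.consensus(allele, length)
            start = int(rng.integers(0, protein_length - length + 1))
            seq[start : start + length] = list(consensus)
            offset = int(oracle.anchors[(allele, length)][0])
            pos0 = start + offset
            alt = consensus[offset]
            ref_choices = [a for a in ALPHABET if a != alt]
            ref = ref_choices[int(rng.integers(len(ref_choices)))]
            seq[pos0] = ref
            proteins[pid] = "".join(seq)
        else:
            pos0 = int(rng.integers(protein_length))
            ref = seq[pos0]
            alt_choices = [a for a in ALPHABET if a != ref]
            alt = alt_choices[int(rng.integers(len(alt_choices)))]
        rows.append((pid, pos0 + 1, proteins[pid][pos0], alt, f"SAMPLE{(j % 10) + 1:02d}"))
    mutations = pd.DataFrame(rows, columns=["protein_id", "position", "ref", "alt", "sample"])
    return SyntheticCohort(proteins=proteins, mutations=mutations, alleles=allele_names)
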