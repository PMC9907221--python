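"""Neoantigen screening with motif matching scores.

Point mutations are expanded into all k-mer windows of the mutant protein
containing the mutated residue (k = 9 by default).  A candidate peptide is
scored against an allele's PWM by summing the PWM probabilities of its
residues at their positions; the raw sum is min-max normalized by the PWM's
analytic bounds (sum of per-column minima / maxima), so scores are comparable
across cohorts.  Discrimination of neoantigens (reference scorer above
threshold) from non-neoantigens uses the rank-based AUC and a two-sided
rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from .env import RewardScorer
from .motifs import PWM
from .sequences import AA_INDEX


@dataclass(frozen=True)
class MutationRecord:
    """A protein-space point mutation: 1-based position, ref and alt residues."""

    protein_id: str
    position: int  # 1-based
    ref: str
    alt: str
    sample: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"alternate residue equals reference at {self.protein_id}:{self.position}")


@dataclass(frozen=True)
class CandidatePeptide:
    sequence: str
    protein_id: str
    window_start: int  # 1-based
    mutation_offset: int  # 0-based offset of the mutated residue inside the window


@dataclass(frozen=True)
class MatchResult:
    peptide: str
    allele: str
    raw_score: float
    normalized_score: float
    degenerate: bool = False


def window_peptides(protein: str, record: MutationRecord, k: int = 9) -> list[CandidatePeptide]:
    """All k-mers of the mutant protein containing the mutated position.

    Windows truncated by the protein ends are omitted; only mutant windows
    (carrying the alternate residue) are returned, in start order.
    """
    pos0 = record.position - 1
    if not (0 <= pos0 < len(protein)):
        raise IndexError(f"position {record.position} outside protein {record.protein_id}")
    if protein[pos0] != record.ref:
        raise ValueError(
            f"reference mismatch at {record.protein_id}:{record.position}: "
            f"protein has {protein[pos0]!r}, record says {record.ref!r}"
        )
    mutant = protein[:pos0] + record.alt + protein[pos0 + 1 :]
    out = []
    for start in range(max(0, pos0 - k + 1), min(pos0, len(protein) - k) + 1):
        out.append(
            CandidatePeptide(
                sequence=mutant[start : start + k],
                protein_id=record.protein_id,
                window_start=start + 1,
                mutation_offset=pos0 - start,
            )
        )
    return out


def matching_score(peptide: str, pwm: PWM, normalization: str = "analytic") -> MatchResult:
    """Sum of PWM probabilities of the peptide's residues at their positions.

    normalization="analytic" rescales by the PWM's attainable bounds
    (sum of column minima to sum of column maxima); "raw" skips rescaling
    (the caller normalizes over its own population).  A PWM whose bounds
    coincide (uniform columns) is degenerate: normalized score 1.0, flagged.
    """
    if len(peptide) != pwm.length:
        raise ValueError(f"peptide length {len(peptide)} != PWM length {pwm.length}")
    idx = [AA_INDEX[ch] for ch in peptide]
    raw = float(pwm.matrix[idx, np.arange(pwm.length)].sum())
    if normalization == "raw":
        return MatchResult(peptide, "", raw, raw)
    lo = float(pwm.matrix.min(axis=0).sum())
    hi = float(pwm.matrix.max(axis=0).sum())
    if hi - lo < 1e-12:
        warnings.warn("degenerate PWM: min and max matching scores coincide")
        return MatchResult(peptide, "", raw, 1.0, degenerate=True)
    return MatchResult(peptide, "", raw, (raw - lo) / (hi - lo))


def screen(
    records: list[MutationRecord],
    proteins: dict[str, str],
    pwms: dict[str, PWM],
    alleles: list[str],
    scorer: RewardScorer,
    threshold: float = 0.75,
    k: int = 9,
    normalization: str = "analytic",
) -> tuple[pd.DataFrame, list[str]]:
    """Score every (candidate peptide, allele) pair and label it via the scorer.

    Returns (report, skipped_alleles).  Report columns: peptide, allele,
    raw_score, normalized_score, label (1 if scorer score > threshold).
    Duplicate (peptide, allele) pairs are deduplicated before metrics.
    Candidates use empirical-population min-max when normalization="empirical".
    """
    skipped = [a for a in alleles if a not in pwms]
    usable = [a for a in alleles if a in pwms]
    pairs: dict[tuple[str, str], None] = {}
    for rec in records:
        if rec.protein_id not in proteins:
            raise KeyError(f"mutation references unknown protein {rec.protein_id!r}")
        for cand in window_peptides(proteins[rec.protein_id], rec, k):
            for allele in usable:
                pairs.setdefault((cand.sequence, allele))
    if not pairs:
        return (
            pd.DataFrame(columns=["peptide", "allele", "raw_score", "normalized_score", "label"]),
            skipped,
        )
    peptides = [p for p, _ in pairs]
    pair_alleles = [a for _, a in pairs]
    ref_scores = np.asarray(scorer.score_batch(peptides, pair_alleles), dtype=float)
    rows = []
    for (pep, allele), ref in zip(pairs, ref_scores):
        mode = "raw" if normalization == "empirical" else "analytic"
        m = matching_score(pep, pwms[allele], normalization=mode)
        rows.append((pep, allele, m.raw_score, m.normalized_score, int(ref > threshold)))
    report = pd.DataFrame(rows, columns=["peptide", "allele", "raw_score", "normalized_score", "label"])
    if normalization == "empirical":
        for allele, grp in report.groupby("allele"):
            lo, hi = grp["raw_score"].min(), grp["raw_score"].max()
            span = hi - lo
            norm = 1.0 if span < 1e-12 else (grp["raw_score"] - lo) / span
            report.loc[grp.index, "normalized_score"] = norm
    return report, skipped


def evaluate_discrimination(scores, labels) -> dict:
    """AUC (rank statistic, ties averaged), two-sided rank-sum p, group medians.

    With a single class present the AUC and p-value are reported as None with
    a reason.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    out = {
        "n_pos": int(len(pos)),
        "n_neg": int(len(neg)),
        "median_pos": float(np.median(pos)) if len(pos) else None,
        "median_neg": float(np.median(neg)) if len(neg) else None,
    }
    if len(pos) == 0 or len(neg) == 0:
        out.update(auc=None, p_value=None, reason="both classes required for AUC")
        return out
    out["auc"] = float(roc_auc_score(labels, scores))
    out["p_value"] = float(mannwhitneyu(pos, neg, alternative="two-sided").pvalue)
    return out
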