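"""File formats: pseudo sequences, binding records, PWMs, proteins, mutations.

All tabular formats are TSV with headers; coordinates in files are 1-based
inclusive.  FASTA goes through biopython.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import PWM
from .screen import MutationRecord
from .sequences import ALPHABET, N_RESIDUES, MHCPseudoSeq


# -- pseudo sequences ---------------------------------------------------

def read_pseudo_sequences(path: str | Path) -> dict[str, MHCPseudoSeq]:
    """Allele pseudo sequences from FASTA (id = allele) or 2-column TSV."""
    path = Path(path)
    out: dict[str, MHCPseudoSeq] = {}
    if path.suffix.lower() in {".fa", ".fasta", ".faa"}:
        for rec in SeqIO.parse(str(path), "fasta"):
            out[rec.id] = MHCPseudoSeq(rec.id, str(rec.seq))
    else:
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected columns allele<TAB>pseudo_sequence")
        for allele, seq in zip(df.iloc[:, 0], df.iloc[:, 1]):
            out[str(allele)] = MHCPseudoSeq(str(allele), str(seq))
    return out


def write_pseudo_sequences(alleles: dict[str, MHCPseudoSeq], path: str | Path) -> None:
    pd.DataFrame(
        [(m.name, m.sequence) for m in alleles.values()],
        columns=["allele", "pseudo_sequence"],
    ).to_csv(path, sep="\t", index=False)


# -- binding records ----------------------------------------------------

def read_binding_dataset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"allele", "peptide", "measurement"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: binding TSV needs columns {sorted(required)}")
    return df


def write_binding_dataset(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# -- PWMs ---------------------------------------------------------------

def write_pwm(pwm: PWM, path: str | Path) -> None:
    """20 rows labeled by residue (canonical order), columns 1..L, 6 decimals."""
    df = pd.DataFrame(
        pwm.matrix, index=list(ALPHABET), columns=[str(j + 1) for j in range(pwm.length)]
    )
    df.index.name = "residue"
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_pwm(path: str | Path) -> PWM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(ALPHABET):
        raise ValueError(f"{path}: PWM rows must be the 20 residues in canonical order")
    matrix = df.to_numpy(dtype=float)
    matrix = matrix / matrix.sum(axis=0, keepdims=True)  # absorb 6-decimal rounding
    return PWM(matrix)


def write_meme_motifs(pwms: dict[str, PWM], path: str | Path) -> None:
    """Write-only export to MEME minimal motif format (protein alphabet)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + ALPHABET + "\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{aa} {1.0 / N_RESIDUES:.5f}" for aa in ALPHABET) + "\n\n")
        for name, pwm in pwms.items():
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= {N_RESIDUES} w= {pwm.length} "
                f"nsites= {max(pwm.n_peptides, 1)}\n"
            )
            for j in range(pwm.length):
                fh.write(" ".join(f"{v:.6f}" for v in pwm.matrix[:, j]) + "\n")
            fh.write("\n")


# -- proteins and mutations --------------------------------------------

def read_proteins(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_proteins(proteins: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteins.items()]
    SeqIO.write(records, str(path), "fasta")


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """MAF-like TSV: protein_id, position (1-based), ref, alt, sample."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "position", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: mutation TSV needs columns {sorted(required)}")
    return [
        MutationRecord(
            protein_id=str(r.protein_id),
            position=int(r.position),
            ref=str(r.ref),
            alt=str(r.alt),
            sample=str(getattr(r, "sample", "")) or None,
        )
        for r in df.itertuples()
    ]


def write_mutations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# -- generated peptides -------------------------------------------------

def write_peptides(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_peptides(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
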