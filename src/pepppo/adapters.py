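"""Adapter for external presentation predictors.

Wraps any command-line predictor behind the RewardScorer contract.  The
command template receives a TSV of (allele, peptide) pairs on a temporary
path and must print one score per line in input order.  Optional at runtime;
the synthetic oracle covers all testing.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

import numpy as np


class ExternalPredictorAdapter:
    """RewardScorer over a subprocess, e.g. a presentation predictor CLI.

    `command` is a format string with an {input} placeholder for the TSV path
    of allele<TAB>peptide pairs; stdout must contain one score in [0, 1] per
    input line.  Scores are cached per (peptide, allele) so repeated queries
    within one instance stay deterministic and cheap.
    """

    def __init__(self, command: str):
        self.command = command
        self._cache: dict[tuple[str, str], float] = {}

    def score(self, peptide: str, allele: str) -> float:
        return float(self.score_batch([peptide], [allele])[0])

    def score_batch(self, peptides, alleles) -> np.ndarray:
        peptides = list(peptides)
        alleles = list(alleles)
        missing = [
            (p, a) for p, a in zip(peptides, alleles) if (p, a) not in self._cache
        ]
        if missing:
            with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
                for p, a in missing:
                    fh.write(f"{a}\t{p}\n")
                path = fh.name
            try:
                out = subprocess.run(
                    self.command.format(input=path),
                    shell=True,
                    check=True,
                    capture_output=True,
                    text=True,
                ).stdout
            finally:
                Path(path).unlink(missing_ok=True)
            values = [float(line) for line in out.split() if line.strip()]
            if len(values) != len(missing):
                raise RuntimeError(
                    f"predictor returned {len(values)} scores for {len(missing)} inputs"
                )
            for (p, a), v in zip(missing, values):
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"score {v} for ({a}, {p}) outside [0, 1]")
                self._cache[(p, a)] = v
        return np.array([self._cache[(p, a)] for p, a in zip(peptides, alleles)])
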