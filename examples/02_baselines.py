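"""Compare the sPWM and Random generation baselines on the synthetic oracle.

sPWM samples each position independently from the expert profile of the
allele; Random draws uniform peptides.  Both are scored by the oracle and
summarized as qualified percentage (score > 0.75), mean and max score.
"""

import numpy as np

from pepppo import build_profiles, evaluate_generation, make_hidden_oracle, random_generate
from pepppo.baselines import generation_report, spwm_generate_for_allele
from pepppo.synthetic import synth_binding_dataset

oracle = make_hidden_oracle(n_alleles=3, lengths=(9,), seed=7)
expert = build_profiles(
    synth_binding_dataset(oracle, n_per_allele=200, seed=8), registry=oracle.alleles
)

rng = np.random.default_rng(0)
rows = []
for name, mhc in oracle.alleles.items():
    peps = spwm_generate_for_allele(mhc, expert, length=9, n=1000, rng=rng)
    rows.append({"method": "sPWM", **evaluate_generation(peps, name, oracle)})
    rows.append({"method": "Random", **evaluate_generation(random_generate(1000, rng, 9, 9), name, oracle)})

print(generation_report(rows).round(3).to_string(index=False))
print(
    "\nsPWM inherits the expert profile's anchors so most of its samples qualify;\n"
    "uniform-random peptides almost never hit 3 of the 4 anchor residues needed\n"
    "to clear the 0.75 presentation threshold."
)
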