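"""Step through the peptide mutation environment by hand.

Builds the synthetic presentation oracle, starts an episode from a random
9-mer, applies the data-derived expert policy's mutations, and prints the
peptide and its presentation score after each step.
"""

import numpy as np

from pepppo import EnvConfig, MutationAction, build_profiles, make_hidden_oracle, reset, step
from pepppo.expert import expert_action
from pepppo.synthetic import synth_binding_dataset

oracle = make_hidden_oracle(n_alleles=1, lengths=(9,), n_anchors=4, kappa=0.9, seed=42)
allele = next(iter(oracle.alleles.values()))
expert = build_profiles(
    synth_binding_dataset(oracle, n_per_allele=200, seed=43),
    registry=oracle.alleles,
)

rng = np.random.default_rng(0)
cfg = EnvConfig(T=8, sigma=0.75)
state = reset(allele, length=9, rng=rng)
print(f"allele {allele.name}, hidden consensus {oracle.consensus(allele.name, 9)}")
print(f"start  {state.peptide}  score {oracle.score(state.peptide, allele.name):.3f}")
while not state.done:
    pos, res = expert_action(state.peptide, allele, expert, rng)
    state, reward, done, score = step(state, MutationAction(pos, res), oracle, cfg)
    print(f"t={state.t}  {state.peptide}  score {score:.3f}  reward {reward:.3f}")
print(
    "Episode ends once the score exceeds sigma=0.75 (a qualified peptide) or after T=8 steps;\n"
    "only that final transition is rewarded — this is the signal PPO learns from."
)
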