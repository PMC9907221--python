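"""End-to-end synthetic-oracle study workflows.

These functions freeze the package's reference study conditions on the
hidden-motif oracle: 3 alleles with 9-mer motifs carrying 4 anchor columns at
concentration 0.9, an expert policy derived from 200 synthetic binders per
allele, behavior-cloning pretraining, and PPO with 1024 environment steps per
iteration for 80 iterations.  They are used by the acceptance checks, the
examples, and anyone wanting a one-call reproduction of the motif-recovery
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import evaluate_generation, random_generate
from .buffer import ExperienceBuffer
from .env import EnvConfig
from .expert import ExpertPolicyTable, build_profiles
from .motifs import PWM, build_pwm, filter_qualified, motif_similarity
from .policy import MutationPolicy, PolicyConfig
from .ppo import PPOConfig, generate_peptides, pretrain_policy, train
from .synthetic import HiddenMotifOracle, make_hidden_oracle, synth_binding_dataset


@dataclass
class StudyResult:
    oracle: HiddenMotifOracle
    policy: MutationPolicy
    env_cfg: EnvConfig
    expert: ExpertPolicyTable
    metrics: pd.DataFrame
    generated: dict[str, pd.DataFrame] = field(default_factory=dict)
    motifs: dict[str, PWM] = field(default_factory=dict)
    qualified_pct: dict[str, float] = field(default_factory=dict)
    anchor_similarity: dict[str, float] = field(default_factory=dict)


def make_study_world(seed: int):
    """The reference oracle + expert policy table (seeded)."""
    oracle = make_hidden_oracle(n_alleles=3, lengths=(9,), n_anchors=4, kappa=0.9,
                                seed=seed % 2**31)
    dataset = synth_binding_dataset(oracle, n_per_allele=200, seed=(seed + 1) % 2**31)
    expert = build_profiles(dataset, registry=oracle.alleles)
    return oracle, expert


def train_motif_policy(
    oracle: HiddenMotifOracle,
    expert: ExpertPolicyTable,
    seed: int,
    iterations: int = 80,
    with_buffer: bool = True,
) -> tuple[MutationPolicy, EnvConfig, pd.DataFrame]:
    """Pretrain + PPO under the reference study conditions."""
    alleles = list(oracle.alleles.values())
    policy = MutationPolicy(PolicyConfig(), seed=seed % 2**31)
    pretrain_policy(policy, expert, alleles, n_states=512, epochs=25, length=9,
                    seed=(seed + 1) % 2**31)
    env_cfg = EnvConfig(T=8, sigma=0.75)
    cfg = PPOConfig(N=1024, iterations=iterations, minibatch=512, buffer_batch=64,
                    lr=5e-4, expert_frac_init=0.5, expert_decay_frac=0.3,
                    init_length=9, seed=(seed + 2) % 2**31)
    buffer = ExperienceBuffer(10_000) if with_buffer else None
    metrics = train(policy, oracle, alleles, env_cfg, cfg, expert=expert, buffer=buffer)
    return policy, env_cfg, metrics


def motif_discovery_study(
    seed: int,
    iterations: int = 80,
    n_generate: int = 1000,
    with_buffer: bool = True,
) -> StudyResult:
    """Full motif-recovery experiment: train, generate, build motifs, compare.

    For each oracle allele: generate `n_generate` peptides from random starts,
    keep the qualified ones, build the PWM, and measure similarity to the
    hidden PWM restricted to its anchor columns.
    """
    oracle, expert = make_study_world(seed)
    policy, env_cfg, metrics = train_motif_policy(oracle, expert, seed + 2,
                                                  iterations, with_buffer)
    result = StudyResult(oracle=oracle, policy=policy, env_cfg=env_cfg,
                         expert=expert, metrics=metrics)
    characterize(result, n_generate=n_generate, seed=seed + 3)
    return result


def characterize(result: StudyResult, n_generate: int = 1000, seed: int = 0) -> None:
    """Generate repertoires and fill in motifs / qualified% / anchor similarity."""
    for i, (name, mhc) in enumerate(result.oracle.alleles.items()):
        df = generate_peptides(result.policy, result.oracle, mhc, result.env_cfg,
                               n=n_generate, length=9, seed=(seed + i) % 2**31)
        result.generated[name] = df
        result.qualified_pct[name] = float(100.0 * (df.score > result.env_cfg.sigma).mean())
        kept = filter_qualified(df.peptide, df.score, result.env_cfg.sigma)
        if kept:
            pwm = build_pwm(kept)
            result.motifs[name] = pwm
            hidden = PWM(result.oracle.pwms[(name, 9)])
            anchors = result.oracle.anchors[(name, 9)]
            result.anchor_similarity[name] = motif_similarity(pwm, hidden, columns=anchors)


def random_baseline_qualified_pct(oracle: HiddenMotifOracle, n: int, seed: int) -> float:
    """Mean qualified percentage of uniform-random 9-mers across oracle alleles."""
    rng = np.random.default_rng(seed % 2**31)
    vals = []
    for name in oracle.alleles:
        peps = random_generate(n, rng, 9, 9)
        vals.append(evaluate_generation(peps, name, oracle)["qualified_pct"])
    return float(np.mean(vals))
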