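"""Proximal Policy Optimization over the peptide mutation environment.

Rollouts are collected in vectorized waves of parallel episodes.  Because the
environment pays reward only at termination, returns are plain discounted
terminal rewards (rewards-to-go R_t = gamma^(T-t) * r_T) and advantages come
from generalized advantage estimation over the temporal-difference errors.
The update maximizes the ratio-clipped surrogate, regularized by a value
loss, an optional diversity-buffer imitation loss, and an entropy bonus,
combined as  L = -L_CLIP + a1*L_V + a2*L_B - a3*H.

An expert mutation policy (see `pepppo.expert`) can both pretrain the policy
network by behavior cloning and drive a decaying fraction of rollout episodes
early in training; expert actions enter the PPO batch with their
log-probabilities evaluated under the current policy at collection time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor, concat as t_concat, minimum
from .buffer import ExperienceBuffer
from .env import EnvConfig, EnvState, MutationAction, RewardScorer, reset, step_batch
from .expert import ExpertPolicyTable, expert_action
from .policy import MutationPolicy, mhc_indices
from .sequences import AA_INDEX, MHCPseudoSeq


@dataclass(frozen=True)
class PPOConfig:
    gamma: float = 0.99
    lam: float = 0.95
    eps_clip: float = 0.2
    alpha1: float = 0.5       # value-loss coefficient
    alpha2: float = 0.1       # buffer imitation-loss coefficient
    alpha3: float = 0.01      # entropy coefficient
    N: int = 2048             # environment steps collected per iteration
    K: int = 4                # optimization epochs per iteration
    minibatch: int = 256
    buffer_batch: int = 64    # state-action pairs drawn from the buffer per update
    lr: float = 1e-3
    iterations: int = 50
    n_envs: int = 256         # parallel episodes per rollout wave
    expert_frac_init: float = 0.5
    expert_decay_frac: float = 0.2  # fraction of iterations over which mixing decays to 0
    normalize_advantages: bool = True
    init_length: int | str = "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lam must be in [0, 1]")
        if self.eps_clip <= 0:
            raise ValueError("eps_clip must be positive")
        if min(self.alpha1, self.alpha2, self.alpha3) < 0:
            raise ValueError("loss coefficients must be nonnegative")
        if self.N < 1 or self.K < 1 or self.minibatch < 1:
            raise ValueError("N, K and minibatch must be positive")


@dataclass
class Trajectory:
    """One complete episode: pre-mutation states, actions, and PPO quantities."""

    mhc: MHCPseudoSeq
    peptides: list[str] = field(default_factory=list)   # s_0 .. s_{T-1}
    actions: list[MutationAction] = field(default_factory=list)
    log_probs: list[float] = field(default_factory=list)
    values: list[float] = field(default_factory=list)   # V(s_0) .. V(s_{T-1})
    rewards: list[float] = field(default_factory=list)
    expert: bool = False
    complete: bool = False
    terminal_score: float = float("nan")
    terminal_peptide: str = ""

    def __len__(self) -> int:
        return len(self.actions)


# -- return / advantage math -------------------------------------------

def rewards_to_go(rewards: np.ndarray, gamma: float, complete: bool = True) -> np.ndarray:
    """R_t = gamma^(T-t) * r_T for transitions t = 0..T-1 (terminal-only reward)."""
    if not complete:
        raise ValueError("rewards-to-go requires a complete episode")
    rewards = np.asarray(rewards, dtype=float)
    T = len(rewards)
    r_T = rewards[-1]
    t = np.arange(T)
    return gamma ** (T - t) * r_T


def gae_advantages(
    rewards: np.ndarray, values: np.ndarray, gamma: float, lam: float
) -> np.ndarray:
    """Generalized advantage estimates by the standard backward recursion.

    `values` must hold V(s_0)..V(s_T) — one more entry than `rewards`, the last
    being the terminal bootstrap (0 for episodes that actually ended).
    """
    rewards = np.asarray(rewards, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) != len(rewards) + 1:
        raise ValueError(f"need len(values) == len(rewards) + 1, got {len(values)} vs {len(rewards)}")
    deltas = rewards + gamma * values[1:] - values[:-1]
    adv = np.empty_like(deltas)
    running = 0.0
    for t in range(len(deltas) - 1, -1, -1):
        running = deltas[t] + gamma * lam * running
        adv[t] = running
    return adv


def clipped_surrogate(
    log_probs_new: Tensor, log_probs_old: np.ndarray, advantages: np.ndarray, eps_clip: float
) -> Tensor:
    """Mean over the batch of min(phi*A, clip(phi, 1-eps, 1+eps)*A), phi = exp(new-old)."""
    ratio = (log_probs_new - Tensor(np.asarray(log_probs_old, dtype=float))).exp()
    if not np.all(np.isfinite(ratio.data)):
        bad = int(np.nonzero(~np.isfinite(ratio.data))[0][0])
        raise FloatingPointError(f"non-finite probability ratio at transition {bad}")
    adv = Tensor(np.asarray(advantages, dtype=float))
    return minimum(ratio * adv, ratio.clip(1 - eps_clip, 1 + eps_clip) * adv).mean()


def value_loss(values: Tensor, returns: np.ndarray) -> Tensor:
    """Mean squared error between state values and rewards-to-go."""
    diff = values - Tensor(np.asarray(returns, dtype=float))
    return (diff * diff).mean()


def combined_loss(
    surrogate: Tensor, v_loss: Tensor, buffer_ce: Tensor | float, entropy: Tensor, cfg: PPOConfig
) -> Tensor:
    return (-surrogate) + cfg.alpha1 * v_loss + cfg.alpha2 * buffer_ce + (-cfg.alpha3) * entropy


# -- rollout collection ------------------------------------------------

def collect_rollouts(
    policy: MutationPolicy,
    scorer: RewardScorer,
    alleles: list[MHCPseudoSeq],
    env_cfg: EnvConfig,
    cfg: PPOConfig,
    rng: np.random.Generator,
    expert: ExpertPolicyTable | None = None,
    expert_fraction: float = 0.0,
) -> list[Trajectory]:
    """Collect at least cfg.N transitions across complete episodes.

    Episodes run in waves of cfg.n_envs parallel environments; each episode
    samples its allele uniformly from `alleles` and, with probability
    `expert_fraction`, follows the expert policy instead of the learned one.
    """
    trajectories: list[Trajectory] = []
    total = 0
    while total < cfg.N:
        n = min(cfg.n_envs, max(1, cfg.N - total))
        states: list[EnvState] = []
        trajs: list[Trajectory] = []
        for _ in range(n):
            mhc = alleles[int(rng.integers(len(alleles)))]
            states.append(reset(mhc, cfg.init_length, rng))
            use_expert = expert is not None and rng.random() < expert_fraction
            trajs.append(Trajectory(mhc=mhc, expert=use_expert))
        alive = list(range(n))
        while alive:
            by_len: dict[int, list[int]] = {}
            for i in alive:
                by_len.setdefault(len(states[i].peptide), []).append(i)
            for idxs in by_len.values():
                group_states = [states[i] for i in idxs]
                forced = []
                for i in idxs:
                    if trajs[i].expert:
                        forced.append(expert_action(states[i].peptide, states[i].mhc, expert, rng))
                    else:
                        forced.append(None)
                actions, log_probs, values = policy.act(
                    [s.peptide for s in group_states],
                    mhc_indices([s.mhc for s in group_states]),
                    rng,
                    forced=forced if any(f is not None for f in forced) else None,
                )
                results = step_batch(group_states, actions, scorer, env_cfg)
                for j, i in enumerate(idxs):
                    nxt, reward, done, score = results[j]
                    tr = trajs[i]
                    tr.peptides.append(states[i].peptide)
                    tr.actions.append(actions[j])
                    tr.log_probs.append(float(log_probs[j]))
                    tr.values.append(float(values[j]))
                    tr.rewards.append(reward)
                    states[i] = nxt
                    if done:
                        tr.complete = True
                        tr.terminal_score = score
                        tr.terminal_peptide = nxt.peptide
            alive = [i for i in alive if not states[i].done]
        trajectories.extend(trajs)
        total += sum(len(t) for t in trajs)
    return trajectories


# -- pretraining -------------------------------------------------------

def pretrain_policy(
    policy: MutationPolicy,
    expert: ExpertPolicyTable,
    alleles: list[MHCPseudoSeq],
    n_states: int = 512,
    epochs: int = 20,
    minibatch: int = 128,
    lr: float = 1e-3,
    length: int | str = "sample",
    seed: int = 0,
) -> list[float]:
    """Behavior-clone the position and residue heads onto expert actions.

    Sampled states are uniform-random peptides paired with alleles drawn from
    `alleles`; the loss is the negative log-likelihood of the expert's chosen
    position and sampled residue under the policy.  Returns per-epoch losses.
    """
    if epochs == 0:
        return []
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n_states):
        mhc = alleles[int(rng.integers(len(alleles)))]
        st = reset(mhc, length, rng)
        pos, res = expert_action(st.peptide, mhc, expert, rng)
        records.append((st.peptide, mhc, pos, AA_INDEX[res]))
    opt = Adam(policy.params, lr=lr)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n_states)
        epoch_loss = 0.0
        for lo in range(0, n_states, minibatch):
            batch = [records[i] for i in order[lo : lo + minibatch]]
            by_len: dict[int, list] = {}
            for rec in batch:
                by_len.setdefault(len(rec[0]), []).append(rec)
            opt.zero_grad()
            loss_terms = []
            for recs in by_len.values():
                pep_idx = policy.peptides_to_indices([r[0] for r in recs])
                midx = mhc_indices([r[1] for r in recs])
                positions = np.array([r[2] for r in recs])
                residues = np.array([r[3] for r in recs])
                log_probs, _, _ = policy.evaluate_actions(pep_idx, midx, positions, residues)
                loss_terms.append(-log_probs.sum())
            loss = sum(loss_terms, Tensor(0.0)) / len(batch)
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
        losses.append(epoch_loss / n_states)
    return losses


# -- main training loop ------------------------------------------------

def train(
    policy: MutationPolicy,
    scorer: RewardScorer,
    alleles: list[MHCPseudoSeq],
    env_cfg: EnvConfig,
    cfg: PPOConfig,
    expert: ExpertPolicyTable | None = None,
    buffer: ExperienceBuffer | None = None,
) -> pd.DataFrame:
    """Run PPO for cfg.iterations; mutates `policy` in place, returns metrics.

    Metrics rows: iteration, mean_terminal_score, qualified_fraction,
    mean_episode_length, and the loss terms of the last minibatch update.
    """
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(policy.params, lr=cfg.lr)
    rows = []
    decay_iters = max(1, int(round(cfg.expert_decay_frac * cfg.iterations)))
    for iteration in range(cfg.iterations):
        frac = cfg.expert_frac_init * max(0.0, 1.0 - iteration / decay_iters)
        trajs = collect_rollouts(policy, scorer, alleles, env_cfg, cfg, rng, expert, frac)

        if buffer is not None:
            for tr in trajs:
                buffer.add_trajectory(tr, env_cfg.sigma)

        # flatten transitions
        peptides, mhcs, positions, residues = [], [], [], []
        logp_old, returns, advantages = [], [], []
        for tr in trajs:
            rew = np.asarray(tr.rewards)
            vals = np.append(np.asarray(tr.values), 0.0)  # episodes end: bootstrap 0
            ret = rewards_to_go(rew, cfg.gamma, complete=tr.complete)
            adv = gae_advantages(rew, vals, cfg.gamma, cfg.lam)
            for t in range(len(tr)):
                peptides.append(tr.peptides[t])
                mhcs.append(tr.mhc)
                positions.append(tr.actions[t].position)
                residues.append(AA_INDEX[tr.actions[t].new_residue])
                logp_old.append(tr.log_probs[t])
                returns.append(ret[t])
                advantages.append(adv[t])
        positions = np.asarray(positions)
        residues = np.asarray(residues)
        logp_old = np.asarray(logp_old)
        returns = np.asarray(returns)
        advantages = np.asarray(advantages)
        if cfg.normalize_advantages and len(advantages) > 1:
            advantages = (advantages - advantages.mean()) / (advantages.std() + 1e-8)

        n_tr = len(peptides)
        last = {}
        for _ in range(cfg.K):
            order = rng.permutation(n_tr)
            for lo in range(0, n_tr, cfg.minibatch):
                mb = order[lo : lo + cfg.minibatch]
                # group by peptide length for batched evaluation
                by_len: dict[int, list[int]] = {}
                for i in mb:
                    by_len.setdefault(len(peptides[i]), []).append(int(i))
                ordered = [i for idxs in by_len.values() for i in idxs]
                lp_parts, ent_parts, val_parts = [], [], []
                for idxs in by_len.values():
                    pep_idx = policy.peptides_to_indices([peptides[i] for i in idxs])
                    midx = mhc_indices([mhcs[i] for i in idxs])
                    lp, ent, val = policy.evaluate_actions(
                        pep_idx, midx, positions[idxs], residues[idxs]
                    )
                    lp_parts.append(lp)
                    ent_parts.append(ent)
                    val_parts.append(val)
                lp_new = t_concat(lp_parts, axis=0) if len(lp_parts) > 1 else lp_parts[0]
                ent = (t_concat(ent_parts, axis=0) if len(ent_parts) > 1 else ent_parts[0]).mean()
                vals = t_concat(val_parts, axis=0) if len(val_parts) > 1 else val_parts[0]
                surr = clipped_surrogate(lp_new, logp_old[ordered], advantages[ordered], cfg.eps_clip)
                v_l = value_loss(vals, returns[ordered])
                if buffer is not None and len(buffer) > 0 and cfg.alpha2 > 0:
                    entries = buffer.sample_batch(min(cfg.buffer_batch, len(buffer)), rng)
                    b_ce = buffer.ce_loss(policy, entries)
                else:
                    b_ce = Tensor(0.0)
                loss = combined_loss(surr, v_l, b_ce, ent, cfg)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at iteration {iteration}: surr={surr.data}, "
                        f"v={v_l.data}, ce={float(b_ce.data)}, H={ent.data}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                last = {
                    "loss": float(loss.data),
                    "surrogate": float(surr.data),
                    "value_loss": float(v_l.data),
                    "buffer_ce": float(b_ce.data),
                    "entropy": float(ent.data),
                }
        term_scores = np.array([tr.terminal_score for tr in trajs])
        rows.append(
            {
                "iteration": iteration,
                "mean_terminal_score": float(term_scores.mean()),
                "qualified_fraction": float((term_scores > env_cfg.sigma).mean()),
                "mean_episode_length": float(np.mean([len(t) for t in trajs])),
                "expert_fraction": frac,
                **last,
            }
        )
    return pd.DataFrame(rows)


# -- generation with a trained policy ----------------------------------

def generate_peptides(
    policy: MutationPolicy,
    scorer: RewardScorer,
    mhc: MHCPseudoSeq,
    env_cfg: EnvConfig,
    n: int = 1000,
    length: int | str = 9,
    seed: int = 0,
) -> pd.DataFrame:
    """Run n episodes from random initial peptides; returns peptide/score/steps.

    The reported score is the terminal presentation score of each episode.
    """
    rng = np.random.default_rng(seed)
    states = [reset(mhc, length, rng) for _ in range(n)]
    done_rows: dict[int, tuple[str, float, int]] = {}
    alive = list(range(n))
    while alive:
        by_len: dict[int, list[int]] = {}
        for i in alive:
            by_len.setdefault(len(states[i].peptide), []).append(i)
        for idxs in by_len.values():
            group = [states[i] for i in idxs]
            actions, _, _ = policy.act(
                [s.peptide for s in group], mhc_indices([s.mhc for s in group]), rng
            )
            results = step_batch(group, actions, scorer, env_cfg)
            for j, i in enumerate(idxs):
                nxt, _, done, score = results[j]
                states[i] = nxt
                if done:
                    done_rows[i] = (nxt.peptide, score, nxt.t)
        alive = [i for i in alive if not states[i].done]
    rows = [done_rows[i] for i in range(n)]
    return pd.DataFrame(rows, columns=["peptide", "score", "steps"])
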