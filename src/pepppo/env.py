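"""The peptide mutation environment.

An episode starts from a (random) peptide and a fixed MHC allele.  Each step
substitutes one residue; the episode ends when the mutated peptide's
presentation score exceeds the threshold sigma or when the step budget T is
exhausted.  Only the terminal transition carries a reward — the terminal
presentation score — so credit must flow back through the value function.

Presentation scoring is delegated to any object satisfying the RewardScorer
protocol (the synthetic hidden-motif oracle in tests, or an adapter around an
installed presentation predictor in production use).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .sequences import (
    ALPHABET,
    MAX_PEPTIDE_LEN,
    MIN_PEPTIDE_LEN,
    MHCPseudoSeq,
    SequenceError,
    validate_peptide,
)


@runtime_checkable
class RewardScorer(Protocol):
    """Contract for presentation scorers: (peptide, allele) -> score in [0, 1].

    Must be deterministic for fixed inputs within one instance; the batch call
    returns scores aligned with input order.
    """

    def score(self, peptide: str, allele: str) -> float: ...

    def score_batch(self, peptides: Sequence[str], alleles: Sequence[str]) -> np.ndarray: ...


@dataclass(frozen=True)
class EnvConfig:
    """Episode control: maximum step budget T and terminal score threshold sigma.

    sigma doubles as the qualified-peptide threshold used downstream (0.75);
    early termination uses the strict inequality score > sigma.
    """

    T: int = 8
    sigma: float = 0.75

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not (0.0 < self.sigma < 1.0):
            raise ValueError("sigma must lie strictly in (0, 1)")


@dataclass(frozen=True)
class MutationAction:
    """Substitute `new_residue` at 0-based `position`."""

    position: int
    new_residue: str


@dataclass(frozen=True)
class EnvState:
    peptide: str
    mhc: MHCPseudoSeq
    t: int = 0
    score: float | None = None  # scorer value of `peptide`, cached by step()
    done: bool = False


def reset(
    mhc: MHCPseudoSeq,
    length: int | str = "sample",
    rng: np.random.Generator | None = None,
) -> EnvState:
    """Start an episode with a uniformly random peptide of the requested length.

    `length="sample"` draws the length uniformly from 8..15 first.
    """
    rng = np.random.default_rng() if rng is None else rng
    if length == "sample":
        length = int(rng.integers(MIN_PEPTIDE_LEN, MAX_PEPTIDE_LEN + 1))
    if not (MIN_PEPTIDE_LEN <= int(length) <= MAX_PEPTIDE_LEN):
        raise SequenceError(f"peptide length {length} outside [{MIN_PEPTIDE_LEN}, {MAX_PEPTIDE_LEN}]")
    peptide = "".join(rng.choice(list(ALPHABET), size=int(length)))
    return EnvState(peptide=peptide, mhc=mhc, t=0)


def apply_mutation(peptide: str, action: MutationAction) -> str:
    """Return the peptide with exactly one residue substituted."""
    validate_peptide(peptide, min_len=1, max_len=10**9)
    if not (0 <= action.position < len(peptide)):
        raise IndexError(f"mutation position {action.position} out of bounds for length {len(peptide)}")
    if action.new_residue not in ALPHABET:
        raise SequenceError(f"unknown residue {action.new_residue!r}")
    chars = list(peptide)
    chars[action.position] = action.new_residue
    return "".join(chars)


def step(
    state: EnvState,
    action: MutationAction,
    scorer: RewardScorer,
    cfg: EnvConfig,
) -> tuple[EnvState, float, bool, float]:
    """Apply one mutation; returns (next_state, reward, done, score).

    The scorer is called once, on the mutated peptide; its value is cached on
    the returned state.  done = score > sigma (strict) or the step budget is
    spent; reward equals the score only on the terminal transition, else 0.
    """
    if state.done:
        raise RuntimeError("cannot step a terminal state")
    peptide = apply_mutation(state.peptide, action)
    score = float(scorer.score(peptide, state.mhc.name))
    t_next = state.t + 1
    done = (score > cfg.sigma) or (t_next >= cfg.T)
    reward = score if done else 0.0
    nxt = EnvState(peptide=peptide, mhc=state.mhc, t=t_next, score=score, done=done)
    return nxt, reward, done, score


def step_batch(
    states: Sequence[EnvState],
    actions: Sequence[MutationAction],
    scorer: RewardScorer,
    cfg: EnvConfig,
) -> list[tuple[EnvState, float, bool, float]]:
    """Vectorized step: one batched scorer call covering all transitions."""
    for s in states:
        if s.done:
            raise RuntimeError("cannot step a terminal state")
    peptides = [apply_mutation(s.peptide, a) for s, a in zip(states, actions)]
    scores = np.asarray(scorer.score_batch(peptides, [s.mhc.name for s in states]), dtype=float)
    out = []
    for s, p, sc in zip(states, peptides, scores):
        t_next = s.t + 1
        done = (sc > cfg.sigma) or (t_next >= cfg.T)
        reward = float(sc) if done else 0.0
        out.append((EnvState(peptide=p, mhc=s.mhc, t=t_next, score=float(sc), done=done), reward, done, float(sc)))
    return out
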