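"""Diversity-promoting experience buffer.

Stores pre-mutation state--action pairs from qualified trajectories (terminal
score above the threshold).  When full, the entry evicted first belongs to the
currently most frequent action key (oldest first within that key), so flooding
the buffer with one action can never push out the sole example of another.
Batches are drawn with weights inversely proportional to each entry's
action-key count, and the imitation loss asks the policy to reproduce the
sampled actions (mean negative log-likelihood of position and residue).

The action key defaults to the replacement residue type (20 keys); position
frequencies are confounded by peptide length, but (position, residue) keys are
available via ``key_mode="position_residue"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .sequences import AA_INDEX, MHCPseudoSeq

if TYPE_CHECKING:  # circular at runtime: ppo imports this module
    from .policy import MutationPolicy
    from .ppo import Trajectory


@dataclass(frozen=True)
class BufferEntry:
    peptide: str
    mhc: MHCPseudoSeq
    t: int
    position: int
    residue: str  # replacement residue

    def key(self, mode: str):
        return self.residue if mode == "residue" else (self.position, self.residue)


class ExperienceBuffer:
    def __init__(self, capacity: int = 10_000, key_mode: str = "residue"):
        if key_mode not in ("residue", "position_residue"):
            raise ValueError(f"unknown key_mode {key_mode!r}")
        self.capacity = capacity
        self.key_mode = key_mode
        self.entries: list[BufferEntry] = []
        self.counts: dict = {}

    def __len__(self) -> int:
        return len(self.entries)

    def _evict_one(self) -> None:
        top = max(self.counts.values())
        # deterministic tie-break: smallest key string representation
        key = min((k for k, c in self.counts.items() if c == top), key=repr)
        for i, e in enumerate(self.entries):  # oldest entry of that key
            if e.key(self.key_mode) == key:
                del self.entries[i]
                break
        self.counts[key] -= 1
        if self.counts[key] == 0:
            del self.counts[key]

    def add(self, entry: BufferEntry) -> None:
        self.entries.append(entry)
        k = entry.key(self.key_mode)
        self.counts[k] = self.counts.get(k, 0) + 1
        while len(self.entries) > self.capacity:
            self._evict_one()

    def add_trajectory(self, traj: "Trajectory", threshold: float) -> None:
        """Add all state-action pairs of a qualified trajectory (score > threshold)."""
        if not (traj.terminal_score > threshold):
            return
        for peptide, action, t in zip(traj.peptides, traj.actions, range(len(traj))):
            self.add(BufferEntry(peptide, traj.mhc, t, action.position, action.new_residue))

    def sample_batch(self, batch_size: int, rng: np.random.Generator) -> list[BufferEntry]:
        """Sample entries with probability inversely proportional to key frequency."""
        if not self.entries:
            return []
        batch_size = min(batch_size, len(self.entries))
        w = np.array([1.0 / self.counts[e.key(self.key_mode)] for e in self.entries])
        idx = rng.choice(len(self.entries), size=batch_size, replace=False, p=w / w.sum())
        return [self.entries[i] for i in idx]

    def ce_loss(self, policy: "MutationPolicy", batch: list[BufferEntry]):
        """Mean of -log pi_c(position|s) - log pi_d(residue|s) over the batch."""
        from .autodiff import Tensor
        from .policy import mhc_indices

        if not batch:
            return Tensor(0.0)
        by_len: dict[int, list[BufferEntry]] = {}
        for e in batch:
            by_len.setdefault(len(e.peptide), []).append(e)
        parts = []
        for entries in by_len.values():
            pep_idx = policy.peptides_to_indices([e.peptide for e in entries])
            midx = mhc_indices([e.mhc for e in entries])
            positions = np.array([e.position for e in entries])
            residues = np.array([AA_INDEX[e.residue] for e in entries])
            lp, _, _ = policy.evaluate_actions(pep_idx, midx, positions, residues)
            parts.append(-lp.sum())
        return sum(parts, Tensor(0.0)) / len(batch)

    # -- serialization (resumable training) -----------------------------
    def state_dict(self) -> dict:
        return {
            "capacity": self.capacity,
            "key_mode": self.key_mode,
            "entries": [
                [e.peptide, e.mhc.name, e.mhc.sequence, e.t, e.position, e.residue]
                for e in self.entries
            ],
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "ExperienceBuffer":
        buf = cls(capacity=state["capacity"], key_mode=state["key_mode"])
        for pep, name, seq, t, pos, res in state["entries"]:
            buf.add(BufferEntry(pep, MHCPseudoSeq(name, seq), int(t), int(pos), res))
        return buf
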