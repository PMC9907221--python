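"""Mutation policy and value networks.

Architecture: each residue of the peptide is encoded (BLOSUM62 + one-hot +
learned embedding) and passed through a one-layer bidirectional LSTM; the
per-residue hidden vector is the concatenation of the two directions, and the
peptide embedding h_p concatenates the end hidden vectors of the two
directions.  The MHC pseudo sequence is encoded the same way, flattened
row-major, and passed through a two-layer ReLU perceptron to give h_m.

Two action heads factorize the mutation: a position head scores every peptide
position from (h_i, h_m), normalized by softmax; a residue head maps the
chosen position's (h_i, h_m) to a 20-way distribution in which the residue
currently at that position is masked out and the rest renormalized, so
self-substitution has probability zero under any parameters.  The joint
log-probability of an action is log p(position) + log p(residue | position).
A small MLP on h_m + h_p provides the state-value estimate for PPO.

All forward passes run on the package's tape-based autodiff; boundary hidden
and cell vectors of the LSTM are drawn once at initialization and kept as
frozen constants so the policy is a deterministic function of the state (a
config flag allows resampling them per call instead).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, embedding, log_softmax, stack
from .encoding import EncodingConfig, fixed_encoding_table
from .env import EnvConfig, EnvState, MutationAction
from .sequences import AA_INDEX, ALPHABET, N_RESIDUES, PSEUDO_SEQ_LEN

_NEG_INF = -1e9  # additive mask excluding the original residue from the head


@dataclass(frozen=True)
class PolicyConfig:
    hidden: int = 64          # LSTM hidden width per direction
    mhc_hidden: int = 128     # hidden width of the MHC perceptron
    mhc_dim: int = 64         # width of h_m
    head_hidden: int = 64     # hidden width of both action heads
    value_hidden: int = 64
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    resample_boundary: bool = False


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


class MutationPolicy:
    """Policy + value networks with explicit parameter dict (autodiff Tensors)."""

    def __init__(self, cfg: PolicyConfig = PolicyConfig(), seed: int = 0):
        self.cfg = cfg
        d = cfg.encoding.d
        H = cfg.hidden
        rng = np.random.default_rng(seed)
        self._fixed_table = fixed_encoding_table(cfg.encoding)

        def P(arr) -> Tensor:
            return Tensor(arr, requires_grad=True)

        p: dict[str, Tensor] = {}
        if cfg.encoding.learned_dim > 0:
            p["emb"] = P(rng.normal(0, 0.1, size=(N_RESIDUES, cfg.encoding.learned_dim)))
        for dirn in ("fwd", "bwd"):
            p[f"{dirn}_Wx"] = P(_xavier(rng, d, 4 * H))
            p[f"{dirn}_Wh"] = P(_xavier(rng, H, 4 * H))
            p[f"{dirn}_b"] = P(np.zeros(4 * H))
        p["W2m"] = P(_xavier(rng, PSEUDO_SEQ_LEN * d, cfg.mhc_hidden))
        p["b2m"] = P(np.zeros(cfg.mhc_hidden))
        p["W1m"] = P(_xavier(rng, cfg.mhc_hidden, cfg.mhc_dim))
        p["b1m"] = P(np.zeros(cfg.mhc_dim))
        p["W1c"] = P(_xavier(rng, 2 * H, cfg.head_hidden))
        p["W2c"] = P(_xavier(rng, cfg.mhc_dim, cfg.head_hidden))
        p["b_c"] = P(np.zeros(cfg.head_hidden))
        p["wc"] = P(_xavier(rng, cfg.head_hidden, 1))
        p["W2d"] = P(_xavier(rng, 2 * H, cfg.head_hidden))
        p["W3d"] = P(_xavier(rng, cfg.mhc_dim, cfg.head_hidden))
        p["b_d"] = P(np.zeros(cfg.head_hidden))
        p["W1d"] = P(_xavier(rng, cfg.head_hidden, N_RESIDUES))
        p["Wv1"] = P(_xavier(rng, cfg.mhc_dim + 2 * H, cfg.value_hidden))
        p["bv1"] = P(np.zeros(cfg.value_hidden))
        p["Wv2"] = P(_xavier(rng, cfg.value_hidden, 1))
        p["bv2"] = P(np.zeros(1))
        self.params = p

        # Boundary states of the two LSTM directions: random noise, frozen.
        self._boundary_rng = np.random.default_rng(rng.integers(2**31))
        self.boundary = {
            k: self._boundary_rng.normal(0, 0.1, size=H)
            for k in ("h0_fwd", "c0_fwd", "h0_bwd", "c0_bwd")
        }

    # -- encoding -------------------------------------------------------
    def _encode_indices(self, idx: np.ndarray) -> Tensor:
        """idx (..., n) residue indices -> (..., n, d) encoding with learned block."""
        fixed = Tensor(self._fixed_table[idx])
        if self.cfg.encoding.learned_dim == 0:
            return fixed
        return concat([fixed, embedding(self.params["emb"], idx)], axis=-1)

    @staticmethod
    def peptides_to_indices(peptides: list[str]) -> np.ndarray:
        return np.array([[AA_INDEX[ch] for ch in p] for p in peptides])

    # -- state embeddings -----------------------------------------------
    def _lstm_direction(self, E: Tensor, dirn: str, reverse: bool) -> list[Tensor]:
        B, L = E.shape[0], E.shape[1]
        H = self.cfg.hidden
        Wx, Wh, b = (self.params[f"{dirn}_{k}"] for k in ("Wx", "Wh", "b"))
        if self.cfg.resample_boundary:
            h = Tensor(np.tile(self._boundary_rng.normal(0, 0.1, size=H), (B, 1)))
            c = Tensor(np.tile(self._boundary_rng.normal(0, 0.1, size=H), (B, 1)))
        else:
            h = Tensor(np.tile(self.boundary[f"h0_{dirn}"], (B, 1)))
            c = Tensor(np.tile(self.boundary[f"c0_{dirn}"], (B, 1)))
        order = range(L - 1, -1, -1) if reverse else range(L)
        hs: dict[int, Tensor] = {}
        for t in order:
            x = E[:, t, :]
            gates = x @ Wx + h @ Wh + b
            i = gates[:, 0 * H : 1 * H].sigmoid()
            f = gates[:, 1 * H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs[t] = h
        return [hs[t] for t in range(L)]

    def embed_peptides(self, pep_idx: np.ndarray) -> tuple[Tensor, Tensor]:
        """(B, l) residue indices -> per-residue hs (B, l, 2H) and peptide h_p (B, 2H)."""
        E = self._encode_indices(pep_idx)
        fwd = self._lstm_direction(E, "fwd", reverse=False)
        bwd = self._lstm_direction(E, "bwd", reverse=True)
        hs = stack([concat([f, bb], axis=1) for f, bb in zip(fwd, bwd)], axis=1)
        h_p = concat([fwd[-1], bwd[0]], axis=1)
        return hs, h_p

    def embed_mhc(self, mhc_idx: np.ndarray) -> Tensor:
        """(B, 34) residue indices -> h_m (B, mhc_dim); row-major flattening.

        Rows with identical pseudo sequences are computed once and shared.
        """
        uniq, inverse = np.unique(mhc_idx, axis=0, return_inverse=True)
        E = self._encode_indices(uniq)  # (U, 34, d)
        flat = E.reshape(uniq.shape[0], -1)
        hidden = (flat @ self.params["W2m"] + self.params["b2m"]).relu()
        h_m_uniq = hidden @ self.params["W1m"] + self.params["b1m"]
        return h_m_uniq[inverse]

    def embed_state(self, pep_idx: np.ndarray, mhc_idx: np.ndarray):
        hs, h_p = self.embed_peptides(pep_idx)
        h_m = self.embed_mhc(mhc_idx)
        return hs, h_p, h_m

    # -- action heads -----------------------------------------------------
    def position_log_probs(self, hs: Tensor, h_m: Tensor) -> Tensor:
        """(B, l) log-probabilities over replacement positions (softmax of f_c)."""
        z = (hs @ self.params["W1c"] + (h_m @ self.params["W2c"]).reshape(
            h_m.shape[0], 1, -1) + self.params["b_c"]).relu()
        logits = (z @ self.params["wc"]).reshape(hs.shape[0], hs.shape[1])
        return log_softmax(logits, axis=1)

    def residue_log_probs(
        self, hs: Tensor, h_m: Tensor, positions: np.ndarray, current_idx: np.ndarray
    ) -> Tensor:
        """(B, 20) log-probs for the replacement residue at the chosen positions.

        The residue currently at the position is masked to probability zero and
        the remaining 19 renormalized.
        """
        B = hs.shape[0]
        h_sel = hs[np.arange(B), positions]
        z = (h_sel @ self.params["W2d"] + h_m @ self.params["W3d"] + self.params["b_d"]).relu()
        logits = z @ self.params["W1d"]
        mask = np.zeros((B, N_RESIDUES))
        mask[np.arange(B), current_idx] = _NEG_INF
        return log_softmax(logits + Tensor(mask), axis=1)

    def state_values(self, h_m: Tensor, h_p: Tensor) -> Tensor:
        x = concat([h_m, h_p], axis=1)
        hidden = (x @ self.params["Wv1"] + self.params["bv1"]).relu()
        return (hidden @ self.params["Wv2"] + self.params["bv2"]).reshape(h_m.shape[0])

    # -- sampling and evaluation ----------------------------------------
    def act(
        self,
        peptides: list[str],
        mhc_idx: np.ndarray,
        rng: np.random.Generator,
        forced: list[tuple[int, str] | None] | None = None,
    ):
        """Sample one mutation per state (all peptides must share a length).

        `forced[i]`, when given, pins the action of state i (expert mixing);
        its log-probability is still evaluated under the current policy.
        Returns (actions, log_probs, values) as plain numpy/python objects.
        """
        pep_idx = self.peptides_to_indices(peptides)
        B, L = pep_idx.shape
        with ad.no_grad():
            hs, h_p, h_m = self.embed_state(pep_idx, mhc_idx)
            pos_lp = self.position_log_probs(hs, h_m).data
            positions = np.empty(B, dtype=int)
            for i in range(B):
                if forced is not None and forced[i] is not None:
                    positions[i] = forced[i][0]
                else:
                    positions[i] = rng.choice(L, p=np.exp(pos_lp[i]))
            current = pep_idx[np.arange(B), positions]
            res_lp = self.residue_log_probs(hs, h_m, positions, current).data
            residues = np.empty(B, dtype=int)
            for i in range(B):
                if forced is not None and forced[i] is not None:
                    residues[i] = AA_INDEX[forced[i][1]]
                else:
                    residues[i] = rng.choice(N_RESIDUES, p=np.exp(res_lp[i]))
            values = self.state_values(h_m, h_p).data
        log_probs = pos_lp[np.arange(B), positions] + res_lp[np.arange(B), residues]
        actions = [MutationAction(int(p), ALPHABET[r]) for p, r in zip(positions, residues)]
        return actions, log_probs, values

    def evaluate_actions(
        self,
        pep_idx: np.ndarray,
        mhc_idx: np.ndarray,
        positions: np.ndarray,
        residues: np.ndarray,
    ) -> tuple[Tensor, Tensor, Tensor]:
        """Differentiable (log_probs, entropies, values) for given state-action pairs.

        Raises if any action references the residue already present (the
        sampler can never produce one).
        """
        B = pep_idx.shape[0]
        current = pep_idx[np.arange(B), positions]
        if np.any(current == residues):
            bad = int(np.nonzero(current == residues)[0][0])
            raise ValueError(f"action {bad} proposes the unchanged residue (self-substitution)")
        hs, h_p, h_m = self.embed_state(pep_idx, mhc_idx)
        pos_lp = self.position_log_probs(hs, h_m)
        res_lp = self.residue_log_probs(hs, h_m, positions, current)
        log_probs = pos_lp[np.arange(B), positions] + res_lp[np.arange(B), residues]
        ent_pos = -(pos_lp.exp() * pos_lp).sum(axis=1)
        ent_res = -(res_lp.exp() * res_lp).sum(axis=1)
        values = self.state_values(h_m, h_p)
        return log_probs, ent_pos + ent_res, values

    def distributions(self, state: EnvState):
        """Convenience single-state view: (position_probs, residue_probs_fn, value).

        `residue_probs_fn(position)` returns the masked 20-way distribution.
        """
        pep_idx = self.peptides_to_indices([state.peptide])
        mhc_idx = np.array([[AA_INDEX[ch] for ch in state.mhc.sequence]])
        with ad.no_grad():
            hs, h_p, h_m = self.embed_state(pep_idx, mhc_idx)
            pos_probs = np.exp(self.position_log_probs(hs, h_m).data[0])
            value = float(self.state_values(h_m, h_p).data[0])

            def residue_probs(position: int) -> np.ndarray:
                cur = pep_idx[0, position]
                lp = self.residue_log_probs(hs, h_m, np.array([position]), np.array([cur]))
                return np.exp(lp.data[0])

        return pos_probs, residue_probs, value


# -- checkpointing ------------------------------------------------------

def save_checkpoint(policy: MutationPolicy, env_cfg: EnvConfig, path: str) -> None:
    """Single .npz archive: all parameters, boundary vectors, and configs.

    A checkpoint plus a seed fully determines generation behavior.
    """
    meta = {
        "alphabet": ALPHABET,
        "policy": {**asdict(policy.cfg), "encoding": asdict(policy.cfg.encoding)},
        "env": asdict(env_cfg),
        "flatten_order": "row-major",
    }
    arrays = {f"param_{k}": v.data for k, v in policy.params.items()}
    arrays.update({f"boundary_{k}": v for k, v in policy.boundary.items()})
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> tuple[MutationPolicy, EnvConfig]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        if meta["alphabet"] != ALPHABET:
            raise ValueError("checkpoint alphabet order does not match this build")
        pc = dict(meta["policy"])
        pc["encoding"] = EncodingConfig(**pc["encoding"])
        policy = MutationPolicy(PolicyConfig(**pc), seed=0)
        for k in policy.params:
            policy.params[k].data = z[f"param_{k}"].copy()
        for k in policy.boundary:
            policy.boundary[k] = z[f"boundary_{k}"].copy()
    return policy, EnvConfig(**meta["env"])


def mhc_indices(alleles) -> np.ndarray:
    """(B, 34) residue indices for a list of MHCPseudoSeq."""
    return np.array([[AA_INDEX[ch] for ch in m.sequence] for m in alleles])
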