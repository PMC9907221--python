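"""Exact math of the PPO objective: returns, GAE, clipped surrogate, losses."""

import numpy as np
import pytest

from pepppo.autodiff import Tensor
from pepppo.ppo import (
    PPOConfig,
    clipped_surrogate,
    combined_loss,
    gae_advantages,
    rewards_to_go,
    value_loss,
)


# -- rewards-to-go ------------------------------------------------------

def test_rewards_to_go_terminal_only_discounting():
    got = rewards_to_go([0.0, 0.0, 1.0], gamma=0.5)
    assert np.allclose(got, [0.125, 0.25, 0.5])


@pytest.mark.parametrize("gamma", [0.5, 0.9, 0.99, 1.0])
@pytest.mark.parametrize("T", [1, 3, 8])
@pytest.mark.parametrize("r_T", [0.0, 0.3, 1.0])
def test_rewards_to_go_closed_form_grid(gamma, T, r_T):
    rewards = np.zeros(T)
    rewards[-1] = r_T
    got = rewards_to_go(rewards, gamma)
    expected = np.array([gamma ** (T - t) * r_T for t in range(T)])
    assert got == pytest.approx(expected, rel=1e-14, abs=0)
    if gamma == 1.0:
        assert np.all(got == r_T)


def test_rewards_to_go_requires_complete_episode():
    with pytest.raises(ValueError):
        rewards_to_go([0.0, 0.0], gamma=0.9, complete=False)


# -- GAE ----------------------------------------------------------------

def _gae_brute_force(rewards, values, gamma, lam):
    """Direct double-sum expansion of the exponentially weighted TD errors."""
    T = len(rewards)
    deltas = [rewards[t] + gamma * values[t + 1] - values[t] for t in range(T)]
    return np.array(
        [sum((gamma * lam) ** k * deltas[t + k] for k in range(T - t)) for t in range(T)]
    )


def test_gae_zero_rewards_zero_values():
    assert np.allclose(gae_advantages(np.zeros(5), np.zeros(6), 0.99, 0.95), 0.0)


def test_gae_lambda_zero_is_td_error():
    rng = np.random.default_rng(0)
    rewards = rng.random(6)
    values = rng.random(7)
    adv = gae_advantages(rewards, values, 0.9, 0.0)
    deltas = rewards + 0.9 * values[1:] - values[:-1]
    assert np.allclose(adv, deltas, atol=1e-12)


def test_gae_matches_brute_force_double_sum():
    rng = np.random.default_rng(42)
    for _ in range(100):
        T = int(rng.integers(1, 9))
        rewards = rng.normal(size=T)
        values = rng.normal(size=T + 1)
        gamma = rng.uniform(0.5, 1.0)
        lam = rng.uniform(0.0, 1.0)
        got = gae_advantages(rewards, values, gamma, lam)
        assert np.allclose(got, _gae_brute_force(rewards, values, gamma, lam), atol=1e-10)


def test_gae_rejects_mismatched_lengths():
    with pytest.raises(ValueError):
        gae_advantages(np.zeros(3), np.zeros(3), 0.9, 0.9)


def test_gae_lambda_one_zero_values_equals_rewards_to_go():
    rewards = np.array([0.0, 0.0, 0.0, 0.8])
    adv = gae_advantages(rewards, np.zeros(5), gamma=0.9, lam=1.0)
    # with exact V = 0 and lambda = 1 the estimator reduces to the raw return
    ret = np.array([0.9**k * 0.8 for k in (3, 2, 1, 0)])
    assert np.allclose(adv, ret, atol=1e-12)
    # the rewards-to-go convention discounts one extra step
    assert np.allclose(rewards_to_go(rewards, 0.9), 0.9 * adv, atol=1e-12)


# -- clipped surrogate --------------------------------------------------

def test_surrogate_identity_when_policies_match():
    adv = np.array([0.7, -0.3, 1.1])
    lp = np.array([-1.0, -2.0, -0.5])
    out = clipped_surrogate(Tensor(lp), lp, adv, 0.2)
    assert float(out.data) == pytest.approx(adv.mean())


@pytest.mark.parametrize(
    "phi,adv,expected",
    [
        (2.0, 1.0, 1.2),    # clip binds above: min(2, 1.2)
        (2.0, -1.0, -2.0),  # negative advantage: min(-2, -1.2)
        (0.5, -1.0, -0.8),  # clip binds below: min(-0.5, -0.8)
        (0.5, 1.0, 0.5),    # min(0.5, 0.8)
        (1.0, 1.0, 1.0),
    ],
)
def test_surrogate_boundary_cases(phi, adv, expected):
    out = clipped_surrogate(Tensor(np.log([phi])), np.zeros(1), np.array([adv]), 0.2)
    assert float(out.data) == pytest.approx(expected, abs=1e-15)


def test_surrogate_flags_nonfinite_ratio():
    with pytest.raises(FloatingPointError, match="transition 1"):
        clipped_surrogate(Tensor(np.array([0.0, 2000.0])), np.array([0.0, -2000.0]), np.ones(2), 0.2)


def test_surrogate_gradient_matches_vanilla_policy_gradient_in_wide_clip_limit():
    """With eps -> inf the clipped surrogate equals the importance-weighted objective."""
    rng = np.random.default_rng(1)
    lp_old = rng.normal(size=8)
    adv = rng.normal(size=8)
    x = Tensor(lp_old + rng.normal(size=8) * 0.1, requires_grad=True)
    wide = clipped_surrogate(x, lp_old, adv, eps_clip=1e9)
    wide.backward()
    g_wide = x.grad.copy()
    x.grad = None
    vanilla = ((x - Tensor(lp_old)).exp() * Tensor(adv)).mean()
    vanilla.backward()
    assert np.allclose(g_wide, x.grad, atol=1e-12)


# -- value and combined losses -----------------------------------------

def test_value_loss_mse():
    assert float(value_loss(Tensor(np.array([1.0, 2.0])), np.array([1.0, 2.0])).data) == 0.0
    assert float(value_loss(Tensor(np.zeros(2)), np.ones(2)).data) == 1.0
    rng = np.random.default_rng(3)
    v, r = rng.normal(size=10), rng.normal(size=10)
    assert float(value_loss(Tensor(v), r).data) == pytest.approx(np.mean((v - r) ** 2))


def test_combined_loss_arithmetic():
    cfg = PPOConfig(alpha1=0.5, alpha2=0.1, alpha3=0.01)
    out = combined_loss(Tensor(1.0), Tensor(2.0), Tensor(3.0), Tensor(4.0), cfg)
    assert float(out.data) == pytest.approx(-1 + 0.5 * 2 + 0.1 * 3 - 0.01 * 4)
    zero = combined_loss(Tensor(0.0), Tensor(0.0), Tensor(0.0), Tensor(0.0), cfg)
    assert float(zero.data) == 0.0
    no_extras = PPOConfig(alpha1=0.5, alpha2=0.0, alpha3=0.0)
    out2 = combined_loss(Tensor(1.0), Tensor(2.0), Tensor(99.0), Tensor(99.0), no_extras)
    assert float(out2.data) == pytest.approx(-1 + 0.5 * 2)


def test_advantage_normalization_preserves_order():
    rng = np.random.default_rng(5)
    adv = rng.normal(size=50)
    norm = (adv - adv.mean()) / (adv.std() + 1e-8)
    assert np.array_equal(np.argsort(adv), np.argsort(norm))


def test_ppo_config_validation():
    with pytest.raises(ValueError):
        PPOConfig(gamma=0.0)
    with pytest.raises(ValueError):
        PPOConfig(eps_clip=0.0)
    with pytest.raises(ValueError):
        PPOConfig(alpha1=-0.1)
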