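"""Expert mutation policy: profiles, position selection, masked sampling, fallback."""

import numpy as np
import pandas as pd
import pytest

from pepppo import MHCPseudoSeq
from pepppo.expert import (
    AlleleProfile,
    ExpertPolicyTable,
    build_profiles,
    expert_sample_residue,
    expert_select_position,
    nearest_allele,
    profile_consensus,
    pseudo_similarity,
)
from pepppo.sequences import AA_INDEX, ALPHABET, N_RESIDUES


def _profile(allele, matrices):
    prof = AlleleProfile(allele)
    for mat in matrices:
        prof.profiles[mat.shape[1]] = mat
        prof.counts[mat.shape[1]] = 100
    return prof


def _dist(length, rng):
    m = rng.random((N_RESIDUES, length))
    return m / m.sum(axis=0)


def test_build_profiles_counts_and_smoothing():
    df = pd.DataFrame(
        {"allele": ["X"] * 2, "peptide": ["AC", "AA"], "measurement": [1, 1]}
    )
    table = build_profiles(df, min_count=2, pseudocount=0.0)
    mat = table.profiles["X"].profiles[2]
    assert mat[AA_INDEX["A"], 0] == 1.0
    assert mat[AA_INDEX["A"], 1] == 0.5 and mat[AA_INDEX["C"], 1] == 0.5
    smoothed = build_profiles(df, min_count=2, pseudocount=1.0).profiles["X"].profiles[2]
    assert smoothed[AA_INDEX["A"], 0] == pytest.approx((2 + 1) / (2 + 20))
    assert smoothed[AA_INDEX["W"], 0] == pytest.approx(1 / 22)
    assert np.allclose(smoothed.sum(axis=0), 1.0, atol=1e-12)


def test_build_profiles_min_count_drops_sparse_lengths():
    df = pd.DataFrame(
        {
            "allele": ["X"] * 13,
            "peptide": ["AC"] * 10 + ["ACD"] * 3,
            "measurement": [1] * 13,
        }
    )
    table = build_profiles(df, min_count=10)
    assert table.profiles["X"].has_length(2)
    assert not table.profiles["X"].has_length(3)
    with pytest.raises(ValueError):
        build_profiles(df[df.measurement == 0], min_count=10)


def test_affinity_threshold_qualification():
    df = pd.DataFrame(
        {
            "allele": ["X"] * 4,
            "peptide": ["AC", "AD", "AE", "AF"],
            "measurement": [100.0, 499.0, 500.0, 5000.0],
        }
    )
    table = build_profiles(df, min_count=2, pseudocount=0.0)
    assert table.profiles["X"].counts[2] == 2  # only < 500 nM records qualify


def test_expert_select_position_worked_example():
    mat = np.zeros((N_RESIDUES, 2))
    mat[AA_INDEX["A"], 0], mat[AA_INDEX["C"], 0] = 0.9, 0.1
    mat[AA_INDEX["A"], 1], mat[AA_INDEX["C"], 1] = 0.2, 0.8
    prof = _profile("X", [mat])
    # peptide "CA": gap at pos 0 = 0.9-0.1 = 0.8; at pos 1 = 0.8-0.2 = 0.6
    assert expert_select_position("CA", prof) == 0


def test_expert_select_position_all_zero_gaps_ties_to_first():
    mat = np.zeros((N_RESIDUES, 3))
    for j, aa in enumerate("ACD"):
        mat[AA_INDEX[aa], j] = 1.0
    assert expert_select_position("ACD", _profile("X", [mat])) == 0


def test_expert_select_position_matches_exhaustive_scan():
    rng = np.random.default_rng(9)
    for _ in range(300):
        length = int(rng.integers(8, 16))
        mat = _dist(length, rng)
        pep = "".join(rng.choice(list(ALPHABET), size=length))
        got = expert_select_position(pep, _profile("X", [mat]))
        gaps = [mat[:, i].max() - mat[AA_INDEX[pep[i]], i] for i in range(length)]
        best = max(range(length), key=lambda i: (gaps[i], -i))
        assert got == best


def test_expert_sample_residue_masks_current():
    rng = np.random.default_rng(2)
    mat = _dist(9, rng)
    draws = [expert_sample_residue(3, mat, "A", rng) for _ in range(2000)]
    assert "A" not in draws
    # empirical frequencies within binomial 4 sigma of the masked distribution
    p = mat[:, 3].copy()
    p[AA_INDEX["A"]] = 0
    p = p / p.sum()
    counts = np.array([draws.count(aa) for aa in ALPHABET])
    n = len(draws)
    sigma = np.sqrt(n * p * (1 - p))
    assert np.all(np.abs(counts - n * p) <= 4 * sigma + 1e-9)


def test_expert_sample_residue_point_mass():
    mat = np.zeros((N_RESIDUES, 1))
    mat[AA_INDEX["A"], 0] = 1.0
    rng = np.random.default_rng(0)
    assert expert_sample_residue(0, mat, "C", rng) == "A"
    with pytest.raises(ValueError):
        expert_sample_residue(0, mat, "A", rng)


def _registry_table(rng, names):
    table = ExpertPolicyTable(profiles={}, registry={})
    for name in names:
        prof = AlleleProfile(name)
        prof.profiles[9] = _dist(9, rng)
        prof.counts[9] = 100
        table.profiles[name] = prof
        seq = "".join(rng.choice(list(ALPHABET), size=34))
        table.registry[name] = MHCPseudoSeq(name, seq)
    return table


def test_nearest_allele_identity_and_dominance(rng):
    table = _registry_table(rng, ["A1", "B1"])
    query = table.registry["A1"]
    name, sim = nearest_allele(query, table, return_similarity=True)
    assert name == "A1" and sim == 1.0


def test_nearest_allele_matches_exhaustive_scan(rng):
    for _ in range(50):
        table = _registry_table(rng, [f"AL{i}" for i in range(5)])
        query = MHCPseudoSeq("Q", "".join(rng.choice(list(ALPHABET), size=34)))
        got = nearest_allele(query, table)
        sims = {n: pseudo_similarity(query.sequence, m.sequence) for n, m in table.registry.items()}
        best = max(sims.values())
        expected = min(n for n, s in sims.items() if s == best)
        assert got == expected


def test_nearest_allele_empty_registry_raises():
    with pytest.raises(ValueError):
        nearest_allele(
            MHCPseudoSeq("Q", "A" * 34), ExpertPolicyTable(profiles={}, registry={})
        )


def test_expert_following_converges_to_consensus(expert_table, alleles, oracle, rng):
    """Repeated expert moves drive any start toward the profile consensus."""
    from pepppo.expert import expert_action

    mhc = alleles[0]
    consensus = profile_consensus(expert_table.profiles[mhc.name], 9)
    dists = []
    for _ in range(30):
        pep = "".join(rng.choice(list(ALPHABET), size=9))
        d0 = sum(a != b for a, b in zip(pep, consensus))
        for _ in range(8):
            pos, res = expert_action(pep, mhc, expert_table, rng)
            pep = pep[:pos] + res + pep[pos + 1 :]
        d1 = sum(a != b for a, b in zip(pep, consensus))
        dists.append(d1 - d0)
    assert np.mean(dists) < 0  # Hamming distance decreases on average


def test_profiles_are_proper_distributions(expert_table):
    for prof in expert_table.profiles.values():
        for mat in prof.profiles.values():
            assert np.all(mat >= 0)
            assert np.allclose(mat.sum(axis=0), 1.0, atol=1e-12)


def test_save_profiles_round_trips_through_pwm_tsvs(expert_table, tmp_path):
    from pepppo.expert import save_profiles
    from pepppo.io import read_pwm

    save_profiles(expert_table, tmp_path)
    for name, prof in expert_table.profiles.items():
        for length, mat in prof.profiles.items():
            loaded = read_pwm(tmp_path / f"{name}.L{length}.pwm.tsv")
            assert np.allclose(loaded.matrix, mat, atol=2e-5)
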