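"""PWM construction and Hellinger-distance motif comparison."""

import numpy as np
import pytest

from pepppo import (
    PWM,
    build_pwm,
    filter_qualified,
    hellinger_column,
    motif_distance,
    motif_similarity,
    pairwise_distance_matrix,
)
from pepppo.sequences import AA_INDEX, ALPHABET, N_RESIDUES


def _rand_dist(rng, n=N_RESIDUES):
    v = rng.random(n)
    return v / v.sum()


def _point(aa):
    v = np.zeros(N_RESIDUES)
    v[AA_INDEX[aa]] = 1.0
    return v


def test_filter_qualified_keeps_threshold_itself():
    assert filter_qualified(["AA", "CC", "DD"], [0.8, 0.75, 0.2], 0.75) == ["AA", "CC"]
    assert filter_qualified(["AA"], [0.1], 0.0) == ["AA"]
    with pytest.raises(ValueError):
        filter_qualified(["AA"], [0.1, 0.2])


def test_build_pwm_counting_and_pseudocount():
    pwm = build_pwm(["AC", "AA"], pseudocount=0)
    assert pwm.matrix[AA_INDEX["A"], 0] == 1.0
    assert pwm.matrix[AA_INDEX["A"], 1] == 0.5 and pwm.matrix[AA_INDEX["C"], 1] == 0.5
    smoothed = build_pwm(["AC", "AA"], pseudocount=1)
    assert smoothed.matrix[AA_INDEX["A"], 0] == pytest.approx(3 / 22)
    single = build_pwm(["ACDEFGHIK"])
    assert single.consensus() == "ACDEFGHIK"
    with pytest.raises(ValueError):
        build_pwm([])
    with pytest.raises(ValueError):
        build_pwm(["AC", "ACD"])


def test_build_pwm_columns_sum_to_one(rng):
    peps = ["".join(rng.choice(list(ALPHABET), size=9)) for _ in range(50)]
    pwm = build_pwm(peps)
    assert np.allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-12)
    assert pwm.n_peptides == 50


def test_hellinger_identity_and_disjoint_point_masses():
    p = _point("A")
    assert hellinger_column(p, p) == 0.0
    assert hellinger_column(_point("A"), _point("C")) == pytest.approx(1.0)


def test_hellinger_analytic_half_mass_case():
    p = np.zeros(N_RESIDUES)
    p[:2] = 0.5
    q = _point("A")
    # Bhattacharyya form: sqrt(1 - sum sqrt(p_i q_i))
    expected = np.sqrt(1 - np.sqrt(0.5))
    assert hellinger_column(p, q) == pytest.approx(expected, abs=1e-12)


def test_hellinger_rejects_unnormalized_input():
    with pytest.raises(ValueError):
        hellinger_column(np.full(N_RESIDUES, 0.06), _point("A"))


def test_hellinger_symmetry_and_triangle_inequality(rng):
    for _ in range(300):
        p, q, r = (_rand_dist(rng) for _ in range(3))
        assert hellinger_column(p, q) == pytest.approx(hellinger_column(q, p), abs=1e-12)
        assert hellinger_column(p, r) <= hellinger_column(p, q) + hellinger_column(q, r) + 1e-12


def test_motif_distance_averages_columns():
    half = np.zeros(N_RESIDUES)
    half[:2] = 0.5
    a = PWM(np.stack([_point("A"), half], axis=1))
    b = PWM(np.stack([_point("A"), _point("A")], axis=1))
    expected = (0.0 + np.sqrt(1 - np.sqrt(0.5))) / 2
    assert motif_distance(a, b) == pytest.approx(expected, abs=1e-12)
    assert motif_similarity(a, a) == 1.0
    disjoint = PWM(np.stack([_point("C"), _point("D")], axis=1))
    point_a = PWM(np.stack([_point("A"), _point("A")], axis=1))
    assert motif_similarity(point_a, disjoint) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        motif_distance(a, PWM(np.full((20, 3), 0.05)))


def test_motif_distance_row_permutation_sensitivity(rng):
    mats = [np.stack([_rand_dist(rng) for _ in range(4)], axis=1) for _ in range(2)]
    a, b = PWM(mats[0]), PWM(mats[1])
    perm = rng.permutation(N_RESIDUES)
    both = motif_distance(PWM(mats[0][perm]), PWM(mats[1][perm]))
    assert both == pytest.approx(motif_distance(a, b), abs=1e-12)
    one = motif_distance(PWM(mats[0][perm]), b)
    assert one != pytest.approx(motif_distance(a, b), abs=1e-6)


def test_pairwise_distance_matrix_symmetric_zero_diagonal(rng):
    pwms = [PWM(np.stack([_rand_dist(rng) for _ in range(3)], axis=1)) for _ in range(4)]
    D = pairwise_distance_matrix(pwms)
    assert D.shape == (4, 4)
    assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)
    assert D[1, 2] == pytest.approx(motif_distance(pwms[1], pwms[2]))
    assert pairwise_distance_matrix([pwms[0]]).shape == (1, 1)


def test_spwm_round_trip_recovers_pwm(rng):
    """Sampling many peptides from a PWM and rebuilding recovers it within 4 sigma."""
    from pepppo.baselines import spwm_generate
    from pepppo.expert import AlleleProfile

    mat = np.stack([_rand_dist(rng) for _ in range(9)], axis=1)
    prof = AlleleProfile("X")
    prof.profiles[9] = mat
    n = 10_000
    peps = spwm_generate(prof, 9, n, rng)
    rebuilt = build_pwm(peps).matrix
    sigma = np.sqrt(mat * (1 - mat) / n)
    assert np.all(np.abs(rebuilt - mat) <= 4 * sigma + 1e-9)


def test_information_content_bounds():
    uniform = PWM(np.full((20, 2), 0.05))
    assert np.allclose(uniform.information_content(), 0.0, atol=1e-12)
    point = PWM(np.stack([_point("A")], axis=1))
    assert point.information_content()[0] == pytest.approx(np.log2(20))


def test_logo_matrix_layout_and_scaling():
    from pepppo.motifs import logo_matrix

    pwm = build_pwm(["AAAA", "AAAC"])
    logo = logo_matrix(pwm)
    assert list(logo.index) == [1, 2, 3, 4]
    assert logo.shape == (4, 20)
    # fully conserved column: single letter at full information content
    assert logo.loc[1, "A"] == pytest.approx(np.log2(20))
    assert logo.loc[1].drop("A").sum() == 0.0


def test_robustness_protocol_counts_and_flags(rng):
    from pepppo.motifs import robustness_protocol

    peps = ["".join(rng.choice(list(ALPHABET), size=9)) for _ in range(30)]

    def deterministic_gen(allele, n, seed):
        import pandas as pd

        return pd.DataFrame({"peptide": peps, "score": [1.0] * len(peps)})

    one = robustness_protocol(deterministic_gen, ["A1"], runs=1)
    assert one.empty
    two = robustness_protocol(deterministic_gen, ["A1"], runs=2)
    assert len(two) == 1 and two.similarity.iloc[0] == pytest.approx(1.0)
    five = robustness_protocol(deterministic_gen, ["A1"], runs=5)
    assert len(five) == 10  # C(5,2) pairwise values

    def failing_gen(allele, n, seed):
        import pandas as pd

        return pd.DataFrame({"peptide": peps, "score": [0.0] * len(peps)})

    flagged = robustness_protocol(failing_gen, ["A1"], runs=3, threshold=0.75)
    assert flagged.flagged.all() and flagged.similarity.isna().all()
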