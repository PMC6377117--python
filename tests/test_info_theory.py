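import numpy as np
import pytest

from igisplus import (
    argmax_jmi,
    entropy,
    interaction_information,
    jmi_criterion,
    mutual_information,
)
from igisplus.info_theory import conditional_mutual_information, joint_entropy

from oracles import (
    oracle_conditional_mi,
    oracle_entropy,
    oracle_interaction_information,
    oracle_mutual_information,
)


def xor_sample():
    """Uniform 4-point joint distribution with c = XOR(x1, x2)."""
    x1 = np.array([0, 0, 1, 1])
    x2 = np.array([0, 1, 0, 1])
    return x1, x2, x1 ^ x2


class TestEntropy:
    def test_constant_is_zero(self):
        assert entropy(np.zeros(7)) == 0.0

    def test_balanced_binary_is_one_bit(self):
        assert entropy(np.array([0] * 4 + [1] * 4)) == pytest.approx(1.0)

    def test_mixed_counts(self):
        x = np.array([0] * 1 + [1] * 2 + [2] * 5)
        assert entropy(x) == pytest.approx(1.2987949406953985, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            entropy(np.array([]))


class TestMutualInformation:
    def test_constant_gives_zero(self):
        c = np.array([0, 1, 0, 1])
        assert mutual_information(np.zeros(4), c) == 0.0

    def test_identical_balanced_binary_is_one_bit(self):
        c = np.array([0] * 4 + [1] * 4)
        assert mutual_information(c, c) == pytest.approx(1.0)

    def test_weak_association_2x2(self):
        # joint counts [[3,1],[1,3]] over x in {-1,+1}, c in {0,1}
        x = np.array([-1] * 4 + [1] * 4)
        c = np.array([0, 0, 0, 1, 0, 1, 1, 1])
        assert mutual_information(x, c) == pytest.approx(
            0.18872187554086717, abs=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information(np.zeros(3), np.zeros(4))


class TestInteractionInformation:
    def test_independent_variables_zero(self, rng):
        # deterministic product construction: all 8 combinations equally often
        g = np.arange(8)
        xj, xi, c = g // 4, (g // 2) % 2, g % 2
        assert interaction_information(xj, xi, c) == pytest.approx(0.0, abs=1e-12)

    def test_xor_is_plus_one_bit(self):
        x1, x2, c = xor_sample()
        assert interaction_information(x1, x2, c) == pytest.approx(1.0, abs=1e-12)

    def test_triple_copy_is_minus_one_bit(self):
        c = np.array([0] * 4 + [1] * 4)
        assert interaction_information(c, c, c) == pytest.approx(-1.0, abs=1e-12)

    def test_symmetric_in_first_two_arguments(self, rng):
        xj = rng.integers(0, 3, 60)
        xi = rng.integers(0, 3, 60)
        c = rng.integers(0, 2, 60)
        assert interaction_information(xj, xi, c) == pytest.approx(
            interaction_information(xi, xj, c), abs=1e-12
        )

    def test_equivalent_joint_form(self, rng):
        # II = I(Xj,Xi; C) - I(Xj;C) - I(Xi;C)
        for _ in range(20):
            xj = rng.integers(0, 3, 40)
            xi = rng.integers(0, 3, 40)
            c = rng.integers(0, 2, 40)
            pair = xj * 3 + xi
            alt = (
                mutual_information(pair, c)
                - mutual_information(xj, c)
                - mutual_information(xi, c)
            )
            assert interaction_information(xj, xi, c) == pytest.approx(alt, abs=1e-12)


class TestOracleAgreement:
    """Plug-in measures agree with the brute-force joint-table oracle."""

    def test_randomized_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 120))
            ka, kb, kc = rng.integers(2, 6, size=3)
            x = rng.integers(0, ka, n)
            y = rng.integers(0, kb, n)
            z = rng.integers(0, kc, n)
            assert entropy(x) == pytest.approx(oracle_entropy(x), abs=1e-12)
            assert mutual_information(x, y) == pytest.approx(
                oracle_mutual_information(x, y), abs=1e-12
            )
            assert conditional_mutual_information(x, y, z) == pytest.approx(
                oracle_conditional_mi(x, y, z), abs=1e-12
            )
            assert interaction_information(x, y, z) == pytest.approx(
                oracle_interaction_information(x, y, z), abs=1e-12
            )

    def test_mi_bounded_by_marginal_entropies(self, rng):
        for _ in range(50):
            x = rng.integers(0, 4, 50)
            c = rng.integers(0, 3, 50)
            mi = mutual_information(x, c)
            assert mi <= min(entropy(x), entropy(c)) + 1e-12

    def test_joint_permutation_invariance(self, rng):
        x = rng.integers(0, 3, 80)
        c = rng.integers(0, 2, 80)
        perm = rng.permutation(80)
        assert mutual_information(x, c) == pytest.approx(
            mutual_information(x[perm], c[perm]), abs=1e-12
        )
        assert joint_entropy(x, c) == pytest.approx(
            joint_entropy(x[perm], c[perm]), abs=1e-12
        )


class TestJmiCriterion:
    def test_independent_selected_gene_leaves_relevance(self, rng):
        g = np.arange(16)
        c = g % 2
        xj = (g // 2) % 2  # identical structure to c? no: alternates pairs
        xi = g // 8  # independent of both
        states = np.column_stack([xj, xi])
        score = jmi_criterion(0, [1], states, c)
        assert score.total == pytest.approx(score.relevance, abs=1e-12)
        assert score.total == pytest.approx(score.relevance + score.mean_interaction)

    def test_xor_pair_scores_one_bit(self):
        x1, x2, c = xor_sample()
        states = np.column_stack([x1, x2])
        score = jmi_criterion(0, [1], states, c)
        assert score.relevance == pytest.approx(0.0, abs=1e-12)
        assert score.total == pytest.approx(1.0, abs=1e-12)

    def test_redundant_copy_scores_zero(self):
        c = np.array([0] * 4 + [1] * 4)
        states = np.column_stack([c, c])
        score = jmi_criterion(0, [1], states, c)
        assert score.relevance == pytest.approx(1.0)
        assert score.mean_interaction == pytest.approx(-1.0)
        assert score.total == pytest.approx(0.0, abs=1e-12)

    def test_empty_selected_set_rejected(self):
        with pytest.raises(ValueError):
            jmi_criterion(0, [], np.zeros((4, 2), dtype=int), np.array([0, 0, 1, 1]))


class TestArgmaxJmi:
    def test_single_candidate(self):
        x1, x2, c = xor_sample()
        states = np.column_stack([x1, x2])
        gene, _ = argmax_jmi([0], [1], states, c)
        assert gene == 0

    def test_highest_total_wins(self):
        c = np.array([0, 0, 1, 1] * 2)
        informative = c.copy()
        noise = np.array([0, 1] * 4)
        anchor = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        states = np.column_stack([noise, informative, anchor])
        gene, score = argmax_jmi([0, 1], [2], states, c)
        assert gene == 1 and score.total > 0

    def test_exact_tie_prefers_smaller_index(self):
        c = np.array([0] * 4 + [1] * 4)
        dup = c.copy()
        states = np.column_stack([dup, dup, c])
        gene, _ = argmax_jmi([0, 1], [2], states, c)
        assert gene == 0

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            argmax_jmi([], [0], np.zeros((4, 1), dtype=int), np.array([0, 0, 1, 1]))
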