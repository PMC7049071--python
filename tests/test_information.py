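"""Unit tests for the discrete information-theory kernel."""

import math

import numpy as np
import pytest

from jsdbalance import (
    DomainError,
    JointProbabilityTable,
    PrefixCode,
    ProbabilityVector,
    ValidationError,
    conditional_entropy,
    entropy,
    expected_code_length,
    jeffreys_divergence,
    joint_entropy,
    jsd_distributions,
    mutual_information,
    relative_entropy,
)


def pv(**kwargs) -> ProbabilityVector:
    return ProbabilityVector.from_dict({k: float(v) for k, v in kwargs.items()})


class TestProbabilityVector:
    def test_from_counts_normalizes_exactly(self):
        p = ProbabilityVector.from_counts(("a", "b", "c"), (3, 1, 4))
        assert p.probs.sum() == 1.0
        assert p.probs[2] == 0.5

    @pytest.mark.parametrize(
        "labels,probs",
        [
            (("a", "b"), (0.5, 0.6)),  # not normalized
            (("a", "b"), (-0.1, 1.1)),  # negative
            (("a", "a"), (0.5, 0.5)),  # duplicate labels
            (("a", "b"), (0.5, np.nan)),  # non-finite
        ],
    )
    def test_invalid_rejected(self, labels, probs):
        with pytest.raises(ValidationError):
            ProbabilityVector(labels, np.array(probs))

    def test_reordered_preserves_mass(self):
        p = pv(a=0.2, b=0.3, c=0.5)
        q = p.reordered(("c", "a", "b"))
        assert q.labels == ("c", "a", "b")
        assert tuple(q.probs) == (0.5, 0.2, 0.3)


class TestEntropy:
    @pytest.mark.parametrize(
        "dist,expected,places",
        [
            ({"A": 0.25, "B": 0.125, "C": 0.5, "D": 0.125}, 1.75, 12),
            ({"A": 1.0}, 0.0, 12),
            ({"A": 2 / 3, "B": 1 / 3}, 0.9183, 4),
            ({f"x{i}": 1 / 8 for i in range(8)}, 3.0, 12),
        ],
    )
    def test_known_values(self, dist, expected, places):
        assert entropy(ProbabilityVector.from_dict(dist)) == pytest.approx(
            expected, abs=10**-places
        )

    def test_alternative_base(self):
        p = pv(a=0.5, b=0.5)
        assert entropy(p, base=math.e) == pytest.approx(math.log(2))
        assert entropy(p, base=10) == pytest.approx(math.log10(2))


class TestJointAndConditional:
    def independent_coins(self):
        return JointProbabilityTable(
            ("H", "T"), ("H", "T"), np.full((2, 2), 0.25)
        )

    def diagonal(self):
        return JointProbabilityTable(
            ("A", "B"), ("A", "B"), np.array([[0.5, 0.0], [0.0, 0.5]])
        )

    def test_joint_entropy_independent_coins(self):
        assert joint_entropy(self.independent_coins()) == pytest.approx(2.0)

    def test_joint_entropy_coupled(self):
        assert joint_entropy(self.diagonal()) == pytest.approx(1.0)

    def test_joint_entropy_with_constant_margin_equals_marginal_entropy(self):
        # outer product with a point mass: brute-force sum over cells == H(X)
        px = np.array([0.25, 0.125, 0.5, 0.125])
        j = JointProbabilityTable(
            ("A", "B", "C", "D"), ("only",), px[:, None]
        )
        brute = -sum(p * math.log2(p) for p in j.probs.ravel() if p > 0)
        assert joint_entropy(j) == pytest.approx(brute) == pytest.approx(1.75)

    def test_conditioning_on_independent_variable_is_uninformative(self):
        j = self.independent_coins()
        assert conditional_entropy(j, given="cols") == pytest.approx(
            entropy(j.row_marginal())
        )

    def test_deterministic_coupling_leaves_no_uncertainty(self):
        assert conditional_entropy(self.diagonal(), given="cols") == pytest.approx(
            0.0, abs=1e-12
        )

    def test_direct_summation_matches_chain_rule(self):
        j = JointProbabilityTable(
            ("A", "B"), ("A", "B"), np.array([[0.4, 0.1], [0.1, 0.4]])
        )
        direct = conditional_entropy(j, given="cols")
        via_chain = joint_entropy(j) - entropy(j.col_marginal())
        assert direct == pytest.approx(via_chain, abs=1e-12)

    def test_invalid_axis_selector(self):
        with pytest.raises(ValidationError):
            conditional_entropy(self.diagonal(), given="diagonal")


class TestMutualInformation:
    def test_independence_gives_zero(self):
        px = np.array([0.2, 0.8])
        py = np.array([0.3, 0.3, 0.4])
        j = JointProbabilityTable(("a", "b"), ("x", "y", "z"), np.outer(px, py))
        assert mutual_information(j) == pytest.approx(0.0, abs=1e-12)

    def test_bijection_gives_marginal_entropy(self):
        j = JointProbabilityTable(
            ("A", "B"), ("A", "B"), np.array([[0.5, 0.0], [0.0, 0.5]])
        )
        assert mutual_information(j) == pytest.approx(1.0)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(9)).reshape(3, 3)
        j = JointProbabilityTable(("a", "b", "c"), ("x", "y", "z"), probs)
        assert mutual_information(j) == pytest.approx(
            mutual_information(j.transposed()), abs=1e-12
        )


class TestRelativeEntropy:
    def test_self_divergence_zero(self):
        p = pv(a=0.3, b=0.7)
        assert relative_entropy(p, p) == pytest.approx(0.0, abs=1e-15)

    def test_asymmetry_with_hand_computed_values(self):
        g = pv(a=0.5, b=0.5)
        f = pv(a=0.25, b=0.75)
        d_gf = 0.5 * math.log2(0.5 / 0.25) + 0.5 * math.log2(0.5 / 0.75)
        d_fg = 0.25 * math.log2(0.25 / 0.5) + 0.75 * math.log2(0.75 / 0.5)
        assert relative_entropy(g, f) == pytest.approx(d_gf)
        assert relative_entropy(f, g) == pytest.approx(d_fg)
        assert relative_entropy(g, f) != pytest.approx(relative_entropy(f, g))

    def test_zero_mass_term_skipped(self):
        g = pv(a=1.0, b=0.0)
        f = pv(a=0.5, b=0.5)
        assert relative_entropy(g, f) == pytest.approx(1.0)

    def test_infinite_divergence_names_label(self):
        g = pv(a=0.5, b=0.5)
        f = pv(a=1.0, b=0.0)
        with pytest.raises(DomainError, match="'b'"):
            relative_entropy(g, f)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            relative_entropy(pv(a=0.5, b=0.5), pv(a=0.5, c=0.5))


class TestJeffreysDivergence:
    def test_sum_of_directed_divergences(self):
        g = pv(a=0.5, b=0.5)
        f = pv(a=0.25, b=0.75)
        assert jeffreys_divergence(g, f) == pytest.approx(
            relative_entropy(g, f) + relative_entropy(f, g)
        )
        assert jeffreys_divergence(g, f) == pytest.approx(jeffreys_divergence(f, g))

    def test_identical_distributions(self):
        p = pv(a=0.4, b=0.6)
        assert jeffreys_divergence(p, p) == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_support_raises(self):
        with pytest.raises(DomainError):
            jeffreys_divergence(pv(a=1.0, b=0.0), pv(a=0.0, b=1.0))


class TestJSD:
    def test_identical_distributions_zero(self):
        p = pv(a=0.3, b=0.7)
        assert jsd_distributions([p, p, p]) == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_point_masses_attain_log_n(self):
        dists = [
            pv(a=1, b=0, c=0),
            pv(a=0, b=1, c=0),
            pv(a=0, b=0, c=1),
        ]
        assert jsd_distributions(dists) == pytest.approx(math.log2(3))
        assert round(jsd_distributions(dists), 4) == 1.5850

    def test_glucose_group_distributions(self):
        # count-derived distributions, not the rounded published ones
        counts = {
            "Disadvantaged": (7191, 1025, 1715),
            "Elderly": (3637, 835, 685),
            "Reference": (64265, 7298, 6932),
        }
        dists = [
            ProbabilityVector.from_counts(("<109", "109-125", ">125"), c)
            for c in counts.values()
        ]
        assert round(jsd_distributions(dists), 4) == 0.0144

    def test_finite_despite_disjoint_components(self):
        # mixture support covers each component: no infinite divergence
        assert math.isfinite(
            jsd_distributions([pv(a=1.0, b=0.0), pv(a=0.0, b=1.0)])
        )

    def test_weighted_form(self):
        g = pv(a=0.9, b=0.1)
        f = pv(a=0.1, b=0.9)
        w = (0.3, 0.7)
        mix = ProbabilityVector(("a", "b"), 0.3 * g.probs + 0.7 * f.probs)
        expected = 0.3 * relative_entropy(g, mix) + 0.7 * relative_entropy(f, mix)
        assert jsd_distributions([g, f], weights=w) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "dists,weights",
        [
            ([], None),
            ([ProbabilityVector.from_dict({"a": 1.0})], None),
            (
                [
                    ProbabilityVector.from_dict({"a": 1.0}),
                    ProbabilityVector.from_dict({"a": 1.0}),
                ],
                (0.5, 0.6),
            ),
        ],
    )
    def test_invalid_inputs(self, dists, weights):
        with pytest.raises(ValidationError):
            jsd_distributions(dists, weights=weights)


class TestExpectedCodeLength:
    def test_optimal_single_symbol_code(self):
        p = pv(A=0.25, B=0.125, C=0.5, D=0.125)
        code = PrefixCode(("A", "B", "C", "D"), (2, 3, 1, 3))
        assert expected_code_length(p, code) == pytest.approx(1.75)

    def test_block_code_per_outcome(self):
        blocks = pv(AA=4 / 9, AB=2 / 9, BA=2 / 9, BB=1 / 9)
        code = PrefixCode(("AA", "AB", "BA", "BB"), (1, 2, 3, 3))
        got = expected_code_length(blocks, code, outcomes_per_codeword=2)
        assert round(got, 4) == 0.9444

    def test_fixed_length_code(self):
        p = pv(a=0.25, b=0.25, c=0.25, d=0.25)
        code = PrefixCode(("a", "b", "c", "d"), (2, 2, 2, 2))
        assert expected_code_length(p, code) == pytest.approx(2.0)

    def test_kraft_violation_rejected(self):
        with pytest.raises(ValidationError, match="Kraft"):
            PrefixCode(("a", "b", "c"), (1, 1, 1))

    def test_misaligned_labels_rejected(self):
        p = pv(a=0.5, b=0.5)
        code = PrefixCode(("a", "c"), (1, 2))
        with pytest.raises(ValidationError):
            expected_code_length(p, code)
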