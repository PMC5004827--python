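"""K2P distances, between-group divergence and distance-based dating."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_alignment
from matriline import (
    DivergenceDate,
    GroupDivergence,
    RateCalibration,
    SaturationError,
    date_divergence,
    distance_matrix,
    group_divergence,
    jc69_distance,
    k2p_distance,
    p_distance,
    simulate_dataset,
    SimulationConfig,
)


class TestK2P:
    def test_identical_sequences_are_zero(self):
        assert k2p_distance("ACGT", "ACGT") == 0.0

    def test_pure_transition_quarter(self):
        # P=0.25, Q=0: d = -1/2 ln(0.5)
        assert k2p_distance("AAAA", "AGAA") == pytest.approx(0.346574, abs=1e-6)

    def test_pure_transversion_quarter(self):
        # P=0, Q=0.25: d = -1/2 ln(0.75) - 1/4 ln(0.5)
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.5)
        assert k2p_distance("AAAA", "ACAA") == pytest.approx(expected, abs=1e-6)
        assert k2p_distance("AAAA", "ACAA") == pytest.approx(0.317128, abs=1e-6)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance("AAAA", "GGGG")

    def test_missing_states_are_pairwise_deleted(self):
        assert k2p_distance("ANGT", "AAGT") == 0.0

    def test_all_missing_overlap_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            k2p_distance("NNNN", "ACGT")

    def test_k2p_collapses_to_jc69_at_expected_ts_tv_split(self):
        # with Q = 2P (the equal-rate expectation) K2P reduces exactly to
        # JC69: -1/2 ln(1-4P) - 1/4 ln(1-4P) = -3/4 ln(1-4P)
        a = "A" * 12
        b = "GCT" + "A" * 9  # 1 transition, 2 transversions: P=1/12, Q=2/12
        assert k2p_distance(a, b) == pytest.approx(jc69_distance(a, b), abs=1e-12)
        assert k2p_distance(a, b) == pytest.approx(-0.75 * math.log(1 - 4 / 12))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(st.sampled_from("ACGT"), min_size=20, max_size=60),
    st.randoms(use_true_random=False),
)
def test_k2p_dominates_p_distance(bases, rnd):
    a = "".join(bases)
    b = list(a)
    for _ in range(3):  # few substitutions, keeps K2P defined
        i = rnd.randrange(len(b))
        b[i] = rnd.choice("ACGT")
    b = "".join(b)
    assert k2p_distance(a, b) >= p_distance(a, b) - 1e-12


class TestDistanceMatrix:
    def test_matrix_matches_pairwise_calls(self, two_species):
        alignment, _, _ = two_species
        ids = list(alignment.ids)[:6]
        dm = distance_matrix(alignment, ids=ids)
        for a, b in itertools.combinations(ids, 2):
            assert dm.get(a, b) == pytest.approx(
                k2p_distance(alignment.sequence(a), alignment.sequence(b))
            )
        assert np.allclose(np.diag(dm.matrix), 0.0)


class TestGroupDivergence:
    def test_identical_groups_zero(self):
        aln = make_alignment({"a1": "ACGTACGT", "a2": "ACGTACGT", "b1": "ACGTACGT"})
        div = group_divergence(aln, ["a1", "a2"], ["b1"], n_bootstrap=100)
        assert div.d_xy == 0.0
        assert div.se == 0.0

    def test_one_vs_one_equals_pairwise_k2p(self):
        aln = make_alignment({"a": "AAAAAAAA", "b": "AGAAAAAA"})
        div = group_divergence(aln, ["a"], ["b"], n_bootstrap=0)
        assert div.d_xy == pytest.approx(k2p_distance(*aln.seqs))

    def test_matches_brute_force_double_loop(self):
        cfg = SimulationConfig(
            species_tree="(x:400000,y:400000);",
            sample_sizes={"x": 6, "y": 6}, seed=19,
        )
        aln, meta, _ = simulate_dataset(cfg)
        ids_a = meta.by_species()["x"]
        ids_b = meta.by_species()["y"]
        div = group_divergence(aln, ids_a, ids_b, n_bootstrap=0)
        brute = np.mean([
            k2p_distance(aln.sequence(a), aln.sequence(b))
            for a in ids_a for b in ids_b
        ])
        assert div.d_xy == pytest.approx(brute, abs=1e-12)

    def test_overlapping_groups_rejected(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGT"})
        with pytest.raises(ValueError, match="disjoint"):
            group_divergence(aln, ["a"], ["a", "b"])

    def test_net_distance_not_larger_than_raw(self, two_species):
        alignment, metadata, _ = two_species
        by = metadata.by_species()
        raw = group_divergence(alignment, by["alpha"], by["beta"], n_bootstrap=0)
        net = group_divergence(alignment, by["alpha"], by["beta"], n_bootstrap=0, net=True)
        assert net.d_xy <= raw.d_xy


class TestDating:
    def test_zero_divergence_dates_to_zero(self):
        div = GroupDivergence(("a",), ("b",), d_xy=0.0, se=0.0)
        age = date_divergence(div)
        assert (age.t_low, age.t_mid, age.t_high) == (0.0, 0.0, 0.0)

    def test_known_divergence_at_mean_rate(self):
        div = GroupDivergence(("a",), ("b",), d_xy=0.0736, se=0.0)
        assert date_divergence(div).t_mid == pytest.approx(1_000_000, rel=1e-9)

    def test_doubling_rates_halves_ages(self):
        div = GroupDivergence(("a",), ("b",), d_xy=0.05, se=0.005)
        r1 = RateCalibration()
        r2 = RateCalibration(
            mu_low=2 * r1.mu_low, mu_mid=2 * r1.mu_mid, mu_fast=2 * r1.mu_fast
        )
        a1, a2 = date_divergence(div, r1), date_divergence(div, r2)
        assert a2.t_mid == pytest.approx(a1.t_mid / 2)
        assert a2.t_low == pytest.approx(a1.t_low / 2)
        assert a2.t_high == pytest.approx(a1.t_high / 2)

    def test_interval_pairs_wide_rate_with_wide_bound(self):
        div = GroupDivergence(("a",), ("b",), d_xy=0.05, se=0.005)
        r = RateCalibration()
        age = date_divergence(div, r)
        assert age.t_low == pytest.approx(div.ci_low / (2 * r.mu_fast))
        assert age.t_high == pytest.approx(div.ci_high / (2 * r.mu_low))
        assert age.t_low <= age.t_mid <= age.t_high

    def test_negative_lower_bound_clamped(self):
        div = GroupDivergence(("a",), ("b",), d_xy=0.001, se=0.01)
        assert date_divergence(div).t_low == 0.0

    def test_invalid_rate_ordering_rejected(self):
        with pytest.raises(ValueError):
            RateCalibration(mu_low=5e-8, mu_mid=3e-8, mu_fast=2e-8)

    def test_inverted_age_interval_rejected(self):
        with pytest.raises(ValueError):
            DivergenceDate(label="x", t_mid=1.0, t_low=2.0, t_high=3.0)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.floats(min_value=0.0, max_value=0.3), st.floats(min_value=0.0, max_value=0.02))
def test_dating_is_linear_in_dxy(d, se):
    r = RateCalibration()
    a1 = date_divergence(GroupDivergence(("a",), ("b",), d_xy=d, se=se), r)
    a2 = date_divergence(GroupDivergence(("a",), ("b",), d_xy=2 * d, se=2 * se), r)
    assert a2.t_mid == pytest.approx(2 * a1.t_mid)
    assert a2.t_high == pytest.approx(2 * a1.t_high)
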