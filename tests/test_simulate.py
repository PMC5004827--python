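"""The synthetic-data generator: determinism, truth bookkeeping and the
closed-form expectations it must reproduce."""

import numpy as np
import pytest
from scipy import stats

from matriline import (
    FIXTURES,
    IntrogressionEvent,
    SimulationConfig,
    SimulationConfigError,
    collapse_haplotypes,
    group_divergence,
    make_fixture,
    simulate_dataset,
)


def two_species_config(**kw):
    base = dict(
        species_tree="(a:1000000,b:1000000);",
        sample_sizes={"a": 5, "b": 5},
        seed=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminismAndValidation:
    def test_same_seed_reproduces_sequences_exactly(self):
        a1, m1, t1 = simulate_dataset(two_species_config())
        a2, m2, t2 = simulate_dataset(two_species_config())
        assert a1.seqs == a2.seqs
        assert t1.genealogy_newick == t2.genealogy_newick

    def test_different_seed_changes_sequences(self):
        a1, _, _ = simulate_dataset(two_species_config(seed=1))
        a2, _, _ = simulate_dataset(two_species_config(seed=2))
        assert a1.seqs != a2.seqs

    def test_written_fixture_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        make_fixture("two_species_clean", outdir=d1)
        make_fixture("two_species_clean", outdir=d2)
        for name in ("alignment.fasta", "metadata.tsv", "truth.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_nonultrametric_tree_rejected(self):
        with pytest.raises(SimulationConfigError, match="ultrametric"):
            simulate_dataset(two_species_config(species_tree="(a:1,b:2);"))

    def test_sample_size_species_mismatch_rejected(self):
        with pytest.raises(SimulationConfigError, match="sample_sizes"):
            simulate_dataset(two_species_config(sample_sizes={"a": 5, "zz": 5}))

    def test_introgression_older_than_split_rejected(self):
        with pytest.raises(SimulationConfigError, match="older"):
            simulate_dataset(two_species_config(
                introgression=(IntrogressionEvent("a", "b", 1, 2_000_000),)
            ))

    def test_truth_split_times_match_tree(self):
        _, _, truth = simulate_dataset(two_species_config())
        assert truth.split_time("a", "b") == pytest.approx(1_000_000)


class TestGenealogyStructure:
    def test_no_mutations_one_haplotype_per_species(self):
        cfg = two_species_config(mu=1e-300)  # effectively zero
        aln, meta, _ = simulate_dataset(cfg)
        table = collapse_haplotypes(aln)
        assert len(table) == 1  # star + shared root sequence
        by = meta.by_species()
        for sp in ("a", "b"):
            haps = {table.haplotype_of(i) for i in by[sp]}
            assert len(haps) == 1

    def test_introgressed_ids_recorded_with_donor(self):
        cfg = two_species_config(
            sample_sizes={"a": 6, "b": 6},
            introgression=(IntrogressionEvent("a", "b", 2, 30_000),),
        )
        _, meta, truth = simulate_dataset(cfg)
        assert len(truth.introgressed) == 2
        for ind, donor in truth.introgressed:
            assert donor == "a"
            assert meta.species_of(ind) == "b"  # field label stays recipient

    def test_coalescent_mode_runs_and_adds_within_species_depth(self):
        star = simulate_dataset(two_species_config(seed=3))[0]
        coal = simulate_dataset(two_species_config(
            seed=3, within_mode="coalescent", theta=400_000.0
        ))[0]
        div_star = np.mean([a != b for a, b in zip(star.seqs[0], star.seqs[1])])
        assert coal.length == star.length

    def test_no_shared_haplotypes_at_deep_divergence(self):
        aln, meta, truth = make_fixture("two_species_clean")
        table = collapse_haplotypes(aln)
        by = meta.by_species()
        haps_a = {table.haplotype_of(i) for i in by["alpha"]}
        haps_b = {table.haplotype_of(i) for i in by["beta"]}
        assert not (haps_a & haps_b)


class TestExpectations:
    def test_between_species_divergence_matches_2muT(self):
        # E[d_xy] = 2 mu T for a star genealogy with instant ancestral
        # coalescence; Monte-Carlo mean over replicates
        T, mu = 1_000_000.0, 3.68e-8
        vals = []
        for seed in range(30):
            aln, meta, _ = simulate_dataset(two_species_config(seed=seed))
            by = meta.by_species()
            vals.append(group_divergence(aln, by["a"], by["b"], n_bootstrap=0).d_xy)
        assert np.mean(vals) == pytest.approx(2 * mu * T, rel=0.10)

    def test_ts_tv_ratio_converges_to_kappa_over_two(self):
        cfg = two_species_config(seq_length=50_000, kappa=4.0, seed=9)
        _, _, truth = simulate_dataset(cfg)
        n = truth.n_transitions + truth.n_transversions
        assert n > 500
        p_ts = 4.0 / (4.0 + 2.0)
        res = stats.binomtest(truth.n_transitions, n, p_ts)
        assert res.pvalue > 0.01
        assert truth.n_transitions / truth.n_transversions == pytest.approx(2.0, rel=0.2)

    def test_realized_mutation_count_near_expectation(self):
        cfg = two_species_config(seed=17)
        _, _, truth = simulate_dataset(cfg)
        # total branch length: 10 tips x 1e5 (star) + 2 x 9e5 (trunks)
        total_years = 10 * 100_000 + 2 * 900_000
        expected = 3.68e-8 * total_years * 588
        assert truth.n_mutations == pytest.approx(expected, rel=0.35)


class TestFixtures:
    def test_registry_contents(self):
        assert {"two_species_clean", "six_species_radiation", "introgression_6"} <= set(
            FIXTURES
        )
        with pytest.raises(KeyError):
            make_fixture("nope")

    def test_radiation_mimics_study_design(self, radiation):
        alignment, metadata, truth = radiation
        assert alignment.n == 118
        assert alignment.length == 588
        assert len(metadata.species_labels()) == 6
        assert truth.split_time("culpaeus", "griseus") == pytest.approx(366_000)
        assert truth.split_time("vetulus", "culpaeus") == pytest.approx(1_353_000)

    def test_introgression_fixture_plants_six(self, introgression):
        _, _, truth = introgression
        assert len(truth.introgressed) == 6
        assert {d for _, d in truth.introgressed} == {"griseus"}
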