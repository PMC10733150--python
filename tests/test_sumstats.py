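import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

import coalabc.sumstats as st
from coalabc.coalsim import LocusConfig, SampleConfig, simulate_dataset
from coalabc.errors import ConfigurationError, InputError
from coalabc.sumstats import FStatResult

from conftest import clade_model, make_dataset, single_pop_model


def random_dataset(rng, n_sites=20, n_ind=10, n_pops=2, missing=0.0):
    G = rng.integers(0, 2, size=(n_sites, 2 * n_ind)).astype(np.int8)
    if missing:
        G[rng.random(G.shape) < missing] = -1
    pops = [f"P{i % n_pops}" for i in range(n_ind)]
    return make_dataset([G], pops)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_monomorphic_gives_zero(self):
        ds = make_dataset([np.zeros((4, 6), dtype=np.int8)], ["A"] * 3)
        assert st.nucleotide_diversity(ds, "A") == 0.0

    def test_singleton_site_of_four_haplotypes(self):
        ds = make_dataset([[[1, 0, 0, 0]]], ["A", "A"], locus_lengths=[1])
        assert st.nucleotide_diversity(ds, "A") == pytest.approx(0.5)

    def test_matches_all_pairs_hamming_oracle(self, rng):
        for _ in range(25):
            ds = random_dataset(rng, n_sites=20, n_ind=5, n_pops=1)
            G = ds.genotypes[0]
            n = G.shape[1]
            total = sum(np.sum(G[:, i] != G[:, j])
                        for i, j in itertools.combinations(range(n), 2))
            oracle = total / (n * (n - 1) / 2) / ds.total_length
            assert st.nucleotide_diversity(ds, "P0") == pytest.approx(oracle)

    def test_absent_population_rejected(self):
        ds = make_dataset([[[1, 0, 0, 0]]], ["A", "B"])
        with pytest.raises(InputError):
            st.nucleotide_diversity(ds, "C")


class TestSegregatingSites:
    def test_globally_variable_but_fixed_within_pop_not_counted(self):
        G = np.array([[1, 1, 1, 1, 0, 0]], dtype=np.int8)
        ds = make_dataset([G], ["A", "A", "B"])
        assert st.segregating_sites(ds, "A") == 0
        assert st.segregating_sites(ds, "B") == 0

    def test_empty_population_gives_zero(self):
        ds = make_dataset([np.zeros((2, 4), dtype=np.int8)], ["A", "A"])
        assert st.segregating_sites(ds, "Z") == 0

    def test_matches_scan_oracle(self, rng):
        for _ in range(25):
            ds = random_dataset(rng, n_sites=30, n_ind=6, n_pops=2, missing=0.1)
            for pop in ("P0", "P1"):
                cols = ds.hap_indices(pop)
                H = ds.genotypes[0][:, cols]
                oracle = sum(1 for row in H
                             if (row == 0).any() and (row == 1).any())
                assert st.segregating_sites(ds, pop) == oracle


class TestTajimasD:
    def test_hand_worked_singleton_case(self):
        # n=4 haplotypes, one singleton: D = (0.5 - 1/a1)/sqrt(e1)
        ds = make_dataset([[[1, 0, 0, 0]]], ["A", "A"])
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1, b2 = 5 / 9, 46 / 108
        c1 = b1 - 1 / a1
        c2 = b2 - 6 / (4 * a1) + a2 / a1**2
        e1 = c1 / a1
        oracle = (0.5 - 1 / a1) / np.sqrt(e1)
        assert st.tajimas_d(ds, "A") == pytest.approx(oracle)
        assert st.tajimas_d(ds, "A") == pytest.approx(-0.61, abs=0.01)

    def test_intermediate_frequency_site_is_positive(self):
        ds = make_dataset([[[1, 1, 0, 0]]], ["A", "A"])
        assert st.tajimas_d(ds, "A") > 0

    def test_no_segregating_sites_is_undefined(self):
        ds = make_dataset([np.zeros((3, 4), dtype=np.int8)], ["A", "A"])
        assert np.isnan(st.tajimas_d(ds, "A"))


# ---------------------------------------------------------------------------
# F statistics
# ---------------------------------------------------------------------------

class TestFStatistics:
    def test_f4_with_duplicated_population_is_exactly_zero(self, rng):
        ds = random_dataset(rng, n_sites=40, n_ind=8, n_pops=4)
        res = st.f_statistic(ds, "F4", ("P0", "P0", "P1", "P2"))
        assert res.estimate == 0.0

    def test_f3_single_site_algebra(self):
        # p_C=0, p_A=1, p_B=1 with large samples: F3 -> (0-1)(0-1) = 1
        G = np.zeros((1, 18), dtype=np.int8)
        G[0, 6:] = 1
        ds = make_dataset([G], ["C"] * 3 + ["A"] * 3 + ["B"] * 3)
        res = st.f_statistic(ds, "F3", ("C", "A", "B"))
        assert res.estimate == pytest.approx(1.0)

    def test_symmetry_identities_exact(self, rng):
        ds = random_dataset(rng, n_sites=60, n_ind=12, n_pops=4)
        pops = ("P0", "P1", "P2", "P3")
        f3_ab = st.f_statistic(ds, "F3", ("P0", "P1", "P2")).estimate
        f3_ba = st.f_statistic(ds, "F3", ("P0", "P2", "P1")).estimate
        assert f3_ab == pytest.approx(f3_ba, rel=1e-12)
        f4 = st.f_statistic(ds, "F4", pops).estimate
        f4_swap = st.f_statistic(ds, "F4", ("P1", "P0", "P2", "P3")).estimate
        f4_pair = st.f_statistic(ds, "F4", ("P2", "P3", "P0", "P1")).estimate
        assert f4 == pytest.approx(-f4_swap, rel=1e-12)
        assert f4 == pytest.approx(f4_pair, rel=1e-12)

    def test_allele_label_flip_invariance(self, rng):
        ds = random_dataset(rng, n_sites=50, n_ind=10, n_pops=3)
        flipped = make_dataset([1 - ds.genotypes[0]], ds.sample_pops)
        for pop in ("P0", "P1"):
            assert st.nucleotide_diversity(ds, pop) == pytest.approx(
                st.nucleotide_diversity(flipped, pop))
            assert st.segregating_sites(ds, pop) == st.segregating_sites(flipped, pop)
        f2 = st.f_statistic(ds, "F2", ("P0", "P1")).estimate
        f2f = st.f_statistic(flipped, "F2", ("P0", "P1")).estimate
        assert f2 == pytest.approx(f2f, rel=1e-12)

    def test_jackknife_se_positive_and_permutation_invariant(self, rng):
        blocks = [rng.integers(0, 2, size=(15, 12)).astype(np.int8)
                  for _ in range(6)]
        pops = ["P0"] * 3 + ["P1"] * 3
        ds = make_dataset(blocks, pops)
        res = st.f_statistic(ds, "F2", ("P0", "P1"))
        assert res.se > 0
        assert np.isfinite(res.z)
        perm = [blocks[i] for i in [3, 1, 5, 0, 4, 2]]
        res_p = st.f_statistic(make_dataset(perm, pops), "F2", ("P0", "P1"))
        assert res_p.estimate == pytest.approx(res.estimate, rel=1e-12)
        assert res_p.se == pytest.approx(res.se, rel=1e-9)

    def test_missing_population_rejected(self, rng):
        ds = random_dataset(rng)
        with pytest.raises(InputError):
            st.f_statistic(ds, "F3", ("P0", "P1", "NOPE"))


class TestVerdicts:
    def test_same_population_f4_is_clade(self, rng):
        ds = random_dataset(rng, n_sites=50, n_ind=12, n_pops=4)
        res = st.cladeness_f4_test(ds, "P2", "P2", png="P1", outgroup="P0")
        assert res.estimate == 0.0
        assert res.verdict == "clade"

    def test_admixed_target_flagged(self, rng):
        # target = 50/50 mixture of two long-diverged sources
        n = 40
        src_a = rng.integers(0, 2, size=(200, 1)).repeat(n, axis=1).astype(np.int8)
        src_b = rng.integers(0, 2, size=(200, 1)).repeat(n, axis=1).astype(np.int8)
        noise = (rng.random((200, 3 * n)) < 0.05)
        half = n // 2
        target = np.concatenate([src_a[:, :half], src_b[:, :half]], axis=1)
        G = (np.concatenate([src_a, src_b, target], axis=1) ^ noise).astype(np.int8)
        blocks = np.array_split(G, 20, axis=0)
        ds = make_dataset(blocks, ["A"] * (n // 2) + ["B"] * (n // 2) + ["T"] * (n // 2))
        res = st.admixture_f3_test(ds, "T", "A", "B")
        assert res.estimate < 0
        assert res.verdict == "admixed"

    def test_identical_sources_give_nonnegative_f3(self, rng):
        ds = random_dataset(rng, n_sites=500, n_ind=20, n_pops=2)
        res = st.admixture_f3_test(ds, "P0", "P1", "P1")
        f2 = st.f_statistic(ds, "F2", ("P0", "P1")).estimate
        assert res.estimate == pytest.approx(f2, abs=0.05)  # F3(T;S,S) ~ F2(T,S)


class TestMoments:
    def test_constant_blocks(self):
        res = FStatResult("F4", ("a", "b", "c", "d"), 1.0,
                          np.full(5, 1.0), np.ones(5), 0.0, np.nan)
        assert st.f_moments(res) == (0.0, 0.0)

    def test_hand_case(self):
        res = FStatResult("F4", ("a", "b", "c", "d"), 0.0,
                          np.array([-1.0, 0.0, 1.0]), np.ones(3), 1.0, 0.0)
        m2, m3 = st.f_moments(res)
        assert m2 == pytest.approx(2 / 3)
        assert m3 == pytest.approx(0.0)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            v = rng.normal(size=rng.integers(3, 30))
            res = FStatResult("F4", ("a", "b", "c", "d"), v.mean(), v,
                              np.ones(v.size), 1.0, 0.0)
            m2, m3 = st.f_moments(res)
            c = v - v.mean()
            assert m2 == pytest.approx(np.sum(c**2) / v.size)
            assert m3 == pytest.approx(np.sum(c**3) / v.size)

    def test_too_few_blocks_rejected(self):
        res = FStatResult("F4", ("a", "b", "c", "d"), 0.0,
                          np.array([1.0, 2.0]), np.ones(2), 1.0, 0.0)
        with pytest.raises(InputError):
            st.f_moments(res)


class TestFst:
    def test_identical_haplotype_sets_near_zero(self, rng):
        G = rng.integers(0, 2, size=(10_000, 20)).astype(np.int8)
        ds = make_dataset([G], ["A", "B"] * 5)  # interleaved, same distribution
        assert abs(st.fst_hudson(ds, "A", "B")) < 0.01

    def test_fixed_difference_gives_one(self):
        G = np.concatenate([np.zeros((1, 10)), np.ones((1, 10))],
                           axis=1).astype(np.int8)
        ds = make_dataset([G], ["A"] * 5 + ["B"] * 5)
        assert st.fst_hudson(ds, "A", "B") == pytest.approx(1.0)

    def test_increases_with_split_time(self):
        values = []
        for t in (100.0, 1000.0, 5000.0):
            from conftest import two_pop_split_model
            ds = simulate_dataset(two_pop_split_model(t_split=t, ne=1000.0),
                                  SampleConfig(diploids={"A": 5, "B": 5}),
                                  LocusConfig(60, 50_000), seed=int(t))
            values.append(st.fst_hudson(ds, "A", "B"))
        assert values[0] < values[1] < values[2]

    def test_ascertainment_restricts_sites(self, rng):
        ds = random_dataset(rng, n_sites=200, n_ind=12, n_pops=3)
        full = st.fst_hudson(ds, "P0", "P1")
        asc = st.fst_hudson(ds, "P0", "P1", ascertainment_pop="P2")
        assert np.isfinite(full) and np.isfinite(asc)


# ---------------------------------------------------------------------------
# sharing classes / spectra (exhaustive oracles live in test_acceptance too)
# ---------------------------------------------------------------------------

class TestSharingClasses:
    CONT = {"TIW": "Australia", "GAL": "Australia", "PNG": "Oceania",
            "OUT": "Africa"}

    def make(self, G):
        return make_dataset([np.asarray(G, dtype=np.int8)],
                            ["TIW", "GAL", "PNG", "OUT"], continents=self.CONT)

    def test_population_private(self):
        t = st.sharing_classes(self.make([[1, 0, 0, 0, 0, 0, 0, 0]]))
        assert t.loc["TIW", "population-private"] == 1
        assert t.loc["TIW"].sum() == 1

    def test_continent_private(self):
        t = st.sharing_classes(self.make([[1, 0, 1, 0, 0, 0, 0, 0]]))
        assert t.loc["TIW", "continent-private"] == 1
        assert t.loc["GAL", "continent-private"] == 1

    def test_shared_some_and_all(self):
        some = st.sharing_classes(self.make([[1, 0, 0, 0, 1, 0, 0, 0]]))
        assert some.loc["TIW", "shared-some-continents"] == 1
        al = st.sharing_classes(self.make([[1, 0, 0, 0, 1, 0, 1, 0]]))
        assert al.loc["TIW", "shared-all-continents"] == 1

    def test_unassigned_population_rejected(self):
        ds = make_dataset([[[1, 0, 0, 0]]], ["A", "B"],
                          continents={"A": "X"})
        with pytest.raises(ConfigurationError):
            st.sharing_classes(ds)

    def test_row_sums_equal_sites_observed_in_population(self, rng):
        for _ in range(20):
            G = rng.integers(0, 2, size=(40, 8)).astype(np.int8)
            t = st.sharing_classes(self.make(G))
            for k, pop in enumerate(["TIW", "GAL", "PNG", "OUT"]):
                present = (G[:, 2 * k:2 * k + 2] == 1).any(axis=1)
                seg = (G == 1).any(axis=1) & (G == 0).any(axis=1)
                assert t.loc[pop].sum() == np.count_nonzero(present & seg) \
                    + np.count_nonzero(present & ~seg)


class TestMacSpectrum:
    def test_fixed_global_minor_lands_in_top_bin(self):
        # pop fixed for an allele that is globally the minor one
        G = np.concatenate([np.ones((1, 4)), np.zeros((1, 8))],
                           axis=1).astype(np.int8)
        ds = make_dataset([G], ["A", "A", "B", "B", "B", "B"])
        spec = st.mac_spectrum(ds, "A", subsample_n=2, seed=0)
        assert spec[-1] == 1 and spec.sum() == 1

    def test_pop_without_minor_contributes_nothing(self):
        G = np.concatenate([np.zeros((1, 4)), np.ones((1, 2)),
                            np.zeros((1, 6))], axis=1).astype(np.int8)
        ds = make_dataset([G], ["A", "A", "B", "B", "B", "B"])
        assert st.mac_spectrum(ds, "A", subsample_n=2, seed=0).sum() == 0

    def test_insufficient_individuals_rejected(self):
        ds = make_dataset([[[1, 0, 0, 0]]], ["A", "A"])
        with pytest.raises(InputError):
            st.mac_spectrum(ds, "A", subsample_n=5)

    def test_total_equals_sites_carrying_minor(self, rng):
        for trial in range(20):
            G = (rng.random((30, 24)) < 0.3).astype(np.int8)
            ds = make_dataset([G], [f"P{i % 2}" for i in range(12)])
            spec = st.mac_spectrum(ds, "P0", subsample_n=5, seed=trial)
            chosen = np.sort(np.random.default_rng(trial).choice(
                ds.sample_indices("P0"), size=5, replace=False))
            haps = np.concatenate([2 * chosen, 2 * chosen + 1])
            freq = (G == 1).sum(axis=1) / G.shape[1]
            minor_is_derived = freq < 0.5
            count = np.where(minor_is_derived, (G[:, haps] == 1).sum(axis=1),
                             (G[:, haps] == 0).sum(axis=1))
            assert spec.sum() == np.count_nonzero((count >= 1) & (count <= 10))


class TestPerIndividual:
    def test_homozygous_individual_zero_het(self):
        G = np.array([[1, 1, 1, 0], [0, 0, 0, 1]], dtype=np.int8)
        ds = make_dataset([G], ["A", "A"])
        het = st.het_per_individual(ds)
        assert het.iloc[0] == 0
        assert het.iloc[1] == 2

    def test_rescaling_arithmetic(self):
        G = np.array([[1, 0, 0, 0]], dtype=np.int8)
        masks = {"s00": [[(0, 20)]]}
        ds = make_dataset([G], ["A", "A"], locus_lengths=[100], masks=masks)
        het = st.het_per_individual(ds, rescale=True)
        assert het.loc["s00"] == pytest.approx(1 / 0.8)

    def test_expected_het_matches_4Nmu(self):
        N, L = 1000.0, 50_000
        mu = 1e-7
        ds = simulate_dataset(single_pop_model(ne=N),
                              SampleConfig(diploids={"A": 10}),
                              LocusConfig(100, L, mu), seed=43)
        het = st.het_per_individual(ds)
        expected = 4 * N * mu * L * 100
        se = het.std() / np.sqrt(len(het))
        # individuals share genealogies, so use a generous 5-sigma guard
        assert abs(het.mean() - expected) < 5 * max(se, np.sqrt(expected))


class TestRareSharing:
    def test_duplicated_genotypes_maximal_on_partner(self, rng):
        G = (rng.random((60, 8)) < 0.15).astype(np.int8)
        G = np.concatenate([G, G[:, :2]], axis=1)  # sample 4 duplicates sample 0
        ds = make_dataset([G], ["A"] * 5)
        mat = st.rare_sharing_matrix(ds, max_count=5)
        row = mat.loc["s04"].drop("s04")
        assert row.idxmax() == "s00"

    def test_disjoint_rare_variants_share_zero(self):
        G = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.int8)
        ds = make_dataset([G], ["A", "A"])
        mat = st.rare_sharing_matrix(ds, max_count=5)
        assert mat.iloc[0, 1] == 0

    def test_common_variants_excluded(self):
        G = np.ones((3, 8), dtype=np.int8)  # global count 8 > max_count
        ds = make_dataset([G], ["A"] * 4)
        assert st.rare_sharing_matrix(ds, max_count=5).to_numpy().sum() == 0


class TestDiscoveryCurves:
    def test_full_sample_recovers_total_segregating_sites(self, rng):
        ds = random_dataset(rng, n_sites=40, n_ind=8, n_pops=1)
        curve = st.discovery_curve(ds, "P0", n_max=8, replicates=5, seed=1)
        assert curve[-1] == st.segregating_sites(ds, "P0")

    def test_monotone_non_decreasing(self, rng):
        ds = random_dataset(rng, n_sites=60, n_ind=10, n_pops=1)
        curve = st.discovery_curve(ds, "P0", n_max=10, replicates=4, seed=2)
        assert np.all(np.diff(curve) >= 0)

    def test_n_max_too_large_rejected(self, rng):
        ds = random_dataset(rng, n_ind=4, n_pops=1)
        with pytest.raises(InputError):
            st.discovery_curve(ds, "P0", n_max=5)

    def test_novel_curve_zero_for_duplicated_continent(self, rng):
        G = rng.integers(0, 2, size=(40, 8)).astype(np.int8)
        G = np.concatenate([G, G], axis=1)  # continent Y duplicates X
        ds = make_dataset([G], ["A"] * 4 + ["B"] * 4,
                          continents={"A": "X", "B": "Y"})
        curve = st.novel_by_continent_curve(ds, "Y", pre_sample=4,
                                            n_max=4, replicates=3, seed=3)
        assert np.all(curve == 0)

    def test_novel_curve_monotone(self, rng):
        ds = random_dataset(rng, n_sites=80, n_ind=12, n_pops=2)
        ds.continents = {"P0": "X", "P1": "Y"}
        curve = st.novel_by_continent_curve(ds, "Y", pre_sample=3,
                                            n_max=6, replicates=4, seed=4)
        assert np.all(np.diff(curve) >= 0)


@pytest.fixture(scope="module")
def cohort_ds():
    from coalabc.demography import scenario4_calibrated_model
    model = scenario4_calibrated_model()
    return simulate_dataset(
        model, SampleConfig(diploids={"TIW": 3, "GAL": 3, "TIJ": 3,
                                      "YAR": 3, "PNG": 3, "OUT": 2}),
        LocusConfig(12, 30_000), seed=47)


class TestSummaryVector:

    def test_schema_complete_and_deterministic(self, cohort_ds):
        sv1 = st.summary_vector(cohort_ds)
        sv2 = st.summary_vector(cohort_ds)
        cfg = st.SummaryConfig()
        assert list(sv1.index) == cfg.schema()
        assert not sv1.isna().any()
        assert (sv1 == sv2).all()

    def test_entries_match_standalone_operations(self, cohort_ds):
        sv = st.summary_vector(cohort_ds)
        res = st.f_statistic(cohort_ds, "F3", ("OUT", "TIW", "GAL"))
        assert sv["F3_TIW_GAL"] == res.estimate
        m2, m3 = st.f_moments(res)
        assert sv["F3_TIW_GAL_m2"] == m2
        assert sv["F3_TIW_GAL_m3"] == m3
        assert sv["pi_TIJ"] == st.nucleotide_diversity(cohort_ds, "TIJ")
        assert sv["S_PNG"] == st.segregating_sites(cohort_ds, "PNG")

    def test_missing_population_rejected(self, rng):
        ds = random_dataset(rng)
        with pytest.raises(InputError):
            st.summary_vector(ds)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(hst.integers(min_value=0, max_value=2**32 - 1))
def test_fstat_sign_conventions_hold_for_random_matrices(seed):
    """Property: F3(C;A,B)=F3(C;B,A) and F4 antisymmetry on random data."""
    rng = np.random.default_rng(seed)
    G = rng.integers(0, 2, size=(12, 16)).astype(np.int8)
    ds = make_dataset([G], [f"P{i % 4}" for i in range(8)])
    a = st.f_statistic(ds, "F3", ("P0", "P1", "P2")).estimate
    b = st.f_statistic(ds, "F3", ("P0", "P2", "P1")).estimate
    assert a == pytest.approx(b, rel=1e-12, abs=1e-12)
    f = st.f_statistic(ds, "F4", ("P0", "P1", "P2", "P3")).estimate
    g = st.f_statistic(ds, "F4", ("P1", "P0", "P2", "P3")).estimate
    assert f == pytest.approx(-g, rel=1e-12, abs=1e-12)
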