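import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan.sweep_stats import (
    CandidateSet,
    ScanTrack,
    combine_evidence,
    hp_track,
    major_minor_counts,
    pi_ratio_log2,
    pooled_heterozygosity,
    select_candidates,
    snp_fst,
    theta_pi_track,
    window_mean,
    z_transform,
)
from sweepscan.windows import assign_snps, make_windows
from tests.conftest import random_matrix
from tests.oracles import hp_oracle, pi_pairwise_oracle, wc_fst_oracle


class TestPooledHeterozygosity:
    def test_hand_worked_example(self):
        # counts (8,2) and (9,1): 2*17*3/20^2
        assert pooled_heterozygosity(np.array([8, 9]), np.array([2, 1])) == pytest.approx(0.255, abs=1e-15)

    def test_fixed_sites_give_zero(self):
        assert pooled_heterozygosity(np.array([10, 10]), np.array([0, 0])) == 0.0

    def test_balanced_sums_reach_maximum(self):
        assert pooled_heterozygosity(np.array([5, 5]), np.array([5, 5])) == pytest.approx(0.5)

    def test_empty_window_is_missing(self):
        assert np.isnan(pooled_heterozygosity(np.array([]), np.array([])))

    @given(st.lists(st.tuples(st.integers(0, 20), st.integers(0, 20)),
                    min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_major_minor_label_swap_invariance(self, counts):
        a = np.array([c[0] for c in counts], dtype=float)
        b = np.array([c[1] for c in counts], dtype=float)
        if (a + b).sum() == 0:
            return
        swap = np.zeros(len(a), dtype=bool)
        swap[::2] = True
        a2 = np.where(swap, b, a)
        b2 = np.where(swap, a, b)
        # the formula only uses the two sums, so per-SNP label swaps change
        # the sums but Hp must stay symmetric under exchanging both sums
        assert pooled_heterozygosity(a, b) == pytest.approx(
            pooled_heterozygosity(b, a), abs=1e-15)
        assert pooled_heterozygosity(a2, b2) == pytest.approx(
            hp_oracle(a2, b2), abs=1e-15)


class TestSnpFst:
    def _vm_from_genotypes(self, *pops):
        g = np.concatenate(pops, axis=1).astype(np.int8)
        from sweepscan.core_io import VariantMatrix
        return VariantMatrix(
            contig="chr1",
            positions=np.arange(1, g.shape[0] + 1),
            genotypes=g,
            sample_ids=[f"s{i}" for i in range(g.shape[1])],
            quality=np.full(g.shape[0], 60.0),
        )

    def test_complete_differentiation(self):
        a = np.full((1, 10), 0, dtype=np.int8)
        b = np.full((1, 10), 2, dtype=np.int8)
        vm = self._vm_from_genotypes(a, b)
        fst = snp_fst(vm, np.arange(10), np.arange(10, 20))
        assert fst[0] == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_site_undefined(self):
        a = np.zeros((1, 10), dtype=np.int8)
        b = np.zeros((1, 10), dtype=np.int8)
        vm = self._vm_from_genotypes(a, b)
        assert np.isnan(snp_fst(vm, np.arange(10), np.arange(10, 20))[0])

    @pytest.mark.parametrize("pa,pb", [(0.5, 0.5), (0.2, 0.8), (0.1, 0.3)])
    def test_matches_component_oracle(self, pa, pb):
        rng = np.random.default_rng(42)
        ga = rng.binomial(1, pa, (30, 10)) + rng.binomial(1, pa, (30, 10))
        gb = rng.binomial(1, pb, (30, 10)) + rng.binomial(1, pb, (30, 10))
        vm = self._vm_from_genotypes(ga, gb)
        fst = snp_fst(vm, np.arange(10), np.arange(10, 20))
        for i in range(30):
            expected = wc_fst_oracle(ga[i], gb[i])
            if np.isnan(expected):
                assert np.isnan(fst[i])
            else:
                assert fst[i] == pytest.approx(expected, abs=1e-12)

    def test_sample_order_permutation_invariant(self, rng):
        vm = random_matrix(rng, n_snps=30, n_samples=12)
        idx_a, idx_b = np.arange(6), np.arange(6, 12)
        base = snp_fst(vm, idx_a, idx_b)
        perm = snp_fst(vm, rng.permutation(idx_a), rng.permutation(idx_b))
        np.testing.assert_allclose(base, perm, atol=1e-14, equal_nan=True)

    def test_random_split_of_one_population_centres_on_zero(self):
        # ratio-of-sums form: the summed between-population variance
        # component has expectation 0 under exchangeability (the per-SNP
        # ratio estimator itself carries a small negative ratio bias)
        from sweepscan.core_io import VariantMatrix
        from sweepscan.sweep_stats import window_fst
        from sweepscan.windows import assign_snps, make_windows

        rng = np.random.default_rng(7)
        pooled = rng.binomial(2, 0.5, (40, 20)).astype(np.int8)
        vm = VariantMatrix(
            contig="chr1", positions=np.arange(1, 41), genotypes=pooled,
            sample_ids=[f"s{i}" for i in range(20)],
            quality=np.full(40, 60.0))
        wins = assign_snps(make_windows("chr1", 100_000), vm)[:1]
        means = []
        for _ in range(1000):
            perm = rng.permutation(20)
            val = window_fst(vm, wins, perm[:10], perm[10:], min_snps=1,
                             ratio_of_sums=True)
            means.append(val[0])
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se

    def test_hudson_estimator_available(self, rng):
        vm = random_matrix(rng, n_snps=20, n_samples=10)
        fst = snp_fst(vm, np.arange(5), np.arange(5, 10), estimator="hudson")
        assert np.nanmax(fst) <= 1.0 + 1e-12


class TestWindowAggregation:
    def test_window_mean_and_exclusion(self):
        wins = make_windows("chr1", 100_000)
        wins[0].snp_indices = np.array([0, 1])
        wins[1].snp_indices = np.array([2, 3])
        vals = np.array([0.1, 0.3, 0.4, np.nan])
        out = window_mean(vals, wins, min_snps=1)
        assert out[0] == pytest.approx(0.2)
        assert out[1] == pytest.approx(0.4)

    def test_below_min_snps_is_missing(self):
        wins = make_windows("chr1", 100_000)
        wins[0].snp_indices = np.array([0])
        wins[1].snp_indices = np.array([], dtype=int)
        out = window_mean(np.array([1.0]), wins, min_snps=2)
        assert np.isnan(out).all()


class TestThetaPi:
    def test_single_site_unbiased_estimate(self, rng):
        # 4 haplotypes with allele counts 2/2 over a 1-bp window:
        # 2*p*(1-p)*n/(n-1) = 2*0.25*4/3, equal to 4 mismatching pairs / 6
        vm = random_matrix(rng, n_snps=1, n_samples=2)
        vm.genotypes[0] = [1, 1]
        vm.haplotypes[0] = [0, 1, 0, 1]
        wins = make_windows("chr1", 1, size=1, step=1)
        wins[0].snp_indices = np.array([0])
        pi = theta_pi_track(vm, wins[:1], np.array([0, 1]), min_snps=1)
        assert pi[0] == pytest.approx(2 / 3, abs=1e-15)
        assert pi[0] == pytest.approx(
            pi_pairwise_oracle(vm.haplotypes[0].reshape(1, 4).T.reshape(4, 1), 1.0))

    def test_monomorphic_window_zero(self, rng):
        vm = random_matrix(rng, n_snps=5, n_samples=4)
        vm.genotypes[:] = 0
        wins = assign_snps(make_windows("chr1", 1_000_000), vm)
        pi = theta_pi_track(vm, wins, np.arange(4), min_snps=1)
        assert np.nansum(pi) == 0.0

    def test_per_bp_normalisation_halves_with_double_length(self, rng):
        vm = random_matrix(rng, n_snps=20, n_samples=6, span=90_000)
        w1 = make_windows("chr1", 100_000, size=100_000, step=100_000)
        w2 = make_windows("chr1", 200_000, size=200_000, step=200_000)
        assign_snps(w1, vm)
        assign_snps(w2, vm)
        pi1 = theta_pi_track(vm, w1, np.arange(6), min_snps=1)
        pi2 = theta_pi_track(vm, w2, np.arange(6), min_snps=1)
        assert pi2[0] == pytest.approx(pi1[0] / 2)


class TestPiRatio:
    def test_fourfold_ratio_is_exactly_two(self):
        out = pi_ratio_log2(np.array([4e-4]), np.array([1e-4]))
        assert out[0] == pytest.approx(2.0)

    def test_equal_diversity_zero(self):
        assert pi_ratio_log2(np.array([1e-3]), np.array([1e-3]))[0] == 0.0

    def test_zero_denominator_missing_not_inf(self):
        out = pi_ratio_log2(np.array([1e-3, 1e-3]), np.array([0.0, np.nan]))
        assert np.isnan(out).all()

    def test_pseudocount_rescues_zero_denominator(self):
        out = pi_ratio_log2(np.array([1e-3]), np.array([0.0]), pseudocount=1e-6)
        assert np.isfinite(out[0])

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            pi_ratio_log2(np.zeros(3), np.zeros(4))


class TestZTransform:
    def test_hand_example(self):
        z = z_transform(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z, [-1.224744871391589, 0, 1.224744871391589],
                                   atol=1e-12)

    @given(st.floats(-100, 100), st.floats(0.01, 50))
    @settings(deadline=None, max_examples=30)
    def test_affine_invariance(self, shift, scale):
        x = np.array([0.3, -1.2, 4.5, 2.2, -0.7])
        np.testing.assert_allclose(z_transform(x), z_transform(scale * x + shift),
                                   atol=1e-9)

    def test_normalisation_identity_with_missing(self):
        x = np.array([1.0, np.nan, 5.0, 2.0, np.nan, 9.0])
        z = z_transform(x)
        ok = np.isfinite(z)
        assert abs(np.mean(z[ok])) < 1e-12
        assert abs(np.std(z[ok]) - 1) < 1e-12
        assert np.isnan(z[~ok]).all()

    def test_zero_spread_raises_with_name(self):
        with pytest.raises(ValueError, match="mytrack"):
            z_transform(np.array([2.0, 2.0, 2.0]), name="mytrack")


def _track(values, threshold, direction, contig="chr1"):
    wins = make_windows(contig, 50_000 * (len(values) + 1))[: len(values)]
    return ScanTrack(name="t", windows=wins, raw=np.asarray(values, float),
                     threshold=threshold, direction=direction)


class TestSelection:
    def test_strict_less_than(self):
        track = _track([-4.5, -4.0, 3.9, 4.2], -4.0, "less")
        cand = select_candidates(track)
        assert {s for _, s in cand.keys} == {0}

    def test_strict_greater_than(self):
        track = _track([0.69, 0.7, 0.71], 0.7, "greater")
        cand = select_candidates(track)
        assert {s for _, s in cand.keys} == {100_000}

    def test_all_missing_empty(self):
        track = _track([np.nan, np.nan], 0.0, "greater")
        assert len(select_candidates(track)) == 0


class TestCombineEvidence:
    def _cs(self, name, starts):
        keys = {("chr1", s) for s in starts}
        return CandidateSet(keys=keys, provenance={k: [name] for k in keys},
                            name=name)

    def test_pairwise_intersection(self):
        out = combine_evidence([self._cs("a", [0, 1]), self._cs("b", [1, 2])], 2)
        assert out.keys == {("chr1", 1)}
        assert out.provenance[("chr1", 1)] == ["a", "b"]

    def test_four_method_window(self):
        sets = [self._cs(n, [5]) for n in "abcd"]
        out = combine_evidence(sets, 2)
        assert out.provenance[("chr1", 5)] == ["a", "b", "c", "d"]

    def test_min_methods_one_is_union(self):
        sets = [self._cs("a", [0]), self._cs("b", [7])]
        assert combine_evidence(sets, 1).keys == {("chr1", 0), ("chr1", 7)}

    def test_min_methods_len_is_intersection(self):
        sets = [self._cs("a", [0, 1]), self._cs("b", [1]), self._cs("c", [1, 2])]
        assert combine_evidence(sets, 3).keys == {("chr1", 1)}

    def test_bad_min_methods(self):
        with pytest.raises(ValueError):
            combine_evidence([], 0)


class TestOracleEquivalenceRandomFixtures:
    """Hp, window theta-pi and window FST vs explicit double-loop oracles."""

    def test_randomised_50_snp_fixtures(self, rng):
        for _ in range(10):
            vm = random_matrix(rng, n_snps=50, n_samples=16, span=200_000)
            wins = assign_snps(make_windows("chr1", 200_000), vm)
            idx_a, idx_b = np.arange(8), np.arange(8, 16)

            nmaj, nmin = major_minor_counts(vm, idx_a)
            hp = hp_track(vm, wins, idx_a, min_snps=1)
            pi = theta_pi_track(vm, wins, idx_a, min_snps=1)
            fst = snp_fst(vm, idx_a, idx_b)
            for wi, w in enumerate(wins):
                idx = w.snp_indices
                if len(idx) == 0:
                    continue
                assert hp[wi] == pytest.approx(
                    hp_oracle(nmaj[idx], nmin[idx]), abs=1e-12)
                hap_a = vm.haplotypes[np.ix_(idx, np.arange(16))].T
                assert pi[wi] == pytest.approx(
                    pi_pairwise_oracle(hap_a, w.end - w.start), abs=1e-12)
                oracle_fst = [
                    wc_fst_oracle(vm.genotypes[i, idx_a], vm.genotypes[i, idx_b])
                    for i in idx
                ]
                mine = fst[idx]
                for o, m in zip(oracle_fst, mine):
                    if np.isnan(o):
                        assert np.isnan(m)
                    else:
                        assert m == pytest.approx(o, abs=1e-12)
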