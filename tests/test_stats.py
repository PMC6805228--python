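"""Population-genetic statistics against brute-force oracles and
closed-form cases."""

import numpy as np
import pytest

from altiscan import (
    block_jackknife,
    f3_statistic,
    genotype_r2,
    patterson_d,
    pooled_heterozygosity,
    tajimas_d,
    theta_pi_ratio,
    wc_fst,
    wc_fst_components,
    window_pi,
    zhp_transform,
)
from altiscan.matrix import MISSING
from altiscan.windows import Window, assign_sites

import oracles
from conftest import make_matrix


def window_over(matrix, start=1, end=None):
    end = end or int(matrix.positions[-1])
    w = Window("chr1", start, end)
    assign_sites([w], matrix, min_snps=1)
    return w


ALL = slice(None)


class TestWindowPi:
    def test_no_segregating_sites_zero(self):
        m = make_matrix([[0, 0, 0], [2, 2, 2]])
        w = window_over(m)
        idx = np.arange(3)
        assert window_pi(m, w, idx) == 0.0

    def test_hand_case_two_two_counts(self):
        # one site, 4 haplotypes with counts 2/2 over a 100 bp window
        m = make_matrix([[1, 1]], positions=[50])
        w = Window("chr1", 1, 100)
        assign_sites([w], m, min_snps=1)
        pi = window_pi(m, w, np.arange(2))
        assert pi == pytest.approx((8 / 12) / 100)
        assert pi == pytest.approx(
            oracles.window_pi_bruteforce([(2, 2)], 100), abs=1e-15
        )

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(25):
            n_sites = rng.integers(1, 20)
            n_samp = rng.integers(2, 8)
            d = rng.integers(0, 3, (n_sites, n_samp)).astype(np.int8)
            m = make_matrix(d, positions=np.arange(1, n_sites + 1) * 7)
            w = Window("chr1", 1, 500)
            assign_sites([w], m, min_snps=1)
            counts = [
                (int(2 * n_samp - d[i].sum()), int(d[i].sum()))
                for i in range(n_sites)
            ]
            assert window_pi(m, w, np.arange(n_samp)) == pytest.approx(
                oracles.window_pi_bruteforce(counts, 500), abs=1e-12
            )

    def test_invariance_to_sample_order_and_allele_swap(self, rng):
        d = rng.integers(0, 3, (10, 6)).astype(np.int8)
        m = make_matrix(d)
        w = window_over(m)
        base = window_pi(m, w, np.arange(6))
        perm = rng.permutation(6)
        assert window_pi(m, w, perm) == pytest.approx(base, abs=1e-15)
        m2 = make_matrix((2 - d).astype(np.int8), positions=m.positions)
        assert window_pi(m2, window_over(m2), np.arange(6)) == pytest.approx(
            base, abs=1e-15
        )


class TestThetaPiRatio:
    def test_equal_diversities_give_one(self):
        assert theta_pi_ratio(0.004, 0.004) == 1.0

    def test_zero_denominator_is_missing(self):
        assert np.isnan(theta_pi_ratio(0.004, 0.0))

    def test_arithmetic(self):
        assert theta_pi_ratio(0.004, 0.001) == pytest.approx(4.0)


class TestPooledHeterozygosity:
    def test_balanced_sites_give_half(self):
        m = make_matrix([[1, 1], [1, 1]])  # 50/50 at each site
        assert pooled_heterozygosity(m, window_over(m), np.arange(2)) == 0.5

    def test_printed_formula_case(self):
        # (nMAJ, nMIN) = (18, 2) and (16, 4): Hp = 2*34*6/40^2 = 0.255
        d = np.zeros((2, 10), dtype=np.int8)
        d[0, 0] = 2          # 2 ALT of 20 alleles
        d[1, :4] = 1         # 4 ALT of 20
        m = make_matrix(d)
        hp = pooled_heterozygosity(m, window_over(m), np.arange(10))
        assert hp == pytest.approx(0.255)
        assert hp == pytest.approx(oracles.hp_bruteforce([(18, 2), (16, 4)]))

    def test_monomorphic_window_zero(self):
        m = make_matrix([[0, 0, 0], [2, 2, 2]])
        assert pooled_heterozygosity(m, window_over(m), np.arange(3)) == 0.0


class TestZHp:
    def test_three_window_standardisation(self):
        out = zhp_transform(np.array([0.1, 0.2, 0.3]))
        assert out == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            zhp_transform(np.array([0.2, 0.2, 0.2]))

    def test_output_standardised(self, rng):
        hp = rng.uniform(0, 0.5, 50)
        z = zhp_transform(hp)
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_nan_windows_propagate(self):
        z = zhp_transform(np.array([0.1, np.nan, 0.3]))
        assert np.isnan(z[1]) and not np.isnan(z[0])


class TestWCFst:
    def test_fixed_difference_is_one(self):
        d = np.array([[0, 0, 0, 2, 2, 2]], dtype=np.int8)
        m = make_matrix(d)
        theta, weighted = wc_fst(m, window_over(m), np.arange(3), np.arange(3, 6))
        assert theta[0] == pytest.approx(1.0)
        assert weighted == pytest.approx(1.0)

    def test_shared_monomorphic_site_skipped(self):
        m = make_matrix([[0, 0, 0, 0]])
        theta, weighted = wc_fst(m, window_over(m), np.arange(2), np.arange(2, 4))
        assert np.isnan(theta[0]) and np.isnan(weighted)

    def test_constructed_counts_match_oracle(self):
        # pop1: 8 REF / 2 ALT alleles with 2 hets; pop2 mirrored
        d = np.array([[1, 1, 0, 0, 0, 1, 1, 2, 2, 2]], dtype=np.int8)
        m = make_matrix(d)
        idx1, idx2 = np.arange(5), np.arange(5, 10)
        a, b, c = wc_fst_components(m, np.array([0]), idx1, idx2)
        oa, ob, oc = oracles.wc_fst_site_bruteforce(
            5, 0.2, 0.4, 5, 0.8, 0.4
        )
        assert (a[0], b[0], c[0]) == pytest.approx((oa, ob, oc), abs=1e-12)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(30):
            n1, n2 = rng.integers(2, 9, 2)
            d = np.concatenate(
                [rng.integers(0, 3, (6, n1)), rng.integers(0, 3, (6, n2))], axis=1
            ).astype(np.int8)
            m = make_matrix(d)
            idx1, idx2 = np.arange(n1), np.arange(n1, n1 + n2)
            a, b, c = wc_fst_components(m, np.arange(6), idx1, idx2)
            for i in range(6):
                p1 = d[i, :n1].sum() / (2 * n1)
                p2 = d[i, n1:].sum() / (2 * n2)
                if p1 in (0.0, 1.0) and p2 == p1:
                    assert np.isnan(a[i])
                    continue
                oa, ob, oc = oracles.wc_fst_site_bruteforce(
                    int(n1), p1, (d[i, :n1] == 1).mean(),
                    int(n2), p2, (d[i, n1:] == 1).mean(),
                )
                assert (a[i], b[i], c[i]) == pytest.approx((oa, ob, oc), abs=1e-10)

    def test_weighted_never_above_one(self, rng):
        for _ in range(10):
            d = rng.integers(0, 3, (15, 8)).astype(np.int8)
            m = make_matrix(d)
            _, weighted = wc_fst(m, window_over(m), np.arange(4), np.arange(4, 8))
            if not np.isnan(weighted):
                assert weighted <= 1.0


class TestTajimasD:
    def test_two_haplotypes_give_zero(self):
        m = make_matrix([[1], [1], [1]])  # het sites, n = 2 haplotypes
        d = tajimas_d(m, window_over(m), np.array([0]))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_no_segregating_sites_missing(self):
        m = make_matrix([[0, 0], [2, 2]])
        assert np.isnan(tajimas_d(m, window_over(m), np.arange(2)))

    def test_matches_oracle_n10(self, rng):
        for _ in range(20):
            d = rng.integers(0, 3, (rng.integers(2, 25), 5)).astype(np.int8)
            m = make_matrix(d, positions=np.arange(1, len(d) + 1) * 3)
            counts = [(int(10 - row.sum()), int(row.sum())) for row in d]
            expect = oracles.tajimas_d_bruteforce(counts, 10)
            got = tajimas_d(m, window_over(m), np.arange(5))
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-10)

    def test_modal_n_drops_other_sites(self):
        # one site with a missing call has n = 8; modal n = 10
        d = np.array([[1, 1, 0, 0, 2], [1, MISSING, 0, 0, 2], [1, 0, 1, 0, 2]],
                     dtype=np.int8)
        m = make_matrix(d)
        counts = [(6, 4), (6, 4)]  # only the two full-data sites
        expect = oracles.tajimas_d_bruteforce(counts, 10)
        assert tajimas_d(m, window_over(m), np.arange(5)) == pytest.approx(
            expect, abs=1e-10
        )


class TestPattersonD:
    def test_equal_p1_p2_gives_zero(self, rng):
        p = rng.uniform(0, 1, 50)
        p3 = rng.uniform(0, 1, 50)
        res = patterson_d(p, p, p3, np.zeros(50), block_size_snps=10)
        assert res.d == pytest.approx(0.0, abs=1e-12)

    def test_single_abba_site(self):
        res = patterson_d([0.0], [1.0], [1.0], [0.0])
        assert res.d == pytest.approx(1.0)
        assert np.isnan(res.z)  # single block -> no SE

    def test_two_site_hand_sum(self):
        freqs = [(0.2, 0.8, 0.9, 0.0), (0.6, 0.1, 0.5, 0.1)]
        res = patterson_d(*map(np.array, zip(*freqs)))
        assert res.d == pytest.approx(oracles.patterson_d_bruteforce(freqs), abs=1e-12)

    def test_matches_oracle_random(self, rng):
        p = rng.uniform(0, 1, (4, 200))
        res = patterson_d(*p, block_size_snps=50)
        expect = oracles.patterson_d_bruteforce(list(zip(*p)))
        assert res.d == pytest.approx(expect, abs=1e-10)
        assert res.n_blocks == 4


class TestF3:
    def test_identical_tracks_zero_uncorrected(self):
        p = np.full(20, 0.4)
        res = f3_statistic(p, p, p, correction=False)
        assert res.f3 == pytest.approx(0.0, abs=1e-15)

    def test_single_site_hand_value(self):
        res = f3_statistic([0.5], [0.0], [1.0], correction=False)
        assert res.f3 == pytest.approx(-0.25)

    def test_correction_matches_oracle(self, rng):
        pc, pa, pb = rng.uniform(0.05, 0.95, (3, 100))
        nc = rng.integers(4, 40, 100)
        res = f3_statistic(pc, pa, pb, nc_alleles=nc, block_size_snps=25)
        expect = oracles.f3_bruteforce(list(zip(pc, pa, pb)), list(nc))
        assert res.f3 == pytest.approx(expect, abs=1e-10)

    def test_admixed_target_negative(self, rng):
        """f3(C; A, B) < 0 when C is a 50/50 mixture of diverged A and B."""
        neg = 0
        for k in range(20):
            r = np.random.default_rng(1000 + k)
            anc = r.uniform(0.1, 0.9, 400)
            # A and B drift far apart, C is their average plus sampling noise
            pa = np.clip(anc + r.normal(0, 0.25, 400), 0, 1)
            pb = np.clip(anc - r.normal(0, 0.25, 400), 0, 1)
            nC = 40
            pc = r.binomial(nC, (pa + pb) / 2) / nC
            res = f3_statistic(pc, pa, pb, nc_alleles=np.full(400, nC),
                               block_size_snps=100)
            neg += res.f3 < 0
        assert neg >= 19


class TestBlockJackknife:
    def test_identical_blocks_no_z(self):
        comps = np.array([[2.0, 1.0]] * 4)
        est, se, z = block_jackknife(comps, lambda v: v[0] / v[1])
        assert est == 2.0 and se == 0.0 and np.isnan(z)

    def test_delete_one_formula(self):
        # delete-one estimates are 3, 4, 5: spread identical to (1, 2, 3)
        comps = np.array([[3.0], [2.0], [1.0]])
        est, se, z = block_jackknife(comps, lambda v: v[0])
        assert se == pytest.approx(np.sqrt((2 / 3) * 2))
        o_est, o_se, o_z = oracles.jackknife_bruteforce(
            comps.tolist(), lambda v: v[0]
        )
        assert (est, se, z) == pytest.approx((o_est, o_se, o_z))

    def test_linear_statistic_mean_identity(self, rng):
        """For the mean, the full estimate equals the average of the
        delete-one estimates."""
        x = rng.normal(size=8)
        comps = np.column_stack([x, np.ones(8)])
        est, _, _ = block_jackknife(comps, lambda v: v[0] / v[1])
        deleted = [(x.sum() - xi) / 7 for xi in x]
        assert est == pytest.approx(np.mean(deleted), abs=1e-12)

    def test_single_block_gives_nan_se(self):
        est, se, z = block_jackknife(np.array([[4.0]]), lambda v: v[0])
        assert est == 4.0 and np.isnan(se) and np.isnan(z)


class TestGenotypeR2:
    def test_identical_vectors_one(self):
        assert genotype_r2([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)

    def test_constant_vector_missing(self):
        assert np.isnan(genotype_r2([1, 1, 1, 1], [0, 1, 2, 0]))

    def test_hand_computation(self):
        x, y = [0, 1, 2, 0], [0, 1, 1, 0]
        assert genotype_r2(x, y) == pytest.approx(
            oracles.r2_bruteforce([float(v) for v in x], [float(v) for v in y]),
            abs=1e-12,
        )

    def test_missing_excluded_pairwise(self):
        x = np.array([0, 1, 2, MISSING, 2], dtype=np.int8)
        y = np.array([0, 1, 2, 2, MISSING], dtype=np.int8)
        assert genotype_r2(x, y) == pytest.approx(
            oracles.r2_bruteforce([0, 1, 2], [0, 1, 2]), abs=1e-12
        )
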