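"""Unit, oracle and property tests for the selection statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsel.errors import DataError
from mirsel import popgen
from mirsel.popgen import (
    WindowStats,
    clr_scan,
    ehh,
    fay_wu_h,
    fst_many,
    fst_per_snp,
    genome_percentile_threshold,
    ihs_scan,
    standardize_ihs,
    unfolded_sfs,
)
from tests.conftest import build_panel


# ---------------------------------------------------------------------------
# oracles (independent transcriptions of the definitions)
# ---------------------------------------------------------------------------


def wc_theta_oracle(derived, sizes):
    """Weir-Cockerham theta via the a/b variance-component form (haploid),
    written independently of the MSP/MSG production code path."""
    derived = np.asarray(derived, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    r = len(sizes)
    p = derived / sizes
    nbar = sizes.mean()
    nc = (r * nbar - (sizes**2).sum() / (r * nbar)) / (r - 1)
    pbar = (sizes * p).sum() / (r * nbar)
    # between- and within-population components, combined as a/(a+b)
    msp = (sizes * (p - pbar) ** 2).sum() / (r - 1)
    msg = (sizes * p * (1 - p)).sum() / (sizes - 1).sum()
    a = (msp - msg) / nc
    b = msg
    denom = a + b
    return np.nan if denom == 0 else a / denom


def ehh_pairwise_oracle(hap):
    """EHH at the last column of ``hap`` = share of identical row pairs."""
    c = hap.shape[0]
    same = 0
    for i in range(c):
        for j in range(i + 1, c):
            if (hap[i] == hap[j]).all():
                same += 1
    return same / (c * (c - 1) / 2)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


class TestFst:
    def test_no_differentiation(self):
        theta = fst_per_snp([50, 50], [100, 100])
        assert abs(theta) < 0.02

    def test_fixed_alternate_alleles(self):
        assert fst_per_snp([0, 100], [100, 100]) == pytest.approx(1.0)

    def test_against_independent_transcription(self):
        theta = fst_per_snp([30, 70], [100, 100])
        assert theta == pytest.approx(wc_theta_oracle([30, 70], [100, 100]), rel=1e-12)

    def test_monomorphic_undefined_not_zero(self):
        assert np.isnan(fst_per_snp([0, 0], [100, 100]))
        assert np.isnan(fst_per_snp([100, 50], [100, 50]))

    def test_needs_two_populations(self):
        with pytest.raises(DataError):
            fst_per_snp([5], [10])

    @settings(max_examples=200, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(2, 200), st.floats(0.0, 1.0)), min_size=2, max_size=6
        )
    )
    def test_oracle_equivalence_random(self, data):
        sizes = np.array([n for n, _ in data], dtype=float)
        derived = np.array([round(n * f) for (n, _), f in zip(data, (f for _, f in data))])
        ours = fst_many(derived[None, :].astype(float), sizes)[0]
        oracle = wc_theta_oracle(derived, sizes)
        if np.isnan(oracle):
            assert np.isnan(ours)
        else:
            assert ours == pytest.approx(oracle, rel=1e-10, abs=1e-12)

    def test_fst_at_most_one(self, rng):
        counts = rng.integers(0, 51, size=(500, 3)).astype(float)
        theta = fst_many(counts, np.array([50.0, 50.0, 50.0]))
        assert np.nanmax(theta) <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# SFS + Fay-Wu H
# ---------------------------------------------------------------------------


class TestSfs:
    def test_single_snp_count(self):
        matrix = np.zeros((4, 1), dtype=np.int8)
        matrix[:3, 0] = 1
        panel = build_panel(matrix)
        stats = unfolded_sfs(panel)
        assert stats.sfs[3] == 1
        assert stats.sfs.sum() == 1

    def test_sum_equals_segregating_sites(self, two_pop_panel):
        stats = unfolded_sfs(two_pop_panel)
        n = two_pop_panel.n_haplotypes
        counts = two_pop_panel.haplotypes.sum(axis=0)
        seg = np.count_nonzero((counts > 0) & (counts < n))
        assert stats.n_segregating == seg

    def test_brute_force_tally(self, rng):
        for _ in range(20):
            matrix = (rng.random((8, 15)) < rng.random()).astype(np.int8)
            panel = build_panel(matrix)
            stats = unfolded_sfs(panel)
            expected = np.zeros(9, dtype=int)
            for j in range(15):
                c = int(matrix[:, j].sum())
                if 0 < c < 8:
                    expected[c] += 1
            np.testing.assert_array_equal(stats.sfs, expected)

    def test_window_without_polarized_flagged(self):
        matrix = np.array([[0, 1], [1, 0], [0, 1], [1, 1]], dtype=np.int8)
        panel = build_panel(matrix)
        stats = unfolded_sfs(panel, window=(10_000, 20_000))
        assert stats.no_polarized
        assert stats.sfs.sum() == 0


class TestFayWuH:
    def test_no_segregating_sites(self):
        w = WindowStats("1", 0, 10, 4, np.zeros(5, dtype=int))
        h, pi, th = fay_wu_h(w)
        assert h == 0 and pi == 0 and th == 0

    def test_low_frequency_derived(self):
        # n=4, one site with derived count 1: pi=0.5, theta_H=1/6
        w = WindowStats("1", 0, 10, 4, np.array([0, 1, 0, 0, 0]))
        h, pi, th = fay_wu_h(w)
        assert pi == pytest.approx(0.5)
        assert th == pytest.approx(1 / 6)
        assert h == pytest.approx(1 / 3)

    def test_high_frequency_derived_negative(self):
        w = WindowStats("1", 0, 10, 4, np.array([0, 0, 0, 1, 0]))
        h, pi, th = fay_wu_h(w)
        assert pi == pytest.approx(0.5)
        assert th == pytest.approx(1.5)
        assert h == pytest.approx(-1.0)

    def test_definitional_sums_random(self, rng):
        n = 10
        sfs = np.zeros(n + 1, dtype=int)
        sfs[1:n] = rng.integers(0, 5, size=n - 1)
        w = WindowStats("1", 0, 10, n, sfs)
        h, pi, th = fay_wu_h(w)
        pi_o = sum(sfs[i] * 2 * i * (n - i) for i in range(1, n)) / (n * (n - 1))
        th_o = sum(sfs[i] * 2 * i * i for i in range(1, n)) / (n * (n - 1))
        assert pi == pytest.approx(pi_o, rel=1e-12)
        assert th == pytest.approx(th_o, rel=1e-12)
        assert h == pytest.approx(pi_o - th_o, rel=1e-12)

    def test_haplotype_permutation_invariance(self, rng, two_pop_panel):
        h0, _, _ = fay_wu_h(unfolded_sfs(two_pop_panel))
        perm = rng.permutation(two_pop_panel.n_haplotypes)
        shuffled = build_panel(
            two_pop_panel.haplotypes[perm],
            positions=[s.pos for s in two_pop_panel.snps],
            populations=["pop1"] * 10 + ["pop2"] * 10,
        )
        h1, _, _ = fay_wu_h(unfolded_sfs(shuffled))
        assert h0 == pytest.approx(h1)


# ---------------------------------------------------------------------------
# EHH / iHS
# ---------------------------------------------------------------------------


class TestEhh:
    def test_ehh_at_zero_distance_is_one(self, two_pop_panel):
        curve = ehh(two_pop_panel, 15, "derived", max_distance=10_000)
        assert curve.grid()[len(curve.left), 1] == 1.0

    def test_identical_carriers_stay_one(self):
        matrix = np.tile(np.array([1, 0, 1, 1, 0, 1], dtype=np.int8), (6, 1))
        panel = build_panel(matrix)
        curve = ehh(panel, 0, "derived", max_distance=10_000)
        assert (curve.right[:, 1] == 1.0).all()

    def test_two_two_split(self):
        # 4 derived carriers splitting 2/2 at the next SNP: EHH = 2/6
        matrix = np.array(
            [
                [1, 0],
                [1, 0],
                [1, 1],
                [1, 1],
                [0, 0],
                [0, 1],
            ],
            dtype=np.int8,
        )
        panel = build_panel(matrix)
        curve = ehh(panel, 0, "derived", max_distance=10_000)
        assert curve.right[0, 1] == pytest.approx(1 / 3)
        carriers = matrix[matrix[:, 0] == 1]
        assert curve.right[0, 1] == pytest.approx(ehh_pairwise_oracle(carriers))

    def test_monotone_non_increasing(self, rng):
        for _ in range(10):
            matrix = (rng.random((12, 20)) < 0.5).astype(np.int8)
            matrix[:6, 10] = 1
            matrix[6:, 10] = 0
            panel = build_panel(matrix)
            curve = ehh(panel, 10, "derived", max_distance=10_000)
            for arm in (curve.left, curve.right):
                if arm.size:
                    assert (np.diff(arm[:, 1]) <= 1e-12).all()

    def test_pairwise_oracle_random(self, rng):
        for _ in range(25):
            matrix = (rng.random((10, 8)) < 0.5).astype(np.int8)
            matrix[:5, 0] = 1
            matrix[5:, 0] = 0
            panel = build_panel(matrix)
            curve = ehh(panel, 0, "derived", max_distance=10_000)
            carriers = matrix[matrix[:, 0] == 1]
            for k in range(curve.right.shape[0]):
                assert curve.right[k, 1] == pytest.approx(
                    ehh_pairwise_oracle(carriers[:, : k + 2]), rel=1e-12
                )

    def test_row_order_invariance(self, rng, two_pop_panel):
        curve = ehh(two_pop_panel, 15, "derived")
        perm = rng.permutation(two_pop_panel.n_haplotypes)
        shuffled = build_panel(
            two_pop_panel.haplotypes[perm],
            positions=[s.pos for s in two_pop_panel.snps],
            populations=["pop1"] * 10 + ["pop2"] * 10,
        )
        curve2 = ehh(shuffled, 15, "derived")
        assert curve.ihh == pytest.approx(curve2.ihh, rel=1e-12)

    def test_fewer_than_two_carriers_is_error(self):
        matrix = np.zeros((4, 3), dtype=np.int8)
        matrix[0, 1] = 1
        panel = build_panel(matrix)
        with pytest.raises(DataError, match="carriers"):
            ehh(panel, 1, "derived")


class TestIhs:
    def test_symmetric_decay_gives_zero(self):
        # derived and ancestral carrier sets with mirrored haplotypes
        block = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1]], dtype=np.int8)
        matrix = np.zeros((8, 7), dtype=np.int8)
        matrix[:4, 3] = 1
        matrix[:4, :3] = block[:, :3]
        matrix[:4, 4:] = block[:, :3]
        matrix[4:, :3] = block[:, :3]
        matrix[4:, 4:] = block[:, :3]
        panel = build_panel(matrix)
        df = ihs_scan(panel, min_maf=0.0, n_bins=1)
        row = df[df["snp_id"] == "snp3"]
        assert row["unstandardized"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_standardized_scores_centered(self, rng):
        df = ihs_scan(
            build_panel((rng.random((40, 60)) < rng.random(60)).astype(np.int8)),
            n_bins=4,
        )
        for _, grp in df.dropna(subset=["ihs"]).groupby("bin"):
            if len(grp) >= 2 and grp["unstandardized"].std(ddof=0) > 0:
                assert abs(grp["ihs"].mean()) < 1e-6
                assert abs(grp["ihs"].std(ddof=0) - 1) < 1e-3

    def test_standardize_empty_frame(self):
        import pandas as pd

        out = standardize_ihs(pd.DataFrame(columns=["derived_freq", "unstandardized"]))
        assert len(out) == 0 and "ihs" in out.columns


# ---------------------------------------------------------------------------
# CLR
# ---------------------------------------------------------------------------


class TestClr:
    def _neutral_panel(self, rng, n_snps=80):
        matrix = (rng.random((30, n_snps)) < rng.uniform(0.1, 0.9, n_snps)).astype(np.int8)
        keep = (matrix.sum(0) > 0) & (matrix.sum(0) < 30)
        matrix = matrix[:, keep]
        positions = np.sort(rng.choice(np.arange(1, 500_000), matrix.shape[1], replace=False))
        return build_panel(matrix, positions=positions)

    def test_neutral_limit_gives_zero(self, rng):
        panel = self._neutral_panel(rng)
        df = clr_scan(panel, alpha_grid=(np.inf,), grid_positions=np.linspace(0, 500_000, 5))
        assert (df["clr"] == 0.0).all()

    def test_clr_non_negative(self, rng):
        panel = self._neutral_panel(rng)
        df = clr_scan(panel, grid_positions=np.linspace(0, 500_000, 8))
        assert (df["clr"] >= -1e-9).all()

    def test_sweep_mixture_row_n_is_background(self, rng):
        q = rng.random(9)
        q /= q.sum()
        a = popgen._sweep_mixture_matrix(q, 10)
        np.testing.assert_allclose(a[10, 1:10], q, rtol=1e-12, atol=1e-12)
        assert a[10, 0] == pytest.approx(0.0, abs=1e-12)
        # every row is a probability distribution over counts 0..n
        np.testing.assert_allclose(a.sum(axis=1), 1.0, rtol=1e-9)

    def test_empty_background_is_error(self):
        matrix = np.zeros((4, 2), dtype=np.int8)
        matrix[0, 0] = 1
        matrix[1, 1] = 1
        panel = build_panel(matrix, ancestral=None)
        with pytest.raises(DataError):
            clr_scan(panel)


# ---------------------------------------------------------------------------
# empirical thresholds
# ---------------------------------------------------------------------------


class TestGenomePercentileThreshold:
    def test_interpolated_between_order_stats(self):
        threshold = genome_percentile_threshold(np.arange(1, 101), 0.05)
        assert 5 < threshold < 6

    def test_all_equal(self):
        assert genome_percentile_threshold(np.full(30, 2.5), 0.05) == 2.5

    def test_matches_sorting_brute_force(self, rng):
        values = rng.normal(size=200)
        for q in (0.01, 0.05, 0.5, 0.95):
            assert genome_percentile_threshold(values, q) == pytest.approx(
                float(np.quantile(np.sort(values), q))
            )

    def test_too_few_values(self):
        with pytest.raises(DataError):
            genome_percentile_threshold([1.0] * 5, 0.05)
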