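"""Oracle and property tests for the haplotype selection statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rooscan import hapstats
from rooscan.hapstats import (
    HaplotypeMatrix,
    SiteFilterSpec,
    apply_site_filter,
    ehh,
    h12_scan,
    haplotype_spectrum,
    ihh,
    ihs_scan,
    nsl_scan,
    nucleotide_diversity,
    segregating_sites,
    tajimas_d,
    xpehh_scan,
    xpehh_unstandardized,
)

from conftest import random_matrix
from oracles import (
    ehh_bruteforce,
    h_stats_bruteforce,
    pi_bruteforce,
    tajimas_d_oracle,
)


# ---------------------------------------------------------------------------
# matrix construction and filtering
# ---------------------------------------------------------------------------

class TestMatrixAndFilter:
    def test_rejects_unordered_positions(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            HaplotypeMatrix(np.zeros((2, 2), dtype=np.int8), [5, 3])

    def test_rejects_single_haplotype(self):
        with pytest.raises(ValueError):
            HaplotypeMatrix(np.zeros((1, 2), dtype=np.int8), [1, 2])

    def test_monomorphic_sites_removed(self):
        hm = HaplotypeMatrix(
            np.array([[0, 1, 1], [0, 0, 1], [0, 1, 1]], dtype=np.int8),
            [10, 20, 30],
        )
        out = apply_site_filter(hm, SiteFilterSpec(maf_threshold=0.0))
        assert out.positions.tolist() == [20]  # cols 1,3 monomorphic

    def test_singleton_kept_at_default_threshold(self):
        # n=25 haploids: singleton MAF 0.04 >= default 1/(2*25) = 0.02
        alleles = np.zeros((25, 1), dtype=np.int8)
        alleles[0, 0] = 1
        hm = HaplotypeMatrix(alleles, [100])
        assert apply_site_filter(hm).n_sites == 1

    def test_indels_dropped(self):
        hm = HaplotypeMatrix(
            np.array([[0, 1], [1, 0], [0, 1]], dtype=np.int8), [10, 20]
        )
        out = apply_site_filter(hm, variant_kinds=["snp", "indel"])
        assert out.positions.tolist() == [10]


# ---------------------------------------------------------------------------
# S, pi, Tajima's D
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_all_zero_matrix_has_no_segregating_sites(self):
        hm = HaplotypeMatrix(np.zeros((3, 4), dtype=np.int8), [1, 2, 3, 4])
        assert segregating_sites(hm) == 0

    def test_segregating_sites_small(self):
        hm = HaplotypeMatrix(
            np.array([[0, 0], [0, 1], [1, 1]], dtype=np.int8), [1, 2]
        )
        assert segregating_sites(hm) == 2

    def test_pi_identical_haplotypes(self):
        hm = HaplotypeMatrix(np.ones((4, 3), dtype=np.int8), [1, 2, 3])
        assert nucleotide_diversity(hm) == 0.0

    def test_pi_two_haplotypes_two_differences(self):
        hm = HaplotypeMatrix(np.array([[0, 0], [1, 1]], dtype=np.int8), [1, 2])
        assert nucleotide_diversity(hm) == pytest.approx(2.0)

    def test_pi_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(100):
            hm = random_matrix(rng, int(rng.integers(2, 12)), int(rng.integers(1, 25)))
            assert nucleotide_diversity(hm) == pytest.approx(
                pi_bruteforce(hm), abs=1e-10
            )

    def test_tajimas_d_undefined_without_segregating_sites(self):
        hm = HaplotypeMatrix(np.zeros((4, 2), dtype=np.int8), [1, 2])
        with pytest.warns(UserWarning):
            assert np.isnan(tajimas_d(hm))

    def test_tajimas_d_matches_oracle_on_fixture(self, small_matrix):
        assert tajimas_d(small_matrix) == pytest.approx(
            tajimas_d_oracle(small_matrix), abs=1e-12
        )

    def test_tajimas_d_matches_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            hm = random_matrix(rng, int(rng.integers(4, 15)), int(rng.integers(2, 30)))
            assert tajimas_d(hm) == pytest.approx(tajimas_d_oracle(hm), abs=1e-12)


# ---------------------------------------------------------------------------
# EHH / iHH / iHS / nSL / XP-EHH
# ---------------------------------------------------------------------------

class TestEHH:
    def test_ehh_is_one_at_core(self, small_matrix):
        prof = ehh(small_matrix, core_site=4, allele=1)
        assert prof.left[0, 1] == 1.0
        assert prof.right[0, 1] == 1.0

    def test_ehh_two_two_split_is_one_third(self):
        # 4 derived carriers split 2/2 at the next site: (1+1)/C(4,2) = 1/3
        alleles = np.array([
            [1, 0], [1, 0], [1, 1], [1, 1], [0, 0], [0, 1],
        ], dtype=np.int8)
        hm = HaplotypeMatrix(alleles, [100, 200])
        prof = ehh(hm, core_site=0, allele=1)
        assert prof.right[1, 1] == pytest.approx(1 / 3)

    def test_ehh_identical_carriers_never_decay(self):
        alleles = np.vstack([np.tile([1, 0, 1, 1, 0], (4, 1)),
                             np.array([[0, 1, 0, 0, 1]] * 2, dtype=np.int8)])
        hm = HaplotypeMatrix(alleles.astype(np.int8), [10, 20, 30, 40, 50])
        prof = ehh(hm, core_site=2, allele=1)
        assert (prof.left[:, 1] == 1.0).all()
        assert (prof.right[:, 1] == 1.0).all()
        # reaches both window edges
        assert prof.left.shape[0] == 3 and prof.right.shape[0] == 3

    def test_ehh_matches_bruteforce(self, rng):
        for _ in range(25):
            hm = random_matrix(rng, 8, 12)
            core = 6
            for allele in (0, 1):
                if (hm.alleles[:, core] == allele).sum() < 2:
                    continue
                prof = ehh(hm, core, allele, decay_cutoff=0.0, max_gap=None)
                for d, e in prof.right[1:]:
                    x = core + np.flatnonzero(
                        hm.positions[core:] - hm.positions[core] == d
                    )[0]
                    assert e == pytest.approx(
                        ehh_bruteforce(hm, core, allele, x), abs=1e-10
                    )

    def test_ehh_monotone_nonincreasing(self, rng):
        for _ in range(25):
            hm = random_matrix(rng, 10, 15)
            prof = ehh(hm, 7, 1) if hm.alleles[:, 7].sum() >= 2 else None
            if prof is None:
                continue
            for side in (prof.left, prof.right):
                assert (np.diff(side[:, 1]) <= 1e-12).all()

    def test_ehh_requires_two_carriers(self):
        alleles = np.array([[1, 0], [0, 0], [0, 1]], dtype=np.int8)
        hm = HaplotypeMatrix(alleles, [1, 2])
        with pytest.raises(ValueError, match="fewer than 2"):
            ehh(hm, 0, 1)


class TestIHH:
    def test_rectangle_profile(self):
        from rooscan.hapstats import EHHProfile
        right = np.array([[0.0, 1.0], [500.0, 1.0], [501.0, 0.0]])
        left = np.array([[0.0, 1.0]])
        prof = EHHProfile(0, 1, left, right, 4)
        # trapezoid: 500 * 1 + 1 * 0.5
        assert ihh(prof) == pytest.approx(500.5)

    def test_matches_numerical_oracle(self, rng):
        from rooscan.hapstats import EHHProfile
        d = np.sort(rng.uniform(0, 1000, size=8))
        e = np.sort(rng.uniform(0, 1, size=8))[::-1]
        d[0], e[0] = 0.0, 1.0
        grid = np.column_stack([d, e])
        prof = EHHProfile(0, 1, grid * np.array([-1, 1]), grid, 5)
        manual = sum(
            (d[k + 1] - d[k]) * (e[k] + e[k + 1]) / 2 for k in range(7)
        )
        assert ihh(prof) == pytest.approx(2 * manual, abs=1e-10)

    def test_mirror_symmetry(self, rng):
        """iHH is invariant under coordinate reflection of the matrix."""
        hm = random_matrix(rng, 8, 15)
        core = 7
        flipped = HaplotypeMatrix(
            hm.alleles[:, ::-1],
            np.sort(hm.positions.max() + 1 - hm.positions),
            hm.chrom,
        )
        for allele in (0, 1):
            if (hm.alleles[:, core] == allele).sum() < 2:
                continue
            a = ihh(ehh(hm, core, allele, max_gap=None))
            b = ihh(ehh(flipped, hm.n_sites - 1 - core, allele, max_gap=None))
            assert a == pytest.approx(b, abs=1e-9)


class TestIHSnSL:
    def _symmetric_matrix(self):
        # derived and ancestral carrier sets are relabelings of each other
        alleles = np.array([
            [0, 1, 0, 1, 0],
            [1, 0, 0, 0, 1],
            [0, 1, 1, 1, 0],
            [1, 0, 1, 0, 1],
        ], dtype=np.int8)
        return HaplotypeMatrix(alleles, [10, 20, 30, 40, 50])

    def test_symmetric_core_gives_zero_uihs(self):
        hm = self._symmetric_matrix()
        df = hapstats.ihs_unstandardized(hm, min_maf=0.05)
        row = df[df.position == 30]
        assert len(row) == 1
        assert row.uihs.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_standardized_bins_have_zero_mean_unit_sd(self, rng):
        hm = random_matrix(rng, 20, 120, region_length=100_000)
        df = ihs_scan(hm)
        for _, grp in df.groupby("freq_bin"):
            if len(grp) < 2:
                continue
            assert grp.ihs.mean() == pytest.approx(0.0, abs=1e-9)
            assert grp.ihs.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_nsl_matches_ihs_ranking_under_uniform_spacing(self, rng):
        n, m = 14, 40
        alleles = random_matrix(rng, n, m).alleles
        positions = np.arange(1, m + 1) * 100  # exactly uniform bp spacing
        hm = HaplotypeMatrix(alleles, positions)
        ihs = ihs_scan(hm, max_gap=None)
        nsl = nsl_scan(hm)
        merged = ihs.merge(nsl, on="position", suffixes=("_i", "_n"))
        assert len(merged) > 3
        # the bp scale cancels in the log-ratio, so the standardized scores
        # coincide and so does any |score| ranking
        assert np.allclose(merged.ihs, merged.nsl, atol=1e-9)


class TestXPEHH:
    def test_identical_panels_give_zero(self, rng):
        hm = random_matrix(rng, 10, 20)
        df = xpehh_unstandardized(hm, hm)
        assert np.allclose(df.uxpehh, 0.0)

    def test_antisymmetry_under_swap(self, rng):
        a = random_matrix(rng, 8, 15)
        b = HaplotypeMatrix(random_matrix(rng, 6, 15).alleles, a.positions)
        ab = xpehh_unstandardized(a, b)
        ba = xpehh_unstandardized(b, a)
        merged = ab.merge(ba, on="position")
        assert np.allclose(merged.uxpehh_x, -merged.uxpehh_y)

    def test_mismatched_positions_rejected(self, rng):
        a = random_matrix(rng, 6, 10)
        bad_pos = a.positions.copy()
        bad_pos[3] += 1
        b = HaplotypeMatrix(a.alleles, bad_pos)
        with pytest.raises(ValueError, match="mismatch"):
            xpehh_unstandardized(a, b)


# ---------------------------------------------------------------------------
# H1 / H12 / H2
# ---------------------------------------------------------------------------

class TestHaplotypeSpectrum:
    def test_all_identical(self):
        hm = HaplotypeMatrix(np.ones((5, 4), dtype=np.int8), [1, 2, 3, 4])
        sp = haplotype_spectrum(hm, (0, 4))
        assert sp.h1 == 1.0 and sp.h12 == 1.0 and sp.h2 == 0.0

    def test_frequencies_half_quarter_quarter(self):
        # 4 haplotypes: two identical + two distinct singletons
        alleles = np.array([
            [0, 0, 0], [0, 0, 0], [1, 0, 1], [0, 1, 1],
        ], dtype=np.int8)
        sp = haplotype_spectrum(HaplotypeMatrix(alleles, [1, 2, 3]), (0, 3))
        assert sp.h1 == pytest.approx(0.375)
        assert sp.h12 == pytest.approx(0.625)

    def test_all_singletons(self):
        alleles = np.eye(5, dtype=np.int8)
        sp = haplotype_spectrum(HaplotypeMatrix(alleles, [1, 2, 3, 4, 5]), (0, 5))
        assert sp.h1 == pytest.approx(1 / 5)

    def test_ordering_invariant_on_random_windows(self, rng):
        for _ in range(50):
            hm = random_matrix(rng, int(rng.integers(3, 15)), 10)
            sp = haplotype_spectrum(hm, (0, 10))
            assert sp.h2 <= sp.h1 + 1e-12
            assert sp.h1 <= sp.h12 + 1e-12
            assert sp.h12 <= 1.0 + 1e-12
            h1, h12, h2 = h_stats_bruteforce(hm, 0, 10)
            assert sp.h1 == pytest.approx(h1, abs=1e-12)
            assert sp.h12 == pytest.approx(h12, abs=1e-12)
            assert sp.h2 == pytest.approx(h2, abs=1e-12)

    def test_window_wider_than_sites_rejected(self, rng):
        hm = random_matrix(rng, 4, 5)
        with pytest.raises(ValueError):
            h12_scan(hm, window_size=6)

    def test_scan_slides_by_step(self, rng):
        hm = random_matrix(rng, 6, 20)
        df = h12_scan(hm, window_size=5, step=3)
        assert df.start.tolist() == [0, 3, 6, 9, 12, 15]


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(2, 10), st.integers(1, 15), st.integers(0, 10_000))
def test_h_ordering_property(n, m, seed):
    """H2 <= H1 <= H12 <= 1 on arbitrary 0/1 matrices."""
    rng = np.random.default_rng(seed)
    alleles = rng.integers(0, 2, size=(n, m), dtype=np.int8)
    hm = HaplotypeMatrix(alleles, np.arange(1, m + 1))
    sp = haplotype_spectrum(hm, (0, m))
    assert sp.h2 <= sp.h1 + 1e-12 and sp.h1 <= sp.h12 + 1e-12 and sp.h12 <= 1 + 1e-12
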