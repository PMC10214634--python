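import numpy as np
import pytest

from balsel import popgen_core as pg
from balsel.io_formats import MaskSet
from balsel.popgen_core import HaplotypeMatrix

from conftest import random_hapmatrix


def _pi_oracle(matrix):
    """O(n^2) all-pairs mean difference, coded independently of the package."""
    n = matrix.shape[0]
    total = 0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(matrix[i] != matrix[j]))
            npairs += 1
    return total / npairs


def _tajima_oracle(matrix):
    """Constant-by-constant second implementation of Tajima's D."""
    n = matrix.shape[0]
    counts = matrix.sum(axis=0)
    S = int(np.sum((counts > 0) & (counts < n)))
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = _pi_oracle(matrix)
    return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestSegSites:
    def test_monomorphic_matrix_has_zero(self):
        H = HaplotypeMatrix(np.zeros((4, 3), dtype=np.uint8), [0, 5, 9])
        assert pg.seg_sites(H) == 0

    def test_hand_count(self):
        m = np.array([[0, 0, 1, 0], [1, 0, 1, 1]], dtype=np.uint8)
        H = HaplotypeMatrix(m, [0, 1, 2, 3])
        assert pg.seg_sites(H) == 2

    def test_simulator_emits_only_segregating_sites(self, rng):
        from balsel.synthetic_data import SimParams, simulate_neutral_locus

        p = SimParams(n_hap=10, locus_len=2000, theta_bp=0.003)
        loc = simulate_neutral_locus(p, rng)
        assert pg.seg_sites(loc.haplotypes) == loc.haplotypes.n_sites


class TestNucleotideDiversity:
    def test_three_haplotype_hand_count(self):
        m = np.array([[0, 0, 0], [0, 1, 1], [1, 1, 0]], dtype=np.uint8)
        H = HaplotypeMatrix(m, [0, 1, 2])
        assert pg.mean_pairwise_diff(H) == pytest.approx(2.0)
        assert pg.nucleotide_diversity(H, 3) == pytest.approx(2.0 / 3.0)

    def test_identical_haplotypes_zero(self):
        H = HaplotypeMatrix(np.ones((5, 4), dtype=np.uint8), [0, 1, 2, 3])
        assert pg.mean_pairwise_diff(H) == 0.0

    def test_matches_all_pairs_oracle_exactly(self, rng):
        for _ in range(100):
            H = random_hapmatrix(rng, n_hap=8, n_sites=20)
            assert pg.mean_pairwise_diff(H) == pytest.approx(
                _pi_oracle(H.matrix), abs=1e-12
            )

    def test_zero_effective_length_is_error(self):
        H = HaplotypeMatrix(np.zeros((2, 1), dtype=np.uint8), [0])
        with pytest.raises(ValueError):
            pg.nucleotide_diversity(H, 0)


class TestWattersonTheta:
    def test_harmonic_sum_by_hand(self):
        # a_4 = 1 + 1/2 + 1/3 = 1.8333...
        assert pg.watterson_theta(3, 4, 1) == pytest.approx(3 / (11 / 6))

    def test_zero_sites(self):
        assert pg.watterson_theta(0, 10, 100) == 0.0

    def test_unbiased_under_neutral_simulation(self, rng):
        from balsel.synthetic_data import SimParams, simulate_neutral_locus

        p = SimParams(n_hap=20, locus_len=4000, theta_bp=0.0025)  # theta = 10
        a = pg.harmonic(20)
        ests = []
        for _ in range(3000):
            H = simulate_neutral_locus(p, rng).haplotypes
            ests.append(pg.watterson_theta(H.n_sites, 20, 1.0))
        assert a == pytest.approx(sum(1 / i for i in range(1, 20)))
        mean = np.mean(ests)
        se = np.std(ests) / np.sqrt(len(ests))
        assert abs(mean - 10.0) <= 3 * se + 0.1


class TestTajimasD:
    def test_zero_when_pi_equals_watterson_numerator(self):
        # 4 haplotypes, a1 = 11/6: 8 singleton columns (pi 1/2 each) plus
        # 3 doubleton columns (pi 2/3 each) give pi_total = 6 = 11/a1 = S/a1.
        m = np.zeros((4, 11), dtype=np.uint8)
        m[0, :8] = 1
        m[0, 8:] = 1
        m[1, 8:] = 1
        H = HaplotypeMatrix(m, np.arange(11))
        assert pg.tajimas_d(H) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_oracle(self, rng):
        for _ in range(25):
            H = random_hapmatrix(rng, n_hap=6, n_sites=10)
            assert pg.tajimas_d(H) == pytest.approx(
                _tajima_oracle(H.matrix), abs=1e-12
            )

    def test_undefined_when_no_segregating_sites(self):
        H = HaplotypeMatrix(np.zeros((6, 2), dtype=np.uint8), [0, 1])
        assert np.isnan(pg.tajimas_d(H))

    def test_near_zero_mean_under_neutrality(self, rng):
        from balsel.synthetic_data import SimParams, simulate_neutral_locus

        p = SimParams(n_hap=62, locus_len=2000, theta_bp=0.005)
        ds = []
        for _ in range(2000):
            H = simulate_neutral_locus(p, rng).haplotypes
            if pg.seg_sites(H) > 0:
                ds.append(pg.tajimas_d(H))
        assert abs(np.mean(ds)) < 0.3

    def test_positive_under_balancing_selection(self, rng):
        from balsel.synthetic_data import SimParams, simulate_balanced_locus

        p = SimParams(
            n_hap=62, locus_len=2000, theta_bp=0.005, model="balanced",
            f_eq=0.5, t_balance=8.0, m_switch=0.05,
        )
        pos = 0
        for _ in range(100):
            H = simulate_balanced_locus(p, rng).haplotypes
            if H.n_sites and pg.tajimas_d(H) > 0:
                pos += 1
        assert pos >= 80


class TestEffectiveLength:
    def test_disjoint_masks_subtract(self):
        masks = MaskSet(
            gaps={"c": np.array([[100, 200]])},
            repeats={"c": np.array([[500, 900]])},
        )
        assert pg.effective_length((0, 2000), masks, "c") == 1500

    def test_overlapping_masks_subtract_union(self):
        masks = MaskSet(
            gaps={"c": np.array([[100, 250]])},
            repeats={"c": np.array([[200, 400]])},
        )
        # union [100, 400) = 300 bp, not 150 + 200
        assert pg.effective_length((0, 1000), masks, "c") == 700

    def test_fully_masked_window_zero(self):
        masks = MaskSet(gaps={"c": np.array([[0, 5000]])})
        assert pg.effective_length((1000, 2000), masks, "c") == 0


class TestSlidingWindows:
    def test_window_enumeration_10kb(self, rng, empty_masks):
        H = random_hapmatrix(rng, n_hap=6, n_sites=30, span=10_000)
        track = pg.sliding_windows(H, (0, 10_000), empty_masks, "c", 2000, 500)
        starts = [w.start for w in track.windows]
        assert starts == list(range(0, 8500, 500))
        assert len(starts) == 17
        assert all(w.end - w.start == 2000 for w in track.windows)

    def test_truncated_tail_emitted_when_quarter_remains(self, rng, empty_masks):
        H = random_hapmatrix(rng, n_hap=6, n_sites=10, span=2500)
        # non-overlapping tiling: [0,2000) full, then 1000 bp >= size/4 remains
        track = pg.sliding_windows(H, (0, 3000), empty_masks, "c", 2000, 2000)
        assert [(w.start, w.end) for w in track.windows] == [(0, 2000), (2000, 3000)]
        # a 100 bp remainder (< size/4) is dropped instead
        track2 = pg.sliding_windows(H, (0, 2100), empty_masks, "c", 2000, 2000)
        assert [(w.start, w.end) for w in track2.windows] == [(0, 2000)]

    def test_empty_window_flagged(self, empty_masks):
        H = HaplotypeMatrix(np.zeros((6, 0), dtype=np.uint8), [])
        track = pg.sliding_windows(H, (0, 1000), empty_masks, "c", 2000, 500)
        assert track.stats[0].S == 0
        assert np.isnan(track.stats[0].tajima_d)

    def test_single_window_equals_whole_region_stats(self, rng, empty_masks):
        H = random_hapmatrix(rng, n_hap=8, n_sites=25, span=3000)
        track = pg.sliding_windows(H, (0, 3000), empty_masks, "c", 3000, 3000)
        assert len(track.windows) == 1
        s = track.stats[0]
        assert s.S == pg.seg_sites(H)
        assert s.pi_site == pytest.approx(pg.nucleotide_diversity(H, 3000))
        assert s.tajima_d == pytest.approx(pg.tajimas_d(H))


class TestThetaMap:
    def test_formula_instantiation(self, empty_masks):
        from conftest import make_variant_table

        m = np.zeros((62, 31), dtype=np.uint8)
        m[:10, :] = 1
        masks = MaskSet(gaps={"c": np.array([[0, 500]])})
        vt = make_variant_table(m, np.arange(600, 600 + 31 * 10, 10), contig="c")
        tm = pg.theta_map(vt, masks, tile=10_000)
        want = 31 / (pg.harmonic(62) * 9500)
        assert tm.lookup("c", 700) == pytest.approx(want)

    def test_lookup_returns_tile_containing_position(self, rng, empty_masks):
        from conftest import make_variant_table

        m = np.zeros((4, 3), dtype=np.uint8)
        m[0] = 1
        vt = make_variant_table(m, [5, 15_001, 15_101], contig="c")
        tm = pg.theta_map(vt, empty_masks, tile=10_000)
        assert tm.lookup("c", 9999) == tm.lookup("c", 0)
        assert tm.lookup("c", 10_000) != tm.lookup("c", 9999)

    def test_missing_tile_is_none_not_zero(self, empty_masks):
        from conftest import make_variant_table

        m = np.array([[1], [0], [0], [0]], dtype=np.uint8)
        vt = make_variant_table(m, [100], contig="c")
        tm = pg.theta_map(vt, empty_masks, tile=10_000)
        assert tm.lookup("c", 50_000) is None

    def test_fully_masked_tile_flagged_missing(self):
        from conftest import make_variant_table

        masks = MaskSet(gaps={"c": np.array([[0, 10_000]])})
        m = np.array([[1, 1], [0, 0], [0, 0], [0, 0]], dtype=np.uint8)
        vt = make_variant_table(m, [100, 15_000], contig="c")
        tm = pg.theta_map(vt, masks, tile=10_000)
        assert tm.lookup("c", 100) is None
        assert tm.lookup("c", 15_000) is not None


def test_pi_and_theta_unbiased_small_montecarlo(rng):
    """Relative bias of pi-hat and theta_W under neutrality (reduced reps;
    the full 5000-rep check runs in the acceptance suite)."""
    from balsel.synthetic_data import SimParams, simulate_neutral_locus

    p = SimParams(n_hap=62, locus_len=2000, theta_bp=0.005)
    pis, tws = [], []
    for _ in range(1500):
        H = simulate_neutral_locus(p, rng).haplotypes
        pis.append(pg.mean_pairwise_diff(H))
        tws.append(H.n_sites / pg.harmonic(62))
    assert abs(np.mean(pis) / 10.0 - 1) < 0.05
    assert abs(np.mean(tws) / 10.0 - 1) < 0.05
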