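"""GC normalization, ratios, MAPD, CBS, diploid anchoring, burden."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scmetseq import (
    PipelineConfig,
    SimConfig,
    anchor_diploid,
    cna_burden,
    compute_ratios,
    gc_normalize,
    mapd,
    profile_cell,
    segment_cbs,
    simulate_cell_counts,
    toy_grid,
)
from scmetseq.profiling import Segment


class TestGcNormalize:
    def test_constant_counts_unchanged(self, rng):
        gc = rng.uniform(0.3, 0.6, 200)
        raw = np.full(200, 77.0)
        norm, masked = gc_normalize(raw, gc)
        assert np.allclose(norm, raw, atol=1e-6)
        assert not masked.any()

    def test_linear_bias_reduces_cv(self, rng):
        gc = rng.uniform(0.3, 0.6, 500)
        raw = 2.0 * gc * 1000
        norm, _ = gc_normalize(raw, gc)
        cv = lambda v: v.std() / v.mean()
        assert cv(norm) < cv(raw)

    def test_known_multiplicative_curve_removed(self, rng):
        gc = rng.uniform(0.30, 0.55, 2000)
        bias = np.exp(1.2 * (gc - 0.4))
        raw = rng.poisson(1000 * bias).astype(float)
        norm, _ = gc_normalize(raw, gc)
        assert abs(np.corrcoef(raw, gc)[0, 1]) > 0.3  # bias is real before
        assert abs(np.corrcoef(norm, gc)[0, 1]) < 0.05

    def test_masked_bins_pass_through(self, rng):
        gc = rng.uniform(0.3, 0.6, 100)
        gc[7] = np.nan
        raw = rng.poisson(500, 100).astype(float)
        norm, masked = gc_normalize(raw, gc)
        assert masked[7] and masked.sum() == 1
        assert norm[7] == raw[7]

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            gc_normalize(np.zeros(100), np.linspace(0.3, 0.6, 100))

    def test_too_few_gc_bins_rejected(self, rng):
        gc = np.full(100, np.nan)
        gc[:10] = 0.4
        with pytest.raises(ValueError, match="50 bins"):
            gc_normalize(rng.poisson(100, 100).astype(float), gc)


class TestComputeRatios:
    def test_constant_counts(self):
        ratios, log2 = compute_ratios(np.full(20, 5.0))
        assert np.allclose(ratios, 1) and np.allclose(log2, 0)

    def test_small_example(self):
        ratios, _ = compute_ratios(np.array([1.0, 1.0, 2.0] * 5))
        assert np.allclose(ratios[:3], [0.75, 0.75, 1.5])

    def test_zero_bins_get_pseudocount(self):
        counts = np.r_[np.zeros(2), np.full(18, 10.0)]
        _, log2 = compute_ratios(counts, pseudocount=0.5)
        assert np.isfinite(log2).all()
        assert log2[0] == pytest.approx(np.log2(0.5 / counts.mean()))

    def test_too_few_nonzero_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            compute_ratios(np.r_[np.ones(9), np.zeros(100)])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mean_ratio_is_one(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.uniform(0.5, 100, size=rng.integers(10, 500))
        ratios, _ = compute_ratios(counts)
        assert abs(ratios.mean() - 1) < 1e-12


class TestMapd:
    def test_constant_is_zero(self):
        assert mapd(np.zeros(50)) == 0.0

    def test_alternating_series(self):
        assert mapd(np.array([0.0, 1.0, 0.0, 1.0])) == 1.0

    def test_monte_carlo_oracle(self):
        # iid N(0, sigma) log2 ratios: adjacent diffs are N(0, 2 sigma^2)
        sigma = 0.3
        rng = np.random.default_rng(7)
        x = rng.normal(0, sigma, 5000)
        observed = mapd(x)
        oracle = np.median(np.abs(rng.normal(0, sigma * np.sqrt(2), 1_000_000)))
        assert observed == pytest.approx(oracle, rel=0.02)

    def test_no_cross_chromosome_pairs(self):
        # a huge offset between chromosomes must not contribute any pair
        # (mean form makes the single cross-boundary jump visible)
        x = np.r_[np.zeros(50), np.full(50, 10.0)]
        assert mapd(x, chrom_bounds=[(0, 50), (50, 100)], statistic="mean") == 0.0
        assert mapd(x, chrom_bounds=[(0, 100)], statistic="mean") > 0.0

    def test_single_bin_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="single-bin"):
            mapd(np.array([1.0, 2.0]), chrom_bounds=[(0, 1), (1, 2)])

    def test_mean_form_switch(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 4.0])  # diffs {1, 0, 0, 3}
        assert mapd(x, statistic="median") == 0.5
        assert mapd(x, statistic="mean") == pytest.approx(1.0)


def brute_force_best_partition(x, max_breaks=2):
    """Exhaustive minimum-RSS partition with up to ``max_breaks`` breakpoints."""
    n = len(x)

    def rss(edges):
        return sum(float(np.sum((x[a:b] - x[a:b].mean()) ** 2))
                   for a, b in zip(edges[:-1], edges[1:]))

    best = rss([0, n])
    for k in range(1, max_breaks + 1):
        for cuts in itertools.combinations(range(1, n), k):
            best = min(best, rss([0, *cuts, n]))
    return best


def segmentation_rss(x, segments):
    return sum(float(np.sum((x[a:b] - x[a:b].mean()) ** 2)) for a, b in segments)


class TestSegmentCbs:
    def test_constant_series_no_breakpoints(self):
        segs = segment_cbs(np.zeros(100), [(0, 100)])
        assert segs == [(0, 100)]

    def test_single_step_found_within_one_bin(self, rng):
        x = np.r_[np.zeros(100), np.ones(100)] + rng.normal(0, 0.1, 200)
        segs = segment_cbs(x, [(0, 200)], rng=np.random.default_rng(0))
        cuts = sorted({a for a, _ in segs} - {0})
        assert len(cuts) == 1 and abs(cuts[0] - 100) <= 1

    def test_breakpoints_respect_chromosome_boundary(self, rng):
        x = np.r_[np.zeros(50), np.ones(50)] + rng.normal(0, 0.05, 100)
        segs = segment_cbs(x, [(0, 50), (50, 100)], rng=np.random.default_rng(0))
        assert (0, 50) in segs and (50, 100) in segs

    @pytest.mark.parametrize("truth", [
        [(0, 25, 0.0)],
        [(0, 10, 0.0), (10, 25, 1.5)],
        [(0, 8, 0.0), (8, 16, 2.0), (16, 25, -1.0)],
    ])
    def test_matches_exhaustive_partition_oracle(self, truth, rng):
        # with effect >> noise the exhaustive optimum with as many cuts as
        # the series truly has sits at the true structure; CBS must match it
        x = np.zeros(25)
        for a, b, mu in truth:
            x[a:b] = mu
        x += rng.normal(0, 0.1, 25)
        segs = segment_cbs(x, [(0, 25)], rng=np.random.default_rng(1))
        optimal = brute_force_best_partition(x, max_breaks=len(truth) - 1)
        assert segmentation_rss(x, segs) <= 1.05 * max(optimal, 1e-12)

    def test_non_finite_input_rejected(self):
        x = np.zeros(30)
        x[3] = np.nan
        with pytest.raises(ValueError, match="bins \\[3\\]"):
            segment_cbs(x, [(0, 30)])


class TestAnchorDiploid:
    def test_single_segment_is_diploid(self):
        anchor, cn, states, ok = anchor_diploid(
            [(0, 10)], np.ones(10), np.full(10, 500_000))
        assert anchor == pytest.approx(1.0)
        assert cn.tolist() == [2] and states == ["neutral"] and ok

    def test_majority_cluster_anchors_two_copies(self):
        # 80% of genome at ratio 1.0, 20% at 1.5 -> CN {2, 3}, burden 0.20
        ratios = np.r_[np.ones(80), np.full(20, 1.5)]
        widths = np.full(100, 500_000)
        anchor, cn, states, _ = anchor_diploid([(0, 80), (80, 100)], ratios, widths)
        assert cn.tolist() == [2, 3] and states == ["neutral", "gain"]
        segs = [
            Segment(0, 79, 0.0, 2, "neutral", 80 * 500_000),
            Segment(80, 99, 0.585, 3, "gain", 20 * 500_000),
        ]
        burden, detectable = cna_burden(segs, 100 * 500_000)
        assert burden == pytest.approx(0.20) and detectable

    def test_guard_band_suppresses_jitter(self):
        # a 1.28 ratio rounds up to CN 3; a stricter log2 guard (0.4 >
        # log2(1.28) = 0.356) pulls it back to neutral, the default keeps it
        ratios = np.r_[np.ones(90), np.full(10, 1.28)]
        widths = np.full(100, 1.0)
        bounds = [(0, 90), (90, 100)]
        _, cn, states, _ = anchor_diploid(bounds, ratios, widths, gain_log2_cut=0.4)
        assert cn.tolist() == [2, 2] and states[1] == "neutral"
        _, cn_default, _, _ = anchor_diploid(bounds, ratios, widths)
        assert cn_default.tolist() == [2, 3]

    def test_recovers_known_copy_numbers_with_noise(self, rng):
        widths = np.full(400, 500_000)
        truth_cn = np.r_[np.full(40, 1), np.full(240, 2), np.full(80, 3), np.full(40, 4)]
        bounds = [(0, 40), (40, 280), (280, 360), (360, 400)]
        correct = 0
        total = 0
        for _ in range(20):
            log2 = np.log2(truth_cn / 2.0) + rng.normal(0, 0.05, 400)
            ratios = 2.0 ** log2
            _, cn, _, _ = anchor_diploid(bounds, ratios, widths)
            for (a, b), c in zip(bounds, cn):
                w = widths[a:b].sum()
                total += w
                if c == truth_cn[a]:
                    correct += w
        assert correct / total >= 0.95

    def test_unconfident_anchor_flagged(self):
        # twenty equal-length, well-separated ratio levels: the heaviest
        # cluster covers only 5% of the genome, below the 10% confidence bar
        levels = 0.5 * 1.25 ** np.arange(20)
        ratios = np.repeat(levels, 5)
        bounds = [(i * 5, (i + 1) * 5) for i in range(20)]
        *_, confident = anchor_diploid(bounds, ratios, np.ones(100))
        assert not confident


class TestCnaBurden:
    def test_all_neutral_profile(self):
        segs = [Segment(0, 99, 0.0, 2, "neutral", 50_000_000)]
        burden, detectable = cna_burden(segs, 50_000_000)
        assert burden == 0.0 and not detectable

    def test_sixty_mb_gain_on_hg19_is_detectable(self):
        # hg19 autosomes total 2,881,033,286 bp (from the tiling oracle)
        autosome = 2_881_033_286
        segs = [
            Segment(0, 119, 0.585, 3, "gain", 60_000_000),
            Segment(120, 5753, 0.0, 2, "neutral", autosome - 60_000_000),
        ]
        burden, detectable = cna_burden(segs, autosome)
        assert burden == pytest.approx(0.0208, abs=1e-4)
        assert detectable  # 0.0208 > 0.02

    def test_burden_exactly_at_threshold_not_detectable(self):
        # strict inequality: a burden of exactly 0.02 is NOT detectable
        segs = [
            Segment(0, 1, 0.585, 3, "gain", 1_000_000),
            Segment(2, 99, 0.0, 2, "neutral", 49_000_000),
        ]
        burden, detectable = cna_burden(segs, 50_000_000)
        assert burden == 0.02 and not detectable


class TestProfileCell:
    def test_diploid_cells_pass_qc_with_low_burden(self, grid, sim_config):
        ok = 0
        n_rep = 100
        master = np.random.default_rng(11)
        diploid = np.full(grid.n_bins, 2, dtype=np.int16)
        for _ in range(n_rep):
            counts = simulate_cell_counts(diploid, grid, sim_config, master)
            prof = profile_cell(counts, grid, PipelineConfig(), "d")
            if prof.qc_pass and prof.cna_burden < 0.02:
                ok += 1
        assert ok >= 95

    def test_high_dispersion_fails_mapd_qc(self, grid, rng):
        noisy = SimConfig(dispersion=0.25)
        counts = simulate_cell_counts(np.full(grid.n_bins, 2), grid, noisy, rng)
        prof = profile_cell(counts, grid, PipelineConfig(), "noisy")
        assert prof.mapd > 0.45 and not prof.qc_pass

    def test_qc_pcr_veto(self, grid, sim_config, rng):
        counts = simulate_cell_counts(np.full(grid.n_bins, 2), grid, sim_config, rng)
        assert profile_cell(counts, grid, cell_id="a", qc_pcr_pass=True).qc_pass
        assert not profile_cell(counts, grid, cell_id="a", qc_pcr_pass=False).qc_pass

    def test_deterministic_given_seed(self, grid, sim_config, rng):
        counts = simulate_cell_counts(np.full(grid.n_bins, 2), grid, sim_config, rng)
        p1 = profile_cell(counts, grid, PipelineConfig(seed=5), "c")
        p2 = profile_cell(counts, grid, PipelineConfig(seed=5), "c")
        assert p1.log2_ratios.tobytes() == p2.log2_ratios.tobytes()
        assert p1.segments == p2.segments
        assert p1.cna_burden == p2.cna_burden and p1.mapd == p2.mapd

    def test_burden_invariant_to_depth_scaling(self, grid, sim_config):
        rng = np.random.default_rng(3)
        clone_cn = np.full(grid.n_bins, 2, dtype=np.int16)
        clone_cn[10:30] = 3
        counts = simulate_cell_counts(clone_cn, grid, sim_config, rng)
        p1 = profile_cell(counts, grid, PipelineConfig(seed=1), "c")
        p3 = profile_cell(counts * 3, grid, PipelineConfig(seed=1), "c")
        assert [(s.start_bin, s.end_bin, s.state) for s in p1.segments] == \
               [(s.start_bin, s.end_bin, s.state) for s in p3.segments]
        assert p1.cna_burden == p3.cna_burden

    def test_stage_errors_carry_stage_name(self, grid):
        with pytest.raises(ValueError, match="gc_normalize"):
            profile_cell(np.zeros(grid.n_bins), grid)

    def test_mapd_monotone_in_dispersion(self, grid):
        # median MAPD over replicates must not decrease along a dispersion grid
        dispersions = [0.01, 0.05, 0.1, 0.2, 0.4]
        rng = np.random.default_rng(9)
        diploid = np.full(grid.n_bins, 2, dtype=np.int16)
        medians = []
        for d in dispersions:
            cfg = SimConfig(dispersion=d)
            vals = []
            for _ in range(20):
                counts = simulate_cell_counts(diploid, grid, cfg, rng)
                prof = profile_cell(counts, grid, PipelineConfig(), "m")
                vals.append(prof.mapd)
            medians.append(np.median(vals))
        assert all(a <= b for a, b in zip(medians, medians[1:]))
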