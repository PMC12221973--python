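"""Insulation scores, boundary calling/classification and domain pile-ups."""

import numpy as np
import pandas as pd
import pytest

from chromarch.insulation import (
    BoundarySet,
    call_boundaries,
    classify_boundaries,
    insulation_profile,
    li_threshold,
    rescaled_pileup,
    scan_parameters,
)
from chromarch.matrix import ContactMatrix, observed_over_expected
from chromarch.simulate import SimulationConfig, build_expected_matrix
from chromarch.validation import oracle_classify_boundaries


def pure_decay_matrix(n=200, bs=5_000, alpha=1.0):
    cfg = SimulationConfig(chrom_lengths={"chr1": n * bs}, bin_size=bs,
                           alpha=alpha, seed=0)
    exp = build_expected_matrix(cfg)["chr1"]
    return ContactMatrix("chr1", bs, exp, weights=np.ones(n),
                         valid=np.ones(n, bool))


class TestInsulationProfile:
    def test_structureless_decay_scores_zero(self):
        m = pure_decay_matrix()
        prof = insulation_profile(m, 10 * m.bin_size)
        fin = prof.scores[np.isfinite(prof.scores)]
        assert np.all(np.abs(fin) < 1e-9)

    def test_planted_boundary_is_local_minimum(self):
        n, bs = 200, 5_000
        cfg = SimulationConfig(chrom_lengths={"chr1": n * bs}, bin_size=bs,
                               alpha=1.0, boundaries={"chr1": [100 * bs]},
                               boundary_attenuation=0.3, seed=0)
        exp = build_expected_matrix(cfg)["chr1"]
        m = ContactMatrix("chr1", bs, exp, weights=np.ones(n),
                          valid=np.ones(n, bool))
        prof = insulation_profile(m, 10 * bs)
        dip = np.nanargmin(prof.scores)
        assert abs(dip - 100) <= 1

    def test_invariant_to_global_count_scaling(self):
        m = pure_decay_matrix()
        m2 = ContactMatrix(m.chrom, m.bin_size, m.counts * 2.0,
                           weights=m.weights, valid=m.valid)
        a = insulation_profile(m, 10 * m.bin_size).scores
        b = insulation_profile(m2, 10 * m.bin_size).scores
        assert np.allclose(a, b, equal_nan=True)

    def test_window_too_large_rejected(self):
        m = pure_decay_matrix(n=50)
        with pytest.raises(ValueError, match="half"):
            insulation_profile(m, 30 * m.bin_size)

    def test_window_not_multiple_of_bin_rejected(self):
        m = pure_decay_matrix()
        with pytest.raises(ValueError, match="multiple"):
            insulation_profile(m, 10 * m.bin_size + 1)


class TestLiThreshold:
    def oracle_li(self, values, n_bins=256):
        """Exhaustive search of the cross-entropy objective on raw values."""
        x = np.sort(values)
        best_t, best = None, np.inf
        for t in np.linspace(x.min(), x.max(), n_bins + 1)[1:-1]:
            lo, hi = x[x < t], x[x >= t]
            if lo.size == 0 or hi.size == 0 or lo.mean() <= 0:
                continue
            obj = -(lo.sum() * np.log(lo.mean()) + hi.sum() * np.log(hi.mean()))
            if obj < best:
                best, best_t = obj, t
        return best_t

    def test_bimodal_split_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([np.abs(rng.normal(0.1, 0.02, 160)),
                            np.abs(rng.normal(1.0, 0.1, 40))])
        t = li_threshold(x)
        t_oracle = self.oracle_li(x)
        # same classification of every point
        assert np.array_equal(x >= t, x >= t_oracle)

    def test_split_accuracy_on_planted_bimodal(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([np.abs(rng.normal(0.1, 0.02, 160)),
                            np.abs(rng.normal(1.0, 0.1, 40))])
        t = li_threshold(x)
        truth = np.arange(200) >= 160
        assert np.mean((x >= t) == truth) >= 0.95

    def test_separates_like_skimage_reference(self):
        from skimage.filters import threshold_li
        rng = np.random.default_rng(2)
        x = np.concatenate([np.abs(rng.normal(0.2, 0.05, 300)),
                            np.abs(rng.normal(2.0, 0.3, 100))])
        ours, ref = li_threshold(x), threshold_li(x)
        # both thresholds must separate the two modes identically
        assert np.array_equal(x >= ours, x >= ref)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            li_threshold(np.full(100, 1.0))


class TestCallBoundaries:
    def test_single_dip_gives_one_boundary(self):
        from chromarch.insulation import InsulationProfile
        scores = np.zeros(100)
        scores[50] = -1.0
        prof = InsulationProfile("chr1", 1_000, 5_000, scores)
        b = call_boundaries(prof)
        assert list(b.bins) == [50]
        assert b.strength[0] == pytest.approx(1.0)

    def test_dip_near_masked_region_removed(self):
        from chromarch.insulation import InsulationProfile
        scores = np.zeros(100)
        scores[50] = -1.0
        prof = InsulationProfile("chr1", 1_000, 5_000, scores)
        b = call_boundaries(prof, unmappable=[(52_000, 54_000)])
        assert b.bins.size == 0  # dip within 2 bins of the mask

    def test_dip_far_from_mask_kept(self):
        from chromarch.insulation import InsulationProfile
        scores = np.zeros(100)
        scores[50] = -1.0
        prof = InsulationProfile("chr1", 1_000, 5_000, scores)
        b = call_boundaries(prof, unmappable=[(60_000, 62_000)])
        assert list(b.bins) == [50]

    def test_two_window_consensus_requires_both(self):
        from chromarch.insulation import InsulationProfile
        s1 = np.zeros(100)
        s1[30] = -1.0
        s1[70] = -1.0
        s2 = np.zeros(100)
        s2[30] = -1.0  # second window confirms only bin 30
        p1 = InsulationProfile("chr1", 1_000, 5_000, s1)
        p2 = InsulationProfile("chr1", 1_000, 10_000, s2)
        b = call_boundaries([p1, p2])
        assert list(b.bins) == [30]

    def test_boundary_positions_invariant_to_score_offset(self):
        from chromarch.insulation import InsulationProfile
        rng = np.random.default_rng(0)
        scores = rng.normal(size=200)
        b1 = call_boundaries(InsulationProfile("c", 1_000, 5_000, scores))
        b2 = call_boundaries(
            InsulationProfile("c", 1_000, 5_000, scores + 5.0))
        assert np.array_equal(b1.bins, b2.bins)
        assert np.allclose(b1.strength, b2.strength)


class TestScanParameters:
    def test_report_covers_full_grid(self, boundary_map):
        _, _, m = boundary_map
        res, w1, w2, report = scan_parameters(
            m.counts, m.bin_size, "chr1", [m.bin_size, 2 * m.bin_size])
        assert set(report.resolution) == {m.bin_size, 2 * m.bin_size}
        assert set(report.multiplier) == {5, 10, 25}

    def test_chosen_windows_are_sorted_and_from_best_resolution(self, boundary_map):
        _, _, m = boundary_map
        res, w1, w2, report = scan_parameters(
            m.counts, m.bin_size, "chr1", [m.bin_size, 2 * m.bin_size])
        assert w1 <= w2
        assert w1 % res == 0 and w2 % res == 0

    def test_single_resolution_rejected(self, boundary_map):
        _, _, m = boundary_map
        with pytest.raises(ValueError, match="2 resolutions"):
            scan_parameters(m.counts, m.bin_size, "chr1", [m.bin_size])


class TestClassifyBoundaries:
    def make_bset(self, bins, bs=5_000):
        bins = np.asarray(bins)
        return BoundarySet("chr1", bs, bins, np.ones(bins.size),
                           np.ones(bins.size, bool), 0.0)

    def test_loop_anchor_beats_tss(self):
        b = self.make_bset([10])
        loops = pd.DataFrame({"chrom1": ["chr1"], "start1": [50_000],
                              "end1": [55_000], "chrom2": ["chr1"],
                              "start2": [200_000], "end2": [205_000]})
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [51_000], "start": [51_000]})
        out = classify_boundaries(b, loops, tss, None, None)
        assert out.classes[0] == "loop-anchor"

    def test_accessible_within_one_bin(self):
        b = self.make_bset([10])
        acc = pd.DataFrame({"chrom": ["chr1"], "start": [56_000], "end": [57_000]})
        out = classify_boundaries(b, None, None, acc, None)
        assert out.classes[0] == "accessible"

    def test_feature_beyond_tolerance_unassigned(self):
        b = self.make_bset([10])
        acc = pd.DataFrame({"chrom": ["chr1"], "start": [80_000], "end": [81_000]})
        out = classify_boundaries(b, None, None, acc, None)
        assert out.classes[0] == "unassigned"

    def test_tss_of_looping_gene_excluded_from_tss_class(self):
        b = self.make_bset([10])
        loops = pd.DataFrame({"chrom1": ["chr1"], "start1": [300_000],
                              "end1": [305_000], "chrom2": ["chr1"],
                              "start2": [400_000], "end2": [405_000]})
        # TSS at the boundary but also inside a loop anchor? here the TSS
        # sits at the boundary and NOT in any anchor: classify as TSS
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [51_000], "start": [51_000]})
        out = classify_boundaries(b, loops, tss, None, None)
        assert out.classes[0] == "TSS"
        # now the same TSS lies inside an anchor: excluded, boundary unassigned
        loops2 = pd.DataFrame({"chrom1": ["chr1"], "start1": [48_000],
                               "end1": [52_000], "chrom2": ["chr1"],
                               "start2": [400_000], "end2": [405_000]})
        out2 = classify_boundaries(self.make_bset([10]), loops2, tss, None, None)
        # the anchor itself overlaps the boundary -> loop-anchor wins anyway
        assert out2.classes[0] == "loop-anchor"

    def test_matches_bruteforce_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        bs = 5_000
        for _ in range(30):
            bins = np.sort(rng.choice(100, size=6, replace=False))
            b = self.make_bset(bins, bs)
            k = int(rng.integers(1, 5))
            s1 = rng.integers(0, 95, k) * bs
            s2 = rng.integers(0, 95, k) * bs
            loops = pd.DataFrame({"chrom1": "chr1", "start1": s1,
                                  "end1": s1 + bs, "chrom2": "chr1",
                                  "start2": s2, "end2": s2 + bs})
            tss = pd.DataFrame({"chrom": "chr1",
                                "tss": rng.integers(0, 100 * bs, 5)})
            tss["start"] = tss.tss
            acc_s = rng.integers(0, 95, 4) * bs
            acc = pd.DataFrame({"chrom": "chr1", "start": acc_s,
                                "end": acc_s + bs})
            lim = pd.DataFrame({"chrom": "chr1", "bin": rng.integers(0, 100, 3)})
            got = classify_boundaries(b, loops, tss, acc, lim).classes
            want = oracle_classify_boundaries(bins, bs, loops, tss, acc, lim)
            assert np.array_equal(got, want)

    def test_wrong_chromosome_reported(self):
        b = self.make_bset([10])
        acc = pd.DataFrame({"chrom": ["chr9"], "start": [0], "end": [1_000]})
        with pytest.raises(ValueError, match="chr9"):
            classify_boundaries(b, None, None, acc, None)


class TestRescaledPileup:
    def domain_map(self):
        # isolated domains: flanks are background, not neighbouring domains
        n, bs = 600, 5_000
        bnds = [100, 115, 250, 262, 400, 414]
        doms = [(100, 115), (250, 262), (400, 414)]
        cfg = SimulationConfig(
            chrom_lengths={"chr1": n * bs}, bin_size=bs, alpha=1.0,
            boundaries={"chr1": [b * bs for b in bnds]},
            boundary_attenuation=0.5,
            domains={"chr1": [(s * bs, e * bs, 1.5) for s, e in doms]},
            seed=0)
        exp = build_expected_matrix(cfg)["chr1"]
        m = ContactMatrix("chr1", bs, exp, weights=np.ones(n),
                          valid=np.ones(n, bool))
        return m, bnds

    def test_planted_domains_enriched_over_flanks(self):
        m, bnds = self.domain_map()
        oe = observed_over_expected(m, smooth=True)
        prof = insulation_profile(m, 10 * m.bin_size)
        b = call_boundaries(prof)
        pile, used = rescaled_pileup(oe, b, max_span=100_000, grid=10)
        assert used >= 3
        G = 10
        centre = np.nanmean(pile[G:2 * G, G:2 * G])
        flank = np.nanmean(np.concatenate([
            pile[:G, :G].ravel(), pile[2 * G:, 2 * G:].ravel()]))
        assert centre / flank >= 1.3

    def test_domains_longer_than_max_span_excluded(self):
        m, bnds = self.domain_map()
        oe = observed_over_expected(m)
        # only boundaries 100 and 300 strong: the 200-bin gap exceeds 100 kb
        bins = np.array([100, 300])
        b = BoundarySet("chr1", m.bin_size, bins, np.ones(2),
                        np.ones(2, bool), 0.0)
        with pytest.raises(ValueError, match="no inter-boundary domains"):
            rescaled_pileup(oe, b, max_span=100_000)

    def test_single_domain_pileup_equals_own_rescaled_map(self):
        m, bnds = self.domain_map()
        oe = observed_over_expected(m)
        bins = np.array([100, 115])
        b = BoundarySet("chr1", m.bin_size, bins, np.ones(2),
                        np.ones(2, bool), 0.0)
        pile, used = rescaled_pileup(oe, b, max_span=100_000, grid=10)
        assert used == 1
        from chromarch.insulation import _resample_1d
        L = 15
        sub = oe[100 - L:115 + L, 100 - L:115 + L]
        R = _resample_1d(3 * L, 30)
        want = (R @ np.nan_to_num(sub) @ R.T) / (
            R @ np.isfinite(sub).astype(float) @ R.T)
        assert np.allclose(pile, want, equal_nan=True)
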