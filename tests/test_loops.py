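"""Loop calling, APA scoring, anchor classes, hubs and gene groups."""

import numpy as np
import pandas as pd
import pytest

from chromarch.loops import (
    LoopSet,
    apa,
    call_loops,
    classify_anchors,
    classify_genes_gp,
    filter_apa_outliers,
    gene_group_apa,
    loop_statistics,
    promoter_hubs,
    quantile_normalize_columns,
)
from chromarch.matrix import ContactMatrix, ice_balance, observed_over_expected
from chromarch.validation import oracle_union_find_components


def make_loopset(pairs, bs=2_000, apa_vals=None):
    table = pd.DataFrame({
        "bin1": [p[0] for p in pairs], "bin2": [p[1] for p in pairs],
        "enrichment": 1.0, "count": 0.0,
    })
    if apa_vals is not None:
        table["apa"] = apa_vals
    return LoopSet("chr1", bs, table)


class TestCallLoops:
    def test_flat_oe_yields_no_loops(self):
        rng = np.random.default_rng(0)
        n = 200
        counts = rng.poisson(20, (n, n))
        counts = np.triu(counts) + np.triu(counts, 1).T
        oe = np.ones((n, n))
        ls = call_loops(oe, counts, min_dist=5)
        assert len(ls) == 0

    def test_shared_anchor_deduplicated_in_anchor_table(self):
        ls = make_loopset([(10, 40), (10, 80)])
        anchors = ls.unique_anchors()
        assert list(anchors["bin"]) == [10, 40, 80]

    def test_min_dist_below_two_rejected(self):
        with pytest.raises(ValueError):
            call_loops(np.ones((50, 50)), np.ones((50, 50)), min_dist=1)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            call_loops(np.ones((50, 50)), np.ones((50, 50)), min_dist=30,
                       max_dist=10)


class TestAPA:
    def planted_oe(self, pairs, e=3.0, n=400):
        oe = np.ones((n, n))
        for b1, b2 in pairs:
            oe[b1 - 1:b1 + 2, b2 - 1:b2 + 2] = 0.9 * e
            oe[b1, b2] = e
        return oe

    def test_planted_loops_score_near_e(self):
        pairs = [(50, 150), (120, 260), (200, 350)]
        oe = self.planted_oe(pairs)
        ls = make_loopset(pairs)
        apa(oe, ls)
        assert 2.5 <= ls.aggregate_apa <= 3.5

    def test_loop_free_map_scores_near_one(self):
        rng = np.random.default_rng(1)
        n = 400
        oe = rng.normal(1.0, 0.1, (n, n))
        ls = make_loopset([(50, 150), (120, 260)])
        apa(oe, ls)
        assert 0.9 <= ls.aggregate_apa <= 1.1

    def test_invariant_to_global_scaling(self):
        pairs = [(50, 150), (120, 260)]
        oe = self.planted_oe(pairs)
        a = make_loopset(pairs)
        b = make_loopset(pairs)
        apa(oe, a)
        apa(oe * 5.0, b)
        assert a.aggregate_apa == pytest.approx(b.aggregate_apa)

    def test_loops_near_diagonal_skipped(self):
        oe = np.ones((100, 100))
        ls = make_loopset([(40, 45)])  # closer than 2*half_window
        with pytest.raises(ValueError, match="skipped"):
            apa(oe, ls, half_window=10)


class TestFilterOutliers:
    def test_homogeneous_apas_untouched(self):
        rng = np.random.default_rng(0)
        pairs = [(10 * i, 10 * i + 50) for i in range(2, 30)]
        ls = make_loopset(pairs, apa_vals=rng.normal(2.0, 0.1, 28))
        kept, removed = filter_apa_outliers(ls)
        assert len(removed) == 0
        assert len(kept) == 28

    def test_hundredfold_outlier_removed(self):
        rng = np.random.default_rng(1)
        apas = np.concatenate([rng.normal(2.0, 0.1, 50), [200.0]])
        pairs = [(10 * i, 10 * i + 50) for i in range(51)]
        ls = make_loopset(pairs, apa_vals=apas)
        kept, removed = filter_apa_outliers(ls)
        assert len(removed) == 1
        assert removed.apa.iloc[0] == pytest.approx(200.0)

    def test_idempotent_on_filtered_output(self):
        rng = np.random.default_rng(2)
        apas = np.concatenate([rng.normal(2.0, 0.1, 50), [200.0]])
        pairs = [(10 * i, 10 * i + 50) for i in range(51)]
        kept, _ = filter_apa_outliers(make_loopset(pairs, apa_vals=apas))
        kept2, removed2 = filter_apa_outliers(kept)
        assert len(removed2) == 0

    def test_too_few_loops_rejected(self):
        ls = make_loopset([(10, 60)], apa_vals=[2.0])
        with pytest.raises(ValueError, match="10 loops"):
            filter_apa_outliers(ls)


class TestQuantileNormalize:
    def test_columns_share_reference_distribution(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(0, 1, 500),
                           "b": rng.normal(10, 5, 500)})
        qn = quantile_normalize_columns(df)
        assert np.allclose(np.sort(qn.a), np.sort(qn.b))

    def test_rank_order_preserved_per_column(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=100),
                           "b": rng.normal(size=100)})
        qn = quantile_normalize_columns(df)
        assert np.array_equal(np.argsort(df.a.values), np.argsort(qn.a.values))


class TestClassifyAnchors:
    def test_planted_identities_recovered(self, gene_dataset):
        cfg, m, tracks, truth = gene_dataset
        bs = cfg.bin_size
        pairs = [(b1, b2) for b1, b2, _ in truth.loops["chr1"]]
        ls = make_loopset(pairs, bs=bs)
        ann = classify_anchors(ls, tracks, cfg.track_bin, window=3 * bs)
        tss_bins = {int(t) // bs for t in
                    truth.genes[truth.genes["class"] == "GP1"].tss}
        enh_bins = {int((r.start + r.end) // 2) // bs
                    for r in truth.enhancers.itertuples()}
        correct = total = 0
        for b, cls in zip(ann.anchors["bin"], ann.anchors["class"]):
            want = "P" if b in tss_bins else "E" if b in enh_bins else None
            if want is not None:
                total += 1
                correct += cls == want
        assert total > 10
        assert correct / total >= 0.9

    def test_background_anchor_is_undefined(self, gene_dataset):
        cfg, m, tracks, truth = gene_dataset
        bs = cfg.bin_size
        # bins far from any gene or enhancer
        feat = set()
        for t in truth.genes.tss:
            feat.update(range(int(t) // bs - 3, int(t) // bs + 4))
        for r in truth.enhancers.itertuples():
            mid = int((r.start + r.end) // 2) // bs
            feat.update(range(mid - 3, mid + 4))
        empty = [b for b in range(20, 1400, 97) if b not in feat][:6]
        pairs = [(a, b) for a, b in zip(empty, empty[1:]) if b - a > 3]
        ls = make_loopset(pairs, bs=bs)
        ann = classify_anchors(ls, tracks, cfg.track_bin, window=3 * bs)
        assert (ann.anchors["class"] == "U").mean() >= 0.8

    def test_missing_chromosome_rejected(self, gene_dataset):
        cfg, m, tracks, truth = gene_dataset
        ls = LoopSet("chrX", cfg.bin_size, pd.DataFrame(
            {"bin1": [5], "bin2": [50], "enrichment": 1.0, "count": 0.0}))
        with pytest.raises(ValueError, match="chrX"):
            classify_anchors(ls, tracks, cfg.track_bin)


class TestPromoterHubs:
    def run_hubs(self, pairs, classes):
        ls = make_loopset(pairs)
        bins = sorted({b for p in pairs for b in p})
        anchors = pd.DataFrame({"chrom": "chr1", "bin": bins,
                                "class": [classes[b] for b in bins]})
        loop_classes = []
        for b1, b2 in pairs:
            c1, c2 = classes[b1], classes[b2]
            loop_classes.append("U" if "U" in (c1, c2)
                                else "-".join(sorted((c1, c2), reverse=True)))
        from chromarch.loops import AnchorAnnotation
        ann = AnchorAnnotation(anchors, 2_000,
                               pd.Series(loop_classes),
                               pd.Series(loop_classes).value_counts())
        return promoter_hubs(ls, ann)

    def test_chained_loops_form_single_hub(self):
        classes = {10: "P", 40: "P", 80: "P"}
        hubs = self.run_hubs([(10, 40), (40, 80)], classes)
        assert len(hubs) == 1
        assert hubs[0].anchors == [10, 40, 80]

    def test_disjoint_pairs_form_two_hubs(self):
        classes = {10: "P", 40: "P", 100: "P", 140: "P"}
        hubs = self.run_hubs([(10, 40), (100, 140)], classes)
        assert [h.n_promoters for h in hubs] == [2, 2]

    def test_pe_loops_do_not_join_hubs(self):
        classes = {10: "P", 40: "P", 80: "E", 120: "P"}
        hubs = self.run_hubs([(10, 40), (40, 80), (80, 120)], classes)
        assert len(hubs) == 1
        assert hubs[0].anchors == [10, 40]

    def test_matches_union_find_oracle_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            n_anchor = int(rng.integers(4, 20))
            bins = (np.arange(n_anchor) + 1) * 10
            classes = {int(b): ("P" if rng.random() < 0.7 else "E")
                       for b in bins}
            n_edges = int(rng.integers(2, 15))
            pairs = []
            for _ in range(n_edges):
                i, j = rng.choice(n_anchor, 2, replace=False)
                pairs.append((int(bins[min(i, j)]), int(bins[max(i, j)])))
            hubs = self.run_hubs(pairs, classes)
            # oracle on the same promoter-promoter graph
            p_bins = [int(b) for b in bins if classes[int(b)] == "P"]
            index = {b: i for i, b in enumerate(p_bins)}
            edges = [(index[a], index[b]) for a, b in pairs
                     if classes[a] == "P" and classes[b] == "P"]
            roots = oracle_union_find_components(len(p_bins), edges)
            want = sorted(
                sorted(np.array(p_bins)[roots == r].tolist())
                for r in np.unique(roots)
                if (roots == r).sum() >= 2)
            got = sorted(h.anchors for h in hubs)
            assert got == want

    def test_membership_invariant_to_loop_order(self):
        classes = {10: "P", 40: "P", 80: "P", 120: "P"}
        a = self.run_hubs([(10, 40), (40, 80), (80, 120)], classes)
        b = self.run_hubs([(80, 120), (10, 40), (40, 80)], classes)
        assert [h.anchors for h in a] == [h.anchors for h in b]


class TestGeneGroups:
    def test_definitions(self):
        genes = pd.DataFrame({
            "gene_id": ["a", "b", "c", "d"], "chrom": "chr1",
            "start": [10_000, 50_000, 90_000, 130_000],
            "end": [12_000, 52_000, 92_000, 132_000], "strand": "+",
            "tss": [10_000, 50_000, 90_000, 130_000],
        })
        peaks = pd.DataFrame({"chrom": ["chr1"] * 3,
                              "start": [9_500, 49_500, 89_500],
                              "end": [10_500, 50_500, 90_500]})
        # loop anchor at gene a only
        ls = make_loopset([(5, 60)], bs=2_000)
        gp = classify_genes_gp(genes, peaks, peaks, ls, tss_window=1_000)
        out = dict(zip(gp.gene_id, gp.group))
        assert out == {"a": "GP1", "b": "GP2", "c": "GP2", "d": "GP3"}

    def test_single_mark_is_partial_gp2(self):
        genes = pd.DataFrame({
            "gene_id": ["a"], "chrom": "chr1", "start": [10_000],
            "end": [12_000], "strand": "+", "tss": [10_000]})
        atac = pd.DataFrame({"chrom": ["chr1"], "start": [9_500],
                             "end": [10_500]})
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        ls = make_loopset([(5, 60)], bs=2_000)
        gp = classify_genes_gp(genes, atac, empty, ls, tss_window=1_000)
        assert gp.group.iloc[0] == "GP2"
        assert bool(gp.partial.iloc[0])

    def test_pure_function_reruns_identically(self, gene_dataset):
        cfg, m, tracks, truth = gene_dataset
        pairs = [(b1, b2) for b1, b2, _ in truth.loops["chr1"]]
        ls = make_loopset(pairs, bs=cfg.bin_size)
        a = classify_genes_gp(truth.genes, truth.peaks["atac"],
                              truth.peaks["h3k4me3"], ls)
        b = classify_genes_gp(truth.genes, truth.peaks["atac"],
                              truth.peaks["h3k4me3"], ls)
        pd.testing.assert_frame_equal(a, b)

    def test_group_apa_ordering_gp1_highest(self, gene_dataset):
        cfg, m, tracks, truth = gene_dataset
        oe = observed_over_expected(m)
        pairs = [(b1, b2) for b1, b2, _ in truth.loops["chr1"]]
        ls = make_loopset(pairs, bs=cfg.bin_size)
        gp = classify_genes_gp(truth.genes, truth.peaks["atac"],
                               truth.peaks["h3k4me3"], ls,
                               tss_window=2 * cfg.bin_size)
        apas = gene_group_apa(oe, gp, cfg.bin_size, "chr1", half_window=8)
        assert apas["GP1"] > apas["GP2"]
        assert apas["GP1"] > apas["GP3"]
        assert abs(apas["GP2"] - 1) < 0.3 and abs(apas["GP3"] - 1) < 0.3


class TestLoopStatistics:
    def test_median_span_and_histogram(self):
        pairs = [(10, 20), (50, 70), (100, 110)]
        ls = make_loopset(pairs, bs=2_000)
        anchors = pd.DataFrame({
            "chrom": "chr1", "bin": [10, 20, 50, 70, 100, 110],
            "class": ["P", "E", "P", "E", "P", "E"]})
        from chromarch.loops import AnchorAnnotation
        lc = pd.Series(["P-E"] * 3)
        ann = AnchorAnnotation(anchors, 2_000, lc, lc.value_counts())
        stats = loop_statistics(ls, ann)
        assert stats["median_span"] == 20 * 1_000  # median pair distance 10 bins
        assert stats["enhancers_per_promoter"] == {1: 3}

    def test_enhancer_context_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(10)], "chrom": "chr1",
            "start": np.arange(10) * 50_000,
            "end": np.arange(10) * 50_000 + 30_000,
        })
        genes["tss"] = genes.start
        genes["strand"] = "+"
        exons = pd.DataFrame({
            "chrom": "chr1", "gene_id": genes.gene_id,
            "start": genes.start, "end": genes.start + 5_000})
        e_bins = [3, 30, 55, 130, 200]
        pairs = [(b, b + 40) for b in e_bins]
        ls = make_loopset(pairs, bs=2_000)
        anchors_df = pd.DataFrame({
            "chrom": "chr1",
            "bin": [b for p in pairs for b in p],
        }).drop_duplicates()
        anchors_df["class"] = ["E" if b in e_bins else "P"
                               for b in anchors_df["bin"]]
        from chromarch.loops import AnchorAnnotation
        lc = pd.Series(["P-E"] * len(pairs))
        ann = AnchorAnnotation(anchors_df, 2_000, lc, lc.value_counts())
        stats = loop_statistics(ls, ann, genes=genes, exons=exons)

        def oracle_context(b):
            lo, hi = b * 2_000, (b + 1) * 2_000
            if any(r.start < hi and r.end > lo for r in exons.itertuples()):
                return "exonic"
            if any(r.start < hi and r.end > lo for r in genes.itertuples()):
                return "intronic"
            return "intergenic"

        want = pd.Series([oracle_context(b) for b in e_bins]).value_counts()
        assert stats["enhancer_context"] == want.to_dict()
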