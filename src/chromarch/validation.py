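"""Standard recovery experiments on simulated data.

Each function runs one self-contained experiment — simulate a dataset with
known planted structure, run the pipeline stage under study, and measure
recovery — returning a flat dict of metrics.  The experiments double as the
package's benchmark suite: the test suite asserts on their outputs and the
acceptance script reports them.

Brute-force reference implementations (interval scans, union-find) used to
cross-check the pipeline's faster routines live here as ``oracle_*``
functions; they are deliberately written independently of the code they
check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compartments import (
    compute_eigenvectors, compartment_strength, fit_three_state_gmm,
    quantile_norm_score, saddle_matrix,
)
from .insulation import (
    call_boundaries, classify_boundaries, insulation_profile, li_threshold,
)
from .loops import (
    apa, call_loops, classify_anchors, classify_genes_gp, gene_group_apa,
    promoter_hubs, LoopSet,
)
from .matrix import ContactMatrix, ice_balance, observed_over_expected, scc
from .simulate import (
    SimulationConfig, build_expected_matrix, checkerboard_compartments,
    sample_contact_counts, simulate_dataset, simulate_ortholog_genomes,
)
from .synteny import (
    OrthologyMap, map_region_to_flanking_genes, sample_background_regions,
    synteny_conservation_test,
)

__all__ = [
    "quantile_score_experiment",
    "ice_experiment",
    "oe_experiment",
    "scc_experiment",
    "compartment_experiment",
    "gmm_experiment",
    "boundary_experiment",
    "classification_oracle_experiment",
    "loop_experiment",
    "hub_gp_experiment",
    "synteny_experiment",
    "oracle_classify_boundaries",
    "oracle_nearest_gene",
    "oracle_union_find_components",
]


def quantile_score_experiment() -> dict:
    """Worked example of the quantile-enrichment score.

    With 64 values whose top two tie, the tied maximum has mid-rank quantile
    63/64 = 1 - 2**-6, so its score is exactly 6; the analytic check of the
    normalisation.  Also reports the median's score (exactly 1).
    """
    values = np.concatenate([np.arange(1.0, 63.0), [63.0, 63.0]])
    scores = quantile_norm_score(values)
    odd = np.arange(1.0, 102.0)
    return {
        "score_at_top64th_quantile": float(scores[-1]),
        "score_at_median": float(quantile_norm_score(odd)[50]),
    }


def _checkerboard_config(n_bins: int, bin_size: int, depth: int, seed: int,
                         boost: float = 2.0) -> SimulationConfig:
    comp = checkerboard_compartments(n_bins, bin_size, seed=seed)
    return SimulationConfig(
        chrom_lengths={"chr1": n_bins * bin_size}, bin_size=bin_size,
        alpha=1.0, compartments={"chr1": comp}, compartment_boost=boost,
        depth=depth, seed=seed,
    )


def ice_experiment(seed: int, n_bins: int = 500) -> dict:
    """Marginal equalisation of ICE balancing on a simulated matrix."""
    cfg = _checkerboard_config(n_bins, 10_000, 2_000_000, seed)
    exp = build_expected_matrix(cfg)["chr1"]
    counts = sample_contact_counts(exp, cfg.depth, seed)
    m = ice_balance(ContactMatrix("chr1", cfg.bin_size, counts))
    bal = m.balanced
    marg = np.nansum(bal[np.ix_(m.valid, m.valid)], axis=0)
    return {
        "marginal_cv": float(marg.std() / marg.mean()),
        "n_valid_bins": int(m.valid.sum()),
    }


def oe_experiment(seed: int, n_bins: int = 400) -> dict:
    """Exactness of the O/E diagonal-mean normalisation."""
    cfg = _checkerboard_config(n_bins, 10_000, 2_000_000, seed)
    exp = build_expected_matrix(cfg)["chr1"]
    counts = sample_contact_counts(exp, cfg.depth, seed)
    m = ice_balance(ContactMatrix("chr1", cfg.bin_size, counts))
    oe = observed_over_expected(m)
    devs = []
    vmask = np.outer(m.valid, m.valid)
    for d in range(1, n_bins):
        vals = np.diagonal(oe, offset=d)
        ok = np.isfinite(vals) & np.diagonal(vmask, offset=d)
        if ok.sum():
            devs.append(abs(vals[ok].mean() - 1.0))
    return {"max_diagonal_mean_deviation": float(max(devs))}


def scc_experiment(seed: int, n_bins: int = 500, depth: int = 1_000_000) -> dict:
    """Reproducibility: replicate pairs score high, different maps lower."""
    cfg = _checkerboard_config(n_bins, 10_000, depth, seed)
    exp = build_expected_matrix(cfg)["chr1"]

    def sample(s):
        c = sample_contact_counts(exp, depth, s)
        return ice_balance(ContactMatrix("chr1", cfg.bin_size, c))

    m1, m2 = sample(seed * 7 + 1), sample(seed * 7 + 2)
    cfg_other = _checkerboard_config(n_bins, 10_000, depth, seed + 101)
    exp_other = build_expected_matrix(cfg_other)["chr1"]
    c3 = sample_contact_counts(exp_other, depth, seed * 7 + 3)
    m3 = ice_balance(ContactMatrix("chr1", cfg.bin_size, c3))
    return {
        "scc_self": float(scc(m1, m1).scc),
        "scc_replicate": float(scc(m1, m2).scc),
        "scc_non_replicate": float(scc(m1, m3).scc),
    }


def compartment_experiment(seed: int, n_bins: int = 1000,
                           depth: int = 10_000_000) -> dict:
    """Checkerboard recovery: per-bin state signs and saddle strength.

    Strength from the sampled map is compared to the oracle value computed
    with the same formula on the noise-free expected matrix (which is
    generatively balanced, so it carries uniform weights).  Both routes use
    the smoothed distance expected, the appropriate choice for saddle
    analysis.
    """
    cfg = _checkerboard_config(n_bins, 10_000, depth, seed)
    exp = build_expected_matrix(cfg)["chr1"]
    truth = cfg.bin_states("chr1")
    ref = (truth == "A").astype(float)

    def strength_of(mat, balanced_already):
        if balanced_already:
            m = ContactMatrix("chr1", cfg.bin_size, mat,
                              weights=np.ones(n_bins),
                              valid=np.ones(n_bins, bool))
        else:
            m = ice_balance(ContactMatrix("chr1", cfg.bin_size, mat))
        oe = observed_over_expected(m, smooth=True)
        prof = compute_eigenvectors(oe, ref, chrom="chr1")
        return compartment_strength(saddle_matrix(oe, prof)), prof

    counts = sample_contact_counts(exp, depth, seed)
    s_obs, prof = strength_of(counts.astype(float), False)
    s_oracle, _ = strength_of(exp, True)
    fin = np.isfinite(prof.e1)
    signs = np.where(truth == "A", 1.0, -1.0)
    agreement = float(np.mean(np.sign(prof.e1[fin]) == signs[fin]))
    return {
        "sign_agreement": agreement,
        "strength_observed": float(s_obs),
        "strength_oracle": float(s_oracle),
        "strength_relative_error": float(abs(s_obs - s_oracle) / s_oracle),
    }


def gmm_experiment(seed: int, n: int = 10_000) -> dict:
    """Threshold and weight recovery for a planted three-state mixture.

    Components at -1/0/1 with sd 0.1 and weights 0.25/0.5/0.25; with equal
    variances the analytic density intersections are the midpoints +-0.5
    shifted by the log-weight term (negligible at sd 0.1).
    """
    rng = np.random.default_rng(seed)
    x = np.concatenate([
        rng.normal(-1, 0.1, n // 4), rng.normal(0, 0.1, n // 2),
        rng.normal(1, 0.1, n - n // 4 - n // 2),
    ])
    fit = fit_three_state_gmm(x)
    return {
        "threshold_low": float(fit.thresholds[0]),
        "threshold_high": float(fit.thresholds[1]),
        "threshold_low_error": float(abs(fit.thresholds[0] + 0.5)),
        "threshold_high_error": float(abs(fit.thresholds[1] - 0.5)),
        "weight_errors_max": float(np.max(np.abs(
            fit.weights - np.array([0.25, 0.5, 0.25])))),
    }


def boundary_experiment(seed: int, n_bins: int = 2000,
                        depth: int = 10_000_000,
                        n_boundaries: int = 20) -> dict:
    """Planted-boundary recovery (F1 at +-1 bin) and the Li strong/weak split."""
    rng = np.random.default_rng(seed)
    bs = 5_000
    # boundaries at least 40 bins apart so each dip is resolvable
    positions = []
    cursor = 60
    while len(positions) < n_boundaries and cursor < n_bins - 60:
        positions.append(cursor)
        cursor += int(rng.integers(40, 150))
    cfg = SimulationConfig(
        chrom_lengths={"chr1": n_bins * bs}, bin_size=bs, alpha=1.0,
        boundaries={"chr1": [p * bs for p in positions]},
        boundary_attenuation=0.4, depth=depth, seed=seed,
    )
    exp = build_expected_matrix(cfg)["chr1"]
    counts = sample_contact_counts(exp, depth, seed)
    m = ice_balance(ContactMatrix("chr1", bs, counts))
    prof = insulation_profile(m, 10 * bs)
    b = call_boundaries(prof)
    called = b.bins[b.strong]
    truth = np.asarray(positions)
    tp = sum(1 for t in truth if np.any(np.abs(called - t) <= 1))
    recall = tp / truth.size
    precision = (sum(1 for c in called if np.any(np.abs(truth - c) <= 1))
                 / max(1, called.size))
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)

    # Li split on a planted bimodal strength distribution
    strengths = np.concatenate([
        np.abs(rng.normal(0.1, 0.02, 160)), np.abs(rng.normal(1.0, 0.1, 40))])
    thr = li_threshold(strengths)
    labels = strengths >= thr
    truth_labels = np.arange(200) >= 160
    li_acc = float(np.mean(labels == truth_labels))
    return {
        "n_planted": int(truth.size),
        "n_called_strong": int(called.size),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "li_split_accuracy": li_acc,
    }


# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_classify_boundaries(boundary_bins, bin_size, loops, tss, accessible,
                               limits, tolerance=1):
    """Reference hierarchical classifier: scan every boundary x feature pair."""
    tol_bp = tolerance * bin_size
    out = []
    for b in boundary_bins:
        b_lo, b_hi = b * bin_size, (b + 1) * bin_size

        def touches(s, e):
            return b_lo < e + tol_bp and b_hi > s - tol_bp

        cls = "unassigned"
        anchor_ivals = []
        if loops is not None:
            for r in loops.itertuples():
                anchor_ivals.append((r.start1, r.end1))
                anchor_ivals.append((r.start2, r.end2))
            if any(touches(s, e) for s, e in anchor_ivals):
                cls = "loop-anchor"
        if cls == "unassigned" and tss is not None:
            for r in tss.itertuples():
                pos = r.tss if hasattr(r, "tss") else r.start
                at_anchor = any(s - tol_bp <= pos < e + tol_bp
                                for s, e in anchor_ivals)
                if not at_anchor and touches(pos, pos + 1):
                    cls = "TSS"
                    break
        if cls == "unassigned" and accessible is not None:
            if any(touches(r.start, r.end) for r in accessible.itertuples()):
                cls = "accessible"
        if cls == "unassigned" and limits is not None:
            if any(touches(r.bin * bin_size, r.bin * bin_size + 1)
                   for r in limits.itertuples()):
                cls = "compartment-limit"
        out.append(cls)
    return np.array(out)


def oracle_nearest_gene(genes: pd.DataFrame, point: int) -> str:
    """Reference closest-overlapping-gene rule: full scan per query."""
    best, best_key = None, None
    for r in genes.itertuples():
        if r.start <= point < r.end:
            dist = -1  # overlap beats any distance
        elif point < r.start:
            dist = r.start - point
        else:
            dist = point - r.end + 1
        key = (dist, r.start)
        if best_key is None or key < best_key:
            best, best_key = r.gene_id, key
    return best


def oracle_union_find_components(n_nodes: int, edges) -> np.ndarray:
    """Reference connected components by plain union-find."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return np.array([find(i) for i in range(n_nodes)])


def classification_oracle_experiment(seed: int, n_fixtures: int = 100) -> dict:
    """Boundary classification and nearest-gene mapping vs brute force.

    Random fixtures of boundaries, loops, TSSs, accessible sites and
    compartment limits; reports the fraction of fixtures on which the fast
    implementations agree exactly with the full-scan oracles.
    """
    rng = np.random.default_rng(seed)
    bs = 5_000
    n_match = 0
    gene_match = 0
    n_gene_queries = 0
    from .insulation import BoundarySet

    for _ in range(n_fixtures):
        n_b = int(rng.integers(3, 12))
        bins = np.sort(rng.choice(200, size=n_b, replace=False))
        b = BoundarySet("chr1", bs, bins, np.ones(n_b), np.ones(n_b, bool), 0.0)
        def ivals(k, w=2):
            starts = rng.integers(0, 198, k) * bs
            return starts, starts + w * bs
        s1, e1 = ivals(int(rng.integers(1, 6)))
        s2, e2 = ivals(int(rng.integers(1, 6)))
        loops_df = pd.DataFrame({"chrom1": "chr1", "start1": s1[:len(s2)],
                                 "end1": e1[:len(s2)], "chrom2": "chr1",
                                 "start2": s2[:len(s1)], "end2": e2[:len(s1)]})
        tss_df = pd.DataFrame({"chrom": "chr1",
                               "tss": rng.integers(0, 200 * bs, int(rng.integers(2, 10))),
                               "gene_id": "g"})
        tss_df["start"] = tss_df.tss
        acc_s, acc_e = ivals(int(rng.integers(1, 8)), w=1)
        acc_df = pd.DataFrame({"chrom": "chr1", "start": acc_s, "end": acc_e})
        lim_df = pd.DataFrame({"chrom": "chr1",
                               "bin": rng.integers(0, 200, int(rng.integers(1, 6)))})
        got = classify_boundaries(b, loops_df, tss_df, acc_df, lim_df).classes
        want = oracle_classify_boundaries(bins, bs, loops_df, tss_df, acc_df,
                                          lim_df)
        n_match += int(np.array_equal(got, want))

        # nearest-gene mapping fixture
        n_g = int(rng.integers(2, 15))
        starts = np.sort(rng.choice(500_000, size=n_g, replace=False))
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n_g)], "chrom": "chr1",
            "start": starts, "end": starts + int(rng.integers(500, 5_000)),
        })
        genes["tss"] = genes.start
        from .synteny import _closest_gene
        for q in rng.integers(0, 520_000, 5):
            i = _closest_gene(genes.start.to_numpy(), genes.end.to_numpy(),
                              int(q))
            got_g = genes.gene_id.to_numpy()[i]
            want_g = oracle_nearest_gene(genes, int(q))
            gene_match += int(got_g == want_g)
            n_gene_queries += 1
    return {
        "classification_agreement": n_match / n_fixtures,
        "nearest_gene_agreement": gene_match / n_gene_queries,
        "n_fixtures": n_fixtures,
    }


def loop_experiment(seed: int, n_bins: int = 1000,
                    depth: int = 10_000_000, n_loops: int = 30) -> dict:
    """Planted-loop recovery and APA on flat-decay maps.

    Flat decay (alpha=0) isolates the focal-caller behaviour from the
    distance-decay gradient; loops are planted at e=3 with spans of
    30-200 bins.  Also reports the aggregate APA of the true loop list and
    of the same list evaluated on a loop-free replicate.
    """
    rng = np.random.default_rng(seed)
    bs = 2_000
    loops = []
    while len(loops) < n_loops:
        b1 = int(rng.integers(30, n_bins - 250))
        b2 = b1 + int(rng.integers(30, 200))
        if all(abs(b1 - u1) > 5 or abs(b2 - u2) > 5 for u1, u2, _ in loops):
            loops.append((b1, b2, 3.0))
    cfg = SimulationConfig(chrom_lengths={"chr1": n_bins * bs}, bin_size=bs,
                           alpha=0.0, loops={"chr1": loops}, depth=depth,
                           seed=seed)
    exp = build_expected_matrix(cfg)["chr1"]
    counts = sample_contact_counts(exp, depth, seed)
    m = ice_balance(ContactMatrix("chr1", bs, counts))
    oe = observed_over_expected(m)
    called_set = call_loops(oe, m.counts, chrom="chr1", bin_size=bs,
                            min_dist=10)
    truth = [(b1, b2) for b1, b2, _ in loops]
    called = list(zip(called_set.table.bin1, called_set.table.bin2))

    def near(p, qs, t=1):
        return any(abs(p[0] - q[0]) <= t and abs(p[1] - q[1]) <= t for q in qs)

    recall = sum(1 for t in truth if near(t, called)) / len(truth)
    precision = (sum(1 for c in called if near(c, truth))
                 / max(1, len(called)))
    true_loops = LoopSet("chr1", bs, pd.DataFrame({
        "bin1": [t[0] for t in truth], "bin2": [t[1] for t in truth],
        "enrichment": 1.0, "count": 0.0}))
    apa(oe, true_loops)

    cfg0 = SimulationConfig(chrom_lengths={"chr1": n_bins * bs}, bin_size=bs,
                            alpha=0.0, depth=depth, seed=seed + 1)
    exp0 = build_expected_matrix(cfg0)["chr1"]
    c0 = sample_contact_counts(exp0, depth, seed + 1)
    m0 = ice_balance(ContactMatrix("chr1", bs, c0))
    oe0 = observed_over_expected(m0)
    free_loops = LoopSet("chr1", bs, true_loops.table.copy())
    apa(oe0, free_loops)
    return {
        "precision": float(precision),
        "recall": float(recall),
        "n_called": len(called),
        "apa_planted": float(true_loops.aggregate_apa),
        "apa_loop_free": float(free_loops.aggregate_apa),
    }


def hub_gp_experiment(seed: int) -> dict:
    """Full annotation chain: anchors, promoter hubs and GP gene groups.

    Simulates a gene-bearing map, calls loops, classifies anchors from the
    generated chromatin tracks, detects promoter hubs (checked exactly
    against a union-find oracle on the same promoter-promoter graph) and
    recovers the planted GP1/GP2/GP3 gene classes.
    """
    bs = 2_000
    cfg = SimulationConfig(chrom_lengths={"chr1": 3_000_000}, bin_size=bs,
                           alpha=1.0, depth=15_000_000, seed=seed,
                           n_genes=60, n_enhancers=25, track_bin=200)
    counts, expected, tracks, truth = simulate_dataset(cfg)
    m = ice_balance(ContactMatrix("chr1", bs, counts["chr1"]))
    oe = observed_over_expected(m)
    called = call_loops(oe, m.counts, chrom="chr1", bin_size=bs, min_dist=5)
    ann = classify_anchors(called, tracks, cfg.track_bin, window=3 * bs)
    hubs = promoter_hubs(called, ann, truth.genes)

    # oracle: union-find over the identical promoter-promoter graph
    p_anchors = ann.anchors.loc[ann.anchors["class"] == "P", "bin"].to_numpy()
    index = {b: i for i, b in enumerate(p_anchors)}
    pp = called.table[ann.loop_classes == "P-P"]
    edges = [(index[b1], index[b2]) for b1, b2 in zip(pp.bin1, pp.bin2)]
    roots = oracle_union_find_components(len(p_anchors), edges)
    oracle_hubs = []
    for root in np.unique(roots):
        members = sorted(int(b) for b in p_anchors[roots == root])
        if len(members) >= 2:
            oracle_hubs.append(members)
    oracle_hubs.sort()
    got_hubs = sorted(h.anchors for h in hubs)
    hubs_equal = got_hubs == oracle_hubs

    gp = classify_genes_gp(truth.genes, truth.peaks["atac"],
                           truth.peaks["h3k4me3"], called, tss_window=2 * bs)
    merged = gp.merge(truth.genes[["gene_id", "class"]], on="gene_id")
    gp_accuracy = float((merged.group == merged["class"]).mean())
    group_apa = gene_group_apa(oe, gp, bs, "chr1", half_window=8)
    return {
        "hubs_equal_oracle": bool(hubs_equal),
        "n_hubs": len(hubs),
        "median_promoters_per_hub": float(np.median(
            [h.n_promoters for h in hubs])) if hubs else float("nan"),
        "gp_accuracy": gp_accuracy,
        "apa_gp1": group_apa.get("GP1", float("nan")),
        "apa_gp2": group_apa.get("GP2", float("nan")),
        "apa_gp3": group_apa.get("GP3", float("nan")),
    }


def _disjoint_regions(rng: np.random.Generator, genome_length: int, n: int,
                      min_len: int, max_len: int) -> pd.DataFrame:
    rows: list[tuple[int, int]] = []
    tries = 0
    while len(rows) < n and tries < 50_000:
        tries += 1
        L = int(rng.integers(min_len, max_len))
        s = int(rng.integers(0, genome_length - L))
        if all(s + L <= s0 or s >= e0 for s0, e0 in rows):
            rows.append((s, s + L))
    rows.sort()
    return pd.DataFrame({"chrom": "chrA", "start": [r[0] for r in rows],
                         "end": [r[1] for r in rows]})


def synteny_null_replicate(seed: int, n_genes: int = 800,
                           n_foreground: int = 30) -> float:
    """One null replicate: uniformly shuffled genome, arbitrary foreground.

    Foreground regions carry no conservation signal, so the one-sided
    Wilcoxon p-value is a draw from the null distribution.
    """
    rng = np.random.default_rng(seed)
    ga, gb, og, _ = simulate_ortholog_genomes(n_genes, 0, 0.5, seed)
    glen = int(ga.end.max())
    fg = _disjoint_regions(rng, glen, n_foreground, 6_000, 16_000)
    bg = sample_background_regions({"chrA": glen}, fg, 3, rng)
    omap = OrthologyMap.from_frame(og)
    fgm = map_region_to_flanking_genes(fg, ga, gb, omap)
    bgm = map_region_to_flanking_genes(bg, ga, gb, omap)
    rep = synteny_conservation_test(fgm, bgm, ga, gb, omap)
    return rep["wilcoxon_p"]


def synteny_power_replicate(seed: int, n_genes: int = 2_000,
                            n_blocks: int = 100,
                            shuffle_fraction: float = 0.5) -> dict:
    """One alternative replicate: conserved blocks as foreground regions."""
    rng = np.random.default_rng(100_000 + seed)
    ga, gb, og, blocks = simulate_ortholog_genomes(
        n_genes, n_blocks, shuffle_fraction, seed)
    fg = blocks[["chrom", "start", "end"]].copy()
    bg = sample_background_regions({"chrA": int(ga.end.max())}, fg, 3, rng)
    omap = OrthologyMap.from_frame(og)
    fgm = map_region_to_flanking_genes(fg, ga, gb, omap)
    bgm = map_region_to_flanking_genes(bg, ga, gb, omap)
    rep = synteny_conservation_test(fgm, bgm, ga, gb, omap)
    return {"wilcoxon_p": rep["wilcoxon_p"], "chi2_p": rep["chi2_p"]}


def synteny_experiment(seed: int, n_null: int = 1000, n_power: int = 50,
                       alpha: float = 0.05) -> dict:
    """Type-I error under the null and power at the planted 50% contrast."""
    null_ps = np.array([synteny_null_replicate(seed * 1_000 + k)
                        for k in range(n_null)])
    power_reps = [synteny_power_replicate(seed * 1_000 + k)
                  for k in range(n_power)]
    wil = np.array([r["wilcoxon_p"] for r in power_reps])
    chi = np.array([r["chi2_p"] for r in power_reps])
    return {
        "type1_error": float(np.mean(null_ps < alpha)),
        "power_wilcoxon": float(np.mean(wil < alpha)),
        "power_chi2": float(np.mean(chi < alpha)),
        "n_null": n_null,
        "n_power": n_power,
    }
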