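"""Synthetic Micro-C data with planted, recoverable structure.

Every downstream stage of the pipeline (balancing, compartments, insulation,
loops, synteny) is validated against maps generated here, where the ground
truth — compartment states, boundary positions, loop anchors, gene classes,
orthology — is known exactly.

The generative model is multiplicative on the expected contact frequency:

    E[i, j] = C * (d_ij)^-alpha * comp(i, j) * ins(i, j) * loop(i, j) * dom(i, j)

with ``d_ij`` the genomic distance between bin centres (clamped to one bin on
the diagonal), a homotypic boost ``f`` for pairs of bins in the same A or B
compartment, an attenuation ``b`` per insulation boundary straddled, a focal
enrichment ``e`` on loop-anchor pixels (with a 0.9e halo on the eight
neighbouring pixels, so the centre stays the unique maximum while the local
3x3 mean remains close to e), and an internal boost for pairs inside a
self-interacting domain.  Counts are Poisson draws on the upper triangle,
symmetrised.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "checkerboard_compartments",
    "build_expected_matrix",
    "sample_contact_counts",
    "simulate_annotations",
    "simulate_ortholog_genomes",
    "simulate_dataset",
]

_STATES = ("A", "I", "B")
_GENE_CLASSES = ("GP1", "GP2", "GP3")


@dataclass
class SimulationConfig:
    """Parameters of one simulated Micro-C experiment.

    Coordinates are 0-based, half-open base pairs; loop anchors are given as
    bin indices.  All multiplicative factors must be strictly positive.
    """

    chrom_lengths: dict[str, int]
    bin_size: int
    alpha: float = 1.0
    #: per-chromosome compartment intervals ``(start_bp, end_bp, state)``
    compartments: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    #: homotypic boost f applied to same-state A/A and B/B bin pairs
    compartment_boost: float = 1.0
    #: per-chromosome boundary positions (bp)
    boundaries: dict[str, list[int]] = field(default_factory=dict)
    #: attenuation b in (0, 1] applied once per boundary straddled
    boundary_attenuation: float = 1.0
    #: per-chromosome loops ``(bin1, bin2, enrichment)``
    loops: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    #: per-chromosome self-interacting domains ``(start_bp, end_bp, boost)``
    domains: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    #: per-chromosome unmappable intervals (bp), zeroed before sampling
    unmappable: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    depth: int = 1_000_000
    seed: int = 0
    # --- annotation / track parameters ---
    n_genes: int = 0
    n_enhancers: int = 0
    #: fractions of genes assigned to GP1 / GP2 / GP3
    gene_class_fractions: tuple[float, float, float] = (0.30, 0.35, 0.35)
    #: "even", "random", or "compartment_biased" (active genes in A, silent in B)
    gene_placement: str = "even"
    track_bin: int = 200
    peak_height: float = 10.0
    peak_width: int = 600
    track_noise: float = 0.5
    track_background: float = 1.0

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.bin_size)

    def validate(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.compartment_boost < 1.0:
            raise ValueError("compartment boost f must be >= 1")
        if not (0.0 < self.boundary_attenuation <= 1.0):
            raise ValueError("boundary attenuation b must lie in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
            ivals = sorted((s, e) for s, e, _ in self.compartments.get(chrom, ()))
            for s, e, state in self.compartments.get(chrom, ()):
                if state not in _STATES:
                    raise ValueError(f"unknown compartment state {state!r}")
                if not (0 <= s < e <= length):
                    raise ValueError(
                        f"compartment interval [{s}, {e}) outside {chrom}"
                    )
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping compartment intervals on {chrom}: "
                        f"[{s1}, {e1}) and [{s2}, {e2})"
                    )
            nb = self.n_bins(chrom)
            unmap = self._unmappable_bins(chrom)
            for b1, b2, e in self.loops.get(chrom, ()):
                if e < 1.0:
                    raise ValueError("loop enrichment e must be >= 1")
                if not (0 <= b1 < nb and 0 <= b2 < nb):
                    raise ValueError(f"loop anchor bin outside {chrom}")
                if b1 in unmap or b2 in unmap:
                    raise ValueError(
                        f"loop anchor in unmappable bin on {chrom}: ({b1}, {b2})"
                    )
            for s, e, boost in self.domains.get(chrom, ()):
                if boost <= 0:
                    raise ValueError("domain boost must be positive")

    def _unmappable_bins(self, chrom: str) -> set[int]:
        bins: set[int] = set()
        nb = self.n_bins(chrom)
        for s, e in self.unmappable.get(chrom, ()):
            lo = max(0, s // self.bin_size)
            hi = min(nb, -(-e // self.bin_size))
            bins.update(range(lo, hi))
        return bins

    def bin_states(self, chrom: str) -> np.ndarray:
        """Per-bin compartment state; bins outside any interval are 'I'."""
        states = np.full(self.n_bins(chrom), "I", dtype="U1")
        for s, e, state in self.compartments.get(chrom, ()):
            lo = s // self.bin_size
            hi = -(-e // self.bin_size)
            states[lo:hi] = state
        return states

    def boundary_bins(self, chrom: str) -> np.ndarray:
        """Boundary positions as bin indices (boundary sits at a bin start)."""
        pos = np.asarray(sorted(self.boundaries.get(chrom, ())), dtype=int)
        return pos // self.bin_size


@dataclass
class GroundTruth:
    """Planted structure of a simulation, for recovery testing."""

    states: dict[str, np.ndarray]
    boundary_bins: dict[str, np.ndarray]
    loops: dict[str, list[tuple[int, int, float]]]
    genes: pd.DataFrame
    enhancers: pd.DataFrame
    peaks: dict[str, pd.DataFrame]
    #: orthology pairs, only populated by the two-genome simulator
    orthology: pd.DataFrame | None = None


def checkerboard_compartments(
    n_bins: int,
    bin_size: int,
    seed: int,
    min_block: int = 20,
    max_block: int = 80,
    states: tuple[str, str] = ("A", "B"),
) -> list[tuple[int, int, str]]:
    """Alternating A/B intervals with randomised block lengths (in bins).

    Variable segment sizes mirror real compartment domains; a strictly
    periodic checkerboard would alias into the distance decay (state pairing
    becomes a function of distance alone) and cancel out of the O/E map.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[int, int, str]] = []
    pos, k = 0, 0
    while pos < n_bins:
        end = min(n_bins, pos + int(rng.integers(min_block, max_block + 1)))
        out.append((pos * bin_size, end * bin_size, states[k % 2]))
        pos, k = end, k + 1
    return out


def build_expected_matrix(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Noise-free expected contact matrix per chromosome.

    The closed-form product of decay, compartment, insulation, loop and domain
    factors; exactly symmetric; unmappable bins zeroed.
    """
    config.validate()
    out: dict[str, np.ndarray] = {}
    for chrom in config.chrom_lengths:
        n = config.n_bins(chrom)
        idx = np.arange(n)
        dist = np.abs(idx[:, None] - idx[None, :])
        dist_bp = np.maximum(dist, 1) * config.bin_size
        expected = dist_bp.astype(float) ** (-config.alpha)

        states = config.bin_states(chrom)
        if config.compartment_boost != 1.0:
            ab = (states == "A") | (states == "B")
            same = (states[:, None] == states[None, :]) & ab[:, None] & ab[None, :]
            expected[same] *= config.compartment_boost

        bbins = config.boundary_bins(chrom)
        if bbins.size and config.boundary_attenuation != 1.0:
            # straddle count for pair (i, j), i < j: boundaries p with i < p <= j
            cum = np.searchsorted(bbins, idx, side="right")
            n_straddle = np.abs(cum[:, None] - cum[None, :])
            expected *= config.boundary_attenuation ** n_straddle

        for s, e, boost in config.domains.get(chrom, ()):
            lo, hi = s // config.bin_size, -(-e // config.bin_size)
            expected[lo:hi, lo:hi] *= boost

        loop_factor = np.ones_like(expected)
        for b1, b2, e in config.loops.get(chrom, ()):
            halo = max(1.0, 0.9 * e)
            lo1, hi1 = max(0, b1 - 1), min(n, b1 + 2)
            lo2, hi2 = max(0, b2 - 1), min(n, b2 + 2)
            block = loop_factor[lo1:hi1, lo2:hi2]
            loop_factor[lo1:hi1, lo2:hi2] = np.maximum(block, halo)
            loop_factor[b1, b2] = max(loop_factor[b1, b2], e)
        loop_factor = np.maximum(loop_factor, loop_factor.T)
        expected *= loop_factor

        unmap = sorted(config._unmappable_bins(chrom))
        if unmap:
            expected[unmap, :] = 0.0
            expected[:, unmap] = 0.0
        out[chrom] = expected
    return out


def sample_contact_counts(
    expected: np.ndarray, depth: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Poisson counts with total mean ``depth``, symmetrised.

    Counts are drawn independently per upper-triangle pixel (diagonal
    included) with mean proportional to the expected matrix, then mirrored.
    """
    expected = np.asarray(expected, dtype=float)
    if not np.all(np.isfinite(expected)):
        raise ValueError("expected matrix contains non-finite values")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu = np.triu_indices(expected.shape[0])
    lam = expected[iu]
    total = lam.sum()
    if total <= 0:
        raise ValueError("expected matrix sums to zero; nothing to sample")
    counts_ut = rng.poisson(lam * (depth / total))
    counts = np.zeros(expected.shape, dtype=np.int64)
    counts[iu] = counts_ut
    counts = counts + np.triu(counts, k=1).T
    return counts


def sample_contact_maps(
    expected: dict[str, np.ndarray], depth: int, seed: int
) -> dict[str, np.ndarray]:
    """Sample all chromosomes, splitting ``depth`` by expected mass."""
    rng = np.random.default_rng(seed)
    masses = {c: float(np.triu(m).sum()) for c, m in expected.items()}
    total = sum(masses.values())
    if total <= 0:
        raise ValueError("all expected matrices are zero")
    return {
        c: sample_contact_counts(m, max(1, int(round(depth * masses[c] / total))), rng)
        for c, m in expected.items()
    }


def _gauss_bump(track: np.ndarray, centre_bp: int, height: float, width_bp: int,
                track_bin: int) -> None:
    n = track.size
    centre = centre_bp / track_bin
    sigma = max(width_bp / track_bin / 2.0, 0.5)
    lo = max(0, int(centre - 4 * sigma))
    hi = min(n, int(centre + 4 * sigma) + 1)
    x = np.arange(lo, hi)
    track[lo:hi] += height * np.exp(-0.5 * ((x - centre) / sigma) ** 2)


def simulate_annotations(
    config: SimulationConfig, seed: int | np.random.Generator | None = None
) -> tuple[dict[str, dict[str, np.ndarray]], pd.DataFrame, pd.DataFrame,
           dict[str, pd.DataFrame]]:
    """Generate chromatin tracks, a gene table, enhancers and peak intervals.

    Genes are assigned classes GP1 (active, looped), GP2 (active, unlooped)
    and GP3 (silent).  GP1/GP2 TSSs receive ATAC and H3K4me3 (plus H3K4me2)
    peaks; enhancers receive H3K4me1 (plus H3K4me2) peaks and no H3K4me3;
    GP3 TSSs receive nothing.  Tracks carry gamma-distributed background
    noise and are binned at ``config.track_bin`` bp.

    Returns ``(tracks, genes, enhancers, peaks)`` where ``tracks[mark][chrom]``
    is a coverage array, and ``peaks[kind]`` are the planted peak intervals
    for ``kind`` in ``{"atac", "h3k4me3", "h3k4me1"}``.
    """
    config.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed)
    marks = ("atac", "h3k4me3", "h3k4me2", "h3k4me1")
    tracks: dict[str, dict[str, np.ndarray]] = {m: {} for m in marks}
    for chrom, length in config.chrom_lengths.items():
        nt = -(-length // config.track_bin)
        for m in marks:
            base = config.track_background
            noise = rng.gamma(2.0, config.track_noise / 2.0, size=nt)
            tracks[m][chrom] = base + noise

    total_bins = sum(config.n_bins(c) for c in config.chrom_lengths)
    if config.n_genes > total_bins:
        raise ValueError("more genes than bins")

    genome_total = sum(config.chrom_lengths.values())
    gene_rows, enh_rows = [], []
    peak_rows: dict[str, list] = {"atac": [], "h3k4me3": [], "h3k4me1": []}
    gid = 0
    classes_pool = _gene_class_sequence(config, rng)
    for chrom, length in config.chrom_lengths.items():
        n_chrom = int(round(config.n_genes * length / genome_total))
        n_chrom = min(n_chrom, config.n_bins(chrom))
        if n_chrom == 0:
            continue
        spacing = length // (n_chrom + 1)
        gene_len = max(config.bin_size, spacing // 2)
        if config.gene_placement == "even":
            starts = np.arange(1, n_chrom + 1) * spacing
            classes = [classes_pool[(gid + k) % len(classes_pool)]
                       for k in range(n_chrom)]
        elif config.gene_placement == "random":
            starts = np.sort(rng.choice(length - spacing, size=n_chrom,
                                        replace=False))
            classes = [classes_pool[(gid + k) % len(classes_pool)]
                       for k in range(n_chrom)]
        elif config.gene_placement == "compartment_biased":
            # active (GP1/GP2) genes live in A intervals, silent in B;
            # mirrors the A-high/B-low feature enrichment of real genomes
            starts, classes = _compartment_biased_placement(
                config, chrom, n_chrom, classes_pool[gid:gid + n_chrom], rng)
        else:
            raise ValueError(
                f"unknown gene_placement {config.gene_placement!r}")
        for s, cls in zip(starts, classes):
            start = int(s)
            end = min(int(s) + gene_len, length)
            gene_rows.append((f"g{gid:05d}", chrom, start, end, "+", start, cls))
            gid += 1
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss", "class"]
    )

    # enhancers go midway between genes, never inside one
    n_enh = config.n_enhancers
    if n_enh and len(genes):
        per_chrom = genes.groupby("chrom", sort=False)
        eid = 0
        for chrom, sub in per_chrom:
            n_here = int(round(n_enh * config.chrom_lengths[chrom] / genome_total))
            mids = (sub["end"].to_numpy()[:-1] + sub["start"].to_numpy()[1:]) // 2
            if n_here and mids.size:
                pick = np.unique(np.linspace(0, mids.size - 1,
                                             min(n_here, mids.size)).astype(int))
                mids = mids[pick]
            for mid in mids:
                enh_rows.append((f"e{eid:04d}", chrom, int(mid) - config.peak_width,
                                 int(mid) + config.peak_width))
                eid += 1
    enhancers = pd.DataFrame(enh_rows, columns=["enh_id", "chrom", "start", "end"])

    w = config.peak_width
    for _, g in genes.iterrows():
        if g["class"] in ("GP1", "GP2"):
            for mark in ("atac", "h3k4me3", "h3k4me2"):
                _gauss_bump(tracks[mark][g.chrom], g.tss, config.peak_height, w,
                            config.track_bin)
            peak_rows["atac"].append((g.chrom, g.tss - w, g.tss + w))
            peak_rows["h3k4me3"].append((g.chrom, g.tss - w, g.tss + w))
    for _, e in enhancers.iterrows():
        mid = (e.start + e.end) // 2
        for mark in ("h3k4me1", "h3k4me2", "atac"):
            _gauss_bump(tracks[mark][e.chrom], mid, config.peak_height, w,
                        config.track_bin)
        peak_rows["h3k4me1"].append((e.chrom, e.start, e.end))
    peaks = {k: pd.DataFrame(v, columns=["chrom", "start", "end"])
             for k, v in peak_rows.items()}
    return tracks, genes, enhancers, peaks


def _compartment_biased_placement(
    config: SimulationConfig, chrom: str, n_chrom: int,
    classes: np.ndarray, rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """TSS positions with active genes in A intervals, silent genes in B."""
    if classes.size < n_chrom:
        extra = np.array(["GP3"] * (n_chrom - classes.size))
        classes = np.concatenate([classes, extra])
    a_ivals = [(s, e) for s, e, st in config.compartments.get(chrom, ())
               if st == "A"]
    b_ivals = [(s, e) for s, e, st in config.compartments.get(chrom, ())
               if st == "B"]
    if not a_ivals or not b_ivals:
        raise ValueError(
            "compartment_biased placement needs both A and B intervals")

    def spread(ivals, k):
        # place k positions evenly across the pooled interval length
        lengths = np.array([e - s for s, e in ivals], dtype=float)
        total = lengths.sum()
        offsets = (np.arange(1, k + 1) / (k + 1)) * total
        pos = []
        for off in offsets:
            cum = 0.0
            for (s, e), L in zip(ivals, lengths):
                if off < cum + L:
                    pos.append(int(s + (off - cum)))
                    break
                cum += L
        return np.array(pos)

    active = np.flatnonzero(np.isin(classes[:n_chrom], ("GP1", "GP2")))
    silent = np.flatnonzero(classes[:n_chrom] == "GP3")
    starts = np.empty(n_chrom, dtype=int)
    starts[active] = spread(a_ivals, active.size)
    starts[silent] = spread(b_ivals, silent.size)
    order = np.argsort(starts)
    return starts[order], [str(c) for c in classes[:n_chrom][order]]


def _gene_class_sequence(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    f1, f2, f3 = config.gene_class_fractions
    n = max(config.n_genes, 1)
    n1, n2 = int(round(f1 * n)), int(round(f2 * n))
    seq = np.array(["GP1"] * n1 + ["GP2"] * n2 + ["GP3"] * (n - n1 - n2), dtype="U3")
    rng.shuffle(seq)
    return seq


def plant_loops_for_genes(
    config: SimulationConfig,
    genes: pd.DataFrame,
    enhancers: pd.DataFrame,
    enrichment: float = 3.0,
    seed: int | np.random.Generator | None = None,
    max_span: int = 150,
) -> dict[str, list[tuple[int, int, float]]]:
    """Derive a loop list connecting each GP1 promoter to a nearby enhancer.

    Each GP1 gene loops to the closest enhancer between 2 and ``max_span``
    bins away; consecutive GP1 genes are additionally chained into
    promoter-promoter hub groups of 2-5 promoters.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed)
    loops: dict[str, list[tuple[int, int, float]]] = {c: [] for c in config.chrom_lengths}
    bs = config.bin_size
    for chrom, sub in genes.groupby("chrom", sort=False):
        unmap = config._unmappable_bins(chrom)
        enh = enhancers[enhancers.chrom == chrom]
        enh_bins = ((enh.start + enh.end) // 2 // bs).to_numpy() if len(enh) else np.array([], int)
        gp1 = sub[sub["class"] == "GP1"]
        gp1_bins = (gp1.tss // bs).to_numpy()
        seen = set()
        for tb in gp1_bins:
            if enh_bins.size:
                near = np.abs(enh_bins - tb)
                cand = enh_bins[(near >= 2) & (near <= max_span)]
                if cand.size:
                    eb = int(cand[np.argmin(np.abs(cand - tb))])
                    pair = (min(tb, eb), max(tb, eb))
                    if pair not in seen and pair[0] not in unmap and pair[1] not in unmap:
                        loops[chrom].append((*pair, enrichment))
                        seen.add(pair)
        # promoter-promoter loops chain consecutive GP1 genes within hub
        # groups of 2-5 promoters, mirroring the observed hub-size scale
        k = 0
        while k < len(gp1_bins) - 1:
            size = int(rng.integers(2, 6))
            group = gp1_bins[k:k + size]
            for b1, b2 in zip(group, group[1:]):
                if b2 - b1 >= 2:
                    pair = (int(b1), int(b2))
                    if pair not in seen and pair[0] not in unmap and pair[1] not in unmap:
                        loops[chrom].append((*pair, enrichment))
                        seen.add(pair)
            k += size
    return {c: v for c, v in loops.items() if v}


def simulate_dataset(config: SimulationConfig):
    """Run the full generator: annotations, loops, expected maps and counts.

    Returns ``(counts, expected, tracks, truth)`` with ``counts`` and
    ``expected`` keyed by chromosome and ``truth`` a :class:`GroundTruth`.
    All randomness derives from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tracks, genes, enhancers, peaks = simulate_annotations(config, rng)
    loops = dict(config.loops)
    if config.n_genes:
        planted = plant_loops_for_genes(config, genes, enhancers, seed=rng)
        for chrom, lst in planted.items():
            loops.setdefault(chrom, [])
            loops[chrom] = list(loops[chrom]) + lst
        # a GP1 gene must actually participate in a loop; demote any that
        # found no partner (no enhancer in range, no hub neighbour) to GP2
        anchor_bins = {
            (chrom, b) for chrom, lst in loops.items() for b1, b2, _ in lst
            for b in (b1, b2)
        }
        demote = [
            i for i, g in genes.iterrows()
            if g["class"] == "GP1"
            and (g.chrom, g.tss // config.bin_size) not in anchor_bins
        ]
        genes.loc[demote, "class"] = "GP2"
    resolved = dataclasses.replace(config, loops=loops)
    expected = build_expected_matrix(resolved)
    counts = {
        c: sample_contact_counts(m, _chrom_depth(expected, c, config.depth), rng)
        for c, m in expected.items()
    }
    truth = GroundTruth(
        states={c: resolved.bin_states(c) for c in config.chrom_lengths},
        boundary_bins={c: resolved.boundary_bins(c) for c in config.chrom_lengths},
        loops=loops,
        genes=genes,
        enhancers=enhancers,
        peaks=peaks,
    )
    return counts, expected, tracks, truth


def _chrom_depth(expected: dict[str, np.ndarray], chrom: str, depth: int) -> int:
    masses = {c: float(np.triu(m).sum()) for c, m in expected.items()}
    total = sum(masses.values())
    return max(1, int(round(depth * masses[chrom] / total)))


def simulate_ortholog_genomes(
    n_genes: int,
    n_conserved_blocks: int,
    shuffle_fraction: float,
    seed: int,
    block_size: int | None = None,
    gene_length: int = 1_000,
    spacing: int = 2_000,
    ortholog_fraction: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two single-chromosome genomes with partially conserved gene order.

    Genome B carries the same genes as genome A with ``shuffle_fraction`` of
    the genes outside conserved blocks relocated (their positions permuted at
    random).  The orthology map is one-to-one on retained genes.

    Returns ``(genes_a, genes_b, orthology, blocks)``; ``blocks`` holds the
    conserved block intervals on genome A (bp), usable as foreground regions.
    """
    if not (0.0 <= shuffle_fraction <= 1.0):
        raise ValueError("shuffle_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = np.array([f"g{i:05d}" for i in range(n_genes)])

    def layout(order: np.ndarray, chrom: str) -> pd.DataFrame:
        starts = np.arange(order.size) * spacing
        return pd.DataFrame({
            "gene_id": ids[order], "chrom": chrom, "start": starts,
            "end": starts + gene_length, "strand": "+", "tss": starts,
        })

    protected = np.zeros(n_genes, dtype=bool)
    blocks_rows = []
    if n_conserved_blocks > 0:
        bsize = block_size or max(3, n_genes // (4 * n_conserved_blocks))
        stride = n_genes // n_conserved_blocks
        for k in range(n_conserved_blocks):
            lo = k * stride + (stride - bsize) // 2
            hi = min(lo + bsize, n_genes)
            protected[lo:hi] = True
            blocks_rows.append(("chrA", lo * spacing,
                                (hi - 1) * spacing + gene_length, lo, hi))
    blocks = pd.DataFrame(blocks_rows,
                          columns=["chrom", "start", "end", "first_gene", "last_gene"])

    order_b = np.arange(n_genes)
    free = np.flatnonzero(~protected)
    n_move = int(round(shuffle_fraction * free.size))
    if n_move > 1:
        moved = rng.choice(free, size=n_move, replace=False)
        perm = rng.permutation(n_move)
        order_b[np.sort(moved)] = order_b[np.sort(moved)][perm]

    genes_a = layout(np.arange(n_genes), "chrA")
    genes_b = layout(order_b, "chrB")
    keep = np.ones(n_genes, dtype=bool)
    if ortholog_fraction < 1.0:
        keep = rng.random(n_genes) < ortholog_fraction
    orthology = pd.DataFrame({
        "gene_a": ids[keep],
        "gene_b": ids[keep],
        "orthogroup": [f"OG{i:05d}" for i in np.flatnonzero(keep)],
    })
    return genes_a, genes_b, orthology, blocks
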