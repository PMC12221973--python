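# chromarch

Comparative 3D chromatin architecture analysis for Micro-C / Hi-C contact
maps, aimed at small, gene-dense genomes (early-branching animals and
unicellular holozoans) where regulatory genome folding happens at the
kilobase scale: chromatin loops between promoters and enhancers, promoter
hubs, fine-grained insulation, and weak or intermediate compartments.

The package implements, as one tested pipeline:

- **Matrix normalisation and comparison** — ICE (iterative correction)
  balancing, distance-decay expected curves, observed-over-expected (O/E)
  transformation, and the stratum-adjusted correlation coefficient (SCC)
  for replicate reproducibility.
- **A/I/B compartments** — eigendecomposition of the per-chromosome O/E
  Pearson-correlation matrix with automatic, reference-guided eigenvector
  selection; saddle analysis over eigenvector-ranked bin groups (40 groups,
  2.5% extreme trim); compartment strength as the homotypic/heterotypic
  corner ratio on the extreme 20% of ranked groups; a three-component
  Gaussian mixture of the genome-wide eigenvalues whose density
  intersections delimit the intermediate I state; and the
  `-log2(1 - quantile)` feature-enrichment normalisation.
- **Insulation boundaries** — diamond-window insulation scores across a
  resolution/window grid, prominence-graded local minima, the Li minimum
  cross-entropy strong/weak split, removal of boundaries within two bins of
  unmappable regions, hierarchical classification (loop anchor > TSS >
  accessible site > compartment limit), and rescaled pile-ups of
  inter-boundary domains up to 100 kb.
- **Chromatin loops** — a transparent ring-background focal-peak caller
  (externally called BEDPE loops can be imported instead), per-loop and
  aggregate APA (centre 3x3 over the short-distance corner quadrant),
  log-APA outlier filtering, promoter/enhancer/undefined anchor classes from
  quantile-normalised H3K4me3/me2/me1 coverage, promoter hubs as connected
  components of the promoter-promoter loop graph, and GP1/GP2/GP3 gene
  groups (active+looped / active+unlooped / silent).
- **Loop synteny conservation** — a test of whether genes flanking loop
  regions are more syntenically conserved across species than 3x
  length-matched background regions, via a chi-squared goodness-of-fit test
  on shared-orthogroup fractions and a one-sided Wilcoxon rank-sum test
  (with continuity correction) on per-region counts.
- **A synthetic Micro-C generator** — power-law distance decay with planted
  checkerboard compartments, insulated domains, focal loops, TSS-anchored
  chromatin tracks, and paired genomes with partially conserved gene order,
  so every stage above is validated against known ground truth.

## Worked example

Simulate a 10-Mb chromosome (1,000 bins at 10 kb) with a planted A/B
checkerboard of homotypic boost f = 2, sample 10 million Poisson contacts,
and recover the compartments:

```python
import numpy as np
from chromarch import (ContactMatrix, ice_balance, observed_over_expected,
                       compute_eigenvectors, saddle_matrix,
                       compartment_strength)
from chromarch.simulate import (SimulationConfig, checkerboard_compartments,
                                build_expected_matrix, sample_contact_counts)

n_bins, bin_size = 1000, 10_000
cfg = SimulationConfig(
    chrom_lengths={"chr1": n_bins * bin_size}, bin_size=bin_size, alpha=1.0,
    compartments={"chr1": checkerboard_compartments(n_bins, bin_size, seed=1)},
    compartment_boost=2.0, depth=10_000_000, seed=1,
)
expected = build_expected_matrix(cfg)["chr1"]
counts = sample_contact_counts(expected, cfg.depth, cfg.seed)

m = ice_balance(ContactMatrix("chr1", bin_size, counts))
oe = observed_over_expected(m, smooth=True)

reference = (cfg.bin_states("chr1") == "A").astype(float)  # GC-like track
profile = compute_eigenvectors(oe, reference, chrom="chr1")
strength = compartment_strength(saddle_matrix(oe, profile))

truth = np.where(cfg.bin_states("chr1") == "A", 1.0, -1.0)
agreement = np.mean(np.sign(profile.e1) == truth)

print(f"selected eigenvector : E{profile.selected + 1}")
print(f"A/B sign agreement   : {agreement:.1%}")
print(f"compartment strength : {strength:.2f}")
```

Output:

```
selected eigenvector : E1
A/B sign agreement   : 100.0%
compartment strength : 1.99
```

Every bin's compartment sign matches the planted state, and the saddle
corner ratio recovers the planted contact preference (a boost of f = 2
yields a strength near 2; an unstructured map scores exactly 1).

## Command line

A thin CLI wraps the main stages:

```bash
chromarch simulate --config sim.yaml --out simdir --seed 3
chromarch balance --cool simdir/contacts.cool --out balanced.cool
chromarch decay --cool balanced.cool --out decay.tsv
chromarch scc --cool-a rep1.cool --cool-b rep2.cool
chromarch compartments --cool balanced.cool --reference gc.bedGraph --out comp
chromarch boundaries --cool balanced.cool --window 50000 --out bnd
chromarch loops --cool balanced.cool --out loops.bedpe
chromarch synteny --foreground loops.bed --genes-a a.tsv --genes-b b.tsv \
    --orthology og.tsv
```

Contact maps are read and written in a cool-style HDF5 layout (`chroms`,
`bins` with balancing weights, upper-triangle `pixels`) with dense TSV as a
fallback; tracks are bedGraph, genes GFF3/BED, loops 10-column BEDPE.

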