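"""Readers and writers for the pipeline's text and HDF5 formats.

Contact maps are stored cool-style (HDF5 with ``chroms``, ``bins`` and
upper-triangle ``pixels`` tables plus per-bin balancing weights) or as dense
TSV; signal tracks as bedGraph; genes as GFF3/BED; loops as BEDPE; simulation
ground truth as a JSON manifest.  Coordinates are 0-based, half-open
throughout (GFF3 is converted to its 1-based convention on write).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .matrix import ContactMatrix

__all__ = [
    "write_cool",
    "read_cool",
    "write_dense_tsv",
    "read_dense_tsv",
    "write_bedgraph",
    "read_bedgraph",
    "write_bed",
    "write_bedpe",
    "read_bedpe",
    "write_gff3",
    "write_ground_truth",
]


def write_cool(path: str | Path, matrices: dict[str, ContactMatrix]) -> None:
    """Write a genome's contact maps as a cool-style HDF5 file."""
    with h5py.File(path, "w") as f:
        chroms = list(matrices)
        lengths = [m.n_bins * m.bin_size for m in matrices.values()]
        bin_size = next(iter(matrices.values())).bin_size
        f.attrs["bin-size"] = bin_size
        f.attrs["format"] = "chromarch-cool"
        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array(chroms, dtype="S"))
        g.create_dataset("length", data=np.array(lengths, dtype=np.int64))

        bin_chrom, bin_start, bin_end, weights = [], [], [], []
        offsets = {}
        off = 0
        for ci, (chrom, m) in enumerate(matrices.items()):
            offsets[chrom] = off
            starts = np.arange(m.n_bins) * m.bin_size
            bin_chrom.append(np.full(m.n_bins, ci, dtype=np.int32))
            bin_start.append(starts)
            bin_end.append(starts + m.bin_size)
            w = m.weights if m.weights is not None else np.full(m.n_bins, np.nan)
            weights.append(w)
            off += m.n_bins
        g = f.create_group("bins")
        g.create_dataset("chrom", data=np.concatenate(bin_chrom))
        g.create_dataset("start", data=np.concatenate(bin_start))
        g.create_dataset("end", data=np.concatenate(bin_end))
        g.create_dataset("weight", data=np.concatenate(weights))

        b1, b2, cnt = [], [], []
        for chrom, m in matrices.items():
            iu = np.triu_indices(m.n_bins)
            vals = m.counts[iu]
            nz = vals > 0
            b1.append(iu[0][nz] + offsets[chrom])
            b2.append(iu[1][nz] + offsets[chrom])
            cnt.append(vals[nz])
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=np.concatenate(b1).astype(np.int64))
        g.create_dataset("bin2_id", data=np.concatenate(b2).astype(np.int64))
        g.create_dataset("count", data=np.concatenate(cnt))


def read_cool(path: str | Path) -> dict[str, ContactMatrix]:
    """Read a cool-style HDF5 file back into per-chromosome matrices."""
    with h5py.File(path, "r") as f:
        names = [n.decode() for n in f["chroms/name"][:]]
        bin_size = int(f.attrs["bin-size"])
        bin_chrom = f["bins/chrom"][:]
        weights = f["bins/weight"][:]
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        cnt = f["pixels/count"][:]
    out: dict[str, ContactMatrix] = {}
    for ci, chrom in enumerate(names):
        sel = np.flatnonzero(bin_chrom == ci)
        off, n = sel[0], sel.size
        mat = np.zeros((n, n))
        here = (b1 >= off) & (b1 < off + n)
        i = (b1[here] - off).astype(int)
        j = (b2[here] - off).astype(int)
        mat[i, j] = cnt[here]
        mat[j, i] = cnt[here]
        w = weights[off:off + n]
        has_w = np.isfinite(w).any()
        out[chrom] = ContactMatrix(
            chrom=chrom, bin_size=bin_size, counts=mat,
            weights=w if has_w else None,
            valid=np.isfinite(w) if has_w else None,
        )
    return out


def write_dense_tsv(path: str | Path, matrix: np.ndarray) -> None:
    np.savetxt(path, matrix, delimiter="\t", fmt="%.6g")


def read_dense_tsv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_bedgraph(path: str | Path, track: dict[str, np.ndarray],
                   bin_size: int) -> None:
    with open(path, "w") as f:
        for chrom, values in track.items():
            starts = np.arange(values.size) * bin_size
            for s, v in zip(starts, values):
                f.write(f"{chrom}\t{s}\t{s + bin_size}\t{v:.6g}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"])


def write_bed(path: str | Path, df: pd.DataFrame,
              extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_bedpe(path: str | Path, df: pd.DataFrame) -> None:
    """10-column BEDPE (0-based half-open); missing columns filled."""
    out = df.copy()
    n = len(out)
    defaults = {
        "name": [f"loop{i}" for i in range(n)],
        "score": 0.0, "strand1": ".", "strand2": ".",
    }
    for col, val in defaults.items():
        if col not in out:
            out[col] = val
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "name", "score", "strand1", "strand2"]
    extra = [c for c in df.columns if c not in cols]
    out[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_bedpe(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    names = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
             "name", "score", "strand1", "strand2"]
    df.columns = names[:df.shape[1]] + [
        f"extra{i}" for i in range(max(0, df.shape[1] - len(names)))]
    return df


def write_gff3(path: str | Path, genes: pd.DataFrame,
               exons: pd.DataFrame | None = None) -> None:
    """Genes (and optional exons) as GFF3; input is 0-based half-open."""
    has_class = "class" in genes.columns
    with open(path, "w") as f:
        f.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g.gene_id}"
            if has_class:
                attrs += f";gene_class={g['class']}"
            f.write(f"{g.chrom}\tchromarch\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n")
            if exons is not None:
                for e in exons[exons.gene_id == g.gene_id].itertuples():
                    f.write(f"{e.chrom}\tchromarch\texon\t{e.start + 1}\t"
                            f"{e.end}\t.\t{g.strand}\t.\tParent={g.gene_id}\n")


def write_ground_truth(path: str | Path, truth) -> None:
    """Serialise a GroundTruth object as a JSON manifest."""
    doc = {
        "states": {c: "".join(v) for c, v in truth.states.items()},
        "boundary_bins": {c: [int(b) for b in v]
                          for c, v in truth.boundary_bins.items()},
        "loops": {c: [[int(b1), int(b2), float(e)] for b1, b2, e in v]
                  for c, v in truth.loops.items()},
        "genes": truth.genes.to_dict(orient="records"),
        "enhancers": truth.enhancers.to_dict(orient="records"),
        "peaks": {k: v.to_dict(orient="records") for k, v in truth.peaks.items()},
    }
    if truth.orthology is not None:
        doc["orthology"] = truth.orthology.to_dict(orient="records")
    with open(path, "w") as f:
        json.dump(doc, f)
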