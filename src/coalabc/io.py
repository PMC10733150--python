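"""Reading and writing the cohort exchange formats.

A dataset is exported as three plain-text files: a minimal VCF 4.2 (one
contig per locus, phased diploid GT, missing as ``.|.``), a population-map
TSV (sample, population, continent), and optionally BED mask tracks
(contig, 0-based half-open start/end, sample id).  ``read_vcf(write_vcf(x))``
reproduces genotypes, positions and labels bit-exactly.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .coalsim import HaplotypeDataset
from .errors import InputError, VcfParseError

CONTIG_FMT = "locus_{:03d}"


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_vcf(ds: HaplotypeDataset, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=coalabc\n")
        for l, length in enumerate(ds.locus_lengths):
            fh.write(f"##contig=<ID={CONTIG_FMT.format(l)},length={int(length)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ds.sample_ids) + "\n")
        for l in range(ds.n_loci):
            contig = CONTIG_FMT.format(l)
            G = ds.genotypes[l]
            for row, pos in enumerate(ds.positions[l]):
                gts = []
                for i in range(ds.n_samples):
                    a, b = G[row, 2 * i], G[row, 2 * i + 1]
                    gts.append(f"{'.' if a < 0 else int(a)}|{'.' if b < 0 else int(b)}")
                fh.write(f"{contig}\t{int(pos)}\t.\tA\tT\t.\t.\t.\tGT\t"
                         + "\t".join(gts) + "\n")


def write_popmap(ds: HaplotypeDataset, path: str) -> None:
    df = pd.DataFrame({
        "sample": ds.sample_ids,
        "population": ds.sample_pops,
        "continent": [ds.continents.get(p, "NA") for p in ds.sample_pops]})
    df.to_csv(path, sep="\t", index=False)


def write_bed(ds: HaplotypeDataset, path: str) -> None:
    """Mask tracks as 4-column BED: contig, start, end (0-based half-open),
    sample id."""
    with open(path, "w") as fh:
        for sample, per_locus in (ds.masks or {}).items():
            for l, intervals in enumerate(per_locus):
                for s, e in intervals:
                    fh.write(f"{CONTIG_FMT.format(l)}\t{s}\t{e}\t{sample}\n")


def write_cohort(ds: HaplotypeDataset, prefix: str) -> dict[str, str]:
    """Write VCF + popmap (+ BED when masks exist); returns the paths."""
    paths = {"vcf": prefix + ".vcf", "popmap": prefix + ".popmap.tsv"}
    write_vcf(ds, paths["vcf"])
    write_popmap(ds, paths["popmap"])
    if ds.masks:
        paths["bed"] = prefix + ".mask.bed"
        write_bed(ds, paths["bed"])
    return paths


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _validate_vcf_text(path: str) -> None:
    """Light structural pass with line numbers (htslib's errors carry none)."""
    n_samples = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise VcfParseError("header has no sample columns", lineno)
                n_samples = len(cols) - 9
                continue
            cols = line.split("\t")
            if n_samples is None:
                raise VcfParseError("data line before #CHROM header", lineno)
            if len(cols) != 9 + n_samples:
                raise VcfParseError(
                    f"expected {9 + n_samples} columns, found {len(cols)}", lineno)
            if not cols[1].isdigit():
                raise VcfParseError(f"POS {cols[1]!r} is not a positive integer",
                                    lineno)
            if int(cols[1]) < 1:
                raise VcfParseError("POS must be >= 1 (VCF is 1-based)", lineno)


def read_popmap(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "population", "continent"}
    if not required <= set(df.columns):
        raise InputError(f"popmap must have columns {sorted(required)}")
    return df


def read_bed(path: str, n_loci: int) -> dict[str, list[list[tuple[int, int]]]]:
    masks: dict[str, list[list[tuple[int, int]]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise InputError(f"BED line {lineno}: need 4 columns")
            contig, start, end, sample = cols[:4]
            try:
                l = int(contig.rsplit("_", 1)[1])
            except (IndexError, ValueError):
                raise InputError(f"BED line {lineno}: unknown contig {contig!r}")
            if sample not in masks:
                masks[sample] = [[] for _ in range(n_loci)]
            masks[sample][l].append((int(start), int(end)))
    for per_locus in masks.values():
        for iv in per_locus:
            iv.sort()
    return masks


def read_vcf(path: str, popmap: str | pd.DataFrame,
             bed: str | None = None) -> HaplotypeDataset:
    """Load a dataset from VCF + popmap (+ optional BED masks).

    Phase is accepted but ignored beyond haplotype order (``0/1`` is read the
    same as ``0|1``); statistics downstream are genotype-based.
    """
    _validate_vcf_text(path)
    pm = read_popmap(popmap) if isinstance(popmap, (str, os.PathLike)) else popmap
    pop_of = dict(zip(pm["sample"], pm["population"]))
    cont_of = dict(zip(pm["population"], pm["continent"]))

    vcf = VCF(path)
    samples = list(vcf.samples)
    for s in samples:
        if s not in pop_of:
            raise InputError(f"sample {s!r} in VCF is absent from the popmap")
    contigs = list(vcf.seqnames)
    lengths = vcf.seqlens
    n_loci = len(contigs)
    contig_idx = {c: i for i, c in enumerate(contigs)}

    pos_by_locus: list[list[int]] = [[] for _ in range(n_loci)]
    gt_by_locus: list[list[np.ndarray]] = [[] for _ in range(n_loci)]
    for v in vcf:
        l = contig_idx[v.CHROM]
        if v.POS < 1:
            raise VcfParseError(f"POS {v.POS} is not 1-based")
        arr = np.array([(g[0], g[1]) for g in v.genotypes], dtype=np.int8).ravel()
        pos_by_locus[l].append(v.POS)
        gt_by_locus[l].append(arr)

    positions, genotypes = [], []
    n_haps = 2 * len(samples)
    for l in range(n_loci):
        pos = np.asarray(pos_by_locus[l], dtype=np.int64)
        if pos.size and np.any(np.diff(pos) <= 0):
            raise VcfParseError(f"positions not strictly increasing on {contigs[l]}")
        positions.append(pos)
        genotypes.append(np.vstack(gt_by_locus[l]).astype(np.int8)
                         if gt_by_locus[l] else np.empty((0, n_haps), dtype=np.int8))

    ds = HaplotypeDataset(
        positions=positions, genotypes=genotypes,
        locus_lengths=np.asarray(lengths, dtype=np.int64),
        sample_ids=samples,
        sample_pops=[pop_of[s] for s in samples],
        continents={p: cont_of.get(p, "NA") for p in set(pop_of.values())})
    if bed is not None:
        ds.masks = read_bed(bed, n_loci) or None
    return ds
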