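"""Reading the standard input files into in-memory structures.

The pipeline consumes four plain files: a VCF of diploid genotypes for
all samples, one callable-region BED per sample (optionally with a depth
column), a genome file (sequence name + length TSV) and a sample file
(sample + population TSV). VCF positions are 1-based on disk and 0-based
in memory; BED intervals are half-open 0-based throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from imscan.blocks import BlockingConfig, GenomeFile, PairBlock, SamplePartition, cut_pair_blocks

logger = logging.getLogger(__name__)


def read_callable_bed(path) -> dict[str, np.ndarray]:
    """Per-contig sorted half-open intervals; extra columns are ignored."""
    by_contig: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            by_contig.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    out = {}
    for contig, ivals in by_contig.items():
        ivals.sort()
        merged = [list(ivals[0])]
        for lo, hi in ivals[1:]:
            if lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        out[contig] = np.array(merged, dtype=np.int64)
    return out


@dataclass
class VcfData:
    """Biallelic-or-not genotype calls per contig.

    ``genotypes[contig]`` has shape (n_sites, n_samples, 2) with allele
    indices and -1 for uncalled; positions are 0-based.
    """

    samples: list[str]
    positions: dict[str, np.ndarray]
    genotypes: dict[str, np.ndarray]


def read_vcf(path, samples: list[str] | None = None) -> VcfData:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = list(vcf.samples)
    if samples is not None:
        missing = set(samples) - set(names)
        if missing:
            raise ValueError(f"samples absent from VCF: {sorted(missing)}")
        idx = [names.index(s) for s in samples]
    else:
        samples = names
        idx = list(range(len(names)))
    pos: dict[str, list[int]] = {}
    gts: dict[str, list[list[tuple[int, int]]]] = {}
    for v in vcf:
        row = []
        for k in idx:
            g = v.genotypes[k]
            a1 = g[0] if len(g) > 1 else -1
            a2 = g[1] if len(g) > 2 else a1
            row.append((-1 if a1 is None or a1 < 0 else a1,
                        -1 if a2 is None or a2 < 0 else a2))
        pos.setdefault(v.CHROM, []).append(v.POS - 1)
        gts.setdefault(v.CHROM, []).append(row)
    return VcfData(
        samples=list(samples),
        positions={c: np.array(p, dtype=np.int64) for c, p in pos.items()},
        genotypes={c: np.array(g, dtype=np.int64) for c, g in gts.items()},
    )


def cut_blocks_dataset(
    callable_by_sample: dict[str, dict[str, np.ndarray]],
    vcf_data: VcfData,
    partition: SamplePartition,
    genome: GenomeFile,
    cfg: BlockingConfig,
    pair_kinds: tuple[str, ...] = ("X", "A", "B"),
) -> dict[str, list[PairBlock]]:
    """Cut pair-blocks for every requested pair kind over every contig."""
    sample_idx = {s: i for i, s in enumerate(vcf_data.samples)}
    for s, _ in partition.assignment:
        if s not in sample_idx:
            raise ValueError(f"sample {s} not present in the VCF")
        if s not in callable_by_sample:
            raise ValueError(f"sample {s} has no callable-region input")
    out: dict[str, list[PairBlock]] = {k: [] for k in pair_kinds}
    for kind in pair_kinds:
        for sa, sb in partition.pairs(kind):
            for contig in genome.names:
                ca = callable_by_sample[sa].get(contig)
                cb = callable_by_sample[sb].get(contig)
                if ca is None or cb is None or len(ca) == 0 or len(cb) == 0:
                    continue
                p = vcf_data.positions.get(contig, np.empty(0, dtype=np.int64))
                g = vcf_data.genotypes.get(
                    contig, np.empty((0, len(vcf_data.samples), 2), dtype=np.int64))
                ia, ib = sample_idx[sa], sample_idx[sb]
                genos = [(int(p[s_]), int(g[s_, ia, 0]), int(g[s_, ia, 1]),
                          int(g[s_, ib, 0]), int(g[s_, ib, 1]))
                         for s_ in range(len(p))]
                out[kind].extend(cut_pair_blocks(
                    ca, cb, genos, (sa, sb), cfg, sequence=contig, pair_type=kind))
    return out
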