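"""Consistent quality/coverage filtering of variant and callable inputs.

Applies a minimal, reproducible set of filters so that variant and
invariant sites are sampled under the same criteria:

* records that are not SNPs are removed (and recorded as exclusion zones);
* SNPs within ``snpgap`` bp of a non-SNP record are removed;
* records failing the quality floor are removed;
* per-sample read depth must lie within ``[min_depth,
  max_depth_factor * mean depth of that sample]`` — both for variant
  records (FORMAT/DP) and for the callable regions (BED depth column).

Outputs: filtered VCF, per-sample callable BED intersected with the depth
bounds, a genome file and a sample list.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from imscan.blocks import GenomeFile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    min_qual: float = 1.0
    snpgap: int = 2
    min_depth: int = 8
    max_depth_factor: float = 3.0
    #: optional minimum genotype quality (distinct from min_qual; off by default)
    min_gq: Optional[float] = None
    #: optional read-balance INFO thresholds, e.g. {"SAF": 1}; off by default
    info_min: dict = field(default_factory=dict)


@dataclass
class PreprocessResult:
    vcf: str
    beds: dict[str, str]
    genome_file: str
    sample_file: str
    n_records_in: int
    n_records_out: int
    mean_depth: dict[str, float]


def _read_depth_bed(path) -> dict[str, np.ndarray]:
    """BED4 (chrom, start, end, depth) -> per-contig (start, end, depth)."""
    rows: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            c, s, e, *rest = line.split("\t")
            depth = float(rest[0]) if rest else np.inf
            rows.setdefault(c, []).append((int(s), int(e), depth))
    return {c: np.array(sorted(v), dtype=float) for c, v in rows.items()}


def _mean_depth(cov: dict[str, np.ndarray]) -> float:
    num = den = 0.0
    for arr in cov.values():
        lengths = arr[:, 1] - arr[:, 0]
        num += float((lengths * arr[:, 2]).sum())
        den += float(lengths.sum())
    return num / den if den else 0.0


def preprocess_filter(
    vcf_path,
    coverage_beds: dict[str, str],
    cfg: Optional[FilterConfig] = None,
    outdir: str = ".",
) -> PreprocessResult:
    """Filter a VCF and per-sample coverage BEDs into analysis-ready inputs."""
    from cyvcf2 import VCF, Writer

    cfg = cfg or FilterConfig()
    os.makedirs(outdir, exist_ok=True)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in coverage_beds]
    if missing:
        raise ValueError(f"samples in VCF without coverage input: {missing}")

    # --- per-sample depth bounds and callable BEDs -----------------------
    mean_depth: dict[str, float] = {}
    bed_paths: dict[str, str] = {}
    for s in samples:
        cov = _read_depth_bed(coverage_beds[s])
        mean = _mean_depth(cov)
        mean_depth[s] = mean
        hi = cfg.max_depth_factor * mean
        out = os.path.join(outdir, f"{s}.callable.bed")
        with open(out, "w") as fh:
            for contig in sorted(cov):
                kept = [(int(lo), int(hi_)) for lo, hi_, d in cov[contig]
                        if cfg.min_depth <= d <= hi]
                merged: list[list[int]] = []
                for lo, e in kept:
                    if merged and lo <= merged[-1][1]:
                        merged[-1][1] = max(merged[-1][1], e)
                    else:
                        merged.append([lo, e])
                for lo, e in merged:
                    fh.write(f"{contig}\t{lo}\t{e}\n")
        bed_paths[s] = out

    # --- pass 1: non-SNP exclusion zones ---------------------------------
    non_snp: dict[str, list[tuple[int, int]]] = {}
    n_in = 0
    for v in VCF(str(vcf_path)):
        n_in += 1
        if not v.is_snp:
            lo = v.POS - 1
            non_snp.setdefault(v.CHROM, []).append((lo, lo + len(v.REF)))
    zones = {c: np.array(sorted(z), dtype=np.int64) for c, z in non_snp.items()}

    def near_non_snp(chrom: str, pos0: int) -> bool:
        z = zones.get(chrom)
        if z is None or len(z) == 0:
            return False
        d = np.where((pos0 >= z[:, 0]) & (pos0 < z[:, 1]), 0,
                     np.minimum(np.abs(pos0 - z[:, 0]), np.abs(pos0 - (z[:, 1] - 1))))
        return bool(d.min() <= cfg.snpgap)

    # --- pass 2: record filtering ----------------------------------------
    src = VCF(str(vcf_path))
    out_vcf = os.path.join(outdir, "filtered.vcf")
    writer = Writer(out_vcf, src)
    n_out = 0
    hi_depth = {s: cfg.max_depth_factor * mean_depth[s] for s in samples}
    for v in src:
        if not v.is_snp:
            continue
        if v.QUAL is not None and v.QUAL < cfg.min_qual:
            continue
        if near_non_snp(v.CHROM, v.POS - 1):
            continue
        dp = v.format("DP")
        if dp is not None:
            dp = np.asarray(dp).ravel()
            ok = True
            for k, s in enumerate(samples):
                if dp[k] >= 0 and not (cfg.min_depth <= dp[k] <= hi_depth[s]):
                    ok = False
                    break
            if not ok:
                continue
        if cfg.min_gq is not None:
            gq = v.format("GQ")
            if gq is not None and np.nanmin(np.asarray(gq, dtype=float)) < cfg.min_gq:
                continue
        keep = True
        for name, floor in cfg.info_min.items():
            val = v.INFO.get(name)
            if val is not None and np.min(np.atleast_1d(val)) < floor:
                keep = False
                break
        if not keep:
            continue
        writer.write_record(v)
        n_out += 1
    writer.close()

    # --- genome + sample files -------------------------------------------
    seqnames = src.seqnames
    seqlens = src.seqlens if src.seqlens else [0] * len(seqnames)
    genome = GenomeFile(tuple(zip(seqnames, (int(l) for l in seqlens))))
    genome_path = os.path.join(outdir, "genome.tsv")
    genome.write(genome_path)
    sample_path = os.path.join(outdir, "samples.txt")
    with open(sample_path, "w") as fh:
        for s in samples:
            fh.write(s + "\n")  # population column to be filled in by the user
    return PreprocessResult(vcf=out_vcf, beds=bed_paths, genome_file=genome_path,
                            sample_file=sample_path, n_records_in=n_in,
                            n_records_out=n_out, mean_depth=mean_depth)
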