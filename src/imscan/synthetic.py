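"""Synthetic end-to-end fixtures: VCF + per-sample BED + genome/sample files.

Renders coalescent-simulated genotypes as the standard input files of the
pipeline, with controllable imperfections (uncallable gaps, missing
genotypes, multiallelic sites, low-quality records, indels, per-sample
depth variation), so the whole preprocess -> blocks -> windows -> tally ->
scan chain can run without any external data.

Every window is simulated independently and laid out on a contig with
uncallable spacer gaps between windows (wider than the block span, so no
block bridges two windows); contigs, samples and depths are plain-text
VCF/BED/TSV, nothing binary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np

from imscan.blocks import GenomeFile, SamplePartition
from imscan.simulate import SimulationSpec, _sim_window_raw, _tally_window

_BASES = ("A", "C", "G", "T")


def _integerize_positions(positions: np.ndarray, win_len: int):
    """Map continuous mutation positions to distinct integer sites.

    Sites keep their order; a floor collision pushes the later site to the
    next free base. Sites pushed past the window end are dropped (in both
    the rendered VCF and the direct tally, so the two stay comparable).
    """
    order = np.argsort(positions, kind="stable")
    ipos = []
    keep = []
    last = -1
    for idx in order:
        q = max(int(np.floor(positions[idx])), last + 1)
        if q >= win_len:
            continue
        ipos.append(q)
        keep.append(idx)
        last = q
    return np.array(ipos, dtype=np.int64), np.array(keep, dtype=np.int64)


@dataclass
class FixtureLayout:
    """Genome layout and imperfection knobs for fixture rendering."""

    windows_per_contig: int = 2
    gap_bp: int = 500              # uncallable spacer between windows (> block_span)
    flank_bp: int = 200            # uncallable contig ends
    missing_rate: float = 0.0      # per genotype call
    multiallelic_rate: float = 0.0 # per site: introduce a third allele in one sample
    low_qual_rate: float = 0.0     # per site: QUAL below any sane min_qual
    n_indels_per_contig: int = 0
    mean_depth: float = 30.0
    low_depth_bp_per_sample: int = 0  # length of one injected low-depth interval


@dataclass
class FixtureSet:
    vcf: str
    beds: dict[str, str]
    genome_file: str
    sample_file: str
    genome: GenomeFile
    partition: SamplePartition
    window_spans: list[tuple[str, int, int]]   # contig, start, end per window
    direct_tallies: list                        # BsfsTally per window, pre-rendering


def write_synthetic_fixtures(
    spec: SimulationSpec,
    outdir: str,
    layout: Optional[FixtureLayout] = None,
    seed: int = 1,
) -> FixtureSet:
    """Simulate `spec` and render it as VCF/BED/TSV under `outdir`.

    The returned ``direct_tallies`` are computed straight from the
    simulated genotypes (before any imperfections are injected); with all
    imperfection knobs at zero the pipeline applied to the rendered files
    reproduces them exactly.
    """
    layout = layout or FixtureLayout()
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_a, n_b = spec.samples_per_taxon
    samples = [f"A_{i}" for i in range(n_a)] + [f"B_{i}" for i in range(n_b)]
    partition = SamplePartition(tuple(
        [(f"A_{i}", "popA") for i in range(n_a)] + [(f"B_{i}", "popB") for i in range(n_b)]
    ))
    win_len = spec.params.block_length * spec.blocks_per_window
    wpc = layout.windows_per_contig
    n_contigs = int(np.ceil(spec.n_windows / wpc))
    contig_len = layout.flank_bp * 2 + wpc * win_len + (wpc - 1) * layout.gap_bp
    contigs = [(f"contig_{c}", contig_len) for c in range(n_contigs)]
    genome = GenomeFile(tuple(contigs))

    rates = spec.window_rates()
    seeds = np.random.default_rng(seed).integers(1, 2 ** 31 - 1, size=(spec.n_windows, 2))

    records = []   # (contig, pos0, ref, alts, qual, genotypes list, is_indel)
    window_spans: list[tuple[str, int, int]] = []
    direct_tallies = []
    for w in range(spec.n_windows):
        contig = f"contig_{w // wpc}"
        slot = w % wpc
        offset = layout.flank_bp + slot * (win_len + layout.gap_bp)
        positions, G = _sim_window_raw(spec, rates[w], tuple(seeds[w]))
        ipos, keep = _integerize_positions(positions, win_len)
        G = G[keep]
        direct_tallies.append(_tally_window(ipos.astype(float), G, spec))
        window_spans.append((contig, offset, offset + win_len))
        for s_idx, p in enumerate(ipos):
            gts = [(int(G[s_idx, 2 * k]), int(G[s_idx, 2 * k + 1]))
                   for k in range(n_a + n_b)]
            ref, alt = rng.choice(4, size=2, replace=False)
            qual = 60.0
            if layout.low_qual_rate and rng.random() < layout.low_qual_rate:
                qual = 0.5
            alts = [_BASES[alt]]
            if layout.multiallelic_rate and rng.random() < layout.multiallelic_rate:
                third = [b for b in range(4) if b not in (ref, alt)][0]
                alts.append(_BASES[third])
                k = rng.integers(0, n_a + n_b)
                a1, _ = gts[k]
                gts[k] = (a1, 2)
            if layout.missing_rate:
                for k in range(n_a + n_b):
                    if rng.random() < layout.missing_rate:
                        gts[k] = (-1, -1)
            records.append((contig, offset + int(p), _BASES[ref], alts, qual, gts, False))
        if slot == wpc - 1 or w == spec.n_windows - 1:
            for _ in range(layout.n_indels_per_contig):
                gap_slot = rng.integers(0, max(1, wpc))
                p = layout.flank_bp + gap_slot * (win_len + layout.gap_bp) \
                    + int(rng.integers(0, win_len))
                gts = [(0, 0)] * (n_a + n_b)
                records.append((contig, p, "AT", ["A"], 60.0, gts, True))

    records.sort(key=lambda r: (r[0], r[1], r[6]))
    # drop SNPs colliding with an injected indel position
    seen = set()
    uniq = []
    for rec in records:
        key = (rec[0], rec[1])
        if key in seen:
            continue
        seen.add(key)
        uniq.append(rec)
    records = uniq

    vcf_path = os.path.join(outdir, "synthetic.vcf")
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for name, length in genome.sequences:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for contig, pos0, ref, alts, qual, gts, _ in records:
            cols = [contig, str(pos0 + 1), ".", ref, ",".join(alts),
                    f"{qual:g}", "PASS", ".", "GT:DP"]
            for a1, a2 in gts:
                gt = "./." if a1 < 0 else f"{a1}/{a2}"
                dp = int(rng.poisson(layout.mean_depth))
                cols.append(f"{gt}:{max(dp, 10)}")
            fh.write("\t".join(cols) + "\n")

    # callable BEDs: the window intervals, minus one optional low-depth hole
    beds = {}
    for k, s in enumerate(samples):
        bed_path = os.path.join(outdir, f"{s}.callable.bed")
        with open(bed_path, "w") as fh:
            for contig, start, end in window_spans:
                rows = [(start, end, layout.mean_depth)]
                if layout.low_depth_bp_per_sample:
                    hole_rng = np.random.default_rng(seed + 7919 * (k + 1))
                    h0 = int(hole_rng.integers(start, end - layout.low_depth_bp_per_sample))
                    h1 = h0 + layout.low_depth_bp_per_sample
                    rows = [(start, h0, layout.mean_depth), (h0, h1, 4.0),
                            (h1, end, layout.mean_depth)]
                for lo, hi, depth in rows:
                    if hi > lo:
                        fh.write(f"{contig}\t{lo}\t{hi}\t{depth:g}\n")
        beds[s] = bed_path

    genome_path = os.path.join(outdir, "genome.tsv")
    genome.write(genome_path)
    sample_path = os.path.join(outdir, "samples.tsv")
    partition.write(sample_path)
    return FixtureSet(vcf=vcf_path, beds=beds, genome_file=genome_path,
                      sample_file=sample_path, genome=genome, partition=partition,
                      window_spans=window_spans, direct_tallies=direct_tallies)
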