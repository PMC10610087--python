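"""Cutting fixed-callable-length pair-blocks and assembling sliding windows.

A pair-block is a stretch of exactly ``block_length`` sites that are
callable in *both* members of one sample pair; its physical span may be
longer than its callable length because of uncallable gaps, but never
longer than ``block_span``. Blocks are cut greedily from left to right and
independently for every sample pair, so adding or removing other samples
never changes the blocks of an existing pair.

Coordinates are BED-style throughout: half-open, 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# input descriptors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeFile:
    """Ordered (sequence name, length in bp) records."""

    sequences: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.sequences]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sequence names in genome file")
        if any(l <= 0 for _, l in self.sequences):
            raise ValueError("sequence lengths must be > 0")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.sequences]

    def length(self, name: str) -> int:
        return dict(self.sequences)[name]

    @classmethod
    def read(cls, path) -> "GenomeFile":
        recs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, length = line.split("\t")[:2]
                recs.append((name, int(length)))
        return cls(tuple(recs))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.sequences:
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class SamplePartition:
    """Sample name -> population label; exactly two labels, A first."""

    assignment: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        labels = self.labels
        if len(labels) != 2:
            raise ValueError(f"exactly two population labels required, got {labels}")

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for _, pop in self.assignment:
            if pop not in seen:
                seen.append(pop)
        return seen

    def samples(self, label: str) -> list[str]:
        return [s for s, p in self.assignment if p == label]

    def pairs(self, kind: str = "X") -> list[tuple[str, str]]:
        """Sample pairs: heterospecific ("X") or within-population ("A"/"B")."""
        la, lb = self.labels
        if kind == "X":
            return [(a, b) for a in self.samples(la) for b in self.samples(lb)]
        pop = self.samples(la if kind == "A" else lb)
        return [(pop[i], pop[j]) for i in range(len(pop)) for j in range(i + 1, len(pop))]

    @classmethod
    def read(cls, path) -> "SamplePartition":
        recs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", "\t").split("\t")
                recs.append((parts[0], parts[1]))
        return cls(tuple(recs))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.assignment:
                fh.write(f"{s}\t{p}\n")


@dataclass(frozen=True)
class BlockingConfig:
    block_length: int = 64
    block_span: int = 128
    max_missing: int = 3
    max_multiallelic: int = 3

    def __post_init__(self) -> None:
        if self.block_span < self.block_length:
            raise ValueError("block_span must be >= block_length")
        if min(self.max_missing, self.max_multiallelic) < 0 or self.block_length < 1:
            raise ValueError("invalid blocking configuration")


@dataclass(frozen=True)
class PairBlock:
    """One emitted block of a single sample pair.

    ``counts`` are the unfolded mutation-type counts in axis order
    (het_b, het_a, het_ab, fixed_diff), from biallelic genotypes only.
    """

    sequence: str
    pair: tuple[str, str]
    start: int                       # physical position of first callable site
    end: int                         # one past the last callable site
    runs: tuple[tuple[int, int], ...]  # half-open callable runs making up the block
    counts: tuple[int, int, int, int]
    n_missing: int = 0
    n_multiallelic: int = 0
    pair_type: str = "X"

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def is_fgv(self) -> bool:
        """Four-gamete violation: both shared hets and fixed differences."""
        return self.counts[2] > 0 and self.counts[3] > 0


@dataclass(frozen=True)
class Window:
    sequence: str
    blocks: tuple[PairBlock, ...]
    index: int

    @property
    def start(self) -> int:
        return min(b.start for b in self.blocks)

    @property
    def end(self) -> int:
        return max(b.end for b in self.blocks)

    @property
    def span(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# genotype classification
# ---------------------------------------------------------------------------

MISSING, MULTIALLELIC, INVARIANT = -2, -3, -1


def classify_pair_genotypes(a1: int, a2: int, b1: int, b2: int) -> int:
    """Mutation type of one site for one pair.

    Returns an axis index (0 het_b, 1 het_a, 2 het_ab, 3 fixed_diff),
    ``INVARIANT`` for sites without an observable mutation in the pair,
    ``MISSING`` if either genotype is uncalled, or ``MULTIALLELIC`` if more
    than two alleles are observed in the pair.
    """
    if min(a1, a2, b1, b2) < 0:
        return MISSING
    if len({a1, a2, b1, b2}) > 2:
        return MULTIALLELIC
    het_a = a1 != a2
    het_b = b1 != b2
    if het_a and het_b:
        return 2
    if het_a:
        return 1
    if het_b:
        return 0
    return 3 if a1 != b1 else INVARIANT


# ---------------------------------------------------------------------------
# interval helpers
# ---------------------------------------------------------------------------


def _as_intervals(intervals) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    starts, ends = arr[:, 0], arr[:, 1]
    if np.any(ends <= starts):
        raise ValueError("empty or inverted interval")
    if np.any(np.diff(starts) < 0) or np.any(starts[1:] < ends[:-1]):
        raise ValueError("intervals must be sorted and non-overlapping")
    return starts, ends


def intersect_intervals(a, b) -> np.ndarray:
    """Intersection of two sorted, non-overlapping half-open interval sets."""
    sa, ea = _as_intervals(a)
    sb, eb = _as_intervals(b)
    out = []
    i = j = 0
    while i < len(sa) and j < len(sb):
        lo = max(sa[i], sb[j])
        hi = min(ea[i], eb[j])
        if lo < hi:
            out.append((lo, hi))
        if ea[i] < eb[j]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


# ---------------------------------------------------------------------------
# the greedy left-to-right packer
# ---------------------------------------------------------------------------


def cut_pair_blocks(
    callable_a,
    callable_b,
    genotypes: Sequence[tuple[int, int, int, int, int]],
    pair: tuple[str, str],
    cfg: BlockingConfig,
    sequence: str = "seq",
    pair_type: str = "X",
) -> list[PairBlock]:
    """Greedy left-to-right packing of jointly callable sites into blocks.

    Parameters
    ----------
    callable_a, callable_b:
        Sorted, non-overlapping half-open intervals of callable sites for
        each sample of the pair.
    genotypes:
        Per-variant tuples ``(pos, a1, a2, b1, b2)`` of 0-based position
        and allele indices (negative = uncalled) for the two samples.
        Sites not listed are invariant. Genotypes at non-callable sites
        are ignored with a logged warning.

    A candidate block of ``block_length`` jointly callable sites is
    emitted iff its physical span is at most ``block_span`` and its
    missing/multiallelic counts are within the caps; on any violation the
    packer advances the start to the next callable site and retries.
    Emitted blocks never overlap.
    """
    joint = intersect_intervals(callable_a, callable_b)
    if len(joint) == 0:
        return []
    starts, ends = joint[:, 0], joint[:, 1]
    lengths = ends - starts
    cum = np.concatenate([[0], np.cumsum(lengths)])  # callable sites before run r
    total = int(cum[-1])
    L = cfg.block_length

    # map variants to callable-site indices
    var_pos = np.array([g[0] for g in genotypes], dtype=np.int64)
    order = np.argsort(var_pos, kind="stable")
    var_pos = var_pos[order]
    var_types = np.empty(len(order), dtype=np.int64)
    for k, o in enumerate(order):
        _, a1, a2, b1, b2 = genotypes[o]
        var_types[k] = classify_pair_genotypes(a1, a2, b1, b2)
    run = np.searchsorted(starts, var_pos, side="right") - 1
    inside = (run >= 0) & (var_pos < ends[np.clip(run, 0, None)])
    n_out = int((~inside).sum())
    if n_out:
        logger.warning("%d genotype(s) at non-callable sites ignored for pair %s",
                       n_out, pair)
    var_cidx = cum[run[inside]] + (var_pos[inside] - starts[run[inside]])
    var_types = var_types[inside]

    def pos_of(cidx: int) -> int:
        r = int(np.searchsorted(cum, cidx, side="right") - 1)
        return int(starts[r] + (cidx - cum[r]))

    def runs_between(c0: int, c1: int) -> tuple[tuple[int, int], ...]:
        """Physical runs covering callable indices [c0, c1]."""
        r0 = int(np.searchsorted(cum, c0, side="right") - 1)
        r1 = int(np.searchsorted(cum, c1, side="right") - 1)
        out = []
        for r in range(r0, r1 + 1):
            lo = starts[r] + (c0 - cum[r]) if r == r0 else starts[r]
            hi = starts[r] + (c1 - cum[r]) + 1 if r == r1 else ends[r]
            out.append((int(lo), int(hi)))
        return tuple(out)

    blocks: list[PairBlock] = []
    c0 = 0
    while c0 + L <= total:
        first = pos_of(c0)
        last = pos_of(c0 + L - 1)
        if last - first + 1 > cfg.block_span:
            c0 += 1
            continue
        lo = np.searchsorted(var_cidx, c0, side="left")
        hi = np.searchsorted(var_cidx, c0 + L, side="left")
        types = var_types[lo:hi]
        n_missing = int((types == MISSING).sum())
        n_multi = int((types == MULTIALLELIC).sum())
        if n_missing > cfg.max_missing or n_multi > cfg.max_multiallelic:
            c0 += 1
            continue
        counts = tuple(int((types == t).sum()) for t in range(4))
        blocks.append(PairBlock(
            sequence=sequence, pair=pair, start=first, end=last + 1,
            runs=runs_between(c0, c0 + L - 1), counts=counts,
            n_missing=n_missing, n_multiallelic=n_multi, pair_type=pair_type,
        ))
        c0 += L
    return blocks


def make_windows(blocks: Iterable[PairBlock], blocks_per_window: int,
                 step: int) -> list[Window]:
    """Sliding windows over heterospecific pair-blocks of one sequence.

    Blocks from all sample pairs are consumed interleaved, in order of
    their start positions; window ``w_k`` contains blocks
    ``[k*step, k*step + blocks_per_window)`` and trailing partial windows
    are not emitted.
    """
    if blocks_per_window <= 0 or step <= 0:
        raise ValueError("blocks_per_window and step must be > 0")
    blocks = sorted(blocks, key=lambda b: (b.start, b.end, b.pair))
    seqs = {b.sequence for b in blocks}
    if len(seqs) > 1:
        raise ValueError("make_windows operates on a single sequence at a time")
    n = len(blocks)
    windows = []
    k = 0
    while k * step + blocks_per_window <= n:
        lo = k * step
        windows.append(Window(
            sequence=blocks[lo].sequence,
            blocks=tuple(blocks[lo:lo + blocks_per_window]),
            index=k,
        ))
        k += 1
    return windows
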