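"""Folded bSFS tallies and standard summary statistics.

The bSFS tally of a dataset (or of a window) is a 4-D count array over
folded mutation configurations, axes ``(het_b, het_a, het_ab,
fixed_diff)``, each of size ``k + 2`` (the last cell is ">k"). Blocks
that violate the four-gamete test (both shared heterozygous sites and
fixed differences) cannot arise on a single genealogy and are excluded
from tallies; because the model assigns those configurations zero
probability, no renormalisation of the retained cells is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from imscan.blocks import PairBlock
from imscan.demography import KmaxSpec


@dataclass
class BsfsTally:
    counts: np.ndarray           # 4-D int64 array, shape kmax.shape
    kmax: KmaxSpec
    scope: str                   # "blocks" | "windows" | "windowsum"
    n_blocks_retained: int
    n_fgv_excluded: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != self.kmax.shape:
            raise ValueError("tally shape does not match kmax")
        if self.counts.min() < 0 or int(self.counts.sum()) != self.n_blocks_retained:
            raise ValueError("tally counts must be >= 0 and sum to n_blocks_retained")

    @classmethod
    def from_array(cls, counts: np.ndarray, kmax: KmaxSpec, scope: str = "blocks",
                   n_fgv_excluded: int = 0) -> "BsfsTally":
        counts = np.asarray(counts, dtype=np.int64)
        return cls(counts=counts, kmax=kmax, scope=scope,
                   n_blocks_retained=int(counts.sum()), n_fgv_excluded=n_fgv_excluded)


def _fold_counts(unfolded: np.ndarray, kmax: KmaxSpec) -> np.ndarray:
    caps = np.array(kmax.caps)
    return np.minimum(unfolded, caps + 1)


def tally_bsfs(blocks_or_windows, kmax: Optional[KmaxSpec] = None,
               scope: str = "blocks"):
    """Fold block mutation counts at kmax and tally them.

    ``scope="blocks"`` tallies an iterable of :class:`PairBlock` into one
    tally; ``scope="windows"`` takes an iterable of :class:`Window` and
    returns one tally per window; ``scope="windowsum"`` sums the
    per-window tallies, counting a block once per window containing it.
    Empty input yields an all-zero tally.
    """
    kmax = kmax or KmaxSpec()
    if scope == "windows":
        return [_tally_blocks(w.blocks, kmax, "windows") for w in blocks_or_windows]
    if scope == "windowsum":
        per = [_tally_blocks(w.blocks, kmax, "windows") for w in blocks_or_windows]
        counts = np.sum([t.counts for t in per], axis=0) if per else np.zeros(kmax.shape, dtype=np.int64)
        return BsfsTally(counts=np.asarray(counts, dtype=np.int64), kmax=kmax,
                         scope="windowsum",
                         n_blocks_retained=sum(t.n_blocks_retained for t in per),
                         n_fgv_excluded=sum(t.n_fgv_excluded for t in per))
    if scope != "blocks":
        raise ValueError(f"unknown scope {scope!r}")
    return _tally_blocks(blocks_or_windows, kmax, "blocks")


def _tally_blocks(blocks: Iterable[PairBlock], kmax: KmaxSpec, scope: str) -> BsfsTally:
    counts = np.zeros(kmax.shape, dtype=np.int64)
    n_fgv = 0
    n_kept = 0
    for b in blocks:
        if b.is_fgv:
            n_fgv += 1
            continue
        idx = tuple(_fold_counts(np.array(b.counts), kmax))
        counts[idx] += 1
        n_kept += 1
    return BsfsTally(counts=counts, kmax=kmax, scope=scope,
                     n_blocks_retained=n_kept, n_fgv_excluded=n_fgv)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SummaryStats:
    """Mean per-bp summaries over blocks.

    ``H_A``/``H_B`` are within-individual heterozygosities measured on the
    heterospecific blocks; ``pi_A``/``pi_B`` are between-individual
    pairwise diversities from within-population pair-blocks (reported
    separately because the two need not agree under inbreeding or
    structure); ``d_xy`` is mean between-taxon divergence and ``F_ST``
    uses the pairwise-difference (Hudson-style) form.
    """

    H_A: float
    H_B: float
    pi_A: Optional[float]
    pi_B: Optional[float]
    d_xy: float
    F_ST: float


def block_dxy(counts: Sequence[int], block_length: int) -> float:
    """Mean pairwise difference per bp between the two diploids of a block.

    Each heterozygous site contributes 1/2 (the average over the two
    possible haplotype pairings of unphased data), a fixed difference 1.
    """
    hb, ha, hab, fd = counts
    return (0.5 * (ha + hb + hab) + fd) / block_length


def fst_from(h_a: float, h_b: float, d_xy: float) -> float:
    """Hudson-style F_ST from mean heterozygosities and divergence."""
    h_bar = 0.5 * (h_a + h_b)
    return (d_xy - h_bar) / (d_xy + h_bar)


def summary_info(x_blocks: Sequence[PairBlock],
                 a_blocks: Sequence[PairBlock] = (),
                 b_blocks: Sequence[PairBlock] = (),
                 block_length: int = 64) -> SummaryStats:
    if not x_blocks:
        raise ValueError("at least one heterospecific block is required")
    xc = np.array([b.counts for b in x_blocks], dtype=float)
    H_A = float((xc[:, 1] + xc[:, 2]).mean() / block_length)
    H_B = float((xc[:, 0] + xc[:, 2]).mean() / block_length)
    d_xy = float(np.mean([block_dxy(b.counts, block_length) for b in x_blocks]))
    pi_A = float(np.mean([block_dxy(b.counts, block_length) for b in a_blocks])) if a_blocks else None
    pi_B = float(np.mean([block_dxy(b.counts, block_length) for b in b_blocks])) if b_blocks else None
    return SummaryStats(H_A=H_A, H_B=H_B, pi_A=pi_A, pi_B=pi_B, d_xy=d_xy,
                        F_ST=fst_from(H_A, H_B, d_xy))
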