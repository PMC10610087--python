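"""Pair-block cutting and window assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from imscan.blocks import (
    BlockingConfig,
    GenomeFile,
    SamplePartition,
    classify_pair_genotypes,
    cut_pair_blocks,
    intersect_intervals,
    make_windows,
)

CFG = BlockingConfig(block_length=64, block_span=128, max_missing=3, max_multiallelic=3)


def test_exact_division_without_gaps():
    blocks = cut_pair_blocks([(0, 200)], [(0, 200)], [], ("a", "b"), CFG)
    assert [(b.start, b.end) for b in blocks] == [(0, 64), (64, 128), (128, 192)]
    assert all(b.span == 64 for b in blocks)


def test_gap_spanning_block_by_hand():
    """Jointly callable {[0,60), [70,144)}: first block takes sites 0-59
    plus 70-73 (span 74), second takes 74-137 (span 64), the trailing six
    callable sites emit nothing."""
    blocks = cut_pair_blocks([(0, 60), (70, 144)], [(0, 200)], [], ("a", "b"), CFG)
    assert [(b.start, b.end, b.span) for b in blocks] == [(0, 74, 74), (74, 138, 64)]
    assert blocks[0].runs == ((0, 60), (70, 74))


def test_span_violation_restarts_at_next_callable_site():
    # 40 callable sites, a 200-bp hole, then plenty: no block can bridge
    # the hole within span 128, so the packer starts after it
    blocks = cut_pair_blocks([(0, 40), (240, 400)], [(0, 400)], [], ("a", "b"), CFG)
    assert blocks[0].start == 240


def test_mutation_type_counting_and_fgv_flag():
    genos = [(5, 0, 1, 0, 1),    # het in both -> het_ab
             (10, 1, 1, 0, 0)]   # opposite homozygotes -> fixed_diff
    blocks = cut_pair_blocks([(0, 64)], [(0, 64)], genos, ("a", "b"), CFG)
    assert blocks[0].counts == (0, 0, 1, 1)
    assert blocks[0].is_fgv


@pytest.mark.parametrize("gts,expected", [
    ((0, 1, 0, 0), 1),      # het only in A
    ((0, 0, 0, 1), 0),      # het only in B
    ((0, 1, 1, 0), 2),      # shared het
    ((1, 1, 0, 0), 3),      # fixed difference
    ((0, 0, 0, 0), -1),     # invariant
    ((1, 1, 1, 1), -1),     # shared alternate homozygote
    ((-1, -1, 0, 1), -2),   # missing
    ((0, 1, 0, 2), -3),     # three alleles in the pair
])
def test_genotype_classification(gts, expected):
    assert classify_pair_genotypes(*gts) == expected


def test_missing_and_multiallelic_caps_suppress_blocks():
    cfg = BlockingConfig(block_length=8, block_span=16, max_missing=1,
                         max_multiallelic=0)
    genos = [(2, -1, -1, 0, 0), (3, -1, -1, 0, 0)]  # two missing sites
    assert cut_pair_blocks([(0, 8)], [(0, 8)], genos, ("a", "b"), cfg) == []
    genos = [(2, 0, 1, 0, 2)]  # one multiallelic site, cap 0
    assert cut_pair_blocks([(0, 8)], [(0, 8)], genos, ("a", "b"), cfg) == []
    # within caps the block is emitted and flags carry the counts
    cfg2 = BlockingConfig(block_length=8, block_span=16, max_missing=2,
                          max_multiallelic=1)
    blocks = cut_pair_blocks([(0, 8)], [(0, 8)],
                             [(2, -1, -1, 0, 0), (3, 0, 1, 0, 2)],
                             ("a", "b"), cfg2)
    assert blocks[0].n_missing == 1 and blocks[0].n_multiallelic == 1
    assert blocks[0].counts == (0, 0, 0, 0)


def test_genotype_outside_callable_is_ignored(caplog):
    genos = [(500, 0, 1, 0, 0)]
    with caplog.at_level("WARNING"):
        blocks = cut_pair_blocks([(0, 64)], [(0, 64)], genos, ("a", "b"), CFG)
    assert blocks[0].counts == (0, 0, 0, 0)
    assert "non-callable" in caplog.text


def test_unsorted_intervals_rejected():
    with pytest.raises(ValueError):
        cut_pair_blocks([(10, 20), (0, 5)], [(0, 64)], [], ("a", "b"), CFG)


@given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 80)),
                min_size=1, max_size=8),
       st.integers(0, 3))
@settings(max_examples=60, deadline=None)
def test_emitted_blocks_always_satisfy_constraints(raw, seed_missing):
    """Property: every emitted block has exactly block_length callable
    sites, span <= block_span, caps respected, and blocks of one pair
    never overlap; consumed sites never exceed the jointly callable total."""
    cfg = BlockingConfig(block_length=16, block_span=40, max_missing=1,
                         max_multiallelic=1)
    # build disjoint sorted intervals from the raw (gap, length) pairs
    intervals = []
    pos = 0
    for gap, length in raw:
        pos += gap
        intervals.append((pos, pos + length))
        pos += length
    rng = np.random.default_rng(seed_missing)
    genos = [(int(p), *rng.integers(-1, 2, size=4))
             for p in rng.integers(0, pos + 1, size=10)]
    blocks = cut_pair_blocks(intervals, [(0, pos + 1)], genos, ("a", "b"), cfg)
    joint = intersect_intervals(intervals, [(0, pos + 1)])
    total = int((joint[:, 1] - joint[:, 0]).sum()) if len(joint) else 0
    prev_end = -1
    for b in blocks:
        assert sum(e - s for s, e in b.runs) == cfg.block_length
        assert b.span <= cfg.block_span
        assert b.n_missing <= cfg.max_missing
        assert b.n_multiallelic <= cfg.max_multiallelic
        assert b.start > prev_end - 1 and b.start >= prev_end
        prev_end = b.end
    assert len(blocks) * cfg.block_length <= total


def test_per_pair_independence():
    """Blocks of a pair only depend on that pair's callable sites and
    genotypes; a third sample changes nothing (checked by construction:
    the API takes only the pair's own inputs)."""
    a = cut_pair_blocks([(0, 200)], [(0, 150)], [], ("s1", "s2"), CFG)
    b = cut_pair_blocks([(0, 200)], [(0, 150)], [], ("s1", "s2"), CFG)
    assert a == b  # determinism: byte-identical outputs


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def _toy_blocks(n, pair=("a", "b"), start0=0, step=64):
    return [
        cut_pair_blocks([(start0 + i * step, start0 + i * step + 64)],
                        [(0, 10 ** 6)], [], pair,
                        BlockingConfig(block_length=64, block_span=64))[0]
        for i in range(n)
    ]


def test_window_count_formula():
    blocks = _toy_blocks(100)
    wins = make_windows(blocks, blocks_per_window=50, step=10)
    assert len(wins) == 6
    assert [w.blocks[0].start for w in wins] == [i * 10 * 64 for i in range(6)]


def test_too_few_blocks_yield_no_window():
    assert make_windows(_toy_blocks(49), 50, 10) == []


def test_invalid_window_parameters():
    with pytest.raises(ValueError):
        make_windows(_toy_blocks(5), 0, 1)
    with pytest.raises(ValueError):
        make_windows(_toy_blocks(5), 5, 0)


def test_blocks_interleave_across_pairs_by_start_position():
    """Windows consume blocks from all pairs in genomic order, verified
    against an explicit sort on a three-pair fixture."""
    blocks = (_toy_blocks(5, ("a", "x"), start0=0)
              + _toy_blocks(5, ("b", "x"), start0=32)
              + _toy_blocks(5, ("c", "x"), start0=48))
    wins = make_windows(blocks, blocks_per_window=4, step=2)
    expected = sorted(blocks, key=lambda b: (b.start, b.end, b.pair))
    got = [b for w in wins for b in w.blocks[:2]]  # step-2 prefixes tile the order
    assert [b.start for w in wins for b in w.blocks] == \
        [b.start for i in range(len(wins)) for b in expected[i * 2:i * 2 + 4]]
    assert wins[0].span == wins[0].end - wins[0].start


def test_genome_and_sample_files_roundtrip(tmp_path):
    g = GenomeFile((("chr1", 1000), ("chr2", 500)))
    g.write(tmp_path / "genome.tsv")
    assert GenomeFile.read(tmp_path / "genome.tsv") == g
    with pytest.raises(ValueError):
        GenomeFile((("chr1", 10), ("chr1", 20)))
    p = SamplePartition((("s1", "popA"), ("s2", "popA"), ("s3", "popB")))
    p.write(tmp_path / "samples.tsv")
    assert SamplePartition.read(tmp_path / "samples.tsv") == p
    assert p.pairs("X") == [("s1", "s3"), ("s2", "s3")]
    assert p.pairs("A") == [("s1", "s2")]
    with pytest.raises(ValueError):
        SamplePartition((("s1", "a"), ("s2", "b"), ("s3", "c")))
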