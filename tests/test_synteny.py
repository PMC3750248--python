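import itertools
import random

import pytest

from _oracles import collinear_runs
from conftest import identity_orthomap, make_genome, permuted_pair

from pairplasma.model import OrthologMap, OrthologPair
from pairplasma.synteny import find_synteny_blocks, synteny_metrics


def block_index_sets(blocks):
    return {tuple(int(p.gene_a[1:]) for p in b.pairs) for b in blocks}


def test_identity_order_yields_single_block():
    A, B, om = permuted_pair(list(range(5)))
    blocks = find_synteny_blocks(om, A, B)
    assert len(blocks) == 1
    assert blocks[0].length == 5
    assert blocks[0].orientation == "same"


def test_spec_two_block_example():
    # A: a1..a5; B carries b-orthologs in order giving pairs
    # (a1,b1)(a2,b2)(a3,b5)(a4,b3)(a5,b4); gap 0 -> two blocks, one unplaced
    A = make_genome("A", {"A_c0": [f"a{i}" for i in range(1, 6)]})
    B = make_genome("B", {"B_c0": ["b1", "b2", "b3", "b4", "b5"]})
    pairs = [
        OrthologPair(gene_a="a1", gene_b="b1", pct_identity=90.0, bit_score=10.0),
        OrthologPair(gene_a="a2", gene_b="b2", pct_identity=90.0, bit_score=10.0),
        OrthologPair(gene_a="a3", gene_b="b5", pct_identity=90.0, bit_score=10.0),
        OrthologPair(gene_a="a4", gene_b="b3", pct_identity=90.0, bit_score=10.0),
        OrthologPair(gene_a="a5", gene_b="b4", pct_identity=90.0, bit_score=10.0),
    ]
    om = OrthologMap("A", "B", pairs, 5, 5)
    blocks = find_synteny_blocks(om, A, B, gap_tolerance=0, min_block_size=2)
    got = [{(p.gene_a, p.gene_b) for p in b.pairs} for b in blocks]
    assert got == [
        {("a1", "b1"), ("a2", "b2")},
        {("a4", "b3"), ("a5", "b4")},
    ]
    frac, mean_len = synteny_metrics(blocks, om)
    assert frac == pytest.approx(0.8)
    assert mean_len == pytest.approx(2.0)


def test_full_reversal_detected_as_inverted_block():
    A, B, om = permuted_pair([2, 1, 0])
    blocks = find_synteny_blocks(om, A, B, gap_tolerance=0, min_block_size=2)
    assert len(blocks) == 1
    assert blocks[0].orientation == "inverted"
    assert blocks[0].length == 3


def test_inversion_ignored_when_disallowed():
    A, B, om = permuted_pair([2, 1, 0])
    blocks = find_synteny_blocks(
        om, A, B, gap_tolerance=0, min_block_size=2, allow_inversion=False
    )
    assert blocks == []


def test_metrics_identity_and_empty_cases():
    A, B, om = permuted_pair(list(range(7)))
    blocks = find_synteny_blocks(om, A, B)
    frac, mean_len = synteny_metrics(blocks, om)
    assert frac == 1.0
    assert mean_len == 7.0
    frac0, mean0 = synteny_metrics([], om)
    assert frac0 == 0.0
    assert mean0 != mean0  # NaN flags the undefined mean


def test_unknown_gene_id_is_reported():
    A, B, om = permuted_pair([0, 1])
    A.contigs[0].genes[0].gene_id = "renamed"
    with pytest.raises(ValueError, match="a0"):
        find_synteny_blocks(om, A, B)


def test_blocks_never_span_contigs():
    A = make_genome("A", {"A_c0": ["a0", "a1"], "A_c1": ["a2", "a3"]})
    B = make_genome("B", {"B_c0": ["b0", "b1", "b2", "b3"]})
    om = identity_orthomap(4)
    blocks = find_synteny_blocks(om, A, B, gap_tolerance=0)
    assert block_index_sets(blocks) == {(0, 1), (2, 3)}
    assert all(b.contig_a in ("A_c0", "A_c1") for b in blocks)


@pytest.mark.parametrize("n", range(1, 7))
def test_exhaustive_equivalence_with_bruteforce_runs(n):
    """Detection at gap 0 equals exhaustive maximal-run enumeration on
    every permutation of n genes."""
    for perm in itertools.permutations(range(n)):
        A, B, om = permuted_pair(list(perm))
        blocks = find_synteny_blocks(om, A, B, gap_tolerance=0, min_block_size=2)
        assert block_index_sets(blocks) == collinear_runs(list(perm), 2), perm
        # each pair in at most one block, total bounded by pair count
        all_pairs = [p for b in blocks for p in b.pairs]
        assert len(all_pairs) == len(set(all_pairs))
        assert len(all_pairs) <= len(om.pairs)


def test_swap_invariance_at_zero_gap():
    rng = random.Random(9)
    for _ in range(100):
        n = rng.randint(2, 8)
        perm = list(range(n))
        rng.shuffle(perm)
        A, B, om = permuted_pair(perm)
        rev_pairs = [
            OrthologPair(gene_a=p.gene_b, gene_b=p.gene_a, pct_identity=p.pct_identity, bit_score=p.bit_score)
            for p in om.pairs
        ]
        om_rev = OrthologMap("B", "A", rev_pairs, n, n)
        fwd = {
            frozenset(frozenset((p.gene_a, p.gene_b)) for p in b.pairs)
            for b in find_synteny_blocks(om, A, B, gap_tolerance=0)
        }
        rev = {
            frozenset(frozenset((p.gene_a, p.gene_b)) for p in b.pairs)
            for b in find_synteny_blocks(om_rev, B, A, gap_tolerance=0)
        }
        assert fwd == rev


def test_gap_tolerance_bridges_missing_orthologs():
    # a2 has no ortholog; gap 1 bridges across it, gap 0 does not
    A = make_genome("A", {"A_c0": ["a0", "a1", "a2", "a3"]})
    B = make_genome("B", {"B_c0": ["b0", "b1", "bx", "b3"]})
    pairs = [
        OrthologPair(gene_a="a0", gene_b="b0", pct_identity=90.0, bit_score=10.0),
        OrthologPair(gene_a="a1", gene_b="b1", pct_identity=90.0, bit_score=10.0),
        OrthologPair(gene_a="a3", gene_b="b3", pct_identity=90.0, bit_score=10.0),
    ]
    om = OrthologMap("A", "B", pairs, 4, 4)
    with_gap = find_synteny_blocks(om, A, B, gap_tolerance=1, min_block_size=2)
    assert [b.length for b in with_gap] == [3]
    without = find_synteny_blocks(om, A, B, gap_tolerance=0, min_block_size=2)
    assert [b.length for b in without] == [2]
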