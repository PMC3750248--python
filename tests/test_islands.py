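import random

import pytest
from hypothesis import given, strategies as st

from _oracles import island_runs
from conftest import make_genome

from pairplasma.islands import composition_deviation, find_islands, foreign_gene_flags
from pairplasma.model import OrthologMap, OrthologPair


def orthomap_for(query_genes, matched, genome_b_id="P0"):
    """Panel map pairing each matched query gene with a panel gene."""
    pairs = [
        OrthologPair(gene_a=g, gene_b=f"{genome_b_id}_{g}", pct_identity=80.0, bit_score=50.0)
        for g in query_genes
        if g in matched
    ]
    return OrthologMap("Q", genome_b_id, pairs, len(query_genes), max(len(matched), 1))


def test_nine_gene_block_without_orthologs_is_one_island():
    genes = [f"g{i}" for i in range(20)]
    genome = make_genome("Q", {"c0": genes})
    matched = {g for i, g in enumerate(genes) if not 6 <= i <= 14}
    maps = [orthomap_for(genes, matched, "P0"), orthomap_for(genes, matched, "P1")]
    (island,) = find_islands(genome, maps, min_run=5)
    assert (island.start_ordinal, island.end_ordinal, island.n_genes) == (6, 14, 9)


def test_no_island_when_every_gene_has_orthologs():
    genes = [f"g{i}" for i in range(12)]
    genome = make_genome("Q", {"c0": genes})
    maps = [orthomap_for(genes, set(genes))]
    assert find_islands(genome, maps, min_run=5) == []


def test_runs_below_min_run_are_not_called():
    genes = [f"g{i}" for i in range(12)]
    genome = make_genome("Q", {"c0": genes})
    matched = {g for i, g in enumerate(genes) if not 4 <= i <= 7}  # run of 4
    maps = [orthomap_for(genes, matched)]
    assert find_islands(genome, maps, min_run=5) == []


def test_max_panel_hits_relaxation():
    genes = [f"g{i}" for i in range(10)]
    genome = make_genome("Q", {"c0": genes})
    # genes 2..7 matched in exactly one of two panel genomes
    m1 = {g for i, g in enumerate(genes) if not 2 <= i <= 7}
    m2 = set(genes)
    maps = [orthomap_for(genes, m1, "P0"), orthomap_for(genes, m2, "P1")]
    assert find_islands(genome, maps, min_run=5, max_panel_hits=0) == []
    (island,) = find_islands(genome, maps, min_run=5, max_panel_hits=1)
    assert (island.start_ordinal, island.end_ordinal) == (2, 7)


def test_empty_panel_rejected():
    genome = make_genome("Q", {"c0": ["g0"]})
    with pytest.raises(ValueError):
        find_islands(genome, [])


@given(st.lists(st.booleans(), min_size=1, max_size=40), st.integers(1, 6))
def test_island_runs_match_bruteforce_enumeration(flags, min_run):
    genes = [f"g{i}" for i in range(len(flags))]
    genome = make_genome("Q", {"c0": genes})
    matched = {g for g, f in zip(genes, flags) if not f}
    maps = [orthomap_for(genes, matched)]
    got = [
        (c.start_ordinal, c.end_ordinal)
        for c in find_islands(genome, maps, min_run=min_run)
    ]
    assert got == island_runs(flags, min_run)


def test_foreign_flags_count_across_panel():
    genes = ["g0", "g1"]
    genome = make_genome("Q", {"c0": genes})
    maps = [orthomap_for(genes, {"g0"}, "P0"), orthomap_for(genes, {"g0", "g1"}, "P1")]
    flags = foreign_gene_flags(genome, maps, max_panel_hits=1)
    assert flags == {"g0": False, "g1": True}


def test_composition_deviation_worked_example():
    # background genes at GC 0.42 and 0.48 -> mean 0.45, sd 0.03
    bg = ["G" * 42 + "A" * 58, "G" * 48 + "A" * 52]
    island = ["G" * 62 + "A" * 38]
    stats = composition_deviation(island, bg)
    assert stats["gc_island"] == pytest.approx(0.62)
    assert stats["gc_genome_mean"] == pytest.approx(0.45)
    assert stats["gc_genome_sd"] == pytest.approx(0.03)
    assert stats["gc_z"] == pytest.approx(5.667, abs=1e-3)


def test_all_g_island_has_maximal_gc_and_positive_skew():
    bg = ["G" * 45 + "C" * 5 + "A" * 50, "G" * 40 + "C" * 15 + "T" * 45]
    stats = composition_deviation(["G" * 100], bg)
    assert stats["gc_island"] == 1.0
    assert stats["gc_z"] > 3
    assert stats["gc_skew"] == 1.0


def test_composition_deviation_rejects_empty():
    with pytest.raises(ValueError):
        composition_deviation([], ["ACGT"])


def test_background_draws_are_rarely_anomalous(small_sim_pair):
    """Windows drawn from the genome's own genes should usually have
    |z| < 2 (the z-score is calibrated against per-gene GC spread)."""
    dna = list(small_sim_pair.a.gene_dna.values())
    rng = random.Random(0)
    ok = 0
    n = 200
    for _ in range(n):
        start = rng.randrange(0, len(dna) - 9)
        stats = composition_deviation(dna[start : start + 9], dna)
        if abs(stats["gc_z"]) < 2:
            ok += 1
    assert ok / n >= 0.9
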