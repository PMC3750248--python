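import pytest

from pairplasma.synteny import find_synteny_blocks
from pairplasma.synthetic_data import (
    EvolverParams,
    IslandSpec,
    evolve_family,
    evolve_pair,
    evolve_panel,
    expected_pairwise_identity,
    make_marker_test_set,
    reverse_translate,
)

import numpy as np
from Bio.Seq import Seq


def test_same_seed_reproduces_byte_identical_output():
    p = EvolverParams(
        n_genes=25, mean_protein_len=100, sub_proportion=0.08, loss_prob=0.05,
        gain_count=2, n_inversions=2, n_translocations=1,
        island_spec=IslandSpec(n_genes=5, gc_shift_sd=3.0), seed=99,
    )
    s1, s2 = evolve_pair(p), evolve_pair(p)
    assert s1.a.proteins == s2.a.proteins
    assert s1.b.proteins == s2.b.proteins
    assert s1.a.gene_dna == s2.a.gene_dna
    assert [c.nucleotide_seq for c in s1.b.genome.contigs] == [
        c.nucleotide_seq for c in s2.b.genome.contigs
    ]
    assert s1.truth.ortholog_pairs == s2.truth.ortholog_pairs
    assert s1.truth.island == s2.truth.island


def test_zero_divergence_produces_identical_proteomes():
    sim = evolve_pair(EvolverParams(n_genes=15, mean_protein_len=80, sub_proportion=0.0, seed=3))
    for ga, gb in sim.truth.ortholog_pairs:
        assert sim.a.proteins[ga] == sim.b.proteins[gb]
    assert all(v == 100.0 for v in sim.truth.realized_identity.values())
    assert len(sim.truth.true_segments) == 1


def test_realized_identity_converges_to_analytic_expectation():
    sim = evolve_pair(EvolverParams(n_genes=350, mean_protein_len=300, sub_proportion=0.09, seed=5))
    total = sum(len(s) for s in sim.a.proteins.values())
    assert total >= 1e5
    assert sim.truth.mean_realized_identity == pytest.approx(
        expected_pairwise_identity(0.09), abs=0.5
    )


def test_rearrangements_fragment_true_segments():
    calm = evolve_pair(EvolverParams(n_genes=40, mean_protein_len=60, seed=8))
    shaken = evolve_pair(EvolverParams(n_genes=40, mean_protein_len=60, n_inversions=3, seed=8))
    assert len(calm.truth.true_segments) == 1
    assert len(shaken.truth.true_segments) > 1


def test_true_segments_match_detection_under_noise_free_settings():
    """With no gaps and no gene turnover, detected blocks (gap 0, min
    size 1) must equal the truth's strictly-adjacent segments."""
    sim = evolve_pair(
        EvolverParams(n_genes=40, mean_protein_len=60, sub_proportion=0.0, n_inversions=3, seed=21)
    )
    from pairplasma.model import OrthologMap, OrthologPair

    pairs = [
        OrthologPair(gene_a=a, gene_b=b, pct_identity=100.0, bit_score=100.0)
        for a, b in sim.truth.ortholog_pairs
    ]
    om = OrthologMap("A", "B", pairs, sim.a.genome.n_genes, sim.b.genome.n_genes)
    blocks = find_synteny_blocks(
        om, sim.a.genome, sim.b.genome, gap_tolerance=0, min_block_size=1
    )
    assert len(blocks) == len(sim.truth.true_segments)


def test_loss_and_gain_change_gene_counts():
    sim = evolve_pair(
        EvolverParams(n_genes=50, mean_protein_len=60, loss_prob=0.2, gain_count=3, seed=13)
    )
    assert sim.a.genome.n_genes < 50 + 3 + 1  # losses happened
    assert any(g.startswith("A_n") for g in sim.a.proteins)
    # orthologs only between genes surviving in both lineages
    for ga, gb in sim.truth.ortholog_pairs:
        assert ga in sim.a.proteins and gb in sim.b.proteins


def test_island_recorded_with_correct_span():
    spec = IslandSpec(n_genes=9, gc_shift_sd=3.0)
    sim = evolve_pair(EvolverParams(n_genes=30, mean_protein_len=60, island_spec=spec, seed=2))
    contig, start, end = sim.truth.island
    assert end - start + 1 == 9
    genes = sim.a.genome.contigs[0].genes[start : end + 1]
    assert [g.gene_id for g in genes] == sim.truth.island_gene_ids
    # island genes are novel: never orthologous to anything
    paired = {a for a, _ in sim.truth.ortholog_pairs}
    assert not paired & set(sim.truth.island_gene_ids)


def test_island_longer_than_genome_rejected():
    with pytest.raises(ValueError):
        EvolverParams(n_genes=5, island_spec=IslandSpec(n_genes=9))


def test_island_gc_is_shifted_upward():
    spec = IslandSpec(n_genes=9, gc_shift_sd=3.0)
    sim = evolve_pair(EvolverParams(n_genes=60, mean_protein_len=120, island_spec=spec, seed=4))

    def gc(s):
        return (s.count("G") + s.count("C")) / len(s)

    island = set(sim.truth.island_gene_ids)
    gc_isl = np.mean([gc(s) for g, s in sim.a.gene_dna.items() if g in island])
    bg = [gc(s) for g, s in sim.a.gene_dna.items() if g not in island]
    assert gc_isl > np.mean(bg) + 2 * np.std(bg)


def test_dna_translates_back_to_protein():
    rng = np.random.default_rng(0)
    protein = "MKVLAWHD" * 5
    dna = reverse_translate(rng, protein, target_gc=0.45)
    assert str(Seq(dna).translate()) == protein


def test_gene_coordinates_consistent_with_contig_sequence():
    sim = evolve_pair(EvolverParams(n_genes=10, mean_protein_len=60, seed=6))
    for contig in sim.a.genome.contigs:
        for gene in contig.genes:
            segment = contig.nucleotide_seq[gene.start - 1 : gene.end]
            assert segment == sim.a.gene_dna[gene.gene_id]


def test_evolve_panel_shares_one_ancestor():
    genomes = evolve_panel(
        EvolverParams(n_genes=20, mean_protein_len=80, seed=10), [0.0, 0.0]
    )
    assert len(genomes) == 2
    a, b = genomes
    for k in range(20):
        assert a.proteins[f"P0_g{k:04d}"] == b.proteins[f"P1_g{k:04d}"]


def test_evolve_family_panel_orthology_and_island():
    fam = evolve_family(
        EvolverParams(
            n_genes=20, mean_protein_len=60, sub_proportion=0.03,
            island_spec=IslandSpec(n_genes=5), seed=12,
        ),
        n_panel=2,
    )
    assert len(fam.panel) == 2
    assert fam.truth.island is not None
    island = set(fam.truth.island_gene_ids)
    assert not {a for a, _ in fam.truth.ortholog_pairs} & island


@pytest.mark.parametrize(
    "fraction, expected", [(0.0, 100.0), (0.1, 90.0), (1.0, 0.0)]
)
def test_marker_test_set_expectation(fraction, expected):
    proteins = {f"g{i}": "MKVLAWHD" * 10 for i in range(60)}
    refs, depleted, exp = make_marker_test_set(proteins, fraction, seed=1, n_markers=50)
    assert exp == expected
    assert len(refs) == 50
    assert len(depleted) == 60 - round(fraction * 50)
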