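import random

import pytest
from hypothesis import HealthCheck, settings

from pairplasma.model import (
    ContigRecord,
    GeneRecord,
    GenomeRecord,
    HitRecord,
    OrthologMap,
    OrthologPair,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_genome(genome_id: str, gene_orders: dict[str, list[str]]) -> GenomeRecord:
    """Build a GenomeRecord from {contig_id: [gene ids in order]}."""
    contigs = []
    for contig_id, order in gene_orders.items():
        genes = [
            GeneRecord(
                gene_id=g,
                contig_id=contig_id,
                ordinal=i,
                start=i * 100 + 1,
                end=i * 100 + 90,
                strand="+",
            )
            for i, g in enumerate(order)
        ]
        contigs.append(ContigRecord(contig_id=contig_id, genes=genes))
    return GenomeRecord(genome_id=genome_id, contigs=contigs)


def identity_orthomap(n: int, genome_a_id: str = "A", genome_b_id: str = "B") -> OrthologMap:
    """Orthologs (a_i, b_i) for i in 0..n-1."""
    pairs = [
        OrthologPair(gene_a=f"a{i}", gene_b=f"b{i}", pct_identity=90.0, bit_score=100.0)
        for i in range(n)
    ]
    return OrthologMap(genome_a_id, genome_b_id, pairs, n, n)


def permuted_pair(perm: list[int]):
    """Genome A with genes a0..a(n-1) in order, genome B with gene b_i at
    position perm.index(i), and the identity orthology between them."""
    n = len(perm)
    A = make_genome("A", {"A_c0": [f"a{i}" for i in range(n)]})
    B = make_genome("B", {"B_c0": [f"b{perm[i]}" for i in range(n)]})
    return A, B, identity_orthomap(n)


def hit(q, s, bits, pident=50.0, evalue=1e-20, q_cov=1.0, s_cov=1.0):
    return HitRecord(
        query_id=q, subject_id=s, pct_identity=pident, aln_length=100,
        evalue=evalue, bit_score=bits, q_cov=q_cov, s_cov=s_cov,
    )


def random_hit_tables(rng: random.Random, n_a: int = 5, n_b: int = 5):
    """A random directed hit-table pair with deliberate score ties and
    occasional sub-threshold rows, to exercise filters and tie-breaks."""
    hits_ab, hits_ba = [], []
    for i in range(n_a):
        for j in range(n_b):
            if rng.random() < 0.5:
                hits_ab.append(
                    hit(
                        f"p{i}", f"q{j}",
                        bits=rng.choice([10.0, 20.0, 30.0]),
                        pident=rng.choice([40.0, 50.0]),
                        evalue=rng.choice([1e-20, 1e-3]),
                        q_cov=rng.choice([1.0, 0.5]),
                    )
                )
            if rng.random() < 0.5:
                hits_ba.append(
                    hit(
                        f"q{j}", f"p{i}",
                        bits=rng.choice([10.0, 20.0, 30.0]),
                        pident=rng.choice([40.0, 50.0]),
                        evalue=rng.choice([1e-20, 1e-3]),
                        q_cov=rng.choice([1.0, 0.5]),
                    )
                )
    return hits_ab, hits_ba


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA) for _ in range(length))


@pytest.fixture(scope="session")
def small_sim_pair():
    """One mid-sized simulated pair shared across tests (seeded)."""
    from pairplasma.synthetic_data import EvolverParams, evolve_pair

    return evolve_pair(
        EvolverParams(n_genes=30, mean_protein_len=120, sub_proportion=0.05, seed=11)
    )
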