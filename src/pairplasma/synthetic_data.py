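"""Genome-pair/panel evolution with recorded ground truth.

An ancestor of random proteins is evolved down independent lineages
under per-site amino acid substitution (uniform across sites; the
replacement residue uniform over the other 19), whole-gene loss, gene
gain, and gene-order rearrangement (inversions and translocations),
optionally with a compositionally shifted gene island inserted into the
first lineage. DNA is produced by reverse-translating each protein with
the standard codon table, choosing synonymous codons with a bias toward
a target GC content. Everything is driven by one seeded generator, so a
given seed reproduces byte-identical output, and the true orthology,
true collinear segments, realized identities and island location are
returned alongside the genomes.

Two lineages at per-site substitution proportion s each are expected to
show pairwise identity 100*(1-s)^2 (a site survives unchanged on both
sides), ignoring back-substitution coincidences of order s^2/19.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from Bio.Data import CodonTable

from .model import ContigRecord, GeneRecord, GenomeRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
INTERGENIC_LEN = 20


@dataclass(frozen=True)
class IslandSpec:
    """A block of novel genes inserted into lineage A.

    ``gc_shift_sd`` shifts the island's target GC by that many standard
    deviations of the genome's per-gene GC distribution.
    """

    n_genes: int = 9
    gc_shift_sd: float = 3.0


@dataclass(frozen=True)
class EvolverParams:
    n_genes: int = 100
    mean_protein_len: int = 300
    min_protein_len: int = 50
    sub_proportion: Union[float, tuple[float, float]] = 0.05
    loss_prob: float = 0.0
    gain_count: int = 0
    n_inversions: int = 0
    n_translocations: int = 0
    island_spec: Optional[IslandSpec] = None
    gc_content: float = 0.45
    n_contigs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        s = self.sub_proportion
        subs = (s, s) if isinstance(s, (int, float)) else tuple(s)
        for v in subs:
            if not 0.0 <= v <= 1.0:
                raise ValueError("sub_proportion must be in [0, 1]")
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ValueError("loss_prob must be in [0, 1]")
        for name in ("n_genes", "gain_count", "n_inversions", "n_translocations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.island_spec is not None and self.island_spec.n_genes > self.n_genes:
            raise ValueError("island cannot be longer than the genome")

    @property
    def subs(self) -> tuple[float, float]:
        s = self.sub_proportion
        return (s, s) if isinstance(s, (int, float)) else (s[0], s[1])


@dataclass
class SimTruth:
    """Ground truth emitted by the evolver."""

    ortholog_pairs: list[tuple[str, str]]
    realized_identity: dict[tuple[str, str], float]
    true_segments: list[list[tuple[str, str]]]
    island: Optional[tuple[str, int, int]]  # (contig_id, start_ord, end_ord) in A
    island_gene_ids: list[str] = field(default_factory=list)
    params: Optional[EvolverParams] = None

    @property
    def mean_realized_identity(self) -> float:
        vals = list(self.realized_identity.values())
        return sum(vals) / len(vals)


@dataclass
class SimulatedGenome:
    genome: GenomeRecord
    proteins: dict[str, str]
    gene_dna: dict[str, str]


@dataclass
class SimulatedPair:
    a: SimulatedGenome
    b: SimulatedGenome
    truth: SimTruth


# ---------------------------------------------------------------- ancestor


def _gene_lengths(rng: np.random.Generator, params: EvolverParams) -> np.ndarray:
    lo, mean = params.min_protein_len, params.mean_protein_len
    if mean <= lo:
        return np.full(params.n_genes, lo, dtype=int)
    p = 1.0 / (mean - lo + 1)
    return lo - 1 + rng.geometric(p, size=params.n_genes)


def _random_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 20, size=length)


def _mutate(rng: np.random.Generator, protein: np.ndarray, s: float) -> np.ndarray:
    """Substitute a Binomial(L, s) number of sites; replacements are
    uniform over the 19 other residues."""
    out = protein.copy()
    n_sub = rng.binomial(len(protein), s)
    if n_sub == 0:
        return out
    sites = rng.choice(len(protein), size=n_sub, replace=False)
    shift = rng.integers(1, 20, size=n_sub)
    out[sites] = (out[sites] + shift) % 20
    return out


def _to_str(protein: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in protein)


# ------------------------------------------------------- reverse translation

_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _BACK_TABLE.setdefault(aa, []).append(codon)
for _aa in _BACK_TABLE:
    _BACK_TABLE[_aa].sort()


_GC_COUNTS: dict[str, np.ndarray] = {
    aa: np.array([sum(b in "GC" for b in cod) for cod in codons], dtype=float)
    for aa, codons in _BACK_TABLE.items()
}


def _codon_weights(target_gc: float, aa_freq: Optional[Mapping[str, float]] = None) -> dict[str, np.ndarray]:
    """Per-amino-acid codon probabilities calibrated to a GC target.

    Synonymous codons are weighted proportionally to exp(beta * GC),
    with beta solved by bisection so the expected GC over the given
    amino acid composition (uniform by default) equals the target —
    clamped to what synonymous choice can achieve at all.
    """
    if aa_freq is None:
        aa_freq = {aa: 1.0 / 20.0 for aa in AMINO_ACIDS}
    total = sum(aa_freq.values())
    freq = {aa: f / total for aa, f in aa_freq.items() if f > 0}

    def expected_gc(beta: float) -> float:
        e = 0.0
        for aa, f in freq.items():
            gc = _GC_COUNTS[aa]
            w = np.exp(beta * (gc - gc.max()))
            e += f * float((w * gc).sum() / w.sum()) / 3.0
        return e

    lo, hi = -60.0, 60.0
    if target_gc <= expected_gc(lo):
        beta = lo
    elif target_gc >= expected_gc(hi):
        beta = hi
    else:
        for _ in range(80):
            mid = (lo + hi) / 2.0
            if expected_gc(mid) < target_gc:
                lo = mid
            else:
                hi = mid
        beta = (lo + hi) / 2.0
    weights = {}
    for aa, codons in _BACK_TABLE.items():
        gc = _GC_COUNTS[aa]
        w = np.exp(beta * (gc - gc.max()))
        weights[aa] = w / w.sum()
    return weights


def _aa_composition(proteins: Mapping[str, str] | Sequence[str]) -> dict[str, float]:
    seqs = proteins.values() if hasattr(proteins, "values") else proteins
    counts: dict[str, float] = {}
    for seq in seqs:
        for aa in seq:
            counts[aa] = counts.get(aa, 0.0) + 1.0
    return counts


def reverse_translate(
    rng: np.random.Generator, protein: str, target_gc: float,
    weights: Optional[dict[str, np.ndarray]] = None,
) -> str:
    if weights is None:
        weights = _codon_weights(target_gc)
    out = []
    for aa in protein:
        codons = _BACK_TABLE[aa]
        idx = rng.choice(len(codons), p=weights[aa])
        out.append(codons[idx])
    return "".join(out)


def _random_spacer(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join("ATGC"[i] for i in rng.choice(4, size=length, p=probs))


# ------------------------------------------------------------ rearrangement


def _invert(order: list, rng: np.random.Generator) -> tuple[list, tuple[int, int]]:
    n = len(order)
    i, j = sorted(rng.choice(n, size=2, replace=False))
    new = order[:i] + [(idx, not flipped) for idx, flipped in reversed(order[i : j + 1])] + order[j + 1 :]
    return new, (i, j)


def _translocate(order: list, rng: np.random.Generator) -> list:
    n = len(order)
    i, j = sorted(rng.choice(n, size=2, replace=False))
    segment = order[i : j + 1]
    rest = order[:i] + order[j + 1 :]
    if not rest:
        return order
    k = int(rng.integers(0, len(rest) + 1))
    return rest[:k] + segment + rest[k:]


# -------------------------------------------------------------- assembly


def _assemble_genome(
    genome_id: str,
    order: Sequence[tuple[str, bool]],  # (gene_id, flipped strand)
    proteins: Mapping[str, str],
    gene_dna: Mapping[str, str],
    n_contigs: int,
    rng: np.random.Generator,
    gc: float,
) -> SimulatedGenome:
    """Lay genes along contigs with random intergenic spacers."""
    chunks = np.array_split(np.arange(len(order)), n_contigs)
    contigs = []
    for ci, chunk in enumerate(chunks):
        contig_id = f"{genome_id}_c{ci}"
        genes = []
        seq_parts = []
        cursor = 0
        for ordinal, k in enumerate(chunk):
            gene_id, flipped = order[k]
            spacer = _random_spacer(rng, INTERGENIC_LEN, gc)
            dna = gene_dna[gene_id]
            start = cursor + len(spacer) + 1
            end = start + len(dna) - 1
            seq_parts.append(spacer)
            seq_parts.append(dna)
            cursor = end
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id=contig_id,
                    ordinal=ordinal,
                    start=start,
                    end=end,
                    strand="-" if flipped else "+",
                    protein_seq=proteins[gene_id],
                )
            )
        seq_parts.append(_random_spacer(rng, INTERGENIC_LEN, gc))
        contigs.append(
            ContigRecord(contig_id=contig_id, genes=genes, nucleotide_seq="".join(seq_parts))
        )
    genome = GenomeRecord(genome_id=genome_id, contigs=contigs)
    return SimulatedGenome(
        genome=genome,
        proteins={g: proteins[g] for g, _ in order},
        gene_dna={g: gene_dna[g] for g, _ in order},
    )


def _true_segments(
    pairs: list[tuple[str, str]],
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
) -> list[list[tuple[str, str]]]:
    """Maximal strictly-adjacent collinear runs of the true orthology.

    Independent of the detector: a plain scan over the ordinal
    permutation, requiring consecutive positions (gap 0) on both
    genomes and a consistent direction.
    """
    pos_a = genome_a.gene_positions()
    pos_b = genome_b.gene_positions()
    anchors = sorted(
        ((pos_a[a], pos_b[b], (a, b)) for a, b in pairs),
        key=lambda t: (t[0][0], t[0][1]),
    )
    segments: list[list[tuple[str, str]]] = []
    current: list = []
    direction = 0
    prev = None
    for (ca, oa), (cb, ob), pair in anchors:
        if current:
            (pca, poa), (pcb, pob) = prev
            step_ok = ca == pca and cb == pcb and oa - poa == 1
            db = ob - pob
            if step_ok and abs(db) == 1 and (direction == 0 or db == direction):
                current.append(pair)
                direction = db
            else:
                segments.append(current)
                current, direction = [pair], 0
        else:
            current = [pair]
            direction = 0
        prev = ((ca, oa), (cb, ob))
    if current:
        segments.append(current)
    return segments


# ------------------------------------------------------------------ evolve


def evolve_pair(params: EvolverParams) -> SimulatedPair:
    """Evolve one genome pair from a common ancestor with full truth.

    Lineage A receives the optional island insertion; lineage B
    receives the inversions and translocations (only relative
    rearrangement is observable downstream).
    """
    rng = np.random.default_rng(params.seed)
    lengths = _gene_lengths(rng, params)
    ancestor = [_random_protein(rng, L) for L in lengths]
    s_a, s_b = params.subs

    prots_a = [_mutate(rng, p, s_a) for p in ancestor]
    prots_b = [_mutate(rng, p, s_b) for p in ancestor]

    keep_a = rng.random(params.n_genes) >= params.loss_prob
    keep_b = rng.random(params.n_genes) >= params.loss_prob

    proteins_a: dict[str, str] = {}
    proteins_b: dict[str, str] = {}
    order_a: list[tuple[int, bool]] = []
    order_b: list[tuple[int, bool]] = []
    ids_a: dict[int, str] = {}
    ids_b: dict[int, str] = {}
    for k in range(params.n_genes):
        if keep_a[k]:
            gid = f"A_g{k:04d}"
            ids_a[k] = gid
            proteins_a[gid] = _to_str(prots_a[k])
            order_a.append((k, False))
        if keep_b[k]:
            gid = f"B_g{k:04d}"
            ids_b[k] = gid
            proteins_b[gid] = _to_str(prots_b[k])
            order_b.append((k, False))

    # gene gain: novel random proteins at random positions, per lineage
    gain_ids_a, gain_ids_b = [], []
    for lineage, order, proteins, gain_ids, tag in (
        ("A", order_a, proteins_a, gain_ids_a, "n"),
        ("B", order_b, proteins_b, gain_ids_b, "n"),
    ):
        for j in range(params.gain_count):
            L = int(_gene_lengths(rng, params)[0]) if params.n_genes else params.min_protein_len
            gid = f"{lineage}_{tag}{j:03d}"
            proteins[gid] = _to_str(_random_protein(rng, L))
            pos = int(rng.integers(0, len(order) + 1))
            order.insert(pos, (gid, False))
            gain_ids.append(gid)

    # switch ancestral indices to gene ids in the A/B orders
    order_a = [(ids_a[k], f) if isinstance(k, int) else (k, f) for k, f in order_a]
    order_b = [(ids_b[k], f) if isinstance(k, int) else (k, f) for k, f in order_b]

    # rearrange lineage B
    for _ in range(params.n_inversions):
        order_b, _span = _invert(order_b, rng)
    for _ in range(params.n_translocations):
        order_b = _translocate(order_b, rng)

    # reverse-translate everything at background GC
    weights_bg = _codon_weights(params.gc_content)
    gene_dna_a = {g: reverse_translate(rng, p, params.gc_content, weights_bg) for g, p in proteins_a.items()}
    gene_dna_b = {g: reverse_translate(rng, p, params.gc_content, weights_bg) for g, p in proteins_b.items()}

    # island insertion into lineage A, with GC shifted in units of the
    # realized per-gene background sd
    island_gene_ids: list[str] = []
    island_span = None
    if params.island_spec is not None:
        spec = params.island_spec
        bg = np.array(
            [
                (seq.count("G") + seq.count("C")) / len(seq)
                for seq in gene_dna_a.values()
            ]
        )
        target = float(np.clip(bg.mean() + spec.gc_shift_sd * bg.std(), 0.05, 0.95))
        # keep the island inside the first contig chunk so it never
        # spans a contig boundary
        first_chunk_len = len(np.array_split(np.arange(len(order_a) + spec.n_genes), params.n_contigs)[0])
        hi = max(2, min(len(order_a) - 1, first_chunk_len - spec.n_genes))
        pos = int(rng.integers(1, hi)) if hi > 1 else 1
        island_prots = []
        for j in range(spec.n_genes):
            L = int(_gene_lengths(rng, params)[0])
            island_prots.append(_to_str(_random_protein(rng, L)))
        weights_isl = _codon_weights(target, _aa_composition(island_prots))
        for j, prot in enumerate(island_prots):
            gid = f"A_i{j:03d}"
            proteins_a[gid] = prot
            gene_dna_a[gid] = reverse_translate(rng, prot, target, weights_isl)
            order_a.insert(pos + j, (gid, False))
            island_gene_ids.append(gid)
        island_span = (pos, pos + spec.n_genes - 1)

    sim_a = _assemble_genome("A", order_a, proteins_a, gene_dna_a, params.n_contigs, rng, params.gc_content)
    sim_b = _assemble_genome("B", order_b, proteins_b, gene_dna_b, params.n_contigs, rng, params.gc_content)

    pairs = []
    realized = {}
    for k in range(params.n_genes):
        if keep_a[k] and keep_b[k]:
            ga, gb = ids_a[k], ids_b[k]
            pairs.append((ga, gb))
            ident = 100.0 * float(np.mean(prots_a[k] == prots_b[k]))
            realized[(ga, gb)] = ident

    island_truth = None
    if island_span is not None:
        pos_a = sim_a.genome.gene_positions()
        c0, o0 = pos_a[island_gene_ids[0]]
        c1, o1 = pos_a[island_gene_ids[-1]]
        island_truth = (c0, o0, o1)

    truth = SimTruth(
        ortholog_pairs=pairs,
        realized_identity=realized,
        true_segments=_true_segments(pairs, sim_a.genome, sim_b.genome),
        island=island_truth,
        island_gene_ids=island_gene_ids,
        params=params,
    )
    return SimulatedPair(a=sim_a, b=sim_b, truth=truth)


def evolve_panel(
    base_params: EvolverParams,
    sub_proportions: Sequence[float],
) -> list[SimulatedGenome]:
    """Evolve several lineages from one ancestor at staggered divergences.

    Lineage i substitutes a fraction ``sub_proportions[i]`` of sites;
    genome ids are P0, P1, ... and gene k of lineage i is ``Pi_g{k}``,
    so the true orthology is the shared ancestral index.
    """
    rng = np.random.default_rng(base_params.seed)
    lengths = _gene_lengths(rng, base_params)
    ancestor = [_random_protein(rng, L) for L in lengths]
    weights_bg = _codon_weights(base_params.gc_content)
    out = []
    for i, s in enumerate(sub_proportions):
        gid = f"P{i}"
        proteins = {
            f"{gid}_g{k:04d}": _to_str(_mutate(rng, p, s)) for k, p in enumerate(ancestor)
        }
        gene_dna = {
            g: reverse_translate(rng, p, base_params.gc_content, weights_bg)
            for g, p in proteins.items()
        }
        order = [(g, False) for g in proteins]
        out.append(
            _assemble_genome(gid, order, proteins, gene_dna, base_params.n_contigs, rng, base_params.gc_content)
        )
    return out


@dataclass
class SimulatedFamily:
    """A query lineage (with optional island) plus panel lineages."""

    query: SimulatedGenome
    panel: list[SimulatedGenome]
    truth: SimTruth


def evolve_family(
    params: EvolverParams,
    n_panel: int = 2,
) -> SimulatedFamily:
    """Evolve a query lineage and ``n_panel`` panel lineages from one
    ancestor; the optional island is inserted into the query only.

    Truth records the query's island location and, per panel lineage,
    the surviving ancestral orthology (query gene -> panel gene).
    """
    rng = np.random.default_rng(params.seed)
    lengths = _gene_lengths(rng, params)
    ancestor = [_random_protein(rng, L) for L in lengths]
    s_q = params.subs[0]
    weights_bg = _codon_weights(params.gc_content)

    def make_lineage(gid: str, s: float) -> tuple[SimulatedGenome, dict[int, str]]:
        keep = rng.random(params.n_genes) >= params.loss_prob
        proteins: dict[str, str] = {}
        ids: dict[int, str] = {}
        order: list[tuple[str, bool]] = []
        for k in range(params.n_genes):
            if keep[k]:
                gene_id = f"{gid}_g{k:04d}"
                ids[k] = gene_id
                proteins[gene_id] = _to_str(_mutate(rng, ancestor[k], s))
                order.append((gene_id, False))
        gene_dna = {
            g: reverse_translate(rng, p, params.gc_content, weights_bg)
            for g, p in proteins.items()
        }
        return (
            _assemble_genome(gid, order, proteins, gene_dna, params.n_contigs, rng, params.gc_content),
            ids,
        )

    # query lineage, then island insertion
    keep_q = rng.random(params.n_genes) >= params.loss_prob
    proteins_q: dict[str, str] = {}
    ids_q: dict[int, str] = {}
    order_q: list[tuple[str, bool]] = []
    for k in range(params.n_genes):
        if keep_q[k]:
            gene_id = f"Q_g{k:04d}"
            ids_q[k] = gene_id
            proteins_q[gene_id] = _to_str(_mutate(rng, ancestor[k], s_q))
            order_q.append((gene_id, False))
    gene_dna_q = {
        g: reverse_translate(rng, p, params.gc_content, weights_bg)
        for g, p in proteins_q.items()
    }
    island_gene_ids: list[str] = []
    island_span = None
    if params.island_spec is not None:
        spec = params.island_spec
        bg = np.array(
            [(s.count("G") + s.count("C")) / len(s) for s in gene_dna_q.values()]
        )
        target = float(np.clip(bg.mean() + spec.gc_shift_sd * bg.std(), 0.05, 0.95))
        hi = max(2, len(order_q) - 1)
        pos = int(rng.integers(1, hi))
        island_prots = []
        for j in range(spec.n_genes):
            L = int(_gene_lengths(rng, params)[0])
            island_prots.append(_to_str(_random_protein(rng, L)))
        weights_isl = _codon_weights(target, _aa_composition(island_prots))
        for j, prot in enumerate(island_prots):
            gid = f"Q_i{j:03d}"
            proteins_q[gid] = prot
            gene_dna_q[gid] = reverse_translate(rng, prot, target, weights_isl)
            order_q.insert(pos + j, (gid, False))
            island_gene_ids.append(gid)
        island_span = (pos, pos + spec.n_genes - 1)
    query = _assemble_genome("Q", order_q, proteins_q, gene_dna_q, params.n_contigs, rng, params.gc_content)

    panel: list[SimulatedGenome] = []
    pairs: list[tuple[str, str]] = []
    realized: dict[tuple[str, str], float] = {}
    for i in range(n_panel):
        sim, ids_p = make_lineage(f"P{i}", params.subs[1])
        panel.append(sim)
        for k, qid in ids_q.items():
            if k in ids_p:
                pairs.append((qid, ids_p[k]))

    island_truth = None
    if island_span is not None:
        pos_q = query.genome.gene_positions()
        c0, o0 = pos_q[island_gene_ids[0]]
        _c1, o1 = pos_q[island_gene_ids[-1]]
        island_truth = (c0, o0, o1)

    truth = SimTruth(
        ortholog_pairs=pairs,
        realized_identity=realized,
        true_segments=[],
        island=island_truth,
        island_gene_ids=island_gene_ids,
        params=params,
    )
    return SimulatedFamily(query=query, panel=panel, truth=truth)


def expected_pairwise_identity(s_a: float, s_b: float = None) -> float:
    """Analytic expected percent identity for two lineages at per-site
    substitution proportions s_a and s_b: 100 * (1-s_a)(1-s_b)."""
    if s_b is None:
        s_b = s_a
    return 100.0 * (1.0 - s_a) * (1.0 - s_b)


def make_marker_test_set(
    proteins: Mapping[str, str],
    fraction_deleted: float,
    seed: int,
    n_markers: Optional[int] = None,
) -> tuple[dict[str, str], dict[str, str], float]:
    """Build a synthetic marker set with known expected completeness.

    Samples marker genes from the proteome, deletes the stated fraction
    of them from a genome copy, and returns (marker_refs,
    depleted_proteins, expected_completeness_pct).
    """
    if not 0.0 <= fraction_deleted <= 1.0:
        raise ValueError("fraction_deleted must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = sorted(proteins)
    if n_markers is None:
        n_markers = min(50, len(gene_ids))
    marker_genes = list(rng.choice(gene_ids, size=n_markers, replace=False))
    marker_refs = {f"marker_{g}": proteins[g] for g in marker_genes}
    n_del = round(fraction_deleted * n_markers)
    deleted = set(rng.choice(marker_genes, size=n_del, replace=False))
    depleted = {g: s for g, s in proteins.items() if g not in deleted}
    expected = 100.0 * (n_markers - n_del) / n_markers
    return marker_refs, depleted, expected
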