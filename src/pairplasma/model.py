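"""Core domain types shared by every pipeline stage.

A genome is an ordered list of contigs, each an ordered list of genes;
all pairwise statistics (AAI, ortholog fraction, synteny) are defined on
pairs of these records. Coordinates are 1-based inclusive (the dominant
annotation convention); gene ordinals are 0-based and consecutive within
each contig.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")
STRANDS = ("+", "-")


@dataclass
class GeneRecord:
    """One called gene: position on its contig plus optional sequences."""

    gene_id: str
    contig_id: str
    ordinal: int
    start: int
    end: int
    strand: str
    protein_seq: Optional[str] = None
    annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")


@dataclass
class ContigRecord:
    contig_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    nucleotide_seq: Optional[str] = None

    def __post_init__(self) -> None:
        for i, g in enumerate(self.genes):
            if g.ordinal != i:
                raise ValueError(
                    f"contig {self.contig_id}: gene {g.gene_id} has ordinal "
                    f"{g.ordinal}, expected {i}"
                )


@dataclass
class GenomeRecord:
    genome_id: str
    contigs: list[ContigRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        seen_contigs: set[str] = set()
        seen_genes: set[str] = set()
        for c in self.contigs:
            if c.contig_id in seen_contigs:
                raise ValueError(f"duplicate contig id {c.contig_id}")
            seen_contigs.add(c.contig_id)
            for g in c.genes:
                if g.gene_id in seen_genes:
                    raise ValueError(f"duplicate gene id {g.gene_id}")
                seen_genes.add(g.gene_id)

    def genes(self) -> Iterator[GeneRecord]:
        for c in self.contigs:
            yield from c.genes

    @property
    def n_genes(self) -> int:
        return sum(len(c.genes) for c in self.contigs)

    def gene_positions(self) -> dict[str, tuple[str, int]]:
        """gene_id -> (contig_id, ordinal) lookup."""
        return {g.gene_id: (g.contig_id, g.ordinal) for g in self.genes()}

    def proteins(self) -> dict[str, str]:
        return {
            g.gene_id: g.protein_seq for g in self.genes() if g.protein_seq
        }


@dataclass
class HitRecord:
    """One directed protein-vs-protein similarity hit (BLAST-tabular-like)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bit_score: float
    q_cov: float
    s_cov: float
    mismatches: int = 0
    gap_opens: int = 0
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} out of [0,100]")
        if not (0.0 <= self.q_cov <= 1.0 and 0.0 <= self.s_cov <= 1.0):
            raise ValueError("coverage out of [0,1]")
        if self.bit_score < 0:
            raise ValueError("bit_score must be >= 0")


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit gene pairing; identity is from the a->b hit."""

    gene_a: str
    gene_b: str
    pct_identity: float
    bit_score: float
    aln_length: int = 0


@dataclass
class OrthologMap:
    genome_a_id: str
    genome_b_id: str
    pairs: list[OrthologPair]
    n_genes_a: int
    n_genes_b: int

    def __post_init__(self) -> None:
        a_seen: set[str] = set()
        b_seen: set[str] = set()
        for p in self.pairs:
            if p.gene_a in a_seen or p.gene_b in b_seen:
                raise ValueError(
                    f"gene appears in more than one ortholog pair: "
                    f"({p.gene_a}, {p.gene_b})"
                )
            a_seen.add(p.gene_a)
            b_seen.add(p.gene_b)
        if len(self.pairs) > min(self.n_genes_a, self.n_genes_b):
            raise ValueError("more ortholog pairs than genes in a genome")

    def a_to_b(self) -> dict[str, str]:
        return {p.gene_a: p.gene_b for p in self.pairs}


@dataclass
class SyntenyBlock:
    """A maximal collinear run of ortholog pairs in both gene orders."""

    pairs: list[OrthologPair]
    contig_a: str
    contig_b: str
    orientation: str  # "same" | "inverted"

    @property
    def length(self) -> int:
        return len(self.pairs)


@dataclass
class RelatednessSummary:
    """Whole-genome relatedness statistics for one genome pair."""

    genome_a_id: str
    genome_b_id: str
    aai: float
    n_orthologs: int
    ortholog_fraction: float
    n_syntenous: int
    synteny_fraction: float
    mean_block_length: float  # nan when no blocks


@dataclass
class CompletenessReport:
    genome_id: str
    n_markers: int
    n_found: int
    per_marker: "object"  # pandas.DataFrame: marker_id, found, best_gene, ...
    note: str = (
        "A completeness estimate of 100% is not exact: draft genomes may "
        "still contain gaps between contigs."
    )

    @property
    def completeness_pct(self) -> float:
        return 100.0 * self.n_found / self.n_markers


@dataclass
class IslandCall:
    """A candidate lineage-specific gene cluster (putative HGT island)."""

    genome_id: str
    contig_id: str
    start_ordinal: int
    end_ordinal: int
    gc_island: Optional[float] = None
    gc_genome_mean: Optional[float] = None
    gc_genome_sd: Optional[float] = None
    gc_z: Optional[float] = None
    gc_skew: Optional[float] = None

    @property
    def n_genes(self) -> int:
        return self.end_ordinal - self.start_ordinal + 1


@dataclass
class AnnotationEvidence:
    """One similarity-search evidence row for a gene's annotation."""

    gene_id: str
    source: str  # "domain_db" (TIGR/Pfam style) | "nr"
    evalue: float
    coverage: float  # fraction of the protein matched, 0-1
    pct_identity: Optional[float] = None  # nr hits only
    hit_description: str = ""
    general_function: bool = False  # domain conveys only general information

    def __post_init__(self) -> None:
        if self.source not in ("domain_db", "nr"):
            raise ValueError(f"unknown evidence source {self.source!r}")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage out of [0,1]")


@dataclass(frozen=True)
class TierCall:
    gene_id: str
    tier: str  # "specific" | "putative" | "probable" | "hypothetical"


@dataclass(frozen=True)
class MotifDef:
    motif_id: str
    pattern: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if len(self.pattern) < 4:
            raise ValueError("motif pattern must be at least 4 residues")
        if self.max_mismatch >= len(self.pattern):
            raise ValueError("max_mismatch must be < pattern length")
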