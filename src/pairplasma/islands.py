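"""Lineage-specific gene-cluster (putative HGT island) detection.

A gene is foreign-like when it has orthologs in at most
``max_panel_hits`` genomes of a reference panel (default 0: virtually
no orthologs anywhere). Islands are maximal runs of at least
``min_run`` consecutive foreign-like genes on one contig. Each call can
be annotated with nucleotide-composition deviation: the island's GC
content as a z-score against the genome's per-gene GC distribution,
plus the strand GC skew (G-C)/(G+C). A transferred block from a donor
with similar GC content leaves no compositional anomaly, so a small
|z| does not argue against transfer.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .model import GenomeRecord, IslandCall, OrthologMap


def foreign_gene_flags(
    query_genome: GenomeRecord,
    orthomaps_to_panel: Sequence[OrthologMap],
    max_panel_hits: int = 0,
) -> dict[str, bool]:
    """gene_id -> True when the gene has orthologs in <= max_panel_hits
    panel genomes."""
    if not orthomaps_to_panel:
        raise ValueError("reference panel must contain at least one ortholog map")
    qid = query_genome.genome_id
    counts = {g.gene_id: 0 for g in query_genome.genes()}
    for om in orthomaps_to_panel:
        if om.genome_a_id == qid:
            matched = {p.gene_a for p in om.pairs}
        elif om.genome_b_id == qid:
            matched = {p.gene_b for p in om.pairs}
        else:
            raise ValueError(
                f"ortholog map {om.genome_a_id}~{om.genome_b_id} does not "
                f"involve query genome {qid}"
            )
        for g in matched:
            if g in counts:
                counts[g] += 1
    return {g: c <= max_panel_hits for g, c in counts.items()}


def find_islands(
    query_genome: GenomeRecord,
    orthomaps_to_panel: Sequence[OrthologMap],
    min_run: int = 5,
    max_panel_hits: int = 0,
) -> list[IslandCall]:
    """Maximal runs of >= min_run consecutive foreign-like genes."""
    foreign = foreign_gene_flags(query_genome, orthomaps_to_panel, max_panel_hits)
    calls: list[IslandCall] = []
    for contig in query_genome.contigs:
        flags = [foreign[g.gene_id] for g in contig.genes]
        i = 0
        n = len(flags)
        while i < n:
            if flags[i]:
                j = i
                while j + 1 < n and flags[j + 1]:
                    j += 1
                if j - i + 1 >= min_run:
                    calls.append(
                        IslandCall(
                            genome_id=query_genome.genome_id,
                            contig_id=contig.contig_id,
                            start_ordinal=i,
                            end_ordinal=j,
                        )
                    )
                i = j + 1
            else:
                i += 1
    return calls


def gc_content(seq: str) -> float:
    if not seq:
        raise ValueError("zero-length sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def gc_skew(seq: str) -> float:
    s = seq.upper()
    g, c = s.count("G"), s.count("C")
    return (g - c) / (g + c) if g + c else 0.0


def composition_deviation(
    island_genes_dna: Sequence[str],
    genome_genes_dna: Sequence[str],
) -> dict[str, float]:
    """Island GC content as a z-score against the per-gene background.

    The background is the distribution of per-gene GC over all genome
    genes (population standard deviation); the island value is the GC
    of its concatenated genes. Also reports strand GC skew.
    """
    if not island_genes_dna or not genome_genes_dna:
        raise ValueError("island and genome gene sequences must be non-empty")
    island_seq = "".join(island_genes_dna)
    gc_isl = gc_content(island_seq)
    background = np.array([gc_content(s) for s in genome_genes_dna], dtype=float)
    mean = float(background.mean())
    sd = float(background.std())
    z = (gc_isl - mean) / sd if sd > 0 else float("inf") * np.sign(gc_isl - mean)
    return {
        "gc_island": gc_isl,
        "gc_genome_mean": mean,
        "gc_genome_sd": sd,
        "gc_z": float(z),
        "gc_skew": gc_skew(island_seq),
    }


def annotate_composition(
    islands: Sequence[IslandCall],
    query_genome: GenomeRecord,
    gene_dna: Mapping[str, str],
) -> list[IslandCall]:
    """Fill the composition fields of island calls in place.

    The background for each call is the per-gene GC distribution of the
    genome *excluding* that island's own genes, so a large island
    cannot dilute its own anomaly signal.
    """
    by_contig = {c.contig_id: c for c in query_genome.contigs}
    for isl in islands:
        contig = by_contig[isl.contig_id]
        island_genes = {
            g.gene_id for g in contig.genes[isl.start_ordinal : isl.end_ordinal + 1]
        }
        island_seqs = [
            gene_dna[g.gene_id]
            for g in contig.genes[isl.start_ordinal : isl.end_ordinal + 1]
        ]
        background = [
            gene_dna[g.gene_id]
            for g in query_genome.genes()
            if g.gene_id in gene_dna and g.gene_id not in island_genes
        ]
        stats = composition_deviation(island_seqs, background)
        isl.gc_island = stats["gc_island"]
        isl.gc_genome_mean = stats["gc_genome_mean"]
        isl.gc_genome_sd = stats["gc_genome_sd"]
        isl.gc_z = stats["gc_z"]
        isl.gc_skew = stats["gc_skew"]
    return list(islands)
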