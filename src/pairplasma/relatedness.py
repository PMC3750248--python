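"""Whole-genome relatedness statistics.

AAI (average amino acid identity) is the mean percent identity over
reciprocal-best-hit ortholog pairs; the ortholog fraction normalizes the
pair count by the mean gene count of the two genomes; nucleotide
identity (e.g. for 16S rRNA genes) comes from a global alignment with
terminal overhangs excluded from the denominator.
"""
from __future__ import annotations

import math
from typing import Mapping, Optional

import pandas as pd
from Bio import Align

from .model import OrthologMap, RelatednessSummary


class NoOrthologsError(ValueError):
    """Raised when a statistic is requested for a pair with no orthologs."""


def compute_aai(orthomap: OrthologMap, weighted: bool = False) -> float:
    """Average amino acid identity over ortholog pairs, in percent.

    Unweighted arithmetic mean by default; ``weighted=True`` weights
    each pair by its alignment length.
    """
    if not orthomap.pairs:
        raise NoOrthologsError(
            f"no orthologs between {orthomap.genome_a_id} and "
            f"{orthomap.genome_b_id}; AAI is undefined"
        )
    if weighted:
        total = sum(p.aln_length for p in orthomap.pairs)
        if total == 0:
            raise ValueError("weighted AAI requires alignment lengths")
        return sum(p.pct_identity * p.aln_length for p in orthomap.pairs) / total
    return sum(p.pct_identity for p in orthomap.pairs) / len(orthomap.pairs)


def compute_ortholog_fraction(orthomap: OrthologMap) -> float:
    """Ortholog count divided by the average gene count of the pair."""
    if orthomap.n_genes_a <= 0 or orthomap.n_genes_b <= 0:
        raise ValueError("both genomes must have at least one gene")
    return len(orthomap.pairs) / ((orthomap.n_genes_a + orthomap.n_genes_b) / 2.0)


def make_dna_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
) -> Align.PairwiseAligner:
    """Global DNA aligner; gap of length L costs gap_open + L*gap_extend."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def nucleotide_identity(
    seq_a: str,
    seq_b: str,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> float:
    """Percent identity of a global alignment, excluding terminal overhangs.

    Columns inside leading/trailing gap runs (where one sequence has not
    started or has already ended) are dropped from the denominator;
    internal gap columns count as differences. Gene-boundary calls
    differ between draft genomes, so internal divergence is the signal.
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    if aligner is None:
        aligner = make_dna_aligner()
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    lo = 0
    hi = len(row_a)
    while lo < hi and (row_a[lo] == "-" or row_b[lo] == "-"):
        lo += 1
    while hi > lo and (row_a[hi - 1] == "-" or row_b[hi - 1] == "-"):
        hi -= 1
    if hi <= lo:
        return 0.0
    matches = sum(1 for i in range(lo, hi) if row_a[i] == row_b[i] and row_a[i] != "-")
    return 100.0 * matches / (hi - lo)


def pairwise_identity_matrix(
    seqs: Mapping[str, str],
    exclude_pairs: Optional[set[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Symmetric percent-identity matrix over a set of marker genes
    (e.g. 16S rRNA); the diagonal is 100."""
    names = list(seqs)
    mat = pd.DataFrame(100.0, index=names, columns=names, dtype=float)
    aligner = make_dna_aligner()
    excluded = {tuple(sorted(p)) for p in (exclude_pairs or set())}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if tuple(sorted((a, b))) in excluded:
                mat.loc[a, b] = mat.loc[b, a] = math.nan
                continue
            pid = nucleotide_identity(seqs[a], seqs[b], aligner)
            mat.loc[a, b] = mat.loc[b, a] = pid
    return mat


def summarize_relatedness(orthomap: OrthologMap, blocks) -> RelatednessSummary:
    """Bundle the pairwise statistics reported per genome pair."""
    from .synteny import synteny_metrics

    n_synt = sum(b.length for b in blocks)
    frac, mean_len = synteny_metrics(blocks, orthomap)
    return RelatednessSummary(
        genome_a_id=orthomap.genome_a_id,
        genome_b_id=orthomap.genome_b_id,
        aai=compute_aai(orthomap),
        n_orthologs=len(orthomap.pairs),
        ortholog_fraction=compute_ortholog_fraction(orthomap),
        n_syntenous=n_synt,
        synteny_fraction=frac,
        mean_block_length=mean_len,
    )
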