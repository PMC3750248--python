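"""Directed protein similarity hits and reciprocal-best-hit orthology.

The internal aligner is exact Smith-Waterman (Biopython's C
implementation) with BLOSUM62 and affine gaps costing
``gap_open + L * gap_extend`` for a gap of length L (the classic
"existence 11, extension 1" convention). E-values follow the
Karlin-Altschul form E = m * n * 2^-S' with the standard gapped
BLOSUM62(11,1) parameters lambda = 0.267, K = 0.041, where m and n are
the total residue counts of the two sets. This is meant for desk-scale
inputs; larger comparisons should be ingested as precomputed hit tables.
"""
from __future__ import annotations

import math
import warnings
from typing import Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .model import HitRecord, OrthologMap, OrthologPair

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap cost 11 + L.
KA_LAMBDA = 0.267
KA_K = 0.041

MAX_INTERNAL_PROTEINS = 5000


class NoProteinsError(ValueError):
    pass


def make_protein_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0
) -> Align.PairwiseAligner:
    """Local protein aligner; gap of length L costs gap_open + L*gap_extend."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def bit_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def evalue(bits: float, m: int, n: int) -> float:
    # 2^-bits underflows for strong hits; that is a clean 0.0
    return m * n * math.pow(2.0, -min(bits, 4000.0))


def _alignment_stats(aln) -> tuple[int, int, int, tuple[int, int], tuple[int, int]]:
    """(identities, columns, aln_length, target_span, query_span) of a local alignment."""
    c = aln.counts()
    columns = c.identities + c.mismatches + c.internal_gaps
    t_blocks, q_blocks = aln.aligned
    t_span = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    return c.identities, columns, columns, t_span, q_span


def align_pair(
    aligner: Align.PairwiseAligner,
    query_id: str,
    query_seq: str,
    subject_id: str,
    subject_seq: str,
    m: int,
    n: int,
) -> HitRecord:
    """Full local alignment of one ordered pair, as a HitRecord."""
    aln = aligner.align(query_seq, subject_seq)[0]
    identities, columns, aln_len, q_span, s_span = _alignment_stats(aln)
    bits = bit_score(aln.score)
    return HitRecord(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=100.0 * identities / columns if columns else 0.0,
        aln_length=aln_len,
        evalue=evalue(bits, m, n),
        bit_score=bits,
        q_cov=(q_span[1] - q_span[0]) / len(query_seq),
        s_cov=(s_span[1] - s_span[0]) / len(subject_seq),
        mismatches=columns - identities,
        q_start=q_span[0] + 1,
        q_end=q_span[1],
        s_start=s_span[0] + 1,
        s_end=s_span[1],
    )


def align_all_vs_all(
    proteins_a: Mapping[str, str],
    proteins_b: Mapping[str, str],
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    evalue_max: float = 1e-5,
) -> list[HitRecord]:
    """All ordered a->b local alignments with E-value <= evalue_max.

    A score-only pass screens every pair; the full alignment (identity,
    coverage) is only computed for pairs passing the E-value filter.
    """
    if not proteins_a or not proteins_b:
        raise NoProteinsError("both protein sets must be non-empty")
    if len(proteins_a) + len(proteins_b) > MAX_INTERNAL_PROTEINS:
        raise ValueError(
            f"internal aligner is limited to {MAX_INTERNAL_PROTEINS} proteins "
            "total; supply precomputed hit tables for larger inputs"
        )
    a_items = [(k, v) for k, v in proteins_a.items()]
    b_items = [(k, v) for k, v in proteins_b.items()]
    for name, seq in a_items + b_items:
        if len(seq) == 0:
            warnings.warn(f"skipping zero-length sequence {name!r}")
    a_items = [(k, v) for k, v in a_items if v]
    b_items = [(k, v) for k, v in b_items if v]
    m = sum(len(v) for _, v in a_items)
    n = sum(len(v) for _, v in b_items)
    aligner = make_protein_aligner(matrix, gap_open, gap_extend)
    hits: list[HitRecord] = []
    for qid, qseq in a_items:
        for sid, sseq in b_items:
            bits = bit_score(aligner.score(qseq, sseq))
            if evalue(bits, m, n) > evalue_max:
                continue
            hits.append(align_pair(aligner, qid, qseq, sid, sseq, m, n))
    return hits


def mirror_hits(hits: Sequence[HitRecord]) -> list[HitRecord]:
    """b->a view of a->b hits (exact local alignment scores are symmetric)."""
    return [
        HitRecord(
            query_id=h.subject_id,
            subject_id=h.query_id,
            pct_identity=h.pct_identity,
            aln_length=h.aln_length,
            evalue=h.evalue,
            bit_score=h.bit_score,
            q_cov=h.s_cov,
            s_cov=h.q_cov,
            mismatches=h.mismatches,
            gap_opens=h.gap_opens,
            q_start=h.s_start,
            q_end=h.s_end,
            s_start=h.q_start,
            s_end=h.q_end,
        )
        for h in hits
    ]


def _qualifies(h: HitRecord, evalue_max: float, cov_min: float, pident_min: float) -> bool:
    # coverage threshold applies to the shorter sequence, whose coverage
    # is the larger of the two fractions
    return (
        h.evalue <= evalue_max
        and max(h.q_cov, h.s_cov) >= cov_min
        and h.pct_identity >= pident_min
    )


def best_hits(
    hits: Sequence[HitRecord],
    evalue_max: float = 1e-5,
    cov_min: float = 0.7,
    pident_min: float = 0.0,
) -> dict[str, HitRecord]:
    """Best qualifying hit per query: max bit score, ties by identity,
    then lexicographically smallest subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        if not _qualifies(h, evalue_max, cov_min, pident_min):
            continue
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key = (h.bit_score, h.pct_identity)
        cur_key = (cur.bit_score, cur.pct_identity)
        if key > cur_key or (key == cur_key and h.subject_id < cur.subject_id):
            best[h.query_id] = h
    return best


def call_rbh(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
    evalue_max: float = 1e-5,
    cov_min: float = 0.7,
    pident_min: float = 0.0,
    genome_a_id: str = "A",
    genome_b_id: str = "B",
    n_genes_a: Optional[int] = None,
    n_genes_b: Optional[int] = None,
) -> OrthologMap:
    """Reciprocal-best-hit ortholog calling between two proteomes.

    (x, y) is a pair iff y is x's best qualifying hit among a->b hits
    and x is y's best qualifying hit among b->a hits. Gene counts
    default to the number of distinct ids seen in the hit lists; pass
    the true proteome sizes when computing ortholog fractions.
    """
    best_ab = best_hits(hits_ab, evalue_max, cov_min, pident_min)
    best_ba = best_hits(hits_ba, evalue_max, cov_min, pident_min)
    pairs = []
    for x, hit in sorted(best_ab.items()):
        y = hit.subject_id
        back = best_ba.get(y)
        if back is not None and back.subject_id == x:
            pairs.append(
                OrthologPair(
                    gene_a=x,
                    gene_b=y,
                    pct_identity=hit.pct_identity,
                    bit_score=hit.bit_score,
                    aln_length=hit.aln_length,
                )
            )
    if n_genes_a is None:
        n_genes_a = len({h.query_id for h in hits_ab} | {h.subject_id for h in hits_ba})
    if n_genes_b is None:
        n_genes_b = len({h.subject_id for h in hits_ab} | {h.query_id for h in hits_ba})
    return OrthologMap(
        genome_a_id=genome_a_id,
        genome_b_id=genome_b_id,
        pairs=pairs,
        n_genes_a=n_genes_a,
        n_genes_b=n_genes_b,
    )


def orthologs_between(
    proteins_a: Mapping[str, str],
    proteins_b: Mapping[str, str],
    genome_a_id: str = "A",
    genome_b_id: str = "B",
    evalue_max: float = 1e-5,
    cov_min: float = 0.7,
    pident_min: float = 0.0,
    **align_kwargs,
) -> OrthologMap:
    """Convenience: align a vs b once (scores are symmetric), mirror the
    hits for the reverse direction, and call RBH orthologs."""
    hits_ab = align_all_vs_all(proteins_a, proteins_b, evalue_max=evalue_max, **align_kwargs)
    return call_rbh(
        hits_ab,
        mirror_hits(hits_ab),
        evalue_max=evalue_max,
        cov_min=cov_min,
        pident_min=pident_min,
        genome_a_id=genome_a_id,
        genome_b_id=genome_b_id,
        n_genes_a=len(proteins_a),
        n_genes_b=len(proteins_b),
    )
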