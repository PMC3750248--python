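"""Readers and writers for the external formats the pipeline touches.

FASTA goes through Bio.SeqIO; gene tables are either GFF3 (CDS features)
or a simple 6-column TSV (genome, contig, gene_id, start, end, strand);
hit tables use the 12-column BLAST-tabular dialect. All writers emit
plain TSV with header rows except FASTA and the hit table (which is
headerless by convention).
"""
from __future__ import annotations

import os
from typing import Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    DNA_ALPHABET,
    PROTEIN_ALPHABET,
    ContigRecord,
    GeneRecord,
    GenomeRecord,
    HitRecord,
)

GENE_TABLE_COLUMNS = ["genome", "contig", "gene_id", "start", "end", "strand"]
HIT_TABLE_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fasta(path: str | os.PathLike, alphabet: str = "protein") -> dict[str, str]:
    """Read a multi-record FASTA into an id -> sequence mapping.

    Sequences are uppercased; a single trailing ``*`` (stop) is stripped
    from protein records. Duplicate ids and residues outside the
    alphabet (20 canonical amino acids + X, or ACGTN) are hard errors.
    """
    if alphabet not in ("protein", "dna"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else DNA_ALPHABET
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if alphabet == "protein" and seq.endswith("*"):
            seq = seq[:-1]
        for i, ch in enumerate(seq):
            if ch not in allowed:
                raise ValueError(
                    f"illegal {alphabet} residue {ch!r} at position {i + 1} "
                    f"of record {rec.id!r}"
                )
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def _build_genome(rows: list[dict], genome_id: str) -> GenomeRecord:
    """Sort rows into contigs, assign ordinals 0..n-1 per contig."""
    by_contig: dict[str, list[dict]] = {}
    for r in rows:
        by_contig.setdefault(r["contig"], []).append(r)
    contigs = []
    for contig_id in by_contig:  # first-appearance order
        rows_c = sorted(by_contig[contig_id], key=lambda r: (r["start"], r["gene_id"]))
        genes = [
            GeneRecord(
                gene_id=r["gene_id"],
                contig_id=contig_id,
                ordinal=i,
                start=int(r["start"]),
                end=int(r["end"]),
                strand=r["strand"],
                protein_seq=r.get("protein_seq"),
            )
            for i, r in enumerate(rows_c)
        ]
        contigs.append(ContigRecord(contig_id=contig_id, genes=genes))
    return GenomeRecord(genome_id=genome_id, contigs=contigs)


def _read_gff3_rows(path: str | os.PathLike) -> list[dict]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    rows: dict[str, dict] = {}
    for ftype in ("CDS", "gene"):
        for feat in db.features_of_type(ftype):
            gene_id = feat.id
            if gene_id in rows:  # gene + CDS sharing an ID collapse to one record
                continue
            if feat.strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: feature {gene_id!r} has unknown strand {feat.strand!r}"
                )
            rows[gene_id] = {
                "contig": feat.seqid,
                "gene_id": gene_id,
                "start": int(feat.start),
                "end": int(feat.end),
                "strand": feat.strand,
            }
    return list(rows.values())


def read_gene_table(
    path: str | os.PathLike,
    dialect: str = "tsv",
    genome_id: Optional[str] = None,
) -> GenomeRecord:
    """Read a gene-order table (TSV or GFF3) into a GenomeRecord.

    Genes are sorted by (contig, start, gene_id) and given 0-based
    consecutive ordinals per contig.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={c: str for c in ("genome", "contig", "gene_id", "strand")})
        missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing gene-table columns {missing}")
        rows = df.to_dict("records")
        ids = df["genome"].unique()
        if genome_id is None:
            if len(ids) != 1:
                raise ValueError(f"{path}: expected a single genome id, found {list(ids)}")
            genome_id = str(ids[0])
    elif dialect == "gff3":
        rows = _read_gff3_rows(path)
        if genome_id is None:
            genome_id = os.path.splitext(os.path.basename(str(path)))[0]
    else:
        raise ValueError(f"unknown gene-table dialect {dialect!r}")
    return _build_genome(rows, genome_id)


def write_gene_table(genome: GenomeRecord, path: str | os.PathLike) -> None:
    rows = [
        {
            "genome": genome.genome_id,
            "contig": g.contig_id,
            "gene_id": g.gene_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
        }
        for g in genome.genes()
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hit_table(
    path: str | os.PathLike,
    query_lengths: Mapping[str, int],
    subject_lengths: Optional[Mapping[str, int]] = None,
) -> list[HitRecord]:
    """Parse a 12-column BLAST-tabular hit file into HitRecords.

    Coverage is the aligned span divided by the sequence length, so the
    caller must supply lengths (e.g. from the corresponding FASTA).
    """
    if subject_lengths is None:
        subject_lengths = query_lengths
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            q, s = fields[0], fields[1]
            try:
                pident = float(fields[2])
                length = int(fields[3])
                mismatch = int(fields[4])
                gapopen = int(fields[5])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({e})") from None
            if q not in query_lengths:
                raise ValueError(f"{path}:{lineno}: no length known for query {q!r}")
            if s not in subject_lengths:
                raise ValueError(f"{path}:{lineno}: no length known for subject {s!r}")
            hits.append(
                HitRecord(
                    query_id=q,
                    subject_id=s,
                    pct_identity=pident,
                    aln_length=length,
                    evalue=evalue,
                    bit_score=bitscore,
                    q_cov=(abs(qend - qstart) + 1) / query_lengths[q],
                    s_cov=(abs(send - sstart) + 1) / subject_lengths[s],
                    mismatches=mismatch,
                    gap_opens=gapopen,
                    q_start=qstart,
                    q_end=qend,
                    s_start=sstart,
                    s_end=send,
                )
            )
    return hits


def write_hit_table(hits: list[HitRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
                        h.aln_length, h.mismatches, h.gap_opens,
                        h.q_start, h.q_end, h.s_start, h.s_end,
                        f"{h.evalue:.3g}", f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


def write_ortholog_table(orthomap, path: str | os.PathLike) -> None:
    rows = [
        {
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "pct_identity": round(p.pct_identity, 2),
            "bit_score": round(p.bit_score, 1),
            "aln_length": p.aln_length,
        }
        for p in orthomap.pairs
    ]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "pct_identity", "bit_score", "aln_length"])
    with open(path, "w") as fh:
        fh.write(
            f"# genome_a={orthomap.genome_a_id}\tgenome_b={orthomap.genome_b_id}"
            f"\tn_genes_a={orthomap.n_genes_a}\tn_genes_b={orthomap.n_genes_b}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_ortholog_table(path: str | os.PathLike):
    """Inverse of :func:`write_ortholog_table`."""
    from .model import OrthologMap, OrthologPair

    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing ortholog-table metadata line")
        meta = dict(item.split("=", 1) for item in header[1:].strip().split("\t"))
        df = pd.read_csv(fh, sep="\t")
    pairs = [
        OrthologPair(
            gene_a=str(r.gene_a),
            gene_b=str(r.gene_b),
            pct_identity=float(r.pct_identity),
            bit_score=float(r.bit_score),
            aln_length=int(r.aln_length),
        )
        for r in df.itertuples()
    ]
    return OrthologMap(
        genome_a_id=meta["genome_a"],
        genome_b_id=meta["genome_b"],
        pairs=pairs,
        n_genes_a=int(meta["n_genes_a"]),
        n_genes_b=int(meta["n_genes_b"]),
    )
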