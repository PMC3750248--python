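"""Marker-based genome completeness.

Completeness is the fraction of a marker-gene set (typically
near-universal single-copy families such as ribosomal proteins) with at
least one qualifying homolog in the genome. The marker set is
user-supplied; a 100% estimate does not imply a closed genome, since
draft assemblies still contain gaps between contigs.
"""
from __future__ import annotations

from typing import Mapping, Sequence, Union

import pandas as pd

from .homology import align_all_vs_all
from .model import CompletenessReport

MarkerRefs = Mapping[str, Union[str, Sequence[str]]]


def estimate_completeness(
    genome_proteins: Mapping[str, str],
    marker_refs: MarkerRefs,
    genome_id: str = "genome",
    evalue_max: float = 1e-10,
    cov_min: float = 0.7,
) -> CompletenessReport:
    """Fraction of marker families with a qualifying homolog.

    ``marker_refs`` maps each marker family id to one reference protein
    or a list of them; a family counts as found if any reference hits
    any genome protein at ``evalue <= evalue_max`` with coverage of the
    shorter sequence ``>= cov_min``.
    """
    if not marker_refs:
        raise ValueError("marker set must be non-empty")
    if not genome_proteins:
        raise ValueError("genome protein set must be non-empty")

    ref_seqs: dict[str, str] = {}
    ref_to_marker: dict[str, str] = {}
    for marker_id, refs in marker_refs.items():
        if isinstance(refs, str):
            refs = [refs]
        for i, seq in enumerate(refs):
            rid = f"{marker_id}__ref{i}"
            ref_seqs[rid] = seq
            ref_to_marker[rid] = marker_id

    hits = align_all_vs_all(ref_seqs, dict(genome_proteins), evalue_max=evalue_max)
    best: dict[str, dict] = {}
    for h in hits:
        if max(h.q_cov, h.s_cov) < cov_min:
            continue
        marker_id = ref_to_marker[h.query_id]
        cur = best.get(marker_id)
        if cur is None or h.bit_score > cur["bit_score"]:
            best[marker_id] = {
                "best_gene": h.subject_id,
                "pct_identity": round(h.pct_identity, 2),
                "evalue": h.evalue,
                "bit_score": round(h.bit_score, 1),
            }

    rows = []
    for marker_id in marker_refs:
        hit = best.get(marker_id)
        rows.append(
            {
                "marker_id": marker_id,
                "found": hit is not None,
                "best_gene": hit["best_gene"] if hit else "",
                "pct_identity": hit["pct_identity"] if hit else float("nan"),
                "evalue": hit["evalue"] if hit else float("nan"),
                "bit_score": hit["bit_score"] if hit else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    return CompletenessReport(
        genome_id=genome_id,
        n_markers=len(marker_refs),
        n_found=int(table["found"].sum()),
        per_marker=table,
    )
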