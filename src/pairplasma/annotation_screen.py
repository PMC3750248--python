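"""Annotation confidence tiers and diagnostic motif screening.

The tier classifier assigns each gene one of four confidence levels
from its similarity-search evidence (domain-database hits and nr-style
protein hits), with precedence specific > putative > probable >
hypothetical. Tiers are cumulative thresholds, so strengthening any
piece of evidence can never lower a gene's tier.

Motif screening covers short diagnostic amino acid patterns with a
mismatch budget (e.g. the sulfocyanin motif FNFNGTS and the aerobic
CODH active-site motif AYRGAGR), plus the type I copper-binding site of
blue-copper proteins: two histidines, one cysteine and one methionine
in cupredoxin spacing.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import AnnotationEvidence, MotifDef, TierCall

TIERS = ("hypothetical", "probable", "putative", "specific")

# Diagnostic motifs shipped with the package. Rusticyanin-specific
# motifs are deliberately not listed: no consensus sequence for them is
# bundled here, so screens for rusticyanin-like proteins should load a
# user-supplied motif table.
BUILTIN_MOTIFS = [
    MotifDef(motif_id="sulfocyanin_FNFNGTS", pattern="FNFNGTS", max_mismatch=1),
    MotifDef(motif_id="codh_form2_active_site", pattern="AYRGAGR", max_mismatch=1),
]


@dataclass(frozen=True)
class TierThresholds:
    """Evidence thresholds for the annotation confidence tiers.

    ``specific``: a function-specific domain hit at evalue <=
    specific_evalue covering more than specific_cov of the protein.
    ``putative``: a domain hit at evalue <= putative_evalue covering at
    least putative_cov, or a general-function domain hit at specific
    strength. ``probable``: an nr hit above probable_pident percent
    identity over more than probable_cov of the protein.
    """

    specific_evalue: float = 1e-10
    specific_cov: float = 0.70  # strict >
    putative_evalue: float = 1e-4
    putative_cov: float = 0.50  # inclusive >=
    probable_pident: float = 30.0  # strict >
    probable_cov: float = 0.70  # strict >


def classify_tier(
    gene_id: str,
    evidence: Sequence[AnnotationEvidence],
    thresholds: TierThresholds = TierThresholds(),
) -> TierCall:
    """Assign one confidence tier to a gene from its evidence set."""
    t = thresholds
    specific = putative = probable = False
    for ev in evidence:
        if ev.source == "domain_db":
            strong = ev.evalue <= t.specific_evalue and ev.coverage > t.specific_cov
            if strong and not ev.general_function:
                specific = True
            elif strong and ev.general_function:
                putative = True
            if ev.evalue <= t.putative_evalue and ev.coverage >= t.putative_cov:
                putative = True
        elif ev.source == "nr":
            if (
                ev.pct_identity is not None
                and ev.pct_identity > t.probable_pident
                and ev.coverage > t.probable_cov
            ):
                probable = True
    if specific:
        tier = "specific"
    elif putative:
        tier = "putative"
    elif probable:
        tier = "probable"
    else:
        tier = "hypothetical"
    return TierCall(gene_id=gene_id, tier=tier)


def scan_motif(protein_seq: str, motif: MotifDef) -> list[tuple[int, int]]:
    """All windows matching the motif within its mismatch budget.

    Returns (0-based position, mismatch count) tuples in ascending
    position order; a pattern longer than the protein yields no matches.
    """
    if not protein_seq:
        raise ValueError("protein sequence must be non-empty")
    seq = protein_seq.upper()
    pat = motif.pattern.upper()
    k = len(pat)
    out = []
    for i in range(len(seq) - k + 1):
        mism = sum(1 for a, b in zip(seq[i : i + k], pat) if a != b)
        if mism <= motif.max_mismatch:
            out.append((i, mism))
    return out


@dataclass(frozen=True)
class CopperSiteSpec:
    """Spacing windows for the type I copper site H...C...H...M.

    Each window is (min, max) offset, inclusive, between consecutive
    ligand residues. Defaults follow canonical cupredoxin architecture:
    the cysteine sits well downstream of the first histidine, and the
    second histidine and methionine follow in short order.
    """

    h1_to_c: tuple[int, int] = (20, 60)
    c_to_h2: tuple[int, int] = (1, 10)
    h2_to_m: tuple[int, int] = (1, 15)


def check_type1_copper_site(
    protein_seq: str,
    spec: CopperSiteSpec = CopperSiteSpec(),
) -> tuple[bool, Optional[tuple[int, int, int, int]]]:
    """Does the protein admit a type I copper-site placement?

    Scans left to right for an ordered placement H..C..H..M within the
    spacing windows and returns (found, (h1, c, h2, m) 0-based) for the
    first placement in lexicographic position order, or (False, None).
    """
    seq = protein_seq.upper()
    h_pos = [i for i, ch in enumerate(seq) if ch == "H"]
    c_pos = [i for i, ch in enumerate(seq) if ch == "C"]
    m_pos = [i for i, ch in enumerate(seq) if ch == "M"]
    for h1 in h_pos:
        for c in c_pos:
            if not spec.h1_to_c[0] <= c - h1 <= spec.h1_to_c[1]:
                continue
            for h2 in h_pos:
                if not spec.c_to_h2[0] <= h2 - c <= spec.c_to_h2[1]:
                    continue
                for m in m_pos:
                    if spec.h2_to_m[0] <= m - h2 <= spec.h2_to_m[1]:
                        return True, (h1, c, h2, m)
    return False, None


def scan_proteins(
    proteins: dict[str, str], motifs: Sequence[MotifDef] = tuple(BUILTIN_MOTIFS)
):
    """Scan every protein against every motif; returns a tidy table."""
    import pandas as pd

    rows = []
    for gene_id, seq in proteins.items():
        for motif in motifs:
            for pos, mism in scan_motif(seq, motif):
                rows.append(
                    {
                        "gene_id": gene_id,
                        "motif_id": motif.motif_id,
                        "position": pos,
                        "mismatches": mism,
                    }
                )
    return pd.DataFrame(rows, columns=["gene_id", "motif_id", "position", "mismatches"])
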