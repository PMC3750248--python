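"""Annotation confidence tiers and diagnostic motif screening.

Tier calls follow the manual-curation thresholds (domain hit strength
and coverage; nr identity as fallback). The motif scan finds the
sulfocyanin fingerprint FNFNGTS with a one-mismatch budget, and the
type I copper-site check looks for the H..C..H..M ligand architecture
of blue-copper proteins.
"""
from pairplasma import (
    AnnotationEvidence,
    check_type1_copper_site,
    classify_tier,
    scan_motif,
)
from pairplasma.annotation_screen import BUILTIN_MOTIFS

cases = [
    ("strong domain hit", AnnotationEvidence("g1", "domain_db", 1e-12, 0.80)),
    ("weak domain hit", AnnotationEvidence("g2", "domain_db", 1e-6, 0.60)),
    ("nr hit only", AnnotationEvidence("g3", "nr", 1e-8, 0.75, pct_identity=35.0)),
    ("nothing convincing", AnnotationEvidence("g4", "domain_db", 1e-2, 0.30)),
]
for label, ev in cases:
    print(f"{label:22s} -> {classify_tier(ev.gene_id, [ev]).tier}")

# a toy cupredoxin-like sequence: sulfocyanin motif + copper ligands
seq = ("MKTA" + "FNFNGTS" + "A" * 25 + "H" + "A" * 29 + "C" + "AAAG" + "H" + "AAAL" + "M" + "AA")
sulfo = BUILTIN_MOTIFS[0]
print()
print(f"motif {sulfo.pattern} (<= {sulfo.max_mismatch} mismatch):",
      scan_motif(seq, sulfo))
found, placement = check_type1_copper_site(seq)
print(f"type I copper site found: {found}, ligand positions (H,C,H,M): {placement}")
print()
print("Hits at 0 mismatches are exact sulfocyanin fingerprints; the copper-site")
print("placement lists 0-based positions of the two histidines, the cysteine")
print("and the methionine that would coordinate the copper atom.")
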