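import random

import pytest
from hypothesis import given, strategies as st

from _oracles import copper_placements, hamming_windows

from pairplasma.annotation_screen import (
    BUILTIN_MOTIFS,
    CopperSiteSpec,
    TIERS,
    check_type1_copper_site,
    classify_tier,
    scan_motif,
)
from pairplasma.model import AnnotationEvidence, MotifDef

AA = "ACDEFGHIKLMNPQRSTVWY"


def ev(source="domain_db", evalue=1e-12, coverage=0.8, pident=None, general=False):
    return AnnotationEvidence(
        gene_id="g", source=source, evalue=evalue, coverage=coverage,
        pct_identity=pident, general_function=general,
    )


@pytest.mark.parametrize(
    "evidence, expected",
    [
        # the curation thresholds: strong specific-function domain hit
        ([ev(evalue=1e-12, coverage=0.80)], "specific"),
        # weaker domain evidence in the intermediate band
        ([ev(evalue=1e-6, coverage=0.60)], "putative"),
        # nr-only evidence above 30% identity over >70% of the length
        ([ev(source="nr", evalue=1e-8, coverage=0.75, pident=35.0)], "probable"),
        # nothing qualifying at all
        ([], "hypothetical"),
        ([ev(evalue=1e-2, coverage=0.30)], "hypothetical"),
        # general-function domain at specific strength stays putative
        ([ev(evalue=1e-12, coverage=0.80, general=True)], "putative"),
        # boundary: coverage exactly 0.70 is not enough for specific
        ([ev(evalue=1e-12, coverage=0.70)], "putative"),
        # boundary: evalue exactly 1e-10 with >70% coverage is specific
        ([ev(evalue=1e-10, coverage=0.71)], "specific"),
        # boundary: coverage exactly 0.50 qualifies for putative
        ([ev(evalue=1e-5, coverage=0.50)], "putative"),
        # nr identity exactly 30% does not qualify
        ([ev(source="nr", evalue=1e-8, coverage=0.80, pident=30.0)], "hypothetical"),
        # precedence: specific beats putative and probable
        (
            [
                ev(evalue=1e-12, coverage=0.80),
                ev(evalue=1e-6, coverage=0.60),
                ev(source="nr", evalue=1e-8, coverage=0.80, pident=50.0),
            ],
            "specific",
        ),
        (
            [ev(evalue=1e-6, coverage=0.60), ev(source="nr", evalue=1e-8, coverage=0.80, pident=50.0)],
            "putative",
        ),
    ],
)
def test_tier_classification(evidence, expected):
    assert classify_tier("g", evidence).tier == expected


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["domain_db", "nr"]),
            st.floats(min_value=1e-30, max_value=1.0),
            st.floats(min_value=0.0, max_value=1.0),
            st.floats(min_value=0.0, max_value=100.0),
            st.booleans(),
        ),
        max_size=5,
    ),
    st.integers(min_value=0, max_value=4),
)
def test_strengthening_evidence_never_lowers_tier(raw, idx):
    evidence = [
        AnnotationEvidence(
            gene_id="g", source=src, evalue=e, coverage=cov,
            pct_identity=pid if src == "nr" else None, general_function=gen,
        )
        for src, e, cov, pid, gen in raw
    ]
    before = TIERS.index(classify_tier("g", evidence).tier)
    if not evidence:
        return
    i = idx % len(evidence)
    target = evidence[i]
    stronger = AnnotationEvidence(
        gene_id="g", source=target.source, evalue=target.evalue / 1e6,
        coverage=min(1.0, target.coverage + 0.2),
        pct_identity=(min(100.0, target.pct_identity + 10.0) if target.pct_identity is not None else None),
        general_function=target.general_function,
    )
    evidence[i] = stronger
    after = TIERS.index(classify_tier("g", evidence).tier)
    assert after >= before


def test_motif_exact_match():
    motif = MotifDef("sulfocyanin", "FNFNGTS", 0)
    assert scan_motif("AAFNFNGTSAA", motif) == [(2, 0)]


def test_motif_single_mismatch_within_budget():
    motif = MotifDef("m", "FNFNATS", 1)
    assert scan_motif("AAFNFNGTSAA", motif) == [(2, 1)]


def test_motif_over_budget_not_reported():
    motif = MotifDef("m", "FNFNGTS", 0)
    assert scan_motif("AAFNFNAAAAA", motif) == []


def test_motif_longer_than_protein_returns_empty():
    assert scan_motif("MKV", MotifDef("m", "FNFNGTS", 0)) == []


def test_builtin_motifs_cover_known_diagnostics():
    patterns = {m.pattern for m in BUILTIN_MOTIFS}
    assert "FNFNGTS" in patterns  # sulfocyanin
    assert "AYRGAGR" in patterns  # aerobic form II CODH active site


@given(st.text(alphabet=AA, min_size=1, max_size=60), st.integers(0, 2))
def test_motif_scan_matches_bruteforce(seq, budget):
    motif = MotifDef("m", "FNFNGTS", budget)
    assert scan_motif(seq, motif) == hamming_windows(seq, "FNFNGTS", budget)


def test_copper_site_found_with_canonical_spacing():
    seq = ["A"] * 60
    seq[10], seq[40], seq[45], seq[50] = "H", "C", "H", "M"
    found, placement = check_type1_copper_site("".join(seq))
    assert found
    assert placement == (10, 40, 45, 50)


def test_copper_site_absent_in_polyalanine():
    assert check_type1_copper_site("A" * 80) == (False, None)


def test_copper_site_requires_all_ligands():
    seq = ["A"] * 60
    seq[10], seq[40], seq[45] = "H", "C", "H"  # no methionine
    assert check_type1_copper_site("".join(seq))[0] is False


def test_copper_site_matches_exhaustive_placement_search():
    rng = random.Random(17)
    spec = CopperSiteSpec()
    for _ in range(30):
        seq = "".join(rng.choice("AHCM") for _ in range(70))
        found, placement = check_type1_copper_site(seq, spec)
        oracle = copper_placements(seq, spec.h1_to_c, spec.c_to_h2, spec.h2_to_m)
        assert found == bool(oracle)
        if oracle:
            assert placement == oracle[0]
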