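"""Marker-based genome completeness with a known answer.

A synthetic marker set is sampled from a simulated proteome and 10% of
the marker genes are deleted from a copy of the genome, so the
estimator should report exactly 90% completeness.
"""
from pairplasma import estimate_completeness
from pairplasma.synthetic_data import EvolverParams, evolve_pair, make_marker_test_set

sim = evolve_pair(EvolverParams(n_genes=40, mean_protein_len=100, seed=21))
markers, depleted, expected = make_marker_test_set(
    sim.a.proteins, fraction_deleted=0.10, seed=3, n_markers=30
)

report = estimate_completeness(depleted, markers, genome_id="depleted_copy")
print(f"markers searched:  {report.n_markers}")
print(f"markers found:     {report.n_found}")
print(f"completeness:      {report.completeness_pct:.1f}%  (expected {expected:.1f}%)")
print(f"note:              {report.note}")
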