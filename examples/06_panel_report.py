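"""All-pairs relatedness report over a staggered four-genome panel.

Four lineages diverge from one ancestor at 0, 3, 6 and 12% per-site
substitution. The AAI matrix should order the panel exactly by
divergence, the way whole-genome identity orders real genome panels.
"""
from pairplasma.pipeline import PanelGenome, run_panel
from pairplasma.synthetic_data import EvolverParams, evolve_panel

genomes = evolve_panel(
    EvolverParams(n_genes=40, mean_protein_len=120, seed=5), [0.0, 0.03, 0.06, 0.12]
)
panel = [
    PanelGenome(genome_id=g.genome.genome_id, genome=g.genome,
                proteins=g.proteins, gene_dna=g.gene_dna)
    for g in genomes
]
report = run_panel({}, panel=panel)

print("AAI matrix (%):")
print(report.aai.round(2).to_string())
print()
print("ortholog fraction:")
print(report.ortholog_fraction.round(3).to_string())
print()
print(f"pairs computed: {report.meta['n_pairs']} (= n(n-1)/2 for n=4)")
print("P0's row decreases left to right because each further column diverged")
print("more from the shared ancestor; the diagonal is 100 by definition.")
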