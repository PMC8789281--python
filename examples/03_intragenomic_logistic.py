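"""Within-genome analysis: does a gene's own 3'UTR GC predict its stop codon?

Generates a panel with intragenomic GC heterogeneity (gene-level GC scattered
around each species' mean, stop codons drawn at the gene's local GC), fits a
per-species logistic regression of stop presence/absence on per-gene UTR GC,
and counts coefficient signs across species.  A decile (binned) view of one
high-variance genome is also shown.
"""

import tempfile

from stopgc import pipeline
from stopgc.pipeline import RunConfig
from stopgc.synthetic import PanelSpec, generate_panel

with tempfile.TemporaryDirectory() as tmp:
    generate_panel(
        PanelSpec(
            n_species=15,
            genes_per_species=250,
            gc_grid=(0.35, 0.55),
            gene_gc_sd=0.1,
            seed=3,
        ),
        tmp,
    )
    _, records = pipeline.load_panel(tmp)

intra = pipeline.run_intragenomic(records)
for codon, sc in sorted(intra.sign_counts.items()):
    print(
        f"{codon}: negative in {sc.negative}/{sc.n_converged} species "
        f"({sc.negative_significant} significant), positive in "
        f"{sc.positive}/{sc.n_converged} ({sc.positive_significant} significant)"
    )
print(intra.binomial_p.round(6).to_string(index=False))

one_species = next(iter(records.values()))
binned = pipeline.run_binned(one_species, RunConfig(n_bins=10))
print("\ndecile view of one genome (bin mean GC vs stop frequencies):")
print(binned.binned.table.round(3).to_string(index=False))
print(
    f"\nTGA vs TAG slope across bins: z={binned.slope_comparison.z:.2f}, "
    f"p={binned.slope_comparison.p_value:.3g}\n"
    "TAA coefficients are negative in nearly all species and TGA positive:\n"
    "local GC pressure predicts stop usage gene by gene, with no appeal to\n"
    "release-factor abundance (identical for all genes of one genome)."
)
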