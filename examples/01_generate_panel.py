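"""Generate a small synthetic genome panel and inspect its ground truth.

Builds 10 species spanning 3'UTR GC 0.3-0.7 (80 genes each), writes standard
FASTA + GFF3 + metadata + truth tables to ./example_panel/, and shows how the
generator's stop-codon frequencies vary along the GC gradient.
"""

import pandas as pd

from stopgc.synthetic import PanelSpec, generate_panel, stop_freqs_from_gc

spec = PanelSpec(
    n_species=10, genes_per_species=80, gc_grid=(0.3, 0.7), seed=42
)
manifest = generate_panel(spec, "example_panel")
print(f"wrote {len(manifest['files'])} files to example_panel/")

truth = pd.read_csv("example_panel/truth_species.tsv", sep="\t")
print("\nspecies-level truth (stop frequencies are linear in GC):")
print(
    truth[["species_id", "gc_target", "true_f_TAA", "true_f_TGA", "true_f_TAG",
           "mean_utr3_gc"]].round(4).to_string(index=False)
)

f_lo, f_hi = stop_freqs_from_gc(0.3), stop_freqs_from_gc(0.7)
print(
    "\nacross the gradient TAA falls from "
    f"{f_lo['TAA']:.2f} to {f_hi['TAA']:.2f} while TGA rises from "
    f"{f_lo['TGA']:.2f} to {f_hi['TGA']:.2f}; TAG stays flat at "
    f"{f_lo['TAG']:.2f} - the qualitative pattern seen across real bacteria."
)
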