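"""Between-species stop-usage trends at three site classes.

Generates a 30-species panel, re-extracts every gene through the genome I/O
layer, and asks whether TAA/TGA/TAG usage tracks mean 3'UTR GC at (a) the
canonical stop site, (b) any-frame 3'UTR windows, (c) in-frame codons
downstream of the first additional stop codon.  Slopes are per GC
percentage point; the Z test compares the TGA and TAG slopes.
"""

import tempfile

from stopgc import pipeline
from stopgc.synthetic import PanelSpec, generate_panel

with tempfile.TemporaryDirectory() as tmp:
    generate_panel(
        PanelSpec(n_species=30, genes_per_species=150, asc_rate=0.45, seed=7),
        tmp,
    )
    _, records = pipeline.load_panel(tmp)
    result = pipeline.run_between_species(records)

print(result.correlations.round(4).to_string(index=False))
for sclass, cmp in result.slope_comparisons.items():
    print(
        f"\n{sclass}: slope(TGA)={cmp.fit_a.slope:.5f}, "
        f"slope(TAG)={cmp.fit_b.slope:.5f}, z={cmp.z:.2f}, p={cmp.p_value:.3g}"
    )

print(
    "\nAt the canonical site TGA rises steeply with GC while TAG stays flat\n"
    "(large z): the generator's decoupling is recovered.  In the UTR classes\n"
    "TGA and TAG share nucleotide content, and with i.i.d. UTR composition\n"
    "their trends coincide (small z) - composition alone cannot separate them."
)
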