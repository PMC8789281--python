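"""Stop-codon enrichment against each genome's dinucleotide-controlled null.

For every species a first-order Markov chain (initial nucleotide frequencies
plus conditional dinucleotide transitions) is fitted to its coding sequence;
10,000 simulated trinucleotides give null stop frequencies, and the deviation
(O-E)/E scores observed canonical usage against them.

Two panels illustrate calibration and detection: one draws each gene's stop
from the genome's own null (no codon should win systematically), the other
inflates TAA 1.5x over the null (TAA should be the most enriched nearly
everywhere).
"""

import numpy as np

from stopgc import pipeline
from stopgc.pipeline import RunConfig
from stopgc.synthetic import generate_null_matched_species

config = RunConfig(n_sims=10_000, seed=0)
rng = np.random.default_rng(123)

for label, inflate in [("self-null", None), ("TAA x1.5", {"TAA": 1.5})]:
    panel = {
        f"S{i:02d}": generate_null_matched_species(
            f"S{i:02d}", float(rng.uniform(0.45, 0.55)), 200,
            seed=1000 + i, inflate=inflate,
        )
        for i in range(30)
    }
    result = pipeline.run_enrichment(panel, config)
    print(
        f"{label:10s} panel: TAA most enriched in "
        f"{result.taa_most_enriched}/{result.n_species} species "
        f"({100 * result.taa_fraction:.1f}%), "
        f"binomial p vs 1/3 = {result.binomial_p:.3g}"
    )

print(
    "\nUnder its own null the TAA-most-enriched fraction sits near 1/3\n"
    "(no systematic winner); with TAA inflated 1.5x the deviation score\n"
    "flags TAA in essentially every genome."
)
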