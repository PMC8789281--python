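"""Cross-domain comparison with GC matching.

Two panels with different TAG responses to GC (an archaea-like query with a
moderate positive TAG slope, a bacteria-like candidate set with a weak one)
are compared after pairing each query species with its nearest candidate by
mean 3'UTR GC.  Matching removes GC-range sampling differences so the slope
comparison reflects the codon's response, not the panels' GC coverage.
"""

import tempfile
from pathlib import Path

from stopgc import pipeline
from stopgc.synthetic import PanelSpec, StopModel, generate_panel

archaea_like = StopModel(
    intercepts={"TAA": 0.92, "TGA": 0.03, "TAG": 0.05},
    slopes={"TAA": -1.1, "TGA": 0.78, "TAG": 0.32},
)
bacteria_like = StopModel(
    intercepts={"TAA": 0.92, "TGA": 0.03, "TAG": 0.05},
    slopes={"TAA": -1.2, "TGA": 1.07, "TAG": 0.13},
)

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    common = dict(genes_per_species=200, gc_grid=(0.30, 0.60))
    generate_panel(
        PanelSpec(n_species=40, stop_model=archaea_like, seed=17, **common),
        tmp / "arch",
    )
    generate_panel(
        PanelSpec(n_species=60, stop_model=bacteria_like, seed=18, **common),
        tmp / "bact",
    )
    _, arch = pipeline.load_panel(tmp / "arch")
    _, bact = pipeline.load_panel(tmp / "bact")
    result = pipeline.run_gc_matched(
        pipeline.species_usage_summary(arch),
        pipeline.species_usage_summary(bact),
        codon="TAG",
    )

print(f"pairs: {len(result.pairing.pairs)}, "
      f"mean |dGC| = {result.pairing.mean_abs_delta:.4f}")
print(f"query TAG slope     = {result.query_fit.slope:.5f} per GC point "
      f"(rho={result.query_corr.rho:.2f})")
print(f"candidate TAG slope = {result.matched_fit.slope:.5f} per GC point "
      f"(rho={result.matched_corr.rho:.2f})")
cmp = result.slope_comparison
print(f"slope difference: z={cmp.z:.2f}, p={cmp.p_value:.3g}")
print(
    "\nBoth GC-matched groups show a positive TAG trend, but the query's\n"
    "slope is significantly steeper - the generator's cross-domain\n"
    "difference survives the matching."
)
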