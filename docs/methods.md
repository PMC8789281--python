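# Methods

`stopgc` implements a comparative analysis of stop-codon usage under GC
pressure: how often genomes use TAA, TGA and TAG as a function of GC content,
at sites that terminate translation and at sites that never do. This note
documents the models, the estimators, the synthetic-data generator behind the
test suite, and the numerical and design choices that were genuinely open.

## Scientific setting

The three stop codons are functionally synonymous but are recognised by
different class I release factors in bacteria (RF1 for TAG, RF2 for TGA, both
for TAA). A long-standing hypothesis holds that genomes tune their TGA/TAG
usage to their RF1:RF2 ratio. The analyses here probe that hypothesis
indirectly, by asking whether the characteristic usage-versus-GC trends —
TAA falling, TGA rising, TAG flat and decoupled from TGA — also appear where
release-factor ratios cannot be the cause: in 3'UTR trinucleotides
(any frame, and in-frame downstream of the first additional stop codon),
within single genomes (where all genes share one RF environment), and in
archaea-style panels decoded by a single RF. A dinucleotide-controlled null
asks, separately, whether TAA is used in excess of what genome composition
alone predicts.

## Site classes and usage frequencies

Usage is always the *relative* frequency of TAA, TGA and TAG among
themselves (not among all 64 trinucleotides), pooled over genes to one count
vector per species. Three site classes are counted:

* **canonical** — each gene's terminal stop codon;
* **UTR, any frame** — every overlapping trinucleotide window of the 3'UTR;
  overlapping occurrences all count (`TAATAA` contains TAA twice);
* **UTR, post-ASC in frame** — the UTR read in frame with the canonical
  stop; the first in-frame stop trinucleotide (the ASC, a putative
  read-through fail-safe and therefore potentially under termination
  selection itself) is excluded, and stops among in-frame codons strictly
  after it are counted. Any-frame counting includes windows overlapping the
  ASC; the exclusion applies only to the in-frame class.

The 3'UTR is operationalised as a fixed window immediately downstream of the
stop codon — 30 nt for prokaryote-style input, 100 nt for protist-style
input — reported only for genes whose 3' intergenic space strictly exceeds
the window. Intergenic space is measured from the nucleotide after the stop
codon to the nearest annotated feature *boundary* on either strand (or the
contig end). Measuring to feature start coordinates only, a plausible
alternative reading, would let a UTR window overlap the body of a convergent
neighbour; the boundary rule is the conservative choice. Exon-aware
eukaryote UTRs are accepted as pre-extracted FASTA keyed by gene id rather
than reconstructed from exon graphs.

Species filters: genome length > 500 kb, translation table 11 (all three
stops present), one genome per genus (genus = first whitespace token of the
organism name; ties keep the largest assembly, then the lexicographically
smallest species id). Gene filters: ATG start, length divisible by three,
terminal TAA/TGA/TAG, unambiguous start and stop codons; minus-strand genes
are reverse-complemented before all checks. Codons or windows containing N
are excluded from counts, and GC fractions use unambiguous positions only.

## Dinucleotide-controlled null and deviation score

Per species a first-order Markov chain over A/C/G/T is fitted to the full
CDS set (start and stop codons included): the initial distribution from
pooled mononucleotide frequencies, the transition row T[x][·] from pooled
adjacent-pair counts, with pairs never spanning two sequences and positions
involving N skipped. A nucleotide with no outgoing pairs receives a uniform
row with a warning.

Null stop frequencies come from `n_sims` (default 10,000) seeded
three-nucleotide draws from the chain, normalised over the three stops. The
exact alternative, P(xyz) = p1(x)·T(x,y)·T(y,z), is implemented as
`analytic_trinucleotide_probs` and serves as the oracle for the simulation
in tests; either mode can back the analysis. The deviation score per codon
is (observed − expected)/expected, both usages relative among the three
stops (the normalisation the observed usage is defined on; absolute
per-trinucleotide null probabilities are reported alongside for
transparency). The most enriched codon is the argmax deviation, and the
fraction of species whose argmax is TAA is tested against 1/3 by exact
binomial test.

Because relative stop frequencies are a ratio of small probabilities, their
Monte-Carlo error is governed by the number of simulated *stop* draws, not
by `n_sims` itself; tests bound errors accordingly.

## Inferential layer

* **Trends.** Spearman rank correlation (average ranks, two-sided p) and
  OLS (slope SE from residual variance). Between-species and binned slopes
  are reported per GC *percentage point* (GC axis 0–100), the scale on which
  such slopes are conventionally printed; correlations are scale-free.
* **Slope differences.** z = (b₁ − b₂)/√(se₁² + se₂²) with a two-sided
  normal p. Within one panel the three codon frequencies sum to one, so the
  TGA and TAG estimates are negatively correlated and the within-panel null
  z is over-dispersed (variance 3/2 for three symmetric codons). This is a
  property of compositional data, not of the test; the calibration test
  therefore fits the two compared slopes on independent replicate panels,
  where z is exactly standard normal.
* **Intragenomic regressions.** Per species and per codon, a logistic
  regression of stop presence (1/0) on the gene's own 3'UTR GC (or GC3) as a
  fraction; Wald p on the GC coefficient; at least 50 informative genes and
  both outcome classes required. Perfect separation, optimiser failure or
  absurd coefficients (|β| > 10³) are reported as non-converged, and
  non-converged fits are excluded from all sign counts and tallied.
  Sign/significance counts across species are tested by exact binomial
  exceedance (one-sided "greater" for "more than chance" claims; null 0.5
  for directions, α for significance counts). The TGA-vs-TAG coupling
  strength is compared as the count of species where |β(TGA)| > |β(TAG)|.
* **Binning.** "10 equal bins" is read as equal-count deciles (the
  alternative, equal-width, is rejected): genes sorted by the predictor and
  cut so sizes differ by at most one, remainder genes going to the
  lowest-GC bins; per-bin pooled usage and mean predictor feed the same
  trend machinery.
* **GC matching.** Each query species is paired with the candidate
  minimising |ΔGC| in mean 3'UTR GC, with replacement (the matched multiset
  has exactly the query panel's size); ties break by lexicographic candidate
  id. Nearest-neighbour with replacement is pointwise optimal, so the mean
  |ΔGC| is minimal over all assignments.
* No multiple-testing correction is applied by default anywhere; a
  Benjamini–Hochberg helper exists for callers who want one.

## Synthetic-data generator

The generator emulates the *statistical* structure the analyses assume, not
real genome biology. Its defaults define the package's study conditions:

* 200 species × 500 genes, species GC targets evenly spaced over 0.2–0.8;
* stop frequencies linear in GC then renormalised:
  f(c) = intercept + slope·gc, defaults TAA 0.97 − 1.2·gc,
  TGA 0.01 + 1.2·gc, TAG 0.02 (slopes ±1.2 per GC fraction = ±0.012 per GC
  percentage point, the magnitude scale observed across real bacterial
  panels; the default intercepts sum to 1 with slopes cancelling, so
  renormalisation is the identity and the per-point slopes are exact).
  A linear-then-renormalise model (rather than logit-linear) keeps the
  linear-fit recovery well-posed. Any non-positive raw frequency is a hard
  error naming the offending GC;
* CDS of 50–150 codons: ATG start, i.i.d. codons at the species GC with
  internal in-frame stops removed by rejection at the codon draw, terminal
  stop drawn from the species (or gene) frequencies;
* 30-nt UTRs drawn i.i.d. at the species GC; optionally the per-gene
  probability of an in-frame UTR stop is steered to a target `asc_rate`
  (per-codon planting probability q = 1 − (1 − rate)^(1/K) over K in-frame
  codons, planted stops drawn by composition weight, remaining codons
  rejection-sampled to be non-stop); `asc_rate=None` leaves the purely
  compositional rate;
* optional intragenomic heterogeneity: gene-level GC targets normal around
  the species GC (SD `gene_gc_sd`, clipped to the stop model's feasible
  interval), with each gene's stop drawn at its *own* GC — the isochore-like
  condition the intragenomic analyses need;
* genes placed on random strands on one contig with unannotated spacers wide
  enough that every gene's 3' intergenic space exceeds the UTR window;
  output is plain FASTA + GFF3 + metadata + truth tables, byte-identical
  for identical specs (per-species seeds spawned from the master seed).

Fast samplers (`sample_panel_usage`, `sample_logistic_genes`) draw the
sufficient statistics of the same models without realising sequence, for
replicated recovery and calibration studies; `generate_null_matched_species`
draws stops from the genome's *own* fitted dinucleotide null (optionally
inflated per codon) to calibrate the enrichment analysis.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: phylogenetic correlation among species, selection
on read-through or ASCs, codon usage bias, k-mer mutation biases (e.g.
CpG effects), operonic gene overlap, annotation error. Two visible
consequences: in UTR site classes TGA and TAG have identical nucleotide
content and i.i.d. composition, so their UTR trends coincide (the real
decoupling of TAG in UTRs is exactly the kind of signal the pipeline exists
to detect, and is absent by construction here); and the default linear-GC
panel has no TAA excess over its own composition null, so enrichment runs on
it find TGA, not TAA, most enriched — TAA enrichment is exercised via the
null-matched generator with explicit inflation.

## Problem sizes and determinism

Desk-scale defaults keep every analysis fast: the full five-analysis run on
a default panel completes in well under ten minutes on one CPU, and the
replicated acceptance studies use 20 panels of 200×500 (slope recovery),
200 replicates of 40×120 (calibration), 100 replicates of 2,000 genes
(logistic recovery) and 60-species enrichment panels of 240 genes — sizes at
which the targeted effects are decisively powered (slope-difference z ≈ 150
under the default conditions). All randomness flows from explicit seeds
(numpy `SeedSequence` spawning for per-species streams); identical
configurations reproduce every output byte for byte.

## Known limitations

* The fixed-window UTR definition ignores real transcript structure;
  exon-aware UTRs must be supplied externally.
* The Markov null is first-order; higher-order composition (codon structure,
  k-mer biases) is deliberately out of scope.
* Logistic fits on rare codons (e.g. TAG at 2% usage with a few hundred
  genes) are noisy; absolute-coefficient comparisons involving them inherit
  that noise.
* Genus deduplication uses the name's first token, not a taxonomy service.
* Within-panel slope comparisons of codon pairs are compositionally coupled
  (see above); reported p-values for such pairs are mildly anti-conservative
  under the null, exactly as they are for the analogous analysis on real
  panels.
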