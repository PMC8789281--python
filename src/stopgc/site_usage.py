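"""Stop-trinucleotide counting at the three site classes, and GC metrics.

Stop codon usage is always expressed *relative to the three stop
trinucleotides* (TAA, TGA, TAG), never over all 64 codons: the quantity of
interest is which of the three synonymous terminators a genome (or a genomic
context) prefers, as a function of GC pressure.

Three site classes are distinguished:

``CANONICAL``
    the terminal codon of each annotated CDS — the codon that actually
    terminates translation;
``UTR_ANY_FRAME``
    every overlapping trinucleotide window of the 3'UTR, irrespective of
    reading frame — positions never used for termination;
``UTR_POST_ASC_IN_FRAME``
    in-frame "codons" of the 3'UTR strictly downstream of the first in-frame
    stop trinucleotide (the additional stop codon, ASC).  The ASC itself is
    excluded because it may act as a selected read-through fail-safe; sites
    after it are plausibly free of termination selection.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "STOP_CODONS",
    "SiteClass",
    "StopUsageTable",
    "GCMetrics",
    "UndefinedMetricError",
    "gc_content",
    "gc3",
    "canonical_usage",
    "utr_anyframe_usage",
    "post_asc_usage",
    "species_gc_metrics",
]

#: The three stop trinucleotides of the standard and bacterial (table 11) codes.
STOP_CODONS: tuple[str, str, str] = ("TAA", "TGA", "TAG")

_STOP_SET = frozenset(STOP_CODONS)


class UndefinedMetricError(ValueError):
    """A sequence metric is undefined (e.g. GC of an empty/all-N sequence)."""


class SiteClass(str, Enum):
    """Genomic context in which stop trinucleotides are counted."""

    CANONICAL = "canonical"
    UTR_ANY_FRAME = "utr_any_frame"
    UTR_POST_ASC_IN_FRAME = "utr_post_asc_in_frame"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class StopUsageTable:
    """Counts and relative frequencies of the three stops in one site class.

    Counts are pooled over genes: the species-level frequency is the pooled
    fraction ``count(c) / sum(counts)``, not a mean of per-gene fractions.
    """

    species_id: str
    site_class: SiteClass
    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in STOP_CODONS}
    )
    n_genes_contributing: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def freqs(self) -> dict[str, float]:
        """Relative frequencies over the three stops; empty if no counts."""
        tot = self.total
        if tot == 0:
            return {}
        return {c: self.counts[c] / tot for c in STOP_CODONS}

    @property
    def is_empty(self) -> bool:
        return self.total == 0


@dataclass(frozen=True)
class GCMetrics:
    """Species-level GC summaries: mean 3'UTR GC and mean GC3."""

    mean_utr3_gc: float
    mean_gc3: float


def gc_content(seq: str) -> float:
    """G+C fraction of ``seq`` over unambiguous (A/C/G/T) positions only.

    ``N`` (and any other ambiguity already normalised to ``N``) is excluded
    from both numerator and denominator.

    Raises
    ------
    UndefinedMetricError
        if no unambiguous position remains.
    """
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise UndefinedMetricError(
            "GC content undefined: no unambiguous A/C/G/T positions"
        )
    return gc / (gc + at)


def gc3(cds_seq: str) -> float:
    """GC fraction at third codon positions, terminal stop codon excluded.

    Raises
    ------
    UndefinedMetricError
        if the CDS consists of a single codon (no non-stop third positions)
        or all third positions are ambiguous.
    ValueError
        if the CDS length is not a multiple of 3.
    """
    if len(cds_seq) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    third = cds_seq[2:-3:3]
    if not third:
        raise UndefinedMetricError("GC3 undefined for a single-codon CDS")
    return gc_content(third)


def canonical_usage(records: Iterable, species_id: str = "") -> StopUsageTable:
    """Usage of the terminal stop codon across genes."""
    table = StopUsageTable(species_id, SiteClass.CANONICAL)
    for rec in records:
        if rec.stop_codon in _STOP_SET:
            table.counts[rec.stop_codon] += 1
            table.n_genes_contributing += 1
    return table


def utr_anyframe_usage(records: Iterable, species_id: str = "") -> StopUsageTable:
    """Stop trinucleotides among all overlapping 3'UTR windows, pooled.

    Every window ``utr[i:i+3]`` for ``i = 0..L-3`` is scanned independently,
    so overlapping occurrences (e.g. both TAAs of ``TAATAA``) each count.
    Windows containing ``N`` match no stop and contribute nothing.
    """
    table = StopUsageTable(species_id, SiteClass.UTR_ANY_FRAME)
    for rec in records:
        utr = rec.utr3_seq
        if not utr:
            continue
        table.n_genes_contributing += 1
        for i in range(len(utr) - 2):
            tri = utr[i : i + 3]
            if tri in _STOP_SET:
                table.counts[tri] += 1
    return table


def post_asc_usage(records: Iterable, species_id: str = "") -> StopUsageTable:
    """In-frame stop usage strictly downstream of the first in-frame ASC.

    The UTR is read in frame with the canonical stop (UTR positions 0–2 form
    the first codon).  The first in-frame stop trinucleotide is the ASC and is
    *excluded*; all stops among in-frame codons after it are counted.  Genes
    with no in-frame UTR stop contribute nothing.
    """
    table = StopUsageTable(species_id, SiteClass.UTR_POST_ASC_IN_FRAME)
    for rec in records:
        utr = rec.utr3_seq
        if not utr:
            continue
        codons = [utr[i : i + 3] for i in range(0, len(utr) - 2, 3)]
        asc_idx = next(
            (i for i, c in enumerate(codons) if c in _STOP_SET), None
        )
        if asc_idx is None:
            continue
        table.n_genes_contributing += 1
        for c in codons[asc_idx + 1 :]:
            if c in _STOP_SET:
                table.counts[c] += 1
    return table


def species_gc_metrics(records: Sequence) -> GCMetrics:
    """Mean 3'UTR GC (over genes with a UTR window) and mean GC3."""
    utr_gcs = [r.utr3_gc for r in records if r.utr3_gc is not None]
    gc3s = [r.gc3 for r in records if r.gc3 is not None]
    if not utr_gcs or not gc3s:
        raise UndefinedMetricError(
            "species GC metrics undefined: no genes with UTR GC / GC3"
        )
    return GCMetrics(
        mean_utr3_gc=sum(utr_gcs) / len(utr_gcs),
        mean_gc3=sum(gc3s) / len(gc3s),
    )
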