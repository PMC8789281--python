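"""Reading genomes and annotations, filtering, and per-gene record extraction.

Input formats are the field's standards: multi-contig FASTA for assemblies
(via Biopython) and GFF3 for annotations (via gffutils).  GFF3 coordinates are
1-based inclusive; they are converted to 0-based half-open intervals at the
parser boundary and all internal arithmetic uses the half-open convention.

The species-level filters mirror a comparative prokaryotic study design:
genomes must exceed a minimum length (default 500 kb, excluding plasmids and
fragments), use a translation table possessing all three stop codons
(default table 11), and only one genome is retained per genus to reduce
phylogenetic non-independence.

Gene-level extraction keeps only CDS that start with ATG, have length
divisible by three and terminate in TAA/TGA/TAG.  The 3'UTR is taken as a
fixed window immediately downstream of the stop codon (30 nt for prokaryotes,
100 nt for protist-style input) and is reported only when the gene's
3' intergenic space exceeds a minimum (default: the window length).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
from Bio import SeqIO

from .site_usage import (
    STOP_CODONS,
    UndefinedMetricError,
    gc3 as _gc3,
    gc_content,
)

__all__ = [
    "GenomeAssembly",
    "SpeciesMeta",
    "GeneAnnotation",
    "GeneRecord",
    "read_fasta",
    "read_annotations",
    "read_species_metadata",
    "filter_species_panel",
    "extract_gene_records",
    "attach_utrs_from_fasta",
    "write_gene_records",
    "read_gene_records",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# IUPAC ambiguity codes (and anything else non-ACGT) collapse to N.
_NORMALISE = str.maketrans(
    {c: "N" for c in "RYSWKMBDHVUrsywkmbdhvu"}
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeAssembly:
    """A genome as a mapping contig id -> uppercase A/C/G/T/N sequence."""

    species_id: str
    contigs: dict[str, str]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class SpeciesMeta:
    species_id: str
    organism_name: str
    domain: str  # bacteria | archaea | eukaryote
    translation_table: int

    @property
    def genus(self) -> str:
        """First whitespace token of the organism name (binomial genus)."""
        tokens = self.organism_name.split()
        if not tokens:
            raise ValueError(f"empty organism name for {self.species_id}")
        return tokens[0]


@dataclass
class GeneAnnotation:
    """One gene model: merged CDS parts, 0-based half-open coordinates."""

    gene_id: str
    contig_id: str
    start: int  # 0-based inclusive (leftmost genomic coordinate)
    end: int  # 0-based exclusive
    strand: str  # "+" | "-"
    feature_type: str = "CDS"
    #: CDS parts in genomic coordinate order, each 0-based half-open.
    parts: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.parts:
            self.parts = [(self.start, self.end)]
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not (0 <= self.start <= self.end):
            raise ValueError(f"bad coordinates for {self.gene_id}")


@dataclass
class GeneRecord:
    """One gene's CDS, terminal stop, 3'UTR window and GC metrics.

    ``utr3_seq`` is ``None`` when the gene lacks sufficient 3' intergenic
    space.  ``utr3_gc`` may be set without a stored sequence for records built
    from pre-computed per-gene tables (e.g. pre-extracted eukaryote UTRs or
    synthetic logistic fixtures).
    """

    gene_id: str
    cds_seq: str
    stop_codon: str
    utr3_seq: Optional[str] = None
    utr3_gc: Optional[float] = None
    gc3: Optional[float] = None


def read_fasta(path: str | Path, species_id: str | None = None) -> GenomeAssembly:
    """Read a (multi-)FASTA into a :class:`GenomeAssembly`.

    Sequences are uppercased; IUPAC ambiguity codes other than A/C/G/T are
    mapped to N.  Empty files and duplicate headers are hard errors.
    """
    path = Path(path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        contigs[rec.id] = str(rec.seq).upper().translate(_NORMALISE)
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeAssembly(species_id or path.stem, contigs)


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Parse GFF3 CDS features into gene models.

    CDS lines sharing a gene identifier (``Parent``, falling back to ``ID``)
    are merged into one multi-part gene model with parts ordered by genomic
    coordinate.  Malformed lines are skipped with a logged warning; a file
    yielding zero usable CDS features is a hard error.
    """
    path = Path(path)
    clean_lines: list[str] = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9 or not cols[3].isdigit() or not cols[4].isdigit():
                n_bad += 1
                continue
            clean_lines.append(line)
    if n_bad:
        logger.warning("%s: skipped %d malformed GFF3 line(s)", path, n_bad)

    db = gffutils.create_db(
        "\n".join(clean_lines),
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    grouped: dict[tuple[str, str, str], list[tuple[int, int]]] = defaultdict(list)
    for feat in db.features_of_type("CDS"):
        parent = feat.attributes.get("Parent") or feat.attributes.get("ID")
        gene_id = parent[0] if parent else f"{feat.seqid}:{feat.start}-{feat.end}"
        grouped[(gene_id, feat.seqid, feat.strand)].append(
            (feat.start - 1, feat.end)  # GFF3 1-based inclusive -> half-open
        )

    annotations: list[GeneAnnotation] = []
    for (gene_id, contig_id, strand), parts in grouped.items():
        parts.sort()
        annotations.append(
            GeneAnnotation(
                gene_id=gene_id,
                contig_id=contig_id,
                start=parts[0][0],
                end=parts[-1][1],
                strand=strand,
                parts=parts,
            )
        )
    if not annotations:
        raise ValueError(f"no usable CDS features in {path}")
    annotations.sort(key=lambda a: (a.contig_id, a.start, a.gene_id))
    return annotations


def read_species_metadata(path: str | Path) -> list[SpeciesMeta]:
    """Read a species metadata TSV.

    Columns: species_id, organism_name, domain, translation_table (header row
    required).
    """
    import csv

    metas: list[SpeciesMeta] = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            metas.append(
                SpeciesMeta(
                    species_id=row["species_id"],
                    organism_name=row["organism_name"],
                    domain=row["domain"],
                    translation_table=int(row["translation_table"]),
                )
            )
    return metas


def filter_species_panel(
    panel: Sequence[tuple[SpeciesMeta, GenomeAssembly]],
    min_length: int = 500_000,
    required_table: int = 11,
) -> list[tuple[SpeciesMeta, GenomeAssembly]]:
    """Apply the species-level filters to a panel.

    Keeps genomes with total length strictly greater than ``min_length`` and
    the required translation table, then retains exactly one species per
    genus.  Genus ties keep the largest assembly; residual ties break by
    lexicographic species_id.  An empty result is a hard error naming the
    filter that removed the last entries.
    """
    if not panel:
        raise ValueError("empty input panel")

    by_length = [(m, a) for m, a in panel if a.total_length > min_length]
    if not by_length:
        raise ValueError(
            f"genome length filter (> {min_length} nt) removed all "
            f"{len(panel)} genomes"
        )
    by_table = [
        (m, a) for m, a in by_length if m.translation_table == required_table
    ]
    if not by_table:
        raise ValueError(
            f"translation table filter (== {required_table}) removed all "
            f"{len(by_length)} remaining genomes"
        )

    best: dict[str, tuple[SpeciesMeta, GenomeAssembly]] = {}
    for meta, asm in by_table:
        genus = meta.genus
        if genus not in best:
            best[genus] = (meta, asm)
            continue
        cur_meta, cur_asm = best[genus]
        key_new = (-asm.total_length, meta.species_id)
        key_cur = (-cur_asm.total_length, cur_meta.species_id)
        if key_new < key_cur:
            best[genus] = (meta, asm)
    return sorted(best.values(), key=lambda pair: pair[0].species_id)


def _downstream_space(
    ann: GeneAnnotation,
    others: Sequence[GeneAnnotation],
    contig_len: int,
) -> int:
    """Nucleotides of annotation-free space 3' of the stop codon.

    Measured from the nucleotide after the stop codon to the nearest annotated
    feature boundary on either strand (or the contig end), in the gene's
    transcriptional 3' direction.
    """
    if ann.strand == "+":
        origin = ann.end  # first position after the stop codon
        space = contig_len - origin
        for other in others:
            if other is ann:
                continue
            if other.end > origin:  # lies (at least partly) downstream
                space = min(space, max(other.start - origin, 0))
    else:
        origin = ann.start  # stop codon occupies start..start+2
        space = origin
        for other in others:
            if other is ann:
                continue
            if other.start < origin:
                space = min(space, max(origin - other.end, 0))
    return space


def extract_gene_records(
    assembly: GenomeAssembly,
    annotations: Sequence[GeneAnnotation],
    utr_len: int = 30,
    min_intergenic: int | None = None,
) -> list[GeneRecord]:
    """Extract validated per-gene records with CDS, stop and 3'UTR window.

    Minus-strand genes are reverse-complemented before all checks.  Genes are
    dropped (with a debug log) when the CDS runs off the contig, is not a
    multiple of 3, does not start with ATG, does not end in a stop codon, or
    has an ambiguous start/stop codon.  The UTR window is present only when
    the 3' intergenic space strictly exceeds ``min_intergenic`` (default:
    ``utr_len``) and the window fits on the contig.
    """
    if min_intergenic is None:
        min_intergenic = utr_len

    by_contig: dict[str, list[GeneAnnotation]] = defaultdict(list)
    for ann in annotations:
        by_contig[ann.contig_id].append(ann)

    records: list[GeneRecord] = []
    for ann in annotations:
        contig = assembly.contigs.get(ann.contig_id)
        if contig is None:
            logger.debug("gene %s: unknown contig %s", ann.gene_id, ann.contig_id)
            continue
        clen = len(contig)
        if ann.end > clen:
            logger.warning(
                "gene %s: CDS runs off contig end, dropped", ann.gene_id
            )
            continue

        spliced = "".join(contig[s:e] for s, e in ann.parts)
        cds = spliced if ann.strand == "+" else reverse_complement(spliced)

        if len(cds) % 3 != 0 or len(cds) < 6:
            continue
        if not cds.startswith("ATG"):
            continue
        stop = cds[-3:]
        if stop not in STOP_CODONS:
            continue
        if "N" in cds[:3] or "N" in stop:
            continue

        utr_seq: Optional[str] = None
        utr_gc: Optional[float] = None
        space = _downstream_space(ann, by_contig[ann.contig_id], clen)
        if space > min_intergenic:
            if ann.strand == "+" and ann.end + utr_len <= clen:
                utr_seq = contig[ann.end : ann.end + utr_len]
            elif ann.strand == "-" and ann.start - utr_len >= 0:
                utr_seq = reverse_complement(
                    contig[ann.start - utr_len : ann.start]
                )
            if utr_seq is not None:
                try:
                    utr_gc = gc_content(utr_seq)
                except UndefinedMetricError:
                    utr_seq = None

        try:
            gc3_val: Optional[float] = _gc3(cds)
        except UndefinedMetricError:
            gc3_val = None

        records.append(
            GeneRecord(
                gene_id=ann.gene_id,
                cds_seq=cds,
                stop_codon=stop,
                utr3_seq=utr_seq,
                utr3_gc=utr_gc,
                gc3=gc3_val,
            )
        )
    return records


def attach_utrs_from_fasta(
    records: Iterable[GeneRecord], utr_fasta: str | Path
) -> list[GeneRecord]:
    """Attach pre-extracted 3'UTR sequences (FASTA keyed by gene_id).

    Intended for eukaryote-style input where UTRs come from exon-aware
    annotation rather than a fixed downstream window.  Records without an
    entry keep ``utr3_seq=None``.
    """
    utrs = {
        rec.id: str(rec.seq).upper().translate(_NORMALISE)
        for rec in SeqIO.parse(str(utr_fasta), "fasta")
    }
    out = []
    for rec in records:
        seq = utrs.get(rec.gene_id)
        if seq:
            try:
                rec.utr3_gc = gc_content(seq)
                rec.utr3_seq = seq
            except UndefinedMetricError:
                pass
        out.append(rec)
    return out


def write_gene_records(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write per-gene records as TSV (gene_id, stop_codon, utr3_gc, gc3, utr3_seq)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tstop_codon\tutr3_gc\tgc3\tutr3_seq\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.stop_codon}\t"
                f"{'' if r.utr3_gc is None else repr(r.utr3_gc)}\t"
                f"{'' if r.gc3 is None else repr(r.gc3)}\t"
                f"{r.utr3_seq or ''}\n"
            )


def read_gene_records(path: str | Path) -> list[GeneRecord]:
    """Read records written by :func:`write_gene_records` (no CDS stored)."""
    import csv

    records = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            records.append(
                GeneRecord(
                    gene_id=row["gene_id"],
                    cds_seq="",
                    stop_codon=row["stop_codon"],
                    utr3_seq=row["utr3_seq"] or None,
                    utr3_gc=float(row["utr3_gc"]) if row["utr3_gc"] else None,
                    gc3=float(row["gc3"]) if row["gc3"] else None,
                )
            )
    return records
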