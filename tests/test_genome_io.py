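"""Unit tests for FASTA/GFF3 reading, filtering and gene-record extraction."""

import pandas as pd
import pytest

from stopgc import genome_io
from stopgc.genome_io import (
    GeneAnnotation,
    GenomeAssembly,
    SpeciesMeta,
    extract_gene_records,
    filter_species_panel,
    read_annotations,
    read_fasta,
    reverse_complement,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_identity_read(self, tmp_path):
        p = write(tmp_path, "a.fa", ">c1\nACGT\n")
        asm = read_fasta(p)
        assert asm.contigs == {"c1": "ACGT"}
        assert asm.total_length == 4

    def test_lowercase_normalised(self, tmp_path):
        p = write(tmp_path, "a.fa", ">c1\nacgt\n")
        assert read_fasta(p).contigs["c1"] == "ACGT"

    def test_ambiguity_mapped_to_n(self, tmp_path):
        p = write(tmp_path, "a.fa", ">c1\nACRT\n")
        assert read_fasta(p).contigs["c1"] == "ACNT"

    def test_empty_file_errors(self, tmp_path):
        p = write(tmp_path, "a.fa", "")
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta(p)

    def test_duplicate_headers_error(self, tmp_path):
        p = write(tmp_path, "a.fa", ">c1\nAC\n>c1\nGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)


GFF_HEADER = "##gff-version 3\n"


class TestReadAnnotations:
    def test_single_exon_cds(self, tmp_path):
        p = write(
            tmp_path,
            "a.gff3",
            GFF_HEADER + "c1\tsrc\tCDS\t10\t18\t.\t+\t0\tID=g1\n",
        )
        (ann,) = read_annotations(p)
        # 1-based inclusive 10..18 -> 0-based half-open [9, 18)
        assert (ann.start, ann.end, ann.strand) == (9, 18, "+")

    def test_non_cds_features_excluded(self, tmp_path):
        p = write(
            tmp_path,
            "a.gff3",
            GFF_HEADER
            + "c1\tsrc\tCDS\t10\t18\t.\t+\t0\tID=g1\n"
            + "c1\tsrc\ttRNA\t30\t60\t.\t+\t.\tID=t1\n",
        )
        anns = read_annotations(p)
        assert [a.gene_id for a in anns] == ["g1"]

    def test_two_cds_lines_merged_by_parent(self, tmp_path):
        p = write(
            tmp_path,
            "a.gff3",
            GFF_HEADER
            + "c1\tsrc\tCDS\t21\t26\t.\t+\t0\tID=g1.c2;Parent=g1\n"
            + "c1\tsrc\tCDS\t10\t15\t.\t+\t0\tID=g1.c1;Parent=g1\n",
        )
        (ann,) = read_annotations(p)
        assert ann.parts == [(9, 15), (20, 26)]  # ordered by coordinate
        assert (ann.start, ann.end) == (9, 26)

    def test_malformed_lines_skipped(self, tmp_path):
        p = write(
            tmp_path,
            "a.gff3",
            GFF_HEADER
            + "garbage line without tabs\n"
            + "c1\tsrc\tCDS\t10\t18\t.\t+\t0\tID=g1\n",
        )
        assert len(read_annotations(p)) == 1

    def test_no_usable_features_errors(self, tmp_path):
        p = write(tmp_path, "a.gff3", GFF_HEADER + "c1\tsrc\tgene\t1\t9\t.\t+\t.\tID=g\n")
        with pytest.raises(ValueError, match="no usable CDS"):
            read_annotations(p)


def _panel_entry(sid, organism, length, table=11):
    meta = SpeciesMeta(sid, organism, "bacteria", table)
    asm = GenomeAssembly(sid, {"c1": "A" * length})
    return meta, asm


class TestFilterSpeciesPanel:
    def test_short_genome_removed(self):
        panel = [
            _panel_entry("s1", "Escherichia coli", 400_000),
            _panel_entry("s2", "Bacillus subtilis", 600_000),
        ]
        kept = filter_species_panel(panel)
        assert [m.species_id for m, _ in kept] == ["s2"]

    def test_distinct_genera_both_kept(self):
        panel = [
            _panel_entry("s1", "Escherichia coli", 5_000_000),
            _panel_entry("s2", "Bacillus subtilis", 4_000_000),
        ]
        assert len(filter_species_panel(panel)) == 2

    def test_same_genus_keeps_largest(self):
        panel = [
            _panel_entry("s1", "Escherichia coli", 5_000_000),
            _panel_entry("s2", "Escherichia fergusonii", 4_000_000),
        ]
        kept = filter_species_panel(panel)
        assert [m.species_id for m, _ in kept] == ["s1"]

    def test_same_genus_size_tie_breaks_lexicographically(self):
        panel = [
            _panel_entry("sB", "Escherichia coli", 5_000_000),
            _panel_entry("sA", "Escherichia fergusonii", 5_000_000),
        ]
        kept = filter_species_panel(panel)
        assert [m.species_id for m, _ in kept] == ["sA"]

    def test_wrong_translation_table_removed(self):
        panel = [_panel_entry("s1", "Mycoplasma sp", 600_000, table=4)]
        with pytest.raises(ValueError, match="translation table"):
            filter_species_panel(panel)

    def test_empty_panel_names_length_filter(self):
        panel = [_panel_entry("s1", "Escherichia coli", 100)]
        with pytest.raises(ValueError, match="length filter"):
            filter_species_panel(panel)


class TestExtractGeneRecords:
    def test_plus_strand_gene_with_utr(self):
        cds = "ATGAAATAA"
        contig = cds + "GCGCGCGCATATATGCGCGCATATATGCGCATATGCGCAT"  # 40 nt after
        asm = GenomeAssembly("s", {"c1": contig})
        ann = GeneAnnotation("g1", "c1", 0, 9, "+")
        (rec,) = extract_gene_records(asm, [ann], utr_len=30)
        assert rec.stop_codon == "TAA"
        assert rec.utr3_seq == contig[9:39]
        assert len(rec.utr3_seq) == 30

    def test_gene_without_stop_dropped(self):
        asm = GenomeAssembly("s", {"c1": "ATGAAATTT" + "A" * 40})
        ann = GeneAnnotation("g1", "c1", 0, 9, "+")
        assert extract_gene_records(asm, [ann]) == []

    def test_gene_without_atg_start_dropped(self):
        asm = GenomeAssembly("s", {"c1": "TTGAAATAA" + "A" * 40})
        ann = GeneAnnotation("g1", "c1", 0, 9, "+")
        assert extract_gene_records(asm, [ann]) == []

    def test_minus_strand_reverse_complemented(self):
        # genomic span reads TTACATCAT; revcomp = ATGATGTAA
        left_pad = "G" * 35
        contig = left_pad + "TTACATCAT" + "C" * 5
        asm = GenomeAssembly("s", {"c1": contig})
        ann = GeneAnnotation("g1", "c1", 35, 44, "-")
        (rec,) = extract_gene_records(asm, [ann], utr_len=30)
        assert rec.cds_seq == "ATGATGTAA"
        assert rec.stop_codon == "TAA"
        # UTR is upstream in genomic coordinates, reverse-complemented
        assert rec.utr3_seq == reverse_complement(contig[5:35])

    def test_cds_off_contig_end_dropped(self):
        asm = GenomeAssembly("s", {"c1": "ATGAAA"})
        ann = GeneAnnotation("g1", "c1", 0, 9, "+")
        assert extract_gene_records(asm, [ann]) == []

    def test_utr_absent_without_intergenic_space(self):
        # second gene starts 10 nt after the first stops: no UTR for gene 1
        g1 = "ATGAAATAA"
        gap = "C" * 10
        g2 = "ATGCCCTGA"
        contig = g1 + gap + g2 + "A" * 40
        asm = GenomeAssembly("s", {"c1": contig})
        anns = [
            GeneAnnotation("g1", "c1", 0, 9, "+"),
            GeneAnnotation("g2", "c1", 19, 28, "+"),
        ]
        recs = extract_gene_records(asm, anns, utr_len=30)
        by_id = {r.gene_id: r for r in recs}
        assert by_id["g1"].utr3_seq is None
        assert by_id["g2"].utr3_seq is not None

    def test_emitted_records_satisfy_invariants(self, small_panel):
        _, records = small_panel
        for recs in records.values():
            for r in recs:
                assert len(r.cds_seq) % 3 == 0
                assert r.cds_seq.startswith("ATG")
                assert r.cds_seq.endswith(r.stop_codon)
                if r.utr3_seq is not None:
                    assert len(r.utr3_seq) == 30
                    assert 0.0 <= r.utr3_gc <= 1.0


def _flip(ann: GeneAnnotation, contig_len: int) -> GeneAnnotation:
    parts = sorted((contig_len - e, contig_len - s) for s, e in ann.parts)
    return GeneAnnotation(
        gene_id=ann.gene_id,
        contig_id=ann.contig_id,
        start=parts[0][0],
        end=parts[-1][1],
        strand="-" if ann.strand == "+" else "+",
        parts=parts,
    )


def test_strand_symmetry(small_panel_dir):
    """Reverse-complementing a contig and flipping coordinates is a no-op."""
    asm = genome_io.read_fasta(small_panel_dir / "S000.fa")
    anns = genome_io.read_annotations(small_panel_dir / "S000.gff3")
    fwd = extract_gene_records(asm, anns, utr_len=30)

    flipped_contigs = {
        cid: reverse_complement(seq) for cid, seq in asm.contigs.items()
    }
    flipped_asm = GenomeAssembly(asm.species_id, flipped_contigs)
    flipped_anns = [_flip(a, len(asm.contigs[a.contig_id])) for a in anns]
    rev = extract_gene_records(flipped_asm, flipped_anns, utr_len=30)

    fwd_by_id = {r.gene_id: r for r in fwd}
    rev_by_id = {r.gene_id: r for r in rev}
    assert set(fwd_by_id) == set(rev_by_id)
    for gid, r in fwd_by_id.items():
        assert r.cds_seq == rev_by_id[gid].cds_seq
        assert r.utr3_seq == rev_by_id[gid].utr3_seq


def test_round_trip_against_truth(small_panel_dir, small_panel):
    """Extraction from generated files reproduces the truth table exactly."""
    _, records = small_panel
    truth = pd.read_csv(small_panel_dir / "truth_genes.tsv", sep="\t")
    truth = truth.set_index("gene_id")
    n_checked = 0
    for recs in records.values():
        for r in recs:
            row = truth.loc[r.gene_id]
            assert r.stop_codon == row["stop_codon"]
            assert r.utr3_seq == row["utr3_seq"]
            assert r.utr3_gc == pytest.approx(row["utr3_gc"], abs=1e-12)
            assert r.gc3 == pytest.approx(row["gc3"], abs=1e-12)
            n_checked += 1
    assert n_checked == len(truth)
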