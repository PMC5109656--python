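"""Sequence utilities, genome parsing and the island-metrics table."""

import dataclasses

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from fgi_typer import (
    FormatError,
    Genome,
    UndefinedContentError,
    ValidationError,
    gc_content,
    load_island_table,
    read_genome,
    write_fasta,
    write_table,
)
from fgi_typer.genome_io import GeneFeature, read_fasta


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GCGC", 1.0), ("ATAT", 0.0), ("ATGNN", 1 / 3), ("acgt", 0.5), ("GgCcNN", 1.0)],
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_and_all_ambiguous_are_undefined(self):
        with pytest.raises(UndefinedContentError):
            gc_content("")
        with pytest.raises(UndefinedContentError):
            gc_content("NNNRYK")

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTNacgtn", min_size=1).filter(
        lambda s: any(c in "ACGTacgt" for c in s)))
    def test_case_and_revcomp_invariance(self, seq):
        base = gc_content(seq)
        assert gc_content(seq.lower()) == pytest.approx(base)
        assert gc_content(str(Seq(seq).reverse_complement())) == pytest.approx(base)


class TestGenome:
    def test_cached_gc_matches_recomputation(self, small_cohort):
        g = small_cohort.genomes[0]
        concat = "".join(g.contigs.values())
        assert g.genome_gc_pct == pytest.approx(gc_content(concat) * 100.0, abs=1e-9)

    def test_feature_out_of_bounds_rejected(self):
        feat = GeneFeature("f1", "c1", 0, 50, "+", protein_seq="M")
        with pytest.raises(ValidationError):
            Genome("s", {"c1": "ACGT" * 10}, [feat])


class TestReadGenome:
    def test_genbank_roundtrip_of_synthetic_cohort(self, small_cohort, tmp_path):
        from fgi_typer.synthetic import _write_cohort

        _write_cohort(small_cohort, tmp_path)
        original = small_cohort.genomes[0]
        back = read_genome(tmp_path / "genomes" / f"{original.strain_id}.gbk")
        assert back.strain_id == original.strain_id
        assert back.contigs == original.contigs
        assert len(back.features) == len(original.features)
        starts = [f.start for f in back.features]
        assert starts == sorted(starts)
        for f_in, f_out in zip(original.features, back.features):
            assert (f_out.start, f_out.end, f_out.strand) == (f_in.start, f_in.end, f_in.strand)
            assert f_out.protein_seq == f_in.protein_seq

    def test_minus_strand_cds_translated(self, tmp_path):
        # CDS on the minus strand over [100, 400): 300 nt -> 99 aa after stop
        from fgi_typer.synthetic import random_protein, reverse_translate

        rng = np.random.default_rng(5)
        protein = random_protein(rng, 99)
        nt = reverse_translate(protein, 0.5, rng)
        assert len(nt) == 300
        plus_strand = str(Seq(nt).reverse_complement())
        contig = ("A" * 100) + plus_strand + ("T" * 100)
        gbk = tmp_path / "mini.gbk"
        from Bio.SeqFeature import FeatureLocation, SeqFeature
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        rec = SeqRecord(Seq(contig), id="ctg1", name="ctg1", description="synthetic mini")
        rec.annotations["molecule_type"] = "DNA"
        rec.features.append(
            SeqFeature(FeatureLocation(100, 400, strand=-1), type="CDS",
                       qualifiers={"locus_tag": ["g1"]})
        )
        SeqIO.write([rec], str(gbk), "genbank")
        genome = read_genome(gbk)
        assert len(genome.features) == 1
        assert genome.features[0].protein_seq == protein
        assert len(genome.features[0].protein_seq) == (400 - 100) // 3 - 1

    def test_fasta_gff3_pair(self, small_cohort, tmp_path):
        genome = small_cohort.genomes[0]
        contig_id = next(iter(genome.contigs))
        fasta = tmp_path / "g.fna"
        gff3 = tmp_path / "g.gff3"
        fasta.write_text(f">{contig_id}\n{genome.contigs[contig_id]}\n")
        with open(gff3, "w") as fh:
            fh.write("##gff-version 3\n")
            for f in genome.features:
                fh.write(
                    f"{contig_id}\ttest\tCDS\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t0\t"
                    f"ID={f.feature_id};gene={f.gene_name}\n"
                )
        back = read_genome(fasta, format="fasta+gff3", gff3_path=gff3,
                           strain_id=genome.strain_id)
        assert len(back.features) == len(genome.features)
        for f_in, f_out in zip(genome.features, back.features):
            assert f_out.protein_seq == f_in.protein_seq

    def test_truncated_file_is_format_error(self, tmp_path):
        bad = tmp_path / "broken.gbk"
        bad.write_text("LOCUS   broken    100 bp\nORIGIN\n  1 acgt\n")  # no //
        with pytest.raises(FormatError):
            read_genome(bad)
        with pytest.raises(FormatError):
            read_genome(tmp_path / "missing.gbk")


class TestIslandTable:
    def test_fixture_integrity(self):
        rows = load_island_table()
        assert len(rows) == 36
        assert sum(1 for r in rows if r.fgi_type is None) == 18
        assert sum(1 for r in rows if r.fgi_type in "I II III IV V".split()) == 18

    def test_fixture_example_rows(self):
        rows = {r.strain_id: r for r in load_island_table()}
        dsm465 = rows["G. thermodenitrificans DSM465^T"]
        assert dsm465.fgi_type is None
        assert dsm465.genome_gc_pct == pytest.approx(49.05)
        assert dsm465.island_gc_pct == pytest.approx(45.08)
        assert dsm465.gc_deviation_pct == pytest.approx(-3.97)
        assert dsm465.size_kb == pytest.approx(0.9)
        assert dsm465.n_cds == 0
        c56t2 = rows["Geobacillus sp. C56-T2"]
        assert c56t2.fgi_type == "III"
        assert c56t2.size_kb == pytest.approx(30.4)
        assert c56t2.n_cds == 23

    def test_deviation_invariant_enforced(self, tmp_path):
        bad = tmp_path / "bad.csv"
        text = (
            "strain_id,isolation_source,fgi_type,genome_gc_pct,island_gc_pct,"
            "gc_deviation_pct,size_kb,n_cds\n"
            "strainX,soil,-,50.00,45.00,-4.00,1.0,0\n"  # true deviation is -5.00
        )
        bad.write_text(text)
        with pytest.raises(ValidationError, match="strainX"):
            load_island_table(bad)

    def test_write_read_roundtrip(self, tmp_path):
        rows = load_island_table()
        out = tmp_path / "table.csv"
        write_table(rows, out)
        again = load_island_table(out)
        assert [dataclasses.asdict(r) for r in again] == [dataclasses.asdict(r) for r in rows]

    def test_empty_rows_write_header_only(self, tmp_path):
        out = tmp_path / "empty.csv"
        write_table([], out)
        assert out.read_text().strip().count("\n") == 0
        assert out.read_text().startswith("strain_id,")


class TestFasta:
    def test_roundtrip_and_empty_sequence_skipped(self, tmp_path):
        out = tmp_path / "p.faa"
        write_fasta([("p1", "MKLV"), ("empty", ""), ("p2", "ACDEFG" * 20)], out)
        back = read_fasta(out)
        assert [n for n, _ in back] == ["p1", "p2"]
        assert back[0][1] == "MKLV"
        assert back[1][1] == "ACDEFG" * 20
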