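"""Dialect parsers: each upstream format into the canonical table.

Expected count values are recomputed in-test by a line-oriented oracle
over the raw files, independent of the pandas-based parsing path.
"""

import gzip
import tarfile
import zipfile

import pytest

from taxbridge import ingest
from taxbridge.model import RANKS_MRDNA, DialectError


def line_oracle_grand_total(path, n_leading_nonsample_cols, sep="\t"):
    """Sum every count cell by splitting raw lines — no pandas involved."""
    total = 0
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            cells = line.rstrip("\n").split(sep)
            total += sum(int(c) for c in cells[n_leading_nonsample_cols:])
    return total


def write(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


class TestAnacapa:
    def test_counts_match_line_oracle(self, tmp_path):
        p = write(tmp_path / "t.txt", [
            "ASV\tsum.taxonomy\tS1\tS2",
            "ASV_1\tBacteria;Proteobacteria;Ga;Eo;Fa;Ge;Sp\t5\t1",
            "ASV_2\tBacteria;Firmicutes;Cl;Or;Fa2;Ge2;Sp2\t0\t3",
            "ASV_3\tBacteria;Bacteroidetes;Cy;Oy;Fy;Gy;Sy\t2\t4",
        ])
        t = ingest.read_anacapa(p)
        assert t.grand_total() == line_oracle_grand_total(p, 2)
        assert t.feature_ids == ["ASV_1", "ASV_2", "ASV_3"]
        assert [t.sample_total(s) for s in t.sample_ids] == [7, 8]

    def test_blank_segments_become_unclassified(self, tmp_path):
        p = write(tmp_path / "t.txt", [
            "ASV\tsum.taxonomy\tS1",
            "ASV_1\tBacteria;Proteobacteria;;Enterobacteriales;;Escherichia;\t5",
        ])
        lin = ingest.read_anacapa(p).lineages[0]
        assert lin.taxa[2] is None and lin.taxa[4] is None and lin.taxa[6] is None
        assert lin.taxa[5] == "Escherichia"

    def test_seven_classified_segments_identity(self, tmp_path):
        segs = ["Bacteria", "P", "C", "O", "F", "G", "S"]
        p = write(tmp_path / "t.txt", [
            "ASV\tsum.taxonomy\tS1", f"ASV_1\t{';'.join(segs)}\t1"])
        assert list(ingest.read_anacapa(p).lineages[0].taxa) == segs

    def test_empty_lineage_string_all_unclassified(self, tmp_path):
        p = write(tmp_path / "t.txt", ["ASV\tsum.taxonomy\tS1", "ASV_1\t\t1"])
        assert ingest.read_anacapa(p).lineages[0].taxa == (None,) * 7

    def test_missing_lineage_column_is_dialect_error(self, tmp_path):
        p = write(tmp_path / "t.txt", ["ASV\tS1", "ASV_1\t1"])
        with pytest.raises(DialectError, match="sum.taxonomy"):
            ingest.read_anacapa(p)

    def test_overlong_lineage_truncated_with_warning(self, tmp_path):
        p = write(tmp_path / "t.txt", [
            "ASV\tsum.taxonomy\tS1", "ASV_1\ta;b;c;d;e;f;g;h;i\t1"])
        with pytest.warns(UserWarning, match="truncating"):
            t = ingest.read_anacapa(p)
        assert len(t.lineages[0].taxa) == 7

    def test_comma_delimiter_sniffed(self, tmp_path):
        p = write(tmp_path / "t.csv", [
            "ASV,sum.taxonomy,S1", "ASV_1,Bacteria;P;C;O;F;G;S,4"])
        assert ingest.read_anacapa(p).grand_total() == 4


class TestMrDNA:
    def _write_rank_files(self, tmp_path, with_tax_col=True):
        # two families, three species; parent count vectors are child sums
        files = {}
        files["family"] = write(tmp_path / "family.txt", [
            "family\tS1\tS2",
            "FamA\t5\t4",
            "FamB\t2\t4",
        ])
        species_header = "species\ttaxonomy\tS1\tS2" if with_tax_col else "species\tS1\tS2"
        rows = [
            ("SpX", "Bacteria;P;C;O;FamA;G1;SpX", "5\t4"),
            ("SpY", "Bacteria;P;C;O;FamB;G2;SpY", "0\t3"),
            ("SpZ", "Bacteria;P;C;O;FamB;G2;SpZ", "2\t1"),
        ]
        lines = [species_header]
        for name, tax, counts in rows:
            lines.append(f"{name}\t{tax}\t{counts}" if with_tax_col else f"{name}\t{counts}")
        files["species"] = write(tmp_path / "species.txt", lines)
        return files

    def test_counts_and_totals_from_deepest_file(self, tmp_path):
        files = self._write_rank_files(tmp_path)
        t = ingest.read_mrdna(files)
        assert t.n_features == 3
        assert [t.sample_total(s) for s in t.sample_ids] == [7, 8]
        assert t.grand_total() == line_oracle_grand_total(files["species"], 2)

    def test_unique_count_vector_join_resolves_parent(self, tmp_path):
        files = self._write_rank_files(tmp_path, with_tax_col=False)
        t = ingest.read_mrdna(files)
        # SpX's vector (5,4) matches FamA uniquely
        assert t.lineages[0].taxa[4] == "FamA"
        # SpY's vector (0,3) matches no family row; rank left unclassified
        assert t.lineages[1].taxa[4] is None

    def test_feature_ids_synthesized_deterministically(self, tmp_path):
        files = self._write_rank_files(tmp_path)
        t = ingest.read_mrdna(files)
        assert t.feature_ids == ["F0000", "F0001", "F0002"]
        assert t.feature_ids == ingest.read_mrdna(files).feature_ids

    def test_duplicate_taxon_rows_stay_distinct_features(self, tmp_path):
        p = write(tmp_path / "species.txt", [
            "species\tS1", "SpA\t3", "SpA\t4"])
        t = ingest.read_mrdna({"species": p})
        assert t.n_features == 2
        assert t.sample_total("S1") == 7

    def test_empty_table_preserves_samples(self, tmp_path):
        p = write(tmp_path / "species.txt", ["species\tS1\tS2"])
        t = ingest.read_mrdna({"species": p})
        assert t.n_features == 0
        assert t.sample_ids == ["S1", "S2"]

    def test_inconsistent_sample_columns_name_offending_file(self, tmp_path):
        files = self._write_rank_files(tmp_path)
        files["genus"] = write(tmp_path / "genus.txt", ["genus\tS1\tS9", "G1\t1\t1"])
        with pytest.raises(DialectError, match="genus.txt"):
            ingest.read_mrdna(files)

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        p = write(tmp_path / "species.txt", ["species\tS1", "SpA\toops"])
        with pytest.raises(DialectError, match=r"row 2.*S1"):
            ingest.read_mrdna({"species": p})


class TestQiime2:
    def _export_lines(self):
        return [
            "# Constructed from biom file",
            "#OTU ID\tS1\tS2\tS3",
            "feat1\t1\t2\t3",
            "feat2\t4\t0\t6",
        ]

    def _tax_lines(self, confidence=False):
        head = "Feature ID\tTaxon" + ("\tConfidence" if confidence else "")
        suffix = "\t0.97" if confidence else ""
        return [
            head,
            f"feat1\tBacteria;P;C;O;F;G;S{suffix}",
            f"feat2\tBacteria;P2;C2;O2;F2;G2;S2{suffix}",
        ]

    def test_export_with_taxonomy(self, tmp_path):
        table = write(tmp_path / "ft.tsv", self._export_lines())
        tax = write(tmp_path / "tax.tsv", self._tax_lines())
        t = ingest.read_qiime2(table, taxonomy=tax)
        assert t.feature_ids == ["feat1", "feat2"]
        assert t.grand_total() == 16
        assert t.lineages[0].taxa[0] == "Bacteria"

    def test_qza_container_transparent(self, tmp_path):
        table = write(tmp_path / "ft.tsv", self._export_lines())
        tax = write(tmp_path / "tax.tsv", self._tax_lines())
        direct = ingest.read_qiime2(table, taxonomy=tax)
        qza = tmp_path / "table.qza"
        with zipfile.ZipFile(qza, "w") as zf:
            zf.write(table, "uuid/data/feature-table.tsv")
            zf.write(tax, "uuid/data/taxonomy.tsv")
        assert ingest.read_qiime2(qza).equals(direct)

    def test_confidence_column_ignored(self, tmp_path):
        table = write(tmp_path / "ft.tsv", self._export_lines())
        tax = write(tmp_path / "tax.tsv", self._tax_lines(confidence=True))
        t = ingest.read_qiime2(table, taxonomy=tax)
        assert t.lineages[1].taxa[6] == "S2"

    def test_missing_taxonomy_warns_and_unclassifies(self, tmp_path):
        table = write(tmp_path / "ft.tsv", self._export_lines())
        with pytest.warns(UserWarning, match="taxonomy"):
            t = ingest.read_qiime2(table)
        assert all(lin.taxa == (None,) * 7 for lin in t.lineages)

    def test_zip_without_payload_lists_members(self, tmp_path):
        qza = tmp_path / "bad.qza"
        with zipfile.ZipFile(qza, "w") as zf:
            zf.writestr("uuid/metadata.yaml", "x: 1")
        with pytest.raises(DialectError, match="metadata.yaml"):
            ingest.read_qiime2(qza)


class TestFasta:
    def test_order_and_ids_preserved(self, tmp_path):
        p = write(tmp_path / "s.fasta", [">b extra words", "ACGT", ">a", "GGCC"])
        ss = ingest.read_fasta(p)
        assert ss.ids == ["b", "a"]
        assert ss.records[0].sequence == "ACGT"

    def test_wrapped_lines_concatenated(self, tmp_path):
        p = write(tmp_path / "s.fasta", [">x", "ACGT", "TTAA", "CC"])
        rec = ingest.read_fasta(p).records[0]
        assert rec.sequence == "ACGTTTAACC"
        # canonical serialized size: header + single joined sequence line
        assert rec.byte_size() == len(">x\nACGTTTAACC\n")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.fasta"
        p.write_text("")
        assert len(ingest.read_fasta(p)) == 0

    def test_duplicate_ids_error(self, tmp_path):
        p = write(tmp_path / "s.fasta", [">x", "A", ">x", "C"])
        with pytest.raises(DialectError, match="duplicate"):
            ingest.read_fasta(p)

    def test_sequence_before_header_error(self, tmp_path):
        p = write(tmp_path / "s.fasta", ["ACGT", ">x", "A"])
        with pytest.raises(DialectError, match="before"):
            ingest.read_fasta(p)


class TestPiphillinTar:
    def _make_tar(self, tmp_path, compress=False, members=None):
        if members is None:
            members = {
                "ko_table.csv": [
                    "KO,S1,S2",
                    "K00001,1.5,2",
                    "K00002,0,3",
                    "K00003,4,0.5",
                ],
            }
        name = "r.tar.gz" if compress else "r.tar"
        tar_path = tmp_path / name
        import io
        mode = "w:gz" if compress else "w"
        with tarfile.open(tar_path, mode) as tf:
            for fname, lines in members.items():
                data = ("\n".join(lines) + "\n").encode()
                info = tarfile.TarInfo(fname)
                info.size = len(data)
                tf.addfile(info, io.BytesIO(data))
        return tar_path

    def test_ko_table_cell_values(self, tmp_path):
        tables = ingest.read_piphillin_tar(self._make_tar(tmp_path))
        assert len(tables) == 1
        t = tables[0]
        assert t.kind == "gene"
        assert t.counts.at["K00001", "S1"] == 1.5
        assert t.counts.at["K00003", "S2"] == 0.5

    def test_gene_and_pathway_members_both_read(self, tmp_path):
        members = {
            "ko.csv": ["KO,S1", "K00001,2"],
            "pathway.csv": ["pathway,S1", "ko00010,7"],
        }
        tables = ingest.read_piphillin_tar(self._make_tar(tmp_path, members=members))
        assert sorted(t.kind for t in tables) == ["gene", "pathway"]

    def test_gzip_compression_transparent(self, tmp_path):
        plain = ingest.read_piphillin_tar(self._make_tar(tmp_path))
        gz = ingest.read_piphillin_tar(self._make_tar(tmp_path, compress=True))
        assert plain[0].counts.equals(gz[0].counts)

    def test_unrecognizable_archive_lists_members(self, tmp_path):
        members = {"readme.txt": ["hello", "world of text"]}
        with pytest.raises(DialectError, match="readme.txt"):
            ingest.read_piphillin_tar(self._make_tar(tmp_path, members=members))
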