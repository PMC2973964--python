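import math

import numpy as np
import pytest

from ccravat import (
    FormatError,
    GeneRecord,
    Region,
    load_chromosome,
    read_gene_file,
    read_map,
    read_ped,
    write_cc_chromosome,
    write_cc_summary,
    write_qt_summary,
    write_region_snplist,
)
from ccravat.assoc_cc import CC2x2, CCResult
from ccravat.assoc_qt import QTGroups, QTResult
from ccravat.collapse import MafRecord
from ccravat.formats import fmt_p


class TestReadMap:
    def test_three_column(self, map3_file):
        markers = read_map(map3_file)
        assert [m.name for m in markers] == ["SNP1", "SNP2", "SNP3", "SNP4"]
        assert markers[0].chrom == "1"
        assert markers[0].bp == 1111
        assert markers[0].genetic_pos is None

    def test_four_column(self, map4_file):
        markers = read_map(map4_file)
        assert markers[1].name == "SNP2"
        assert markers[1].genetic_pos == 1.0
        assert markers[1].bp == 2111

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.map"
        p.write_text("")
        assert read_map(p) == []

    def test_mixed_column_counts_rejected(self, tmp_path):
        p = tmp_path / "mixed.map"
        p.write_text("1 SNP1 1111\n1 SNP2 1 2111\n")
        with pytest.raises(FormatError, match="line 2"):
            read_map(p)

    def test_non_integer_bp_names_line(self, tmp_path):
        p = tmp_path / "bad.map"
        p.write_text("1 SNP1 1111\n1 SNP2 xyz\n")
        with pytest.raises(FormatError, match="line 2"):
            read_map(p)

    def test_multiple_chromosomes_rejected(self, tmp_path):
        p = tmp_path / "two.map"
        p.write_text("1 SNP1 1111\n2 SNP2 2111\n")
        with pytest.raises(FormatError, match="chromosome"):
            read_map(p)


class TestReadPed:
    def test_binary_parse(self, ped_file):
        individuals, a1, a2, pheno = read_ped(ped_file, n_markers=3)
        assert len(individuals) == 4
        ind = individuals[0]
        assert (ind.ped_id, ind.indiv_id, ind.father_id, ind.mother_id,
                ind.sex) == ("1", "1", "0", "0", 1)
        assert pheno[0] == 1.0  # unaffected
        assert pheno[2] == 2.0  # affected
        assert list(zip(a1[0], a2[0])) == [("A", "A"), ("A", "C"), ("T", "G")]

    def test_binary_missing_codes(self, tmp_path):
        p = tmp_path / "m.ped"
        p.write_text("1 1 0 0 1 0 A A\n2 2 0 0 1 -9 A G\n")
        _, _, _, pheno = read_ped(p, n_markers=1)
        assert np.isnan(pheno).all()

    def test_quantitative_parse_and_missing_sentinel(self, tmp_path):
        p = tmp_path / "q.ped"
        p.write_text("1 1 0 0 1 0.73 A A\n2 2 0 0 1 -9 A G\n")
        _, _, _, pheno = read_ped(p, n_markers=1, trait_mode="quantitative")
        assert pheno[0] == pytest.approx(0.73)
        assert math.isnan(pheno[1])

    def test_quantitative_zero_is_legal_trait(self, tmp_path):
        p = tmp_path / "q0.ped"
        p.write_text("1 1 0 0 1 0 A A\n")
        _, _, _, pheno = read_ped(p, n_markers=1, trait_mode="quantitative")
        assert pheno[0] == 0.0

    def test_genotype_count_mismatch_names_individual(self, ped_file):
        with pytest.raises(FormatError, match="1/1"):
            read_ped(ped_file, n_markers=5)

    def test_non_numeric_trait_rejected(self, tmp_path):
        p = tmp_path / "bad.ped"
        p.write_text("1 1 0 0 1 tall A A\n")
        with pytest.raises(FormatError, match="trait"):
            read_ped(p, n_markers=1, trait_mode="quantitative")

    def test_duplicate_individual_rejected(self, tmp_path):
        p = tmp_path / "dup.ped"
        p.write_text("1 1 0 0 1 1 A A\n1 1 0 0 1 2 A G\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_ped(p, n_markers=1)


class TestLoadChromosome:
    def test_markers_sorted_with_genotypes(self, tmp_path, ped_file):
        # map deliberately out of bp order
        p = tmp_path / "shuf.map"
        p.write_text("1 SNP3 3111\n1 SNP1 1111\n1 SNP2 2111\n")
        panel = load_chromosome(p, ped_file)
        assert [m.name for m in panel.markers] == ["SNP1", "SNP2", "SNP3"]
        # file column order was SNP3, SNP1, SNP2: individual 1's genotypes
        # (A,A),(A,C),(T,G) must follow the markers into sorted order
        assert (panel.a1[0, 0], panel.a2[0, 0]) == ("A", "C")
        assert (panel.a1[0, 1], panel.a2[0, 1]) == ("T", "G")
        assert (panel.a1[0, 2], panel.a2[0, 2]) == ("A", "A")

    def test_half_missing_genotype_is_missing(self, tmp_path, map3_file):
        p = tmp_path / "h.ped"
        p.write_text("1 1 0 0 1 1 0 A A A A A C C\n")
        panel = load_chromosome(map3_file, p)
        miss = panel.genotype_missing()
        assert miss[0, 0] and not miss[0, 1:].any()


class TestReadGeneFile:
    def test_records(self, gene_file):
        genes = read_gene_file(gene_file)
        assert genes[0] == GeneRecord("7293", "TNFRSF4", "1", 1136569, 1139375)
        assert genes[1].gene_name == "SDF4"
        assert (genes[1].start_bp, genes[1].stop_bp) == (1142151, 1157274)

    def test_start_after_stop_names_gene(self, tmp_path):
        p = tmp_path / "bad_genes.txt"
        p.write_text("1 GENEX 1 500 100\n")
        with pytest.raises(FormatError, match="GENEX"):
            read_gene_file(p)

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "w.txt"
        p.write_text("1 GENEX 1 100\n")
        with pytest.raises(FormatError, match="5 columns"):
            read_gene_file(p)


def _cc_result(name="R1", table=(26, 1877, 7, 2906), chi2=21.44,
               p=3.7e-6, p_fisher=5.94e-6, skipped=False, n_total=12,
               n_rare=6, perm=None):
    return CCResult(
        region=Region(name=name, chrom="5", start_bp=100, end_bp=200),
        table=CC2x2(*table), n_snps_total=n_total, n_snps_rare=n_rare,
        chi2=chi2, p_pearson=p, p_fisher=p_fisher, fisher_skipped=skipped,
        min_cell_threshold=30, perm=perm,
    )


class TestCCWriters:
    def test_summary_filters_and_formats(self, tmp_path):
        res = [
            _cc_result(name="HIT", p=3.7e-6),
            _cc_result(name="NULLISH", table=(10, 90, 10, 90), chi2=0.0,
                       p=1.0, p_fisher=None, skipped=True),
        ]
        path = tmp_path / "sum.txt"
        write_cc_summary(res, path, sig_threshold=1e-3)
        lines = path.read_text().splitlines()
        assert len(lines) == 2  # header + HIT only
        fields = lines[1].split("\t")
        assert fields[0] == "HIT"
        assert fields[4] == "(12/6)"
        assert fields[5:9] == ["26", "1877", "7", "2906"]
        assert fields[9] == "21.44"
        assert fields[10] == "3.7E-06"

    def test_fisher_skip_sentinel(self, tmp_path):
        res = [_cc_result(name="ADAMTS2", table=(62, 1859, 44, 2885),
                          chi2=16.15, p=5.9e-5, p_fisher=None, skipped=True)]
        path = tmp_path / "sum.txt"
        write_cc_summary(res, path, sig_threshold=1.0)
        assert path.read_text().splitlines()[1].split("\t")[11] == "No < 30"

    def test_empty_results_header_only(self, tmp_path):
        path = tmp_path / "sum.txt"
        write_cc_summary([], path, sig_threshold=0.05)
        assert len(path.read_text().splitlines()) == 1

    def test_chromosome_file_contains_all_rows_and_perm(self, tmp_path):
        res = [
            _cc_result(name="A", p=1e-5, perm=(1, 10, 0.1)),
            _cc_result(name="B", p=0.9, p_fisher=None, skipped=True),
        ]
        path = tmp_path / "chr.txt"
        write_cc_chromosome(res, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3
        assert lines[1].split("\t")[-1] == "Perm: 1/10 = 0.1"
        assert lines[2].split("\t")[-1] == ""

    def test_summary_rows_subset_of_chromosome_rows(self, tmp_path):
        res = [_cc_result(name=f"R{i}", p=p)
               for i, p in enumerate([1e-5, 0.5, 1e-4, 0.2])]
        s, c = tmp_path / "s.txt", tmp_path / "c.txt"
        write_cc_summary(res, s, sig_threshold=1e-3)
        write_cc_chromosome(res, c)
        srows = {l.split("\t")[0] for l in s.read_text().splitlines()[1:]}
        crows = [l.split("\t") for l in c.read_text().splitlines()[1:]]
        assert srows <= {r[0] for r in crows}
        # inclusion is exactly the p <= threshold predicate
        expected = {r.region.name for r in res if r.p_pearson <= 1e-3}
        assert srows == expected


class TestQTWriter:
    def test_ci_formatting_and_columns(self, tmp_path):
        res = QTResult(
            region=Region(name="MIB2", chrom="1", start_bp=0, end_bp=107622),
            groups=QTGroups(106, 1125, -0.367, 0.037, 1.0, 1.0),
            n_snps_total=10, n_snps_rare=1,
            beta=0.404, se=0.101, ci_low=0.206, ci_high=0.602,
            p_reg=6.77e-5, t_stat=-3.975, p_t=3.72e-5, undefined=False,
        )
        path = tmp_path / "qt.txt"
        write_qt_summary([res], path, sig_threshold=1e-3)
        fields = path.read_text().splitlines()[1].split("\t")
        assert fields[4] == "(10/1)"
        assert fields[12] == "[0.206 - 0.602]"
        assert fields[10] == "0.404"

    def test_degenerate_row_written_with_p_one(self, tmp_path):
        res = QTResult(
            region=Region(name="EMPTY", chrom="1", start_bp=0, end_bp=10),
            groups=QTGroups(0, 50, math.nan, 0.1, math.nan, 1.0),
            n_snps_total=3, n_snps_rare=0,
            beta=math.nan, se=math.nan, ci_low=math.nan, ci_high=math.nan,
            p_reg=1.0, t_stat=math.nan, p_t=1.0, undefined=True,
        )
        path = tmp_path / "qt.txt"
        write_qt_summary([res], path, sig_threshold=1.0)
        fields = path.read_text().splitlines()[1].split("\t")
        assert fields[5] == "0"
        assert fields[9] == "1"
        assert fields[10] == "" and fields[12] == ""


class TestSnplistWriter:
    def test_all_markers_listed_with_maf(self, tmp_path, panel_factory):
        panel = panel_factory(
            [[("A", "A"), ("A", "G")]], [1.0], bp_start=1212830,
            bp_spacing=100,
        )
        region = Region(name="R", chrom="1", start_bp=0, end_bp=2_000_000,
                        marker_indices=[0, 1])
        mafs = [MafRecord(0, None, 0.042, 1), MafRecord(1, "G", 0.301, 1)]
        path = tmp_path / "snps.txt"
        write_region_snplist(region, panel.markers, mafs, path)
        lines = path.read_text().splitlines()
        assert lines[1].split("\t") == ["SNP1", "1", "1212830", "0.042"]
        assert lines[2].split("\t")[3] == "0.301"  # common marker included

    def test_empty_region_header_only(self, tmp_path):
        path = tmp_path / "snps.txt"
        region = Region(name="R", chrom="1", start_bp=0, end_bp=1)
        write_region_snplist(region, [], [], path)
        assert len(path.read_text().splitlines()) == 1


@pytest.mark.parametrize(
    "p, expected",
    [
        (1.0, "1"),
        (0.0, "0"),
        (0.12, "0.12"),
        (0.029, "0.029"),
        (3.7e-6, "3.7E-06"),
        (float("nan"), ""),
    ],
)
def test_p_value_formatting(p, expected):
    assert fmt_p(p) == expected
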