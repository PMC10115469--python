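"""Summary-statistics I/O, allele harmonization, gene grouping, panel readers."""

import numpy as np
import pandas as pd
import pytest

from twt.corr import CovariateKind
from twt.sumstats import (
    GeneRegion,
    ReferencePanel,
    SummaryTable,
    assign_snps_to_genes,
    build_gene_units,
    harmonize_alleles,
    read_gene_regions,
    read_plink_panel,
    read_summary_table,
    read_vcf_panel,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tI1\tI2\tI3\tI4
"""


def write_vcf(path, records):
    path.write_text(VCF_HEADER + "".join(records))
    return path


def vcf_line(pos, ident, ref, alt, gts):
    cols = ["1", str(pos), ident, ref, alt, ".", "PASS", ".", "GT"] + list(gts)
    return "\t".join(cols) + "\n"


@pytest.fixture
def toy_panel():
    return ReferencePanel(
        snps=["rs1", "rs2", "rs3"],
        counted_allele=["A", "G", "C"],
        other_allele=["G", "A", "T"],
        dosages=np.array(
            [[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 1], [1, 0, 2], [2, 1, 0]],
            dtype=float,
        ),
        chrom=["1", "1", "1"],
        pos=np.array([100, 200, 300]),
    )


def summary_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["snp", "trait", "z", "counted_allele", "other_allele", "chrom", "pos"],
    )


@pytest.fixture
def toy_summary():
    rows = []
    for k, (snp, pos, (a1, a2)) in enumerate(
        [
            ("rs1", 100, ("A", "G")),
            ("rs2", 200, ("A", "G")),  # reversed relative to the panel's G/A
            ("rs3", 300, ("C", "T")),
        ]
    ):
        for i, trait in enumerate(["oleic", "linoleic"]):
            rows.append([snp, trait, 0.5 * i + 0.3 * k - 1.0, a1, a2, "1", pos])
    return SummaryTable(summary_frame(rows))


class TestReadSummaryTable:
    def test_toy_file_parses_all_records(self, tmp_path, toy_summary):
        path = tmp_path / "summary.tsv"
        toy_summary.to_file(path)
        table = read_summary_table(path)
        assert len(table.data) == 6
        assert table.traits == ["linoleic", "oleic"]
        assert table.snps == ["rs1", "rs2", "rs3"]

    def test_missing_column_is_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("snp\ttrait\tz\n rs1\toleic\t1.0\n")
        with pytest.raises(ValueError, match="counted_allele"):
            read_summary_table(path)

    def test_unparsable_z_dropped_or_strict_error(self, tmp_path):
        path = tmp_path / "na.tsv"
        path.write_text(
            "snp\ttrait\tz\tcounted_allele\tother_allele\n"
            "rs1\toleic\tNA\tA\tG\n"
            "rs2\toleic\t1.5\tA\tG\n"
        )
        table = read_summary_table(path)
        assert len(table.data) == 1
        with pytest.raises(ValueError, match="strict"):
            read_summary_table(path, strict=True)

    def test_duplicate_records_rejected(self):
        rows = [["rs1", "oleic", 1.0, "A", "G", "1", 100]] * 2
        with pytest.raises(ValueError, match="duplicate"):
            SummaryTable(summary_frame(rows))

    def test_round_trip_preserves_records(self, tmp_path, toy_summary):
        path = tmp_path / "round.tsv"
        toy_summary.to_file(path)
        back = read_summary_table(path)
        pd.testing.assert_frame_equal(
            back.data.sort_values(["snp", "trait"]).reset_index(drop=True),
            toy_summary.data.sort_values(["snp", "trait"]).reset_index(drop=True),
            check_dtype=False,
        )


class TestHarmonizeAlleles:
    def test_exact_match_kept_unchanged(self, toy_summary, toy_panel):
        out = harmonize_alleles(toy_summary, toy_panel, mode="strict")
        assert set(out.snps) == {"rs1", "rs3"}  # rs2 is swapped in the panel
        original = toy_summary.data.set_index(["snp", "trait"])["z"]
        kept = out.data.set_index(["snp", "trait"])["z"]
        assert all(kept[key] == original[key] for key in kept.index)

    def test_swap_mode_flips_sign(self, toy_summary, toy_panel):
        out = harmonize_alleles(toy_summary, toy_panel, mode="swap")
        assert set(out.snps) == {"rs1", "rs2", "rs3"}
        original = toy_summary.data.set_index(["snp", "trait"])["z"]
        flipped = out.data.set_index(["snp", "trait"])["z"]
        for (snp, trait), value in flipped.items():
            expected = -original[(snp, trait)] if snp == "rs2" else original[(snp, trait)]
            assert value == expected

    def test_allele_mismatch_dropped_in_all_modes(self, toy_panel):
        rows = [["rs1", "oleic", 1.0, "A", "C", "1", 100]]
        table = SummaryTable(summary_frame(rows))
        for mode in ("strict", "swap"):
            assert len(harmonize_alleles(table, toy_panel, mode=mode).data) == 0

    def test_strand_ambiguous_swap_dropped(self):
        panel = ReferencePanel(
            snps=["rs9"],
            counted_allele=["A"],
            other_allele=["T"],
            dosages=np.array([[0.0], [1.0], [2.0]]),
        )
        rows = [["rs9", "oleic", 2.0, "T", "A", "1", 50]]
        table = SummaryTable(summary_frame(rows))
        assert len(harmonize_alleles(table, panel, mode="swap").data) == 0

    def test_absent_from_panel_dropped(self, toy_summary, toy_panel):
        rows = toy_summary.data.copy()
        rows.loc[len(rows)] = ["rs99", "oleic", 1.0, "A", "G", "1", 999]
        out = harmonize_alleles(SummaryTable(rows), toy_panel, mode="swap")
        assert "rs99" not in out.snps

    def test_magnitudes_never_change(self, toy_summary, toy_panel):
        for mode in ("strict", "swap"):
            out = harmonize_alleles(toy_summary, toy_panel, mode=mode)
            original = toy_summary.data.set_index(["snp", "trait"])["z"].abs()
            for (snp, trait), value in out.data.set_index(["snp", "trait"])["z"].items():
                assert abs(value) == original[(snp, trait)]


class TestGeneAssignment:
    REGIONS = [
        GeneRegion("GENE_A", "1", 10_000, 20_000, flank=5000),
        GeneRegion("GENE_B", "1", 18_000, 30_000, flank=5000),
    ]

    @staticmethod
    def positions(mapping):
        return pd.DataFrame(
            {"chrom": ["1"] * len(mapping), "pos": list(mapping.values())},
            index=list(mapping.keys()),
        )

    def test_flank_boundary_inclusive(self):
        pos = self.positions({"rs_in": 5000, "rs_out": 4999, "rs_pad": 6000})
        genes = assign_snps_to_genes(pos, self.REGIONS, m_min=1)
        assert "rs_in" in genes["GENE_A"]
        assert "rs_pad" in genes["GENE_A"]
        assert "rs_out" not in genes.get("GENE_A", [])

    def test_overlapping_genes_share_snp(self):
        pos = self.positions({"rs_shared": 19_000, "rs_a": 11_000, "rs_b": 29_000})
        genes = assign_snps_to_genes(pos, self.REGIONS, m_min=1)
        assert "rs_shared" in genes["GENE_A"] and "rs_shared" in genes["GENE_B"]

    def test_result_independent_of_input_order(self, rng):
        names = [f"rs{i}" for i in range(30)]
        coords = rng.integers(1, 40_000, size=30)
        base = dict(zip(names, coords))
        shuffled = dict(
            (names[i], coords[i]) for i in rng.permutation(30)
        )
        a = assign_snps_to_genes(self.positions(base), self.REGIONS, m_min=1)
        b = assign_snps_to_genes(self.positions(shuffled), self.REGIONS, m_min=1)
        assert a == b

    def test_snp_count_limits_exclude_genes(self):
        pos = self.positions({"rs1": 11_000, "rs2": 12_000, "rs3": 29_000})
        genes = assign_snps_to_genes(pos, self.REGIONS, m_min=2, m_max=500)
        assert "GENE_A" in genes and "GENE_B" not in genes  # B has one SNP
        genes = assign_snps_to_genes(pos, self.REGIONS, m_min=1, m_max=1)
        assert "GENE_B" in genes and "GENE_A" not in genes

    def test_snps_ordered_by_position(self):
        pos = self.positions({"rs_late": 19_000, "rs_early": 11_000})
        genes = assign_snps_to_genes(pos, self.REGIONS, m_min=1)
        assert genes["GENE_A"] == ["rs_early", "rs_late"]

    def test_bed_regions_converted_to_one_based(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t999\t2000\tGENE_X\n")
        regions = read_gene_regions(bed, flank=0)
        assert regions[0].start == 1000 and regions[0].end == 2000


class TestPanelReaders:
    def test_vcf_round_trip(self, tmp_path):
        records = [
            vcf_line(100, "rs1", "G", "A", ["0/0", "0/1", "1/1", "0/1"]),
            vcf_line(200, "rs2", "A", "G", ["0/1", "1/1", "0/0", "./."]),
            vcf_line(300, "rs3", "T", "C,G", ["0/0", "0/1", "0/0", "0/0"]),
        ]
        panel = read_vcf_panel(write_vcf(tmp_path / "panel.vcf", records))
        assert panel.snps == ["rs1", "rs2"]  # multi-allelic rs3 skipped
        assert panel.counted_allele == ["A", "G"]
        assert panel.other_allele == ["G", "A"]
        assert np.allclose(panel.dosages[:, 0], [0, 1, 2, 1])
        assert np.allclose(panel.dosages[:3, 1], [1, 2, 0])
        assert np.isnan(panel.dosages[3, 1])

    def test_plink_round_trip(self, tmp_path):
        # five individuals, two SNPs; codes packed little-endian two bits each
        prefix = tmp_path / "panel"
        (tmp_path / "panel.bim").write_text(
            "1\trs1\t0\t100\tA\tG\n1\trs2\t0\t200\tC\tT\n"
        )
        (tmp_path / "panel.fam").write_text(
            "".join(f"F{i} I{i} 0 0 0 -9\n" for i in range(5))
        )
        # dosages of A1: rs1 -> (2, 1, 0, missing, 2); rs2 -> (0, 0, 1, 1, 2)
        code_map = {2: 0b00, None: 0b01, 1: 0b10, 0: 0b11}
        doses = [[2, 1, None, 0, 2], [0, 0, 1, 1, 2]]

        def pack(values):
            raw = bytearray()
            for chunk_start in range(0, len(values), 4):
                byte = 0
                for offset, value in enumerate(values[chunk_start : chunk_start + 4]):
                    byte |= code_map[value] << (2 * offset)
                raw.append(byte)
            return bytes(raw)

        body = b"".join(pack(row) for row in doses)
        (tmp_path / "panel.bed").write_bytes(bytes([0x6C, 0x1B, 0x01]) + body)
        panel = read_plink_panel(prefix)
        assert panel.snps == ["rs1", "rs2"]
        assert panel.counted_allele == ["A", "C"]
        expected0 = [2.0, 1.0, np.nan, 0.0, 2.0]
        assert np.allclose(panel.dosages[:, 0], expected0, equal_nan=True)
        assert np.allclose(panel.dosages[:, 1], [0, 0, 1, 1, 2])

    def test_bad_bed_magic_rejected(self, tmp_path):
        (tmp_path / "x.bim").write_text("1\trs1\t0\t100\tA\tG\n")
        (tmp_path / "x.fam").write_text("F1 I1 0 0 0 -9\n")
        (tmp_path / "x.bed").write_bytes(b"\x00\x00\x00\x00")
        with pytest.raises(ValueError, match="PLINK"):
            read_plink_panel(tmp_path / "x")


class TestBuildGeneUnits:
    @pytest.fixture
    def inputs(self, rng):
        m_total = 6
        positions = [100, 200, 300, 10_100, 10_200, 10_300]
        snps = [f"rs{i}" for i in range(m_total)]
        dosages = rng.integers(0, 3, size=(40, m_total)).astype(float)
        dosages[0] = 0.0
        dosages[1] = 2.0  # guard against monomorphism
        panel = ReferencePanel(
            snps=snps,
            counted_allele=["A"] * m_total,
            other_allele=["G"] * m_total,
            dosages=dosages,
            chrom=["1"] * m_total,
            pos=np.array(positions),
        )
        rows = []
        for k, snp in enumerate(snps):
            for trait in ["t1", "t2", "t3"]:
                rows.append([snp, trait, rng.standard_normal(), "A", "G", "1", positions[k]])
        summary = SummaryTable(summary_frame(rows))
        regions = [
            GeneRegion("GENE_A", "1", 50, 350, flank=0),
            GeneRegion("GENE_B", "1", 10_050, 10_350, flank=0),
        ]
        return summary, panel, regions

    def test_units_have_consistent_shapes(self, inputs):
        summary, panel, regions = inputs
        units = build_gene_units(summary, panel, regions)
        assert [u.gene for u in units] == ["GENE_A", "GENE_B"]
        for unit in units:
            assert unit.z.values.shape == (3, 3)
            assert unit.snp_corr.labels == unit.snps == unit.z.snps

    def test_gene_with_missing_z_cell_skipped(self, inputs):
        summary, panel, regions = inputs
        trimmed = SummaryTable(summary.data.iloc[1:].reset_index(drop=True))
        units = build_gene_units(trimmed, panel, regions)
        assert [u.gene for u in units] == ["GENE_B"]

    def test_stratification_case_residualizes_ld(self, inputs):
        summary, panel, regions = inputs
        plain = build_gene_units(summary, panel, regions)
        adjusted = build_gene_units(
            summary, panel, regions, covariate_kind=CovariateKind.STRATIFICATION
        )
        assert len(adjusted) == len(plain)
        # principal-coordinate adjustment perturbs the LD estimate
        assert not np.allclose(adjusted[0].snp_corr.values, plain[0].snp_corr.values)
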