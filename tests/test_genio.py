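"""I/O, harmonization, filters, gene assignment and locus annealing."""

import numpy as np
import pandas as pd
import pytest

from polaris import genio
from polaris.genio import (
    GenotypeDataset,
    PlinkFormatError,
    SnpRecord,
    SummaryStats,
    anneal_significant_genes,
    assign_snps_to_sets,
    compute_mafs,
    genomic_control_adjust,
    harmonize,
    impute_missing,
    maf_filter,
    read_plink,
    read_summary_stats,
    write_plink,
)

from conftest import make_dataset


def summary_frame(rows):
    return SummaryStats(pd.DataFrame(
        rows, columns=["snp", "effect_allele", "other_allele", "beta", "se", "p"]))


# ---------------------------------------------------------------------------
# PLINK round trips
# ---------------------------------------------------------------------------

class TestPlinkIO:
    def test_roundtrip_exact_values(self, tmp_path):
        g = np.array([[0, 2], [1, 1], [2, 0.0]])
        d = make_dataset(g, phenotype=[1, 0, 1])
        write_plink(d, tmp_path / "toy")
        back = read_plink(tmp_path / "toy")
        np.testing.assert_array_equal(back.genotypes, g)
        np.testing.assert_array_equal(back.phenotype, [1, 0, 1])
        assert back.snp_ids == d.snp_ids
        assert [s.allele1 for s in back.snps] == ["A", "A"]

    def test_roundtrip_preserves_missing_call(self, tmp_path):
        g = np.array([[0, 2], [np.nan, 1], [2, 0.0]])
        d = make_dataset(g, phenotype=[1, 0, 0])
        write_plink(d, tmp_path / "toy")
        back = read_plink(tmp_path / "toy")
        assert np.isnan(back.genotypes[1, 0])
        mask = ~np.isnan(g)
        np.testing.assert_array_equal(back.genotypes[mask], g[mask])

    def test_bed_fam_dimension_mismatch_is_format_error(self, tmp_path):
        d = make_dataset(np.zeros((3, 2)), phenotype=[0, 1, 0])
        write_plink(d, tmp_path / "toy")
        fam = (tmp_path / "toy.fam").read_text()
        extra = "".join(f"f{i}\ti{i}\t0\t0\t0\t1\n" for i in range(4, 6))
        (tmp_path / "toy.fam").write_text(fam + extra)
        with pytest.raises(PlinkFormatError, match="expected"):
            read_plink(tmp_path / "toy")

    def test_bad_magic_rejected(self, tmp_path):
        d = make_dataset(np.zeros((3, 2)), phenotype=[0, 1, 0])
        write_plink(d, tmp_path / "toy")
        raw = (tmp_path / "toy.bed").read_bytes()
        (tmp_path / "toy.bed").write_bytes(b"\x00\x00\x00" + raw[3:])
        with pytest.raises(PlinkFormatError, match="magic"):
            read_plink(tmp_path / "toy")

    def test_unknown_phenotype_code_lists_rows(self, tmp_path):
        d = make_dataset(np.zeros((3, 2)), phenotype=[0, 1, 0])
        write_plink(d, tmp_path / "toy")
        lines = (tmp_path / "toy.fam").read_text().splitlines()
        lines[1] = lines[1].rsplit("\t", 1)[0] + "\t7"
        (tmp_path / "toy.fam").write_text("\n".join(lines) + "\n")
        with pytest.raises(PlinkFormatError, match=r"row\(s\) \[2\]"):
            read_plink(tmp_path / "toy")

    def test_missing_phenotype_codes_become_nan(self, tmp_path):
        d = make_dataset(np.eye(2), phenotype=[np.nan, 1])
        write_plink(d, tmp_path / "toy")
        back = read_plink(tmp_path / "toy")
        assert np.isnan(back.phenotype[0]) and back.phenotype[1] == 1


def test_read_summary_stats_or_conversion(tmp_path):
    path = tmp_path / "sumstats.txt"
    path.write_text("SNP A1 A2 OR SE\nrs1 A G 1.1 0.05\nrs2 C T 0.9 0.04\n")
    ss = read_summary_stats(path, effects_are_or=True)
    np.testing.assert_allclose(ss.table["beta"], np.log([1.1, 0.9]))
    assert ss.table["p"].isna().all()


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

SNPS = [
    SnpRecord("rs1", "1", 100, "A", "G", 0.2),
    SnpRecord("rs2", "1", 200, "A", "T", 0.3),  # strand-ambiguous
    SnpRecord("rs3", "1", 300, "C", "T", 0.4),
]


class TestHarmonize:
    def test_reversed_alleles_invert_beta(self):
        ss = summary_frame([("rs1", "G", "A", 0.10, 0.02, 0.5)])
        out, rep = harmonize(ss, SNPS)
        assert rep.n_inverted == 1
        assert out.table.loc[0, "beta"] == pytest.approx(-0.10)
        # aligned to the test convention afterwards
        assert out.table.loc[0, "effect_allele"] == "A"

    def test_ambiguous_pair_excluded(self):
        ss = summary_frame([("rs2", "A", "T", 0.3, 0.02, 0.5)])
        out, rep = harmonize(ss, SNPS)
        assert len(out) == 0 and rep.n_excluded_ambiguous == 1

    def test_aligned_alleles_unchanged(self):
        ss = summary_frame([("rs1", "A", "G", 0.10, 0.02, 0.5)])
        out, rep = harmonize(ss, SNPS)
        assert rep.n_matched == 1
        assert out.table.loc[0, "beta"] == pytest.approx(0.10)

    def test_unmatchable_alleles_removed_with_reason(self):
        ss = summary_frame([("rs3", "A", "G", 0.10, 0.02, 0.5)])
        out, rep = harmonize(ss, SNPS)
        assert len(out) == 0
        assert rep.n_excluded_mismatch == 1 and rep.mismatched_ids == ["rs3"]

    def test_absent_snps_counted(self):
        ss = summary_frame([("rs99", "A", "G", 0.1, 0.02, 0.5)])
        _, rep = harmonize(ss, SNPS)
        assert rep.n_absent == 1

    def test_idempotent_once_aligned(self):
        ss = summary_frame([
            ("rs1", "G", "A", 0.10, 0.02, 0.5),
            ("rs3", "C", "T", -0.2, 0.03, 0.1),
        ])
        once, _ = harmonize(ss, SNPS)
        twice, rep2 = harmonize(once, SNPS)
        pd.testing.assert_frame_equal(once.table, twice.table)
        assert rep2.n_inverted == 0


# ---------------------------------------------------------------------------
# imputation and MAF filter
# ---------------------------------------------------------------------------

class TestImputeMissing:
    def test_missing_replaced_by_twice_maf(self):
        g = np.array([[0, 0], [1, 0], [np.nan, 1], [1, 0.0]])
        # column 1: calls (0,1,1) -> freq 1/3, maf 1/3... use explicit column
        d = make_dataset(np.array([[0.0], [np.nan], [1.0], [1.0]]))
        out = impute_missing(d)
        assert out.genotypes[1, 0] == pytest.approx(2 * (2 / 6))

    def test_known_example_maf_half(self):
        d = make_dataset(np.array([[0.0], [2.0], [np.nan], [1.0]]))
        out = impute_missing(d)
        assert out.genotypes[2, 0] == pytest.approx(1.0)  # freq (0+2+1)/6 = 0.5

    def test_no_missing_is_identity(self):
        d = make_dataset(np.array([[0, 1], [2, 1.0]]))
        assert impute_missing(d) is d

    def test_all_missing_column_errors(self):
        d = make_dataset(np.array([[np.nan, 1], [np.nan, 0.0]]))
        with pytest.raises(ValueError, match="all calls missing"):
            impute_missing(d)

    def test_mean_preserved_under_random_masking(self, rng):
        # mask a few known values per column at random; the imputed column
        # mean must come back to the pre-mask mean within 2/N when the
        # counted allele is the minor one
        n = 500
        g = rng.binomial(2, 0.3, size=(n, 4)).astype(float)
        pre_mean = g.mean(axis=0)
        masked = g.copy()
        for j in range(4):
            masked[rng.choice(n, size=3, replace=False), j] = np.nan
        out = impute_missing(make_dataset(masked))
        assert np.all(np.abs(out.genotypes.mean(axis=0) - pre_mean) < 2 / n)


class TestMafFilter:
    def test_boundary_kept_strictly_below_removed(self):
        # MAFs 0.005 / 0.30 / 0.01 with threshold 0.01: first removed only
        cols = [np.r_[np.ones(1), np.zeros(99)],          # freq 0.005
                np.r_[np.ones(60), np.zeros(40)],          # freq 0.30
                np.r_[np.ones(2), np.zeros(98)]]           # freq 0.01
        d = make_dataset(np.array(cols).T)
        out = maf_filter(d, 0.01)
        assert out.snp_ids == ["rs2", "rs3"]

    def test_zero_threshold_identity(self):
        d = make_dataset(np.array([[0, 1], [2, 1.0]]))
        assert maf_filter(d, 0.0).snp_ids == d.snp_ids

    def test_survivor_count_matches_enumeration(self, rng):
        n = 400
        freqs = rng.uniform(0.0, 0.5, size=100)
        g = rng.binomial(2, freqs, size=(n, 100)).astype(float)
        d = make_dataset(g)
        out = maf_filter(d, 0.05)
        expected = int((compute_mafs(g) >= 0.05).sum())
        assert out.m == expected

    def test_all_removed_errors(self):
        d = make_dataset(np.array([[0, 0], [0, 1.0], [0, 0], [0, 0]] * 30))
        with pytest.raises(ValueError, match="0.4"):
            maf_filter(d, 0.4)


# ---------------------------------------------------------------------------
# gene assignment and annealing
# ---------------------------------------------------------------------------

def _snp(i, chrom, pos):
    return SnpRecord(f"s{i}", chrom, pos, "A", "G", 0.2)


class TestAssignSnpsToSets:
    GENES = pd.DataFrame({"gene_id": ["G1", "G2"], "chrom": ["1", "1"],
                          "start": [100, 250], "end": [300, 400]})

    def test_boundaries_inclusive(self):
        snps = [_snp(1, "1", 100), _snp(2, "1", 300), _snp(3, "1", 99)]
        sets = assign_snps_to_sets(snps, self.GENES.iloc[:1])
        assert sets[0].snp_ids == ["s1", "s2"]

    def test_outside_not_assigned_and_empty_gene_omitted(self):
        snps = [_snp(1, "1", 500)]
        assert assign_snps_to_sets(snps, self.GENES) == []

    def test_overlapping_genes_share_snp(self):
        snps = [_snp(1, "1", 260)]
        sets = assign_snps_to_sets(snps, self.GENES)
        assert [s.set_id for s in sets] == ["G1", "G2"]
        assert all(s.snp_ids == ["s1"] for s in sets)

    def test_chromosome_must_match(self):
        snps = [_snp(1, "2", 150)]
        assert assign_snps_to_sets(snps, self.GENES) == []

    def test_membership_sum_exceeds_distinct_iff_overlap(self):
        snps = [_snp(i, "1", p) for i, p in enumerate([120, 260, 350])]
        sets = assign_snps_to_sets(snps, self.GENES)
        total = sum(len(s.snp_ids) for s in sets)
        distinct = len({i for s in sets for i in s.snp_ids})
        assert total == 4 and distinct == 3  # s1 once, s2 twice, s3 once


class TestAnneal:
    def test_close_genes_merge(self):
        hits = [("A", "1", 1_000_000, 1_100_000, 1e-8),
                ("B", "1", 1_200_000, 1_250_000, 1e-7)]  # 100 kb gap
        loci = anneal_significant_genes(hits)
        assert len(loci) == 1 and loci[0].genes == ["A", "B"]
        assert loci[0].min_p == 1e-8

    def test_distant_genes_stay_separate(self):
        hits = [("A", "1", 1_000_000, 1_100_000, 1e-8),
                ("B", "1", 1_400_000, 1_450_000, 1e-7)]  # 300 kb gap
        assert len(anneal_significant_genes(hits)) == 2

    def test_transitive_chain_merges(self):
        # A-B gap 200 kb, B-C gap 200 kb, A-C gap 450 kb
        hits = [("A", "1", 1_000_000, 1_050_000, 1e-8),
                ("B", "1", 1_250_000, 1_300_000, 1e-7),
                ("C", "1", 1_500_000, 1_550_000, 1e-6)]
        loci = anneal_significant_genes(hits)
        assert len(loci) == 1 and sorted(loci[0].genes) == ["A", "B", "C"]

    def test_gap_exactly_250kb_not_merged(self):
        hits = [("A", "1", 1_000_000, 1_050_000, 1e-8),
                ("B", "1", 1_300_000, 1_350_000, 1e-7)]
        assert len(anneal_significant_genes(hits)) == 2

    def test_input_order_irrelevant(self):
        hits = [("C", "2", 1_500_000, 1_550_000, 1e-6),
                ("A", "1", 1_000_000, 1_050_000, 1e-8),
                ("B", "1", 1_150_000, 1_200_000, 1e-7)]
        a = anneal_significant_genes(hits)
        b = anneal_significant_genes(list(reversed(hits)))
        assert [(l.chrom, l.start, l.end, sorted(l.genes)) for l in a] == \
               [(l.chrom, l.start, l.end, sorted(l.genes)) for l in b]


# ---------------------------------------------------------------------------
# genomic control
# ---------------------------------------------------------------------------

class TestGenomicControl:
    def test_identity_at_lambda_one(self):
        ss = summary_frame([("rs1", "A", "G", 0.1, 0.05, 0.0455)])
        out = genomic_control_adjust(ss, 1.0)
        pd.testing.assert_frame_equal(out.table, ss.table)

    def test_se_inflated_by_sqrt_lambda(self):
        ss = summary_frame([("rs1", "A", "G", 0.1, 0.10, np.nan)])
        out = genomic_control_adjust(ss, 1.087)
        assert out.table.loc[0, "se"] == pytest.approx(0.10 * np.sqrt(1.087))
        assert out.table.loc[0, "beta"] == 0.1  # beta untouched

    def test_chi_square_divided(self):
        from scipy import stats
        # chi-square 10.87 at lambda 1.087 must become exactly 10.0
        se = 0.1 / np.sqrt(10.87)
        ss = summary_frame([("rs1", "A", "G", 0.1, se, np.nan)])
        out = genomic_control_adjust(ss, 1.087)
        chi_adj = (out.table.loc[0, "beta"] / out.table.loc[0, "se"]) ** 2
        assert chi_adj == pytest.approx(10.0)
        assert out.table.loc[0, "p"] == pytest.approx(stats.chi2.sf(10.0, 1))

    def test_p_only_snps_adjusted_through_chi(self):
        from scipy import stats
        p0 = 0.0455
        ss = summary_frame([("rs1", "A", "G", 0.1, np.nan, p0)])
        out = genomic_control_adjust(ss, 2.0)
        chi = stats.chi2.isf(p0, 1) / 2.0
        assert out.table.loc[0, "p"] == pytest.approx(stats.chi2.sf(chi, 1))

    def test_deflation_rejected(self):
        ss = summary_frame([("rs1", "A", "G", 0.1, 0.05, np.nan)])
        with pytest.raises(ValueError, match="deflation"):
            genomic_control_adjust(ss, 0.9)
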