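"""PLINK I/O, minor-allele coding, QC filters and single-SNP association."""

import numpy as np
import pytest
from scipy import stats

from force_epistasis import (MISSING, PlinkParseError, collapse_pair,
                             drop_main_effect_snps, interaction_odds_ratio,
                             qc_filter, read_plink, univariate_association,
                             write_plink)
from conftest import make_gm, random_gm


class TestReaders:
    def test_ped_map_hand_transcription(self, tiny_ped):
        gm = read_plink(tiny_ped, dialect="ped_map")
        assert gm.sample_ids == ["s1", "s2", "s3"]
        assert list(gm.phenotype) == [1, 0, 1]
        assert list(gm.snp_meta["id"]) == ["rs1", "rs2"]
        # rs1: T minor (freq 2/6) -> codes count T: CT=1, CT=1, CC=0
        assert list(gm.genotypes[:, 0]) == [1, 1, 0]
        # rs2: A minor (freq 1/4); sample 2 missing
        assert list(gm.genotypes[:, 1]) == [0, MISSING, 1]
        assert gm.snp_meta.loc[0, "allele1"] == "T"
        assert gm.snp_meta.loc[1, "allele1"] == "A"

    def test_bed_and_ped_encodings_agree(self, rng, tmp_path):
        gm = random_gm(rng, n_samples=37, n_snps=11)   # odd count exercises padding
        write_plink(gm, tmp_path / "x", dialect="ped_map")
        write_plink(gm, tmp_path / "x2", dialect="bed_bim_fam")
        g_ped = read_plink(tmp_path / "x", dialect="ped_map")
        g_bed = read_plink(tmp_path / "x2", dialect="bed_bim_fam")
        np.testing.assert_array_equal(g_ped.genotypes, g_bed.genotypes)
        np.testing.assert_array_equal(g_ped.phenotype, g_bed.phenotype)
        assert g_ped.sample_ids == g_bed.sample_ids

    def test_round_trip_preserves_matrix(self, rng, tmp_path):
        gm = random_gm(rng, n_samples=30, n_snps=6)
        for dialect in ("ped_map", "bed_bim_fam"):
            write_plink(gm, tmp_path / dialect, dialect=dialect)
            back = read_plink(tmp_path / dialect, dialect=dialect)
            np.testing.assert_array_equal(back.genotypes, gm.genotypes)
            np.testing.assert_array_equal(back.phenotype, gm.phenotype)
            assert list(back.snp_meta["pos"]) == list(gm.snp_meta["pos"])

    def test_major_allele1_input_is_flipped(self, tmp_path):
        # allele G has frequency 5/6: minor is T, codes must count T
        (tmp_path / "m.map").write_text("1 rs9 0 100\n")
        (tmp_path / "m.ped").write_text(
            "a a 0 0 0 2 G G\n"
            "b b 0 0 0 1 G T\n"
            "c c 0 0 0 2 G G\n"
        )
        gm = read_plink(tmp_path / "m")
        assert list(gm.genotypes[:, 0]) == [0, 1, 0]
        assert gm.snp_meta.loc[0, "allele1"] == "T"

    def test_allele_label_order_invariance(self, rng, tmp_path):
        """Swapping which allele is listed first leaves downstream u(I_OR) unchanged.

        The same samples are written twice: once coding copies of one allele,
        once coding copies of the other (alleles swapped in the metadata).
        The reader re-derives the minor allele from the data, so both files
        must load to the identical matrix and statistic.
        """
        gm = random_gm(rng, n_samples=50, n_snps=4, missing_rate=0.05)
        g_flip = gm.genotypes.copy()
        g_flip[g_flip != MISSING] = 2 - g_flip[g_flip != MISSING]
        gm_flip = make_gm(g_flip, gm.phenotype, alleles=("A", "a"))
        for dialect in ("ped_map", "bed_bim_fam"):
            write_plink(gm, tmp_path / f"fwd_{dialect}", dialect=dialect)
            write_plink(gm_flip, tmp_path / f"swp_{dialect}", dialect=dialect)
            g_fwd = read_plink(tmp_path / f"fwd_{dialect}", dialect=dialect)
            g_swp = read_plink(tmp_path / f"swp_{dialect}", dialect=dialect)
            np.testing.assert_array_equal(g_fwd.genotypes, g_swp.genotypes)
            u_fwd = interaction_odds_ratio(collapse_pair(
                g_fwd.genotypes[:, 0], g_fwd.genotypes[:, 1], g_fwd.phenotype)).u_ior
            u_swp = interaction_odds_ratio(collapse_pair(
                g_swp.genotypes[:, 0], g_swp.genotypes[:, 1], g_swp.phenotype)).u_ior
            assert u_swp == pytest.approx(u_fwd, rel=1e-12)

    def test_unknown_phenotype_dropped(self, tmp_path):
        (tmp_path / "u.map").write_text("1 rs1 0 100\n")
        (tmp_path / "u.ped").write_text(
            "a a 0 0 0 2 A C\n"
            "b b 0 0 0 0 A A\n"
            "c c 0 0 0 -9 C C\n"
            "d d 0 0 0 1 A C\n"
        )
        gm = read_plink(tmp_path / "u")
        assert gm.sample_ids == ["a", "d"]

    def test_malformed_ped_names_file_and_line(self, tmp_path):
        (tmp_path / "bad.map").write_text("1 rs1 0 100\n")
        (tmp_path / "bad.ped").write_text("a a 0 0 0 2 A\n")
        with pytest.raises(PlinkParseError, match=r"bad\.ped:1"):
            read_plink(tmp_path / "bad")

    def test_invalid_phenotype_code(self, tmp_path):
        (tmp_path / "p.map").write_text("1 rs1 0 100\n")
        (tmp_path / "p.ped").write_text("a a 0 0 0 7 A C\n")
        with pytest.raises(PlinkParseError, match="phenotype"):
            read_plink(tmp_path / "p")


class TestQc:
    def test_sample_above_missing_threshold_removed(self):
        g = np.zeros((4, 50), dtype=np.int8)
        g[:, ::2] = 1                       # keep SNPs polymorphic
        g[0, :3] = MISSING                  # 6% missing -> removed
        g[1, :2] = MISSING                  # 4% missing -> kept
        gm = make_gm(g, [1, 1, 0, 0])
        out, report = qc_filter(gm)
        assert out.n_samples == 3
        assert report.loc[report.step == "sample_missingness", "n_removed"].item() == 1

    def test_maf_exactly_at_threshold_retained(self):
        # one SNP at MAF exactly 0.05 (2/40 alleles), one below (1/40)
        g = np.zeros((20, 2), dtype=np.int8)
        g[0, 0] = 2          # MAF 2/40 = 0.05 -> retained (strict "below")
        g[0, 1] = 1          # MAF 1/40 = 0.025 -> removed
        gm = make_gm(g, [1] * 10 + [0] * 10)
        out, report = qc_filter(gm)
        assert list(out.snp_meta["id"]) == ["snp1"]
        assert report.loc[report.step == "maf", "n_removed"].item() == 1

    def test_clean_data_identity(self, rng):
        from force_epistasis import recode_to_minor
        gm = recode_to_minor(random_gm(rng, missing_rate=0.0, maf_range=(0.2, 0.5)))
        out, report = qc_filter(gm)
        np.testing.assert_array_equal(out.genotypes, gm.genotypes)
        assert report["n_removed"].sum() == 0

    def test_idempotent(self, rng):
        gm = random_gm(rng, n_samples=80, n_snps=30, missing_rate=0.02)
        once, _ = qc_filter(gm)
        twice, report2 = qc_filter(once)
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)
        assert report2["n_removed"].sum() == 0

    def test_all_removed_raises(self):
        g = np.full((3, 2), MISSING, dtype=np.int8)
        g[:, :] = MISSING
        with pytest.raises(ValueError, match="empty after QC"):
            qc_filter(make_gm(g, [1, 0, 1]))


class TestUnivariate:
    def test_no_association_gives_p_near_one(self):
        g = np.array([[0], [1], [2], [0], [1], [2]], dtype=np.int8)
        gm = make_gm(g, [1, 1, 1, 0, 0, 0])
        assert univariate_association(gm)[0] == pytest.approx(1.0)

    def test_allelic_chi_square_closed_form(self):
        # cases: 30/70 minor/major alleles; controls: 70/30 (n = 200 alleles)
        g = np.concatenate([
            np.repeat([2, 0], [15, 35]),       # 50 cases
            np.repeat([2, 0], [35, 15]),       # 50 controls
        ]).reshape(-1, 1).astype(np.int8)
        gm = make_gm(g, [1] * 50 + [0] * 50)
        chi2 = 200 * (30 * 30 - 70 * 70) ** 2 / (100 * 100 * 100 * 100)
        assert chi2 == pytest.approx(32.0)
        assert univariate_association(gm)[0] == pytest.approx(
            stats.chi2.sf(chi2, 1), rel=1e-12)

    def test_monomorphic_p_is_one(self):
        g = np.zeros((6, 1), dtype=np.int8)
        gm = make_gm(g, [1, 1, 1, 0, 0, 0])
        assert univariate_association(gm)[0] == 1.0

    def test_planted_main_effect_removed(self, rng):
        gm = random_gm(rng, n_samples=300, n_snps=5, missing_rate=0)
        g = gm.genotypes.copy()
        g[:, 2] = np.where(gm.phenotype == 1, 2, 0)    # perfect association
        gm = make_gm(g, gm.phenotype)
        out, removed = drop_main_effect_snps(gm, threshold=1e-5)
        assert removed == ["snp3"]
        assert out.n_snps == 4
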