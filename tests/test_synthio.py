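import numpy as np
import pandas as pd
import pytest
from scipy import stats

from relnxpress import CohortConfig, ConfigError, ExpressionModel, GenotypeModel, generate_bundle
from relnxpress import synthio
from relnxpress.assoc import hwe_exact


class TestCohort:
    def test_default_group_sizes(self):
        subj = synthio.generate_cohort(CohortConfig(), seed=0)
        counts = subj["diagnosis"].value_counts()
        assert counts["SCZ"] == 35 and counts["BPD"] == 32 and counts["CTRL"] == 35
        assert len(subj) == 102
        assert subj["subject_id"].is_unique

    def test_empty_cohort(self):
        subj = synthio.generate_cohort(CohortConfig(n_scz=0, n_bpd=0, n_ctrl=0), seed=0)
        assert len(subj) == 0

    def test_negative_count_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_scz=-1)

    def test_same_seed_identical(self):
        a = synthio.generate_cohort(CohortConfig(), seed=42)
        b = synthio.generate_cohort(CohortConfig(), seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_controls_have_no_onset(self):
        subj = synthio.generate_cohort(CohortConfig(), seed=3)
        assert subj.loc[subj.diagnosis == "CTRL", "age_of_onset"].isna().all()
        assert subj.loc[subj.diagnosis != "CTRL", "age_of_onset"].notna().all()


class TestGenotypes:
    def test_maf_zero_all_major_homozygous(self):
        subj = synthio.generate_cohort(CohortConfig(), seed=0)
        model = GenotypeModel(n_region_snps=2, maf_range=(0.0, 0.0), rs2229864_maf=0.0)
        geno, _ = synthio.generate_genotypes(subj, model, seed=1)
        assert (geno[["snp001", "snp002", "rs2229864"]] == 0).all().all()

    def test_bad_frequency_map_rejected(self):
        with pytest.raises(ConfigError):
            GenotypeModel(ggc_allele_freqs={8: 0.5, 10: 0.4})

    def test_heterozygosity_calibration(self):
        # MAF 1/3 => expected het fraction 2p(1-p) = 4/9 ~ 0.444
        subj = synthio.generate_cohort(CohortConfig(n_scz=0, n_bpd=0, n_ctrl=10_000), seed=5)
        geno, _ = synthio.generate_genotypes(subj, GenotypeModel(n_region_snps=0), seed=5)
        het = (geno["rs2229864"] == 1).mean()
        se = np.sqrt(4 / 9 * 5 / 9 / 10_000)
        assert abs(het - 4 / 9) < 3 * se

    def test_ggc_common_allele_mass(self):
        subj = synthio.generate_cohort(CohortConfig(n_scz=0, n_bpd=0, n_ctrl=1000), seed=6)
        _, ggc = synthio.generate_genotypes(subj, GenotypeModel(n_region_snps=0), seed=6)
        alleles = np.concatenate([ggc["allele1"], ggc["allele2"]])
        frac = np.isin(alleles, [8, 10]).mean()
        se = np.sqrt(0.948 * 0.052 / 2000)
        assert abs(frac - 0.948) < 3 * se

    def test_region_snps_in_hwe(self):
        # exact-test P values over 83 independent SNPs at n=10,000 ~ uniform
        subj = synthio.generate_cohort(CohortConfig(n_scz=0, n_bpd=0, n_ctrl=10_000), seed=9)
        geno, _ = synthio.generate_genotypes(subj, GenotypeModel(), seed=9)
        pvals = []
        for c in geno.columns:
            if not c.startswith("snp"):
                continue
            g = geno[c]
            pvals.append(hwe_exact((g == 0).sum(), (g == 1).sum(), (g == 2).sum()))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestExpression:
    def test_noiseless_group_means_exact(self, noiseless_bundle):
        truth = noiseless_bundle.truth
        means = truth.groupby("diagnosis")["polya_true"].agg(["min", "max"])
        assert np.allclose(means.loc["CTRL"], 0.085)
        assert np.allclose(means.loc["SCZ"], 0.087)
        assert np.allclose(means.loc["BPD"], 0.060)
        assert np.allclose(truth["retention_true"], 0.833)

    def test_noiseless_gxs_cell_means(self):
        expr = ExpressionModel(
            retention_sd=0.0, ph_effect_on_skipping=0.0, polya_sd=0.0, pmi_effect_on_polya=0.0
        )
        b = generate_bundle(expression=expr, seed=2)
        t = b.truth.merge(b.subjects[["subject_id", "sex"]], on="subject_id", suffixes=("", "_s"))
        carrier = b.genotypes.loc[t["subject_id"], "rs7341475"].to_numpy() > 0
        male_gg = t[(t["sex"] == "M") & ~carrier]
        assert np.allclose(male_gg["skipping_true"], 0.158)
        female_a = t[(t["sex"] == "F") & carrier]
        assert np.allclose(female_a["skipping_true"], 0.1464)

    def test_population_polya_mean_matches_group_mixture(self):
        # weighted mean of (0.087, 0.060, 0.085) over (35, 32, 35) = 0.0778
        expected = (35 * 0.087 + 32 * 0.060 + 35 * 0.085) / 102
        means = [generate_bundle(seed=s).truth["polya_true"].mean() for s in range(20)]
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - expected) < 3 * se
        assert abs(expected - 0.0778) < 5e-4

    def test_scz_allelic_deviation_elevated(self, bundle):
        t = bundle.truth.dropna(subset=["aei_dev_true"])
        scz = t[t.diagnosis == "SCZ"]["aei_dev_true"].abs().mean()
        rest = t[t.diagnosis != "SCZ"]["aei_dev_true"].abs().mean()
        assert scz > rest

    def test_proportions_in_open_interval(self, bundle):
        t = bundle.truth
        for col in ("polya_true", "skipping_true", "retention_true"):
            assert ((t[col] > 0) & (t[col] < 1)).all()


class TestRendering:
    def test_bundle_tables_reference_known_subjects(self, bundle):
        ids = set(bundle.subjects["subject_id"])
        assert set(bundle.ct["subject_id"]) <= ids
        assert set(bundle.peaks["subject_id"]) <= ids
        assert set(bundle.allele_signals["sample_id"]) <= ids
        assert len(bundle.truth) == len(bundle.subjects)

    def test_noiseless_ct_inverts_to_truth(self, noiseless_bundle):
        from relnxpress import qpcr

        expr = qpcr.quantify(noiseless_bundle.ct)
        merged = expr.merge(noiseless_bundle.truth, on="subject_id")
        assert np.allclose(merged["polya_proportion"], merged["polya_true"])
        assert np.allclose(merged["relative_expression"], 2.0 ** merged["total_expr_log2"])

    def test_noiseless_peaks_invert_to_truth(self, noiseless_bundle):
        from relnxpress import microexon

        mex = microexon.quantify(noiseless_bundle.peaks)
        merged = mex.merge(noiseless_bundle.truth, on="subject_id")
        assert np.allclose(merged["skipping_proportion"], merged["skipping_true"])

    def test_gdna_heterozygote_balanced_when_unbiased(self, noiseless_bundle):
        sig = noiseless_bundle.allele_signals
        het = noiseless_bundle.truth.loc[noiseless_bundle.truth.rs2229864_copies == 1, "subject_id"]
        g = sig[(sig.material == "gDNA") & sig.sample_id.isin(het)]
        p = g.signal_T / (g.signal_T + g.signal_C)
        assert np.allclose(p, 0.5)

    def test_determinism_identical_bundles(self):
        a = generate_bundle(seed=123)
        b = generate_bundle(seed=123)
        for attr in ("subjects", "genotypes", "truth", "ct", "peaks", "allele_signals"):
            pd.testing.assert_frame_equal(getattr(a, attr), getattr(b, attr))

    def test_write_read_roundtrip(self, bundle, tmp_path):
        bundle.write(tmp_path)
        back = synthio.SyntheticBundle.read(tmp_path)
        assert len(back.subjects) == len(bundle.subjects)
        assert list(back.genotypes.columns) == list(bundle.genotypes.columns)

    def test_vcf_roundtrip_preserves_dosages(self, bundle, tmp_path):
        path = tmp_path / "genotypes.vcf"
        synthio.write_vcf(bundle.genotypes, path)
        back = synthio.read_vcf(path)
        pd.testing.assert_frame_equal(back, bundle.genotypes, check_dtype=False)
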