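import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from relnxpress import assoc, microexon, qpcr


def _pheno_from(values, name="polya_proportion", transform="auto"):
    return assoc.normality_and_transform(pd.Series(values), name, transform)


class TestNormality:
    def test_normal_data_usually_passes_shapiro(self):
        n_pass = 0
        for seed in range(50):
            v = pd.Series(np.random.default_rng(seed).normal(size=100))
            p = assoc.normality_and_transform(v, "aei").shapiro_p
            n_pass += p > 0.05
        assert n_pass >= 45  # ~nominal type-I level of the test

    def test_log_transform_restores_normality(self):
        rng = np.random.default_rng(4)
        v = pd.Series(np.exp(rng.normal(size=200)))
        res = assoc.normality_and_transform(v, "polya_proportion")
        assert res.transform == "log10"
        assert res.shapiro_p > 0.05 > res.shapiro_p_raw

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            _pheno_from([1.0] * 10)

    def test_aei_left_untransformed(self):
        res = assoc.normality_and_transform(pd.Series(np.random.default_rng(0).random(20)), "aei")
        assert res.transform == "none"


class TestSequentialAnova:
    def test_reduces_to_one_way_without_confounders(self, rng):
        g = rng.integers(0, 3, 60)
        y = rng.normal(size=60) + 0.5 * (g == 2)
        dummies = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
        rep = assoc.sequential_anova(y, [("g", dummies)])[0]
        ref = stats.f_oneway(y[g == 0], y[g == 1], y[g == 2])
        assert rep.F == pytest.approx(ref.statistic)
        assert rep.p == pytest.approx(ref.pvalue)

    def test_matches_manual_nested_least_squares(self, rng):
        n = 70
        conf = rng.normal(size=n)
        g = rng.integers(0, 3, n)
        y = rng.normal(size=n) + 0.3 * conf
        dummies = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
        rep = assoc.sequential_anova(y, [("conf", conf[:, None]), ("g", dummies)])[-1]
        X0 = np.column_stack([np.ones(n), conf])
        X1 = np.column_stack([X0, dummies])
        rss0 = ((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2).sum()
        rss1 = ((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2).sum()
        F = ((rss0 - rss1) / 2) / (rss1 / (n - 4))
        assert rep.F == pytest.approx(F)

    def test_saturated_design_rejected(self):
        with pytest.raises(ValueError):
            assoc.sequential_anova(np.array([1.0, 2.0]), [("x", np.array([[1.0], [2.0]]))])


class TestDiagnosisAnova:
    def test_bipolar_deficit_detected(self, bundle):
        expr = qpcr.quantify(bundle.ct).set_index("subject_id")
        pheno = assoc.normality_and_transform(expr["polya_proportion"], "polya_proportion")
        reports = assoc.diagnosis_anova(pheno, bundle.subjects)
        by_term = {r.term: r for r in reports}
        assert by_term["diagnosis"].df == 2
        assert by_term["BPD_vs_CTRL"].df == 1
        assert by_term["BPD_vs_CTRL"].p < 0.05

    def test_single_group_rejected(self, bundle):
        expr = qpcr.quantify(bundle.ct).set_index("subject_id")
        pheno = assoc.normality_and_transform(expr["polya_proportion"], "polya_proportion")
        scz_only = bundle.subjects[bundle.subjects.diagnosis == "SCZ"]
        with pytest.raises(ValueError):
            assoc.diagnosis_anova(pheno, scz_only)


class TestConfounderScreen:
    def test_ph_most_significant_for_skipping(self, bundle):
        mex = microexon.quantify(bundle.peaks).set_index("subject_id")
        pheno = assoc.normality_and_transform(mex["skipping_proportion"], "microexon_skipping")
        screen = assoc.confounder_screen(pheno, bundle.subjects)
        assert screen.iloc[0]["covariate"] == "ph"
        assert screen.iloc[0]["selected"]

    def test_null_covariates_rarely_selected(self):
        rng = np.random.default_rng(17)
        hits = 0
        n_rep = 120
        for _ in range(n_rep):
            subj = pd.DataFrame(
                {"subject_id": [f"s{i}" for i in range(40)], "age": rng.normal(size=40)}
            )
            pheno = assoc.PhenotypeVector(
                "aei", pd.Series(rng.normal(size=40), index=subj.subject_id), "none", 1, 1
            )
            screen = assoc.confounder_screen(pheno, subj, covariates=("age",))
            hits += bool(screen.iloc[0]["selected"])
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(hits / n_rep - 0.05) < 3 * se


class TestGxsInteraction:
    @staticmethod
    def _fit(bundle, confounders=("ph",)):
        mex = microexon.quantify(bundle.peaks).set_index("subject_id")
        pheno = assoc.normality_and_transform(mex["skipping_proportion"], "microexon_skipping")
        carrier = bundle.genotypes["rs7341475"].map(lambda c: "GG" if c == 0 else "A")
        sex = bundle.subjects.set_index("subject_id")["sex"]
        return assoc.gxs_interaction(pheno, carrier, sex, bundle.subjects, confounders=confounders)

    def test_opposite_trend_detected(self, bundle):
        rep = self._fit(bundle)
        assert rep.df == 1
        assert rep.p < 0.05
        t = bundle.truth.set_index("subject_id")
        carrier = bundle.genotypes["rs7341475"] > 0
        sex = bundle.subjects.set_index("subject_id")["sex"]
        male_trend = t.loc[(sex == "M") & carrier, "skipping_true"].mean() - t.loc[
            (sex == "M") & ~carrier, "skipping_true"
        ].mean()
        female_trend = t.loc[(sex == "F") & carrier, "skipping_true"].mean() - t.loc[
            (sex == "F") & ~carrier, "skipping_true"
        ].mean()
        assert male_trend > 0 > female_trend  # men skip more with A, women with GG

    def test_null_interaction_p_uniform(self):
        from relnxpress import generate_bundle
        from relnxpress.config import ExpressionModel

        pvals = []
        for seed in range(25):
            b = generate_bundle(
                expression=ExpressionModel(use_gxs_cells=False), seed=1000 + seed
            )
            pvals.append(self._fit(b, confounders=()).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_collapsed_genotype_rejected(self, bundle):
        mex = microexon.quantify(bundle.peaks).set_index("subject_id")
        pheno = assoc.normality_and_transform(mex["skipping_proportion"], "microexon_skipping")
        carrier = pd.Series("GG", index=bundle.genotypes.index)
        sex = bundle.subjects.set_index("subject_id")["sex"]
        with pytest.raises(ValueError):
            assoc.gxs_interaction(pheno, carrier, sex, bundle.subjects)


class TestHweExact:
    def test_perfect_hwe_most_probable(self):
        assert assoc.hwe_exact(25, 50, 25) > 0.5

    def test_total_het_deficit(self):
        assert assoc.hwe_exact(50, 0, 50) < 1e-20

    def test_matches_enumeration_on_sample_tables(self):
        from fractions import Fraction
        from math import comb

        def brute(nAA, nAa, naa):
            n = nAA + nAa + naa
            na = 2 * nAA + nAa
            ways = {}
            for k in range(na % 2, min(na, 2 * n - na) + 1, 2):
                a = (na - k) // 2
                ways[k] = Fraction(comb(n, a) * comb(n - a, k) * 2**k)
            tot = sum(ways.values())
            p_obs = ways[nAa] / tot
            return float(sum(w for w in ways.values() if w / tot <= p_obs) / tot)

        rng = np.random.default_rng(3)
        for _ in range(60):
            counts = rng.integers(0, 8, 3)
            if counts.sum() == 0:
                continue
            assert assoc.hwe_exact(*counts) == pytest.approx(brute(*counts), abs=1e-12)


class TestSnpQc:
    @staticmethod
    def _geno_from_counts(n0, n1, n2):
        return pd.Series([0] * n0 + [1] * n1 + [2] * n2)

    def test_hwe_threshold_is_bonferroni_scaled(self):
        # 83 SNPs: cut-off 0.05/83 ~ 6.0e-4; a SNP at P = 5e-4 must fail
        cols = {f"snp{i:03d}": self._geno_from_counts(40, 44, 16) for i in range(82)}
        bad = self._geno_from_counts(50, 22, 28)  # strong het deficit
        assert assoc.hwe_exact(50, 22, 28) < 0.05 / 83
        cols["snp_bad"] = bad
        qc = assoc.snp_qc(pd.DataFrame(cols)).set_index("snp")
        assert not qc.loc["snp_bad", "pass"]

    def test_maf_exactly_five_percent_fails(self):
        g = self._geno_from_counts(90, 10, 0)  # MAF exactly 0.05
        qc = assoc.snp_qc(pd.DataFrame({"s": g}))
        assert qc.iloc[0]["maf"] == pytest.approx(0.05)
        assert not qc.iloc[0]["pass"]

    def test_sparse_homozygotes_pooled(self):
        g = self._geno_from_counts(58, 40, 4)
        qc = assoc.snp_qc(pd.DataFrame({"s": g}))
        row = qc.iloc[0]
        assert row["pass"] and row["merged"] == "minor_hom"
        codes = assoc.pooled_codes(g, row["merged"])
        assert set(codes) == {0.0, 1.0}
        assert (codes == 1).sum() == 44


class TestScan:
    def test_causal_snp_attains_min_p(self, rng):
        n = 120
        geno = pd.DataFrame(
            {f"snp{j:03d}": rng.binomial(2, 0.3, n) for j in range(20)},
            index=[f"s{i}" for i in range(n)],
        )
        y = pd.Series(geno["snp007"].astype(float) + 0.0, index=geno.index)
        pheno = assoc.PhenotypeVector("aei", y + rng.normal(0, 0.01, n), "none", 1, 1)
        qc = assoc.snp_qc(geno)
        table, _, _ = assoc.eqtl_scan(pheno, geno, qc=qc)
        assert table.loc[table["p_nominal"].idxmin(), "snp"] == "snp007"

    def test_null_scan_p_uniform(self):
        rng = np.random.default_rng(8)
        n = 1000
        geno = pd.DataFrame(
            {f"snp{j:03d}": rng.binomial(2, 0.3, n) for j in range(83)},
            index=[f"s{i}" for i in range(n)],
        )
        pheno = assoc.PhenotypeVector(
            "aei", pd.Series(rng.normal(size=n), index=geno.index), "none", 1, 1
        )
        table, _, _ = assoc.eqtl_scan(pheno, geno, qc=assoc.snp_qc(geno))
        assert stats.kstest(table["p_nominal"], "uniform").pvalue > 0.01

    def test_no_passing_snps_empty(self, rng):
        geno = pd.DataFrame({"s1": [0] * 50}, index=[f"s{i}" for i in range(50)])
        pheno = assoc.PhenotypeVector(
            "aei", pd.Series(rng.normal(size=50), index=geno.index), "none", 1, 1
        )
        table, engine, _ = assoc.eqtl_scan(pheno, geno)
        assert len(table) == 0 and engine is None


class TestAdaptivePermutation:
    def test_degenerate_min_p_one(self, rng):
        n = 50
        eng = assoc.ScanEngine({"s": rng.integers(0, 3, n).astype(float)})
        y = rng.normal(size=n)
        res = assoc.adaptive_permutation(eng, y, 1.0, seed=0, target_hits=20)
        assert res.n_perm == 20 and res.corrected_p == 1.0

    def test_single_snp_corrected_matches_nominal(self, rng):
        n = 300
        eng = assoc.ScanEngine({"s": rng.integers(0, 3, n).astype(float)})
        y = rng.normal(size=n)
        nominal = eng.scan(y)[1][0, 0]
        res = assoc.adaptive_permutation(eng, y, nominal, seed=1, target_hits=200, cap=100_000)
        assert abs(res.corrected_p - nominal) / nominal < 0.10

    def test_family_correction_matches_sidak(self, rng):
        n = 300
        geno = {f"s{j}": rng.integers(0, 3, n).astype(float) for j in range(83)}
        eng = assoc.ScanEngine(geno)
        y = rng.normal(size=n)
        min_p = eng.scan(y)[1].min()
        k = 150
        res = assoc.adaptive_permutation(eng, y, float(min_p), seed=2, target_hits=k)
        sidak = 1 - (1 - min_p) ** 83
        mc_sd = sidak * math.sqrt((1 - sidak) / k)
        assert abs(res.corrected_p - sidak) < 4 * mc_sd + 0.02

    def test_cap_returns_flagged_bound(self, rng):
        n = 40
        eng = assoc.ScanEngine({"s": rng.integers(0, 3, n).astype(float)})
        y = rng.normal(size=n)
        res = assoc.adaptive_permutation(eng, y, 1e-12, seed=3, target_hits=20, cap=100)
        assert res.capped and res.n_perm == 100
        assert res.corrected_p == pytest.approx((res.n_hits + 1) / 101)


class TestAeiSnpTest:
    def test_het_shift_detected(self, rng):
        n = 400
        geno = pd.DataFrame(
            {f"snp{j:03d}": rng.integers(0, 3, n) for j in range(10)},
            index=[f"s{i}" for i in range(n)],
        )
        aei = pd.Series(rng.normal(0.05, 0.01, n), index=geno.index)
        aei[geno["snp004"] == 1] += 0.05
        table, _, _ = assoc.aei_snp_test(aei, geno)
        assert table.loc[table["p_nominal"].idxmin(), "snp"] == "snp004"

    def test_monomorphic_het_snp_skipped(self, rng):
        geno = pd.DataFrame({"allhet": [1] * 30}, index=[f"s{i}" for i in range(30)])
        aei = pd.Series(rng.normal(size=30), index=geno.index)
        table, _, _ = assoc.aei_snp_test(aei, geno)
        assert len(table) == 0
        assert table.attrs["skipped"][0]["snp"] == "allhet"
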