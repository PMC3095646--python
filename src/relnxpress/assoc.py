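"""Statistical inference for the expression-genetics analysis.

Covers the whole inferential surface: Shapiro-Wilk normality screening with
log10 transforms, single-covariate confounder screening, diagnosis ANOVA with
sequential (type-I) sums of squares, genotype-by-sex interaction, the exact
conditional Hardy-Weinberg test, SNP QC (HWE and MAF filters plus pooling of
sparse homozygote classes into the heterozygotes), the candidate-region eQTL
scan, family-wise min-P correction by adaptive permutation, and the
heterozygote-vs-homozygote AEI test.

Model fits go through statsmodels OLS/anova_lm; the permutation loop uses a
dedicated least-squares engine (per-SNP QR decompositions reused across
permutations) because re-fitting formula models tens of thousands of times
would dominate the run time.  The two routes are cross-checked in the test
suite.

Sequential SS means confounders are entered first and the term of interest
is tested on what remains — equivalent to regressing out the confounder and
testing the residuals, up to degrees of freedom.  With no confounders it
reduces exactly to the classical one-way ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "PhenotypeVector",
    "AnovaReport",
    "PermutationResult",
    "normality_and_transform",
    "confounder_screen",
    "diagnosis_anova",
    "gxs_interaction",
    "hwe_exact",
    "snp_qc",
    "pooled_codes",
    "ScanEngine",
    "eqtl_scan",
    "adaptive_permutation",
    "aei_snp_test",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "sex", "pmi", "ph", "brain_weight", "age_of_onset")

#: Measures whose raw scale is a proportion or linear fold change; these are
#: log10-transformed before modelling.
LOG_MEASURES = {"total_expression", "relative_expression", "polya_proportion", "microexon_skipping"}


@dataclass
class PhenotypeVector:
    measure: str
    values: pd.Series  # indexed by subject_id, transform already applied
    transform: str  # 'none' | 'log10'
    shapiro_p_raw: float
    shapiro_p: float  # after transform


@dataclass
class AnovaReport:
    term: str
    F: float
    df: int
    p: float
    covariates: tuple[str, ...] = ()


@dataclass
class PermutationResult:
    min_p: float
    n_perm: int
    n_hits: int
    corrected_p: float
    capped: bool
    target_hits: int


def normality_and_transform(
    values: pd.Series, measure: str, transform: str = "auto", floor: float = 1e-4
) -> PhenotypeVector:
    """Shapiro-Wilk screen and the measure's standard normalization.

    Proportion-type measures and linear-scale relative expression get log10
    (with a zero floor); AEI stays on its natural scale.  ``transform`` may
    force 'none' or 'log10'.
    """
    v = pd.Series(values).dropna()
    if len(v) < 3:
        raise ValueError("need >= 3 non-missing values")
    if v.nunique() == 1:
        raise ValueError("degenerate (constant) phenotype")
    p_raw = float(stats.shapiro(v.to_numpy()).pvalue)
    if transform == "auto":
        transform = "log10" if measure in LOG_MEASURES else "none"
    if transform == "log10":
        if (v < 0).any():
            raise ValueError("negative values cannot be log10-transformed")
        out = np.log10(np.maximum(v, floor))
        p_t = float(stats.shapiro(out.to_numpy()).pvalue)
    elif transform == "none":
        out, p_t = v, p_raw
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return PhenotypeVector(measure, out, transform, p_raw, p_t)


def _dummy_block(values: pd.Series) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped) for a factor."""
    levels = sorted(pd.unique(values.dropna()))
    if len(levels) < 2:
        raise ValueError("factor has fewer than 2 levels")
    return np.column_stack([(values == lv).to_numpy(dtype=float) for lv in levels[1:]])


def sequential_anova(y: np.ndarray, blocks: list[tuple[str, np.ndarray]]) -> list[AnovaReport]:
    """Type-I (sequential) ANOVA over ordered column blocks.

    Each block is entered after all preceding ones; the F for a block tests
    its incremental sum of squares against the full-model residual.  The
    design order is exactly the caller's order — no term reordering.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    rss = [float(((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2).sum())]
    dfs = []
    for _, cols in blocks:
        cols = np.atleast_2d(np.asarray(cols, dtype=float))
        if cols.shape[0] != n:
            cols = cols.T
        X = np.column_stack([X, cols])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        rss.append(float((resid**2).sum()))
        dfs.append(cols.shape[1])
    df_resid = n - X.shape[1]
    if df_resid < 1:
        raise ValueError("singular or saturated design: no residual degrees of freedom")
    mse = rss[-1] / df_resid
    out = []
    for i, (name, _) in enumerate(blocks):
        F = ((rss[i] - rss[i + 1]) / dfs[i]) / mse
        out.append(AnovaReport(name, float(F), dfs[i], float(stats.f.sf(F, dfs[i], df_resid))))
    return out


def _frame(pheno: PhenotypeVector, subjects: pd.DataFrame, extra: dict | None = None) -> pd.DataFrame:
    df = subjects.set_index("subject_id").copy()
    df["y"] = pheno.values
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df.dropna(subset=["y"])


def confounder_screen(
    pheno: PhenotypeVector,
    subjects: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Each covariate tested alone against the phenotype; one row per test.

    Categorical covariates (sex) enter as factors.  Returns all covariates
    ordered by P with a ``selected`` flag (P < alpha); the first selected row
    is "the most significant confounding factor".
    """
    df = _frame(pheno, subjects)
    rows = []
    for cov in covariates:
        if cov not in df.columns:
            continue
        sub = df.dropna(subset=[cov])
        if sub[cov].nunique() < 2 or len(sub) < 3:
            continue
        term = f"C({cov})" if sub[cov].dtype == object else cov
        fit = smf.ols(f"y ~ {term}", data=sub).fit()
        an = sm.stats.anova_lm(fit, typ=1)
        rows.append(
            {
                "covariate": cov,
                "F": float(an["F"].iloc[0]),
                "df": int(an["df"].iloc[0]),
                "p": float(an["PR(>F)"].iloc[0]),
                "n": len(sub),
            }
        )
    out = pd.DataFrame(rows).sort_values("p").reset_index(drop=True)
    out["selected"] = out["p"] < alpha
    return out


def _confounder_blocks(df: pd.DataFrame, confounders) -> list[tuple[str, np.ndarray]]:
    blocks = []
    for c in confounders:
        col = df[c]
        blocks.append((c, _dummy_block(col) if col.dtype == object else col.to_numpy(dtype=float)[:, None]))
    return blocks


def _seq_anova(df: pd.DataFrame, factor: pd.Series, term: str, confounders) -> AnovaReport:
    """Sequential-SS ANOVA with confounders entered before the factor."""
    sub = df.dropna(subset=list(confounders)) if confounders else df
    blocks = _confounder_blocks(sub, confounders)
    blocks.append((term, _dummy_block(factor.loc[sub.index])))
    rep = sequential_anova(sub["y"].to_numpy(), blocks)[-1]
    return AnovaReport(term, rep.F, rep.df, rep.p, tuple(confounders))


def diagnosis_anova(
    pheno: PhenotypeVector,
    subjects: pd.DataFrame,
    confounders=(),
    pairwise: bool = True,
) -> list[AnovaReport]:
    """Omnibus 3-group diagnosis ANOVA plus pairwise 2-group contrasts.

    Confounders enter first (sequential SS), diagnosis last.  Pairwise
    contrasts refit on the two-group subset (confounders re-estimated there).
    """
    df = _frame(pheno, subjects)
    groups = [g for g in ("SCZ", "BPD", "CTRL") if g in set(df["diagnosis"])]
    if len(groups) < 2 or any((df["diagnosis"] == g).sum() < 2 for g in groups):
        raise ValueError("need >= 2 diagnosis groups with >= 2 subjects each")
    reports = [_seq_anova(df, df["diagnosis"], "diagnosis", confounders)]
    if pairwise and len(groups) == 3:
        for a, b in (("SCZ", "CTRL"), ("BPD", "CTRL"), ("SCZ", "BPD")):
            sub = df[df["diagnosis"].isin([a, b])]
            rep = _seq_anova(sub, sub["diagnosis"], "diagnosis", confounders)
            reports.append(AnovaReport(f"{a}_vs_{b}", rep.F, rep.df, rep.p, rep.covariates))
    return reports


def gxs_interaction(
    pheno: PhenotypeVector,
    genotype_binary: pd.Series,
    sex: pd.Series,
    subjects: pd.DataFrame,
    confounders=(),
) -> AnovaReport:
    """Genotype-by-sex interaction, sequential SS, interaction entered last.

    ``genotype_binary`` codes GG homozygotes vs A-allele carriers (any two
    labels).  All four genotype x sex cells must be occupied.
    """
    df = _frame(pheno, subjects, extra={"geno": genotype_binary, "sx": sex})
    df = df.dropna(subset=["geno", "sx"])
    cells = df.groupby(["geno", "sx"]).size()
    if df["geno"].nunique() < 2:
        raise ValueError("genotype collapsed to one level")
    if len(cells) < 4 or (cells == 0).any():
        empty = [c for c in cells.index[cells == 0]]
        raise ValueError(f"empty genotype x sex cell(s): {empty or 'missing combinations'}")
    sub = df.dropna(subset=list(confounders)) if confounders else df
    g_dum = _dummy_block(sub["geno"])
    s_dum = _dummy_block(sub["sx"])
    inter = np.column_stack([g_dum[:, i] * s_dum[:, j] for i in range(g_dum.shape[1]) for j in range(s_dum.shape[1])])
    blocks = _confounder_blocks(sub, confounders)
    blocks += [("geno", g_dum), ("sex", s_dum), ("genotype:sex", inter)]
    rep = sequential_anova(sub["y"].to_numpy(), blocks)[-1]
    return AnovaReport("genotype:sex", rep.F, rep.df, rep.p, tuple(confounders))


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test P value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability is at or below the
    observed one (two-sided by probability ordering).
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa < 1:
        raise ValueError("genotype counts must be non-negative with total >= 1")
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_AA + n_Aa  # rarer-allele labelling is irrelevant to the P value
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    homs_a = (n_a - hets) // 2
    homs_b = n - hets - homs_a
    logp = (
        hets * math.log(2.0)
        + gammaln(n + 1)
        - gammaln(homs_a + 1)
        - gammaln(hets + 1)
        - gammaln(homs_b + 1)
    )
    logp = logp - logp.max()
    p = np.exp(logp)
    p = p / p.sum()
    p_obs = p[np.where(hets == n_Aa)[0][0]]
    return float(min(1.0, p[p <= p_obs * (1.0 + 1e-12)].sum()))


def snp_qc(
    genotypes: pd.DataFrame,
    maf_threshold: float = 0.05,
    hwe_alpha: float = 0.05,
    pool_max: int = 5,
) -> pd.DataFrame:
    """Per-SNP QC: MAF, exact HWE P, pass flag, and homozygote pooling.

    pass = (hwe_p >= hwe_alpha / n_snps) and (maf > maf_threshold, strict).
    For passing SNPs, a homozygote class with <= pool_max subjects is pooled
    with the heterozygotes before modelling (recorded in ``merged``).
    """
    n_snps = genotypes.shape[1]
    rows = []
    for snp in genotypes.columns:
        g = genotypes[snp].dropna().astype(int)
        counts = [(g == k).sum() for k in (0, 1, 2)]
        n = sum(counts)
        maf = (counts[1] + 2 * counts[2]) / (2 * n) if n else math.nan
        maf = min(maf, 1 - maf)
        hwe_p = hwe_exact(counts[0], counts[1], counts[2]) if n else math.nan
        ok = (hwe_p >= hwe_alpha / n_snps) and (maf > maf_threshold)
        merged = []
        if ok:
            for k, label in ((0, "major_hom"), (2, "minor_hom")):
                if 0 < counts[k] <= pool_max:
                    merged.append(label)
        rows.append(
            {
                "snp": snp,
                "maf": maf,
                "hwe_p": hwe_p,
                "n_AA": counts[0],
                "n_Aa": counts[1],
                "n_aa": counts[2],
                "merged": "+".join(merged) if merged else "",
                "pass": bool(ok),
            }
        )
    return pd.DataFrame(rows)


def pooled_codes(genotypes: pd.Series, merged: str) -> np.ndarray:
    """Apply the homozygote-pooling rule: pooled classes take the het code 1."""
    g = genotypes.to_numpy(dtype=float)
    out = g.copy()
    if "major_hom" in merged:
        out[g == 0] = 1
    if "minor_hom" in merged:
        out[g == 2] = 1
    return out


class ScanEngine:
    """Batched sequential-SS F tests of a phenotype on many genotype factors.

    For each SNP the design is [1 | confounders | genotype dummies]; the F
    statistic for the genotype block is computed from residual sums of
    squares via pre-factored orthonormal bases, so scanning B permuted
    phenotype vectors is a handful of matrix products per SNP.
    """

    def __init__(self, genotype_codes: dict[str, np.ndarray], confounder: np.ndarray | None = None):
        snps = list(genotype_codes)
        n = len(next(iter(genotype_codes.values())))
        x0 = [np.ones(n)]
        if confounder is not None:
            conf = np.asarray(confounder, dtype=float)
            if conf.ndim == 1:
                conf = conf[:, None]
            if len(conf) != n:
                raise ValueError("confounder length mismatch")
            x0.extend(conf.T)
        X0 = np.column_stack(x0)
        self.n = n
        self.q0 = np.linalg.qr(X0)[0]
        self.k0 = X0.shape[1]
        self.snps: list[str] = []
        self._q: list[np.ndarray] = []
        self._df1: list[int] = []
        self._df2: list[int] = []
        self.untestable: list[str] = []
        for snp in snps:
            codes = np.asarray(genotype_codes[snp])
            levels = np.unique(codes)
            if len(levels) < 2:
                self.untestable.append(snp)
                continue
            dummies = np.column_stack([(codes == lv).astype(float) for lv in levels[1:]])
            X = np.column_stack([X0, dummies])
            q = np.linalg.qr(X)[0]
            self.snps.append(snp)
            self._q.append(q)
            self._df1.append(len(levels) - 1)
            self._df2.append(n - X.shape[1])

    def scan(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Y: (n,) or (n, B) phenotype matrix -> (F, P), each (n_snps, B)."""
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        tot = (Y**2).sum(axis=0)
        rss0 = tot - ((self.q0.T @ Y) ** 2).sum(axis=0)
        F = np.empty((len(self.snps), Y.shape[1]))
        P = np.empty_like(F)
        for i, q in enumerate(self._q):
            rss1 = tot - ((q.T @ Y) ** 2).sum(axis=0)
            rss1 = np.maximum(rss1, 1e-300)
            df1, df2 = self._df1[i], self._df2[i]
            F[i] = ((rss0 - rss1) / df1) / (rss1 / df2)
            P[i] = stats.f.sf(F[i], df1, df2)
        return F, P

    def min_p(self, Y: np.ndarray) -> np.ndarray:
        return self.scan(Y)[1].min(axis=0)


def eqtl_scan(
    pheno: PhenotypeVector,
    genotypes: pd.DataFrame,
    qc: pd.DataFrame | None = None,
    confounder: pd.Series | None = None,
) -> tuple[pd.DataFrame, ScanEngine, np.ndarray]:
    """Per-SNP ANOVA of the phenotype on genotype (post-pooling).

    Only QC-passing SNPs are scanned (``qc`` defaults to :func:`snp_qc` on
    the matrix).  Returns the result table (snp, F, df, p_nominal), the
    fitted engine (reused for permutations), and the aligned phenotype array.
    An empty table (with a warning column) results if no SNP passes.
    """
    if qc is None:
        qc = snp_qc(genotypes)
    passing = qc[qc["pass"]]
    y = pheno.values.dropna()
    idx = y.index.intersection(genotypes.index)
    y = y.loc[idx]
    conf = None
    if confounder is not None:
        conf = pd.Series(confounder).loc[idx]
        keep = conf.notna() & y.notna()
        y, conf = y[keep], conf[keep]
        idx = y.index
        conf = conf.to_numpy(dtype=float)
    codes = {
        row["snp"]: pooled_codes(genotypes.loc[idx, row["snp"]], row["merged"])
        for _, row in passing.iterrows()
    }
    if not codes:
        return pd.DataFrame(columns=["snp", "F", "df", "p_nominal"]), None, y.to_numpy()
    engine = ScanEngine(codes, conf)
    F, P = engine.scan(y.to_numpy())
    table = pd.DataFrame(
        {"snp": engine.snps, "F": F[:, 0], "df": engine._df1, "p_nominal": P[:, 0]}
    )
    return table, engine, y.to_numpy()


def adaptive_permutation(
    engine: ScanEngine,
    y: np.ndarray,
    min_p_observed: float,
    seed,
    target_hits: int = 20,
    cap: int = 100_000,
    batch: int = 256,
) -> PermutationResult:
    """Family-wise min-P correction with adaptive stopping.

    Permutes the phenotype across subjects (genotypes and confounders fixed),
    records each permutation's minimum nominal P over the SNP family, and
    stops once ``target_hits`` permutation minima are <= the observed minimum
    (ties count).  Corrected P = target_hits / n_perm at stopping; if the cap
    is reached first, the (hits+1)/(n_perm+1) upper-bound estimator is
    returned with ``capped=True``.
    """
    if not math.isfinite(min_p_observed):
        raise ValueError("observed min P must be finite")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    thresh = min_p_observed * (1.0 + 1e-12)
    hits = 0
    done = 0
    while done < cap:
        b = min(batch, cap - done)
        Y = np.empty((len(y), b))
        for j in range(b):
            Y[:, j] = rng.permutation(y)
        minp = engine.min_p(Y)
        is_hit = minp <= thresh
        cum = hits + np.cumsum(is_hit)
        reach = np.nonzero(cum >= target_hits)[0]
        if reach.size:
            n_perm = done + int(reach[0]) + 1
            return PermutationResult(min_p_observed, n_perm, target_hits, target_hits / n_perm, False, target_hits)
        hits = int(cum[-1])
        done += b
    return PermutationResult(min_p_observed, done, hits, (hits + 1) / (done + 1), True, target_hits)


def aei_snp_test(
    aei: pd.Series,
    genotypes: pd.DataFrame,
    min_group: int = 2,
) -> tuple[pd.DataFrame, ScanEngine, np.ndarray]:
    """Heterozygote vs pooled-homozygote comparison of AEI per SNP.

    For each SNP the two homozygote classes are combined and AEI is compared
    between heterozygotes and homozygotes by one-way ANOVA (df = 1).  SNPs
    with fewer than ``min_group`` subjects in either class are skipped with
    a reason.  Returns (table, engine for permutations, aligned AEI values).
    """
    y = pd.Series(aei).dropna()
    idx = y.index.intersection(genotypes.index)
    y = y.loc[idx]
    codes = {}
    skipped = []
    for snp in genotypes.columns:
        het = (genotypes.loc[idx, snp] == 1).to_numpy().astype(float)
        n_het, n_hom = int(het.sum()), int(len(het) - het.sum())
        if n_het < min_group or n_hom < min_group:
            skipped.append({"snp": snp, "reason": f"het={n_het},hom={n_hom}"})
            continue
        codes[snp] = het
    if not codes:
        table = pd.DataFrame(columns=["snp", "F", "df", "p_nominal"])
        table.attrs["skipped"] = skipped
        return table, None, y.to_numpy()
    engine = ScanEngine(codes)
    F, P = engine.scan(y.to_numpy())
    table = pd.DataFrame({"snp": engine.snps, "F": F[:, 0], "df": engine._df1, "p_nominal": P[:, 0]})
    table.attrs["skipped"] = skipped
    return table, engine, y.to_numpy()
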