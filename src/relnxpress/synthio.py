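"""Synthetic study-input generator.

Emits every table the analysis consumes — subject covariates, triplicate qPCR
Ct values, capillary peak-height pairs for the microexon assay, two-channel
allele-specific bead intensities, a candidate-region genotype matrix, and
restriction-fragment / repeat-fragment tables — with the statistical structure
the downstream statistics assume: a three-group diagnosis design, pH and PMI
covariate effects on isoform proportions, Hardy-Weinberg genotypes, an
intensity-dependent allelic-proportion bias, and per-assay measurement noise.

The generator works in two layers.  ``generate_expression`` draws *latent*
per-subject quantities (total expression on the log2 scale, true isoform
proportions, true allelic deviation) — the "truth table".
``render_measurements`` then turns truths into noisy instrument readouts.
Setting every SD and effect to zero makes the rendered measurements invert
exactly to the configured means, which is what the recovery tests exploit.

Everything is driven by :class:`numpy.random.Generator`; a single integer
seed is spawned into independent child streams so adding a table never
perturbs another table's draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig, ConfigError, ExpressionModel, GenotypeModel

__all__ = [
    "ASSAYS",
    "CT_BASELINE",
    "TRUE_EFFICIENCY",
    "SyntheticBundle",
    "generate_cohort",
    "generate_genotypes",
    "generate_expression",
    "render_measurements",
    "render_fragments",
    "make_oligo_dilution_series",
    "make_qpcr_dilution_series",
    "write_vcf",
    "read_vcf",
    "generate_bundle",
]

ASSAYS = ("RELN_total", "CHL1", "POLYA")
#: Amplification efficiencies used when rendering the qPCR dilution series.
TRUE_EFFICIENCY = {"RELN_total": 0.99, "CHL1": 0.95, "POLYA": 0.95}
#: Reference-gene baseline Ct; arbitrary, cancels in every delta-Ct.
CT_BASELINE = 25.0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_cohort(config: CohortConfig, seed=None) -> pd.DataFrame:
    """Draw the subjects table: one row per brain donor.

    Columns: subject_id, diagnosis (SCZ/BPD/CTRL), sex (M/F), age, pmi, ph,
    brain_weight, age_of_onset (NaN for controls).  Deterministic for a fixed
    seed; group counts match the config exactly.
    """
    rng = _rng(config.seed if seed is None else seed)
    n = config.n_total
    diagnosis = np.repeat(["SCZ", "BPD", "CTRL"], [config.n_scz, config.n_bpd, config.n_ctrl])
    sex = np.where(rng.random(n) < config.male_fraction, "M", "F")
    age = rng.normal(config.age_mean, config.age_sd, n)
    pmi = np.clip(rng.normal(config.pmi_mean, config.pmi_sd, n), 1.0, None)
    ph = rng.normal(config.ph_mean, config.ph_sd, n)
    weight = rng.normal(config.brain_weight_mean, config.brain_weight_sd, n)
    onset = age - rng.uniform(10.0, 30.0, n)
    onset[diagnosis == "CTRL"] = np.nan
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "diagnosis": diagnosis,
            "sex": sex,
            "age": np.round(age, 1),
            "pmi": np.round(pmi, 1),
            "ph": np.round(ph, 3),
            "brain_weight": np.round(weight, 0),
            "age_of_onset": np.round(onset, 1),
        }
    )


def _hwe_genotypes(rng: np.random.Generator, n: int, maf: float) -> np.ndarray:
    """0/1/2 copies of the minor allele, two independent allele draws."""
    return (rng.random((n, 2)) < maf).sum(axis=1)


def generate_genotypes(
    subjects: pd.DataFrame, model: GenotypeModel, seed=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region-SNP genotype matrix plus GGC repeat-allele table.

    The genotype matrix is indexed by subject_id with one column per marker,
    values 0/1/2 copies of the minor allele.  rs7341475 is coded as copies of
    the A allele (minor at the default G frequency 0.80); rs2229864 as copies
    of its minor allele.  GGC genotypes are unordered repeat-count pairs.
    """
    if len(subjects) == 0:
        raise ConfigError("subjects table is empty")
    rng = _rng(seed)
    n = len(subjects)
    data: dict[str, np.ndarray] = {}
    mafs = rng.uniform(*model.maf_range, model.n_region_snps)
    for j, maf in enumerate(mafs):
        data[f"snp{j + 1:03d}"] = _hwe_genotypes(rng, n, maf)
    data["rs7341475"] = _hwe_genotypes(rng, n, 1.0 - model.rs7341475_g_freq)
    data["rs2229864"] = _hwe_genotypes(rng, n, model.rs2229864_maf)
    geno = pd.DataFrame(data, index=pd.Index(subjects["subject_id"], name="subject_id"))

    repeats = np.array(sorted(model.ggc_allele_freqs))
    freqs = np.array([model.ggc_allele_freqs[r] for r in repeats], dtype=float)
    freqs = freqs / freqs.sum()  # guard rounding; validated to 1e-9 upstream
    pairs = rng.choice(repeats, size=(n, 2), p=freqs)
    pairs.sort(axis=1)
    ggc = pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "allele1": pairs[:, 0],
            "allele2": pairs[:, 1],
        }
    )
    return geno, ggc


def _clip_open(p: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def generate_expression(
    subjects: pd.DataFrame,
    genotypes: pd.DataFrame,
    model: ExpressionModel,
    seed=None,
) -> pd.DataFrame:
    """Draw latent per-subject expression truths.

    polyA proportion = diagnosis mean + PMI slope * (PMI - mean PMI) + noise;
    microexon skipping = sex x rs7341475 cell mean + pH slope * (pH - mean pH)
    + noise; allelic deviation is a signed half-normal, shifted upward in
    schizophrenia, defined only for rs2229864 heterozygotes.  With
    ``model.logit_scale`` the Gaussian noise is added on the logit scale
    instead of the linear one.  Proportions are clipped to the open interval
    (1e-4, 1 - 1e-4).
    """
    rng = _rng(seed)
    n = len(subjects)
    geno = genotypes.loc[subjects["subject_id"]]
    diag = subjects["diagnosis"].to_numpy()
    sex = subjects["sex"].to_numpy()

    total = rng.normal(0.0, model.total_expr_log2_sd, n)

    polya_mean = np.array([model.polya_mean_by_group[d] for d in diag])
    pmi = subjects["pmi"].to_numpy(dtype=float)
    polya_shift = model.pmi_effect_on_polya * (pmi - pmi.mean())

    if model.use_gxs_cells:
        carrier = np.where(geno["rs7341475"].to_numpy() > 0, "A", "GG")
        skip_mean = np.array([model.gxs_skipping_means[(s, c)] for s, c in zip(sex, carrier)])
    else:
        skip_mean = np.full(n, 1.0 - model.retention_mean)
    ph = subjects["ph"].to_numpy(dtype=float)
    skip_shift = model.ph_effect_on_skipping * (ph - ph.mean())

    if model.logit_scale:
        def noisy(mean, shift, sd):
            lo = np.log(mean / (1 - mean)) + rng.normal(0.0, sd / (mean * (1 - mean)), n)
            p = 1.0 / (1.0 + np.exp(-lo))
            return _clip_open(p + shift)
    else:
        def noisy(mean, shift, sd):
            return _clip_open(mean + shift + rng.normal(0.0, sd, n))

    polya = noisy(polya_mean, polya_shift, model.polya_sd)
    skipping = noisy(skip_mean, skip_shift, model.retention_sd)

    het = geno["rs2229864"].to_numpy() == 1
    shift = np.where(diag == "SCZ", model.aei_shift_scz, 0.0)
    dev_mag = np.abs(rng.normal(shift, model.aei_base_sd, n))
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    aei_dev = np.where(het, sign * dev_mag, np.nan)
    aei_dev = np.where(het, np.clip(aei_dev, -0.49, 0.49), np.nan)

    return pd.DataFrame(
        {
            "subject_id": subjects["subject_id"].to_numpy(),
            "diagnosis": diag,
            "sex": sex,
            "total_expr_log2": total,
            "polya_true": polya,
            "skipping_true": skipping,
            "retention_true": 1.0 - skipping,
            "rs2229864_copies": geno["rs2229864"].to_numpy(),
            "aei_dev_true": aei_dev,
        }
    )


def make_oligo_dilution_series(
    grid=None,
    replicates: int = 3,
    cv: float = 0.03,
    total_height: float = 5000.0,
    seed=None,
) -> pd.DataFrame:
    """Two-synthetic-oligo mixing series for the capillary-assay validation.

    Long (microexon-retained analogue) and short oligos are mixed at known
    short fractions across ``grid`` (default 0, 0.1, ..., 1.0) and read as
    triplicate peak pairs with multiplicative lognormal noise of the given CV.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.1), 10)
    rng = _rng(seed)
    rows = []
    sigma = np.sqrt(np.log1p(cv**2))
    for expected in grid:
        for rep in range(1, replicates + 1):
            noise = np.exp(rng.normal(0.0, sigma, 2)) if cv > 0 else np.ones(2)
            rows.append(
                {
                    "expected_proportion": float(expected),
                    "replicate": rep,
                    "height_retained": (1.0 - expected) * total_height * noise[0],
                    "height_skipped": expected * total_height * noise[1],
                }
            )
    return pd.DataFrame(rows)


def make_qpcr_dilution_series(
    efficiencies=None,
    n_points: int = 6,
    step: float = -0.5,
    ct_noise_sd: float = 0.0,
    seed=None,
) -> pd.DataFrame:
    """Six-point qPCR standard curve per assay.

    Ct = baseline + slope * log10(dilution) with slope = -1/log10(1+E), so a
    regression of Ct on log10 dilution recovers each assay's efficiency.
    """
    if efficiencies is None:
        efficiencies = TRUE_EFFICIENCY
    rng = _rng(seed)
    dil = np.arange(n_points) * step  # log10 relative concentration, 0 down
    rows = []
    for assay, eff in efficiencies.items():
        slope = -1.0 / np.log10(1.0 + eff)
        for x in dil:
            ct = CT_BASELINE + slope * x
            reps = ct + rng.normal(0.0, ct_noise_sd, 3)
            rows.append(
                {
                    "assay": assay,
                    "log10_dilution": float(x),
                    "rep1": reps[0],
                    "rep2": reps[1],
                    "rep3": reps[2],
                }
            )
    return pd.DataFrame(rows)


def render_measurements(
    truth: pd.DataFrame, model: ExpressionModel, seed=None
) -> dict[str, pd.DataFrame]:
    """Instrument readouts from latent truths.

    Returns a dict with keys ``ct`` (triplicate threshold cycles per subject
    and assay), ``peaks`` (triplicate capillary peak pairs), ``allele_signals``
    (two-channel bead intensities, gDNA and six cDNA replicates), and the two
    dilution series (``dilution_oligo``, ``dilution_qpcr``).

    Ct rendering: Ct = 25 - log2(relative quantity) + N(0, ct_noise_sd); the
    polyA assay quantity is total x polyA fraction so that
    2^(Ct_total - Ct_polyA) inverts to the latent fraction.  Allele signals:
    measured T fraction = true fraction + bias_slope x (log10 intensity -
    reference) + noise, split over the two channels.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    r_ct, r_peak, r_sig, r_dil1, r_dil2 = [np.random.default_rng(s) for s in ss.spawn(5)]
    n = len(truth)
    sid = truth["subject_id"].to_numpy()

    quantity_log2 = {
        "RELN_total": truth["total_expr_log2"].to_numpy(),
        "CHL1": np.zeros(n),
        "POLYA": truth["total_expr_log2"].to_numpy() + np.log2(truth["polya_true"].to_numpy()),
    }
    ct_rows = []
    for assay in ASSAYS:
        base = CT_BASELINE - quantity_log2[assay]
        reps = base[:, None] + r_ct.normal(0.0, model.ct_noise_sd, (n, 3))
        for i in range(n):
            ct_rows.append(
                {"subject_id": sid[i], "assay": assay, "rep1": reps[i, 0], "rep2": reps[i, 1], "rep3": reps[i, 2]}
            )
    ct = pd.DataFrame(ct_rows)

    sigma = np.sqrt(np.log1p(model.peak_noise_cv**2))
    skip = truth["skipping_true"].to_numpy()
    peak_rows = []
    for rep in range(1, 4):
        total = 10000.0 * np.exp(r_peak.normal(0.0, 0.2, n))
        nz_r = np.exp(r_peak.normal(0.0, sigma, n)) if sigma > 0 else np.ones(n)
        nz_s = np.exp(r_peak.normal(0.0, sigma, n)) if sigma > 0 else np.ones(n)
        for i in range(n):
            peak_rows.append(
                {
                    "subject_id": sid[i],
                    "tissue": "DLPFC",
                    "replicate": rep,
                    "height_retained": (1.0 - skip[i]) * total[i] * nz_r[i],
                    "height_skipped": skip[i] * total[i] * nz_s[i],
                }
            )
    peaks = pd.DataFrame(peak_rows)

    sig_rows = []
    copies = truth["rs2229864_copies"].to_numpy()
    dev = truth["aei_dev_true"].to_numpy()
    for material, n_rep in (("gDNA", model.gdna_replicates), ("cDNA", model.cdna_replicates)):
        for rep in range(1, n_rep + 1):
            log_i = r_sig.normal(model.intensity_log_mean, model.intensity_log_sd, n)
            intensity = 10.0**log_i
            p_true = np.where(copies == 1, 0.5, np.where(copies == 2, 1.0, 0.0))
            if material == "cDNA":
                p_true = np.where(copies == 1, 0.5 + np.nan_to_num(dev), p_true)
            p_meas = p_true + model.bias_slope * (log_i - model.intensity_ref)
            p_meas = p_meas + r_sig.normal(0.0, model.aspe_noise_sd, n)
            p_meas = np.clip(p_meas, 0.0, 1.0)
            for i in range(n):
                sig_rows.append(
                    {
                        "sample_id": sid[i],
                        "material": material,
                        "replicate": rep,
                        "signal_T": intensity[i] * p_meas[i],
                        "signal_C": intensity[i] * (1.0 - p_meas[i]),
                        "total_intensity": intensity[i],
                    }
                )
    signals = pd.DataFrame(sig_rows)

    return {
        "ct": ct,
        "peaks": peaks,
        "allele_signals": signals,
        "dilution_oligo": make_oligo_dilution_series(cv=model.peak_noise_cv, seed=r_dil1),
        "dilution_qpcr": make_qpcr_dilution_series(ct_noise_sd=model.ct_noise_sd / 10.0, seed=r_dil2),
    }


_RFLP_FRAGMENTS = {0: (233, 188), 2: (233, 158, 30), 1: (233, 188, 158, 30)}


def render_fragments(
    genotypes: pd.DataFrame, ggc: pd.DataFrame, model: GenotypeModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fragment-size tables for the RFLP and GGC-repeat assays.

    rs7341475 ApoI digestion yields 233+188 bp for the G allele and
    233+158+30 bp for the A allele; GGC fragments are base_size + 3 x repeats.
    Sizes are rendered exactly (no sizing jitter): jitter tolerance belongs to
    the caller, round-trip concordance to the generator.
    """
    rflp_rows = []
    for sid, copies in genotypes["rs7341475"].items():
        sizes = _RFLP_FRAGMENTS[int(copies)]
        rflp_rows.append(
            {"sample_id": sid, "assay": "rs7341475_rflp", "fragment_sizes": ";".join(str(s) for s in sizes)}
        )
    ggc_rows = []
    for _, row in ggc.iterrows():
        sizes = sorted({model.ggc_base_size + 3 * int(row["allele1"]), model.ggc_base_size + 3 * int(row["allele2"])})
        ggc_rows.append(
            {
                "sample_id": row["subject_id"],
                "assay": "ggc_repeat",
                "fragment_sizes": ";".join(f"{s:g}" for s in sizes),
            }
        )
    return pd.DataFrame(rflp_rows), pd.DataFrame(ggc_rows)


def write_vcf(genotypes: pd.DataFrame, path) -> None:
    """Minimal VCF v4.2 export of a 0/1/2 genotype matrix (GT field only).

    Markers become unplaced records (CHROM '7', dummy positions, REF/ALT
    'A'/'B'); only the dosage information survives a round trip.
    """
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.index),
    ]
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    for pos, snp in enumerate(genotypes.columns, start=1):
        calls = "\t".join(gt_code[int(c)] for c in genotypes[snp])
        lines.append(f"7\t{pos}\t{snp}\tA\tB\t.\t.\t.\tGT\t{calls}")
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a GT-only VCF back into the subject x SNP 0/1/2 matrix."""
    samples: list[str] = []
    data: dict[str, list[int]] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("##") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if line.startswith("#CHROM"):
            samples = fields[9:]
            continue
        snp = fields[2]
        data[snp] = [sum(int(a) for a in gt.replace("|", "/").split("/")) for gt in fields[9:]]
    return pd.DataFrame(data, index=pd.Index(samples, name="subject_id"))


@dataclass
class SyntheticBundle:
    """All generated tables for one synthetic study, plus the truth table."""

    subjects: pd.DataFrame
    genotypes: pd.DataFrame
    ggc: pd.DataFrame
    truth: pd.DataFrame
    ct: pd.DataFrame
    peaks: pd.DataFrame
    allele_signals: pd.DataFrame
    rflp_fragments: pd.DataFrame
    ggc_fragments: pd.DataFrame
    dilution_oligo: pd.DataFrame
    dilution_qpcr: pd.DataFrame

    _FILES = {
        "subjects": "subjects.tsv",
        "genotypes": "genotypes.tsv",
        "ggc": "ggc_genotypes.tsv",
        "truth": "truth.tsv",
        "ct": "ct.tsv",
        "peaks": "peaks.tsv",
        "allele_signals": "allele_signals.tsv",
        "rflp_fragments": "rflp_fragments.tsv",
        "ggc_fragments": "ggc_fragments.tsv",
        "dilution_oligo": "dilution_oligo.tsv",
        "dilution_qpcr": "dilution_qpcr.tsv",
    }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._FILES.items():
            df = getattr(self, attr)
            df.to_csv(outdir / fname, sep="\t", index=attr == "genotypes", float_format="%.8g")

    @classmethod
    def read(cls, indir) -> "SyntheticBundle":
        indir = Path(indir)
        kwargs = {}
        for attr, fname in cls._FILES.items():
            path = indir / fname
            if not path.exists():
                raise FileNotFoundError(f"missing bundle file: {path}")
            kwargs[attr] = pd.read_csv(path, sep="\t", index_col=0 if attr == "genotypes" else None)
        return cls(**kwargs)


def generate_bundle(
    cohort: CohortConfig | None = None,
    expression: ExpressionModel | None = None,
    genotype: GenotypeModel | None = None,
    seed: int | None = 0,
) -> SyntheticBundle:
    """One-call generation of a complete synthetic study."""
    cohort = cohort or CohortConfig()
    expression = expression or ExpressionModel()
    genotype = genotype or GenotypeModel()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_cohort, s_geno, s_expr, s_meas = ss.spawn(4)
    subjects = generate_cohort(cohort, seed=np.random.default_rng(s_cohort))
    genotypes, ggc = generate_genotypes(subjects, genotype, seed=np.random.default_rng(s_geno))
    truth = generate_expression(subjects, genotypes, expression, seed=np.random.default_rng(s_expr))
    measured = render_measurements(truth, expression, seed=s_meas)
    rflp, ggc_frag = render_fragments(genotypes, ggc, genotype)
    return SyntheticBundle(
        subjects=subjects,
        genotypes=genotypes,
        ggc=ggc,
        truth=truth,
        ct=measured["ct"],
        peaks=measured["peaks"],
        allele_signals=measured["allele_signals"],
        rflp_fragments=rflp,
        ggc_fragments=ggc_frag,
        dilution_oligo=measured["dilution_oligo"],
        dilution_qpcr=measured["dilution_qpcr"],
    )
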