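"""Allelic-expression imbalance (AEI) from two-channel bead intensities.

In a heterozygote the two alleles of a gene should contribute equally to the
mRNA pool; a *cis*-acting variant (or imprinting defect) on one haplotype
shows up as a departure of the measured T-allele fraction in cDNA from the
balanced expectation.  Bead assays carry a systematic intensity-dependent
shift in the measured allele fraction, so the balanced expectation is not
exactly 0.5: it is calibrated by regressing the T fraction in genomic DNA
(where every heterozygote truly is 50/50) on signal intensity, and evaluating
that line at each cDNA sample's intensity.

The AEI statistic is |observed - expected| T fraction.  For display, the
calibration-corrected fraction p* = observed - (expected - 0.5) is converted
to a major/minor allelic ratio max(p*, 1-p*)/min(p*, 1-p*), classified at
the conventional 1.2 and 1.4 cut-offs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Calibration",
    "AEIResult",
    "t_proportion",
    "fit_calibration",
    "aei_statistic",
    "classify_ratio",
    "run_aei",
    "group_aei_summary",
]

RATIO_CUTS = (1.2, 1.4)


@dataclass
class Calibration:
    """Linear model of gDNA-heterozygote T fraction on intensity."""

    slope: float
    intercept: float
    n_points: int
    intensity_scale: str = "log10"  # or "linear"

    def expected_p(self, intensity: float) -> float:
        x = math.log10(intensity) if self.intensity_scale == "log10" else intensity
        return self.intercept + self.slope * x


@dataclass
class AEIResult:
    sample_id: str
    observed_p: float
    expected_p: float
    aei: float
    corrected_p: float
    allelic_ratio: float
    ratio_class: str
    n_replicates: int


def t_proportion(signal_T: float, signal_C: float) -> tuple[float, float]:
    """(T fraction, total intensity); NaN fraction when both channels are 0."""
    if signal_T < 0 or signal_C < 0:
        raise ValueError("signals must be non-negative")
    total = signal_T + signal_C
    if total == 0:
        return math.nan, 0.0
    return signal_T / total, total


def fit_calibration(
    signals: pd.DataFrame,
    het_sample_ids,
    intensity_scale: str = "log10",
) -> Calibration:
    """OLS of gDNA-heterozygote T fraction on (log10) total intensity.

    ``signals`` is the long allele-signal table; only rows with
    material == 'gDNA' and sample_id in ``het_sample_ids`` enter the fit.
    Requires >= 3 points with non-constant intensity.
    """
    het = set(het_sample_ids)
    g = signals[(signals["material"] == "gDNA") & (signals["sample_id"].isin(het))]
    if len(g) < 3:
        raise ValueError(f"need >= 3 gDNA heterozygote measurements, got {len(g)}")
    pt = [t_proportion(t, c) for t, c in zip(g["signal_T"], g["signal_C"])]
    p = np.array([v[0] for v in pt])
    inten = np.array([v[1] for v in pt])
    x = np.log10(inten) if intensity_scale == "log10" else inten
    if np.ptp(x) == 0:
        raise ValueError("constant intensity: calibration not identifiable")
    fit = stats.linregress(x, p)
    return Calibration(float(fit.slope), float(fit.intercept), len(g), intensity_scale)


def classify_ratio(ratio: float, cuts: tuple[float, float] = RATIO_CUTS) -> str:
    """Strict-threshold class label: below_1.2 / 1.2_to_1.4 / above_1.4."""
    lo, hi = cuts
    if ratio > hi:
        return f"above_{hi:g}"
    if ratio > lo:
        return f"{lo:g}_to_{hi:g}"
    return f"below_{lo:g}"


def aei_statistic(cdna: pd.DataFrame, calibration: Calibration, sample_id: str = "") -> AEIResult:
    """AEI for one heterozygous sample from its cDNA replicates.

    observed_p = mean replicate T fraction; expected_p = calibration line at
    the mean replicate intensity; aei = |observed - expected|; the allelic
    ratio derives from the corrected fraction p* = observed - (expected - 0.5).
    """
    if len(cdna) < 1:
        raise ValueError("need >= 1 cDNA replicate")
    pt = [t_proportion(t, c) for t, c in zip(cdna["signal_T"], cdna["signal_C"])]
    p = np.array([v[0] for v in pt])
    inten = np.array([v[1] for v in pt])
    ok = np.isfinite(p)
    p, inten = p[ok], inten[ok]
    if p.size == 0:
        return AEIResult(sample_id, math.nan, math.nan, math.nan, math.nan, math.nan, "no_data", 0)
    observed = float(np.mean(p))
    x = np.log10(inten) if calibration.intensity_scale == "log10" else inten
    expected = calibration.intercept + calibration.slope * float(np.mean(x))
    aei = abs(observed - expected)
    p_star = min(max(observed - (expected - 0.5), 1e-6), 1 - 1e-6)
    ratio = max(p_star, 1 - p_star) / min(p_star, 1 - p_star)
    return AEIResult(sample_id, observed, expected, aei, p_star, ratio, classify_ratio(ratio), int(p.size))


def run_aei(
    signals: pd.DataFrame,
    rs2229864_copies: pd.Series,
    subjects: pd.DataFrame | None = None,
    calibration: Calibration | None = None,
    intensity_scale: str = "log10",
) -> tuple[pd.DataFrame, Calibration]:
    """Full AEI stage over a cohort.

    Heterozygotes at rs2229864 (copies == 1) are informative; homozygotes are
    excluded.  The calibration is fitted on all available gDNA heterozygote
    replicates unless one is supplied.  Returns the per-sample AEI table
    (with diagnosis merged in when ``subjects`` is given) and the calibration.
    """
    het_ids = rs2229864_copies[rs2229864_copies == 1].index
    if calibration is None:
        calibration = fit_calibration(signals, het_ids, intensity_scale)
    rows = []
    cdna = signals[signals["material"] == "cDNA"]
    for sid, grp in cdna.groupby("sample_id", sort=False):
        if sid not in set(het_ids):
            continue  # homozygote: not informative
        res = aei_statistic(grp, calibration, sample_id=sid)
        rows.append(
            {
                "sample_id": sid,
                "observed_p": res.observed_p,
                "expected_p": res.expected_p,
                "aei": res.aei,
                "corrected_p": res.corrected_p,
                "allelic_ratio": res.allelic_ratio,
                "ratio_class": res.ratio_class,
                "n_replicates": res.n_replicates,
            }
        )
    aei_df = pd.DataFrame(rows)
    if subjects is not None and len(aei_df):
        aei_df = aei_df.merge(
            subjects[["subject_id", "diagnosis"]],
            left_on="sample_id",
            right_on="subject_id",
            how="left",
        ).drop(columns="subject_id")
    return aei_df, calibration


def group_aei_summary(aei_df: pd.DataFrame, cuts: tuple[float, float] = RATIO_CUTS) -> pd.DataFrame:
    """Per-diagnosis AEI summary: n, mean ratio, counts/fractions above cuts."""
    if "diagnosis" not in aei_df.columns:
        raise ValueError("aei table lacks a diagnosis column")
    lo, hi = cuts
    rows = []
    for diag, grp in aei_df.groupby("diagnosis"):
        n = len(grp)
        if n == 0:
            continue
        above_lo = int((grp["allelic_ratio"] > lo).sum())
        above_hi = int((grp["allelic_ratio"] > hi).sum())
        rows.append(
            {
                "diagnosis": diag,
                "n": n,
                "mean_ratio": float(grp["allelic_ratio"].mean()),
                f"n_above_{lo:g}": above_lo,
                f"frac_above_{lo:g}": above_lo / n,
                f"n_above_{hi:g}": above_hi,
                f"frac_above_{hi:g}": above_hi / n,
            }
        )
    return pd.DataFrame(rows)
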