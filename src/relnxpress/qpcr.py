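"""Relative expression and isoform proportions from qPCR threshold cycles.

The comparative-Ct (delta-delta-Ct) framework: the difference in threshold
cycle between two assays on the same cDNA is the log2 ratio of their starting
quantities when both amplify with efficiency 1 (perfect doubling).  Relative
RELN expression is taken against the CHL1 reference gene; the proportion of
the short, alternatively polyadenylated transcript is 2^(Ct_total - Ct_polyA).
Amplification efficiency E is estimated from a dilution standard curve via the
slope of Ct on log10 dilution (E = 10^(-1/slope) - 1) and can optionally
replace the factor-2 assumption: linear value = (1+E)^(-delta Ct).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtSummary",
    "EfficiencyEstimate",
    "DeltaCt",
    "summarize_ct",
    "summarize_ct_table",
    "efficiency_from_dilution",
    "efficiencies_from_table",
    "relative_expression",
    "polya_proportion",
    "quantify",
]

#: Replicate-SD QC threshold in cycles (conventional qPCR practice).
DEFAULT_QC_SD = 0.5


@dataclass
class CtSummary:
    mean_ct: float
    sd_ct: float
    n: int
    qc_pass: bool


@dataclass
class EfficiencyEstimate:
    assay: str
    slope: float
    efficiency: float
    r_squared: float


@dataclass
class DeltaCt:
    delta_ct: float
    linear_value: float


def summarize_ct(replicates, qc_sd_threshold: float = DEFAULT_QC_SD) -> CtSummary:
    """Triplicate (or more) Ct values -> mean, SD, and a QC flag.

    Fewer than 2 finite replicates yields a missing summary (NaN mean,
    qc_pass False).  A replicate SD above the threshold flags the record but
    keeps it.
    """
    vals = np.asarray(list(replicates), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        return CtSummary(math.nan, math.nan, int(vals.size), False)
    if np.any(vals <= 0):
        raise ValueError("Ct values must be positive")
    sd = float(np.std(vals, ddof=1))
    return CtSummary(float(np.mean(vals)), sd, int(vals.size), sd <= qc_sd_threshold)


def summarize_ct_table(ct: pd.DataFrame, qc_sd_threshold: float = DEFAULT_QC_SD) -> pd.DataFrame:
    """Per (subject, assay) Ct summary from a table with rep1..repK columns."""
    rep_cols = [c for c in ct.columns if c.startswith("rep")]
    rows = []
    for _, row in ct.iterrows():
        s = summarize_ct(row[rep_cols].to_numpy(dtype=float), qc_sd_threshold)
        rows.append(
            {
                "subject_id": row["subject_id"],
                "assay": row["assay"],
                "mean_ct": s.mean_ct,
                "sd_ct": s.sd_ct,
                "n_reps": s.n,
                "qc_pass": s.qc_pass,
            }
        )
    return pd.DataFrame(rows)


def efficiency_from_dilution(series, assay: str = "") -> EfficiencyEstimate:
    """OLS of mean Ct on log10 dilution -> amplification efficiency.

    ``series`` is an iterable of (log10_dilution, mean_ct) pairs; at least 3
    distinct dilutions are required.  E = 10^(-1/slope) - 1; a perfect
    doubling assay has slope -1/log10(2) ~ -3.32 and E = 1.
    """
    pts = [(float(x), float(y)) for x, y in series]
    if len(pts) < 3:
        raise ValueError("need at least 3 dilution points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("dilutions have zero variance")
    fit = stats.linregress(x, y)
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    return EfficiencyEstimate(assay, float(fit.slope), float(eff), float(fit.rvalue**2))


def efficiencies_from_table(dilution: pd.DataFrame) -> dict[str, EfficiencyEstimate]:
    """Standard-curve table (assay, log10_dilution, rep1..repK) -> per-assay E."""
    rep_cols = [c for c in dilution.columns if c.startswith("rep")]
    out = {}
    for assay, grp in dilution.groupby("assay"):
        mean_ct = grp[rep_cols].mean(axis=1)
        out[assay] = efficiency_from_dilution(zip(grp["log10_dilution"], mean_ct), assay)
    return out


def relative_expression(target_ct: float, reference_ct: float, efficiency: float = 1.0) -> DeltaCt:
    """delta Ct = target - reference; linear value = (1+E)^(-delta Ct)."""
    if not (math.isfinite(target_ct) and math.isfinite(reference_ct)):
        return DeltaCt(math.nan, math.nan)
    d = target_ct - reference_ct
    return DeltaCt(d, (1.0 + efficiency) ** (-d))


def polya_proportion(polya_ct: float, total_ct: float, efficiency: float = 1.0) -> float:
    """Short-isoform proportion = (1+E)^(total Ct - polyA Ct).

    Values above 1 are physically impossible and indicate a QC anomaly; they
    are returned as-is so the caller can flag them.
    """
    if not (math.isfinite(polya_ct) and math.isfinite(total_ct)):
        return math.nan
    return (1.0 + efficiency) ** (total_ct - polya_ct)


def quantify(
    ct: pd.DataFrame,
    efficiency: dict[str, float] | None = None,
    qc_sd_threshold: float = DEFAULT_QC_SD,
) -> pd.DataFrame:
    """Full qPCR stage: Ct table -> per-subject expression table.

    Columns: delta_ct_reln (RELN - CHL1), relative_expression (linear),
    polya_delta_ct, polya_proportion, qc_pass (all three assay summaries
    passed), polya_anomaly (proportion > 1).  ``efficiency`` optionally maps
    assay names to measured efficiencies; by default every assay is assumed
    to double each cycle (E = 1).
    """
    summ = summarize_ct_table(ct, qc_sd_threshold)
    wide_ct = summ.pivot(index="subject_id", columns="assay", values="mean_ct")
    wide_qc = summ.pivot(index="subject_id", columns="assay", values="qc_pass")
    e_reln = efficiency.get("RELN_total", 1.0) if efficiency else 1.0
    e_polya = efficiency.get("POLYA", 1.0) if efficiency else 1.0
    rows = []
    for sid, r in wide_ct.iterrows():
        rel = relative_expression(r.get("RELN_total", math.nan), r.get("CHL1", math.nan), e_reln)
        prop = polya_proportion(r.get("POLYA", math.nan), r.get("RELN_total", math.nan), e_polya)
        rows.append(
            {
                "subject_id": sid,
                "delta_ct_reln": rel.delta_ct,
                "relative_expression": rel.linear_value,
                "polya_delta_ct": (
                    r.get("POLYA", math.nan) - r.get("RELN_total", math.nan)
                ),
                "polya_proportion": prop,
                "qc_pass": bool(wide_qc.loc[sid].fillna(False).all()),
                "polya_anomaly": bool(prop > 1.0) if math.isfinite(prop) else True,
            }
        )
    return pd.DataFrame(rows)
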