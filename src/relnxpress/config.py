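"""Configuration objects for the synthetic cohort generator and the pipeline.

All generator parameters are plain dataclass fields so a study design can be
described in YAML, validated once, and passed around explicitly.  Defaults
encode the study conditions the pipeline is designed for: a three-group
postmortem prefrontal-cortex cohort (35 schizophrenia / 32 bipolar disorder /
35 control donors) with the covariate structure typical of brain banks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ConfigError",
    "CohortConfig",
    "ExpressionModel",
    "GenotypeModel",
    "DIAGNOSES",
]

DIAGNOSES = ("SCZ", "BPD", "CTRL")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check_proportion(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must be in [0, 1], got {value!r}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ConfigError(f"{name} must be >= 0, got {value!r}")


@dataclass
class CohortConfig:
    """Design of the donor cohort.

    Group sizes default to 35 schizophrenia (SCZ), 32 bipolar disorder (BPD)
    and 35 unaffected controls (CTRL).  Continuous covariates are drawn from
    normal distributions; pH in pH units, postmortem interval (PMI) in hours,
    age in years, brain weight in grams.
    """

    n_scz: int = 35
    n_bpd: int = 32
    n_ctrl: int = 35
    male_fraction: float = 0.65
    ph_mean: float = 6.5
    ph_sd: float = 0.25
    pmi_mean: float = 30.0
    pmi_sd: float = 13.0
    age_mean: float = 45.0
    age_sd: float = 9.0
    brain_weight_mean: float = 1450.0
    brain_weight_sd: float = 130.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_scz", "n_bpd", "n_ctrl"):
            n = getattr(self, name)
            if n < 0 or n != int(n):
                raise ConfigError(f"{name} must be a non-negative integer, got {n!r}")
        _check_proportion("male_fraction", self.male_fraction)
        for name in ("ph_sd", "pmi_sd", "age_sd", "brain_weight_sd"):
            _check_nonneg(name, getattr(self, name))

    @property
    def n_total(self) -> int:
        return self.n_scz + self.n_bpd + self.n_ctrl


@dataclass
class ExpressionModel:
    """Latent expression structure of the cohort.

    ``polya_mean_by_group`` are the per-diagnosis mean proportions of the
    short, alternatively polyadenylated transcript (truncated C-terminus).
    ``gxs_skipping_means`` are the mean microexon-skipping proportions in the
    four sex x rs7341475-genotype cells (GG homozygotes vs A-allele
    carriers); when ``use_gxs_cells`` is False every subject instead gets
    mean skipping ``1 - retention_mean`` (a null-interaction mode).

    Allelic deviation is the signed departure of the true T-allele fraction
    of transcripts from 0.5 in rs2229864 heterozygotes; its magnitude is
    half-normal with scale ``aei_base_sd``, shifted by ``aei_shift_scz`` in
    schizophrenia.  Measurement parameters (Ct replicate noise, capillary
    peak-height CV, bead-intensity bias) live here too because they are part
    of what the generator emulates.
    """

    polya_mean_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"CTRL": 0.085, "SCZ": 0.087, "BPD": 0.060}
    )
    polya_sd: float = 0.02
    retention_mean: float = 0.833
    retention_sd: float = 0.05
    ph_effect_on_skipping: float = -0.08  # proportion per pH unit
    pmi_effect_on_polya: float = 0.00035  # proportion per hour
    gxs_skipping_means: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("M", "GG"): 0.158,
            ("M", "A"): 0.226,
            ("F", "GG"): 0.1643,
            ("F", "A"): 0.1464,
        }
    )
    use_gxs_cells: bool = True
    aei_shift_scz: float = 0.0672
    aei_base_sd: float = 0.0323
    total_expr_log2_sd: float = 0.5
    ct_noise_sd: float = 0.15  # cycles, per replicate
    peak_noise_cv: float = 0.03  # multiplicative, per peak
    bias_slope: float = 0.02  # T-proportion per log10-intensity unit
    intensity_log_mean: float = 3.0
    intensity_log_sd: float = 0.3
    intensity_ref: float = 3.0
    aspe_noise_sd: float = 0.01  # per-replicate proportion noise
    gdna_replicates: int = 3
    cdna_replicates: int = 6
    logit_scale: bool = False

    def __post_init__(self) -> None:
        for g, m in self.polya_mean_by_group.items():
            _check_proportion(f"polya_mean_by_group[{g}]", m)
        _check_proportion("retention_mean", self.retention_mean)
        for cell, m in self.gxs_skipping_means.items():
            _check_proportion(f"gxs_skipping_means[{cell}]", m)
        for name in (
            "polya_sd",
            "retention_sd",
            "aei_base_sd",
            "total_expr_log2_sd",
            "ct_noise_sd",
            "peak_noise_cv",
            "intensity_log_sd",
            "aspe_noise_sd",
        ):
            _check_nonneg(name, getattr(self, name))
        if self.cdna_replicates < 1 or self.gdna_replicates < 1:
            raise ConfigError("replicate counts must be >= 1")


@dataclass
class GenotypeModel:
    """Allele frequencies for the candidate-region markers.

    The 83 anonymous region SNPs get minor-allele frequencies drawn uniformly
    from ``maf_range`` and genotypes under Hardy-Weinberg equilibrium.
    rs2229864 (the coding SNP used for allelic expression) defaults to
    MAF 1/3 so the expected heterozygosity is 2p(1-p) = 4/9 ~ 44.4%.
    ``ggc_allele_freqs`` maps GGC-repeat counts to allele frequencies, with
    94.8% of the mass on the two common alleles (8 and 10 repeats) and the
    remainder on rare long alleles (12-16 repeats).
    """

    n_region_snps: int = 83
    maf_range: tuple[float, float] = (0.05, 0.5)
    rs7341475_g_freq: float = 0.80
    rs2229864_maf: float = 1.0 / 3.0
    ggc_allele_freqs: Mapping[int, float] = field(
        default_factory=lambda: {8: 0.55, 10: 0.398, 12: 0.02, 13: 0.012, 14: 0.01, 16: 0.01}
    )
    ggc_base_size: float = 100.0  # non-repeat amplicon length, bp

    def __post_init__(self) -> None:
        if self.n_region_snps < 0:
            raise ConfigError("n_region_snps must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 <= lo <= hi <= 0.5, got {self.maf_range!r}")
        _check_proportion("rs7341475_g_freq", self.rs7341475_g_freq)
        if not 0.0 <= self.rs2229864_maf <= 0.5:
            raise ConfigError("rs2229864_maf must be in [0, 0.5]")
        total = sum(self.ggc_allele_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"ggc_allele_freqs must sum to 1 (got {total!r})")
        if any(f < 0 for f in self.ggc_allele_freqs.values()):
            raise ConfigError("ggc_allele_freqs must be non-negative")


def asdict(cfg) -> dict:
    """Dataclass -> plain dict (tuples kept, mappings copied)."""
    return dataclasses.asdict(cfg)
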