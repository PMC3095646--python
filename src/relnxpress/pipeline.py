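"""End-to-end orchestration: simulate -> quantify -> aei -> associate -> report.

Every stage reads and writes plain-text TSV/JSON in a single working
directory so any intermediate can be inspected or diffed; a stage failure
aborts the run naming the stage.  All randomness flows from one integer seed
recorded, together with a configuration hash and the package version, in the
report's provenance block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import allelic, assoc, genocall, microexon, qpcr, synthio
from .config import CohortConfig, ExpressionModel, GenotypeModel

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize_groups",
           "stage_simulate", "stage_quantify", "stage_aei", "stage_associate", "stage_report"]

MEASURES = ("relative_expression", "polya_proportion", "microexon_skipping", "aei")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one run needs: paths, thresholds, permutation settings."""

    workdir: str = "."
    seed: int = 0
    # permutation settings
    perm_cap: int = 100_000
    perm_target_hits: int = 20
    # thresholds
    maf_threshold: float = 0.05
    hwe_alpha: float = 0.05
    pool_max: int = 5
    aei_cuts: tuple[float, float] = (1.2, 1.4)
    ct_qc_sd: float = 0.5
    ggc_base_size: float = 100.0
    use_measured_efficiency: bool = False
    # generator configs (used by the simulate stage)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    expression: ExpressionModel = field(default_factory=ExpressionModel)
    genotype: GenotypeModel = field(default_factory=GenotypeModel)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for name, sub in (("cohort", CohortConfig), ("expression", ExpressionModel), ("genotype", GenotypeModel)):
            if name in raw:
                d = raw.pop(name)
                if name == "expression" and "gxs_skipping_means" in d:
                    d["gxs_skipping_means"] = {tuple(k.split(":")): v for k, v in d["gxs_skipping_means"].items()}
                kwargs[name] = sub(**d)
        if "aei_cuts" in raw:
            raw["aei_cuts"] = tuple(raw["aei_cuts"])
        kwargs.update(raw)
        return cls(**kwargs)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("workdir", None)  # hash the analysis settings, not the path
        blob = repr(d)  # tuple-keyed maps are not JSON
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _require(workdir: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (workdir / name).exists():
            raise PipelineError(f"stage '{stage}': required input file missing: {workdir / name}")


def _read(workdir: Path, name: str, **kw) -> pd.DataFrame:
    return pd.read_csv(workdir / name, sep="\t", **kw)


def _write(df: pd.DataFrame, workdir: Path, name: str, **kw) -> None:
    df.to_csv(workdir / name, sep="\t", index=False, float_format="%.8g", **kw)


def _write_json(obj, workdir: Path, name: str) -> None:
    (workdir / name).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def summarize_groups(values: pd.Series, subjects: pd.DataFrame) -> pd.DataFrame:
    """Per-diagnosis n, mean and standard error of the mean.

    SEM = sd/sqrt(n) with sample sd; undefined (NaN) for a single subject.
    """
    df = subjects.set_index("subject_id").copy()
    df["value"] = pd.Series(values)
    rows = []
    for diag, grp in df.groupby("diagnosis"):
        v = grp["value"].dropna()
        n = len(v)
        rows.append(
            {
                "diagnosis": diag,
                "n": n,
                "mean": float(v.mean()) if n else math.nan,
                "sem": float(v.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan,
            }
        )
    return pd.DataFrame(rows)


def stage_simulate(config: RunConfig) -> None:
    workdir = Path(config.workdir)
    bundle = synthio.generate_bundle(config.cohort, config.expression, config.genotype, seed=config.seed)
    bundle.write(workdir)


def stage_quantify(config: RunConfig) -> None:
    workdir = Path(config.workdir)
    _require(workdir, "quantify", "ct.tsv", "peaks.tsv", "dilution_qpcr.tsv", "dilution_oligo.tsv")
    ct = _read(workdir, "ct.tsv")
    eff = qpcr.efficiencies_from_table(_read(workdir, "dilution_qpcr.tsv"))
    eff_map = {a: e.efficiency for a, e in eff.items()} if config.use_measured_efficiency else None
    expr = qpcr.quantify(ct, efficiency=eff_map, qc_sd_threshold=config.ct_qc_sd)
    _write(expr, workdir, "expression.tsv")
    _write_json({a: dataclasses.asdict(e) for a, e in eff.items()}, workdir, "efficiency.json")

    mex = microexon.quantify(_read(workdir, "peaks.tsv"))
    _write(mex, workdir, "microexon.tsv")
    fit = microexon.validate_dilution(_read(workdir, "dilution_oligo.tsv"))
    _write_json(
        {"slope": fit.slope, "intercept": fit.intercept, "r_squared": fit.r_squared},
        workdir,
        "validation.json",
    )


def stage_aei(config: RunConfig) -> None:
    workdir = Path(config.workdir)
    _require(workdir, "aei", "allele_signals.tsv", "genotypes.tsv", "subjects.tsv")
    signals = _read(workdir, "allele_signals.tsv")
    geno = _read(workdir, "genotypes.tsv", index_col=0)
    subjects = _read(workdir, "subjects.tsv")
    aei_df, calib = allelic.run_aei(signals, geno["rs2229864"], subjects)
    _write(aei_df, workdir, "aei.tsv")
    _write_json(dataclasses.asdict(calib), workdir, "calibration.json")
    if {"rflp_fragments.tsv", "ggc_fragments.tsv"} <= {p.name for p in workdir.iterdir()}:
        calls = pd.concat(
            [
                genocall.call_rflp_table(_read(workdir, "rflp_fragments.tsv")),
                genocall.call_ggc_table(_read(workdir, "ggc_fragments.tsv"), config.ggc_base_size),
            ],
            ignore_index=True,
        )
        _write(calls, workdir, "calls.tsv")


def _phenotypes(workdir: Path) -> dict[str, assoc.PhenotypeVector]:
    expr = _read(workdir, "expression.tsv").set_index("subject_id")
    mex = _read(workdir, "microexon.tsv").set_index("subject_id")
    out = {
        "relative_expression": assoc.normality_and_transform(
            expr["relative_expression"], "relative_expression"
        ),
        "polya_proportion": assoc.normality_and_transform(expr["polya_proportion"], "polya_proportion"),
        "microexon_skipping": assoc.normality_and_transform(
            mex["skipping_proportion"], "microexon_skipping"
        ),
    }
    aei_path = workdir / "aei.tsv"
    if aei_path.exists():
        aei_df = _read(workdir, "aei.tsv").set_index("sample_id")
        if len(aei_df) >= 3:
            out["aei"] = assoc.normality_and_transform(aei_df["aei"], "aei")
    return out


def stage_associate(config: RunConfig) -> dict:
    workdir = Path(config.workdir)
    _require(workdir, "associate", "subjects.tsv", "expression.tsv", "microexon.tsv", "genotypes.tsv")
    subjects = _read(workdir, "subjects.tsv")
    geno = _read(workdir, "genotypes.tsv", index_col=0)
    region = geno[[c for c in geno.columns if c.startswith("snp")]]
    qc = assoc.snp_qc(region, config.maf_threshold, config.hwe_alpha, config.pool_max)
    _write(qc, workdir, "qc_snps.tsv")

    phenos = _phenotypes(workdir)
    report: dict = {"anova": {}, "scan": {}, "gxs": {}, "aei_snp": {}}
    scan_tables = []
    rng_seeds = np.random.SeedSequence(config.seed).spawn(len(MEASURES))
    for (measure, pheno), sub_seed in zip(phenos.items(), rng_seeds):
        screen = assoc.confounder_screen(pheno, subjects)
        top = [screen.iloc[0]["covariate"]] if len(screen) and screen.iloc[0]["selected"] else []
        anova = assoc.diagnosis_anova(pheno, subjects, confounders=top)
        report["anova"][measure] = {
            "confounders": top,
            "screen": screen.to_dict("records"),
            "tests": [dataclasses.asdict(a) for a in anova],
        }
        if measure == "aei":
            table, engine, yv = assoc.aei_snp_test(pheno.values, region)
        else:
            conf = subjects.set_index("subject_id")[top[0]] if top else None
            table, engine, yv = assoc.eqtl_scan(pheno, region, qc=qc, confounder=conf)
        entry: dict = {"n_snps": len(table)}
        if len(table):
            min_p = float(table["p_nominal"].min())
            perm = assoc.adaptive_permutation(
                engine, yv, min_p, seed=sub_seed,
                target_hits=config.perm_target_hits, cap=config.perm_cap,
            )
            entry.update(
                min_p=min_p,
                top_snp=str(table.loc[table["p_nominal"].idxmin(), "snp"]),
                n_perm=perm.n_perm,
                corrected_p=perm.corrected_p,
                capped=perm.capped,
            )
            table = table.assign(measure=measure)
            scan_tables.append(table)
        key = "aei_snp" if measure == "aei" else "scan"
        report[key][measure] = entry

    if scan_tables:
        _write(pd.concat(scan_tables, ignore_index=True), workdir, "scan_results.tsv")

    # genotype-by-sex interaction of rs7341475 (GG vs A-carrier) per measure
    carrier = geno["rs7341475"].map(lambda c: "GG" if c == 0 else "A")
    sex = subjects.set_index("subject_id")["sex"]
    for measure in ("relative_expression", "polya_proportion", "microexon_skipping"):
        pheno = phenos[measure]
        screen = assoc.confounder_screen(pheno, subjects)
        top = [screen.iloc[0]["covariate"]] if len(screen) and screen.iloc[0]["selected"] else []
        top = [t for t in top if t != "sex"]  # sex is a main effect in this model
        try:
            rep = assoc.gxs_interaction(pheno, carrier, sex, subjects, confounders=top)
            report["gxs"][measure] = dataclasses.asdict(rep)
        except ValueError as e:
            report["gxs"][measure] = {"error": str(e)}

    corrected = {
        m: {k: v for k, v in entry.items() if k in ("min_p", "n_perm", "corrected_p", "capped")}
        for m, entry in {**report["scan"], **report["aei_snp"]}.items()
    }
    corrected["seed"] = config.seed
    corrected["cap"] = config.perm_cap
    corrected["target_hits"] = config.perm_target_hits
    _write_json(corrected, workdir, "corrected.json")
    _write_json(report["anova"], workdir, "anova_report.json")
    return report


def stage_report(config: RunConfig, assoc_report: dict | None = None) -> dict:
    workdir = Path(config.workdir)
    _require(workdir, "report", "subjects.tsv", "expression.tsv", "microexon.tsv")
    subjects = _read(workdir, "subjects.tsv")
    expr = _read(workdir, "expression.tsv").set_index("subject_id")
    mex = _read(workdir, "microexon.tsv").set_index("subject_id")
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_sha256": config.digest(),
        },
        "group_summaries": {
            "polya_proportion": summarize_groups(expr["polya_proportion"], subjects).to_dict("records"),
            "relative_expression": summarize_groups(expr["relative_expression"], subjects).to_dict("records"),
            "microexon_retention": summarize_groups(mex["retention_proportion"], subjects).to_dict("records"),
        },
    }
    if (workdir / "validation.json").exists():
        report["microexon_validation"] = json.loads((workdir / "validation.json").read_text())
    if (workdir / "aei.tsv").exists():
        aei_df = _read(workdir, "aei.tsv")
        if len(aei_df) and "diagnosis" in aei_df.columns:
            report["aei_groups"] = allelic.group_aei_summary(aei_df, config.aei_cuts).to_dict("records")
    if assoc_report is not None:
        report["association"] = assoc_report
    elif (workdir / "anova_report.json").exists():
        report["association"] = {"anova": json.loads((workdir / "anova_report.json").read_text())}
    if (workdir / "corrected.json").exists():
        report["corrected"] = json.loads((workdir / "corrected.json").read_text())
    _write_json(report, workdir, "report.json")
    return report


_STAGES = ("simulate", "quantify", "aei", "associate", "report")


def run_pipeline(config: RunConfig, simulate: bool = True) -> dict:
    """Run all stages in order; returns the report dict.

    Any exception inside a stage is re-raised as :class:`PipelineError`
    naming the failing stage.
    """
    Path(config.workdir).mkdir(parents=True, exist_ok=True)
    assoc_report = None
    for stage in _STAGES:
        if stage == "simulate" and not simulate:
            continue
        fn = globals()[f"stage_{stage}"]
        try:
            if stage == "associate":
                assoc_report = fn(config)
            elif stage == "report":
                return fn(config, assoc_report)
            else:
                fn(config)
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001 - stage attribution is the point
            raise PipelineError(f"stage '{stage}' failed: {e}") from e
    raise AssertionError("unreachable")
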