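"""End-to-end orchestration: phantoms/volumes -> lesions -> burden -> survival.

The imaging stage reads per-patient SUV volumes and liver masks, runs the
two-step delineation and writes per-lesion and patient-level burden CSVs.
The survival stage takes a patient table (burden metrics joined with
clinical columns ``time_months``, ``event``, ``psa``, ``ldh``) and writes
the report bundle: a correlation table, a univariate + stepwise-multivariate
regression table, quantile-strata Kaplan-Meier exports with log-rank tests,
and a binarized maximally-selected-cutoff table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from psmaburden import survival as surv
from psmaburden.metrics import burden_table, lesion_table
from psmaburden.segmentation import SegmentationConfig, segment_patient
from psmaburden.synthetic import CohortSpec, fixture_suite, generate_cohort
from psmaburden.volume import read_mask, read_volume

logger = logging.getLogger("psmaburden")

__all__ = ["PipelineConfig", "ConfigError", "run_imaging_stage", "run_survival_stage", "run_all"]

PET_PARAMETERS = ["lesion_count", "psma_tv_ml", "psma_tlu", "psma_tlq"]
BLOOD_PARAMETERS = ["psa", "ldh"]


class ConfigError(ValueError):
    """Unknown or inconsistent pipeline configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: str = "psmaburden_out"
    seed: int = 0
    fixtures_dir: str | None = None
    patients: tuple[dict, ...] = ()          # {patient_id, volume, liver_mask, manual_masks?, exclusion?}
    clinical_csv: str | None = None
    n_patients: int = 5                      # fixture phantoms when simulating
    cohort_n: int = 110                      # simulated cohort size
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    covariates: tuple[str, ...] = tuple(PET_PARAMETERS + BLOOD_PARAMETERS)
    stepwise_covariates: tuple[str, ...] = ("lesion_count", "psma_tv_ml", "psa", "ldh", "psma_tlq")
    schemes: tuple[str, ...] = ("quartiles", "quintile_1_24_5")
    min_group_fraction: float = 0.10
    removal_alpha: float = 0.10
    ties: str = "breslow"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        seg_raw = raw.pop("segmentation", {})
        known_seg = set(SegmentationConfig.__dataclass_fields__)
        unknown = set(seg_raw) - known_seg
        if unknown:
            raise ConfigError(f"unknown segmentation config key(s): {sorted(unknown)}")
        known = set(cls.__dataclass_fields__) - {"segmentation"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("patients", "covariates", "stepwise_covariates", "schemes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(segmentation=SegmentationConfig(**seg_raw), **raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def _patients_from_fixtures(fixtures_dir: str) -> tuple[dict, ...]:
    manifest = json.loads((Path(fixtures_dir) / "manifest.json").read_text())
    base = Path(fixtures_dir)
    return tuple(
        {
            "patient_id": p["patient_id"],
            "volume": str(base / p["volume"]),
            "liver_mask": str(base / p["liver_mask"]),
        }
        for p in manifest["patients"]
    )


def run_imaging_stage(config: PipelineConfig):
    """Segment every patient volume; write per-lesion and patient-level CSVs.

    Per-patient failures are logged and collected, not silently dropped;
    returns ``(patient_df, lesion_df, errors)``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients = config.patients or (
        _patients_from_fixtures(config.fixtures_dir) if config.fixtures_dir else ()
    )
    if not patients:
        raise ConfigError("no patients given: set 'patients' or 'fixtures_dir'")

    burdens, errors = [], []
    for entry in patients:
        pid = entry["patient_id"]
        try:
            volume = read_volume(entry["volume"])
            liver = read_mask(entry["liver_mask"], volume, label="liver")
            manual = [
                read_mask(p, volume, label="manual") for p in entry.get("manual_masks", [])
            ]
            exclusion = (
                read_mask(entry["exclusion"], volume, label="exclusion")
                if entry.get("exclusion")
                else None
            )
            burden = segment_patient(
                volume, liver, manual_masks=manual, exclusion=exclusion,
                patient_id=pid, config=config.segmentation,
            )
            logger.info("patient %s: %d lesions, PSMA-TV %.2f ml (%d manual)",
                        pid, burden.lesion_count, burden.psma_tv,
                        sum(1 for les in burden.lesions if les.provenance == "manual"))
            burdens.append(burden)
        except Exception as exc:
            logger.error("patient %s failed: %s", pid, exc)
            errors.append({"patient_id": pid, "error": str(exc)})

    patient_df = burden_table(burdens)
    lesion_df = lesion_table(burdens)
    patient_df.to_csv(out / "patient_burden.csv", index=False)
    lesion_df.to_csv(out / "lesions.csv", index=False)
    if errors:
        pd.DataFrame(errors).to_csv(out / "imaging_errors.csv", index=False)
    return patient_df, lesion_df, errors


def _fmt_months(value: float) -> str:
    return "NR" if not np.isfinite(value) else f"{value:.1f}"


def _fmt_median_ci(median: float, ci: tuple[float, float]) -> str:
    return f"{_fmt_months(median)} [{_fmt_months(ci[0])}-{_fmt_months(ci[1])}]"


def run_survival_stage(config: PipelineConfig, patient_table: pd.DataFrame) -> dict:
    """Full statistical stage on a joined patient table; writes the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    required = ["time_months", "event"] + list(config.covariates)
    missing = [c for c in required if c not in patient_table.columns]
    if missing:
        raise ConfigError(f"patient table is missing column(s): {missing}")

    report: dict = {}

    # -- correlation table (PET parameters vs blood parameters) --------------
    corr_rows = []
    for param in [c for c in PET_PARAMETERS if c in config.covariates]:
        row = {"parameter": param}
        for blood in [c for c in BLOOD_PARAMETERS if c in patient_table.columns]:
            sub = patient_table[[param, blood]].dropna()
            rho, p = surv.spearman_correlation(sub[param], sub[blood])
            row[f"{blood}_rho"], row[f"{blood}_p"] = rho, p
        corr_rows.append(row)
    correlation = pd.DataFrame(corr_rows)
    correlation.to_csv(out / "correlation_table.csv", index=False)
    report["correlation"] = correlation

    # -- log2 transform and Cox regressions ----------------------------------
    table = surv.log2_covariates(patient_table, list(config.covariates))
    uni_rows = []
    for name in config.covariates:
        fit = surv.fit_cox(table, [f"{name}_log2"], ties=config.ties)
        c = fit.coefficients.iloc[0]
        uni_rows.append(
            {
                "parameter": name,
                "univariate_hr": c["hr"],
                "univariate_ci_low": c["ci_low"],
                "univariate_ci_high": c["ci_high"],
                "univariate_p": c["p"],
            }
        )
    regression = pd.DataFrame(uni_rows).set_index("parameter")

    step_names = [f"{n}_log2" for n in config.stepwise_covariates]
    stepwise = surv.stepwise_backward_lr(
        table, step_names, removal_alpha=config.removal_alpha, ties=config.ties
    )
    for name in config.stepwise_covariates:
        col = f"{name}_log2"
        if col in stepwise.final.covariate_names:
            c = stepwise.final.coefficients.loc[col]
            regression.loc[name, "multivariate_hr"] = c["hr"]
            regression.loc[name, "multivariate_ci_low"] = c["ci_low"]
            regression.loc[name, "multivariate_ci_high"] = c["ci_high"]
            regression.loc[name, "multivariate_p"] = c["p"]
    regression.reset_index().to_csv(out / "regression_table.csv", index=False)
    trace = pd.DataFrame(stepwise.removal_trace, columns=["removed", "lr_p"])
    trace.to_csv(out / "stepwise_trace.csv", index=False)
    report["regression"] = regression
    report["stepwise_trace"] = trace

    # -- quantile stratification + KM exports --------------------------------
    strata_rows = []
    for param in config.covariates:
        for scheme in config.schemes:
            labels = surv.quantile_stratify(patient_table[param].to_numpy(), scheme=scheme)
            order = [lab for lab in dict.fromkeys(sorted(np.unique(labels)))]
            groups, names = [], []
            for lab in order:
                sel = labels == lab
                if sel.sum() == 0:
                    continue
                sub = patient_table.loc[sel]
                km = surv.km_estimate(sub)
                km.to_frame().to_csv(out / f"km_{param}_{scheme}_{lab}.csv", index=False)
                groups.append(sub)
                names.append(lab)
                strata_rows.append(
                    {
                        "parameter": param,
                        "scheme": scheme,
                        "stratum": lab,
                        "n": int(sel.sum()),
                        "median_os": _fmt_median_ci(km.median, km.median_ci),
                    }
                )
            if len(groups) >= 2:
                global_p = surv.logrank_test(*groups).p
                first_last_p = surv.logrank_test(groups[0], groups[-1]).p
                for row in strata_rows:
                    if row["parameter"] == param and row["scheme"] == scheme:
                        row.setdefault("global_logrank_p", global_p)
                        row.setdefault("first_vs_last_p", first_last_p)
    strata = pd.DataFrame(strata_rows)
    strata.to_csv(out / "strata_table.csv", index=False)
    report["strata"] = strata

    # -- binarized ideal cutoffs ----------------------------------------------
    cutoff_rows = []
    for param in config.covariates:
        res = surv.find_ideal_cutoff(
            patient_table, param, min_group_fraction=config.min_group_fraction
        )
        cutoff_rows.append(
            {
                "parameter": param,
                "threshold": res.cutoff,
                "os_above": _fmt_median_ci(res.median_above, res.median_above_ci),
                "n_above": res.n_above,
                "os_below": _fmt_median_ci(res.median_below, res.median_below_ci),
                "n_below": res.n_below,
                "p": res.p,
                "p_bonferroni": res.p_bonferroni,
                "maximally_selected": res.maximally_selected,
            }
        )
    cutoffs = pd.DataFrame(cutoff_rows)
    cutoffs.to_csv(out / "cutoff_table.csv", index=False)
    report["cutoffs"] = cutoffs
    return report


def run_all(config: PipelineConfig) -> dict:
    """Fixture generation (if needed), imaging stage, survival stage, manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    if not cfg.patients and not cfg.fixtures_dir:
        fixtures = out / "fixtures"
        logger.info("no inputs configured: generating fixture suite in %s", fixtures)
        fixture_suite(fixtures, seed=cfg.seed, n_patients=cfg.n_patients, cohort_n=cfg.cohort_n)
        cfg = replace(cfg, fixtures_dir=str(fixtures))

    patient_df, lesion_df, errors = run_imaging_stage(cfg)

    if cfg.clinical_csv:
        clinical = pd.read_csv(cfg.clinical_csv)
        cohort = patient_df.merge(clinical, on="patient_id", validate="one_to_one")
    else:
        cohort_path = Path(cfg.fixtures_dir) / "cohort.csv" if cfg.fixtures_dir else None
        if cohort_path is None or not cohort_path.exists():
            raise ConfigError("no clinical_csv configured and no simulated cohort available")
        cohort = pd.read_csv(cohort_path)

    report = run_survival_stage(cfg, cohort)
    manifest = {
        "seed": cfg.seed,
        "n_imaging_patients": int(len(patient_df)),
        "n_imaging_errors": len(errors),
        "n_cohort": int(len(cohort)),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report["manifest"] = manifest
    report["patient_burden"] = patient_df
    report["lesions"] = lesion_df
    report["imaging_errors"] = errors
    return report
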