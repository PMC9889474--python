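"""End-to-end orchestration of the delta-radiomics study replica.

``run_all`` executes the full chain on a synthetic cohort: simulate →
resample/rings → feature extraction (F0, F1, re-test) → ICC stability
filter → per-day delta assembly → three signature pools (all / baseline /
intratumor) → clinical Cox baselines → C-index comparison → maxstat risk
stratification and time-dependent ROC.  All randomness derives from one
master seed via per-stage seeds, so two runs with equal (config, seed)
produce identical reports.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clin
from . import processing as proc
from .config import PipelineConfig, config_hash, stage_seed
from .features import extract_all
from .grid import make_rings, resample_isotropic, resample_mask_isotropic
from .signature import SignatureModel, build_signature, signature_score
from .stratify import stratify_and_report
from .synth import SyntheticPatient, simulate_cohort

log = logging.getLogger(__name__)

__all__ = ["run_all", "extract_patient_features", "clinical_covariates", "PipelineResult"]

CLINICAL_COVARIATES = [
    "sex", "age_group", "smoking", "ethnicity",
    "t_stage", "n_stage", "m_stage", "tki_drug", "baseline_volume_ml",
]


def clinical_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    """Candidate covariate table: age dichotomized at 60, rest as recorded."""
    out = clinical.copy()
    out["age_group"] = np.where(out["age"] < 60, "<60", ">=60")
    return out[CLINICAL_COVARIATES]


def extract_patient_features(
    patient: SyntheticPatient, n_bins: int = 32, with_retest: bool = False
) -> dict[str, dict[str, float]]:
    """Resample to 1 mm isotropic, build rings, extract the catalogue.

    Returns feature dicts keyed ``F0``, ``F1`` and optionally ``retest``
    (the re-test segmentation of the F0 scan, reported under the F0 tag so
    its names align with the F0 table for the ICC filter).
    """
    sp = patient.scan_pair
    f0 = resample_isotropic(sp.f0)
    f1 = resample_isotropic(sp.f1)
    lung = resample_mask_isotropic(sp.lung_mask)
    m0 = resample_mask_isotropic(sp.f0_mask)
    m1 = resample_mask_isotropic(sp.f1_mask)
    out = {
        "F0": extract_all(f0, make_rings(m0, lung, patient.patient_id), "F0", n_bins),
        "F1": extract_all(f1, make_rings(m1, lung, patient.patient_id), "F1", n_bins),
    }
    if with_retest:
        mr = resample_mask_isotropic(patient.retest_mask)
        out["retest"] = extract_all(
            f0, make_rings(mr, lung, patient.patient_id + ":retest"), "F0", n_bins
        )
    return out


@dataclass
class PipelineResult:
    report: dict
    signatures: dict[str, SignatureModel]
    scores: dict[str, dict[str, np.ndarray]]     # model -> cohort -> scores
    tables: dict[str, pd.DataFrame]
    icc: pd.DataFrame
    clinical_fits: dict = field(default_factory=dict)


def _stage(name: str, pid: str | None = None):
    where = f"stage '{name}'" + (f", patient {pid}" if pid else "")
    return where


def run_all(config: PipelineConfig, seed: int, out_dir: str | Path) -> PipelineResult:
    """Run the complete study replica; writes tables, report and plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_cfg = config.cohort_config()

    # ---- stage 1: simulate ------------------------------------------------
    log.info("stage simulate")
    patients = simulate_cohort(
        cohort_cfg, stage_seed(seed, "simulate"),
        out_dir=(out / "cohort") if config.write_images else None,
    )
    train = [p for p in patients if p.cohort == "train"]
    valid = [p for p in patients if p.cohort == "valid"]
    retest_ids = [p.patient_id for p in train[: cohort_cfg.retest_n]]

    # ---- stage 2: rings + extraction -------------------------------------
    log.info("stage extract (%d patients)", len(patients))
    rows_f0, rows_f1, rows_rt = {}, {}, {}
    for p in patients:
        try:
            feats = extract_patient_features(
                p, config.n_bins, with_retest=p.patient_id in retest_ids
            )
        except Exception as exc:
            raise RuntimeError(f"{_stage('extract', p.patient_id)}: {exc}") from exc
        rows_f0[p.patient_id] = feats["F0"]
        rows_f1[p.patient_id] = feats["F1"]
        if "retest" in feats:
            rows_rt[p.patient_id] = feats["retest"]
    f0 = pd.DataFrame.from_dict(rows_f0, orient="index").sort_index()
    f1 = pd.DataFrame.from_dict(rows_f1, orient="index").sort_index()
    rt = pd.DataFrame.from_dict(rows_rt, orient="index").sort_index()
    f0.to_csv(out / "features_F0.csv", index_label="patient_id")
    f1.to_csv(out / "features_F1.csv", index_label="patient_id")
    rt.to_csv(out / "features_F0_retest.csv", index_label="patient_id")

    # ---- stage 3: ICC stability filter (training re-test patients) -------
    log.info("stage icc-filter")
    icc_report = proc.retest_filter(f0.loc[rt.index], rt, config.icc_threshold)
    icc_report.frame().to_csv(out / "icc.csv", index_label="feature")
    retained_base = [proc.base_name(c) for c in icc_report.retained]

    # ---- stage 4: per-day deltas + table assembly -------------------------
    log.info("stage assemble")
    intervals = pd.Series(
        {p.patient_id: p.scan_pair.interval_days for p in patients}, name="diff_days"
    )
    train_ids = [p.patient_id for p in train]
    valid_ids = [p.patient_id for p in valid]
    table_train, state = proc.assemble_feature_table(
        f0.loc[train_ids], f1.loc[train_ids], retained_base, intervals,
        epsilon_factor=config.delta_epsilon_factor,
        max_missing_fraction=config.max_missing_fraction,
    )
    table_valid, _ = proc.assemble_feature_table(
        f0.loc[valid_ids], f1.loc[valid_ids], retained_base, intervals, state=state
    )
    table_train.to_csv(out / "table_train.csv", index_label="patient_id")
    table_valid.to_csv(out / "table_valid.csv", index_label="patient_id")

    outcomes = {
        "train": pd.DataFrame({
            "pfs_months": [p.outcome.time_months for p in train],
            "event": [p.outcome.event for p in train],
        }, index=train_ids).loc[table_train.index],
        "valid": pd.DataFrame({
            "pfs_months": [p.outcome.time_months for p in valid],
            "event": [p.outcome.event for p in valid],
        }, index=valid_ids).loc[table_valid.index],
    }
    tr_t = outcomes["train"]["pfs_months"].to_numpy()
    tr_e = outcomes["train"]["event"].to_numpy(bool)
    va_t = outcomes["valid"]["pfs_months"].to_numpy()
    va_e = outcomes["valid"]["event"].to_numpy(bool)

    # ---- stage 5: signatures ---------------------------------------------
    signatures: dict[str, SignatureModel] = {}
    scores: dict[str, dict[str, np.ndarray]] = {}
    for pool in ("all", "baseline", "intratumor"):
        log.info("stage signature pool=%s", pool)
        sig = build_signature(
            table_train, tr_t, tr_e, pool=pool, k=config.k_features,
            seed=stage_seed(seed, f"signature:{pool}"),
            n_trees=config.rsf_n_trees,
            boruta_n_trees=config.boruta_n_trees,
            boruta_max_iter=config.boruta_max_iter,
            boruta_alpha=config.boruta_alpha,
            min_samples_leaf=config.rsf_min_samples_leaf,
        )
        signatures[pool] = sig
        scores[f"model_{pool}"] = {
            "train": signature_score(sig, table_train),
            "valid": signature_score(sig, table_valid),
        }

    # ---- stage 6: clinical Cox baselines ----------------------------------
    log.info("stage clinical")
    clinical_df = pd.DataFrame(
        {
            "age": [p.clinical.age for p in patients],
            "sex": [p.clinical.sex for p in patients],
            "smoking": [p.clinical.smoking for p in patients],
            "ethnicity": [p.clinical.ethnicity for p in patients],
            "t_stage": [p.clinical.t_stage for p in patients],
            "n_stage": [p.clinical.n_stage for p in patients],
            "m_stage": [p.clinical.m_stage for p in patients],
            "tki_drug": [p.clinical.tki_drug for p in patients],
            "baseline_volume_ml": [p.clinical.baseline_volume_ml for p in patients],
        },
        index=[p.patient_id for p in patients],
    )
    cov = clinical_covariates(clinical_df)
    cov_train = cov.loc[table_train.index]
    cov_valid = cov.loc[table_valid.index]
    univariate = {
        c: clin.cox_univariate(cov_train[c], tr_t, tr_e) for c in cov_train.columns
    }
    clinical_fit = clin.cox_forward_aic(cov_train, tr_t, tr_e)
    design_train = clin.expand_design(cov_train)
    design_valid = clin.expand_design(cov_valid)
    scores["model_clinical"] = {
        "train": clinical_fit.linear_predictor(design_train),
        "valid": clinical_fit.linear_predictor(design_valid),
    }

    # combined = best radiomics signature + selected clinical covariates
    selected_cols = clinical_fit.covariates
    combined_fit = clin.combine_clinico_radiomics(
        scores["model_all"]["train"],
        design_train[selected_cols].reset_index(drop=True) if selected_cols else None,
        tr_t, tr_e,
    )
    def _combined(which: str, design: pd.DataFrame) -> np.ndarray:
        d = pd.DataFrame({"signature_score": scores["model_all"][which]})
        for c in selected_cols:
            d[c] = design[c].to_numpy()
        return combined_fit.linear_predictor(d)
    scores["model_combined"] = {
        "train": _combined("train", design_train),
        "valid": _combined("valid", design_valid),
    }

    # ---- stage 7: C-index comparison --------------------------------------
    log.info("stage compare")
    cmp_seed = stage_seed(seed, "compare")
    cindex: dict[str, dict] = {}
    for model, sc in scores.items():
        cindex[model] = {}
        for which, (t, e) in (("train", (tr_t, tr_e)), ("valid", (va_t, va_e))):
            c, ci = clin.harrell_c_ci(sc[which], t, e,
                                      n_boot=config.n_bootstrap_ci, seed=cmp_seed)
            cindex[model][which] = {"c": c, "ci": ci}
    pairs = [
        ("model_all", "model_clinical"),
        ("model_all", "model_baseline"),
        ("model_all", "model_intratumor"),
        ("model_combined", "model_all"),
    ]
    comparisons = {}
    for a, b in pairs:
        comparisons[f"{a}_vs_{b}"] = {
            which: clin.compare_c_paired(
                scores[a][which], scores[b][which], t, e,
                n_boot=config.n_bootstrap_compare, seed=cmp_seed,
            )
            for which, (t, e) in (("train", (tr_t, tr_e)), ("valid", (va_t, va_e)))
        }

    # ---- stage 8: stratification + tdROC ----------------------------------
    log.info("stage stratify")
    strat = stratify_and_report(
        scores["model_all"]["train"], scores["model_all"]["valid"],
        outcomes["train"], outcomes["valid"],
        horizons=config.tdroc_horizons_months,
        quantile_range=config.maxstat_quantile_range,
        out_dir=out / "stratification",
        seed=stage_seed(seed, "stratify"),
        n_permutations=config.n_permutations_maxstat,
        n_boot=config.tdroc_n_boot,
    )

    report = {
        "n_train": len(table_train),
        "n_valid": len(table_valid),
        "event_fraction": float(np.mean([p.outcome.event for p in patients])),
        "interval_days": {
            "min": int(intervals.min()), "median": float(intervals.median()),
            "max": int(intervals.max()),
        },
        "n_features_extracted": int(f0.shape[1]),
        "n_features_stable": len(icc_report.retained),
        "n_table_columns": int(table_train.shape[1]),
        "signatures": {
            pool: {
                "features": sig.features,
                "n_confirmed": len(sig.selection.confirmed),
                "oob_cindex": sig.rsf.oob_cindex,
            }
            for pool, sig in signatures.items()
        },
        "clinical": {
            "selected": clinical_fit.covariates,
            "aic": clinical_fit.aic,
            "univariate": {
                c: {"hr": f.hr, "ci": f.ci, "p": f.p, "converged": f.converged}
                for c, f in univariate.items()
            },
        },
        "cindex": cindex,
        "comparisons": comparisons,
        "stratification": strat,
        "config_hash": config_hash(config),
        "seed": seed,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    _write_html(report, out / "report.html")
    _write_manifest(config, seed, out)
    return PipelineResult(
        report=report, signatures=signatures, scores=scores,
        tables={"train": table_train, "valid": table_valid},
        icc=icc_report.frame(),
        clinical_fits={"univariate": univariate, "selected": clinical_fit,
                       "combined": combined_fit},
    )


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return str(x)


def _write_manifest(config: PipelineConfig, seed: int, out: Path) -> None:
    checksums = {}
    for f in sorted(out.glob("*.csv")):
        checksums[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()[:16]
    manifest = {
        "config_hash": config_hash(config),
        "master_seed": seed,
        "stage_seeds": {
            s: stage_seed(seed, s)
            for s in ("simulate", "signature:all", "signature:baseline",
                      "signature:intratumor", "compare", "stratify")
        },
        "checksums": checksums,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _write_html(report: dict, path: Path) -> None:
    rows = []
    for model, d in report["cindex"].items():
        rows.append(
            f"<tr><td>{model}</td>"
            f"<td>{d['train']['c']:.3f} [{d['train']['ci'][0]:.3f}, {d['train']['ci'][1]:.3f}]</td>"
            f"<td>{d['valid']['c']:.3f} [{d['valid']['ci'][0]:.3f}, {d['valid']['ci'][1]:.3f}]</td></tr>"
        )
    comps = "".join(
        f"<li>{k}: p(train)={v['train']:.4g}, p(valid)={v['valid']:.4g}</li>"
        for k, v in report["comparisons"].items()
    )
    html = (
        "<html><head><title>delta-radiomics report</title></head><body>"
        f"<h1>Model comparison (seed {report['seed']})</h1>"
        "<table border=1><tr><th>model</th><th>C-index train [95% CI]</th>"
        "<th>C-index valid [95% CI]</th></tr>"
        + "".join(rows)
        + "</table><h2>Pairwise comparisons</h2><ul>" + comps + "</ul>"
        + f"<h2>Stratification</h2><p>cutoff = {report['stratification']['cutoff']:.2f}</p>"
        "</body></html>"
    )
    path.write_text(html)
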