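"""End-to-end orchestration: screen -> quantify -> select -> validate ->
risk model -> ROC, for each configured case/reference contrast.

The pipeline mirrors a multiphase case-control biomarker study: a pooled
sequencing screen proposes candidates, RT-qPCR quantifies them absolutely
in individual sera, a training set applies the fold-change + t-test
selection rule, an independent validation set confirms direction and
significance, and the confirmed panel is turned into a dichotomized
weighted risk score whose discrimination is compared against single
markers and conventional protein biomarkers by ROC analysis.

In synthetic mode every input is generated from one seed, so a run is a
pure function of (config, seed) and the report JSON is byte-identical
across repeats.  In file mode the same stages consume user-supplied TSV
tables; the screen stage is advisory and is skipped when no count table
is given.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as mio
from .errors import ConfigurationError, DataError, MirpanelError
from .markers import differential_stats, select_markers, validate_markers
from .qpcr import quantify_samples
from .risk import build_risk_model, compute_rsf, dichotomize
from .roc import roc_curve
from .screen import detect_mirnas, screen_filter
from .synthetic import (
    CohortConfig,
    GROUPS,
    default_config,
    generate_cohort,
    make_true_curves,
    simulate_calibration,
    simulate_cq,
    simulate_pool_counts,
)

__all__ = [
    "StageParams",
    "PipelineConfig",
    "PipelineStageError",
    "run_pipeline",
    "summarize_auc_table",
    "report_to_json",
]

FORMAT_VERSION = 1


class PipelineStageError(MirpanelError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


class StageParams(BaseModel):
    """Tunable thresholds for the analysis stages."""

    min_copies: int = 1000
    min_fold_screen: float = 5.0
    min_fold_select: float = 2.0
    alpha: float = 0.05
    detection_min: int = 1
    reference_method: str = "parametric"   # parametric | empirical
    ci_method: str = "delong"              # delong | hanley
    test_scale: str = "log10"              # log10 | raw
    serum_volume_ml: float = 0.2
    restrict_to_screen: bool = False
    fit_subset: str = "all"                # all | training
    up_only: bool = False


class PipelineConfig(BaseModel):
    """Single-document configuration for :func:`run_pipeline`."""

    mode: str = "synthetic"                # synthetic | files
    cohort: CohortConfig | None = None
    metadata_path: str | None = None
    cq_path: str | None = None
    calibration_path: str | None = None
    counts_path: str | None = None
    params: StageParams = Field(default_factory=StageParams)
    contrasts: list[tuple[str, str]] = Field(
        default_factory=lambda: [("AMI", "control"), ("AP", "control"),
                                 ("AMI", "AP")]
    )
    covariate_scorers: list[str] = Field(default_factory=lambda: ["ctnt", "ckmb"])
    output_dir: str | None = None
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "PipelineConfig":
        if self.mode not in ("synthetic", "files"):
            raise ConfigurationError(f"mode must be synthetic|files, got {self.mode!r}")
        if self.mode == "files":
            for name in ("metadata_path", "cq_path", "calibration_path"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigurationError(f"files mode requires {name}")
                if not Path(p).exists():
                    raise ConfigurationError(f"{name}: no such file {p!r}")
            if self.counts_path is not None and not Path(self.counts_path).exists():
                raise ConfigurationError(
                    f"counts_path: no such file {self.counts_path!r}")
        if not self.contrasts:
            raise ConfigurationError("at least one contrast is required")
        return self


def _jsonable(obj: Any) -> Any:
    """Recursively coerce numpy/pandas scalars into plain JSON types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def report_to_json(report: Mapping[str, Any]) -> str:
    return json.dumps(_jsonable(report), sort_keys=True, indent=2)


def _config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _roc_summary(scores, labels, ci_method: str) -> dict[str, Any]:
    rc = roc_curve(scores, labels, ci_method=ci_method)
    return {
        "auc": rc.auc,
        "ci_low": rc.ci95[0],
        "ci_high": rc.ci95[1],
        "cutoff": rc.optimal_cutoff,
        "sensitivity": rc.optimal_sensitivity,
        "specificity": rc.optimal_specificity,
        "n_case": rc.n_case,
        "n_control": rc.n_control,
    }


def _write_failed_sentinel(output_dir: str | None, stage: str, cause: Exception
                           ) -> None:
    if output_dir is None:
        return
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "FAILED").write_text(f"stage: {stage}\ncause: {cause}\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages and return the machine-readable report.

    Fails fast on configuration problems (unknown contrast groups) before
    any stage runs; a stage failure raises :class:`PipelineStageError`
    naming the stage, after writing a FAILED sentinel next to any partial
    outputs.
    """
    params = config.params
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        failed = out_dir / "FAILED"
        if failed.exists():
            failed.unlink()

    # ---- acquire inputs -------------------------------------------------
    stage = "input"
    try:
        if config.mode == "synthetic":
            cohort_cfg = config.cohort or default_config(seed=config.seed)
            known_groups = set(GROUPS)
            for case, ref in config.contrasts:
                for g in (case, ref):
                    if g not in known_groups:
                        raise ConfigurationError(
                            f"contrast references unknown group {g!r}")
            cohort = generate_cohort(cohort_cfg)
            metadata = cohort.metadata
            true_curves = make_true_curves(cohort_cfg)
            calibration = simulate_calibration(cohort_cfg, true_curves)
            curves = mio.fit_curves_from_calibration(calibration)
            screen_sizes = cohort_cfg.sizes.get("screen")
            counts = None
            if screen_sizes is not None and screen_sizes.ami > 0 \
                    and screen_sizes.control > 0:
                case_counts = simulate_pool_counts(cohort, "AMI")
                ctrl_counts = simulate_pool_counts(cohort, "control")
                counts = pd.DataFrame(
                    {
                        "mirna_id": case_counts.index,
                        "count_case": case_counts.to_numpy(),
                        "count_control": ctrl_counts.to_numpy(),
                    }
                )
            cq = simulate_cq(cohort, true_curves, cohort_cfg)
        else:
            metadata = mio.read_metadata(config.metadata_path)
            known_groups = set(metadata["group"])
            for case, ref in config.contrasts:
                for g in (case, ref):
                    if g not in known_groups:
                        raise ConfigurationError(
                            f"contrast references unknown group {g!r}")
            calibration = mio.read_calibration(config.calibration_path)
            curves = mio.fit_curves_from_calibration(calibration)
            cq = mio.read_cq(config.cq_path)
            counts = (mio.read_counts(config.counts_path)
                      if config.counts_path else None)
    except ConfigurationError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrapped with stage context
        _write_failed_sentinel(config.output_dir, stage, exc)
        raise PipelineStageError(stage, exc) from exc

    report: dict[str, Any] = {
        "format_version": FORMAT_VERSION,
        "provenance": {
            "seed": config.seed,
            "config_sha256": _config_hash(config),
            "mode": config.mode,
        },
    }

    def _run_stage(name: str, fn):
        nonlocal stage
        stage = name
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001
            _write_failed_sentinel(config.output_dir, name, exc)
            raise PipelineStageError(name, exc) from exc

    # ---- screen ---------------------------------------------------------
    def _screen():
        if counts is None:
            return None
        det = detect_mirnas(counts, detection_min=params.detection_min)
        hits = screen_filter(counts, min_copies=params.min_copies,
                             min_fold=params.min_fold_screen)
        passing = hits[hits["passes"]]
        if out_dir is not None:
            mio.write_counts(counts, out_dir / "screen_counts.tsv")
            hits.to_csv(out_dir / "screen_results.tsv", sep="\t", index=False)
        return {
            "n_detected_case": det.n_case,
            "n_detected_control": det.n_control,
            "n_detected_union": det.n_union,
            "n_pass": int(len(passing)),
            "pass_ids": list(passing["mirna_id"]),
        }

    report["screen"] = _run_stage("screen", _screen)

    # ---- quantify -------------------------------------------------------
    def _quantify():
        quant = quantify_samples(cq, curves, params.serum_volume_ml)
        if out_dir is not None:
            mio.write_concentration(quant.concentration,
                                    out_dir / "concentrations.tsv")
            mio.write_metadata(metadata, out_dir / "metadata.tsv")
        return quant

    quant = _run_stage("quantify", _quantify)
    conc = quant.concentration

    # ---- select (training) ---------------------------------------------
    def _select():
        cols = list(conc.columns)
        if params.restrict_to_screen and report["screen"] is not None:
            keep = [c for c in cols if c in set(report["screen"]["pass_ids"])]
            if not keep:
                raise DataError("no quantified miRNA passed the screen filter")
            cols = keep
        res = differential_stats(
            conc[cols], metadata, phase="training",
            alpha=params.alpha, min_fold=params.min_fold_select,
            test_scale=params.test_scale, up_only=params.up_only,
        )
        sel = select_markers(res)
        if out_dir is not None:
            res.to_csv(out_dir / "training_differential.tsv", sep="\t",
                       index=False)
        return res, sel

    train_res, selected = _run_stage("select", _select)
    report["selection"] = {
        "n_tested": int(len(train_res)),
        "selected": list(selected),
        "fold_change": {m: float(train_res.loc[m, "fold_change"])
                        for m in selected},
        "p_value": {m: float(train_res.loc[m, "p_value"]) for m in selected},
    }

    # ---- validate -------------------------------------------------------
    def _validate():
        if not selected:
            return None
        directions = {m: train_res.loc[m, "direction"] for m in selected}
        val = validate_markers(
            conc, metadata, selected, directions,
            alpha=params.alpha, test_scale=params.test_scale,
        )
        if out_dir is not None:
            val.to_csv(out_dir / "validation_results.tsv", sep="\t", index=False)
        return val

    val_res = _run_stage("validate", _validate)
    report["validation"] = (
        None if val_res is None else {
            "consistent": list(val_res.loc[val_res["consistent"], "mirna_id"]),
            "fold_change": {m: float(val_res.loc[m, "fold_change"])
                            for m in val_res.index},
            "p_value": {m: float(val_res.loc[m, "p_value"])
                        for m in val_res.index},
        }
    )

    # ---- risk model + ROC per contrast ----------------------------------
    analysis_meta = metadata[metadata["phase"].isin(["training", "validation"])]

    def _contrast_block(case: str, ref: str):
        sub = analysis_meta[analysis_meta["group"].isin([case, ref])]
        ids = [s for s in sub["sample_id"] if s in conc.index]
        sub = sub.set_index("sample_id").loc[ids]
        labels = (sub["group"] == case).astype(int).to_numpy()
        block: dict[str, Any] = {"case": case, "reference": ref,
                                 "n_case": int(labels.sum()),
                                 "n_reference": int(len(labels) - labels.sum())}
        roc_block: dict[str, Any] = {}

        if selected:
            if params.fit_subset == "training":
                fit_mask = (sub["phase"] == "training").to_numpy()
                if labels[fit_mask].sum() == 0 or (1 - labels[fit_mask]).sum() == 0:
                    fit_mask = np.ones(len(labels), dtype=bool)
            else:
                fit_mask = np.ones(len(labels), dtype=bool)
            model = build_risk_model(
                conc.loc[ids].iloc[fit_mask], labels[fit_mask], selected,
                contrast=(case, ref),
                reference_method=params.reference_method,
            )
            s = dichotomize(conc.loc[ids, selected], model.thresholds)
            scores = compute_rsf(s, model)
            block["risk_model"] = json.loads(model.to_json())
            roc_block["panel"] = _roc_summary(scores.rsf.to_numpy(), labels,
                                              params.ci_method)
            for m in selected:
                roc_block[m] = _roc_summary(conc.loc[ids, m].to_numpy(),
                                            labels, params.ci_method)
            if out_dir is not None:
                tag = f"{case}_vs_{ref}"
                (out_dir / f"risk_model_{tag}.json").write_text(model.to_json())
                scored = s.copy()
                scored["rsf"] = scores.rsf
                scored["rank"] = scores.rank
                scored.insert(0, "sample_id", scored.index)
                scored.to_csv(out_dir / f"risk_scores_{tag}.tsv", sep="\t",
                              index=False)
        for cov in config.covariate_scorers:
            if cov in sub.columns:
                roc_block[cov] = _roc_summary(sub[cov].to_numpy(dtype=float),
                                              labels, params.ci_method)
        block["roc"] = roc_block
        return block

    contrasts_report: dict[str, Any] = {}
    for case, ref in config.contrasts:
        tag = f"{case}_vs_{ref}"
        contrasts_report[tag] = _run_stage(f"contrast:{tag}",
                                           lambda c=case, r=ref: _contrast_block(c, r))
    report["contrasts"] = contrasts_report

    if out_dir is not None:
        (out_dir / "report.json").write_text(report_to_json(report))
        summarize_auc_table(report).to_csv(out_dir / "auc_summary.tsv",
                                           sep="\t", index=False)
    return _jsonable(report)


def summarize_auc_table(report: Mapping[str, Any]) -> pd.DataFrame:
    """One row per (contrast, scorer): AUC, CI, cutoff, sens/spec.

    The combined risk-score row is flagged via ``is_panel``.
    """
    if not report.get("contrasts"):
        raise DataError("report contains no contrasts")
    rows = []
    for tag, block in report["contrasts"].items():
        for scorer, summ in block.get("roc", {}).items():
            rows.append(
                {
                    "contrast": tag,
                    "scorer": scorer,
                    "is_panel": scorer == "panel",
                    "auc": summ["auc"],
                    "ci_low": summ["ci_low"],
                    "ci_high": summ["ci_high"],
                    "cutoff": summ["cutoff"],
                    "sensitivity": summ["sensitivity"],
                    "specificity": summ["specificity"],
                }
            )
    return pd.DataFrame(rows)
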