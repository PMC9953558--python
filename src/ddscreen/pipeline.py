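"""End-to-end orchestration and on-disk formats.

Two entry points mirror the two halves of the workflow:

* :func:`run_simulate` writes a complete synthetic cohort to disk —
  one droplet-amplitude CSV per well, a cohort manifest CSV, and a truth
  sidecar JSON.
* :func:`run_analyze` reads a manifest + droplet CSVs and executes the
  analysis in study order: classify -> quantify -> calibrate the
  false-positive MAF cutoff on the control group -> subtract it from every
  sample -> evaluate the cohort.  Outputs are a per-sample results CSV, a
  calibration JSON per assay and a diagnostic report JSON.

Every output embeds the global seed and a hash of the configuration so
reruns are attributable; all stages are deterministic given (inputs,
config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import calibrate as _calibrate
from . import diagnostics as _diagnostics
from .quantify import SampleResult, SaturationError, quantify_well
from .simulate import (
    CohortConfig,
    DropletSet,
    read_droplet_csv,
    simulate_cohort,
    write_droplet_csv,
)

__all__ = ["PipelineConfig", "run_simulate", "run_analyze",
            "quantify_manifest", "calibrate_results", "evaluate_results"]

logger = logging.getLogger("ddscreen")

MANIFEST_NAME = "manifest.csv"
TRUTH_NAME = "truth.json"
RESULTS_NAME = "results.csv"
REPORT_NAME = "report.json"


@dataclass
class PipelineConfig:
    """Analysis options shared by the CLI and the library entry points."""

    output_dir: str = "ddscreen_out"
    control_groups_for_cutoff: tuple[str, ...] = ("control",)
    control_groups_for_roc: tuple[str, ...] = ("control", "cystitis")
    case_group: str = "UBC"
    delta: float = _calibrate.DEFAULT_DELTA
    thresholds: tuple[float | str, float | str] | str = "auto"
    auto_k: float = 6.0
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the analysis-relevant options (paths excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def run_simulate(cohort: CohortConfig, out_dir: str | Path) -> Path:
    """Simulate a cohort and write droplet CSVs + manifest + truth sidecar.

    Returns the manifest path.  Idempotent given the cohort seed.
    """
    out = Path(out_dir)
    droplet_dir = out / "droplets"
    droplet_dir.mkdir(parents=True, exist_ok=True)
    samples = simulate_cohort(cohort)
    rows = []
    truth: dict[str, dict] = {}
    for sample in samples:
        truth[sample.sample_id] = {
            "group": sample.group,
            "dna_input_copies": sample.dna_input_copies,
            "positive": sample.truth_positive,
            "true_maf_percent": sample.truth_maf,
        }
        for marker, well in sample.wells.items():
            rel = f"droplets/{well.well_id}.csv"
            write_droplet_csv(well, out / rel)
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "group": sample.group,
                    "assay": marker,
                    "path": rel,
                    "true_positive": sample.truth_positive[marker],
                    "true_maf_percent": sample.truth_maf[marker],
                }
            )
    manifest = pd.DataFrame(
        rows, columns=["sample_id", "group", "assay", "path",
                       "true_positive", "true_maf_percent"],
    )
    manifest_path = out / MANIFEST_NAME
    manifest.to_csv(manifest_path, index=False)
    (out / TRUTH_NAME).write_text(json.dumps(
        {"seed": cohort.seed, "samples": truth}, indent=2))
    logger.info("simulated %d samples, %d wells -> %s",
                len(samples), len(rows), out)
    return manifest_path


def quantify_manifest(
    manifest_path: str | Path, config: PipelineConfig
) -> pd.DataFrame:
    """Classify + quantify every well listed in a cohort manifest.

    Per-well failures (e.g. a saturated channel) are logged and excluded;
    the returned frame carries one row per successfully quantified well.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    rows, n_failed = [], 0
    for rec in manifest.itertuples(index=False):
        try:
            droplets = read_droplet_csv(base / rec.path)
            result = quantify_well(
                droplets, assay=rec.assay, thresholds=config.thresholds,
                group=rec.group,
            )
        except (SaturationError, ValueError) as exc:
            n_failed += 1
            logger.warning("well %s/%s excluded: %s", rec.sample_id, rec.assay, exc)
            continue
        rows.append(
            {
                "sample_id": result.sample_id,
                "group": result.group,
                "assay": result.assay,
                "n_droplets": result.n_droplets,
                "n_wt_pos": result.n_wt_positive,
                "n_mut_pos": result.n_mut_positive,
                "c_wt": result.c_wt,
                "c_mut": result.c_mut,
                "raw_maf": result.raw_maf,
            }
        )
    logger.info("quantified %d wells (%d excluded)", len(rows), n_failed)
    df = pd.DataFrame(rows)
    df.attrs["n_failed"] = n_failed
    return df


def calibrate_results(
    results: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, dict[str, _calibrate.CalibrationResult]]:
    """Per-assay cutoff from the control group; subtract it everywhere.

    Returns the results frame extended with corrected_maf and call columns
    plus the per-assay calibration results.
    """
    controls_mask = results["group"].isin(config.control_groups_for_cutoff)
    if not controls_mask.any():
        raise ValueError("no control-group wells available for calibration")
    out = results.copy()
    out["corrected_maf"] = np.nan
    out["call"] = False
    calibrations: dict[str, _calibrate.CalibrationResult] = {}
    for assay_name, sub in results.groupby("assay"):
        ctrl = sub.loc[sub["group"].isin(config.control_groups_for_cutoff), "raw_maf"]
        if ctrl.empty:
            raise ValueError(f"no control wells for assay {assay_name!r}")
        cases = sub.loc[sub["group"] == config.case_group, "raw_maf"]
        calib = _calibrate.determine_cutoff(
            ctrl.to_numpy(), cases.to_numpy() if len(cases) else None,
            delta=config.delta,
        )
        calibrations[assay_name] = calib
        idx = sub.index
        corrected = (sub["raw_maf"] - calib.cutoff).clip(lower=0.0)
        out.loc[idx, "corrected_maf"] = corrected
        out.loc[idx, "call"] = corrected > 0
    return out, calibrations


def evaluate_results(
    corrected: pd.DataFrame, config: PipelineConfig
) -> _diagnostics.DiagnosticReport:
    """Cohort-level diagnostic report from calibrated results."""
    return _diagnostics.evaluate_cohort(
        corrected,
        case_group=config.case_group,
        control_groups=config.control_groups_for_roc,
    )


def run_analyze(manifest_path: str | Path, config: PipelineConfig) -> dict:
    """Full analysis: quantify, calibrate on controls, correct, evaluate.

    Writes results.csv, calibration_<assay>.json and report.json into
    ``config.output_dir`` and returns the in-memory artefacts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"seed": config.seed, "config_hash": config.config_hash()}

    results = quantify_manifest(manifest_path, config)
    if results.empty:
        raise ValueError("no wells could be quantified")
    corrected, calibrations = calibrate_results(results, config)
    report = evaluate_results(corrected, config)

    corrected.to_csv(out / RESULTS_NAME, index=False)
    for assay_name, calib in calibrations.items():
        payload = dataclasses.asdict(calib) | provenance | {
            "quantile_convention": "weighted_average",
            "manifest": str(manifest_path),
        }
        (out / f"calibration_{assay_name}.json").write_text(
            json.dumps(payload, indent=2))
    report_payload = json.loads(report.to_json()) | provenance
    (out / REPORT_NAME).write_text(json.dumps(report_payload, indent=2))
    logger.info("analysis complete: %d wells, report -> %s",
                len(corrected), out / REPORT_NAME)
    return {
        "results": corrected,
        "calibrations": calibrations,
        "report": report,
        "provenance": provenance,
    }
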