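"""In-silico assay-validation experiments.

Reproduces the three bench validation protocols of the assay as seeded
simulation experiments:

* spike-in linearity — wells at known expected MAFs (0.5-50%), several
  replicates each, summarised by the R^2 of observed vs expected MAF;
* false-positive input sweep — wild-type-only wells over a 100-fold DNA
  input range, showing that false-positive mutant *copies* track input
  while false-positive *MAF* does not (the rationale for calibrating the
  blank cutoff on the MAF scale);
* replicate variability — replicate CVs of false-positive MAF in
  wild-type-only wells vs true MAF in mutant-bearing wells, showing the
  randomness signature of the false-positive signal.

The input sweep deliberately spans concentrations up to ~5 copies/droplet,
beyond the reach of the automatic threshold (which needs a sizeable
negative population), so it quantifies with fixed thresholds placed at the
known inter-cluster midpoint of the simulated amplitude model.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import compare_replicate_variability, replicate_cv
from .diagnostics import linearity_r2, spearman
from .quantify import quantify_well
from .simulate import MarkerConfig, SimulationConfig, simulate_well, default_markers

__all__ = [
    "spike_in_linearity",
    "false_positive_input_sweep",
    "replicate_variability_experiment",
]

#: Inter-cluster midpoint of the default amplitude model (negative mean
#: 1000, positive mean 8000), used where thresholds are set explicitly.
MODEL_MIDPOINT = 4500.0


def _spawn(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def spike_in_linearity(
    expected_mafs: Sequence[float] = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0),
    total_copies: int = 5000,
    n_replicates: int = 3,
    n_droplets: int = 20_000,
    mutant_genotype: str = "M1",
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Simulate the spike-in dilution series and score its linearity.

    Each well loads ``total_copies`` templates split between wild type and
    mutant according to the expected MAF.  Returns the per-well table
    (expected_maf, replicate, observed_maf) and the OLS R^2 of observed on
    expected.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for maf in expected_mafs:
        mut = int(round(total_copies * maf / 100.0))
        copies = {"WT": total_copies - mut, mutant_genotype: mut}
        for rep in range(n_replicates):
            well = simulate_well(
                SimulationConfig(copies=copies, n_droplets=n_droplets,
                                 seed=_spawn(rng)),
                well_id=f"spike_{maf}_{rep}",
            )
            result = quantify_well(well)
            rows.append({"expected_maf": maf, "replicate": rep,
                         "observed_maf": result.raw_maf})
    df = pd.DataFrame(rows)
    r2 = linearity_r2(df["expected_maf"], df["observed_maf"])
    return df, r2


def false_positive_input_sweep(
    n_wells: int = 30,
    input_range: tuple[float, float] = (1000.0, 100_000.0),
    epsilon: float = 0.003,
    n_droplets: int = 20_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Wild-type-only wells across a wide DNA input range.

    Returns the per-well table (input_copies, fp_copies_per_ul, fp_maf)
    and the two Spearman correlations against input — positive for
    absolute false-positive copies, near zero for false-positive MAF.
    The low end of the input range keeps the expected misread count at
    ~epsilon * input >= 3 so the MAF is not zero-censored.
    """
    rng = np.random.default_rng(seed)
    lo, hi = input_range
    rows = []
    for i in range(n_wells):
        inp = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        well = simulate_well(
            SimulationConfig(copies={"WT": inp}, epsilon=epsilon,
                             n_droplets=n_droplets, seed=_spawn(rng)),
            well_id=f"sweep_{i}",
        )
        result = quantify_well(well, thresholds=(MODEL_MIDPOINT, MODEL_MIDPOINT))
        rows.append({"input_copies": inp, "fp_copies_per_ul": result.c_mut,
                     "fp_maf": result.raw_maf})
    df = pd.DataFrame(rows)
    stats = {
        "copies_vs_input": spearman(df["fp_copies_per_ul"], df["input_copies"]),
        "maf_vs_input": spearman(df["fp_maf"], df["input_copies"]),
    }
    return df, stats


def replicate_variability_experiment(
    n_per_group: int = 9,
    n_replicates: int = 3,
    input_range: tuple[float, float] = (1000.0, 20_000.0),
    epsilon: float = 0.003,
    n_droplets: int = 20_000,
    marker: MarkerConfig | None = None,
    seed: int = 0,
) -> dict:
    """Replicate CV of false-positive MAF vs true MAF.

    Simulates ``n_per_group`` wild-type-only samples and ``n_per_group``
    mutant-bearing samples (true MAF drawn from the marker's cohort
    distribution), measures each in ``n_replicates`` wells, and compares
    the per-sample CVs (SD as % of the mean MAF) between groups with a
    Mann-Whitney U test.  False-positive MAFs rest on a handful of misread
    molecules, so their replicate CV is far larger than that of a true
    mutant signal of ordinary magnitude.
    """
    marker = marker or default_markers()[0]
    rng = np.random.default_rng(seed)
    lo, hi = input_range

    def measure(copies: dict[str, int]) -> float:
        well = simulate_well(
            SimulationConfig(copies=copies, epsilon=epsilon,
                             n_droplets=n_droplets, seed=_spawn(rng)))
        return quantify_well(well).raw_maf

    control_cvs, case_cvs = [], []
    for _ in range(n_per_group):
        inp = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        mafs = [measure({"WT": inp}) for _ in range(n_replicates)]
        control_cvs.append(replicate_cv(mafs))
    for _ in range(n_per_group):
        inp = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        true_maf = float(marker.draw_maf(rng))
        mut = int(round(inp * true_maf / 100.0))
        copies = {"WT": inp - mut, marker.mutant_genotype: mut}
        mafs = [measure(dict(copies)) for _ in range(n_replicates)]
        case_cvs.append(replicate_cv(mafs))

    comparison = compare_replicate_variability(control_cvs, case_cvs)
    comparison["control_cvs"] = control_cvs
    comparison["case_cvs"] = case_cvs
    return comparison
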