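# ddscreen

Analysis toolkit for two-channel droplet digital PCR (ddPCR) mutation
screening in urine liquid biopsies — from raw droplet amplitudes to a
cohort-level diagnostic report.

Urothelial bladder cancer sheds tumour DNA into urine. Two non-coding
mutational hotspots cover most tumours: the *GPR126* (*ADGRG6*)
sixth-intron enhancer (chr6:142,706,206 G>A and chr6:142,706,209 C>T,
GRCh37) and the *TERT* promoter. A *screening* ddPCR assay detects any of
the *GPR126* variants in a single tube: one primer pair, one HEX-labelled
wild-type probe and three FAM-labelled mutant probes that share a channel,
so any mutation lights FAM but genotypes are not distinguished from one
another. This package implements everything downstream of (or in place of)
the instrument:

- **`ddscreen.assay`** — the screening-assay model: published oligos,
  probe-by-genotype mismatch discrimination, conversion to a single-target
  assay (one mutant probe at triple concentration), amplicon placement
  checks.
- **`ddscreen.simulate`** — a seeded generator of synthetic droplet data:
  exact multinomial partitioning of template molecules into ~20,000
  droplets, a per-molecule *misread* mechanism that reproduces the
  empirical false-positive behaviour of blank samples, two-channel
  amplitude rendering with rain, and full three-group cohorts.
- **`ddscreen.quantify`** — quadrant droplet classification
  (scikit-learn-style `DropletClassifier`) and Poisson inversion
  `lambda = -ln(1 - p)` to copies/µL, giving the mutant allele fraction
  `MAF = 100 · C_mut / (C_wt + C_mut)`.
- **`ddscreen.calibrate`** — the false-positive MAF cutoff: fitted on a
  known-negative control cohort at 100% specificity (`MafCutoff`,
  scikit-learn-style), then *subtracted* from every sample's raw MAF;
  plus replicate-variability (CV) analysis.
- **`ddscreen.diagnostics`** — tie-aware ROC/AUC
  (`AUC = [#(case>control) + ½#(case=control)] / (n₁n₂)`), detection
  rates, OR-combination of the marker panel, and the nonparametric test
  battery (Wilcoxon, Mann–Whitney, Spearman, Fisher exact, OLS R²).
- **`ddscreen.validation`** — in-silico versions of the bench validation
  protocols: spike-in linearity series, false-positive input sweep,
  replicate-CV comparison.
- **`ddscreen.pipeline` / CLI `ddscreen`** — end-to-end orchestration
  (simulate → quantify → calibrate → evaluate) over CSV/JSON files.

Why a MAF cutoff rather than a copy-number cutoff? In wild-type-only
samples the absolute false-positive mutant copies rise with DNA input
(Spearman r ≈ +0.99 in the simulator), while the false-positive MAF stays
flat at roughly the misread rate. A threshold on MAF therefore transfers
across samples of very different DNA content; a threshold on copies does
not.

## Worked example

Simulate a small cohort (10 controls, 4 cystitis, 16 cancer samples, one
well per marker) and analyse it end to end:

```python
import ddscreen as d
from ddscreen.pipeline import PipelineConfig, run_simulate, run_analyze

cohort = d.CohortConfig(n_control=10, n_cystitis=4, n_ubc=16,
                        n_droplets=4000, dna_input_range=(100, 4000), seed=3)
manifest = run_simulate(cohort, "cohort_demo")
art = run_analyze(manifest, PipelineConfig(output_dir="cohort_demo", seed=3))
calib = art["calibrations"]["GPR126"]
print(f"GPR126 cutoff: {calib.cutoff:.2f}% "
      f"(control max {calib.control_max:.2f}%, median {calib.control_median:.2f}%)")
print(art["report"].to_text())
```

prints

```
GPR126 cutoff: 1.95% (control max 0.84%, median 0.20%)
marker         cases detected  sens %  spec %    AUC
GPR126            16        5    31.2   100.0  0.656
TERT              16        8    50.0   100.0  0.750
GPR126+TERT       16       11    68.8   100.0  0.844
case overlap: both=2 either=11 neither=5
```

Reading the output: the control wells' false-positive MAFs top out at
0.84%, so the calibrated cutoff (placed between the control maximum and
the smallest case MAF) is 1.95%; after subtraction every control is
negative (specificity 100%) and 5 of 16 cancer samples remain positive for
GPR126, 8 for TERT, 11 for at least one marker. With all negatives at
exactly 0, each AUC equals (1 + sensitivity)/2 — e.g. 0.844 =
(1 + 11/16)/2 for the combined panel. The same workflow is available from
the shell: `ddscreen run-all --out cohort_demo --seed 3 ...`.

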