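# Methods

## The measurement model

A ddPCR well partitions a reaction of volume ~17 µL into D droplets of
nominal volume v = 0.85 nL (Bio-Rad QX200 geometry; the droplet count and
volume are configurable, defaults D = 20,000). Template molecules land in
droplets independently and uniformly; after endpoint PCR a droplet is
positive on a channel iff it received at least one template detectable on
that channel. With positive fraction p on a channel, the mean occupancy is
the Poisson inversion

    lambda = -ln(1 - p),    C [copies/µL] = lambda / (v · 10⁻³)

and the mutant allele fraction of a well is
MAF = 100 · C_mut / (C_wt + C_mut) (%). The 95% CI on C propagates the
binomial SE of p through the log transform (delta method); at D = 20,000
this is indistinguishable from exact ratio intervals. p = 1 (saturation)
has no finite lambda and raises an error rather than returning a guess.
Double-positive droplets count toward both channels' positive totals —
standard duplex bookkeeping; the two channels are quantified independently.

## The screening assay model

The shipped assay targets the two enhancer substitutions in the *GPR126*
sixth intron: one primer pair (0.9 µM each), one HEX wild-type probe
(0.25 µM) and three FAM mutant probes (0.083 µM each) covering G/A, C/T
and G/A + C/T genotypes; amplicon 121 bp. All sequences are stored 5'→3'
as synthesised; probes hybridise to the antisense strand, i.e. they read
along the sense strand, so probe-vs-template comparison is direct string
matching and the probe-by-genotype mismatch matrix has a zero diagonal
with off-diagonal entries 1 or 2 (the two variant sites are three bases
apart, inside every probe). Converting to a single-target assay keeps the
primers and wild-type probe bit-identical, retains one FAM probe and
triples its concentration, restoring the 3 × 0.083 ≈ 0.25 µM FAM/HEX
balance (checked with a 0.005 µM tolerance, since 0.249 ≠ 0.25 exactly).

The genomic sense-strand sequence between the primers is not published.
Amplicon-placement validation therefore ships with a *synthetic* reference
fragment (`synthetic_reference_fragment`): the printed primers and probe
region embedded at offsets consistent with their GRCh37 coordinates
(fragment chr6:142,705,865–142,706,619, amplicon start 142,706,150), with
seeded random filler elsewhere. It exercises the placement logic — unique
priming sites, forward-start-to-reverse-end length — not the human genome;
given a real reference FASTA the same check runs against it unchanged.

## The synthetic-data generator

`partition_templates` assigns each molecule to a droplet uniformly at
random (multinomial), so per-genotype totals are conserved *exactly* and
Poisson statistics emerge in the limit — this makes conservation testable
as an identity rather than an approximation.

**Misreads.** Each wild-type molecule is independently flagged misread
with probability epsilon (default 0.003); a droplet holding a misread
molecule renders the mutant channel positive (and not the wild-type
channel for that molecule). Modelling the misread per *molecule* rather
than per droplet makes absolute false-positive copies proportional to DNA
input while the false-positive MAF concentrates near epsilon regardless of
input — the empirically observed behaviour of blank urinary DNA, and the
reason the blank cutoff is defined on the MAF scale. epsilon = 0.003 puts
the control-group false-positive MAF at the observed order of magnitude
(median ≈ 0.3%).

**Amplitudes.** Per channel, negatives draw from N(1000, 150²), positives
from N(8000, 400²), and a rain_fraction (default 0.002) of positive draws
lands uniformly between the cluster means. These numbers only shape the
scatter geometry; classification tests additionally use a well-separated,
rain-free model where truth recovery must be exact.

**Cohorts.** Default group sizes are the study's 50 control / 22 cystitis
/ 70 cancer samples, one well per marker. Total template input per well is
log-uniform over 200–20,000 copies (the data vary over orders of
magnitude; the upper end keeps mean occupancy ≤ 1, inside the automatic
threshold's working range — see below). A cancer sample is truly positive
for a marker with the study's detection probability (25/70 for GPR126,
40/70 for TERT, independent across markers); positive samples draw a true
MAF from a log-normal matched to the published cohort summaries
(GPR126 21.61 [8.30–44.52] %, TERT 28.29 [19.03–38.08] %) and the input
splits between mutant and wild-type copies accordingly. mu = ln(median);
sigma = ln(q75/q25)/(2 · 0.6745). The printed IQRs are asymmetric about
their medians in log space, so a two-parameter log-normal misses each
quartile by ~12%; draws are clipped to (0, 100] (resampling instead of
clipping would drag the median ~16% below the target). Control and
cystitis samples carry zero true mutant copies; their mutant signal is
misread-driven only.

**What the generator does not emulate:** PCR efficiency/cycle kinetics,
droplet volume variation, probe cross-hybridisation shoulders, sample
degradation, extraction-kit effects, or correlated marker positivity
(the observed 18/70 dual positivity slightly exceeds independence).
Passing tests show the *analysis* chain is correct under the stated
generative model, not that the assay performs identically on real urine.

## Droplet classification

Quadrant thresholding: a droplet is positive on a channel iff its
amplitude exceeds that channel's threshold. Automatic thresholds place
each cutoff at the robust centre of the channel's negative (lower) mode
plus k robust SDs (default k = 6, conservative against rain). The lower
mode is located from low quantiles only: sigma_hat = (P25 − P5)/0.9704
(the standard-normal quantile gap) and centre = P25 + 0.6745 · sigma_hat.
This needs no labels, returns exact-zero false positives on an
all-negative channel at D = 20,000 (the threshold sits ~6 sigma out), and
stays anchored in the negative cluster while at least ~25% of droplets are
negative, i.e. mean occupancy up to ~1.4. Wells loaded beyond that (the
false-positive input sweep deliberately reaches lambda ≈ 5) are quantified
with fixed thresholds at the known inter-cluster midpoint, exactly as an
operator would gate a saturated-looking well manually; in practice such
samples are diluted and rerun. Degenerate amplitude distributions (zero
lower-mode spread) and wells under 100 droplets are errors in auto mode.

## Cutoff calibration

The false-positive cutoff is the ROC operating point with full
specificity on the calibration controls: the midpoint between the largest
control MAF and the smallest case MAF exceeding it; when no case brackets
the control maximum (or no cases are supplied) the cutoff is
control_max + delta with declared offset delta = 0.05 percentage points.
The exact coordinate convention that commercial statistics packages use to
report such cutoffs is not recoverable from a printed value, so delta is a
documented convention, not a reproduction. The cutoff is then subtracted
from every sample's raw MAF (clipped at 0) and a sample is called positive
iff the corrected MAF exceeds 0 — controls are negative by construction,
so specificity on the calibration set is exactly 100% for any input.
By default only the healthy-volunteer group calibrates the cutoff
(configurable); the ROC evaluation uses volunteers + cystitis as the
negative class — with every negative at 0 after subtraction the AUC is
insensitive to this choice and reduces to (1 + sensitivity)/2.

Quantile convention throughout: weighted average (linear interpolation),
matching mainstream statistics packages. Replicate variability uses the
sample SD (n−1) as percent of the mean; n−1 is a declared choice.

## Statistics

The tie-aware AUC is computed from joint midranks (Mann–Whitney U
normalisation) and cross-checked in tests against the O(n₁n₂) pairwise
half-credit count and against the U statistic itself. Wilcoxon
signed-rank (zeros dropped, exact p when ≤ 25 untied non-zero pairs),
Mann–Whitney U (exact when the smaller group ≤ 8 and untied), Spearman,
Fisher exact and OLS R² delegate to scipy.stats behind the package's
interfaces. All-equal paired samples are flagged degenerate rather than
raised; an all-tied Mann–Whitney comparison returns U at its null mean
with p = 1. No multiple-testing correction is applied, matching the
study-style reporting.

## Problem sizes and determinism

Every stochastic routine is a pure function of an integer seed
(numpy Generator; well seeds spawned from the cohort seed). The shipped
validation experiments use 30 wells (input sweep), 7 × 3 wells at 20,000
droplets (linearity series), and 9 + 9 samples × 3 replicates
(variability comparison); test-suite cohorts are scaled to a few thousand
droplets with the DNA input range scaled proportionally, keeping
occupancy in the quantifiable range. These sizes were chosen so the full
suite and the acceptance script each run in well under a minute while the
binomial/Poisson error bands the tests assert remain narrow.

## Known limitations

- Quadrant gating only; no multi-cluster automatic gating (sufficient for
  this two-channel geometry, not for higher-order multiplexes).
- The automatic threshold assumes a visible negative population
  (lambda ≲ 1.4) and a unimodal negative cluster.
- The misread mechanism is a phenomenological stand-in for whatever
  mixture of polymerase error, probe cross-reactivity and droplet
  artefacts produces false positives on real instruments; it reproduces
  the input-scaling signature, not the mechanism.
- Concentrations are reported per µL of reaction mixture only; no
  back-conversion to per-mL-urine.
- The cutoff procedure is cohort-level; no per-sample rare-event
  limit-of-detection modelling.
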