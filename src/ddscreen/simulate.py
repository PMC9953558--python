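"""Synthetic two-channel ddPCR data generator.

Emulates the raw instrument output of a duplex/multiplex droplet digital
PCR experiment: template molecules are partitioned into ~20,000 droplets,
each droplet ends up positive or negative per fluorescence channel, and the
read-out is a pair of endpoint amplitudes per droplet.

The one non-standard ingredient is the *misread* mechanism: each wild-type
template molecule independently renders its droplet mutant-channel
positive with a small probability ``epsilon``.  This reproduces the
empirical signature of ddPCR false positives in known-negative samples —
absolute false-positive copies scale with DNA input while the
false-positive mutant allele fraction (MAF) stays at ~epsilon regardless
of input, which is why a blank cutoff must be set on the MAF rather than
on absolute concentration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChannelAmplitudeModel",
    "AmplitudeModel",
    "SimulationConfig",
    "MarkerConfig",
    "CohortConfig",
    "WellOccupancy",
    "DropletSet",
    "SampleTruth",
    "CohortSample",
    "partition_templates",
    "apply_misread",
    "render_amplitudes",
    "simulate_well",
    "simulate_cohort",
    "lognormal_from_median_iqr",
    "write_droplet_csv",
    "read_droplet_csv",
]

MUTANT_GENOTYPES = ("M1", "M2", "M1M2")

# standard-normal quantile of 0.75; converts an IQR in log space to sigma
_Z75 = stats.norm.ppf(0.75)


@dataclass(frozen=True)
class ChannelAmplitudeModel:
    """Endpoint fluorescence geometry for one detection channel."""

    negative_mean: float = 1000.0
    negative_sd: float = 150.0
    positive_mean: float = 8000.0
    positive_sd: float = 400.0
    rain_fraction: float = 0.002

    def __post_init__(self) -> None:
        if self.positive_mean <= self.negative_mean:
            raise ValueError("positive cluster mean must exceed negative mean")
        if not 0 <= self.rain_fraction < 1:
            raise ValueError("rain_fraction must be in [0, 1)")


@dataclass(frozen=True)
class AmplitudeModel:
    """Two-channel amplitude geometry (FAM = mutant, HEX = wild type)."""

    fam: ChannelAmplitudeModel = field(default_factory=ChannelAmplitudeModel)
    hex: ChannelAmplitudeModel = field(default_factory=ChannelAmplitudeModel)


def well_separated_model() -> AmplitudeModel:
    """Amplitude model with >10 SD cluster separation and no rain."""
    ch = ChannelAmplitudeModel(1000.0, 100.0, 8000.0, 100.0, rain_fraction=0.0)
    return AmplitudeModel(fam=ch, hex=ch)


@dataclass(frozen=True)
class SimulationConfig:
    """One simulated well.

    ``copies`` maps genotype (``"WT"``, ``"M1"``, ``"M2"``, ``"M1M2"``) to
    the number of template molecules loaded into the well.  ``epsilon`` is
    the per-WT-molecule misread probability.  Droplet volume is the Bio-Rad
    nominal 0.85 nL.
    """

    copies: Mapping[str, int]
    n_droplets: int = 20_000
    droplet_volume_nl: float = 0.85
    epsilon: float = 0.0
    amplitude_model: AmplitudeModel = field(default_factory=AmplitudeModel)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet_volume_nl must be positive")
        if any(c < 0 for c in self.copies.values()):
            raise ValueError("copy numbers must be non-negative")
        if not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must be in [0, 1]")

    @property
    def true_maf_percent(self) -> float:
        """Ground-truth mutant allele fraction implied by the loaded copies."""
        mut = sum(self.copies.get(g, 0) for g in MUTANT_GENOTYPES)
        wt = self.copies.get("WT", 0)
        if mut + wt == 0:
            return float("nan")
        return 100.0 * mut / (mut + wt)


@dataclass
class WellOccupancy:
    """Per-droplet template molecule counts, by genotype, plus misreads."""

    counts: dict[str, np.ndarray]  # genotype -> (n_droplets,) int array
    misread: np.ndarray | None = None  # misread WT molecules per droplet

    @property
    def n_droplets(self) -> int:
        return len(next(iter(self.counts.values())))

    def mutant_positive(self) -> np.ndarray:
        """Droplets that render mutant-channel positive (true mutant or misread)."""
        pos = np.zeros(self.n_droplets, dtype=bool)
        for g in MUTANT_GENOTYPES:
            if g in self.counts:
                pos |= self.counts[g] > 0
        if self.misread is not None:
            pos |= self.misread > 0
        return pos

    def wild_type_positive(self) -> np.ndarray:
        """Droplets with at least one non-misread WT molecule."""
        wt = self.counts.get("WT")
        if wt is None:
            return np.zeros(self.n_droplets, dtype=bool)
        misread = self.misread if self.misread is not None else 0
        return (wt - misread) > 0


@dataclass
class SampleTruth:
    """Ground truth carried alongside simulated amplitudes."""

    occupancy: WellOccupancy
    copies: dict[str, int]
    epsilon: float
    true_maf_percent: float


@dataclass
class DropletSet:
    """Per-droplet endpoint amplitudes for one well.

    ``amplitudes`` has shape (N, 2) with column 0 = FAM (mutant channel)
    and column 1 = HEX (wild-type channel).
    """

    amplitudes: np.ndarray
    well_id: str = "well"
    sample_id: str = "sample"
    truth: SampleTruth | None = None

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 2 or self.amplitudes.shape[1] != 2:
            raise ValueError("amplitudes must be an (N, 2) array [FAM, HEX]")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")

    @property
    def n_droplets(self) -> int:
        return len(self.amplitudes)

    @property
    def fam(self) -> np.ndarray:
        return self.amplitudes[:, 0]

    @property
    def hex(self) -> np.ndarray:
        return self.amplitudes[:, 1]


# ---------------------------------------------------------------------------
# Core generative steps
# ---------------------------------------------------------------------------

def partition_templates(
    copies: Mapping[str, int], n_droplets: int, seed: int | np.random.Generator | None = None
) -> WellOccupancy:
    """Distribute template molecules uniformly at random over droplets.

    Each molecule independently picks one of ``n_droplets`` droplets
    (multinomial partitioning), so per-genotype totals are conserved
    exactly; Poisson occupancy statistics emerge in the usual limit.
    """
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts: dict[str, np.ndarray] = {}
    for genotype, n in copies.items():
        if n < 0:
            raise ValueError("copy numbers must be non-negative")
        assignment = rng.integers(0, n_droplets, size=int(n))
        counts[genotype] = np.bincount(assignment, minlength=n_droplets).astype(np.int64)
    return WellOccupancy(counts=counts)


def apply_misread(
    occupancy: WellOccupancy, epsilon: float,
    seed: int | np.random.Generator | None = None,
) -> WellOccupancy:
    """Flag wild-type molecules as misread, independently with prob ``epsilon``.

    A droplet holding >= 1 misread molecule will later render the mutant
    channel positive.  Expected misread total is ``epsilon * WT copies``.
    """
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    wt = occupancy.counts.get("WT")
    if wt is None:
        misread = np.zeros(occupancy.n_droplets, dtype=np.int64)
    else:
        misread = rng.binomial(wt, epsilon).astype(np.int64)
    return WellOccupancy(counts=dict(occupancy.counts), misread=misread)


def render_amplitudes(
    occupancy: WellOccupancy,
    model: AmplitudeModel | None = None,
    seed: int | np.random.Generator | None = None,
    well_id: str = "well",
    sample_id: str = "sample",
) -> DropletSet:
    """Turn droplet occupancy into endpoint fluorescence amplitudes.

    HEX is drawn from its positive cluster for droplets holding >= 1
    non-misread WT molecule; FAM for droplets holding >= 1 mutant or
    misread molecule; droplets positive on both channels draw both high
    (the double-positive cluster); empty droplets draw both negative.
    A ``rain_fraction`` share of positive draws lands uniformly between
    the cluster means instead.
    """
    model = model or AmplitudeModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = occupancy.n_droplets
    fam_pos = occupancy.mutant_positive()
    hex_pos = occupancy.wild_type_positive()

    amplitudes = np.empty((n, 2))
    for col, (positive, ch) in enumerate(
        ((fam_pos, model.fam), (hex_pos, model.hex))
    ):
        amp = rng.normal(ch.negative_mean, ch.negative_sd, size=n)
        n_pos = int(positive.sum())
        if n_pos:
            pos_amp = rng.normal(ch.positive_mean, ch.positive_sd, size=n_pos)
            if ch.rain_fraction > 0:
                is_rain = rng.random(n_pos) < ch.rain_fraction
                n_rain = int(is_rain.sum())
                if n_rain:
                    pos_amp[is_rain] = rng.uniform(
                        ch.negative_mean, ch.positive_mean, size=n_rain
                    )
            amp[positive] = pos_amp
        amplitudes[:, col] = amp
    return DropletSet(amplitudes=amplitudes, well_id=well_id, sample_id=sample_id)


def simulate_well(config: SimulationConfig, well_id: str = "well",
                  sample_id: str = "sample") -> DropletSet:
    """Partition, misread and render one well; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    occ = partition_templates(config.copies, config.n_droplets, rng)
    occ = apply_misread(occ, config.epsilon, rng)
    droplets = render_amplitudes(occ, config.amplitude_model, rng,
                                 well_id=well_id, sample_id=sample_id)
    droplets.truth = SampleTruth(
        occupancy=occ,
        copies={k: int(v) for k, v in config.copies.items()},
        epsilon=config.epsilon,
        true_maf_percent=config.true_maf_percent,
    )
    return droplets


# ---------------------------------------------------------------------------
# Cohort-level generation
# ---------------------------------------------------------------------------

def lognormal_from_median_iqr(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """(mu, sigma) of a log-normal matched to a printed median and IQR.

    mu = ln(median); sigma is fitted from the quartile ratio in log space,
    sigma = ln(q75/q25) / (2 * z_0.75).  A printed IQR that is asymmetric
    about the median on the log scale cannot be matched exactly by a
    two-parameter log-normal; this choice splits the misfit between the
    two quartiles.
    """
    q25, q75 = iqr
    if not 0 < q25 <= median <= q75:
        raise ValueError("median must lie within the IQR and all must be positive")
    mu = np.log(median)
    sigma = np.log(q75 / q25) / (2 * _Z75)
    return float(mu), float(sigma)


@dataclass(frozen=True)
class MarkerConfig:
    """One mutation marker of the urine panel, as simulated in UBC samples.

    ``positivity`` is the probability a UBC sample truly carries the
    mutation in its urinary DNA; positive samples draw a true MAF (%) from
    a log-normal parameterised by the published cohort median and IQR,
    clipped to (0, 100].
    """

    name: str
    positivity: float
    maf_median: float
    maf_iqr: tuple[float, float]
    mutant_genotype: str = "M1"

    def __post_init__(self) -> None:
        if not 0 <= self.positivity <= 1:
            raise ValueError("positivity must be in [0, 1]")
        lognormal_from_median_iqr(self.maf_median, self.maf_iqr)  # validates

    def draw_maf(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        mu, sigma = lognormal_from_median_iqr(self.maf_median, self.maf_iqr)
        draw = rng.lognormal(mu, sigma, size=size)
        return np.clip(draw, None, 100.0)


def default_markers() -> tuple[MarkerConfig, ...]:
    """The two-marker urine panel at its published cohort parameters."""
    return (
        MarkerConfig("GPR126", positivity=25 / 70, maf_median=21.61, maf_iqr=(8.30, 44.52)),
        MarkerConfig("TERT", positivity=40 / 70, maf_median=28.29, maf_iqr=(19.03, 38.08)),
    )


@dataclass(frozen=True)
class CohortConfig:
    """A simulated three-group urine cohort.

    Group sizes default to the study cohort: 50 healthy volunteers, 22
    cystitis patients, 70 urothelial bladder cancer (UBC) patients.
    Total template input per well is log-uniform over ``dna_input_range``
    (orders of magnitude, as in real urine) and is split between wild-type
    and mutant copies by the sample's true MAF.  Control and cystitis
    samples carry no true mutant templates; any mutant signal there arises
    from the misread mechanism alone.
    """

    n_control: int = 50
    n_cystitis: int = 22
    n_ubc: int = 70
    dna_input_range: tuple[float, float] = (200.0, 20_000.0)
    markers: tuple[MarkerConfig, ...] = field(default_factory=default_markers)
    epsilon: float = 0.003
    n_droplets: int = 20_000
    droplet_volume_nl: float = 0.85
    amplitude_model: AmplitudeModel = field(default_factory=AmplitudeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_cystitis, self.n_ubc) < 0:
            raise ValueError("group sizes must be non-negative")
        lo, hi = self.dna_input_range
        if not 0 < lo <= hi:
            raise ValueError("dna_input_range must be positive and ordered")
        if not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must be in [0, 1]")


@dataclass
class CohortSample:
    """Simulated per-sample record: metadata, truth, one well per marker."""

    sample_id: str
    group: str  # control | cystitis | UBC
    dna_input_copies: int
    truth_positive: dict[str, bool]
    truth_maf: dict[str, float]  # % per marker; 0 where negative
    wells: dict[str, DropletSet]  # marker name -> droplets


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def simulate_cohort(config: CohortConfig) -> list[CohortSample]:
    """Simulate every sample of the cohort, one well per marker assay.

    Ground-truth positivity and MAF are recorded per sample and marker.
    Output is a pure function of the config (seeded).
    """
    rng = np.random.default_rng(config.seed)
    groups = (
        ["control"] * config.n_control
        + ["cystitis"] * config.n_cystitis
        + ["UBC"] * config.n_ubc
    )
    samples: list[CohortSample] = []
    for i, group in enumerate(groups):
        sample_id = f"{group}_{i:03d}"
        total = int(round(_log_uniform(rng, *config.dna_input_range)))
        truth_pos: dict[str, bool] = {}
        truth_maf: dict[str, float] = {}
        wells: dict[str, DropletSet] = {}
        for marker in config.markers:
            positive = group == "UBC" and rng.random() < marker.positivity
            maf = float(marker.draw_maf(rng)) if positive else 0.0
            mut = int(round(total * maf / 100.0)) if positive else 0
            copies = {"WT": total - mut, marker.mutant_genotype: mut}
            well_seed = int(rng.integers(0, 2**31 - 1))
            well_cfg = SimulationConfig(
                copies=copies,
                n_droplets=config.n_droplets,
                droplet_volume_nl=config.droplet_volume_nl,
                epsilon=config.epsilon,
                amplitude_model=config.amplitude_model,
                seed=well_seed,
            )
            wells[marker.name] = simulate_well(
                well_cfg, well_id=f"{sample_id}_{marker.name}", sample_id=sample_id
            )
            truth_pos[marker.name] = positive
            truth_maf[marker.name] = well_cfg.true_maf_percent if positive else 0.0
        samples.append(
            CohortSample(sample_id, group, total, truth_pos, truth_maf, wells)
        )
    return samples


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_droplet_csv(droplets: DropletSet, path: str | Path) -> None:
    """One row per droplet: sample_id, well_id, fam_amplitude, hex_amplitude."""
    df = pd.DataFrame(
        {
            "sample_id": droplets.sample_id,
            "well_id": droplets.well_id,
            "fam_amplitude": droplets.fam,
            "hex_amplitude": droplets.hex,
        }
    )
    df.to_csv(path, index=False, float_format="%.2f")


def read_droplet_csv(
    path: str | Path,
    fam_column: str = "fam_amplitude",
    hex_column: str = "hex_amplitude",
) -> DropletSet:
    """Read a droplet amplitude table (column names configurable)."""
    df = pd.read_csv(path)
    for col in (fam_column, hex_column):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    sample_id = str(df["sample_id"].iloc[0]) if "sample_id" in df else "sample"
    well_id = str(df["well_id"].iloc[0]) if "well_id" in df else "well"
    return DropletSet(
        amplitudes=np.column_stack([df[fam_column].to_numpy(float),
                                    df[hex_column].to_numpy(float)]),
        well_id=well_id,
        sample_id=sample_id,
    )
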