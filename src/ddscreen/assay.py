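"""Multiplex ddPCR screening-assay model.

A *screening* assay detects any of several hotspot mutations in a single
tube: one primer pair, one HEX-labelled wild-type hydrolysis probe, and one
FAM-labelled probe per mutant genotype.  All mutant probes share the FAM
channel, so any mutation lights up the mutant channel but individual
genotypes are not distinguished from one another.

The concrete assay shipped here targets the two recurrent substitutions in
the sixth-intron enhancer of *GPR126* (*ADGRG6*), chr6:142,706,206 G>A and
chr6:142,706,209 C>T (GRCh37), which together with their co-occurrence give
four template genotypes: WT, M1 (G/A), M2 (C/T) and M1M2 (both).

All oligo sequences are stored 5'->3' as synthesised.  Probes hybridise to
the antisense strand, i.e. their sequences read along the sense strand, so
probe-vs-template comparison is direct string matching on the sense strand.
Coordinates are 1-based inclusive, GRCh37.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio import SeqIO

__all__ = [
    "GenomicVariant",
    "Oligo",
    "AssayDefinition",
    "ValidationReport",
    "InvalidSequenceError",
    "AmbiguousPrimingError",
    "reverse_complement",
    "mismatch_count",
    "genotype_templates",
    "discrimination_matrix",
    "to_single_target_assay",
    "validate_assay",
    "gpr126_screening_assay",
    "tert_single_assay",
    "synthetic_reference_fragment",
    "read_reference_fragment",
]

_DNA_ALPHABET = frozenset("ACGT")

#: Tolerance (µM) for the "total FAM probe ~ HEX probe concentration" check.
#: Tripling 0.083 gives 0.249, not 0.25 exactly; equality is clearly intended.
CONCENTRATION_TOL_UM = 0.005


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside {A, C, G, T} or is empty."""


class AmbiguousPrimingError(ValueError):
    """A primer is absent from, or occurs more than once in, a reference."""


def _check_dna(seq: str, what: str = "sequence") -> str:
    if not seq:
        raise InvalidSequenceError(f"empty {what}")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise InvalidSequenceError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of a strict-ACGT DNA string (an involution)."""
    _check_dna(seq)
    return str(Seq(seq).reverse_complement())


def mismatch_count(a: str, b: str) -> int:
    """Hamming distance between two equal-length DNA strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class GenomicVariant:
    """A single-nucleotide substitution, 1-based GRCh37 coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError("pos must be positive (1-based)")
        for base, name in ((self.ref, "ref"), (self.alt, "alt")):
            if base not in _DNA_ALPHABET:
                raise InvalidSequenceError(f"{name} must be a single A/C/G/T base")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


@dataclass(frozen=True)
class Oligo:
    """One synthetic oligonucleotide of the reaction mixture.

    ``sequence`` is 5'->3'; ``concentration`` is µM in the final ddPCR mix.
    ``target_genotype`` names the template a probe perfectly matches
    (``"WT"``, ``"M1"``, ...); it is ``None`` for primers.
    """

    name: str
    sequence: str
    role: str  # forward_primer | reverse_primer | probe
    fluorophore: str = "none"  # HEX | FAM | none
    quencher: str = "none"  # BHQ1 | none
    concentration: float = 0.0
    target_genotype: str | None = None

    def __post_init__(self) -> None:
        _check_dna(self.sequence, f"oligo {self.name!r}")
        if self.role not in {"forward_primer", "reverse_primer", "probe"}:
            raise ValueError(f"unknown oligo role {self.role!r}")
        if self.role == "probe" and self.fluorophore == "none":
            raise ValueError("probes must carry a fluorophore")
        if self.role != "probe" and self.fluorophore != "none":
            raise ValueError("primers must not carry a fluorophore")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive (µM)")


@dataclass(frozen=True)
class AssayDefinition:
    """A two-channel duplex/multiplex ddPCR assay.

    ``probe_region_start`` is the 1-based genomic coordinate of the first
    base of the wild-type probe on the sense strand; genotype templates are
    derived by substituting each covered variant at its offset into the
    wild-type probe sequence.
    """

    name: str
    oligos: tuple[Oligo, ...]
    genotypes: tuple[str, ...]
    variants: dict[str, GenomicVariant]  # genotype component -> variant
    amplicon_length: int
    probe_region_start: int
    wild_type_channel: str = "HEX"
    mutant_channel: str = "FAM"

    def __post_init__(self) -> None:
        if len(self.forward_primers) != 1 or len(self.reverse_primers) != 1:
            raise ValueError("assay needs exactly one forward and one reverse primer")
        if len(self.wild_type_probes) != 1:
            raise ValueError("assay needs exactly one HEX (wild-type) probe")
        if not self.mutant_probes:
            raise ValueError("assay needs at least one FAM (mutant) probe")
        primer_span = sum(len(p.sequence) for p in self.forward_primers + self.reverse_primers)
        if self.amplicon_length <= primer_span:
            raise ValueError("amplicon_length must exceed the combined primer length")

    # -- convenience views -------------------------------------------------
    @property
    def forward_primers(self) -> tuple[Oligo, ...]:
        return tuple(o for o in self.oligos if o.role == "forward_primer")

    @property
    def reverse_primers(self) -> tuple[Oligo, ...]:
        return tuple(o for o in self.oligos if o.role == "reverse_primer")

    @property
    def probes(self) -> tuple[Oligo, ...]:
        return tuple(o for o in self.oligos if o.role == "probe")

    @property
    def wild_type_probes(self) -> tuple[Oligo, ...]:
        return tuple(o for o in self.probes if o.fluorophore == self.wild_type_channel)

    @property
    def mutant_probes(self) -> tuple[Oligo, ...]:
        return tuple(o for o in self.probes if o.fluorophore == self.mutant_channel)

    # -- serialisation -----------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "genotypes": list(self.genotypes),
            "variants": {
                k: {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt}
                for k, v in self.variants.items()
            },
            "amplicon_length": self.amplicon_length,
            "probe_region_start": self.probe_region_start,
            "wild_type_channel": self.wild_type_channel,
            "mutant_channel": self.mutant_channel,
            "oligos": [
                {
                    "name": o.name,
                    "sequence": o.sequence,
                    "role": o.role,
                    "fluorophore": o.fluorophore,
                    "quencher": o.quencher,
                    "concentration": o.concentration,
                    "target_genotype": o.target_genotype,
                }
                for o in self.oligos
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AssayDefinition":
        d = json.loads(text)
        return cls(
            name=d["name"],
            oligos=tuple(Oligo(**o) for o in d["oligos"]),
            genotypes=tuple(d["genotypes"]),
            variants={k: GenomicVariant(**v) for k, v in d["variants"].items()},
            amplicon_length=d["amplicon_length"],
            probe_region_start=d["probe_region_start"],
            wild_type_channel=d["wild_type_channel"],
            mutant_channel=d["mutant_channel"],
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_assay`; ``ok`` iff every check passed."""

    checks: list[tuple[str, bool, str]] = field(default_factory=list)
    amplicon_length: int | None = None
    forward_primer_start: int | None = None
    reverse_primer_end: int | None = None

    def add(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks.append((name, passed, detail))

    @property
    def ok(self) -> bool:
        return all(passed for _, passed, _ in self.checks)


def _strip(seq: str) -> str:
    """Drop the whitespace used to group printed sequences into triplets."""
    return "".join(seq.split())


def genotype_templates(assay: AssayDefinition) -> dict[str, str]:
    """Sense-strand template sequence of the probe region per genotype.

    The wild-type probe sequence is the WT template; each mutant genotype
    substitutes its component variants at their genomic offsets.  Composite
    genotypes name their components joined without separator (``"M1M2"``).
    """
    wt = assay.wild_type_probes[0].sequence
    out: dict[str, str] = {}
    for gt in assay.genotypes:
        tmpl = list(wt)
        for comp, var in assay.variants.items():
            if comp in gt and gt != "WT":
                off = var.pos - assay.probe_region_start
                if not 0 <= off < len(tmpl):
                    raise ValueError(f"variant {comp} outside the probe region")
                if tmpl[off] != var.ref:
                    raise ValueError(
                        f"reference base mismatch for {comp}: probe has {tmpl[off]}, "
                        f"variant expects {var.ref}"
                    )
                tmpl[off] = var.alt
        out[gt] = "".join(tmpl)
    return out


def discrimination_matrix(assay: AssayDefinition) -> "np.ndarray":
    """Probe-by-genotype mismatch-count matrix.

    Row order follows ``assay.probes``; column order ``assay.genotypes``.
    Each probe must align to the probe region (equal length); under the
    matched ordering the diagonal is zero — every probe perfectly matches
    exactly its own target genotype.
    """
    templates = genotype_templates(assay)
    mat = np.zeros((len(assay.probes), len(assay.genotypes)), dtype=int)
    for i, probe in enumerate(assay.probes):
        for j, gt in enumerate(assay.genotypes):
            tmpl = templates[gt]
            if len(probe.sequence) != len(tmpl):
                raise ValueError(
                    f"probe {probe.name!r} not alignable to the probe region "
                    f"({len(probe.sequence)} vs {len(tmpl)} bp)"
                )
            mat[i, j] = mismatch_count(probe.sequence, tmpl)
    return mat


def to_single_target_assay(assay: AssayDefinition, genotype: str) -> AssayDefinition:
    """Convert a screening multiplex into a single-target duplex.

    Keeps the primers and the wild-type probe untouched, retains only the
    FAM probe matching ``genotype``, and triples its concentration (the
    probe takes over the reaction share of the two that were removed).
    """
    if len(assay.mutant_probes) < 2:
        raise ValueError("assay is already single-target; nothing to reduce")
    keep = [p for p in assay.mutant_probes if p.target_genotype == genotype]
    if not keep:
        raise ValueError(f"no mutant probe targets genotype {genotype!r}")
    chosen = replace(keep[0], concentration=keep[0].concentration * 3)
    oligos = tuple(
        chosen if o is keep[0] else o
        for o in assay.oligos
        if o.role != "probe" or o.fluorophore != assay.mutant_channel or o is keep[0]
    )
    return replace(assay, name=f"{assay.name}_{genotype}", oligos=oligos,
                   genotypes=("WT", genotype))


def validate_assay(
    assay: AssayDefinition, reference_fragment: str | None = None
) -> ValidationReport:
    """Static consistency checks, optionally with primer placement.

    Always checks oligo roles/counts and that the summed FAM probe
    concentration balances the HEX probe concentration (tolerance
    ``CONCENTRATION_TOL_UM``).  Given a sense-strand reference fragment, it
    additionally requires each primer to sit in the fragment exactly once
    (forward as printed, reverse as its reverse complement) and reports the
    implied amplicon length, first forward base through last reverse base.
    """
    report = ValidationReport()
    report.add("one_forward_primer", len(assay.forward_primers) == 1)
    report.add("one_reverse_primer", len(assay.reverse_primers) == 1)
    report.add("one_wild_type_probe", len(assay.wild_type_probes) == 1)
    report.add("mutant_probes_present", len(assay.mutant_probes) >= 1)

    fam_total = sum(p.concentration for p in assay.mutant_probes)
    hex_conc = assay.wild_type_probes[0].concentration
    balanced = abs(fam_total - hex_conc) <= CONCENTRATION_TOL_UM
    report.add(
        "probe_concentration_balance",
        balanced,
        f"sum FAM = {fam_total:.3f} µM vs HEX = {hex_conc:.3f} µM",
    )

    if reference_fragment is not None:
        ref = _check_dna(_strip(reference_fragment).upper(), "reference fragment")
        fwd = assay.forward_primers[0].sequence
        rev_rc = reverse_complement(assay.reverse_primers[0].sequence)
        if ref.count(fwd) != 1:
            raise AmbiguousPrimingError(
                f"forward primer found {ref.count(fwd)} times in reference"
            )
        if ref.count(rev_rc) != 1:
            raise AmbiguousPrimingError(
                f"reverse primer found {ref.count(rev_rc)} times in reference"
            )
        start = ref.index(fwd)
        end = ref.index(rev_rc) + len(rev_rc)  # exclusive
        length = end - start
        report.forward_primer_start = start
        report.reverse_primer_end = end - 1
        report.amplicon_length = length
        report.add(
            "amplicon_length",
            length == assay.amplicon_length,
            f"computed {length} bp vs declared {assay.amplicon_length} bp",
        )
    return report


# ---------------------------------------------------------------------------
# Shipped assay definitions
# ---------------------------------------------------------------------------

#: First genomic base of the wild-type probe on the sense strand (GRCh37).
#: Offsets 7 and 10 of the probe are the G>A and C>T hotspot positions.
_GPR126_PROBE_START = 142_706_199

_GPR126_VARIANTS = {
    "M1": GenomicVariant("chr6", 142_706_206, "G", "A"),
    "M2": GenomicVariant("chr6", 142_706_209, "C", "T"),
}


def gpr126_screening_assay() -> AssayDefinition:
    """The GPR126 sixth-intron non-coding mutation screening assay.

    One primer pair, one HEX wild-type probe, three FAM mutant probes
    (G/A, C/T and G/A + C/T), with the published final-mix concentrations.
    Amplicon length 121 bp.
    """
    oligos = (
        Oligo("GPR126_F", _strip("ATG GGA ATA TTA TAA TTC TAA CTA A"),
              "forward_primer", concentration=0.9),
        Oligo("GPR126_R", _strip("CAC CGT ATA AAT GTT CTT G"),
              "reverse_primer", concentration=0.9),
        Oligo("GPR126_WT_probe", _strip("TT TGT ATG AAC ATA CAA AGA GCC TC"),
              "probe", fluorophore="HEX", quencher="BHQ1",
              concentration=0.25, target_genotype="WT"),
        Oligo("GPR126_M1_probe", _strip("TTT GTA TAA ACA TAC AAA GAG CCT C"),
              "probe", fluorophore="FAM", quencher="BHQ1",
              concentration=0.083, target_genotype="M1"),
        Oligo("GPR126_M2_probe", _strip("TTT GTA TGA ATA TAC AAA GAG CCT C"),
              "probe", fluorophore="FAM", quencher="BHQ1",
              concentration=0.083, target_genotype="M2"),
        Oligo("GPR126_M1M2_probe", _strip("TTT GTA TAA ATA TAC AAA GAG CCT C"),
              "probe", fluorophore="FAM", quencher="BHQ1",
              concentration=0.083, target_genotype="M1M2"),
    )
    return AssayDefinition(
        name="GPR126_screening",
        oligos=oligos,
        genotypes=("WT", "M1", "M2", "M1M2"),
        variants=dict(_GPR126_VARIANTS),
        amplicon_length=121,
        probe_region_start=_GPR126_PROBE_START,
    )


def tert_single_assay(position: int = 1_295_228) -> AssayDefinition:
    """Abstract two-channel model of a commercial TERT promoter assay.

    The real product's oligo sequences are proprietary; this stand-in keeps
    the two-channel semantics (HEX wild type, FAM mutant) so the promoter
    G>A hotspots at chr5:1,295,228 (-124) and chr5:1,295,250 (-146, GRCh37)
    can be quantified with the same machinery.  Sequences are synthetic
    placeholders, not the commercial design.
    """
    region = "ACGTACCCGGGAGAGCTGGAAGTCA"  # synthetic placeholder probe region
    variant = GenomicVariant("chr5", position, region[12], "A" if region[12] != "A" else "T")
    oligos = (
        Oligo("TERT_F", "GTCCTGCCCCTTCACCTT", "forward_primer", concentration=0.9),
        Oligo("TERT_R", "GGCTTCCCACGTGCGCAG", "reverse_primer", concentration=0.9),
        Oligo("TERT_WT_probe", region, "probe", fluorophore="HEX",
              quencher="BHQ1", concentration=0.25, target_genotype="WT"),
        Oligo("TERT_MUT_probe",
              region[:12] + variant.alt + region[13:], "probe", fluorophore="FAM",
              quencher="BHQ1", concentration=0.25, target_genotype="M1"),
    )
    return AssayDefinition(
        name="TERT_promoter",
        oligos=oligos,
        genotypes=("WT", "M1"),
        variants={"M1": variant},
        amplicon_length=80,
        probe_region_start=position - 12,
    )


# region modelled by the synthetic fragment, 1-based inclusive (GRCh37)
SYNTHETIC_FRAGMENT_REGION = ("chr6", 142_705_865, 142_706_619)
_SYNTHETIC_AMPLICON_START = 142_706_150  # chosen so the probe sits between primers


def synthetic_reference_fragment(seed: int = 20_230_208) -> str:
    """SYNTHETIC stand-in for GRCh37 chr6:142,705,865-142,706,619.

    The true genomic sense-strand sequence between the primers is not
    published, so this fragment is *constructed*: the printed forward
    primer, wild-type probe region and reverse-complemented reverse primer
    are embedded at offsets consistent with their stated GRCh37 coordinates
    and a 121 bp amplicon; everything else is seeded random filler.  It
    exercises primer placement and amplicon-length computation only — it is
    not the human reference sequence.
    """
    assay = gpr126_screening_assay()
    _, frag_start, frag_end = SYNTHETIC_FRAGMENT_REGION
    n = frag_end - frag_start + 1
    fwd = assay.forward_primers[0].sequence
    rev_rc = reverse_complement(assay.reverse_primers[0].sequence)
    probe = assay.wild_type_probes[0].sequence

    amp_off = _SYNTHETIC_AMPLICON_START - frag_start  # 0-based
    probe_off = _GPR126_PROBE_START - frag_start
    rev_off = amp_off + assay.amplicon_length - len(rev_rc)

    rng = np.random.default_rng(seed)
    frag = list(rng.choice(list("ACGT"), size=n))
    for off, seq in ((amp_off, fwd), (probe_off, probe), (rev_off, rev_rc)):
        frag[off:off + len(seq)] = list(seq)
    out = "".join(frag)
    # filler must not create a second priming site
    assert out.count(fwd) == 1 and out.count(rev_rc) == 1
    return out


def read_reference_fragment(path: str) -> str:
    """First record of a FASTA file, as an upper-case sequence string."""
    record = next(SeqIO.parse(path, "fasta"))
    return str(record.seq).upper()
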