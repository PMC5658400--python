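"""Domain types shared across the pipeline.

The central currency is the abundance table: per-species read counts and,
once spike-normalized, semi-absolute abundances in fmol per microgram of
total RNA, keyed by (species, RNA class, culture, fraction, library).
Fractions follow the sequential-filtration design: cells (CELL), large
microvesicles (MV), exosomes (EXO), non-vesicular ribonucleoprotein
particles (RNP), and fresh unconditioned media (FM) as the blank control.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Tuple


class PipelineError(Exception):
    """Base class for pipeline-specific failures."""


class FormatError(PipelineError):
    """A table or file violates the expected schema."""


class NormalizationError(PipelineError):
    """A unit cannot be spike-normalized (e.g. zero spike reads)."""


class CompositionError(PipelineError):
    """A unit has no annotated non-rRNA reads; composition undefined."""


class ConfigurationError(PipelineError):
    """Missing or inconsistent configuration (e.g. no FM mass ratio)."""


class Library(str, enum.Enum):
    """Sequencing library type: small-insert (15-65 nt) or long RNA."""

    SMALL = "SMALL"
    LONG = "LONG"


class Fraction(str, enum.Enum):
    """Cellular / extracellular compartment of origin."""

    CELL = "CELL"
    MV = "MV"
    EXO = "EXO"
    RNP = "RNP"
    FM = "FM"


#: Conditioned-media fractions compared against CELL and corrected against FM.
EXTRACELLULAR_FRACTIONS: Tuple[Fraction, ...] = (Fraction.MV, Fraction.EXO, Fraction.RNP)


class RnaClass(str, enum.Enum):
    """Annotation class of an RNA species.

    ``rRNA``, ``spike_in`` and ``unannotated`` are excluded from the
    "annotated non-rRNA" denominator used for composition profiles.
    """

    RRNA = "rRNA"
    MIRNA = "miRNA"
    TRNA_FRAGMENT = "tRNA_fragment"
    YRNA = "YRNA"
    YRNA_FRAGMENT = "YRNA_fragment"
    PIRNA = "piRNA"
    SNORNA = "snoRNA"
    SNRNA = "snRNA"
    SCRNA = "scRNA"
    SRP_RNA = "SRP_RNA"
    VRNA = "vRNA"
    LNCRNA = "lncRNA"
    MRNA_EXON = "mRNA_exon"
    INTRON = "intron"
    REPEAT = "repeat"
    SPIKE_IN = "spike_in"
    UNANNOTATED = "unannotated"

    @classmethod
    def from_label(cls, label: str) -> "RnaClass":
        """Map a free-text class label to the enumeration.

        Unknown labels map to ``unannotated`` with a warning, so that the
        composition denominator stays computable on imperfect annotation.
        """
        try:
            return cls(label)
        except ValueError:
            warnings.warn(
                f"unknown RNA class label {label!r}; mapped to 'unannotated'",
                stacklevel=2,
            )
            return cls.UNANNOTATED


#: Classes excluded from the "annotated non-rRNA" composition denominator.
NON_ANNOTATED_CLASSES = frozenset(
    {RnaClass.RRNA, RnaClass.SPIKE_IN, RnaClass.UNANNOTATED}
)


class SpikeTarget(str, enum.Enum):
    """Which sample type a spike-in was dosed into."""

    CELLULAR = "CELLULAR"
    EXTRACELLULAR = "EXTRACELLULAR"


@dataclass(frozen=True)
class SpikeIn:
    """One exogenous spike-in species with its known input amount."""

    spike_id: str
    known_fmol_per_ug: float
    applies_to: SpikeTarget

    def __post_init__(self) -> None:
        if self.known_fmol_per_ug <= 0:
            raise ValueError(
                f"spike {self.spike_id}: known_fmol_per_ug must be > 0, "
                f"got {self.known_fmol_per_ug}"
            )


@dataclass(frozen=True)
class SpikeInSet:
    """The spike-in design anchoring semi-absolute quantification."""

    entries: Tuple[SpikeIn, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        object.__setattr__(self, "entries", entries)
        for target in SpikeTarget:
            if not any(e.applies_to is target for e in entries):
                raise ValueError(f"SpikeInSet has no spike for {target.value} samples")

    def for_fraction(self, fraction: Fraction) -> Tuple[SpikeIn, ...]:
        """Spikes dosed into samples of this fraction (CELL is cellular,
        everything else — including FM blanks — is extracellular)."""
        target = (
            SpikeTarget.CELLULAR if fraction is Fraction.CELL else SpikeTarget.EXTRACELLULAR
        )
        return tuple(e for e in self.entries if e.applies_to is target)

    @property
    def ids(self) -> Tuple[str, ...]:
        return tuple(e.spike_id for e in self.entries)


def default_spike_set() -> SpikeInSet:
    """The study's dosing: 1.25 fmol/ug in cellular and 5.0 fmol/ug in
    extracellular samples of a single synthetic spike species each."""
    return SpikeInSet(
        entries=(
            SpikeIn("UniSp2_cell", 1.25, SpikeTarget.CELLULAR),
            SpikeIn("UniSp2_ex", 5.0, SpikeTarget.EXTRACELLULAR),
        )
    )


@dataclass(frozen=True)
class TranscriptModel:
    """Transcript coordinates, 1-based inclusive.

    Regions must be ordered 5'UTR < CDS < 3'UTR, non-overlapping, and fall
    within [1, length_nt]. Any region may be absent (non-coding RNA).
    """

    transcript_id: str
    length_nt: int
    utr5: Optional[Tuple[int, int]] = None
    cds: Optional[Tuple[int, int]] = None
    utr3: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ValueError(f"{self.transcript_id}: length_nt must be positive")
        regions = [
            (name, r)
            for name, r in (("utr5", self.utr5), ("cds", self.cds), ("utr3", self.utr3))
            if r is not None
        ]
        prev_end = 0
        for name, (start, end) in regions:
            if not (1 <= start <= end <= self.length_nt):
                raise ValueError(
                    f"{self.transcript_id}: region {name} {(start, end)} outside "
                    f"[1, {self.length_nt}]"
                )
            if start <= prev_end:
                raise ValueError(
                    f"{self.transcript_id}: region {name} overlaps or is out of order"
                )
            prev_end = end


@dataclass(frozen=True)
class EvPhysical:
    """Bulk physical measurements of an EV preparation.

    rna_yield_ng_per_ml : total RNA recovered per ml of conditioned media.
    particle_conc_per_ml : particle concentration from nanoparticle tracking.
    non_rrna_mass_fraction : fraction of per-EV RNA mass that is non-rRNA.
    """

    rna_yield_ng_per_ml: float
    particle_conc_per_ml: float
    non_rrna_mass_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.rna_yield_ng_per_ml <= 0:
            raise ValueError("rna_yield_ng_per_ml must be > 0")
        if self.particle_conc_per_ml <= 0:
            raise ValueError("particle_conc_per_ml must be > 0")
        if not (0 < self.non_rrna_mass_fraction <= 1):
            raise ValueError("non_rrna_mass_fraction must be in (0, 1]")


@dataclass
class ValidationReport:
    """Outcome of dataset validation; passes iff there are no errors."""

    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        lines = [f"passed: {self.passed}"]
        lines += [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)
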