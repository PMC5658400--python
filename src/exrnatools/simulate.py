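"""Synthetic exRNA experiments with known ground truth.

The generator emulates the study design the pipeline targets: several
donor cultures, each yielding a cellular sample plus three extracellular
fractions (microvesicles, exosomes, RNP particles) and a fresh-media
blank, sequenced as small and long RNA libraries with spike-ins.

True abundances are log-normal per species, multiplied by class-specific
fraction enrichments (miRNA up in exosomes, tRNA/Y-RNA fragments up in
RNPs, mRNA up in microvesicles by default), a per-culture log-normal
jitter on those enrichments (driving cross-culture heterogeneity, larger
extracellularly), and independent per-species log-normal noise. Observed
read counts are multinomial draws over the unit's relative true
abundances including the spikes, so spike normalization recovers the true
fmol values up to counting noise. Fresh-media background species carry
over into conditioned-media fractions in proportion to the per-fraction
FM mass ratio, reproducing the media-contamination artifact the blank
correction removes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fragments import CoverageProfile
from .tables import AbundanceTable
from .types import (
    ConfigurationError,
    EXTRACELLULAR_FRACTIONS,
    EvPhysical,
    Fraction,
    Library,
    RnaClass,
    SpikeInSet,
    default_spike_set,
)

#: Which classes populate which library by default.
SMALL_LIBRARY_CLASSES: Tuple[RnaClass, ...] = (
    RnaClass.MIRNA,
    RnaClass.TRNA_FRAGMENT,
    RnaClass.YRNA_FRAGMENT,
    RnaClass.PIRNA,
    RnaClass.SNORNA,
    RnaClass.SNRNA,
    RnaClass.SCRNA,
    RnaClass.SRP_RNA,
    RnaClass.REPEAT,
    RnaClass.RRNA,
)
LONG_LIBRARY_CLASSES: Tuple[RnaClass, ...] = (
    RnaClass.MRNA_EXON,
    RnaClass.LNCRNA,
    RnaClass.YRNA,
    RnaClass.INTRON,
    RnaClass.VRNA,
    RnaClass.RRNA,
)

#: Default species panel sizes per class.
DEFAULT_N_SPECIES: Dict[RnaClass, int] = {
    RnaClass.MIRNA: 120,
    RnaClass.TRNA_FRAGMENT: 40,
    RnaClass.YRNA_FRAGMENT: 8,
    RnaClass.PIRNA: 20,
    RnaClass.SNORNA: 30,
    RnaClass.SNRNA: 20,
    RnaClass.SCRNA: 5,
    RnaClass.SRP_RNA: 3,
    RnaClass.REPEAT: 20,
    RnaClass.RRNA: 5,
    RnaClass.MRNA_EXON: 250,
    RnaClass.LNCRNA: 60,
    RnaClass.YRNA: 4,
    RnaClass.INTRON: 30,
    RnaClass.VRNA: 2,
}

#: Median per-species true abundance (fmol/ug) per class; sets the class
#: ranking of the composition profile without fixing exact percentages.
DEFAULT_CLASS_MEDIAN_FMOL: Dict[RnaClass, float] = {
    RnaClass.MIRNA: 3.0,
    RnaClass.TRNA_FRAGMENT: 2.0,
    RnaClass.YRNA_FRAGMENT: 2.5,
    RnaClass.PIRNA: 0.3,
    RnaClass.SNORNA: 0.8,
    RnaClass.SNRNA: 0.8,
    RnaClass.SCRNA: 0.5,
    RnaClass.SRP_RNA: 0.5,
    RnaClass.REPEAT: 0.2,
    RnaClass.RRNA: 5.0,
    RnaClass.MRNA_EXON: 0.5,
    RnaClass.LNCRNA: 0.2,
    RnaClass.YRNA: 1.0,
    RnaClass.INTRON: 0.1,
    RnaClass.VRNA: 0.05,
}

#: Default class-by-fraction enrichment factors (everything absent is 1):
#: miRNA enriched in exosomes, tRNA and Y-RNA fragments in RNPs, mRNA in
#: microvesicles, rRNA depleted extracellularly.
DEFAULT_FRACTION_EFFECTS: Dict[Tuple[RnaClass, Fraction], float] = {
    (RnaClass.MIRNA, Fraction.EXO): 3.0,
    (RnaClass.TRNA_FRAGMENT, Fraction.RNP): 3.0,
    (RnaClass.YRNA_FRAGMENT, Fraction.RNP): 3.0,
    (RnaClass.YRNA_FRAGMENT, Fraction.EXO): 1.5,
    (RnaClass.MRNA_EXON, Fraction.MV): 2.0,
    (RnaClass.RRNA, Fraction.EXO): 0.3,
    (RnaClass.RRNA, Fraction.RNP): 0.1,
}

#: Default FM-to-conditioned-media mass ratios, within the 1.3-15% range
#: the blank measurements span.
DEFAULT_FM_MASS_RATIO: Dict[Fraction, float] = {
    Fraction.MV: 0.02,
    Fraction.EXO: 0.05,
    Fraction.RNP: 0.15,
}

FM_CULTURE_ID = "FM"


@dataclass(frozen=True)
class FragmentPair:
    """A full-length transcript (long library) paired with its processed
    fragment (small library), with a true fragment:full-length fmol ratio
    per fraction (fractions not listed default to 1)."""

    full_id: str
    fragment_id: str
    ratio_by_fraction: Mapping[Fraction, float]


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    The defaults encode the study conditions the pipeline assumes: four
    donor cultures, log-normal species abundances spanning a few orders of
    magnitude (sigma 1.5 in natural log), class-level fraction enrichments
    as above, stronger culture-to-culture jitter extracellularly than in
    cells, and single-spike designs at 1.25 (cellular) and 5.0
    (extracellular) fmol per microgram.
    """

    n_cultures: int = 4
    n_species_per_class: Mapping[RnaClass, int] = field(
        default_factory=lambda: dict(DEFAULT_N_SPECIES)
    )
    lognormal_sigma: float = 1.5
    fraction_effects: Mapping[Tuple[RnaClass, Fraction], float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTION_EFFECTS)
    )
    fm_background: Mapping[str, float] = field(default_factory=dict)
    spike_design: SpikeInSet = field(default_factory=default_spike_set)
    sequencing_depth: int = 200_000
    impactful_truth: Sequence[Tuple[str, float]] = ()
    fragment_pairs: Sequence[FragmentPair] = ()
    seed: int = 0
    culture_jitter_sigma_cell: float = 0.1
    culture_jitter_sigma_ex: float = 0.5
    species_noise_sigma: float = 0.35
    fm_mass_ratio: Mapping[Fraction, float] = field(
        default_factory=lambda: dict(DEFAULT_FM_MASS_RATIO)
    )
    class_median_fmol: Mapping[RnaClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MEDIAN_FMOL)
    )
    recipient_types: Sequence[str] = ("astrocyte",)
    n_recipient_replicates: int = 4
    recipient_offset_sigma: float = 0.5

    def validate(self) -> None:
        if self.n_cultures < 1:
            raise ConfigurationError("n_cultures must be >= 1")
        if self.sequencing_depth < 1:
            raise ConfigurationError("sequencing_depth must be >= 1")
        if self.lognormal_sigma <= 0:
            raise ConfigurationError("lognormal_sigma must be > 0")
        for (cls, frac), factor in self.fraction_effects.items():
            if factor <= 0:
                raise ConfigurationError(
                    f"fraction effect for ({cls}, {frac}) must be > 0"
                )
            if self.n_species_per_class.get(RnaClass(cls), 0) <= 0:
                raise ConfigurationError(
                    f"fraction_effects names class {RnaClass(cls).value} with no species"
                )


@dataclass
class SimTruth:
    """Everything needed to recompute every planted effect.

    fmol : long frame (species_id, rna_class, library, culture_id,
        fraction, fmol_true) of conditioned-media truth (carry-over from
        FM included; ``fmol_cell_derived`` carries the pre-contamination
        value, which is the post-correction truth).
    fm : blank levels (species_id, rna_class, library, fmol_true).
    recipients : (recipient, culture_id, species_id, fmol_true).
    """

    config: SimConfig
    fmol: pd.DataFrame
    fm: pd.DataFrame
    fm_mass_ratio: Dict[Fraction, float]
    recipients: pd.DataFrame

    def true_enrichment(
        self, species_id: str, fraction: Fraction, culture_id: Optional[str] = None
    ) -> float:
        """True (cell-derived) fraction-over-cell abundance ratio; mean
        across cultures unless one is named."""
        df = self.fmol[self.fmol["species_id"] == species_id]
        if culture_id is not None:
            df = df[df["culture_id"] == culture_id]
        ex = df[df["fraction"] == Fraction(fraction).value]
        cell = df[df["fraction"] == Fraction.CELL.value]
        merged = ex.merge(cell, on="culture_id", suffixes=("_ex", "_cell"))
        ratios = merged["fmol_cell_derived_ex"] / merged["fmol_cell_derived_cell"]
        return float(ratios.mean())


@dataclass
class SyntheticDataset:
    """A realized synthetic experiment: observed count tables plus truth."""

    tables: AbundanceTable
    truth: SimTruth
    ev_physical: Dict[str, EvPhysical]
    coverage: Dict[str, CoverageProfile]
    recipient_miRNomes: Dict[str, AbundanceTable]
    n_plants: int = 0


def _culture_ids(n: int) -> List[str]:
    return [f"GSC{i + 1}" for i in range(n)]


def _species_panel(config: SimConfig) -> pd.DataFrame:
    """Species id / class / library panel; rRNA gets library-tagged ids
    since its fragments appear in both libraries."""
    rows = []
    for library, classes in (
        (Library.SMALL, SMALL_LIBRARY_CLASSES),
        (Library.LONG, LONG_LIBRARY_CLASSES),
    ):
        for cls in classes:
            n = int(config.n_species_per_class.get(cls, 0))
            for i in range(n):
                if cls is RnaClass.RRNA:
                    sid = f"{cls.value}_{library.value}_{i:03d}"
                else:
                    sid = f"{cls.value}_{i:03d}"
                rows.append((sid, cls.value, library.value))
    return pd.DataFrame(rows, columns=["species_id", "rna_class", "library"])


def generate_experiment(config: SimConfig) -> SyntheticDataset:
    """Draw one complete synthetic experiment; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cultures = _culture_ids(config.n_cultures)
    panel = _species_panel(config)

    # planted impactful miRNAs must exist in the panel
    planted = dict(config.impactful_truth)
    extra = [
        (mid, RnaClass.MIRNA.value, Library.SMALL.value)
        for mid in planted
        if mid not in set(panel["species_id"])
    ]
    if extra:
        panel = pd.concat(
            [panel, pd.DataFrame(extra, columns=panel.columns)], ignore_index=True
        )
    # fragment-pair members must exist too
    for pair in config.fragment_pairs:
        for sid, cls, lib in (
            (pair.full_id, RnaClass.YRNA.value, Library.LONG.value),
            (pair.fragment_id, RnaClass.YRNA_FRAGMENT.value, Library.SMALL.value),
        ):
            if sid not in set(panel["species_id"]):
                panel = pd.concat(
                    [panel, pd.DataFrame([(sid, cls, lib)], columns=panel.columns)],
                    ignore_index=True,
                )

    medians = {RnaClass(k): v for k, v in config.class_median_fmol.items()}
    base = np.array(
        [
            medians.get(RnaClass(cls), 0.5)
            for cls in panel["rna_class"]
        ]
    ) * rng.lognormal(0.0, config.lognormal_sigma, size=len(panel))
    # planted impactful miRNAs sit in the abundant tail of the miRNome:
    # the screen's criteria (high fold over recipient at measurable levels)
    # select abundant secreted species, so their base is pinned above the
    # class median rather than drawn from the log-normal.
    mirna_median = medians.get(RnaClass.MIRNA, 1.0)
    base = np.where(
        np.isin(panel["species_id"], list(planted)), 10.0 * mirna_median, base
    )
    panel = panel.assign(base_fmol=base)

    effects = {
        (RnaClass(c), Fraction(f)): v for (c, f), v in config.fraction_effects.items()
    }
    fractions = (Fraction.CELL,) + EXTRACELLULAR_FRACTIONS

    rows = []
    for culture in cultures:
        for fraction in fractions:
            # culture-level dispersion acts per species: each culture
            # releases (or retains) each species somewhat differently, and
            # far more variably in the extracellular fractions, which is
            # what drives the within-class chi^2 heterogeneity upward
            # outside the cell. Combined with the baseline species noise
            # as one log-normal draw.
            jitter_sigma = (
                config.culture_jitter_sigma_cell
                if fraction is Fraction.CELL
                else config.culture_jitter_sigma_ex
            )
            sigma = float(np.hypot(jitter_sigma, config.species_noise_sigma))
            noise = (
                rng.lognormal(0.0, sigma, size=len(panel))
                if sigma > 0
                else np.ones(len(panel))
            )
            for (sid, cls, lib, b), nz in zip(
                panel[["species_id", "rna_class", "library", "base_fmol"]].itertuples(
                    index=False
                ),
                noise,
            ):
                e = 1.0 if fraction is Fraction.CELL else effects.get(
                    (RnaClass(cls), fraction), 1.0
                )
                rows.append((sid, cls, lib, culture, fraction.value, b * e * nz))
    truth_fmol = pd.DataFrame(
        rows,
        columns=["species_id", "rna_class", "library", "culture_id", "fraction",
                 "fmol_cell_derived"],
    )

    # fragment pairs: fragment truth is ratio * full-length truth
    for pair in config.fragment_pairs:
        full = truth_fmol[truth_fmol["species_id"] == pair.full_id].set_index(
            ["culture_id", "fraction"]
        )["fmol_cell_derived"]
        ratios = {Fraction(k): float(v) for k, v in pair.ratio_by_fraction.items()}
        mask = truth_fmol["species_id"] == pair.fragment_id
        for idx in truth_fmol.index[mask]:
            culture = truth_fmol.at[idx, "culture_id"]
            fraction = Fraction(truth_fmol.at[idx, "fraction"])
            truth_fmol.at[idx, "fmol_cell_derived"] = ratios.get(fraction, 1.0) * full[
                (culture, fraction.value)
            ]

    # fresh-media background and its carry-over into conditioned media
    fm_ratio = {Fraction(k): float(v) for k, v in config.fm_mass_ratio.items()}
    known_class = panel.set_index("species_id")[["rna_class", "library"]]
    fm_rows = []
    for sid, level in config.fm_background.items():
        if sid in known_class.index:
            cls, lib = known_class.loc[sid]
        else:
            cls, lib = RnaClass.MIRNA.value, Library.SMALL.value
        fm_rows.append((sid, cls, lib, float(level)))
    truth_fm = pd.DataFrame(
        fm_rows, columns=["species_id", "rna_class", "library", "fmol_true"]
    )
    truth_fmol = _apply_carryover(truth_fmol, truth_fm, fm_ratio, cultures)

    # recipient miRNomes
    mirna_panel = panel[panel["rna_class"] == RnaClass.MIRNA.value]
    rec_rows = []
    for recipient in config.recipient_types:
        offset = rng.lognormal(
            0.0, config.recipient_offset_sigma, size=len(mirna_panel)
        )
        rec_base = mirna_panel["base_fmol"].to_numpy() * offset
        for i, (sid, b) in enumerate(
            zip(mirna_panel["species_id"], mirna_panel["base_fmol"])
        ):
            if sid in planted:
                rec_base[i] = b / planted[sid]
        for rep in range(config.n_recipient_replicates):
            noise = rng.lognormal(
                0.0, config.species_noise_sigma, size=len(mirna_panel)
            )
            for sid, rb, nz in zip(mirna_panel["species_id"], rec_base, noise):
                rec_rows.append((recipient, f"{recipient}_rep{rep + 1}", sid, rb * nz))
    truth_recipients = pd.DataFrame(
        rec_rows, columns=["recipient", "culture_id", "species_id", "fmol_true"]
    )

    truth = SimTruth(
        config=config,
        fmol=truth_fmol,
        fm=truth_fm,
        fm_mass_ratio=fm_ratio,
        recipients=truth_recipients,
    )

    tables = _realize_counts(truth, rng)
    recipient_tables = _realize_recipients(truth, rng)

    ev_physical = {
        culture: EvPhysical(
            rna_yield_ng_per_ml=float(8.9 * rng.lognormal(0.0, 0.35)),
            particle_conc_per_ml=float(2e9 * rng.lognormal(0.0, 0.25)),
            non_rrna_mass_fraction=0.1,
        )
        for culture in cultures
    }

    coverage = {}
    for i, pair in enumerate(config.fragment_pairs):
        coverage[pair.fragment_id] = generate_coverage_profile(
            length_nt=100,
            site=30,
            fragment_share=0.8,
            mean_depth=200.0,
            seed=int(rng.integers(2**31)),
            transcript_id=pair.fragment_id,
        )

    return SyntheticDataset(
        tables=tables,
        truth=truth,
        ev_physical=ev_physical,
        coverage=coverage,
        recipient_miRNomes=recipient_tables,
    )


def _apply_carryover(
    truth_fmol: pd.DataFrame,
    truth_fm: pd.DataFrame,
    fm_ratio: Mapping[Fraction, float],
    cultures: Sequence[str],
) -> pd.DataFrame:
    """Total conditioned-media truth = cell-derived + mass-ratio * FM level.

    Species present only in FM gain zero cell-derived rows in the
    extracellular fractions (not in CELL).
    """
    df = truth_fmol.copy()
    existing = set(df["species_id"])
    new_rows = []
    for sid, cls, lib, level in truth_fm[
        ["species_id", "rna_class", "library", "fmol_true"]
    ].itertuples(index=False):
        if sid in existing:
            continue
        for culture in cultures:
            for fraction in EXTRACELLULAR_FRACTIONS:
                new_rows.append((sid, cls, lib, culture, fraction.value, 0.0))
    if new_rows:
        df = pd.concat(
            [df, pd.DataFrame(new_rows, columns=df.columns)], ignore_index=True
        )
    fm_level = truth_fm.set_index("species_id")["fmol_true"]
    carry = np.zeros(len(df))
    for i, (sid, fraction) in enumerate(
        zip(df["species_id"], df["fraction"])
    ):
        if fraction in (Fraction.CELL.value, Fraction.FM.value):
            continue
        if sid in fm_level.index:
            carry[i] = fm_ratio.get(Fraction(fraction), 0.0) * fm_level[sid]
    df["fmol_true"] = df["fmol_cell_derived"] + carry
    return df


def _unit_counts(
    species: pd.DataFrame,
    fraction: Fraction,
    spikes: SpikeInSet,
    depth: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Multinomial read counts for one unit; spike rows appended."""
    spike_entries = spikes.for_fraction(fraction)
    fmol = np.concatenate(
        [
            species["fmol_true"].to_numpy(dtype=float),
            [e.known_fmol_per_ug for e in spike_entries],
        ]
    )
    total = fmol.sum()
    if total <= 0:
        raise ConfigurationError("unit has zero total true abundance")
    counts = rng.multinomial(depth, fmol / total)
    out = species[["species_id", "rna_class"]].copy()
    out["read_count"] = counts[: len(species)]
    spike_df = pd.DataFrame(
        {
            "species_id": [e.spike_id for e in spike_entries],
            "rna_class": RnaClass.SPIKE_IN.value,
            "read_count": counts[len(species):],
        }
    )
    return pd.concat([out, spike_df], ignore_index=True)


def _realize_counts(truth: SimTruth, rng: np.random.Generator) -> AbundanceTable:
    """Observed count tables for every (culture, fraction, library) unit
    plus the FM blanks."""
    config = truth.config
    parts = []
    fm_col = truth.fmol.get("fmol_true", truth.fmol["fmol_cell_derived"])
    df = truth.fmol.assign(fmol_true=fm_col)
    for (culture, fraction, library), grp in df.groupby(
        ["culture_id", "fraction", "library"], sort=True
    ):
        unit = _unit_counts(
            grp, Fraction(fraction), config.spike_design, config.sequencing_depth, rng
        )
        unit["culture_id"] = culture
        unit["fraction"] = fraction
        unit["library"] = library
        parts.append(unit)
    # FM blanks, one per library that has background species
    for library, grp in truth.fm.groupby("library", sort=True):
        unit = _unit_counts(
            grp.rename(columns={"fmol_true": "fmol_true"}),
            Fraction.FM,
            config.spike_design,
            config.sequencing_depth,
            rng,
        )
        unit["culture_id"] = FM_CULTURE_ID
        unit["fraction"] = Fraction.FM.value
        unit["library"] = library
        parts.append(unit)
    combined = pd.concat(parts, ignore_index=True)
    combined["fmol_per_ug"] = np.nan
    return AbundanceTable(combined)


def _realize_recipients(
    truth: SimTruth, rng: np.random.Generator
) -> Dict[str, AbundanceTable]:
    """Observed recipient miRNome counts (cellular spike design)."""
    config = truth.config
    out: Dict[str, AbundanceTable] = {}
    for recipient, grp in truth.recipients.groupby("recipient", sort=True):
        parts = []
        for rep, rep_grp in grp.groupby("culture_id", sort=True):
            species = rep_grp.rename(columns={"fmol_true": "fmol_true"})[
                ["species_id", "fmol_true"]
            ].assign(rna_class=RnaClass.MIRNA.value)
            unit = _unit_counts(
                species, Fraction.CELL, config.spike_design,
                config.sequencing_depth, rng,
            )
            unit["culture_id"] = rep
            unit["fraction"] = Fraction.CELL.value
            unit["library"] = Library.SMALL.value
            parts.append(unit)
        combined = pd.concat(parts, ignore_index=True)
        combined["fmol_per_ug"] = np.nan
        out[recipient] = AbundanceTable(combined)
    return out


def plant_contaminant(
    dataset: SyntheticDataset, species_id: str, fm_level: float
) -> SyntheticDataset:
    """Add a fresh-media contaminant and its carry-over to a dataset.

    The species' FM level increases by ``fm_level``; every conditioned-
    media fraction gains fm_mass_ratio[fraction] * fm_level on top of its
    cell-derived truth, so pre-correction enrichment is inflated while the
    post-correction truth is unchanged. Counts are re-drawn from the
    updated truth with a seed derived from the dataset's. Successive
    plants of the same species add. A zero level returns the dataset
    unchanged.
    """
    if fm_level < 0:
        raise ValueError("fm_level must be >= 0")
    if fm_level == 0:
        return dataset
    truth = dataset.truth
    fm = truth.fm.copy()
    if species_id in set(fm["species_id"]):
        fm.loc[fm["species_id"] == species_id, "fmol_true"] += fm_level
    else:
        panel = truth.fmol[truth.fmol["species_id"] == species_id]
        if len(panel):
            cls = panel["rna_class"].iloc[0]
            lib = panel["library"].iloc[0]
        else:
            cls, lib = RnaClass.MIRNA.value, Library.SMALL.value
        new_row = pd.DataFrame(
            [(species_id, cls, lib, float(fm_level))], columns=fm.columns
        )
        fm = new_row if fm.empty else pd.concat([fm, new_row], ignore_index=True)
    cultures = sorted(truth.fmol["culture_id"].unique())
    base = truth.fmol.drop(columns=["fmol_true"], errors="ignore")
    new_fmol = _apply_carryover(base, fm, truth.fm_mass_ratio, cultures)
    new_truth = SimTruth(
        config=truth.config,
        fmol=new_fmol,
        fm=fm,
        fm_mass_ratio=truth.fm_mass_ratio,
        recipients=truth.recipients,
    )
    n_plants = dataset.n_plants + 1
    rng = np.random.default_rng([truth.config.seed, 7700 + n_plants])
    return SyntheticDataset(
        tables=_realize_counts(new_truth, rng),
        truth=new_truth,
        ev_physical=dataset.ev_physical,
        coverage=dataset.coverage,
        recipient_miRNomes=dataset.recipient_miRNomes,
        n_plants=n_plants,
    )


def generate_coverage_profile(
    length_nt: int,
    site: Optional[int],
    fragment_share: float,
    mean_depth: float,
    seed: int,
    transcript_id: str = "synthetic",
) -> CoverageProfile:
    """Poisson per-base coverage with an optional 5' processing step.

    When ``site`` is given, positions 1..site share ``fragment_share`` of
    the total expected depth (length * mean_depth) uniformly, and the
    remainder is spread over the downstream positions; without a site the
    profile is uniform at ``mean_depth``.
    """
    if length_nt <= 0:
        raise ValueError("length_nt must be positive")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not (0 <= fragment_share <= 1):
        raise ValueError("fragment_share must lie in [0, 1]")
    if site is not None and not (1 <= site < length_nt):
        raise ValueError("site must lie in [1, length_nt)")
    rng = np.random.default_rng(seed)
    if site is None:
        lam = np.full(length_nt, float(mean_depth))
    else:
        total = mean_depth * length_nt
        lam = np.empty(length_nt)
        lam[:site] = fragment_share * total / site
        lam[site:] = (1.0 - fragment_share) * total / (length_nt - site)
    return CoverageProfile(transcript_id, rng.poisson(lam).astype(float))


def generate_region_rates(
    n_cultures: int,
    utr3_bias: float,
    noise_sigma: float,
    seed: int,
    fraction: Fraction = Fraction.MV,
):
    """Paired cellular / extracellular UTR-CDS alignment rates.

    Cellular rates center on (5'UTR 0.15, CDS 0.60, 3'UTR 0.25); the
    extracellular fraction multiplies the 3'UTR rate by ``utr3_bias``
    before renormalization, with log-normal per-culture noise on every
    region. Returns (cell_rates, fraction_rates) as RegionRates.
    """
    from .fragments import RegionRates

    rng = np.random.default_rng(seed)
    base = np.array([0.15, 0.60, 0.25])
    cultures = _culture_ids(n_cultures)
    cell_rows, frac_rows = [], []
    for _ in cultures:
        cell = base * rng.lognormal(0.0, noise_sigma, 3)
        cell = cell / cell.sum()
        biased = base * np.array([1.0, 1.0, utr3_bias])
        frac = biased * rng.lognormal(0.0, noise_sigma, 3)
        frac = frac / frac.sum()
        cell_rows.append(cell)
        frac_rows.append(frac)
    cell_df = pd.DataFrame(cell_rows, index=cultures, columns=["UTR5", "CDS", "UTR3"])
    frac_df = pd.DataFrame(frac_rows, index=cultures, columns=["UTR5", "CDS", "UTR3"])
    return (
        RegionRates(fraction=Fraction.CELL, rates=cell_df),
        RegionRates(fraction=Fraction(fraction), rates=frac_df),
    )
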