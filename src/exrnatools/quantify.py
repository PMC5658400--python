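"""Spike-in semi-absolute quantification and fresh-media blank correction.

Read counts are converted to fmol per microgram of total RNA using the
known input amounts of exogenous spike-ins: with the pooled-ratio
estimator, one fmol-per-read scale per (culture, fraction, library) unit
is the total known spike input divided by the total spike read count.
Conditioned-media abundances are then corrected against the fresh-media
(FM) blank by mass-weighted subtraction, and enrichment over the cellular
fraction is a pseudo-counted ratio of fmol values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .tables import AbundanceTable, concat_tables
from .types import (
    ConfigurationError,
    Fraction,
    Library,
    NormalizationError,
    RnaClass,
    SpikeInSet,
)


@dataclass(frozen=True)
class NormalizationFit:
    """Result of fitting the spike scale for one unit.

    scale : fmol per read.
    spikes_used : spike ids with nonzero counts that entered the estimate.
    r_squared : quality of the through-origin linear relation between known
        fmol and observed reads; only defined with >= 2 spikes.
    """

    scale: float
    spikes_used: tuple
    r_squared: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


@dataclass(frozen=True)
class CorrectionParams:
    """Per-fraction ratio of FM-derived RNA mass to conditioned-media RNA
    mass (per ml-equivalent); the study reports 1.3-15% depending on the
    fraction."""

    fm_mass_ratio: Mapping[Fraction, float]

    def __post_init__(self) -> None:
        ratios = {Fraction(k): float(v) for k, v in self.fm_mass_ratio.items()}
        if any(v < 0 for v in ratios.values()):
            raise ValueError("fm_mass_ratio values must be >= 0")
        object.__setattr__(self, "fm_mass_ratio", ratios)

    def ratio_for(self, fraction: Fraction) -> float:
        try:
            return self.fm_mass_ratio[Fraction(fraction)]
        except KeyError:
            raise ConfigurationError(
                f"no fm_mass_ratio configured for fraction {Fraction(fraction).value}"
            ) from None


def fit_spike_scale(counts: AbundanceTable, spikes: SpikeInSet) -> NormalizationFit:
    """Pooled-ratio spike-scale estimate for a single-unit table.

    scale = (sum of known fmol over spikes with reads) / (sum of their reads).
    With >= 2 usable spikes the through-origin linear fit quality is also
    reported as r_squared = (sum xy)^2 / (sum x^2 * sum y^2).
    """
    units = counts.units()
    if len(units) != 1:
        raise ValueError(f"expected a single (culture, fraction, library) unit, got {len(units)}")
    _, fraction, _ = units[0]
    applicable = {e.spike_id: e.known_fmol_per_ug for e in spikes.for_fraction(Fraction(fraction))}
    spike_rows = counts.df[
        (counts.df["rna_class"] == RnaClass.SPIKE_IN.value)
        & counts.df["species_id"].isin(applicable)
    ]
    used = spike_rows[spike_rows["read_count"] > 0]
    if used.empty:
        raise NormalizationError(
            f"unit {units[0]} has no spike-in reads; fraction unquantifiable"
        )
    reads = used["read_count"].to_numpy(dtype=float)
    known = np.array([applicable[s] for s in used["species_id"]])
    scale = known.sum() / reads.sum()
    r2 = None
    if len(used) >= 2:
        r2 = float((reads @ known) ** 2 / ((reads @ reads) * (known @ known)))
    return NormalizationFit(scale=float(scale), spikes_used=tuple(used["species_id"]), r_squared=r2)


def to_fmol(counts: AbundanceTable, fit: NormalizationFit) -> AbundanceTable:
    """Apply a fitted scale: fmol_per_ug = read_count * scale for every
    non-spike row; counts are preserved unchanged."""
    df = counts.df.copy()
    non_spike = df["rna_class"] != RnaClass.SPIKE_IN.value
    df.loc[non_spike, "fmol_per_ug"] = df.loc[non_spike, "read_count"] * fit.scale
    return AbundanceTable(df)


def quantify_dataset(
    tables: AbundanceTable, spikes: SpikeInSet
) -> tuple[AbundanceTable, Dict[tuple, NormalizationFit]]:
    """Fit and apply the spike scale per (culture, fraction, library) unit.

    Returns the quantified table and the per-unit fits. Units without spike
    reads raise NormalizationError.
    """
    fits: Dict[tuple, NormalizationFit] = {}
    parts = []
    for culture, fraction, library in tables.units():
        unit = tables.subset(culture=culture, fraction=Fraction(fraction), library=Library(library))
        fit = fit_spike_scale(unit, spikes)
        fits[(culture, fraction, library)] = fit
        parts.append(to_fmol(unit, fit))
    return concat_tables(parts), fits


def media_correct(
    cm: AbundanceTable, fm: AbundanceTable, params: CorrectionParams
) -> AbundanceTable:
    """Blank-correct conditioned-media abundances against fresh media.

    corrected fmol = max(0, cm_fmol - fm_mass_ratio[fraction] * fm_fmol),
    per species; species absent from the FM blank are unchanged. Both
    tables must already be quantified.
    """
    for tab, name in ((cm, "conditioned-media"), (fm, "FM")):
        missing = tab.df[tab.df["rna_class"] != RnaClass.SPIKE_IN.value]["fmol_per_ug"].isna()
        if missing.any():
            raise ValueError(f"{name} table is not fully quantified")
    fm_df = fm.df[fm.df["rna_class"] != RnaClass.SPIKE_IN.value]
    fm_level = fm_df.groupby(["species_id", "library"])["fmol_per_ug"].mean()
    df = cm.df.copy()
    out = df["fmol_per_ug"].to_numpy(dtype=float).copy()
    for i, row in enumerate(df.itertuples(index=False)):
        if row.rna_class == RnaClass.SPIKE_IN.value or row.fraction == Fraction.FM.value:
            continue
        key = (row.species_id, row.library)
        if key in fm_level.index:
            ratio = params.ratio_for(Fraction(row.fraction))
            out[i] = max(0.0, row.fmol_per_ug - ratio * fm_level[key])
    df["fmol_per_ug"] = out
    return AbundanceTable(df)


def default_pseudocount(*tables: AbundanceTable) -> float:
    """Half the smallest nonzero fmol across the compared tables; keeps
    ratios finite for species absent from one side."""
    vals = np.concatenate([t.df["fmol_per_ug"].to_numpy(dtype=float) for t in tables])
    pos = vals[np.isfinite(vals) & (vals > 0)]
    if pos.size == 0:
        return 1e-6
    return float(pos.min() / 2.0)


def enrichment_ratio(
    extracellular: AbundanceTable,
    cellular: AbundanceTable,
    pseudo: Optional[float] = None,
) -> pd.Series:
    """Per-species (ex + pseudo) / (cell + pseudo) fmol ratio.

    Species present in only one table are treated as zero in the other.
    """
    if pseudo is None:
        pseudo = default_pseudocount(extracellular, cellular)
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")

    def _fmol(t: AbundanceTable) -> pd.Series:
        d = t.df[t.df["rna_class"] != RnaClass.SPIKE_IN.value]
        return d.groupby("species_id")["fmol_per_ug"].mean()

    ex, cell = _fmol(extracellular), _fmol(cellular)
    species = ex.index.union(cell.index)
    ex = ex.reindex(species, fill_value=0.0)
    cell = cell.reindex(species, fill_value=0.0)
    return (ex + pseudo) / (cell + pseudo)
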