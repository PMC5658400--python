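"""RNA-class composition and abundance-ranked transcript-length profiles.

Composition is reported as percent of annotated non-rRNA reads per
(culture, fraction, library) unit: rRNA, spike-ins and unannotated reads
are excluded from the denominator, so profiles are comparable between
samples with very different rRNA carry-over. Small and long libraries are
never pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable
from .types import (
    CompositionError,
    Fraction,
    Library,
    NON_ANNOTATED_CLASSES,
    RnaClass,
    TranscriptModel,
)


@dataclass
class CompositionProfile:
    """Percent-of-annotated-non-rRNA composition per unit.

    percent : long-format frame (culture_id, fraction, library, rna_class,
        percent); within a unit percentages sum to 100.
    errors : units whose denominator was zero, left out of ``percent``.
    """

    percent: pd.DataFrame
    errors: List[str] = field(default_factory=list)

    def unit(self, culture: str, fraction: Fraction, library: Library) -> pd.Series:
        df = self.percent
        sel = df[
            (df["culture_id"] == culture)
            & (df["fraction"] == Fraction(fraction).value)
            & (df["library"] == Library(library).value)
        ]
        return sel.set_index("rna_class")["percent"]


def class_composition(table: AbundanceTable) -> CompositionProfile:
    """Per-unit percentage of each annotated non-rRNA class."""
    excluded = {c.value for c in NON_ANNOTATED_CLASSES}
    rows = []
    errors: List[str] = []
    df = table.df
    for culture, fraction, library in table.units():
        unit = df[
            (df["culture_id"] == culture)
            & (df["fraction"] == fraction)
            & (df["library"] == library)
        ]
        annotated = unit[~unit["rna_class"].isin(excluded)]
        denom = annotated["read_count"].sum()
        if denom == 0:
            errors.append(
                f"unit ({culture}, {fraction}, {library}) has zero annotated "
                "non-rRNA reads; composition undefined"
            )
            continue
        by_class = annotated.groupby("rna_class")["read_count"].sum()
        for rna_class, count in by_class.items():
            rows.append(
                {
                    "culture_id": culture,
                    "fraction": fraction,
                    "library": library,
                    "rna_class": rna_class,
                    "percent": 100.0 * count / denom,
                }
            )
    return CompositionProfile(
        percent=pd.DataFrame(
            rows, columns=["culture_id", "fraction", "library", "rna_class", "percent"]
        ),
        errors=errors,
    )


@dataclass(frozen=True)
class LengthDistribution:
    """Parent-transcript lengths of the most abundant mRNA species."""

    lengths: np.ndarray
    species: Tuple[str, ...]
    median: float
    q1: float
    q3: float


def top_length_distribution(
    table: AbundanceTable,
    models: Mapping[str, TranscriptModel],
    n_top: int,
) -> LengthDistribution:
    """Lengths of the n_top most abundant species in a single-unit table.

    Ranking is by fmol (descending) with lexicographic species-id
    tie-break, so the selection is deterministic. If fewer species are
    available than requested, all are used with a warning.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    df = table.df[table.df["rna_class"] != RnaClass.SPIKE_IN.value]
    missing = [s for s in df["species_id"] if s not in models]
    if missing:
        raise KeyError(f"no transcript model for species: {missing[:5]}")
    if n_top > len(df):
        warnings.warn(
            f"n_top={n_top} exceeds the {len(df)} species available; using all",
            stacklevel=2,
        )
        n_top = len(df)
    ordered = df.sort_values(
        ["fmol_per_ug", "species_id"], ascending=[False, True]
    ).head(n_top)
    species = tuple(ordered["species_id"])
    lengths = np.array([models[s].length_nt for s in species], dtype=float)
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    return LengthDistribution(lengths=lengths, species=species, median=float(med), q1=float(q1), q3=float(q3))


def compare_length_distributions(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney rank-test p-value comparing two length
    samples; exact null distribution for n <= 50 per side, normal
    approximation above."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    method = "exact" if (len(a) <= 50 and len(b) <= 50) else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        # exact method rejects ties; fall back to the tie-corrected normal
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)
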