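"""Abundance tables: the pipeline's universal data container.

An :class:`AbundanceTable` wraps a pandas DataFrame with one row per
(species, culture, fraction, library) carrying the raw read count and,
after spike normalization, the abundance in fmol per microgram of total
RNA. On-disk format is plain UTF-8 TSV with a single header line and '.'
as the decimal separator; one file holds one library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    FormatError,
    Fraction,
    Library,
    RnaClass,
    SpikeInSet,
    ValidationReport,
)

#: Column order of the in-memory frame and of TSV files (minus 'library',
#: which is per-file on disk).
COLUMNS = (
    "species_id",
    "rna_class",
    "culture_id",
    "fraction",
    "library",
    "read_count",
    "fmol_per_ug",
)

KEY_COLUMNS = ("species_id", "culture_id", "fraction", "library")


@dataclass
class AbundanceTable:
    """Validated per-species abundance table.

    Parameters
    ----------
    df : DataFrame with columns ``species_id, rna_class, culture_id,
        fraction, library, read_count, fmol_per_ug``. ``fmol_per_ug`` may be
        NaN until the table has been quantified.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in COLUMNS if c not in df.columns and c != "fmol_per_ug"]
        if missing:
            raise FormatError(f"abundance table missing columns: {missing}")
        if "fmol_per_ug" not in df.columns:
            df["fmol_per_ug"] = np.nan
        df = df.loc[:, list(COLUMNS)].reset_index(drop=True)
        df["rna_class"] = df["rna_class"].map(lambda v: RnaClass(v).value)
        df["fraction"] = df["fraction"].map(lambda v: Fraction(v).value)
        df["library"] = df["library"].map(lambda v: Library(v).value)
        counts = pd.to_numeric(df["read_count"])
        if (counts < 0).any():
            bad = df.loc[counts < 0].iloc[0]
            raise ValueError(
                f"negative read_count for species {bad['species_id']!r} "
                f"({bad['culture_id']}/{bad['fraction']}/{bad['library']})"
            )
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("read_count must be integral")
        df["read_count"] = counts.astype(np.int64)
        fmol = pd.to_numeric(df["fmol_per_ug"])
        if (fmol.dropna() < 0).any():
            raise ValueError("fmol_per_ug must be non-negative")
        df["fmol_per_ug"] = fmol.astype(float)
        dup = df.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            key = tuple(df.loc[dup.idxmax(), list(KEY_COLUMNS)])
            raise ValueError(f"duplicated key {key}")
        nclass = df.groupby(["species_id", "library"])["rna_class"].nunique()
        if (nclass > 1).any():
            sid, lib = nclass[nclass > 1].index[0]
            raise ValueError(
                f"species {sid!r} has multiple rna_class values in library {lib}"
            )
        self.df = df

    # -- convenience accessors -------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def subset(
        self,
        culture: Optional[str] = None,
        fraction: Optional[Fraction] = None,
        library: Optional[Library] = None,
        rna_class: Optional[RnaClass] = None,
    ) -> "AbundanceTable":
        """Row filter by any combination of key fields."""
        mask = pd.Series(True, index=self.df.index)
        if culture is not None:
            mask &= self.df["culture_id"] == culture
        if fraction is not None:
            mask &= self.df["fraction"] == Fraction(fraction).value
        if library is not None:
            mask &= self.df["library"] == Library(library).value
        if rna_class is not None:
            mask &= self.df["rna_class"] == RnaClass(rna_class).value
        return AbundanceTable(self.df.loc[mask])

    def units(self) -> Iterable[tuple]:
        """Distinct (culture_id, fraction, library) units in the table."""
        return [
            tuple(t)
            for t in self.df[["culture_id", "fraction", "library"]]
            .drop_duplicates()
            .itertuples(index=False)
        ]

    def fmol_series(self) -> pd.Series:
        """fmol_per_ug indexed by species_id (single-unit tables)."""
        return self.df.set_index("species_id")["fmol_per_ug"]

    def count_series(self) -> pd.Series:
        return self.df.set_index("species_id")["read_count"]

    @property
    def is_quantified(self) -> bool:
        return not self.df["fmol_per_ug"].isna().any()

    def equals(self, other: "AbundanceTable", fmol_rtol: float = 1e-5) -> bool:
        """Equality up to row order; fmol compared to relative tolerance."""
        a = self.df.sort_values(list(KEY_COLUMNS)).reset_index(drop=True)
        b = other.df.sort_values(list(KEY_COLUMNS)).reset_index(drop=True)
        if len(a) != len(b):
            return False
        cat = [c for c in COLUMNS if c != "fmol_per_ug"]
        if not a[cat].equals(b[cat]):
            return False
        fa, fb = a["fmol_per_ug"].to_numpy(), b["fmol_per_ug"].to_numpy()
        both_nan = np.isnan(fa) & np.isnan(fb)
        close = np.isclose(fa, fb, rtol=fmol_rtol, equal_nan=False)
        return bool(np.all(both_nan | close))


def concat_tables(tables: Sequence[AbundanceTable]) -> AbundanceTable:
    """Stack tables row-wise into one validated table."""
    return AbundanceTable(pd.concat([t.df for t in tables], ignore_index=True))


def read_abundance_table(path: Union[str, Path], library: Library) -> AbundanceTable:
    """Read a TSV abundance table for one library.

    Required columns: species_id, rna_class, culture_id, fraction,
    read_count; fmol_per_ug is optional. Unknown class labels are mapped
    to ``unannotated`` with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str, "culture_id": str})
    required = ["species_id", "rna_class", "culture_id", "fraction", "read_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df["rna_class"] = df["rna_class"].map(lambda s: RnaClass.from_label(str(s)).value)
    df["library"] = Library(library).value
    return AbundanceTable(df)


def write_abundance_table(table: AbundanceTable, path: Union[str, Path]) -> None:
    """Write a single-library table as TSV; fmol to 6 significant digits."""
    libs = table.df["library"].unique()
    if len(libs) > 1:
        raise ValueError("write one library per file; got " + ", ".join(libs))
    out = table.df.drop(columns=["library"]).copy()
    if out["fmol_per_ug"].isna().all():
        out = out.drop(columns=["fmol_per_ug"])
    out.to_csv(Path(path), sep="\t", index=False, float_format="%.6g")


def validate_dataset(
    tables: Union[AbundanceTable, Sequence[AbundanceTable]],
    spikes: Optional[SpikeInSet] = None,
) -> ValidationReport:
    """Check dataset-level preconditions common to all downstream stages.

    Errors are invariant violations (duplicate keys, inconsistent classes);
    warnings flag units lacking spike-in rows and libraries lacking an FM
    blank, both of which limit (but do not preclude) downstream analysis.
    """
    report = ValidationReport()
    if isinstance(tables, AbundanceTable):
        tables = [tables]
    try:
        combined = concat_tables(list(tables))
    except (ValueError, FormatError) as exc:
        report.errors.append(str(exc))
        return report

    df = combined.df
    for culture, fraction, library in combined.units():
        unit = df[
            (df["culture_id"] == culture)
            & (df["fraction"] == fraction)
            & (df["library"] == library)
        ]
        has_spike = (unit["rna_class"] == RnaClass.SPIKE_IN.value).any()
        if spikes is not None and not has_spike:
            report.warnings.append(
                f"unit ({culture}, {fraction}, {library}) has no spike-in rows; "
                "it cannot be quantified"
            )
    for library in df["library"].unique():
        if not (
            (df["library"] == library) & (df["fraction"] == Fraction.FM.value)
        ).any():
            report.warnings.append(
                f"library {library} has no FM blank; media correction unavailable"
            )
    return report
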