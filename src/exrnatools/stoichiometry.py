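"""Copies-per-EV stoichiometry.

From the bulk RNA yield of an EV preparation and its particle
concentration, the average RNA mass per vesicle follows directly; with a
mean ribonucleotide residue mass it converts to ribonucleotides per EV,
and any spike-normalized abundance (fmol per microgram of total RNA)
converts to average copies per EV. Copy numbers are summarized on a
nearest-decade scale ("one copy per 10^b EVs").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import pandas as pd

from .tables import AbundanceTable
from .types import EvPhysical, RnaClass

#: Avogadro's number, molecules per mole.
AVOGADRO = 6.022e23

#: Mean ribonucleotide residue mass of single-stranded RNA, g/mol.
MEAN_NT_MASS_G_PER_MOL = 320.5

#: Sentinel copy-bin exponent for species above one copy per EV.
MORE_THAN_ONE_PER_EV = -1


def per_ev_rna_mass(phys: EvPhysical) -> float:
    """Average total RNA mass per vesicle, in attograms.

    mass_ag = (yield in ng/ml) * 1e9 ag/ng / (particles per ml).
    """
    return phys.rna_yield_ng_per_ml * 1e9 / phys.particle_conc_per_ml


def nucleotides_per_ev(
    mass_ag: float, mean_nt_mass_g_per_mol: float = MEAN_NT_MASS_G_PER_MOL
) -> float:
    """Ribonucleotide residues corresponding to a per-EV RNA mass."""
    if mass_ag < 0:
        raise ValueError("mass_ag must be non-negative")
    if mean_nt_mass_g_per_mol <= 0:
        raise ValueError("mean_nt_mass_g_per_mol must be positive")
    return mass_ag * 1e-18 * AVOGADRO / mean_nt_mass_g_per_mol


def copies_per_ev(abundance_fmol_per_ug: float, mass_per_ev_ag: float) -> float:
    """Average copies of a species per EV.

    An abundance of a fmol per microgram of total RNA, in vesicles each
    carrying m ag of RNA, gives a * 1e-15 * N_A molecules per 1e12 ag, i.e.
    copies = a * m * 6.022e-4.
    """
    if abundance_fmol_per_ug < 0:
        raise ValueError("abundance must be non-negative")
    if mass_per_ev_ag <= 0:
        raise ValueError("mass_per_ev_ag must be positive")
    return abundance_fmol_per_ug * 1e-15 * AVOGADRO * mass_per_ev_ag * 1e-12


def bin_copy_level(copies: float) -> int:
    """Nearest-decade copy bin: exponent b meaning one copy per ~10^b EVs.

    copies > 1 returns the sentinel ``MORE_THAN_ONE_PER_EV`` (-1); otherwise
    b = round(-log10(copies)) with half-decade ties rounded toward the
    more abundant bin (smaller b), clamped at 0.
    """
    if copies <= 0:
        raise ValueError("copies must be > 0")
    if copies > 1:
        return MORE_THAN_ONE_PER_EV
    x = -math.log10(copies)
    b = math.floor(x + 0.5)
    if x - math.floor(x) == 0.5:  # tie: prefer the more abundant (smaller) bin
        b = math.floor(x)
    return max(0, b)


def bin_label(b: int) -> str:
    if b == MORE_THAN_ONE_PER_EV:
        return "more than 1 copy per EV"
    if b == 0:
        return "~1 copy per EV"
    return f"one copy per {10 ** b} EVs"


def extracellular_accumulation_percent(
    exrna_ng_per_ml: float, cellular_rna_ug_per_ml: float
) -> float:
    """Percent of the cellular RNA pool found extracellularly, from the
    exRNA yield (ng per ml of media) and the cellular RNA content of the
    same culture volume (ug per ml)."""
    if exrna_ng_per_ml < 0 or cellular_rna_ug_per_ml <= 0:
        raise ValueError("yields must be positive")
    return 100.0 * exrna_ng_per_ml * 1e-3 / cellular_rna_ug_per_ml


@dataclass
class StoichResult:
    """Per-EV stoichiometry of one quantified sample.

    copies_per_ev / copy_bin are keyed by species id and, in parallel
    frames, by RNA class (class copies are the sum of member species,
    additivity holding by construction; the most abundant member is also
    reported as a representative).
    """

    mass_per_ev_ag: float
    non_rrna_mass_ag: float
    nt_per_ev: float
    species: pd.DataFrame  # species_id, rna_class, copies, copy_bin, bin_label
    classes: pd.DataFrame  # rna_class, copies, copy_bin, bin_label, top_species


def stoichiometry_table(
    table: AbundanceTable,
    phys: EvPhysical,
    mean_nt_mass_g_per_mol: float = MEAN_NT_MASS_G_PER_MOL,
) -> StoichResult:
    """Full copies-per-EV summary for a quantified single-unit table."""
    mass = per_ev_rna_mass(phys)
    non_rrna_mass = mass * phys.non_rrna_mass_fraction
    df = table.df[table.df["rna_class"] != RnaClass.SPIKE_IN.value]
    if df["fmol_per_ug"].isna().any():
        raise ValueError("table must be quantified (fmol_per_ug set)")
    species = df[["species_id", "rna_class", "fmol_per_ug"]].copy()
    species["copies"] = [copies_per_ev(a, mass) for a in species["fmol_per_ug"]]
    species["copy_bin"] = [
        bin_copy_level(c) if c > 0 else None for c in species["copies"]
    ]
    species["bin_label"] = [
        bin_label(b) if b is not None else "not detected" for b in species["copy_bin"]
    ]
    cls_rows = []
    for rna_class, grp in species.groupby("rna_class"):
        total = grp["copies"].sum()
        top = grp.sort_values(["copies", "species_id"], ascending=[False, True]).iloc[0]
        b = bin_copy_level(total) if total > 0 else None
        cls_rows.append(
            {
                "rna_class": rna_class,
                "copies": total,
                "copy_bin": b,
                "bin_label": bin_label(b) if b is not None else "not detected",
                "top_species": top["species_id"],
            }
        )
    return StoichResult(
        mass_per_ev_ag=mass,
        non_rrna_mass_ag=non_rrna_mass,
        nt_per_ev=nucleotides_per_ev(non_rrna_mass, mean_nt_mass_g_per_mol),
        species=species.drop(columns=["fmol_per_ug"]),
        classes=pd.DataFrame(cls_rows),
    )
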