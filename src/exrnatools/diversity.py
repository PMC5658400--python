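"""Inequality and cross-culture heterogeneity statistics.

Two cutoff-free inequality measures over a vector of species abundances:

* The evenness factor: the unique percentage epsilon such that epsilon% of
  the species account for (100 - epsilon)% of total abundance, computed on
  the linearly interpolated top-share (complementary Lorenz) curve. A
  perfectly even repertoire gives 50; extreme dominance approaches 0.
* The Gini coefficient G = sum_ij |x_i - x_j| / (2 n^2 mean(x)), with 0 for
  perfect evenness.

Heterogeneity across cultures is a sum of squared errors of within-class
relative abundances ("chi^2"), compared between extracellular fractions
and the cellular fraction as a fold change, plus top-k species overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tables import AbundanceTable
from .types import Fraction, Library, PipelineError, RnaClass


@dataclass(frozen=True)
class InequalityStats:
    """Inequality summary of one abundance vector."""

    evenness_factor: float
    gini: float
    n_top_for_q: int
    q: float = 0.8


def _clean_vector(abundances) -> np.ndarray:
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("abundances must be a non-empty 1-D vector")
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    if not (x > 0).any():
        raise ValueError("abundances must contain at least one positive value")
    return x


def top_share_curve(abundances) -> Tuple[np.ndarray, np.ndarray]:
    """Knots of the piecewise-linear top-share curve F.

    F(k/N) is the cumulative abundance share of the k most abundant
    species; F(0) = 0. Returns (p_knots, F_knots).
    """
    x = _clean_vector(abundances)
    xs = np.sort(x)[::-1]
    n = xs.size
    p = np.arange(n + 1) / n
    shares = np.concatenate([[0.0], np.cumsum(xs) / xs.sum()])
    return p, shares


def evenness_factor(abundances) -> float:
    """Solve F(p) = 1 - p on the interpolated top-share curve; return 100 p*.

    g(p) = F(p) - (1 - p) increases strictly from -1 at p=0 to 1 at p=1, so
    the root exists and is unique. Because F is piecewise linear between
    the knots (k/N, top-k share), the bracketing segment is located by the
    sign of g at the knots and the root solved in closed form on it, which
    is deterministic and exact to floating-point precision (uniform input
    gives exactly 50).
    """
    x = _clean_vector(abundances)
    if np.all(x == x[0]):
        # uniform input satisfies F(p) = p identically, so the root is 1/2
        return 50.0
    p_knots, f_knots = top_share_curve(x)
    g_knots = f_knots - (1.0 - p_knots)
    k = int(np.searchsorted(g_knots, 0.0, side="left"))
    if k == 0:
        return 100.0 * p_knots[0]
    p0, p1 = p_knots[k - 1], p_knots[k]
    f0, f1 = f_knots[k - 1], f_knots[k]
    slope = (f1 - f0) / (p1 - p0)
    p_star = (1.0 - f0 + slope * p0) / (slope + 1.0)
    return 100.0 * p_star


def gini(abundances) -> float:
    """Gini coefficient via the sorted-rank formula.

    Equivalent to sum_ij |x_i - x_j| / (2 n^2 mean) to numerical precision.
    """
    x = np.sort(_clean_vector(abundances))
    n = x.size
    ranks = np.arange(1, n + 1)
    return float((2.0 * (ranks @ x)) / (n * x.sum()) - (n + 1.0) / n)


def n_top_for_share(abundances, q: float = 0.8) -> int:
    """Smallest k such that the top-k species hold at least share q."""
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    x = _clean_vector(abundances)
    shares = np.cumsum(np.sort(x)[::-1]) / x.sum()
    return int(np.searchsorted(shares, q - 1e-12) + 1)


def inequality_stats(abundances, q: float = 0.8) -> InequalityStats:
    return InequalityStats(
        evenness_factor=evenness_factor(abundances),
        gini=gini(abundances),
        n_top_for_q=n_top_for_share(abundances, q),
        q=q,
    )


def chi2_heterogeneity(
    table: AbundanceTable,
    rna_class: RnaClass,
    fraction: Fraction,
    library: Optional[Library] = None,
) -> float:
    """Sum of squared errors of within-class composition across cultures.

    Each species' reads are divided by the culture's class total; the
    statistic is sum over species and cultures of the squared deviation
    from the cross-culture mean share. Absent species count as zero, so
    presence/absence differences are penalized. Cultures with zero class
    reads in this fraction are excluded with a warning; fewer than two
    remaining cultures is an error.
    """
    sub = table.subset(fraction=Fraction(fraction), rna_class=RnaClass(rna_class))
    if library is not None:
        sub = sub.subset(library=Library(library))
    mat = sub.df.pivot_table(
        index="species_id", columns="culture_id", values="read_count",
        aggfunc="sum", fill_value=0,
    ).astype(float)
    totals = mat.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(
            f"cultures {empty} have zero {RnaClass(rna_class).value} reads in "
            f"{Fraction(fraction).value}; excluded",
            stacklevel=2,
        )
        mat = mat.drop(columns=empty)
        totals = totals.drop(empty)
    if mat.shape[1] < 2:
        raise PipelineError("chi2 heterogeneity needs >= 2 cultures with class reads")
    shares = mat / totals
    dev = shares.sub(shares.mean(axis=1), axis=0)
    return float((dev.to_numpy() ** 2).sum())


@dataclass(frozen=True)
class FoldChange:
    """chi^2 fold change of a fraction over the cellular baseline; folds
    beyond two-fold either way are labeled."""

    fold: float
    label: str  # "increased", "decreased", or ""


def heterogeneity_fold_change(
    chi2_by_fraction: Mapping[Fraction, float]
) -> Dict[Fraction, FoldChange]:
    """Fold change of each extracellular chi^2 over the cellular chi^2.

    Values > 2 are labeled "increased" and < 0.5 "decreased", mirroring the
    two-fold highlighting convention.
    """
    values = {Fraction(k): float(v) for k, v in chi2_by_fraction.items()}
    cell = values.get(Fraction.CELL)
    if cell is None or cell <= 0:
        raise PipelineError("cellular chi^2 must be present and > 0")
    out: Dict[Fraction, FoldChange] = {}
    for fraction, chi2 in values.items():
        if fraction is Fraction.CELL:
            continue
        fold = chi2 / cell
        label = "increased" if fold > 2 else ("decreased" if fold < 0.5 else "")
        out[fraction] = FoldChange(fold=fold, label=label)
    return out


@dataclass(frozen=True)
class TopkOverlap:
    """Venn-style overlap of per-culture top-k species sets."""

    k: int
    cultures: Tuple[str, ...]
    pairwise: Mapping[Tuple[str, str], int]
    common_all: int
    region_counts: Mapping[Tuple[str, ...], int]  # exclusive Venn regions


def _topk_species(unit: AbundanceTable, k: int) -> set:
    df = unit.df[unit.df["rna_class"] != RnaClass.SPIKE_IN.value]
    by = "fmol_per_ug" if not df["fmol_per_ug"].isna().any() else "read_count"
    ordered = df.sort_values([by, "species_id"], ascending=[False, True])
    if len(ordered) < k:
        raise ValueError(f"k={k} exceeds the {len(ordered)} species available")
    return set(ordered["species_id"].head(k))


def topk_overlap(
    tables: Mapping[str, AbundanceTable], k: int
) -> TopkOverlap:
    """Overlap statistics of the k most abundant species per culture.

    ``tables`` maps culture id to a single-unit table; ranking is by fmol
    when quantified (counts otherwise) with lexicographic id tie-break.
    """
    cultures = tuple(sorted(tables))
    sets = {c: _topk_species(tables[c], k) for c in cultures}
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(cultures, 2)
    }
    common_all = len(set.intersection(*sets.values())) if sets else 0
    union = set.union(*sets.values())
    regions: Dict[Tuple[str, ...], int] = {}
    for sp in union:
        members = tuple(c for c in cultures if sp in sets[c])
        regions[members] = regions.get(members, 0) + 1
    return TopkOverlap(
        k=k, cultures=cultures, pairwise=pairwise,
        common_all=common_all, region_counts=regions,
    )
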