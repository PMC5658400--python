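"""Fragment analyses: fragment/full-length ratios, 5' processing-site
calling from per-base coverage, and UTR/CDS alignment-rate enrichment.

Many extracellular transcripts (tRNAs, Y RNAs, mRNAs) circulate as
precisely processed fragments. The small-library abundance of a species is
used as the fragment proxy and the long-library abundance as the
full-length proxy, so the fragment:full-length ratio is a simple
pseudo-counted fmol ratio. Processing sites appear as sharp drops in 5'
coverage; the caller scans smoothed per-base depth for the largest
relative decrease between adjacent positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import Fraction, PipelineError


@dataclass(frozen=True)
class CoverageProfile:
    """Per-base read depth along one transcript (1-based positions)."""

    transcript_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth, dtype=float)
        if depth.ndim != 1 or depth.size == 0:
            raise ValueError("depth must be a non-empty 1-D vector")
        if (depth < 0).any():
            raise ValueError("depth must be non-negative")
        object.__setattr__(self, "depth", depth)

    @property
    def length_nt(self) -> int:
        return int(self.depth.size)


@dataclass(frozen=True)
class FragmentCall:
    """A called 5' processing site and the share of depth upstream of it."""

    site: Optional[int]
    fragment_fraction: float
    drop_magnitude: float


def fragment_fulllength_ratio(
    small_fmol: float, long_fmol: float, pseudo: float
) -> float:
    """(small + pseudo) / (long + pseudo); small-library abundance proxies
    the fragment pool and long-library abundance the full-length pool."""
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    if small_fmol < 0 or long_fmol < 0:
        raise ValueError("abundances must be non-negative")
    if small_fmol == 0 and long_fmol == 0:
        raise PipelineError("both small and long abundances are zero; ratio undefined")
    return (small_fmol + pseudo) / (long_fmol + pseudo)


def _moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean; edges use the available positions only."""
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return sums / counts


def call_processing_site(
    profile: CoverageProfile, min_drop: float = 0.5, window: int = 3
) -> FragmentCall:
    """Call the 5' processing site as the steepest coverage drop.

    The depth vector is smoothed by a centered moving mean of the given
    window, then the relative decrease (s[i] - s[i+1]) / s[i] between every
    adjacent pair is evaluated; the position of the maximum decrease is the
    site if the decrease reaches ``min_drop`` (ties resolved to the
    5'-most position), otherwise no site is called. fragment_fraction is
    the share of raw depth at positions <= site (or <= window when no site
    is called).
    """
    depth = profile.depth
    if depth.sum() == 0:
        raise ValueError("all-zero coverage profile")
    if not (0 < min_drop <= 1):
        raise ValueError("min_drop must be in (0, 1]")
    if window < 1:
        raise ValueError("window must be >= 1")
    smoothed = _moving_mean(depth, window)
    upstream = smoothed[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        drops = np.where(upstream > 0, (upstream - smoothed[1:]) / upstream, -np.inf)
    best = int(np.argmax(drops))  # argmax takes the first (5'-most) maximum
    magnitude = float(drops[best])
    total = depth.sum()
    if magnitude >= min_drop:
        site = best + 1  # 1-based position upstream of the drop
        return FragmentCall(
            site=site,
            fragment_fraction=float(depth[:site].sum() / total),
            drop_magnitude=magnitude,
        )
    return FragmentCall(
        site=None,
        fragment_fraction=float(depth[: min(window, depth.size)].sum() / total),
        drop_magnitude=magnitude,
    )


@dataclass(frozen=True)
class RegionRates:
    """Per-culture alignment rates to 5'UTR, CDS and 3'UTR for one
    fraction; rates within a culture share the same read denominator."""

    fraction: Fraction
    rates: pd.DataFrame  # index: culture_id; columns: UTR5, CDS, UTR3

    REGIONS = ("UTR5", "CDS", "UTR3")

    def __post_init__(self) -> None:
        df = self.rates
        missing = [r for r in self.REGIONS if r not in df.columns]
        if missing:
            raise ValueError(f"RegionRates missing regions {missing}")
        vals = df[list(self.REGIONS)].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("alignment rates must lie in [0, 1]")


@dataclass(frozen=True)
class RegionEnrichment:
    """Log-ratio of extracellular over cellular alignment rates per region,
    with cross-region pairwise t-test p-values."""

    log_ratios: pd.DataFrame  # index: culture_id; columns: regions
    mean: pd.Series
    sem: pd.Series
    pairwise_p: Dict[Tuple[str, str], float]
    log_base: float


def utr_cds_enrichment(
    rates: RegionRates,
    cell_rates: RegionRates,
    log_base: float = 2.0,
) -> RegionEnrichment:
    """Per-region log(rate_fraction / rate_cell) across cultures.

    Regions with a zero cellular rate in any culture are excluded with a
    warning; the three regions are compared pairwise by unpaired two-sided
    Welch t-tests on the per-culture log-ratios.
    """
    cultures = rates.rates.index.intersection(cell_rates.rates.index)
    if len(cultures) < 2:
        raise PipelineError("need >= 2 shared cultures for region enrichment")
    frac = rates.rates.loc[cultures, list(RegionRates.REGIONS)]
    cell = cell_rates.rates.loc[cultures, list(RegionRates.REGIONS)]
    keep = []
    for region in RegionRates.REGIONS:
        if (cell[region] <= 0).any():
            warnings.warn(
                f"region {region} has a zero cellular rate; excluded", stacklevel=2
            )
        else:
            keep.append(region)
    log_ratios = np.log(frac[keep] / cell[keep]) / np.log(log_base)
    pairwise: Dict[Tuple[str, str], float] = {}
    for a, b in combinations(keep, 2):
        res = stats.ttest_ind(log_ratios[a], log_ratios[b], equal_var=False)
        pairwise[(a, b)] = float(res.pvalue)
    return RegionEnrichment(
        log_ratios=log_ratios,
        mean=log_ratios.mean(),
        sem=log_ratios.sem(),
        pairwise_p=pairwise,
        log_base=log_base,
    )


def read_coverage_tsv(path) -> Dict[str, CoverageProfile]:
    """Read per-base coverage from TSV (transcript_id, position, depth);
    positions are 1-based and must be contiguous from 1."""
    df = pd.read_csv(path, sep="\t")
    out: Dict[str, CoverageProfile] = {}
    for tid, grp in df.groupby("transcript_id"):
        grp = grp.sort_values("position")
        expected = np.arange(1, len(grp) + 1)
        if not np.array_equal(grp["position"].to_numpy(), expected):
            raise ValueError(f"{tid}: positions must be contiguous from 1")
        out[str(tid)] = CoverageProfile(str(tid), grp["depth"].to_numpy(dtype=float))
    return out


def write_coverage_tsv(profiles: Mapping[str, CoverageProfile], path) -> None:
    rows = []
    for tid, prof in profiles.items():
        for pos, depth in enumerate(prof.depth, start=1):
            rows.append((tid, pos, depth))
    pd.DataFrame(rows, columns=["transcript_id", "position", "depth"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
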