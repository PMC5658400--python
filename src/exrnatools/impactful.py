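"""The impactful-miRNA screen.

A secreted miRNA can only shift a recipient cell's regulatory state if its
delivered amount is large relative to the recipient's own expression. The
screen therefore compares each miRNA's extracellular abundance (across
donor cultures) with its level in a recipient cell type: log10 fold change
of the means, Welch two-sided t-test on per-replicate log10 abundances,
and a flag when the fold change exceeds 10^1.7 (~50-fold) at p < 0.05. The
number of extracellular fractions (MV, EXO, RNP) meeting the criteria is
tallied as a "+" count per miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import default_pseudocount
from .tables import AbundanceTable
from .types import EXTRACELLULAR_FRACTIONS, Fraction, PipelineError, RnaClass

#: log10 fold-change cutoff; 10^1.7 is approximately a 50-fold change.
DEFAULT_LFC_THRESHOLD = 1.7
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ImpactRecord:
    """Cross-fraction impact summary for one miRNA vs one recipient."""

    mirna_id: str
    recipient: str
    log10_fc: Mapping[Fraction, float]
    p_value: Mapping[Fraction, float]
    plus_count: int
    impactful: bool


def _mirna_matrix(table: AbundanceTable) -> pd.DataFrame:
    """Species x replicate fmol matrix of the miRNA rows of a table;
    replicates are the distinct culture ids."""
    df = table.df[table.df["rna_class"] == RnaClass.MIRNA.value]
    if df["fmol_per_ug"].isna().any():
        raise ValueError("tables must be quantified before the impact screen")
    return df.pivot_table(
        index="species_id", columns="culture_id", values="fmol_per_ug", fill_value=0.0
    )


def volcano_compare(
    exrna: AbundanceTable,
    recipient: AbundanceTable,
    pseudo: Optional[float] = None,
) -> pd.DataFrame:
    """Per-miRNA log10 fold change and t-test p-value, exRNA vs recipient.

    Columns of the result: log10_fc, p_value, mean_ex, mean_recipient.
    The fold change is computed on the means; the p-value is a Welch
    unpaired two-sided t-test on log10(fmol + pseudo) per replicate.
    miRNAs absent from both sides are excluded.
    """
    ex = _mirna_matrix(exrna)
    rec = _mirna_matrix(recipient)
    if ex.shape[1] < 2 or rec.shape[1] < 2:
        raise PipelineError("volcano_compare needs >= 2 replicates per side")
    if pseudo is None:
        pseudo = default_pseudocount(exrna, recipient)
    species = ex.index.union(rec.index)
    ex = ex.reindex(species, fill_value=0.0)
    rec = rec.reindex(species, fill_value=0.0)
    present = (ex.sum(axis=1) > 0) | (rec.sum(axis=1) > 0)
    ex, rec = ex[present], rec[present]
    log_ex = np.log10(ex.to_numpy() + pseudo)
    log_rec = np.log10(rec.to_numpy() + pseudo)
    res = stats.ttest_ind(log_ex, log_rec, axis=1, equal_var=False)
    mean_ex = ex.mean(axis=1)
    mean_rec = rec.mean(axis=1)
    return pd.DataFrame(
        {
            "log10_fc": np.log10((mean_ex + pseudo) / (mean_rec + pseudo)),
            "p_value": res.pvalue,
            "mean_ex": mean_ex,
            "mean_recipient": mean_rec,
        },
        index=ex.index,
    )


def flag_impactful(
    volcano_by_fraction: Mapping[Fraction, pd.DataFrame],
    recipient: str = "recipient",
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    p_adjust: str = "none",
) -> List[ImpactRecord]:
    """Tally, per miRNA, the extracellular fractions meeting the impact
    criteria (log10 FC strictly above the threshold and p < alpha).

    Raw p-values are compared against alpha by default; ``p_adjust="bh"``
    applies a per-fraction Benjamini-Hochberg correction first. Records
    are sorted by descending plus_count, then best log10 FC, then id; a
    miRNA is impactful if it qualifies in at least one fraction.
    """
    if p_adjust not in ("none", "bh"):
        raise ValueError("p_adjust must be 'none' or 'bh'")
    frames = {Fraction(f): df for f, df in volcano_by_fraction.items()}
    if p_adjust == "bh":
        adjusted = {}
        for fraction, df in frames.items():
            df = df.copy()
            df["p_value"] = stats.false_discovery_control(df["p_value"], method="bh")
            adjusted[fraction] = df
        frames = adjusted
    unknown = set(frames) - set(EXTRACELLULAR_FRACTIONS)
    if unknown:
        raise ValueError(f"unexpected fractions {sorted(f.value for f in unknown)}")
    all_ids = sorted(set().union(*[set(df.index) for df in frames.values()]))
    records = []
    for mirna in all_ids:
        lfc: Dict[Fraction, float] = {}
        pval: Dict[Fraction, float] = {}
        plus = 0
        for fraction, df in frames.items():
            if mirna not in df.index:
                continue
            lfc[fraction] = float(df.loc[mirna, "log10_fc"])
            pval[fraction] = float(df.loc[mirna, "p_value"])
            if lfc[fraction] > lfc_threshold and pval[fraction] < alpha:
                plus += 1
        records.append(
            ImpactRecord(
                mirna_id=mirna,
                recipient=recipient,
                log10_fc=lfc,
                p_value=pval,
                plus_count=plus,
                impactful=plus >= 1,
            )
        )
    records.sort(
        key=lambda r: (
            -r.plus_count,
            -(max(r.log10_fc.values()) if r.log10_fc else -np.inf),
            r.mirna_id,
        )
    )
    return records


def fraction_enrichment_screen(
    extracellular: AbundanceTable,
    cellular: AbundanceTable,
    alpha: float = DEFAULT_ALPHA,
    pseudo: Optional[float] = None,
) -> pd.DataFrame:
    """Per-species fraction-vs-cell enrichment calls across cultures.

    For each species, the per-culture (fraction + pseudo)/(cell + pseudo)
    fmol ratio is log10-transformed and tested against zero with a
    one-sample two-sided t-test; a species is called enriched when the mean
    log-ratio is positive and p < alpha. Columns: mean_log10_ratio,
    p_value, enriched.
    """
    def _matrix(t: AbundanceTable) -> pd.DataFrame:
        df = t.df[t.df["rna_class"] != RnaClass.SPIKE_IN.value]
        if df["fmol_per_ug"].isna().any():
            raise ValueError("tables must be quantified")
        return t.df[t.df["rna_class"] != RnaClass.SPIKE_IN.value].pivot_table(
            index="species_id", columns="culture_id", values="fmol_per_ug",
            fill_value=0.0,
        )

    ex, cell = _matrix(extracellular), _matrix(cellular)
    cultures = ex.columns.intersection(cell.columns)
    if len(cultures) < 2:
        raise PipelineError("fraction_enrichment_screen needs >= 2 shared cultures")
    if pseudo is None:
        pseudo = default_pseudocount(extracellular, cellular)
    species = ex.index.union(cell.index)
    ex = ex.reindex(index=species, columns=cultures, fill_value=0.0)
    cell = cell.reindex(index=species, columns=cultures, fill_value=0.0)
    log_ratio = np.log10((ex.to_numpy() + pseudo) / (cell.to_numpy() + pseudo))
    mean = log_ratio.mean(axis=1)
    res = stats.ttest_1samp(log_ratio, 0.0, axis=1)
    out = pd.DataFrame(
        {"mean_log10_ratio": mean, "p_value": res.pvalue}, index=species
    )
    out["enriched"] = (out["mean_log10_ratio"] > 0) & (out["p_value"] < alpha)
    return out
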