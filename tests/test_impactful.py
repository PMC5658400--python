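"""Volcano comparison, impact flagging and fraction-vs-cell enrichment
screens."""

import numpy as np
import pandas as pd
import pytest

from exrnatools import (
    Fraction,
    Library,
    RnaClass,
    SimConfig,
    flag_impactful,
    fraction_enrichment_screen,
    generate_experiment,
    quantify_dataset,
    volcano_compare,
)
from exrnatools.impactful import DEFAULT_LFC_THRESHOLD
from exrnatools.types import PipelineError

from conftest import build_table


def _mirna_table(values_by_rep, fraction="EXO"):
    """values_by_rep: {replicate_id: {mirna: fmol}}"""
    rows = []
    for rep, values in values_by_rep.items():
        for mid, v in values.items():
            rows.append((mid, "miRNA", rep, fraction, "SMALL", 1, v))
    return build_table(rows, with_fmol=True)


def test_equal_means_give_zero_log_fold_change():
    ex = _mirna_table({f"c{i}": {"m": 2.0} for i in range(3)})
    rec = _mirna_table({f"r{i}": {"m": 2.0} for i in range(3)}, fraction="CELL")
    res = volcano_compare(ex, rec, pseudo=0.1)
    assert res.loc["m", "log10_fc"] == 0.0


def test_absent_recipient_mirna_yields_finite_large_fold_change():
    """A miRNA missing from the recipient (knockout-like) still gets a
    finite fold change through the pseudo-count."""
    ex = _mirna_table({f"c{i}": {"m": 100.0} for i in range(3)})
    rec = _mirna_table({f"r{i}": {"m": 0.0} for i in range(3)}, fraction="CELL")
    res = volcano_compare(ex, rec, pseudo=0.001)
    assert np.isfinite(res.loc["m", "log10_fc"])
    assert res.loc["m", "log10_fc"] > DEFAULT_LFC_THRESHOLD


def test_threshold_is_strict_and_plus_count_tallies_fractions():
    near = pd.DataFrame({"log10_fc": [1.69], "p_value": [0.01]}, index=["m"])
    above = pd.DataFrame({"log10_fc": [2.0], "p_value": [0.01]}, index=["m"])
    records = flag_impactful({Fraction.MV: near, Fraction.EXO: above, Fraction.RNP: above})
    (rec,) = records
    assert rec.plus_count == 2
    assert rec.impactful
    all_above = flag_impactful(
        {f: above for f in (Fraction.MV, Fraction.EXO, Fraction.RNP)}
    )
    assert all_above[0].plus_count == 3
    none = flag_impactful({f: near for f in (Fraction.MV, Fraction.EXO, Fraction.RNP)})
    assert none[0].plus_count == 0 and not none[0].impactful


def test_bh_adjustment_never_adds_flags():
    rng = np.random.default_rng(14)
    frames = {
        f: pd.DataFrame(
            {
                "log10_fc": rng.normal(1.8, 0.3, 40),
                "p_value": rng.uniform(0, 0.1, 40),
            },
            index=[f"m{i}" for i in range(40)],
        )
        for f in (Fraction.MV, Fraction.EXO, Fraction.RNP)
    }
    raw = sum(r.plus_count for r in flag_impactful(frames))
    adjusted = sum(r.plus_count for r in flag_impactful(frames, p_adjust="bh"))
    assert adjusted <= raw
    with pytest.raises(ValueError, match="p_adjust"):
        flag_impactful(frames, p_adjust="bonferroni")


def test_fold_threshold_corresponds_to_fifty_fold():
    assert round(10 ** DEFAULT_LFC_THRESHOLD) == 50


def test_plus_count_is_monotone_in_threshold_and_alpha():
    rng = np.random.default_rng(8)
    frames = {
        f: pd.DataFrame(
            {
                "log10_fc": rng.normal(1.5, 0.5, 30),
                "p_value": rng.uniform(0, 0.2, 30),
            },
            index=[f"m{i}" for i in range(30)],
        )
        for f in (Fraction.MV, Fraction.EXO, Fraction.RNP)
    }

    def total_plus(lfc, alpha):
        return sum(
            r.plus_count
            for r in flag_impactful(frames, lfc_threshold=lfc, alpha=alpha)
        )

    assert total_plus(1.2, 0.05) >= total_plus(1.7, 0.05) >= total_plus(2.2, 0.05)
    assert total_plus(1.7, 0.10) >= total_plus(1.7, 0.05) >= total_plus(1.7, 0.01)


def test_planted_enrichment_is_recovered_in_one_experiment():
    config = SimConfig(
        seed=42,
        n_species_per_class={RnaClass.MIRNA: 60},
        fraction_effects={},
        sequencing_depth=50_000,
        impactful_truth=[("miRNA_000", 100.0)],
    )
    dataset = generate_experiment(config)
    quant, _ = quantify_dataset(dataset.tables, config.spike_design)
    rec, _ = quantify_dataset(
        dataset.recipient_miRNomes["astrocyte"], config.spike_design
    )
    volcano = {
        f: volcano_compare(quant.subset(fraction=f, library=Library.SMALL), rec)
        for f in (Fraction.MV, Fraction.EXO, Fraction.RNP)
    }
    records = {r.mirna_id: r for r in flag_impactful(volcano)}
    planted = records["miRNA_000"]
    assert planted.impactful
    assert max(planted.log10_fc.values()) == pytest.approx(2.0, abs=0.5)
    assert min(planted.p_value.values()) < 0.05


def test_identical_fraction_and_cell_tables_yield_no_enrichment_calls():
    table = _mirna_table({f"c{i}": {"m": 2.0, "n": 1.0} for i in range(4)})
    res = fraction_enrichment_screen(table, table, alpha=0.05, pseudo=0.1)
    assert not res["enriched"].any()


def test_swapping_fraction_and_cell_negates_mean_log_ratios():
    rng = np.random.default_rng(4)
    a = _mirna_table(
        {f"c{i}": {f"m{j}": rng.lognormal(0, 1) for j in range(10)} for i in range(4)}
    )
    b = _mirna_table(
        {f"c{i}": {f"m{j}": rng.lognormal(0, 1) for j in range(10)} for i in range(4)}
    )
    fwd = fraction_enrichment_screen(a, b, pseudo=0.01)
    rev = fraction_enrichment_screen(b, a, pseudo=0.01)
    assert np.allclose(
        fwd["mean_log10_ratio"], -rev["mean_log10_ratio"], atol=1e-12
    )


def test_enrichment_screen_power_and_false_positive_rate():
    """A 10x planted enrichment across 4 cultures is called essentially
    always at low noise, while null species are called at roughly the
    sign-restricted two-sided rate (about alpha/2)."""
    rng = np.random.default_rng(99)
    n_species, n_seeds, alpha = 30, 500, 0.05
    planted_called = 0
    false_calls, null_trials = 0, 0
    for _ in range(n_seeds):
        base = rng.lognormal(0, 1.0, n_species)
        cell = {f"c{i}": None for i in range(4)}
        ex_rows, cell_rows = {}, {}
        for i in range(4):
            noise_c = rng.lognormal(0, 0.2, n_species)
            noise_e = rng.lognormal(0, 0.2, n_species)
            fold = np.ones(n_species)
            fold[0] = 10.0
            cell_rows[f"c{i}"] = {
                f"m{j}": base[j] * noise_c[j] for j in range(n_species)
            }
            ex_rows[f"c{i}"] = {
                f"m{j}": base[j] * fold[j] * noise_e[j] for j in range(n_species)
            }
        res = fraction_enrichment_screen(
            _mirna_table(ex_rows, fraction="MV"),
            _mirna_table(cell_rows, fraction="CELL"),
            alpha=alpha,
            pseudo=1e-3,
        )
        planted_called += bool(res.loc["m0", "enriched"])
        null = res.drop(index="m0")
        false_calls += int(null["enriched"].sum())
        null_trials += len(null)
    assert planted_called / n_seeds >= 0.95
    fpr = false_calls / null_trials
    assert 0.1 * alpha <= fpr <= 1.5 * alpha


def test_screen_requires_two_cultures():
    table = _mirna_table({"c0": {"m": 1.0}})
    with pytest.raises(PipelineError, match="cultures"):
        fraction_enrichment_screen(table, table, pseudo=0.1)
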