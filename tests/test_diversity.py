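"""Inequality (evenness factor, Gini, top-share) and heterogeneity (chi^2
SSE) statistics against brute-force oracles and their invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exrnatools import (
    Fraction,
    Library,
    RnaClass,
    chi2_heterogeneity,
    evenness_factor,
    gini,
    heterogeneity_fold_change,
    n_top_for_share,
    topk_overlap,
)
from exrnatools.diversity import top_share_curve
from exrnatools.types import PipelineError

from conftest import build_table


# ---- brute-force oracles -------------------------------------------------

def gini_pairwise_oracle(x):
    x = np.asarray(x, dtype=float)
    n = len(x)
    return np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean())


def evenness_grid_oracle(x, grid_size=1_000_001):
    p_knots, f_knots = top_share_curve(x)
    grid = np.linspace(0.0, 1.0, grid_size)
    g = np.interp(grid, p_knots, f_knots) - (1.0 - grid)
    k = int(np.searchsorted(g >= 0, True))
    if k == 0:
        return 0.0
    # refine linearly between the bracketing grid points
    g0, g1 = g[k - 1], g[k]
    p = grid[k - 1] + (grid[k] - grid[k - 1]) * (-g0) / (g1 - g0)
    return 100.0 * p


positive_vectors = st.lists(
    st.floats(min_value=1e-3, max_value=1e6, allow_nan=False),
    min_size=2,
    max_size=40,
)


@pytest.mark.parametrize(
    "vector,expected",
    [
        ([1.0] * 7, 50.0),
        ([90, 5, 3, 1, 1], 100 / 5.5),
        ([1.0] + [0.0] * 99, 100 / 101),
    ],
)
def test_evenness_factor_closed_form_examples(vector, expected):
    assert evenness_factor(vector) == pytest.approx(expected, abs=1e-9)


def test_uniform_vector_gives_exactly_fifty():
    for n in (2, 3, 10, 101):
        assert evenness_factor([3.7] * n) == 50.0


@settings(derandomize=True, max_examples=60, deadline=None)
@given(positive_vectors)
def test_evenness_factor_matches_dense_grid_oracle(vector):
    assert evenness_factor(vector) == pytest.approx(
        evenness_grid_oracle(vector), abs=1e-4
    )


@pytest.mark.parametrize(
    "vector,expected",
    [
        ([5.0] * 9, 0.0),
        ([90, 5, 3, 1, 1], 0.728),
        ([1.0] + [0.0] * 9, 1 - 1 / 10),
    ],
)
def test_gini_examples(vector, expected):
    assert gini(vector) == pytest.approx(expected, abs=1e-12)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(positive_vectors)
def test_gini_sorted_rank_formula_matches_pairwise_sum(vector):
    assert gini(vector) == pytest.approx(gini_pairwise_oracle(vector), abs=1e-12)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(positive_vectors, st.floats(min_value=0.05, max_value=0.95))
def test_n_top_for_share_matches_exhaustive_scan(vector, q):
    x = np.sort(np.asarray(vector))[::-1]
    shares = np.cumsum(x) / x.sum()
    brute = next(k for k in range(1, len(x) + 1) if shares[k - 1] >= q - 1e-12)
    assert n_top_for_share(vector, q) == brute


@pytest.mark.parametrize(
    "vector,q,expected",
    [([1] * 10, 0.8, 8), ([90, 5, 3, 1, 1], 0.8, 1)],
)
def test_n_top_for_share_examples(vector, q, expected):
    assert n_top_for_share(vector, q) == expected


@settings(derandomize=True, max_examples=60, deadline=None)
@given(positive_vectors, st.floats(min_value=1.1, max_value=1e4))
def test_inequality_measures_are_scale_invariant(vector, factor):
    scaled = [v * factor for v in vector]
    assert gini(scaled) == pytest.approx(gini(vector), abs=1e-10)
    assert evenness_factor(scaled) == pytest.approx(evenness_factor(vector), abs=1e-9)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    positive_vectors,
    st.data(),
)
def test_pigou_dalton_transfer_raises_gini_and_lowers_evenness(vector, data):
    """Moving mass from a poorer to a richer species never decreases the
    Gini coefficient and never increases the evenness factor."""
    x = np.asarray(vector, dtype=float)
    i = data.draw(st.integers(0, len(x) - 1))
    j = data.draw(st.integers(0, len(x) - 1))
    if x[i] == x[j]:
        return
    rich, poor = (i, j) if x[i] > x[j] else (j, i)
    delta = data.draw(st.floats(min_value=0, max_value=float(x[poor])))
    y = x.copy()
    y[rich] += delta
    y[poor] -= delta
    assert gini(y) >= gini(x) - 1e-10
    assert evenness_factor(y) <= evenness_factor(x) + 1e-9


def test_all_zero_vector_is_rejected():
    for fn in (gini, evenness_factor, n_top_for_share):
        with pytest.raises(ValueError):
            fn(np.zeros(4))


# ---- chi^2 heterogeneity -------------------------------------------------

def _culture_rows(shares_by_culture, total=1000, fraction="EXO"):
    rows = []
    for culture, shares in shares_by_culture.items():
        for i, s in enumerate(shares):
            rows.append(
                (f"m{i}", "miRNA", culture, fraction, "SMALL", int(round(s * total)))
            )
    return build_table(rows)


def test_identical_cultures_have_zero_chi2():
    table = _culture_rows({"A": [0.5, 0.5], "B": [0.5, 0.5], "C": [0.5, 0.5]})
    assert chi2_heterogeneity(table, RnaClass.MIRNA, Fraction.EXO) == 0.0


def test_two_culture_hand_example():
    table = _culture_rows({"A": [0.5, 0.5], "B": [0.7, 0.3]})
    assert chi2_heterogeneity(table, RnaClass.MIRNA, Fraction.EXO) == pytest.approx(0.04)


def test_chi2_is_invariant_to_culture_label_permutation():
    rng = np.random.default_rng(5)
    shares = {c: rng.dirichlet(np.ones(6)) for c in "ABCD"}
    base = chi2_heterogeneity(
        _culture_rows(shares), RnaClass.MIRNA, Fraction.EXO
    )
    permuted = {c: shares[p] for c, p in zip("ABCD", "CADB")}
    assert chi2_heterogeneity(
        _culture_rows(permuted), RnaClass.MIRNA, Fraction.EXO
    ) == pytest.approx(base, rel=1e-12)


def test_culture_without_class_reads_is_excluded_then_errors_below_two():
    table = build_table(
        [
            ("m0", "miRNA", "A", "EXO", "SMALL", 10),
            ("m0", "miRNA", "B", "EXO", "SMALL", 0),
            ("m0", "miRNA", "C", "EXO", "SMALL", 20),
        ]
    )
    with pytest.warns(UserWarning, match="excluded"):
        value = chi2_heterogeneity(table, RnaClass.MIRNA, Fraction.EXO)
    assert value == 0.0  # one species: shares identical
    two = build_table(
        [
            ("m0", "miRNA", "A", "EXO", "SMALL", 10),
            ("m0", "miRNA", "B", "EXO", "SMALL", 0),
        ]
    )
    with pytest.warns(UserWarning):
        with pytest.raises(PipelineError, match="2 cultures"):
            chi2_heterogeneity(two, RnaClass.MIRNA, Fraction.EXO)


def test_fold_change_labels_follow_twofold_rule():
    folds = heterogeneity_fold_change(
        {Fraction.CELL: 0.02, Fraction.EXO: 0.02, Fraction.MV: 0.06, Fraction.RNP: 0.008}
    )
    assert folds[Fraction.EXO].fold == pytest.approx(1.0)
    assert folds[Fraction.EXO].label == ""
    assert folds[Fraction.MV].label == "increased"
    assert folds[Fraction.RNP].label == "decreased"
    with pytest.raises(PipelineError):
        heterogeneity_fold_change({Fraction.CELL: 0.0, Fraction.EXO: 1.0})


def test_resampled_replicates_are_more_concordant_than_distinct_cultures(
    default_dataset,
):
    """Technical multinomial replicates of one culture show a smaller chi^2
    than biologically distinct cultures at the generator defaults."""
    config, dataset = default_dataset
    df = dataset.tables.df
    sel = df[
        (df.fraction == "EXO") & (df.library == "SMALL") & (df.rna_class == "miRNA")
    ]
    across = chi2_heterogeneity(dataset.tables, RnaClass.MIRNA, Fraction.EXO, Library.SMALL)
    one = sel[sel.culture_id == "GSC1"].set_index("species_id")["read_count"]
    rng = np.random.default_rng(17)
    rows = []
    for rep in range(4):
        counts = rng.multinomial(int(one.sum()), one / one.sum())
        for sid, c in zip(one.index, counts):
            rows.append((sid, "miRNA", f"rep{rep}", "EXO", "SMALL", int(c)))
    within = chi2_heterogeneity(build_table(rows), RnaClass.MIRNA, Fraction.EXO)
    assert within < across


# ---- top-k overlap -------------------------------------------------------

def _ranked_table(culture, values):
    return build_table(
        [
            (f"s{i}", "miRNA", culture, "CELL", "SMALL", 10, v)
            for i, v in enumerate(values)
        ],
        with_fmol=True,
    )


def test_identical_tables_share_their_full_topk():
    tables = {c: _ranked_table(c, range(1, 201)) for c in ("A", "B", "C")}
    res = topk_overlap(tables, k=100)
    assert res.common_all == 100
    assert all(v == 100 for v in res.pairwise.values())


def test_disjoint_topk_sets_have_no_overlap():
    a = _ranked_table("A", [10] * 5 + [1] * 5)
    b = _ranked_table("B", [1] * 5 + [10] * 5)
    res = topk_overlap({"A": a, "B": b}, k=5)
    assert res.common_all == 0
    assert res.pairwise[("A", "B")] == 0


def test_topk_counts_match_bruteforce_set_intersections():
    rng = np.random.default_rng(3)
    tables, sets = {}, {}
    for c in "ABC":
        vals = rng.permutation(100) + 1.0
        tables[c] = _ranked_table(c, vals)
        order = sorted(range(100), key=lambda i: (-vals[i], f"s{i}"))
        sets[c] = {f"s{i}" for i in order[:20]}
    res = topk_overlap(tables, k=20)
    assert res.common_all == len(sets["A"] & sets["B"] & sets["C"])
    for (a, b), n in res.pairwise.items():
        assert n == len(sets[a] & sets[b])
    assert sum(res.region_counts.values()) == len(sets["A"] | sets["B"] | sets["C"])


def test_k_beyond_species_count_is_an_error():
    with pytest.raises(ValueError, match="exceeds"):
        topk_overlap({"A": _ranked_table("A", [1, 2]), "B": _ranked_table("B", [1, 2])}, k=5)
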