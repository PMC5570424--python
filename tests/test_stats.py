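import math
from fractions import Fraction as Frac

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from poolscreen import (
    CountMatrix,
    Fraction,
    SampleMeta,
    ValidationError,
    fold_changes,
    hypergeom_tail,
    normalize_counts,
    rsa_score,
    score_fold_changes,
)
from poolscreen.stats import ContrastSpec, _rsa_min_tail


def _raw(cols: dict, fractions: dict) -> CountMatrix:
    ids = [f"r{i}" for i in range(len(next(iter(cols.values()))))]
    samples = [
        SampleMeta(s, fractions[s][0], fractions[s][1]) for s in cols
    ]
    return CountMatrix(
        values=pd.DataFrame(cols, index=pd.Index(ids, name="reagent_id")),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalize_is_proportional_scaling():
    m = _raw({"s1": [1, 2, 3]}, {"s1": (Fraction.INPUT, 1)})
    norm = normalize_counts(m, scale=12e6)
    np.testing.assert_allclose(norm.values["s1"], [2e6, 4e6, 6e6])


def test_normalized_columns_sum_to_scale(small_library):
    from poolscreen import SimulationConfig, simulate_screen

    m, _ = simulate_screen(small_library, SimulationConfig(seed=5, depth=50_000))
    norm = normalize_counts(m)
    np.testing.assert_allclose(norm.values.sum(axis=0), 12_000_000, rtol=1e-9)


def test_normalize_rejects_all_zero_column():
    m = _raw({"s1": [1, 2, 3], "s2": [0, 0, 0]},
             {"s1": (Fraction.INPUT, 1), "s2": (Fraction.M2POS, 1)})
    with pytest.raises(ValidationError, match="s2"):
        normalize_counts(m)


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

def _fc_matrix(num_col, ref_col, tiny_library):
    m = CountMatrix(
        values=pd.DataFrame(
            {"num": num_col, "ref": ref_col},
            index=pd.Index(tiny_library.reagent_ids, name="reagent_id"),
        ),
        samples=[
            SampleMeta("num", Fraction.M2POS, 1),
            SampleMeta("ref", Fraction.INPUT, 1),
        ],
    )
    return normalize_counts(m, scale=12e6)


CONTRAST = ContrastSpec("M2pos_vs_input", Fraction.M2POS, Fraction.INPUT)


def test_equal_counts_give_zero_log2fc(tiny_library):
    norm = _fc_matrix([10, 20, 30], [10, 20, 30], tiny_library)
    fc = fold_changes(norm, CONTRAST, tiny_library)
    np.testing.assert_allclose(fc.log2fc, 0.0, atol=1e-12)


def test_doubled_counts_approach_log2fc_one(tiny_library):
    # equal column totals so normalization preserves the 2:1 reagent ratio
    norm = _fc_matrix([200_000, 100, 100], [100_000, 100, 100_100],
                      tiny_library)
    fc = fold_changes(norm, CONTRAST, tiny_library)
    assert fc.log2fc.iloc[0] == pytest.approx(1.0, abs=2e-2)


def test_dropout_reagent_fold_change_matches_stated_formula(tiny_library):
    # reagent r1: 0 reads in the sorted fraction, 923 (normalized) in input;
    # both columns total exactly 12e6 raw so the propagated pseudocount is
    # eps = 1 * 12e6 / 12e6 = 1 in every sample.
    norm = _fc_matrix(
        [0, 923, 11_999_077], [923, 923, 11_998_154], tiny_library
    )
    fc = fold_changes(norm, CONTRAST, tiny_library)
    expected = math.log2((0 + 1.0) / (923 + 1.0))  # oracle: -9.85175...
    assert fc.log2fc.iloc[0] == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(-9.851749041416057)
    assert np.isfinite(fc.log2fc).all()


def test_fold_changes_invariant_to_raw_column_scaling(tiny_library):
    norm1 = _fc_matrix([5, 7, 11], [13, 17, 19], tiny_library)
    norm2 = _fc_matrix([50, 70, 110], [13, 17, 19], tiny_library)
    fc1 = fold_changes(norm1, CONTRAST, tiny_library)
    fc2 = fold_changes(norm2, CONTRAST, tiny_library)
    np.testing.assert_allclose(fc1.log2fc, fc2.log2fc, rtol=1e-12)


def test_fold_changes_averages_replicates(tiny_library):
    m = CountMatrix(
        values=pd.DataFrame(
            {"n1": [10, 20, 30], "n2": [30, 20, 10], "ref": [20, 20, 20]},
            index=pd.Index(tiny_library.reagent_ids, name="reagent_id"),
        ),
        samples=[
            SampleMeta("n1", Fraction.M2POS, 1),
            SampleMeta("n2", Fraction.M2POS, 2),
            SampleMeta("ref", Fraction.INPUT, 1),
        ],
    )
    fc = fold_changes(normalize_counts(m, scale=60.0), CONTRAST, tiny_library)
    # replicate mean of (10,30) equals the reference 20 for reagent r1
    np.testing.assert_allclose(fc.log2fc, 0.0, atol=1e-12)


def test_fold_changes_requires_fraction(tiny_library):
    norm = _fc_matrix([1, 2, 3], [1, 2, 3], tiny_library)
    bad = ContrastSpec("x", Fraction.M1POS, Fraction.INPUT)
    with pytest.raises(ValidationError, match="M1pos"):
        fold_changes(norm, bad, tiny_library)


# ---------------------------------------------------------------------------
# hypergeometric tails
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "N, k, r, j, expected",
    [
        (10, 2, 1, 1, Frac(2, 10)),
        (10, 2, 2, 2, Frac(1, 45)),
        (20, 20, 7, 5, Frac(1, 1)),  # k = N: every draw is a success
    ],
)
def test_hypergeom_tail_micro_examples(N, k, r, j, expected):
    assert expected == oracles.exact_hypergeom_tail(N, k, r, j)
    assert hypergeom_tail(N, k, r, j) == pytest.approx(float(expected),
                                                       rel=1e-13)


def test_hypergeom_tail_matches_exact_oracle_on_grid():
    rng = np.random.default_rng(0)
    worst = 0.0
    for N in (10, 50, 200, 1000, 2000):
        for k in (1, 3, 10, 25):
            if k > N:
                continue
            for _ in range(10):
                j = int(rng.integers(1, k + 1))
                r = int(rng.integers(j, N + 1))
                exact = oracles.exact_hypergeom_tail(N, k, r, j)
                got = hypergeom_tail(N, k, r, j)
                worst = max(worst, abs(got - float(exact)) / float(exact))
    assert worst < 1e-12


@pytest.mark.parametrize("args", [(10, 2, 1, 0), (10, 2, 1, 3), (10, 11, 5, 1),
                                  (10, 2, 11, 1), (10, 5, 2, 3)])
def test_hypergeom_tail_rejects_out_of_range(args):
    with pytest.raises(ValidationError):
        hypergeom_tail(*args)


# ---------------------------------------------------------------------------
# RSA scoring
# ---------------------------------------------------------------------------

def test_rsa_top_ranked_gene(make_fc):
    # gene A's two reagents at ranks 1 and 2 of 10
    fc = make_fc(np.arange(10, dtype=float), ["A", "A"] + ["B"] * 8)
    score = rsa_score(fc, "A", "mediator")
    assert score.rsa_p == pytest.approx(1 / 45, rel=1e-13)
    assert score.rsa_logp == pytest.approx(-1.6532, abs=1e-4)
    assert score.best_j == 2 and score.best_rank == 2
    exact_p, exact_j = oracles.exact_rsa(10, [1, 2])
    assert (exact_p, exact_j) == (Frac(1, 45), 2)


def test_rsa_gene_owning_all_reagents_scores_one(make_fc):
    fc = make_fc(np.arange(6, dtype=float), ["A"] * 6)
    score = rsa_score(fc, "A", "mediator")
    assert score.rsa_p == 1.0
    assert score.rsa_logp == 0.0


def test_rsa_worst_ranked_gene_scores_one(make_fc):
    # ranks {9, 10}: with r_j draws covering nearly the whole list every
    # cutoff tail is forced to 1 — the unfavorable extreme carries no signal
    fc = make_fc(np.arange(10, dtype=float), ["B"] * 8 + ["A", "A"])
    score = rsa_score(fc, "A", "mediator")
    exact_p, _ = oracles.exact_rsa(10, [9, 10])
    assert exact_p == 1
    assert score.rsa_p == pytest.approx(1.0)


def test_rsa_quartiles_linear_interpolation(make_fc):
    vals = [-4.0, -2.0, 0.0, 2.0]
    fc = make_fc(vals + [5.0] * 6, ["A"] * 4 + ["B"] * 6)
    score = rsa_score(fc, "A", "mediator")
    assert score.q1 == pytest.approx(np.percentile(vals, 25))
    assert score.q3 == pytest.approx(np.percentile(vals, 75))
    assert score.q1 <= score.q3


def test_rsa_unknown_gene_rejected(make_fc):
    fc = make_fc([0.0, 1.0], ["A", "B"])
    with pytest.raises(ValidationError, match="ZZZ"):
        rsa_score(fc, "ZZZ", "mediator")


def test_rsa_matches_exact_oracle_on_random_rank_sets():
    rng = np.random.default_rng(42)
    for _ in range(50):
        N = int(rng.integers(5, 400))
        k = int(rng.integers(1, min(12, N) + 1))
        ranks = np.sort(rng.choice(np.arange(1, N + 1), size=k, replace=False))
        p, best_j, _ = _rsa_min_tail(N, ranks)
        exact_p, exact_j = oracles.exact_rsa(N, list(ranks))
        assert p == pytest.approx(float(exact_p), rel=1e-12)
        assert best_j == exact_j


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_rsa_improving_one_rank_never_hurts(data):
    """Moving any single reagent of a gene to a better (smaller) rank can
    only decrease or preserve the gene's RSA p-value."""
    N = data.draw(st.integers(6, 80))
    k = data.draw(st.integers(1, min(6, N - 1)))
    ranks = sorted(data.draw(
        st.lists(st.integers(2, N), min_size=k, max_size=k, unique=True)))
    free = sorted(set(range(1, N + 1)) - set(ranks))
    pick = data.draw(st.sampled_from(range(k)))
    better = [f for f in free if f < ranks[pick]]
    if not better:
        return
    new_rank = data.draw(st.sampled_from(better))
    improved = sorted(set(ranks) - {ranks[pick]} | {new_rank})
    p_before, _, _ = _rsa_min_tail(N, np.array(ranks))
    p_after, _, _ = _rsa_min_tail(N, np.array(improved))
    assert p_after <= p_before * (1 + 1e-12)


def test_mode_duality_suppressor_equals_mediator_on_negated(make_fc):
    rng = np.random.default_rng(7)
    vals = rng.normal(size=60)
    genes = [f"G{i % 12}" for i in range(60)]
    fc = make_fc(vals, genes)
    supp = score_fold_changes(fc, "suppressor").set_index("gene")
    med_neg = score_fold_changes(fc.negated(), "mediator").set_index("gene")
    for g in supp.index:
        assert supp.loc[g, "rsa_p"] == pytest.approx(
            med_neg.loc[g, "rsa_p"], rel=1e-12)
        assert supp.loc[g, "best_rank"] == med_neg.loc[g, "best_rank"]


def test_score_table_complete_and_sorted(make_fc):
    rng = np.random.default_rng(1)
    genes = [f"G{i % 20}" for i in range(100)]
    fc = make_fc(rng.normal(size=100), genes)
    df = score_fold_changes(fc, "mediator")
    assert sorted(df["gene"]) == sorted(set(genes))
    assert (np.diff(df["rsa_p"]) >= 0).all()
    assert list(df["rank"]) == list(range(1, 21))


def test_tied_scores_break_by_effect_quartile_then_gene():
    from poolscreen.stats import sort_gene_scores

    df = pd.DataFrame(
        {
            "gene": ["A", "B", "C", "D"],
            "rsa_p": [0.5, 0.01, 0.01, 0.01],
            "q1": [0.0, -1.0, -2.0, -2.0],
            "q3": [0.0, 1.0, 2.0, 2.0],
        }
    )
    med = sort_gene_scores(df, "mediator")
    # p tie -> more negative q1 wins; q1 tie -> lexicographic gene symbol
    assert list(med["gene"]) == ["C", "D", "B", "A"]
    assert list(med["rank"]) == [1, 2, 3, 4]
    supp = sort_gene_scores(df, "suppressor")
    assert list(supp["gene"]) == ["C", "D", "B", "A"]  # larger q3 wins
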