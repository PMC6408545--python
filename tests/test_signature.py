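from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from comonet import (
    ExpressionMatrix,
    SampleGroups,
    consensus_signature,
    distance_matrix,
    enrichment_score,
    extract_signature,
    fold_change_profiles,
    select_features,
    signature_distance,
    similarity_graph,
)
from comonet.signature import FoldChangeMatrix

from conftest import make_signature


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

def test_fold_change_identical_profiles_are_unity():
    # with every sample equal to the reference, ratios are 1 and log-diffs 0
    df = pd.DataFrame({"s1": [4.0, 5.0], "s2": [4.0, 5.0]}, index=["P1", "P2"])
    expr = ExpressionMatrix(df)
    assert np.allclose(fold_change_profiles(expr, "linear").data, 1.0)
    assert np.allclose(fold_change_profiles(expr, "log2").data, 0.0)


def test_fold_change_linear_and_log2_arithmetic():
    df = pd.DataFrame({"s1": [4.0, 5.0], "s2": [2.0, 7.0]}, index=["g", "h"])
    expr = ExpressionMatrix(df)
    fc_lin = fold_change_profiles(expr, "linear").data
    assert np.allclose(fc_lin.loc["g"], [4 / 3, 2 / 3])
    fc_log = fold_change_profiles(expr, "log2").data
    assert np.allclose(fc_log.loc["h"], [-1.0, 1.0])


def test_fold_change_zero_mean_names_row():
    df = pd.DataFrame({"s1": [1.0, -2.0], "s2": [1.0, 2.0]}, index=["ok", "bad"])
    with pytest.raises(ValueError, match="bad"):
        fold_change_profiles(ExpressionMatrix(df), "linear")


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def _fc(df):
    return FoldChangeMatrix(df, "log2")


def test_select_features_zero_variance_equal_means_excluded(two_group_labels):
    df = pd.DataFrame(
        {"s1": [1.0, 0.0], "s2": [1.0, 5.0], "s3": [1.0, 0.1], "s4": [1.0, 4.9]},
        index=["flat", "noisy"],
    )
    out = select_features(_fc(df), two_group_labels, [("case", "ctrl")], alpha=0.99)
    assert "flat" not in out


def test_select_features_matches_t_distribution_oracle():
    """A 10-SD mean separation at n=5 per group must pass alpha=0.01."""
    rng = np.random.default_rng(0)
    case = rng.normal(10.0, 1.0, 5)
    ctrl = rng.normal(0.0, 1.0, 5)
    df = pd.DataFrame([np.concatenate([case, ctrl])], index=["g"],
                      columns=[f"s{i}" for i in range(10)])
    groups = SampleGroups({f"s{i}": ("case" if i < 5 else "ctrl") for i in range(10)})
    selected = select_features(_fc(df), groups, [("case", "ctrl")], alpha=0.01)
    t, p = stats.ttest_ind(case, ctrl, equal_var=True)  # independent oracle
    assert p < 0.01
    assert selected == ["g"]


def test_select_features_union_over_contrasts():
    rng = np.random.default_rng(1)
    base = rng.normal(0, 1, (2, 8))
    base[0, 0:2] += 50.0   # separates groups a vs b only
    base[1, 4:6] += 50.0   # separates groups c vs d only
    df = pd.DataFrame(base, index=["g1", "g2"], columns=[f"s{i}" for i in range(8)])
    groups = SampleGroups(
        {f"s{i}": lab for i, lab in enumerate(["a", "a", "b", "b", "c", "c", "d", "d"])}
    )
    out = select_features(_fc(df), groups, [("a", "b"), ("c", "d")], alpha=0.01)
    assert out == ["g1", "g2"]


def test_select_features_unknown_group_is_hard_error(two_group_labels):
    df = pd.DataFrame(np.ones((1, 4)), index=["g"], columns=["s1", "s2", "s3", "s4"])
    with pytest.raises(KeyError):
        select_features(_fc(df), two_group_labels, [("case", "nope")])


# ---------------------------------------------------------------------------
# signature extraction
# ---------------------------------------------------------------------------

def test_extract_signature_orders_and_cuts():
    profile = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=["a", "b", "c", "d", "e"])
    s = extract_signature(profile, n1=2, n2=1, sample_id="x")
    assert s.up == ("a", "b")
    assert s.down == ("e",)
    assert s.ranking == ("a", "b", "c", "d", "e")


def test_extract_signature_tie_breaks_lexicographically():
    profile = pd.Series([1.0, 1.0, 0.0], index=["b", "a", "c"])
    s = extract_signature(profile, n1=2, n2=1)
    assert s.up == ("a", "b")


def test_extract_signature_rejects_oversized_cut():
    profile = pd.Series([1.0, 2.0], index=["a", "b"])
    with pytest.raises(ValueError, match="exceeds"):
        extract_signature(profile, n1=2, n2=1)


# ---------------------------------------------------------------------------
# enrichment-score distance
# ---------------------------------------------------------------------------

def oracle_enrichment_score(members, ranking):
    """Step-by-step running sum in exact rational arithmetic."""
    members = set(members)
    size, total = len(members), len(ranking)
    running, best = Fraction(0), Fraction(0)
    for feat in ranking:
        if feat in members:
            running += Fraction(1, size)
        else:
            running -= Fraction(1, total - size)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return float(best)


def test_identical_signatures_have_zero_distance():
    s = make_signature("x", "abcdef", 2, 2)
    t = make_signature("y", "abcdef", 2, 2)
    assert signature_distance(s, t) == pytest.approx(0.0)


def test_reversed_signatures_have_distance_two():
    s = make_signature("x", "abcdef", 2, 2)
    t = make_signature("y", "fedcba", 2, 2)
    assert signature_distance(s, t) == pytest.approx(2.0)


def test_enrichment_score_matches_exhaustive_oracle_on_toy():
    """G=6, |up|=|down|=1, scored against a printed foreign ranking."""
    ranking_b = ("c", "a", "f", "b", "e", "d")
    for members in [("a",), ("d",), ("f",)]:
        assert enrichment_score(members, ranking_b) == pytest.approx(
            oracle_enrichment_score(members, ranking_b)
        )
    sig_a = make_signature("A", "abcdef", 1, 1)
    sig_b = make_signature("B", ranking_b, 1, 1)
    expected_similarity = (
        oracle_enrichment_score(sig_a.up, sig_b.ranking)
        - oracle_enrichment_score(sig_a.down, sig_b.ranking)
        + oracle_enrichment_score(sig_b.up, sig_a.ranking)
        - oracle_enrichment_score(sig_b.down, sig_a.ranking)
    ) / 4
    assert signature_distance(sig_a, sig_b) == pytest.approx(1 - expected_similarity)


def test_enrichment_score_depends_only_on_hit_positions():
    # permuting the misses between two hits cannot change the running sum path
    a = enrichment_score({"x", "y"}, ("x", "m1", "m2", "m3", "y", "m4"))
    b = enrichment_score({"x", "y"}, ("x", "m3", "m1", "m2", "y", "m4"))
    assert a == b


def test_mismatched_universes_rejected():
    s = make_signature("x", "abcdef", 1, 1)
    t = make_signature("y", "abcdeg", 1, 1)
    with pytest.raises(ValueError, match="universes"):
        signature_distance(s, t)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.data())
def test_distance_matrix_symmetry_and_range(data):
    """Random signatures: symmetric matrix, zero diagonal, entries in [0,2]."""
    n_feat = data.draw(st.integers(6, 12))
    n_samp = data.draw(st.integers(2, 5))
    features = [f"f{i}" for i in range(n_feat)]
    rng = np.random.default_rng(data.draw(st.integers(0, 2**16)))
    sigs = []
    for i in range(n_samp):
        order = list(rng.permutation(features))
        sigs.append(make_signature(f"s{i}", order, 2, 2))
    dm = distance_matrix(sigs)
    arr = dm.to_numpy()
    assert np.allclose(arr, arr.T)
    assert np.allclose(np.diag(arr), 0.0)
    assert (arr >= 0).all() and (arr <= 2).all()
    i, j = 0, n_samp - 1
    if i != j:
        assert arr[i, j] == pytest.approx(signature_distance(sigs[i], sigs[j]))


# ---------------------------------------------------------------------------
# similarity graph
# ---------------------------------------------------------------------------

def _dm_from_condensed(values, n):
    mat = np.zeros((n, n))
    mat[np.triu_indices(n, 1)] = values
    mat += mat.T
    ids = [f"s{i}" for i in range(n)]
    return pd.DataFrame(mat, index=ids, columns=ids)


def test_similarity_graph_percentile_threshold():
    """Distances 1..6 at k=10: manual linear interpolation gives 1.5."""
    dm = _dm_from_condensed([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], 4)
    g = similarity_graph(dm, k=10)
    # oracle: rank = k/100 * (m-1) = 0.5 between the 1st and 2nd order stats
    assert g.graph["threshold"] == pytest.approx(1.0 + 0.5 * (2.0 - 1.0))
    assert g.number_of_edges() == 1
    assert not any(a == b for a, b in g.edges)


def test_similarity_graph_k100_is_complete():
    dm = _dm_from_condensed([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], 4)
    assert similarity_graph(dm, k=100).number_of_edges() == 6


def test_similarity_graph_all_ties_complete_for_any_k():
    dm = _dm_from_condensed([0.7] * 6, 4)
    for k in (1, 10, 50, 100):
        assert similarity_graph(dm, k=k).number_of_edges() == 6


def test_similarity_graph_needs_two_samples():
    dm = pd.DataFrame([[0.0]], index=["s"], columns=["s"])
    with pytest.raises(ValueError):
        similarity_graph(dm, k=10)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def test_consensus_of_single_subject_is_its_signature():
    s = make_signature("x", "abcdefgh", 3, 2)
    cs = consensus_signature([s], 3, 2, group="g")
    assert set(cs.up) == set(s.up)
    assert set(cs.down) == set(s.down)
    assert all(cs.up_popularity[f] == 1 for f in cs.up)


def test_consensus_popularity_order():
    # g is in all three up-lists, h in only one → g must outrank h
    sigs = [
        make_signature("a", ["g", "h", "x", "y", "z"], 2, 1),
        make_signature("b", ["g", "x", "h", "y", "z"], 2, 1),
        make_signature("c", ["g", "y", "x", "h", "z"], 2, 1),
    ]
    cs = consensus_signature(sigs, 2, 1)
    assert cs.up[0] == "g"
    assert cs.up_popularity["g"] == 3
    assert cs.up_popularity.get("h", 0) == 1


def test_consensus_sizes_match_n1_n2():
    rng = np.random.default_rng(3)
    features = [f"f{i}" for i in range(30)]
    sigs = [
        make_signature(f"s{i}", list(rng.permutation(features)), 5, 4)
        for i in range(6)
    ]
    cs = consensus_signature(sigs, 5, 4)
    assert len(cs.up) == 5 and len(cs.down) == 4


def test_consensus_insufficient_distinct_features_rejected():
    s = make_signature("x", "abcde", 2, 1)
    with pytest.raises(ValueError, match="distinct up"):
        consensus_signature([s], 3, 1)
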