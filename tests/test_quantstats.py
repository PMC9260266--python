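import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msapkit.io import MsapValidationError
from msapkit.quantstats import (
    DegenerateInputError,
    anova_duncan,
    compact_letter_display,
    ddct_fold_change,
    duncan_significant_pairs,
    five_mc_percent,
)

# ---------------------------------------------------------------------------
# 2^-ddCt


def _records(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])


def test_control_group_fold_is_one():
    rec = _records(
        [("s1", "ctl", "T", 25.0), ("s1", "ctl", "R", 20.0),
         ("s2", "ctl", "T", 25.5), ("s2", "ctl", "R", 20.5)]
    )
    out = ddct_fold_change(rec, "T", "R", "ctl")
    assert out.loc[out["group"] == "ctl", "fold_change"].item() == 1.0


def test_two_cycle_shift_gives_fourfold():
    rec = _records(
        [("c", "ctl", "T", 25.0), ("c", "ctl", "R", 20.0),
         ("t", "trt", "T", 23.0), ("t", "trt", "R", 20.0)]
    )
    out = ddct_fold_change(rec, "T", "R", "ctl").set_index("group")
    assert out.at["trt", "fold_change"] == pytest.approx(4.0)


def test_fold_matches_spreadsheet_oracle_with_replicates():
    """Three replicates per group: recompute ddCt cell-by-cell the way one
    would in a spreadsheet and compare."""
    cts = {
        "ctl": [(24.8, 20.1), (25.2, 19.9), (25.0, 20.0)],
        "trt": [(22.9, 20.2), (23.1, 19.8), (23.0, 20.0)],
    }
    rows = []
    for group, pairs in cts.items():
        for i, (t, r) in enumerate(pairs):
            rows += [(f"{group}{i}", group, "T", t), (f"{group}{i}", group, "R", r)]
    out = ddct_fold_change(_records(rows), "T", "R", "ctl").set_index("group")

    mean_dct = {g: np.mean([t - r for t, r in pairs]) for g, pairs in cts.items()}
    expected = 2.0 ** (-(mean_dct["trt"] - mean_dct["ctl"]))
    assert out.at["trt", "fold_change"] == pytest.approx(expected, rel=1e-12)


def test_missing_reference_ct_rejected():
    rec = _records([("s1", "ctl", "T", 25.0)])
    with pytest.raises(MsapValidationError, match="reference"):
        ddct_fold_change(rec, "T", "R", "ctl")


def test_unknown_control_group_rejected():
    rec = _records([("s1", "ctl", "T", 25.0), ("s1", "ctl", "R", 20.0)])
    with pytest.raises(MsapValidationError, match="control group"):
        ddct_fold_change(rec, "T", "R", "mock")


@settings(derandomize=True, max_examples=50)
@given(shift=st.floats(-5, 5, allow_nan=False))
def test_fold_invariant_to_common_ct_shift(shift):
    """Adding a constant to every Ct of the target gene changes folds only
    if the reference is not shifted too — the dCt construction check."""
    base = _records(
        [("c", "ctl", "T", 25.0), ("c", "ctl", "R", 20.0),
         ("t", "trt", "T", 23.0), ("t", "trt", "R", 21.0)]
    )
    both = base.copy()
    both["ct"] = both["ct"] + shift  # shift target AND reference
    f0 = ddct_fold_change(base, "T", "R", "ctl").set_index("group")["fold_change"]
    f1 = ddct_fold_change(both, "T", "R", "ctl").set_index("group")["fold_change"]
    assert np.allclose(f0, f1)
    target_only = base.copy()
    target_only.loc[target_only["gene"] == "T", "ct"] += shift
    f2 = ddct_fold_change(target_only, "T", "R", "ctl").set_index("group")[
        "fold_change"
    ]
    # a uniform target-only shift still cancels in ddCt (affects all groups)
    assert np.allclose(f0, f2)


# ---------------------------------------------------------------------------
# 5mC percentage


def test_five_mc_direct_ratio():
    assert five_mc_percent(1.0, 3.0) == pytest.approx(25.0)


def test_five_mc_zero_numerator():
    assert five_mc_percent(0.0, 2.0) == 0.0


def test_five_mc_with_response_factors():
    assert five_mc_percent(2.0, 2.0, rf_5mc=2.0, rf_c=1.0) == pytest.approx(100 / 3)


def test_five_mc_scaling_invariance():
    a = five_mc_percent(1.7, 4.3, 1.2, 0.9)
    b = five_mc_percent(17.0, 43.0, 1.2, 0.9)
    assert a == pytest.approx(b, rel=1e-12)


def test_five_mc_degenerate_input():
    with pytest.raises(MsapValidationError):
        five_mc_percent(0.0, 0.0)


# ---------------------------------------------------------------------------
# ANOVA + Duncan


def _dataset(spec, seed=0):
    """spec: list of (label, mean, sd, n)."""
    rng = np.random.default_rng(seed)
    values, groups = [], []
    for label, mean, sd, n in spec:
        values.extend(rng.normal(mean, sd, n))
        groups.extend([label] * n)
    return np.array(values), np.array(groups)


def test_overwhelming_separation_distinct_letters():
    values, groups = _dataset([("low", 0, 0.1, 3), ("high", 100, 0.1, 3)])
    res = anova_duncan(values, groups)
    assert res.letters["low"] != res.letters["high"]
    assert res.p_value < 1e-6


def test_indistinguishable_groups_share_a_letter():
    # identical jitter pattern in every group: nonzero MS_error, tied means
    values = np.tile(5.0 + np.array([-1e-10, 0.0, 1e-10]), 3)
    groups = np.repeat(["g1", "g2", "g3"], 3)
    res = anova_duncan(values, groups)
    assert set(res.letters.values()) == {"a"}


def test_zero_within_group_variance_is_degenerate():
    with pytest.raises(DegenerateInputError):
        anova_duncan([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])


def test_group_with_single_observation_rejected():
    with pytest.raises(MsapValidationError, match="< 2 observations"):
        anova_duncan([1.0, 2.0, 3.0], ["a", "a", "b"])


def test_invalid_alpha_rejected():
    with pytest.raises(MsapValidationError, match="alpha"):
        anova_duncan([1, 2, 3, 4], ["a", "a", "b", "b"], alpha=1.5)


def _oracle_letters(sig):
    """Brute-force compact-letter display: enumerate every maximal clique of
    the non-significance graph (feasible at <= 4 groups) and letter them in
    order of their best-ranked member."""
    k = sig.shape[0]
    cliques = []
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(k), r):
            if all(not sig[i, j] for i, j in itertools.combinations(combo, 2)):
                cliques.append(set(combo))
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    maximal.sort(key=min)
    letters = ["" for _ in range(k)]
    for ci, clique in enumerate(maximal):
        for g in sorted(clique):
            letters[g] += "abcdefghijklmnopqrstuvwxyz"[ci]
    return letters


FOUR_GROUP_CASES = [
    [("A", 0.0, 1.0, 5), ("B", 1.0, 1.0, 5), ("C", 5.0, 1.0, 5), ("D", 9.0, 1.0, 5)],
    [("A", 0.0, 0.5, 4), ("B", 0.2, 0.5, 4), ("C", 0.4, 0.5, 4), ("D", 0.6, 0.5, 4)],
    [("A", 0.0, 0.1, 3), ("B", 10.0, 0.1, 3), ("C", 20.0, 0.1, 3), ("D", 30.0, 0.1, 3)],
    [("A", 0.0, 2.0, 6), ("B", 1.5, 2.0, 6), ("C", 1.6, 2.0, 6), ("D", 8.0, 2.0, 6)],
]


@pytest.mark.parametrize("spec", FOUR_GROUP_CASES)
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_letters_match_brute_force_oracle(spec, seed):
    values, groups = _dataset(spec, seed=seed)
    res = anova_duncan(values, groups)
    order = res.groups["group"].tolist()
    means = res.groups["mean"].to_numpy()
    ns = res.groups["n"].to_numpy()
    sig = duncan_significant_pairs(means, ns, res.ms_error, res.df_error, res.alpha)
    expected = dict(zip(order, _oracle_letters(sig)))
    assert res.letters == expected


@pytest.mark.parametrize("spec", FOUR_GROUP_CASES)
def test_letter_display_validity(spec):
    """Every non-significant pair shares >= 1 letter; every significant pair
    shares none."""
    values, groups = _dataset(spec, seed=3)
    res = anova_duncan(values, groups)
    means = res.groups["mean"].to_numpy()
    ns = res.groups["n"].to_numpy()
    sig = duncan_significant_pairs(means, ns, res.ms_error, res.df_error, res.alpha)
    letters = res.groups["letters"].tolist()
    for i, j in itertools.combinations(range(len(letters)), 2):
        shared = set(letters[i]) & set(letters[j])
        assert bool(shared) == (not sig[i, j])


def test_relabeling_permutes_letters_consistently():
    spec = FOUR_GROUP_CASES[0]
    values, groups = _dataset(spec, seed=4)
    res1 = anova_duncan(values, groups)
    renamed = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
    res2 = anova_duncan(values, np.array([renamed[g] for g in groups]))
    assert {renamed[g]: s for g, s in res1.letters.items()} == res2.letters


def test_more_liberal_alpha_never_merges_more():
    values, groups = _dataset(FOUR_GROUP_CASES[1], seed=5)
    res = anova_duncan(values, groups)
    means = res.groups["mean"].to_numpy()
    ns = res.groups["n"].to_numpy()
    previous = -1
    for alpha in (0.01, 0.05, 0.10, 0.20):
        sig = duncan_significant_pairs(means, ns, res.ms_error, res.df_error, alpha)
        n_sig = int(sig.sum()) // 2
        assert n_sig >= previous
        previous = n_sig


def test_cld_on_hand_built_matrix():
    # chain: adjacent pairs not separated, extremes separated
    sig = np.array(
        [[False, False, True], [False, False, False], [True, False, False]]
    )
    letters = compact_letter_display(sig)
    assert set(letters[0]) & set(letters[1])
    assert set(letters[1]) & set(letters[2])
    assert not (set(letters[0]) & set(letters[2]))
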