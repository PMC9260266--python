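"""Supporting quantitation: 2^-ΔΔCt relative expression, 5mC percentage from
chromatogram peak areas, and one-way ANOVA followed by Duncan's multiple
range test with a compact-letter display.

Duncan's multiple range test
----------------------------
After a one-way ANOVA, group means are sorted in descending order.  Two means
whose sorted positions span ``p`` consecutive means differ significantly when
their difference exceeds the critical range

    R_p = q(1 - alpha_p; p, df_error) * sqrt(MS_error / n_h)

where ``q`` is the studentized-range quantile, ``n_h`` the (harmonic mean)
group size, and ``alpha_p = 1 - (1 - alpha)^(p - 1)`` Duncan's protection
level, which relaxes the per-range significance level as the span grows.
The standard step-down protection applies: a range contained inside a
non-significant wider range is itself declared non-significant.  Letters are
assigned by insert-and-absorb so that two groups share a letter iff they are
not significantly different.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MsapValidationError

__all__ = [
    "DegenerateInputError",
    "GroupComparisonResult",
    "ddct_fold_change",
    "five_mc_percent",
    "anova_duncan",
    "duncan_significant_pairs",
]


class DegenerateInputError(ValueError):
    """The within-group mean square is zero, so range tests are undefined."""


# ---------------------------------------------------------------------------
# Relative expression


def ddct_fold_change(
    records: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_group: str,
) -> pd.DataFrame:
    """Per-group 2^-ΔΔCt relative expression of ``target_gene``.

    ``records`` holds one row per (sample, gene) with columns ``sample_id``,
    ``group``, ``gene``, ``ct``.  Per sample, ΔCt = Ct(target) − Ct(reference);
    ΔΔCt is the group-mean ΔCt minus the control group's mean ΔCt, and the
    fold change is 2^−ΔΔCt (the control group is 1 by construction).
    """
    req = {"sample_id", "group", "gene", "ct"}
    missing = req - set(records.columns)
    if missing:
        raise MsapValidationError(f"Ct records missing columns: {sorted(missing)}")
    tgt = records[records["gene"] == target_gene]
    ref = records[records["gene"] == reference_gene]
    if tgt.empty:
        raise MsapValidationError(f"no Ct records for target gene {target_gene!r}")
    ref_ct = ref.groupby("sample_id")["ct"].mean()
    tgt_ct = tgt.groupby("sample_id")["ct"].mean()
    no_ref = sorted(set(tgt_ct.index) - set(ref_ct.index))
    if no_ref:
        raise MsapValidationError(
            f"samples lack a reference-gene ({reference_gene!r}) Ct: {no_ref}"
        )
    dct = (tgt_ct - ref_ct.loc[tgt_ct.index]).rename("dct")
    sample_group = tgt.drop_duplicates("sample_id").set_index("sample_id")["group"]
    per_group = (
        pd.DataFrame({"dct": dct, "group": sample_group.loc[dct.index]})
        .groupby("group")["dct"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "mean_dct", "count": "n"})
    )
    if control_group not in per_group.index:
        raise MsapValidationError(
            f"unknown control group {control_group!r}; groups present: "
            f"{sorted(per_group.index)}"
        )
    per_group["ddct"] = per_group["mean_dct"] - per_group.at[control_group, "mean_dct"]
    per_group["fold_change"] = 2.0 ** (-per_group["ddct"])
    return per_group.reset_index()[["group", "n", "mean_dct", "ddct", "fold_change"]]


# ---------------------------------------------------------------------------
# 5-methylcytosine percentage


def five_mc_percent(
    area_5mc: float,
    area_c: float,
    rf_5mc: float = 1.0,
    rf_c: float = 1.0,
) -> float:
    """5mC as a percentage of total cytosine from HPLC peak areas.

    Peak areas are converted to molar amounts with per-analyte response
    factors (area per unit amount; default 1, i.e. equal detector response):

        5mC% = 100 * (A_5mC/rf_5mC) / (A_5mC/rf_5mC + A_C/rf_C)
    """
    if rf_5mc <= 0 or rf_c <= 0:
        raise MsapValidationError("response factors must be positive")
    if area_5mc < 0 or area_c < 0:
        raise MsapValidationError("peak areas must be non-negative")
    mc = area_5mc / rf_5mc
    c = area_c / rf_c
    if mc + c == 0:
        raise MsapValidationError("both corrected peak areas are zero")
    return 100.0 * mc / (mc + c)


# ---------------------------------------------------------------------------
# ANOVA + Duncan's multiple range test


@dataclass(frozen=True)
class GroupComparisonResult:
    """One-way ANOVA plus Duncan letters.

    ``groups`` has one row per group (sorted by descending mean) with columns
    ``group``, ``n``, ``mean``, ``sd``, ``letters``.  Two groups share a
    letter iff Duncan's test does not separate them at ``alpha``.
    """

    groups: pd.DataFrame
    f_stat: float
    p_value: float
    alpha: float
    ms_error: float
    df_error: int

    @property
    def letters(self) -> dict:
        return dict(zip(self.groups["group"], self.groups["letters"]))


def _group_arrays(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise MsapValidationError("values and groups must have equal length")
    labels = list(pd.unique(groups))
    arrs = [values[groups == g] for g in labels]
    if len(labels) < 2:
        raise MsapValidationError("need >= 2 groups")
    small = [str(g) for g, a in zip(labels, arrs) if a.size < 2]
    if small:
        raise MsapValidationError(f"groups with < 2 observations: {small}")
    return labels, arrs


def _critical_range(p_span, alpha, ms_error, df_error, n_h):
    alpha_p = 1.0 - (1.0 - alpha) ** (p_span - 1)
    q = stats.studentized_range.ppf(1.0 - alpha_p, p_span, df_error)
    return q * np.sqrt(ms_error / n_h)


def duncan_significant_pairs(
    means: np.ndarray,
    ns: np.ndarray,
    ms_error: float,
    df_error: int,
    alpha: float,
) -> np.ndarray:
    """Boolean matrix of significant pairs under Duncan's MRT.

    ``means``/``ns`` must already be sorted by descending mean.  Each pair is
    first tested against its span's critical range R_p (harmonic-mean group
    size for unequal n), then the step-down protection de-flags any pair
    nested inside a non-significant wider range.
    """
    k = len(means)
    raw = np.zeros((k, k), dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        span = j - i + 1
        n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
        r_p = _critical_range(span, alpha, ms_error, df_error, n_h)
        raw[i, j] = raw[j, i] = abs(means[i] - means[j]) > r_p
    sig = raw.copy()
    # protection: a range inside a non-significant range is non-significant
    for i, j in itertools.combinations(range(k), 2):
        if not raw[i, j]:
            for a in range(i, j + 1):
                for b in range(a + 1, j + 1):
                    if (a, b) != (i, j):
                        sig[a, b] = sig[b, a] = False
    return sig


def compact_letter_display(sig: np.ndarray) -> list[str]:
    """Insert-and-absorb letter assignment from a significance matrix.

    Groups are indexed 0..k-1 in descending-mean order; returns one letter
    string per group such that two groups share a letter iff their pair is
    non-significant.
    """
    k = sig.shape[0]
    columns: list[set] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not sig[i, j]:
            continue
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            columns.extend([col - {i}, col - {j}])
        # absorb columns that became subsets of another
        columns = [
            c
            for idx, c in enumerate(columns)
            if c
            and not any(
                c < other or (c == other and idx > jdx)
                for jdx, other in enumerate(columns)
            )
        ]
    columns.sort(key=lambda c: min(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = []
    for g in range(k):
        out.append("".join(alphabet[ci] for ci, c in enumerate(columns) if g in c))
    return out


def anova_duncan(values, groups, alpha: float = 0.05) -> GroupComparisonResult:
    """One-way ANOVA followed by Duncan's multiple range test.

    Parameters
    ----------
    values, groups : array-like
        Measurements and their group labels (>= 2 groups, each n >= 2).
    alpha : float
        Base significance level of the range tests, in (0, 1).

    Raises
    ------
    DegenerateInputError
        When MS_error is exactly zero (no within-group variation), since the
        studentized-range scale collapses.
    """
    if not 0.0 < alpha < 1.0:
        raise MsapValidationError(f"alpha must be in (0, 1), got {alpha}")
    labels, arrs = _group_arrays(values, groups)
    ns = np.array([a.size for a in arrs])
    means = np.array([a.mean() for a in arrs])
    sds = np.array([a.std(ddof=1) for a in arrs])
    n_total = int(ns.sum())
    grand = float(np.concatenate(arrs).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df_between = len(labels) - 1
    df_error = n_total - len(labels)
    ms_between = ss_between / df_between
    ms_error = ss_within / df_error
    if ms_error == 0.0:
        raise DegenerateInputError(
            "zero within-group variance: MS_error is 0, Duncan's ranges are "
            "undefined (add measurement jitter or more replicates)"
        )
    f_stat = ms_between / ms_error
    p_value = float(stats.f.sf(f_stat, df_between, df_error))

    order = np.argsort(-means, kind="stable")
    sig = duncan_significant_pairs(
        means[order], ns[order], ms_error, df_error, alpha
    )
    letters_sorted = compact_letter_display(sig)
    table = pd.DataFrame(
        {
            "group": [labels[i] for i in order],
            "n": ns[order],
            "mean": means[order],
            "sd": sds[order],
            "letters": letters_sorted,
        }
    )
    return GroupComparisonResult(
        groups=table,
        f_stat=float(f_stat),
        p_value=p_value,
        alpha=alpha,
        ms_error=ms_error,
        df_error=df_error,
    )
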