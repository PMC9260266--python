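"""Control-vs-treatment methylation transition typing.

Pairing a control (CK) and a treated MSAP profile locus-by-locus gives 16
possible pattern changes.  Eight carry a definite methylation direction:

* B types (methylation gained — the HpaII band is lost):
  B1 = I->III, B2 = II->III, B3 = II->IV, B4 = I->IV
* C types (demethylation — the HpaII band is gained):
  C1 = III->I, C2 = III->II, C3 = IV->II, C4 = IV->I

The four identity pairs are UNCHANGED.  The remaining four (I<->II and
III<->IV, where only the MspI band moves) are AMBIGUOUS: MSAP cannot tell
whether methylation rose or fell because a hypermethylated site and an
unmethylated one bracket the same M-lane change.  Ambiguous pairs are
tallied but excluded from the methylation/demethylation totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources

import pandas as pd

from .io import BandMatrix, MsapValidationError, SampleMeta
from .scoring import FLAGS_BY_PATTERN, Pattern

__all__ = [
    "TransitionType",
    "TransitionTable",
    "TransitionSummary",
    "classify_transition",
    "transition_table",
    "summarize_transitions",
    "load_azac_transition_counts",
    "expand_transition_counts",
]


class TransitionType(str, Enum):
    B1 = "B1"
    B2 = "B2"
    B3 = "B3"
    B4 = "B4"
    C1 = "C1"
    C2 = "C2"
    C3 = "C3"
    C4 = "C4"
    UNCHANGED = "UNCHANGED"
    AMBIGUOUS = "AMBIGUOUS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


B_TYPES = (TransitionType.B1, TransitionType.B2, TransitionType.B3, TransitionType.B4)
C_TYPES = (TransitionType.C1, TransitionType.C2, TransitionType.C3, TransitionType.C4)

_TRANSITIONS = {
    (Pattern.I, Pattern.III): TransitionType.B1,
    (Pattern.II, Pattern.III): TransitionType.B2,
    (Pattern.II, Pattern.IV): TransitionType.B3,
    (Pattern.I, Pattern.IV): TransitionType.B4,
    (Pattern.III, Pattern.I): TransitionType.C1,
    (Pattern.III, Pattern.II): TransitionType.C2,
    (Pattern.IV, Pattern.II): TransitionType.C3,
    (Pattern.IV, Pattern.I): TransitionType.C4,
}


def classify_transition(ck: Pattern, treated: Pattern) -> TransitionType:
    """Type one control->treated pattern change.

    Total over all 16 pairs: 8 directional (B/C), 4 UNCHANGED, 4 AMBIGUOUS.
    """
    ck, treated = Pattern(ck), Pattern(treated)
    if ck == treated:
        return TransitionType.UNCHANGED
    return _TRANSITIONS.get((ck, treated), TransitionType.AMBIGUOUS)


@dataclass(frozen=True)
class TransitionTable:
    """Per-type transition counts for one CK-vs-treatment comparison."""

    label: str
    counts: dict  # TransitionType -> int
    n_loci_compared: int
    n_excluded: int = 0  # loci dropped for a missing call in either profile

    def count(self, t: TransitionType) -> int:
        return self.counts.get(t, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in TransitionType:
            if t in _TRANSITIONS.values():
                (ck, treat) = next(k for k, v in _TRANSITIONS.items() if v is t)
                ck_h, ck_m = FLAGS_BY_PATTERN[ck]
                tr_h, tr_m = FLAGS_BY_PATTERN[treat]
                change = f"{ck}->{treat}"
            else:
                ck_h = ck_m = tr_h = tr_m = pd.NA
                change = t.value
            rows.append(
                {
                    "band_type": t.value,
                    "change": change,
                    "ck_h": ck_h,
                    "ck_m": ck_m,
                    "treat_h": tr_h,
                    "treat_m": tr_m,
                    "n_sites": self.count(t),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TransitionSummary:
    label: str
    methylation_total: int
    demethylation_total: int
    dominant_B: tuple
    dominant_C: tuple
    n_unchanged: int
    n_ambiguous: int
    n_loci_compared: int


def _single_profile(matrix: BandMatrix, which: str) -> str:
    if len(matrix.samples) != 1:
        raise MsapValidationError(
            f"{which} matrix must hold exactly one (consensus) sample, "
            f"got {len(matrix.samples)}; run aggregate_replicates first"
        )
    return matrix.samples[0].sample_id


def transition_table(
    ck: BandMatrix, treated: BandMatrix, label: str | None = None
) -> TransitionTable:
    """Classify every shared locus of a CK/treated pair and tally by type.

    Both matrices must carry exactly one sample (use
    :func:`~msapkit.scoring.aggregate_replicates` to collapse replicates) and
    an identical locus list.  Loci with a missing call in either profile are
    excluded and counted in ``n_excluded``.
    """
    ck_id = _single_profile(ck, "CK")
    tr_id = _single_profile(treated, "treated")
    if list(ck.loci) != list(treated.loci):
        raise MsapValidationError(
            "CK and treated matrices must share an identical locus list"
        )
    if label is None:
        s = treated.samples[0]
        dose = str(int(s.dose)) if float(s.dose).is_integer() else str(s.dose)
        label = f"{s.tissue}_CK-{dose}uM"

    counts: dict[TransitionType, int] = {t: 0 for t in TransitionType}
    excluded = 0
    for locus in ck.loci:
        vals = (
            ck.h.at[locus, ck_id],
            ck.m.at[locus, ck_id],
            treated.h.at[locus, tr_id],
            treated.m.at[locus, tr_id],
        )
        if any(pd.isna(v) for v in vals):
            excluded += 1
            continue
        ck_pat = Pattern(
            {(1, 1): "I", (1, 0): "II", (0, 1): "III", (0, 0): "IV"}[
                (int(vals[0]), int(vals[1]))
            ]
        )
        tr_pat = Pattern(
            {(1, 1): "I", (1, 0): "II", (0, 1): "III", (0, 0): "IV"}[
                (int(vals[2]), int(vals[3]))
            ]
        )
        counts[classify_transition(ck_pat, tr_pat)] += 1
    n_compared = sum(counts.values())
    return TransitionTable(label, counts, n_compared, excluded)


def summarize_transitions(table: TransitionTable) -> TransitionSummary:
    """Totals and dominant types for one comparison.

    ``methylation_total`` sums the B types, ``demethylation_total`` the C
    types; AMBIGUOUS loci are excluded from both.  ``dominant_B`` /
    ``dominant_C`` are the argmax types (ties reported as multiple; empty
    when every count is zero).
    """

    def dominant(types):
        mx = max((table.count(t) for t in types), default=0)
        if mx == 0:
            return ()
        return tuple(t for t in types if table.count(t) == mx)

    return TransitionSummary(
        label=table.label,
        methylation_total=sum(table.count(t) for t in B_TYPES),
        demethylation_total=sum(table.count(t) for t in C_TYPES),
        dominant_B=dominant(B_TYPES),
        dominant_C=dominant(C_TYPES),
        n_unchanged=table.count(TransitionType.UNCHANGED),
        n_ambiguous=table.count(TransitionType.AMBIGUOUS),
        n_loci_compared=table.n_loci_compared,
    )


# ---------------------------------------------------------------------------
# Packaged 5-azaC study counts (root/leaf x 15/50/100 uM) and their expander.

#: Comparison columns available in the packaged count table.
AZAC_COMPARISONS = (
    "root_15uM",
    "root_50uM",
    "root_100uM",
    "leaf_15uM",
    "leaf_50uM",
    "leaf_100uM",
)


def load_azac_transition_counts() -> pd.DataFrame:
    """Load the packaged per-band-type site counts from the 5-azaC dose study
    (root and leaf tissue, 15/50/100 μM, each versus untreated control)."""
    with resources.files("msapkit.data").joinpath(
        "azac_transition_counts.tsv"
    ).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def expand_transition_counts(
    counts: pd.DataFrame, comparison: str
) -> tuple[BandMatrix, BandMatrix]:
    """Materialize one synthetic locus per counted site for a comparison
    column, returning (ck, treated) single-sample band matrices.

    Each band-type row contributes ``counts[comparison]`` loci whose CK and
    treated H/M flags are the row's definition, so running
    :func:`transition_table` on the pair recovers the counts end-to-end.
    """
    if comparison not in counts.columns:
        raise MsapValidationError(
            f"unknown comparison {comparison!r}; expected one of "
            f"{[c for c in counts.columns if c.endswith('uM')]}"
        )
    tissue, dose_label = comparison.split("_")
    dose = float(dose_label.removesuffix("uM"))
    loci, ck_h, ck_m, tr_h, tr_m = [], [], [], [], []
    for row in counts.itertuples(index=False):
        n = int(getattr(row, comparison))
        for i in range(n):
            loci.append(f"{comparison}_{row.band_type}_{i + 1}")
            ck_h.append(int(row.ck_h))
            ck_m.append(int(row.ck_m))
            tr_h.append(int(row.treat_h))
            tr_m.append(int(row.treat_m))
    idx = pd.Index(loci, name="locus_id")
    ck = BandMatrix(
        samples=[SampleMeta(f"{tissue}_CK", tissue, "M", 0.0, 1)],
        h=pd.DataFrame({f"{tissue}_CK": ck_h}, index=idx, dtype="Int64"),
        m=pd.DataFrame({f"{tissue}_CK": ck_m}, index=idx, dtype="Int64"),
    )
    treated = BandMatrix(
        samples=[SampleMeta(f"{tissue}_{dose_label}", tissue, "M", dose, 1)],
        h=pd.DataFrame({f"{tissue}_{dose_label}": tr_h}, index=idx, dtype="Int64"),
        m=pd.DataFrame({f"{tissue}_{dose_label}": tr_m}, index=idx, dtype="Int64"),
    )
    return ck, treated
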