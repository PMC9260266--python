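"""Methylation-pattern classification and level statistics for MSAP data.

Each CCGG locus is scored by a pair of band calls: H (EcoRI+HpaII digest)
and M (EcoRI+MspI digest).  HpaII will not cut a fully methylated site and
cuts a hemi-methylated external cytosine, while MspI cuts when the internal
cytosine is methylated; this yields four banding patterns:

=========  =====  =====  ==================================================
Pattern     H      M     interpretation
=========  =====  =====  ==================================================
I           1      1     unmethylated site
II          1      0     hemi-methylated (one strand)
III         0      1     fully methylated internal cytosine
IV          0      0     hypermethylated — invisible to both digests
=========  =====  =====  ==================================================

Methylation levels are ratios over the detectable patterns only:

    total % = (II + III) / (I + II + III) * 100
    hemi %  =  II        / (I + II + III) * 100
    full %  =  III       / (I + II + III) * 100

Pattern IV is tallied but never enters the denominators: a locus dark in
both lanes cannot be distinguished from a primer/restriction-site absence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .io import BandMatrix, MsapValidationError, SampleMeta

__all__ = [
    "Pattern",
    "PatternCounts",
    "MethylationLevels",
    "UndefinedLevelError",
    "classify_pattern",
    "classify_matrix",
    "count_patterns",
    "methylation_levels",
    "aggregate_replicates",
]

logger = logging.getLogger(__name__)


class Pattern(str, Enum):
    """The four MSAP banding patterns."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_PATTERN_BY_FLAGS = {
    (1, 1): Pattern.I,
    (1, 0): Pattern.II,
    (0, 1): Pattern.III,
    (0, 0): Pattern.IV,
}

#: Band rendering of each pattern, the inverse of :func:`classify_pattern`.
FLAGS_BY_PATTERN = {v: k for k, v in _PATTERN_BY_FLAGS.items()}


class UndefinedLevelError(ValueError):
    """All scored loci are pattern IV, so the level denominator is zero."""


def classify_pattern(h: int, m: int) -> Pattern:
    """Map one (H, M) band pair to its methylation pattern.

    The mapping is the bijection (1,1)->I, (1,0)->II, (0,1)->III, (0,0)->IV.
    """
    try:
        return _PATTERN_BY_FLAGS[(int(h), int(m))]
    except (KeyError, TypeError, ValueError):
        raise MsapValidationError(f"band flags must be 0/1, got h={h!r} m={m!r}")


def classify_matrix(matrix: BandMatrix) -> pd.DataFrame:
    """Classify every (locus, sample) cell of a band matrix.

    Returns a DataFrame of pattern labels ("I".."IV") indexed like the band
    matrix; cells with a missing H or M call are NA.
    """
    out = {}
    for sid in matrix.sample_ids:
        h = matrix.h[sid]
        m = matrix.m[sid]
        col = []
        for hv, mv in zip(h, m):
            if pd.isna(hv) or pd.isna(mv):
                col.append(pd.NA)
            else:
                col.append(_PATTERN_BY_FLAGS[(int(hv), int(mv))].value)
        out[sid] = col
    return pd.DataFrame(out, index=matrix.h.index, dtype="string")


@dataclass(frozen=True)
class PatternCounts:
    """Tally of the four patterns over the scored cells of one group."""

    group: tuple
    n_I: int
    n_II: int
    n_III: int
    n_IV: int
    n_missing: int = 0

    @property
    def n_scored(self) -> int:
        return self.n_I + self.n_II + self.n_III + self.n_IV

    def __add__(self, other: "PatternCounts") -> "PatternCounts":
        return PatternCounts(
            self.group,
            self.n_I + other.n_I,
            self.n_II + other.n_II,
            self.n_III + other.n_III,
            self.n_IV + other.n_IV,
            self.n_missing + other.n_missing,
        )


@dataclass(frozen=True)
class MethylationLevels:
    total_pct: float
    hemi_pct: float
    full_pct: float


def count_patterns(
    matrix: BandMatrix, grouping: tuple[str, ...] = ("tissue", "stage", "dose")
) -> list[PatternCounts]:
    """Tally patterns per metadata group.

    ``grouping`` names :class:`~msapkit.io.SampleMeta` fields (any of
    ``tissue``, ``stage``, ``dose``, ``replicate``, ``sample_id``).  Cells
    with a missing band call are excluded from the tallies and reported in
    ``n_missing``.
    """
    valid = {"tissue", "stage", "dose", "replicate", "sample_id"}
    bad = [g for g in grouping if g not in valid]
    if bad:
        raise MsapValidationError(f"unknown grouping keys: {bad}")
    patterns = classify_matrix(matrix)
    buckets: dict[tuple, dict] = {}
    for s in matrix.samples:
        key = tuple(getattr(s, g) for g in grouping)
        col = patterns[s.sample_id]
        tally = buckets.setdefault(
            key, {"I": 0, "II": 0, "III": 0, "IV": 0, "missing": 0}
        )
        counts = col.value_counts(dropna=False)
        for label, n in counts.items():
            if pd.isna(label):
                tally["missing"] += int(n)
            else:
                tally[str(label)] += int(n)
    return [
        PatternCounts(key, t["I"], t["II"], t["III"], t["IV"], t["missing"])
        for key, t in buckets.items()
    ]


def methylation_levels(counts: PatternCounts) -> MethylationLevels:
    """Compute total/hemi/full methylation percentages from pattern counts.

    Raises :class:`UndefinedLevelError` when no detectable locus exists
    (all pattern IV): the ratio denominator I + II + III is zero.
    """
    denom = counts.n_I + counts.n_II + counts.n_III
    if denom == 0:
        raise UndefinedLevelError(
            f"group {counts.group!r}: all {counts.n_IV} scored loci are pattern "
            "IV; methylation levels are undefined"
        )
    return MethylationLevels(
        total_pct=(counts.n_II + counts.n_III) / denom * 100.0,
        hemi_pct=counts.n_II / denom * 100.0,
        full_pct=counts.n_III / denom * 100.0,
    )


_CONSENSUS_RULES = ("majority", "any", "all")


def _consensus(values: list, rule: str, where: str) -> object:
    """Merge replicate band calls for one flag.  NA calls are dropped first;
    an all-NA set stays NA."""
    obs = [int(v) for v in values if not pd.isna(v)]
    if not obs:
        return pd.NA
    ones = sum(obs)
    if rule == "any":
        return 1 if ones > 0 else 0
    if rule == "all":
        return 1 if ones == len(obs) else 0
    # strict majority; ties resolve to band-absent (a call needs positive evidence)
    if 2 * ones == len(obs):
        logger.warning("replicate tie at %s resolved to 0 (band absent)", where)
        return 0
    return 1 if 2 * ones > len(obs) else 0


def aggregate_replicates(matrix: BandMatrix, rule: str = "majority") -> BandMatrix:
    """Collapse replicates to one consensus sample per (tissue, stage, dose).

    H and M flags are merged independently under ``rule`` (``majority`` with
    ties to 0, ``any``, or ``all``).  The consensus sample id is
    ``<tissue>_<stage>_<dose>`` and its replicate index is 1.
    """
    if rule not in _CONSENSUS_RULES:
        raise MsapValidationError(
            f"unknown consensus rule {rule!r}; expected one of {_CONSENSUS_RULES}"
        )
    cells: dict[tuple, list[SampleMeta]] = {}
    for s in matrix.samples:
        cells.setdefault((s.tissue, s.stage, s.dose), []).append(s)

    new_samples, h_cols, m_cols = [], {}, {}
    for (tissue, stage, dose), members in cells.items():
        dose_label = str(int(dose)) if float(dose).is_integer() else str(dose)
        sid = f"{tissue}_{stage}_{dose_label}"
        new_samples.append(SampleMeta(sid, tissue, stage, dose, 1))
        member_ids = [s.sample_id for s in members]
        h_cols[sid] = [
            _consensus(list(row), rule, f"locus {locus!r} H in {sid}")
            for locus, row in matrix.h[member_ids].iterrows()
        ]
        m_cols[sid] = [
            _consensus(list(row), rule, f"locus {locus!r} M in {sid}")
            for locus, row in matrix.m[member_ids].iterrows()
        ]
    idx = matrix.h.index
    return BandMatrix(
        samples=new_samples,
        h=pd.DataFrame(h_cols, index=idx, dtype="Int64"),
        m=pd.DataFrame(m_cols, index=idx, dtype="Int64"),
    )


def levels_table(
    matrix: BandMatrix, grouping: tuple[str, ...] = ("tissue", "stage", "dose")
) -> pd.DataFrame:
    """Per-group pattern counts and methylation levels as one tidy table.

    Groups whose loci are all pattern IV get NA levels rather than an error,
    so one degenerate group does not abort a multi-group report.
    """
    rows = []
    for counts in count_patterns(matrix, grouping):
        row = dict(zip(grouping, counts.group))
        row.update(
            n_I=counts.n_I,
            n_II=counts.n_II,
            n_III=counts.n_III,
            n_IV=counts.n_IV,
            n_missing=counts.n_missing,
        )
        try:
            lv = methylation_levels(counts)
            row.update(
                total_pct=round(lv.total_pct, 2),
                hemi_pct=round(lv.hemi_pct, 2),
                full_pct=round(lv.full_pct, 2),
            )
        except UndefinedLevelError:
            row.update(total_pct=pd.NA, hemi_pct=pd.NA, full_pct=pd.NA)
        rows.append(row)
    return pd.DataFrame(rows).sort_values(list(grouping)).reset_index(drop=True)
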