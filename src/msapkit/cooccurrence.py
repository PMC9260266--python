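"""Gene co-occurrence rates over a taxa x genes presence/absence matrix.

The co-occurrence rate of a gene is the percentage of surveyed taxa in which
a homolog was found; the matched-query count of a taxon is how many of the
query genes have a homolog there.  The packaged survey covers the five
iridoid glycoside biosynthesis genes (DXS, DXR, 10HGO, G10H, GPPS) across 72
plant taxa.
"""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd

from .io import MsapValidationError, read_occurrence_matrix

__all__ = [
    "load_iridoid_cooccurrence",
    "validate_occurrence",
    "cooccurrence_rate",
    "queries_matched",
    "round_half_up",
    "cooccurrence_report",
]


def load_iridoid_cooccurrence() -> pd.DataFrame:
    """Load the packaged 72-taxon x 5-gene iridoid-pathway survey."""
    ref = resources.files("msapkit.data").joinpath("iridoid_gene_cooccurrence.tsv")
    with resources.as_file(ref) as path:
        return read_occurrence_matrix(path)


def validate_occurrence(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check an occurrence DataFrame (taxa rows x gene columns, 0/1)."""
    if matrix.shape[0] < 1 or matrix.shape[1] < 1:
        raise MsapValidationError("occurrence matrix needs >=1 taxon and >=1 gene")
    if matrix.index.has_duplicates:
        raise MsapValidationError("duplicate taxa in occurrence matrix")
    if not matrix.isin([0, 1]).all().all():
        raise MsapValidationError("occurrence matrix entries must be 0/1")
    return matrix


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (68.5 -> 69, not banker's 68)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def cooccurrence_rate(matrix: pd.DataFrame, decimals: int = 1) -> pd.Series:
    """Per-gene presence percentage, rounded half away from zero.

    rate(gene) = 100 * (# taxa with presence) / (# taxa)
    """
    validate_occurrence(matrix)
    n_taxa = matrix.shape[0]
    raw = matrix.sum(axis=0) / n_taxa * 100.0
    return raw.map(lambda v: round_half_up(float(v), decimals)).rename("rate_pct")


def queries_matched(matrix: pd.DataFrame) -> pd.Series:
    """Per-taxon count of query genes with a homolog present (row sums)."""
    validate_occurrence(matrix)
    return matrix.sum(axis=1).rename("n_queries_matched")


def cooccurrence_report(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-gene rates table, per-taxon matched-count table)."""
    validate_occurrence(matrix)
    n_taxa = matrix.shape[0]
    genes = pd.DataFrame(
        {
            "gene": matrix.columns,
            "n_present": matrix.sum(axis=0).to_numpy(),
            "n_taxa": n_taxa,
        }
    )
    genes["rate_pct"] = cooccurrence_rate(matrix).to_numpy()
    taxa = (
        queries_matched(matrix)
        .reset_index()
        .sort_values(["n_queries_matched", "taxon"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return genes, taxa
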