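"""Readers and writers for MSAP band matrices, sample metadata, occurrence
matrices, and Ct tables.

MSAP (methylation-sensitive amplified polymorphism) scores each locus in two
parallel digests of the same genomic DNA: EcoRI+HpaII ("H") and EcoRI+MspI
("M").  HpaII and MspI are isoschizomers of the CCGG site with different
methylation sensitivity, so the presence/absence pattern of a band across the
two lanes reads out the methylation state of the site.

File dialects
-------------
Band matrix
    TSV, UTF-8, mandatory header.  First column ``locus_id``; then two columns
    per sample named ``<sample_id>.H`` and ``<sample_id>.M``.  Cells are the
    literal characters ``0``, ``1``, or ``NA`` (band call missing).  Lines
    starting with ``#`` are comments and are skipped.
Sample metadata
    TSV with columns ``sample_id``, ``tissue``, ``stage``, ``dose_uM``,
    ``replicate``.
Occurrence matrix
    TSV, taxa as rows, genes as columns, 0/1 cells.
Ct table
    CSV with columns ``sample_id``, ``group``, ``gene``, ``ct``.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MsapValidationError",
    "SampleMeta",
    "BandMatrix",
    "read_band_matrix",
    "write_band_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_occurrence_matrix",
    "read_ct_table",
]


class MsapValidationError(ValueError):
    """A structured input failed validation (malformed header, non-binary
    cell, duplicate identifier, metadata mismatch, ...)."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one MSAP sample lane pair.

    Parameters
    ----------
    sample_id : str
        Unique label within a dataset.
    tissue : str
        Tissue of origin, e.g. ``root`` or ``leaf``.
    stage : str
        Growth stage code (``E`` elongate, ``I`` intumescent, ``M`` mature).
    dose : float
        5-azacytidine dose in μM; 0 denotes the untreated control (CK).
    replicate : int
        1-based biological replicate index.
    """

    sample_id: str
    tissue: str
    stage: str
    dose: float
    replicate: int

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise MsapValidationError(
                f"sample {self.sample_id!r}: dose must be >= 0, got {self.dose}"
            )
        if self.replicate < 1:
            raise MsapValidationError(
                f"sample {self.sample_id!r}: replicate must be >= 1, "
                f"got {self.replicate}"
            )


@dataclass
class BandMatrix:
    """Loci x samples grid of paired H/M band presence calls.

    ``h`` and ``m`` are integer DataFrames (pandas nullable ``Int64``) indexed
    by locus id with one column per sample id, aligned with ``samples``.
    Missing band calls are ``pd.NA``.
    """

    samples: list[SampleMeta]
    h: pd.DataFrame
    m: pd.DataFrame
    _meta_index: dict[str, SampleMeta] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise MsapValidationError(f"duplicate sample ids: {dup}")
        for name, frame in (("H", self.h), ("M", self.m)):
            if list(frame.columns) != sample_ids:
                raise MsapValidationError(
                    f"{name} columns {list(frame.columns)} do not match "
                    f"sample metadata ids {sample_ids}"
                )
        if not self.h.index.equals(self.m.index):
            raise MsapValidationError("H and M locus indices differ")
        if self.h.index.has_duplicates:
            dup = sorted(self.h.index[self.h.index.duplicated()].unique())
            raise MsapValidationError(f"duplicate locus ids: {dup}")
        for name, frame in (("H", self.h), ("M", self.m)):
            bad_mask = frame.notna() & ~frame.isin([0, 1])
            if bad_mask.to_numpy().any():
                i, j = np.argwhere(bad_mask.to_numpy())[0]
                raise MsapValidationError(
                    f"non-binary {name} value at locus {frame.index[i]!r}, "
                    f"sample {frame.columns[j]!r}"
                )
        self._meta_index = {s.sample_id: s for s in self.samples}

    @property
    def loci(self) -> list[str]:
        return list(self.h.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_loci(self) -> int:
        return len(self.h.index)

    def meta(self, sample_id: str) -> SampleMeta:
        return self._meta_index[sample_id]

    def equals(self, other: "BandMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.h.equals(other.h)
            and self.m.equals(other.m)
        )


def _strip_comments(path: Path) -> _stdio.StringIO:
    text = Path(path).read_text(encoding="utf-8")
    kept = [ln for ln in text.splitlines() if not ln.startswith("#")]
    return _stdio.StringIO("\n".join(kept))


def _parse_band_cell(raw: str, locus: str, column: str):
    s = str(raw).strip()
    if s in ("0", "1"):
        return int(s)
    if s == "NA":
        return pd.NA
    raise MsapValidationError(
        f"non-binary cell value {raw!r} at locus {locus!r}, column {column!r} "
        "(expected 0, 1, or NA)"
    )


def read_sample_metadata(path) -> list[SampleMeta]:
    """Read a sample metadata TSV into a list of :class:`SampleMeta`."""
    df = pd.read_csv(_strip_comments(path), sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "tissue", "stage", "dose_uM", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MsapValidationError(f"metadata file missing columns: {missing}")
    samples = []
    for row in df.itertuples(index=False):
        try:
            dose = float(row.dose_uM)
            rep = int(row.replicate)
        except ValueError as exc:
            raise MsapValidationError(
                f"sample {row.sample_id!r}: non-numeric dose_uM or replicate"
            ) from exc
        samples.append(
            SampleMeta(str(row.sample_id), str(row.tissue), str(row.stage), dose, rep)
        )
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise MsapValidationError(f"duplicate sample_id in metadata: {dup}")
    return samples


def write_sample_metadata(samples: list[SampleMeta], path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "tissue": [s.tissue for s in samples],
            "stage": [s.stage for s in samples],
            "dose_uM": [_fmt_dose(s.dose) for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def _fmt_dose(dose: float) -> str:
    # integral doses render without a trailing .0 so files round-trip verbatim
    return str(int(dose)) if float(dose).is_integer() else repr(float(dose))


def read_band_matrix(path, meta_path) -> BandMatrix:
    """Read a band-matrix TSV plus its sample metadata TSV.

    Every sample column pair ``<id>.H`` / ``<id>.M`` must have a metadata row
    and vice versa.  Cells are coerced only from the literal strings ``0``,
    ``1`` and ``NA``; anything else raises :class:`MsapValidationError`.
    """
    samples = read_sample_metadata(meta_path)
    df = pd.read_csv(_strip_comments(path), sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "locus_id":
        raise MsapValidationError(
            f"band file must start with a 'locus_id' column, got {df.columns[0]!r}"
        )
    band_cols = list(df.columns[1:])
    file_ids: list[str] = []
    for col in band_cols:
        base, dot, digest = col.rpartition(".")
        if dot != "." or digest not in ("H", "M"):
            raise MsapValidationError(
                f"malformed band column {col!r}: expected '<sample_id>.H' or "
                "'<sample_id>.M'"
            )
        if base not in file_ids:
            file_ids.append(base)
    for sid in file_ids:
        for digest in ("H", "M"):
            if f"{sid}.{digest}" not in band_cols:
                raise MsapValidationError(
                    f"sample {sid!r} lacks its .{digest} column in the band file"
                )
    meta_ids = [s.sample_id for s in samples]
    extra = [s for s in file_ids if s not in meta_ids]
    if extra:
        raise MsapValidationError(
            f"samples present in band file but absent from metadata: {extra}"
        )
    orphan = [s for s in meta_ids if s not in file_ids]
    if orphan:
        raise MsapValidationError(
            f"samples present in metadata but absent from band file: {orphan}"
        )

    loci = [str(x) for x in df["locus_id"]]
    if len(set(loci)) != len(loci):
        dup = sorted({x for x in loci if loci.count(x) > 1})
        raise MsapValidationError(f"duplicate locus id: {dup}")

    ordered = [s for s in samples if s.sample_id in file_ids]
    # preserve the band file's column order
    ordered.sort(key=lambda s: file_ids.index(s.sample_id))

    data = {"H": {}, "M": {}}
    for digest in ("H", "M"):
        for sid in file_ids:
            col = f"{sid}.{digest}"
            data[digest][sid] = [
                _parse_band_cell(v, locus, col) for v, locus in zip(df[col], loci)
            ]
    idx = pd.Index(loci, name="locus_id")
    h = pd.DataFrame(data["H"], index=idx, dtype="Int64")[file_ids]
    m = pd.DataFrame(data["M"], index=idx, dtype="Int64")[file_ids]
    return BandMatrix(samples=ordered, h=h, m=m)


def write_band_matrix(matrix: BandMatrix, path) -> Path:
    """Write a band matrix to TSV; ``read_band_matrix`` round-trips exactly."""
    path = Path(path)
    cols = {"locus_id": matrix.loci}
    for sid in matrix.sample_ids:
        for digest, frame in (("H", matrix.h), ("M", matrix.m)):
            cols[f"{sid}.{digest}"] = [
                "NA" if pd.isna(v) else str(int(v)) for v in frame[sid]
            ]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    return path


def read_occurrence_matrix(path) -> pd.DataFrame:
    """Read a gene presence/absence TSV (taxa rows x gene columns) into an
    integer DataFrame indexed by taxon.

    Raises :class:`MsapValidationError` on non-binary cells, duplicate taxa,
    or an empty matrix.
    """
    df = pd.read_csv(_strip_comments(path), sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise MsapValidationError(
            "occurrence matrix needs a taxon column plus at least one gene column"
        )
    taxa = [str(t) for t in df.iloc[:, 0]]
    if len(taxa) == 0:
        raise MsapValidationError("occurrence matrix has no taxa")
    if len(set(taxa)) != len(taxa):
        dup = sorted({t for t in taxa if taxa.count(t) > 1})
        raise MsapValidationError(f"duplicate taxon: {dup}")
    body = df.iloc[:, 1:]
    out = {}
    for gene in body.columns:
        vals = []
        for taxon, v in zip(taxa, body[gene]):
            s = str(v).strip()
            if s not in ("0", "1"):
                raise MsapValidationError(
                    f"non-binary value {v!r} for taxon {taxon!r}, gene {gene!r}"
                )
            vals.append(int(s))
        out[gene] = vals
    return pd.DataFrame(out, index=pd.Index(taxa, name="taxon"))


def read_ct_table(path) -> pd.DataFrame:
    """Read a qPCR Ct table (CSV: sample_id, group, gene, ct)."""
    df = pd.read_csv(_strip_comments(path), dtype={"sample_id": str, "group": str, "gene": str})
    required = ["sample_id", "group", "gene", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MsapValidationError(f"Ct table missing columns: {missing}")
    ct = pd.to_numeric(df["ct"], errors="coerce")
    if ct.isna().any() or (ct <= 0).any():
        bad = df.loc[ct.isna() | (ct <= 0), "sample_id"].tolist()
        raise MsapValidationError(f"non-positive or non-numeric ct for samples {bad}")
    df = df.copy()
    df["ct"] = ct.astype(float)
    return df
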