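"""Readers and writers for the on-disk formats the pipeline consumes.

Four inputs are handled:

* AIRR Rearrangement-schema TSV of per-cell TCR contigs,
* a cells x genes count matrix (Matrix Market triplet with name sidecars,
  or a dense CSV),
* a per-clonotype binding-score CSV in the convention of external
  TCR-pMHC predictors (one score in [0, 1] per full-length clonotype),
* a per-cell sample-tag (donor) CSV.

All readers validate into domain types and raise :class:`FormatError`
with the offending column/row rather than silently coercing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "Locus",
    "TcrContig",
    "ExpressionMatrix",
    "BINDING_COLUMNS",
    "read_airr_rearrangements",
    "write_airr_rearrangements",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_binding_scores",
    "write_binding_scores",
    "read_sample_tags",
    "write_sample_tags",
]


class FormatError(ValueError):
    """An input file violates the expected format or an invariant."""


class Locus(str, Enum):
    """TCR chain locus: alpha (TRA) or beta (TRB)."""

    TRA = "TRA"
    TRB = "TRB"


@dataclass(frozen=True)
class TcrContig:
    """One sequenced TCR chain of one cell.

    ``junction_aa`` is the amino-acid CDR3 including the conserved
    flanking residues (AIRR ``junction_aa``); ``umi_count`` is the
    molecule count supporting the contig (AIRR ``duplicate_count``).
    """

    cell_id: str
    locus: Locus
    v_call: str
    j_call: str
    junction_aa: str
    productive: bool
    umi_count: int = 1

    def __post_init__(self) -> None:
        if self.umi_count < 0:
            raise FormatError(f"umi_count must be >= 0, got {self.umi_count}")
        if self.productive and not self.junction_aa:
            raise FormatError(
                f"productive contig of cell {self.cell_id!r} has empty junction_aa"
            )


AIRR_REQUIRED = ("cell_id", "locus", "v_call", "j_call", "junction_aa", "productive")

_TRUE = {"t", "true"}
_FALSE = {"f", "false"}


def _parse_bool(raw: str, line_no: int) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise FormatError(f"line {line_no}: unparseable boolean {raw!r}")


def read_airr_rearrangements(path: str | Path) -> list[TcrContig]:
    """Read an AIRR Rearrangement TSV into a list of :class:`TcrContig`.

    Rows whose ``locus`` is neither TRA nor TRB (e.g. IGH) are dropped
    and counted in a single log message.  A missing ``duplicate_count``
    column (or empty value) yields ``umi_count = 1``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in AIRR_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    has_dup = "duplicate_count" in df.columns
    contigs: list[TcrContig] = []
    n_dropped = 0
    valid_loci = {m.value for m in Locus}
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        locus = getattr(row, "locus").strip().upper()
        if locus not in valid_loci:
            n_dropped += 1
            continue
        if has_dup:
            raw = getattr(row, "duplicate_count").strip()
            if raw == "":
                umi = 1
            else:
                try:
                    umi = int(raw)
                except ValueError:
                    raise FormatError(
                        f"line {line_no}: unparseable duplicate_count {raw!r}"
                    ) from None
        else:
            umi = 1
        contigs.append(
            TcrContig(
                cell_id=getattr(row, "cell_id"),
                locus=Locus(locus),
                v_call=getattr(row, "v_call"),
                j_call=getattr(row, "j_call"),
                junction_aa=getattr(row, "junction_aa"),
                productive=_parse_bool(getattr(row, "productive"), line_no),
                umi_count=umi,
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d non-TRA/TRB rows", path, n_dropped)
    return contigs


def write_airr_rearrangements(contigs: list[TcrContig], path: str | Path) -> None:
    """Write contigs as an AIRR Rearrangement TSV (read-back identical)."""
    df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in contigs],
            "locus": [c.locus.value for c in contigs],
            "v_call": [c.v_call for c in contigs],
            "j_call": [c.j_call for c in contigs],
            "junction_aa": [c.junction_aa for c in contigs],
            "productive": ["T" if c.productive else "F" for c in contigs],
            "duplicate_count": [c.umi_count for c in contigs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix of non-negative integer molecule counts."""

    cell_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell_ids in expression matrix")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene_ids in expression matrix")
        if self.counts.size:
            if np.any(self.counts < 0):
                raise FormatError("negative counts in expression matrix")
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("non-integer counts in expression matrix")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a count matrix from dense CSV or Matrix Market triplet.

    CSV: header row = gene ids, first column = cell ids.
    MTX: ``<stem>.mtx`` plus ``<stem>.cells.txt`` / ``<stem>.genes.txt``
    sidecars, one id per line, rows = cells.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        m = mmread(path)
        counts = np.asarray(m.todense()) if hasattr(m, "todense") else np.asarray(m)
        stem = path.with_suffix("")
        cells = Path(f"{stem}.cells.txt").read_text().split()
        genes = Path(f"{stem}.genes.txt").read_text().split()
        return ExpressionMatrix(cells, genes, counts)
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate cell or gene ids")
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric counts")
    return ExpressionMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write as dense CSV (``.csv``) or Matrix Market + sidecars (``.mtx``)."""
    path = Path(path)
    if path.suffix == ".mtx":
        mmwrite(path, coo_matrix(m.counts))
        stem = path.with_suffix("")
        Path(f"{stem}.cells.txt").write_text("\n".join(m.cell_ids) + "\n")
        Path(f"{stem}.genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        return
    pd.DataFrame(m.counts, index=m.cell_ids, columns=m.gene_ids).to_csv(path)


BINDING_COLUMNS = (
    "cdr3_alpha",
    "cdr3_beta",
    "v_alpha",
    "j_alpha",
    "v_beta",
    "j_beta",
    "peptide",
    "mhc",
    "t_cell_type",
    "score",
)

#: columns identifying one predictor query (everything except the score)
BINDING_KEY_COLUMNS = BINDING_COLUMNS[:-1]


def _validate_binding(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in BINDING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{origin}: missing binding-score column(s) {missing}")
    df = df.loc[:, list(BINDING_COLUMNS)].copy()
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    bad = df.index[(df["score"] < 0) | (df["score"] > 1) | df["score"].isna()]
    if len(bad):
        raise FormatError(
            f"{origin}: score outside [0, 1] at row(s) {list(bad[:10])}"
        )
    dupes = df.duplicated(subset=list(BINDING_KEY_COLUMNS))
    if dupes.any():
        raise FormatError(
            f"{origin}: duplicate query keys at row(s) {list(df.index[dupes][:10])}"
        )
    return df


def read_binding_scores(path: str | Path) -> pd.DataFrame:
    """Read a binding-score CSV; scores must already lie in [0, 1].

    Out-of-range scores raise — they are never clamped, since a value
    outside the predictor's range signals a corrupted or foreign file.
    """
    df = pd.read_csv(path, dtype={c: str for c in BINDING_KEY_COLUMNS})
    return _validate_binding(df, str(path))


def write_binding_scores(df: pd.DataFrame, path: str | Path) -> None:
    _validate_binding(df, "in-memory table").to_csv(path, index=False)


def read_sample_tags(path: str | Path) -> dict[str, str]:
    """Read a ``cell_id,donor`` CSV into a cell -> donor mapping."""
    df = pd.read_csv(path, dtype=str)
    for col in ("cell_id", "donor"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df["cell_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate cell_id in sample tags")
    return dict(zip(df["cell_id"], df["donor"]))


def write_sample_tags(tags: dict[str, str], path: str | Path) -> None:
    pd.DataFrame({"cell_id": list(tags), "donor": list(tags.values())}).to_csv(
        path, index=False
    )
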