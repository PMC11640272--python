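"""Predictor-ready queries for an external TCR-pMHC binding model.

The binding predictor itself (a neural network scoring TCR-peptide-MHC
binding in [0, 1] from CDR3a/b, V/J genes, peptide, MHC and T-cell type)
is invoked out-of-band by the user; this module builds its input CSV,
validates its output, and provides a deterministic stub so the pipeline
is fully testable without trained weights.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .clonotyping import ClonotypeTable, FullLengthKey, Resolution
from .io_airr import BINDING_COLUMNS, FormatError

__all__ = [
    "PeptideContext",
    "BindingQuery",
    "build_predictor_input",
    "write_predictor_input",
    "stub_predictor",
    "validate_scores",
    "ScoreReport",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideContext:
    """The peptide/MHC/T-cell-type context all queries share.

    Defaults target the HER2/neu class-I epitope KIFGSLAFL presented on
    HLA-A*02:01 and recognized by CD8 T cells.
    """

    peptide: str = "KIFGSLAFL"
    mhc: str = "HLA-A*02:01"
    t_cell_type: str = "CD8"

    def __post_init__(self) -> None:
        if not self.peptide or set(self.peptide) - _AA:
            raise ValueError(f"peptide must be uppercase amino acids, got {self.peptide!r}")
        if not 8 <= len(self.peptide) <= 11:
            raise ValueError(
                f"class-I peptide length must be 8-11, got {len(self.peptide)}"
            )
        if self.t_cell_type not in ("CD4", "CD8"):
            raise ValueError(f"t_cell_type must be CD4 or CD8, got {self.t_cell_type!r}")
        if not self.mhc:
            raise ValueError("mhc must be non-empty")


class BindingQuery(NamedTuple):
    cdr3_alpha: str
    cdr3_beta: str
    v_alpha: str
    j_alpha: str
    v_beta: str
    j_beta: str
    peptide: str
    mhc: str
    t_cell_type: str


def build_predictor_input(
    table: ClonotypeTable, ctx: PeptideContext
) -> list[BindingQuery]:
    """One query per full-length clonotype, in sorted key order."""
    if table.resolution is not Resolution.FULL_LENGTH:
        raise ValueError("predictor input requires full_length clonotypes")
    queries = []
    for key in sorted(table.entries):
        assert isinstance(key, FullLengthKey)
        if not key.cdr3_alpha or not key.cdr3_beta:
            raise ValueError(f"clonotype with empty CDR3 cannot be queried: {key}")
        queries.append(
            BindingQuery(
                key.cdr3_alpha,
                key.cdr3_beta,
                key.v_alpha,
                key.j_alpha,
                key.v_beta,
                key.j_beta,
                ctx.peptide,
                ctx.mhc,
                ctx.t_cell_type,
            )
        )
    return queries


def write_predictor_input(queries: list[BindingQuery], path: str | Path) -> None:
    """Write queries as CSV (binding-score columns minus ``score``)."""
    pd.DataFrame(queries, columns=list(BindingQuery._fields)).to_csv(path, index=False)


def _stub_score(q: BindingQuery) -> float:
    digest = zlib.crc32("|".join(q).encode("utf-8"))
    return digest / 0xFFFFFFFF


def stub_predictor(queries: list[BindingQuery]) -> pd.DataFrame:
    """Deterministic stand-in for the external binding predictor.

    score = CRC-32 of the UTF-8 "|"-joined query fields, divided by the
    digest maximum — the same query maps to the same score in [0, 1] on
    every platform and process.  The scores carry no biology; they only
    give the pipeline a stable, well-spread score column.
    """
    df = pd.DataFrame(queries, columns=list(BindingQuery._fields))
    df["score"] = [_stub_score(q) for q in queries]
    return df.loc[:, list(BINDING_COLUMNS)]


class ScoreReport(NamedTuple):
    n: int
    min_score: float | None
    max_score: float | None
    ok: bool
    bad_rows: tuple[int, ...]


def validate_scores(table: pd.DataFrame) -> ScoreReport:
    """Check every score lies in [0, 1]; report min, max and offenders."""
    if "score" not in table.columns:
        raise FormatError("binding table has no 'score' column")
    s = pd.to_numeric(table["score"], errors="coerce")
    bad = tuple(int(i) for i in table.index[(s < 0) | (s > 1) | s.isna()])
    n = len(s)
    return ScoreReport(
        n=n,
        min_score=float(s.min()) if n else None,
        max_score=float(s.max()) if n else None,
        ok=not bad,
        bad_rows=bad,
    )
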