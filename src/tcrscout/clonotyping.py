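"""Chain pairing, clonotype counting, singleton filtering, dominant-clone selection.

A *clonotype* is a set of cells carrying the identical receptor, defined at
one of two resolutions:

* ``full_length`` — V gene, J gene and CDR3 of both chains (six components);
* ``cdr3_pair`` — the CDR3 amino-acid pair alone.

Antigen-driven clonal expansion makes the specific clones numerically
dominant, so the dominant clonotype is the one maximizing cell count, with
the predicted TCR-pMHC binding score as the discriminator among equally
expanded clones.  Comparing the two resolutions exposes how many distinct
V/J contexts share one CDR3 pair — the reason CDR3 identity alone does not
determine binding specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .io_airr import Locus, TcrContig

logger = logging.getLogger(__name__)

__all__ = [
    "Resolution",
    "Chain",
    "PairedCellReceptor",
    "FullLengthKey",
    "Cdr3PairKey",
    "ClonotypeRecord",
    "ClonotypeTable",
    "FilterReport",
    "DominantClonotype",
    "strip_allele",
    "percent",
    "pair_chains",
    "count_clonotypes",
    "filter_singletons",
    "attach_scores",
    "select_dominant",
    "compare_resolutions",
    "write_clonotype_table",
]


class Resolution(str, Enum):
    FULL_LENGTH = "full_length"
    CDR3_PAIR = "cdr3_pair"


def strip_allele(gene_call: str) -> str:
    """Drop an IMGT allele suffix: ``TRBV9*01`` -> ``TRBV9``.

    Clonotype identity is gene-level; binding predictors consume
    gene-level V/J as well.
    """
    return gene_call.split("*", 1)[0].strip()


def percent(part: float, whole: float) -> float:
    """100*part/whole, rounded half-up to one decimal (printing convention)."""
    pct = Decimal(100 * part) / Decimal(whole)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class Chain(NamedTuple):
    """One receptor chain of a cell (V call, J call, CDR3 amino acids)."""

    v_call: str
    j_call: str
    junction_aa: str


@dataclass(frozen=True)
class PairedCellReceptor:
    """The one alpha + one beta chain chosen to represent a cell."""

    cell_id: str
    alpha: Chain | None = None
    beta: Chain | None = None

    @property
    def complete(self) -> bool:
        return self.alpha is not None and self.beta is not None


class FullLengthKey(NamedTuple):
    v_alpha: str
    j_alpha: str
    cdr3_alpha: str
    v_beta: str
    j_beta: str
    cdr3_beta: str

    @property
    def cdr3_pair(self) -> "Cdr3PairKey":
        return Cdr3PairKey(self.cdr3_alpha, self.cdr3_beta)


class Cdr3PairKey(NamedTuple):
    cdr3_alpha: str
    cdr3_beta: str


ClonotypeKey = FullLengthKey | Cdr3PairKey


def _key_of(cell: PairedCellReceptor, resolution: Resolution) -> ClonotypeKey:
    assert cell.alpha is not None and cell.beta is not None
    if resolution is Resolution.FULL_LENGTH:
        return FullLengthKey(
            strip_allele(cell.alpha.v_call),
            strip_allele(cell.alpha.j_call),
            cell.alpha.junction_aa,
            strip_allele(cell.beta.v_call),
            strip_allele(cell.beta.j_call),
            cell.beta.junction_aa,
        )
    return Cdr3PairKey(cell.alpha.junction_aa, cell.beta.junction_aa)


@dataclass
class ClonotypeRecord:
    cell_ids: set[str]
    binding_score: float | None = None

    @property
    def cell_count(self) -> int:
        return len(self.cell_ids)


@dataclass
class ClonotypeTable:
    """Clonotype key -> member cells (+ optional binding score)."""

    resolution: Resolution
    entries: dict[ClonotypeKey, ClonotypeRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_cells(self) -> int:
        return sum(r.cell_count for r in self.entries.values())

    def counts(self) -> dict[ClonotypeKey, int]:
        return {k: r.cell_count for k, r in self.entries.items()}

    def to_frame(self) -> pd.DataFrame:
        key_cols = (
            list(FullLengthKey._fields)
            if self.resolution is Resolution.FULL_LENGTH
            else list(Cdr3PairKey._fields)
        )
        rows = []
        for key, rec in sorted(self.entries.items()):
            rows.append(
                dict(
                    zip(key_cols, key),
                    cell_count=rec.cell_count,
                    binding_score=rec.binding_score,
                )
            )
        return pd.DataFrame(rows, columns=key_cols + ["cell_count", "binding_score"])


class FilterReport(NamedTuple):
    n_before: int
    n_after: int
    retained_pct: float | None


@dataclass(frozen=True)
class DominantClonotype:
    """The most expanded clonotype, score-disambiguated among ties."""

    key: FullLengthKey
    cell_count: int
    binding_score: float
    cell_ids: frozenset[str]
    candidates: tuple[FullLengthKey, ...]  # all max-count clonotypes


def pair_chains(contigs: list[TcrContig]) -> list[PairedCellReceptor]:
    """Choose at most one productive TRA and one TRB chain per cell.

    Multiple productive chains at a locus are resolved by highest UMI
    count, ties by lexicographically smallest CDR3 (deterministic).
    Cells with no productive chain at either locus are omitted.
    """
    by_cell: dict[str, dict[Locus, TcrContig]] = {}
    n_ambiguous = 0
    for contig in contigs:
        if not contig.productive:
            continue
        slot = by_cell.setdefault(contig.cell_id, {})
        prev = slot.get(contig.locus)
        if prev is None:
            slot[contig.locus] = contig
        else:
            n_ambiguous += 1
            best = min(
                (prev, contig), key=lambda c: (-c.umi_count, c.junction_aa)
            )
            slot[contig.locus] = best
    if n_ambiguous:
        logger.info("resolved %d multi-chain loci by UMI count", n_ambiguous)

    def chain(c: TcrContig | None) -> Chain | None:
        return None if c is None else Chain(c.v_call, c.j_call, c.junction_aa)

    return [
        PairedCellReceptor(cell_id, chain(slot.get(Locus.TRA)), chain(slot.get(Locus.TRB)))
        for cell_id, slot in by_cell.items()
    ]


def count_clonotypes(
    cells: list[PairedCellReceptor], resolution: Resolution | str
) -> ClonotypeTable:
    """Partition complete cells into clonotypes at the given resolution."""
    resolution = Resolution(resolution)
    table = ClonotypeTable(resolution)
    n_complete = 0
    for cell in cells:
        if not cell.complete:
            continue
        n_complete += 1
        key = _key_of(cell, resolution)
        table.entries.setdefault(key, ClonotypeRecord(set())).cell_ids.add(cell.cell_id)
    if cells and n_complete == 0:
        logger.warning("no complete (alpha+beta) cells; clonotype table is empty")
    return table


def filter_singletons(table: ClonotypeTable) -> tuple[ClonotypeTable, FilterReport]:
    """Drop clonotypes represented by exactly one cell.

    Clonal expansion is the selection signal; a clone seen once carries
    none, so singletons are removed before repertoire-level analysis.
    """
    retained = ClonotypeTable(
        table.resolution,
        {k: r for k, r in table.entries.items() if r.cell_count >= 2},
    )
    n_before, n_after = len(table), len(retained)
    if n_before == 0:
        logger.warning("singleton filter on empty table; retained_pct undefined")
        return retained, FilterReport(0, 0, None)
    return retained, FilterReport(n_before, n_after, percent(n_after, n_before))


def attach_scores(table: ClonotypeTable, scores: pd.DataFrame) -> ClonotypeTable:
    """Join predictor scores onto full-length clonotypes.

    Score rows are keyed by the six clonotype components (V/J allele
    suffixes stripped on both sides).  Unmatched clonotypes keep an
    absent score and are counted in the log; two rows matching one
    clonotype is ambiguous and raises.
    """
    if table.resolution is not Resolution.FULL_LENGTH:
        raise ValueError("scores attach to full_length clonotypes only")
    by_key: dict[FullLengthKey, float] = {}
    for row in scores.itertuples(index=False):
        key = FullLengthKey(
            strip_allele(row.v_alpha),
            strip_allele(row.j_alpha),
            row.cdr3_alpha,
            strip_allele(row.v_beta),
            strip_allele(row.j_beta),
            row.cdr3_beta,
        )
        if key in by_key and by_key[key] != float(row.score):
            raise ValueError(f"ambiguous: multiple score rows match clonotype {key}")
        by_key[key] = float(row.score)
    out = ClonotypeTable(table.resolution)
    n_unmatched = 0
    for key, rec in table.entries.items():
        score = by_key.get(key)
        if score is None:
            n_unmatched += 1
        out.entries[key] = ClonotypeRecord(set(rec.cell_ids), score)
    if n_unmatched:
        logger.warning("%d clonotype(s) without a matching score row", n_unmatched)
    return out


def select_dominant(table: ClonotypeTable) -> DominantClonotype:
    """Pick the dominant clonotype: argmax by (cell count, binding score).

    Remaining ties break on the lexicographically smallest key so the
    result is invariant to table row order.  Every max-count candidate
    must carry a score — the score is the designated discriminator.
    """
    if table.resolution is not Resolution.FULL_LENGTH:
        raise ValueError("dominant selection requires full_length resolution")
    if not table.entries:
        raise ValueError("cannot select a dominant clonotype from an empty table")
    max_count = max(r.cell_count for r in table.entries.values())
    candidates = {
        k: r for k, r in table.entries.items() if r.cell_count == max_count
    }
    unscored = [k for k, r in candidates.items() if r.binding_score is None]
    if unscored:
        raise ValueError(
            f"max-count clonotype(s) lack binding scores: {unscored[:3]} — "
            "attach predictor scores before selection"
        )
    best_key = min(candidates, key=lambda k: (-candidates[k].binding_score, k))
    rec = candidates[best_key]
    return DominantClonotype(
        key=best_key,
        cell_count=rec.cell_count,
        binding_score=rec.binding_score,
        cell_ids=frozenset(rec.cell_ids),
        candidates=tuple(sorted(candidates)),
    )


def compare_resolutions(cells: list[PairedCellReceptor]) -> pd.DataFrame:
    """Per CDR3 pair: cells on the pair vs the full-length clones within it.

    Columns: ``cdr3_alpha, cdr3_beta, pair_cell_count,
    n_full_length_clonotypes, max_full_length_count``.  Because
    full-length keys refine CDR3-pair keys, ``pair_cell_count`` equals
    the sum of the full-length counts sharing the pair.
    """
    full = count_clonotypes(cells, Resolution.FULL_LENGTH)
    per_pair: dict[Cdr3PairKey, list[int]] = {}
    for key, rec in full.entries.items():
        per_pair.setdefault(key.cdr3_pair, []).append(rec.cell_count)
    rows = [
        {
            "cdr3_alpha": pair.cdr3_alpha,
            "cdr3_beta": pair.cdr3_beta,
            "pair_cell_count": sum(counts),
            "n_full_length_clonotypes": len(counts),
            "max_full_length_count": max(counts),
        }
        for pair, counts in sorted(per_pair.items())
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "cdr3_alpha",
            "cdr3_beta",
            "pair_cell_count",
            "n_full_length_clonotypes",
            "max_full_length_count",
        ],
    ).sort_values("pair_cell_count", ascending=False, kind="stable").reset_index(drop=True)


def write_clonotype_table(table: ClonotypeTable, path: str | Path) -> None:
    df = table.to_frame()
    df.insert(0, "resolution", table.resolution.value)
    df.to_csv(path, index=False)


def export_dominant(dom: DominantClonotype, json_path: str | Path, fasta_path: str | Path) -> None:
    """Write the dominant clonotype as JSON plus a CDR3 amino-acid FASTA."""
    import json

    Path(json_path).write_text(
        json.dumps(
            {
                "key": dict(zip(FullLengthKey._fields, dom.key)),
                "cell_count": dom.cell_count,
                "binding_score": dom.binding_score,
                "cell_ids": sorted(dom.cell_ids),
                "n_max_count_candidates": len(dom.candidates),
            },
            indent=2,
        )
        + "\n"
    )
    Path(fasta_path).write_text(
        f">CDR3_alpha {dom.key.v_alpha} {dom.key.j_alpha}\n{dom.key.cdr3_alpha}\n"
        f">CDR3_beta {dom.key.v_beta} {dom.key.j_beta}\n{dom.key.cdr3_beta}\n"
    )
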