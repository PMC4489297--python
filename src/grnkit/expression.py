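"""Differential-expression tables and DEG selection.

Three dialects are read: a minimal 3-column format (gene id, log2 fold
change, statistical value), LIMMA ``topTable`` output, and Cuffdiff
``gene_exp.diff`` output. All reduce to one :class:`ExpressionRecord` per
gene; duplicate gene rows keep the smallest statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

from .annotation import AliasTable, resolve_id
from .genomic_io import FormatError

logger = logging.getLogger(__name__)

EXPRESSION_DIALECTS = ("simple", "limma", "cuffdiff")

#: conventional DEG cutoffs, applied inclusively; configurable everywhere.
DEFAULT_MIN_ABS_LOG2FC = 1.0
DEFAULT_MAX_STAT = 0.05

PERTURBATION_DIRECTIONS = ("loss", "gain")


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's perturbation readout.

    ``log2fc`` is signed (perturbed vs control, must be finite); ``stat`` is
    a p-like statistic in [0, 1] (adjusted p, q-value...) used only for
    thresholding, never recomputed here.
    """

    gene_id: str
    log2fc: float
    stat: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise ValueError(f"{self.gene_id}: log2fc must be finite")
        if self.stat < 0:
            raise ValueError(f"{self.gene_id}: stat must be >= 0")


@dataclass(frozen=True)
class Perturbation:
    """The experiment that produced the expression table: which factor was
    perturbed and in which direction (loss = knockdown/knockout,
    gain = overexpression/treatment)."""

    factor_id: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in PERTURBATION_DIRECTIONS:
            raise ValueError(
                f"direction must be one of {PERTURBATION_DIRECTIONS}, got {self.direction!r}"
            )


def _split(line: str) -> list[str]:
    stripped = line.rstrip("\n")
    if "\t" in stripped:
        return stripped.split("\t")
    if "," in stripped and " " not in stripped.strip():
        return stripped.split(",")
    return stripped.split()


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _find_column(header: list[str], candidates: list[str], what: str) -> int:
    lowered = [h.strip().lower() for h in header]
    for cand in candidates:
        if cand in lowered:
            return lowered.index(cand)
    raise FormatError(f"could not locate {what} column among header {header!r}")


def read_expression(
    path: str | Path,
    dialect: str = "simple",
    aliases: AliasTable | None = None,
) -> list[ExpressionRecord]:
    """Parse a differential-expression table into one record per gene.

    simple
        ``gene_id  log2fc  stat`` (tab, comma or whitespace separated);
        a header row is detected and skipped if the second field is not
        numeric.
    limma
        header row with ``logFC`` and ``adj.P.Val`` (fallback ``P.Value``)
        columns; the gene id comes from an ``ID``/``gene`` column or, when
        absent, the first column (topTable row names written out).
    cuffdiff
        header row with ``gene`` (fallback ``gene_id``/``test_id``),
        ``log2(fold_change)`` and ``q_value`` columns.

    Rows with non-finite fold changes (Cuffdiff prints ``inf`` for on/off
    genes) are dropped with a warning, since downstream ranking needs finite
    values. Gene ids are passed through the alias table when supplied.
    Duplicate genes keep the row with the smaller statistic.
    """
    if dialect not in EXPRESSION_DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; supported: {', '.join(EXPRESSION_DIALECTS)}"
        )
    with open(path) as handle:
        rows = [
            (lineno, _split(line))
            for lineno, line in enumerate(handle, start=1)
            if line.strip() and not line.startswith("#")
        ]
    if not rows:
        return []

    best: dict[str, ExpressionRecord] = {}

    def _add(gene_id: str, log2fc_s: str, stat_s: str, lineno: int) -> None:
        try:
            log2fc = float(log2fc_s)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric log2fc {log2fc_s!r}") from exc
        try:
            stat = float(stat_s)
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric statistic {stat_s!r}") from exc
        if not math.isfinite(log2fc):
            logger.warning("line %d: dropping %s with non-finite log2fc", lineno, gene_id)
            return
        gene_id = resolve_id(gene_id, aliases)
        record = ExpressionRecord(gene_id, log2fc, stat)
        if gene_id in best:
            logger.warning("duplicate expression rows for %s; keeping smaller statistic", gene_id)
            if record.stat < best[gene_id].stat:
                best[gene_id] = record
        else:
            best[gene_id] = record

    if dialect == "simple":
        start_idx = 0
        first = rows[0][1]
        if len(first) >= 2 and not _is_number(first[1]):
            start_idx = 1  # header row
        for lineno, f in rows[start_idx:]:
            if len(f) < 3:
                raise FormatError(f"line {lineno}: simple format needs 3 columns, got {len(f)}")
            _add(f[0], f[1], f[2], lineno)
    else:
        header = rows[0][1]
        if dialect == "limma":
            fc_idx = _find_column(header, ["logfc"], "log fold-change")
            try:
                stat_idx = _find_column(header, ["adj.p.val", "adj_p_val"], "adjusted p")
            except FormatError:
                stat_idx = _find_column(header, ["p.value", "pvalue"], "p-value")
            try:
                id_idx = _find_column(header, ["id", "gene", "symbol", "genes"], "gene id")
            except FormatError:
                id_idx = 0
        else:  # cuffdiff
            try:
                id_idx = _find_column(header, ["gene"], "gene id")
            except FormatError:
                id_idx = _find_column(header, ["gene_id", "test_id"], "gene id")
            fc_idx = _find_column(header, ["log2(fold_change)"], "log2 fold-change")
            stat_idx = _find_column(header, ["q_value"], "q-value")
        for lineno, f in rows[1:]:
            needed = max(id_idx, fc_idx, stat_idx)
            if len(f) <= needed:
                raise FormatError(f"line {lineno}: expected >= {needed + 1} columns, got {len(f)}")
            _add(f[id_idx], f[fc_idx], f[stat_idx], lineno)

    return list(best.values())


def write_expression_simple(records: list[ExpressionRecord], path: str | Path) -> None:
    """Write records in the simple 3-column dialect with full precision."""
    with open(path, "w") as out:
        for r in records:
            out.write(f"{r.gene_id}\t{r.log2fc!r}\t{r.stat!r}\n")


def select_degs(
    records: list[ExpressionRecord],
    min_abs_log2fc: float = DEFAULT_MIN_ABS_LOG2FC,
    max_stat: float = DEFAULT_MAX_STAT,
) -> dict[str, ExpressionRecord]:
    """Differentially expressed genes: ``|log2fc| >= min_abs_log2fc`` and
    ``stat <= max_stat`` (both inclusive). Returns gene id -> record."""
    if min_abs_log2fc < 0:
        raise ValueError("min_abs_log2fc must be >= 0")
    return {
        r.gene_id: r
        for r in records
        if abs(r.log2fc) >= min_abs_log2fc and r.stat <= max_stat
    }
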