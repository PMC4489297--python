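"""Gene models, strand-aware promoter windows, and gene identifier aliases.

One TSS per gene: multi-isoform genes must be collapsed to a single
annotated TSS upstream of this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .genomic_io import FormatError, GenomicInterval, _data_lines, _parse_int

logger = logging.getLogger(__name__)

GENE_DIALECTS = ("bed12", "tss_table")

#: default promoter extent on each side of the TSS (bp); conventional
#: promoter-proximal scale, matching the abundance decay constant default.
DEFAULT_PROMOTER_UPSTREAM = 5000
DEFAULT_PROMOTER_DOWNSTREAM = 5000


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its canonical identifier and a single TSS.

    ``is_tf`` marks membership in a user-supplied TF registry; it is never
    inferred from the annotation itself.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    symbol: str | None = None
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: TSS must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


class AliasTable:
    """Mapping from probe names / symbols / alternate IDs to canonical gene ids."""

    def __init__(self, mapping: dict[str, str] | None = None):
        self.mapping = dict(mapping or {})

    def __contains__(self, alias: str) -> bool:
        return alias in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    def get(self, alias: str) -> str | None:
        return self.mapping.get(alias)


def read_gene_models(
    path: str | Path,
    dialect: str = "tss_table",
    tf_registry: set[str] | None = None,
) -> list[GeneModel]:
    """Read gene models from BED12 or a 4-column TSS table.

    BED12 rows give the TSS as ``start`` on the + strand and ``end - 1`` on
    the − strand; the ``name`` column is the gene id. The TSS table has
    columns ``gene_id  chrom  position  strand``. Duplicate gene ids are an
    error. Genes present in ``tf_registry`` are flagged ``is_tf``.
    """
    if dialect not in GENE_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; supported: {', '.join(GENE_DIALECTS)}")
    tf_registry = tf_registry or set()
    genes: list[GeneModel] = []
    seen: dict[str, int] = {}
    for lineno, f in _data_lines(path):
        if dialect == "bed12":
            if len(f) < 6:
                raise FormatError(f"line {lineno}: BED12 needs >= 6 columns, got {len(f)}")
            chrom, start, end = f[0], _parse_int(f[1], "start", lineno), _parse_int(f[2], "end", lineno)
            gene_id, strand = f[3], f[5]
            if strand not in ("+", "-"):
                raise FormatError(f"line {lineno}: bad strand symbol {strand!r}")
            tss = start if strand == "+" else end - 1
        else:
            if len(f) < 4:
                raise FormatError(f"line {lineno}: TSS table needs 4 columns, got {len(f)}")
            gene_id, chrom = f[0], f[1]
            tss = _parse_int(f[2], "position", lineno)
            strand = f[3]
            if strand not in ("+", "-"):
                raise FormatError(f"line {lineno}: bad strand symbol {strand!r}")
        seen[gene_id] = seen.get(gene_id, 0) + 1
        genes.append(GeneModel(gene_id, chrom, tss, strand, is_tf=gene_id in tf_registry))
    duplicates = sorted(g for g, n in seen.items() if n > 1)
    if duplicates:
        raise FormatError(f"duplicate gene ids: {', '.join(duplicates)}")
    return genes


def write_tss_table(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as out:
        for g in genes:
            out.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


def promoter_window(
    gene: GeneModel,
    upstream: int = DEFAULT_PROMOTER_UPSTREAM,
    downstream: int = DEFAULT_PROMOTER_DOWNSTREAM,
) -> GenomicInterval:
    """Strand-aware promoter interval around the TSS, clamped at 0.

    ``upstream`` extends against the direction of transcription and
    ``downstream`` with it, so windows for +/− genes at the same TSS are
    mirror images about the TSS.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("promoter extents must be >= 0")
    if upstream + downstream == 0:
        raise ValueError("promoter window has zero extent")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    return GenomicInterval(gene.chrom, max(0, start), end, gene.strand)


def read_alias_table(path: str | Path) -> AliasTable:
    """Read a 2-column TSV of ``alias<TAB>canonical_gene_id``."""
    mapping: dict[str, str] = {}
    for lineno, f in _data_lines(path):
        if len(f) < 2:
            raise FormatError(f"line {lineno}: alias table needs 2 columns")
        mapping[f[0]] = f[1]
    return AliasTable(mapping)


def resolve_id(raw_id: str, aliases: AliasTable | None, strict: bool = False) -> str:
    """Map an identifier through the alias table to its canonical gene id.

    Unknown ids pass through unchanged (with a warning) unless ``strict``.
    Canonical ids map to themselves, making resolution idempotent.
    """
    if aliases is None:
        return raw_id
    canonical = aliases.get(raw_id)
    if canonical is not None:
        return canonical
    if raw_id in set(aliases.mapping.values()):
        return raw_id
    if strict:
        raise KeyError(f"unresolvable gene identifier {raw_id!r}")
    logger.warning("unrecognized gene identifier %r passed through unchanged", raw_id)
    return raw_id
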