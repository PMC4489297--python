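"""Hypergeometric gene-set enrichment with BH correction.

For a query of n genes drawn from a universe of N, a set with K members in
the universe and k of them in the query has upper-tail probability

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n)

evaluated through scipy's hypergeometric survival function. Adjusted
p-values use Benjamini–Hochberg step-up. A binary gene × set membership
matrix over the significant sets supports the usual overlap heat-table
display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset[str]]
    source: str = ""

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float | None
    overlap: frozenset[str]


def read_gene_sets(path: str | Path, source: str = "") -> GeneSetCollection:
    """Read a GMT file: name, description, then member genes per line.

    Duplicate members within a line are deduplicated; empty sets are
    dropped with a warning; a repeated set name is an error.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: GMT needs name, description, members")
            name = fields[0]
            if name in sets:
                raise ValueError(f"line {lineno}: duplicate gene set name {name!r}")
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                logger.warning("dropping empty gene set %r (line %d)", name, lineno)
                continue
            sets[name] = members
    return GeneSetCollection(sets, source=source or str(path))


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as out:
        for name, members in collection.sets.items():
            out.write("\t".join([name, collection.source] + sorted(members)) + "\n")


def hypergeom_enrich(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    adjust: bool = True,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of every set against the query.

    Query genes outside the universe are dropped with a warning; set
    membership is likewise restricted to the universe. Results come back
    sorted by (p, name) with BH-adjusted values attached.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    outside = query - universe
    if outside:
        logger.warning("%d query genes outside the universe were dropped", len(outside))
    query_in = query & universe
    N, n = len(universe), len(query_in)
    results: list[EnrichmentResult] = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        K = len(members)
        if K == 0:
            continue
        overlap = frozenset(query_in & members)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        results.append(EnrichmentResult(name, k, K, n, N, min(p, 1.0), None, overlap))
    results.sort(key=lambda r: (r.p, r.name))
    if adjust and results:
        adjusted = bh_adjust([r.p for r in results])
        for r, q in zip(results, adjusted):
            r.p_adj = float(q)
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_matrix(
    query: set[str],
    results: list[EnrichmentResult],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Binary gene × set membership table over significant sets.

    Columns are sets with ``p_adj <= alpha``; rows are query genes
    belonging to at least one of them; a cell is 1 iff the gene is in the
    set's query overlap.
    """
    significant = [r for r in results if r.p_adj is not None and r.p_adj <= alpha]
    columns = [r.name for r in significant]
    rows: dict[str, list[int]] = {}
    for gene in sorted(query):
        membership = [1 if gene in r.overlap else 0 for r in significant]
        if any(membership):
            rows[gene] = membership
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns, dtype=int)
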