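"""Peak-to-gene assignment and direct-target detection.

Two routes from peaks to genes: promoter-proximal overlap with a
strand-aware TSS window, and loop-mediated linkage where a peak sits in one
anchor of a chromatin interaction whose partner anchor touches the
promoter. Two detection methods on top: plain intersection of peak-bearing
genes with DEGs ("direct"), and a rank-product score combining per-gene
peak abundance with expression change ("rank product").

Peak abundance for gene g is

    a_g = sum_k  s_k * exp(-d_k / d0)

over the gene's assigned peaks, where s_k is peak intensity, d_k the
distance from the peak reference point (summit, else midpoint) to the TSS,
and d0 a decay constant (default 5 kb). Loop-mediated assignments enter at
d = 0: a loop collapses genomic distance, so a distal peak wired to the
promoter counts as promoter-equivalent evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .annotation import GeneModel, promoter_window
from .expression import ExpressionRecord
from .genomic_io import GenomicInterval, IntervalIndex, Loop, Peak, overlap_length

#: default exponential decay constant for distance weighting (bp)
DEFAULT_D0 = 5000.0

ASSIGNMENT_MODES = ("promoter", "loop")


@dataclass(frozen=True)
class PeakAssignment:
    """One (gene, peak) evidence link.

    ``distance_to_tss`` is |reference point − TSS| for promoter-mode
    assignments and 0 for loop-mode ones (the loop stands in for the
    distance). ``loop`` records the backing interaction for loop mode.
    """

    gene_id: str
    peak: Peak
    mode: str
    distance_to_tss: int
    loop: Loop | None = None

    def __post_init__(self) -> None:
        if self.mode not in ASSIGNMENT_MODES:
            raise ValueError(f"mode must be one of {ASSIGNMENT_MODES}")
        if self.mode == "loop" and self.loop is None:
            raise ValueError("loop-mode assignment requires the backing loop")
        if self.distance_to_tss < 0:
            raise ValueError("distance_to_tss must be >= 0")


@dataclass
class AbundanceScore:
    """Per-gene aggregate binding evidence (the a_g above)."""

    gene_id: str
    score: float
    assignments: list[PeakAssignment] = field(default_factory=list)


@dataclass
class RankProductResult:
    """A gene's joint binding/expression ranking.

    Ranks are descending (1 = strongest) with average ranks on ties;
    ``rp`` is the geometric mean of the two ranks, so low values mean
    strong joint evidence.
    """

    gene_id: str
    abundance: float
    abs_log2fc: float
    rank_peak: float
    rank_expr: float
    rp: float
    selected: bool = False


@dataclass
class DirectResult:
    """Direct targets plus a flag for expression-free (binding-only) runs."""

    targets: set[str]
    binding_only: bool = False


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def assign_peaks_promoter(
    peaks: list[Peak],
    genes: list[GeneModel],
    upstream: int,
    downstream: int,
) -> list[PeakAssignment]:
    """Assign every peak to every gene whose promoter window it overlaps by
    >= 1 bp. A peak straddling two adjacent windows yields two assignments."""
    windows = [promoter_window(g, upstream, downstream) for g in genes]
    index = IntervalIndex(windows)
    assignments: list[PeakAssignment] = []
    for peak in peaks:
        for gi in index.query(peak.region):
            gene = genes[gi]
            distance = abs(peak.reference_point - gene.tss)
            assignments.append(PeakAssignment(gene.gene_id, peak, "promoter", distance))
    return assignments


def assign_peaks_loops(
    peaks: list[Peak],
    genes: list[GeneModel],
    loops: list[Loop],
    upstream: int,
    downstream: int,
    existing: list[PeakAssignment] | None = None,
) -> list[PeakAssignment]:
    """Loop-mediated assignments: peak in one anchor, promoter in the other.

    Both anchor orientations are tried (and inter-chromosomal loops work as
    a matter of course: each anchor is matched on its own chromosome).
    Pairs already covered by a promoter-mode assignment in ``existing`` are
    suppressed, as are duplicates across loops.
    """
    windows = [promoter_window(g, upstream, downstream) for g in genes]
    window_index = IntervalIndex(windows)
    peak_index = IntervalIndex([p.region for p in peaks])
    covered: set[tuple[str, int]] = set()
    if existing:
        peak_pos = {id(p): i for i, p in enumerate(peaks)}
        for a in existing:
            if id(a.peak) in peak_pos:
                covered.add((a.gene_id, peak_pos[id(a.peak)]))
    assignments: list[PeakAssignment] = []
    for loop in loops:
        for peak_anchor, gene_anchor in (
            (loop.anchor_a, loop.anchor_b),
            (loop.anchor_b, loop.anchor_a),
        ):
            peak_hits = peak_index.query(peak_anchor)
            if not peak_hits:
                continue
            gene_hits = window_index.query(gene_anchor)
            for gi in gene_hits:
                gene = genes[gi]
                for pi in peak_hits:
                    key = (gene.gene_id, pi)
                    if key in covered:
                        continue
                    covered.add(key)
                    assignments.append(
                        PeakAssignment(gene.gene_id, peaks[pi], "loop", 0, loop=loop)
                    )
    return assignments


def group_assignments(assignments: list[PeakAssignment]) -> dict[str, list[PeakAssignment]]:
    grouped: dict[str, list[PeakAssignment]] = {}
    for a in assignments:
        grouped.setdefault(a.gene_id, []).append(a)
    return grouped


# ---------------------------------------------------------------------------
# abundance and detection
# ---------------------------------------------------------------------------

def peak_abundance(
    gene_id: str,
    assignments: list[PeakAssignment],
    d0: float = DEFAULT_D0,
) -> AbundanceScore:
    """Exponentially distance-weighted intensity sum for one gene.

    Additive over assignments; zero iff the gene has none.
    """
    if d0 <= 0:
        raise ValueError("d0 must be > 0")
    score = 0.0
    for a in assignments:
        d = 0 if a.mode == "loop" else a.distance_to_tss
        score += a.peak.intensity * math.exp(-d / d0)
    return AbundanceScore(gene_id, score, list(assignments))


def compute_abundances(
    assignments: list[PeakAssignment],
    d0: float = DEFAULT_D0,
) -> dict[str, AbundanceScore]:
    """Per-gene abundance scores over all assignments."""
    return {
        gene: peak_abundance(gene, gene_assignments, d0)
        for gene, gene_assignments in group_assignments(assignments).items()
    }


def detect_direct_intersection(
    peak_genes: set[str],
    degs: set[str] | None,
) -> DirectResult:
    """Direct targets as the intersection of peak-bearing genes and DEGs.

    With no expression data supplied the peak-bearing set is returned
    unchanged and the result flagged binding-only (no expression evidence
    entered the call, so no indirect expansion should follow).
    """
    if degs is None:
        return DirectResult(set(peak_genes), binding_only=True)
    return DirectResult(peak_genes & degs, binding_only=False)


def detect_direct_rank_product(
    scores: dict[str, AbundanceScore],
    records: list[ExpressionRecord],
    top_k: int | None = None,
    rp_cutoff: float | None = None,
) -> list[RankProductResult]:
    """Rank-product scoring over genes with both binding and expression data.

    Genes are ranked descending by abundance and by |log2fc| (average ranks
    on ties); ``rp = sqrt(rank_peak * rank_expr)``. Results come back sorted
    ascending by rp with ties broken by gene id; ``selected`` marks the top
    ``top_k`` genes, or genes with ``rp <= rp_cutoff``, or every candidate
    when no selection rule is given.
    """
    by_gene = {r.gene_id: r for r in records}
    candidates = sorted(g for g in scores if g in by_gene)
    if not candidates:
        raise ValueError("no gene has both binding and expression evidence")
    abundance = np.array([scores[g].score for g in candidates])
    abs_fc = np.array([abs(by_gene[g].log2fc) for g in candidates])
    rank_peak = rankdata(-abundance, method="average")
    rank_expr = rankdata(-abs_fc, method="average")
    rp = np.sqrt(rank_peak * rank_expr)
    results = [
        RankProductResult(g, abundance[i], abs_fc[i], rank_peak[i], rank_expr[i], rp[i])
        for i, g in enumerate(candidates)
    ]
    results.sort(key=lambda r: (r.rp, r.gene_id))
    if top_k is not None:
        for i, r in enumerate(results):
            r.selected = i < top_k
    elif rp_cutoff is not None:
        for r in results:
            r.selected = r.rp <= rp_cutoff
    else:
        for r in results:
            r.selected = True
    return results
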