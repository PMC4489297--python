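"""Assembly, annotation, analysis and export of the regulatory network.

The network is centred on one regulator (a TF, a histone-modification
change, or a named perturbation). Direct edges run center→target and carry
the binding evidence class (promoter peak and/or loop-linked distal peak,
or predicted TFBS when no ChIP data exist). Indirect edges run TF→target
for direct targets that are themselves TFs, evidenced by that TF's curated
binding or by accessible predicted TFBSs, and additionally require the
target to be differentially expressed under the original perturbation.

Edge signs come from the perturbation logic: under a loss-of-function
perturbation a down-regulated target is activated by the factor, an
up-regulated one repressed (and vice versa for gain). For an indirect edge
TF→gene the center→TF sign propagates: an activating center→TF edge
transmits the perturbation direction to the TF, a repressing one flips it,
and the gene's fold change is then read against that effective direction.

Co-occupancy between two factors' peak sets is tested against a circular
within-chromosome permutation null: peaks of set A are rotated by a uniform
random offset per chromosome, preserving their spacing, and the proximity
count is recomputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import GeneModel, promoter_window
from .expression import ExpressionRecord, Perturbation
from .genomic_io import GenomicInterval, IntervalIndex, Peak
from .motif_scan import TFBSHit
from .target_detection import PeakAssignment, group_assignments

logger = logging.getLogger(__name__)

EDGE_TIERS = ("direct", "indirect")
EVIDENCE_KINDS = ("promoter_peak", "loop_distal_peak", "predicted_tfbs", "curated_binding")
SIGNS = ("activate", "repress", "unknown")
NODE_ROLES = ("center", "tf", "gene")
EXPORT_FORMATS = ("edge_table_tsv", "sif", "graph_json")
MAX_INDIRECT_DEPTH = 3


@dataclass
class Node:
    gene_id: str
    role: str = "gene"
    log2fc: float | None = None
    marks: set[str] = field(default_factory=set)


@dataclass
class Edge:
    regulator: str
    target: str
    tier: str
    evidence: frozenset[str]
    sign: str = "unknown"
    support: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tier not in EDGE_TIERS:
            raise ValueError(f"tier must be one of {EDGE_TIERS}")
        if not self.evidence:
            raise ValueError("edge evidence must be nonempty")
        unknown = set(self.evidence) - set(EVIDENCE_KINDS)
        if unknown:
            raise ValueError(f"unknown evidence kinds {unknown}")
        if self.sign not in SIGNS:
            raise ValueError(f"sign must be one of {SIGNS}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.regulator, self.target, self.tier)


@dataclass
class Network:
    """Evidence-annotated regulatory network around one center."""

    center: str
    nodes: dict[str, Node] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)
    binding_only: bool = False

    def __post_init__(self) -> None:
        if self.center not in self.nodes:
            self.nodes[self.center] = Node(self.center, role="center")

    def add_edge(self, edge: Edge) -> None:
        if any(e.key == edge.key for e in self.edges):
            raise ValueError(f"duplicate edge {edge.key}")
        for endpoint in (edge.regulator, edge.target):
            self.nodes.setdefault(endpoint, Node(endpoint))
        self.edges.append(edge)

    def has_edge(self, regulator: str, target: str, tier: str) -> bool:
        return any(e.key == (regulator, target, tier) for e in self.edges)

    def targets(self, tier: str) -> set[str]:
        return {e.target for e in self.edges if e.tier == tier}

    def to_networkx(self):
        """A networkx MultiDiGraph view with node/edge attributes."""
        import networkx as nx

        g = nx.MultiDiGraph(center=self.center)
        for node in self.nodes.values():
            g.add_node(node.gene_id, role=node.role, log2fc=node.log2fc,
                       marks=sorted(node.marks))
        for e in self.edges:
            g.add_edge(e.regulator, e.target, tier=e.tier,
                       evidence=sorted(e.evidence), sign=e.sign,
                       n_support=len(e.support))
        return g


def networks_equal(a: Network, b: Network) -> bool:
    """Structural equality: center, node annotations and edge attributes
    (support records are runtime objects and not compared)."""
    if a.center != b.center or set(a.nodes) != set(b.nodes):
        return False
    for gene_id, node in a.nodes.items():
        other = b.nodes[gene_id]
        if (node.role, node.marks) != (other.role, other.marks):
            return False
        if (node.log2fc is None) != (other.log2fc is None):
            return False
        if node.log2fc is not None and abs(node.log2fc - other.log2fc) > 0:
            return False
    def edge_set(n: Network):
        return {(e.regulator, e.target, e.tier, e.evidence, e.sign) for e in n.edges}
    return edge_set(a) == edge_set(b)


# ---------------------------------------------------------------------------
# sign inference
# ---------------------------------------------------------------------------

def infer_sign(log2fc: float, perturbation: Perturbation) -> str:
    """Regulatory sign of factor→target from the target's fold change.

    loss perturbation: target down ⇒ the factor was activating it;
    gain perturbation: target up ⇒ activating. Zero fold change gives
    ``unknown``.
    """
    p = -1.0 if perturbation.direction == "loss" else 1.0
    product = log2fc * p
    if product > 0:
        return "activate"
    if product < 0:
        return "repress"
    return "unknown"


def _flip_direction(direction: str) -> str:
    return "gain" if direction == "loss" else "loss"


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_direct_network(
    center: str,
    targets: set[str],
    assignments: list[PeakAssignment],
    expression: dict[str, ExpressionRecord] | None = None,
    perturbation: Perturbation | None = None,
    tf_registry: set[str] | None = None,
    tfbs_support: dict[str, list[TFBSHit]] | None = None,
) -> Network:
    """One direct edge center→target per detected target.

    Evidence per target comes from its peak assignments (promoter and/or
    loop mode) and, for peak-free runs, from predicted TFBS support.
    Targets in the TF registry are typed ``tf`` so indirect expansion can
    find them.
    """
    tf_registry = tf_registry or set()
    tfbs_support = tfbs_support or {}
    by_gene = group_assignments(assignments)
    network = Network(center=center, binding_only=expression is None)
    for target in sorted(targets):
        evidence: set[str] = set()
        support: list = []
        for a in by_gene.get(target, []):
            evidence.add("promoter_peak" if a.mode == "promoter" else "loop_distal_peak")
            support.append(a)
        for hit in tfbs_support.get(target, []):
            evidence.add("predicted_tfbs")
            support.append(hit)
        if not evidence:
            raise ValueError(f"target {target} has no binding evidence")
        sign = "unknown"
        log2fc = None
        if expression is not None and target in expression:
            log2fc = expression[target].log2fc
            if perturbation is not None:
                sign = infer_sign(log2fc, perturbation)
        network.add_edge(Edge(center, target, "direct", frozenset(evidence), sign, support))
        node = network.nodes[target]
        node.log2fc = log2fc
        node.role = "tf" if target in tf_registry else "gene"
    return network


def expand_indirect(
    network: Network,
    binding_evidence: dict[str, dict[str, list]],
    degs: dict[str, ExpressionRecord] | set[str],
    perturbation: Perturbation | None = None,
    tf_registry: set[str] | None = None,
    depth: int = 1,
) -> Network:
    """Add indirect edges through TF direct targets, in place.

    ``binding_evidence`` maps each TF gene id to its candidate targets,
    each with a list of support records — PeakAssignments for curated
    binding or accessible TFBSHits for predicted sites (the record type
    sets the evidence tag). An indirect edge TF→gene is added when the TF
    is a direct (or, at depth > 1, previously added indirect) target typed
    ``tf``, the gene carries that TF's binding evidence, and the gene is a
    DEG under the original perturbation. Self-edges are skipped and a
    direct edge for the same pair wins over an indirect one.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth > MAX_INDIRECT_DEPTH:
        raise ValueError(f"depth {depth} exceeds the maximum of {MAX_INDIRECT_DEPTH}")
    tf_registry = tf_registry or set()
    deg_records = degs if isinstance(degs, dict) else None
    deg_set = set(degs)

    frontier = sorted(
        t for t in network.targets("direct")
        if network.nodes[t].role == "tf" or t in tf_registry
    )
    for _ in range(depth):
        next_frontier: list[str] = []
        for tf in frontier:
            for gene in sorted(binding_evidence.get(tf, {})):
                if gene == tf or gene not in deg_set:
                    continue
                if network.has_edge(tf, gene, "direct") or network.has_edge(tf, gene, "indirect"):
                    continue
                support = binding_evidence[tf][gene]
                if not support:
                    continue
                kinds = {
                    "curated_binding" if isinstance(s, PeakAssignment) else "predicted_tfbs"
                    for s in support
                }
                sign = "unknown"
                log2fc = None
                if deg_records is not None and gene in deg_records:
                    log2fc = deg_records[gene].log2fc
                if log2fc is not None and perturbation is not None:
                    upstream_sign = _edge_sign(network, tf)
                    if upstream_sign == "unknown":
                        sign = "unknown"
                    else:
                        direction = perturbation.direction
                        if upstream_sign == "repress":
                            direction = _flip_direction(direction)
                        sign = infer_sign(log2fc, Perturbation(tf, direction))
                network.add_edge(Edge(tf, gene, "indirect", frozenset(kinds), sign, list(support)))
                node = network.nodes[gene]
                if node.log2fc is None:
                    node.log2fc = log2fc
                if gene in tf_registry:
                    node.role = "tf"
                    next_frontier.append(gene)
        frontier = sorted(set(next_frontier))
        if not frontier:
            break
    return network


def _edge_sign(network: Network, target: str) -> str:
    for e in network.edges:
        if e.target == target:
            return e.sign
    return "unknown"


def annotate_promoter_marks(
    network: Network,
    genes: list[GeneModel],
    tracks: list,
    upstream: int,
    downstream: int,
) -> Network:
    """Attach to each node the names of tracks overlapping its promoter.

    Purely descriptive: repressive marks are welcome here (a promoter
    carrying both H3K4me3 and H3K27me3 shows up as bivalent), and no edge
    is changed.
    """
    by_id = {g.gene_id: g for g in genes}
    indexes = [(track.name, IntervalIndex(track.intervals)) for track in tracks]
    for gene_id, node in network.nodes.items():
        gene = by_id.get(gene_id)
        if gene is None:
            continue
        window = promoter_window(gene, upstream, downstream)
        node.marks = {name for name, index in indexes if index.any_overlap(window)}
    return network


# ---------------------------------------------------------------------------
# co-occupancy
# ---------------------------------------------------------------------------

@dataclass
class CooccupancyResult:
    factor_a: str
    factor_b: str
    observed: int
    expected: float
    p_value: float
    jaccard: float
    n_permutations: int
    seed: int


def _reference_points(peaks: list[Peak], chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    points: dict[str, list[int]] = {}
    for p in peaks:
        size = chrom_sizes.get(p.region.chrom)
        if size is None or p.region.end > size:
            raise ValueError(
                f"peak {p.region.chrom}:{p.region.start}-{p.region.end} "
                "extends beyond the stated chromosome size"
            )
        points.setdefault(p.region.chrom, []).append(p.reference_point)
    return {c: np.sort(np.array(v)) for c, v in points.items()}


def _proximity_count(a_points: dict[str, np.ndarray], b_points: dict[str, np.ndarray], window: int) -> int:
    count = 0
    for chrom, a in a_points.items():
        b = b_points.get(chrom)
        if b is None or b.size == 0:
            continue
        left = np.searchsorted(b, a - window, side="left")
        right = np.searchsorted(b, a + window, side="right")
        count += int(np.count_nonzero(right > left))
    return count


def _coverage(peaks: list[Peak]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.region.chrom, []).append((p.region.start, p.region.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


def _jaccard(peaks_a: list[Peak], peaks_b: list[Peak]) -> float:
    cov_a, cov_b = _coverage(peaks_a), _coverage(peaks_b)
    inter = 0
    total_a = sum(e - s for ivs in cov_a.values() for s, e in ivs)
    total_b = sum(e - s for ivs in cov_b.values() for s, e in ivs)
    for chrom, ivs_a in cov_a.items():
        for s_a, e_a in ivs_a:
            for s_b, e_b in cov_b.get(chrom, []):
                inter += max(0, min(e_a, e_b) - max(s_a, s_b))
    union = total_a + total_b - inter
    return inter / union if union > 0 else 0.0


def cooccupancy(
    peaks_a: list[Peak],
    peaks_b: list[Peak],
    chrom_sizes: dict[str, int],
    window: int = 500,
    n_permutations: int = 1000,
    seed: int = 0,
    factor_a: str = "A",
    factor_b: str = "B",
) -> CooccupancyResult:
    """Test whether two factors' peaks coincide beyond chance.

    Observed statistic: the number of A peaks whose reference point lies
    within ``window`` bp of any B reference point. Null: A's points are
    circularly rotated within each chromosome by a uniform random offset
    (one offset per chromosome per permutation), preserving inter-peak
    spacing. The empirical p is (1 + #{null >= observed}) / (n + 1) and is
    bounded below by 1/(n+1) by construction. The jaccard index of merged
    base coverage is reported alongside.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    a_points = _reference_points(peaks_a, chrom_sizes)
    b_points = _reference_points(peaks_b, chrom_sizes)
    observed = _proximity_count(a_points, b_points, window)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    chroms = sorted(a_points)
    for i in range(n_permutations):
        shifted = {}
        for chrom in chroms:
            size = chrom_sizes[chrom]
            offset = int(rng.integers(0, size))
            shifted[chrom] = np.sort((a_points[chrom] + offset) % size)
        null[i] = _proximity_count(shifted, b_points, window)
    p = (1 + int(np.count_nonzero(null >= observed))) / (n_permutations + 1)
    return CooccupancyResult(
        factor_a, factor_b, observed, float(null.mean()), p,
        _jaccard(peaks_a, peaks_b), n_permutations, seed,
    )


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def _apply_node_cap(network: Network, max_nodes: int) -> Network:
    """Keep the center plus the highest-|log2fc| nodes up to the cap and
    drop edges with a missing endpoint."""
    def sort_key(node: Node):
        fc = abs(node.log2fc) if node.log2fc is not None else -1.0
        return (-fc, node.gene_id)

    others = sorted((n for g, n in network.nodes.items() if g != network.center), key=sort_key)
    keep = {network.center} | {n.gene_id for n in others[: max_nodes - 1]}
    capped = Network(network.center, binding_only=network.binding_only)
    capped.nodes = {g: n for g, n in network.nodes.items() if g in keep}
    capped.edges = [e for e in network.edges if e.regulator in keep and e.target in keep]
    return capped


def export_network(
    network: Network,
    path: str | Path,
    fmt: str = "edge_table_tsv",
    max_nodes: int | None = None,
    metadata: dict | None = None,
) -> None:
    """Write the network as a TSV edge table, SIF, or a JSON graph.

    The edge table round-trips through :func:`read_edge_table`; SIF keeps
    only regulator—tier—target triples; the JSON document carries all node
    and edge annotations plus run metadata. ``max_nodes`` caps the export
    to the center plus the strongest-responding genes.
    """
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; supported: {', '.join(EXPORT_FORMATS)}")
    if max_nodes is not None:
        network = _apply_node_cap(network, max_nodes)
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as out:
            for e in network.edges:
                out.write(f"{e.regulator}\t{e.tier}\t{e.target}\n")
        return
    if fmt == "graph_json":
        doc = {
            "center": network.center,
            "binding_only": network.binding_only,
            "metadata": metadata or {},
            "nodes": [
                {
                    "gene_id": n.gene_id,
                    "role": n.role,
                    "log2fc": n.log2fc,
                    "marks": sorted(n.marks),
                }
                for n in (network.nodes[g] for g in sorted(network.nodes))
            ],
            "edges": [
                {
                    "regulator": e.regulator,
                    "target": e.target,
                    "tier": e.tier,
                    "evidence": sorted(e.evidence),
                    "sign": e.sign,
                    "n_support": len(e.support),
                }
                for e in network.edges
            ],
        }
        with open(path, "w") as out:
            json.dump(doc, out, indent=1, sort_keys=True)
            out.write("\n")
        return
    # edge_table_tsv
    with open(path, "w") as out:
        out.write(f"#center={network.center}\tbinding_only={int(network.binding_only)}\n")
        for gene_id in sorted(network.nodes):
            n = network.nodes[gene_id]
            fc = "" if n.log2fc is None else repr(n.log2fc)
            out.write(f"#node\t{n.gene_id}\t{n.role}\t{fc}\t{','.join(sorted(n.marks))}\n")
        out.write("regulator\ttarget\ttier\tevidence\tsign\tn_support\n")
        for e in network.edges:
            out.write(
                f"{e.regulator}\t{e.target}\t{e.tier}\t{','.join(sorted(e.evidence))}\t"
                f"{e.sign}\t{len(e.support)}\n"
            )


def read_edge_table(path: str | Path) -> Network:
    """Re-import a network written by :func:`export_network` as
    ``edge_table_tsv`` (support records are not restored)."""
    center = None
    binding_only = False
    nodes: dict[str, Node] = {}
    edges: list[Edge] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#center="):
                fields = line.split("\t")
                center = fields[0][len("#center="):]
                for extra in fields[1:]:
                    if extra.startswith("binding_only="):
                        binding_only = bool(int(extra.split("=", 1)[1]))
                continue
            if line.startswith("#node\t"):
                _, gene_id, role, fc, marks = line.split("\t")
                nodes[gene_id] = Node(
                    gene_id, role,
                    float(fc) if fc else None,
                    set(marks.split(",")) if marks else set(),
                )
                continue
            if line.startswith("regulator\t"):
                continue
            regulator, target, tier, evidence, sign, n_support = line.split("\t")
            edges.append(Edge(regulator, target, tier, frozenset(evidence.split(",")), sign))
    if center is None:
        raise ValueError("edge table lacks a #center header line")
    network = Network(center, binding_only=binding_only)
    network.nodes.update(nodes)
    for e in edges:
        network.add_edge(e)
    return network
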