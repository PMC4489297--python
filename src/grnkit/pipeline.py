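"""End-to-end batch pipeline: files in, evidence-annotated network out.

Runs the method in input order: parse peaks / expression / loops / tracks
/ gene models, assign peaks to promoters and through loops, detect direct
targets (intersection or rank product), expand one or more indirect tiers
through TF direct targets using accessibility-filtered predicted TFBSs,
annotate promoter marks, and export the network and target table.

Degraded modes follow the data that is present: with no expression table
the run is binding-only and no indirect tier is inferred (indirect
inference without expression support has an unacceptable false-positive
rate); with no ChIP peaks but a motif for the center, accessible predicted
TFBSs stand in for observed binding on the direct tier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import annotation, expression as expr_mod, genomic_io, motif_scan, target_detection
from .annotation import AliasTable, GeneModel
from .expression import ExpressionRecord, Perturbation
from .genomic_io import Peak, Track
from .motif_scan import PWM, TFBSHit
from .network_builder import Network, build_direct_network, expand_indirect, annotate_promoter_marks, export_network
from .target_detection import PeakAssignment

logger = logging.getLogger(__name__)


@dataclass
class BuildConfig:
    """Inputs and parameters of one network-construction run."""

    center: str
    genes_path: str | Path
    genes_dialect: str = "tss_table"
    peaks_path: str | Path | None = None
    peaks_dialect: str = "bed"
    intensity_column: int | str | None = None
    expression_path: str | Path | None = None
    expression_dialect: str = "simple"
    loops_path: str | Path | None = None
    #: (path, name, role) triples; role in genomic_io.TRACK_ROLES
    tracks: list[tuple[str, str, str]] = field(default_factory=list)
    pwms_path: str | Path | None = None
    promoters_fasta: str | Path | None = None
    tf_list_path: str | Path | None = None
    alias_path: str | Path | None = None
    method: str = "direct"  # or "rankprod"
    promoter_upstream: int = annotation.DEFAULT_PROMOTER_UPSTREAM
    promoter_downstream: int = annotation.DEFAULT_PROMOTER_DOWNSTREAM
    d0: float = target_detection.DEFAULT_D0
    min_abs_log2fc: float = expr_mod.DEFAULT_MIN_ABS_LOG2FC
    max_stat: float = expr_mod.DEFAULT_MAX_STAT
    top_k: int | None = None
    rp_cutoff: float | None = None
    depth: int = 1
    perturbation_direction: str = "loss"
    scan_threshold: float = motif_scan.DEFAULT_SCAN_THRESHOLD
    accessibility_filter: bool = True
    seed: int = 0


@dataclass
class BuildResult:
    network: Network
    targets_table: pd.DataFrame
    assignments: list[PeakAssignment]
    degs: dict[str, ExpressionRecord] | None
    binding_only: bool


def _load_tracks(cfg: BuildConfig) -> list[Track]:
    return [genomic_io.read_track(path, name, role) for path, name, role in cfg.tracks]


def _activity_tracks(tracks: list[Track]) -> list[Track]:
    return [t for t in tracks if t.role in ("accessibility", "active_mark")]


def run_build(cfg: BuildConfig) -> BuildResult:
    """Execute the full pipeline described by ``cfg``."""
    if cfg.method not in ("direct", "rankprod"):
        raise ValueError(f"unknown method {cfg.method!r}; supported: direct, rankprod")

    aliases = annotation.read_alias_table(cfg.alias_path) if cfg.alias_path else None
    tf_registry: set[str] = set()
    if cfg.tf_list_path:
        with open(cfg.tf_list_path) as handle:
            tf_registry = {line.strip() for line in handle if line.strip()}
    genes = annotation.read_gene_models(cfg.genes_path, cfg.genes_dialect, tf_registry)
    tracks = _load_tracks(cfg)

    records: list[ExpressionRecord] | None = None
    degs: dict[str, ExpressionRecord] | None = None
    if cfg.expression_path:
        records = expr_mod.read_expression(cfg.expression_path, cfg.expression_dialect, aliases)
        degs = expr_mod.select_degs(records, cfg.min_abs_log2fc, cfg.max_stat)
        logger.info("%d DEGs of %d expression records", len(degs), len(records))

    pwms: list[PWM] = []
    promoters = None
    if cfg.pwms_path:
        pwms = motif_scan.read_pwms(cfg.pwms_path)
    if cfg.promoters_fasta:
        promoters = motif_scan.read_promoter_fasta(cfg.promoters_fasta)

    assignments: list[PeakAssignment] = []
    tfbs_support: dict[str, list[TFBSHit]] = {}
    perturbation = Perturbation(cfg.center, cfg.perturbation_direction)

    if cfg.peaks_path:
        peaks = genomic_io.read_intervals(cfg.peaks_path, cfg.peaks_dialect, cfg.intensity_column)
        assignments = target_detection.assign_peaks_promoter(
            peaks, genes, cfg.promoter_upstream, cfg.promoter_downstream)
        if cfg.loops_path:
            loops = genomic_io.read_loops(cfg.loops_path)
            assignments += target_detection.assign_peaks_loops(
                peaks, genes, loops, cfg.promoter_upstream, cfg.promoter_downstream,
                existing=assignments)
        candidate_genes = {a.gene_id for a in assignments}
    elif pwms and promoters is not None:
        # peak-free degraded mode: the center's own motif, accessibility-gated
        center_pwms = [m for m in pwms if m.factor == cfg.center]
        if not center_pwms:
            raise ValueError(
                f"no ChIP peaks supplied and no PWM maps to center {cfg.center!r}")
        for pwm in center_pwms:
            per_gene = motif_scan.scan_promoters(promoters, pwm, cfg.scan_threshold)
            for gene_id, hits in per_gene.items():
                kept = motif_scan.filter_accessible(
                    hits, _activity_tracks(tracks), enabled=cfg.accessibility_filter)
                if kept:
                    tfbs_support.setdefault(gene_id, []).extend(kept)
        candidate_genes = set(tfbs_support)
        logger.info("peak-free mode: %d genes with accessible predicted sites",
                    len(candidate_genes))
    else:
        raise ValueError("need either a peak file or PWMs + promoter sequences")

    # --- direct tier ------------------------------------------------------
    targets_table: pd.DataFrame
    if cfg.method == "direct" or records is None:
        result = target_detection.detect_direct_intersection(
            candidate_genes, set(degs) if degs is not None else None)
        targets = result.targets
        binding_only = result.binding_only
        targets_table = _intersection_table(targets, assignments, tfbs_support, degs)
    else:
        scores = target_detection.compute_abundances(assignments, cfg.d0)
        if not scores and tfbs_support:
            raise ValueError("rank product requires peak-derived abundances")
        rp = target_detection.detect_direct_rank_product(
            scores, records, top_k=cfg.top_k, rp_cutoff=cfg.rp_cutoff)
        targets = {r.gene_id for r in rp if r.selected}
        binding_only = False
        targets_table = pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id, "abundance": r.abundance,
                    "abs_log2fc": r.abs_log2fc, "rank_peak": r.rank_peak,
                    "rank_expr": r.rank_expr, "rp": r.rp, "selected": r.selected,
                }
                for r in rp
            ]
        )

    expression_map = degs if degs is not None else None
    network = build_direct_network(
        cfg.center, targets, assignments,
        expression={r.gene_id: r for r in records} if records else None,
        perturbation=perturbation if records else None,
        tf_registry=tf_registry,
        tfbs_support=tfbs_support,
    )
    network.binding_only = binding_only

    # --- indirect tier ----------------------------------------------------
    if degs is not None and cfg.depth > 0 and pwms and promoters is not None:
        binding_evidence: dict[str, dict[str, list]] = {}
        direct_tfs = [t for t in network.targets("direct")
                      if network.nodes[t].role == "tf"]
        activity = _activity_tracks(tracks)
        for tf in sorted(direct_tfs):
            tf_pwms = [m for m in pwms if m.factor == tf]
            evidence: dict[str, list] = {}
            for pwm in tf_pwms:
                per_gene = motif_scan.scan_promoters(promoters, pwm, cfg.scan_threshold)
                for gene_id, hits in per_gene.items():
                    kept = motif_scan.filter_accessible(
                        hits, activity, enabled=cfg.accessibility_filter)
                    if kept:
                        evidence.setdefault(gene_id, []).extend(kept)
            if evidence:
                binding_evidence[tf] = evidence
        expand_indirect(network, binding_evidence, degs, perturbation,
                        tf_registry, cfg.depth)

    annotate_promoter_marks(network, genes, tracks,
                            cfg.promoter_upstream, cfg.promoter_downstream)
    return BuildResult(network, targets_table, assignments, degs, binding_only)


def _intersection_table(
    targets: set[str],
    assignments: list[PeakAssignment],
    tfbs_support: dict[str, list[TFBSHit]],
    degs: dict[str, ExpressionRecord] | None,
) -> pd.DataFrame:
    by_gene = target_detection.group_assignments(assignments)
    rows = []
    for gene in sorted(targets):
        modes = sorted({a.mode for a in by_gene.get(gene, [])})
        if gene in tfbs_support:
            modes.append("predicted_tfbs")
        record = degs.get(gene) if degs else None
        rows.append({
            "gene_id": gene,
            "n_peaks": len(by_gene.get(gene, [])) + len(tfbs_support.get(gene, [])),
            "evidence_modes": ",".join(modes),
            "log2fc": record.log2fc if record else float("nan"),
            "stat": record.stat if record else float("nan"),
        })
    return pd.DataFrame(rows)


def write_outputs(result: BuildResult, out_dir: str | Path, cfg: BuildConfig) -> dict[str, Path]:
    """Export the network (TSV / SIF / JSON) and the target table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(cfg).items()}
    paths = {
        "edge_table": out_dir / "network.tsv",
        "sif": out_dir / "network.sif",
        "graph_json": out_dir / "network.json",
        "targets": out_dir / "targets.tsv",
    }
    export_network(result.network, paths["edge_table"], "edge_table_tsv")
    export_network(result.network, paths["sif"], "sif")
    export_network(result.network, paths["graph_json"], "graph_json", metadata=meta)
    result.targets_table.to_csv(paths["targets"], sep="\t", index=False)
    return paths
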