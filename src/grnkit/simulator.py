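"""Synthetic multi-omics data with a planted regulatory network.

The generator lays genes along one synthetic chromosome at fixed spacing
and plants a known network around a perturbed center factor:

* direct targets get a ChIP peak on their promoter — except a stated
  fraction reachable only through a chromatin loop, which get a distal
  peak wired to the promoter by a loop instead (the first of these sits on
  a second chromosome, exercising inter-chromosomal contacts);
* a few promoter-bound direct targets are designated TFs; each receives a
  motif and a set of indirect targets whose promoter sequences carry the
  motif consensus, with a stated fraction of those planted sites covered
  by an open-chromatin track (the rest are inactive decoys that an
  accessibility filter must remove);
* every true target responds to the perturbation with a signed log2 fold
  change encoding a planted activate/repress label; non-targets fluctuate
  around zero with non-significant statistics; optional noise peaks land
  in intergenic space and noise DEGs on non-target genes.

Everything is written in the text formats the pipeline reads, the truth as
JSON, and the whole dataset is a deterministic function of the seed. What
this emulates — and deliberately does not — is discussed in the package's
methods document: recovery on these data demonstrates pipeline
correctness, not performance on real chromatin biology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .annotation import GeneModel, write_tss_table
from .expression import ExpressionRecord, write_expression_simple
from .genomic_io import (
    GenomicInterval,
    Loop,
    Peak,
    write_intervals_bed,
    write_loops_bedpe,
    write_peaks_bed,
)
from .motif_scan import BASES, PWM, write_pwms_jaspar
from .network_builder import Network

CENTER = "centerTF"


@dataclass
class SimulationParams:
    """Knobs of the synthetic study.

    Defaults describe the reference condition used throughout the test
    suite: 200 genes at 50 kb spacing, 40 direct targets of which a
    quarter are loop-only, two TF intermediates with 10 indirect targets
    each, half of the planted TFBSs accessible, and no noise.
    """

    chrom: str = "chrS"
    chrom_size: int | None = None  # computed from n_genes * gene_spacing if None
    alt_chrom: str = "chrT"
    alt_chrom_size: int = 1_000_000
    n_genes: int = 200
    gene_spacing: int = 50_000
    promoter_upstream: int = 5_000
    promoter_downstream: int = 5_000
    n_direct: int = 40
    fraction_loop_only: float = 0.25
    n_tf_among_direct: int = 2
    n_indirect_per_tf: int = 10
    fraction_accessible: float = 0.5
    n_noise_peaks: int = 0
    n_noise_degs: int = 0
    #: log-normal peak intensity (natural-log scale)
    intensity_mu: float = 3.0
    intensity_sigma: float = 0.5
    #: |log2fc| of true targets ~ Normal(mu_t, sigma_t); nulls ~ Normal(0, sigma_0)
    lfc_mu: float = 3.0
    lfc_sigma: float = 0.5
    lfc_null_sigma: float = 0.2
    motif_length: int = 15
    perturbation_direction: str = "loss"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_direct", "n_tf_among_direct", "n_indirect_per_tf",
                     "n_noise_peaks", "n_noise_degs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fraction_loop_only", "fraction_accessible"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_direct > self.n_genes:
            raise ValueError("n_direct cannot exceed n_genes")
        if self.perturbation_direction not in ("loss", "gain"):
            raise ValueError("perturbation_direction must be 'loss' or 'gain'")
        if self.chrom_size is None:
            self.chrom_size = self.n_genes * self.gene_spacing + 50_000
        if self.n_genes * self.gene_spacing + 50_000 > self.chrom_size:
            raise ValueError(
                f"cannot pack {self.n_genes} genes at {self.gene_spacing} bp "
                f"spacing into {self.chrom_size} bp"
            )
        needed = (self.n_direct
                  + self.n_tf_among_direct * self.n_indirect_per_tf
                  + self.n_noise_degs)
        if needed > self.n_genes:
            raise ValueError("not enough genes for the requested target/noise counts")

    @property
    def n_loop_only(self) -> int:
        return round(self.n_direct * self.fraction_loop_only)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {self.chrom: self.chrom_size, self.alt_chrom: self.alt_chrom_size}


@dataclass
class SyntheticTruth:
    """The planted ground truth a reconstruction is scored against."""

    center: str
    perturbation_direction: str
    #: gene -> {"mode": promoter|loop, "label": activate|repress}
    direct: dict[str, dict] = field(default_factory=dict)
    tf_intermediates: list[str] = field(default_factory=list)
    #: tf -> gene -> {"accessible": bool, "label": ..., "site": [chrom, start, end]}
    indirect: dict[str, dict[str, dict]] = field(default_factory=dict)
    noise_degs: list[str] = field(default_factory=list)

    @property
    def direct_targets(self) -> set[str]:
        return set(self.direct)

    @property
    def loop_only_targets(self) -> set[str]:
        return {g for g, info in self.direct.items() if info["mode"] == "loop"}

    def indirect_targets(self, accessible: bool | None = None) -> set[str]:
        out: set[str] = set()
        for targets in self.indirect.values():
            for gene, info in targets.items():
                if accessible is None or info["accessible"] == accessible:
                    out.add(gene)
        return out

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as out:
            json.dump(asdict(self), out, indent=1, sort_keys=True)
            out.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as handle:
            return cls(**json.load(handle))


@dataclass
class SimulatedDataset:
    """File paths of one simulated study plus its truth and parameters."""

    out_dir: Path
    params: SimulationParams
    truth: SyntheticTruth
    genes: Path
    peaks: Path
    loops: Path
    expression: Path
    track_dhs: Path
    track_h3k4me3: Path
    track_h3k27me3: Path
    promoters: Path
    pwms: Path
    tf_list: Path
    chrom_sizes: Path
    truth_json: Path


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _to_string(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def simulate_dataset(params: SimulationParams, out_dir: str | Path) -> SimulatedDataset:
    """Generate one coupled multi-omics dataset under ``params``.

    Writes TSS table, center ChIP peaks (BED), loops (BEDPE), expression
    (simple 3-column), DHS / H3K4me3 / H3K27me3 tracks (BED), promoter
    FASTA, JASPAR motifs for the TF intermediates, the TF registry, a
    chromosome-sizes table and the truth JSON. Byte-identical for a fixed
    seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    p = params

    gene_ids = [f"g{i + 1:04d}" for i in range(p.n_genes)]
    tss = {g: 25_000 + i * p.gene_spacing for i, g in enumerate(gene_ids)}
    strand = {g: "+" if i % 2 == 0 else "-" for i, g in enumerate(gene_ids)}
    genes = [GeneModel(g, p.chrom, tss[g], strand[g]) for g in gene_ids]

    # --- choose roles -----------------------------------------------------
    def _shuffled(items: list[str]) -> list[str]:
        return [items[i] for i in rng.permutation(len(items))]

    direct_ids = sorted(gene_ids[i] for i in rng.permutation(p.n_genes)[: p.n_direct])
    loop_only = sorted(_shuffled(direct_ids)[: p.n_loop_only])
    promoter_mode = sorted(set(direct_ids) - set(loop_only))
    tf_ids = sorted(_shuffled(promoter_mode)[: p.n_tf_among_direct])

    remaining = _shuffled([g for g in gene_ids if g not in set(direct_ids)])
    indirect: dict[str, list[str]] = {}
    cursor = 0
    for tf in tf_ids:
        indirect[tf] = sorted(remaining[cursor: cursor + p.n_indirect_per_tf])
        cursor += p.n_indirect_per_tf
    noise_deg_ids = sorted(remaining[cursor: cursor + p.n_noise_degs])

    truth = SyntheticTruth(CENTER, p.perturbation_direction,
                           tf_intermediates=list(tf_ids),
                           noise_degs=list(noise_deg_ids))

    # --- center ChIP peaks and loops -------------------------------------
    peaks: list[Peak] = []
    loops: list[Loop] = []
    for g in direct_ids:
        mode = "loop" if g in set(loop_only) else "promoter"
        intensity = float(rng.lognormal(p.intensity_mu, p.intensity_sigma))
        if mode == "promoter":
            region = GenomicInterval(p.chrom, tss[g] - 250, tss[g] + 250)
            peaks.append(Peak(region, intensity, summit=tss[g], name=f"peak_{g}"))
        else:
            # distal element halfway to the next gene; the first loop-only
            # target's element sits on the second chromosome instead
            if g == loop_only[0]:
                chrom_d, pos = p.alt_chrom, p.alt_chrom_size // 2
            else:
                chrom_d, pos = p.chrom, tss[g] + p.gene_spacing // 2
            peaks.append(Peak(GenomicInterval(chrom_d, pos - 150, pos + 150),
                              intensity, summit=pos, name=f"distal_{g}"))
            loops.append(Loop(GenomicInterval(chrom_d, pos - 500, pos + 500),
                              GenomicInterval(p.chrom, tss[g] - 1_000, tss[g] + 1_000),
                              name=f"loop_{g}"))
        truth.direct[g] = {"mode": mode, "label": None}  # label filled below

    for i in range(p.n_noise_peaks):
        gi = int(rng.integers(0, p.n_genes))
        pos = tss[gene_ids[gi]] + p.gene_spacing // 3
        intensity = float(rng.lognormal(p.intensity_mu, p.intensity_sigma))
        peaks.append(Peak(GenomicInterval(p.chrom, pos - 150, pos + 150),
                          intensity, name=f"noise_{i + 1}"))

    # --- expression -------------------------------------------------------
    all_true = set(direct_ids) | {g for tf in tf_ids for g in indirect[tf]}
    labels: dict[str, str] = {}
    for g in sorted(all_true):
        labels[g] = "activate" if rng.random() < 0.5 else "repress"
    records: list[ExpressionRecord] = []
    sign_for = {"loss": {"activate": -1.0, "repress": 1.0},
                "gain": {"activate": 1.0, "repress": -1.0}}[p.perturbation_direction]
    for g in gene_ids:
        if g in all_true:
            magnitude = abs(rng.normal(p.lfc_mu, p.lfc_sigma))
            records.append(ExpressionRecord(g, sign_for[labels[g]] * magnitude, 1e-4))
        elif g in set(noise_deg_ids):
            magnitude = abs(rng.normal(p.lfc_mu, p.lfc_sigma))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            records.append(ExpressionRecord(g, sign * magnitude, 1e-4))
        else:
            records.append(ExpressionRecord(g, float(rng.normal(0.0, p.lfc_null_sigma)),
                                            float(rng.uniform(0.5, 1.0))))
    for g, info in truth.direct.items():
        info["label"] = labels[g]

    # --- motifs, promoter sequences, accessibility ------------------------
    motifs: list[PWM] = []
    consensus: dict[str, np.ndarray] = {}
    for tf in tf_ids:
        codes = _random_sequence(rng, p.motif_length)
        consensus[tf] = codes
        matrix = np.full((p.motif_length, 4), 1.0)
        matrix[np.arange(p.motif_length), codes] = 97.0
        motifs.append(PWM(f"M_{tf}", tf, matrix))

    planted_sites: dict[str, tuple[str, str, int]] = {}  # gene -> (tf, chrom, start)
    for tf in tf_ids:
        targets = indirect[tf]
        n_accessible = round(p.n_indirect_per_tf * p.fraction_accessible)
        accessible_set = set(_shuffled(list(targets))[:n_accessible])
        truth.indirect[tf] = {}
        for g in targets:
            window_start = tss[g] - p.promoter_upstream if strand[g] == "+" \
                else tss[g] - p.promoter_downstream
            window_start = max(0, window_start)
            site_start = window_start + 2_000
            planted_sites[g] = (tf, p.chrom, site_start)
            truth.indirect[tf][g] = {
                "accessible": g in accessible_set,
                "label": labels[g],
                "site": [p.chrom, site_start, site_start + p.motif_length],
            }

    sequences: dict[str, tuple[str, int, str]] = {}
    for g in gene_ids:
        window_start = tss[g] - p.promoter_upstream if strand[g] == "+" \
            else tss[g] - p.promoter_downstream
        window_start = max(0, window_start)
        length = p.promoter_upstream + p.promoter_downstream
        codes = _random_sequence(rng, length)
        if g in planted_sites:
            tf, _, site_start = planted_sites[g]
            rel = site_start - window_start
            codes[rel: rel + p.motif_length] = consensus[tf]
        sequences[g] = (p.chrom, window_start, _to_string(codes))

    dhs: list[GenomicInterval] = []
    for tf in tf_ids:
        for g, info in truth.indirect[tf].items():
            if info["accessible"]:
                _, site_start, site_end = info["site"][0], info["site"][1], info["site"][2]
                dhs.append(GenomicInterval(p.chrom, site_start - 100, site_end + 100))
    dhs.sort(key=lambda iv: (iv.chrom, iv.start))

    h3k4me3 = sorted(
        (GenomicInterval(p.chrom, max(0, tss[g] - 1_000), tss[g] + 1_000)
         for g in direct_ids),
        key=lambda iv: iv.start,
    )
    h3k27me3 = sorted(
        (GenomicInterval(p.chrom, max(0, tss[g] - 1_000), tss[g] + 1_000)
         for g in direct_ids if labels[g] == "repress"),
        key=lambda iv: iv.start,
    )

    # --- write everything -------------------------------------------------
    paths = SimulatedDataset(
        out_dir=out_dir, params=p, truth=truth,
        genes=out_dir / "genes.tsv",
        peaks=out_dir / "peaks.bed",
        loops=out_dir / "loops.bedpe",
        expression=out_dir / "expression.tsv",
        track_dhs=out_dir / "track_dhs.bed",
        track_h3k4me3=out_dir / "track_h3k4me3.bed",
        track_h3k27me3=out_dir / "track_h3k27me3.bed",
        promoters=out_dir / "promoters.fasta",
        pwms=out_dir / "motifs.jaspar",
        tf_list=out_dir / "tf_list.txt",
        chrom_sizes=out_dir / "chrom_sizes.tsv",
        truth_json=out_dir / "truth.json",
    )
    write_tss_table(genes, paths.genes)
    write_peaks_bed(peaks, paths.peaks)
    write_loops_bedpe(loops, paths.loops)
    write_expression_simple(records, paths.expression)
    write_intervals_bed(dhs, paths.track_dhs)
    write_intervals_bed(h3k4me3, paths.track_h3k4me3)
    write_intervals_bed(h3k27me3, paths.track_h3k27me3)
    with open(paths.promoters, "w") as out:
        for g in gene_ids:
            chrom, start, seq = sequences[g]
            out.write(f">{g}::{chrom}:{start}-{start + len(seq)}\n")
            for i in range(0, len(seq), 80):
                out.write(seq[i: i + 80] + "\n")
    write_pwms_jaspar(motifs, paths.pwms)
    with open(paths.tf_list, "w") as out:
        for tf in tf_ids:
            out.write(tf + "\n")
    with open(paths.chrom_sizes, "w") as out:
        for chrom, size in sorted(p.chrom_sizes.items()):
            out.write(f"{chrom}\t{size}\n")
    truth.to_json(paths.truth_json)
    return paths


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class TierScores:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0

    @property
    def f1(self) -> float:
        denom = self.precision + self.recall
        return 2 * self.precision * self.recall / denom if denom else 0.0


@dataclass
class RecoveryReport:
    direct: TierScores
    indirect: TierScores


def evaluate_recovery(
    network: Network,
    truth: SyntheticTruth,
    indirect_reference: str = "accessible",
) -> RecoveryReport:
    """Score a reconstructed network against the planted truth.

    The direct tier compares the network's direct targets with the planted
    direct set. The indirect tier compares indirect targets against either
    the accessible planted TFBS targets (``indirect_reference=
    "accessible"``, the expectation with the accessibility filter on) or
    all planted indirect targets (``"all"``, the filter-off expectation).
    Precision with an empty prediction is defined as 1 (nothing asserted,
    nothing wrong).
    """
    if indirect_reference not in ("accessible", "all"):
        raise ValueError("indirect_reference must be 'accessible' or 'all'")
    pred_direct = network.targets("direct")
    pred_indirect = network.targets("indirect")
    true_direct = truth.direct_targets
    true_indirect = truth.indirect_targets(
        True if indirect_reference == "accessible" else None
    )

    def score(pred: set[str], true: set[str]) -> TierScores:
        return TierScores(len(pred & true), len(pred - true), len(true - pred))

    return RecoveryReport(score(pred_direct, true_direct),
                          score(pred_indirect, true_indirect))
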