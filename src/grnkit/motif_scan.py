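"""PWM scanning of promoter sequences and chromatin-accessibility filtering.

A position count matrix is turned into a log2-odds weight table

    w(i, b) = log2( f(i, b) / background(b) ),
    f(i, b) = (count(i, b) + pc * background(b)) / sum_b' (count(i, b') + pc * background(b'))

with a background-distributed pseudocount ``pc`` keeping the odds finite.
Windows on both strands scoring at least ``threshold`` times the maximal
achievable score are reported as hits; the threshold is a fraction in
[0, 1], which makes it invariant to motif length. Predicted sites can then
be filtered against the union of open-chromatin / active-histone-mark
tracks — a predicted site with no covering mark is considered inactive in
the assayed tissue and removed, exactly the evidence chain used when a
predicted site must stand in for observed binding.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

from .genomic_io import GenomicInterval, IntervalIndex, Track

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
#: scan thresholds offered by convention (fraction of maximal score)
SCAN_THRESHOLDS = (0.75, 0.80, 0.85, 0.90)
DEFAULT_SCAN_THRESHOLD = 0.85


@dataclass(frozen=True)
class PWM:
    """A position count/frequency matrix over A, C, G, T.

    ``matrix`` has shape (length, 4) in ACGT order; every column (position)
    must have a positive total. ``factor`` is the gene id of the TF the
    motif belongs to.
    """

    motif_id: str
    factor: str
    matrix: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: tuple[float, float, float, float] = DEFAULT_BACKGROUND

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (length, 4)")
        if np.any(m.sum(axis=1) <= 0):
            raise ValueError("every PWM position must have a positive count total")
        bg = np.asarray(self.background, dtype=float)
        if np.any(bg <= 0):
            raise ValueError("background entries must be > 0")
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=1))


@dataclass(frozen=True)
class TFBSHit:
    """A predicted binding site in genomic coordinates.

    ``accessible`` is None until the hit has been through the
    accessibility filter, then True for kept hits.
    """

    region: GenomicInterval
    motif_id: str
    factor: str
    score: float
    strand: str
    accessible: bool | None = None


def log_odds(pwm: PWM) -> np.ndarray:
    """Per-position log2-odds weight table, shape (length, 4)."""
    bg = np.asarray(pwm.background)
    smoothed = pwm.matrix + pwm.pseudocount * bg[np.newaxis, :]
    freqs = smoothed / smoothed.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):  # -inf weights are legal at pseudocount 0
        return np.log2(freqs / bg[np.newaxis, :])


def max_score(pwm: PWM) -> float:
    """Maximal achievable log2-odds score (best base at every position)."""
    return float(log_odds(pwm).max(axis=1).sum())


def read_pwms(
    path: str | Path,
    motif_factor_map: dict[str, str] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: tuple[float, float, float, float] = DEFAULT_BACKGROUND,
) -> list[PWM]:
    """Read JASPAR-style 4-row count matrices.

    The motif→factor association comes from ``motif_factor_map`` (motif id
    → gene id); unmapped motifs fall back to the JASPAR name field.
    """
    with open(path) as handle:
        parsed = bio_motifs.parse(handle, "jaspar")
    pwms = []
    for m in parsed:
        matrix = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
        motif_id = m.matrix_id or m.name
        factor = (motif_factor_map or {}).get(motif_id, m.name)
        pwms.append(PWM(motif_id, factor, matrix, pseudocount, background))
    return pwms


def write_pwms_jaspar(pwms: list[PWM], path: str | Path) -> None:
    with open(path, "w") as out:
        for pwm in pwms:
            out.write(f">{pwm.motif_id}\t{pwm.factor}\n")
            for bi, base in enumerate(BASES):
                counts = " ".join(f"{v:.0f}" for v in pwm.matrix[:, bi])
                out.write(f"{base}  [ {counts} ]\n")


def _encode(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, anything else (N...) = -1."""
    table = np.full(256, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores for every length-L window plus a validity mask (no N)."""
    length = weights.shape[0]
    n_win = codes.size - length + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    safe = np.where(codes >= 0, codes, 0)
    for i in range(length):
        window_codes = safe[i : i + n_win]
        scores += weights[i, window_codes]
        valid &= codes[i : i + n_win] >= 0
    return scores, valid


def scan_sequence(
    seq: str,
    pwm: PWM,
    threshold: float = DEFAULT_SCAN_THRESHOLD,
    chrom: str = "seq",
    offset: int = 0,
) -> list[TFBSHit]:
    """Scan both strands of a sequence for PWM matches.

    A window is a hit when its log2-odds score is at least
    ``threshold * max_score(pwm)``; windows containing N are skipped. Hit
    coordinates are genomic (``offset`` added); hits come back ordered by
    position with + before − at the same position. A minus-strand hit at
    window [p, p+L) scores the reverse complement of that window.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    codes = _encode(seq)
    weights = log_odds(pwm)
    # scoring the forward sequence with the reverse-complemented weight
    # table equals scoring the window's reverse complement forward
    weights_rc = weights[::-1, ::-1]
    cutoff = threshold * max_score(pwm)
    hits: list[TFBSHit] = []
    fwd, fwd_valid = _window_scores(codes, weights)
    rev, rev_valid = _window_scores(codes, weights_rc)
    length = len(pwm)
    for pos in range(fwd.size):
        for strand, scores, valid in (("+", fwd, fwd_valid), ("-", rev, rev_valid)):
            if valid[pos] and scores[pos] >= cutoff:
                hits.append(
                    TFBSHit(
                        GenomicInterval(chrom, offset + pos, offset + pos + length, strand),
                        pwm.motif_id,
                        pwm.factor,
                        float(scores[pos]),
                        strand,
                    )
                )
    return hits


_FASTA_HEADER = re.compile(r"^(?P<gene>.+?)::(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def read_promoter_fasta(path: str | Path) -> dict[str, tuple[str, int, str]]:
    """Read promoter sequences keyed by gene id.

    Headers must look like ``gene_id::chrom:start-end`` (0-based half-open)
    so hits can be lifted back to genomic coordinates. Returns
    gene id -> (chrom, start, sequence).
    """
    out: dict[str, tuple[str, int, str]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        match = _FASTA_HEADER.match(record.id)
        if match is None:
            raise ValueError(
                f"promoter FASTA header {record.id!r} is not gene_id::chrom:start-end"
            )
        out[match["gene"]] = (match["chrom"], int(match["start"]), str(record.seq).upper())
    return out


def scan_promoters(
    promoters: dict[str, tuple[str, int, str]],
    pwm: PWM,
    threshold: float = DEFAULT_SCAN_THRESHOLD,
) -> dict[str, list[TFBSHit]]:
    """Scan one PWM over a set of promoter sequences; gene id -> hits."""
    hits: dict[str, list[TFBSHit]] = {}
    for gene_id, (chrom, start, seq) in promoters.items():
        gene_hits = scan_sequence(seq, pwm, threshold, chrom=chrom, offset=start)
        if gene_hits:
            hits[gene_id] = gene_hits
    return hits


def filter_accessible(
    hits: list[TFBSHit],
    tracks: list[Track],
    enabled: bool = True,
) -> list[TFBSHit]:
    """Keep only hits overlapping open-chromatin / active-mark regions.

    Accepts tracks with role ``accessibility`` or ``active_mark``; passing
    a repressive mark is an error — a repressive mark is not evidence that
    a site is active. A kept hit gets ``accessible=True``. Disabled (or no
    tracks supplied): hits pass through unchanged.
    """
    for track in tracks:
        if track.role == "repressive_mark":
            raise ValueError(
                f"track {track.name!r} has role repressive_mark; repressive "
                "marks cannot serve as TFBS activity evidence"
            )
    if not enabled or not tracks:
        return list(hits)
    union = [iv for track in tracks for iv in track.intervals]
    index = IntervalIndex(union)
    return [
        replace(hit, accessible=True)
        for hit in hits
        if index.any_overlap(hit.region)
    ]


def write_hits_bed(hits: list[TFBSHit], path: str | Path) -> None:
    """Export hits as BED6 with the log2-odds score in the score column."""
    with open(path, "w") as out:
        for hit in hits:
            r = hit.region
            out.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{hit.motif_id}\t{hit.score:.4f}\t{hit.strand}\n"
            )
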