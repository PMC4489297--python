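"""Genomic interval formats and overlap primitives.

All coordinates are held internally as 0-based half-open ``[start, end)``
intervals; 1-based dialects (GFF, MACS ``.xls`` tables) are converted at the
parsing boundary. Readers skip comment (``#``), ``track`` and ``browser``
lines and report errors with the offending line number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: roles a signal track may take; repressive marks are admissible only as
#: descriptive promoter annotations, never as TFBS activity evidence.
TRACK_ROLES = ("accessibility", "active_mark", "repressive_mark")

PEAK_DIALECTS = ("bed", "gff", "macs")

_SKIP_PREFIXES = ("#", "track", "browser")


class FormatError(ValueError):
    """A malformed record in a genomic input file."""


@dataclass(frozen=True)
class GenomicInterval:
    """A located genomic region, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name (non-empty).
    start, end : int
        0-based inclusive start, exclusive end; ``0 <= start < end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unspecified).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A binding/enrichment peak: an interval plus a nonnegative intensity.

    ``intensity`` units are dialect dependent (fold enrichment, −log10 p,
    pileup...); missing values default to 1.0 so that score-less BED input
    degrades to pure distance weighting downstream. ``summit``, if present,
    is an absolute position inside the region.
    """

    region: GenomicInterval
    intensity: float = 1.0
    summit: int | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")
        if self.summit is not None and not (
            self.region.start <= self.summit < self.region.end
        ):
            raise ValueError(
                f"summit {self.summit} outside region "
                f"{self.region.chrom}:{self.region.start}-{self.region.end}"
            )

    @property
    def reference_point(self) -> int:
        """Summit if recorded, else the region midpoint."""
        return self.summit if self.summit is not None else self.region.midpoint


@dataclass(frozen=True)
class Loop:
    """A long-range chromatin interaction: two anchors, possibly on
    different chromosomes (inter-chromosomal contacts are retained)."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    score: float | None = None
    name: str | None = None


@dataclass
class Track:
    """A named signal track (e.g. DHS, H3K4me3) with a functional role."""

    name: str
    intervals: list[GenomicInterval]
    role: str

    def __post_init__(self) -> None:
        if self.role not in TRACK_ROLES:
            raise ValueError(
                f"track role {self.role!r} not one of {TRACK_ROLES}"
            )


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for data lines of a tabular file."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, stripped.split("\t") if "\t" in stripped else stripped.split()


def _parse_int(value: str, what: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer {what} {value!r}") from exc


def _parse_float(value: str, what: str, lineno: int) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-numeric {what} {value!r}") from exc


def _make_interval(chrom: str, start: int, end: int, strand: str, lineno: int) -> GenomicInterval:
    try:
        return GenomicInterval(chrom, start, end, strand)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: {exc}") from exc


def _resolve_intensity_column(
    fields: Sequence[str],
    header: Sequence[str] | None,
    intensity_column: int | str | None,
    lineno: int,
) -> float | None:
    """Pull the intensity value selected by index or (MACS) header name."""
    if intensity_column is None:
        return None
    if isinstance(intensity_column, str):
        if header is None or intensity_column not in header:
            raise FormatError(
                f"intensity column {intensity_column!r} not found in header"
            )
        idx = header.index(intensity_column)
    else:
        idx = intensity_column
    if idx >= len(fields):
        raise FormatError(f"line {lineno}: missing intensity column {intensity_column!r}")
    return _parse_float(fields[idx], "intensity", lineno)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_intervals(
    path: str | Path,
    dialect: str = "bed",
    intensity_column: int | str | None = None,
) -> list[Peak]:
    """Read peak regions from BED, GFF or a MACS tabular peak file.

    Parameters
    ----------
    path : path
        Input file.
    dialect : {"bed", "gff", "macs"}
        * ``bed`` — 3–6 columns, 0-based half-open; column 5 (``score``) is
          the default intensity.
        * ``gff`` — tab-separated, 1-based inclusive; start is decremented
          on read; the ``score`` column is the default intensity.
        * ``macs`` — the MACS ``peaks.xls`` tabular dialect (1-based start,
          named header row); ``fold_enrichment`` is the default intensity
          and ``abs_summit`` populates the peak summit. Differential-binding
          callers (PePr, DBChIP, DiffBind) reduce to BED-like tables with a
          configurable ``intensity_column``.
    intensity_column : int or str, optional
        0-based column index (bed/gff) or header name (macs) to use as the
        intensity instead of the dialect default. Peaks with no intensity
        available get intensity 1.0.

    Returns
    -------
    list of Peak in file order.
    """
    if dialect not in PEAK_DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; supported: {', '.join(PEAK_DIALECTS)}"
        )
    peaks: list[Peak] = []
    if dialect == "bed":
        for lineno, f in _data_lines(path):
            if len(f) < 3:
                raise FormatError(f"line {lineno}: BED needs >= 3 columns, got {len(f)}")
            start = _parse_int(f[1], "start", lineno)
            end = _parse_int(f[2], "end", lineno)
            strand = f[5] if len(f) > 5 and f[5] in STRANDS else "."
            region = _make_interval(f[0], start, end, strand, lineno)
            name = f[3] if len(f) > 3 else None
            intensity = _resolve_intensity_column(f, None, intensity_column, lineno)
            if intensity is None and len(f) > 4:
                intensity = _parse_float(f[4], "score", lineno)
            peaks.append(Peak(region, intensity if intensity is not None else 1.0, name=name))
    elif dialect == "gff":
        for lineno, f in _data_lines(path):
            if len(f) < 5:
                raise FormatError(f"line {lineno}: GFF needs >= 5 columns, got {len(f)}")
            start = _parse_int(f[3], "start", lineno) - 1  # 1-based -> 0-based
            end = _parse_int(f[4], "end", lineno)
            strand = f[6] if len(f) > 6 and f[6] in STRANDS else "."
            region = _make_interval(f[0], start, end, strand, lineno)
            intensity = _resolve_intensity_column(f, None, intensity_column, lineno)
            if intensity is None and len(f) > 5 and f[5] not in (".", ""):
                intensity = _parse_float(f[5], "score", lineno)
            peaks.append(Peak(region, intensity if intensity is not None else 1.0, name=f[2]))
    else:  # macs
        header: list[str] | None = None
        if intensity_column is None:
            intensity_column = "fold_enrichment"
        for lineno, f in _data_lines(path):
            if header is None:
                if f[0] == "chr" or not f[1].lstrip("-").isdigit():
                    header = f
                    continue
                raise FormatError(f"line {lineno}: MACS table needs a header row")
            start = _parse_int(f[1], "start", lineno) - 1  # MACS .xls is 1-based
            end = _parse_int(f[2], "end", lineno)
            region = _make_interval(f[0], start, end, ".", lineno)
            intensity = _resolve_intensity_column(f, header, intensity_column, lineno)
            summit = None
            if "abs_summit" in header:
                summit = _parse_int(f[header.index("abs_summit")], "abs_summit", lineno) - 1
            name = f[header.index("name")] if "name" in header else None
            peaks.append(
                Peak(region, intensity if intensity is not None else 1.0, summit=summit, name=name)
            )
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as 6-column BED; intensities go in the score column with
    full float precision so a read-back reproduces them exactly."""
    with open(path, "w") as out:
        for i, peak in enumerate(peaks):
            r = peak.region
            name = peak.name if peak.name is not None else f"peak{i + 1}"
            out.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{peak.intensity!r}\t{r.strand}\n"
            )


def read_loops(path: str | Path) -> list[Loop]:
    """Read chromatin interactions from a BEDPE-like file.

    Requires at least six columns (chromA startA endA chromB startB endB);
    optional ``name`` and ``score`` follow. Inter-chromosomal rows are
    retained — a distal anchor on another chromosome is still valid contact
    evidence for a promoter.
    """
    loops: list[Loop] = []
    for lineno, f in _data_lines(path):
        if len(f) < 6:
            raise FormatError(f"line {lineno}: BEDPE needs >= 6 columns, got {len(f)}")
        a = _make_interval(f[0], _parse_int(f[1], "startA", lineno), _parse_int(f[2], "endA", lineno), ".", lineno)
        b = _make_interval(f[3], _parse_int(f[4], "startB", lineno), _parse_int(f[5], "endB", lineno), ".", lineno)
        name = f[6] if len(f) > 6 and f[6] != "." else None
        score = _parse_float(f[7], "score", lineno) if len(f) > 7 and f[7] != "." else None
        loops.append(Loop(a, b, score=score, name=name))
    return loops


def write_loops_bedpe(loops: Iterable[Loop], path: str | Path) -> None:
    with open(path, "w") as out:
        for i, lp in enumerate(loops):
            a, b = lp.anchor_a, lp.anchor_b
            name = lp.name if lp.name is not None else f"loop{i + 1}"
            score = "." if lp.score is None else repr(lp.score)
            out.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{name}\t{score}\n"
            )


def read_track(path: str | Path, name: str, role: str) -> Track:
    """Read a BED file of regions as a named Track with the given role."""
    peaks = read_intervals(path, dialect="bed")
    return Track(name=name, intervals=[p.region for p in peaks], role=role)


def write_intervals_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as out:
        for iv in intervals:
            out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# overlap primitives
# ---------------------------------------------------------------------------

def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals; 0 for different chromosomes
    and for half-open abutment. Symmetric in its arguments."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class IntervalIndex:
    """Per-chromosome interval tree over a list of intervals.

    Queries return the 0-based positions (in the input list) of all members
    overlapping a probe by at least one base, in input order.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        self._intervals = list(intervals)
        for i, iv in enumerate(self._intervals):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)

    def __len__(self) -> int:
        return len(self._intervals)

    def query(self, probe: GenomicInterval) -> list[int]:
        tree = self._trees.get(probe.chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(probe.start, probe.end))

    def query_intervals(self, probe: GenomicInterval) -> list[GenomicInterval]:
        return [self._intervals[i] for i in self.query(probe)]

    def any_overlap(self, probe: GenomicInterval) -> bool:
        tree = self._trees.get(probe.chrom)
        return bool(tree is not None and tree.overlaps(probe.start, probe.end))


def build_interval_index(intervals: Sequence[GenomicInterval]) -> IntervalIndex:
    return IntervalIndex(intervals)
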