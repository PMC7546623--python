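"""Plain-text genomic interval and coverage I/O.

This module speaks the four text formats the pipeline consumes and emits:
BED6 for TSS anchors, BED3/BEDPE for paired-end fragments, bedGraph for
per-base coverage and BED3 for peak sets.  All in-memory coordinates are
0-based half-open, which is also the native convention of each of these
formats.  Files are whitespace-separated; ``track``, ``browser`` and ``#``
lines are skipped on read.

It also provides the two fragment-level computations everything downstream
builds on: rendering a fragment set to a per-base coverage track (optionally
depth-normalised to counts per million fragments) and splitting fragments at
the non-nucleosomal size cutoff (fragments shorter than 150 bp behave as
sub-nucleosomal, accessibility-derived material; fragments of nucleosomal
size and above are treated as nucleosome-protected).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "ParseError",
    "LayoutError",
    "GenomeLayout",
    "TSSRecord",
    "FragmentSet",
    "CoverageTrack",
    "PeakSet",
    "read_tss_bed",
    "write_tss_bed",
    "read_fragments",
    "write_fragments",
    "split_by_size",
    "coverage_from_fragments",
    "region_rpkm",
    "read_bedgraph",
    "write_bedgraph",
    "read_peaks_bed",
    "write_peaks_bed",
    "sample_random_regions",
]

NNF_CUTOFF = 150
"""Default fragment-length cutoff (bp): lengths < 150 are non-nucleosomal."""

_SKIP_PREFIXES = ("#", "track", "browser")


class ParseError(ValueError):
    """A malformed line in a text genomic file (message names the line)."""


class LayoutError(ValueError):
    """A record referencing an unknown chromosome or out-of-bounds interval."""


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split()


def _parse_int(text: str, path: str | Path, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: expected integer, got {text!r}") from None


@dataclass(frozen=True)
class GenomeLayout:
    """An ordered set of chromosomes with their lengths in bp.

    Every interval handled by the pipeline must lie within ``[0, size)`` of
    its chromosome.  Any layout is accepted; nothing is assembly-specific.
    """

    chrom_sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        sizes = dict(self.chrom_sizes)
        if not sizes:
            raise LayoutError("layout must contain at least one chromosome")
        for name, size in sizes.items():
            if size <= 0:
                raise LayoutError(f"chromosome {name!r} has non-positive size {size}")
        object.__setattr__(self, "chrom_sizes", sizes)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(self.chrom_sizes)

    def size(self, chrom: str) -> int:
        try:
            return self.chrom_sizes[chrom]
        except KeyError:
            raise LayoutError(f"unknown chromosome {chrom!r}") from None

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        size = self.size(chrom)
        if not (0 <= start < end <= size):
            raise LayoutError(
                f"interval {chrom}:{start}-{end} outside [0, {size}) of {chrom!r}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column chromosome-sizes table (chrom, length)."""
        sizes: dict[str, int] = {}
        for lineno, fields in _data_lines(path):
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            sizes[fields[0]] = _parse_int(fields[1], path, lineno)
        return cls(sizes)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for name, size in self.chrom_sizes.items():
                handle.write(f"{name}\t{size}\n")


@dataclass(frozen=True)
class TSSRecord:
    """One promoter anchor: the transcription start site of a gene."""

    chrom: str
    tss: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class FragmentSet:
    """Paired-end fragments as genomic intervals (0-based half-open).

    ``n_rejected`` counts record-level failures (inverted coordinates,
    inter-chromosomal mate pairs) that were skipped on read.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    n_rejected: int = 0

    @classmethod
    def empty(cls) -> "FragmentSet":
        return cls(
            chrom=np.array([], dtype=object),
            start=np.array([], dtype=np.int64),
            end=np.array([], dtype=np.int64),
        )

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int]], n_rejected: int = 0
    ) -> "FragmentSet":
        rows = list(intervals)
        if not rows:
            out = cls.empty()
            out.n_rejected = n_rejected
            return out
        chrom = np.array([r[0] for r in rows], dtype=object)
        start = np.array([r[1] for r in rows], dtype=np.int64)
        end = np.array([r[2] for r in rows], dtype=np.int64)
        return cls(chrom=chrom, start=start, end=end, n_rejected=n_rejected)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def __len__(self) -> int:
        return len(self.start)

    def subset(self, mask: np.ndarray) -> "FragmentSet":
        return FragmentSet(self.chrom[mask], self.start[mask], self.end[mask])

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for c, s, e in zip(self.chrom, self.start, self.end):
            yield str(c), int(s), int(e)


@dataclass
class CoverageTrack:
    """Dense per-base nonnegative signal over a genome layout.

    One float array per chromosome.  ``scale_note`` records the
    normalisation applied (free text, e.g. ``"cpm (n=1000)"``).
    """

    layout: GenomeLayout
    data: dict[str, np.ndarray]
    scale_note: str = ""

    @classmethod
    def zeros(cls, layout: GenomeLayout, scale_note: str = "") -> "CoverageTrack":
        data = {c: np.zeros(layout.size(c)) for c in layout.chrom_names}
        return cls(layout=layout, data=data, scale_note=scale_note)

    def values(self, chrom: str) -> np.ndarray:
        try:
            return self.data[chrom]
        except KeyError:
            raise LayoutError(f"unknown chromosome {chrom!r}") from None

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def mirrored(self) -> "CoverageTrack":
        """The track with every chromosome's per-base values reversed."""
        data = {c: v[::-1].copy() for c, v in self.data.items()}
        return CoverageTrack(self.layout, data, self.scale_note)


@dataclass
class PeakSet:
    """A labelled list of genomic intervals (0-based half-open)."""

    intervals: list[tuple[str, int, int]]
    label: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        return iter(self.intervals)


# ---------------------------------------------------------------------------
# readers / writers


def read_tss_bed(path: str | Path, layout: GenomeLayout) -> list[TSSRecord]:
    """Read TSS anchors from a BED6 file.

    The TSS is the 5' end of the feature in gene orientation: ``start`` on
    the plus strand, ``end - 1`` on the minus strand.
    """
    records: list[TSSRecord] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 6:
            raise ParseError(f"{path}:{lineno}: BED6 requires 6 columns, got {len(fields)}")
        chrom, name, strand = fields[0], fields[3], fields[5]
        start = _parse_int(fields[1], path, lineno)
        end = _parse_int(fields[2], path, lineno)
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
        size = layout.size(chrom)
        tss = start if strand == "+" else end - 1
        if not (0 <= tss < size):
            raise LayoutError(f"{path}:{lineno}: TSS {tss} outside [0, {size}) of {chrom!r}")
        records.append(TSSRecord(chrom=chrom, tss=tss, strand=strand, gene_id=name))
    return records


def write_tss_bed(
    records: Iterable[TSSRecord],
    path: str | Path,
    layout: GenomeLayout | None = None,
    flank: int = 0,
) -> None:
    """Write TSS anchors as BED6.

    With ``flank == 0`` each record is a single-base feature ``[tss, tss+1)``,
    which round-trips exactly through :func:`read_tss_bed` on both strands.
    With ``flank > 0`` the feature is ``TSS ± flank`` (clipped to the layout),
    the form used for exported promoter lists.
    """
    with open(path, "w") as handle:
        for rec in records:
            if flank == 0:
                start, end = rec.tss, rec.tss + 1
            else:
                start, end = rec.tss - flank, rec.tss + flank
                if layout is not None:
                    size = layout.size(rec.chrom)
                    start, end = max(0, start), min(size, end)
            handle.write(f"{rec.chrom}\t{start}\t{end}\t{rec.gene_id}\t0\t{rec.strand}\n")


def read_fragments(path: str | Path, layout: GenomeLayout) -> FragmentSet:
    """Read paired-end fragments from fragment BED (3/6 cols) or BEDPE (10 cols).

    The dialect is auto-detected from the column count of the first data
    line.  A BEDPE row contributes the outer span of the two mate intervals;
    mate pairs on different chromosomes and records with inverted
    coordinates are skipped and counted in ``n_rejected``.
    """
    intervals: list[tuple[str, int, int]] = []
    n_rejected = 0
    ncols: int | None = None
    for lineno, fields in _data_lines(path):
        if ncols is None:
            if len(fields) in (3, 6):
                ncols = len(fields)
            elif len(fields) == 10:
                ncols = 10
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected 3/6 (fragment BED) or 10 (BEDPE) "
                    f"columns, got {len(fields)}"
                )
        if len(fields) < ncols:
            raise ParseError(f"{path}:{lineno}: expected {ncols} columns, got {len(fields)}")
        if ncols == 10:
            c1, c2 = fields[0], fields[3]
            s1 = _parse_int(fields[1], path, lineno)
            e1 = _parse_int(fields[2], path, lineno)
            s2 = _parse_int(fields[4], path, lineno)
            e2 = _parse_int(fields[5], path, lineno)
            if c1 != c2:
                n_rejected += 1
                continue
            chrom, start, end = c1, min(s1, s2), max(e1, e2)
        else:
            chrom = fields[0]
            start = _parse_int(fields[1], path, lineno)
            end = _parse_int(fields[2], path, lineno)
        if start >= end:
            n_rejected += 1
            continue
        layout.check_interval(chrom, start, end)
        intervals.append((chrom, start, end))
    return FragmentSet.from_intervals(intervals, n_rejected=n_rejected)


def write_fragments(frags: FragmentSet, path: str | Path) -> None:
    """Write fragments as 3-column fragment BED."""
    with open(path, "w") as handle:
        for chrom, start, end in frags:
            handle.write(f"{chrom}\t{start}\t{end}\n")


def split_by_size(
    frags: FragmentSet, cutoff: int = NNF_CUTOFF
) -> tuple[FragmentSet, FragmentSet]:
    """Split fragments at a length cutoff into (non-nucleosomal, nucleosomal).

    Non-nucleosomal fragments are strictly shorter than ``cutoff``;
    fragments of exactly ``cutoff`` bp fall in the nucleosomal class, so the
    non-nucleosomal set matches the strict "< 150 bp" definition.
    """
    if cutoff < 1:
        raise ValueError(f"cutoff must be >= 1, got {cutoff}")
    mask = frags.lengths < cutoff
    return frags.subset(mask), frags.subset(~mask)


def coverage_from_fragments(
    frags: FragmentSet, layout: GenomeLayout, normalize: str = "none"
) -> CoverageTrack:
    """Render fragments to per-base coverage (count of overlapping fragments).

    ``normalize="cpm"`` scales every base by ``1e6 / n_fragments`` so tracks
    from libraries of different depth are comparable.
    """
    if normalize not in ("none", "cpm"):
        raise ValueError(f"normalize must be 'none' or 'cpm', got {normalize!r}")
    if normalize == "cpm" and len(frags) == 0:
        raise ValueError("cpm normalization is undefined for an empty fragment set")
    track = CoverageTrack.zeros(layout)
    for chrom in layout.chrom_names:
        mask = frags.chrom == chrom
        if not mask.any():
            continue
        starts = frags.start[mask]
        ends = frags.end[mask]
        size = layout.size(chrom)
        if starts.min() < 0 or ends.max() > size:
            raise LayoutError(f"fragment outside [0, {size}) on {chrom!r}")
        diff = np.zeros(size + 1)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        track.data[chrom] = np.cumsum(diff)[:size]
    if normalize == "cpm":
        scale = 1e6 / len(frags)
        for chrom in track.data:
            track.data[chrom] *= scale
        track.scale_note = f"cpm (n={len(frags)})"
    else:
        track.scale_note = "raw fragment count"
    return track


def region_rpkm(frags: FragmentSet, region: tuple[str, int, int]) -> float:
    """Reads-per-kilobase-per-million for one region.

    A fragment counts if it shares at least one base with the region.
    """
    chrom, start, end = region
    if end <= start:
        raise ValueError(f"zero-length region {chrom}:{start}-{end}")
    if len(frags) == 0:
        raise ValueError("region_rpkm is undefined for an empty fragment set")
    hits = int(np.sum((frags.chrom == chrom) & (frags.start < end) & (frags.end > start)))
    kb = (end - start) / 1000.0
    per_million = len(frags) / 1e6
    return hits / (kb * per_million)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a coverage track as bedGraph, omitting zero-valued runs.

    Values are written with Python's shortest round-trip float repr, so
    ``read_bedgraph(write_bedgraph(t))`` reproduces per-base values exactly.
    """
    with open(path, "w") as handle:
        for chrom in track.layout.chrom_names:
            v = track.data[chrom]
            if len(v) == 0:
                continue
            breaks = np.flatnonzero(np.diff(v)) + 1
            bounds = np.concatenate(([0], breaks, [len(v)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                val = v[s]
                if val == 0.0:
                    continue
                handle.write(f"{chrom}\t{s}\t{e}\t{float(val)!s}\n")


def read_bedgraph(path: str | Path, layout: GenomeLayout) -> CoverageTrack:
    """Read a bedGraph file into a dense coverage track.

    Intervals must be non-overlapping per chromosome; bases not covered by
    any interval are zero.
    """
    per_chrom: dict[str, list[tuple[int, int, float, int]]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: bedGraph requires 4 columns")
        chrom = fields[0]
        start = _parse_int(fields[1], path, lineno)
        end = _parse_int(fields[2], path, lineno)
        try:
            value = float(fields[3])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad value {fields[3]!r}") from None
        layout.check_interval(chrom, start, end)
        per_chrom.setdefault(chrom, []).append((start, end, value, lineno))
    track = CoverageTrack.zeros(layout)
    for chrom, rows in per_chrom.items():
        rows.sort(key=lambda r: (r[0], r[1]))
        last_end = 0
        v = track.data[chrom]
        for start, end, value, lineno in rows:
            if start < last_end:
                raise ParseError(f"{path}:{lineno}: overlapping bedGraph interval on {chrom}")
            v[start:end] = value
            last_end = end
    return track


def read_peaks_bed(
    path: str | Path, layout: GenomeLayout | None = None, label: str = ""
) -> PeakSet:
    """Read a peak set from BED (first three columns used)."""
    intervals: list[tuple[str, int, int]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: BED requires at least 3 columns")
        chrom = fields[0]
        start = _parse_int(fields[1], path, lineno)
        end = _parse_int(fields[2], path, lineno)
        if start >= end:
            raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
        if layout is not None:
            layout.check_interval(chrom, start, end)
        intervals.append((chrom, start, end))
    return PeakSet(intervals=intervals, label=label or str(path))


def write_peaks_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as handle:
        for chrom, start, end in peaks:
            handle.write(f"{chrom}\t{start}\t{end}\n")


def sample_random_regions(
    layout: GenomeLayout, n: int, width: int, seed: int
) -> PeakSet:
    """Sample ``n`` fixed-width regions uniformly over the genome.

    Chromosomes are chosen with probability proportional to their size and
    start positions uniformly over the valid range, so the sample is the
    standard null model for genome-wide enrichment comparisons.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if width < 1:
        raise ValueError("width must be >= 1")
    sizes = np.array([layout.size(c) for c in layout.chrom_names], dtype=float)
    if width > sizes.min():
        raise LayoutError(
            f"width {width} exceeds the smallest chromosome ({int(sizes.min())} bp)"
        )
    rng = np.random.default_rng(seed)
    probs = sizes / sizes.sum()
    idx = rng.choice(len(sizes), size=n, p=probs)
    max_start = sizes.astype(np.int64)[idx] - width
    starts = rng.integers(0, max_start + 1)
    names = layout.chrom_names
    intervals = [(names[i], int(s), int(s) + width) for i, s in zip(idx, starts)]
    return PeakSet(intervals=intervals, label=f"random w={width} n={n}")
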