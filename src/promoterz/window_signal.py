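"""Strand-aware TSS flank windows and windowed signal extraction.

Every promoter is summarised by the mean per-base signal in two windows in
gene orientation: the "-1 nucleosome" window upstream of the TSS and the
"+1 nucleosome" window downstream.  Two presets are used:

* ``hierarchy`` mode, offsets (100, 600): −600..−100 bp and +100..+600 bp,
  the windows over the −1 and +1 nucleosome dyad regions used to classify
  promoters into positional classes;
* ``change`` mode, offsets (0, 500): the 500 bp windows immediately
  flanking the TSS used to partition promoters by where the histone-variant
  signal changed between conditions.

On the minus strand the two windows are swapped in genomic space so that
the −1 window is always transcription-upstream; all matrices and profiles
are oriented with transcription running left to right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, FragmentSet, GenomeLayout, TSSRecord, split_by_size, coverage_from_fragments

__all__ = [
    "FlankWindows",
    "WindowOutsideLayout",
    "MODE_OFFSETS",
    "flank_windows",
    "window_mean",
    "log2fc",
    "flank_signals",
    "SignalMatrix",
    "tss_matrix",
    "nnf_promoter_signal",
    "mirror_tss",
]

MODE_OFFSETS: dict[str, tuple[int, int]] = {
    "hierarchy": (100, 600),
    "change": (0, 500),
}


class WindowOutsideLayout(ValueError):
    """A flank window extends past a chromosome edge."""


@dataclass(frozen=True)
class FlankWindows:
    """The −1 / +1 nucleosome windows of one promoter, in genomic coordinates.

    ``minus1`` is always the transcription-upstream window; ``ndr`` is the
    gap between the two windows around the TSS (empty in change mode).
    """

    minus1: tuple[int, int]
    plus1: tuple[int, int]
    ndr: tuple[int, int]


def flank_windows(
    tss: TSSRecord,
    offset_near: int,
    offset_far: int,
    layout: GenomeLayout | None = None,
) -> FlankWindows:
    """Windows at ``offset_near..offset_far`` bp on each side of the TSS.

    On the plus strand the −1 window is ``[tss - far, tss - near)`` and the
    +1 window ``[tss + near, tss + far)``; on the minus strand the two are
    mirrored about the TSS boundary.
    """
    if not (0 <= offset_near < offset_far):
        raise ValueError(f"need 0 <= offset_near < offset_far, got ({offset_near}, {offset_far})")
    t = tss.tss
    upstream = (t - offset_far, t - offset_near)
    downstream = (t + offset_near, t + offset_far)
    if tss.strand == "+":
        minus1, plus1 = upstream, downstream
    else:
        minus1, plus1 = downstream, upstream
    ndr = (t - offset_near, t + offset_near)
    if layout is not None:
        size = layout.size(tss.chrom)
        lo = min(minus1[0], plus1[0])
        hi = max(minus1[1], plus1[1])
        if lo < 0 or hi > size:
            raise WindowOutsideLayout(
                f"{tss.gene_id}: windows [{lo}, {hi}) outside [0, {size}) of {tss.chrom}"
            )
    return FlankWindows(minus1=minus1, plus1=plus1, ndr=ndr)


def window_mean(track: CoverageTrack, chrom: str, window: tuple[int, int]) -> float:
    """Arithmetic mean of per-base values over a half-open window.

    Uses exact (order-invariant) summation so the result is bit-identical
    under coordinate mirroring, where the same values are visited in
    reverse order.
    """
    start, end = window
    if end <= start:
        raise ValueError(f"window {window} has non-positive width")
    v = track.values(chrom)
    if start < 0 or end > len(v):
        raise WindowOutsideLayout(f"window {chrom}:{start}-{end} outside layout")
    return math.fsum(v[start:end]) / (end - start)


def log2fc(alt: float, ref: float, pseudocount: float = 0.01) -> float:
    """``log2((alt + pc) / (ref + pc))`` — pseudocounted fold change.

    The default pseudocount of 0.01 is sized for counts-per-million-scale
    tracks, where typical promoter window means are of order 1–100.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(np.log2((alt + pseudocount) / (ref + pseudocount)))


def flank_signals(
    track: CoverageTrack,
    tsss: list[TSSRecord],
    mode: str = "hierarchy",
    offsets: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-promoter mean signal in the −1 and +1 windows.

    Returns a DataFrame with columns ``gene_id, chrom, tss, strand,
    minus1_mean, plus1_mean``.  Promoters whose windows fall off a
    chromosome edge are excluded; their count is in ``df.attrs["n_dropped"]``.
    """
    near, far = offsets if offsets is not None else MODE_OFFSETS[mode]
    rows = []
    n_dropped = 0
    for rec in tsss:
        try:
            win = flank_windows(rec, near, far, layout=track.layout)
        except WindowOutsideLayout:
            n_dropped += 1
            continue
        rows.append(
            {
                "gene_id": rec.gene_id,
                "chrom": rec.chrom,
                "tss": rec.tss,
                "strand": rec.strand,
                "minus1_mean": window_mean(track, rec.chrom, win.minus1),
                "plus1_mean": window_mean(track, rec.chrom, win.plus1),
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tss", "strand", "minus1_mean", "plus1_mean"]
    )
    df.attrs["n_dropped"] = n_dropped
    df.attrs["offsets"] = (near, far)
    return df


@dataclass
class SignalMatrix:
    """TSS-anchored binned signal, one row per promoter.

    Rows cover ``TSS ± flank`` in gene orientation (transcription left to
    right); column means give the aggregate profile.
    """

    values: np.ndarray
    gene_ids: list[str]
    flank: int
    binsize: int
    n_dropped: int = 0

    def profile(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def bin_starts(self) -> np.ndarray:
        """Gene-oriented start offset of each bin relative to the TSS."""
        return np.arange(-self.flank, self.flank, self.binsize)


def tss_matrix(
    track: CoverageTrack,
    tsss: list[TSSRecord],
    flank: int = 1000,
    binsize: int = 10,
) -> SignalMatrix:
    """Bin-mean signal over ``[tss - flank, tss + flank)`` for each promoter.

    The spanned width ``2*flank`` must be a multiple of ``binsize`` (the
    single-bin case ``binsize == 2*flank`` reduces each row to one window
    mean).  Minus-strand rows are reversed so transcription runs left to
    right.  Promoters too close to a chromosome edge are dropped (counted
    in ``n_dropped``).
    """
    if (2 * flank) % binsize != 0:
        raise ValueError(f"2*flank ({2 * flank}) must be a multiple of binsize {binsize}")
    nbins = 2 * flank // binsize
    rows, ids = [], []
    n_dropped = 0
    for rec in tsss:
        v = track.values(rec.chrom)
        start, end = rec.tss - flank, rec.tss + flank
        if start < 0 or end > len(v):
            n_dropped += 1
            continue
        binned = v[start:end].reshape(nbins, binsize).mean(axis=1)
        if rec.strand == "-":
            binned = binned[::-1]
        rows.append(binned)
        ids.append(rec.gene_id)
    values = np.array(rows) if rows else np.empty((0, nbins))
    return SignalMatrix(values=values, gene_ids=ids, flank=flank, binsize=binsize, n_dropped=n_dropped)


def nnf_promoter_signal(
    frags: FragmentSet,
    tsss: list[TSSRecord],
    layout: GenomeLayout,
    cutoff: int = 150,
    halfwidth: int = 250,
) -> pd.DataFrame:
    """Per-promoter non-nucleosomal accessibility signal.

    Fragments shorter than ``cutoff`` bp are rendered to depth-normalised
    coverage and averaged over ``TSS ± halfwidth``, the nucleosome-depleted
    region where sub-nucleosomal accessibility fragments concentrate.
    Returns columns ``gene_id, nnf_mean``; edge promoters are dropped.
    """
    nnf, _ = split_by_size(frags, cutoff=cutoff)
    if len(nnf) == 0:
        raise ValueError("no non-nucleosomal fragments below the cutoff")
    track = coverage_from_fragments(nnf, layout, normalize="cpm")
    rows = []
    n_dropped = 0
    for rec in tsss:
        start, end = rec.tss - halfwidth, rec.tss + halfwidth
        v = track.values(rec.chrom)
        if start < 0 or end > len(v):
            n_dropped += 1
            continue
        rows.append({"gene_id": rec.gene_id, "nnf_mean": float(v[start:end].mean())})
    df = pd.DataFrame(rows, columns=["gene_id", "nnf_mean"])
    df.attrs["n_dropped"] = n_dropped
    return df


def mirror_tss(layout: GenomeLayout, rec: TSSRecord) -> TSSRecord:
    """Reflect a TSS through its chromosome and flip the strand.

    Coordinates are mirrored as half-open boundaries (``t -> L - t``), which
    is the reflection under which the strand-swapped flank windows of
    :func:`flank_windows` map exactly onto each other.
    """
    size = layout.size(rec.chrom)
    return TSSRecord(
        chrom=rec.chrom,
        tss=size - rec.tss,
        strand="-" if rec.strand == "+" else "+",
        gene_id=rec.gene_id,
    )
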