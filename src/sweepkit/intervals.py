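"""Genetic binning, interval anchoring and the hypergeometric overlap test.

The question asked here: do QTL likelihood intervals and selection-signature
regions co-occupy more genetic bins than random placement would give?  The
genome is tiled into fixed-width genetic bins (30 cM by default, the
approximate size of a QTL likelihood interval); a bin "has" a feature if any
feature interval overlaps it by more than 0 cM.  With n total bins, l
signature bins, s QTL bins and m doubly-marked bins, the colocalization
p-value is the upper hypergeometric tail

    P(X >= m),  X ~ Hypergeom(n, l, s),
    P(X = k) = C(l, k) C(n-l, s-k) / C(n, s),

i.e. sampling s bins without replacement from n of which l are marked.

The module also unifies genetic and physical coordinates: piecewise-linear
interpolation between map markers for point queries, and a flanking-marker
anchoring rule for QTL intervals (the mapped marker nearest the likelihood
peak on each side of the interval).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import AnchoringError, ExtrapolationError
from .io import GeneticMap, Interval


# ---------------------------------------------------------------------------
# genetic bins
# ---------------------------------------------------------------------------

@dataclass
class BinSet:
    """Fixed-width cM bins tiling each chromosome of a map."""

    bins: list[Interval]
    width_cM: float

    @property
    def n(self) -> int:
        return len(self.bins)


def make_bins(gmap: GeneticMap, width_cM: float = 30.0) -> BinSet:
    """Tile each chromosome from its first to last marker cM with bins of
    ``width_cM``; the last bin per chromosome is truncated at the map end.

    A chromosome spanning less than one width yields a single truncated bin
    (with a warning).
    """
    if width_cM <= 0:
        raise ValueError("width_cM must be positive")
    bins: list[Interval] = []
    for chrom in gmap.chromosomes:
        lo, hi = gmap.cm_range(chrom)
        span = hi - lo
        if span < width_cM:
            warnings.warn(f"chromosome {chrom} spans {span:g} cM "
                          f"< bin width {width_cM:g}; single truncated bin",
                          stacklevel=2)
            bins.append(Interval(chrom, lo, hi, unit="cM"))
            continue
        start = lo
        while start < hi:
            bins.append(Interval(chrom, start, min(start + width_cM, hi), unit="cM"))
            start += width_cM
    return BinSet(bins=bins, width_cM=width_cM)


# ---------------------------------------------------------------------------
# genetic <-> physical coordinate conversion
# ---------------------------------------------------------------------------

def _mapped_arrays(gmap: GeneticMap, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    grp = gmap.chrom_markers(chrom, mapped_only=True)
    if len(grp) < 2:
        raise AnchoringError(f"chromosome {chrom} has < 2 mapped markers")
    return grp["cM"].to_numpy(float), grp["bp"].to_numpy(float)


def genetic_to_physical(gmap: GeneticMap, chrom: str, cM: float) -> float:
    """bp position of a cM query by piecewise-linear interpolation between
    flanking mapped markers; exact at markers.  Out-of-range queries raise."""
    cm_arr, bp_arr = _mapped_arrays(gmap, chrom)
    if cM < cm_arr[0] or cM > cm_arr[-1]:
        raise ExtrapolationError(
            f"{cM} cM outside mapped range [{cm_arr[0]}, {cm_arr[-1]}] of {chrom}")
    return float(np.interp(cM, cm_arr, bp_arr))


def physical_to_genetic(gmap: GeneticMap, chrom: str, bp: float) -> float:
    """Inverse of :func:`genetic_to_physical` (same interpolation on the
    mapped markers, bp as abscissa)."""
    cm_arr, bp_arr = _mapped_arrays(gmap, chrom)
    if bp < bp_arr[0] or bp > bp_arr[-1]:
        raise ExtrapolationError(
            f"{bp} bp outside mapped range [{bp_arr[0]}, {bp_arr[-1]}] of {chrom}")
    return float(np.interp(bp, bp_arr, cm_arr))


def interval_to_cm(gmap: GeneticMap, iv: Interval) -> Interval:
    """Convert a bp interval to cM via the map (cM intervals pass through).
    Ends beyond the mapped range are clipped to it."""
    if iv.unit == "cM":
        return iv
    cm_arr, bp_arr = _mapped_arrays(gmap, iv.chrom)
    start = float(np.interp(np.clip(iv.start, bp_arr[0], bp_arr[-1]), bp_arr, cm_arr))
    end = float(np.interp(np.clip(iv.end, bp_arr[0], bp_arr[-1]), bp_arr, cm_arr))
    return Interval(iv.chrom, start, end, unit="cM", trait=iv.trait,
                    source=iv.source, score=iv.score)


def anchor_interval(gmap: GeneticMap,
                    interval: Interval,
                    peak_cM: float) -> Interval:
    """Anchor a cM likelihood interval to physical coordinates.

    The physical region is delineated by the two mapped flanking markers
    nearest the likelihood peak: on the left, the mapped marker closest to the
    peak with cM <= interval.start (or, if none lies outside, the first mapped
    marker inside the interval); symmetric on the right.
    """
    if interval.unit != "cM":
        raise ValueError("anchor_interval expects a cM interval")
    if not (interval.start <= peak_cM <= interval.end):
        raise ValueError("peak must lie inside the interval")
    cm_arr, bp_arr = _mapped_arrays(gmap, interval.chrom)

    left_outside = np.flatnonzero(cm_arr <= interval.start)
    if len(left_outside):
        left = left_outside[-1]  # nearest to the peak from the left
    else:
        inside = np.flatnonzero((cm_arr > interval.start) & (cm_arr <= interval.end))
        if not len(inside):
            raise AnchoringError("no mapped marker at or inside the interval (left)")
        left = inside[0]
    right_outside = np.flatnonzero(cm_arr >= interval.end)
    if len(right_outside):
        right = right_outside[0]
    else:
        inside = np.flatnonzero((cm_arr >= interval.start) & (cm_arr < interval.end))
        if not len(inside):
            raise AnchoringError("no mapped marker at or inside the interval (right)")
        right = inside[-1]
    return Interval(interval.chrom, float(bp_arr[left]), float(bp_arr[right]),
                    unit="bp", trait=interval.trait, source=interval.source)


# ---------------------------------------------------------------------------
# overlap counting and the hypergeometric test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapCounts:
    """Bin counts for the overlap test: n total, l with selection signal,
    s with QTL, m with both."""

    n: int
    l: int
    s: int
    m: int

    def __post_init__(self) -> None:
        if not (0 <= self.m <= min(self.l, self.s) and
                max(self.l, self.s) <= self.n):
            raise ValueError(f"invalid overlap counts {self}")


def _bins_hit(gmap: GeneticMap, bins: Sequence[Interval],
              features: Sequence[Interval]) -> np.ndarray:
    feats = [interval_to_cm(gmap, f) for f in features]
    hit = np.zeros(len(bins), dtype=bool)
    for i, b in enumerate(bins):
        for f in feats:
            if f.chrom != b.chrom:
                continue
            if min(f.end, b.end) - max(f.start, b.start) > 0:
                hit[i] = True
                break
    return hit


def count_overlap(bin_set: BinSet,
                  selection: Sequence[Interval],
                  qtl: Sequence[Interval],
                  gmap: GeneticMap) -> OverlapCounts:
    """Count bins carrying selection signals, QTL, and both.

    A bin has a feature iff some feature interval overlaps it by > 0 cM; bp
    intervals are converted to cM through the map first.
    """
    sel_hit = _bins_hit(gmap, bin_set.bins, selection)
    qtl_hit = _bins_hit(gmap, bin_set.bins, qtl)
    return OverlapCounts(n=bin_set.n,
                         l=int(sel_hit.sum()),
                         s=int(qtl_hit.sum()),
                         m=int((sel_hit & qtl_hit).sum()))


def hypergeom_overlap_pmf(c: OverlapCounts, k: int) -> float:
    """P(X = k) with X ~ Hypergeom(n, l, s)."""
    return float(stats.hypergeom.pmf(k, c.n, c.l, c.s))


def hypergeom_overlap_p(c: OverlapCounts) -> float:
    """Upper-tail colocalization p-value P(X >= m), X ~ Hypergeom(n, l, s).

    Computed through the survival function (log-space internally), exact for
    m = 0 (p = 1).
    """
    return float(stats.hypergeom.sf(c.m - 1, c.n, c.l, c.s))
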