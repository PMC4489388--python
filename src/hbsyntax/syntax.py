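"""Gap-constrained motif-pair "syntax elements" and their genomic context.

A syntax element is a non-overlapping pair of one PBX-HOX hit and one
MEIS/PREP hit on the same sequence separated by at most ``max_gap``
intervening bases (gap 0 = adjacent).  Either motif may lie upstream, on
either strand.  Elements whose two hits each sit fully inside a conserved
interval are the conserved pairs; those with gap <= 40 are the "hb_40"
elements used for genome-wide enhancer prediction.
"""

from __future__ import annotations

import bisect
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .motifs import MotifHit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


class RegionSet:
    """A named collection of genomic intervals with overlap/nearest queries."""

    def __init__(self, intervals: Iterable[GenomicInterval], label: str = "") -> None:
        self.label = label
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._midpoints: dict[str, list[float]] = {}
        for iv in self.intervals:
            self._midpoints.setdefault(iv.chrom, []).append(iv.midpoint)
        for mids in self._midpoints.values():
            mids.sort()

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    @property
    def total_bp(self) -> int:
        """Total bases covered by the merged union of the intervals."""
        total = 0
        last_chrom, last_end = None, -1
        for iv in self.intervals:
            if iv.chrom != last_chrom:
                last_chrom, last_end = iv.chrom, iv.start
            start = max(iv.start, last_end)
            if iv.end > start:
                total += iv.end - start
            last_end = max(last_end, iv.end)
        return total

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((h.data for h in tree.overlap(start, end)),
                      key=lambda iv: (iv.start, iv.end))

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) lies fully within a single interval."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return any(h.begin <= start and end <= h.end for h in tree.overlap(start, end))

    def nearest_midpoint_distance(self, chrom: str, point: float) -> float | None:
        """Distance from ``point`` to the nearest interval midpoint on ``chrom``."""
        mids = self._midpoints.get(chrom)
        if not mids:
            return None
        i = bisect.bisect_left(mids, point)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(mids):
                d = abs(mids[j] - point)
                best = d if best is None else min(best, d)
        return best


@dataclass(frozen=True)
class SyntaxElement:
    """An ordered, non-overlapping PBX-HOX + MEIS/PREP hit pair with its gap."""

    pbxhox_hit: MotifHit
    meis_hit: MotifHit
    gap: int
    conserved: bool = False
    category: str | None = None

    def __post_init__(self) -> None:
        if self.pbxhox_hit.seq_id != self.meis_hit.seq_id:
            raise ValueError("paired hits must share a sequence")
        if self.pbxhox_hit.overlaps(self.meis_hit):
            raise ValueError("paired hits must not overlap")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")

    @property
    def seq_id(self) -> str:
        return self.pbxhox_hit.seq_id

    @property
    def start(self) -> int:
        return min(self.pbxhox_hit.start, self.meis_hit.start)

    @property
    def end(self) -> int:
        return max(self.pbxhox_hit.end, self.meis_hit.end)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.seq_id, self.start, self.end)

    @property
    def upstream_hit(self) -> MotifHit:
        return self.pbxhox_hit if self.pbxhox_hit.start <= self.meis_hit.start else self.meis_hit

    @property
    def downstream_hit(self) -> MotifHit:
        return self.meis_hit if self.pbxhox_hit.start <= self.meis_hit.start else self.pbxhox_hit


def _gap_between(a: MotifHit, b: MotifHit) -> int | None:
    """Intervening bases between two disjoint hits; None if they overlap."""
    if b.start >= a.end:
        return b.start - a.end
    if a.start >= b.end:
        return a.start - b.end
    return None


def pair_hits(pbxhox_hits: Sequence[MotifHit], meis_hits: Sequence[MotifHit], *,
              max_gap: int = 100, min_gap: int = 0) -> list[SyntaxElement]:
    """All non-overlapping (PBX-HOX, MEIS/PREP) pairs with min_gap <= gap <= max_gap.

    A hit may participate in several elements and elements may overlap one
    another; nothing is collapsed.  Pair order and strand orientation are
    unconstrained — the gap is symmetric in which motif lies upstream.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    if not 0 <= min_gap <= max_gap:
        raise ValueError("require 0 <= min_gap <= max_gap")
    by_seq: dict[str, list[MotifHit]] = {}
    for h in meis_hits:
        by_seq.setdefault(h.seq_id, []).append(h)
    for hs in by_seq.values():
        hs.sort(key=lambda h: h.start)
    elements: list[SyntaxElement] = []
    for p in pbxhox_hits:
        candidates = by_seq.get(p.seq_id, [])
        starts = [m.start for m in candidates]
        # window wide enough for either orientation
        lo = bisect.bisect_left(starts, p.start - max_gap - max(
            (len(m.matched_word) for m in candidates), default=0) - 1)
        hi = bisect.bisect_right(starts, p.end + max_gap)
        for m in candidates[lo:hi]:
            g = _gap_between(p, m)
            if g is not None and min_gap <= g <= max_gap:
                elements.append(SyntaxElement(p, m, g))
    elements.sort(key=lambda e: (e.seq_id, e.start, e.end,
                                 e.pbxhox_hit.start, e.meis_hit.start))
    return elements


def filter_conserved(elements: Sequence[SyntaxElement],
                     conserved: RegionSet) -> list[SyntaxElement]:
    """Keep elements whose two hits are EACH fully inside a conserved interval.

    The two hits may sit in different intervals.  A hit straddling an
    interval boundary disqualifies the element.
    """
    if not conserved:
        warnings.warn("empty conserved region set: no element retained", stacklevel=2)
        return []
    kept = []
    for e in elements:
        if (conserved.contains(e.seq_id, e.pbxhox_hit.start, e.pbxhox_hit.end)
                and conserved.contains(e.seq_id, e.meis_hit.start, e.meis_hit.end)):
            kept.append(SyntaxElement(e.pbxhox_hit, e.meis_hit, e.gap,
                                      conserved=True, category=e.category))
    return kept


def select_hb(elements: Sequence[SyntaxElement], *, max_gap: int = 40) -> list[SyntaxElement]:
    """Subset with gap <= max_gap (the "hb_40" elements at the default)."""
    return [e for e in elements if e.gap <= max_gap]


def gap_histogram(elements: Sequence[SyntaxElement], *, bin_width: int = 1) -> Counter:
    """Counts of elements per gap bin (bin = gap // bin_width)."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    return Counter((e.gap // bin_width) * bin_width for e in elements)


_CATEGORIES = ("promoter", "exonic", "intronic", "intergenic")


def classify_by_gene_context(elements: Sequence[SyntaxElement], genes: RegionSet,
                             coding_exons: RegionSet,
                             tss: Sequence[tuple[str, int]], *,
                             promoter_window: int = 1000) -> list[str]:
    """Assign each element one of promoter > exonic > intronic > intergenic.

    promoter: span within ``promoter_window`` bp of a (most 5') TSS, either
    side; exonic: span overlaps a coding exon; intronic: span overlaps a gene
    body with no exon overlap; else intergenic.  Categories are exhaustive
    and mutually exclusive by the stated priority.
    """
    tss_by_chrom: dict[str, list[int]] = {}
    for chrom, pos in tss:
        tss_by_chrom.setdefault(chrom, []).append(pos)
    for v in tss_by_chrom.values():
        v.sort()
    categories = []
    for e in elements:
        cat = "intergenic"
        positions = tss_by_chrom.get(e.seq_id, [])
        if positions:
            i = bisect.bisect_left(positions, e.start)
            near = any(
                # distance from the span to the TSS point
                max(positions[j] - (e.end - 1), e.start - positions[j], 0) <= promoter_window
                for j in (i - 1, i, i + 1) if 0 <= j < len(positions))
        else:
            near = False
        if near:
            cat = "promoter"
        elif coding_exons.overlapping(e.seq_id, e.start, e.end):
            cat = "exonic"
        elif genes.overlapping(e.seq_id, e.start, e.end):
            cat = "intronic"
        categories.append(cat)
    return categories


def nearest_feature_distances(elements: Sequence[SyntaxElement],
                              features: RegionSet) -> list[float]:
    """Midpoint-to-midpoint distance from each element to its closest feature.

    Elements on sequences with no feature are skipped (logged).
    """
    distances = []
    for e in elements:
        d = features.nearest_midpoint_distance(e.seq_id, e.span.midpoint)
        if d is None:
            logger.warning("no feature on %s: element at %d skipped", e.seq_id, e.start)
            continue
        distances.append(d)
    return distances
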