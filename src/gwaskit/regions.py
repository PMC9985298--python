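"""Toy-scale interval operations over GDM regions.

Two demonstration queries over integrated datasets: an overlap-count MAP
(for each reference region, how many experiment regions overlap it) and a
bounded closest JOIN (for each anchor SNP, the nearest target region within
a distance bound).  Semantics are deliberately minimal demo-grade: distance
is the gap between intervals (0 when they overlap) and ties resolve to the
leftmost, then smallest, target.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .gdm import GdmRegion


def _by_chrom(regions: list[GdmRegion]) -> dict[str, list[GdmRegion]]:
    out: dict[str, list[GdmRegion]] = {}
    for r in regions:
        out.setdefault(r.chrom, []).append(r)
    return out


def map_count(
    reference: list[GdmRegion], experiment: list[GdmRegion], min_count: int = 0
) -> list[tuple[GdmRegion, int]]:
    """Count, per reference region, the overlapping experiment regions.

    Overlap is strict interval intersection on the same chromosome
    (start < other.stop and stop > other.start).  ``min_count=1`` keeps only
    references with at least one overlapping region.
    """
    # Distinct data payloads keep duplicate intervals countable.
    trees = {
        chrom: IntervalTree.from_tuples((r.start, r.stop, i) for i, r in enumerate(regs))
        for chrom, regs in _by_chrom(experiment).items()
    }
    out = []
    for ref in reference:
        tree = trees.get(ref.chrom)
        count = len(tree.overlap(ref.start, ref.stop)) if tree is not None else 0
        if count >= min_count:
            out.append((ref, count))
    return out


def gap(a: GdmRegion, b: GdmRegion) -> int:
    """Base-pair gap between two regions on the same chromosome; 0 if they overlap."""
    if a.start < b.stop and a.stop > b.start:
        return 0
    return b.start - a.stop if b.start >= a.stop else a.start - b.stop


@dataclass(frozen=True)
class ClosestHit:
    anchor: GdmRegion
    target: GdmRegion
    distance: int


def closest_within(
    anchors: list[GdmRegion], targets: list[GdmRegion], max_distance: int
) -> list[ClosestHit]:
    """Per anchor, the minimum-gap same-chromosome target with gap < max_distance.

    Anchors with no qualifying target are omitted.  Ties resolve to the
    leftmost then shortest target, which pins determinism for tests.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    targets_by_chrom = {
        chrom: sorted(regs, key=lambda r: (r.start, r.stop))
        for chrom, regs in _by_chrom(targets).items()
    }
    hits = []
    for anchor in anchors:
        best: tuple[int, int, int] | None = None
        best_target = None
        for t in targets_by_chrom.get(anchor.chrom, ()):
            d = gap(anchor, t)
            if d >= max_distance:
                continue
            key = (d, t.start, t.stop - t.start)
            if best is None or key < best:
                best = key
                best_target = t
        if best_target is not None:
            hits.append(ClosestHit(anchor=anchor, target=best_target, distance=best[0]))
    return hits
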