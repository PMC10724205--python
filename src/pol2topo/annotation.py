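"""Annotate anchors and features with TF occupancy, CpG overlap and TSS class."""

from __future__ import annotations

import bisect
import math
from collections.abc import Sequence
from dataclasses import dataclass

from .contact_features import TopoFeature
from .io_formats import BedRecord, GeneModel, GenomicInterval

__all__ = [
    "AnchorAnnotation",
    "PeakIndex",
    "overlap_count",
    "classify_tss_proximity",
    "annotate_anchor",
    "annotate_feature",
    "loop_category",
    "genes_in_feature",
]

PROXIMAL = "proximal"
DISTAL = "distal"
DEFAULT_PROXIMAL_WINDOW = 5000


@dataclass(frozen=True, slots=True)
class AnchorAnnotation:
    anchor: GenomicInterval
    n_p3f: int
    n_p300: int
    overlaps_cpg: bool
    tss_class: str
    nearest_tss_distance: float  # bp; inf when no gene is on the chromosome


class PeakIndex:
    """Sorted per-chromosome peak index for O(log n + k) overlap counting."""

    def __init__(self, peaks: Sequence[GenomicInterval | BedRecord]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in peaks:
            iv = p.interval if isinstance(p, BedRecord) else p
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._by_chrom = {}
        for chrom, items in by_chrom.items():
            items.sort()
            starts = [s for s, _ in items]
            # running max of ends lets us bound the left scan
            max_end = []
            m = 0
            for _, e in items:
                m = max(m, e)
                max_end.append(m)
            self._by_chrom[chrom] = (starts, items, max_end)

    def count(self, query: GenomicInterval) -> int:
        entry = self._by_chrom.get(query.chrom)
        if entry is None:
            return 0
        starts, items, max_end = entry
        hi = bisect.bisect_left(starts, query.end)  # peaks starting before query end
        n = 0
        for i in range(hi - 1, -1, -1):
            if max_end[i] <= query.start:
                break  # nothing further left can reach the query
            if items[i][1] > query.start:
                n += 1
        return n


def overlap_count(
    interval: GenomicInterval, peaks: Sequence[GenomicInterval] | PeakIndex
) -> int:
    """Number of peaks overlapping ``interval`` by >= 1 bp (half-open)."""
    if isinstance(peaks, PeakIndex):
        return peaks.count(interval)
    return PeakIndex(peaks).count(interval)


def classify_tss_proximity(
    anchor: GenomicInterval,
    genes: Sequence[GeneModel],
    window: int = DEFAULT_PROXIMAL_WINDOW,
) -> tuple[str, float]:
    """Distance from the anchor to the nearest gene TSS, and its class.

    Distance is 0 when a TSS falls inside the anchor; otherwise it is
    measured from the half-open interval boundary.  Proximal iff
    distance <= window (inclusive).  With no gene on the anchor's chromosome
    the anchor is distal at infinite distance.
    """
    best = math.inf
    for g in genes:
        if g.chrom != anchor.chrom:
            continue
        d = anchor.distance_to_point(g.tss)
        if d < best:
            best = d
            if best == 0:
                break
    return (PROXIMAL if best <= window else DISTAL), best


def annotate_anchor(
    anchor: GenomicInterval,
    p3f: Sequence[GenomicInterval] | PeakIndex,
    p300: Sequence[GenomicInterval] | PeakIndex,
    cpg: Sequence[GenomicInterval] | PeakIndex,
    genes: Sequence[GeneModel],
    window: int = DEFAULT_PROXIMAL_WINDOW,
) -> AnchorAnnotation:
    tss_class, dist = classify_tss_proximity(anchor, genes, window)
    return AnchorAnnotation(
        anchor=anchor,
        n_p3f=overlap_count(anchor, p3f),
        n_p300=overlap_count(anchor, p300),
        overlaps_cpg=overlap_count(anchor, cpg) > 0,
        tss_class=tss_class,
        nearest_tss_distance=dist,
    )


def _anchor_label(ann: AnchorAnnotation) -> str:
    tf = "P3F+p300" if ann.n_p3f > 0 else ("p300" if ann.n_p300 > 0 else "noTF")
    cpg = "CpG" if ann.overlaps_cpg else "noCpG"
    return f"{ann.tss_class}.{tf}.{cpg}"


def loop_category(
    ann_a: AnchorAnnotation, ann_b: AnchorAnnotation, scheme: str = "collapse"
) -> str:
    """Symmetric category label for a loop from its two anchor annotations.

    Schemes:
      - "tss": proximal/distal combination of the two ends.
      - "cpg": CpG-island combination of the two ends.
      - "tf":  strongest TF occupancy across the two ends.
      - "collapse": the condition-contrast taxonomy — "cpgTSSxcpgTSS" when
        both ends are CpG-island TSS-proximal anchors, else "distalP3F" when
        an end is TSS-distal and P3F-bound, else "other".
    """
    if scheme == "tss":
        return "x".join(sorted([ann_a.tss_class, ann_b.tss_class]))
    if scheme == "cpg":
        labels = sorted("CpG" if a.overlaps_cpg else "noCpG" for a in (ann_a, ann_b))
        return "x".join(labels)
    if scheme == "tf":
        def tf(a):
            return "P3F+p300" if a.n_p3f > 0 else ("p300" if a.n_p300 > 0 else "noTF")
        return "x".join(sorted([tf(ann_a), tf(ann_b)]))
    if scheme == "collapse":
        if all(
            a.overlaps_cpg and a.tss_class == PROXIMAL for a in (ann_a, ann_b)
        ):
            return "cpgTSSxcpgTSS"
        if any(a.tss_class == DISTAL and a.n_p3f > 0 for a in (ann_a, ann_b)):
            return "distalP3F"
        return "other"
    raise ValueError(f"unknown category scheme {scheme!r}")


def annotate_feature(
    feature: TopoFeature,
    p3f: Sequence[GenomicInterval] | PeakIndex,
    p300: Sequence[GenomicInterval] | PeakIndex,
    cpg: Sequence[GenomicInterval] | PeakIndex,
    genes: Sequence[GeneModel],
    window: int = DEFAULT_PROXIMAL_WINDOW,
) -> TopoFeature:
    """Attach per-anchor annotations and feature-level summaries in place.

    Summaries:
      - n_p3f_total: P3F peaks counted over loop-end anchors (anchors with
        >= 1 passing edge; for 0-loop peak features, the bare anchor).
      - fraction_loop_ends_in_cpg: loop ends overlapping a CpG island over
        2 x n_loops (each edge contributes its two ends; a self-edge's two
        ends coincide).
      - fraction_anchors_in_cpg: the anchor-level variant of the same
        quantity, with distinct anchors as the denominator.
    """
    p3f = p3f if isinstance(p3f, PeakIndex) else PeakIndex(p3f)
    p300 = p300 if isinstance(p300, PeakIndex) else PeakIndex(p300)
    cpg = cpg if isinstance(cpg, PeakIndex) else PeakIndex(cpg)
    per_anchor = {
        a: annotate_anchor(a, p3f, p300, cpg, genes, window) for a in feature.anchors
    }
    if feature.edges:
        loop_ends = [end for e in feature.edges for end in (e.anchor_a, e.anchor_b)]
    else:
        loop_ends = list(feature.anchors)
    n_cpg_ends = sum(1 for a in loop_ends if per_anchor[a].overlaps_cpg)
    n_cpg_anchors = sum(1 for a in feature.anchors if per_anchor[a].overlaps_cpg)
    feature.annotations.update(
        anchor_annotations=per_anchor,
        n_p3f_total=sum(per_anchor[a].n_p3f for a in set(loop_ends)),
        n_p300_total=sum(per_anchor[a].n_p300 for a in set(loop_ends)),
        fraction_loop_ends_in_cpg=n_cpg_ends / len(loop_ends) if loop_ends else 0.0,
        fraction_anchors_in_cpg=n_cpg_anchors / len(feature.anchors)
        if feature.anchors
        else 0.0,
    )
    return feature


def genes_in_feature(feature: TopoFeature, genes: Sequence[GeneModel]) -> list[str]:
    """Gene ids whose TSS lies within the feature span (half-open test).

    Trans features are handled per chromosome.
    """
    out = []
    for chrom in feature.chroms:
        span = feature.span(chrom)
        if span is None:
            continue
        for g in genes:
            if span.contains_point(g.chrom, g.tss):
                out.append(g.gene_id)
    return sorted(set(out))
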