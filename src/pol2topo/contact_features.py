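"""Threshold contacts, cluster anchors into topological features, rank them.

A feature is a connected component of the thresholded anchor graph:
0 passing edges (a bare 1D peak) -> "peak", exactly 1 edge -> "loop",
2 or more edges -> "cluster".
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .aqua_norm import ContactRecord
from .io_formats import BedRecord, GenomicInterval

__all__ = [
    "TopoFeature",
    "build_feature_graph",
    "extract_features",
    "rank_features",
    "cluster_stats",
]

PEAK = "peak"
LOOP = "loop"
CLUSTER = "cluster"


@dataclass
class TopoFeature:
    feature_id: str
    kind: str
    anchors: tuple[GenomicInterval, ...]
    edges: tuple[ContactRecord, ...]
    total_signal: float = 0.0
    rank: int | None = None
    annotations: dict = field(default_factory=dict)

    @property
    def n_loops(self) -> int:
        return len(self.edges)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(sorted({a.chrom for a in self.anchors}))

    @property
    def is_trans(self) -> bool:
        return len(self.chroms) > 1

    def span(self, chrom: str | None = None) -> GenomicInterval | None:
        """Genomic extent of the feature's anchors on one chromosome.

        For cis features the chromosome is implied; trans features require an
        explicit chromosome and report per-chromosome spans.
        """
        if chrom is None:
            if self.is_trans:
                raise ValueError(
                    f"{self.feature_id} spans {self.chroms}; pass chrom explicitly"
                )
            chrom = self.anchors[0].chrom
        on = [a for a in self.anchors if a.chrom == chrom]
        if not on:
            return None
        return GenomicInterval(chrom, min(a.start for a in on), max(a.end for a in on))

    def span_bp(self) -> int:
        iv = self.span()
        return iv.length() if iv else 0


def build_feature_graph(
    contacts: Iterable[ContactRecord], aqua_cpm_threshold: float = 0.0
) -> nx.Graph:
    """Graph whose nodes are anchors and edges are contacts above threshold.

    "Above" is strict: an edge is kept iff aqua_cpm > threshold.  Self-edges
    (intra-bin contacts that survived the distance filter) are kept.
    """
    if aqua_cpm_threshold < 0:
        raise ValueError("threshold must be >= 0")
    g = nx.Graph()
    for c in contacts:
        if c.aqua_cpm is None:
            raise ValueError("contacts must be normalized before graph construction")
        if c.aqua_cpm > aqua_cpm_threshold:
            if g.has_edge(c.anchor_a, c.anchor_b):
                raise ValueError(f"duplicate contact {c.anchor_a} x {c.anchor_b}")
            g.add_edge(c.anchor_a, c.anchor_b, contact=c)
    return g


def _anchor_key(a: GenomicInterval) -> tuple:
    return (a.chrom, a.start, a.end)


def extract_features(
    graph: nx.Graph,
    pol2_anchor_peaks: Sequence[BedRecord] = (),
    *,
    bin_size: int = 5000,
    include_trans: bool = True,
) -> list[TopoFeature]:
    """Connected components classified as loops/clusters, plus 0-edge peaks.

    1D Pol2 peaks whose midpoint bin participates in no passing edge become
    "peak" features; their total_signal is the BED score when present.
    Feature ids are assigned in coordinate-sorted order so every downstream
    table is deterministic.
    """
    raw: list[dict] = []
    for comp in nx.connected_components(graph):
        anchors = tuple(sorted(comp, key=_anchor_key))
        sub = graph.subgraph(comp)
        edges = tuple(
            sorted(
                (d["contact"] for _, _, d in sub.edges(data=True)),
                key=lambda c: (_anchor_key(c.anchor_a), _anchor_key(c.anchor_b)),
            )
        )
        if not include_trans and len({a.chrom for a in anchors}) > 1:
            continue
        kind = CLUSTER if len(edges) >= 2 else LOOP
        total = sum(c.aqua_cpm for c in edges)
        raw.append(dict(kind=kind, anchors=anchors, edges=edges, total=total))

    used_bins = {_anchor_key(a) for a in graph.nodes}
    for peak in pol2_anchor_peaks:
        iv = peak.interval
        k = iv.midpoint() // bin_size
        anchor = GenomicInterval(iv.chrom, k * bin_size, (k + 1) * bin_size)
        if _anchor_key(anchor) in used_bins:
            continue
        raw.append(
            dict(
                kind=PEAK,
                anchors=(anchor,),
                edges=(),
                total=float(peak.score) if peak.score is not None else 0.0,
            )
        )

    raw.sort(key=lambda d: _anchor_key(d["anchors"][0]))
    width = max(1, len(str(len(raw))))
    return [
        TopoFeature(
            feature_id=f"F{i:0{width}d}",
            kind=d["kind"],
            anchors=d["anchors"],
            edges=d["edges"],
            total_signal=d["total"],
        )
        for i, d in enumerate(raw, 1)
    ]


def rank_features(features: Iterable[TopoFeature]) -> list[TopoFeature]:
    """Order features by increasing total signal, assigning 1-based ranks.

    Ties break by (span, feature_id), keeping the ordering stable and
    reproducible for hockey-stick style rank plots.
    """
    ordered = sorted(
        features, key=lambda f: (f.total_signal, f.span_bp(), f.feature_id)
    )
    for i, f in enumerate(ordered, 1):
        f.rank = i
    return ordered


def rank_table(features: Iterable[TopoFeature]) -> pd.DataFrame:
    ordered = rank_features(features)
    return pd.DataFrame(
        {
            "rank": [f.rank for f in ordered],
            "feature_id": [f.feature_id for f in ordered],
            "kind": [f.kind for f in ordered],
            "n_loops": [f.n_loops for f in ordered],
            "total_signal": [f.total_signal for f in ordered],
        }
    )


def cluster_stats(
    features: Iterable[TopoFeature], p3f_peaks: Sequence[BedRecord]
) -> tuple[pd.DataFrame, dict]:
    """Per-cluster loop counts, spans and P3F occupancy, plus cohort means.

    The cohort summary averages over clusters carrying at least one P3F peak
    at any anchor (the "with P3F" cohort).
    """
    from .annotation import overlap_count

    peak_ivs = [p.interval for p in p3f_peaks]
    rows = []
    for f in features:
        if f.kind != CLUSTER:
            continue
        n_p3f = sum(overlap_count(a, peak_ivs) for a in f.anchors)
        span_kb = f.span_bp() / 1000.0 if not f.is_trans else float("nan")
        rows.append(
            dict(
                feature_id=f.feature_id,
                n_loops=f.n_loops,
                n_anchors=len(f.anchors),
                span_kb=span_kb,
                n_p3f_peaks=n_p3f,
                total_signal=f.total_signal,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "feature_id", "n_loops", "n_anchors", "span_kb", "n_p3f_peaks", "total_signal",
        ],
    )
    cohort = table[table["n_p3f_peaks"] >= 1]
    summary = {
        "n_clusters": int(len(table)),
        "n_clusters_with_p3f": int(len(cohort)),
        "mean_loops_per_cluster": float(cohort["n_loops"].mean()) if len(cohort) else float("nan"),
        "mean_p3f_peaks": float(cohort["n_p3f_peaks"].mean()) if len(cohort) else float("nan"),
        "mean_span_kb": float(cohort["span_kb"].mean()) if len(cohort) else float("nan"),
    }
    return table, summary
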