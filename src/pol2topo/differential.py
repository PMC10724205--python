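"""Two-condition comparison of normalized contacts: L2FC tables, rank plots,
long-range windowing and aggregate peak analysis (APA)."""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aqua_norm import ContactRecord
from .io_formats import GenomicInterval

__all__ = [
    "DeltaRecord",
    "APAMatrix",
    "l2fc",
    "delta_table",
    "category_summary",
    "long_range_filter",
    "rank_plot_table",
    "contact_lookup",
    "apa",
    "delta_apa",
]

DEFAULT_EPSILON = 0.5
LONG_RANGE_MIN = 25_000
LONG_RANGE_MAX = 3_000_000


@dataclass(frozen=True, slots=True)
class DeltaRecord:
    unit_id: str
    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    signal_ctrl: float
    signal_trt: float
    l2fc: float
    mean_a: float
    distance: int
    category: str


def l2fc(signal_trt: float, signal_ctrl: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """log2((trt + eps) / (ctrl + eps)); eps keeps zeros finite."""
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if signal_trt < 0 or signal_ctrl < 0:
        raise ValueError("signals must be >= 0")
    return math.log2((signal_trt + epsilon) / (signal_ctrl + epsilon))


def _unit_key(c: ContactRecord) -> tuple:
    return (
        c.anchor_a.chrom, c.anchor_a.start, c.anchor_a.end,
        c.anchor_b.chrom, c.anchor_b.start, c.anchor_b.end,
    )


def delta_table(
    contacts_ctrl: Sequence[ContactRecord],
    contacts_trt: Sequence[ContactRecord],
    categories: Mapping[tuple, str] | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> list[DeltaRecord]:
    """Per-unit L2FC over the union of the two conditions' bin-pair units.

    A unit absent in one condition enters with signal 0 rather than being
    dropped — collapse means disappearance, and dropping would bias toward
    the null.  ``categories`` maps unit keys (the 6-tuple of anchor coords)
    to labels; unlabeled units get "uncategorized".
    """
    ctrl = {_unit_key(c): c for c in contacts_ctrl}
    trt = {_unit_key(c): c for c in contacts_trt}
    keys = set(ctrl) | set(trt)
    if ctrl and trt and not (set(ctrl) & set(trt)):
        raise ValueError(
            "control and treated unit universes are disjoint; "
            "check that both were binned identically"
        )
    records = []
    for key in sorted(keys):
        c, t = ctrl.get(key), trt.get(key)
        ref = c or t
        sc = c.aqua_cpm if c is not None else 0.0
        st = t.aqua_cpm if t is not None else 0.0
        if sc is None or st is None:
            raise ValueError("contacts must carry aqua_cpm; run aqua_normalize first")
        category = categories.get(key, "uncategorized") if categories else "uncategorized"
        records.append(
            DeltaRecord(
                unit_id=f"{ref.anchor_a}|{ref.anchor_b}",
                anchor_a=ref.anchor_a,
                anchor_b=ref.anchor_b,
                signal_ctrl=sc,
                signal_trt=st,
                l2fc=l2fc(st, sc, epsilon),
                mean_a=0.5 * math.log2((st + epsilon) * (sc + epsilon)),
                distance=ref.distance,
                category=category,
            )
        )
    return records


def category_summary(records: Iterable[DeltaRecord]) -> pd.DataFrame:
    """Median and quartiles of l2fc per category (box-plot style summary)."""
    df = pd.DataFrame(
        {"category": [r.category for r in records], "l2fc": [r.l2fc for r in records]}
    )
    if df.empty:
        return pd.DataFrame(columns=["category", "n", "median", "q1", "q3"])
    out = (
        df.groupby("category")["l2fc"]
        .agg(n="size", median="median", q1=lambda s: s.quantile(0.25),
             q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return out


def long_range_filter(
    records: Sequence,
    min_distance: int = LONG_RANGE_MIN,
    max_distance: int = LONG_RANGE_MAX,
):
    """Keep cis records with min_distance <= distance <= max_distance (inclusive)."""
    if min_distance > max_distance:
        raise ValueError("min_distance > max_distance")
    return [
        r for r in records
        if r.anchor_a.chrom == r.anchor_b.chrom
        and min_distance <= r.distance <= max_distance
    ]


def rank_plot_table(records: Sequence[DeltaRecord]) -> pd.DataFrame:
    """Records ordered by ascending l2fc with rank index and CDF columns.

    fraction_below_zero counts strictly negative l2fc; fraction_at_or_below
    includes zeros (the all-zero case reports 0 and 1 respectively).
    """
    ordered = sorted(records, key=lambda r: (r.l2fc, r.unit_id))
    n = len(ordered)
    df = pd.DataFrame(
        {
            "rank": range(1, n + 1),
            "unit_id": [r.unit_id for r in ordered],
            "l2fc": [r.l2fc for r in ordered],
            "category": [r.category for r in ordered],
        }
    )
    df.attrs["fraction_below_zero"] = (
        sum(1 for r in ordered if r.l2fc < 0) / n if n else float("nan")
    )
    df.attrs["fraction_at_or_below_zero"] = (
        sum(1 for r in ordered if r.l2fc <= 0) / n if n else float("nan")
    )
    return df


@dataclass
class APAMatrix:
    """Element-wise mean of contact submatrices centered on a loop set."""

    matrix: np.ndarray  # (2*flank+1, 2*flank+1)
    bin_size: int
    flank: int
    n_loops: int
    n_skipped: int = 0

    def __post_init__(self):
        side = 2 * self.flank + 1
        if self.matrix.shape != (side, side):
            raise ValueError(f"APA matrix must be {side}x{side}")

    @property
    def center(self) -> float:
        return float(self.matrix[self.flank, self.flank])

    @property
    def background(self) -> float:
        """Mean over the four corner quadrants of side max(1, flank // 2)."""
        q = max(1, self.flank // 2)
        m = self.matrix
        corners = np.concatenate(
            [
                m[:q, :q].ravel(), m[:q, -q:].ravel(),
                m[-q:, :q].ravel(), m[-q:, -q:].ravel(),
            ]
        )
        return float(corners.mean())

    def enrichment(self, epsilon: float = 1e-9) -> float:
        return self.center / max(self.background, epsilon)


def contact_lookup(contacts: Iterable[ContactRecord]) -> dict[tuple, float]:
    """Index aqua_cpm by (chrom, bin_index_a, bin_index_b), a <= b."""
    out: dict[tuple, float] = {}
    for c in contacts:
        if not c.is_cis:
            continue
        if c.aqua_cpm is None:
            raise ValueError("contacts must be normalized")
        bin_size = c.anchor_a.length()
        i, j = c.anchor_a.start // bin_size, c.anchor_b.start // bin_size
        if j < i:
            i, j = j, i
        out[(c.anchor_a.chrom, i, j)] = c.aqua_cpm
    return out


def apa(
    contacts: Iterable[ContactRecord] | Mapping[tuple, float],
    loops: Sequence,
    bin_size: int = 5000,
    flank: int = 10,
    chrom_sizes: Mapping[str, int] | None = None,
) -> APAMatrix:
    """Mean (2*flank+1)^2 submatrix of aqua_cpm centered on each loop.

    ``loops`` need anchor_a/anchor_b on one chromosome.  Loops whose window
    would cross a chromosome edge are skipped and counted.  Bins with no
    observed contact contribute 0.
    """
    lookup = contacts if isinstance(contacts, Mapping) else contact_lookup(contacts)
    side = 2 * flank + 1
    subs: list[np.ndarray] = []
    n_skipped = 0
    for loop in loops:
        a, b = loop.anchor_a, loop.anchor_b
        if a.chrom != b.chrom:
            n_skipped += 1
            continue
        ia, ib = a.start // bin_size, b.start // bin_size
        if ia > ib:
            ia, ib = ib, ia
        if ia - flank < 0:
            n_skipped += 1
            continue
        if chrom_sizes is not None:
            n_bins = chrom_sizes[a.chrom] // bin_size
            if ib + flank >= n_bins:
                n_skipped += 1
                continue
        sub = np.zeros((side, side))
        for r in range(side):
            for ccol in range(side):
                i, j = ia - flank + r, ib - flank + ccol
                key = (a.chrom, i, j) if i <= j else (a.chrom, j, i)
                sub[r, ccol] = lookup.get(key, 0.0)
        subs.append(sub)
    if not subs:
        raise ValueError("no usable loops for APA")
    # exactly-rounded per-cell mean: n identical submatrices average to
    # themselves (bitwise for power-of-two n, 1 ulp otherwise)
    stack = np.stack(subs).reshape(len(subs), -1)
    mean = np.array(
        [math.fsum(stack[:, k]) for k in range(stack.shape[1])]
    ).reshape(side, side) / len(subs)
    return APAMatrix(mean, bin_size, flank, len(subs), n_skipped)


def delta_apa(apa_trt: APAMatrix, apa_ctrl: APAMatrix) -> APAMatrix:
    """Element-wise treated - control APA on matching grids."""
    if apa_trt.bin_size != apa_ctrl.bin_size or apa_trt.flank != apa_ctrl.flank:
        raise ValueError("APA grids differ in bin size or flank")
    return APAMatrix(
        apa_trt.matrix - apa_ctrl.matrix,
        apa_trt.bin_size,
        apa_trt.flank,
        min(apa_trt.n_loops, apa_ctrl.n_loops),
    )
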