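"""Spike-in (AQuA) normalization of HiChIP valid pairs.

Pipeline: distance-filter pairs, count spike-in vs human pairs, bin human
pairs into bin-pair contacts, and scale raw counts by the spike-in total
to reference-reads-per-million (RRPM, here called aqua_cpm).
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable
from dataclasses import dataclass, replace

from .io_formats import HUMAN, SPIKEIN, CoverageTrack, GenomicInterval, ValidPair

__all__ = [
    "SpikeInStats",
    "ContactRecord",
    "FilterReport",
    "filter_pairs",
    "spikein_stats",
    "bin_contacts",
    "aqua_normalize",
    "anchor_signal",
    "delta_track",
]

DEFAULT_MIN_DISTANCE = 1000
DEFAULT_BIN_SIZE = 5000


@dataclass(frozen=True, slots=True)
class SpikeInStats:
    """Valid-pair totals driving normalization for one sample."""

    sample_id: str
    human_valid_pairs: int
    spikein_valid_pairs: int

    def __post_init__(self):
        if self.human_valid_pairs <= 0:
            raise ValueError("human valid-pair count must be positive")
        if self.spikein_valid_pairs <= 0:
            raise ValueError(
                "zero spike-in pairs: spike-in normalization is undefined"
            )

    @property
    def ratio(self) -> float:
        return self.spikein_valid_pairs / self.human_valid_pairs


@dataclass(frozen=True, slots=True)
class ContactRecord:
    """A binned contact between two anchors in canonical order."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    raw_count: int
    distance: int  # bp between bin midpoints; 0 for trans
    aqua_cpm: float | None = None

    @property
    def is_cis(self) -> bool:
        return self.anchor_a.chrom == self.anchor_b.chrom


@dataclass
class FilterReport:
    n_kept: int = 0
    n_removed_short: int = 0
    n_duplicates_dropped: int = 0


def filter_pairs(
    pairs: Iterable[ValidPair],
    min_distance: int = DEFAULT_MIN_DISTANCE,
    *,
    drop_duplicates: bool = False,
    report: FilterReport | None = None,
) -> list[ValidPair]:
    """Remove cis pairs with separation of ``min_distance`` bp or less.

    Trans pairs always pass.  PCR duplicates are retained by default because
    punctate pull-downs pile duplicates at true peaks; ``drop_duplicates``
    enables removal for non-punctate use.
    """
    kept: list[ValidPair] = []
    for p in pairs:
        if drop_duplicates and p.is_duplicate:
            if report:
                report.n_duplicates_dropped += 1
            continue
        if p.is_cis and p.distance <= min_distance:
            if report:
                report.n_removed_short += 1
            continue
        kept.append(p)
    if report:
        report.n_kept = len(kept)
    return kept


def spikein_stats(pairs: Iterable[ValidPair], sample_id: str = "sample") -> SpikeInStats:
    """Count human and spike-in pairs (expects already-filtered pairs)."""
    n_human = n_spike = 0
    for p in pairs:
        if p.genome_tag == SPIKEIN:
            n_spike += 1
        elif p.genome_tag == HUMAN:
            n_human += 1
        else:
            raise ValueError(f"unknown genome tag {p.genome_tag!r}")
    return SpikeInStats(sample_id, n_human, n_spike)


def _bin_interval(chrom: str, pos: int, bin_size: int) -> GenomicInterval:
    k = pos // bin_size
    return GenomicInterval(chrom, k * bin_size, (k + 1) * bin_size)


def bin_contacts(
    pairs: Iterable[ValidPair], bin_size: int = DEFAULT_BIN_SIZE
) -> list[ContactRecord]:
    """Aggregate human pairs into bin-pair contacts with raw counts.

    Each end is assigned to bin floor(pos / bin_size); the ordered bin pair
    is canonicalized so (chrom_a, start_a) <= (chrom_b, start_b).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    counts: Counter[tuple[str, int, str, int]] = Counter()
    for p in pairs:
        if p.genome_tag != HUMAN:
            continue
        ka, kb = p.pos_a // bin_size, p.pos_b // bin_size
        key = (p.chrom_a, ka, p.chrom_b, kb)
        if (p.chrom_b, kb) < (p.chrom_a, ka):
            key = (p.chrom_b, kb, p.chrom_a, ka)
        counts[key] += 1
    contacts = []
    for (ca, ka, cb, kb), n in sorted(counts.items()):
        a = GenomicInterval(ca, ka * bin_size, (ka + 1) * bin_size)
        b = GenomicInterval(cb, kb * bin_size, (kb + 1) * bin_size)
        dist = abs(b.midpoint() - a.midpoint()) if ca == cb else 0
        contacts.append(ContactRecord(a, b, n, dist))
    return contacts


def aqua_normalize(
    contacts: Iterable[ContactRecord], stats: SpikeInStats
) -> list[ContactRecord]:
    """Attach aqua_cpm = raw_count * 1e6 / spikein_valid_pairs to each contact.

    The spike-in denominator reflects a constant chromatin input across
    samples, so the scaled values are directly comparable between conditions.
    """
    scale = 1e6 / stats.spikein_valid_pairs
    return [replace(c, aqua_cpm=c.raw_count * scale) for c in contacts]


def anchor_signal(
    contacts: Iterable[ContactRecord], stats: SpikeInStats | None = None
) -> dict[GenomicInterval, float]:
    """1D per-anchor signal: sum of contact signal over all edges at an anchor.

    Uses aqua_cpm when present, otherwise raw counts scaled by ``stats``.
    """
    out: dict[GenomicInterval, float] = {}
    for c in contacts:
        if c.aqua_cpm is not None:
            v = c.aqua_cpm
        elif stats is not None:
            v = c.raw_count * 1e6 / stats.spikein_valid_pairs
        else:
            v = float(c.raw_count)
        out[c.anchor_a] = out.get(c.anchor_a, 0.0) + v
        if c.anchor_b != c.anchor_a:
            out[c.anchor_b] = out.get(c.anchor_b, 0.0) + v
    return out


def delta_track(treated: CoverageTrack, control: CoverageTrack) -> CoverageTrack:
    """Piecewise subtraction treated - control over union step boundaries.

    Resulting values may be negative; zero-valued spans where neither track
    has a step are omitted.
    """
    steps = []
    chroms = set(treated.chroms) | set(control.chroms)
    for chrom in sorted(chroms):
        bounds: set[int] = set()
        for track in (treated, control):
            for iv, _ in track.steps(chrom):
                bounds.add(iv.start)
                bounds.add(iv.end)
        cuts = sorted(bounds)
        for s, e in zip(cuts, cuts[1:]):
            vt = treated.value_at(chrom, s)
            vc = control.value_at(chrom, s)
            if vt != 0.0 or vc != 0.0:
                steps.append((GenomicInterval(chrom, s, e), vt - vc))
    # negative values are legal here (only bedGraph *input* must be >= 0)
    return CoverageTrack(steps)
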