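"""Readers and writers for the text formats the pipeline touches.

All internal coordinates are 0-based half-open.  allValidPairs positions are
1-based in the source files and converted on read; everything else (BED,
bedGraph, BEDPE) is already half-open and passes through unchanged.
"""

from __future__ import annotations

import bisect
import math
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = [
    "GenomicInterval",
    "BedRecord",
    "ValidPair",
    "GeneModel",
    "CoverageTrack",
    "GenomeTagRule",
    "PairReadReport",
    "ParseError",
    "read_valid_pairs",
    "write_valid_pairs",
    "read_bed",
    "write_bed",
    "read_genes",
    "read_bedgraph",
    "write_bedgraph",
    "write_bedpe",
    "read_bedpe",
    "write_tsv",
    "read_tsv",
]

HUMAN = "human"
SPIKEIN = "spikein"


class ParseError(ValueError):
    """Malformed line in an input file; carries path and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


@dataclass(frozen=True, order=True, slots=True)
class GenomicInterval:
    """A 0-based half-open genomic region [start, end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self}")

    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def distance_to_point(self, pos: int) -> int:
        """Distance from the interval to a point on the same chromosome.

        0 if the point is inside; otherwise the gap measured from the
        half-open boundary (point p >= end gives p - end).
        """
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end
        return 0

    def __str__(self) -> str:  # chr1:100-200
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True, slots=True)
class BedRecord:
    interval: GenomicInterval
    name: str | None = None
    score: float | None = None
    strand: str | None = None


@dataclass(frozen=True, slots=True)
class ValidPair:
    """One HiC-Pro valid pair, stored with 0-based positions in canonical order."""

    read_id: str
    genome_tag: str  # "human" | "spikein"
    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    is_duplicate: bool = False

    @property
    def is_cis(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def distance(self) -> int:
        """Genomic separation of the two ends; 0 for trans pairs."""
        return abs(self.pos_b - self.pos_a) if self.is_cis else 0

    def canonical(self) -> "ValidPair":
        if (self.chrom_a, self.pos_a) <= (self.chrom_b, self.pos_b):
            return self
        return replace(
            self,
            chrom_a=self.chrom_b,
            pos_a=self.pos_b,
            strand_a=self.strand_b,
            chrom_b=self.chrom_a,
            pos_b=self.pos_a,
            strand_b=self.strand_a,
        )


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene reduced to its transcript span.

    ``tss`` and ``tes`` are genome coordinates of the transcription start
    and end; for '-' strand genes tss > tes.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"'+' gene {self.gene_id} needs tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"'-' gene {self.gene_id} needs tss > tes")

    @property
    def length(self) -> int:
        return abs(self.tes - self.tss)

    @property
    def span(self) -> GenomicInterval:
        lo, hi = sorted((self.tss, self.tes))
        return GenomicInterval(self.chrom, lo, hi)


class CoverageTrack:
    """Sorted, non-overlapping (interval, value) steps per chromosome.

    bedGraph semantics: bases not covered by a step have value 0.
    """

    def __init__(self, steps: Iterable[tuple[GenomicInterval, float]] = ()):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, value in steps:
            if not math.isfinite(value):
                raise ValueError(f"non-finite value at {iv}")
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, float(value)))
        self._steps: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, items in per_chrom.items():
            items.sort()
            for (s1, e1, _), (s2, _, _) in zip(items, items[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping steps on {chrom}: [{s1},{e1}) and start {s2}"
                    )
            self._steps[chrom] = items

    @property
    def chroms(self) -> list[str]:
        return sorted(self._steps)

    def steps(self, chrom: str | None = None) -> Iterator[tuple[GenomicInterval, float]]:
        chroms = [chrom] if chrom is not None else self.chroms
        for c in chroms:
            for s, e, v in self._steps.get(c, []):
                yield GenomicInterval(c, s, e), v

    def signal(self, query: GenomicInterval) -> float:
        """Area under the track over ``query``: sum of value x overlap length."""
        items = self._steps.get(query.chrom, [])
        i = bisect.bisect_left(items, (query.start,)) if items else 0
        if i > 0 and items[i - 1][1] > query.start:
            i -= 1
        total = 0.0
        for s, e, v in items[i:]:
            if s >= query.end:
                break
            overlap = min(e, query.end) - max(s, query.start)
            if overlap > 0:
                total += v * overlap
        return total

    def value_at(self, chrom: str, pos: int) -> float:
        items = self._steps.get(chrom, [])
        if not items:
            return 0.0
        i = bisect.bisect_right(items, (pos, float("inf"), float("inf"))) - 1
        if i >= 0 and items[i][0] <= pos < items[i][1]:
            return items[i][2]
        return 0.0


@dataclass(frozen=True)
class GenomeTagRule:
    """Maps chromosome-name prefixes to a genome tag.

    The default treats mouse ("mm_") and Drosophila ("dm_") prefixes as
    spike-in and everything else as human.
    """

    spikein_prefixes: tuple[str, ...] = ("mm_", "dm_")

    def tag(self, chrom: str) -> str:
        for p in self.spikein_prefixes:
            if chrom.startswith(p):
                return SPIKEIN
        return HUMAN


@dataclass
class PairReadReport:
    """Counters accumulated while streaming an allValidPairs file."""

    n_yielded: int = 0
    n_malformed: int = 0
    n_mixed_genome: int = 0
    tag_counts: dict[str, int] = field(default_factory=dict)


def read_valid_pairs(
    path,
    tag_rule: GenomeTagRule | None = None,
    *,
    report: PairReadReport | None = None,
    on_malformed: str = "error",
) -> Iterator[ValidPair]:
    """Stream canonical ValidPairs from a HiC-Pro allValidPairs file.

    Columns: readID chr1 pos1 strand1 chr2 pos2 strand2 [ignored...].
    Positions are 1-based in the file and converted to 0-based.  Pairs whose
    two ends map to different genomes (human vs spike-in) are dropped and
    counted.  ``on_malformed`` is "error" (raise ParseError) or "drop".
    """
    tag_rule = tag_rule or GenomeTagRule()
    if on_malformed not in ("error", "drop"):
        raise ValueError("on_malformed must be 'error' or 'drop'")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                if on_malformed == "error":
                    raise ParseError(path, lineno, f"expected >= 7 fields, got {len(fields)}")
                if report:
                    report.n_malformed += 1
                continue
            read_id, c1, p1, s1, c2, p2, s2 = fields[:7]
            try:
                pos1, pos2 = int(p1) - 1, int(p2) - 1
            except ValueError:
                if on_malformed == "error":
                    raise ParseError(path, lineno, f"non-integer position: {p1!r}/{p2!r}")
                if report:
                    report.n_malformed += 1
                continue
            tag1, tag2 = tag_rule.tag(c1), tag_rule.tag(c2)
            if tag1 != tag2:
                if report:
                    report.n_mixed_genome += 1
                continue
            pair = ValidPair(read_id, tag1, c1, pos1, s1, c2, pos2, s2).canonical()
            if report:
                report.n_yielded += 1
                report.tag_counts[tag1] = report.tag_counts.get(tag1, 0) + 1
            yield pair


def write_valid_pairs(pairs: Iterable[ValidPair], path) -> int:
    """Write pairs in allValidPairs dialect (positions back to 1-based)."""
    n = 0
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                f"{p.read_id}\t{p.chrom_a}\t{p.pos_a + 1}\t{p.strand_a}"
                f"\t{p.chrom_b}\t{p.pos_b + 1}\t{p.strand_b}\n"
            )
            n += 1
    return n


def read_bed(path) -> list[BedRecord]:
    """Read BED3/BED6 into sorted records; rejects inverted intervals."""
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "expected >= 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if end <= start or start < 0:
                raise ParseError(path, lineno, f"invalid interval [{start},{end})")
            name = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(path, lineno, f"non-numeric score {fields[4]!r}") from None
            strand = fields[5] if len(fields) > 5 else None
            records.append(
                BedRecord(GenomicInterval(fields[0], start, end), name, score, strand)
            )
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
    return records


def write_bed(records: Iterable[BedRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [r.interval.chrom, str(r.interval.start), str(r.interval.end)]
            if r.name is not None or r.score is not None or r.strand is not None:
                cols.append(r.name if r.name is not None else ".")
            if r.score is not None or r.strand is not None:
                cols.append(format_number(r.score) if r.score is not None else ".")
            if r.strand is not None:
                cols.append(r.strand)
            fh.write("\t".join(cols) + "\n")


def read_genes(path) -> list[GeneModel]:
    """Read gene models from a 5-column TSV or BED12.

    TSV dialect: gene_id chrom strand start end (start < end, half-open span);
    BED12 is detected by >= 12 columns with chrom in column 1.  Exon structure
    is ignored: only the transcript span defines TSS/TES.  For '-' strand the
    TSS is the span end and the TES the span start.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 12 and fields[5] in ("+", "-"):
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                gene_id, strand = fields[3], fields[5]
            elif len(fields) >= 5:
                gene_id, chrom, strand = fields[0], fields[1], fields[2]
                try:
                    start, end = int(fields[3]), int(fields[4])
                except ValueError:
                    raise ParseError(path, lineno, "non-integer gene coordinates") from None
            else:
                raise ParseError(path, lineno, "expected 5-column TSV or BED12")
            if start == end:
                raise ParseError(path, lineno, f"zero-length gene {gene_id}")
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"unknown strand {strand!r}")
            if strand == "+":
                tss, tes = start, end
            else:
                tss, tes = end, start
            genes.append(GeneModel(gene_id, chrom, strand, tss, tes))
    return genes


def read_bedgraph(path) -> CoverageTrack:
    """Read a 4-column bedGraph; overlapping steps or negative values fail."""
    steps: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(path, lineno, "expected 4 fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise ParseError(path, lineno, "malformed bedGraph line") from None
            if value < 0:
                raise ParseError(path, lineno, f"negative value {value}")
            if end <= start:
                raise ParseError(path, lineno, f"invalid step [{start},{end})")
            steps.append((GenomicInterval(fields[0], start, end), value))
    try:
        return CoverageTrack(steps)
    except ValueError as exc:
        raise ParseError(path, 0, str(exc)) from None


def format_number(x: float) -> str:
    """Render a float compactly, keeping integers integral (round-trip safe)."""
    if isinstance(x, int) or (math.isfinite(x) and float(x).is_integer()):
        return str(int(x))
    return repr(float(x))


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for iv, v in track.steps():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{format_number(v)}\n")


def write_bedpe(records, path, extra_columns: Iterable[str] = ()) -> None:
    """Write anchored records as BEDPE, sorted by anchor coordinates.

    Each record must expose ``anchor_a``/``anchor_b`` GenomicIntervals; extra
    columns are pulled from attributes of the same name.
    """
    extra_columns = list(extra_columns)
    header = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"] + extra_columns
    records = sorted(
        records,
        key=lambda r: (
            r.anchor_a.chrom, r.anchor_a.start, r.anchor_b.chrom, r.anchor_b.start,
        ),
    )
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for r in records:
            a, b = r.anchor_a, r.anchor_b
            cols = [a.chrom, str(a.start), str(a.end), b.chrom, str(b.start), str(b.end)]
            for name in extra_columns:
                val = getattr(r, name)
                cols.append(format_number(val) if isinstance(val, float) else str(val))
            fh.write("\t".join(cols) + "\n")


def read_bedpe(path) -> list[dict]:
    """Read a BEDPE written by :func:`write_bedpe` back into dicts."""
    rows: list[dict] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first:
            return rows
        if not first.startswith("#"):
            raise ParseError(path, 1, "missing BEDPE header")
        header = first[1:].split("\t")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(path, lineno, "column count mismatch")
            row = dict(zip(header, fields))
            row["anchor_a"] = GenomicInterval(
                row.pop("chrom_a"), int(row.pop("start_a")), int(row.pop("end_a"))
            )
            row["anchor_b"] = GenomicInterval(
                row.pop("chrom_b"), int(row.pop("start_b")), int(row.pop("end_b"))
            )
            rows.append(row)
    return rows


def write_tsv(table, path) -> None:
    """Write a pandas DataFrame as plain TSV (no index)."""
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
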