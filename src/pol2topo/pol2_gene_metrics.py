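"""Gene-level Pol2 metrics from coverage tracks.

Each gene is split into four windows measured from the TSS/TES in the
direction of transcription:

    promoter  [-800, -30)   from the TSS
    TSSR      [-30, +300)   from the TSS (pause region)
    body      [+300, TES)
    TESR      [TES, TES+4000)

Traveling ratio TR = TSSR / body.  UnLoading ratio PULR = everything before
the TES (promoter + TSSR + body by default) over the TESR.  Signals are
areas (coverage x bp); both ratios are invariant to global coverage scaling.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

from .io_formats import CoverageTrack, GeneModel, GenomicInterval

__all__ = [
    "GeneRegions",
    "GeneMetrics",
    "gene_regions",
    "region_signals",
    "traveling_ratio",
    "pulr",
    "gene_metrics",
    "gene_metrics_table",
    "compare_metrics",
    "decile_rank_join",
]

PROMOTER_UP = 800
PROMOTER_DOWN = 30  # promoter ends 30 bp upstream of the TSS
TSSR_DOWN = 300
TESR_LEN = 4000
MIN_BODY_GENE_LENGTH = TSSR_DOWN  # body empty unless gene length > 300

PULR_NUMERATOR_PRE_TES = "pre_tes"
PULR_NUMERATOR_PROMOTER_TSSR = "promoter_tssr_only"


@dataclass(frozen=True, slots=True)
class GeneRegions:
    gene_id: str
    promoter: GenomicInterval
    tssr: GenomicInterval
    body: GenomicInterval
    tesr: GenomicInterval
    clipped: bool = False


@dataclass(frozen=True, slots=True)
class GeneMetrics:
    gene_id: str
    signal_promoter: float
    signal_tssr: float
    signal_body: float
    signal_tesr: float
    tr: float  # nan when body signal is 0
    pulr: float  # nan when TESR signal is 0


def gene_regions(gene: GeneModel, chrom_length: int | None = None) -> GeneRegions:
    """Derive the four windows for a gene; strand-mirrored for '-'.

    The '-' strand windows are the exact base-level reflection of the '+'
    windows, so every base is assigned to exactly one window and region
    lengths match the '+' case.  Regions are clipped at [0, chrom_length)
    with a flag.  Genes of length <= 300 bp have an empty body and no
    defined metrics.
    """
    if gene.length <= MIN_BODY_GENE_LENGTH:
        raise ValueError(
            f"gene {gene.gene_id} has length {gene.length} <= {MIN_BODY_GENE_LENGTH}; "
            "body region is empty and TR/PULR are undefined"
        )
    t, e = gene.tss, gene.tes
    if gene.strand == "+":
        windows = [
            (t - PROMOTER_UP, t - PROMOTER_DOWN),
            (t - PROMOTER_DOWN, t + TSSR_DOWN),
            (t + TSSR_DOWN, e),
            (e, e + TESR_LEN),
        ]
    else:
        # reflection of the '+' layout: base at offset d downstream of the
        # TSS maps to genomic position tss - d
        windows = [
            (t + PROMOTER_DOWN + 1, t + PROMOTER_UP + 1),
            (t - TSSR_DOWN + 1, t + PROMOTER_DOWN + 1),
            (e + 1, t - TSSR_DOWN + 1),
            (e - TESR_LEN + 1, e + 1),
        ]
    clipped = False
    out = []
    for s, w_end in windows:
        cs = max(s, 0)
        ce = w_end if chrom_length is None else min(w_end, chrom_length)
        if (cs, ce) != (s, w_end):
            clipped = True
        if ce <= cs:
            raise ValueError(
                f"gene {gene.gene_id}: window [{s},{w_end}) vanishes after clipping"
            )
        out.append(GenomicInterval(gene.chrom, cs, ce))
    return GeneRegions(gene.gene_id, *out, clipped=clipped)


def region_signals(coverage: CoverageTrack, regions: GeneRegions) -> tuple[float, float, float, float]:
    return (
        coverage.signal(regions.promoter),
        coverage.signal(regions.tssr),
        coverage.signal(regions.body),
        coverage.signal(regions.tesr),
    )


def traveling_ratio(coverage: CoverageTrack, gene: GeneModel) -> float:
    """TSSR signal over gene-body signal; nan when the body is silent."""
    regions = gene_regions(gene)
    s_tssr = coverage.signal(regions.tssr)
    s_body = coverage.signal(regions.body)
    return s_tssr / s_body if s_body > 0 else math.nan


def pulr(
    coverage: CoverageTrack,
    gene: GeneModel,
    numerator: str = PULR_NUMERATOR_PRE_TES,
) -> float:
    """Pol2 UnLoading Ratio: pre-TES signal over TESR signal.

    ``numerator`` selects the pre-TES definition: "pre_tes" sums promoter,
    TSSR and body; "promoter_tssr_only" omits the body.  nan when the TESR
    is silent.
    """
    regions = gene_regions(gene)
    sp, st, sb, ste = region_signals(coverage, regions)
    if ste <= 0:
        return math.nan
    if numerator == PULR_NUMERATOR_PRE_TES:
        return (sp + st + sb) / ste
    if numerator == PULR_NUMERATOR_PROMOTER_TSSR:
        return (sp + st) / ste
    raise ValueError(f"unknown PULR numerator mode {numerator!r}")


def gene_metrics(
    coverage: CoverageTrack,
    gene: GeneModel,
    numerator: str = PULR_NUMERATOR_PRE_TES,
    chrom_length: int | None = None,
) -> GeneMetrics:
    regions = gene_regions(gene, chrom_length)
    sp, st, sb, ste = region_signals(coverage, regions)
    tr = st / sb if sb > 0 else math.nan
    if ste > 0:
        num = sp + st + sb if numerator == PULR_NUMERATOR_PRE_TES else sp + st
        p = num / ste
    else:
        p = math.nan
    return GeneMetrics(gene.gene_id, sp, st, sb, ste, tr, p)


def gene_metrics_table(
    coverage: CoverageTrack,
    genes: Sequence[GeneModel],
    numerator: str = PULR_NUMERATOR_PRE_TES,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    cols = ["gene_id", "signal_promoter", "signal_tssr", "signal_body",
            "signal_tesr", "tr", "pulr"]
    rows = []
    for g in genes:
        if g.length <= MIN_BODY_GENE_LENGTH:
            continue  # empty body: metrics undefined, gene excluded
        cl = chrom_sizes.get(g.chrom) if chrom_sizes else None
        m = gene_metrics(coverage, g, numerator, cl)
        rows.append({c: getattr(m, c) for c in cols})
    return pd.DataFrame(rows, columns=cols)


def compare_metrics(
    metrics_ctrl: pd.DataFrame, metrics_trt: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene treated/control ratios of PULR and TR over the shared universe.

    Genes missing from either condition (or with undefined metrics) are
    excluded; the count of exclusions is in ``df.attrs['n_excluded']``.
    """
    merged = metrics_ctrl.merge(
        metrics_trt, on="gene_id", suffixes=("_ctrl", "_trt"), how="outer",
        indicator=True,
    )
    n_total = len(merged)
    both = merged[merged["_merge"] == "both"].drop(columns="_merge").copy()
    both["pulr_ratio"] = both["pulr_trt"] / both["pulr_ctrl"]
    both["tr_ratio"] = both["tr_trt"] / both["tr_ctrl"]
    ok = both.dropna(subset=["pulr_ratio", "tr_ratio"]).reset_index(drop=True)
    ok.attrs["n_excluded"] = n_total - len(ok)
    return ok


def decile_rank_join(
    gene_signal: pd.DataFrame, expression_l2fc: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign signal deciles (10 = highest) and summarize expression L2FC.

    ``gene_signal`` needs columns (gene_id, signal); ``expression_l2fc``
    needs (gene_id, l2fc).  Ties are broken deterministically by gene_id so
    equal signals still yield a reproducible decile assignment.  Returns the
    joined per-gene table and a per-decile median/quartile summary.  A
    gene-id overlap below 50% triggers a warning.
    """
    import warnings

    joined = gene_signal.merge(expression_l2fc, on="gene_id", how="inner")
    overlap = len(joined) / max(len(gene_signal), 1)
    if overlap < 0.5:
        warnings.warn(
            f"only {overlap:.0%} of signal genes have an expression L2FC",
            stacklevel=2,
        )
    joined = joined.sort_values(["signal", "gene_id"]).reset_index(drop=True)
    n = len(joined)
    # rank-based deciles: gene at rank r (1-based) gets ceil(10*r/n)
    joined["decile"] = [max(1, math.ceil(10 * (i + 1) / n)) for i in range(n)]
    summary = (
        joined.groupby("decile")["l2fc"]
        .agg(n="size", median="median", q1=lambda s: s.quantile(0.25),
             q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return joined, summary
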