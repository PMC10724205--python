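"""Synthetic miniature genome, HiChIP valid pairs and Pol2 coverage.

The generator plants a known architecture — multi-loop clusters hubbed on
gene promoters with enhancer and CpG-promoter satellites, a distance-decaying
contact background, a fixed spike-in chromatin fraction, and a
condition-dependent "collapse" (distal P3F contact depletion, CpG-promoter
contact gain, TESR coverage depletion) — and emits ground-truth tables that
the pipeline under test never reads.

Spike-in pairs are emitted in proportion to the *input* chromatin (the
condition-independent expected human pair total), mirroring how a fixed
chromatin ratio behaves when a treatment removes contacts: the treated
sample then shows a higher spike-in fraction, which is exactly the signal
AQuA normalization exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    BedRecord,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    ValidPair,
    write_bed,
    write_bedgraph,
    write_tsv,
    write_valid_pairs,
)
from .pol2_gene_metrics import MIN_BODY_GENE_LENGTH, gene_regions

__all__ = [
    "SyntheticGenomeConfig",
    "ArchitectureConfig",
    "SyntheticGenome",
    "ContactSimulation",
    "CoverageSimulation",
    "generate_genome",
    "generate_contacts",
    "generate_coverage",
    "CONTROL",
    "TREATED",
]

CONTROL = "control"
TREATED = "treated"
_CONDITION_INDEX = {CONTROL: 0, TREATED: 1}

SPIKEIN_CHROM = "mm_chr1"
SPIKEIN_CHROM_LENGTH = 10_000_000


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    n_chroms: int = 2
    chrom_length: int = 4_000_000
    n_genes: int = 60
    fraction_cpg_promoters: float = 0.5
    n_enhancer_peaks: int = 120  # p300 peaks; P3F on a fraction of them
    p3f_fraction: float = 0.6
    min_gene_length: int = 2_000
    max_gene_length: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction_cpg_promoters <= 1.0:
            raise ValueError("fraction_cpg_promoters must be in [0, 1]")
        if not 0.0 <= self.p3f_fraction <= 1.0:
            raise ValueError("p3f_fraction must be in [0, 1]")
        if self.min_gene_length <= MIN_BODY_GENE_LENGTH:
            raise ValueError("genes must be longer than the TSSR offset")


@dataclass(frozen=True)
class ArchitectureConfig:
    n_clusters: int = 20
    loops_per_cluster_mean: float = 7.7
    cluster_span_mean: int = 75_000
    anchor_bin: int = 5_000
    contact_rate: float = 50.0  # expected raw pairs per planted contact
    background_rate: float = 0.0  # expected background pairs genome-wide
    distance_decay_exponent: float = 1.0
    spikein_fraction: float = 0.1
    collapse_distal_factor: float = 1.0  # gamma_d, applied to treated distal-P3F loops
    collapse_cpg_gain_factor: float = 1.0  # gamma_c, treated CpG-TSS x CpG-TSS loops
    tesr_depletion_factor: float = 1.0  # gamma_t, treated TESR coverage
    tssr_gain_factor: float = 1.0  # treated TSSR coverage multiplier
    cpg_loop_fraction: float = 0.3  # loops of a CpG hub that target another CpG TSS
    promoter_level: float = 1.0
    tssr_level: float = 4.0
    body_level: float = 1.0
    tesr_level: float = 1.0
    coverage_noise_depth: float | None = None  # Poisson read depth; None = noiseless
    coverage_noise_step: int = 10  # bp granularity of the noise
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.collapse_distal_factor <= 1.0:
            raise ValueError("collapse_distal_factor must be in (0, 1]")
        if self.collapse_cpg_gain_factor < 1.0:
            raise ValueError("collapse_cpg_gain_factor must be >= 1")
        if not 0.0 < self.tesr_depletion_factor:
            raise ValueError("tesr_depletion_factor must be > 0")
        if self.contact_rate <= 0 or self.anchor_bin <= 0:
            raise ValueError("contact_rate and anchor_bin must be positive")
        if self.loops_per_cluster_mean < 2:
            raise ValueError("clusters need >= 2 loops on average")


@dataclass
class SyntheticGenome:
    config: SyntheticGenomeConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    cpg_islands: list[BedRecord]
    p3f_peaks: list[BedRecord]
    p300_peaks: list[BedRecord]
    enhancer_anchors: list[dict]  # chrom, position, has_p3f, peak intervals
    cpg_gene_ids: set[str]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "chrom_sizes.tsv", "w") as fh:
            for chrom in sorted(self.chrom_sizes):
                fh.write(f"{chrom}\t{self.chrom_sizes[chrom]}\n")
        rows = [
            f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{min(g.tss, g.tes)}\t{max(g.tss, g.tes)}"
            for g in self.genes
        ]
        (outdir / "genes.tsv").write_text("\n".join(rows) + ("\n" if rows else ""))
        write_bed(self.cpg_islands, outdir / "cpg_islands.bed")
        write_bed(self.p3f_peaks, outdir / "p3f_peaks.bed")
        write_bed(self.p300_peaks, outdir / "p300_peaks.bed")


def generate_genome(config: SyntheticGenomeConfig) -> SyntheticGenome:
    """Place non-overlapping genes and enhancer peaks into per-chromosome slots.

    Each gene or enhancer owns one slot, so annotations never overlap and
    every enhancer is well separated (> 5 kb) from every TSS.  CpG islands of
    500-2000 bp are centered on the TSS of a fixed-size subset of promoters.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    margin = 50_000
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_sizes = {c: config.chrom_length for c in chroms}

    # round-robin allocation of genes and enhancers to chromosomes
    genes_per = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        genes_per[i] += 1
    enh_per = [config.n_enhancer_peaks // config.n_chroms] * config.n_chroms
    for i in range(config.n_enhancer_peaks % config.n_chroms):
        enh_per[i] += 1

    min_slot = config.max_gene_length + 800 + 4000 + 4_000
    genes: list[GeneModel] = []
    enhancer_anchors: list[dict] = []
    p3f_peaks: list[BedRecord] = []
    p300_peaks: list[BedRecord] = []

    gene_idx = enh_idx = 0
    for ci, chrom in enumerate(chroms):
        n_slots = genes_per[ci] + enh_per[ci]
        if n_slots == 0:
            continue
        slot_len = (config.chrom_length - 2 * margin) // n_slots
        if slot_len < min_slot:
            raise ValueError(
                f"chromosome length {config.chrom_length} too small for "
                f"{n_slots} slots of >= {min_slot} bp"
            )
        slot_types = np.array(["gene"] * genes_per[ci] + ["enh"] * enh_per[ci])
        slot_types = rng.permutation(slot_types)
        for si, slot_type in enumerate(slot_types):
            center = margin + si * slot_len + slot_len // 2
            if slot_type == "gene":
                gene_idx += 1
                length = int(rng.integers(config.min_gene_length, config.max_gene_length + 1))
                start = center - length // 2 + int(rng.integers(-500, 501))
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    tss, tes = start, start + length
                else:
                    tss, tes = start + length, start
                genes.append(GeneModel(f"g{gene_idx:04d}", chrom, strand, tss, tes))
            else:
                enh_idx += 1
                width = int(rng.integers(400, 1001))
                pos = center + int(rng.integers(-1000, 1001))
                p300 = GenomicInterval(chrom, pos - width // 2, pos - width // 2 + width)
                enhancer_anchors.append(
                    dict(enh_id=f"e{enh_idx:04d}", chrom=chrom, position=pos, p300=p300)
                )

    # P3F on a fixed-size subset of enhancers, always inside the p300 peak
    n_p3f = round(config.p3f_fraction * len(enhancer_anchors))
    p3f_chosen = set(
        rng.choice(len(enhancer_anchors), size=n_p3f, replace=False).tolist()
        if n_p3f
        else []
    )
    for i, enh in enumerate(enhancer_anchors):
        enh["has_p3f"] = i in p3f_chosen
        p300_peaks.append(BedRecord(enh["p300"], name=enh["enh_id"]))
        if enh["has_p3f"]:
            w = int(rng.integers(150, 301))
            s = enh["position"] - w // 2
            p3f = GenomicInterval(enh["chrom"], s, s + w)
            enh["p3f"] = p3f
            p3f_peaks.append(BedRecord(p3f, name=enh["enh_id"]))

    n_cpg = round(config.fraction_cpg_promoters * len(genes))
    cpg_idx = set(
        rng.choice(len(genes), size=n_cpg, replace=False).tolist() if n_cpg else []
    )
    cpg_islands: list[BedRecord] = []
    cpg_gene_ids: set[str] = set()
    for i in sorted(cpg_idx):
        g = genes[i]
        width = int(rng.integers(500, 2001))
        start = max(0, g.tss - width // 2)
        cpg_islands.append(BedRecord(GenomicInterval(g.chrom, start, start + width), name=g.gene_id))
        cpg_gene_ids.add(g.gene_id)

    return SyntheticGenome(
        config=config,
        chrom_sizes=chrom_sizes,
        genes=genes,
        cpg_islands=sorted(cpg_islands, key=lambda r: (r.interval.chrom, r.interval.start)),
        p3f_peaks=sorted(p3f_peaks, key=lambda r: (r.interval.chrom, r.interval.start)),
        p300_peaks=sorted(p300_peaks, key=lambda r: (r.interval.chrom, r.interval.start)),
        enhancer_anchors=enhancer_anchors,
        cpg_gene_ids=cpg_gene_ids,
    )


# planted loop categories (match annotation.loop_category scheme="collapse")
CAT_DISTAL_P3F = "distalP3F"
CAT_CPG_CPG = "cpgTSSxcpgTSS"
CAT_OTHER = "other"


@dataclass
class ContactSimulation:
    condition: str
    pairs: list[ValidPair]
    truth_clusters: pd.DataFrame
    truth_loops: pd.DataFrame
    n_human_pairs: int
    n_spikein_pairs: int
    n_background_pairs: int

    def write(self, outdir, prefix: str | None = None) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.condition
        path = outdir / f"{prefix}.allValidPairs"
        write_valid_pairs(self.pairs, path)
        write_tsv(self.truth_clusters, outdir / f"{prefix}.truth_clusters.tsv")
        write_tsv(self.truth_loops, outdir / f"{prefix}.truth_loops.tsv")
        return path


def _plan_architecture(
    genome: SyntheticGenome, arch: ArchitectureConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic cluster plan shared by both conditions.

    Clusters are hub-and-spoke: a hub gene TSS bin connected to satellite
    anchors (enhancers, or other CpG-gene promoters when the hub promoter
    is CpG).  All anchor bins are globally unique, so the planted clusters
    are disjoint connected components by construction.
    """
    B = arch.anchor_bin
    rng = np.random.default_rng([arch.seed, 917])
    genes_by_id = {g.gene_id: g for g in genome.genes}
    window = 5_000  # proximal window used by downstream annotation

    def tss_bin(g: GeneModel) -> tuple[str, int]:
        return (g.chrom, g.tss // B)

    used_bins: set[tuple[str, int]] = set()
    used_genes: set[str] = set()
    used_enh: set[str] = set()

    # enhancer anchors that are safely distal from every TSS
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genome.genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    enh_pool = []
    for enh in genome.enhancer_anchors:
        k = enh["position"] // B
        anchor = GenomicInterval(enh["chrom"], k * B, (k + 1) * B)
        if any(anchor.distance_to_point(t) <= window for t in tss_by_chrom.get(enh["chrom"], [])):
            continue
        enh_pool.append(dict(enh, bin=(enh["chrom"], k)))

    hub_order = rng.permutation(len(genome.genes))
    loop_rows, cluster_rows = [], []
    loop_id = 0
    n_planted = 0
    for gi in hub_order:
        if n_planted >= arch.n_clusters:
            break
        hub = genome.genes[gi]
        if hub.gene_id in used_genes or tss_bin(hub) in used_bins:
            continue
        hub_cpg = hub.gene_id in genome.cpg_gene_ids
        n_loops = max(2, int(rng.poisson(arch.loops_per_cluster_mean)))

        # candidate satellites, nearest-first from the hub
        enh_cands = sorted(
            (e for e in enh_pool
             if e["enh_id"] not in used_enh and e["chrom"] == hub.chrom
             and e["bin"] not in used_bins and e["bin"] != tss_bin(hub)),
            key=lambda e: abs(e["position"] - hub.tss),
        )
        cpg_cands = sorted(
            (genes_by_id[gid] for gid in genome.cpg_gene_ids
             if gid not in used_genes and gid != hub.gene_id
             and genes_by_id[gid].chrom == hub.chrom
             and tss_bin(genes_by_id[gid]) not in used_bins),
            key=lambda g: abs(g.tss - hub.tss),
        ) if hub_cpg else []

        satellites = []
        taken_bins = {tss_bin(hub)}
        ei = ci = 0
        for _ in range(n_loops):
            want_cpg = hub_cpg and rng.random() < arch.cpg_loop_fraction
            sat = None
            if want_cpg:
                while ci < len(cpg_cands) and tss_bin(cpg_cands[ci]) in taken_bins:
                    ci += 1
                if ci < len(cpg_cands):
                    g = cpg_cands[ci]
                    ci += 1
                    sat = dict(kind="cpg_gene", ref=g.gene_id, bin=tss_bin(g))
            if sat is None:
                while ei < len(enh_cands) and enh_cands[ei]["bin"] in taken_bins:
                    ei += 1
                if ei < len(enh_cands):
                    e = enh_cands[ei]
                    ei += 1
                    sat = dict(kind="enhancer", ref=e["enh_id"], bin=e["bin"],
                               has_p3f=e["has_p3f"])
            if sat is None:
                break  # no satellites left on this chromosome
            taken_bins.add(sat["bin"])
            satellites.append(sat)

        if len(satellites) < 2:
            continue  # cannot form a planted cluster here
        n_planted += 1
        cluster_id = f"C{n_planted:03d}"
        used_genes.add(hub.gene_id)
        used_bins.update(taken_bins)
        anchors = [tss_bin(hub)] + [s["bin"] for s in satellites]
        for s in satellites:
            loop_id += 1
            if s["kind"] == "cpg_gene":
                category = CAT_CPG_CPG
                used_genes.add(s["ref"])
            else:
                category = CAT_DISTAL_P3F if s["has_p3f"] else CAT_OTHER
                used_enh.add(s["ref"])
            lam = arch.contact_rate
            mod_treated = 1.0
            if category == CAT_DISTAL_P3F:
                mod_treated = arch.collapse_distal_factor
            elif category == CAT_CPG_CPG:
                mod_treated = arch.collapse_cpg_gain_factor
            hub_bin = tss_bin(hub)
            loop_rows.append(
                dict(
                    loop_id=f"L{loop_id:04d}",
                    cluster_id=cluster_id,
                    chrom=hub.chrom,
                    bin_a=min(hub_bin[1], s["bin"][1]),
                    bin_b=max(hub_bin[1], s["bin"][1]),
                    satellite_kind=s["kind"],
                    satellite_ref=s["ref"],
                    category=category,
                    lam_control=lam,
                    lam_treated=lam * mod_treated,
                )
            )
        cluster_rows.append(
            dict(
                cluster_id=cluster_id,
                hub_gene=hub.gene_id,
                hub_cpg=hub_cpg,
                chrom=hub.chrom,
                n_loops=len(satellites),
                anchor_bins=";".join(f"{c}:{k}" for c, k in sorted(anchors)),
            )
        )

    if n_planted < arch.n_clusters:
        raise ValueError(
            f"could only plant {n_planted}/{arch.n_clusters} clusters; "
            "increase n_genes/n_enhancer_peaks or chromosome length"
        )
    return pd.DataFrame(cluster_rows), pd.DataFrame(loop_rows)


def generate_contacts(
    genome: SyntheticGenome, arch: ArchitectureConfig, condition: str
) -> ContactSimulation:
    """Emit valid pairs for one condition plus the ground-truth tables.

    Planted loop counts are Poisson(lambda x modifier), where the modifier is
    the collapse factor for treated distal-P3F loops, the CpG gain factor for
    treated CpG-TSS pairs, and 1 otherwise.  Background pairs connect random
    bins with P(distance) ~ distance^-alpha.  The expected spike-in total is
    spikein_fraction x (expected unmodified human total), i.e. proportional
    to input chromatin and shared across conditions.
    """
    if condition not in _CONDITION_INDEX:
        raise ValueError(f"condition must be one of {sorted(_CONDITION_INDEX)}")
    clusters, loops = _plan_architecture(genome, arch)
    if len(clusters) == 0:
        import warnings

        warnings.warn("no planted clusters; recovery tests will be vacuous", stacklevel=2)
    rng = np.random.default_rng([arch.seed, 31, _CONDITION_INDEX[condition]])
    B = arch.anchor_bin
    lam_col = f"lam_{condition}"
    pairs: list[ValidPair] = []
    n = 0

    def emit(chrom, bin_a, bin_b, count):
        nonlocal n
        for _ in range(count):
            while True:
                pa = int(bin_a * B + rng.integers(0, B))
                pb = int(bin_b * B + rng.integers(0, B))
                if abs(pb - pa) > 1000:  # must survive the MNase distance filter
                    break
            n += 1
            pairs.append(
                ValidPair(
                    f"sim{condition[0]}{n:07d}", "human",
                    chrom, pa, "+", chrom, pb, "-",
                ).canonical()
            )

    for row in loops.itertuples():
        count = int(rng.poisson(getattr(row, lam_col)))
        emit(row.chrom, row.bin_a, row.bin_b, count)
    n_planted_pairs = len(pairs)

    # distance-decaying background
    n_bg = int(rng.poisson(arch.background_rate)) if arch.background_rate > 0 else 0
    chroms = sorted(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    for _ in range(n_bg):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        n_bins = genome.chrom_sizes[chrom] // B
        # inverse-CDF sample of d^-alpha on [2, n_bins/2] bins
        lo, hi = 2, max(3, n_bins // 2)
        a = arch.distance_decay_exponent
        u = rng.random()
        if abs(a - 1.0) < 1e-12:
            d = int(lo * (hi / lo) ** u)
        else:
            d = int((lo ** (1 - a) + u * (hi ** (1 - a) - lo ** (1 - a))) ** (1 / (1 - a)))
        i = int(rng.integers(0, n_bins - d))
        emit(chrom, i, i + d, 1)
    n_background = len(pairs) - n_planted_pairs

    # spike-in on mock mouse chromosome, proportional to input chromatin
    expected_human = float(loops["lam_control"].sum()) + arch.background_rate
    n_spike = int(rng.poisson(arch.spikein_fraction * expected_human))
    for _ in range(n_spike):
        pa = int(rng.integers(0, SPIKEIN_CHROM_LENGTH - 200_000))
        pb = pa + int(rng.integers(5_000, 200_000))
        n += 1
        pairs.append(
            ValidPair(
                f"sim{condition[0]}{n:07d}", "spikein",
                SPIKEIN_CHROM, pa, "+", SPIKEIN_CHROM, pb, "-",
            )
        )

    return ContactSimulation(
        condition=condition,
        pairs=pairs,
        truth_clusters=clusters,
        truth_loops=loops,
        n_human_pairs=n_planted_pairs + n_background,
        n_spikein_pairs=n_spike,
        n_background_pairs=n_background,
    )


@dataclass
class CoverageSimulation:
    condition: str
    track: CoverageTrack
    truth: pd.DataFrame

    def write(self, outdir, prefix: str | None = None) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.condition
        path = outdir / f"{prefix}.pol2_coverage.bedGraph"
        write_bedgraph(self.track, path)
        write_tsv(self.truth, outdir / f"{prefix}.truth_coverage.tsv")
        return path


def generate_coverage(
    genome: SyntheticGenome, arch: ArchitectureConfig, condition: str
) -> CoverageSimulation:
    """Piecewise-constant Pol2 coverage per gene, with planted PULR shifts.

    Levels: promoter p, TSSR s, body b, TESR t.  The treated condition
    multiplies t by the TESR depletion factor and s by the TSSR gain factor,
    so the planted PULR(treated)/PULR(control) ratio is analytically known
    and recorded in the truth table.  Overlapping gene regions are summed
    and flagged.  Optional Poisson noise simulates finite read depth at
    ``coverage_noise_step`` bp resolution.
    """
    if condition not in _CONDITION_INDEX:
        raise ValueError(f"condition must be one of {sorted(_CONDITION_INDEX)}")
    rng = np.random.default_rng([arch.seed, 57, _CONDITION_INDEX[condition]])
    treated = condition == TREATED
    s_level = arch.tssr_level * (arch.tssr_gain_factor if treated else 1.0)
    t_level = arch.tesr_level * (arch.tesr_depletion_factor if treated else 1.0)

    spans: dict[str, list[tuple[int, int, float]]] = {}
    truth_rows = []
    for g in genome.genes:
        if g.length <= MIN_BODY_GENE_LENGTH:
            continue
        regions = gene_regions(g, genome.chrom_sizes[g.chrom])
        levels = {
            "promoter": arch.promoter_level,
            "tssr": s_level,
            "body": arch.body_level,
            "tesr": t_level,
        }
        areas = {}
        for name, level in levels.items():
            iv: GenomicInterval = getattr(regions, name)
            spans.setdefault(g.chrom, []).append((iv.start, iv.end, level))
            areas[name] = level * iv.length()
        pre_tes = areas["promoter"] + areas["tssr"] + areas["body"]
        truth_rows.append(
            dict(
                gene_id=g.gene_id,
                condition=condition,
                level_promoter=levels["promoter"],
                level_tssr=levels["tssr"],
                level_body=levels["body"],
                level_tesr=levels["tesr"],
                pulr_planted=pre_tes / areas["tesr"],
                tr_planted=areas["tssr"] / areas["body"],
            )
        )

    steps = []
    overlap_flag = False
    for chrom, items in spans.items():
        events: dict[int, float] = {}
        for s, e, v in items:
            events[s] = events.get(s, 0.0) + v
            events[e] = events.get(e, 0.0) - v
        cuts = sorted(events)
        level = 0.0
        for pos, nxt in zip(cuts, cuts[1:] + [None]):
            level += events[pos]
            if abs(level) < 1e-12:
                level = 0.0
            if nxt is None:
                break
            if level > 0.0:
                steps.append((GenomicInterval(chrom, pos, nxt), level))
    # detect summed overlaps for the truth flag
    merged_area = sum(iv.length() for iv, _ in steps)
    flat_area = sum(e - s for items in spans.values() for s, e, _ in items)
    overlap_flag = merged_area < flat_area

    if arch.coverage_noise_depth is not None:
        depth = float(arch.coverage_noise_depth)
        step_bp = int(arch.coverage_noise_step)
        noisy = []
        for iv, v in steps:
            pos = iv.start
            while pos < iv.end:
                end = min(pos + step_bp, iv.end)
                width = end - pos
                lam = v * depth * width
                val = rng.poisson(lam) / (depth * width)
                if val > 0:
                    noisy.append((GenomicInterval(iv.chrom, pos, end), float(val)))
                pos = end
        steps = noisy

    truth = pd.DataFrame(truth_rows)
    truth.attrs["has_overlapping_genes"] = bool(overlap_flag)
    return CoverageSimulation(condition=condition, track=CoverageTrack(steps), truth=truth)
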