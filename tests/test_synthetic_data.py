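import math

import numpy as np
import pytest
from scipy import stats as sps

from pol2topo import aqua_norm as an
from pol2topo import synthetic_data as sd
from pol2topo.io_formats import GenomicInterval


def small_arch(**kw):
    defaults = dict(n_clusters=8, loops_per_cluster_mean=5.0, contact_rate=30.0, seed=5)
    defaults.update(kw)
    return sd.ArchitectureConfig(**defaults)


class TestGenomeGeneration:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = sd.SyntheticGenomeConfig(seed=3, n_genes=20, n_enhancer_peaks=40,
                                       chrom_length=2_000_000)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sd.generate_genome(cfg).write(d1)
        sd.generate_genome(cfg).write(d2)
        for name in ("genes.tsv", "cpg_islands.bed", "p3f_peaks.bed", "p300_peaks.bed"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_all_promoters_cpg_at_fraction_one(self):
        cfg = sd.SyntheticGenomeConfig(
            n_genes=10, n_enhancer_peaks=10, fraction_cpg_promoters=1.0,
            chrom_length=1_000_000, n_chroms=1, seed=2,
        )
        genome = sd.generate_genome(cfg)
        islands = [r.interval for r in genome.cpg_islands]
        for g in genome.genes:
            assert any(iv.contains_point(g.chrom, g.tss) for iv in islands)

    def test_no_cpg_at_fraction_zero(self):
        cfg = sd.SyntheticGenomeConfig(
            n_genes=10, n_enhancer_peaks=10, fraction_cpg_promoters=0.0,
            chrom_length=1_000_000, n_chroms=1, seed=2,
        )
        assert sd.generate_genome(cfg).cpg_islands == []

    def test_annotations_do_not_overlap(self, small_genome):
        spans = [g.span for g in small_genome.genes] + [
            r.interval for r in small_genome.p300_peaks
        ]
        spans.sort(key=lambda iv: (iv.chrom, iv.start))
        for a, b in zip(spans, spans[1:]):
            assert not a.overlaps(b)

    def test_placement_impossible_raises(self):
        cfg = sd.SyntheticGenomeConfig(
            n_genes=100, n_enhancer_peaks=100, chrom_length=500_000, n_chroms=1
        )
        with pytest.raises(ValueError, match="too small"):
            sd.generate_genome(cfg)


class TestContactGeneration:
    def test_determinism(self, small_genome):
        arch = small_arch()
        s1 = sd.generate_contacts(small_genome, arch, "control")
        s2 = sd.generate_contacts(small_genome, arch, "control")
        assert s1.pairs == s2.pairs

    def test_conditions_differ_but_share_truth(self, small_genome):
        arch = small_arch()
        c = sd.generate_contacts(small_genome, arch, "control")
        t = sd.generate_contacts(small_genome, arch, "treated")
        assert c.truth_loops.drop(columns=["lam_treated"]).equals(
            t.truth_loops.drop(columns=["lam_treated"])
        )
        assert c.pairs != t.pairs

    def test_null_effect_equal_expected_counts(self, small_genome):
        arch = small_arch(collapse_distal_factor=1.0, collapse_cpg_gain_factor=1.0)
        c = sd.generate_contacts(small_genome, arch, "control")
        assert (c.truth_loops["lam_control"] == c.truth_loops["lam_treated"]).all()

    def test_planted_loop_count_within_poisson_interval(self, small_genome):
        lam = 50.0
        arch = small_arch(contact_rate=lam, background_rate=0.0, seed=9)
        sim = sd.generate_contacts(small_genome, arch, "control")
        contacts = an.bin_contacts(
            [p for p in sim.pairs if p.genome_tag == "human"], arch.anchor_bin
        )
        by_key = {
            (c.anchor_a.chrom, c.anchor_a.start // arch.anchor_bin,
             c.anchor_b.start // arch.anchor_bin): c.raw_count
            for c in contacts
        }
        lo, hi = sps.poisson.ppf([0.005, 0.995], lam)
        n_outside = 0
        for row in sim.truth_loops.itertuples():
            count = by_key.get((row.chrom, row.bin_a, row.bin_b), 0)
            if not lo <= count <= hi:
                n_outside += 1
        # 99% interval: allow a small failure budget over ~60 loops
        assert n_outside <= max(2, int(0.05 * len(sim.truth_loops)))

    def test_truth_loops_materialized_in_contact_file(self, small_genome):
        arch = small_arch(contact_rate=80.0, background_rate=0.0)
        sim = sd.generate_contacts(small_genome, arch, "control")
        bins = set()
        for p in sim.pairs:
            if p.genome_tag != "human":
                continue
            bins.add((p.chrom_a, p.pos_a // arch.anchor_bin))
            bins.add((p.chrom_b, p.pos_b // arch.anchor_bin))
        for row in sim.truth_loops.itertuples():
            assert (row.chrom, row.bin_a) in bins
            assert (row.chrom, row.bin_b) in bins

    def test_spikein_ratio_lln(self):
        genome = sd.generate_genome(
            sd.SyntheticGenomeConfig(
                n_chroms=2, chrom_length=6_000_000, n_genes=60,
                n_enhancer_peaks=200, seed=4,
            )
        )
        # ~ 40 clusters x 4 loops x 1200 pairs ~ 2e5 human pairs
        arch = sd.ArchitectureConfig(
            n_clusters=40, loops_per_cluster_mean=4.0, contact_rate=1200.0,
            spikein_fraction=0.1, seed=8,
        )
        sim = sd.generate_contacts(genome, arch, "control")
        assert sim.n_human_pairs > 1e5
        ratio = sim.n_spikein_pairs / sim.n_human_pairs
        assert abs(ratio - 0.1) / 0.1 < 0.01

    def test_all_pairs_survive_distance_filter(self, small_genome):
        sim = sd.generate_contacts(small_genome, small_arch(), "control")
        filtered = an.filter_pairs(sim.pairs)
        assert len(filtered) == len(sim.pairs)

    def test_unknown_condition(self, small_genome):
        with pytest.raises(ValueError):
            sd.generate_contacts(small_genome, small_arch(), "dmso")

    def test_clusters_have_at_least_two_loops(self, small_genome):
        sim = sd.generate_contacts(small_genome, small_arch(), "control")
        assert (sim.truth_clusters["n_loops"] >= 2).all()


class TestCoverageGeneration:
    def test_null_condition_identical_pulr(self, small_genome):
        arch = small_arch(tesr_depletion_factor=1.0, tssr_gain_factor=1.0)
        c = sd.generate_coverage(small_genome, arch, "control")
        t = sd.generate_coverage(small_genome, arch, "treated")
        assert np.allclose(
            c.truth["pulr_planted"].to_numpy(), t.truth["pulr_planted"].to_numpy()
        )
        assert list(c.track.steps()) == list(t.track.steps())

    def test_uniform_levels_give_pulr_point_seven_shape(self):
        """With all levels equal, planted PULR = (L + 800) / 4000 per gene."""
        genome = sd.generate_genome(
            sd.SyntheticGenomeConfig(n_genes=6, n_enhancer_peaks=6, n_chroms=1,
                                     chrom_length=1_000_000, seed=7)
        )
        arch = small_arch(promoter_level=1.0, tssr_level=1.0, body_level=1.0,
                          tesr_level=1.0)
        cov = sd.generate_coverage(genome, arch, "control")
        genes = {g.gene_id: g for g in genome.genes}
        for row in cov.truth.itertuples():
            expect = (genes[row.gene_id].length + 800) / 4000
            assert row.pulr_planted == pytest.approx(expect)

    def test_planted_pulr_ratio_from_depletion(self, small_genome):
        ctrl = sd.generate_coverage(small_genome, small_arch(), "control")
        trt = sd.generate_coverage(
            small_genome, small_arch(tesr_depletion_factor=0.5), "treated"
        )
        merged = ctrl.truth.merge(trt.truth, on="gene_id", suffixes=("_c", "_t"))
        ratio = merged["pulr_planted_t"] / merged["pulr_planted_c"]
        assert np.allclose(ratio.to_numpy(), 2.0)

    def test_track_matches_truth_levels(self, small_genome):
        from pol2topo import pol2_gene_metrics as pgm

        arch = small_arch()
        cov = sd.generate_coverage(small_genome, arch, "control")
        table = pgm.gene_metrics_table(
            cov.track, small_genome.genes, chrom_sizes=small_genome.chrom_sizes
        )
        merged = table.merge(cov.truth, on="gene_id")
        assert len(merged) == len(table)
        assert np.allclose(merged["pulr"], merged["pulr_planted"])
        assert np.allclose(merged["tr"], merged["tr_planted"])

    def test_noise_keeps_pulr_close(self, small_genome):
        from pol2topo import pol2_gene_metrics as pgm

        arch = small_arch(coverage_noise_depth=20.0)
        cov = sd.generate_coverage(small_genome, arch, "control")
        table = pgm.gene_metrics_table(
            cov.track, small_genome.genes, chrom_sizes=small_genome.chrom_sizes
        )
        merged = table.merge(cov.truth, on="gene_id")
        rel = np.abs(merged["pulr"] / merged["pulr_planted"] - 1.0)
        assert float(rel.max()) < 0.05


class TestUniformPulrExample:
    def test_planted_uniform_gene_value(self):
        """A 2000-bp gene with unit levels has planted PULR 0.7 and TR 330/1700."""
        genome = sd.generate_genome(
            sd.SyntheticGenomeConfig(
                n_genes=1, n_enhancer_peaks=2, n_chroms=1, chrom_length=500_000,
                min_gene_length=2_000, max_gene_length=2_000, seed=1,
            )
        )
        arch = small_arch(n_clusters=1, promoter_level=1.0, tssr_level=1.0,
                          body_level=1.0, tesr_level=1.0)
        cov = sd.generate_coverage(genome, arch, "control")
        assert cov.truth["pulr_planted"].iloc[0] == pytest.approx(0.7)
        assert cov.truth["tr_planted"].iloc[0] == pytest.approx(330 / 1700)
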