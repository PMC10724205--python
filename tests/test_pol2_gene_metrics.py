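import math

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import uniform_track
from pol2topo import pol2_gene_metrics as pgm
from pol2topo.io_formats import CoverageTrack, GeneModel, GenomicInterval


PLUS_GENE = GeneModel("gp", "chr1", "+", 1000, 3000)
MINUS_GENE = GeneModel("gm", "chr1", "-", 9000, 7000)  # same 2000-bp length


class TestGeneRegions:
    def test_plus_strand_windows(self):
        r = pgm.gene_regions(PLUS_GENE)
        assert (r.promoter.start, r.promoter.end) == (200, 970)
        assert (r.tssr.start, r.tssr.end) == (970, 1300)
        assert (r.body.start, r.body.end) == (1300, 3000)
        assert (r.tesr.start, r.tesr.end) == (3000, 7000)

    def test_minus_strand_lengths_mirror_plus(self):
        r = pgm.gene_regions(MINUS_GENE)
        assert r.promoter.length() == 770
        assert r.tssr.length() == 330
        assert r.body.length() == 1700
        assert r.tesr.length() == 4000

    def test_minus_strand_windows_partition_contiguously(self):
        r = pgm.gene_regions(MINUS_GENE)
        # tesr | body | tssr | promoter tile left-to-right without gaps
        assert r.tesr.end == r.body.start
        assert r.body.end == r.tssr.start
        assert r.tssr.end == r.promoter.start

    def test_clipping_flagged(self):
        g = GeneModel("g0", "chr1", "+", 500, 3000)
        r = pgm.gene_regions(g)
        assert r.promoter.start == 0 and r.clipped

    def test_short_gene_rejected(self):
        g = GeneModel("gs", "chr1", "+", 1000, 1300)
        with pytest.raises(ValueError, match="undefined"):
            pgm.gene_regions(g)

    def test_chrom_length_clip(self):
        g = GeneModel("ge", "chr1", "+", 1000, 3000)
        r = pgm.gene_regions(g, chrom_length=5000)
        assert r.tesr.end == 5000 and r.clipped


class TestWorkedExample:
    def test_tr_uniform_coverage(self):
        track = uniform_track(end=20_000)
        assert pgm.traveling_ratio(track, PLUS_GENE) == pytest.approx(330 / 1700)

    def test_pulr_uniform_coverage(self):
        track = uniform_track(end=20_000)
        assert pgm.pulr(track, PLUS_GENE) == pytest.approx(0.7)
        # (770 + 330 + 1700) / 4000

    def test_minus_strand_mirror_identical(self):
        track = uniform_track(end=20_000)
        assert pgm.pulr(track, MINUS_GENE) == pytest.approx(0.7)
        assert pgm.traveling_ratio(track, MINUS_GENE) == pytest.approx(330 / 1700)

    def test_pause_peak_tr(self):
        track = CoverageTrack(
            [
                (GenomicInterval("chr1", 0, 970), 1.0),
                (GenomicInterval("chr1", 970, 1300), 10.0),
                (GenomicInterval("chr1", 1300, 20_000), 1.0),
            ]
        )
        assert pgm.traveling_ratio(track, PLUS_GENE) == pytest.approx(3300 / 1700)

    def test_tesr_halved_doubles_pulr(self):
        track = CoverageTrack(
            [
                (GenomicInterval("chr1", 0, 3000), 1.0),
                (GenomicInterval("chr1", 3000, 20_000), 0.5),
            ]
        )
        assert pgm.pulr(track, PLUS_GENE) == pytest.approx(1.4)

    def test_promoter_tssr_only_numerator(self):
        track = uniform_track(end=20_000)
        assert pgm.pulr(track, PLUS_GENE, numerator="promoter_tssr_only") == (
            pytest.approx((770 + 330) / 4000)
        )

    def test_zero_body_signal_is_nan(self):
        track = CoverageTrack([(GenomicInterval("chr1", 0, 1300), 1.0)])
        assert math.isnan(pgm.traveling_ratio(track, PLUS_GENE))

    def test_zero_tesr_signal_is_nan(self):
        track = CoverageTrack([(GenomicInterval("chr1", 0, 3000), 1.0)])
        assert math.isnan(pgm.pulr(track, PLUS_GENE))


class TestInvariants:
    @given(scale=st.floats(0.01, 1000))
    def test_scale_invariance(self, scale):
        base = CoverageTrack(
            [
                (GenomicInterval("chr1", 0, 1300), 2.0),
                (GenomicInterval("chr1", 1300, 8000), 0.7),
            ]
        )
        scaled = CoverageTrack(
            [(iv, v * scale) for iv, v in base.steps()]
        )
        assert pgm.pulr(base, PLUS_GENE) == pytest.approx(pgm.pulr(scaled, PLUS_GENE))
        assert pgm.traveling_ratio(base, PLUS_GENE) == pytest.approx(
            pgm.traveling_ratio(scaled, PLUS_GENE)
        )

    def test_reflection_invariance_with_mirrored_coverage(self):
        """A '-' gene with base-wise mirrored coverage gives identical metrics."""
        import numpy as np

        rng = np.random.default_rng(21)
        length = 20_000
        values = rng.random(40)  # 40 steps of 500 bp
        fwd = CoverageTrack(
            [
                (GenomicInterval("chr1", i * 500, (i + 1) * 500), float(v))
                for i, v in enumerate(values)
            ]
        )
        # mirror the genome about its midpoint: base x -> length-1-x
        rev = CoverageTrack(
            [
                (GenomicInterval("chr1", length - (i + 1) * 500, length - i * 500), float(v))
                for i, v in enumerate(values)
            ]
        )
        plus = GeneModel("g", "chr1", "+", 6000, 9000)
        minus = GeneModel("g", "chr1", "-", length - 1 - 6000, length - 1 - 9000)
        assert pgm.pulr(fwd, plus) == pytest.approx(pgm.pulr(rev, minus))
        assert pgm.traveling_ratio(fwd, plus) == pytest.approx(
            pgm.traveling_ratio(rev, minus)
        )

    def test_pre_tes_additivity_per_base(self):
        import numpy as np

        rng = np.random.default_rng(14)
        values = rng.random(80)
        track = CoverageTrack(
            [
                (GenomicInterval("chr1", i * 250, (i + 1) * 250), float(v))
                for i, v in enumerate(values)
            ]
        )
        r = pgm.gene_regions(PLUS_GENE)
        split = (
            track.signal(r.promoter) + track.signal(r.tssr) + track.signal(r.body)
        )
        brute = sum(track.value_at("chr1", b) for b in range(200, 3000))
        assert split == pytest.approx(brute)


class TestCompareMetrics:
    def table(self, tesr_value):
        track = CoverageTrack(
            [
                (GenomicInterval("chr1", 0, 3000), 1.0),
                (GenomicInterval("chr1", 3000, 20_000), tesr_value),
            ]
        )
        return pgm.gene_metrics_table(track, [PLUS_GENE])

    def test_identical_conditions(self):
        out = pgm.compare_metrics(self.table(1.0), self.table(1.0))
        assert out["pulr_ratio"].tolist() == [1.0]
        assert out["tr_ratio"].tolist() == [1.0]

    def test_tesr_depletion_recovered_exactly(self):
        out = pgm.compare_metrics(self.table(1.0), self.table(0.5))
        assert out["pulr_ratio"].tolist() == [2.0]

    def test_missing_gene_excluded_and_counted(self):
        other = GeneModel("gx", "chr1", "+", 5000, 8000)
        track = uniform_track(end=20_000)
        a = pgm.gene_metrics_table(track, [PLUS_GENE, other])
        b = pgm.gene_metrics_table(track, [PLUS_GENE])
        out = pgm.compare_metrics(a, b)
        assert out["gene_id"].tolist() == ["gp"]
        assert out.attrs["n_excluded"] == 1


class TestDecileRankJoin:
    def test_distinct_signals_one_per_decile(self):
        signal = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(10)], "signal": range(10)}
        )
        expr = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(10)], "l2fc": [0.0] * 10}
        )
        joined, _ = pgm.decile_rank_join(signal, expr)
        assert sorted(joined["decile"]) == list(range(1, 11))
        top = joined.loc[joined["signal"].idxmax()]
        assert top["decile"] == 10

    def test_tie_break_deterministic(self):
        signal = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(10)], "signal": [1.0] * 10}
        )
        expr = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(10)], "l2fc": [0.0] * 10}
        )
        j1, _ = pgm.decile_rank_join(signal, expr)
        j2, _ = pgm.decile_rank_join(signal.sample(frac=1, random_state=1), expr)
        merged = j1.merge(j2, on="gene_id", suffixes=("_1", "_2"))
        assert (merged["decile_1"] == merged["decile_2"]).all()

    def test_planted_monotone_trend(self):
        import numpy as np

        rng = np.random.default_rng(30)
        n = 500
        signal = pd.DataFrame(
            {"gene_id": [f"g{i:03d}" for i in range(n)], "signal": rng.random(n) * 100}
        )
        rank = signal["signal"].rank(method="first")
        decile_true = np.ceil(10 * rank / n)
        expr = pd.DataFrame(
            {
                "gene_id": signal["gene_id"],
                "l2fc": -0.5 * decile_true + rng.normal(0, 0.1, n),
            }
        )
        _, summary = pgm.decile_rank_join(signal, expr)
        medians = summary.sort_values("decile")["median"].to_numpy()
        assert (np.diff(medians) < 0).all()

    def test_low_overlap_warns(self):
        signal = pd.DataFrame({"gene_id": ["a", "b", "c"], "signal": [1, 2, 3]})
        expr = pd.DataFrame({"gene_id": ["a"], "l2fc": [0.0]})
        with pytest.warns(UserWarning):
            pgm.decile_rank_join(signal, expr)
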