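import math

import numpy as np
import pandas as pd
import pytest

from netprism import metrics
from netprism.metrics import (
    TRRecord,
    feature_density,
    oriented_window,
    rpkm,
    sense_antisense_split,
    tr_cumulative,
    travelling_ratio,
)
from netprism.tracks import SignalTrack, build_track

from conftest import make_gene


def uniform_track(gene, value=1.0, size=20_000):
    t = SignalTrack({gene.chrom: size})
    t.data[gene.chrom][gene.strand][:] = value
    return t


def brute_force_tr(gene, track, promoter=(-30, 250), body_start=300, body_end=200):
    """Independent per-base summation oracle."""
    arr = track.get(gene.chrom, gene.strand)
    d = 1 if gene.strand == "+" else -1
    prom = [arr[gene.tss + d * o] for o in range(promoter[0], promoter[1])]
    body = [arr[gene.tss + d * o]
            for o in range(body_start, gene.length - body_end)]
    pd_, bd = sum(prom) / len(prom), sum(body) / len(body)
    return pd_ / bd if bd > 0 else float("nan")


class TestOrientedWindow:
    @pytest.mark.parametrize(
        "strand,expected", [("+", (970, 1250)), ("-", (751, 1031))],
        ids=["plus", "minus"],
    )
    def test_promoter_window_is_280_bp(self, strand, expected):
        lo, hi = oriented_window(1000, strand, -30, 250)
        assert (lo, hi) == expected
        assert hi - lo == 280


class TestTravellingRatio:
    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("value", [0.5, 1.0, 7.3])
    def test_uniform_coverage_gives_tr_one(self, strand, value):
        exons = [(5000, 6000), (7000, 9000)] if strand == "+" else [(5000, 7000), (8000, 9000)]
        g = make_gene(strand=strand, exons=exons)
        rec = travelling_ratio(g, uniform_track(g, value))
        assert rec.tr == pytest.approx(1.0)

    def test_all_signal_in_promoter_gives_undefined(self):
        g = make_gene(exons=[(5000, 9000)])
        t = SignalTrack({"chr1": 20_000})
        t.data["chr1"]["+"][5000:5100] = 10.0
        rec = travelling_ratio(g, t)
        assert math.isnan(rec.tr)
        assert rec.reason == "zero_body"

    def test_short_gene_excluded_with_reason(self):
        g = make_gene(exons=[(5000, 5400)])
        rec = travelling_ratio(g, uniform_track(g))
        assert rec.reason == "too_short"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_per_base_summation_oracle(self, strand):
        rng = np.random.default_rng(17)
        for trial in range(5):
            length = int(rng.integers(800, 4000))
            start = 6000
            g = make_gene(f"g{trial}", strand=strand,
                          exons=[(start, start + length)])
            t = SignalTrack({"chr1": 20_000})
            t.data["chr1"][strand][:] = rng.poisson(0.5, size=20_000)
            rec = travelling_ratio(g, t)
            assert rec.tr == pytest.approx(brute_force_tr(g, t), rel=1e-12)

    def test_hand_placed_positions(self):
        # 7 positions: 4 in the promoter window, 3 in the body
        g = make_gene(exons=[(5000, 6500)])  # length 1500, body window 1000 bp
        pos = [("chr1", p, "+") for p in (4990, 5000, 5100, 5200, 5400, 5800, 6200)]
        t = build_track(pos, {"chr1": 20_000})
        rec = travelling_ratio(g, t)
        assert rec.tr == pytest.approx((4 / 280) / (3 / 1000))


class TestCumulative:
    def test_single_gene_single_step(self):
        df = tr_cumulative([TRRecord("g", 1, 1, 2.5)])
        assert df.tr.tolist() == [2.5] and df.fraction.tolist() == [1.0]

    def test_fraction_at_median(self):
        recs = [TRRecord(f"g{i}", 1, 1, float(v)) for i, v in enumerate([1, 2, 3, 4])]
        df = tr_cumulative(recs)
        assert df.loc[df.tr == 2, "fraction"].iloc[0] == 0.5

    def test_undefined_counted_not_plotted(self):
        recs = [TRRecord("a", 1, 1, 2.0), TRRecord("b", 1, 0, float("nan"), "zero_body")]
        df = tr_cumulative(recs)
        assert len(df) == 1 and df.attrs["n_undefined"] == 1

    def test_all_undefined_errors(self):
        with pytest.raises(ValueError):
            tr_cumulative([TRRecord("a", 1, 0, float("nan"), "zero_body")])


class TestRpkm:
    def test_closed_form(self):
        assert rpkm(10, 1000, 10**6) == pytest.approx(10.0)
        assert rpkm(0, 1000, 10**6) == 0.0

    def test_linearity(self):
        base = rpkm(7, 1500, 2_000_000)
        assert rpkm(14, 1500, 2_000_000) == pytest.approx(2 * base)
        assert rpkm(7, 1500, 4_000_000) == pytest.approx(base / 2)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 1000)

    def test_tracks_programmed_body_rate(self, tmp_path):
        from netprism import simulate as sim

        model, truth = sim.build_toy_genome(
            seed=21, n_genes=10, n_enhancers=0,
            gene_params=dict(pause_height=0.0, antisense_height=0.0,
                             intermediates_per_terminal=0.0, body_start_offset=0),
        )
        truth.mispriming_fraction = 0.0
        paths = sim.simulate_reads(model, truth, str(tmp_path / "d"),
                                   write_reference=False)
        t = pd.read_csv(paths["truth"], sep="\t")
        track = build_track(
            zip(t.chrom, t.pos, t.transcript_strand), model.chrom_sizes
        )
        total = len(t)
        vals = []
        for g in model.genes:
            count = metrics.count_in_region(track, g.chrom, g.start, g.end, g.strand)
            vals.append((truth.genes[g.gene_id].body_rate, rpkm(count, g.length, total)))
        rates, rpkms = zip(*vals)
        r = np.corrcoef(rates, rpkms)[0, 1]
        assert r > 0.9


class TestFeatureDensity:
    def test_zero_and_uniform_tracks(self):
        from netprism.annotation import derive_introns

        g = make_gene(exons=[(100, 200), (300, 400), (500, 600)])
        introns = derive_introns(g)
        t = SignalTrack({"chr1": 1000})
        assert all(d.density == 0 for d in feature_density(introns, t))
        t.data["chr1"]["+"][:] = 2.5
        recs = feature_density(introns, t)
        assert all(d.density == pytest.approx(2.5) for d in recs)


class TestSenseAntisense:
    def test_all_sense(self):
        g = make_gene(exons=[(5000, 9000)])
        pos = [("chr1", 5000 + i, "+") for i in range(10)]
        df = sense_antisense_split(pos, [g])
        assert df.sense.iloc[0] == 10 and df.antisense.iloc[0] == 0

    def test_global_strand_flip_swaps_counts(self):
        g = make_gene(exons=[(5000, 9000)])
        rng = np.random.default_rng(3)
        pos = [("chr1", int(p), "+" if rng.random() < 0.7 else "-")
               for p in rng.integers(4200, 5800, size=50)]
        flip = [(c, p, "-" if s == "+" else "+") for c, p, s in pos]
        a = sense_antisense_split(pos, [g]).iloc[0]
        b = sense_antisense_split(flip, [g]).iloc[0]
        assert (a.sense, a.antisense) == (b.antisense, b.sense)

    def test_divergent_peak_located_at_programmed_offset(self, sim_run, sim_truth_table):
        model, truth, _ = sim_run
        t = sim_truth_table
        track = build_track(
            zip(t.chrom, t.pos, t.transcript_strand), model.chrom_sizes
        )
        # pooled antisense profile over TSSs, oriented: argmax near -antisense_offset
        prof = np.zeros(2000)
        for g in model.genes:
            anti = "-" if g.strand == "+" else "+"
            arr = track.get(g.chrom, anti)
            if g.strand == "+":
                win = arr[g.tss - 1000 : g.tss + 1000]
            else:
                win = arr[g.tss - 999 : g.tss + 1001][::-1]
            prof += win
        peak_offset = int(np.argmax(prof)) - 1000
        gt = next(iter(truth.genes.values()))
        assert abs(-peak_offset - gt.antisense_offset) <= gt.antisense_sd
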