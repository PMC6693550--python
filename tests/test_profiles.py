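import numpy as np
import pytest

from netprism import profiles
from netprism.profiles import (
    Anchor,
    ProfileMatrix,
    artifact_row_filter,
    boundary_anchors,
    build_matrix,
    concentration,
    metaplot,
)
from netprism.tracks import SignalTrack

from conftest import make_gene


def delta_track(chrom="chr1", size=10_000, pos=5000, strand="+", mass=3.0):
    t = SignalTrack({chrom: size})
    t.data[chrom][strand][pos] = mass
    return t


class TestBuildMatrix:
    def test_plus_strand_delta_at_offset_zero(self):
        t = delta_track(strand="+")
        m = build_matrix(t, [Anchor("a", "chr1", 5000, "+")], 100, "sense")
        col = np.flatnonzero(m.values[0])
        assert m.offsets[col[0]] == 0 and m.values[0, col[0]] == 3.0

    def test_minus_strand_delta_mirrors_to_same_column(self):
        t = delta_track(strand="-")
        m = build_matrix(t, [Anchor("a", "chr1", 5000, "-")], 100, "sense")
        col = np.flatnonzero(m.values[0])
        assert m.offsets[col[0]] == 0

    def test_antisense_channel_reads_opposite_strand(self):
        t = delta_track(strand="-")
        m = build_matrix(t, [Anchor("a", "chr1", 5000, "+")], 100, "antisense")
        assert m.values[0, 100] == 3.0

    def test_matches_naive_slicing_oracle(self):
        rng = np.random.default_rng(5)
        t = SignalTrack({"chr1": 5000})
        t.data["chr1"]["+"][:] = rng.poisson(1.0, 5000)
        t.data["chr1"]["-"][:] = rng.poisson(1.0, 5000)
        anchors = [Anchor(f"a{i}", "chr1", int(c), s)
                   for i, (c, s) in enumerate(zip(rng.integers(300, 4700, 20),
                                                  "+-" * 10))]
        m = build_matrix(t, anchors, 200, "sense")
        for i, a in enumerate(anchors):
            arr = t.get("chr1", a.strand)
            for j, off in enumerate(m.offsets):
                g = a.coord + off if a.strand == "+" else a.coord - off
                assert m.values[i, j] == arr[g]

    def test_clipped_window_zero_padded_and_flagged(self):
        t = delta_track(pos=10)
        m = build_matrix(t, [Anchor("a", "chr1", 10, "+")], 100, "sense")
        assert m.clipped_rows == [0]
        assert m.values[0, :90].sum() == 0.0


class TestBoundaryAnchors:
    def test_plus_strand_exon(self):
        g = make_gene(exons=[(100, 200), (300, 400), (500, 600)])
        three, five = boundary_anchors([g])
        assert (three[0].coord, five[0].coord) == (300, 399)

    def test_minus_strand_mirror(self):
        g = make_gene(strand="-", exons=[(100, 200), (300, 400), (500, 600)])
        three, five = boundary_anchors([g])
        assert (three[0].coord, five[0].coord) == (399, 300)


def brute_force_concentration(values, span):
    out = []
    for row in values:
        total = row.sum()
        if total == 0:
            out.append(0.0)
            continue
        best = max(row[i : i + span].sum() for i in range(len(row) - span + 1))
        out.append(best / total)
    return np.array(out)


def matrix_from_rows(rows):
    rows = np.asarray(rows, dtype=float)
    anchors = [Anchor(f"r{i}", "chr1", 0, "+") for i in range(rows.shape[0])]
    offsets = np.arange(-rows.shape[1] // 2, rows.shape[1] // 2)
    return ProfileMatrix(anchors, offsets, rows, "sense")


class TestArtifactRowFilter:
    def test_uniform_rows_untouched(self):
        m = matrix_from_rows(np.ones((20, 400)))
        kept, removed = artifact_row_filter(m)
        assert removed == [] and kept.values.shape == (20, 400)

    def test_planted_spike_removed(self):
        rng = np.random.default_rng(0)
        rows = rng.poisson(1.0, size=(30, 400)).astype(float)
        spike = np.zeros(400)
        spike[200:250] = 50.0  # all mass within 50 bp, total far above P90
        rows = np.vstack([rows, spike])
        m = matrix_from_rows(rows)
        kept, removed = artifact_row_filter(m)
        assert removed == ["r30"]
        assert kept.values.shape[0] == 30

    def test_idempotent_and_matches_oracle(self):
        rng = np.random.default_rng(1)
        rows = rng.poisson(0.8, size=(40, 400)).astype(float)
        for i in (3, 17):  # plant two ncRNA-like spikes
            rows[i] = 0.0
            rows[i, 100:160] = 30.0
        m = matrix_from_rows(rows)
        conc = concentration(m.values, 100)
        assert np.allclose(conc, brute_force_concentration(m.values, 100))
        kept, removed = artifact_row_filter(m)
        assert set(removed) == {"r3", "r17"}
        kept2, removed2 = artifact_row_filter(kept)
        assert removed2 == []
        assert np.array_equal(kept2.values, kept.values)

    def test_zero_rows_never_removed(self):
        rows = np.zeros((10, 400))
        rows[0, 150:200] = 5.0  # single concentrated row among zeros
        m = matrix_from_rows(rows)
        _, removed = artifact_row_filter(m)
        assert "r1" not in removed and "r9" not in removed

    def test_kmeans_mode_removes_planted_cluster(self):
        rng = np.random.default_rng(2)
        rows = rng.poisson(1.0, size=(40, 400)).astype(float)
        for i in range(35, 40):
            rows[i] = 0.0
            rows[i, 200:240] = rng.uniform(20, 40)
        m = matrix_from_rows(rows)
        _, removed = artifact_row_filter(m, mode="kmeans")
        assert set(removed) == {f"r{i}" for i in range(35, 40)}


class TestMetaplot:
    def test_identical_rows_zero_width_interval(self):
        m = matrix_from_rows(np.tile(np.arange(100.0), (5, 1)))
        df = metaplot(m, smooth_window=1)
        assert np.allclose(df["lo"], df["mean"])
        assert np.allclose(df["hi"], df["mean"])

    def test_two_row_mean(self):
        m = matrix_from_rows([[0.0] * 10, [2.0] * 10])
        df = metaplot(m, smooth_window=1)
        assert np.allclose(df["mean"], 1.0)

    def test_bootstrap_close_to_normal_on_gaussian_rows(self):
        rng = np.random.default_rng(7)
        rows = rng.normal(5.0, 1.0, size=(200, 50))
        m = matrix_from_rows(rows)
        a = metaplot(m, smooth_window=1, ci="normal95")
        b = metaplot(m, smooth_window=1, ci="bootstrap95")
        width_a = (a["hi"] - a["lo"]).to_numpy()
        width_b = (b["hi"] - b["lo"]).to_numpy()
        assert np.all(np.abs(width_a - width_b) / width_a < 0.25)
        assert np.allclose(a["mean"], b["mean"])

    def test_strand_flip_symmetry(self):
        """Antisense metaplot of strand-flipped data = sense metaplot of original."""
        rng = np.random.default_rng(9)
        t = SignalTrack({"chr1": 4000})
        t.data["chr1"]["+"][:] = rng.poisson(1.0, 4000)
        t.data["chr1"]["-"][:] = rng.poisson(1.0, 4000)
        flipped = SignalTrack({"chr1": 4000})
        flipped.data["chr1"]["+"] = t.data["chr1"]["-"].copy()
        flipped.data["chr1"]["-"] = t.data["chr1"]["+"].copy()
        anchors = [Anchor("a", "chr1", 2000, "+"), Anchor("b", "chr1", 1500, "-")]
        sense = metaplot(build_matrix(t, anchors, 300, "sense"), smooth_window=1)
        anti = metaplot(build_matrix(flipped, anchors, 300, "antisense"),
                        smooth_window=1)
        assert np.allclose(sense["mean"], anti["mean"])
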