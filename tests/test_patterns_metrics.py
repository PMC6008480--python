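"""Pattern generation/encoding and the analysis metrics."""

import numpy as np
import pytest

from memstdp.coding import temporal_program
from memstdp.metrics import completion_quality, connection_census, symmetry_index
from memstdp.network import SimulationResult, WeightMatrix
from memstdp.patterns import (
    Pattern,
    edge_detect,
    fragment_pattern,
    load_pbm,
    make_grid_patterns,
    save_pbm,
    synth_contour_image,
)


class TestGridPatterns:
    def test_fixture_contracts(self):
        p1, p2 = make_grid_patterns()
        assert p1.n == p2.n == 9
        assert not np.array_equal(p1.pixels, p2.pixels)
        assert p1.n_active >= 2 and p2.n_active >= 2
        overlap = np.logical_and(p1.pixels, p2.pixels).sum()
        assert 0 < overlap < min(p1.n_active, p2.n_active)  # partial overlap


class TestContourImages:
    @pytest.mark.parametrize("shape", ["circle", "polygon", "blob"])
    def test_contour_is_thin_centered_and_reproducible(self, shape):
        p = synth_contour_image(shape, size=32, seed=42)
        g = p.grid()
        assert p.n_active > 0
        # 1-px outline, no filled interior: active share stays sparse
        assert p.n_active < 0.35 * p.n
        ys, xs = np.nonzero(g)
        assert abs(ys.mean() - 15.5) <= 1.0 and abs(xs.mean() - 15.5) <= 1.0
        p2 = synth_contour_image(shape, size=32, seed=42)
        assert np.array_equal(p.pixels, p2.pixels)

    def test_interior_not_filled(self):
        p = synth_contour_image("circle", size=32, seed=0)
        g = p.grid()
        cy, cx = 16, 16
        assert g[cy, cx] == 0  # centre of a closed outline is dark

    def test_small_size_raises(self):
        with pytest.raises(ValueError):
            synth_contour_image(size=4)


class TestEdgeDetect:
    def test_constant_image_is_empty(self):
        p = edge_detect(np.full((8, 8), 0.5), threshold=0.1)
        assert p.n_active == 0

    def test_step_edge_matches_bruteforce_oracle(self):
        img = np.zeros((5, 5))
        img[:, 3:] = 1.0
        thr = 0.5
        # brute-force 4-neighbour oracle
        expected = np.zeros((5, 5), dtype=np.uint8)
        for y in range(5):
            for x in range(5):
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < 5 and 0 <= xx < 5 and abs(img[y, x] - img[yy, xx]) > thr:
                        expected[y, x] = 1
        from memstdp.patterns import center_pattern

        assert np.array_equal(
            edge_detect(img, thr).pixels, center_pattern(Pattern.from_grid(expected)).pixels
        )

    def test_output_is_binary(self):
        rng = np.random.default_rng(1)
        p = edge_detect(rng.random((12, 12)), threshold=0.3)
        assert set(np.unique(p.pixels)) <= {0, 1}

    def test_bad_threshold_raises(self):
        with pytest.raises(ValueError):
            edge_detect(np.zeros((4, 4)), threshold=0.0)


class TestFragment:
    def test_full_fraction_identity(self):
        p = synth_contour_image("circle", seed=3)
        f = fragment_pattern(p, 1.0, seed=0)
        assert np.array_equal(f.pixels, p.pixels)

    def test_half_fraction_subset(self):
        px = np.zeros(25, dtype=np.uint8)
        px[:10] = 1
        p = Pattern(5, 5, px)
        f = fragment_pattern(p, 0.5, seed=7)
        assert f.n_active == 5
        assert set(f.active()) <= set(p.active())

    def test_seeded_determinism(self):
        p = synth_contour_image("blob", seed=9)
        a = fragment_pattern(p, 0.4, seed=5)
        b = fragment_pattern(p, 0.4, seed=5)
        assert np.array_equal(a.pixels, b.pixels)

    def test_bad_fraction_raises(self):
        p, _ = make_grid_patterns()
        with pytest.raises(ValueError):
            fragment_pattern(p, 0.0)


class TestTemporalProgram:
    def test_nine_pixel_single_loop_duration(self):
        prog = temporal_program(list(range(9)), 9, per_item_ms=17.0, loops=1,
                                drive_current=1.0)
        assert prog.total_duration_ms == pytest.approx(9 * 17.0)

    def test_image_sequence_schedule(self):
        pats = [Pattern(2, 2, np.eye(4, dtype=int)[i].astype(np.uint8)) for i in range(4)]
        prog = temporal_program(pats, 4, per_item_ms=19.2, loops=500, drive_current=1.0)
        assert prog.total_duration_ms == pytest.approx(38400.0)

    def test_single_item_active_at_any_instant(self):
        prog = temporal_program(list(range(5)), 5, per_item_ms=10.0, loops=2,
                                drive_current=2.0)
        for t in np.arange(0.0, prog.total_duration_ms, 1.0):
            assert np.count_nonzero(prog.current_at(t)) <= 1


def _result_with_rates(rates_hz, duration_ms=1000.0):
    neurons, times = [], []
    for i, r in enumerate(rates_hz):
        k = int(round(r * duration_ms / 1000.0))
        neurons.extend([i] * k)
        times.extend(np.linspace(1, duration_ms - 1, k) if k else [])
    order = np.argsort(times) if times else []
    return SimulationResult(
        spike_neurons=np.asarray(neurons, dtype=int)[order] if len(neurons) else np.array([], dtype=int),
        spike_times_ms=np.asarray(times)[order] if len(times) else np.array([]),
        snapshots=[], traces=None, trace_times_ms=None, seed=None,
    )


class TestCompletionQuality:
    def test_full_rate_gives_one(self):
        p = Pattern(2, 2, np.array([1, 1, 0, 0], dtype=np.uint8))
        res = _result_with_rates([40.0, 40.0, 0.0, 0.0])
        assert completion_quality(res, p, [], 40.0, (0.0, 1000.0)) == pytest.approx(1.0)

    def test_silence_gives_zero(self):
        p = Pattern(2, 2, np.array([1, 1, 0, 0], dtype=np.uint8))
        res = _result_with_rates([0.0, 0.0, 0.0, 0.0])
        assert completion_quality(res, p, [], 40.0, (0.0, 1000.0)) == 0.0

    def test_half_active_gives_half(self):
        p = Pattern(2, 2, np.array([1, 1, 0, 0], dtype=np.uint8))
        res = _result_with_rates([40.0, 0.0, 0.0, 0.0])
        assert completion_quality(res, p, [], 40.0, (0.0, 1000.0)) == pytest.approx(0.5)

    def test_relabeling_invariance(self):
        p = Pattern(2, 2, np.array([1, 0, 1, 0], dtype=np.uint8))
        res = _result_with_rates([30.0, 0.0, 10.0, 0.0])
        res2 = _result_with_rates([10.0, 0.0, 30.0, 0.0])
        q1 = completion_quality(res, p, [], 40.0, (0.0, 1000.0))
        q2 = completion_quality(res2, p, [], 40.0, (0.0, 1000.0))
        assert q1 == pytest.approx(q2)

    def test_zero_fmax_raises(self):
        p, _ = make_grid_patterns()
        with pytest.raises(ValueError):
            completion_quality(_result_with_rates([0] * 9), p, [], 0.0)


class TestConnectionCensus:
    def test_symmetric_matrix(self):
        w = np.full((4, 4), 0.8)
        np.fill_diagonal(w, 0.0)
        nb, nu, s = connection_census(w, 0.525)
        assert (nb, nu) == (6, 0)
        assert s == pytest.approx(1.0)

    def test_directed_chain_counts(self):
        w = np.full((9, 9), 0.05)
        for i in range(8):
            w[i, i + 1] = 0.9
        np.fill_diagonal(w, 0.0)
        nb, nu, _ = connection_census(w, 0.525)
        assert (nb, nu) == (0, 8)

    def test_all_weak_still_defined(self):
        w = np.full((5, 5), 0.1)
        np.fill_diagonal(w, 0.0)
        nb, nu, s = connection_census(w, 0.525)
        assert (nb, nu) == (0, 0)
        assert 0.0 <= s <= 1.0

    def test_matches_exhaustive_reference(self):
        """Vectorized census agrees with an O(n^2) loop on random
        matrices up to n = 50."""
        rng = np.random.default_rng(12)
        for n in (5, 20, 50):
            w = rng.uniform(0.05, 1.0, (n, n))
            np.fill_diagonal(w, 0.0)
            thr = 0.525
            nb = nu = 0
            num = den = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = w[i, j] >= thr, w[j, i] >= thr
                    nb += a and b
                    nu += a != b
                    num += abs(w[i, j] - w[j, i])
                    den += w[i, j] + w[j, i]
            got = connection_census(w, thr)
            assert got[0] == nb and got[1] == nu
            assert got[2] == pytest.approx(1 - num / den)

    def test_symmetry_index_subset(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.7  # symmetric inside {0,1}
        w[2, 3] = 0.9  # asymmetric elsewhere
        assert symmetry_index(w, subset=[0, 1]) == pytest.approx(1.0)
        assert symmetry_index(w) < 1.0


class TestPatternIO:
    def test_pbm_round_trip_and_pil_readable(self, tmp_path):
        p = synth_contour_image("circle", seed=2)
        path = tmp_path / "c.pbm"
        save_pbm(p, path)
        assert np.array_equal(load_pbm(path).pixels, p.pixels)
        from PIL import Image

        img = np.asarray(Image.open(path))
        # PBM semantics: file value 1 = black, which PIL renders as 0
        assert np.array_equal(~img.astype(bool), p.grid().astype(bool))
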