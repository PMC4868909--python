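"""Tests for window splicing, prefilters, detection and the map stage."""

import numpy as np
import pytest

from tswta.cell import DisparityCellState, init_receptive_field, train_bank
from tswta.stereo import (
    DisparityMap,
    PipelineConfig,
    average_error,
    detect_disparity,
    disparity_map,
    edge_prefilter,
    extract_and_splice,
    gaussian_prefilter,
    interior_mask,
    matched_pattern_set,
    splice_at,
)
from tswta.synth import StereoPair, make_stereo_pair, quadrant_layout


def _pair(h=40, w=40, layout=None, **kw):
    return make_stereo_pair(h, w, layout or quadrant_layout(h, w), **kw)


@pytest.fixture(scope="module")
def bank():
    return train_bank(matched_pattern_set(PipelineConfig(), 4), seed=3)


class TestSplice:
    def test_default_geometry_gives_9x9(self):
        pair = _pair()
        window, valid = extract_and_splice(pair, (20, 20), 9, 4, 5)
        assert window.shape == (9, 9) and valid

    def test_wide_geometry_gives_10x40(self):
        pair = _pair(60, 60)
        window, valid = extract_and_splice(pair, (30, 30), 10, 20, 20)
        assert window.shape == (10, 40) and valid

    def test_corner_window_padded_and_flagged(self):
        pair = _pair()
        window, valid = extract_and_splice(pair, (0, 0), 9, 4, 5)
        assert window.shape == (9, 9) and not valid

    def test_rows_come_from_the_same_epipolar_band(self):
        pair = _pair()
        window, _ = splice_at(pair, 10, 12, 9, 4, 5)
        assert np.array_equal(window[:, :4], pair.left[10:19, 12:16])
        assert np.array_equal(window[:, 4:], pair.right[10:19, 12:17])


class TestPrefilters:
    def test_gaussian_zero_sigma_is_identity(self):
        img = np.random.default_rng(0).random((15, 15))
        assert np.array_equal(gaussian_prefilter(img, 0.0), img)

    def test_gaussian_preserves_constant(self):
        img = np.full((12, 12), 0.7)
        assert np.allclose(gaussian_prefilter(img, 2.0), img)

    def test_gaussian_impulse_matches_kernel(self):
        img = np.zeros((21, 21))
        img[10, 10] = 1.0
        out = gaussian_prefilter(img, 1.0)
        x = np.arange(-10, 11)
        k = np.exp(-(x**2) / 2.0)
        k /= k.sum()
        assert np.allclose(out, np.outer(k, k), atol=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_prefilter(np.zeros((5, 5)), -1.0)

    def test_edge_of_constant_is_zero(self):
        assert not edge_prefilter(np.full((10, 10), 0.3)).any()

    def test_step_edge_peaks_on_the_step(self):
        img = np.zeros((12, 12))
        img[:, 6:] = 1.0
        out = edge_prefilter(img)
        assert set(np.flatnonzero(out.max(axis=0) == 1.0)) <= {5, 6}

    def test_edge_matches_finite_difference_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.random((16, 16))
        out = edge_prefilter(img)
        # brute-force Sobel at an interior point
        r, c = 8, 8
        kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]])
        gx = (img[r - 1 : r + 2, c - 1 : c + 2] * kx).sum()
        gy = (img[r - 1 : r + 2, c - 1 : c + 2] * kx.T).sum()
        mag = np.hypot(gx, gy)
        # the map is normalised to peak 1; recover the scale at one point
        scale = out[r, c] / mag
        others = []
        for rr, cc in [(5, 9), (9, 5), (7, 7)]:
            gx = (img[rr - 1 : rr + 2, cc - 1 : cc + 2] * kx).sum()
            gy = (img[rr - 1 : rr + 2, cc - 1 : cc + 2] * kx.T).sum()
            others.append((np.hypot(gx, gy), out[rr, cc]))
        for mag_o, got in others:
            assert got == pytest.approx(mag_o * scale, rel=1e-9)


class TestDetect:
    def test_window_at_true_disparity_wins(self, bank):
        pats = matched_pattern_set(PipelineConfig(), 4)
        for p in pats[:4]:
            d, responses, unique = detect_disparity(p.bits.astype(float), bank)
            assert d == p.disparity and unique

    def test_agrees_with_brute_force_oracle(self, bank):
        rng = np.random.default_rng(8)
        for _ in range(20):
            window = rng.random((9, 9))
            d, responses, _ = detect_disparity(window, bank)
            # oracle: independent per-cell response computation via loops
            med = float(np.median(window))
            scores = []
            for cell in bank:
                tot = acc = 0.0
                for r in range(9):
                    for c in range(9):
                        e1 = np.exp(-cell.params.kappa * (cell.rf.vfg1[r, c] - cell.params.vfg_min))
                        e2 = np.exp(-cell.params.kappa * (cell.rf.vfg2[r, c] - cell.params.vfg_min))
                        acc += e1 if window[r, c] > med else e2
                        tot += e1 + e2
                scores.append(acc / tot)
            assert d == bank[int(np.argmax(scores))].learned_disparity
            assert np.allclose(responses, scores)

    def test_degenerate_window_ties_on_identical_bank(self):
        rf = init_receptive_field(9, 9, seed=0)
        rf.vfg1[:] = rf.vfg2[:] = 5.0
        cells = []
        for d in range(4):
            c = DisparityCellState(rf=rf.copy())
            c.learned_disparity = d
            cells.append(c)
        d, _, unique = detect_disparity(np.zeros((9, 9)), cells)
        assert d == 0 and not unique

    def test_bank_of_one_always_answers_its_disparity(self, bank):
        d, _, unique = detect_disparity(np.random.default_rng(1).random((9, 9)), bank[2:3])
        assert d == 2 and unique

    def test_untrained_cell_rejected(self):
        cell = DisparityCellState(rf=init_receptive_field(9, 9, seed=1))
        with pytest.raises(ValueError):
            detect_disparity(np.zeros((9, 9)), [cell])


class TestDisparityMapStage:
    def test_single_region_zero_disparity_all_zero(self, bank):
        pair = make_stereo_pair(40, 40, [(0, 40, 0, 40, 0)], seed=2)
        dm = disparity_map(pair, bank)
        inner = dm.values[10:30, 10:30]
        assert (inner == 0).all()

    def test_deterministic(self, bank):
        pair = _pair(seed=6)
        a = disparity_map(pair, bank)
        b = disparity_map(pair, bank)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.valid_mask, b.valid_mask)

    def test_quadrant_plateaus_recovered(self, bank):
        layout = quadrant_layout(60, 60, (2, 0, 3, 1))
        pair = make_stereo_pair(60, 60, layout, seed=5)
        dm = disparity_map(pair, bank)
        inter = interior_mask(layout, (60, 60), margin=10)
        assert average_error(dm, pair.ground_truth, where=inter) == 0.0

    def test_shift_equivariance(self, bank):
        """Translating images and layout by one pixel translates the map."""
        base = [(0, 48, 0, 24, 0), (0, 48, 24, 48, 2)]
        shifted = [(0, 48, 0, 25, 0), (0, 48, 25, 48, 2)]
        a = make_stereo_pair(48, 48, base, seed=3)
        b = make_stereo_pair(48, 48, shifted, seed=3)
        # embed the same texture shifted by one column
        b.left[:, 1:] = a.left[:, :-1]
        b.right[:, 1:] = a.right[:, :-1]
        b.left[:, 0] = a.left[:, 0]
        b.right[:, 0] = a.right[:, 0]
        ma = disparity_map(a, bank)
        mb = disparity_map(b, bank)
        ok = ma.valid_mask[:, 12:-13] & mb.valid_mask[:, 13:-12]
        assert (ma.values[:, 12:-13] == mb.values[:, 13:-12])[ok].all()

    def test_oversized_geometry_rejected(self, bank):
        pair = _pair()
        with pytest.raises(ValueError):
            disparity_map(pair, bank, PipelineConfig(h=50))


class TestAverageError:
    def test_identical_maps_have_zero_error(self):
        truth = np.zeros((10, 10), dtype=int)
        assert average_error(truth.copy(), truth) == 0.0

    def test_one_wrong_quadrant_is_25_percent(self):
        truth = np.zeros((10, 10), dtype=int)
        est = truth.copy()
        est[:5, :5] = 1
        assert average_error(est, truth) == pytest.approx(25.0)

    def test_complement_labelling_is_100_percent(self):
        truth = np.zeros((8, 8), dtype=int)
        assert average_error(truth + 1, truth) == pytest.approx(100.0)

    def test_no_valid_pixels_signalled(self):
        truth = np.zeros((4, 4), dtype=int)
        dm = DisparityMap(values=truth.copy(), valid_mask=np.zeros_like(truth, bool))
        with pytest.raises(ValueError):
            average_error(dm, truth)
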