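"""Tests for disparity-cell structure, learning, tuning and coupling."""

import numpy as np
import pytest

from tswta.cell import (
    DisparityCellState,
    HalfHeightUndefined,
    TuningCurve,
    bias_toward,
    cell_response,
    couple_cells,
    hwhh,
    init_receptive_field,
    representable_disparities,
    train_cell,
    train_ensemble,
    tuning_curve,
)
from tswta.synth import make_pattern_set


class TestCapacity:
    @pytest.mark.parametrize("w,n", [(9, 4), (40, 20), (2, 1), (10, 5)])
    def test_known_widths(self, w, n):
        assert representable_disparities(w) == n

    def test_too_narrow_rejected(self):
        with pytest.raises(ValueError):
            representable_disparities(1)


class TestInitField:
    def test_range_and_shape(self):
        rf = init_receptive_field(9, 9, seed=1)
        assert rf.vfg1.shape == rf.vfg2.shape == (9, 9)
        for arr in (rf.vfg1, rf.vfg2):
            assert arr.min() >= 4.8 and arr.max() <= 5.5

    def test_same_seed_identical(self):
        a, b = (init_receptive_field(9, 9, seed=3) for _ in range(2))
        assert np.array_equal(a.vfg1, b.vfg1) and np.array_equal(a.vfg2, b.vfg2)

    def test_minimal_field(self):
        rf = init_receptive_field(1, 2, seed=0)
        assert rf.vfg1.shape == (1, 2)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            init_receptive_field(9, 9, seed=0, init_range=(5.0, 5.0))


class TestResponse:
    def test_symmetric_field_answers_half_to_everything(self, pattern_set):
        rf = init_receptive_field(9, 9, seed=0)
        rf.vfg1[:] = 5.1
        rf.vfg2[:] = 5.1
        cell = DisparityCellState(rf=rf)
        responses = {round(cell_response(cell, p), 12) for p in pattern_set}
        assert responses == {round(0.5 * cell.params.i_b, 12)}

    def test_template_match_is_maximal_anti_match_minimal(self, probes):
        target = probes[2]
        rf = init_receptive_field(9, 9, seed=5)
        rf.vfg1 = np.where(target.bits, 4.5, 6.0)
        rf.vfg2 = np.where(target.bits, 6.0, 4.5)
        cell = DisparityCellState(rf=rf)
        r = [cell_response(cell, p) for p in probes]
        assert np.argmax(r) == 2
        assert cell_response(cell, target) + cell_response(cell, target.complement()) \
            == pytest.approx(cell.params.i_b)
        assert cell_response(cell, target.complement()) < min(r)

    def test_dimension_mismatch_rejected(self, fresh_cell):
        bad = make_pattern_set(5, 9, 4)[0]
        with pytest.raises(ValueError):
            cell_response(fresh_cell, bad)


class TestTraining:
    def test_single_pattern_set_is_always_learned(self):
        pats = make_pattern_set(9, 9, 1, seed=3)
        cell = DisparityCellState(rf=init_receptive_field(9, 9, seed=8))
        cell, trace = train_cell(cell, pats, seed=1)
        assert cell.learned_disparity == 0
        assert trace.shape == (81, 1)

    def test_biased_cell_learns_its_target(self, pattern_set, probes):
        rf = bias_toward(init_receptive_field(9, 9, seed=21), probes[3], 0.3)
        cell, _ = train_cell(DisparityCellState(rf=rf), pattern_set, seed=2)
        assert cell.learned_disparity == 3

    def test_missing_complements_rejected(self, probes, fresh_cell):
        with pytest.raises(ValueError):
            train_cell(fresh_cell, list(probes), seed=0)

    def test_learning_selects_initial_argmax_when_clear(self, pattern_set):
        """With a clear initial preference, training amplifies it; only
        marginal (near-tie) initializations may flip."""
        checked = matched = 0
        for s in range(60):
            cell = DisparityCellState(rf=init_receptive_field(9, 9, seed=400 + s))
            r = np.array([cell_response(cell, p) for p in pattern_set])
            order = np.argsort(r)[::-1]
            if (r[order[0]] - r[order[1]]) / r[order[0]] < 0.01:
                continue  # marginal: either phase may win
            want = pattern_set[order[0]].disparity
            cell, _ = train_cell(cell, pattern_set, seed=700 + s)
            checked += 1
            matched += cell.learned_disparity == want
        assert checked >= 30
        assert matched / checked >= 0.9

    def test_tuning_sharpens_on_average(self, pattern_set):
        traces = []
        for s in range(25):
            cell = DisparityCellState(rf=init_receptive_field(9, 9, seed=50 + s))
            cell, trace = train_cell(cell, pattern_set, seed=150 + s)
            traces.append(trace[:, int(np.argmax(trace[-1]))])
        avg = np.mean(traces, axis=0)
        diffs = np.diff(avg)
        assert avg[-1] > avg[0] + 0.2
        # growth, then a saturated plateau (sub-millivolt wobble allowed)
        assert np.all(diffs >= -1e-3)
        assert np.all(diffs[:20] > 0)           # strict growth before saturation


class TestTuningCurve:
    def test_trained_cell_peaks_at_learned_disparity(self, pattern_set, probes):
        rf = bias_toward(init_receptive_field(9, 9, seed=31), probes[1], 0.3)
        cell, _ = train_cell(DisparityCellState(rf=rf), pattern_set, seed=4)
        curve = tuning_curve(cell, probes)
        assert curve.disparities[int(np.argmax(curve.responses))] == 1

    def test_untrained_symmetric_cell_is_flat(self, probes):
        rf = init_receptive_field(9, 9, seed=0)
        rf.vfg1[:] = rf.vfg2[:] = 5.0
        curve = tuning_curve(DisparityCellState(rf=rf), probes)
        assert np.ptp(curve.responses) == pytest.approx(0.0)

    def test_bank_of_one(self, fresh_cell, probes):
        curve = tuning_curve(fresh_cell, probes[:1])
        assert len(curve.responses) == 1

    def test_empty_bank_rejected(self, fresh_cell):
        with pytest.raises(ValueError):
            tuning_curve(fresh_cell, [])


class TestHwhh:
    def test_triangle_closed_form(self):
        assert hwhh(TuningCurve([0, 1, 2], [0.0, 1.0, 0.0])) == pytest.approx(0.5)

    def test_shallow_shoulder_still_crosses_midheight(self):
        # half-height is (max+min)/2, so any non-flat curve crosses it
        # somewhere; a shallow rectangle gives the interpolated half-step
        assert hwhh(TuningCurve([0, 1, 2, 3], [0.8, 1.0, 0.8, 0.8])) == pytest.approx(0.5)

    def test_curve_never_reaching_half_inside_support_is_signalled(self):
        with pytest.raises(HalfHeightUndefined):
            hwhh(TuningCurve([2], [1.0]))

    def test_flat_curve_has_no_unique_peak(self):
        with pytest.raises(ValueError):
            hwhh(TuningCurve([0, 1, 2], [0.5, 0.5, 0.5]))

    def test_gaussian_matches_dense_grid_oracle(self):
        sigma = 1.8
        xs = np.arange(-6, 7)
        curve = TuningCurve(list(xs), list(np.exp(-(xs**2) / (2 * sigma**2))))
        # oracle: locate the half-height crossing on a dense grid
        dense = np.linspace(0, 6, 200001)
        y = np.exp(-(dense**2) / (2 * sigma**2))
        half = 0.5 * (1.0 + y.min())
        want = dense[np.argmin(np.abs(y - half))]
        assert hwhh(curve) == pytest.approx(want, abs=0.05)


class TestCoupling:
    def test_very_weak_coupling_behaves_like_uncoupled(self, pattern_set):
        rfs = [init_receptive_field(9, 9, seed=s) for s in (61, 62)]
        solo = []
        for rf in rfs:
            c, _ = train_cell(DisparityCellState(rf=rf.copy()), pattern_set, seed=9)
            solo.append(c.learned_disparity)
        ens = couple_cells(
            [DisparityCellState(rf=rf.copy()) for rf in rfs], [(0, 1)], r_c=1e12
        )
        train_ensemble(ens, pattern_set, seed=9)
        assert [c.learned_disparity for c in ens.cells] == solo

    def test_strong_coupling_spreads_the_stronger_bias(self, pattern_set, probes):
        rf_a = bias_toward(init_receptive_field(9, 9, seed=71), probes[2], 0.3)
        rf_b = init_receptive_field(9, 9, seed=72)
        ens = couple_cells(
            [DisparityCellState(rf=rf_a), DisparityCellState(rf=rf_b)], [(0, 1)], r_c=100.0
        )
        train_ensemble(ens, pattern_set, seed=11)
        assert ens.cells[0].learned_disparity == ens.cells[1].learned_disparity == 2

    def test_self_loops_rejected(self, fresh_cell):
        with pytest.raises(ValueError):
            couple_cells([fresh_cell], [(0, 0)])

    def test_buffer_is_one_way(self, pattern_set, fresh_cell):
        """An uncoupled cell's response is bit-identical no matter what a
        neighbour's output or diffusion node does."""
        probe = pattern_set[0]
        before = cell_response(fresh_cell, probe)
        neighbour = DisparityCellState(rf=init_receptive_field(9, 9, seed=99))
        neighbour.output_level = 123.0
        neighbour.diffusion_level = -7.0
        assert cell_response(fresh_cell, probe) == before

    def test_diffusion_solver_mixes_toward_neighbours(self, fresh_cell):
        cells = [fresh_cell, DisparityCellState(rf=init_receptive_field(9, 9, seed=1))]
        ens = couple_cells(cells, [(0, 1)], r_c=100.0)
        v = ens.diffusion_levels(np.array([1.0, 0.0]))
        assert 0.5 < v[0] < 1.0 and 0.0 < v[1] < 0.5
        assert v[0] + v[1] == pytest.approx(1.0, abs=1e-6)
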