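"""Generator behaviour: analytic transient shape, determinism, monotonic
effect injection, and the constructed variant tables."""

import numpy as np
import pandas as pd
import pytest

from caflux import (
    CellParams,
    GroupEffect,
    LayoutError,
    ParameterError,
    RoiLayout,
    RoiSpec,
    de_novo_variant,
    index_family_variant,
    plate_target_ratio,
    simulate_evoked_experiment,
    simulate_evoked_trace,
    simulate_image_stack,
    simulate_plate_traces,
    simulate_variant_table,
    transient,
    transient_peak,
    transient_time_to_peak,
)


class TestEvokedTrace:
    def test_no_signal_gives_constant_baseline(self, evoked_schedule):
        params = CellParams(
            amplitude_a=0.0, noise_sd=0.0, drift_per_s=0.0, soce_amplitude=0.0
        )
        tr = simulate_evoked_trace(evoked_schedule, params, seed=0)
        assert np.all(tr.values == params.baseline_f0)

    def test_same_seed_bit_identical(self, evoked_schedule):
        a = simulate_evoked_trace(evoked_schedule, seed=42)
        b = simulate_evoked_trace(evoked_schedule, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_different_seed_differs(self, evoked_schedule):
        a = simulate_evoked_trace(evoked_schedule, seed=1)
        b = simulate_evoked_trace(evoked_schedule, seed=2)
        assert not np.array_equal(a.values, b.values)

    def test_amplitude_multiplier_halves_peak(self, evoked_schedule, quiet_params):
        """With noise off, the max dF/F0 scales linearly in the multiplier,
        matching the closed-form transient maximum."""
        f0 = quiet_params.baseline_f0
        peaks = {}
        for mult in (0.5, 1.0):
            eff = GroupEffect(label="g", amplitude_multiplier=mult)
            params = CellParams(
                noise_sd=0.0, drift_per_s=0.0, soce_amplitude=0.0
            )
            tr = simulate_evoked_trace(evoked_schedule, params, eff, seed=0)
            peaks[mult] = (tr.values.max() - f0) / f0
        assert peaks[0.5] == pytest.approx(peaks[1.0] / 2, rel=1e-12)
        analytic = transient_peak(
            quiet_params.amplitude_a,
            quiet_params.tau_rise_s,
            quiet_params.tau_decay_s,
        )
        # 1 s sampling undershoots the continuous-time maximum only slightly
        assert peaks[1.0] == pytest.approx(analytic, rel=5e-3)

    def test_soce_transient_confined_to_readdition_phase(
        self, evoked_schedule, quiet_params
    ):
        params = CellParams(amplitude_a=0.0, noise_sd=0.0, drift_per_s=0.0)
        tr = simulate_evoked_trace(evoked_schedule, params, seed=0)
        before = tr.values[tr.time_s < 600.0]
        during = tr.values[tr.time_s >= 600.0]
        assert np.all(before == params.baseline_f0)
        assert during.max() > params.baseline_f0

    @pytest.mark.parametrize("mults", [(0.3, 0.6, 1.0, 1.5)])
    def test_auc_and_peak_monotone_in_amplitude_multiplier(
        self, evoked_schedule, mults
    ):
        params = CellParams(noise_sd=0.0, drift_per_s=0.0, soce_amplitude=0.0)
        aucs, peaks = [], []
        for m in mults:
            tr = simulate_evoked_trace(
                evoked_schedule, params, GroupEffect("g", amplitude_multiplier=m), seed=0
            )
            dff = (tr.values - params.baseline_f0) / params.baseline_f0
            aucs.append(np.trapezoid(dff, tr.time_s))
            peaks.append(dff.max())
        assert np.all(np.diff(aucs) > 0)
        assert np.all(np.diff(peaks) > 0)

    def test_time_to_peak_monotone_in_latency_shift(self, evoked_schedule):
        params = CellParams(noise_sd=0.0, drift_per_s=0.0, soce_amplitude=0.0)
        ttps = []
        for shift in (0.0, 5.0, 10.0):
            tr = simulate_evoked_trace(
                evoked_schedule, params, GroupEffect("g", latency_shift_s=shift), seed=0
            )
            ttps.append(tr.time_s[np.argmax(tr.values)])
        assert np.all(np.diff(ttps) > 0)


class TestTransientClosedForm:
    def test_peak_location_and_value(self):
        t = np.linspace(0, 300, 300_001)
        y = transient(t, 0.0, 2.0, 4.0, 30.0)
        s_star = transient_time_to_peak(4.0, 30.0)
        assert t[np.argmax(y)] == pytest.approx(s_star, abs=1e-2)
        assert y.max() == pytest.approx(transient_peak(2.0, 4.0, 30.0), rel=1e-9)

    def test_zero_before_onset(self):
        y = transient(np.array([-5.0, -0.1, 0.0, 1.0]), 0.0, 1.0, 2.0, 10.0)
        assert y[0] == 0.0 and y[1] == 0.0 and y[3] > 0


class TestCellParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"baseline_f0": 0.0},
            {"tau_rise_s": -1.0},
            {"tau_decay_s": 1.0, "tau_rise_s": 3.0},
            {"amplitude_a": -0.1},
            {"noise_sd": -1.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            CellParams(**kwargs)

    def test_negative_amplitude_multiplier_rejected(self):
        with pytest.raises(ParameterError):
            GroupEffect("g", amplitude_multiplier=-1.0)


class TestImageStack:
    def test_roi_mean_matches_trace_without_noise(
        self, evoked_schedule, three_roi_layout
    ):
        traces = [
            simulate_evoked_trace(evoked_schedule, seed=s, cell_id=f"c{s}")
            for s in range(3)
        ]
        stack, mask = simulate_image_stack(three_roi_layout, traces, seed=0)
        for roi, tr in zip(three_roi_layout.rois, traces):
            sel = mask == roi.label
            # every ROI pixel carries the trace value verbatim
            assert np.all(stack[:, sel] == tr.values[:, None])

    def test_background_at_fixed_level(self, evoked_schedule, three_roi_layout):
        traces = [
            simulate_evoked_trace(evoked_schedule, seed=s) for s in range(3)
        ]
        stack, mask = simulate_image_stack(three_roi_layout, traces, seed=0)
        assert np.all(stack[:, mask == 0] == three_roi_layout.background)

    def test_roi_outside_frame_rejected(self):
        with pytest.raises(LayoutError):
            RoiLayout(
                frame_shape=(16, 16),
                rois=(RoiSpec(label=1, y0=10, x0=10, height=10, width=4),),
            )

    def test_overlapping_rois_rejected(self):
        with pytest.raises(LayoutError):
            RoiLayout(
                frame_shape=(16, 16),
                rois=(
                    RoiSpec(label=1, y0=0, x0=0, height=8, width=8),
                    RoiSpec(label=2, y0=4, x0=4, height=8, width=8),
                ),
            )

    def test_trace_count_mismatch_rejected(self, evoked_schedule, three_roi_layout):
        traces = [simulate_evoked_trace(evoked_schedule, seed=0)]
        with pytest.raises(LayoutError):
            simulate_image_stack(three_roi_layout, traces, seed=0)


class TestPlateTraces:
    def test_zero_amplitude_group_is_flat(self, plate_schedule):
        eff = GroupEffect(label="flat", amplitude_multiplier=0.0)
        (well,) = simulate_plate_traces(plate_schedule, [eff], 1, seed=0)
        ratio = well.f340 / well.f380
        assert np.allclose(ratio, ratio[0])

    def test_amplitude_multiplier_doubles_normalized_peak(self, plate_schedule):
        from caflux.synthetic import PlateParams

        params = PlateParams(well_cv=0.0, noise_sd=0.0)
        peaks = {}
        for m in (1.0, 2.0):
            eff = GroupEffect(label="g", amplitude_multiplier=m)
            (well,) = simulate_plate_traces(
                plate_schedule, [eff], 1, seed=0, params=params
            )
            ratio = well.f340 / well.f380
            norm = ratio / ratio[well.time_s < 90].mean()
            peaks[m] = norm.max() - 1.0
        assert peaks[2.0] == pytest.approx(2 * peaks[1.0], rel=1e-9)

    def test_channels_strictly_positive(self, plate_schedule):
        wells = simulate_plate_traces(
            plate_schedule, [GroupEffect("a"), GroupEffect("b")], 4, seed=5
        )
        for w in wells:
            assert np.all(w.f340 > 0) and np.all(w.f380 > 0)

    def test_ratio_matches_target_curve_without_noise(self, plate_schedule):
        from caflux.synthetic import PlateParams

        params = PlateParams(well_cv=0.0, noise_sd=0.0)
        eff = GroupEffect("g", amplitude_multiplier=0.7)
        (well,) = simulate_plate_traces(
            plate_schedule, [eff], 1, seed=0, params=params
        )
        target = plate_target_ratio(plate_schedule, eff, params)
        rest_ratio = params.f340_rest / params.f380_rest
        assert np.allclose(well.f340 / well.f380, rest_ratio * target, rtol=1e-12)

    def test_determinism(self, plate_schedule):
        a = simulate_plate_traces(plate_schedule, [GroupEffect("g")], 2, seed=9)
        b = simulate_plate_traces(plate_schedule, [GroupEffect("g")], 2, seed=9)
        for wa, wb in zip(a, b):
            assert np.array_equal(wa.f340, wb.f340)
            assert np.array_equal(wa.f380, wb.f380)


class TestVariantTable:
    def test_row_count_and_determinism(self):
        spikes = [index_family_variant()]
        a = simulate_variant_table(50, spikes, seed=7)
        b = simulate_variant_table(50, spikes, seed=7)
        assert len(a) == 51
        pd.testing.assert_frame_equal(a, b)

    def test_spike_in_present_verbatim(self):
        spike = index_family_variant()
        table = simulate_variant_table(20, [spike], seed=1)
        hit = table[(table["pos"] == spike.pos) & (table["chrom"] == spike.chrom)]
        assert len(hit) == 1
        assert hit.iloc[0]["cadd"] == spike.cadd
        assert hit.iloc[0]["gt_P1"] == "0/1"

    def test_de_novo_constructor_profile(self):
        rec = de_novo_variant()
        assert rec.genotypes["P5"] == "0/1"
        assert rec.genotypes["father"] == "0/0"
        assert rec.genotypes["mother"] == "0/0"
        assert rec.cadd == 32.0


def test_experiment_generator_layout(evoked_schedule):
    traces, grouping = simulate_evoked_experiment(
        evoked_schedule, GroupEffect("control"), n_coverslips=3,
        cells_per_coverslip=4, seed=0,
    )
    assert len(traces) == 12
    assert len(set(grouping.values())) == 3
    assert all(t.id in grouping for t in traces)
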