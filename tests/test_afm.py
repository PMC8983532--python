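"""Force-distance curve analysis: contact point, events, map statistics."""

import numpy as np
import pytest

import desmoquant as dq
from desmoquant.core import DesmoquantError
from desmoquant.synthetic import CurveSimParams, MapSimParams, generate_force_curve


def _binding_params(**kw):
    defaults = dict(binding=True, unbinding_force_pN=50.0, step_position_nm=80.0,
                    n_points=1500)
    defaults.update(kw)
    return CurveSimParams(**defaults)


class TestContactPoint:
    def test_noiseless_curve_recovers_truth(self):
        curve, truth = generate_force_curve(_binding_params())
        assert dq.find_contact_point(curve) == pytest.approx(truth.contact_z_nm, abs=1.0)

    def test_shift_equivariance(self):
        curve, _ = generate_force_curve(_binding_params(baseline_noise_sd_pN=2.0,
                                                        rng_seed=11))
        z0 = dq.find_contact_point(curve)
        shifted = dq.ForceDistanceCurve(curve.z_nm + 37.0, curve.force_pN,
                                        "retract", curve.meta)
        assert dq.find_contact_point(shifted) == pytest.approx(z0 + 37.0, abs=1e-6)

    def test_pure_baseline_curve_raises(self):
        rng = np.random.default_rng(0)
        flat = dq.ForceDistanceCurve(np.linspace(0, 1500, 600),
                                     rng.normal(0, 3.0, 600), "retract")
        with pytest.raises(DesmoquantError):
            dq.find_contact_point(flat)


class TestEventDetection:
    def test_zero_noise_round_trip_is_exact(self):
        curve, truth = generate_force_curve(_binding_params())
        events = dq.detect_unbinding_events(curve, 6.0)
        assert len(events) == 1
        dz = curve.z_nm[1] - curve.z_nm[0]
        assert events[0].force_pN == pytest.approx(truth.force_pN, abs=1e-9)
        assert events[0].step_position_nm == pytest.approx(truth.step_position_nm,
                                                           abs=dz)

    def test_ramp_model_round_trip(self):
        curve, truth = generate_force_curve(_binding_params(tether_plateau=False))
        events = dq.detect_unbinding_events(curve, 6.0)
        assert len(events) == 1
        dz = curve.z_nm[1] - curve.z_nm[0]
        slope = truth.force_pN / truth.step_position_nm
        assert events[0].force_pN == pytest.approx(truth.force_pN, abs=5 * slope * dz)

    def test_nonbinding_curve_yields_no_events(self):
        curve, truth = generate_force_curve(CurveSimParams(binding=False))
        assert dq.detect_unbinding_events(curve, 6.0) == []
        beyond = curve.z_nm > truth.contact_z_nm
        assert np.abs(curve.force_pN[beyond]).max() == 0.0

    def test_infinite_threshold_suppresses_all_events(self):
        curve, _ = generate_force_curve(_binding_params(baseline_noise_sd_pN=5.0,
                                                        rng_seed=3))
        assert dq.detect_unbinding_events(curve, np.inf) == []

    def test_false_positive_rate_below_one_percent(self):
        """Non-binding curves at noise 5 pN, threshold 6 sigma: < 1% of 500
        replicates may report an event."""
        n_fp = 0
        for seed in range(500):
            curve, _ = generate_force_curve(CurveSimParams(
                binding=False, baseline_noise_sd_pN=5.0, n_points=800,
                rng_seed=seed))
            if dq.detect_unbinding_events(curve, 6.0):
                n_fp += 1
        assert n_fp / 500 < 0.01

    def test_parameter_recovery_at_snr_10(self):
        """200 binding curves at SNR 10: >= 95% detected, median force error
        < 5%, median step-position error < 5 nm."""
        forces, steps, detected = [], [], 0
        for seed in range(200):
            curve, truth = generate_force_curve(_binding_params(
                baseline_noise_sd_pN=5.0, n_points=1000, rng_seed=seed))
            events = dq.detect_unbinding_events(curve, 6.0)
            if events:
                detected += 1
                ev = max(events, key=lambda e: e.force_pN)
                forces.append(ev.force_pN)
                steps.append(ev.step_position_nm)
        assert detected / 200 >= 0.95
        assert abs(np.median(forces) - 50.0) / 50.0 < 0.05
        assert abs(np.median(steps) - 80.0) < 5.0


class TestMapStatistics:
    def _small_map(self, p_border, p_surface, seed=0, noise=5.0):
        return dq.generate_force_map(MapSimParams(
            region_um=(3.0, 1.0), grid_spacing_um=0.1,
            border_stripe=dq.synthetic.BorderStripe(center_um=0.5, width_um=0.4),
            p_bind_border=p_border, p_bind_surface=p_surface,
            curve_params=CurveSimParams(n_points=500, baseline_noise_sd_pN=noise),
            rng_seed=seed))

    def test_all_bound_gives_unit_frequency_and_coefficient(self):
        fmap = self._small_map(1.0, 1.0, noise=0.0)
        stats = dq.map_statistics(fmap)
        assert stats.binding_frequency == pytest.approx(1.0)
        assert stats.distribution_coefficient == pytest.approx(1.0)

    def test_uniform_binding_gives_coefficient_near_one(self):
        fmap = self._small_map(0.3, 0.3, seed=5)
        stats = dq.map_statistics(fmap)
        se = np.sqrt(0.3 * 0.7 * (1 / stats.n_border_px + 1 / stats.n_surface_px)) / 0.3
        assert abs(stats.distribution_coefficient - 1.0) <= 3 * se

    def test_no_surface_binding_reports_undefined_coefficient(self):
        fmap = self._small_map(1.0, 0.0, noise=0.0)
        stats = dq.map_statistics(fmap)
        assert stats.distribution_coefficient is None
        assert stats.n_border_px > 0 and stats.n_surface_px > 0

    def test_detection_matches_bernoulli_truth(self):
        fmap = self._small_map(0.6, 0.3, seed=2)
        dq.afm.analyze_map(fmap)
        bound = np.array([[len(e) > 0 for e in row] for row in fmap.events])
        assert np.array_equal(bound, fmap.truth["binding"])


class TestPoolEvents:
    def test_pooled_rows_equal_total_events_and_bounded_by_curves(self):
        maps = [dq.generate_force_map(MapSimParams(
            region_um=(2.0, 1.0), grid_spacing_um=0.2,
            border_stripe=dq.synthetic.BorderStripe(center_um=0.5, width_um=0.4),
            curve_params=CurveSimParams(n_points=400, baseline_noise_sd_pN=5.0),
            rng_seed=s)) for s in (1, 2)]
        table = dq.pool_events(maps, ["a", "b"])
        total = sum(len(e) for m in maps for row in m.events for e in row)
        assert len(table) == total
        assert len(table) <= sum(m.n_curves for m in maps)

    def test_empty_maps_pool_to_empty_table(self):
        fmap = dq.generate_force_map(MapSimParams(
            region_um=(1.0, 1.0), grid_spacing_um=0.2,
            border_stripe=dq.synthetic.BorderStripe(center_um=0.5, width_um=0.4),
            p_bind_border=0.0, p_bind_surface=0.0,
            curve_params=CurveSimParams(n_points=400), rng_seed=1))
        assert len(dq.pool_events([fmap])) == 0

    def test_pooling_is_order_invariant(self):
        maps = [dq.generate_force_map(MapSimParams(
            region_um=(1.0, 1.0), grid_spacing_um=0.2,
            border_stripe=dq.synthetic.BorderStripe(center_um=0.5, width_um=0.4),
            curve_params=CurveSimParams(n_points=400), rng_seed=s))
            for s in (3, 4)]
        t1 = dq.pool_events(maps, ["a", "b"])
        t2 = dq.pool_events(maps[::-1], ["b", "a"])
        key = ["group", "row", "col", "force_pN"]
        assert sorted(map(tuple, t1[key].values.tolist())) == \
            sorted(map(tuple, t2[key].values.tolist()))
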