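"""Synthetic dynamic-MRS generator: construction, confounds, determinism."""

import numpy as np
import pytest

from mrsglm.core import (
    AcquisitionParams,
    MrsInputError,
    Spectrum,
    TaskDesign,
    fids_to_display,
    ppm_slice,
)
from mrsglm import synthdata as sd
from mrsglm.quality import fwhm_ppm, snr_single_shot


def lactate_only_table(effect=0.2, shape="boxcar"):
    # no other resonances, so the band integral scales exactly with the task
    return sd.ResonanceTable([
        sd.TableEntry("lactate",
                      [sd.Resonance(1.28, 0.5), sd.Resonance(1.35, 0.5)],
                      sd.DynamicResponse(shape, effect)),
    ])


class TestResponses:
    def test_boxcar_response_limits(self, study_task):
        r = sd.DynamicResponse("boxcar", 0.2)
        t = np.array([0.0, 179.0, 180.0, 659.0, 660.0, 1499.0])
        assert list(r.response(t, study_task)) == [0, 0, 1, 1, 0, 0]

    def test_lagged_trapezoid_ramps_and_decays(self, study_task):
        r = sd.DynamicResponse("lagged_trapezoid", 0.2, lag_s=120, decay_s=120)
        t = np.array([180.0, 240.0, 300.0, 660.0, 720.0, 780.0, 1000.0])
        expected = [0.0, 0.5, 1.0, 1.0, 0.5, 0.0, 0.0]
        assert np.allclose(r.response(t, study_task), expected)

    def test_constant_ignores_effect(self, study_task):
        r = sd.DynamicResponse("constant", 0.5)
        assert np.all(r.amplitude_factor(np.arange(0, 1500, 100.0),
                                         study_task) == 1.0)


class TestSimulateScan:
    def test_noise_only_scan_is_white(self, params, small_task):
        table = sd.ResonanceTable([sd.TableEntry("tCr",
                                                 [sd.Resonance(3.03, 0.0)])])
        conf = sd.no_confounds(noise_sd=1.0)
        scan = sd.simulate_scan(table, conf, params, small_task, 150, seed=0)
        spec = scan.spectra()
        # zero mean and flat per-bin variance across frequency
        assert np.abs(spec.mean()) < 0.5
        var = np.var(np.real(spec), axis=0)
        assert var.mean() == pytest.approx(params.n_points, rel=0.05)
        lo, hi = np.quantile(var / params.n_points, [0.001, 0.999])
        assert lo > 0.5 and hi < 1.6

    def test_boxcar_effect_scales_band_integral_exactly(self, params,
                                                        small_task):
        scan = sd.simulate_scan(lactate_only_table(), sd.no_confounds(),
                                params, small_task, 150, seed=0)
        spec = np.real(scan.spectra())
        sl = ppm_slice(params.ppm_axis(), 1.24, 1.40)
        course = spec[:, sl].sum(axis=1)
        times = scan.times_s()
        task = (times >= 60) & (times < 180)
        ratio = course[task].mean() / course[~task].mean()
        assert ratio == pytest.approx(1.20, rel=1e-9)

    def test_drift_scales_linewidth_by_stated_fraction(self, params,
                                                       small_task):
        table = sd.ResonanceTable([
            sd.TableEntry("tNAA", [sd.Resonance(2.01, 1.0)]),
            sd.TableEntry("tCr", [sd.Resonance(3.03, 1.0)]),
        ])
        conf = sd.no_confounds()
        conf.drift_fwhm_frac = 0.40
        scan = sd.simulate_scan(table, conf, params, small_task, 150, seed=0)
        axis = params.ppm_axis()
        first = fwhm_ppm(Spectrum(fids_to_display(scan.fids[0]), axis), 2.01, 0.3)
        last = fwhm_ppm(Spectrum(fids_to_display(scan.fids[-1]), axis), 2.01, 0.3)
        assert last / first == pytest.approx(1.40, rel=0.03)

    def test_linearity_of_resonance_tables(self, params, small_task):
        t1 = sd.ResonanceTable([sd.TableEntry("tCr", [sd.Resonance(3.03, 1.0)])])
        t2 = sd.ResonanceTable([sd.TableEntry("tNAA", [sd.Resonance(2.01, 0.7)])])
        both = sd.ResonanceTable(t1.entries + t2.entries)
        from mrsglm.core import TaskDesign
        kw = dict(params=params, task=TaskDesign(4, 6, 10), n_transients=10,
                  seed=0)
        sum_fids = (sd.simulate_scan(t1, sd.no_confounds(), **kw).fids
                    + sd.simulate_scan(t2, sd.no_confounds(), **kw).fids)
        assert np.allclose(sd.simulate_scan(both, sd.no_confounds(), **kw).fids,
                           sum_fids, atol=1e-12)

    def test_inconsistent_timing_rejected(self, params, small_task):
        with pytest.raises(MrsInputError):
            sd.simulate_scan(sd.default_table(), sd.no_confounds(), params,
                             small_task, 99, seed=0)


class TestCohort:
    def test_same_seed_is_bit_identical(self, params, small_task):
        conf = sd.study_confounds(31.0, params=params)
        a = sd.simulate_cohort(3, sd.default_table(), conf, params, small_task,
                               150, seed=42)
        b = sd.simulate_cohort(3, sd.default_table(), conf, params, small_task,
                               150, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x.fids, y.fids)

    def test_single_scan_cohort_matches_seed_derivation(self, params,
                                                        small_task):
        conf = sd.study_confounds(31.0, params=params)
        cohort = sd.simulate_cohort(1, sd.default_table(), conf, params,
                                    small_task, 150, seed=5)
        child = np.random.SeedSequence(5).spawn(1)[0]
        direct = sd.simulate_scan(sd.default_table(), conf, params, small_task,
                                  150, seed=child)
        assert np.array_equal(cohort[0].fids, direct.fids)

    def test_lipid_amplitude_follows_inverse_sqrt_n_law(self, small_task):
        # random per-scan phases: the artefact in an N-scan average falls
        # as N^(-1/2); compare N=5 vs N=20 over repetitions
        p = AcquisitionParams(n_points=512)
        table = sd.ResonanceTable([sd.TableEntry("tCr",
                                                 [sd.Resonance(3.03, 1.0)])])
        conf = sd.no_confounds()
        conf.lipid_amplitude_frac = 0.15

        def residual(n_scans, seed):
            scans = sd.simulate_cohort(n_scans, table, conf, p, small_task,
                                       150, seed=seed)
            mean = np.mean([s.mean_fid() for s in scans], axis=0)
            spec = np.real(fids_to_display(mean))
            sl = ppm_slice(p.ppm_axis(), 1.0, 1.5)
            tcr = spec[ppm_slice(p.ppm_axis(), 2.98, 3.08)].max()
            return np.abs(spec[sl]).max() / tcr

        reps = 60
        r5 = np.mean([residual(5, 1000 + i) for i in range(reps)])
        r20 = np.mean([residual(20, 5000 + i) for i in range(reps)])
        assert r5 / r20 == pytest.approx(2.0, rel=0.25)
        assert r20 == pytest.approx(0.15 / np.sqrt(20), rel=0.45)


class TestNoiseCalibration:
    def test_noise_sd_inversely_proportional_to_target(self, params):
        table = sd.default_table()
        assert sd.calibrate_noise(table, params, 62.0) == pytest.approx(
            sd.calibrate_noise(table, params, 31.0) / 2)

    def test_round_trip_through_snr_estimator(self, params, small_task):
        table = sd.default_table(0, 0, 0)
        sigma = sd.calibrate_noise(table, params, 31.0)
        conf = sd.no_confounds(noise_sd=sigma)
        scan = sd.simulate_scan(table, conf, params, small_task, 150, seed=3)
        axis = params.ppm_axis()
        spec = scan.spectra()
        snrs = [snr_single_shot(Spectrum(spec[i], axis)) for i in range(150)]
        assert np.median(snrs) == pytest.approx(31.0, rel=0.10)

    def test_table_without_tnaa_rejected(self, params):
        table = sd.ResonanceTable([sd.TableEntry("tCr",
                                                 [sd.Resonance(3.03, 1.0)])])
        with pytest.raises(MrsInputError):
            sd.calibrate_noise(table, params, 31.0)


class TestScenarioSerialisation:
    def test_round_trip(self, params, small_task):
        table = sd.default_table()
        conf = sd.study_confounds(31.0, table, params)
        d = sd.scenario_to_dict(table, conf, params, small_task, 150, 3)
        t2, c2, p2, task2, n_tr, n_sc = sd.scenario_from_dict(d)
        assert p2 == params and task2 == small_task
        assert (n_tr, n_sc) == (150, 3)
        assert t2.names() == table.names()
        assert c2.noise_sd == conf.noise_sd

    def test_default_table_covers_required_resonances(self):
        table = sd.default_table()
        ppms = sorted(r.ppm for e in table.entries for r in e.resonances)
        for required in (2.01, 3.03, 3.92, 3.22, 1.28, 1.35, 2.35, 2.74,
                         2.78, 3.55, 3.59):
            assert any(abs(x - required) < 1e-9 for x in ppms)
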