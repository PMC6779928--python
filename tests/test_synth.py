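"""Synthetic cohort generator: determinism, planted effects, behaviour."""
import numpy as np
import pytest
from scipy.stats import binom

from srmeeg.connectivity import analytic_phase, pli_timeseries, window_pli
from srmeeg.epochs import CONDITIONS
from srmeeg.preprocess import bandpass
from srmeeg.synth import (SimulationConfig, expected_pli, gen_behavior,
                          gen_cohort, gen_epoch_set, iter_cohort,
                          subject_latents)
from srmeeg.timefreq import WaveletSpec, band_window_mean, evoked_power

ALPHA_SPEC = WaveletSpec(grid=np.arange(8.0, 13.1, 0.5))


def _amps(val):
    return {g: {c: val for c in CONDITIONS} for g in ("control", "patient")}


def _cons(val):
    return {g: {c: val for c in CONDITIONS} for g in ("control", "patient")}


def small_config(**kw):
    base = dict(n_per_group=2, n_channels=4, fs=250.0,
                n_trials_per_condition=10, seed=7)
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_same_seed_identical_arrays(self):
        cfg = small_config()
        a = gen_epoch_set(cfg, "control-00", "control", "self", seed=42)
        b = gen_epoch_set(cfg, "control-00", "control", "self", seed=42)
        assert np.array_equal(a.data, b.data)

    def test_different_seed_differs(self):
        cfg = small_config()
        a = gen_epoch_set(cfg, "control-00", "control", "self", seed=42)
        b = gen_epoch_set(cfg, "control-00", "control", "self", seed=43)
        assert not np.array_equal(a.data, b.data)

    def test_behavior_same_seed_same_counts(self):
        cfg = small_config()
        a = gen_behavior(cfg, "patient-01", "patient", seed=5)
        b = gen_behavior(cfg, "patient-01", "patient", seed=5)
        assert a.conditions == b.conditions

    def test_cohort_regeneration_bit_identical(self):
        cfg = small_config()
        c1 = gen_cohort(cfg)
        c2 = gen_cohort(cfg)
        for key in c1.epoch_sets:
            assert np.array_equal(c1.epoch_sets[key].data,
                                  c2.epoch_sets[key].data)
        for sid in c1.behavior:
            assert c1.behavior[sid].conditions == c2.behavior[sid].conditions

    def test_subject_latents_stable_across_conditions(self):
        cfg = small_config()
        lat1 = subject_latents(cfg, "control-01")
        lat2 = subject_latents(cfg, "control-01")
        assert lat1 == lat2


class TestCohortStructure:
    def test_subject_and_epoch_set_counts(self):
        cohort = gen_cohort(small_config())
        assert len(cohort.subjects) == 4
        assert len(cohort.epoch_sets) == 12  # subjects x 3 conditions
        assert len(cohort.behavior) == 4

    def test_epoch_set_shape_and_metadata(self):
        cfg = small_config()
        es = gen_epoch_set(cfg, "patient-00", "patient", "other", seed=1)
        assert es.data.shape == (4, 275, 10)
        assert es.t0 == -300.0
        assert es.group == "patient" and es.condition == "other"

    def test_iter_matches_eager_generation(self):
        cfg = small_config()
        eager = gen_cohort(cfg)
        for sid, group, cond, es in iter_cohort(cfg):
            assert np.array_equal(es.data, eager.epoch_sets[(sid, cond)].data)

    def test_invalid_labels_rejected(self):
        cfg = small_config()
        with pytest.raises(ValueError):
            gen_epoch_set(cfg, "x", "ghosts", "self", seed=0)
        with pytest.raises(ValueError):
            gen_epoch_set(cfg, "x", "control", "dreaming", seed=0)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError, match="span"):
            small_config(burst_window=(700.0, 900.0))
        with pytest.raises(ValueError, match="consistency"):
            small_config(coupling_consistency=_cons(0.3))
        with pytest.raises(ValueError, match="integer"):
            small_config(fs=499.7)


class TestPlantedSignal:
    def test_zero_burst_amp_means_no_evoked_alpha(self):
        """Without a planted burst the active window is noise-floor flat."""
        cfg = small_config(burst_amp=_amps(0.0), coupling_amp=0.0,
                           n_trials_per_condition=30)
        active, base = [], []
        for seed in range(25):
            es = gen_epoch_set(cfg, "control-00", "control", "self",
                               seed=seed)
            tf = evoked_power(es, ALPHA_SPEC)
            active.append(band_window_mean(tf, (8, 13), (100, 300)))
            base.append(band_window_mean(tf, (8, 13), (-150, 50)))
        from srmeeg.stats import ttest_ind
        assert ttest_ind(active, base).p > 0.01

    def test_burst_amp_monotonically_raises_evoked_power(self):
        powers = []
        for amp in (0.5, 1.0, 2.0, 4.0):
            cfg = small_config(burst_amp=_amps(amp), coupling_amp=0.0,
                               alpha_amp_cv=0.0)
            vals = [band_window_mean(
                evoked_power(gen_epoch_set(cfg, "control-00", "control",
                                           "self", seed=s), ALPHA_SPEC),
                (8, 13), (100, 300)) for s in range(6)]
            powers.append(np.mean(vals))
        assert np.all(np.diff(powers) > 0)

    def test_full_consistency_drives_pli_to_one(self):
        cfg = small_config(
            n_channels=2, n_trials_per_condition=70,
            burst_amp=_amps(0.0), coupling_consistency=_cons(1.0),
            coupled_edge_set=[(0, 1)], consistency_sd=0.0, noise_rms=2.0)
        es = gen_epoch_set(cfg, "control-00", "control", "self", seed=3)
        ph = analytic_phase(bandpass(es, 8, 13), check_band=False)
        m = window_pli(pli_timeseries(ph), (100.0, 300.0))
        assert m.m[0, 1] > 0.98

    def test_consistency_monotonically_raises_pli(self):
        vals = []
        for p in (0.6, 0.75, 0.9, 1.0):
            cfg = small_config(
                n_channels=2, n_trials_per_condition=70,
                burst_amp=_amps(0.0), coupling_consistency=_cons(p),
                coupled_edge_set=[(0, 1)], consistency_sd=0.0, noise_rms=2.0)
            runs = []
            for s in range(8):
                es = gen_epoch_set(cfg, "control-00", "control", "self",
                                   seed=s)
                ph = analytic_phase(bandpass(es, 8, 13), check_band=False)
                runs.append(window_pli(pli_timeseries(ph),
                                       (100.0, 300.0)).m[0, 1])
            vals.append(np.mean(runs))
        assert np.all(np.diff(vals) > 0)

    def test_coupling_is_not_phase_locked(self):
        """Antithetic phase pairing keeps coupling out of evoked power."""
        cfg = small_config(n_channels=2, n_trials_per_condition=70,
                           burst_amp=_amps(0.0),
                           coupled_edge_set=[(0, 1)], noise_rms=0.0)
        es = gen_epoch_set(cfg, "control-00", "control", "self", seed=4)
        # raw per-trial alpha source is strong ...
        assert es.data.std() > 1.0
        # ... yet the trial average cancels (up to one unpaired trial)
        resid = np.abs(es.data.mean(axis=2)).max()
        assert resid < 3 * cfg.coupling_amp / cfg.n_trials_per_condition


class TestBehaviour:
    def test_perfect_memory_scores_one(self):
        bp = {
            "p_hit": {g: {c: 1.0 for c in CONDITIONS}
                      for g in ("control", "patient")},
            "p_fa": {g: {c: 0.0 for c in CONDITIONS}
                     for g in ("control", "patient")},
            "n_old": 70, "n_new": 30,
        }
        cfg = small_config(behavior_params=bp, mem_sd=0.0, bias_sd=0.0,
                           power_bias_corr={"control": 0.0, "patient": 0.0})
        rec = gen_behavior(cfg, "control-00", "control", seed=0)
        for cond in CONDITIONS:
            assert rec.recognition(cond) == 1.0

    def test_expected_bias_matches_binomial_expectation(self):
        bp = {
            "p_hit": {"control": {"self": 0.8, "other": 0.65,
                                  "physical": 0.65},
                      "patient": {"self": 0.8, "other": 0.65,
                                  "physical": 0.65}},
            "p_fa": {g: {c: 0.3 for c in CONDITIONS}
                     for g in ("control", "patient")},
            "n_old": 70, "n_new": 100,
        }
        cfg = small_config(behavior_params=bp, mem_sd=0.0, bias_sd=0.0,
                           power_bias_corr={"control": 0.0, "patient": 0.0})
        biases = [gen_behavior(cfg, "control-00", "control", seed=s).srm_bias
                  for s in range(1000)]
        se = np.std(biases, ddof=1) / np.sqrt(len(biases))
        assert abs(np.mean(biases) - 0.15) < 3 * se

    def test_invalid_item_counts_rejected(self):
        bp = {
            "p_hit": {g: {c: 0.5 for c in CONDITIONS}
                      for g in ("control", "patient")},
            "p_fa": {g: {c: 0.1 for c in CONDITIONS}
                     for g in ("control", "patient")},
            "n_old": 0, "n_new": 30,
        }
        with pytest.raises(ValueError):
            small_config(behavior_params=bp)


class TestGroundTruth:
    def test_expected_pli_matches_direct_binomial_simulation(self, rng):
        for p in (0.6, 0.9):
            draws = np.abs(2 * rng.binomial(70, p, 40000) / 70 - 1)
            assert abs(expected_pli(p, 70) - draws.mean()) < 0.005

    def test_expected_pli_closed_form_endpoints(self):
        assert expected_pli(1.0, 70) == pytest.approx(1.0)
        # symmetric p = 0.5: mean |2B/N - 1| from the exact pmf
        n = 10
        exact = sum(binom.pmf(k, n, 0.5) * abs(2 * k / n - 1)
                    for k in range(n + 1))
        assert expected_pli(0.5, n) == pytest.approx(exact)

    def test_ground_truth_contrast_signs(self):
        gt = gen_cohort(small_config()).ground_truth
        signs = gt["contrast_signs"]
        assert signs["alpha_power_patient_minus_control_self"] == -1
        assert signs["alpha_power_patient_minus_control_physical"] == 0
        assert signs["pli_patient_minus_control_self"] == -1
        assert signs["e_global_patient_minus_control_self"] == 1
        assert signs["cpl_patient_minus_control_self"] == 0
        assert gt["expected_coupled_pli"]["control"]["self"] == \
            pytest.approx(expected_pli(0.85, 10))
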