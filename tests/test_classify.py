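"""Peri-event rates and MF / PC-SS response classification."""

import numpy as np
import pytest

from vermis.classify import (
    PeriEventRate,
    SimpleSpikeClassifier,
    classify_mf_unit,
    classify_pc_pca_lda,
    detect_modulation_bounds,
    find_local_extrema,
    gaussian_smooth,
    label_pc_by_threshold,
    perievent_rate,
)
from vermis.synth import SessionConfig, generate_session


def _rate(config, mean, t=None):
    t = t if t is not None else np.arange(
        config.mf_grid_start_ms, config.mf_grid_stop_ms, config.bin_ms
    ) + config.bin_ms / 2
    return PeriEventRate(time_ms=t, mean_rate=np.asarray(mean, float),
                         per_trial=np.asarray(mean, float)[None, :])


class TestPerieventRate:
    def test_single_spike_unit_conversion(self):
        pr = perievent_rate([np.array([0.0])], -10.0, 10.0, 1.0)
        assert pr.mean_rate[pr.window_mask(0.0, 1.0)][0] == 1000.0
        assert pr.mean_rate.sum() == 1000.0

    def test_gaussian_mass_preserved(self):
        pr = perievent_rate([np.array([0.5])], -100.0, 100.0, 1.0, smoothing_sd_ms=5.0)
        assert pr.mean_rate.sum() == pytest.approx(1000.0, abs=1e-6)
        center = pr.mean_rate[pr.window_mask(0.0, 1.0)][0]
        assert center == pytest.approx(1000.0 / (np.sqrt(2 * np.pi) * 5.0), rel=1e-3)

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(0)
        trains = [np.sort(rng.uniform(-250, 400, rng.poisson(0.05 * 650)))
                  for _ in range(200)]
        pr = perievent_rate(trains, -250.0, 400.0, 1.0)
        sem = pr.per_trial.mean(axis=1).std() / np.sqrt(200)
        assert abs(pr.mean_rate.mean() - 50.0) < 3 * sem + 0.5

    def test_empty_trials_error(self):
        with pytest.raises(ValueError):
            perievent_rate([], -10, 10)


class TestLocalExtrema:
    def test_prominence_filters_shallow_peak(self):
        y = np.array([0, 5, 4.5, 5.2, 0, 0], float)
        assert list(find_local_extrema(y, 1, 2.0)) == [3]
        assert set(find_local_extrema(y, 1, 0.1)) == {1, 3}

    def test_min_distance_keeps_higher(self):
        y = np.array([0, 3, 0, 5, 0], float)
        assert list(find_local_extrema(y, 3, 0.0)) == [3]

    def test_minima(self):
        y = np.array([0, -4, 0, -2, 0], float)
        assert list(find_local_extrema(y, 1, 3.0, kind="min")) == [1]


class TestMFClassification:
    @pytest.fixture(scope="class")
    def mf_rates(self, medium_session, config):
        _, bundle, units, _ = medium_session
        cf = bundle.trials[bundle.trials["type"] == "centrifugal"]
        keep = set(cf["trial_index"].astype(int))
        out = []
        for rec in units:
            if rec.kind != "MF":
                continue
            trains = [sp for ti, sp in zip(rec.trial_index, rec.spikes) if ti in keep]
            pr = perievent_rate(trains, config.mf_grid_start_ms,
                                config.mf_grid_stop_ms, config.bin_ms)
            out.append((rec.class_label, pr))
        return out

    def test_accuracy_on_generator_units(self, mf_rates, config):
        hits = [classify_mf_unit(pr, config) == lab for lab, pr in mf_rates]
        assert np.mean(hits) >= 0.9

    def test_constant_shift_invariance(self, mf_rates, config):
        for lab, pr in mf_rates[:6]:
            shifted = PeriEventRate(pr.time_ms, pr.mean_rate + 37.0, pr.per_trial + 37.0)
            assert classify_mf_unit(shifted, config) == classify_mf_unit(pr, config)

    def test_missing_window_error(self, config):
        pr = perievent_rate([np.array([0.0])], -100.0, 100.0, 1.0)
        with pytest.raises(ValueError):
            classify_mf_unit(pr, config)


class TestModulationBounds:
    def test_rectangular_burst(self, config):
        t = np.arange(config.mf_grid_start_ms, config.mf_grid_stop_ms,
                      config.bin_ms) + 0.5
        rng = np.random.default_rng(0)
        r = np.where((t >= -20) & (t < 60), 100.0, 5.0) + 0.05 * rng.standard_normal(t.size)
        onset, offset = detect_modulation_bounds(_rate(config, r, t), 60.0, config)
        assert onset == pytest.approx(-20, abs=2)
        assert offset == pytest.approx(60, abs=2)

    def test_flat_rate_no_modulation(self, config):
        t = np.arange(config.mf_grid_start_ms, config.mf_grid_stop_ms,
                      config.bin_ms) + 0.5
        assert detect_modulation_bounds(_rate(config, np.full_like(t, 20.0), t),
                                        60.0, config) is None

    def test_burst_offset_tracks_duration(self, medium_session, config):
        """LLB burst offsets regress linearly on saccade duration."""
        from vermis.behavior import bin_by_peak_velocity
        from scipy.stats import linregress

        _, bundle, units, _ = medium_session
        cf = bundle.trials[bundle.trials["type"] == "centrifugal"]
        bins = bin_by_peak_velocity(cf, config)
        llb = [u for u in units if u.class_label == "LLB"]
        durs, offs = [], []
        for key, sub in bins.items():
            keep = set(sub["trial_index"].astype(int))
            pooled = [sp for u in llb
                      for ti, sp in zip(u.trial_index, u.spikes) if ti in keep]
            pr = perievent_rate(pooled, config.mf_grid_start_ms,
                                config.mf_grid_stop_ms, config.bin_ms)
            b = detect_modulation_bounds(pr, float(sub["duration_ms"].mean()), config)
            if b is not None:
                durs.append(sub["duration_ms"].mean())
                offs.append(b[1])
        fit = linregress(durs, offs)
        assert fit.rvalue**2 >= 0.9
        assert fit.slope > 0


class TestPCThresholdLabels:
    def _template(self, config, kind, amp=60.0):
        t = np.arange(config.mf_grid_start_ms, config.mf_grid_stop_ms,
                      config.bin_ms) + 0.5
        g1 = np.exp(-0.5 * ((t - 30) / 14.0) ** 2)
        g2 = np.exp(-0.5 * ((t - 65) / 14.0) ** 2)
        base = 70.0
        shapes = {
            "burst": base + amp * g1,
            "pause": base - amp * g1,
            "burst-pause": base + amp * g1 - 0.8 * amp * g2,
            "pause-burst": base - amp * g1 + 0.8 * amp * g2,
        }
        # tiny baseline jitter so the significance SD is nonzero
        rng = np.random.default_rng(0)
        return _rate(config, shapes[kind] + 0.2 * rng.standard_normal(t.size), t)

    @pytest.mark.parametrize("kind", ["burst", "pause", "burst-pause", "pause-burst"])
    def test_templates(self, config, kind):
        assert label_pc_by_threshold(self._template(config, kind), 60.0, config) == kind

    def test_subthreshold_unlabeled(self, config):
        assert label_pc_by_threshold(self._template(config, "burst", amp=0.5),
                                     60.0, config) == "unlabeled"

    def test_accuracy_on_generator_units(self, medium_session, config):
        _, bundle, units, _ = medium_session
        cf = bundle.trials[bundle.trials["type"] == "centrifugal"]
        keep = set(cf["trial_index"].astype(int))
        mean_dur = float(cf["duration_ms"].mean())
        hits = []
        for rec in units:
            if rec.kind != "PC":
                continue
            trains = [sp for ti, sp in zip(rec.trial_index, rec.spikes) if ti in keep]
            pr = perievent_rate(trains, config.mf_grid_start_ms,
                                config.mf_grid_stop_ms, config.bin_ms,
                                smoothing_sd_ms=config.ss_smoothing_sd_ms)
            hits.append(label_pc_by_threshold(pr, mean_dur, config) == rec.class_label)
        assert np.mean(hits) >= 0.9


class TestPCALDA:
    @pytest.fixture(scope="class")
    def templates(self, config):
        rng = np.random.default_rng(1)
        t = np.arange(-250, 400, 1.0)
        g1 = np.exp(-0.5 * ((t - 30) / 14.0) ** 2)
        g2 = np.exp(-0.5 * ((t - 65) / 14.0) ** 2)
        shapes = {
            "burst": g1, "pause": -g1,
            "burst-pause": g1 - 0.8 * g2, "pause-burst": -g1 + 0.8 * g2,
        }
        X, y = [], []
        for name, shape in shapes.items():
            for _ in range(25):
                amp = rng.uniform(40, 90)
                X.append(amp * shape + 3.0 * rng.standard_normal(t.size))
                y.append(name)
        return np.array(X), np.array(y)

    def test_holdout_accuracy(self, templates):
        X, y = templates
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(y))
        tr, te = idx[:70], idx[70:]
        clf = SimpleSpikeClassifier().fit(X[tr], y[tr])
        assert (clf.predict(X[te]) == y[te]).mean() >= 0.95

    def test_duplicate_gets_same_class(self, templates):
        X, y = templates
        clf = SimpleSpikeClassifier().fit(X, y)
        assert clf.predict(X[:1])[0] == clf.predict(X[:1].copy())[0]

    def test_scores_centered(self, templates):
        X, y = templates
        clf = SimpleSpikeClassifier().fit(X, y)
        assert np.abs(clf.scores_.mean(axis=0)).max() < 1e-10

    def test_agreement_with_threshold_rule(self, templates):
        X, y = templates
        labels = y.copy()
        labels[::10] = "unlabeled"  # some responses lack a threshold label
        pred, clf = classify_pc_pca_lda(X, labels)
        assert (pred == y).mean() >= 0.95

    def test_too_few_per_class(self, templates):
        X, y = templates
        idx = [0, 1, 2, 25, 26]
        with pytest.raises(ValueError):
            SimpleSpikeClassifier(min_per_class=4).fit(X[idx], y[idx])

    def test_boundaries_exported(self, templates):
        X, y = templates
        clf = SimpleSpikeClassifier().fit(X, y)
        bounds = clf.decision_boundaries()
        assert set(bounds) == set(np.unique(y))
        assert all(len(b["weights"]) == 2 for b in bounds.values())
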