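"""Generator tests: events, coupled sources, lead field, sensor projection."""

import numpy as np
import pytest

from conftest import uniform_coupling_spec
from salnet.connectivity import wpli
from salnet.simulate import (ERPSpec, LeadField, SimulationConfig,
                             expected_wpli_vonmises, generate_events,
                             make_leadfield, project_to_sensors,
                             roi_voxel_indices, simulate_cohort,
                             simulate_coupled_sources, spherical_gain)


class TestEvents:
    def test_deviant_fraction_within_binomial_band(self):
        cfg = SimulationConfig(seed=11)
        ev = generate_events(cfg)
        assert len(ev) == 750
        n_dev = (ev["code"] == "deviant").sum()
        # 95% binomial band around p = 0.10 at n = 750
        sd = np.sqrt(750 * 0.1 * 0.9)
        assert abs(n_dev - 75) <= 1.96 * sd
        assert ev["onset_sample"].is_monotonic_increasing
        assert np.all(np.diff(ev["onset_sample"]) == 600)

    def test_probability_limit_all_standard(self):
        cfg = SimulationConfig(deviant_probability=1e-12, seed=1)
        ev = generate_events(cfg)
        assert (ev["code"] == "standard").all()

    def test_seeded_replay_reproduces_deviant_count(self):
        # oracle: an independent re-draw of the same seeded stream
        cfg = SimulationConfig(n_oddball_trials=20, deviant_probability=0.5,
                               seed=7)
        ev = generate_events(cfg)
        expected = (np.random.default_rng(7).random(20) < 0.5).sum()
        assert (ev["code"] == "deviant").sum() == expected
        ev2 = generate_events(cfg)
        assert ev.equals(ev2)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(deviant_probability=0.0)


class TestCoupledSources:
    def _phases(self, kappa, n_epochs=250, seed=3):
        cfg = SimulationConfig(coupling_spec=uniform_coupling_spec(kappa),
                               noise_sd=0.0)
        rng = np.random.default_rng(seed)
        _, truth = simulate_coupled_sources(cfg, "HC", "RS", n_epochs * 0.7,
                                            rng, bands=("high_beta",))
        px = truth.source_phases[("high_beta", "dACC")]
        py = truth.source_phases[("high_beta", "lIns")]
        n = n_epochs * 700
        return px[:n].reshape(n_epochs, 700), py[:n].reshape(n_epochs, 700)

    def _mean_wpli(self, kappa, n_epochs=250, seed=3):
        px, py = self._phases(kappa, n_epochs, seed)
        return np.mean([wpli(px[e], py[e], 1000.0, 0.1).value
                        for e in range(px.shape[0])])

    def test_infinite_concentration_gives_unit_wpli(self):
        assert self._mean_wpli(np.inf, n_epochs=20) == pytest.approx(1.0)

    def test_zero_concentration_gives_small_wpli(self):
        # uniform phase difference: wPLI → 0; finite epochs leave a
        # positive bias of order 1/sqrt(blocks per epoch)
        assert self._mean_wpli(0.0, n_epochs=250) < 0.3

    def test_kappa2_matches_vonmises_monte_carlo_oracle(self):
        oracle = expected_wpli_vonmises(2.0, np.pi / 4)
        assert self._mean_wpli(2.0, n_epochs=250) == pytest.approx(
            oracle, abs=0.05)

    def test_wpli_monotone_in_kappa(self):
        vals = [self._mean_wpli(k, n_epochs=250)
                for k in (0.0, 0.5, 1.0, 2.0, 4.0, np.inf)]
        assert np.all(np.diff(vals) > -0.02)

    def test_zero_lag_with_locking_warns(self):
        with pytest.warns(UserWarning, match="mean lag 0"):
            SimulationConfig(
                coupling_spec=uniform_coupling_spec(2.0, lag_l=0.0))


class TestLeadField:
    def test_random_mode_deterministic(self):
        a = make_leadfield(mode="random", seed=5)
        b = make_leadfield(mode="random", seed=5)
        assert np.array_equal(a.gain, b.gain)
        assert np.array_equal(a.voxel_coords, b.voxel_coords)

    def test_central_source_axially_symmetric(self):
        # mirror-symmetric electrodes about the dipole axis see equal gain
        elec = np.array([[30.0, 40.0, 60.0], [-30.0, 40.0, 60.0],
                         [30.0, -40.0, 60.0]])
        vox = np.array([[0.0, 0.0, 1e-12]])
        g = spherical_gain(elec, vox, 85.0)
        assert g[0, 0] == pytest.approx(g[1, 0], abs=1e-9)
        assert g[0, 0] == pytest.approx(g[2, 0], abs=1e-9)

    def test_column_norm_decreases_with_depth(self):
        # same ray toward the vertex, two depths: analytic formula says the
        # deeper source has strictly smaller total gain
        lf_chans = make_leadfield(grid_spacing_mm=40.0)
        elec = np.array([[0, 0, 85.0], [60, 0, 60.0], [0, 60, 60.0],
                         [-60, 0, 60.0]])
        shallow = np.array([[0.0, 0.0, 70.0]])
        deep = np.array([[0.0, 0.0, 30.0]])
        g_sh = spherical_gain(elec, shallow, 85.0)
        g_dp = spherical_gain(elec, deep, 85.0)
        assert np.linalg.norm(g_dp) < np.linalg.norm(g_sh)
        assert lf_chans.gain.shape[0] == 62

    def test_grid_contains_roi_seeds(self, spherical_leadfield):
        idx = roi_voxel_indices(spherical_leadfield)
        from salnet.config import ROI_SEEDS_MM
        for roi, i in idx.items():
            assert np.allclose(spherical_leadfield.voxel_coords[i],
                               ROI_SEEDS_MM[roi])


class TestSensorProjection:
    def test_single_voxel_projection_equals_gain_column(
            self, random_leadfield):
        src = {"alpha": np.vstack([np.sin(np.arange(100) / 7.0),
                                   np.zeros(100), np.zeros(100)])}
        idx = {"dACC": 4, "lIns": 9, "rIns": 12}
        rng = np.random.default_rng(0)
        data = project_to_sensors(src, random_leadfield, idx, 0.0, rng)
        expected = random_leadfield.gain[:, [4]] @ src["alpha"][:1]
        assert np.allclose(data, expected)

    def test_noise_only_variance(self, random_leadfield):
        src = {"alpha": np.zeros((3, 40000))}
        idx = {"dACC": 0, "lIns": 1, "rIns": 2}
        rng = np.random.default_rng(1)
        data = project_to_sensors(src, random_leadfield, idx, 2.0, rng)
        assert np.var(data) == pytest.approx(4.0, rel=0.05)

    def test_superposition(self, random_leadfield):
        rng = np.random.default_rng(2)
        t = np.arange(200)
        idx = {"dACC": 3, "lIns": 7, "rIns": 11}
        s1 = {"alpha": np.vstack([np.sin(t / 5), np.zeros(200),
                                  np.zeros(200)])}
        s2 = {"alpha": np.vstack([np.zeros(200), np.cos(t / 3),
                                  np.zeros(200)])}
        both = {"alpha": s1["alpha"] + s2["alpha"]}
        d1 = project_to_sensors(s1, random_leadfield, idx, 0.0, rng)
        d2 = project_to_sensors(s2, random_leadfield, idx, 0.0, rng)
        d12 = project_to_sensors(both, random_leadfield, idx, 0.0, rng)
        assert np.allclose(d12, d1 + d2)

    def test_deviant_locked_average_reproduces_erp_amplitude(
            self, spherical_leadfield):
        # pure ERP: no sources, no noise → the deviant-locked average must
        # reproduce the planted peak within 1%
        cfg = SimulationConfig(n_oddball_trials=40, seed=9, noise_sd=0.0,
                               source_amplitude=0.0)
        from salnet.simulate import generate_events, _erp_waveform
        events = generate_events(cfg)
        n = int(events["onset_sample"].iloc[-1]) + 700
        src = {"alpha": np.zeros((3, n))}
        idx = roi_voxel_indices(spherical_leadfield)
        rng = np.random.default_rng(0)
        data = project_to_sensors(src, spherical_leadfield, idx, 0.0, rng,
                                  erp_spec=cfg.erp_spec, events=events,
                                  fs=1000.0)
        ch = spherical_leadfield.channel_names.index("FCz")
        dev = events.loc[events["code"] == "deviant", "onset_sample"]
        assert len(dev) > 0
        avg = np.mean([data[ch, o:o + 600] for o in dev], axis=0)
        assert avg.min() == pytest.approx(cfg.erp_spec.amplitude_uv,
                                          rel=0.01)


class TestDeterminism:
    def test_cohort_generation_bit_identical(self, spherical_leadfield,
                                             tiny_sim_config):
        def run():
            out = {}
            for sid, _g, recs, _t in simulate_cohort(tiny_sim_config,
                                                     spherical_leadfield):
                out[sid] = {c: r.data.copy() for c, r in recs.items()}
            return out

        a, b = run(), run()
        assert a.keys() == b.keys()
        for sid in a:
            for cond in a[sid]:
                assert np.array_equal(a[sid][cond], b[sid][cond])
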