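"""Head layouts, session simulation, spikes, seizures, evoked, hypnograms."""

import numpy as np
import pytest

from subscalp_eeg.core import DEFAULT_BANDS, Hypnogram
from subscalp_eeg.spectral import multitaper_psd
from subscalp_eeg.synthdata import (
    EvokedComponent,
    SimulationConfig,
    SourceSpec,
    corrupt_hypnogram,
    make_head_layout,
    make_night_hypnogram,
    simulate_evoked,
    simulate_seizure,
    simulate_session,
    simulate_spikes,
    spatial_gain,
    sphere_point,
)

FS = 256.0


def _band_power(x, band):
    spec = multitaper_psd(x, FS)
    mask = spec.band_slice(band)
    return np.trapezoid(spec.power[mask], spec.frequencies[mask])


def _quiet_config(**kw):
    return SimulationConfig(
        sources=[], background_rms_uv=0.0,
        sensor_noise_uv={"subscalp": 0.0, "scalp": 0.0, "intracranial": 0.0},
        **kw,
    )


class TestHeadLayout:
    def test_full_implant_counts(self, layout4):
        assert len(layout4.by_modality("scalp")) == 25
        assert len(layout4.by_modality("subscalp")) == 28
        assert len(layout4.by_modality("intracranial")) == 6

    def test_single_trident_counts(self, layout1):
        assert len(layout1.by_modality("scalp")) == 25
        assert len(layout1.by_modality("subscalp")) == 7

    def test_radial_invariants(self, layout4):
        for c in layout4.contacts:
            r = np.linalg.norm(c.position)
            if c.modality == "scalp":
                assert r == pytest.approx(92.0)
            elif c.modality == "subscalp":
                assert r == pytest.approx(85.0)
            else:
                assert r < 85.0

    def test_deterministic(self):
        a = make_head_layout(3, 4, seed=7)
        b = make_head_layout(3, 4, seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert a.names == b.names

    @pytest.mark.parametrize("n", [0, 5, -1])
    def test_invalid_trident_count_rejected(self, n):
        with pytest.raises(ValueError, match="between 1 and 4"):
            make_head_layout(n)

    def test_unique_names(self, layout4):
        assert len(set(layout4.names)) == len(layout4)


class TestSpatialGain:
    @pytest.mark.parametrize("kernel", ["exponential", "gaussian"])
    def test_strictly_decreasing_with_distance(self, kernel):
        src = np.array([0.0, 0.0, 50.0])
        d = np.linspace(0, 140, 60)
        sensors = np.column_stack([d, np.zeros_like(d), np.full_like(d, 50.0)])
        g = spatial_gain(src, sensors, 60.0, kernel=kernel)
        nonzero = g[g > 0]
        assert np.all(np.diff(nonzero) < 0)

    def test_floor_clamps_to_zero(self):
        src = np.zeros(3)
        far = np.array([[400.0, 0, 0]])
        assert spatial_gain(src, far, 35.0)[0] == 0.0

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            spatial_gain(np.zeros(3), np.ones((1, 3)), 50.0, kernel="cubic")


class TestSimulateSession:
    def test_deterministic(self, layout1):
        hyp = Hypnogram(stages=["W", "N2"])
        cfg = SimulationConfig(seed=5)
        a = simulate_session(layout1, hyp, cfg)
        b = simulate_session(layout1, hyp, cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_alpha_gradient_posterior_to_frontal(self, layout4):
        hyp = Hypnogram(stages=["W"] * 4)
        rec = simulate_session(layout4, hyp, SimulationConfig(seed=3))
        alpha = DEFAULT_BANDS["alpha"]
        assert _band_power(rec.channel("O1"), alpha) > \
            2 * _band_power(rec.channel("Fp1"), alpha)

    def test_zero_amplitude_matches_pure_background(self, layout1):
        hyp = Hypnogram(stages=["W"] * 4)
        base = SimulationConfig(seed=9, sources=[])
        nulled = SimulationConfig(seed=9)
        for s in nulled.sources:
            s.amplitude_uv = 0.0
        a = simulate_session(layout1, hyp, base)
        b = simulate_session(layout1, hyp, nulled)
        np.testing.assert_array_equal(a.data, b.data)

    def test_eyes_open_removes_alpha(self, layout1):
        hyp = Hypnogram(stages=["W"] * 4)
        closed = simulate_session(layout1, hyp, SimulationConfig(seed=4))
        opened = simulate_session(
            layout1, hyp, SimulationConfig(seed=4, eyes_closed=False)
        )
        alpha = DEFAULT_BANDS["alpha"]
        assert _band_power(opened.channel("O1"), alpha) < \
            0.7 * _band_power(closed.channel("O1"), alpha)

    def test_energy_scaling_quadratic(self, layout1):
        # doubling a source amplitude quadruples its band-power contribution
        hyp = Hypnogram(stages=["N2"] * 2)
        powers = []
        for amp in (10.0, 20.0):
            cfg = _quiet_config(seed=11)
            cfg.sources = [
                SourceSpec("s", "N2", DEFAULT_BANDS["sigma"],
                           sphere_point(48, 85, 78.0), 80.0, amp)
            ]
            rec = simulate_session(layout1, hyp, cfg)
            powers.append(_band_power(rec.channel("C3"), DEFAULT_BANDS["sigma"]))
        assert powers[1] == pytest.approx(4 * powers[0], rel=1e-6)

    def test_modality_consistency_at_matched_direction(self):
        # subscalp and scalp contacts along the same radius sense the same
        # field: with gain 1 their noiseless signals are identical
        from subscalp_eeg.core import Contact, HeadLayout

        layout = HeadLayout(
            [
                Contact("S", sphere_point(60, 120, 85.0), "subscalp"),
                Contact("C", sphere_point(60, 120, 92.0), "scalp"),
                Contact("Other", sphere_point(20, 0, 92.0), "scalp"),
            ]
        )
        cfg = _quiet_config(seed=2)
        cfg.sources = [
            SourceSpec("a", "W", DEFAULT_BANDS["alpha"],
                       sphere_point(80, 160, 78.0), 80.0, 15.0)
        ]
        rec = simulate_session(layout, Hypnogram(stages=["W"] * 2), cfg)
        np.testing.assert_allclose(rec.channel("S"), rec.channel("C"),
                                   atol=1e-12)

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown stage"):
            Hypnogram(stages=["W", "X"])


class TestSimulateSpikes:
    def test_noiseless_average_peak_equals_projected_amplitude(self, layout1):
        cfg = _quiet_config(seed=1)
        bg = simulate_session(layout1, Hypnogram(stages=["W"] * 4), cfg)
        pos = sphere_point(85, 0, 70.0)
        mom = pos / np.linalg.norm(pos)
        rec = simulate_spikes(bg, 30, pos, mom, amplitude_uv=40.0, seed=3)
        from subscalp_eeg.events import spike_peak_average
        from subscalp_eeg.synthdata import _sensing_positions

        onsets = [e.onset for e in rec.annotations.of_kind("spike")]
        subs = layout1.by_modality("subscalp")
        d = [np.linalg.norm(c.position - pos) for c in subs]
        align = subs[int(np.argmin(d))].name
        avg = spike_peak_average(rec, onsets, align)
        sense = _sensing_positions(layout1)[layout1.index(align)]
        vec = sense - pos
        gain = spatial_gain(pos, sense, 90.0, kernel="gaussian") * (
            vec @ mom / np.linalg.norm(vec)
        )
        assert avg.amplitude_of(align) == pytest.approx(40.0 * gain, rel=1e-6)

    def test_noise_averages_down_as_sqrt_n(self, layout1):
        # residual of the n-spike average scales as sigma/sqrt(n)
        cfg = SimulationConfig(seed=8, sources=[], background_rms_uv=0.0,
                               sensor_noise_uv={"subscalp": 5.0, "scalp": 5.0,
                                                "intracranial": 5.0})
        bg = simulate_session(layout1, Hypnogram(stages=["W"] * 8), cfg)
        from subscalp_eeg.events import epoch_average
        from subscalp_eeg.core import Event

        resid = {}
        for n in (10, 40):
            events = [Event("stimulus", 2.0 + 1.0 * k, 0.0) for k in range(n)]
            avg = epoch_average(bg, events, window_ms=(0, 200),
                                baseline_ms=(-50, 0))
            resid[n] = avg.data.std()
        assert resid[40] == pytest.approx(resid[10] / 2, rel=0.25)

    def test_overlapping_spikes_rejected(self, layout1):
        cfg = _quiet_config(seed=1)
        bg = simulate_session(layout1, Hypnogram(stages=["W"] * 1), cfg)
        pos = sphere_point(85, 0, 70.0)
        with pytest.raises(ValueError, match="overlap"):
            simulate_spikes(bg, 3, pos, pos, onsets=[1.0, 1.02, 5.0])

    def test_two_dipoles_distinct_topographies(self, layout4):
        # the bifocal case: two spike types with different fields
        from subscalp_eeg.synthdata import _sensing_positions

        sense = _sensing_positions(layout4)
        maps = []
        for th, ph in ((80, 60), (70, -120)):
            pos = sphere_point(th, ph, 70.0)
            mom = pos / np.linalg.norm(pos)
            vec = sense - pos
            dist = np.linalg.norm(vec, axis=1)
            g = spatial_gain(pos, sense, 90.0, kernel="gaussian")
            maps.append(g * (vec @ mom) / dist)
        rho = np.corrcoef(maps[0], maps[1])[0, 1]
        assert rho < 0.5


class TestSimulateSeizure:
    def _background(self, layout, n_epochs=4, seed=0):
        return simulate_session(
            layout, Hypnogram(stages=["W"] * n_epochs), _quiet_config(seed=seed)
        )

    def test_pz_activates_after_propagation_delay(self):
        # zones separated well beyond the mixing length so each intracranial
        # contact is dominated by its own zone
        soz = sphere_point(100, 90, 60.0)
        pz = sphere_point(40, 90, 60.0)
        layout = make_head_layout(4, 2, seed=1,
                                  intracranial_positions=[soz, pz])
        rec = simulate_session(layout, Hypnogram(stages=["W"] * 4),
                               _quiet_config(seed=0))
        rec = simulate_seizure(rec, soz, pz, onset=10.0, duration=90.0,
                               freq_start=12.0, freq_end=4.0,
                               propagation_delay=10.0, seed=2)

        def onset_time(x):
            env = np.abs(x)
            smooth = np.convolve(env, np.ones(256) / 256, mode="same")
            return np.argmax(smooth > 0.15 * smooth.max()) / FS

        # intracranial contacts sit exactly in the two zones
        t_soz = onset_time(rec.channel("IC1"))
        t_pz = onset_time(rec.channel("IC2"))
        assert 10.0 <= t_soz <= 45.0
        assert t_pz - t_soz >= 5.0

    def test_zero_amplitude_leaves_recording_unchanged(self, layout1):
        rec = self._background(layout1)
        out = simulate_seizure(rec, sphere_point(90, 0, 60.0),
                               sphere_point(70, 0, 60.0), onset=5.0,
                               duration=30.0, freq_start=10.0, freq_end=3.0,
                               amplitude_uv=0.0, seed=1)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_deep_seizure_invisible_extracranially(self, layout4):
        # surface gain below the floor: extracranial channels untouched
        rec = self._background(layout4)
        soz = np.array([0.0, 0.0, 5.0])
        pz = np.array([0.0, 25.0, 5.0])
        out = simulate_seizure(rec, soz, pz, onset=5.0, duration=60.0,
                               freq_start=10.0, freq_end=3.0, spread_mm=12.0,
                               seed=4)
        extracranial = [i for i, m in enumerate(layout4.modalities)
                        if m != "intracranial"]
        np.testing.assert_array_equal(out.data[extracranial],
                                      rec.data[extracranial])

    def test_frequency_outside_nyquist_rejected(self, layout1):
        rec = self._background(layout1)
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_seizure(rec, sphere_point(90, 0, 60.0),
                             sphere_point(70, 0, 60.0), onset=5.0,
                             duration=30.0, freq_start=10.0, freq_end=200.0)

    def test_identical_soz_pz_rejected(self, layout1):
        rec = self._background(layout1)
        p = sphere_point(90, 0, 60.0)
        with pytest.raises(ValueError, match="differ"):
            simulate_seizure(rec, p, p, onset=5.0, duration=30.0,
                             freq_start=10.0, freq_end=3.0)


class TestSimulateEvoked:
    def test_noiseless_component_recovered_exactly(self, layout1):
        cfg = _quiet_config()
        comp = EvokedComponent(100.0, 8.0, sphere_point(85, 180, 78.0))
        rec = simulate_evoked(layout1, 10, "visual", [comp], isi_s=0.5,
                              config=cfg, seed=0)
        from subscalp_eeg.events import epoch_average

        avg = epoch_average(rec, rec.annotations.of_kind("stimulus"))
        ch = avg.channel("O1")
        i_peak = np.argmin(np.abs(avg.times_ms - 100.0))
        from subscalp_eeg.synthdata import _sensing_positions

        sense = _sensing_positions(layout1)[layout1.index("O1")]
        g = spatial_gain(comp.center, sense, comp.spread_mm)
        assert ch[i_peak] == pytest.approx(8.0 * g, rel=0.02)

    def test_long_latency_warns_but_simulates(self, layout1):
        comp = EvokedComponent(350.0, 5.0, sphere_point(85, 180, 78.0))
        with pytest.warns(UserWarning, match="300 ms"):
            rec = simulate_evoked(layout1, 3, "auditory", [comp], 0.6,
                                  _quiet_config(), seed=1)
        assert len(rec.annotations.of_kind("stimulus")) == 3

    def test_invalid_args_rejected(self, layout1):
        with pytest.raises(ValueError, match="n_trials"):
            simulate_evoked(layout1, 0, "visual", [], 0.5, _quiet_config())
        with pytest.raises(ValueError, match="modality"):
            simulate_evoked(layout1, 3, "tactile", [], 0.5, _quiet_config())


class TestHypnograms:
    def test_corrupt_zero_rate_identity(self):
        hyp = make_night_hypnogram(200, seed=1)
        out = corrupt_hypnogram(hyp, 0.0, seed=2)
        assert out == hyp

    def test_corrupt_full_rate_always_differs(self):
        hyp = make_night_hypnogram(500, seed=3)
        out = corrupt_hypnogram(hyp, 1.0, seed=4)
        agree = sum(a == b for a, b in zip(hyp.stages, out.stages))
        assert agree == 0

    def test_corrupt_partial_rate_kappa_matches_closed_form(self):
        # balanced stages: pe = 1/5 exactly, po = 1 - flip_rate in
        # expectation, so kappa = (0.9 - 0.2) / 0.8 = 0.875
        from subscalp_eeg.agreement import cohens_kappa

        stages = list(np.repeat(["W", "N1", "N2", "N3", "REM"], 400))
        hyp = Hypnogram(stages=stages)
        kappas = [
            cohens_kappa(hyp, corrupt_hypnogram(hyp, 0.1, seed=s)).kappa
            for s in range(10)
        ]
        assert np.mean(kappas) == pytest.approx(0.875, abs=0.02)

    def test_invalid_flip_rate_rejected(self):
        hyp = make_night_hypnogram(10, seed=0)
        with pytest.raises(ValueError, match="flip_rate"):
            corrupt_hypnogram(hyp, 1.5)

    def test_night_hypnogram_shape(self):
        hyp = make_night_hypnogram(960, seed=5)
        assert len(hyp) == 960
        assert set(hyp.stages) <= {"W", "N1", "N2", "N3", "REM"}
        assert hyp.duration == 960 * 30.0
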