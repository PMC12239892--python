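"""Evoked averaging, global field power, spike alignment, ictal analyses."""

import numpy as np
import pytest

from subscalp_eeg.core import Event, Hypnogram
from subscalp_eeg.events import (
    EvokedAverage,
    epoch_average,
    global_field_power,
    ictal_coherence_profile,
    ictal_power_increase_map,
    select_ictal_triplet,
    spike_peak_average,
)
from subscalp_eeg.synthdata import (
    SimulationConfig,
    make_head_layout,
    simulate_seizure,
    simulate_session,
    simulate_spikes,
    sphere_point,
)

FS = 256.0


def _quiet(layout, n_epochs=4, seed=0, noise=0.0):
    cfg = SimulationConfig(
        sources=[], background_rms_uv=0.0, seed=seed,
        sensor_noise_uv={"subscalp": noise, "scalp": noise,
                         "intracranial": noise},
    )
    return simulate_session(layout, Hypnogram(stages=["W"] * n_epochs), cfg)


class TestEpochAverage:
    def test_noiseless_template_recovered_exactly(self, layout1):
        rec = _quiet(layout1)
        tmpl = np.sin(2 * np.pi * 20 * np.arange(int(0.1 * FS)) / FS)
        events = [Event("stimulus", 2.0 + k, 0.0) for k in range(20)]
        for ev in events:
            i0 = int(ev.onset * FS)
            rec.data[:, i0 : i0 + len(tmpl)] += tmpl
        avg = epoch_average(rec, events)
        i0 = int(np.argmin(np.abs(avg.times_ms)))
        np.testing.assert_allclose(avg.data[0][i0 : i0 + len(tmpl)], tmpl,
                                   atol=1e-9)
        assert avg.n_trials == 20

    def test_residual_scales_as_inverse_sqrt_n(self, layout1):
        rms = {}
        for n in (10, 30, 100):
            rec = _quiet(layout1, n_epochs=5, noise=5.0, seed=n)
            events = [Event("stimulus", 1.0 + 0.5 * k, 0.0) for k in range(n)]
            avg = epoch_average(rec, events, window_ms=(0, 100),
                                baseline_ms=(-50, 0))
            rms[n] = float(np.sqrt((avg.data**2).mean()))
        assert rms[30] / rms[10] == pytest.approx(np.sqrt(10 / 30), rel=0.3)
        assert rms[100] / rms[10] == pytest.approx(np.sqrt(10 / 100), rel=0.3)

    def test_edge_events_dropped_and_counted(self, layout1):
        rec = _quiet(layout1, n_epochs=1)
        events = [Event("stimulus", t, 0.0) for t in (0.02, 5.0, 29.95)]
        avg = epoch_average(rec, events)
        assert avg.n_trials == 1 and avg.n_dropped == 2

    def test_all_events_outside_rejected(self, layout1):
        rec = _quiet(layout1, n_epochs=1)
        with pytest.raises(ValueError, match="edge-dropping"):
            epoch_average(rec, [Event("stimulus", 29.99, 0.0)])
        with pytest.raises(ValueError, match="no events"):
            epoch_average(rec, [])


class TestGlobalFieldPower:
    def _evoked(self, data):
        return EvokedAverage(
            data=np.asarray(data, float),
            times_ms=np.arange(np.asarray(data).shape[1], dtype=float),
            n_trials=1,
            channel_names=[f"c{i}" for i in range(np.asarray(data).shape[0])],
            window_ms=(0, 10),
        )

    def test_equal_channels_zero(self):
        gfp = global_field_power(self._evoked(np.ones((5, 40))))
        assert np.allclose(gfp, 0)

    def test_antisymmetric_pair_gives_abs(self):
        v = np.sin(np.linspace(0, 3, 50))
        gfp = global_field_power(self._evoked(np.vstack([v, -v])))
        np.testing.assert_allclose(gfp, np.abs(v), atol=1e-12)

    def test_matches_std_oracle(self, rng):
        data = rng.normal(0, 1, (8, 30))
        np.testing.assert_allclose(
            global_field_power(self._evoked(data)), data.std(axis=0), atol=1e-12
        )

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            global_field_power(self._evoked(np.ones((1, 10))))


class TestSpikePeakAverage:
    def _spiked(self, layout, jitter_onsets, seed=0):
        rec = _quiet(layout, n_epochs=4)
        pos = sphere_point(85, 0, 70.0)
        mom = pos / np.linalg.norm(pos)
        true_onsets = 2.0 + 2.0 * np.arange(30)
        rec = simulate_spikes(rec, 30, pos, mom, amplitude_uv=40.0,
                              onsets=true_onsets, seed=seed)
        subs = layout.by_modality("subscalp")
        d = [np.linalg.norm(c.position - pos) for c in subs]
        align = subs[int(np.argmin(d))].name
        rng = np.random.default_rng(seed)
        annotated = true_onsets + (
            rng.uniform(-0.02, 0.02, 30) if jitter_onsets else 0.0
        )
        return rec, annotated, align

    def test_alignment_removes_annotation_jitter(self, layout1):
        rec, onsets, align = self._spiked(layout1, jitter_onsets=True)
        rec_exact, exact_onsets, _ = self._spiked(layout1, jitter_onsets=False)
        jittered = spike_peak_average(rec, onsets, align)
        exact = spike_peak_average(rec_exact, exact_onsets, align)
        assert jittered.amplitude_of(align) == pytest.approx(
            exact.amplitude_of(align), rel=1e-6
        )

    def test_misaligned_average_strictly_smaller(self, layout1):
        rec, onsets, align = self._spiked(layout1, jitter_onsets=True)
        aligned = spike_peak_average(rec, onsets, align)
        smeared = spike_peak_average(rec, onsets, align, align=False)
        assert abs(smeared.amplitude_of(align)) < abs(aligned.amplitude_of(align))

    def test_dipolar_field_has_both_polarities(self, layout4):
        rec = _quiet(layout4, n_epochs=4)
        pos = sphere_point(90, 90, 70.0)
        radial = pos / np.linalg.norm(pos)
        # tilted moment so both lobes land on the montage
        tilt = np.array([0.0, 0.0, 1.0])
        mom = 0.4 * radial + tilt
        onsets = 2.0 + 2.0 * np.arange(30)
        rec = simulate_spikes(rec, 30, pos, mom, amplitude_uv=40.0,
                              onsets=onsets, far_lobe_attenuation=1.0)
        subs = layout4.by_modality("subscalp")
        d = [np.linalg.norm(c.position - pos) for c in subs]
        align = subs[int(np.argmin(d))].name
        avg = spike_peak_average(rec, onsets, align)
        amps = [avg.amplitude_of(c.name) for c in subs]
        assert min(amps) < -0.5 and max(amps) > 0.5

    def test_no_spikes_rejected(self, layout1):
        rec = _quiet(layout1)
        with pytest.raises(ValueError, match="no spikes"):
            spike_peak_average(rec, [], "EF1")


class TestIctalTriplet:
    def test_soz_at_subscalp_contact_selects_it(self, layout4):
        target = layout4.by_modality("subscalp")[10]
        triplet = select_ictal_triplet(layout4, target.position)
        assert triplet.subscalp == target.name

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_search(self, seed):
        layout = make_head_layout(2 + seed % 3, 4, seed=seed)
        rng = np.random.default_rng(seed)
        soz = rng.normal(0, 30, 3)
        triplet = select_ictal_triplet(layout, soz)

        def nearest(mod, ref):
            cands = sorted(layout.by_modality(mod), key=lambda c: c.name)
            d = [np.linalg.norm(c.position - ref) for c in cands]
            return cands[int(np.argmin(d))]

        sub = nearest("subscalp", soz)
        assert triplet.subscalp == sub.name
        assert triplet.scalp == nearest("scalp", sub.position).name
        assert triplet.intracranial == nearest("intracranial", sub.position).name

    def test_single_trident_restricts_choice(self, layout1):
        soz = sphere_point(100, 170, 60.0)  # far from the frontal trident
        with pytest.raises(ValueError, match="intracranial"):
            select_ictal_triplet(layout1, soz)
        # layout1 has no intracranial contacts -> rejected; with them added:
        layout = make_head_layout(1, 2, seed=0)
        triplet = select_ictal_triplet(layout, soz)
        assert triplet.subscalp in {c.name for c in layout.by_modality("subscalp")}


class TestIctalCoherence:
    def _seizure_recording(self, layout, duration=50.0, amplitude=60.0,
                           spread=40.0, seed=0):
        cfg = SimulationConfig(seed=seed, sources=[])
        n_epochs = int(np.ceil(140.0 / 30))
        rec = simulate_session(layout, Hypnogram(stages=["W"] * n_epochs), cfg)
        soz = layout.by_modality("intracranial")[0].position
        pz = layout.by_modality("intracranial")[1].position
        rec = simulate_seizure(rec, soz, pz, onset=60.0, duration=duration,
                               freq_start=12.0, freq_end=4.0,
                               propagation_delay=8.0, amplitude_uv=amplitude,
                               spread_mm=spread, seed=seed)
        return rec, rec.annotations.of_kind("seizure")[0], soz

    def test_copied_channel_fully_coherent(self, layout4):
        rec, seizure, soz = self._seizure_recording(layout4)
        triplet = select_ictal_triplet(rec.layout, soz)
        # feed the scalp member a copy of the SOZ channel
        i_sc = rec.layout.index(triplet.scalp)
        i_soz = rec.layout.index("IC1")
        rec.data[i_sc] = rec.data[i_soz]
        prof = ictal_coherence_profile(rec, seizure, triplet, "IC1", "IC2")
        assert prof.scalp_vs_soz == pytest.approx(1.0, abs=1e-6)

    def test_noise_channels_near_bias_floor(self, layout4):
        rec, seizure, soz = self._seizure_recording(layout4, amplitude=0.0)
        triplet = select_ictal_triplet(rec.layout, soz)
        prof = ictal_coherence_profile(rec, seizure, triplet, "IC1", "IC2")
        # 17 windows x 6 tapers -> floor ~0.01
        for v in (prof.subscalp_vs_soz, prof.scalp_vs_soz,
                  prof.subscalp_vs_pz, prof.scalp_vs_pz):
            assert v < 0.05

    def test_short_segment_falls_back_to_short_windows(self, layout4):
        rec, seizure, soz = self._seizure_recording(layout4, duration=15.0)
        triplet = select_ictal_triplet(rec.layout, soz)
        prof = ictal_coherence_profile(rec, seizure, triplet, "IC1", "IC2")
        assert prof.short_segment

    def test_propagating_seizure_coherent_with_pz(self, layout4):
        rec, seizure, soz = self._seizure_recording(layout4, spread=45.0)
        triplet = select_ictal_triplet(rec.layout, soz)
        prof = ictal_coherence_profile(rec, seizure, triplet, "IC1", "IC2",
                                       compute_tf=True)
        assert prof.subscalp_vs_soz > 0.1
        # time-frequency masks exist and are boolean
        times, freqs, coh, mask = prof.tf_masks["subscalp_vs_soz"]
        assert mask.dtype == bool and mask.shape == coh.shape


class TestIctalPowerMap:
    def test_no_seizure_map_near_zero(self, layout4):
        cfg = SimulationConfig(seed=5, sources=[])
        rec = simulate_session(layout4, Hypnogram(stages=["W"] * 5), cfg)
        ev = Event("seizure", 90.0, 45.0, {})
        tm = ictal_power_increase_map(rec, ev, baseline=(30.0, 75.0))
        assert np.abs(tm.values).max() < 1.5

    def test_injected_oscillation_peaks_at_its_channel(self, layout4):
        cfg = SimulationConfig(seed=6, sources=[])
        rec = simulate_session(layout4, Hypnogram(stages=["W"] * 5), cfg)
        i = rec.layout.index("EP3")
        t = np.arange(rec.n_samples) / FS
        burst = (t > 90) & (t < 135)
        rec.data[i] += 30 * np.sin(2 * np.pi * 8 * t) * burst
        ev = Event("seizure", 90.0, 45.0, {})
        tm = ictal_power_increase_map(rec, ev, baseline=(30.0, 75.0))
        assert tm.names[int(np.argmax(tm.values))] == "EP3"

    def test_overlapping_baseline_rejected(self, layout4):
        cfg = SimulationConfig(seed=7, sources=[])
        rec = simulate_session(layout4, Hypnogram(stages=["W"] * 5), cfg)
        ev = Event("seizure", 60.0, 45.0, {})
        with pytest.raises(ValueError, match="overlap"):
            ictal_power_increase_map(rec, ev, baseline=(50.0, 70.0))

    def test_deep_seizure_invisible_superficial_visible(self, layout4):
        # the extracranially invisible minority of seizures: deep source
        # below the gain floor produces no power increase, a superficial
        # one does
        cfg = SimulationConfig(seed=8, sources=[])
        base = simulate_session(layout4, Hypnogram(stages=["W"] * 7), cfg)
        ev_kwargs = dict(onset=90.0, duration=45.0, freq_start=12.0,
                         freq_end=4.0, propagation_delay=8.0, seed=3)
        deep = simulate_seizure(base.copy(), np.array([0, 0, 5.0]),
                                np.array([0, 25, 5.0]), spread_mm=12.0,
                                **ev_kwargs)
        shallow = simulate_seizure(base.copy(), sphere_point(95, 90, 72.0),
                                   sphere_point(70, 90, 72.0), spread_mm=40.0,
                                   **ev_kwargs)
        baseline = (30.0, 75.0)
        deep_map = ictal_power_increase_map(
            deep, deep.annotations.of_kind("seizure")[0], baseline)
        shallow_map = ictal_power_increase_map(
            shallow, shallow.annotations.of_kind("seizure")[0], baseline)
        assert np.abs(deep_map.values).max() < 1.5
        assert shallow_map.values.max() > 5.0
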