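"""Event-locked analyses: evoked averaging, spike averaging, ictal coherence.

Three families of analyses anchor the concordance assessment on discrete
events.  Evoked potentials are baseline-corrected trial averages over a
0-300 ms post-stimulus window, summarized spatially by the global field
power.  Interictal spikes are averaged after aligning each epoch on the
waveform extremum of an alignment channel, and the signed peak amplitude of
the average is read per channel.  Ictal discharges are analyzed through the
closest-contact triplet: the subscalp contact nearest the seizure onset
zone, plus the scalp and intracranial contacts nearest that subscalp
contact, whose 0.5-30 Hz mean spectral coherence with the SOZ and PZ
channels is the paired measurement under the -0.03 coherence margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import Event, HeadLayout, Recording
from .spectral import (
    CoherenceSpectrum,
    band_mean_coherence,
    coherence,
    multitaper_psd,
    n_sliding_windows,
)
from .topo import TopoMap, make_topomap

__all__ = [
    "EvokedAverage",
    "SpikeAverage",
    "IctalTriplet",
    "IctalCoherenceProfile",
    "epoch_average",
    "global_field_power",
    "spike_peak_average",
    "select_ictal_triplet",
    "ictal_coherence_profile",
    "ictal_power_increase_map",
]


@dataclass
class EvokedAverage:
    data: np.ndarray  # channels x time, uV
    times_ms: np.ndarray  # relative to stimulus onset
    n_trials: int
    channel_names: list[str]
    window_ms: tuple[float, float]
    n_dropped: int = 0

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


@dataclass
class SpikeAverage:
    data: np.ndarray  # channels x time, centered on the aligned spike peak
    times_ms: np.ndarray
    n_spikes: int
    channel_names: list[str]
    alignment_channel: str
    peak_amplitudes: np.ndarray  # signed uV at t=0, one per channel
    n_excluded: int = 0

    def amplitude_of(self, name: str) -> float:
        return float(self.peak_amplitudes[self.channel_names.index(name)])


@dataclass
class IctalTriplet:
    subscalp: str
    scalp: str
    intracranial: str
    distances_mm: dict[str, float] = field(default_factory=dict)


@dataclass
class IctalCoherenceProfile:
    """Mean 0.5-30 Hz coherence of each extracranial member with SOZ and PZ."""

    subscalp_vs_soz: float
    scalp_vs_soz: float
    subscalp_vs_pz: float
    scalp_vs_pz: float
    short_segment: bool = False  # fell back to 2-s windows
    tf_masks: Optional[dict] = None  # member -> (times, freqs, coherence, mask)


def epoch_average(
    recording: Recording,
    events: Sequence[Event],
    window_ms: tuple[float, float] = (-100.0, 300.0),
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
) -> EvokedAverage:
    """Baseline-corrected average over stimulus-locked epochs.

    The per-channel mean of the baseline segment is subtracted from each
    trial before averaging.  Events whose window falls outside the recording
    are dropped (counted in ``n_dropped``); if none remain, an error is
    raised.
    """
    if len(events) == 0:
        raise ValueError("no events to average")
    fs = recording.sampling_rate
    i_lo = int(round(window_ms[0] / 1000 * fs))
    i_hi = int(round(window_ms[1] / 1000 * fs))
    times_ms = 1000 * np.arange(i_lo, i_hi) / fs
    # the extracted segment must cover both the analysis window and the
    # baseline, which may start before the window
    b_lo = int(round(baseline_ms[0] / 1000 * fs))
    b_hi = int(round(baseline_ms[1] / 1000 * fs))
    if b_hi <= b_lo:
        raise ValueError("empty baseline interval")
    s_lo = min(i_lo, b_lo)
    acc = np.zeros((recording.n_channels, i_hi - i_lo))
    kept = 0
    dropped = 0
    for ev in events:
        c = int(round(ev.onset * fs))
        if c + s_lo < 0 or c + i_hi > recording.n_samples:
            dropped += 1
            continue
        seg = recording.data[:, c + s_lo : c + i_hi]
        baseline = seg[:, b_lo - s_lo : b_hi - s_lo].mean(axis=1, keepdims=True)
        acc += seg[:, i_lo - s_lo :] - baseline
        kept += 1
    if kept == 0:
        raise ValueError("all events fell outside the recording after edge-dropping")
    return EvokedAverage(
        data=acc / kept,
        times_ms=times_ms,
        n_trials=kept,
        channel_names=recording.layout.names,
        window_ms=window_ms,
        n_dropped=dropped,
    )


def global_field_power(evoked: EvokedAverage) -> np.ndarray:
    """Per-timepoint spatial standard deviation across channels."""
    if evoked.data.shape[0] < 2:
        raise ValueError("global field power needs at least 2 channels")
    return evoked.data.std(axis=0)


def spike_peak_average(
    recording: Recording,
    spike_onsets: Sequence[float],
    alignment_channel: str,
    window_ms: float = 250.0,
    search_ms: float = 50.0,
    n_max: int = 30,
    align: bool = True,
) -> SpikeAverage:
    """Peak-aligned spike average with per-channel signed peak amplitudes.

    Each epoch is shifted so that the absolute extremum of the alignment
    channel — searched within +-``search_ms`` of the annotated onset — sits
    at t = 0, then epochs are averaged and the signed value at t = 0 is the
    per-channel peak amplitude.  Epochs whose extremum lands on the search
    boundary are excluded as unresolved.
    """
    if len(spike_onsets) == 0:
        raise ValueError("no spikes to average")
    fs = recording.sampling_rate
    ai = recording.layout.index(alignment_channel)
    half = int(round(window_ms / 1000 * fs))
    search = int(round(search_ms / 1000 * fs))
    onsets = list(spike_onsets)[:n_max]

    centers = []
    excluded = 0
    for onset in onsets:
        c = int(round(onset * fs))
        if align:
            lo, hi = c - search, c + search + 1
            if lo < 0 or hi > recording.n_samples:
                excluded += 1
                continue
            seg = recording.data[ai, lo:hi]
            k = int(np.argmax(np.abs(seg)))
            if k == 0 or k == len(seg) - 1:
                excluded += 1
                continue
            c = lo + k
        if c - half < 0 or c + half > recording.n_samples:
            excluded += 1
            continue
        centers.append(c)
    if not centers:
        raise ValueError("no alignable spikes within the recording")

    acc = np.zeros((recording.n_channels, 2 * half))
    for c in centers:
        acc += recording.data[:, c - half : c + half]
    avg = acc / len(centers)
    times_ms = 1000 * np.arange(-half, half) / fs
    return SpikeAverage(
        data=avg,
        times_ms=times_ms,
        n_spikes=len(centers),
        channel_names=recording.layout.names,
        alignment_channel=alignment_channel,
        peak_amplitudes=avg[:, half].copy(),
        n_excluded=excluded,
    )


def select_ictal_triplet(layout: HeadLayout, soz_position: np.ndarray) -> IctalTriplet:
    """Two-step nearest-contact selection around the seizure onset zone.

    First the subscalp contact closest to the SOZ; then the scalp and
    intracranial contacts closest to that subscalp contact.  Distance ties
    break by contact name.
    """
    soz = np.asarray(soz_position, float)

    def nearest(modality: str, ref: np.ndarray) -> tuple[str, float]:
        group = sorted(layout.by_modality(modality), key=lambda c: c.name)
        if not group:
            raise ValueError(f"layout has no {modality} contacts")
        d = np.linalg.norm(np.array([c.position for c in group]) - ref, axis=1)
        i = int(np.argmin(d))
        return group[i].name, float(d[i])

    sub_name, d_sub = nearest("subscalp", soz)
    sub_pos = layout.position_of(sub_name)
    sc_name, d_sc = nearest("scalp", sub_pos)
    ic_name, d_ic = nearest("intracranial", sub_pos)
    return IctalTriplet(
        subscalp=sub_name,
        scalp=sc_name,
        intracranial=ic_name,
        distances_mm={
            "subscalp_to_soz": d_sub,
            "scalp_to_subscalp": d_sc,
            "intracranial_to_subscalp": d_ic,
        },
    )


def _segment_coherence(
    a: np.ndarray, b: np.ndarray, fs: float, window_s: float
) -> CoherenceSpectrum:
    return coherence(a, b, fs, window_s=window_s)


def ictal_coherence_profile(
    recording: Recording,
    seizure: Event,
    triplet: IctalTriplet,
    soz_channel: str,
    pz_channel: str,
    freq_range: tuple[float, float] = (0.5, 30.0),
    window_s: float = 5.0,
    tf_block_s: float = 20.0,
    contour_threshold: float = 0.3,
    compute_tf: bool = False,
) -> IctalCoherenceProfile:
    """Seizure-segment coherence of the triplet's extracranial members.

    Mean magnitude-squared coherence over ``freq_range`` between each
    extracranial member (subscalp, scalp) and the intracranial SOZ and PZ
    channels, over the annotated seizure segment.  Segments too short for 8
    sliding 5-s windows fall back to 2-s windows, flagged in the result.
    Optionally computes block-wise time-frequency coherence with the > 0.3
    contour mask used for rendering.
    """
    fs = recording.sampling_rate
    i0 = int(round(seizure.onset * fs))
    i1 = int(round((seizure.onset + seizure.duration) * fs))
    if i1 > recording.n_samples:
        raise ValueError("seizure segment extends beyond the recording")
    step = window_s * 0.5
    n_win = n_sliding_windows(i1 - i0, int(window_s * fs), int(step * fs))
    short = n_win < 8
    eff_window = 2.0 if short else window_s

    def seg(name: str) -> np.ndarray:
        return recording.channel(name)[i0:i1]

    sub, sc = seg(triplet.subscalp), seg(triplet.scalp)
    soz, pz = seg(soz_channel), seg(pz_channel)

    def mean_coh(x: np.ndarray, y: np.ndarray) -> float:
        return band_mean_coherence(
            _segment_coherence(x, y, fs, eff_window), freq_range
        )

    tf_masks = None
    if compute_tf:
        tf_masks = {}
        blk = int(tf_block_s * fs)
        starts = list(range(0, (i1 - i0) - blk + 1, blk // 2)) or [0]
        for member, x in (("subscalp", sub), ("scalp", sc)):
            for refname, ref in (("soz", soz), ("pz", pz)):
                mats, times = [], []
                for s in starts:
                    e = min(s + blk, i1 - i0)
                    c = _segment_coherence(x[s:e], ref[s:e], fs, 2.0)
                    mats.append(c.coherence)
                    times.append(seizure.onset + (s + e) / (2 * fs))
                coh_tf = np.array(mats).T  # freqs x time blocks
                tf_masks[f"{member}_vs_{refname}"] = (
                    np.array(times),
                    c.frequencies,
                    coh_tf,
                    coh_tf > contour_threshold,
                )
    return IctalCoherenceProfile(
        subscalp_vs_soz=mean_coh(sub, soz),
        scalp_vs_soz=mean_coh(sc, soz),
        subscalp_vs_pz=mean_coh(sub, pz),
        scalp_vs_pz=mean_coh(sc, pz),
        short_segment=short,
        tf_masks=tf_masks,
    )


def ictal_power_increase_map(
    recording: Recording,
    seizure: Event,
    baseline: tuple[float, float],
    modality: str = "subscalp",
    freq_range: tuple[float, float] = (0.5, 30.0),
    window_s: float = 5.0,
) -> TopoMap:
    """Per-channel mean dB power increase (ictal minus baseline), as a map.

    The ictal and baseline segments must not overlap.  One map per modality;
    maps from the two extracranial modalities are the inputs to the ictal
    spatial-correlation comparison.
    """
    t0, t1 = seizure.onset, seizure.onset + seizure.duration
    b0, b1 = baseline
    if max(t0, b0) < min(t1, b1):
        raise ValueError("baseline and ictal segments overlap")
    fs = recording.sampling_rate
    values = {}
    for c in recording.layout.by_modality(modality):
        x = recording.channel(c.name)
        inc = _mean_band_db(x[int(t0 * fs): int(t1 * fs)], fs, freq_range, window_s) \
            - _mean_band_db(x[int(b0 * fs): int(b1 * fs)], fs, freq_range, window_s)
        values[c.name] = inc
    return make_topomap(recording.layout, values, modality)


def _mean_band_db(x: np.ndarray, fs: float, freq_range: tuple[float, float],
                  window_s: float) -> float:
    spec = multitaper_psd(x, fs, window_s=window_s)
    mask = spec.band_slice(freq_range)
    return float(spec.power_db[mask].mean())
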