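"""Synthetic multimodal EEG generator with known ground truth.

Emulates the recording setup of a full-head subscalp EEG implant study: a
25-contact 10-20 scalp montage, one to four subscalp "trident" leads (three
branches fanning out ~30 degrees from a single entry point, 7 contacts per
trident, so up to 28 subscalp contacts), and intracranial contacts near the
seizure onset and propagation zones.  On top of a 1/f^chi background the
generator places stage-specific narrowband oscillations (posterior alpha in
quiet wake, central sigma in N2, frontal delta in N3, frontal beta in REM),
dipolar interictal spikes, chirp-like propagating seizures and
stimulus-locked evoked components.

The geometry is a deliberately simple single-sphere head model: sources
project to sensors with an exponential distance-decay gain rather than a
volume-conductor forward model.  Extracranial contacts (scalp and subscalp
alike) sense the field at their radial projection onto the scalp sphere, so
a paired subscalp/scalp measurement differs only through sensor noise and
the lateral offset between the two contacts; the simulator's null condition
is therefore exact signal equality across modalities, and any systematic
subscalp deficit is injected explicitly through the subscalp gain factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .core import (
    DEFAULT_BANDS,
    SLEEP_STAGES,
    Contact,
    Event,
    EventSet,
    HeadLayout,
    Hypnogram,
    Recording,
)

__all__ = [
    "TEN_TWENTY_ANGLES",
    "TRIDENT_ENTRY_SITES",
    "SourceSpec",
    "EvokedComponent",
    "SimulationConfig",
    "sphere_point",
    "spatial_gain",
    "sensing_position",
    "make_head_layout",
    "simulate_session",
    "simulate_spikes",
    "simulate_seizure",
    "simulate_evoked",
    "corrupt_hypnogram",
    "make_night_hypnogram",
    "spike_template",
]

# ---------------------------------------------------------------------------
# geometry

#: (polar angle from vertex, azimuth from nose, positive toward the left) in
#: degrees for the 25-contact montage: the 19 standard 10-20 positions plus
#: the six inferior temporal contacts (F9/10, T9/10, P9/10) routinely added
#: for better basal-temporal coverage.
TEN_TWENTY_ANGLES: dict[str, tuple[float, float]] = {
    "Cz": (0.0, 0.0),
    "Fz": (45.0, 0.0),
    "Pz": (45.0, 180.0),
    "C3": (45.0, 90.0),
    "C4": (45.0, -90.0),
    "F3": (62.0, 40.0),
    "F4": (62.0, -40.0),
    "P3": (62.0, 140.0),
    "P4": (62.0, -140.0),
    "Fp1": (90.0, 18.0),
    "Fp2": (90.0, -18.0),
    "F7": (90.0, 54.0),
    "F8": (90.0, -54.0),
    "T7": (90.0, 90.0),
    "T8": (90.0, -90.0),
    "P7": (90.0, 126.0),
    "P8": (90.0, -126.0),
    "O1": (90.0, 162.0),
    "O2": (90.0, -162.0),
    "F9": (112.0, 54.0),
    "F10": (112.0, -54.0),
    "T9": (112.0, 90.0),
    "T10": (112.0, -90.0),
    "P9": (112.0, 126.0),
    "P10": (112.0, -126.0),
}

#: Trident entry sites (polar, azimuth) in degrees: frontal, left/right
#: temporal, parietal — the four insertion locations used clinically, at the
#: periphery of the head so the branches fan inward over the convexity.
TRIDENT_ENTRY_SITES: dict[str, tuple[float, float]] = {
    "F": (85.0, 0.0),
    "TL": (100.0, 90.0),
    "TR": (100.0, -90.0),
    "P": (95.0, 180.0),
}

#: Source-to-sensor gains below this value are clamped to zero: a stand-in
#: for sources too deep to produce a measurable extracranial field.
GAIN_FLOOR = 0.01


def sphere_point(polar_deg: float, azimuth_deg: float, radius: float) -> np.ndarray:
    """3D position (mm) on a head-centred sphere.

    Coordinates: +x right, +y anterior (nose), +z up.  ``polar_deg`` is
    measured from the vertex, ``azimuth_deg`` from the nose, positive toward
    the left ear.
    """
    th = np.deg2rad(polar_deg)
    ph = np.deg2rad(azimuth_deg)
    return radius * np.array(
        [-np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph), np.cos(th)]
    )


def spatial_gain(
    source_pos: np.ndarray,
    sensor_pos: np.ndarray,
    spread_mm: float,
    floor: float = GAIN_FLOOR,
    kernel: str = "exponential",
) -> np.ndarray:
    """Distance-decay source-to-sensor gain, floored to zero.

    ``exponential`` — exp(-d / spread): graded decay with constant
    log-gradient, used for the distributed oscillatory sources.
    ``gaussian`` — exp(-d^2 / (2 spread^2)): flat at the field apex, the
    shape of a skull-blurred focal field, used for dipolar discharge fields.
    Both are strictly decreasing in the Euclidean source-sensor distance
    down to the floor, below which the gain is exactly zero (deep-source
    invisibility).
    """
    d = np.linalg.norm(
        np.atleast_2d(sensor_pos) - np.asarray(source_pos, float), axis=-1
    )
    if kernel == "exponential":
        g = np.exp(-d / float(spread_mm))
    elif kernel == "gaussian":
        g = np.exp(-(d**2) / (2 * float(spread_mm) ** 2))
    else:
        raise ValueError(f"unknown gain kernel {kernel!r}")
    g[g < floor] = 0.0
    out = g if np.ndim(sensor_pos) > 1 else float(g[0])
    return out


def sensing_position(contact: Contact, layout: HeadLayout) -> np.ndarray:
    """Point at which a contact senses the source field.

    Extracranial contacts sense at their radial projection onto the scalp
    sphere; intracranial contacts sense at their actual position.
    """
    if contact.modality == "intracranial":
        return contact.position
    r = np.linalg.norm(contact.position)
    if r == 0:
        raise ValueError(f"contact {contact.name} at origin cannot be projected")
    return contact.position * (layout.head_radius_mm / r)


def _sensing_positions(layout: HeadLayout) -> np.ndarray:
    return np.array([sensing_position(c, layout) for c in layout.contacts])


def make_head_layout(
    n_tridents: int,
    n_intracranial: int = 0,
    seed: int = 0,
    head_radius_mm: float = 92.0,
    scalp_thickness_mm: float = 7.0,
    contact_spacing_mm: float = 40.0,
    intracranial_positions: Optional[Sequence[np.ndarray]] = None,
) -> HeadLayout:
    """Build a co-registered scalp + subscalp (+ intracranial) layout.

    The 25 scalp contacts sit at standard 10-20 angular positions on the
    sphere of radius ``head_radius_mm``.  Each trident contributes 7 subscalp
    contacts on the concentric sphere 7 mm deeper, along three branches
    100-120 mm long fanning 30 degrees apart from one of the four entry
    sites (frontal, temporal left/right, parietal).  Intracranial contacts
    are placed strictly inside (at the given positions, or at random
    cortical-depth positions drawn from ``seed``).
    """
    if not 1 <= n_tridents <= 4:
        raise ValueError(
            f"n_tridents must be between 1 and 4, got {n_tridents}"
        )
    rng = np.random.default_rng(seed)
    r_sub = head_radius_mm - scalp_thickness_mm

    contacts = [
        Contact(name, sphere_point(th, ph, head_radius_mm), "scalp")
        for name, (th, ph) in TEN_TWENTY_ANGLES.items()
    ]

    # per-branch contact counts summing to the 7 contacts of one trident
    branch_counts = (3, 2, 2)
    sites = list(TRIDENT_ENTRY_SITES)[:n_tridents]
    for site in sites:
        th, ph = TRIDENT_ENTRY_SITES[site]
        entry = sphere_point(th, ph, r_sub)
        u = entry / np.linalg.norm(entry)
        # central branch direction: tangent pointing toward the vertex
        zhat = np.array([0.0, 0.0, 1.0])
        t0 = zhat - np.dot(zhat, u) * u
        t0 /= np.linalg.norm(t0)
        side = np.cross(u, t0)
        k = 0
        for b, (ang, n_b) in enumerate(zip((-30.0, 0.0, 30.0), branch_counts)):
            a = np.deg2rad(ang)
            tdir = np.cos(a) * t0 + np.sin(a) * side
            length = rng.uniform(100.0, 120.0)
            # contacts spaced `contact_spacing_mm` apart ending at the branch tip
            dists = length - contact_spacing_mm * np.arange(n_b)[::-1]
            for d in dists:
                s = d / r_sub  # geodesic angle along the great circle
                pos = r_sub * (u * np.cos(s) + tdir * np.sin(s))
                k += 1
                contacts.append(Contact(f"E{site}{k}", pos, "subscalp"))

    if intracranial_positions is not None:
        if len(intracranial_positions) != n_intracranial:
            raise ValueError(
                "intracranial_positions length must equal n_intracranial"
            )
        for i, pos in enumerate(intracranial_positions):
            pos = np.asarray(pos, float)
            if np.linalg.norm(pos) >= r_sub:
                raise ValueError("intracranial contacts must lie strictly inside")
            contacts.append(Contact(f"IC{i + 1}", pos, "intracranial"))
    else:
        for i in range(n_intracranial):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            radius = rng.uniform(40.0, 0.85 * r_sub)
            contacts.append(Contact(f"IC{i + 1}", radius * direction, "intracranial"))

    return HeadLayout(
        contacts, head_radius_mm=head_radius_mm, scalp_thickness_mm=scalp_thickness_mm
    )


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SourceSpec:
    """A stage-locked narrowband cortical source."""

    name: str
    stage: str  # hypnogram stage whose epochs carry this source
    band: tuple[float, float]  # Hz
    center: np.ndarray  # 3-vector mm
    spread_mm: float = 80.0
    amplitude_uv: float = 20.0  # RMS at unit gain
    eyes_closed_only: bool = False

    def __post_init__(self) -> None:
        if self.stage not in SLEEP_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.amplitude_uv < 0:
            raise ValueError("amplitude must be non-negative")
        self.center = np.asarray(self.center, float).reshape(3)


def default_stage_sources() -> list[SourceSpec]:
    """The four stage-specific oscillations at their canonical locations.

    Posterior alpha and the sleep oscillations are modelled as bilateral
    source pairs (occipital alpha, central sigma over the hand-knob areas,
    frontal delta and beta), which is both physiologically conventional and
    avoids tying the field maximum to a single montage site.
    """
    r_src = 78.0  # cortical shell, mm
    return [
        SourceSpec("wake_alpha_l", "W", DEFAULT_BANDS["alpha"],
                   sphere_point(75, 160, r_src), 110.0, 22.0, eyes_closed_only=True),
        SourceSpec("wake_alpha_r", "W", DEFAULT_BANDS["alpha"],
                   sphere_point(75, -160, r_src), 110.0, 22.0, eyes_closed_only=True),
        SourceSpec("n2_sigma_l", "N2", DEFAULT_BANDS["sigma"],
                   sphere_point(48, 85, r_src), 80.0, 18.0),
        SourceSpec("n2_sigma_r", "N2", DEFAULT_BANDS["sigma"],
                   sphere_point(48, -85, r_src), 80.0, 18.0),
        SourceSpec("n3_delta_l", "N3", DEFAULT_BANDS["delta"],
                   sphere_point(55, 35, r_src), 80.0, 140.0),
        SourceSpec("n3_delta_r", "N3", DEFAULT_BANDS["delta"],
                   sphere_point(55, -35, r_src), 80.0, 140.0),
        SourceSpec("rem_beta_l", "REM", DEFAULT_BANDS["beta"],
                   sphere_point(55, 35, r_src), 80.0, 15.0),
        SourceSpec("rem_beta_r", "REM", DEFAULT_BANDS["beta"],
                   sphere_point(55, -35, r_src), 80.0, 15.0),
    ]


@dataclass
class EvokedComponent:
    """One Gaussian-windowed evoked peak."""

    latency_ms: float
    amplitude_uv: float
    center: np.ndarray
    width_ms: float = 15.0
    spread_mm: float = 60.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float).reshape(3)


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines the output."""

    sampling_rate: float = 256.0
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    sources: list[SourceSpec] = field(default_factory=default_stage_sources)
    aperiodic_exponent: float = 1.5
    background_rms_uv: float = 10.0
    sensor_noise_uv: dict = field(
        default_factory=lambda: {"subscalp": 2.0, "scalp": 2.0, "intracranial": 2.0}
    )
    subscalp_gain: float = 1.0  # amplitude factor on subscalp source projections
    eyes_closed: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.sampling_rate / 2
        for name, (lo, hi) in self.bands.items():
            if not (0 <= lo < hi < nyq):
                raise ValueError(
                    f"band {name!r} edges ({lo}, {hi}) must satisfy "
                    f"0 <= lo < hi < Nyquist ({nyq} Hz)"
                )
        for s in self.sources:
            lo, hi = s.band
            if not (0 <= lo < hi < nyq):
                raise ValueError(f"source {s.name!r} band outside (0, Nyquist)")


# ---------------------------------------------------------------------------
# noise and source waveforms

def one_over_f_noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    fs: float,
    exponent: float,
    rms_uv: float,
) -> np.ndarray:
    """1/f^exponent background synthesized by spectral shaping of white noise.

    Each row is independently shaped and scaled to ``rms_uv`` microvolts RMS.
    """
    n_ch, n = shape
    if rms_uv == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2)
    spec *= shaping
    x = np.fft.irfft(spec, n=n, axis=-1)
    # analytic normalization to the target RMS in expectation; the realized
    # per-channel RMS wobbles by a few percent (the low-frequency bins carry
    # most of the power and have few degrees of freedom), as real channels do.
    # E[var] = (2*sum interior s_k^2 + s_Nyq^2) / n for unit-variance input
    s2 = shaping**2
    expected_var = (2 * s2[1:-1].sum() + s2[-1] * (2 - n % 2)) / n
    return (rms_uv / np.sqrt(expected_var)) * x


def narrowband_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` (6th-order Butterworth,
    applied forward-backward so out-of-band leakage stays far below the 1/f
    background)."""
    sos = signal.butter(6, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    std = x.std()
    return x / std if std > 0 else x


# ---------------------------------------------------------------------------
# session simulation

def simulate_session(
    layout: HeadLayout, hypnogram: Hypnogram, config: SimulationConfig
) -> Recording:
    """Simulate a sleep-wake session on ``layout`` following ``hypnogram``.

    Each epoch carries its stage's narrowband sources projected to the
    sensors with exponential distance decay, on top of per-channel 1/f
    background and white sensor noise.  Subscalp channels receive the source
    projection scaled by ``config.subscalp_gain``.
    """
    fs = config.sampling_rate
    n = int(round(hypnogram.duration * fs))
    n_ch = len(layout)
    rng = np.random.default_rng(config.seed)

    data = one_over_f_noise(
        rng, (n_ch, n), fs, config.aperiodic_exponent, config.background_rms_uv
    )
    noise_sd = np.array([config.sensor_noise_uv[m] for m in layout.modalities])
    data += noise_sd[:, None] * rng.standard_normal((n_ch, n))

    sense = _sensing_positions(layout)
    sub_mask = np.array([m == "subscalp" for m in layout.modalities])

    for src in config.sources:
        if src.amplitude_uv == 0:
            continue
        if src.eyes_closed_only and not config.eyes_closed:
            continue
        stage_samples = hypnogram.stage_mask(src.stage, fs, n)
        if not stage_samples.any():
            continue
        series = src.amplitude_uv * narrowband_noise(rng, n, fs, src.band)
        series = np.where(stage_samples, series, 0.0)
        gains = spatial_gain(src.center, sense, src.spread_mm)
        gains = np.where(sub_mask, gains * config.subscalp_gain, gains)
        data += gains[:, None] * series[None, :]

    return Recording(
        data=data,
        sampling_rate=fs,
        layout=layout,
        hypnogram=hypnogram,
    )


# ---------------------------------------------------------------------------
# interictal spikes

def spike_template(fs: float, duration_s: float = 0.070) -> np.ndarray:
    """Biphasic interictal spike template, 70 ms total, ~20 ms rise, peak +1."""
    t = np.arange(int(round(duration_s * fs))) / fs
    main = np.exp(-((t - 0.020) ** 2) / (2 * 0.006**2))
    after = -0.45 * np.exp(-((t - 0.045) ** 2) / (2 * 0.012**2))
    w = main + after
    return w / np.abs(w).max()


def simulate_spikes(
    recording: Recording,
    n_spikes: int,
    dipole_position: np.ndarray,
    dipole_moment: np.ndarray,
    amplitude_uv: float = 50.0,
    amplitude_jitter_uv: float = 0.0,
    spread_mm: float = 90.0,
    seed: int = 0,
    onsets: Optional[Sequence[float]] = None,
    subscalp_gain: float = 1.0,
    kernel: str = "gaussian",
    far_lobe_attenuation: float = 0.3,
) -> Recording:
    """Add dipolar interictal spikes and annotate their onsets.

    The spike field is signed: sensors on the moment side of the dipole see
    a positive lobe, sensors on the far side a negative lobe (gain times the
    cosine between the dipole moment and the dipole-to-sensor direction,
    with the far lobe attenuated by ``far_lobe_attenuation`` — scalp maps of
    focal discharges show a dominant pole with a much weaker opposite
    field).  The default Gaussian kernel gives the flat-topped apex of a
    skull-smoothed focal field.
    """
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    rng = np.random.default_rng(seed)
    fs = recording.sampling_rate
    template = spike_template(fs)
    dur = len(template) / fs

    if onsets is None:
        onsets = _draw_onsets(rng, n_spikes, recording.duration, dur)
    else:
        onsets = np.sort(np.asarray(onsets, float))
        if len(onsets) != n_spikes:
            raise ValueError("len(onsets) must equal n_spikes")
        if (np.diff(onsets) < dur).any() or onsets[0] < 0 or (
            onsets[-1] + dur > recording.duration
        ):
            raise ValueError(
                "spikes would overlap or fall outside the recording"
            )

    pos = np.asarray(dipole_position, float)
    mom = np.asarray(dipole_moment, float)
    mom = mom / np.linalg.norm(mom)
    sense = _sensing_positions(recording.layout)
    vec = sense - pos
    dist = np.linalg.norm(vec, axis=1)
    dist[dist == 0] = 1e-9
    cosang = (vec / dist[:, None]) @ mom
    lobe = np.where(cosang >= 0, cosang, far_lobe_attenuation * cosang)
    gains = spatial_gain(pos, sense, spread_mm, kernel=kernel) * lobe
    sub_mask = np.array([m == "subscalp" for m in recording.layout.modalities])
    gains = np.where(sub_mask, gains * subscalp_gain, gains)

    out = recording.copy()
    for onset in onsets:
        amp = amplitude_uv + (
            rng.normal(0.0, amplitude_jitter_uv) if amplitude_jitter_uv > 0 else 0.0
        )
        i0 = int(round(onset * fs))
        out.data[:, i0 : i0 + len(template)] += (
            amp * gains[:, None] * template[None, :]
        )
        out.annotations.events.append(
            Event(
                "spike",
                onset=onset,
                duration=dur,
                attributes={
                    "dipole_position": pos.tolist(),
                    "dipole_moment": mom.tolist(),
                    "amplitude_uv": float(amp),
                },
            )
        )
    return out


def _draw_onsets(
    rng: np.random.Generator, n_events: int, total: float, min_gap: float
) -> np.ndarray:
    """Random onsets with pairwise spacing >= min_gap, or an explicit error."""
    if n_events * min_gap * 2 > total:
        raise ValueError(
            f"{n_events} events of {min_gap:.3f}s cannot be placed without "
            f"overlap in {total:.1f}s"
        )
    for _ in range(200):
        cand = np.sort(rng.uniform(0, total - min_gap, n_events))
        if n_events == 1 or np.diff(cand).min() >= min_gap:
            return cand
    raise ValueError("spikes would overlap: could not place non-overlapping onsets")


# ---------------------------------------------------------------------------
# seizures

def simulate_seizure(
    recording: Recording,
    soz_position: np.ndarray,
    pz_position: np.ndarray,
    onset: float,
    duration: float,
    freq_start: float,
    freq_end: float,
    propagation_delay: float = 10.0,
    amplitude_uv: float = 60.0,
    phase_jitter: float = 0.05,
    spread_mm: float = 35.0,
    seed: int = 0,
    subscalp_gain: float = 1.0,
) -> Recording:
    """Add a propagating ictal discharge and annotate it.

    A linear chirp (``freq_start`` to ``freq_end``) with a linear amplitude
    ramp over its first third starts at the SOZ; a phase-perturbed copy
    appears at the PZ after ``propagation_delay`` seconds.  All channels
    receive distance-weighted mixtures of the two.
    """
    fs = recording.sampling_rate
    nyq = fs / 2
    if duration <= 0:
        raise ValueError("seizure duration must be > 0")
    if onset + duration > recording.duration + 1e-9:
        raise ValueError("seizure extends beyond the recording")
    if not (0 < freq_start < nyq and 0 < freq_end < nyq):
        raise ValueError("frequency trajectory must lie within (0, Nyquist)")
    soz = np.asarray(soz_position, float)
    pz = np.asarray(pz_position, float)
    if np.allclose(soz, pz):
        raise ValueError("SOZ and PZ positions must differ")

    rng = np.random.default_rng(seed)
    n_sz = int(round(duration * fs))
    t = np.arange(n_sz) / fs
    inst_freq = freq_start + (freq_end - freq_start) * t / duration
    phase = 2 * np.pi * np.cumsum(inst_freq) / fs
    ramp = np.clip(t / (duration / 3), 0, 1)
    soz_wave = amplitude_uv * ramp * np.sin(phase)

    delay_n = int(round(propagation_delay * fs))
    pz_wave = np.zeros(n_sz)
    if delay_n < n_sz:
        jitter = np.cumsum(rng.normal(0, phase_jitter, n_sz - delay_n))
        pz_wave[delay_n:] = (
            amplitude_uv
            * ramp[: n_sz - delay_n]
            * np.sin(phase[: n_sz - delay_n] + jitter)
        )

    sense = _sensing_positions(recording.layout)
    g_soz = spatial_gain(soz, sense, spread_mm)
    g_pz = spatial_gain(pz, sense, spread_mm)
    sub = np.array([m == "subscalp" for m in recording.layout.modalities])
    out = recording.copy()
    mix = g_soz[:, None] * soz_wave[None, :] + g_pz[:, None] * pz_wave[None, :]
    i0 = int(round(onset * fs))
    out.data[:, i0 : i0 + n_sz] += np.where(sub[:, None], subscalp_gain, 1.0) * mix
    out.annotations.events.append(
        Event(
            "seizure",
            onset=onset,
            duration=duration,
            attributes={
                "soz_position": soz.tolist(),
                "pz_position": pz.tolist(),
                "freq_start": freq_start,
                "freq_end": freq_end,
                "propagation_delay": propagation_delay,
                "amplitude_uv": amplitude_uv,
            },
        )
    )
    return out


# ---------------------------------------------------------------------------
# evoked responses

def simulate_evoked(
    layout: HeadLayout,
    n_trials: int,
    modality: str,
    components: Sequence[EvokedComponent],
    isi_s: float,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> Recording:
    """Simulate a stimulation block with Gaussian-windowed evoked components.

    Stimuli of the given sensory ``modality`` (visual or auditory) repeat
    every ``isi_s`` seconds; each adds the component waveform to the
    post-stimulus samples.  Onsets are annotated as stimulus events.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if modality not in ("visual", "auditory"):
        raise ValueError("stimulus modality must be 'visual' or 'auditory'")
    for c in components:
        if c.latency_ms > 300:
            warnings.warn(
                f"component latency {c.latency_ms} ms exceeds the 0-300 ms "
                "analysis window; simulated anyway",
                stacklevel=2,
            )
    fs = config.sampling_rate
    pre = 1.0
    duration = pre + n_trials * isi_s + 1.0
    n = int(round(duration * fs))
    n_ch = len(layout)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    data = one_over_f_noise(
        rng, (n_ch, n), fs, config.aperiodic_exponent, config.background_rms_uv
    )
    noise_sd = np.array([config.sensor_noise_uv[m] for m in layout.modalities])
    data += noise_sd[:, None] * rng.standard_normal((n_ch, n))

    sense = _sensing_positions(layout)
    sub = np.array([m == "subscalp" for m in layout.modalities])

    # one waveform per channel covering 0..350 ms post-stimulus
    wave_len = int(round(0.400 * fs))
    t_ms = 1000 * np.arange(wave_len) / fs
    waves = np.zeros((n_ch, wave_len))
    for c in components:
        gains = spatial_gain(c.center, sense, c.spread_mm)
        # subscalp source projections carry the configured gain factor
        gains = np.where(sub, gains * config.subscalp_gain, gains)
        shape = np.exp(-((t_ms - c.latency_ms) ** 2) / (2 * c.width_ms**2))
        waves += c.amplitude_uv * gains[:, None] * shape[None, :]

    events = EventSet()
    for k in range(n_trials):
        onset = pre + k * isi_s
        i0 = int(round(onset * fs))
        data[:, i0 : i0 + wave_len] += waves
        events.events.append(
            Event("stimulus", onset=onset, duration=0.0,
                  attributes={"modality": modality})
        )
    return Recording(data=data, sampling_rate=fs, layout=layout, annotations=events)


def default_evoked_components(modality: str) -> list[EvokedComponent]:
    """Canonical two-component evoked responses for each stimulus modality."""
    if modality == "visual":
        occ = sphere_point(85, 180, 78.0)
        return [
            EvokedComponent(100.0, 10.0, occ, spread_mm=70.0),
            EvokedComponent(180.0, -6.0, occ, spread_mm=70.0),
        ]
    if modality == "auditory":
        left = sphere_point(45, 60, 78.0)
        right = sphere_point(45, -60, 78.0)
        return [
            EvokedComponent(100.0, -6.0, left, spread_mm=70.0),
            EvokedComponent(100.0, -6.0, right, spread_mm=70.0),
            EvokedComponent(200.0, 4.0, left, spread_mm=70.0),
            EvokedComponent(200.0, 4.0, right, spread_mm=70.0),
        ]
    raise ValueError("modality must be 'visual' or 'auditory'")


# ---------------------------------------------------------------------------
# hypnograms

def corrupt_hypnogram(hypnogram: Hypnogram, flip_rate: float, seed: int = 0) -> Hypnogram:
    """Independently replace each epoch by a random *different* stage.

    Emulates imperfect human scoring: with probability ``flip_rate`` an epoch
    label is swapped for one of the four other stages, uniformly.
    """
    if not 0 <= flip_rate <= 1:
        raise ValueError("flip_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    stages = list(hypnogram.stages)
    for i, s in enumerate(stages):
        if rng.random() < flip_rate:
            others = [x for x in SLEEP_STAGES if x != s]
            stages[i] = others[rng.integers(len(others))]
    return Hypnogram(stages=stages, epoch_length=hypnogram.epoch_length)


def make_night_hypnogram(n_epochs: int = 960, seed: int = 0,
                         epoch_length: float = 30.0) -> Hypnogram:
    """A plausible full-night hypnogram built from NREM-REM cycles.

    Starts awake, then repeats N1 -> N2 -> N3 -> N2 -> REM cycles with
    seeded random stage durations and occasional brief awakenings.
    """
    rng = np.random.default_rng(seed)
    stages: list[str] = ["W"] * int(rng.integers(5, 15))
    pattern = ("N1", "N2", "N3", "N2", "REM")
    mean_len = {"N1": 6, "N2": 30, "N3": 35, "REM": 25}
    while len(stages) < n_epochs:
        for s in pattern:
            k = max(1, int(rng.normal(mean_len[s], mean_len[s] / 4)))
            stages.extend([s] * k)
            if rng.random() < 0.25:
                stages.extend(["W"] * int(rng.integers(1, 4)))
            if len(stages) >= n_epochs:
                break
    return Hypnogram(stages=stages[:n_epochs], epoch_length=epoch_length)
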