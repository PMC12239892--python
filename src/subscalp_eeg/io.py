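"""File formats: BIDS-style TSV sidecars, NPZ containers, and EDF export.

Layouts travel as ``electrodes.tsv`` (name, x, y, z, modality; mm),
hypnograms as two-column TSV (epoch_index, stage), events as
``events.tsv`` (onset, duration, trial_type, attributes-as-JSON).  Whole
recordings round-trip through a compressed NPZ container, and can be
exported as 16-bit EDF (physical dimension uV) readable by any EDF tool;
reading EDF back goes through MNE.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Contact, Event, EventSet, HeadLayout, Hypnogram, Recording

__all__ = [
    "write_electrodes_tsv",
    "read_electrodes_tsv",
    "write_hypnogram_tsv",
    "read_hypnogram_tsv",
    "write_events_tsv",
    "read_events_tsv",
    "save_recording_npz",
    "load_recording_npz",
    "write_edf",
    "read_edf",
]


# ---------------------------------------------------------------------------
# TSV sidecars

def write_electrodes_tsv(layout: HeadLayout, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "name": layout.names,
            "x": layout.positions[:, 0],
            "y": layout.positions[:, 1],
            "z": layout.positions[:, 2],
            "modality": layout.modalities,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_electrodes_tsv(
    path: str | Path, head_radius_mm: float = 92.0, scalp_thickness_mm: float = 7.0
) -> HeadLayout:
    df = pd.read_csv(path, sep="\t")
    contacts = [
        Contact(str(n), np.array([x, y, z]), str(m))
        for n, x, y, z, m in zip(df["name"], df["x"], df["y"], df["z"],
                                 df["modality"])
    ]
    return HeadLayout(contacts, head_radius_mm=head_radius_mm,
                      scalp_thickness_mm=scalp_thickness_mm)


def write_hypnogram_tsv(hypnogram: Hypnogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# epoch_length_s={hypnogram.epoch_length}\n")
        fh.write("epoch_index\tstage\n")
        for i, s in enumerate(hypnogram.stages):
            fh.write(f"{i}\t{s}\n")


def read_hypnogram_tsv(path: str | Path) -> Hypnogram:
    epoch_length = 30.0
    stages = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "epoch_length_s=" in line:
                    epoch_length = float(line.split("=", 1)[1])
                continue
            if not line or line.startswith("epoch_index"):
                continue
            _, stage = line.split("\t")
            stages.append(stage)
    return Hypnogram(stages=stages, epoch_length=epoch_length)


def write_events_tsv(events: EventSet, path: str | Path) -> None:
    rows = [
        {
            "onset": e.onset,
            "duration": e.duration,
            "trial_type": e.kind,
            "attributes": json.dumps(e.attributes),
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "attributes"]).to_csv(
        path, sep="\t", index=False
    )


def read_events_tsv(path: str | Path) -> EventSet:
    df = pd.read_csv(path, sep="\t")
    events = [
        Event(
            kind=str(r.trial_type),
            onset=float(r.onset),
            duration=float(r.duration),
            attributes=json.loads(r.attributes) if isinstance(r.attributes, str) else {},
        )
        for r in df.itertuples()
    ]
    return EventSet(events)


# ---------------------------------------------------------------------------
# NPZ container

def save_recording_npz(recording: Recording, path: str | Path) -> None:
    meta = {
        "sampling_rate": recording.sampling_rate,
        "head_radius_mm": recording.layout.head_radius_mm,
        "scalp_thickness_mm": recording.layout.scalp_thickness_mm,
        "events": [
            {"kind": e.kind, "onset": e.onset, "duration": e.duration,
             "attributes": e.attributes}
            for e in recording.annotations
        ],
        "hypnogram": None
        if recording.hypnogram is None
        else {"epoch_length": recording.hypnogram.epoch_length,
              "stages": recording.hypnogram.stages},
    }
    np.savez_compressed(
        path,
        data=recording.data,
        names=np.array(recording.layout.names),
        positions=recording.layout.positions,
        modalities=np.array(recording.layout.modalities),
        meta=np.array(json.dumps(meta)),
    )


def load_recording_npz(path: str | Path) -> Recording:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        contacts = [
            Contact(str(n), p, str(m))
            for n, p, m in zip(z["names"], z["positions"], z["modalities"])
        ]
        layout = HeadLayout(
            contacts,
            head_radius_mm=meta["head_radius_mm"],
            scalp_thickness_mm=meta["scalp_thickness_mm"],
        )
        events = EventSet(
            [Event(e["kind"], e["onset"], e["duration"], e["attributes"])
             for e in meta["events"]]
        )
        hyp = meta["hypnogram"]
        hypnogram = (
            None if hyp is None
            else Hypnogram(stages=hyp["stages"], epoch_length=hyp["epoch_length"])
        )
        return Recording(
            data=z["data"],
            sampling_rate=meta["sampling_rate"],
            layout=layout,
            annotations=events,
            hypnogram=hypnogram,
        )


# ---------------------------------------------------------------------------
# EDF

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF with physical dimension uV.

    Uses 1-second data records; the sampling rate must therefore be a whole
    number of samples per second, and a trailing partial second is dropped.
    """
    fs = recording.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_rec = recording.n_samples // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    ns = recording.n_channels

    phys_max = np.maximum(np.abs(recording.data).max(axis=1), 1.0) * 1.0001
    dig_max = 32767

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (ns + 1)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    fields = [
        [_pad(name, 16) for name in recording.layout.names],
        [_pad("AgAgCl electrode", 80)] * ns,
        [_pad("uV", 8)] * ns,
        [_pad(f"{-m:.6g}"[:8], 8) for m in phys_max],
        [_pad(f"{m:.6g}"[:8], 8) for m in phys_max],
        [_pad(str(-dig_max), 8)] * ns,
        [_pad(str(dig_max), 8)] * ns,
        [_pad("", 80)] * ns,
        [_pad(str(spr), 8)] * ns,
        [_pad("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.writelines(group)
        scale = dig_max / phys_max
        for r in range(n_rec):
            block = recording.data[:, r * spr : (r + 1) * spr]
            digital = np.round(block * scale[:, None]).astype("<i2")
            fh.write(digital.tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file via MNE; returns (channels x samples uV, fs, names)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


# ---------------------------------------------------------------------------
# analysis exports

def write_spectrum_tsv(frequencies, values, path: str | Path,
                       value_name: str = "power_db") -> None:
    """Two-column TSV export for spectra and coherence profiles."""
    pd.DataFrame({"frequency_hz": np.asarray(frequencies),
                  value_name: np.asarray(values)}).to_csv(
        path, sep="\t", index=False)


def write_topomap_tsv(topomap, path: str | Path) -> None:
    pd.DataFrame({"contact": topomap.names,
                  "value": topomap.values}).to_csv(path, sep="\t", index=False)


def write_pairing_tsv(pairing, path: str | Path) -> None:
    pd.DataFrame(pairing.pairs,
                 columns=["subscalp", "scalp", "distance_mm"]).to_csv(
        path, sep="\t", index=False)


def render_topomap(topomap, path: str | Path, title: str = "") -> None:
    """Render an interpolated topomap to PNG (requires a grid)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if topomap.grid_values is None:
        from .topo import interpolate_topomap

        topomap = interpolate_topomap(topomap)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.pcolormesh(topomap.grid_x, topomap.grid_y, topomap.grid_values,
                       shading="auto", cmap="RdBu_r")
    ax.scatter(*topomap.positions_2d.T, s=8, c="k")
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.75)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
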