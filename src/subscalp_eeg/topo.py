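"""Electrode pairing, topographic maps, and spatial correlation statistics.

Noninferiority is assessed on pairs of neighboring electrodes: each subscalp
contact is matched to its closest scalp contact in 3D.  Topographic maps
(one scalar per contact, interpolated on a projected head disk) from the two
modalities are compared with a Pearson spatial correlation, whose
significance is assessed against a permutation null built by shuffling the
contact-to-value assignment 100 times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.stats import pearsonr

from .core import HeadLayout

__all__ = [
    "ElectrodePairing",
    "TopoMap",
    "SpatialCorrelationResult",
    "nearest_neighbor_pairing",
    "project_2d",
    "spatial_correlation",
    "permutation_spatial_test",
    "interpolate_topomap",
]

#: Prespecified interpretation thresholds for spatial correlations.
RHO_MODERATE = 0.5
RHO_STRONG = 0.7


@dataclass
class ElectrodePairing:
    """Each subscalp contact matched to its closest scalp neighbor."""

    pairs: list[tuple[str, str, float]]  # (subscalp, scalp, distance mm)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def subscalp_names(self) -> list[str]:
        return [p[0] for p in self.pairs]

    @property
    def scalp_names(self) -> list[str]:
        return [p[1] for p in self.pairs]


@dataclass
class TopoMap:
    """One scalar per contact with 2D head-projected positions."""

    names: list[str]
    values: np.ndarray
    positions_2d: np.ndarray  # (n, 2), mm in the projected plane
    grid_x: Optional[np.ndarray] = None
    grid_y: Optional[np.ndarray] = None
    grid_values: Optional[np.ndarray] = None  # NaN outside the head disk

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.positions_2d = np.asarray(self.positions_2d, float)
        if len(self.values) != len(self.names):
            raise ValueError("value count must equal contact count")
        if self.positions_2d.shape != (len(self.names), 2):
            raise ValueError("positions_2d must be (n_contacts, 2)")

    def with_values(self, values: np.ndarray) -> "TopoMap":
        return TopoMap(self.names, np.asarray(values, float), self.positions_2d)


@dataclass
class SpatialCorrelationResult:
    rho: float
    p_perm: float
    n_shuffles: int
    null_rhos: Optional[np.ndarray] = None


def nearest_neighbor_pairing(layout: HeadLayout) -> ElectrodePairing:
    """Match every subscalp contact to its closest scalp contact.

    Distance ties are broken by the lexicographically smallest scalp name so
    the pairing is deterministic and independent of contact listing order.
    """
    subs = layout.by_modality("subscalp")
    scalps = layout.by_modality("scalp")
    if not subs or not scalps:
        raise ValueError("layout must contain at least one subscalp and one scalp contact")
    scalps = sorted(scalps, key=lambda c: c.name)
    scalp_pos = np.array([c.position for c in scalps])
    pairs = []
    for sub in subs:
        d = np.linalg.norm(scalp_pos - sub.position, axis=1)
        best = int(np.argmin(d))  # first minimum = alphabetically first
        pairs.append((sub.name, scalps[best].name, float(d[best])))
    return ElectrodePairing(pairs)


def project_2d(layout: HeadLayout, modality: Optional[str] = None) -> TopoMap:
    """Azimuthal-equidistant top-view projection about the vertex.

    The vertex maps to the origin; a contact at polar angle theta lands at
    planar radius R*theta, preserving its azimuth.  Positions off the sphere
    are projected via normalization.  Returns a TopoMap scaffold with zero
    values for the selected contacts.
    """
    contacts = layout.contacts if modality is None else layout.by_modality(modality)
    if not contacts:
        raise ValueError(f"no contacts of modality {modality!r}")
    R = layout.head_radius_mm
    out = np.zeros((len(contacts), 2))
    for i, c in enumerate(contacts):
        p = c.position
        r = np.linalg.norm(p)
        if r == 0:
            raise ValueError(f"contact {c.name} at origin cannot be projected")
        u = p / r
        theta = np.arccos(np.clip(u[2], -1, 1))
        rho_xy = np.hypot(u[0], u[1])
        if rho_xy < 1e-12:
            out[i] = (0.0, 0.0)
        else:
            out[i] = R * theta * np.array([u[0], u[1]]) / rho_xy
    return TopoMap(names=[c.name for c in contacts],
                   values=np.zeros(len(contacts)),
                   positions_2d=out)


def make_topomap(layout: HeadLayout, values_by_name: dict[str, float],
                 modality: str) -> TopoMap:
    """Convenience: TopoMap of one modality from a name -> value mapping."""
    base = project_2d(layout, modality)
    vals = np.array([values_by_name[n] for n in base.names])
    return base.with_values(vals)


def _grid_vector(m: TopoMap) -> np.ndarray:
    if m.grid_values is None:
        raise ValueError("common_grid mode requires interpolated maps")
    return m.grid_values[np.isfinite(m.grid_values)]


def spatial_correlation(
    map_a: TopoMap,
    map_b: TopoMap,
    mode: str = "common_grid",
    pairing: Optional[ElectrodePairing] = None,
) -> float:
    """Pearson spatial correlation between two topographic maps.

    ``matched_contacts`` correlates one value per subscalp-scalp pair;
    ``common_grid`` correlates the interpolated head-disk grids (both maps
    must share the same grid).  Constant maps have undefined correlation.
    """
    if mode == "matched_contacts":
        if pairing is None:
            raise ValueError("matched_contacts mode requires a pairing")
        ia = {n: i for i, n in enumerate(map_a.names)}
        ib = {n: i for i, n in enumerate(map_b.names)}
        # the pairing decides which map holds the subscalp values, so the
        # correlation is symmetric in its arguments
        if all(s in ia for s in pairing.subscalp_names):
            sub_map, sub_idx, sc_map, sc_idx = map_a, ia, map_b, ib
        else:
            sub_map, sub_idx, sc_map, sc_idx = map_b, ib, map_a, ia
        a = np.array([sub_map.values[sub_idx[s]] for s in pairing.subscalp_names])
        b = np.array([sc_map.values[sc_idx[s]] for s in pairing.scalp_names])
    elif mode == "common_grid":
        a = _grid_vector(map_a)
        b = _grid_vector(map_b)
        if a.shape != b.shape:
            raise ValueError("maps are not interpolated on the same grid")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for v in (a, b):
        if np.ptp(v) <= 1e-10 * max(1.0, np.abs(v).max()):
            raise ValueError("spatial correlation undefined for a constant map")
    return float(pearsonr(a, b)[0])


def interpolate_topomap(
    topomap: TopoMap,
    grid_resolution: int = 32,
    disk_radius: Optional[float] = None,
) -> TopoMap:
    """Thin-plate-spline interpolation of contact values onto a head-disk grid.

    Exact at contact locations; grid points outside the disk are NaN.
    """
    if len(topomap.names) < 4:
        raise ValueError("interpolation requires at least 4 contacts")
    if disk_radius is None:
        disk_radius = 1.05 * np.linalg.norm(topomap.positions_2d, axis=1).max()
    ax = np.linspace(-disk_radius, disk_radius, grid_resolution)
    gx, gy = np.meshgrid(ax, ax)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = np.hypot(pts[:, 0], pts[:, 1]) <= disk_radius
    interp = RBFInterpolator(topomap.positions_2d, topomap.values,
                             kernel="thin_plate_spline")
    vals = np.full(len(pts), np.nan)
    vals[inside] = interp(pts[inside])
    return TopoMap(
        names=topomap.names,
        values=topomap.values,
        positions_2d=topomap.positions_2d,
        grid_x=gx,
        grid_y=gy,
        grid_values=vals.reshape(gx.shape),
    )


def permutation_spatial_test(
    map_a: TopoMap,
    map_b: TopoMap,
    n_shuffles: int = 100,
    seed: int = 0,
    mode: str = "common_grid",
    pairing: Optional[ElectrodePairing] = None,
    grid_resolution: int = 32,
    disk_radius: Optional[float] = None,
) -> SpatialCorrelationResult:
    """Spatial correlation with a shuffled-label permutation null.

    The null reassigns ``map_a``'s values to its contacts at random
    ``n_shuffles`` times (shuffled electrode labels); the one-sided p-value
    is (1 + #{null rho >= observed}) / (n_shuffles + 1).
    """
    if n_shuffles < 19:
        raise ValueError(
            "n_shuffles must be >= 19 to resolve significance at alpha = 0.05"
        )
    rng = np.random.default_rng(seed)

    if mode == "common_grid" and disk_radius is None:
        ra = np.linalg.norm(map_a.positions_2d, axis=1).max()
        rb = np.linalg.norm(map_b.positions_2d, axis=1).max()
        disk_radius = 1.05 * max(ra, rb)

    def prepared(m: TopoMap) -> TopoMap:
        if mode == "common_grid":
            return interpolate_topomap(m, grid_resolution, disk_radius)
        return m

    obs = spatial_correlation(prepared(map_a), prepared(map_b), mode, pairing)
    ref_b = prepared(map_b)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        perm_vals = rng.permutation(map_a.values)
        null[i] = spatial_correlation(
            prepared(map_a.with_values(perm_vals)), ref_b, mode, pairing
        )
    p = (1 + int((null >= obs).sum())) / (n_shuffles + 1)
    return SpatialCorrelationResult(rho=obs, p_perm=float(p),
                                    n_shuffles=n_shuffles, null_rhos=null)
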