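"""Spherical-probe pore profiling along the membrane normal.

For each height z the profile records the largest spherical probe that fits in
the protein at that level: ``radius(z) = max over in-plane centers c of
[min over atoms i of (|c - x_i| - vdw_i)]``. Two deterministic search modes are
provided, both exactly reproducible by a dense grid search. ``"axis"`` (the
default) maximizes at every z over a disk of radius ``track_radius`` around
the channel seed, so on an oriented structure the probe tracks the (straight)
pore rather than jumping to surface pockets or bulk. ``"box"`` maximizes over
a fixed square box and is the mode used for analytic benchmark geometries.

Radii are capped at ``r_max`` to mark bulk solvent. Gate regions flank the
central cavity: the cavity center z0 is the profile maximum within the central
half of the spanned z range, the cytoplasmic gate region is [z_min, z0 - 2 Å]
and the periplasmic region [z0 + 2 Å, z_max]. Each gate is summarized by the
mean radius over a 4 Å window centered on its constriction (the region
minimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .structure_io import Structure

__all__ = [
    "SearchSettings",
    "PoreProfile",
    "GateRadii",
    "compute_profile",
    "locate_gate_regions",
    "gate_min_radius",
    "state_plane_coordinates",
]


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class SearchSettings:
    """Probe-center search configuration.

    mode
        ``"axis"``: per-z search over a disk of radius ``track_radius`` around
        ``seed_center`` (the pore axis of an oriented structure).
        ``"box"``: per-z search over a square box of half-width
        ``box_halfwidth`` around ``seed_center``.
    r_max
        Radius cap (Å) marking bulk solvent.
    """

    mode: str = "axis"
    seed_center: tuple[float, float] = (0.0, 0.0)
    box_halfwidth: float = 6.0
    track_radius: float = 3.5
    coarse_step: float = 0.25
    r_max: float = 5.0

    def __post_init__(self) -> None:
        if self.mode not in ("axis", "box"):
            raise ValueError(f"unknown search mode {self.mode!r}")
        if self.r_max <= 0 or self.box_halfwidth <= 0 or self.track_radius <= 0:
            raise ValueError("search settings must be positive")


@dataclass
class PoreProfile:
    """Probe radius as a function of z, plus the located gate regions."""

    z_grid: np.ndarray
    radius: np.ndarray
    probe_center: np.ndarray  # (n, 2)
    unbounded: np.ndarray  # bool per grid point: no atoms constrained the slab
    r_max: float
    gate_regions: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": self.z_grid,
                "radius": self.radius,
                "x": self.probe_center[:, 0],
                "y": self.probe_center[:, 1],
            }
        )


@dataclass(frozen=True)
class GateRadii:
    """4 Å-window mean probe radius around each gate constriction."""

    cytoplasmic_min: float
    periplasmic_min: float
    constriction_z: dict[str, float]


def _clearance(center: np.ndarray, coords: np.ndarray, vdw: np.ndarray) -> float:
    if coords.shape[0] == 0:
        return np.inf
    d = np.linalg.norm(coords - center, axis=1) - vdw
    return float(d.min())


def _refine(
    start: np.ndarray,
    z: float,
    coords: np.ndarray,
    vdw: np.ndarray,
    anchor: np.ndarray,
    max_dist: float,
    box: bool,
) -> tuple[np.ndarray, float]:
    """Deterministic Nelder–Mead maximization of clearance, kept near ``anchor``."""

    def neg(xy: np.ndarray) -> float:
        delta = xy - anchor
        if box:
            excess = max(abs(delta[0]) - max_dist, abs(delta[1]) - max_dist, 0.0)
        else:
            excess = max(float(np.linalg.norm(delta)) - max_dist, 0.0)
        c = np.array([xy[0], xy[1], z])
        return -_clearance(c, coords, vdw) + 10.0 * excess

    res = minimize(
        neg,
        start,
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200, "initial_simplex": np.array([start, start + [0.3, 0.0], start + [0.0, 0.3]])},
    )
    best = res.x
    # clamp into the admissible region
    delta = best - anchor
    if box:
        delta = np.clip(delta, -max_dist, max_dist)
    else:
        norm = float(np.linalg.norm(delta))
        if norm > max_dist:
            delta *= max_dist / norm
    best = anchor + delta
    val = _clearance(np.array([best[0], best[1], z]), coords, vdw)
    return best, val


def _grid_candidates(anchor: np.ndarray, halfwidth: float, step: float, box: bool) -> np.ndarray:
    ax = np.arange(-halfwidth, halfwidth + step / 2, step)
    gx, gy = np.meshgrid(ax, ax)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    if not box:
        pts = pts[np.linalg.norm(pts, axis=1) <= halfwidth + 1e-9]
    return pts + anchor


def _slab_atoms(
    coords: np.ndarray, vdw: np.ndarray, z: float, r_max: float
) -> tuple[np.ndarray, np.ndarray]:
    reach = r_max + vdw
    mask = np.abs(coords[:, 2] - z) <= reach
    return coords[mask], vdw[mask]


def _solve_z(
    z: float,
    coords: np.ndarray,
    vdw: np.ndarray,
    anchor: np.ndarray,
    halfwidth: float,
    step: float,
    settings: SearchSettings,
    box: bool,
) -> tuple[np.ndarray, float, bool]:
    sc, sv = _slab_atoms(coords, vdw, z, settings.r_max)
    if sc.shape[0] == 0:
        return anchor.copy(), settings.r_max, True
    cands = _grid_candidates(anchor, halfwidth, step, box)
    c3 = np.column_stack([cands, np.full(len(cands), z)])
    d = np.linalg.norm(c3[:, None, :] - sc[None, :, :], axis=2) - sv[None, :]
    clear = d.min(axis=1)
    # refine from the best few well-separated coarse starts (the clearance
    # landscape between sparse atoms is multimodal)
    order = np.argsort(-clear)
    starts: list[np.ndarray] = []
    for k in order:
        if len(starts) >= 2:
            break
        if all(np.linalg.norm(cands[k] - s0) > 0.6 for s0 in starts):
            starts.append(cands[k])
    best, val = cands[order[0]], float(clear[order[0]])
    for s0 in starts:
        b, v = _refine(s0, z, sc, sv, anchor, halfwidth, box)
        if v > val:
            best, val = b, v
    return best, min(val, settings.r_max), False


def compute_profile(
    s: Structure,
    z_min: float | None = None,
    z_max: float | None = None,
    z_step: float = 0.25,
    search: SearchSettings = SearchSettings(),
    model: int = 0,
) -> PoreProfile:
    """Maximum probe radius along z for an oriented structure.

    The z range defaults to the Cα span of the structure. Raises
    :class:`ProfileError` if no slab anywhere is constrained by atoms.
    """
    if z_step <= 0:
        raise ValueError("z_step must be positive")
    coords = s.model_coords(model)
    vdw = s.vdw
    if z_min is None or z_max is None:
        ca = coords[s.ca_mask()] if s.ca_mask().any() else coords
        z_min = float(ca[:, 2].min()) if z_min is None else z_min
        z_max = float(ca[:, 2].max()) if z_max is None else z_max
    if z_max <= z_min:
        raise ValueError("z_max must exceed z_min")
    z_grid = np.arange(z_min, z_max + z_step / 2, z_step)
    n = len(z_grid)
    radius = np.empty(n)
    centers = np.empty((n, 2))
    unbounded = np.zeros(n, dtype=bool)
    seed = np.asarray(search.seed_center, dtype=float)

    box = search.mode == "box"
    halfwidth = search.box_halfwidth if box else search.track_radius
    for i, z in enumerate(z_grid):
        centers[i], radius[i], unbounded[i] = _solve_z(
            z, coords, vdw, seed, halfwidth, search.coarse_step, search, box=box
        )

    if unbounded.all():
        raise ProfileError("no slab is constrained by atoms; structure/z-range mismatch?")
    profile = PoreProfile(
        z_grid=z_grid, radius=radius, probe_center=centers, unbounded=unbounded, r_max=search.r_max
    )
    profile.gate_regions = locate_gate_regions(profile)
    return profile


def locate_gate_regions(p: PoreProfile, cavity_margin: float = 2.0) -> dict[str, tuple[float, float]]:
    """Gate regions flanking the central cavity.

    The cavity center z0 is the z of maximum radius within the central 50% of
    the profiled span; the cytoplasmic region runs from the bottom of the span
    to z0 - margin and the periplasmic region from z0 + margin to the top.
    """
    z = p.z_grid
    span = z[-1] - z[0]
    central = (z >= z[0] + 0.25 * span) & (z <= z[0] + 0.75 * span)
    zc = z[central]
    z0 = float(zc[int(np.argmax(p.radius[central]))])
    return {
        "cytoplasmic": (float(z[0]), z0 - cavity_margin),
        "periplasmic": (z0 + cavity_margin, float(z[-1])),
    }


def gate_min_radius(p: PoreProfile, window: float = 4.0) -> GateRadii:
    """Windowed-mean radius at each gate constriction.

    Per region the constriction is the z of the global radius minimum (ties
    resolved toward smaller |z|, i.e. toward the cavity); the reported value is
    the mean radius over a ``window``-wide interval centered there, clipped to
    the region.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not p.gate_regions:
        p.gate_regions = locate_gate_regions(p)
    step = p.z_grid[1] - p.z_grid[0]
    out: dict[str, float] = {}
    zs: dict[str, float] = {}
    for name, (lo, hi) in p.gate_regions.items():
        if hi - lo < step:
            raise ProfileError(f"{name} gate region narrower than one grid step")
        in_region = (p.z_grid >= lo) & (p.z_grid <= hi)
        zr, rr = p.z_grid[in_region], p.radius[in_region]
        rmin = rr.min()
        at_min = np.isclose(rr, rmin)
        z_candidates = zr[at_min]
        zc = float(z_candidates[int(np.argmin(np.abs(z_candidates)))])
        win = (p.z_grid >= max(zc - window / 2, lo)) & (p.z_grid <= min(zc + window / 2, hi))
        out[name] = float(p.radius[win].mean())
        zs[name] = zc
    return GateRadii(
        cytoplasmic_min=out["cytoplasmic"],
        periplasmic_min=out["periplasmic"],
        constriction_z=zs,
    )


def state_plane_coordinates(
    structures: Sequence[tuple],
    z_step: float = 0.25,
    search: SearchSettings = SearchSettings(),
    window: float = 4.0,
) -> pd.DataFrame:
    """Per-structure (cytoplasmic, periplasmic) gate radii for the quadrant plot.

    Accepts ``(Structure, HelixMap)`` pairs (id taken from the structure) or
    ``(id, Structure, HelixMap)`` triples.
    """
    rows = []
    for item in structures:
        if len(item) == 3:
            sid, s, _hm = item
        else:
            s, _hm = item
            sid = s.identifier
        prof = compute_profile(s, z_step=z_step, search=search)
        gr = gate_min_radius(prof, window=window)
        rows.append(
            {"id": sid, "cytoplasmic_min": gr.cytoplasmic_min, "periplasmic_min": gr.periplasmic_min}
        )
    return pd.DataFrame(rows, columns=["id", "cytoplasmic_min", "periplasmic_min"])
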