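"""Conformational-state classification from the two gate tip distances.

A structure is *occluded* when both the periplasmic and cytoplasmic gate
distances are below 9 Å, *outward open* when only the periplasmic distance is
at or above 9 Å, *inward open* in the mirrored case, and *channel-like* when
both gates are open (a regime without crystallographic precedent, named here
for completeness). The module also provides density-of-states maps over the
two distances, per-Cα/per-helix/per-repeat-unit mobility (RMSF) for ensembles,
and a quadrant classification on probe radii with an optional calibration of
the radius threshold against the 9 Å tip-distance rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .gate_geometry import (
    CYTOPLASMIC_DEFAULT,
    PERIPLASMIC_DEFAULT,
    PairCombination,
    min_tip_distance,
)
from .structure_io import HelixMap, RepeatUnits, Structure

__all__ = [
    "StateLabel",
    "STATE_LABELS",
    "classify",
    "classify_ensemble",
    "classify_by_radius",
    "calibrate_radius_threshold",
    "StateDensity",
    "MobilityProfile",
    "mobility",
]

StateLabel = Literal["inward_open", "outward_open", "occluded", "channel_like"]
STATE_LABELS: tuple[str, ...] = ("inward_open", "outward_open", "occluded", "channel_like")

SCAFFOLD_HELICES = ("H3", "H6", "H9", "H12")


def classify(peri: float, cyto: float, threshold: float = 9.0) -> str:
    """Apply the two-distance 9 Å rule to one (periplasmic, cytoplasmic) pair."""
    if peri < 0 or cyto < 0:
        raise ValueError("gate distances must be non-negative")
    peri_open = peri >= threshold
    cyto_open = cyto >= threshold
    if peri_open and cyto_open:
        return "channel_like"
    if peri_open:
        return "outward_open"
    if cyto_open:
        return "inward_open"
    return "occluded"


@dataclass
class StateDensity:
    """2D histogram over (periplasmic, cytoplasmic) distance and state occupancies."""

    peri_edges: np.ndarray
    cyto_edges: np.ndarray
    counts: np.ndarray
    occupancy: dict[str, float]

    @property
    def populated_bins(self) -> int:
        return int((self.counts > 0).sum())


def classify_ensemble(
    e: Structure,
    hm: HelixMap,
    peri_pair: PairCombination = PERIPLASMIC_DEFAULT,
    cyto_pair: PairCombination = CYTOPLASMIC_DEFAULT,
    threshold: float = 9.0,
    bin_width: float = 0.5,
    n_tip_residues: int = 10,
    direction: Literal["topology", "auto"] | int = "topology",
) -> tuple[list[str], StateDensity, pd.DataFrame]:
    """Label every model of an ensemble and accumulate the density of states.

    Returns ``(labels, density, per_frame_table)`` where the table holds the
    two distances and label per frame.
    """
    peris, cytos, labels = [], [], []
    for mi in range(e.n_models):
        dp = min_tip_distance(e, hm, peri_pair, n_tip_residues, model=mi, direction=direction)
        dc = min_tip_distance(e, hm, cyto_pair, n_tip_residues, model=mi, direction=direction)
        peris.append(dp)
        cytos.append(dc)
        labels.append(classify(dp, dc, threshold))
    peris_a, cytos_a = np.array(peris), np.array(cytos)
    lo = np.floor(min(peris_a.min(), cytos_a.min()) / bin_width) * bin_width
    hi = np.ceil(max(peris_a.max(), cytos_a.max()) / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, pe, ce = np.histogram2d(peris_a, cytos_a, bins=(edges, edges))
    occupancy = {s: labels.count(s) / len(labels) for s in STATE_LABELS}
    density = StateDensity(peri_edges=pe, cyto_edges=ce, counts=counts, occupancy=occupancy)
    table = pd.DataFrame(
        {"frame": np.arange(e.n_models), "peri_distance": peris_a, "cyto_distance": cytos_a, "state": labels}
    )
    return labels, density, table


def classify_by_radius(
    cyto_min: float,
    peri_min: float,
    threshold: float = 1.15,
    cyto_threshold: float | None = None,
    peri_threshold: float | None = None,
) -> str:
    """Quadrant classification on the two gate probe radii.

    The 1.15 Å default follows the color break conventionally used to display
    probe surfaces of real MFS structures; it is a display convention, not a
    physical constant, and per-gate thresholds (e.g. from
    :func:`calibrate_radius_threshold`) may be supplied instead.
    """
    ct = threshold if cyto_threshold is None else cyto_threshold
    pt = threshold if peri_threshold is None else peri_threshold
    peri_open = peri_min >= pt
    cyto_open = cyto_min >= ct
    if peri_open and cyto_open:
        return "channel_like"
    if peri_open:
        return "outward_open"
    if cyto_open:
        return "inward_open"
    return "occluded"


def calibrate_radius_threshold(
    apertures: Sequence[float],
    radii: Sequence[float],
    aperture_threshold: float = 9.0,
) -> float:
    """Map the 9 Å tip-distance criterion onto a probe-radius threshold.

    Fits radius ~ aperture linearly over a calibration sweep and returns the
    fitted radius at ``aperture_threshold``. Useful when the radius scale of a
    structure set (e.g. synthetic bundles) differs from real transporters.
    """
    a = np.asarray(apertures, dtype=float)
    r = np.asarray(radii, dtype=float)
    if a.size < 3:
        raise ValueError("need >=3 calibration points")
    slope, intercept = np.polyfit(a, r, 1)
    return float(slope * aperture_threshold + intercept)


@dataclass
class MobilityProfile:
    """Per-Cα RMSF after superposition, with helix/unit/half aggregates."""

    resnum: np.ndarray
    chain: np.ndarray
    rmsf: np.ndarray
    per_helix: dict[str, float]
    per_unit: dict[str, float]
    per_half: dict[str, float]


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    mm, tm = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tm, mobile - mm)
    return (mobile - mm) @ rot.as_matrix().T + tm


def mobility(
    e: Structure,
    hm: HelixMap,
    reference_helices: Sequence[str] = SCAFFOLD_HELICES,
    units: RepeatUnits = RepeatUnits(),
    n_iter: int = 2,
) -> MobilityProfile:
    """RMSF of every Cα across an ensemble after scaffold-based superposition.

    Models are superposed on the ensemble mean over the reference selection
    (by default the scaffold helices H3/H6/H9/H12, the least mobile third helix
    of each repeat unit), iterating mean and fit a couple of times.
    """
    if e.n_models < 2:
        raise ValueError("mobility needs >=2 models")
    ca_mask = e.ca_mask()
    ca_idx = np.nonzero(ca_mask)[0]
    ref_mask = np.zeros(e.n_atoms, dtype=bool)
    for hid in reference_helices:
        chain, first, last = hm[hid]
        ref_mask |= (e.chain == chain) & (e.resnum >= first) & (e.resnum <= last) & ca_mask
    ref_idx = np.nonzero(ref_mask)[0]
    if ref_idx.size < 3:
        raise ValueError("reference selection too small")

    coords = e.coords.copy()
    for _ in range(n_iter):
        mean_ref = coords[:, ref_idx].mean(axis=0)
        for mi in range(e.n_models):
            mob = coords[mi, ref_idx]
            mm, tm = mob.mean(axis=0), mean_ref.mean(axis=0)
            rot, _ = Rotation.align_vectors(mean_ref - tm, mob - mm)
            coords[mi] = (coords[mi] - mm) @ rot.as_matrix().T + tm

    ca = coords[:, ca_idx]
    mean_ca = ca.mean(axis=0)
    rmsf = np.sqrt(((ca - mean_ca) ** 2).sum(axis=2).mean(axis=0))

    resnum = e.resnum[ca_idx]
    chain_arr = e.chain[ca_idx]

    def agg(helices: Sequence[str]) -> float:
        m = np.zeros(len(ca_idx), dtype=bool)
        for hid in helices:
            c, first, last = hm[hid]
            m |= (chain_arr == c) & (resnum >= first) & (resnum <= last)
        return float(rmsf[m].mean()) if m.any() else float("nan")

    per_helix = {hid: agg([hid]) for hid in hm.tm_helices}
    per_unit = {"A": agg(units.A), "B": agg(units.B), "C": agg(units.C), "D": agg(units.D)}
    per_half = {
        "N": agg([f"H{i}" for i in range(1, 7)]),
        "C": agg([f"H{i}" for i in range(7, 13)]),
    }
    return MobilityProfile(
        resnum=resnum, chain=chain_arr, rmsf=rmsf, per_helix=per_helix, per_unit=per_unit, per_half=per_half
    )
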