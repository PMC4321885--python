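"""Synthetic 12-helix two-bundle transporter structures with known ground truth.

The generator emulates the canonical MFS fold at fixture fidelity: two six-helix
bundles related by a two-fold axis along z, a central cavity between them, a
periplasmic gate formed by the tips of H1 & H2 packing against H7 & H8, and a
cytoplasmic gate formed by H4 & H5 against H10 & H11. Gate apertures are set by
rigid scissor rotations of each gate-helix pair about a hinge at the membrane
midplane; scaffold helices H3/H6/H9/H12 stay fixed. Helices are ideal
poly-alanine (N, CA, C, O, CB per residue on a canonical α-helical trace);
charged residues requested through ``charge_spec`` additionally carry the
side-chain charge-center pseudo-atoms used by salt-bridge detection.

Every generated structure comes with a :class:`GroundTruth` recording the
intended apertures, the conformational state they imply under the 9 Å rule, and
any scheduled salt-bridge formation — the oracle for every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from .structure_io import VDW_RADII, HelixMap, Structure

__all__ = [
    "BundleParams",
    "BridgeSchedule",
    "GroundTruth",
    "FrameTruth",
    "GeometryError",
    "OPEN_APERTURE",
    "CLOSED_APERTURE",
    "generate_bundle",
    "generate_ensemble",
    "helix_direction",
    "classify_apertures",
]

# Per-state tip-distance aperture ranges (Å). Open straddles the 9 Å criterion
# from above, closed from below, each with a margin.
OPEN_APERTURE: tuple[float, float] = (10.5, 16.0)
CLOSED_APERTURE: tuple[float, float] = (4.5, 8.0)

STATE_APERTURES: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    # state -> (periplasmic range, cytoplasmic range)
    "inward_open": (CLOSED_APERTURE, OPEN_APERTURE),
    "outward_open": (OPEN_APERTURE, CLOSED_APERTURE),
    "occluded": (CLOSED_APERTURE, CLOSED_APERTURE),
    "channel_like": (OPEN_APERTURE, OPEN_APERTURE),
}

PERIPLASMIC_GATE = (("H1", "H2"), ("H7", "H8"))
CYTOPLASMIC_GATE = (("H4", "H5"), ("H10", "H11"))
SCAFFOLD_HELICES = ("H3", "H6", "H9", "H12")

# In-plane anchors (x, y) of each helix at the membrane midplane. The C-terminal
# half is the 180° rotation of the N-terminal half about z (the MFS pseudo-twofold).
# Spacing leaves enough margin that the seeded placement jitter of the static
# helices can never push two axes below the 2 x helix_radius steric floor.
_N_HALF_ANCHORS: dict[str, tuple[float, float]] = {
    "H1": (-10.0, 2.9),
    "H2": (-10.0, -2.9),
    "H3": (-14.6, 8.5),
    "H4": (-1.2, 9.6),
    "H5": (-9.0, 8.4),
    "H6": (-6.5, -8.1),
}
ANCHORS: dict[str, tuple[float, float]] = dict(_N_HALF_ANCHORS)
ANCHORS.update({f"H{i + 6}": (-x, -y) for i, (x, y) in ((int(h[1:]), xy) for h, xy in _N_HALF_ANCHORS.items())})

# helices whose anchors receive seeded placement jitter (the gate helices stay
# exact: their scissor angles are re-solved against the requested apertures)
_JITTERED_HELICES = ("H3", "H5", "H6", "H9", "H11", "H12")
_ANCHOR_JITTER_CLIP = 0.45  # Å, hard clip keeping the steric floor unreachable


def _instance_anchors(seed: int, jitter_sd: float) -> dict[str, tuple[float, float]]:
    """Per-structure anchors: base layout plus clipped placement jitter.

    Emulates the structural heterogeneity of a set of distinct transporter
    structures; without it every non-gate helix would sit at identical
    coordinates across a sweep and spurious tip-distance correlations appear.
    """
    anchors = dict(ANCHORS)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        for hid in _JITTERED_HELICES:
            d = np.clip(rng.normal(0.0, jitter_sd, 2), -_ANCHOR_JITTER_CLIP, _ANCHOR_JITTER_CLIP)
            x, y = anchors[hid]
            anchors[hid] = (x + float(d[0]), y + float(d[1]))
    return anchors

# Idealized α-helix cylindrical offsets per backbone atom relative to the CA
# trace: (radius Å, phase offset °, z offset Å). Approximate canonical values.
_ATOM_OFFSETS: tuple[tuple[str, str, float, float, float], ...] = (
    ("N", "N", 1.56, -26.3, -0.91),
    ("CA", "C", 2.30, 0.0, 0.0),
    ("C", "C", 1.64, 27.1, 1.05),
    ("O", "O", 1.93, 23.8, 2.06),
    ("CB", "C", 3.30, -5.0, -0.50),
)

# CB stands in for the whole side chain (poly-alanine bundles would otherwise be
# far more porous than a real transporter); its effective radius approximates a
# side-chain centroid sphere rather than a bare carbon.
_CB_VDW = 2.25

# Side-chain charge-center pseudo-atoms: name -> (element, extension from CA Å,
# perpendicular offset Å). Extensions approximate fully extended side chains.
_CHARGE_ATOMS: dict[str, tuple[tuple[str, str, float, float], ...]] = {
    "LYS": (("NZ", "N", 5.0, 0.0),),
    "ARG": (("NE", "N", 4.0, 0.0), ("NH1", "N", 5.2, 0.6), ("NH2", "N", 5.2, -0.6)),
    "ASP": (("OD1", "O", 3.0, 0.5), ("OD2", "O", 3.0, -0.5)),
    "GLU": (("OE1", "O", 4.2, 0.5), ("OE2", "O", 4.2, -0.5)),
}

_FORMED_NO_DIST = 3.0  # realized N–O distance for a scheduled formed bridge
_BROKEN_NO_DIST = 7.0  # and for a scheduled broken one (beyond cutoff + diagnostics)

_RESIDUES_PER_SLOT = 30  # helix h occupies resnums 30(h-1)+1 .. 30(h-1)+length


class GeometryError(ValueError):
    """Requested apertures are not realizable without helix–helix overlap."""


@dataclass(frozen=True)
class BundleParams:
    """Construction parameters for one synthetic transporter bundle."""

    helix_length: int = 24
    rise_per_residue: float = 1.5
    helix_radius: float = 2.3
    peri_aperture: float = 12.0
    cyto_aperture: float = 6.0
    kink_spec: tuple[str, int, float] | None = None  # (helix, hinge resnum, angle °)
    charge_spec: tuple[tuple[str, int, str], ...] = ()  # (helix, index 1..L, restype)
    n_tip_residues: int = 10
    anchor_jitter_sd: float = 0.3  # Å, seeded placement heterogeneity of static helices
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peri_aperture <= 0 or self.cyto_aperture <= 0:
            raise ValueError("apertures must be positive")
        if self.helix_length < 8:
            raise ValueError("helix_length too short for tip analysis")
        if self.kink_spec is not None:
            helix, hinge, _ = self.kink_spec
            first, last = _helix_interval(helix, self.helix_length)
            if not (first < hinge < last):
                raise ValueError("kink hinge residue must lie strictly inside the helix")
        for helix, idx, restype in self.charge_spec:
            if restype not in _CHARGE_ATOMS:
                raise ValueError(f"unsupported charged residue type {restype!r}")
            if not (1 <= idx <= self.helix_length):
                raise ValueError(f"charge residue index {idx} outside helix")


@dataclass(frozen=True)
class BridgeSchedule:
    """A scheduled salt bridge: which frames it is formed in.

    ``basic``/``acidic`` are ``(helix id, residue index within helix, restype)``.
    """

    basic: tuple[str, int, str]
    acidic: tuple[str, int, str]
    formed: tuple[bool, ...]


@dataclass
class FrameTruth:
    state: str
    peri_aperture: float
    cyto_aperture: float
    bridges: dict[tuple[str, str], bool] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Generator-side oracle for a bundle or ensemble."""

    frames: list[FrameTruth]

    @property
    def intended_state(self) -> str:
        return self.frames[0].state

    @property
    def states(self) -> list[str]:
        return [f.state for f in self.frames]

    def to_table(self) -> str:
        lines = ["frame\tstate\tperi_aperture\tcyto_aperture\tbridges_formed"]
        for i, f in enumerate(self.frames):
            formed = ",".join(f"{b}-{a}" for (b, a), on in sorted(f.bridges.items()) if on)
            lines.append(f"{i}\t{f.state}\t{f.peri_aperture:.3f}\t{f.cyto_aperture:.3f}\t{formed or '-'}")
        return "\n".join(lines) + "\n"


def classify_apertures(peri: float, cyto: float, threshold: float = 9.0) -> str:
    """The two-distance state rule (shared with :mod:`mfsgate.state_classify`)."""
    if peri < 0 or cyto < 0:
        raise ValueError("distances must be non-negative")
    if peri < threshold and cyto < threshold:
        return "occluded"
    if peri >= threshold and cyto < threshold:
        return "outward_open"
    if cyto >= threshold and peri < threshold:
        return "inward_open"
    return "channel_like"


def helix_direction(hid: str) -> int:
    """+1 if the helix runs cytoplasm->periplasm (odd helices), else -1."""
    return 1 if int(hid[1:]) % 2 == 1 else -1


def _helix_interval(hid: str, length: int) -> tuple[int, int]:
    h = int(hid[1:])
    first = _RESIDUES_PER_SLOT * (h - 1) + 1
    return first, first + length - 1


def default_helix_map(length: int = 24) -> HelixMap:
    return HelixMap({f"H{h}": ("A", *_helix_interval(f"H{h}", length)) for h in range(1, 13)})


def _rot_about(axis: str, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


@dataclass
class _HelixGeometry:
    """Local-frame helix atoms before anchoring, plus per-residue radial vectors."""

    atoms: list[tuple[int, str, str, np.ndarray]]  # (residue index 0-based, atom name, element, xyz)
    radial: np.ndarray  # (L, 3) outward radial unit vector per residue
    ca: np.ndarray  # (L, 3)
    axis_points: np.ndarray  # (L, 3) points on the (possibly kinked) helix axis


def _build_local_helix(p: BundleParams, hid: str) -> _HelixGeometry:
    L = p.helix_length
    phase0 = np.deg2rad((int(hid[1:]) * 77.0) % 360.0)
    turn = np.deg2rad(100.0)
    atoms: list[tuple[int, str, str, np.ndarray]] = []
    ca = np.zeros((L, 3))
    radial = np.zeros((L, 3))
    axis_pts = np.zeros((L, 3))
    for j in range(L):
        t = j - (L - 1) / 2.0
        psi = phase0 + j * turn
        z = t * p.rise_per_residue
        axis_pts[j] = (0.0, 0.0, z)
        radial[j] = (np.cos(psi), np.sin(psi), 0.0)
        for name, elem, r, dphi, dz in _ATOM_OFFSETS:
            a = psi + np.deg2rad(dphi)
            scale = r / 2.30 if name == "CA" else 1.0
            xyz = np.array([r * np.cos(a), r * np.sin(a), z + dz])
            if name == "CA":
                xyz[:2] *= p.helix_radius / 2.30
                ca[j] = xyz
            atoms.append((j, name, elem, xyz))

    # flip even-numbered helices: 180° about local x keeps chirality, reverses z
    if helix_direction(hid) < 0:
        flip = _rot_about("x", np.pi)
        atoms = [(j, n, e, flip @ xyz) for j, n, e, xyz in atoms]
        ca = ca @ flip.T
        radial = radial @ flip.T
        axis_pts = axis_pts @ flip.T

    if p.kink_spec is not None and p.kink_spec[0] == hid:
        _, hinge_resnum, angle_deg = p.kink_spec
        first, _ = _helix_interval(hid, L)
        hinge_j = hinge_resnum - first
        pivot = ca[hinge_j].copy()
        # bend the C-terminal segment radially outward from the bundle center
        r_out = np.array([*ANCHORS[hid], 0.0])
        r_out /= np.linalg.norm(r_out)
        kink_axis = np.cross([0.0, 0.0, 1.0], r_out)
        kink_axis /= np.linalg.norm(kink_axis)
        ang = np.deg2rad(angle_deg) * helix_direction(hid)
        from scipy.spatial.transform import Rotation as _R

        R = _R.from_rotvec(kink_axis * ang).as_matrix()
        moved = []
        for j, n, e, xyz in atoms:
            if j > hinge_j:
                xyz = R @ (xyz - pivot) + pivot
            moved.append((j, n, e, xyz))
        atoms = moved
        sel = np.arange(L) > hinge_j
        ca[sel] = (ca[sel] - pivot) @ R.T + pivot
        radial[sel] = radial[sel] @ R.T
        axis_pts[sel] = (axis_pts[sel] - pivot) @ R.T + pivot

    return _HelixGeometry(atoms=atoms, radial=radial, ca=ca, axis_points=axis_pts)


def _gate_tilt_matrix(hid: str, angle: float) -> np.ndarray:
    """Scissor rotation for a gate helix about its midplane hinge.

    Positive angles close the gate (move the gate-side tip toward the pore axis).
    The aperture-setting motion is carried by the helices adjacent to the pore
    axis (all four periplasmic-gate helices; H4/H10 on the cytoplasmic side,
    with H5/H11 acting as static wall supports).
    """
    ax, ay = ANCHORS[hid]
    peri = hid in PERIPLASMIC_GATE[0] + PERIPLASMIC_GATE[1]
    if peri:
        # tips move in x; sign so that +angle moves the periplasmic (top) tip inward
        sign = 1.0 if ax < 0 else -1.0
        return _rot_about("y", sign * angle)
    if hid in ("H5", "H11"):
        return np.eye(3)
    # cytoplasmic gate: tips move in y; +angle moves the bottom tip inward
    sign = -1.0 if ay > 0 else 1.0
    return _rot_about("x", sign * angle)


def _placed_ca(
    geo: _HelixGeometry, hid: str, tilt: float, anchors: Mapping[str, tuple[float, float]]
) -> np.ndarray:
    anchor = np.array([*anchors[hid], 0.0])
    R = _gate_tilt_matrix(hid, tilt)
    return geo.ca @ R.T + anchor


def _tip_ca(ca: np.ndarray, side: str, n: int) -> np.ndarray:
    order = np.argsort(ca[:, 2])
    return ca[order[-n:]] if side == "periplasmic" else ca[order[:n]]


def _measured_aperture(
    geos: Mapping[str, _HelixGeometry], gate, side: str, tilt: float, n_tip: int, anchors
) -> float:
    (na, nb), (cc, cd) = gate
    tips_n = np.vstack([_tip_ca(_placed_ca(geos[h], h, tilt, anchors), side, n_tip) for h in (na, nb)])
    tips_c = np.vstack([_tip_ca(_placed_ca(geos[h], h, tilt, anchors), side, n_tip) for h in (cc, cd)])
    return float(cdist(tips_n, tips_c).min())


def _solve_tilt(geos, gate, side: str, target: float, n_tip: int, anchors) -> float:
    lo, hi = -0.45, 0.50  # radians; generous scissor range
    f = lambda th: _measured_aperture(geos, gate, side, th, n_tip, anchors) - target
    flo, fhi = f(lo), f(hi)
    # aperture decreases with closing angle: f(lo) > 0 > f(hi) for feasible targets
    if flo < 0 or fhi > 0:
        raise GeometryError(
            f"{side} aperture {target:.2f} Å is outside the realizable range "
            f"[{f(hi) + target:.2f}, {f(lo) + target:.2f}] Å"
        )
    return float(brentq(f, lo, hi, xtol=1e-6))


def _axis_clearance(placed_axis: Mapping[str, np.ndarray]) -> float:
    hids = list(placed_axis)
    best = np.inf
    for i, hi_ in enumerate(hids):
        for hj in hids[i + 1 :]:
            best = min(best, float(cdist(placed_axis[hi_], placed_axis[hj]).min()))
    return best


def _assemble(
    p: BundleParams,
    peri_tilt: float,
    cyto_tilt: float,
    anchors: Mapping[str, tuple[float, float]],
    bridge_atoms: Mapping[tuple[str, int], dict[str, np.ndarray]] | None = None,
) -> Structure:
    """Place all helices at the given scissor angles and emit a Structure."""
    charge_by_residue: dict[tuple[str, int], str] = {
        (h, idx): rt for h, idx, rt in p.charge_spec
    }
    serials, names, elems, resnames, resnums, chains, vdw = [], [], [], [], [], [], []
    xyz: list[np.ndarray] = []
    axis_by_helix: dict[str, np.ndarray] = {}
    serial = 1
    for h in range(1, 13):
        hid = f"H{h}"
        geo = _build_local_helix(p, hid)
        anchor = np.array([*anchors[hid], 0.0])
        gate_helices = PERIPLASMIC_GATE[0] + PERIPLASMIC_GATE[1] + CYTOPLASMIC_GATE[0] + CYTOPLASMIC_GATE[1]
        if hid in PERIPLASMIC_GATE[0] + PERIPLASMIC_GATE[1]:
            tilt = peri_tilt
        elif hid in CYTOPLASMIC_GATE[0] + CYTOPLASMIC_GATE[1]:
            tilt = cyto_tilt
        else:
            tilt = 0.0
        R = _gate_tilt_matrix(hid, tilt) if hid in gate_helices else np.eye(3)
        axis_by_helix[hid] = geo.axis_points @ R.T + anchor
        first, _ = _helix_interval(hid, p.helix_length)
        placed_ca_arr = geo.ca @ R.T + anchor
        placed_radial = geo.radial @ R.T
        for j, name, elem, local in geo.atoms:
            restype = charge_by_residue.get((hid, j + 1), "ALA")
            pos = R @ local + anchor
            serials.append(serial)
            serial += 1
            names.append(name)
            elems.append(elem)
            resnames.append(restype)
            resnums.append(first + j)
            chains.append("A")
            vdw.append(_CB_VDW if name == "CB" else VDW_RADII[elem])
            xyz.append(pos)
            if name == "CB" and restype in _CHARGE_ATOMS:
                u = placed_radial[j]
                perp = np.cross(u, [0.0, 0.0, 1.0])
                perp /= max(np.linalg.norm(perp), 1e-9)
                override = (bridge_atoms or {}).get((hid, j + 1))
                for aname, aelem, ext, poff in _CHARGE_ATOMS[restype]:
                    if override is not None and aname in override:
                        pos_sc = override[aname]
                    else:
                        pos_sc = placed_ca_arr[j] + ext * u + poff * perp
                    serials.append(serial)
                    serial += 1
                    names.append(aname)
                    elems.append(aelem)
                    resnames.append(restype)
                    resnums.append(first + j)
                    chains.append("A")
                    vdw.append(VDW_RADII[aelem])
                    xyz.append(pos_sc)

    clearance = _axis_clearance(axis_by_helix)
    if clearance < 2 * p.helix_radius:
        raise GeometryError(
            f"helix axes approach {clearance:.2f} Å (< {2 * p.helix_radius:.2f} Å); "
            "requested apertures are sterically infeasible"
        )

    n = len(serials)
    return Structure(
        serial=np.array(serials),
        name=np.array(names, dtype="U4"),
        element=np.array(elems, dtype="U2"),
        resname=np.array(resnames, dtype="U3"),
        resnum=np.array(resnums),
        chain=np.array(chains, dtype="U1"),
        icode=np.full(n, "", dtype="U1"),
        coords=np.array(xyz)[None],
        vdw=np.array(vdw),
        identifier=f"bundle_p{p.peri_aperture:.1f}_c{p.cyto_aperture:.1f}",
    )


def _resolve_bridge_atoms(
    p: BundleParams,
    peri_tilt: float,
    cyto_tilt: float,
    bridges: Sequence[BridgeSchedule],
    frame: int,
    anchors: Mapping[str, tuple[float, float]],
) -> dict[tuple[str, int], dict[str, np.ndarray]]:
    """Place charge-center atoms of scheduled bridge residues at, or beyond, contact."""
    overrides: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    ca_cache: dict[str, np.ndarray] = {}

    def ca_of(hid: str, idx: int) -> np.ndarray:
        if hid not in ca_cache:
            geo = _build_local_helix(p, hid)
            gate_p = PERIPLASMIC_GATE[0] + PERIPLASMIC_GATE[1]
            gate_c = CYTOPLASMIC_GATE[0] + CYTOPLASMIC_GATE[1]
            tilt = peri_tilt if hid in gate_p else cyto_tilt if hid in gate_c else 0.0
            ca_cache[hid] = _placed_ca(geo, hid, tilt, anchors)
        return ca_cache[hid][idx - 1]

    for br in bridges:
        bh, bi, btype = br.basic
        ah, ai, atype = br.acidic
        formed = br.formed[frame]
        ca_b, ca_a = ca_of(bh, bi), ca_of(ah, ai)
        u = ca_b - ca_a
        u /= max(np.linalg.norm(u), 1e-9)
        perp = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        o_primary = ca_a + 3.0 * u
        acid: dict[str, np.ndarray] = {}
        for aname, _, ext, poff in _CHARGE_ATOMS[atype]:
            acid[aname] = o_primary + (ext - 3.0) * u + poff * perp
        d = _FORMED_NO_DIST if formed else _BROKEN_NO_DIST
        nearest_o = max(acid.values(), key=lambda v: float(np.dot(v - ca_a, u)))
        n_primary = nearest_o + d * u
        basic: dict[str, np.ndarray] = {}
        prim_names = {"LYS": "NZ", "ARG": "NH1"}
        for aname, _, ext, poff in _CHARGE_ATOMS[btype]:
            if aname == prim_names.get(btype, "NZ"):
                basic[aname] = n_primary
            else:
                basic[aname] = n_primary + 0.8 * u + poff * perp
        overrides[(ah, ai)] = acid
        overrides[(bh, bi)] = basic
    return overrides


def generate_bundle(p: BundleParams) -> tuple[Structure, HelixMap, GroundTruth]:
    """Build one bundle whose measured gate apertures match the requested ones.

    The scissor angles are solved numerically so that the measured minimum
    tip–tip Cα distance of each designated gate equals the requested aperture
    (well within the 0.5 Å contract).
    """
    anchors = _instance_anchors(p.seed, p.anchor_jitter_sd)
    geos = {f"H{h}": _build_local_helix(p, f"H{h}") for h in range(1, 13)}
    peri_tilt = _solve_tilt(geos, PERIPLASMIC_GATE, "periplasmic", p.peri_aperture, p.n_tip_residues, anchors)
    cyto_tilt = _solve_tilt(geos, CYTOPLASMIC_GATE, "cytoplasmic", p.cyto_aperture, p.n_tip_residues, anchors)
    s = _assemble(p, peri_tilt, cyto_tilt, anchors)
    hm = default_helix_map(p.helix_length)
    truth = GroundTruth(
        frames=[
            FrameTruth(
                state=classify_apertures(p.peri_aperture, p.cyto_aperture),
                peri_aperture=p.peri_aperture,
                cyto_aperture=p.cyto_aperture,
            )
        ]
    )
    return s, hm, truth


def generate_ensemble(
    p: BundleParams,
    state_schedule: Sequence[str],
    jitter_sd: float = 0.0,
    seed: int | None = None,
    aperture_ranges: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] | None = None,
    bridges: Sequence[BridgeSchedule] = (),
) -> tuple[Structure, HelixMap, GroundTruth]:
    """Build a multi-model ensemble following a per-frame state schedule.

    Each frame is a bundle at apertures drawn uniformly from its state's range,
    plus isotropic Gaussian coordinate jitter of width ``jitter_sd``. Scheduled
    salt bridges are realized by placing the charge-center atoms at contact
    (formed) or well beyond it (broken).
    """
    if len(state_schedule) == 0:
        raise ValueError("empty state schedule")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    for br in bridges:
        if len(br.formed) != len(state_schedule):
            raise ValueError("bridge schedule length must match state schedule")
    ranges = dict(STATE_APERTURES)
    if aperture_ranges:
        ranges.update(aperture_ranges)
    rng = np.random.default_rng(p.seed if seed is None else seed)

    extra_charges = tuple(
        spec for br in bridges for spec in (br.basic, br.acidic)
    )
    p_frames = BundleParams(
        helix_length=p.helix_length,
        rise_per_residue=p.rise_per_residue,
        helix_radius=p.helix_radius,
        peri_aperture=p.peri_aperture,
        cyto_aperture=p.cyto_aperture,
        kink_spec=p.kink_spec,
        charge_spec=tuple(p.charge_spec) + extra_charges,
        n_tip_residues=p.n_tip_residues,
        anchor_jitter_sd=p.anchor_jitter_sd,
        seed=p.seed,
    )

    anchors = _instance_anchors(p.seed, p.anchor_jitter_sd)
    geos = {f"H{h}": _build_local_helix(p_frames, f"H{h}") for h in range(1, 13)}
    frames: list[FrameTruth] = []
    model_coords: list[np.ndarray] = []
    template: Structure | None = None
    for fi, state in enumerate(state_schedule):
        if state not in ranges:
            raise ValueError(f"unknown state {state!r}")
        (plo, phi_), (clo, chi) = ranges[state]
        peri = float(rng.uniform(plo, phi_))
        cyto = float(rng.uniform(clo, chi))
        peri_tilt = _solve_tilt(geos, PERIPLASMIC_GATE, "periplasmic", peri, p.n_tip_residues, anchors)
        cyto_tilt = _solve_tilt(geos, CYTOPLASMIC_GATE, "cytoplasmic", cyto, p.n_tip_residues, anchors)
        overrides = (
            _resolve_bridge_atoms(p_frames, peri_tilt, cyto_tilt, bridges, fi, anchors) if bridges else None
        )
        s = _assemble(p_frames, peri_tilt, cyto_tilt, anchors, overrides)
        coords = s.coords[0]
        if jitter_sd > 0:
            coords = coords + rng.normal(0.0, jitter_sd, coords.shape)
        model_coords.append(coords)
        if template is None:
            template = s
        bridge_flags = {
            (f"{br.basic[0]}:{br.basic[1]}", f"{br.acidic[0]}:{br.acidic[1]}"): bool(br.formed[fi])
            for br in bridges
        }
        frames.append(FrameTruth(state=state, peri_aperture=peri, cyto_aperture=cyto, bridges=bridge_flags))

    assert template is not None
    ensemble = template.with_coords(np.stack(model_coords))
    ensemble.identifier = "ensemble"
    return ensemble, default_helix_map(p.helix_length), GroundTruth(frames=frames)
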