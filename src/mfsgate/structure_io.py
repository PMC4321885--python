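"""PDB-format structure I/O, helix annotation, membrane orientation and superposition.

The in-memory :class:`Structure` is a thin array-of-atoms container: per-atom
identity arrays shared across models plus a ``(n_models, n_atoms, 3)`` coordinate
block. All downstream geometry assumes an *oriented* structure: z is the membrane
normal and +z points to the periplasmic side (see :func:`orient_membrane_normal`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "VDW_RADII",
    "Structure",
    "HelixMap",
    "RepeatUnits",
    "read_pdb",
    "write_pdb",
    "orient_membrane_normal",
    "superpose_rmsd",
    "paired_ca_coordinates",
]

# Bondi-type van der Waals radii (Å), element-keyed. Crystal structures rarely
# include hydrogens; they are dropped by default on read.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "FE": 2.00,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
}
DEFAULT_VDW = 1.70


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


class DegenerateGeometryError(ValueError):
    """Raised when a geometric operation is underdetermined."""


@dataclass
class Structure:
    """Ordered atom records with one or more models sharing identical atom lists.

    Attributes
    ----------
    serial, name, element, resname, resnum, chain, icode
        Per-atom identity arrays, identical across models.
    coords
        ``(n_models, n_atoms, 3)`` Cartesian coordinates in Å.
    vdw
        Per-atom van der Waals radii in Å.
    bfactor
        Per-atom B column (used by :mod:`mfsgate.repeat_swap` to flag placed
        residues in written templates).
    """

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    resname: np.ndarray
    resnum: np.ndarray
    chain: np.ndarray
    icode: np.ndarray
    coords: np.ndarray
    vdw: np.ndarray
    identifier: str = ""
    bfactor: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.bfactor is None:
            self.bfactor = np.zeros(self.n_atoms)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.vdw <= 0):
            raise ValueError("van der Waals radii must be positive")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def model_coords(self, model: int = 0) -> np.ndarray:
        return self.coords[model]

    def copy(self) -> "Structure":
        return Structure(
            serial=self.serial.copy(),
            name=self.name.copy(),
            element=self.element.copy(),
            resname=self.resname.copy(),
            resnum=self.resnum.copy(),
            chain=self.chain.copy(),
            icode=self.icode.copy(),
            coords=self.coords.copy(),
            vdw=self.vdw.copy(),
            identifier=self.identifier,
            bfactor=self.bfactor.copy(),
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float)
        if out.coords.ndim == 2:
            out.coords = out.coords[None]
        return out

    def select(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask, dtype=bool)
        return Structure(
            serial=self.serial[mask],
            name=self.name[mask],
            element=self.element[mask],
            resname=self.resname[mask],
            resnum=self.resnum[mask],
            chain=self.chain[mask],
            icode=self.icode[mask],
            coords=self.coords[:, mask],
            vdw=self.vdw[mask],
            identifier=self.identifier,
            bfactor=self.bfactor[mask],
        )

    def single_model(self, model: int) -> "Structure":
        out = self.copy()
        out.coords = self.coords[model][None]
        return out

    def ca_mask(self) -> np.ndarray:
        return self.name == "CA"

    def residue_ca(self, chain: str, resnum: int, model: int = 0) -> np.ndarray:
        m = (self.chain == chain) & (self.resnum == resnum) & (self.name == "CA")
        idx = np.nonzero(m)[0]
        if idx.size == 0:
            raise KeyError(f"no CA atom for {chain}:{resnum}")
        return self.coords[model, idx[0]]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Apply ``x -> R x + t`` to every model."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return self.with_coords(self.coords @ R.T + t)


_HELIX_IDS = tuple(f"H{i}" for i in range(1, 13))
_EXTRA_IDS = ("HA", "HB", "LH")


@dataclass(frozen=True)
class HelixMap:
    """Assignment of helix identifiers to ``(chain, first_residue, last_residue)``.

    H1–H12 intervals must be non-overlapping and in ascending sequence order;
    HA/HB/LH (the POT-specific accessory helices) may also be present.
    """

    entries: Mapping[str, tuple[str, int, int]]

    def __post_init__(self) -> None:
        prev_end = None
        for hid in _HELIX_IDS:
            if hid not in self.entries:
                continue
            chain, first, last = self.entries[hid]
            if first > last:
                raise ValueError(f"{hid}: first_residue > last_residue")
            if prev_end is not None and first <= prev_end:
                raise ValueError(f"{hid}: transmembrane helix intervals overlap or are out of order")
            prev_end = last
        for hid in self.entries:
            if hid not in _HELIX_IDS and hid not in _EXTRA_IDS:
                raise ValueError(f"unknown helix id {hid!r}")

    def __getitem__(self, hid: str) -> tuple[str, int, int]:
        return self.entries[hid]

    def __contains__(self, hid: str) -> bool:
        return hid in self.entries

    @property
    def tm_helices(self) -> tuple[str, ...]:
        return tuple(h for h in _HELIX_IDS if h in self.entries)

    def residues(self, hid: str) -> list[int]:
        _, first, last = self.entries[hid]
        return list(range(first, last + 1))

    def helix_ca(self, s: Structure, hid: str, model: int = 0) -> np.ndarray:
        """Cα coordinates of a helix in sequence (N-to-C) order."""
        chain, first, last = self.entries[hid]
        mask = (
            (s.chain == chain)
            & (s.resnum >= first)
            & (s.resnum <= last)
            & (s.name == "CA")
        )
        idx = np.nonzero(mask)[0]
        order = np.argsort(s.resnum[idx], kind="stable")
        return s.coords[model, idx[order]]

    def helix_ca_resnums(self, s: Structure, hid: str) -> np.ndarray:
        chain, first, last = self.entries[hid]
        mask = (
            (s.chain == chain)
            & (s.resnum >= first)
            & (s.resnum <= last)
            & (s.name == "CA")
        )
        return np.sort(s.resnum[mask])

    @classmethod
    def from_file(cls, path: str | Path) -> "HelixMap":
        """Read a plain-text map: one ``HELIX CHAIN:FIRST-LAST`` entry per line."""
        entries: dict[str, tuple[str, int, int]] = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            m = re.fullmatch(r"(\w+)[\s=]+(\w):(-?\d+)-(-?\d+)", line)
            if m is None:
                raise PDBParseError(f"{path}:{ln}: cannot parse helix-map line {line!r}")
            entries[m.group(1)] = (m.group(2), int(m.group(3)), int(m.group(4)))
        return cls(entries)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{hid} {c}:{a}-{b}" for hid, (c, a, b) in self.entries.items()]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class RepeatUnits:
    """The four inverted-topology three-helix repeat units of the MFS fold."""

    A: tuple[str, str, str] = ("H1", "H2", "H3")
    B: tuple[str, str, str] = ("H4", "H5", "H6")
    C: tuple[str, str, str] = ("H7", "H8", "H9")
    D: tuple[str, str, str] = ("H10", "H11", "H12")

    def __post_init__(self) -> None:
        all_h = self.A + self.B + self.C + self.D
        if sorted(all_h) != sorted(_HELIX_IDS):
            raise ValueError("repeat units must partition H1–H12")
        for unit in (self.A, self.B, self.C, self.D):
            if len(unit) != 3:
                raise ValueError("each repeat unit has exactly 3 helices")


_WATER_LIPID = {"HOH", "WAT", "DOD", "POP", "POPC", "POPE", "DPPC", "DMPC", "LDA", "OLC"}


def _vdw_for(element: str, table: Mapping[str, float]) -> float:
    return table.get(element.upper(), DEFAULT_VDW)


def read_pdb(
    path: str | Path,
    altloc_policy: str = "highest_occupancy",
    include_hetatm: bool = False,
    keep_hydrogens: bool = False,
    vdw_table: Mapping[str, float] | None = None,
) -> Structure:
    """Read a (possibly multi-model) PDB file into a :class:`Structure`.

    Alternate locations are resolved per ``altloc_policy``: ``"highest_occupancy"``
    keeps the highest-occupancy conformer (ties broken toward label ``A``);
    ``"first"`` keeps the first encountered. HETATM water/lipid is always
    dropped; other HETATM records are kept only with ``include_hetatm``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = vdw_table or VDW_RADII
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:  # gemmi names the offending line
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models found")

    def atom_key(chain: str, res: gemmi.Residue, atom: gemmi.Atom) -> tuple:
        return (chain, res.seqid.num, res.seqid.icode.strip(), res.name, atom.name)

    # Resolve altlocs on the first model, then require identical keys elsewhere.
    chosen: dict[tuple, gemmi.Atom] = {}
    order: list[tuple] = []
    meta: dict[tuple, tuple] = {}
    for chain in st[0]:
        for res in chain:
            het = res.het_flag == "H"
            if het and (res.name in _WATER_LIPID or not include_hetatm):
                continue
            for atom in res:
                if atom.is_hydrogen() and not keep_hydrogens:
                    continue
                key = atom_key(chain.name, res, atom)
                if key not in chosen:
                    chosen[key] = atom
                    order.append(key)
                    meta[key] = (chain.name, res, atom)
                elif altloc_policy == "highest_occupancy":
                    old = chosen[key]
                    if atom.occ > old.occ or (
                        atom.occ == old.occ and (atom.altloc or "Z") < (old.altloc or "Z")
                    ):
                        chosen[key] = atom
                        meta[key] = (chain.name, res, atom)
    if not order:
        raise PDBParseError(f"{path}: no atoms after filtering")

    n_atoms = len(order)
    serial = np.empty(n_atoms, dtype=int)
    name = np.empty(n_atoms, dtype="U4")
    element = np.empty(n_atoms, dtype="U2")
    resname = np.empty(n_atoms, dtype="U3")
    resnum = np.empty(n_atoms, dtype=int)
    chain_arr = np.empty(n_atoms, dtype="U1")
    icode = np.empty(n_atoms, dtype="U1")
    vdw = np.empty(n_atoms)
    bfac = np.empty(n_atoms)
    coords = np.empty((len(st), n_atoms, 3))

    for i, key in enumerate(order):
        chain_name, res, atom = meta[key]
        serial[i] = atom.serial
        name[i] = atom.name
        element[i] = atom.element.name.upper()
        resname[i] = res.name
        resnum[i] = res.seqid.num
        chain_arr[i] = chain_name[:1]
        icode[i] = res.seqid.icode.strip()
        vdw[i] = _vdw_for(atom.element.name, table)
        bfac[i] = atom.b_iso
        coords[0, i] = (atom.pos.x, atom.pos.y, atom.pos.z)

    for mi in range(1, len(st)):
        model = st[mi]
        lookup: dict[tuple, gemmi.Atom] = {}
        for chain in model:
            for res in chain:
                for atom in res:
                    lookup[atom_key(chain.name, res, atom)] = atom
        for i, key in enumerate(order):
            atom = lookup.get(key)
            if atom is None:
                raise PDBParseError(
                    f"{path}: model {mi + 1} lacks atom {key}; models must share atom lists"
                )
            coords[mi, i] = (atom.pos.x, atom.pos.y, atom.pos.z)

    return Structure(
        serial=serial,
        name=name,
        element=element,
        resname=resname,
        resnum=resnum,
        chain=chain_arr,
        icode=icode,
        coords=coords,
        vdw=vdw,
        identifier=path.stem,
        bfactor=bfac,
    )


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a Structure as standard PDB text (MODEL/ENDMDL for ensembles)."""
    lines: list[str] = []
    multi = s.n_models > 1
    for mi in range(s.n_models):
        if multi:
            lines.append(f"MODEL     {mi + 1:4d}")
        for i in range(s.n_atoms):
            nm = s.name[i]
            # PDB atom-name column convention: element right-aligned in 13–14
            padded = f" {nm:<3s}" if len(nm) < 4 and len(s.element[i]) == 1 else f"{nm:<4s}"
            x, y, z = s.coords[mi, i]
            lines.append(
                f"ATOM  {s.serial[i] % 100000:5d} {padded}"
                f" {s.resname[i]:<3s} {s.chain[i]:1s}{s.resnum[i]:4d}{s.icode[i]:1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{s.bfactor[i]:6.2f}"
                f"          {s.element[i]:>2s}"
            )
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit principal axis of a point cloud, sign-aligned with first->last."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    direction = points[-1] - points[0]
    if np.dot(axis, direction) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _rotation_onto_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector v onto +z (minimal rotation)."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return Rotation.from_rotvec([np.pi, 0, 0]).as_matrix()
    axis = np.cross(v, z)
    axis /= np.linalg.norm(axis)
    angle = np.arccos(np.clip(c, -1, 1))
    return Rotation.from_rotvec(axis * angle).as_matrix()


def orient_membrane_normal(
    s: Structure,
    hm: HelixMap,
    n_term_cytoplasmic: bool = True,
    model: int = 0,
) -> Structure:
    """Rotate/translate so the mean helix axis lies on +z and the TM centroid at origin.

    Helix axes are per-helix Cα principal axes, sign-aligned to the direction of
    H1 (N-to-C). With the N terminus cytoplasmic (the default topology), H1 runs
    cytoplasm -> periplasm, so the mean axis points periplasmic and +z ends up on
    the periplasmic side.
    """
    axes = []
    tm_points = []
    h1_axis = None
    for k, hid in enumerate(hm.tm_helices):
        ca = hm.helix_ca(s, hid, model=model)
        if ca.shape[0] < 4:
            raise DegenerateGeometryError(f"{hid}: needs >=4 CA atoms for an axis fit")
        axis = _principal_axis(ca)
        if hid == "H1":
            h1_axis = axis if n_term_cytoplasmic else -axis
        axes.append(axis)
        tm_points.append(ca)
    if h1_axis is None:
        h1_axis = axes[0]
    # sign-align every axis with H1's membrane direction before averaging
    aligned = np.array([a if np.dot(a, h1_axis) >= 0 else -a for a in axes])
    mean_axis = aligned.mean(axis=0)
    mean_axis /= np.linalg.norm(mean_axis)
    R = _rotation_onto_z(mean_axis)
    center = np.vstack(tm_points).mean(axis=0)
    return s.transformed(R, -R @ center)


def superpose_rmsd(
    a: Structure,
    b: Structure,
    selection: Callable[[Structure], np.ndarray] | None = None,
    model_a: int = 0,
    model_b: int = 0,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Least-squares (Kabsch) superposition of paired Cα sets.

    Atoms are paired by ``(chain, residue_number, icode)`` over Cα; ``selection``
    may restrict which atoms of each structure are candidates. Returns
    ``(rotation, translation, rmsd, n_atoms)`` with the transform mapping ``a``
    onto ``b``.
    """
    xa, xb = paired_ca_coordinates(a, b, selection, model_a=model_a, model_b=model_b)
    if xa.shape[0] < 3:
        raise DegenerateGeometryError("fewer than 3 paired CA atoms; superposition underdetermined")
    ca_mean, cb_mean = xa.mean(axis=0), xb.mean(axis=0)
    rot, rssd = Rotation.align_vectors(xb - cb_mean, xa - ca_mean)
    R = rot.as_matrix()
    t = cb_mean - R @ ca_mean
    rmsd = float(rssd / np.sqrt(xa.shape[0]))
    return R, t, rmsd, int(xa.shape[0])


def paired_ca_coordinates(
    a: Structure,
    b: Structure,
    selection: Callable[[Structure], np.ndarray] | None = None,
    model_a: int = 0,
    model_b: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Correspondence-ordered Cα coordinate pairs keyed by (chain, resnum, icode)."""

    def keyed(s: Structure) -> dict[tuple, int]:
        mask = s.ca_mask()
        if selection is not None:
            mask = mask & np.asarray(selection(s), dtype=bool)
        out = {}
        for i in np.nonzero(mask)[0]:
            out[(s.chain[i], int(s.resnum[i]), s.icode[i])] = i
        return out

    ka, kb = keyed(a), keyed(b)
    common = [k for k in ka if k in kb]
    common.sort()
    ia = np.array([ka[k] for k in common], dtype=int)
    ib = np.array([kb[k] for k in common], dtype=int)
    return a.coords[model_a, ia], b.coords[model_b, ib]


def rmsd_benchmark(
    path_a: str | Path,
    path_b: str | Path,
    exclude_ranges: Sequence[tuple[str, int, int]] = (),
) -> tuple[float, int]:
    """Cα RMSD between two deposited structures over shared residues.

    ``exclude_ranges`` lists ``(chain, first, last)`` intervals to drop (e.g. the
    HA/HB accessory motif of bacterial POT transporters).
    """
    a = read_pdb(path_a)
    b = read_pdb(path_b)

    def sel(s: Structure) -> np.ndarray:
        keep = np.ones(s.n_atoms, dtype=bool)
        for chain, first, last in exclude_ranges:
            keep &= ~((s.chain == chain) & (s.resnum >= first) & (s.resnum <= last))
        return keep

    _, _, rmsd, n = superpose_rmsd(a, b, selection=sel)
    return rmsd, n
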