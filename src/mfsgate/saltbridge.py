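"""Salt-bridge detection and state-conditioned formation propensities.

A salt bridge is scored between a basic side-chain nitrogen (Lys NZ; Arg
NE/NH1/NH2) and an acidic carboxylate oxygen (Asp OD1/OD2; Glu OE1/OE2) when
the minimum nitrogen–oxygen distance is at or below a cutoff (4.0 Å by
default, the common crystallographic convention). Histidine is excluded by
default because its protonation state is unknown in crystal structures.
Propensities are the per-state fraction of frames in which each bridge is
formed, conditioned on the conformational-state labels of the same frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import HelixMap, Structure

__all__ = ["SaltBridgeContact", "detect_bridges", "propensity_by_state", "NAMED_BRIDGES"]

_BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}
_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

# Bridges reported for the proton-coupled oligopeptide transporters, shipped as
# named presets for reporting runs on the corresponding structures.
NAMED_BRIDGES: dict[str, tuple[tuple[str, str], ...]] = {
    "PepT_So": (("D136", "K439"), ("K84", "D79"), ("R52", "D328")),
    "PepT_St": (("R33", "E300"), ("R53", "E312"), ("K126", "E25"), ("K126", "E22")),
}


@dataclass(frozen=True)
class SaltBridgeContact:
    basic: tuple[str, int]  # (chain, resnum)
    acidic: tuple[str, int]
    basic_resname: str
    acidic_resname: str
    frame: int
    min_no_distance: float
    formed: bool


def _charge_centers(s: Structure, model: int, table: dict, kinds: Sequence[str]):
    """Group charge-center atom coordinates per residue."""
    out: dict[tuple[str, int], tuple[str, np.ndarray]] = {}
    skipped: set[tuple[str, int]] = set()
    for resname, atom_names in table.items():
        if resname not in kinds:
            continue
        res_mask = s.resname == resname
        for key in {(s.chain[i], int(s.resnum[i])) for i in np.nonzero(res_mask)[0]}:
            m = res_mask & (s.chain == key[0]) & (s.resnum == key[1]) & np.isin(s.name, atom_names)
            if not m.any():
                skipped.add(key)
                continue
            out[key] = (resname, s.coords[model, m])
    for key in skipped:
        warnings.warn(f"residue {key} lacks side-chain charge atoms; skipped")
    return out


def detect_bridges(
    s: Structure,
    cutoff: float = 4.0,
    model: int = 0,
    include_his: bool = False,
    diagnostic_margin: float = 2.0,
) -> list[SaltBridgeContact]:
    """All basic/acidic residue pairs within ``cutoff`` (plus near misses).

    Pairs with min N–O distance in ``(cutoff, cutoff + diagnostic_margin]`` are
    reported with ``formed=False`` for diagnostics; more distant pairs are
    omitted.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    basics = ("LYS", "ARG") + (("HIS",) if include_his else ())
    b = _charge_centers(s, model, _BASIC_ATOMS, basics)
    a = _charge_centers(s, model, _ACIDIC_ATOMS, ("ASP", "GLU"))
    contacts = []
    for bkey, (bname, bxyz) in b.items():
        for akey, (aname, axyz) in a.items():
            d = float(cdist(bxyz, axyz).min())
            if d <= cutoff + diagnostic_margin:
                contacts.append(
                    SaltBridgeContact(
                        basic=bkey,
                        acidic=akey,
                        basic_resname=bname,
                        acidic_resname=aname,
                        frame=model,
                        min_no_distance=d,
                        formed=d <= cutoff,
                    )
                )
    contacts.sort(key=lambda c: (c.basic, c.acidic))
    return contacts


def detect_bridges_ensemble(
    e: Structure, cutoff: float = 4.0, include_his: bool = False
) -> list[SaltBridgeContact]:
    """Per-frame bridge detection over every model of an ensemble."""
    out: list[SaltBridgeContact] = []
    for mi in range(e.n_models):
        out.extend(detect_bridges(e, cutoff=cutoff, model=mi, include_his=include_his))
    return out


def propensity_by_state(
    contacts: Sequence[SaltBridgeContact],
    labels: Sequence[str],
) -> pd.DataFrame:
    """Fraction of frames, per state, in which each bridge is formed.

    ``labels`` holds one conformational-state label per frame. Bridges never
    formed in any frame are excluded. Columns: bridge, basic, acidic, state,
    fraction_formed, n_frames (frames of that state).
    """
    n_frames = len(labels)
    if contacts and max(c.frame for c in contacts) >= n_frames:
        raise ValueError("contact frame index exceeds label count")
    formed_pairs = {(c.basic, c.acidic) for c in contacts if c.formed}
    if not formed_pairs:
        return pd.DataFrame(
            columns=["bridge", "basic", "acidic", "state", "fraction_formed", "n_frames"]
        )
    formed_by_pair: dict[tuple, set[int]] = {p: set() for p in formed_pairs}
    for c in contacts:
        if c.formed and (c.basic, c.acidic) in formed_by_pair:
            formed_by_pair[(c.basic, c.acidic)].add(c.frame)
    state_frames: dict[str, list[int]] = {}
    for fi, lab in enumerate(labels):
        state_frames.setdefault(lab, []).append(fi)
    rows = []
    for pair in sorted(formed_by_pair):
        basic, acidic = pair
        for state, frames in sorted(state_frames.items()):
            formed_n = sum(1 for fi in frames if fi in formed_by_pair[pair])
            rows.append(
                {
                    "bridge": f"{basic[0]}{basic[1]}-{acidic[0]}{acidic[1]}",
                    "basic": f"{basic[0]}:{basic[1]}",
                    "acidic": f"{acidic[0]}:{acidic[1]}",
                    "state": state,
                    "fraction_formed": formed_n / len(frames),
                    "n_frames": len(frames),
                }
            )
    return pd.DataFrame(rows)
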