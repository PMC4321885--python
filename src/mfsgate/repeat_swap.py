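"""Repeat-swap modelling: the opposite conformational state from inverted repeats.

The MFS fold is built from four three-helix inverted-topology repeat units
(A = H1–H3, B = H4–H6, C = H7–H9, D = H10–H12). Because A and B (and C and D)
are related by a pseudo-twofold axis in the membrane plane, threading the
sequence of unit A onto the structure of unit B — and vice versa, simultaneously
for C and D — produces a template of the same protein in the opposite
conformational state: an inward-open input yields an outward-open template.

This module builds the swap alignment (structural superposition of partner
units, residue pairing by nearest Cα, per-helix contiguous-offset cleanup so
that no gaps remain inside transmembrane helices) and transfers backbone
coordinates to produce the raw swapped template. Refinement into a full
homology model is deliberately out of scope; accessory helices (HA/HB/LH) are
not part of any repeat unit and never enter alignments or templates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure_io import HelixMap, RepeatUnits, Structure

__all__ = ["SwapAlignment", "build_repeat_alignment", "build_swapped_template"]

_BACKBONE = ("N", "CA", "C", "O", "CB")
_HELIX_PARTNERS = (("H1", "H4"), ("H2", "H5"), ("H3", "H6"), ("H7", "H10"), ("H8", "H11"), ("H9", "H12"))


class AlignmentError(ValueError):
    pass


@dataclass
class SwapAlignment:
    """Symmetric residue correspondence between partner repeat units.

    ``pairs`` maps a target residue to the template residue whose backbone it
    adopts; the map is an involution (if a -> b then b -> a).
    """

    pairs: dict[tuple[str, int], tuple[str, int]]
    unit_rmsd: dict[str, float] = field(default_factory=dict)
    helix_offsets: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_file(self, path: str | Path) -> None:
        lines = ["# target_chain:resnum\ttemplate_chain:resnum"]
        for (tc, tr), (pc, pr) in sorted(self.pairs.items()):
            lines.append(f"{tc}:{tr}\t{pc}:{pr}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SwapAlignment":
        pairs: dict[tuple[str, int], tuple[str, int]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            t, p = line.split("\t")
            tc, tr = t.split(":")
            pc, pr = p.split(":")
            pairs[(tc, int(tr))] = (pc, int(pr))
        return cls(pairs=pairs)


def _unit_ca(s: Structure, hm: HelixMap, helices, model: int):
    coords, keys = [], []
    for hid in helices:
        chain, first, last = hm[hid]
        ca = hm.helix_ca(s, hid, model=model)
        resnums = hm.helix_ca_resnums(s, hid)
        coords.append(ca)
        keys.extend((hid, chain, int(r)) for r in resnums)
    return np.vstack(coords), keys


def build_repeat_alignment(
    s: Structure,
    hm: HelixMap,
    units: RepeatUnits = RepeatUnits(),
    pairing_cap: float = 5.0,
    rmsd_ceiling: float = 12.0,
    model: int = 0,
) -> SwapAlignment:
    """Align each repeat unit onto its partner (A<->B, C<->D).

    The seed superposition pairs helix residues index-wise (H1 onto H4, etc.,
    N-to-C, truncated to the shorter helix). Residues are then re-paired by
    nearest Cα within ``pairing_cap`` and the votes reduced to one contiguous
    sequence offset per helix, so helix blocks contain no internal gaps (the
    automatic stand-in for manual alignment curation). A seed RMSD above
    ``rmsd_ceiling`` means the units are not structurally similar enough for
    automatic alignment.
    """
    for hid in [h for pair in _HELIX_PARTNERS for h in pair]:
        if hid not in hm:
            raise AlignmentError(f"helix {hid} missing from helix map")

    pairs: dict[tuple[str, int], tuple[str, int]] = {}
    unit_rmsd: dict[str, float] = {}
    helix_offsets: dict[str, int] = {}

    for block, helix_pairs in (("AB", _HELIX_PARTNERS[:3]), ("CD", _HELIX_PARTNERS[3:])):
        # index-wise seed correspondence per partner helix pair
        xa_l, xb_l = [], []
        for ha, hb in helix_pairs:
            ca_a = hm.helix_ca(s, ha, model=model)
            ca_b = hm.helix_ca(s, hb, model=model)
            n = min(len(ca_a), len(ca_b))
            xa_l.append(ca_a[:n])
            xb_l.append(ca_b[:n])
        xa, xb = np.vstack(xa_l), np.vstack(xb_l)
        ma, mb = xa.mean(axis=0), xb.mean(axis=0)
        rot, rssd = Rotation.align_vectors(xb - mb, xa - ma)
        rmsd = float(rssd / np.sqrt(len(xa)))
        unit_rmsd[block] = rmsd
        if rmsd > rmsd_ceiling:
            raise AlignmentError(
                f"unit superposition RMSD {rmsd:.1f} Å exceeds {rmsd_ceiling} Å for block {block}; "
                "units are not similar enough — provide a manual alignment file"
            )
        R = rot.as_matrix()

        for ha, hb in helix_pairs:
            ca_a = hm.helix_ca(s, ha, model=model)
            ca_b = hm.helix_ca(s, hb, model=model)
            res_a = hm.helix_ca_resnums(s, ha)
            res_b = hm.helix_ca_resnums(s, hb)
            chain_a, chain_b = hm[ha][0], hm[hb][0]
            moved = (ca_a - ma) @ R.T + mb
            d = cdist(moved, ca_b)
            votes: Counter[int] = Counter()
            for i in range(len(res_a)):
                j = int(np.argmin(d[i]))
                if d[i, j] <= pairing_cap:
                    votes[j - i] += 1
            # the offset must keep the helix block contiguous; prefer maximal
            # residue coverage (register preservation), then nearest-Cα votes
            candidates = set(votes) | {0}
            def overlap(off: int) -> int:
                return max(0, min(len(res_a), len(res_b) - off) - max(0, -off))
            offset = max(candidates, key=lambda off: (overlap(off), votes.get(off, 0), -abs(off)))
            helix_offsets[f"{ha}->{hb}"] = offset
            for i in range(len(res_a)):
                j = i + offset
                if 0 <= j < len(res_b):
                    a_key = (chain_a, int(res_a[i]))
                    b_key = (chain_b, int(res_b[j]))
                    pairs[a_key] = b_key
                    pairs[b_key] = a_key

    return SwapAlignment(pairs=pairs, unit_rmsd=unit_rmsd, helix_offsets=helix_offsets)


def build_swapped_template(
    s: Structure,
    alignment: SwapAlignment,
    hm: HelixMap | None = None,
    model: int = 0,
) -> Structure:
    """Transfer backbone coordinates along the swap alignment.

    Every aligned residue's backbone (N, CA, C, O, and CB where both residues
    have one) is placed at its template partner's coordinates; the B-factor
    column flags placed residues with 1 and untouched ones with 0. Residues of
    accessory helices never appear. Raises if a template residue lacks the
    backbone atoms the target needs.
    """
    out = s.single_model(model)
    out.bfactor = np.zeros(out.n_atoms)

    index: dict[tuple[str, int, str], int] = {}
    for i in range(out.n_atoms):
        index[(out.chain[i], int(out.resnum[i]), out.name[i])] = i

    new_coords = out.coords[0].copy()
    missing: list[str] = []
    for target, template in alignment.pairs.items():
        placed_any = False
        for atom in _BACKBONE:
            ti = index.get((target[0], target[1], atom))
            if ti is None:
                continue
            si = index.get((template[0], template[1], atom))
            if si is None:
                if atom in ("N", "CA", "C"):
                    missing.append(f"{template[0]}:{template[1]}:{atom}")
                continue
            new_coords[ti] = out.coords[0][si]
            out.bfactor[ti] = 1.0
            placed_any = True
        if not placed_any:
            missing.append(f"{template[0]}:{template[1]}")
    if missing:
        raise AlignmentError(f"alignment references missing atoms: {sorted(set(missing))[:10]}")

    # drop any side-chain atoms beyond CB: the template is backbone-only
    keep = np.isin(out.name, _BACKBONE)
    out = out.with_coords(new_coords[None]).select(keep)
    out.identifier = f"{s.identifier}_swapped"
    return out


def placed_residue_count(template: Structure) -> int:
    placed = set()
    for i in np.nonzero(template.bfactor > 0.5)[0]:
        placed.add((template.chain[i], int(template.resnum[i])))
    return len(placed)
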