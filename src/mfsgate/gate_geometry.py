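"""Helix-tip extraction, tip-pair distances, gate-pair selection and kink angles.

Both transporter gates are assumed to be formed by the tips of two contiguous
helix pairs, one pair from each six-helix half. On the periplasmic side the
candidate pairs per half are (H1&H2, H3&H4, H5&H6) × (H7&H8, H9&H10, H11&H12);
on the cytoplasmic side (H2&H3, H4&H5) × (H8&H9, H10&H11). The gate-defining
combination is the one whose minimum tip–tip distance across a structure set
correlates best with the spherical-probe radius of the same gate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr, spearmanr

from .structure_io import DegenerateGeometryError, HelixMap, Structure

__all__ = [
    "PairCombination",
    "enumerate_pairs",
    "tip_ca",
    "min_tip_distance",
    "tip_distance_table",
    "select_gate_pairs",
    "kink_angle",
]

Side = Literal["periplasmic", "cytoplasmic"]

_PERI_N = (("H1", "H2"), ("H3", "H4"), ("H5", "H6"))
_PERI_C = (("H7", "H8"), ("H9", "H10"), ("H11", "H12"))
_CYTO_N = (("H2", "H3"), ("H4", "H5"))
_CYTO_C = (("H8", "H9"), ("H10", "H11"))


@dataclass(frozen=True)
class PairCombination:
    """A candidate gate: one contiguous helix pair from each half."""

    side: Side
    n_half_pair: tuple[str, str]
    c_half_pair: tuple[str, str]

    def __str__(self) -> str:
        return (
            f"{self.n_half_pair[0]}&{self.n_half_pair[1]}-"
            f"{self.c_half_pair[0]}&{self.c_half_pair[1]}"
        )


PERIPLASMIC_DEFAULT = PairCombination("periplasmic", ("H1", "H2"), ("H7", "H8"))
CYTOPLASMIC_DEFAULT = PairCombination("cytoplasmic", ("H4", "H5"), ("H10", "H11"))


def enumerate_pairs(side: Side) -> list[PairCombination]:
    """All candidate pair combinations for a side, in canonical product order.

    Nine combinations on the periplasmic side, four on the cytoplasmic side.
    """
    if side == "periplasmic":
        halves = product(_PERI_N, _PERI_C)
    elif side == "cytoplasmic":
        halves = product(_CYTO_N, _CYTO_C)
    else:
        raise ValueError(f"unknown side {side!r}")
    return [PairCombination(side, n, c) for n, c in halves]


def _topology_direction(hid: str, n_term_cytoplasmic: bool = True) -> int:
    d = 1 if int(hid[1:]) % 2 == 1 else -1
    return d if n_term_cytoplasmic else -d


def tip_ca(
    s: Structure,
    hm: HelixMap,
    hid: str,
    side: Side,
    n_tip_residues: int = 10,
    model: int = 0,
    direction: Literal["topology", "auto"] | int = "topology",
) -> np.ndarray:
    """Cα coordinates of a helix tip: the first or last n residues on that side.

    ``direction`` resolves which sequence end faces the periplasm:
    ``"topology"`` (default) assumes strict alternation with the N terminus
    cytoplasmic. The sequence-based rule is essential for raw repeat-swapped
    templates, whose threaded helices deliberately occupy their partner's
    (inverted) position. ``"auto"`` instead uses the end with greater mean z on
    an oriented structure; an explicit ``+1``/``-1`` (N-to-C running
    cytoplasm->periplasm / reverse) overrides both.
    """
    ca = hm.helix_ca(s, hid, model=model)  # N-to-C order
    if ca.shape[0] == 0:
        raise DegenerateGeometryError(f"helix {hid} has no CA atoms")
    n = n_tip_residues
    if ca.shape[0] < n:
        warnings.warn(f"{hid}: only {ca.shape[0]} residues; using all as the tip")
        n = ca.shape[0]
    if isinstance(direction, int):
        d = direction
    elif direction == "topology":
        d = _topology_direction(hid)
    else:
        head_z = ca[: max(ca.shape[0] // 3, 1), 2].mean()
        tail_z = ca[-max(ca.shape[0] // 3, 1) :, 2].mean()
        d = 1 if tail_z >= head_z else -1
    peri_is_tail = d > 0
    want_tail = peri_is_tail == (side == "periplasmic")
    return ca[-n:] if want_tail else ca[:n]


def min_tip_distance(
    s: Structure,
    hm: HelixMap,
    combo: PairCombination,
    n_tip_residues: int = 10,
    model: int = 0,
    direction: Literal["topology", "auto"] | int = "topology",
) -> float:
    """Minimum Cα–Cα distance between the tip unions of the two half-pairs."""
    tips_n = np.vstack(
        [tip_ca(s, hm, h, combo.side, n_tip_residues, model, direction) for h in combo.n_half_pair]
    )
    tips_c = np.vstack(
        [tip_ca(s, hm, h, combo.side, n_tip_residues, model, direction) for h in combo.c_half_pair]
    )
    return float(cdist(tips_n, tips_c).min())


def tip_distance_table(
    structures: Sequence[tuple[str, Structure, HelixMap]],
    sides: Sequence[Side] = ("periplasmic", "cytoplasmic"),
    n_tip_residues: int = 10,
    direction: Literal["topology", "auto"] | int = "topology",
) -> pd.DataFrame:
    """Tip distances for every candidate combination of every structure.

    One row per (structure, combination): 9 periplasmic + 4 cytoplasmic rows
    per structure when both sides are requested.
    """
    rows = []
    for sid, s, hm in structures:
        for side in sides:
            for combo in enumerate_pairs(side):
                rows.append(
                    {
                        "id": sid,
                        "side": side,
                        "combination": str(combo),
                        "min_distance": min_tip_distance(
                            s, hm, combo, n_tip_residues, direction=direction
                        ),
                    }
                )
    return pd.DataFrame(rows, columns=["id", "side", "combination", "min_distance"])


def select_gate_pairs(
    table: pd.DataFrame,
    gate_radii: Mapping[str, float],
    side: Side,
    method: Literal["pearson", "spearman"] = "pearson",
) -> list[tuple[PairCombination, float]]:
    """Rank candidate combinations by correlation of tip distance with gate radius.

    ``gate_radii`` maps structure id to the minimum probe radius of the same
    side's gate. Combinations whose distance (or the radius) has zero variance
    get an undefined correlation and are ranked last (r reported as NaN).
    Requires at least three structures.
    """
    combos = enumerate_pairs(side)
    sub = table[table["side"] == side]
    ids = [i for i in sub["id"].unique() if i in gate_radii]
    if len(ids) < 3:
        raise ValueError("need >=3 structures with matching gate radii")
    radii = np.array([gate_radii[i] for i in ids])
    scored: list[tuple[PairCombination, float]] = []
    corr = pearsonr if method == "pearson" else spearmanr
    for combo in combos:
        d = (
            sub[sub["combination"] == str(combo)]
            .set_index("id")
            .loc[ids, "min_distance"]
            .to_numpy()
        )
        if np.std(d) == 0 or np.std(radii) == 0:
            scored.append((combo, float("nan")))
            continue
        r = float(corr(d, radii)[0])
        scored.append((combo, r))
    scored.sort(key=lambda t: (np.isnan(t[1]), -(t[1] if not np.isnan(t[1]) else -np.inf)))
    return scored


def _segment_axis(points: np.ndarray) -> np.ndarray:
    # smooth the Cα spiral over roughly one helical turn before the line fit;
    # otherwise non-integral turn counts tilt the axis of short segments by ~3°
    if points.shape[0] >= 6:
        k = 4
        kernel = np.ones(k) / k
        points = np.column_stack([np.convolve(points[:, d], kernel, mode="valid") for d in range(3)])
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, points[-1] - points[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def kink_angle(
    s: Structure,
    hm: HelixMap,
    hid: str,
    hinge_residue: int,
    model: int = 0,
) -> float:
    """Angle (°) between least-squares axes of the pre- and post-hinge segments.

    The hinge residue belongs to both segments. Requires at least four Cα on
    each side so both axis fits are well conditioned.
    """
    chain, first, last = hm[hid]
    ca = hm.helix_ca(s, hid, model=model)
    resnums = hm.helix_ca_resnums(s, hid)
    pre = ca[resnums <= hinge_residue]
    post = ca[resnums >= hinge_residue]
    if pre.shape[0] < 4 or post.shape[0] < 4:
        raise DegenerateGeometryError(
            f"{hid}: need >=4 CA on both sides of hinge {hinge_residue}"
        )
    cosang = float(np.clip(np.dot(_segment_axis(pre), _segment_axis(post)), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))
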