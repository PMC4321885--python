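import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from oracles import brute_min_tip_distance

from conftest import make_point_structure
from mfsgate.gate_geometry import (
    CYTOPLASMIC_DEFAULT,
    PERIPLASMIC_DEFAULT,
    PairCombination,
    enumerate_pairs,
    kink_angle,
    min_tip_distance,
    select_gate_pairs,
    tip_ca,
    tip_distance_table,
)
from mfsgate.structure_io import HelixMap
from mfsgate.synthetic_bundle import helix_direction


def test_pair_combination_census():
    peri = enumerate_pairs("periplasmic")
    cyto = enumerate_pairs("cytoplasmic")
    assert len(peri) == 9
    assert len(cyto) == 4
    assert PERIPLASMIC_DEFAULT in peri
    assert CYTOPLASMIC_DEFAULT in cyto
    # canonical product order: N-half pair varies slowest
    assert peri[0].n_half_pair == ("H1", "H2") and peri[0].c_half_pair == ("H7", "H8")
    with pytest.raises(ValueError):
        enumerate_pairs("sideways")


def test_min_tip_distance_single_atoms():
    # two helices with one CA each at (0,0,0) and (3,4,0): Euclidean 5.0
    s = make_point_structure([[0, 0, 0], [3, 4, 0], [0, 0, 0], [3, 4, 0]], resnums=[1, 31, 91, 121])
    hm = HelixMap({"H1": ("A", 1, 1), "H2": ("A", 31, 31), "H7": ("A", 91, 91), "H8": ("A", 121, 121)})
    combo = PairCombination("periplasmic", ("H1", "H2"), ("H7", "H8"))
    d = min_tip_distance(s, hm, combo, n_tip_residues=1)
    # H1 and H7 coincide -> min over union is 0; use distinct pairs instead
    assert d == pytest.approx(0.0)
    s2 = make_point_structure([[0, 0, 0], [0, 0, 0], [3, 4, 0], [3, 4, 0]], resnums=[1, 31, 91, 121])
    assert min_tip_distance(s2, hm, combo, n_tip_residues=1) == pytest.approx(5.0)


def test_min_tip_distance_matches_brute_force(inward_bundle, occluded_bundle):
    for s, hm, _ in (inward_bundle, occluded_bundle):
        for combo in enumerate_pairs("periplasmic") + enumerate_pairs("cytoplasmic"):
            tips_n = np.vstack(
                [tip_ca(s, hm, h, combo.side) for h in combo.n_half_pair]
            )
            tips_c = np.vstack(
                [tip_ca(s, hm, h, combo.side) for h in combo.c_half_pair]
            )
            assert min_tip_distance(s, hm, combo) == pytest.approx(
                brute_min_tip_distance(tips_n, tips_c), abs=1e-12
            )


def test_tip_side_matches_generator_directions(inward_bundle):
    """Periplasmic tips sit at greater z, for both up- and down-running helices."""
    s, hm, _ = inward_bundle
    for hid in hm.tm_helices:
        peri = tip_ca(s, hm, hid, "periplasmic")
        cyto = tip_ca(s, hm, hid, "cytoplasmic")
        assert peri[:, 2].mean() > cyto[:, 2].mean()
        # and the topology rule picks sequence head/tail per direction
        ca = hm.helix_ca(s, hid)
        expect = ca[-10:] if helix_direction(hid) > 0 else ca[:10]
        assert np.allclose(peri, expect)


def test_short_helix_uses_all_residues_with_warning():
    pts = [[0, 0, float(i)] for i in range(5)] + [[10, 0, float(i)] for i in range(5)]
    s = make_point_structure(pts, resnums=list(range(1, 6)) + list(range(31, 36)))
    hm = HelixMap({"H1": ("A", 1, 5), "H2": ("A", 31, 35)})
    with pytest.warns(UserWarning):
        tips = tip_ca(s, hm, "H1", "periplasmic", n_tip_residues=10)
    assert tips.shape[0] == 5


def _ranking_fixture(rng, n=12):
    """Distances for all combinations; the designated pair is exactly 2x the radius."""
    radii = {f"s{i}": float(rng.uniform(0.5, 4.0)) for i in range(n)}
    rows = []
    for sid, r in radii.items():
        for combo in enumerate_pairs("periplasmic"):
            if combo == PERIPLASMIC_DEFAULT:
                d = 2.0 * r
            else:
                d = float(rng.uniform(5, 15))
            rows.append({"id": sid, "side": "periplasmic", "combination": str(combo), "min_distance": d})
    return pd.DataFrame(rows), radii


def test_select_gate_pairs_perfect_linearity():
    rng = np.random.default_rng(1)
    table, radii = _ranking_fixture(rng)
    ranked = select_gate_pairs(table, radii, "periplasmic")
    assert ranked[0][0] == PERIPLASMIC_DEFAULT
    assert ranked[0][1] == pytest.approx(1.0)


def test_select_gate_pairs_anticorrelation_ranked_last():
    rng = np.random.default_rng(2)
    table, radii = _ranking_fixture(rng)
    # make one combination perfectly anti-correlated
    combo = str(enumerate_pairs("periplasmic")[3])
    mask = table["combination"] == combo
    table.loc[mask, "min_distance"] = [
        20.0 - 2.0 * radii[i] for i in table.loc[mask, "id"]
    ]
    ranked = select_gate_pairs(table, radii, "periplasmic")
    assert ranked[-1][1] == pytest.approx(-1.0)
    assert str(ranked[-1][0]) == combo


def test_select_gate_pairs_zero_variance_flagged():
    rng = np.random.default_rng(3)
    table, radii = _ranking_fixture(rng)
    combo = str(enumerate_pairs("periplasmic")[5])
    table.loc[table["combination"] == combo, "min_distance"] = 7.0
    ranked = select_gate_pairs(table, radii, "periplasmic")
    assert str(ranked[-1][0]) == combo and np.isnan(ranked[-1][1])


def test_select_gate_pairs_needs_three_structures():
    rng = np.random.default_rng(4)
    table, radii = _ranking_fixture(rng, n=2)
    with pytest.raises(ValueError):
        select_gate_pairs(table, radii, "periplasmic")


def test_pearson_matches_two_pass_formula():
    from scipy.stats import pearsonr

    x = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
    y = np.array([2.0, 1.5, 5.0, 7.5, 11.0])
    sx, sy = x - x.mean(), y - y.mean()
    direct = float((sx * sy).sum() / np.sqrt((sx**2).sum() * (sy**2).sum()))
    assert pearsonr(x, y)[0] == pytest.approx(direct, abs=1e-10)


def test_kink_straight_helix_near_zero(inward_bundle):
    s, hm, _ = inward_bundle
    assert kink_angle(s, hm, "H3", hinge_residue=73) == pytest.approx(0.0, abs=2.0)


def test_kink_thirty_degrees_ground_truth():
    from mfsgate.synthetic_bundle import BundleParams, generate_bundle

    s, hm, _ = generate_bundle(BundleParams(kink_spec=("H8", 223, 30.0), seed=6))
    assert kink_angle(s, hm, "H8", hinge_residue=223) == pytest.approx(30.0, abs=2.0)


def test_kink_invariant_under_rigid_rotation():
    from mfsgate.synthetic_bundle import BundleParams, generate_bundle

    s, hm, _ = generate_bundle(BundleParams(kink_spec=("H8", 223, 30.0), seed=6))
    a0 = kink_angle(s, hm, "H8", hinge_residue=223)
    R = Rotation.from_euler("zyx", [40, 25, 10], degrees=True).as_matrix()
    a1 = kink_angle(s.transformed(R, np.array([5.0, -2.0, 1.0])), hm, "H8", hinge_residue=223)
    assert a1 == pytest.approx(a0, abs=1e-9)


def test_kink_needs_residues_both_sides(inward_bundle):
    from mfsgate.structure_io import DegenerateGeometryError

    s, hm, _ = inward_bundle
    with pytest.raises(DegenerateGeometryError):
        kink_angle(s, hm, "H3", hinge_residue=62)  # second residue of H3


def test_tip_distance_table_shape(inward_bundle):
    s, hm, _ = inward_bundle
    table = tip_distance_table([("b0", s, hm)])
    assert len(table) == 13  # 9 periplasmic + 4 cytoplasmic rows
    assert (table["min_distance"] >= 0).all()
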