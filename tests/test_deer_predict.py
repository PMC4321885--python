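import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_point_structure
from mfsgate.deer_predict import (
    DistanceDistribution,
    LabelingError,
    RotamerLibrary,
    SiteRotamers,
    attach_rotamers,
    compare_distributions,
    default_mtsl_library,
    predict_distribution,
)
from mfsgate.synthetic_bundle import BundleParams, generate_bundle


def single_residue_structure(extra_atoms=()):
    """One residue with backbone N/CA/C plus optional decoy atoms."""
    pts = [[-1.45, 0.0, 0.0], [0.0, 0.0, 0.0], [1.0, 1.1, 0.0]]
    names = ["N", "CA", "C"]
    resnums = [1, 1, 1]
    for p in extra_atoms:
        pts.append(list(p))
        names.append("CA")
        resnums.append(99)
    return make_point_structure(pts, names=names, resnums=resnums)


def test_library_invariants():
    lib = default_mtsl_library()
    assert len(lib) == 20
    assert np.all(lib.weights > 0)
    assert np.linalg.norm(lib.offsets, axis=1).max() <= 9.0  # MTSL linker reach
    with pytest.raises(ValueError):
        RotamerLibrary(offsets=np.array([[0, 0, 12.0]]), weights=np.array([1.0]))
    with pytest.raises(ValueError):
        RotamerLibrary(offsets=np.array([[0, 0, 5.0]]), weights=np.array([-1.0]))


def test_isolated_site_retains_all_rotamers():
    s = single_residue_structure()
    site = attach_rotamers(s, ("A", 1))
    assert len(site.weights) == len(default_mtsl_library())
    assert site.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_decoy_clash_removes_rotamer():
    s0 = single_residue_structure()
    full = attach_rotamers(s0, ("A", 1))
    decoy = full.positions[0]  # place an atom on the first rotamer's spin center
    s1 = single_residue_structure(extra_atoms=[decoy])
    filtered = attach_rotamers(s1, ("A", 1))
    assert len(filtered.weights) < len(full.weights)
    assert filtered.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_all_rotamers_clash_is_an_error():
    s0 = single_residue_structure()
    full = attach_rotamers(s0, ("A", 1))
    s1 = single_residue_structure(extra_atoms=list(full.positions))
    with pytest.raises(LabelingError):
        attach_rotamers(s1, ("A", 1))


def test_monotone_in_clash_tolerance():
    s0 = single_residue_structure()
    full = attach_rotamers(s0, ("A", 1))
    s1 = single_residue_structure(extra_atoms=[full.positions[0] + [0.5, 0, 0]])
    counts = []
    for tol in (1.5, 1.0, 0.5, 0.2):  # shrinking tolerance = stricter filter
        try:
            counts.append(len(attach_rotamers(s1, ("A", 1), clash_tol=tol).weights))
        except LabelingError:
            counts.append(0)
    assert counts == sorted(counts, reverse=True)


def test_single_rotamer_delta():
    a = SiteRotamers(("A", 1), np.array([[0.0, 0.0, 0.0]]), np.array([1.0]))
    b = SiteRotamers(("A", 2), np.array([[25.0, 0.0, 0.0]]), np.array([1.0]))
    dist = predict_distribution(a, b, bin_width=0.5)
    assert dist.mass.sum() == pytest.approx(1.0, abs=1e-12)
    assert dist.peak == pytest.approx(25.0, abs=0.25)
    assert (dist.mass > 0).sum() == 1


def test_four_pair_enumeration():
    """Two rotamers per site with pair distances {10, 20, 20, 30} -> masses 1/4, 1/2, 1/4."""
    a = SiteRotamers(("A", 1), np.array([[0.0, 0, 0], [40.0, 0, 0]]), np.array([0.5, 0.5]))
    b = SiteRotamers(("A", 2), np.array([[10.0, 0, 0], [20.0, 0, 0]]), np.array([0.5, 0.5]))
    dist = predict_distribution(a, b, bin_width=1.0)
    for r, want in ((10.0, 0.25), (20.0, 0.5), (30.0, 0.25)):
        k = int(np.searchsorted(dist.bin_edges, r, side="right")) - 1
        assert dist.mass[k] == pytest.approx(want, abs=1e-12)
    assert dist.mass.sum() == pytest.approx(1.0, abs=1e-9)


def test_prediction_invariant_under_rigid_motion():
    s, hm, _ = generate_bundle(BundleParams(seed=3))
    sites = (("A", 271), ("A", 61))  # surface-exposed residues, one per half
    pa, pb = attach_rotamers(s, sites[0]), attach_rotamers(s, sites[1])
    d0 = predict_distribution(pa, pb)
    R = Rotation.from_euler("xyz", [15, 75, -30], degrees=True).as_matrix()
    moved = s.transformed(R, np.array([7.0, -3.0, 12.0]))
    qa, qb = attach_rotamers(moved, sites[0]), attach_rotamers(moved, sites[1])
    d1 = predict_distribution(qa, qb)
    n = min(len(d0.mass), len(d1.mass))
    assert np.allclose(d0.mass[:n], d1.mass[:n], atol=1e-9)


def test_support_bounded_by_linker_reach():
    s, hm, _ = generate_bundle(BundleParams(seed=3))
    sites = (("A", 271), ("A", 61))
    ca1 = s.residue_ca("A", 271)
    ca2 = s.residue_ca("A", 61)
    pa, pb = attach_rotamers(s, sites[0]), attach_rotamers(s, sites[1])
    dist = predict_distribution(pa, pb)
    support_max = dist.bin_edges[np.nonzero(dist.mass)[0].max() + 1]
    assert support_max <= np.linalg.norm(ca1 - ca2) + 2 * 9.0 + dist.bin_width


def test_compare_identical_and_disjoint():
    edges = np.arange(0, 11.0, 1.0)
    p = DistanceDistribution(edges, np.array([0, 0.2, 0.5, 0.3, 0, 0, 0, 0, 0, 0]))
    overlap, offset, within = compare_distributions(p, p)
    assert overlap == pytest.approx(1.0, abs=1e-9)
    assert offset == 0.0 and within
    q = DistanceDistribution(edges, np.array([0, 0, 0, 0, 0, 0, 0.4, 0.6, 0, 0]))
    overlap, _, within = compare_distributions(p, q)
    assert overlap == pytest.approx(0.0, abs=1e-12)
    assert not within


def test_compare_half_overlap():
    edges = np.arange(0, 4.0, 1.0)
    p = DistanceDistribution(edges, np.array([0.5, 0.5, 0.0]))
    q = DistanceDistribution(edges, np.array([0.0, 0.5, 0.5]))
    overlap, offset, _ = compare_distributions(p, q)
    assert overlap == pytest.approx(0.5, abs=1e-12)
    assert offset == pytest.approx(1.0)


def test_distribution_file_round_trip(tmp_path):
    edges = np.arange(10, 30.5, 0.5)
    rng = np.random.default_rng(0)
    mass = rng.random(len(edges) - 1)
    mass /= mass.sum()
    d = DistanceDistribution(edges, mass)
    path = tmp_path / "pr.tsv"
    d.to_file(path)
    back = DistanceDistribution.from_file(path)
    assert np.allclose(back.mass, d.mass, atol=1e-7)
    assert np.allclose(back.bin_edges, d.bin_edges, atol=1e-9)


def test_zero_bin_width_rejected():
    a = SiteRotamers(("A", 1), np.zeros((1, 3)), np.array([1.0]))
    with pytest.raises(ValueError):
        predict_distribution(a, a, bin_width=0.0)
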