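import numpy as np
import pandas as pd
import pytest

from oracles import brute_profile_axis, brute_profile_box, cylinder_structure

from conftest import make_point_structure
from mfsgate.pore_profile import (
    PoreProfile,
    ProfileError,
    SearchSettings,
    compute_profile,
    gate_min_radius,
    state_plane_coordinates,
)
from mfsgate.state_classify import calibrate_radius_threshold


@pytest.fixture(scope="module")
def cylinder_profile():
    s = cylinder_structure(wall_r=8.0, vdw=1.7)
    settings = SearchSettings(mode="box", r_max=8.0)
    prof = compute_profile(s, z_min=-8, z_max=8, z_step=0.5, search=settings)
    return s, settings, prof


def test_cylinder_on_axis_radius_analytic(cylinder_profile):
    """Hollow cylinder: probe radius equals wall radius minus atom vdw (8.0 - 1.7)."""
    _, _, prof = cylinder_profile
    interior = (prof.z_grid > -6) & (prof.z_grid < 6)
    assert np.all(np.abs(prof.radius[interior] - 6.3) <= 0.05)


def test_pinched_cylinder_minimum(cylinder_profile):
    s = cylinder_structure(wall_r=8.0, vdw=1.7, pinch=(0.0, 4.0))
    prof = compute_profile(s, z_min=-8, z_max=8, z_step=0.5, search=SearchSettings(mode="box", r_max=8.0))
    k = int(np.argmin(prof.radius))
    assert prof.z_grid[k] == pytest.approx(0.0, abs=0.5)
    assert prof.radius[k] == pytest.approx(2.3, abs=0.05)


def test_fully_blocked_slab_reports_nonpositive_radius():
    # dense lattice with spacing < 2 vdw across the whole box
    xs = np.arange(-8, 8.1, 2.0)
    pts = [[x, y, 0.0] for x in xs for y in xs]
    s = make_point_structure(pts, vdw=1.7)
    prof = compute_profile(s, z_min=-0.5, z_max=0.5, z_step=0.5, search=SearchSettings(mode="box", box_halfwidth=4.0))
    assert prof.radius[1] <= 0.0


def test_brute_force_oracle_agreement_box(cylinder_profile):
    s, settings, prof = cylinder_profile
    ref = brute_profile_box(
        s.coords[0], s.vdw, prof.z_grid, halfwidth=settings.box_halfwidth, r_max=settings.r_max
    )
    assert np.abs(prof.radius - ref).max() <= 0.1


def test_brute_force_oracle_agreement_axis(occluded_bundle):
    s, hm, _ = occluded_bundle
    prof = compute_profile(s)
    ref = brute_profile_axis(s.coords[0], s.vdw, prof.z_grid)
    assert np.abs(prof.radius - ref).max() <= 0.1


def test_vdw_inflation_shifts_radius_exactly():
    """radius = max-min( |c-x| - vdw ): inflating every vdw by d lowers it by exactly d."""
    s = cylinder_structure(wall_r=6.0, vdw=1.5)
    settings = SearchSettings(mode="box", r_max=8.0)
    p1 = compute_profile(s, z_min=-6, z_max=6, z_step=1.0, search=settings)
    s2 = s.copy()
    s2.vdw = s.vdw + 0.3
    p2 = compute_profile(s2, z_min=-6, z_max=6, z_step=1.0, search=settings)
    assert np.abs((p1.radius - p2.radius) - 0.3).max() < 1e-6


def test_profile_invariant_under_z_rotation_and_xy_translation(occluded_bundle):
    s, hm, _ = occluded_bundle
    base = compute_profile(s)
    th = np.deg2rad(35.0)
    R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    rot = s.transformed(R, np.zeros(3))
    prof_rot = compute_profile(rot)
    assert np.abs(base.radius - prof_rot.radius).max() <= 0.05
    t = np.array([4.0, -3.0, 0.0])
    moved = s.transformed(np.eye(3), t)
    prof_moved = compute_profile(moved, search=SearchSettings(seed_center=(4.0, -3.0)))
    assert np.abs(base.radius - prof_moved.radius).max() <= 0.05


def _toy_profile(radii, z0=-2.0, step=1.0):
    z = z0 + np.arange(len(radii)) * step
    return PoreProfile(
        z_grid=z,
        radius=np.asarray(radii, dtype=float),
        probe_center=np.zeros((len(radii), 2)),
        unbounded=np.zeros(len(radii), dtype=bool),
        r_max=5.0,
        gate_regions={"cytoplasmic": (z[0], 0.0), "periplasmic": (0.0, z[-1])},
    )


def test_gate_min_constant_region():
    prof = _toy_profile([2.0] * 9, z0=-4.0)
    gr = gate_min_radius(prof, window=4.0)
    assert gr.cytoplasmic_min == pytest.approx(2.0)
    assert gr.periplasmic_min == pytest.approx(2.0)


def test_gate_min_windowed_mean_with_clipping():
    # region [-2, 0] etc.; radii (3,2,1,2,3) at 1 Å spacing centred on the 1.
    prof = _toy_profile([3, 2, 1, 2, 3], z0=-2.0)
    prof.gate_regions = {"cytoplasmic": (-2.0, 2.0), "periplasmic": (-2.0, 2.0)}
    gr = gate_min_radius(prof, window=4.0)
    # window [-2,2] covers all five samples: mean = 11/5
    assert gr.cytoplasmic_min == pytest.approx(11 / 5)


def test_gate_min_tie_breaks_toward_cavity():
    prof = _toy_profile([1, 2, 3, 2, 1, 2], z0=-4.0)  # minima at z=-4 and z=0
    prof.gate_regions = {"cytoplasmic": (-4.0, 1.0), "periplasmic": (-4.0, 1.0)}
    gr = gate_min_radius(prof, window=1.0)
    assert gr.constriction_z["cytoplasmic"] == pytest.approx(0.0)  # smaller |z| wins


def test_gate_region_narrower_than_step_rejected():
    prof = _toy_profile([1, 2, 3], z0=-1.0)
    prof.gate_regions = {"cytoplasmic": (-1.0, -0.5), "periplasmic": (0.0, 1.0)}
    with pytest.raises(ProfileError):
        gate_min_radius(prof)


def test_state_plane_orderings(inward_bundle, occluded_bundle):
    si, hmi, _ = inward_bundle
    so, hmo, _ = occluded_bundle
    table = state_plane_coordinates([("inward", si, hmi), ("occluded", so, hmo)])
    row_in = table.set_index("id").loc["inward"]
    assert row_in["cytoplasmic_min"] > row_in["periplasmic_min"]
    # occluded: both gates below a threshold calibrated to the generator's radius scale
    from mfsgate.pore_profile import compute_profile as _cp
    from mfsgate.synthetic_bundle import BundleParams, generate_bundle

    apertures, peri_r, cyto_r = [], [], []
    for i, a in enumerate((5.0, 8.0, 11.0, 14.0)):
        sb, _, _ = generate_bundle(BundleParams(peri_aperture=a, cyto_aperture=a, seed=40 + i))
        gr = gate_min_radius(_cp(sb))
        apertures.append(a)
        peri_r.append(gr.periplasmic_min)
        cyto_r.append(gr.cytoplasmic_min)
    peri_thr = calibrate_radius_threshold(apertures, peri_r)
    cyto_thr = calibrate_radius_threshold(apertures, cyto_r)
    row_oc = table.set_index("id").loc["occluded"]
    assert row_oc["periplasmic_min"] < peri_thr
    assert row_oc["cytoplasmic_min"] < cyto_thr


def test_state_plane_empty_input():
    table = state_plane_coordinates([])
    assert isinstance(table, pd.DataFrame) and table.empty


def test_unconstrained_everywhere_raises():
    s = make_point_structure([[0, 0, 0]], vdw=1.7)
    with pytest.raises(ProfileError):
        compute_profile(s, z_min=100.0, z_max=101.0, z_step=0.5)


def test_search_settings_validation():
    with pytest.raises(ValueError):
        SearchSettings(mode="global")
    with pytest.raises(ValueError):
        SearchSettings(r_max=0)
    with pytest.raises(ValueError):
        compute_profile(make_point_structure([[0, 0, 0]]), z_min=0, z_max=1, z_step=-1)
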