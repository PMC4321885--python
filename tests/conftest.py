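import numpy as np
import pytest

from mfsgate.synthetic_bundle import BundleParams, generate_bundle, generate_ensemble


@pytest.fixture(scope="session")
def inward_bundle():
    """Inward-open bundle: periplasmic gate closed (6 Å), cytoplasmic open (14 Å)."""
    return generate_bundle(BundleParams(peri_aperture=6.0, cyto_aperture=14.0, seed=1))


@pytest.fixture(scope="session")
def occluded_bundle():
    return generate_bundle(BundleParams(peri_aperture=5.0, cyto_aperture=5.0, seed=2))


@pytest.fixture(scope="session")
def outward_bundle():
    return generate_bundle(BundleParams(peri_aperture=14.0, cyto_aperture=6.0, seed=3))


@pytest.fixture(scope="session")
def small_ensemble():
    """Noiseless four-frame ensemble with a mixed state schedule."""
    return generate_ensemble(
        BundleParams(seed=4),
        ["inward_open", "occluded", "outward_open", "occluded"],
        jitter_sd=0.0,
        seed=11,
    )


def make_point_structure(points, names=None, resnums=None, resnames=None, vdw=1.7):
    """Tiny hand-built Structure for arithmetic fixtures."""
    from mfsgate.structure_io import Structure

    pts = np.asarray(points, dtype=float)
    n = len(pts)
    return Structure(
        serial=np.arange(n) + 1,
        name=np.array(names or ["CA"] * n, dtype="U4"),
        element=np.array(["C"] * n, dtype="U2"),
        resname=np.array(resnames or ["ALA"] * n, dtype="U3"),
        resnum=np.array(resnums if resnums is not None else np.arange(n) + 1),
        chain=np.array(["A"] * n, dtype="U1"),
        icode=np.full(n, "", dtype="U1"),
        coords=pts[None],
        vdw=np.full(n, vdw, dtype=float),
        identifier="toy",
    )
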