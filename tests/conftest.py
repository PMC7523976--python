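import numpy as np
import pytest

from plaquestress import phantom as ph


def make_annulus_mesh(Ri=3.0, Ro=4.0, n_theta=64, n_r=8, region_code=0):
    """Concentric annulus as a SectionMesh (homogeneous unless labelled)."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    rr = np.linspace(Ri, Ro, n_r + 1)
    nodes = np.empty((n_theta * (n_r + 1), 2))
    for i, t in enumerate(theta):
        sl = slice(i * (n_r + 1), (i + 1) * (n_r + 1))
        nodes[sl, 0] = rr * np.cos(t)
        nodes[sl, 1] = rr * np.sin(t)

    def nid(i, j):
        return (i % n_theta) * (n_r + 1) + j

    quads = np.array([
        (nid(i, j), nid(i, j + 1), nid(i + 1, j + 1), nid(i + 1, j))
        for i in range(n_theta)
        for j in range(n_r)
    ])
    m = len(quads)
    th_c = np.repeat(theta, n_r) + np.pi / n_theta
    return ph.SectionMesh(
        nodes=nodes,
        quads=quads,
        region=np.full(m, region_code, dtype=np.int64),
        n_theta=n_theta,
        n_radial=n_r,
        station_z=0.0,
        lumen_loop=np.array([nid(i, 0) for i in range(n_theta)]),
        band_id=np.zeros(m, dtype=np.int64),
        cap_band=0,
        lc_band=1,
        wall_rings=n_r,
        wall_band_start=0,
        elem_theta=np.angle(np.exp(1j * th_c)),
    )


@pytest.fixture(scope="session")
def default_spec():
    return ph.PhantomSpec()


@pytest.fixture(scope="session")
def master_stack(default_spec):
    return ph.build_phantom(default_spec)


@pytest.fixture(scope="session")
def dip_station(master_stack):
    return int(np.nanargmin(master_stack.cap_thickness_profile()))
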