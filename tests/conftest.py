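import numpy as np
import pytest
import trimesh

from myowork import (
    EndocardialSurface,
    SyntheticPatientParams,
    make_lv_mesh,
    make_patient,
)


def spheroid_surface(a=30.0, b=30.0, theta0=np.pi / 2, n_phi=48, n_rings=32,
                     closed=False):
    """Param-grid spheroid (cap if theta0 > 0) as a one-frame surface.

    x = a sin(t) cos(p), z = b (1 + cos(t)); apex pole at the origin. With
    ``closed`` the grid starts at the far pole, producing a closed surface.
    """
    t0 = 1e-9 if closed else theta0
    theta = np.linspace(t0, np.pi, n_rings + 1)[:-1]
    phi = np.arange(n_phi) * (2 * np.pi / n_phi)
    th, ph = np.meshgrid(theta, phi, indexing="ij")
    verts = np.column_stack([
        (a * np.sin(th) * np.cos(ph)).ravel(),
        (a * np.sin(th) * np.sin(ph)).ravel(),
        (b * (1 + np.cos(th))).ravel(),
    ])
    apex = len(verts)
    verts = np.vstack([verts, [0.0, 0.0, 0.0]])
    tris = []
    for i in range(n_rings - 1):
        for j in range(n_phi):
            v00, v01 = i * n_phi + j, i * n_phi + (j + 1) % n_phi
            v10, v11 = (i + 1) * n_phi + j, (i + 1) * n_phi + (j + 1) % n_phi
            tris.append((v00, v01, v10))
            tris.append((v01, v11, v10))
    last = (n_rings - 1) * n_phi
    for j in range(n_phi):
        tris.append((last + j, last + (j + 1) % n_phi, apex))
    if closed:
        # close the far pole as well
        far = len(verts)
        verts = np.vstack([verts, [0.0, 0.0, 2 * b]])
        for j in range(n_phi):
            tris.append((j, far, (j + 1) % n_phi))
    zmax = verts[:, 2].max()
    return EndocardialSurface(
        vertices=verts[None], triangles=np.asarray(tris, dtype=np.intp),
        frame_times=np.array([0.0]), apex_point=np.zeros(3),
        base_centroid=np.array([0.0, 0.0, zmax]),
        long_axis=np.array([0.0, 0.0, 1.0]),
    )


def as_surface(mesh: trimesh.Trimesh) -> EndocardialSurface:
    """Wrap a closed trimesh (e.g. an icosphere) as a one-frame surface."""
    v = np.asarray(mesh.vertices, float)
    lo, hi = v[:, 2].min(), v[:, 2].max()
    return EndocardialSurface(
        vertices=v[None], triangles=np.asarray(mesh.faces, dtype=np.intp),
        frame_times=np.array([0.0]),
        apex_point=np.array([0.0, 0.0, lo]),
        base_centroid=np.array([0.0, 0.0, hi]),
    )


@pytest.fixture(scope="session")
def icosphere30():
    return trimesh.creation.icosphere(subdivisions=4, radius=30.0)


@pytest.fixture(scope="session")
def lv_mesh():
    return make_lv_mesh(SyntheticPatientParams())


@pytest.fixture(scope="session")
def lbbb_patient():
    """One noise-free dyssynchronous patient with both states."""
    return make_patient(SyntheticPatientParams(severity=0.8, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
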