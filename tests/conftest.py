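import numpy as np
import pytest
import trimesh as _trimesh

from headspectra.geometry import TriMesh, equidistant_sphere_points, triangulate_sphere_points
from headspectra.sphere_forward import ShellModel


@pytest.fixture(scope="session")
def model() -> ShellModel:
    """Default four-shell head model (80/81/86/92 mm, 0.33/1.79/0.0066/0.33 S/m)."""
    return ShellModel()


def icosphere_mesh(subdivisions: int = 3, radius: float = 1.0) -> TriMesh:
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(np.asarray(ico.vertices, dtype=float), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def unit_icosphere() -> TriMesh:
    """Dense unit sphere (2562 vertices) for spectral convergence checks."""
    return icosphere_mesh(subdivisions=4, radius=1.0)


@pytest.fixture(scope="session")
def small_icosphere() -> TriMesh:
    """Coarse unit sphere (42 vertices) for full-basis (Parseval) checks."""
    return icosphere_mesh(subdivisions=1, radius=1.0)


@pytest.fixture(scope="session")
def layout34(model) -> TriMesh:
    pts = equidistant_sphere_points(34, model.R4, seed=7)
    return triangulate_sphere_points(pts)


@pytest.fixture(scope="session")
def layout104(model) -> TriMesh:
    pts = equidistant_sphere_points(104, model.R4, seed=7)
    return triangulate_sphere_points(pts)


def sphere_quadrature(radius_mm: float, n_theta: int = 120, n_phi: int = 240):
    """Gauss-Legendre x trapezoid quadrature nodes (mm) and weights (m^2)."""
    from headspectra.sphere_forward import MM

    x, w = np.polynomial.legendre.leggauss(n_theta)
    phi = np.arange(n_phi) * 2.0 * np.pi / n_phi
    TH, PH = np.meshgrid(np.arccos(x), phi, indexing="ij")
    pts = radius_mm * np.column_stack(
        [
            (np.sin(TH) * np.cos(PH)).ravel(),
            (np.sin(TH) * np.sin(PH)).ravel(),
            np.cos(TH).ravel(),
        ]
    )
    W = (np.tile(w[:, None], (1, n_phi)) * (2.0 * np.pi / n_phi)).ravel()
    return pts, W * (radius_mm * MM) ** 2
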