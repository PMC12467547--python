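"""Synthetic inputs: dipole ensembles, open-cap fixtures and lead-field IO.

The default ensemble reproduces the simulation design used throughout the
validation analyses: 100 unit sources on each of 77 concentric shells with
radii 0-76 mm in 1 mm steps (7700 sources per orientation class).  Non-centre
sources are approximately equidistributed on their shell by the same seeded
relaxation used for sensor layouts; tangential moments get seeded random
azimuths in the plane orthogonal to the radial direction, and the 100 centre
sources get seeded random orientations (radial/tangential is undefined at the
centre).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import TriMesh, equidistant_sphere_points, extract_cap, load_mesh, save_mesh, triangulate_sphere_points
from .sphere_forward import Dipole, ShellModel, forward_potential

SOURCE_COLUMNS = ["x", "y", "z", "mx", "my", "mz", "depth_mm", "orientation_deg"]


@dataclass(frozen=True)
class DipoleEnsemble:
    """Seeded ensemble of unit dipoles on concentric shells."""

    positions: np.ndarray  # (N, 3) mm
    moments: np.ndarray  # (N, 3) unit
    shell_radius: np.ndarray  # (N,) mm
    orientation_class: np.ndarray  # (N,) str: radial | tangential | free
    seed: int

    def __len__(self) -> int:
        return len(self.positions)

    def dipoles(self):
        for p, m, oc in zip(self.positions, self.moments, self.orientation_class):
            yield Dipole(p, m, str(oc))

    def to_frame(self, outer_radius: float = 92.0) -> pd.DataFrame:
        """Source table with depth (distance to outer surface) and orientation angle."""
        r = np.linalg.norm(self.positions, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            radial = np.where(r[:, None] > 0, self.positions / np.where(r[:, None] > 0, r[:, None], 1.0), 0.0)
        cosang = np.abs(np.einsum("ij,ij->i", radial, self.moments))
        ang = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
        ang[r == 0] = np.nan
        return pd.DataFrame(
            {
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "mx": self.moments[:, 0],
                "my": self.moments[:, 1],
                "mz": self.moments[:, 2],
                "depth_mm": outer_radius - r,
                "orientation_deg": ang,
            }
        )


def _shell_positions(radius: float, per_shell: int, seed: int) -> np.ndarray:
    if per_shell >= 4:
        return equidistant_sphere_points(per_shell, radius, seed=seed)
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((per_shell, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * radius


def _tangential_moments(positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    radial = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    # seeded random azimuth in the tangent plane
    helper = np.where(
        np.abs(radial[:, 2:3]) < 0.9,
        np.tile([0.0, 0.0, 1.0], (len(radial), 1)),
        np.tile([1.0, 0.0, 0.0], (len(radial), 1)),
    )
    e1 = np.cross(radial, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(radial, e1)
    az = rng.uniform(0.0, 2.0 * np.pi, size=len(radial))
    return e1 * np.cos(az)[:, None] + e2 * np.sin(az)[:, None]


def dipole_ensemble(
    radii: np.ndarray | None = None,
    per_shell: int = 100,
    orientation_class: str = "radial",
    seed: int = 0,
    inner_radius: float = 80.0,
) -> DipoleEnsemble:
    """Build the shell ensemble of unit dipoles.

    Defaults give 77 shells (0-76 mm, step 1 mm) x 100 sources = 7700
    dipoles.  Shell positions and random orientations are drawn from
    per-shell seeds spawned from ``seed``, and do not depend on
    ``orientation_class`` — radial and tangential ensembles built with the
    same seed share positions and centre-source orientations.
    """
    if radii is None:
        radii = np.arange(0.0, 77.0)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii >= inner_radius):
        raise ValueError(f"shell radii must be < inner radius R1 = {inner_radius} mm")
    if per_shell < 1:
        raise ValueError("per_shell must be >= 1")
    if orientation_class not in ("radial", "tangential"):
        raise ValueError("orientation_class must be 'radial' or 'tangential'")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * len(radii))
    pos_list, mom_list, shell_list, class_list = [], [], [], []
    for i, r in enumerate(radii):
        pos_seed = children[2 * i]
        orient_rng = np.random.default_rng(children[2 * i + 1])
        if r == 0.0:
            pos = np.zeros((per_shell, 3))
            mom = orient_rng.standard_normal((per_shell, 3))
            mom /= np.linalg.norm(mom, axis=1, keepdims=True)
            cls = np.full(per_shell, "free")
        else:
            pos = _shell_positions(r, per_shell, seed=pos_seed.generate_state(1)[0] % (2**31))
            if orientation_class == "radial":
                mom = pos / np.linalg.norm(pos, axis=1, keepdims=True)
            else:
                mom = _tangential_moments(pos, orient_rng)
            cls = np.full(per_shell, orientation_class)
        pos_list.append(pos)
        mom_list.append(mom)
        shell_list.append(np.full(per_shell, r))
        class_list.append(cls)
    return DipoleEnsemble(
        positions=np.concatenate(pos_list),
        moments=np.concatenate(mom_list),
        shell_radius=np.concatenate(shell_list),
        orientation_class=np.concatenate(class_list),
        seed=seed,
    )


def write_sources(ensemble: DipoleEnsemble, path: str, outer_radius: float = 92.0) -> None:
    ensemble.to_frame(outer_radius).to_csv(path, index=False)


def read_sources(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SOURCE_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"source table missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# open-surface fixture and lead-field bundle


def pseudo_leadfield(
    sources: DipoleEnsemble | pd.DataFrame,
    mesh: TriMesh,
    model: ShellModel,
    tol: float = 1e-10,
) -> np.ndarray:
    """Forward-model lead field (n_sources x n_vertices) on a surface mesh.

    Built from the semi-analytical four-shell solution, so that the imported
    lead-field route can be exercised and cross-checked against the direct
    analytic route on spherical geometry.
    """
    if isinstance(sources, DipoleEnsemble):
        dips = list(sources.dipoles())
    else:
        dips = [
            Dipole(row[["x", "y", "z"]].to_numpy(float), row[["mx", "my", "mz"]].to_numpy(float))
            for _, row in sources.iterrows()
        ]
    L = np.empty((len(dips), mesh.n_vertices))
    for i, d in enumerate(dips):
        L[i] = forward_potential(d, model, mesh.vertices, tol=tol).values
    return L


def open_surface_fixture(
    n_points: int,
    radius: float,
    cap_angle_deg: float,
    seed: int = 0,
    model: ShellModel | None = None,
    sources: DipoleEnsemble | None = None,
) -> tuple[TriMesh, np.ndarray, pd.DataFrame]:
    """Open spherical cap with a pseudo lead field.

    ``n_points`` sensors are spread over the full sphere, triangulated, and
    the cap within ``cap_angle_deg`` of +z is extracted (at 180 degrees the
    closed sphere is returned).  The lead field holds the four-shell forward
    potentials of ``sources`` (default: a small seeded mixed-depth ensemble)
    at the cap vertices.
    """
    if not (0.0 < cap_angle_deg <= 180.0):
        raise ValueError("cap angle must be in (0, 180]")
    model = model or ShellModel()
    pts = equidistant_sphere_points(n_points, radius, seed=seed)
    mesh = triangulate_sphere_points(pts)
    if cap_angle_deg < 180.0:
        mesh = extract_cap(mesh, np.array([0.0, 0.0, 1.0]), cap_angle_deg)
        if mesh.n_vertices < 4:
            raise ValueError("cap retains too few vertices; enlarge angle or n_points")
    if sources is None:
        sources = dipole_ensemble(
            radii=np.array([0.0, 30.0, 50.0, 70.0]), per_shell=10,
            orientation_class="radial", seed=seed,
        )
    L = pseudo_leadfield(sources, mesh, model)
    return mesh, L, sources.to_frame(outer_radius=model.R4)


def leadfield_export(
    mesh: TriMesh, leadfield: np.ndarray, sources: pd.DataFrame,
    mesh_path: str, matrix_path: str, sources_path: str,
) -> None:
    save_mesh(mesh, mesh_path)
    np.savetxt(matrix_path, leadfield, delimiter="\t")
    sources.to_csv(sources_path, index=False)


def leadfield_import(
    mesh_path: str, matrix_path: str, sources_path: str
) -> tuple[TriMesh, np.ndarray, pd.DataFrame]:
    """Load and validate a (mesh, lead field, sources) bundle.

    The matrix must be n_sources x n_vertices; a transposed matrix is
    auto-corrected when unambiguous.
    """
    mesh = load_mesh(mesh_path)
    L = np.atleast_2d(np.loadtxt(matrix_path, delimiter="\t"))
    src = read_sources(sources_path)
    n_s, n_v = len(src), mesh.n_vertices
    if L.shape == (n_s, n_v):
        pass
    elif L.shape == (n_v, n_s):
        L = L.T
    else:
        raise ValueError(
            f"lead field shape {L.shape} matches neither (n_sources={n_s}, "
            f"n_vertices={n_v}) nor its transpose"
        )
    return mesh, L, src
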