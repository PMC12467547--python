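"""Sphara: generalized spatial Fourier basis on a triangle mesh.

The discrete Laplace-Beltrami operator of the sensor mesh is assembled with
linear finite elements, giving the cotangent stiffness matrix ``S`` and the
consistent mass matrix ``B``.  The generalized eigenproblem

    S x_i = tau_i B x_i

yields eigenvectors that are orthonormal under the B inner product
``<f, g>_B = f^T B g`` and eigenvalues ``tau_i >= 0`` (units mm^-2) that map
to spatial wavenumbers via ``k_i = sqrt(tau_i) = 2 pi omega_i = 2 pi /
lambda_i``.  The DC mode (constant eigenvector, tau = 0) exists on closed and
open meshes alike; open meshes carry natural (Neumann) boundary conditions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import eigh

from .geometry import TriMesh


@dataclass(frozen=True)
class FemMatrices:
    """Linear-FEM stiffness and mass matrices of a mesh.

    ``S`` is symmetric positive semi-definite with zero row sums (constants in
    the null space); ``B`` is symmetric positive definite and its entries sum
    to the total mesh area.
    """

    S: sp.csr_matrix
    B: sp.csr_matrix


@dataclass(frozen=True)
class WaveQuantities:
    k: float  # rad / mm
    omega: float  # 1 / mm
    lam: float  # mm, inf at tau = 0


def fem_matrices(mesh: TriMesh, lumped: bool = False) -> FemMatrices:
    """Assemble cotangent stiffness and (consistent) mass matrices.

    Parameters
    ----------
    mesh : triangle mesh with positive-area triangles.
    lumped : if True, row-lump the mass matrix (diagonal); the default is the
        consistent linear-FEM mass (area/6 diagonal, area/12 off-diagonal per
        triangle), which preserves the B-inner-product structure.
    """
    v = mesh.vertices
    t = mesh.triangles
    n = mesh.n_vertices
    areas = mesh.triangle_areas
    bad = np.flatnonzero(areas <= 0.0)
    if bad.size:
        raise ValueError(f"zero-area triangle(s) in FEM assembly: {bad.tolist()}")

    rows, cols, s_vals, b_vals = [], [], [], []
    corners = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
    # cotangent weights: for each corner a with opposite edge (b, c),
    # w = cot(angle_a) / 2 couples b and c.
    for a, b, c in corners:
        e1 = v[t[:, b]] - v[t[:, a]]
        e2 = v[t[:, c]] - v[t[:, a]]
        cot = np.einsum("ij,ij->i", e1, e2) / (2.0 * areas)
        w = 0.5 * cot
        rows += [t[:, b], t[:, c], t[:, b], t[:, c]]
        cols += [t[:, c], t[:, b], t[:, b], t[:, c]]
        s_vals += [-w, -w, w, w]
        # consistent mass: diagonal area/6 (counted once per corner), each
        # off-diagonal pair area/12
        b_vals += [areas / 12.0, areas / 12.0, areas / 6.0, np.zeros_like(areas)]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    S = sp.coo_matrix((np.concatenate(s_vals), (rows, cols)), shape=(n, n)).tocsr()
    B = sp.coo_matrix((np.concatenate(b_vals), (rows, cols)), shape=(n, n)).tocsr()
    if lumped:
        B = sp.diags(np.asarray(B.sum(axis=1)).ravel()).tocsr()
    return FemMatrices(S=S, B=B)


@dataclass(frozen=True)
class SpharaBasis:
    """B-orthonormal eigenbasis of the discrete Laplace-Beltrami operator.

    ``eigenvalues`` are ascending (tau_0 ~ 0 on a connected mesh, units
    mm^-2); ``eigenvectors`` holds the modes as columns with the sign fixed so
    each column's largest-magnitude entry is positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mesh: TriMesh
    B: sp.csr_matrix

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def sphara_basis(
    matrices: FemMatrices,
    n_modes: int,
    mesh: TriMesh | None = None,
    *,
    dense_threshold: int = 500,
    tol: float = 1e-10,
) -> SpharaBasis:
    """Solve ``S x = tau B x`` for the ``n_modes`` lowest modes.

    Uses a dense generalized eigensolver below ``dense_threshold`` vertices
    and a sparse shift-invert Lanczos solver above.
    """
    S, B = matrices.S, matrices.B
    n = S.shape[0]
    if not (1 <= n_modes <= n):
        raise ValueError(f"n_modes must be in [1, {n}]")
    if n <= dense_threshold or n_modes > n // 2:
        vals, vecs = eigh(S.toarray(), B.toarray(),
                          subset_by_index=(0, n_modes - 1))
    else:
        # small negative shift keeps the factorized matrix definite although
        # S itself is singular (constant null space); a buffer of extra modes
        # protects degenerate clusters at the truncation boundary, and a
        # fixed start vector makes the Lanczos iteration reproducible
        scale = S.diagonal().mean() / B.diagonal().mean()
        sigma = -1e-4 * scale
        k = min(n - 1, n_modes + max(8, n_modes // 8))
        v0 = np.random.default_rng(0).standard_normal(n)
        try:
            vals, vecs = spla.eigsh(S, k=k, M=B, sigma=sigma, which="LM",
                                    tol=tol, v0=v0)
        except Exception as exc:
            raise RuntimeError(
                f"sparse generalized eigensolver failed (n={n}, k={k}): {exc}"
            ) from exc
        order = np.argsort(vals)[:n_modes]
        vals, vecs = vals[order], vecs[:, order]
    order = np.argsort(vals)
    vals = np.maximum(vals[order], 0.0)
    vals[np.abs(vals) < 1e-12 * max(vals.max(), 1.0)] = np.abs(
        vals[np.abs(vals) < 1e-12 * max(vals.max(), 1.0)]
    )
    vecs = vecs[:, order]
    # exact B-orthonormalization within degenerate clusters is already
    # guaranteed by the solver; renormalize and fix signs for reproducibility
    bn = np.sqrt(np.einsum("ij,ij->j", vecs, B @ vecs))
    vecs = vecs / bn
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    if mesh is None:
        mesh = TriMesh(np.zeros((n, 3)), np.zeros((0, 3), dtype=int))
    return SpharaBasis(eigenvalues=np.asarray(vals, dtype=float),
                       eigenvectors=vecs, mesh=mesh, B=B)


def analyze(basis: SpharaBasis, f: np.ndarray) -> np.ndarray:
    """Forward Sphara transform: coefficients ``c_i = f^T B x_i``."""
    f = np.asarray(f, dtype=float)
    if f.shape[-1] != basis.eigenvectors.shape[0]:
        raise ValueError(
            f"field length {f.shape[-1]} != mesh size {basis.eigenvectors.shape[0]}"
        )
    return (basis.B @ f.T).T @ basis.eigenvectors if f.ndim > 1 else (
        basis.eigenvectors.T @ (basis.B @ f)
    )


def synthesize(basis: SpharaBasis, coefficients: np.ndarray) -> np.ndarray:
    """Inverse Sphara transform: ``f = sum_i c_i x_i``."""
    c = np.asarray(coefficients, dtype=float)
    if c.shape[-1] > basis.n_modes:
        raise ValueError(
            f"{c.shape[-1]} coefficients but basis holds {basis.n_modes} modes"
        )
    return basis.eigenvectors[:, : c.shape[-1]] @ c.T if c.ndim == 1 else (
        c @ basis.eigenvectors[:, : c.shape[-1]].T
    )


def field_energy(f: np.ndarray, B: sp.spmatrix) -> float:
    """Discrete surface energy ``E = f^T B f`` of a vertex-sampled field."""
    f = np.asarray(f, dtype=float)
    if f.shape[0] != B.shape[0]:
        raise ValueError("field length does not match mass matrix")
    return float(f @ (B @ f))


def eigen_to_wave(tau: float) -> WaveQuantities:
    """Map a Laplace-Beltrami eigenvalue to wavenumber/frequency/wavelength."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    k = float(np.sqrt(tau))
    if k == 0.0:
        return WaveQuantities(k=0.0, omega=0.0, lam=np.inf)
    return WaveQuantities(k=k, omega=k / (2.0 * np.pi), lam=2.0 * np.pi / k)


def residuals(basis: SpharaBasis, S: sp.spmatrix) -> np.ndarray:
    """Relative eigen-residuals ``|S x - tau B x| / |B x|`` per mode."""
    X = basis.eigenvectors
    R = S @ X - (basis.B @ X) * basis.eigenvalues
    return np.linalg.norm(R, axis=0) / np.linalg.norm(basis.B @ X, axis=0)


# ---------------------------------------------------------------------------
# export


def mesh_hash(mesh: TriMesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.round(mesh.vertices, 9)).tobytes())
    h.update(np.ascontiguousarray(mesh.triangles).tobytes())
    return h.hexdigest()[:16]


def export_basis(basis: SpharaBasis, prefix: str) -> None:
    """Write eigenvectors/eigenvalues as delimited text plus a JSON sidecar."""
    np.savetxt(prefix + "_eigenvectors.tsv", basis.eigenvectors, delimiter="\t")
    np.savetxt(prefix + "_eigenvalues.tsv", basis.eigenvalues, delimiter="\t")
    meta = {
        "mesh_hash": mesh_hash(basis.mesh),
        "n_modes": int(basis.n_modes),
        "n_vertices": int(basis.eigenvectors.shape[0]),
        "eigenvalue_units": "mm^-2",
    }
    with open(prefix + "_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
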