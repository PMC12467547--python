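"""Real spherical harmonics, discrete least-squares expansion and sampling bounds.

The real basis uses the geodesy 4pi normalization without the Condon-Shortley
phase:

    Y_lm(theta, phi) = Pbar_l^m(cos theta) * cos(m phi)      for m >= 0
    Y_l,-|m|          = Pbar_l^|m|(cos theta) * sin(|m| phi)  for m < 0

with ``Pbar_l^m = sqrt((2 - delta_0m)(2l+1)(l-m)!/(l+m)!) P_l^m`` so that
``(1/4pi) int Y_lm Y_l'm' dOmega = delta_ll' delta_mm'``.  On scattered
(e.g. equidistant) samplings the coefficients are obtained by least squares.
The Cartesian wavelength equivalent of degree l on a sphere of radius R is
given by the Jeans relation ``lambda = 2 pi R / sqrt(l (l+1))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, lpmv


@dataclass(frozen=True)
class ShCoefficients:
    """Real SH coefficients F_lm, flat-indexed as ``l^2 + l + m``."""

    values: np.ndarray
    l_max: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape[-1] != (self.l_max + 1) ** 2:
            raise ValueError("coefficient count must be (l_max+1)^2")
        object.__setattr__(self, "values", v)

    def get(self, l: int, m: int) -> float:
        if abs(m) > l or l > self.l_max:
            raise ValueError(f"invalid (l, m) = ({l}, {m})")
        return float(self.values[l * l + l + m])

    def degree_energies(self) -> np.ndarray:
        """sum_m F_lm^2 per degree l = 0..l_max (4pi-normalized Parseval)."""
        out = np.empty(self.l_max + 1)
        for l in range(self.l_max + 1):
            out[l] = np.sum(self.values[l * l: (l + 1) * (l + 1)] ** 2)
        return out


@dataclass(frozen=True)
class ShSamplingBounds:
    N_GLQ: int
    N_DH: int
    l_up: int | None = None


def _norm_legendre(l: int, m: int, x: np.ndarray) -> np.ndarray:
    """Geodesy-normalized associated Legendre, Condon-Shortley removed."""
    ln_norm = 0.5 * (
        np.log(2.0 * l + 1.0) + gammaln(l - m + 1) - gammaln(l + m + 1)
    )
    if m > 0:
        ln_norm += 0.5 * np.log(2.0)
    return ((-1.0) ** m) * np.exp(ln_norm) * lpmv(m, l, x)


def real_sh(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic at colatitude ``theta``, longitude ``phi`` (rad)."""
    if abs(m) > l:
        raise ValueError(f"|m| = {abs(m)} exceeds degree l = {l}")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    p = _norm_legendre(l, abs(m), np.cos(theta))
    if m >= 0:
        return p * np.cos(m * phi)
    return p * np.sin(abs(m) * phi)


def _angles(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    points = np.asarray(points, dtype=float)
    r = np.linalg.norm(points, axis=1)
    theta = np.arccos(np.clip(points[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(points[:, 1], points[:, 0])
    return theta, phi


def design_matrix(points: np.ndarray, l_max: int) -> np.ndarray:
    """Basis matrix: column ``l^2 + l + m`` holds Y_lm at each point."""
    theta, phi = _angles(points)
    cols = []
    for l in range(l_max + 1):
        for m in range(-l, l + 1):
            cols.append(real_sh(l, m, theta, phi))
    return np.column_stack(cols)


def sh_expand_lsq(
    points: np.ndarray, values: np.ndarray, l_max: int
) -> ShCoefficients:
    """Least-squares SH expansion of scattered samples on a sphere.

    Requires at least ``(l_max+1)^2`` points; rank deficiency of the design
    matrix raises with a suggestion to lower ``l_max``.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(points)
    n_coef = (l_max + 1) ** 2
    if n < n_coef:
        raise ValueError(
            f"{n} points cannot resolve l_max={l_max} "
            f"(need >= {n_coef}; try l_max <= {sampling_bounds(n=n).l_up})"
        )
    A = design_matrix(points, l_max)
    coef, _, rank, _ = np.linalg.lstsq(A, values, rcond=None)
    if rank < n_coef:
        raise ValueError(
            f"rank-deficient SH design matrix (rank {rank} < {n_coef}); "
            f"reduce l_max (suggested l_max <= {sampling_bounds(n=n).l_up})"
        )
    return ShCoefficients(values=coef.T if values.ndim > 1 else coef, l_max=l_max)


def sh_synthesize(coefficients: ShCoefficients, points: np.ndarray) -> np.ndarray:
    """Evaluate the truncated SH series at points on the sphere."""
    A = design_matrix(points, coefficients.l_max)
    return A @ np.asarray(coefficients.values, dtype=float).T


def jeans_wavelength(l: int, radius: float) -> float:
    """Cartesian wavelength of SH degree l on a sphere of radius R (mm)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if l == 0:
        return np.inf
    if l < 0:
        raise ValueError("degree l must be >= 0")
    return 2.0 * np.pi * radius / np.sqrt(l * (l + 1.0))


def sampling_bounds(l: int | None = None, n: int | None = None) -> ShSamplingBounds:
    """Sampling-point requirements for degree l, and the resolvable bound for n.

    ``N_GLQ = (l+1)(2l+1)`` (Gauss-Legendre grid), ``N_DH = (2l+2)^2``
    (Driscoll-Healy grid); ``l_up(n) = floor(sqrt(n/2) - 1)`` inverts the GLQ
    count ``N ~ 2 l^2`` for scattered equidistant samplings.
    """
    if l is None and n is None:
        raise ValueError("give a degree l and/or a point count n")
    N_GLQ = (l + 1) * (2 * l + 1) if l is not None else 0
    N_DH = (2 * l + 2) ** 2 if l is not None else 0
    l_up = int(np.floor(np.sqrt(n / 2.0) - 1.0)) if n is not None else None
    return ShSamplingBounds(N_GLQ=N_GLQ, N_DH=N_DH, l_up=l_up)
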