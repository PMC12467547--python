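"""Semi-analytical four-shell spherical EEG forward model.

The head is modelled as four concentric spherical shells (brain, CSF, skull,
scalp) with radii ``R1 < R2 < R3 < R4`` and piecewise-constant conductivities
``sigma_1..sigma_4``.  The scalp potential of a current dipole at distance
``b = f R4`` from the centre, rotated to the +z axis with moment components
``(Px, Py, Pz)``, is the Legendre series

    V(theta, phi) = 1 / (4 pi sigma_4 R4^2) * sum_{l>=1} w_l f^(l-1)
                    [ (Px cos phi + Py sin phi) P_l^1(cos theta)
                      + Pz * l * P_l(cos theta) ]

where ``w_l = (2l+1)^4 / (l C(l))`` collects the shell-dependent coefficient
``C(l)`` built from the conductivity ratios ``k_i = sigma_i / sigma_{i+1}``
and radius ratios.  For equal conductivities the series reduces to the
homogeneous-sphere dipole potential, ``w_l -> (2l+1)/l``.

Two properties of the series drive everything downstream: the l-th term is a
pure degree-l (associated) Legendre pattern, so it contributes exclusively to
one spatial frequency; and its exact surface energy has the closed form

    E_l = R4^2 A_l^2 [ (Px^2+Py^2) 2 pi l(l+1)/(2l+1) + Pz^2 l^2 4 pi/(2l+1) ]

with amplitude ``A_l = w_l f^(l-1) / (4 pi sigma_4 R4^2)``, using the
Legendre orthogonality integrals ``int P_l^2 dOmega = 4 pi/(2l+1)`` and
``int (P_l^1)^2 sin(theta) dtheta = 2 l(l+1)/(2l+1)``.

The coefficient chain is evaluated by a backward Moebius recursion of the
mode ratio through the shells; all factors are bounded products of decaying
radius-ratio powers, keeping the evaluation stable far beyond l = 600.

Lengths are accepted in mm and converted to metres internally, so that with
conductivities in S/m and unit dipole moments (A m) potentials come out in
volts; all relative and dB quantities are unit-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

MM = 1e-3  # mm -> m


@dataclass(frozen=True)
class ShellModel:
    """Four-shell concentric head model (radii in mm, conductivities in S/m)."""

    radii: tuple[float, float, float, float] = (80.0, 81.0, 86.0, 92.0)
    conductivities: tuple[float, float, float, float] = (0.33, 1.79, 0.0066, 0.33)

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        s = np.asarray(self.conductivities, dtype=float)
        if r.shape != (4,) or s.shape != (4,):
            raise ValueError("need exactly four radii and four conductivities")
        if np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError("radii must be positive and strictly increasing")
        if np.any(s <= 0):
            raise ValueError("conductivities must be positive")
        object.__setattr__(self, "radii", tuple(float(x) for x in r))
        object.__setattr__(self, "conductivities", tuple(float(x) for x in s))

    @property
    def R4(self) -> float:
        return self.radii[3]

    @property
    def conductivity_ratios(self) -> tuple[float, float, float]:
        """k1 = s1/s2, k2 = s2/s3, k3 = s3/s4."""
        s = self.conductivities
        return (s[0] / s[1], s[1] / s[2], s[2] / s[3])


@dataclass(frozen=True)
class Dipole:
    """Unit current dipole: position (mm, inside R1) and unit moment."""

    position: np.ndarray
    moment: np.ndarray
    orientation_class: str = "free"  # radial | tangential | free

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float).reshape(3)
        m = np.asarray(self.moment, dtype=float).reshape(3)
        nm = np.linalg.norm(m)
        if nm == 0:
            raise ValueError("moment must be nonzero")
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "moment", m / nm)

    def eccentricity(self, outer_radius: float) -> float:
        """f = |position| / R4."""
        return float(np.linalg.norm(self.position) / outer_radius)


def rotate_to_canonical(dipole: Dipole) -> tuple[Dipole, np.ndarray]:
    """Rotate a dipole so its position lies on the +z axis.

    Returns the canonical dipole and the rotation matrix ``R`` (``R @ v``
    maps original coordinates into the canonical frame; ``R.T`` maps back).
    A dipole at the centre gets the identity rotation.
    """
    p = dipole.position
    r = np.linalg.norm(p)
    if r == 0.0:
        return dipole, np.eye(3)
    z = np.array([0.0, 0.0, 1.0])
    u = p / r
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    c = float(u @ z)
    if s < 1e-15:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        axis = axis / s
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + s * K + (1 - c) * (K @ K)
    return (
        Dipole(R @ p, R @ dipole.moment, dipole.orientation_class),
        R,
    )


# ---------------------------------------------------------------------------
# shell coefficient chain


def surface_gain(ls: np.ndarray, model: ShellModel) -> np.ndarray:
    """Dimensionless surface gain ``G_l``.

    Defined by ``V_l(surface) = G_l * q * b^(l-1) / R4^(l+1) * angular part``
    with ``q = moment/(4 pi sigma_1)``; for equal conductivities
    ``G_l = (2l+1)/l`` (homogeneous insulated sphere).

    The outer insulating boundary fixes the growing/decaying mode ratio,
    which is propagated inward through the interfaces by Moebius maps; the
    surface value is then a telescoping product of ``(1 + mu)`` factors, so
    no growing powers ever appear.
    """
    l = np.asarray(ls, dtype=float)
    if np.any(l < 1):
        raise ValueError("degree l must be >= 1")
    R1, R2, R3, R4 = model.radii
    x = np.array([R1 / R4, R2 / R4, R3 / R4, 1.0])
    s = model.conductivities
    mu = (l + 1.0) / l  # A/B mode ratio at the insulated outer surface
    M = [None, None, None, mu]
    for j in (2, 1, 0):
        mu = mu * (x[j] / x[j + 1]) ** (2.0 * l + 1.0)
        sa, sb = s[j], s[j + 1]
        mu = (mu * (l * sb + (l + 1.0) * sa) - (l + 1.0) * (sb - sa)) / (
            (l * sa + (l + 1.0) * sb) - mu * l * (sb - sa)
        )
        M[j] = mu
    G = 1.0 + M[0]
    for j in (0, 1, 2):
        mu_in = M[j + 1] * (x[j] / x[j + 1]) ** (2.0 * l + 1.0)
        G = G * (1.0 + M[j + 1]) / (1.0 + mu_in)
    if not np.all(np.isfinite(G)):
        bad = int(np.asarray(ls)[~np.isfinite(np.atleast_1d(G))][0])
        raise FloatingPointError(f"shell coefficient overflow at l={bad}")
    return G


def C_of_l(l: int | np.ndarray, model: ShellModel) -> float | np.ndarray:
    """Shell-dependent series coefficient ``C(l) = sigma1/sigma4 (2l+1)^4 / (l G_l)``.

    For equal conductivities ``C(l) = (2l+1)^3``.
    """
    larr = np.atleast_1d(np.asarray(l, dtype=float))
    if np.any(larr < 1):
        raise ValueError("degree l must be >= 1")
    s = model.conductivities
    G = surface_gain(larr, model)
    C = (s[0] / s[3]) * (2.0 * larr + 1.0) ** 4 / (larr * G)
    return C if np.ndim(l) else float(C[0])


def series_weights(l_max: int, model: ShellModel) -> np.ndarray:
    """``w_l = (2l+1)^4 / (l C(l))`` for l = 1..l_max (index 0 is l=1)."""
    ls = np.arange(1, l_max + 1, dtype=float)
    s = model.conductivities
    return surface_gain(ls, model) * s[0] / s[3]


# ---------------------------------------------------------------------------
# term potentials and energies


def _check_on_surface(points: np.ndarray, R4: float) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    r = np.linalg.norm(points, axis=1)
    if np.any(np.abs(r - R4) > 1e-6 * R4):
        raise ValueError("evaluation points must lie on the outer shell R4")
    return points


def _f_powers(f: float, ls: np.ndarray) -> np.ndarray:
    """f^(l-1) with the centre-source convention 0^0 = 1."""
    if f == 0.0:
        out = np.zeros_like(ls, dtype=float)
        out[ls == 1] = 1.0
        return out
    return np.power(float(f), ls - 1.0)


def _legendre_pair(x: np.ndarray, l_max: int) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
    """Yield (l, P_l(x), P_l^1(x)) via stable recurrences, no Condon-Shortley."""
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - x * x))
    p_prev = np.ones_like(x)      # P_0
    p_cur = x.copy()              # P_1
    q_prev = np.zeros_like(x)     # P_0^1
    q_cur = sin_t.copy()          # P_1^1
    yield 1, p_cur, q_cur
    for l in range(2, l_max + 1):
        p_next = ((2 * l - 1) * x * p_cur - (l - 1) * p_prev) / l
        q_next = ((2 * l - 1) * x * q_cur - l * q_prev) / (l - 1)
        yield l, p_next, q_next
        p_prev, p_cur = p_cur, p_next
        q_prev, q_cur = q_cur, q_next


@dataclass(frozen=True)
class TermPotential:
    """Single degree-l term of the series: sampled values and exact energy."""

    degree: int
    values: np.ndarray  # volts at the surface points
    energy: float  # closed-form surface energy, V^2 m^2


@dataclass(frozen=True)
class ForwardResult:
    """Summed series potential with convergence metadata."""

    values: np.ndarray  # volts
    l_used: int
    converged: bool
    tail_fraction: float  # bound on neglected relative energy


def _amplitudes(dipole: Dipole, model: ShellModel, l_max: int) -> tuple[np.ndarray, float, float, float]:
    """Per-degree amplitude A_l (SI) and canonical moment components."""
    can, _ = rotate_to_canonical(dipole)
    f = can.eccentricity(model.R4)
    if np.linalg.norm(can.position) >= model.radii[0]:
        raise ValueError("dipole must lie strictly inside the innermost shell R1")
    ls = np.arange(1, l_max + 1, dtype=float)
    w = series_weights(l_max, model)
    R4_m = model.R4 * MM
    A = w * _f_powers(f, ls) / (4.0 * np.pi * model.conductivities[3] * R4_m**2)
    Px, Py, Pz = can.moment
    return A, Px, Py, Pz


def term_energy(l: int, dipole: Dipole, model: ShellModel) -> float:
    """Exact surface energy of the degree-l series term (V^2 m^2)."""
    if l < 1:
        raise ValueError("degree l must be >= 1")
    return float(term_energies(dipole, model, l)[l - 1])


def term_energies(dipole: Dipole, model: ShellModel, l_max: int) -> np.ndarray:
    """Closed-form per-degree surface energies for l = 1..l_max (V^2 m^2)."""
    A, Px, Py, Pz = _amplitudes(dipole, model, l_max)
    ls = np.arange(1, l_max + 1, dtype=float)
    R4_m = model.R4 * MM
    tang = (Px**2 + Py**2) * 2.0 * np.pi * ls * (ls + 1.0) / (2.0 * ls + 1.0)
    rad = Pz**2 * ls**2 * 4.0 * np.pi / (2.0 * ls + 1.0)
    return R4_m**2 * A**2 * (tang + rad)


def total_energy(
    dipole: Dipole, model: ShellModel, tol: float = 1e-10, l_max_cap: int = 600
) -> tuple[float, int]:
    """Total surface energy by summing term energies to relative tolerance."""
    E = term_energies(dipole, model, l_max_cap)
    total = float(E.sum())
    if total == 0.0:
        return 0.0, 1
    tail = np.cumsum(E[::-1])[::-1]
    keep = np.flatnonzero(tail > tol * total)
    l_used = int(keep[-1]) + 1 if keep.size else 1
    return total, l_used


def term_potential(
    l: int, dipole: Dipole, model: ShellModel, surface_points: np.ndarray
) -> TermPotential:
    """Degree-l term of the potential at canonical-frame surface points."""
    if l < 1:
        raise ValueError("degree l must be >= 1")
    points = _check_on_surface(surface_points, model.R4)
    A, Px, Py, Pz = _amplitudes(dipole, model, l)
    x = points[:, 2] / np.linalg.norm(points, axis=1)
    phi = np.arctan2(points[:, 1], points[:, 0])
    for ll, Pl, Pl1 in _legendre_pair(x, l):
        if ll == l:
            vals = A[l - 1] * (
                (Px * np.cos(phi) + Py * np.sin(phi)) * Pl1 + Pz * ll * Pl
            )
    return TermPotential(degree=l, values=vals,
                         energy=term_energy(l, dipole, model))


def forward_potential(
    dipole: Dipole,
    model: ShellModel,
    surface_points: np.ndarray,
    tol: float = 1e-10,
    l_max_cap: int = 600,
) -> ForwardResult:
    """Scalp potential of a dipole anywhere inside R1 at surface points.

    The dipole is rotated to the canonical +z frame internally, the series is
    summed until the closed-form tail energy falls below ``tol`` of the total
    (or ``l_max_cap``), and values are returned for the original points.
    """
    points = _check_on_surface(surface_points, model.R4)
    can, R = rotate_to_canonical(dipole)
    E = term_energies(can, model, l_max_cap)
    total = float(E.sum())
    if total > 0.0:
        tail = np.cumsum(E[::-1])[::-1]
        keep = np.flatnonzero(tail > tol * total)
        l_used = int(keep[-1]) + 1 if keep.size else 1
    else:
        l_used = 1
    tail_fraction = float(E[l_used:].sum() / total) if total > 0 else 0.0
    converged = l_used < l_max_cap or tail_fraction <= tol

    pts = points @ R.T
    r = np.linalg.norm(pts, axis=1)
    x = pts[:, 2] / r
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    A, Px, Py, Pz = _amplitudes(can, model, l_used)
    azim = Px * np.cos(phi) + Py * np.sin(phi)
    vals = np.zeros(len(pts))
    for l, Pl, Pl1 in _legendre_pair(x, l_used):
        a = A[l - 1]
        if a != 0.0:
            vals += a * (azim * Pl1 + Pz * l * Pl)
    return ForwardResult(values=vals, l_used=l_used, converged=converged,
                         tail_fraction=tail_fraction)
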