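"""Spatial energy spectra and sampling-sufficiency analyses.

All relative energies are expressed against a declared 0 dB reference.  For
the spherical validation analyses the reference is the (orientation
independent) scalp-surface energy of a unit source at the model centre — for
discrete routes, the mean energy of an ensemble of centre sources computed
through the same route.  dB uses the energy convention ``10 log10`` (50% is
about -3 dB).

Discrete "captured" energy of a sampled potential distribution is the
mass-matrix quadratic form ``f^T B f`` of the layout mesh; comparing it with
the exact closed-form series energy quantifies how much a finite electrode
layout misestimates scalp-potential energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import TriMesh
from .sphara import SpharaBasis, analyze, fem_matrices, field_energy
from .sphere_forward import (
    MM,
    Dipole,
    ShellModel,
    forward_potential,
    term_energies,
    total_energy,
)
from .spherical_harmonics import design_matrix, sh_expand_lsq

PERCENTILES = (50.0, 90.0, 99.0, 99.9)


def to_db(fraction: float | np.ndarray) -> float | np.ndarray:
    """Energy ratio to decibels, ``10 log10``; 0 maps to -inf."""
    arr = np.asarray(fraction, dtype=float)
    if np.any(arr < 0):
        raise ValueError("energy fractions must be non-negative")
    with np.errstate(divide="ignore"):
        out = 10.0 * np.log10(arr)
    return float(out) if np.ndim(fraction) == 0 else out


@dataclass(frozen=True)
class EnergySpectrum:
    """Per-degree energy contributions relative to a reference energy."""

    degrees: np.ndarray  # spherical degree l (0 = DC)
    fraction: np.ndarray  # linear energy fraction per degree
    reference_energy: float  # V^2 m^2 defining 0 dB
    kind: str = "semi-analytic"  # semi-analytic | sh | sphara

    def __post_init__(self) -> None:
        d = np.asarray(self.degrees, dtype=int)
        f = np.asarray(self.fraction, dtype=float)
        if d.shape != f.shape:
            raise ValueError("degrees and fractions must align")
        if np.any(f < 0):
            raise ValueError("energy fractions must be non-negative")
        object.__setattr__(self, "degrees", d)
        object.__setattr__(self, "fraction", f)

    @property
    def db(self) -> np.ndarray:
        return to_db(self.fraction)


@dataclass(frozen=True)
class SpectralReport:
    """Percentile/maximum envelopes of per-frequency energy contributions."""

    degrees: np.ndarray
    percentile_curves: dict[float, np.ndarray]
    max_curve: np.ndarray
    n_sources: int
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# references and exact spectra


def center_reference_energy(model: ShellModel) -> float:
    """Exact surface energy of a unit dipole at the model centre (V^2 m^2).

    The centre source excites only the l=1 term, whose energy is independent
    of the moment direction.
    """
    d = Dipole(np.zeros(3), np.array([0.0, 0.0, 1.0]), "free")
    return float(term_energies(d, model, 1)[0])


def center_sources(n: int = 100, seed: int = 0) -> list[Dipole]:
    """Centre dipoles with seeded random orientations."""
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((n, 3))
    m /= np.linalg.norm(m, axis=1, keepdims=True)
    return [Dipole(np.zeros(3), mi, "free") for mi in m]


def energy_gain_curve(
    model: ShellModel,
    radii_mm: np.ndarray,
    orientations: tuple[str, ...] = ("radial", "tangential"),
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Total surface energy vs. source depth, relative to the centre source.

    Uses the closed-form term energies; the dipole azimuth is irrelevant by
    symmetry, so one dipole per (radius, orientation) suffices.
    """
    ref = center_reference_energy(model)
    rows = []
    for r in np.asarray(radii_mm, dtype=float):
        for orient in orientations:
            if r == 0.0:
                d = Dipole(np.zeros(3), [0, 0, 1.0], "free")
            elif orient == "radial":
                d = Dipole([0, 0, r], [0, 0, 1.0], "radial")
            else:
                d = Dipole([0, 0, r], [1.0, 0, 0], "tangential")
            E, _ = total_energy(d, model, tol=tol)
            rows.append(
                {"radius_mm": r, "orientation": orient, "energy_ratio": E / ref,
                 "energy_db": to_db(E / ref)}
            )
    return pd.DataFrame(rows)


def term_spectrum(
    model: ShellModel, dipole: Dipole, l_max: int = 15
) -> EnergySpectrum:
    """Exact per-degree energy spectrum of a source, centre-referenced.

    Degree 0 is included (identically zero on the closed sphere: the series
    has no DC term).
    """
    ref = center_reference_energy(model)
    E = term_energies(dipole, model, l_max)
    frac = np.concatenate([[0.0], E / ref])
    return EnergySpectrum(degrees=np.arange(l_max + 1), fraction=frac,
                          reference_energy=ref, kind="semi-analytic")


# ---------------------------------------------------------------------------
# discrete sampling analyses


def mass_matrix_m2(mesh: TriMesh):
    """Mass matrix of a layout mesh with areas in m^2 (mesh given in mm)."""
    return fem_matrices(mesh).B * (MM**2)


def potentials(
    dipoles, model: ShellModel, points_mm: np.ndarray, tol: float = 1e-10
) -> np.ndarray:
    """Forward potentials (volts) of many dipoles at surface points, stacked."""
    dipoles = list(dipoles)
    out = np.empty((len(dipoles), len(points_mm)))
    for i, d in enumerate(dipoles):
        out[i] = forward_potential(d, model, points_mm, tol=tol).values
    return out


def sampled_energy_deviation(
    layouts: dict[str, TriMesh],
    model: ShellModel,
    dipoles,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Relative deviation of discretely captured energy from the exact energy.

    For each source and each layout mesh, ``deviation = (E_discrete -
    E_exact) / E_exact`` with ``E_discrete = f^T B f`` on the layout and
    ``E_exact`` the closed-form series energy.  Negative values mean the
    layout underestimates the energy of the potential distribution.
    """
    dipoles = list(dipoles)
    mats = {name: mass_matrix_m2(mesh) for name, mesh in layouts.items()}
    rows = []
    for i, d in enumerate(dipoles):
        E_exact, _ = total_energy(d, model, tol=tol)
        ecc = d.eccentricity(model.R4)
        for name, mesh in layouts.items():
            f = forward_potential(d, model, mesh.vertices, tol=tol).values
            E_disc = field_energy(f, mats[name])
            rows.append(
                {
                    "source": i,
                    "layout": name,
                    "radius_mm": ecc * model.R4,
                    "orientation": d.orientation_class,
                    "E_exact": E_exact,
                    "E_discrete": E_disc,
                    "deviation": (E_disc - E_exact) / E_exact,
                }
            )
    return pd.DataFrame(rows)


def sh_degree_energies(
    points_mm: np.ndarray, fields: np.ndarray, l_max: int
) -> np.ndarray:
    """Per-degree energies (V^2 m^2) of sampled fields via least-squares SH.

    With the 4pi-normalized real basis, the surface integral of the squared
    degree-l component is ``4 pi R^2 sum_m F_lm^2``.
    """
    fields = np.atleast_2d(fields)
    coefs = sh_expand_lsq(points_mm, fields.T, l_max)
    R_m = float(np.mean(np.linalg.norm(points_mm, axis=1))) * MM
    vals = np.atleast_2d(coefs.values)
    out = np.empty((fields.shape[0], l_max + 1))
    for l in range(l_max + 1):
        out[:, l] = np.sum(vals[:, l * l: (l + 1) * (l + 1)] ** 2, axis=1)
    return 4.0 * np.pi * R_m**2 * out


def degree_blocks(l_max: int) -> list[slice]:
    """Mode-index blocks per degree: DC, then 2l+1 consecutive modes each."""
    return [slice(l * l, (l + 1) * (l + 1)) for l in range(l_max + 1)]


def sphara_degree_energies(
    basis: SpharaBasis, fields: np.ndarray, l_max: int
) -> np.ndarray:
    """Per-degree energies (V^2 m^2) of sampled fields in the Sphara basis.

    Mode coefficients ``c_i = f^T B x_i`` are computed on the mm-scale mesh
    and converted to m^2 surface measure; after the DC mode, consecutive
    blocks of ``2l+1`` modes are assigned to degree l (exact grouping on the
    sphere's degenerate spectrum).
    """
    if basis.n_modes < (l_max + 1) ** 2:
        raise ValueError(
            f"basis holds {basis.n_modes} modes; degree {l_max} needs {(l_max+1)**2}"
        )
    fields = np.atleast_2d(fields)
    c = np.stack([analyze(basis, f) for f in fields])
    e_modes = c**2 * (MM**2)
    out = np.empty((fields.shape[0], l_max + 1))
    for l, blk in enumerate(degree_blocks(l_max)):
        out[:, l] = e_modes[:, blk].sum(axis=1)
    return out


def sphara_mode_energies(basis: SpharaBasis, fields: np.ndarray) -> np.ndarray:
    """Per-mode energies (V^2 m^2) of sampled fields in the Sphara basis."""
    fields = np.atleast_2d(fields)
    c = np.stack([analyze(basis, f) for f in fields])
    return c**2 * (MM**2)


def sh_spectrum(
    points_mm: np.ndarray,
    model: ShellModel,
    dipole: Dipole,
    l_max: int,
    reference_energy: float,
    tol: float = 1e-10,
) -> EnergySpectrum:
    """Discrete SH energy spectrum of one source on a sampled sphere."""
    f = forward_potential(dipole, model, points_mm, tol=tol).values
    E = sh_degree_energies(points_mm, f, l_max)[0]
    return EnergySpectrum(degrees=np.arange(l_max + 1),
                          fraction=E / reference_energy,
                          reference_energy=reference_energy, kind="sh")


def sphara_spectrum(
    basis: SpharaBasis,
    model: ShellModel,
    dipole: Dipole,
    l_max: int,
    reference_energy: float,
    tol: float = 1e-10,
) -> EnergySpectrum:
    """Discrete Sphara energy spectrum of one source on the basis mesh."""
    f = forward_potential(dipole, model, basis.mesh.vertices, tol=tol).values
    E = sphara_degree_energies(basis, f, l_max)[0]
    return EnergySpectrum(degrees=np.arange(l_max + 1),
                          fraction=E / reference_energy,
                          reference_energy=reference_energy, kind="sphara")


def compare_spectra(a: EnergySpectrum, b: EnergySpectrum) -> dict[str, float]:
    """Elementwise differences of relative contributions, in percentage points."""
    if not np.array_equal(a.degrees, b.degrees):
        raise ValueError("spectra use different degree groupings")
    diff = np.abs(a.fraction - b.fraction) * 100.0
    return {"max_abs_diff": float(diff.max()),
            "median_abs_diff": float(np.median(diff))}


# ---------------------------------------------------------------------------
# envelopes and source geometry


def percentile_envelopes(
    contributions: np.ndarray,
    degrees: np.ndarray | None = None,
    percentiles: tuple[float, ...] = PERCENTILES,
    metadata: dict | None = None,
) -> SpectralReport:
    """Percentile and maximum envelopes over sources, per frequency.

    ``contributions`` is (n_sources, n_frequencies) of relative energies.
    """
    contributions = np.atleast_2d(np.asarray(contributions, dtype=float))
    if degrees is None:
        degrees = np.arange(contributions.shape[1])
    curves = {
        p: np.percentile(contributions, p, axis=0) for p in sorted(percentiles)
    }
    return SpectralReport(
        degrees=np.asarray(degrees),
        percentile_curves=curves,
        max_curve=contributions.max(axis=0),
        n_sources=contributions.shape[0],
        metadata=metadata or {},
    )


def depth_group_envelopes(
    contributions: np.ndarray,
    depths_mm: np.ndarray,
    edges_mm: np.ndarray | None = None,
    n_groups: int = 6,
) -> pd.DataFrame:
    """Per-depth-group maximum envelopes of spectral contributions.

    Groups default to equal-count (quantile) depth bins.  Returns a long
    DataFrame with group label, depth range, source count and per-frequency
    maxima; empty groups are dropped with a warning.
    """
    contributions = np.atleast_2d(contributions)
    depths_mm = np.asarray(depths_mm, dtype=float)
    if len(depths_mm) != contributions.shape[0]:
        raise ValueError("one depth per source required")
    if edges_mm is None:
        edges_mm = np.quantile(depths_mm, np.linspace(0, 1, n_groups + 1))
        edges_mm[0] -= 1e-9
        edges_mm[-1] += 1e-9
    edges_mm = np.asarray(edges_mm, dtype=float)
    if np.any(np.diff(edges_mm) <= 0):
        raise ValueError("group edges must be strictly increasing")
    rows = []
    for g in range(len(edges_mm) - 1):
        sel = (depths_mm > edges_mm[g]) & (depths_mm <= edges_mm[g + 1])
        if not sel.any():
            warnings.warn(f"empty depth group ({edges_mm[g]:.1f}, {edges_mm[g+1]:.1f}] mm; omitted")
            continue
        mx = contributions[sel].max(axis=0)
        for j, v in enumerate(mx):
            rows.append(
                {"group": g, "depth_lo_mm": edges_mm[g], "depth_hi_mm": edges_mm[g + 1],
                 "n_sources": int(sel.sum()), "frequency_index": j, "max_contribution": v}
            )
    return pd.DataFrame(rows)


def _nearest_on_surface(point: np.ndarray, surface) -> tuple[float, np.ndarray]:
    """Distance and nearest surface point; surface is a radius or a TriMesh."""
    point = np.asarray(point, dtype=float)
    if np.isscalar(surface) or isinstance(surface, float) or isinstance(surface, int):
        R = float(surface)
        r = np.linalg.norm(point)
        if r == 0.0:
            return R, np.array([0.0, 0.0, R])
        return abs(R - r), point / r * R
    import trimesh as _trimesh

    mesh: TriMesh = surface
    tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles, process=False)
    closest, dist, _ = _trimesh.proximity.closest_point_naive(tm, point[None])
    return float(dist[0]), closest[0]


def source_geometry_metrics(
    position: np.ndarray,
    moment: np.ndarray,
    outer_surface,
    inner_surface,
) -> dict[str, float]:
    """Depth and orientation metrics of a source.

    depth = distance to the nearest point of the outer (scalp) surface;
    orientation = angle between the moment and the direction to the nearest
    point of the inner-skull surface, folded into [0, 90] degrees (0 =
    radial).  Surfaces may be analytic sphere radii or triangle meshes.
    """
    position = np.asarray(position, dtype=float)
    moment = np.asarray(moment, dtype=float)
    if np.isscalar(inner_surface) or isinstance(inner_surface, (int, float)):
        if np.linalg.norm(position) >= float(inner_surface):
            raise ValueError("source lies outside the inner-skull surface")
    depth, _ = _nearest_on_surface(position, outer_surface)
    _, nearest_inner = _nearest_on_surface(position, inner_surface)
    direction = nearest_inner - position
    nd = np.linalg.norm(direction)
    nm = np.linalg.norm(moment)
    if nd == 0.0 or nm == 0.0:
        angle = 0.0
    else:
        c = abs(float(direction @ moment) / (nd * nm))
        angle = float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))
    return {"depth_mm": float(depth), "orientation_deg": angle}
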