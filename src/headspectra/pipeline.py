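"""End-to-end pipelines: spherical validation and lead-field spectral analysis.

``run_validate_sphere`` reproduces the spherical-model analyses (layout
statistics and Nyquist limits, depth-dependent energy gain, per-degree term
spectra, sampled-energy deviations per layout, and the SH-vs-Sphara spectral
comparison on a dense layout) and writes delimited tables plus a single
machine-readable ``summary.json``.

``run_analyze_leadfield`` runs the open-surface route on an imported (mesh,
lead field, source table) bundle: Sphara decomposition per source, percentile
and depth-group envelopes, with the 0 dB reference set to the median energy
of the 15 deepest sources.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, dump_config
from .geometry import edge_stats, equidistant_sphere_points, nyquist_limits, triangulate_sphere_points
from .sphara import SpharaBasis, fem_matrices, field_energy, sphara_basis
from .spectra import (
    MM,
    center_reference_energy,
    center_sources,
    compare_spectra,
    depth_group_envelopes,
    energy_gain_curve,
    mass_matrix_m2,
    percentile_envelopes,
    potentials,
    sampled_energy_deviation,
    sh_degree_energies,
    sphara_degree_energies,
    sphara_mode_energies,
    term_spectrum,
    to_db,
)
from .sphere_forward import Dipole, ShellModel
from .synthetic import DipoleEnsemble, dipole_ensemble

logger = logging.getLogger("headspectra")


def _ensemble_radii(cfg: RunConfig) -> np.ndarray:
    e = cfg.ensemble
    return np.arange(e.radius_start_mm, e.radius_stop_mm + 0.5 * e.radius_step_mm,
                     e.radius_step_mm)


def _both_class_ensembles(cfg: RunConfig, radii=None, per_shell=None):
    e = cfg.ensemble
    kw = dict(
        radii=radii if radii is not None else _ensemble_radii(cfg),
        per_shell=per_shell or e.per_shell,
        seed=e.seed,
        inner_radius=cfg.shell_radii_mm[0],
    )
    return (
        dipole_ensemble(orientation_class="radial", **kw),
        dipole_ensemble(orientation_class="tangential", **kw),
    )


def run_validate_sphere(config: RunConfig, out_dir: str) -> dict:
    """Run the full spherical validation; returns the summary dict."""
    os.makedirs(out_dir, exist_ok=True)
    dump_config(config, os.path.join(out_dir, "resolved_config.yaml"))
    model = ShellModel(config.shell_radii_mm, config.conductivities_S_per_m)
    summary: dict = {
        "version": __version__,
        "seeds": {"layout": config.layout_seed, "ensemble": config.ensemble.seed},
        "series_tol": config.series_tol,
    }

    # -- stage 1: layouts, edge statistics, Nyquist limits
    logger.info("stage 1: layouts")
    layouts = {}
    rows = []
    for n in config.layout_sizes:
        pts = equidistant_sphere_points(n, config.layout_radius_mm, seed=config.layout_seed)
        mesh = triangulate_sphere_points(pts)
        layouts[n] = mesh
        st = edge_stats(mesh)
        ny = nyquist_limits(st.h_max)
        rows.append(
            {"n_sensors": n, "n_triangles": st.n_triangles, "h_mean_mm": st.h_mean,
             "h_sd_mm": st.h_sd, "h_max_mm": st.h_max, "lambda_N_mm": ny.lambda_N,
             "omega_N_per_mm": ny.omega_N}
        )
    layout_df = pd.DataFrame(rows)
    layout_df.to_csv(os.path.join(out_dir, "layouts.csv"), index=False)
    summary["layouts"] = layout_df.set_index("n_sensors").to_dict("index")

    # -- stage 2: depth-dependent energy gain (closed form)
    logger.info("stage 2: energy gain")
    radii = _ensemble_radii(config)
    gain = energy_gain_curve(model, radii, tol=config.series_tol)
    gain.to_csv(os.path.join(out_dir, "energy_gain.csv"), index=False)
    for orient in ("radial", "tangential"):
        sub = gain[(gain.orientation == orient)]
        summary[f"gain_{orient}_at_max_depth"] = float(
            sub.loc[sub.radius_mm.idxmax(), "energy_ratio"]
        )

    # -- stage 3: per-degree term spectra at selected depths
    logger.info("stage 3: term spectra")
    spec_rows = []
    for r in config.spectrum.subset_shells_mm:
        for orient, mom in (("radial", [0, 0, 1.0]), ("tangential", [1.0, 0, 0])):
            if r == 0.0 and orient == "tangential":
                continue
            pos = [0, 0, r]
            d = Dipole(pos, mom, "free" if r == 0 else orient)
            sp = term_spectrum(model, d, l_max=config.spectrum.l_max)
            for l, fr in zip(sp.degrees, sp.fraction):
                spec_rows.append({"radius_mm": r, "orientation": orient,
                                  "degree": int(l), "fraction": fr})
    pd.DataFrame(spec_rows).to_csv(os.path.join(out_dir, "term_spectra.csv"), index=False)

    # -- stage 4: sampled-energy deviations over the ensemble
    logger.info("stage 4: sampled-energy deviations")
    rad_ens, tan_ens = _both_class_ensembles(config)
    named = {str(n): layouts[n] for n in config.layout_sizes}
    dev_frames = []
    for ens in (rad_ens, tan_ens):
        dev_frames.append(
            sampled_energy_deviation(named, model, ens.dipoles(), tol=config.series_tol)
        )
    dev = pd.concat(dev_frames, ignore_index=True)
    dev.to_csv(os.path.join(out_dir, "deviations.csv"), index=False)
    dev_stats = {}
    for name, g in dev.groupby("layout"):
        dev_stats[name] = {
            "max_abs_deviation_pct": float(100 * g.deviation.abs().max()),
            "median_underestimation_pct": float(-100 * g.deviation.median()),
            "frac_nonpositive": float((g.deviation <= 1e-12).mean()),
        }
    summary["sampled_energy"] = dev_stats

    # -- stage 5: SH vs Sphara spectra on the dense layout
    if config.spectrum.enabled:
        logger.info("stage 5: SH/Sphara spectra")
        sc = config.spectrum
        pts = equidistant_sphere_points(sc.layout_n, config.layout_radius_mm,
                                        seed=config.layout_seed)
        mesh = triangulate_sphere_points(pts)
        fem = fem_matrices(mesh)
        n_modes = (sc.l_max + 1) ** 2
        basis = sphara_basis(fem, n_modes, mesh=mesh)
        subset_r, subset_t = _both_class_ensembles(
            config, radii=np.asarray(sc.subset_shells_mm), per_shell=sc.sources_per_shell
        )
        dips = list(subset_r.dipoles()) + [
            d for d in subset_t.dipoles() if d.orientation_class == "tangential"
        ]
        fields = potentials(dips, model, mesh.vertices, tol=config.series_tol)
        ref_fields = potentials(center_sources(sc.n_center_reference, seed=config.ensemble.seed),
                                model, mesh.vertices, tol=config.series_tol)
        B_m2 = mass_matrix_m2(mesh)
        ref_sphara = float(np.mean([field_energy(f, B_m2) for f in ref_fields]))
        ref_sh = float(np.mean(
            sh_degree_energies(mesh.vertices, ref_fields, sc.l_max).sum(axis=1)
        ))
        e_sh = sh_degree_energies(mesh.vertices, fields, sc.l_max) / ref_sh
        e_sp = sphara_degree_energies(basis, fields, sc.l_max) / ref_sphara
        diff_pp = np.abs(e_sh - e_sp) * 100.0
        summary["spectra"] = {
            "layout_n": sc.layout_n,
            "l_max": sc.l_max,
            "n_sources": len(dips),
            "sh_dc_max_db": float(to_db(max(e_sh[:, 0].max(), 1e-300))),
            "sh_vs_sphara_max_diff_pp": float(diff_pp.max()),
            "sh_vs_sphara_median_diff_pp": float(np.median(diff_pp)),
        }
        np.savetxt(os.path.join(out_dir, "sh_degree_fractions.tsv"), e_sh, delimiter="\t")
        np.savetxt(os.path.join(out_dir, "sphara_degree_fractions.tsv"), e_sp, delimiter="\t")

        if config.make_plots:
            _plot_validation(out_dir, gain, e_sh, e_sp)

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def run_analyze_leadfield(
    mesh, leadfield: np.ndarray, sources: pd.DataFrame, out_dir: str,
    n_modes: int | None = None, depth_groups: int = 6, n_reference: int = 15,
    make_plots: bool = False,
) -> dict:
    """Open-surface Sphara spectral analysis of an imported lead field."""
    os.makedirs(out_dir, exist_ok=True)
    fem = fem_matrices(mesh)
    if n_modes is None:
        n_modes = min(mesh.n_vertices, 256)
    basis = sphara_basis(fem, n_modes, mesh=mesh)
    e_modes = sphara_mode_energies(basis, leadfield)
    B_m2 = fem.B * (MM**2)
    totals = np.array([field_energy(f, B_m2) for f in leadfield])
    depths = sources["depth_mm"].to_numpy(float)
    deepest = np.argsort(depths)[-n_reference:]
    reference = float(np.median(totals[deepest]))
    contrib = e_modes / reference

    pd.DataFrame(
        {"depth_mm": depths, "energy": totals, "energy_rel": totals / reference,
         "energy_db": to_db(np.maximum(totals / reference, 1e-300))}
    ).to_csv(os.path.join(out_dir, "sources_energy.csv"), index=False)

    report = percentile_envelopes(contrib, metadata={"reference": "median of "
                                  f"{n_reference} deepest sources"})
    env = pd.DataFrame({"mode": report.degrees,
                        "eigenvalue": basis.eigenvalues[: contrib.shape[1]],
                        "max": report.max_curve})
    for p, curve in report.percentile_curves.items():
        env[f"p{p:g}"] = curve
    env.to_csv(os.path.join(out_dir, "envelopes.csv"), index=False)

    groups = depth_group_envelopes(contrib, depths, n_groups=depth_groups)
    groups.to_csv(os.path.join(out_dir, "depth_groups.csv"), index=False)

    summary = {
        "version": __version__,
        "n_sources": int(len(sources)),
        "n_modes": int(n_modes),
        "reference_energy": reference,
        "reference_rule": f"median of {n_reference} deepest sources",
        "dc_max_contribution": float(contrib[:, 0].max()),
        "max_contribution": float(contrib.max()),
    }
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    if make_plots:
        _plot_envelopes(out_dir, report)
    return summary


def _plot_validation(out_dir, gain, e_sh, e_sp) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for orient, g in gain.groupby("orientation"):
        axes[0].plot(g.radius_mm, g.energy_db, label=orient)
    axes[0].set_xlabel("source radius (mm)")
    axes[0].set_ylabel("energy gain (dB)")
    axes[0].legend()
    axes[1].plot(np.arange(e_sh.shape[1]), to_db(np.maximum(e_sh.max(axis=0), 1e-300)),
                 "o-", label="SH max")
    axes[1].plot(np.arange(e_sp.shape[1]), to_db(np.maximum(e_sp.max(axis=0), 1e-300)),
                 "s--", label="Sphara max")
    axes[1].set_xlabel("degree l")
    axes[1].set_ylabel("max contribution (dB)")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "validation.png"), dpi=120)
    plt.close(fig)


def _plot_envelopes(out_dir, report) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for p, curve in report.percentile_curves.items():
        ax.semilogy(report.degrees, np.maximum(curve, 1e-300), label=f"p{p:g}")
    ax.semilogy(report.degrees, np.maximum(report.max_curve, 1e-300), "k", label="max")
    ax.set_xlabel("mode")
    ax.set_ylabel("relative energy contribution")
    ax.legend()
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "envelopes.png"), dpi=120)
    plt.close(fig)
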