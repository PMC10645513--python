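"""High-level run entry points shared by the CLI and scripts.

Each runner resolves a :class:`~embryoflow.config.RunConfig`, executes the
corresponding computation and writes deterministic CSV/JSON outputs (floats
at 17 significant digits for bit-stable round-trips).  One structured log
line per stage goes to stderr and to ``run.log`` in the output directory.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .fixtures import slip_profile
from .geometry import make_geometry, to_spheroidal
from .lubrication import LubricationFlowField, compare_to_exact
from .reduced import density_exact, optimal_chi_1d, T_from_chi
from .stokes import (
    StokesFlowField,
    count_vortices,
    solve_slip_flow,
    streamfunction,
    velocity_rz,
)
from .transport import TransportConfig, ensemble_homogeneity

__all__ = ["run_flow", "run_transport", "run_reduced"]

FLOAT_FMT = "%.17g"


class _Log:
    def __init__(self, outdir: Path):
        outdir.mkdir(parents=True, exist_ok=True)
        self.path = outdir / "run.log"
        self.fh = self.path.open("a")

    def __call__(self, stage: str, **kv):
        line = f"[{stage}] " + " ".join(f"{k}={v}" for k, v in kv.items())
        print(line, file=sys.stderr)
        print(line, file=self.fh, flush=True)


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def _write_json(obj: dict, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_flow(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Solve the flow for a configured slip and export field + coefficients.

    Writes ``field.csv`` with columns (r_um, z_um, u_r, u_z, psi) on an
    interior grid, ``coefficients.json`` (exact solver) and, when both
    solvers run (``solver = "both"``), an error-field CSV.
    """
    outdir = Path(outdir or cfg.outdir) / "flow"
    log = _Log(outdir)
    g = make_geometry(cfg.bx_um, cfg.bz_um)
    vs = slip_profile(cfg.slip, g)
    log("geometry", bx_um=g.bx, bz_um=g.bz, c_um=round(g.c, 4), tau0=round(g.tau0, 6))
    coeffs = solve_slip_flow(vs, g, cfg.nmax)
    res = _boundary_residuals(coeffs, g)
    log("series", nmax=cfg.nmax, slip=cfg.slip, **res)

    zg = np.linspace(-0.98 * g.bz, 0.98 * g.bz, 81)
    rg = np.linspace(0.0, 0.98 * g.bx, 41)
    R, Z = np.meshgrid(rg, zg)
    keep = g.contains_rz(R / 0.98, Z / 0.98)
    r, z = R[keep], Z[keep]
    if cfg.solver in ("exact", "both"):
        u_r, u_z = velocity_rz(coeffs, r, z)
    else:
        lub = LubricationFlowField.for_spheroid(vs, g)
        u_r, u_z = lub.velocity_rz(np.minimum(r, g.radius_at(z) * (1 - 1e-9)), z)
    tau, zeta = to_spheroidal(r, z, g, rtol=1e-6)
    psi = streamfunction(coeffs, tau, zeta)
    _write_csv(
        pd.DataFrame({"r_um": r, "z_um": z, "u_r": u_r, "u_z": u_z, "psi": psi}),
        outdir / "field.csv",
    )
    (outdir / "coefficients.json").write_text(coeffs.to_json())
    summary = {
        "config": cfg.to_dict(),
        "vortices": count_vortices(coeffs, g),
        "boundary_residuals": res,
    }
    if cfg.solver == "both":
        err_uz, err_ur, fields = compare_to_exact(vs, g, coeffs=coeffs, return_fields=True)
        _write_csv(pd.DataFrame(fields), outdir / "error_field.csv")
        summary["lubrication_error"] = {"max_err_uz": err_uz, "max_err_ux": err_ur}
        log("lubrication", max_err_uz=round(err_uz, 5), max_err_ux=round(err_ur, 5))
    _write_json(summary, outdir / "summary.json")
    log("done", outdir=str(outdir))
    return summary


def _boundary_residuals(coeffs, g) -> dict:
    zeta = np.linspace(-0.99, 0.99, 99)
    psi_b = streamfunction(coeffs, np.full_like(zeta, g.tau0), zeta)
    from .stokes import velocity_spheroidal

    u_tau_b, _ = velocity_spheroidal(coeffs, np.full_like(zeta, g.tau0), zeta)
    return {
        "max_psi_boundary": float(np.max(np.abs(psi_b))),
        "max_u_tau_boundary": float(np.max(np.abs(u_tau_b))),
    }


def run_transport(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run a seeded transport ensemble and export the homogeneity curve.

    Writes ``homogeneity.csv`` (chi_um, phi_mean, phi_min, phi_max) and a
    JSON summary with chi_star and the normalized variance (and its excess
    over the minimum) at any chi values in ``cfg.eval_chi_um``.
    """
    outdir = Path(outdir or cfg.outdir) / "transport"
    log = _Log(outdir)
    g = make_geometry(cfg.bx_um, cfg.bz_um)
    vs = slip_profile(cfg.slip, g)
    if cfg.solver == "exact":
        flow = StokesFlowField(solve_slip_flow(vs, g, cfg.nmax))
    else:
        flow = LubricationFlowField.for_spheroid(vs, g)
    log("geometry", bx_um=g.bx, bz_um=g.bz, solver=cfg.solver, slip=cfg.slip)
    tc = TransportConfig(
        geometry=g,
        flow=flow,
        n_particles=cfg.n_particles,
        kernel_bandwidth=cfg.kernel_bandwidth_um,
        n_seeds=cfg.n_seeds,
        base_seed=cfg.base_seed,
        chi_grid=cfg.chi_grid(),
        dchi=cfg.dchi_um,
        measure=cfg.measure,
        n_strips=cfg.n_strips,
    )
    log("ensemble", n_seeds=cfg.n_seeds, n_particles=cfg.n_particles,
        measure=cfg.measure, base_seed=cfg.base_seed)
    curve = ensemble_homogeneity(tc)
    _write_csv(
        pd.DataFrame(
            {
                "chi_um": curve.chi_grid,
                "phi_mean": curve.phi_mean,
                "phi_min": curve.phi_min,
                "phi_max": curve.phi_max,
            }
        ),
        outdir / "homogeneity.csv",
    )
    summary = {
        "config": cfg.to_dict(),
        "chi_star_um": curve.chi_star,
        "R_um": cfg.kernel_bandwidth_um,
        "N": cfg.n_particles,
        "n_seeds": cfg.n_seeds,
        "base_seed": cfg.base_seed,
        "phi_at": {
            str(chi): {"value": curve.value_at(chi), "excess": curve.excess_at(chi)}
            for chi in cfg.eval_chi_um
        },
    }
    _write_json(summary, outdir / "summary.json")
    log("done", chi_star_um=round(curve.chi_star, 2), outdir=str(outdir))
    return summary


def run_reduced(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Evaluate the 1D reduced model: density snapshots and optimal chi."""
    outdir = Path(outdir or cfg.outdir) / "reduced"
    log = _Log(outdir)
    bz = cfg.bz_um
    Z0 = cfg.z0_frac
    Zg = np.linspace(-1.0, 1.0, 2001)
    frames = []
    for chi in cfg.snapshot_chi_um:
        n = density_exact(Zg, float(T_from_chi(chi, bz)), Z0=Z0)
        frames.append(pd.DataFrame({"chi_um": chi, "Z": Zg, "n": n}))
    _write_csv(pd.concat(frames, ignore_index=True), outdir / "snapshots.csv")
    chi_star = optimal_chi_1d(bz, Z0)
    summary = {
        "config": cfg.to_dict(),
        "chi_star_1d_um": chi_star,
        "Z0": Z0,
        "bz_um": bz,
    }
    _write_json(summary, outdir / "summary.json")
    log("done", chi_star_1d_um=round(chi_star, 2), outdir=str(outdir))
    return summary
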