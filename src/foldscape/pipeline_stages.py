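"""Pipeline stage registry: thin adapters from config dicts to library calls.

Each stage function takes (params, seed, outdir) and returns a FitReport;
simulate stages also write their generated traces under the output
directory so fit stages (and the user) can read them back.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import aggregation, fcs, md, synthetic, unfolding
from .constants import DEFAULT_ASPECT_RATIO, ROOM_TEMPERATURE, WATER_VISCOSITY


def _report(stage, params, residual_norm=None):
    from .io import FitReport

    return FitReport(
        stage=stage,
        parameters={k: {"value": v} for k, v in params.items()},
        residual_norm=residual_norm,
    )


def _noise(cfg: dict, seed: int) -> synthetic.NoiseSpec:
    sigma = float(cfg.get("sigma", 0.01))
    if sigma == 0:
        return synthetic.NoiseSpec(model="none", sigma=0.0, seed=seed)
    return synthetic.NoiseSpec(sigma=sigma, seed=seed)


def _log_grid(cfg: dict, lo=1e-6, hi=1.0, n=200) -> np.ndarray:
    return np.logspace(
        np.log10(float(cfg.get("lag_min", lo))),
        np.log10(float(cfg.get("lag_max", hi))),
        int(cfg.get("n_lags", n)),
    )


def simulate_fcs(cfg: dict, seed: int, outdir: Path):
    from .io import write_table

    species = [
        synthetic.SpeciesSpec(
            diffusion_time=float(s["diffusion_time"]),
            amplitude_fraction=float(s["amplitude_fraction"]),
            log_width=float(s.get("log_width", 0.0)),
        )
        for s in cfg["species"]
    ]
    curve = synthetic.gen_fcs_curve(
        species,
        n_avg=float(cfg.get("n_avg", 10.0)),
        aspect_ratio=float(cfg.get("aspect_ratio", DEFAULT_ASPECT_RATIO)),
        lag_grid=_log_grid(cfg),
        noise=_noise(cfg, seed),
    )
    out = outdir / cfg.get("out", "fcs_curve.tsv")
    write_table(out, {"lag_s": curve.lags, "g": curve.g}, curve.metadata)
    return _report("simulate_fcs", {"n_points": len(curve.lags)})


def calibrate(cfg: dict, seed: int, outdir: Path):
    from .io import read_table

    df, _ = read_table(
        outdir / cfg["input"], ["lag_s", "g"], monotone_columns=["lag_s"]
    )
    curve = fcs.CorrelationCurve(df["lag_s"].to_numpy(), df["g"].to_numpy())
    cal = fcs.calibrate(
        curve,
        d_ref=float(cfg.get("d_ref", 4.14e-10)),
        aspect_ratio=float(cfg.get("aspect_ratio", DEFAULT_ASPECT_RATIO)),
    )
    (outdir / cfg.get("out", "calibration.json")).write_text(
        json.dumps(cal.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return _report("calibrate", cal.to_dict())


def _load_calibration(path: Path) -> fcs.Calibration:
    return fcs.Calibration.from_dict(json.loads(Path(path).read_text()))


def fit_fcs(cfg: dict, seed: int, outdir: Path):
    from .io import read_table, write_table

    df, _ = read_table(
        outdir / cfg["input"], ["lag_s", "g"], monotone_columns=["lag_s"]
    )
    curve = fcs.CorrelationCurve(df["lag_s"].to_numpy(), df["g"].to_numpy())
    n_comp = int(cfg.get("components", 1))
    temperature = float(cfg.get("temperature", ROOM_TEMPERATURE))
    viscosity = float(cfg.get("viscosity", WATER_VISCOSITY))
    if cfg.get("calibration"):
        cal = _load_calibration(outdir / cfg["calibration"])
    else:
        cal = None
    if n_comp == 0:  # single-component 3D diffusion model
        aspect = cal.aspect_ratio if cal else float(
            cfg.get("aspect_ratio", DEFAULT_ASPECT_RATIO)
        )
        f = fcs.fit_single_3d(curve, aspect_ratio=aspect)
        params = {"n_avg": f.n_avg, "tau_d_s": f.tau_d}
        if cal is not None:
            d = fcs.diffusion_coefficient(f.tau_d, cal)
            params["diffusion_m2_s"] = d
            params["rh_m"] = fcs.stokes_einstein_rh(d, temperature, viscosity)
        return _report("fit_fcs", params, f.residual_norm)
    if cal is None:
        raise ValueError("GDM fits require a calibration")
    f = fcs.fit_gdm(curve, n_components=n_comp, calibration=cal)
    dist = fcs.rh_distribution(f, cal, temperature, viscosity)
    params = {}
    for i, (comp, mean_rh) in enumerate(zip(f.components, dist.mean_rh), start=1):
        params[f"component{i}_amplitude"] = comp.amplitude
        params[f"component{i}_tau_p_s"] = comp.tau_p
        params[f"component{i}_log_width"] = comp.log_width
        params[f"component{i}_mean_rh_m"] = mean_rh
    write_table(
        outdir / cfg.get("out", "rh_distribution.tsv"),
        {"rh_m": dist.rh_grid, "density": dist.density,
         "component": dist.component_index},
        {"stage": "fit_fcs", "components": n_comp},
    )
    return _report("fit_fcs", params, f.residual_norm)


def simulate_unfolding(cfg: dict, seed: int, outdir: Path):
    from .io import write_table

    truth = synthetic.TwoStateTruth(
        dg_h2o=float(cfg.get("dg_h2o", 3.02)),
        m_value=float(cfg.get("m_value", -0.736)),
        temperature=float(cfg.get("temperature", ROOM_TEMPERATURE)),
    )
    grid = np.linspace(0.0, float(cfg.get("c_max", 8.0)), int(cfg.get("n_points", 33)))
    series = synthetic.gen_chemical_unfolding(truth, grid, _noise(cfg, seed))
    out = outdir / cfg.get("out", "unfolding.tsv")
    write_table(out, {"denaturant_M": series.x, "theta_deg": series.theta},
                series.metadata)
    return _report("simulate_unfolding", {"n_points": len(grid)})


def fit_unfolding(cfg: dict, seed: int, outdir: Path):
    from .io import read_table

    df, meta = read_table(
        outdir / cfg["input"], ["denaturant_M", "theta_deg"],
        monotone_columns=["denaturant_M"],
    )
    f = unfolding.fit_two_state_chemical(
        df["denaturant_M"].to_numpy(),
        df["theta_deg"].to_numpy(),
        temperature=float(cfg.get("temperature", ROOM_TEMPERATURE)),
    )
    return _report(
        "fit_unfolding",
        {"dg_h2o_kcal_mol": f.dg_h2o, "m_value": f.m_value, "midpoint_M": f.midpoint},
        f.residual_norm,
    )


def simulate_dsc(cfg: dict, seed: int, outdir: Path):
    from .io import write_table

    truth = synthetic.DSCTruth(
        tm=float(cfg.get("tm", 329.35)),
        dh_vh=float(cfg.get("dh_vh", 120.0)),
        scale=float(cfg.get("scale", 1.0)),
    )
    grid = np.arange(
        float(cfg.get("t_min", 298.15)),
        float(cfg.get("t_max", 363.15)),
        float(cfg.get("t_step", 0.1)),
    )
    scan = synthetic.gen_dsc_scan(truth, grid, _noise(cfg, seed))
    write_table(
        outdir / cfg.get("out", "dsc.tsv"),
        {"temperature_K": scan.temperature, "excess_cp": scan.excess_cp},
        scan.metadata,
    )
    return _report("simulate_dsc", {"n_points": len(grid)})


def fit_dsc(cfg: dict, seed: int, outdir: Path):
    from .io import read_table

    df, _ = read_table(
        outdir / cfg["input"], ["temperature_K", "excess_cp"],
        monotone_columns=["temperature_K"],
    )
    scan = synthetic.DSCScan(df["temperature_K"].to_numpy(), df["excess_cp"].to_numpy())
    f = unfolding.fit_dsc(
        scan, reference_temperature=float(cfg.get("t_ref", ROOM_TEMPERATURE))
    )
    return _report(
        "fit_dsc",
        {
            "tm_K": f.tm,
            "dh_vh_kcal_mol": f.dh_vh,
            "ds_m_kcal_mol_K": f.ds_m,
            "dg_ref_kcal_mol": f.dg_ref,
            "scale": f.scale,
        },
        f.residual_norm,
    )


def simulate_tht(cfg: dict, seed: int, outdir: Path):
    from .io import write_table

    truth = synthetic.ThTTruth(
        f0=float(cfg.get("f0", 50.0)),
        amplitude=float(cfg.get("amplitude", 1000.0)),
        t50=float(cfg.get("t50", 10.0)),
        rate_k=float(cfg.get("rate_k", 0.5)),
    )
    grid = np.linspace(0.0, float(cfg.get("t_max", 40.0)), int(cfg.get("n_points", 81)))
    trace = synthetic.gen_tht_trace(truth, grid, _noise(cfg, seed))
    write_table(
        outdir / cfg.get("out", "tht.tsv"),
        {"time_h": trace.time, "fluorescence": trace.fluorescence},
        trace.condition,
    )
    return _report("simulate_tht", {"n_points": len(grid)})


def fit_tht(cfg: dict, seed: int, outdir: Path):
    from .io import read_table

    df, _ = read_table(
        outdir / cfg["input"], ["time_h", "fluorescence"], monotone_columns=["time_h"]
    )
    trace = aggregation.ThTTrace(df["time_h"].to_numpy(), df["fluorescence"].to_numpy())
    if cfg.get("normalize"):
        trace = aggregation.normalize_trace(trace, cfg["normalize"])
    f = aggregation.fit_sigmoid(trace)
    return _report(
        "fit_tht",
        {
            "f0": f.f0,
            "amplitude": f.amplitude,
            "t50_h": f.t50,
            "rate_k_per_h": f.rate_k,
            "lag_time_h": f.lag_time,
        },
        f.residual_norm,
    )


def simulate_trajectory(cfg: dict, seed: int, outdir: Path):
    from .io import write_xyz

    n_atoms = int(cfg.get("n_atoms", 20))
    n_frames = int(cfg.get("n_frames", 2000))
    rng = np.random.default_rng(seed)
    mean = rng.uniform(-10, 10, size=(n_atoms, 3))
    n_modes = int(cfg.get("n_modes", 2))
    modes = synthetic.random_internal_modes(mean, n_modes, seed=seed)
    amps = np.asarray(cfg.get("mode_amplitudes", [2.0, 1.0][:n_modes]), dtype=float)
    truth = synthetic.TrajectoryTruth(
        mean_structure=mean,
        mode_vectors=modes,
        mode_amplitudes=amps,
        n_frames=n_frames,
        basin_centers=cfg.get("basin_centers"),
        basin_weights=cfg.get("basin_weights"),
        seed=seed,
    )
    traj = synthetic.gen_trajectory(truth)
    write_xyz(outdir / cfg.get("out", "traj.xyz"), traj)
    return _report(
        "simulate_trajectory", {"n_frames": n_frames, "n_atoms": n_atoms}
    )


def md_pca(cfg: dict, seed: int, outdir: Path):
    from .io import read_xyz, write_table

    traj = read_xyz(outdir / cfg["input"])
    n = int(cfg.get("n_components", 10))
    res = md.pca(traj, n_components=min(n, 3 * traj.n_atoms))
    write_table(
        outdir / cfg.get("out", "projections.tsv"),
        {f"pc{i+1}": res.projections[:, i] for i in range(min(2, n))},
        {"stage": "md_pca", "eigenvalues": [float(v) for v in res.eigenvalues[:n]]},
    )
    return _report(
        "md_pca",
        {f"eigenvalue_{i+1}": float(v) for i, v in enumerate(res.eigenvalues[:3])},
    )


def md_fel(cfg: dict, seed: int, outdir: Path):
    from .io import read_table, write_table

    df, _ = read_table(outdir / cfg["input"], ["pc1", "pc2"])
    grid = md.fel(
        df[["pc1", "pc2"]].to_numpy(),
        temperature=float(cfg.get("temperature", ROOM_TEMPERATURE)),
        bins=int(cfg.get("bins", 50)),
        units=cfg.get("units", "kT"),
    )
    centers1 = 0.5 * (grid.pc1_edges[:-1] + grid.pc1_edges[1:])
    centers2 = 0.5 * (grid.pc2_edges[:-1] + grid.pc2_edges[1:])
    i, j = np.meshgrid(np.arange(len(centers1)), np.arange(len(centers2)), indexing="ij")
    write_table(
        outdir / cfg.get("out", "fel.tsv"),
        {
            "pc1": centers1[i.ravel()],
            "pc2": centers2[j.ravel()],
            "free_energy": grid.free_energy.ravel(),
        },
        {"stage": "md_fel", "units": grid.units, "temperature_K": grid.temperature},
    )
    occ = grid.free_energy[~grid.mask]
    return _report(
        "md_fel",
        {"occupied_bins": int(occ.size), "max_free_energy": float(occ.max())},
    )


REGISTRY = {
    "simulate_fcs": simulate_fcs,
    "calibrate": calibrate,
    "fit_fcs": fit_fcs,
    "simulate_unfolding": simulate_unfolding,
    "fit_unfolding": fit_unfolding,
    "simulate_dsc": simulate_dsc,
    "fit_dsc": fit_dsc,
    "simulate_tht": simulate_tht,
    "fit_tht": fit_tht,
    "simulate_trajectory": simulate_trajectory,
    "md_pca": md_pca,
    "md_fel": md_fel,
}
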