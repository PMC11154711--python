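"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator evaluates the same closed-form model its fitting counterpart
assumes — single/multi-species FCS correlation decays, two-state chemical
denaturation transitions with linear baselines, van't Hoff excess-heat-capacity
peaks, four-parameter logistic ThT time courses, and Gaussian-mode Calpha
trajectories — and optionally adds multiplicative Gaussian noise.  Identical
seeds give bit-identical output, so every fitting stage is testable by
parameter recovery without any instrument data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import R_KCAL, ROOM_TEMPERATURE
from .fcs import CorrelationCurve, g_gdm, g_single, GDMComponent

__all__ = [
    "NoiseSpec",
    "SpeciesSpec",
    "TwoStateTruth",
    "DSCTruth",
    "ThTTruth",
    "TrajectoryTruth",
    "gen_fcs_curve",
    "gen_chemical_unfolding",
    "gen_dsc_scan",
    "gen_tht_trace",
    "gen_trajectory",
    "random_internal_modes",
    "project_internal",
    "rigid_body_basis",
    "two_state_fraction_unfolded",
    "excess_cp",
    "logistic4",
]


@dataclass
class NoiseSpec:
    """Noise model applied to a generated trace.

    Multiplicative Gaussian (``y * (1 + sigma*eps)``) is the default family:
    FCS and plate-reader noise scales with signal amplitude.
    """

    model: str = "multiplicative_gaussian"
    sigma: float = 0.01  # relative standard deviation
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("none", "multiplicative_gaussian"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, y: np.ndarray) -> np.ndarray:
        if self.model == "none" or self.sigma == 0:
            return np.array(y, dtype=float, copy=True)
        rng = np.random.default_rng(self.seed)
        return y * (1.0 + self.sigma * rng.standard_normal(np.shape(y)))


NO_NOISE = NoiseSpec(model="none", sigma=0.0)


@dataclass
class SpeciesSpec:
    """One diffusing species: diffusion time, amplitude fraction, ln-width."""

    diffusion_time: float  # seconds
    amplitude_fraction: float  # in (0, 1]
    log_width: float = 0.0  # b >= 0; 0 means monodisperse

    def __post_init__(self):
        if self.diffusion_time <= 0:
            raise ValueError("diffusion_time must be strictly positive")
        if not (0 < self.amplitude_fraction <= 1):
            raise ValueError("amplitude_fraction must be in (0, 1]")
        if self.log_width < 0:
            raise ValueError("log_width must be >= 0")


def gen_fcs_curve(
    species: list[SpeciesSpec],
    n_avg: float,
    aspect_ratio: float,
    lag_grid: np.ndarray,
    noise: NoiseSpec = NO_NOISE,
) -> CorrelationCurve:
    """Generate an autocorrelation curve for a mixture of diffusing species.

    Monodisperse species (log_width 0) contribute the single-component
    closed-form shape; polydisperse species contribute the Gaussian
    Distribution Model grid sum.  G(0+) = 1/n_avg since amplitude fractions
    sum to one.
    """
    if not species:
        raise ValueError("species list must not be empty")
    if n_avg <= 0:
        raise ValueError("n_avg must be positive")
    if aspect_ratio <= 0:
        raise ValueError("aspect_ratio must be positive")
    lag_grid = np.asarray(lag_grid, dtype=float)
    if np.any(lag_grid <= 0) or np.any(np.diff(lag_grid) <= 0):
        raise ValueError("lag grid must be strictly increasing and positive")
    total = sum(s.amplitude_fraction for s in species)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"amplitude fractions must sum to 1 (got {total})")

    g = np.zeros_like(lag_grid)
    for s in species:
        if s.log_width == 0:
            g += s.amplitude_fraction * g_single(
                lag_grid, 1.0, s.diffusion_time, aspect_ratio
            )
        else:
            g += g_gdm(
                lag_grid,
                [GDMComponent(s.amplitude_fraction, s.diffusion_time, s.log_width)],
                aspect_ratio,
            )
    g = g / n_avg
    meta = {
        "generator": "gen_fcs_curve",
        "n_avg": n_avg,
        "aspect_ratio": aspect_ratio,
        "species": [
            {
                "diffusion_time_s": s.diffusion_time,
                "amplitude_fraction": s.amplitude_fraction,
                "log_width": s.log_width,
            }
            for s in species
        ],
        "noise": {"model": noise.model, "sigma": noise.sigma, "seed": noise.seed},
    }
    # known error model: multiplicative noise has per-point sd sigma * G
    weights = None
    if noise.model == "multiplicative_gaussian" and noise.sigma > 0:
        weights = noise.sigma * g
    return CorrelationCurve(
        lags=lag_grid, g=noise.apply(g), weights=weights, metadata=meta
    )


# --------------------------------------------------------------------------
# chemical (denaturant) unfolding


@dataclass
class TwoStateTruth:
    """Ground truth for a two-state chemical denaturation transition.

    dG(C) = dg_h2o + m_value * C (kcal/mol, m negative by convention), and
    the unfolded fraction follows fU = K/(1+K) with K = exp(-dG/RT).
    Baselines are (intercept, slope) pairs in signal units.
    """

    dg_h2o: float  # kcal/mol
    m_value: float  # kcal/(mol M), negative
    native_baseline: tuple[float, float] = (-0.02, 0.0)
    unfolded_baseline: tuple[float, float] = (-0.004, 0.0)
    temperature: float = ROOM_TEMPERATURE  # K

    def __post_init__(self):
        if self.m_value == 0:
            raise ValueError("m_value = 0 gives no transition")

    @property
    def midpoint(self) -> float:
        return -self.dg_h2o / self.m_value


def two_state_fraction_unfolded(
    dg_h2o: float, m_value: float, conc, temperature: float = ROOM_TEMPERATURE
):
    """Unfolded fraction of a two-state protein at denaturant concentration C."""
    dg = dg_h2o + m_value * np.asarray(conc, dtype=float)
    k = np.exp(-dg / (R_KCAL * temperature))
    return k / (1.0 + k)


def gen_chemical_unfolding(
    truth: TwoStateTruth,
    denaturant_grid: np.ndarray,
    noise: NoiseSpec = NO_NOISE,
    concentration: float = 0.15,
    path_length: float = 0.1,
    molar_mass: float = 31280.0,
    n_residues: int = 271,
):
    """Generate an ellipticity-vs-denaturant series from two-state truth.

    The signal is the baseline mixture weighted by the two-state folded and
    unfolded fractions.  Sample metadata defaults (concentration in mg/ml,
    path in cm, molar mass, residue count) describe the 271-residue
    deubiquitinase used throughout the synthetic studies.
    """
    from .unfolding import EllipticitySeries

    c = np.asarray(denaturant_grid, dtype=float)
    if np.any(c < 0) or np.any(np.diff(c) <= 0):
        raise ValueError("denaturant grid must be non-negative and increasing")
    fu = two_state_fraction_unfolded(truth.dg_h2o, truth.m_value, c, truth.temperature)
    y_n = truth.native_baseline[0] + truth.native_baseline[1] * c
    y_u = truth.unfolded_baseline[0] + truth.unfolded_baseline[1] * c
    theta = y_n * (1.0 - fu) + y_u * fu
    return EllipticitySeries(
        x=c,
        theta=noise.apply(theta),
        concentration=concentration,
        path_length=path_length,
        molar_mass=molar_mass,
        n_residues=n_residues,
        x_kind="denaturant_M",
        metadata={
            "generator": "gen_chemical_unfolding",
            "dg_h2o_kcal_mol": truth.dg_h2o,
            "m_value_kcal_mol_M": truth.m_value,
            "temperature_K": truth.temperature,
            "noise": {"model": noise.model, "sigma": noise.sigma, "seed": noise.seed},
        },
    )


# --------------------------------------------------------------------------
# DSC


@dataclass
class DSCTruth:
    """Ground truth for a two-state (scaled) van't Hoff DSC endotherm."""

    tm: float  # kelvin
    dh_vh: float  # kcal/mol
    scale: float = 1.0
    baseline: tuple = (0.0,)  # polynomial coefficients, ascending order

    def __post_init__(self):
        if self.tm <= 0:
            raise ValueError("tm must be positive")
        if self.dh_vh <= 0:
            raise ValueError("dh_vh must be positive")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")


def excess_cp(temperature, tm: float, dh_vh: float, scale: float = 1.0):
    """Two-state van't Hoff excess heat capacity, kcal/(mol K).

    Cp(T) = scale * dH^2/(R T^2) * K/(1+K)^2 with
    K = exp[-(dH/R) (1/T - 1/Tm)].
    """
    t = np.asarray(temperature, dtype=float)
    k = np.exp(-(dh_vh / R_KCAL) * (1.0 / t - 1.0 / tm))
    return scale * dh_vh**2 / (R_KCAL * t**2) * k / (1.0 + k) ** 2


@dataclass
class DSCScan:
    """An excess-heat-capacity scan vs temperature."""

    temperature: np.ndarray  # kelvin, increasing
    excess_cp: np.ndarray  # kcal/(mol K)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.excess_cp = np.asarray(self.excess_cp, dtype=float)
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")


def gen_dsc_scan(
    truth: DSCTruth,
    temperature_grid: np.ndarray,
    noise: NoiseSpec = NO_NOISE,
) -> DSCScan:
    """Generate a DSC excess-heat-capacity scan from van't Hoff truth."""
    t = np.asarray(temperature_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    if not (t[0] < truth.tm < t[-1]):
        warnings.warn(
            "temperature grid does not bracket Tm; the fit will be ill-posed",
            RuntimeWarning,
        )
    cp = excess_cp(t, truth.tm, truth.dh_vh, truth.scale) + np.polyval(
        truth.baseline[::-1], t
    )
    return DSCScan(
        temperature=t,
        excess_cp=noise.apply(cp),
        metadata={
            "generator": "gen_dsc_scan",
            "tm_K": truth.tm,
            "dh_vh_kcal_mol": truth.dh_vh,
            "scale": truth.scale,
            "baseline": list(truth.baseline),
            "noise": {"model": noise.model, "sigma": noise.sigma, "seed": noise.seed},
        },
    )


# --------------------------------------------------------------------------
# ThT kinetics


@dataclass
class ThTTruth:
    """Ground truth of a sigmoidal ThT aggregation time course."""

    f0: float  # baseline fluorescence
    amplitude: float  # plateau - baseline
    t50: float  # hours
    rate_k: float  # 1/hours

    def __post_init__(self):
        if self.rate_k <= 0:
            raise ValueError("rate_k must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def logistic4(t, f0: float, amplitude: float, t50: float, rate_k: float):
    """Four-parameter logistic: F(t) = f0 + A / (1 + exp(-k (t - t50)))."""
    t = np.asarray(t, dtype=float)
    return f0 + amplitude / (1.0 + np.exp(-rate_k * (t - t50)))


def gen_tht_trace(
    truth: ThTTruth,
    time_grid: np.ndarray,
    noise: NoiseSpec = NO_NOISE,
    replicate_id: str | None = None,
    condition: dict | None = None,
):
    """Generate a ThT fluorescence time course from 4-parameter logistic truth."""
    from .aggregation import ThTTrace

    t = np.asarray(time_grid, dtype=float)
    if t[0] < 0 or np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be increasing from >= 0")
    f = logistic4(t, truth.f0, truth.amplitude, truth.t50, truth.rate_k)
    cond = dict(condition or {})
    cond.update(
        generator="gen_tht_trace",
        f0=truth.f0,
        amplitude=truth.amplitude,
        t50_h=truth.t50,
        rate_k_per_h=truth.rate_k,
        noise={"model": noise.model, "sigma": noise.sigma, "seed": noise.seed},
    )
    return ThTTrace(
        time=t, fluorescence=noise.apply(f), replicate_id=replicate_id, condition=cond
    )


# --------------------------------------------------------------------------
# trajectories


@dataclass
class TrajectoryTruth:
    """Ground truth for a Gaussian-mode (optionally multi-basin) trajectory.

    Frames are mean + sum_k (amplitude_k z_k + offset_k) mode_k with z
    standard normal; offsets come from the frame's basin (sampled with
    ``basin_weights``), producing multi-basin sampling along the modes.
    """

    mean_structure: np.ndarray  # (N, 3) angstrom
    mode_vectors: np.ndarray  # (n_modes, 3N), orthonormal rows
    mode_amplitudes: np.ndarray  # (n_modes,) angstrom
    n_frames: int
    basin_centers: np.ndarray | None = None  # (n_basins, n_modes) projections
    basin_weights: np.ndarray | None = None  # (n_basins,) populations
    seed: int = 0

    def __post_init__(self):
        self.mean_structure = np.asarray(self.mean_structure, dtype=float)
        self.mode_vectors = np.atleast_2d(np.asarray(self.mode_vectors, dtype=float))
        self.mode_amplitudes = np.atleast_1d(
            np.asarray(self.mode_amplitudes, dtype=float)
        )
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        n3 = self.mean_structure.size
        if self.mode_vectors.shape[1] != n3:
            raise ValueError("mode vectors must have length 3N")
        gram = self.mode_vectors @ self.mode_vectors.T
        if not np.allclose(gram, np.eye(len(self.mode_vectors)), atol=1e-8):
            raise ValueError("mode vectors must be mutually orthonormal")
        if self.basin_centers is not None:
            self.basin_centers = np.atleast_2d(
                np.asarray(self.basin_centers, dtype=float)
            )
            if self.basin_centers.shape[1] != len(self.mode_vectors):
                raise ValueError("basin centers must give one offset per mode")
            if self.basin_weights is not None:
                self.basin_weights = np.asarray(self.basin_weights, dtype=float)
                if len(self.basin_weights) != len(self.basin_centers):
                    raise ValueError("one weight per basin required")


def rigid_body_basis(mean_structure: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6 x 3N) of rigid translations and rotations.

    Collective modes sampled orthogonal to this subspace represent internal
    motion only, so least-squares superposition leaves them intact.
    """
    x = np.asarray(mean_structure, dtype=float)
    n = x.shape[0]
    centered = x - x.mean(axis=0)
    basis = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        basis.append(t.reshape(-1))
    for axis in np.eye(3):
        basis.append(np.cross(axis, centered).reshape(-1))
    q, _ = np.linalg.qr(np.array(basis).T)
    return q.T


def random_internal_modes(
    mean_structure: np.ndarray, n_modes: int, seed: int = 0
) -> np.ndarray:
    """Random orthonormal internal (non-rigid-body) modes, (n_modes x 3N)."""
    x = np.asarray(mean_structure, dtype=float)
    rng = np.random.default_rng(seed)
    rigid = rigid_body_basis(x)
    raw = rng.standard_normal((3 * x.shape[0], n_modes))
    raw = raw - rigid.T @ (rigid @ raw)
    q, _ = np.linalg.qr(raw)
    return q.T


def project_internal(
    mode_vectors: np.ndarray, mean_structure: np.ndarray
) -> np.ndarray:
    """Remove rigid-body components from mode vectors and re-orthonormalize."""
    rigid = rigid_body_basis(mean_structure)
    m = np.atleast_2d(np.asarray(mode_vectors, dtype=float)).T
    m = m - rigid.T @ (rigid @ m)
    q, _ = np.linalg.qr(m)
    return q.T


def gen_trajectory(truth: TrajectoryTruth):
    """Sample a synthetic Calpha trajectory from Gaussian-mode truth."""
    from .md import Trajectory

    rng = np.random.default_rng(truth.seed)
    n_modes = len(truth.mode_vectors)
    z = rng.standard_normal((truth.n_frames, n_modes))
    proj = truth.mode_amplitudes[None, :] * z
    if truth.basin_centers is not None:
        w = truth.basin_weights
        if w is None:
            w = np.full(len(truth.basin_centers), 1.0 / len(truth.basin_centers))
        else:
            w = w / w.sum()
        which = rng.choice(len(truth.basin_centers), size=truth.n_frames, p=w)
        proj = proj + truth.basin_centers[which]
    flat = truth.mean_structure.reshape(-1)[None, :] + proj @ truth.mode_vectors
    coords = flat.reshape(truth.n_frames, -1, 3)
    return Trajectory(coordinates=coords)
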