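"""Fluorescence correlation spectroscopy: diffusion models, calibration and sizing.

The single-component model for translational 3D diffusion through a
Gaussian-shaped confocal volume is

    G(tau) = (1/<N>) * (1 + tau/tau_D)^-1 * (1 + (r/l)^2 * tau/tau_D)^-1/2

with ``<N>`` the mean occupancy of the confocal volume, ``tau_D`` the
diffusion time, and ``l/r`` the aspect ratio of the observation volume.
Polydisperse samples are described by the Gaussian Distribution Model (GDM):
each component is a Gaussian distribution of amplitudes in ln(tau_D),

    a_i(tau_Di) = A_i * exp(-((ln tau_Di - ln tau_p)/b)^2),

summed over a log-spaced grid of diffusion times.  Diffusion times convert
to diffusion coefficients through the calibrated lateral radius
(D = r^2 / 4 tau_D) and to hydrodynamic radii through the Stokes–Einstein
relation (Rh = kT / 6 pi eta D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import (
    DEFAULT_ASPECT_RATIO,
    KB,
    ROOM_TEMPERATURE,
    WATER_VISCOSITY,
)

__all__ = [
    "CorrelationCurve",
    "Calibration",
    "DiffusionFit",
    "GDMComponent",
    "GDMFit",
    "RhDistribution",
    "g_single",
    "g_gdm",
    "gdm_component_grid",
    "fit_single_3d",
    "calibrate",
    "diffusion_coefficient",
    "stokes_einstein_rh",
    "stokes_einstein_d",
    "rh_to_tau_d",
    "fit_gdm",
    "rh_distribution",
    "oligomer_units",
]

GDM_GRID_POINTS = 60
GDM_GRID_SPAN = 3.0  # half-width of the tau_D grid, in units of the ln-width b
GDM_MIN_LOG_WIDTH = 0.01
DEGENERATE_LN_SEPARATION = 0.5


@dataclass
class CorrelationCurve:
    """An autocorrelation trace G(tau) on a strictly increasing lag grid."""

    lags: np.ndarray  # seconds
    g: np.ndarray
    weights: np.ndarray | None = None  # per-point standard errors
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.lags.ndim != 1 or self.lags.shape != self.g.shape:
            raise ValueError("lags and g must be 1-D arrays of equal length")
        if np.any(self.lags <= 0):
            raise ValueError("lag times must be strictly positive")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("correlation amplitudes must be finite")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.g.shape or np.any(self.weights <= 0):
                raise ValueError("weights must be positive, one per point")

    @property
    def lag_decades(self) -> float:
        return float(np.log10(self.lags[-1] / self.lags[0]))


@dataclass
class Calibration:
    """Confocal-volume geometry derived from a reference dye of known D."""

    lateral_radius: float  # meters (r)
    aspect_ratio: float  # l/r
    effective_volume: float  # liters
    reference_diffusion_coefficient: float  # m^2/s
    reference_tau_d: float  # seconds

    def __post_init__(self):
        for name in (
            "lateral_radius",
            "aspect_ratio",
            "effective_volume",
            "reference_diffusion_coefficient",
            "reference_tau_d",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return {
            "lateral_radius_m": self.lateral_radius,
            "aspect_ratio": self.aspect_ratio,
            "effective_volume_l": self.effective_volume,
            "reference_diffusion_coefficient_m2_s": self.reference_diffusion_coefficient,
            "reference_tau_d_s": self.reference_tau_d,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(
            lateral_radius=d["lateral_radius_m"],
            aspect_ratio=d["aspect_ratio"],
            effective_volume=d["effective_volume_l"],
            reference_diffusion_coefficient=d["reference_diffusion_coefficient_m2_s"],
            reference_tau_d=d["reference_tau_d_s"],
        )


@dataclass
class DiffusionFit:
    """Single-component 3D diffusion fit: mean occupancy and diffusion time."""

    n_avg: float
    tau_d: float  # seconds
    aspect_ratio: float
    aspect_fitted: bool
    residual_norm: float
    covariance: np.ndarray | None = None

    def __post_init__(self):
        if self.n_avg <= 0 or self.tau_d <= 0:
            raise ValueError("n_avg and tau_d must be positive")


@dataclass
class GDMComponent:
    amplitude: float  # A_i, total amplitude of the component
    tau_p: float  # seconds, peak of the Gaussian in ln tau_D
    log_width: float  # b, dimensionless width in ln tau_D


@dataclass
class GDMFit:
    components: list[GDMComponent]
    aspect_ratio: float
    residual_norm: float
    degenerate: bool = False
    covariance: np.ndarray | None = None


@dataclass
class RhDistribution:
    """Amplitude-weighted hydrodynamic-radius distribution from a GDM fit."""

    rh_grid: np.ndarray  # meters, per grid point (component blocks concatenated)
    density: np.ndarray  # normalized to sum 1
    mean_rh: list[float]  # per component, amplitude-weighted arithmetic mean
    component_index: np.ndarray  # which component each grid point belongs to

    def __post_init__(self):
        total = float(np.sum(self.density))
        if abs(total - 1.0) > 1e-9:
            raise ValueError("density must sum to 1")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")


# --------------------------------------------------------------------------
# model evaluation


def _shape(lags: np.ndarray, tau_d: float, aspect_ratio: float) -> np.ndarray:
    """Unit-amplitude single-species correlation shape (value 1 at tau -> 0)."""
    x = lags / tau_d
    return 1.0 / (1.0 + x) / np.sqrt(1.0 + x / aspect_ratio**2)


def g_single(
    lags: np.ndarray, n_avg: float, tau_d: float, aspect_ratio: float
) -> np.ndarray:
    """Single-component 3D diffusion autocorrelation, amplitude 1/<N> at tau=0."""
    if n_avg <= 0 or tau_d <= 0 or aspect_ratio <= 0:
        raise ValueError("n_avg, tau_d and aspect_ratio must be positive")
    return _shape(np.asarray(lags, dtype=float), tau_d, aspect_ratio) / n_avg


def gdm_component_grid(
    tau_p: float,
    log_width: float,
    n_points: int = GDM_GRID_POINTS,
    span: float = GDM_GRID_SPAN,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced tau_D grid and normalized Gaussian amplitude weights.

    The grid spans ``tau_p * exp(±span*b)``; weights follow
    exp(-((ln tau - ln tau_p)/b)^2) and are normalized to sum to 1, so the
    component's total amplitude multiplies the weights unchanged.  A width at
    or below ``GDM_MIN_LOG_WIDTH`` collapses to a single grid point (delta
    limit).
    """
    if tau_p <= 0:
        raise ValueError("tau_p must be positive")
    if log_width < 0:
        raise ValueError("log_width must be non-negative")
    if log_width <= GDM_MIN_LOG_WIDTH:
        return np.array([tau_p]), np.array([1.0])
    ln_tau = np.log(tau_p) + np.linspace(-span * log_width, span * log_width, n_points)
    w = np.exp(-(((ln_tau - np.log(tau_p)) / log_width) ** 2))
    return np.exp(ln_tau), w / w.sum()


def g_gdm(
    lags: np.ndarray,
    components: list[GDMComponent],
    aspect_ratio: float,
) -> np.ndarray:
    """GDM correlation curve: sum of Gaussian-in-ln(tau_D) component blocks."""
    lags = np.asarray(lags, dtype=float)
    out = np.zeros_like(lags)
    for comp in components:
        taus, w = gdm_component_grid(comp.tau_p, comp.log_width)
        # shape matrix (grid x lags) collapsed with the normalized weights
        x = lags[None, :] / taus[:, None]
        shapes = 1.0 / (1.0 + x) / np.sqrt(1.0 + x / aspect_ratio**2)
        out += comp.amplitude * (w[:, None] * shapes).sum(axis=0)
    return out


# --------------------------------------------------------------------------
# fitting


def _residuals(model: np.ndarray, curve: CorrelationCurve) -> np.ndarray:
    r = model - curve.g
    if curve.weights is not None:
        r = r / curve.weights
    return r


def fit_single_3d(
    curve: CorrelationCurve,
    aspect_ratio: float = DEFAULT_ASPECT_RATIO,
    fit_aspect: bool = False,
) -> DiffusionFit:
    """Weighted least-squares fit of the single-component 3D diffusion model.

    Requires at least 8 points spanning two decades of lag.  The aspect
    ratio is fixed unless ``fit_aspect`` is set.
    """
    if curve.lags.size < 8:
        raise ValueError("need at least 8 data points")
    if curve.lag_decades < 2.0:
        raise ValueError("lag grid must span at least 2 decades")

    g0 = max(float(curve.g[0]), 1e-12)
    n0 = 1.0 / g0
    half = g0 / 2.0
    below = np.nonzero(curve.g <= half)[0]
    tau0 = float(curve.lags[below[0]]) if below.size else float(curve.lags[-1] / 10)

    if fit_aspect:
        x0 = np.log([n0, tau0, aspect_ratio])

        def resid(p):
            n, tau, ar = np.exp(p)
            return _residuals(g_single(curve.lags, n, tau, ar), curve)
    else:
        x0 = np.log([n0, tau0])

        def resid(p):
            n, tau = np.exp(p)
            return _residuals(g_single(curve.lags, n, tau, aspect_ratio), curve)

    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise RuntimeError(f"single-component fit failed: {sol.message}")
    p = np.exp(sol.x)
    cov = _covariance_from_jacobian(sol, p)
    return DiffusionFit(
        n_avg=float(p[0]),
        tau_d=float(p[1]),
        aspect_ratio=float(p[2]) if fit_aspect else aspect_ratio,
        aspect_fitted=fit_aspect,
        residual_norm=float(np.linalg.norm(sol.fun)),
        covariance=cov,
    )


def _covariance_from_jacobian(sol, p_linear: np.ndarray) -> np.ndarray | None:
    """Gauss-Newton covariance in the linear parameters from a log-space fit."""
    m, n = sol.jac.shape
    if m <= n:
        return None
    try:
        jtj_inv = np.linalg.inv(sol.jac.T @ sol.jac)
    except np.linalg.LinAlgError:
        return None
    s2 = 2.0 * sol.cost / (m - n)
    cov_log = s2 * jtj_inv
    # delta method: d(exp x) = exp(x) dx
    scale = np.outer(p_linear, p_linear)
    return cov_log * scale


def calibrate(
    reference_curve: CorrelationCurve,
    d_ref: float,
    aspect_ratio: float = DEFAULT_ASPECT_RATIO,
) -> Calibration:
    """Calibrate the confocal volume from a reference dye of known D.

    Fits the reference curve with the single-component model, then
    ``r = sqrt(4 * D_ref * tau_D)`` and ``V_eff = pi^{3/2} r^2 l`` with
    ``l = aspect_ratio * r``.
    """
    if d_ref <= 0:
        raise ValueError("reference diffusion coefficient must be positive")
    fit = fit_single_3d(reference_curve, aspect_ratio=aspect_ratio)
    r = float(np.sqrt(4.0 * d_ref * fit.tau_d))
    veff_m3 = np.pi**1.5 * r**2 * (aspect_ratio * r)
    return Calibration(
        lateral_radius=r,
        aspect_ratio=aspect_ratio,
        effective_volume=veff_m3 * 1e3,  # m^3 -> liters
        reference_diffusion_coefficient=d_ref,
        reference_tau_d=fit.tau_d,
    )


def diffusion_coefficient(tau_d: float, calibration: Calibration) -> float:
    """Translational diffusion coefficient D = r^2 / (4 tau_D), m^2/s."""
    if np.any(np.asarray(tau_d) <= 0):
        raise ValueError("tau_d must be positive")
    return calibration.lateral_radius**2 / (4.0 * tau_d)


def stokes_einstein_rh(
    d: float,
    temperature: float = ROOM_TEMPERATURE,
    viscosity: float = WATER_VISCOSITY,
) -> float:
    """Hydrodynamic radius Rh = kT / (6 pi eta D), meters."""
    if np.any(np.asarray(d) <= 0) or temperature <= 0 or viscosity <= 0:
        raise ValueError("all arguments must be positive")
    return KB * temperature / (6.0 * np.pi * viscosity * d)


def stokes_einstein_d(
    rh: float,
    temperature: float = ROOM_TEMPERATURE,
    viscosity: float = WATER_VISCOSITY,
) -> float:
    """Inverse Stokes-Einstein: D for a particle of hydrodynamic radius rh."""
    if np.any(np.asarray(rh) <= 0):
        raise ValueError("rh must be positive")
    return KB * temperature / (6.0 * np.pi * viscosity * rh)


def rh_to_tau_d(
    rh: float,
    calibration: Calibration,
    temperature: float = ROOM_TEMPERATURE,
    viscosity: float = WATER_VISCOSITY,
) -> float:
    """Diffusion time of a particle of radius rh under a given calibration."""
    d = stokes_einstein_d(rh, temperature, viscosity)
    return calibration.lateral_radius**2 / (4.0 * d)


def _gdm_pack(components: list[GDMComponent]) -> np.ndarray:
    return np.array(
        [v for c in components for v in (np.log(c.amplitude), np.log(c.tau_p), c.log_width)]
    )


def _gdm_unpack(p: np.ndarray) -> list[GDMComponent]:
    comps = []
    for i in range(0, len(p), 3):
        comps.append(
            GDMComponent(
                amplitude=float(np.exp(p[i])),
                tau_p=float(np.exp(p[i + 1])),
                log_width=float(p[i + 2]),
            )
        )
    return comps


def fit_gdm(
    curve: CorrelationCurve,
    n_components: int,
    calibration: Calibration | None = None,
    aspect_ratio: float | None = None,
    shared_width: bool = True,
) -> GDMFit:
    """Fit a 1- or 2-component Gaussian Distribution Model to a curve.

    The aspect ratio is taken from the calibration (standard practice: fixed
    during sample fits).  With ``shared_width`` (the default) the ln-width b
    is common to both components: in dual fits the minority slow component's
    width is barely constrained by the data on its own, and tying it to the
    majority component suppresses a width-position degeneracy; set
    ``shared_width=False`` for fully independent components.  Dual fits use
    a 3-point multi-start in the peak positions to avoid the local-minimum
    trap, and the result is flagged degenerate when the two peaks collapse
    within 0.5 in ln(tau).
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if aspect_ratio is None:
        if calibration is None:
            raise ValueError("provide a calibration or an explicit aspect ratio")
        aspect_ratio = calibration.aspect_ratio
    if n_components == 2 and curve.lag_decades < 3.0:
        raise ValueError("dual-component fits need >= 3 decades of lag")

    g0 = max(float(np.max(curve.g[:3])), 1e-12)
    half = g0 / 2.0
    below = np.nonzero(curve.g <= half)[0]
    tau_half = float(curve.lags[below[0]]) if below.size else float(
        np.sqrt(curve.lags[0] * curve.lags[-1])
    )

    tied = shared_width and n_components == 2

    def unpack(p):
        if tied:
            # (lnA1, lntau1, lnA2, lntau2, b)
            full = np.array([p[0], p[1], p[4], p[2], p[3], p[4]])
            return _gdm_unpack(full)
        return _gdm_unpack(p)

    def resid(p):
        return _residuals(g_gdm(curve.lags, unpack(p), aspect_ratio), curve)

    lo = np.log(curve.lags[0] / 10.0)
    hi = np.log(curve.lags[-1] * 10.0)
    if n_components == 1:
        starts = [
            [GDMComponent(g0, tau_half * s, 0.3)] for s in (0.5, 1.0, 2.0)
        ]
    else:
        starts = [
            [
                GDMComponent(g0 * 0.5, tau_half / 1.5, 0.3),
                GDMComponent(g0 * 0.5, tau_half * s, 0.3),
            ]
            for s in (3.0, 10.0, 30.0)
        ]
    if tied:
        bounds_lo = np.array([np.log(g0 * 1e-4), lo] * 2 + [0.0])
        bounds_hi = np.array([np.log(g0 * 1e2), hi] * 2 + [2.0])

        def pack(comps):
            return np.array(
                [
                    np.log(comps[0].amplitude),
                    np.log(comps[0].tau_p),
                    np.log(comps[1].amplitude),
                    np.log(comps[1].tau_p),
                    comps[0].log_width,
                ]
            )
    else:
        bounds_lo = np.tile([np.log(g0 * 1e-4), lo, 0.0], n_components)
        bounds_hi = np.tile([np.log(g0 * 1e2), hi, 2.0], n_components)
        pack = _gdm_pack

    best = None
    for comps0 in starts:
        x0 = np.clip(pack(comps0), bounds_lo + 1e-9, bounds_hi - 1e-9)
        sol = least_squares(
            resid, x0, bounds=(bounds_lo, bounds_hi), xtol=1e-12, ftol=1e-12
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError("GDM fit did not converge")

    comps = sorted(unpack(best.x), key=lambda c: c.tau_p)
    degenerate = False
    if n_components == 2:
        sep = abs(np.log(comps[1].tau_p) - np.log(comps[0].tau_p))
        if sep < DEGENERATE_LN_SEPARATION:
            degenerate = True
            warnings.warn(
                "dual-GDM components collapsed onto one peak "
                f"(ln-tau separation {sep:.3f} < {DEGENERATE_LN_SEPARATION})",
                RuntimeWarning,
            )
    return GDMFit(
        components=comps,
        aspect_ratio=aspect_ratio,
        residual_norm=float(np.linalg.norm(best.fun)),
        degenerate=degenerate,
    )


def rh_distribution(
    fit: GDMFit,
    calibration: Calibration,
    temperature: float = ROOM_TEMPERATURE,
    viscosity: float = WATER_VISCOSITY,
) -> RhDistribution:
    """Map a GDM fit's tau_D grid to a hydrodynamic-radius distribution.

    Every grid diffusion time converts through D = r^2/4tau and the
    Stokes-Einstein relation; the amplitude weights are renormalized to a
    unit-sum density.  The per-component mean is the amplitude-weighted
    arithmetic mean over the component's Rh grid.
    """
    rhs, dens, comp_idx, means = [], [], [], []
    for i, comp in enumerate(fit.components):
        taus, w = gdm_component_grid(comp.tau_p, comp.log_width)
        d = diffusion_coefficient(taus, calibration)
        rh = stokes_einstein_rh(d, temperature, viscosity)
        a = comp.amplitude * w
        rhs.append(rh)
        dens.append(a)
        comp_idx.append(np.full(rh.shape, i))
        means.append(float(np.sum(a * rh) / np.sum(a)))
    rh_grid = np.concatenate(rhs)
    density = np.concatenate(dens)
    density = density / density.sum()
    return RhDistribution(
        rh_grid=rh_grid,
        density=density,
        mean_rh=means,
        component_index=np.concatenate(comp_idx),
    )


def oligomer_units(
    rh_species: float, rh_monomer: float, scaling: str = "linear"
) -> float:
    """Apparent number of monomer units under a linear size-scaling convention."""
    if rh_species <= 0 or rh_monomer <= 0:
        raise ValueError("radii must be positive")
    if scaling != "linear":
        raise ValueError("only the linear scaling convention is supported")
    return rh_species / rh_monomer
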