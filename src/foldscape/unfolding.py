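"""Equilibrium unfolding thermodynamics: chemical denaturation and DSC.

Chemical denaturation is analysed with the two-state linear extrapolation
method (LEM): the unfolding free energy is linear in denaturant,
dG(C) = dG(H2O) + m*C with m negative, so the midpoint satisfies
[den]50% = -dG(H2O)/m.  Thermal unfolding is analysed with the two-state
(scaled) van't Hoff model of the excess heat capacity,

    Cp_exc(T) = s * dH^2/(R T^2) * K/(1+K)^2,   K = exp[-(dH/R)(1/T - 1/Tm)],

from which dS_m = dH/Tm and dG(T_ref) = dH (1 - T_ref/Tm) (dCp = 0 default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .constants import R_KCAL, ROOM_TEMPERATURE

__all__ = [
    "EllipticitySeries",
    "TwoStateChemicalFit",
    "DSCFit",
    "CompensationFit",
    "compute_mre",
    "fraction_unfolded",
    "fit_two_state_chemical",
    "dg_from_lem",
    "fit_dsc",
    "dg_thermal",
    "refolding_efficiency",
    "compensation_regression",
]


@dataclass
class EllipticitySeries:
    """CD ellipticity vs wavelength, denaturant concentration or temperature.

    ``theta`` is in degrees; ``concentration`` mg/ml, ``path_length`` cm,
    ``molar_mass`` g/mol — the units entering the mean-residue-ellipticity
    conversion.
    """

    x: np.ndarray
    theta: np.ndarray  # degrees
    concentration: float  # mg/ml
    path_length: float  # cm
    molar_mass: float  # g/mol
    n_residues: int
    x_kind: str = "denaturant_M"  # or "wavelength_nm", "temperature_K"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        for name in ("concentration", "path_length", "molar_mass", "n_residues"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def compute_mre(series: EllipticitySeries) -> np.ndarray:
    """Mean residue molar ellipticity, deg cm^2 dmol^-1.

    [theta] = theta * 100 * M / (c * l * n) with theta in degrees, c in
    mg/ml and l in cm.
    """
    return (
        series.theta
        * 100.0
        * series.molar_mass
        / (series.concentration * series.path_length * series.n_residues)
    )


def fraction_unfolded(
    x: np.ndarray,
    y: np.ndarray,
    native_baseline: tuple[float, float],
    unfolded_baseline: tuple[float, float],
) -> np.ndarray:
    """Convert a signal-vs-denaturant series to the unfolded fraction.

    fU(C) = (y_N(C) - y(C)) / (y_N(C) - y_U(C)) with linear baselines
    (intercept, slope).  Values are clipped to [-0.05, 1.05] to tolerate
    baseline noise, then winsorized to [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    y_n = native_baseline[0] + native_baseline[1] * x
    y_u = unfolded_baseline[0] + unfolded_baseline[1] * x
    gap = y_n - y_u
    if np.any(gap == 0) or np.any(np.sign(gap) != np.sign(gap[0])):
        raise ValueError("baselines cross on the grid; fractions are undefined")
    fu = (y_n - y) / gap
    return np.clip(np.clip(fu, -0.05, 1.05), 0.0, 1.0)


@dataclass
class TwoStateChemicalFit:
    """Linear-extrapolation two-state fit of a denaturant unfolding curve."""

    dg_h2o: float  # kcal/mol
    m_value: float  # kcal/(mol M), negative convention
    midpoint: float  # M
    native_baseline: tuple[float, float]
    unfolded_baseline: tuple[float, float]
    temperature: float  # K
    residual_norm: float
    covariance: np.ndarray | None = None

    def __post_init__(self):
        if not np.isfinite(self.dg_h2o):
            raise ValueError("dg_h2o must be finite")
        if abs(self.midpoint - (-self.dg_h2o / self.m_value)) > 1e-9 * abs(
            self.midpoint
        ):
            raise ValueError("midpoint inconsistent with -dg_h2o/m_value")


def dg_from_lem(m_value: float, midpoint: float) -> float:
    """dG(H2O) from the printed m-value and transition midpoint: -m * C50."""
    return -m_value * midpoint


def _two_state_signal(c, p, temperature):
    """Signal model: linear baselines mixed by the two-state fraction."""
    dg, m, n0, n1, u0, u1 = p
    k = np.exp(-(dg + m * c) / (R_KCAL * temperature))
    fu = k / (1.0 + k)
    return (n0 + n1 * c) * (1.0 - fu) + (u0 + u1 * c) * fu


def fit_two_state_chemical(
    concentration: np.ndarray,
    signal: np.ndarray,
    temperature: float = ROOM_TEMPERATURE,
    signal_is_fraction: bool = False,
) -> TwoStateChemicalFit:
    """Fit a two-state denaturation curve, baselines estimated jointly.

    With ``signal_is_fraction`` the input is already an unfolded-fraction
    curve and the baselines are fixed at 0 and 1.  The transition must be
    covered on both sides (min fU < 0.2, max fU > 0.8).
    """
    c = np.asarray(concentration, dtype=float)
    y = np.asarray(signal, dtype=float)
    if c.size != y.size or c.size < 6:
        raise ValueError("need at least 6 matching points")

    if signal_is_fraction:
        if np.min(y) > 0.2 or np.max(y) < 0.8:
            raise ValueError(
                "insufficient transition coverage (need fU below 0.2 and above 0.8)"
            )
        # crude midpoint/slope for initialization
        mid0 = float(np.interp(0.5, y, c)) if y[0] < y[-1] else float(np.median(c))
        m0 = -1.0
        x0 = np.array([max(mid0, 0.5), m0])

        def resid(p):
            dg, m = p
            k = np.exp(-(dg + m * c) / (R_KCAL * temperature))
            return k / (1.0 + k) - y

        x0 = np.array([-m0 * max(mid0, 0.5), m0])
        sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
        if not sol.success:
            raise RuntimeError(f"two-state fit failed: {sol.message}")
        dg, m = sol.x
        nb, ub = (0.0, 0.0), (1.0, 0.0)
    else:
        n0 = float(np.mean(y[:2]))
        u0 = float(np.mean(y[-2:]))
        ymid = 0.5 * (n0 + u0)
        mid0 = float(c[np.argmin(np.abs(y - ymid))])
        mid0 = max(mid0, c[1] if c[0] == 0 else c[0])
        x0 = np.array([0.736 * mid0, -0.736, n0, 0.0, u0, 0.0])

        def resid(p):
            return _two_state_signal(c, p, temperature) - y

        sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
        if not sol.success:
            raise RuntimeError(f"two-state fit failed: {sol.message}")
        dg, m = sol.x[:2]
        nb = (float(sol.x[2]), float(sol.x[3]))
        ub = (float(sol.x[4]), float(sol.x[5]))

    if m > 0:  # enforce the negative-m convention (fU increasing with C)
        raise RuntimeError("fitted m-value is positive; curve is not an unfolding transition")
    cov = None
    if sol.jac.shape[0] > sol.jac.shape[1]:
        try:
            cov = (
                2.0
                * sol.cost
                / (sol.jac.shape[0] - sol.jac.shape[1])
                * np.linalg.inv(sol.jac.T @ sol.jac)
            )
        except np.linalg.LinAlgError:
            cov = None
    return TwoStateChemicalFit(
        dg_h2o=float(dg),
        m_value=float(m),
        midpoint=float(-dg / m),
        native_baseline=nb,
        unfolded_baseline=ub,
        temperature=temperature,
        residual_norm=float(np.linalg.norm(sol.fun)),
        covariance=cov,
    )


# --------------------------------------------------------------------------
# DSC


@dataclass
class DSCFit:
    """Two-state (scaled) van't Hoff fit of a DSC excess-Cp scan."""

    tm: float  # kelvin
    dh_vh: float  # kcal/mol
    ds_m: float  # kcal/(mol K), = dh_vh / tm
    dg_ref: float  # kcal/mol at reference_temperature
    reference_temperature: float  # K
    scale: float
    baseline: tuple[float, float]  # linear (intercept, slope)
    residual_norm: float
    covariance: np.ndarray | None = None

    def __post_init__(self):
        if abs(self.ds_m * self.tm - self.dh_vh) > 1e-9 * abs(self.dh_vh):
            raise ValueError("ds_m * tm must equal dh_vh")


def fit_dsc(scan, reference_temperature: float = ROOM_TEMPERATURE) -> DSCFit:
    """Fit the two-state scaled van't Hoff model plus a linear baseline.

    dS_m = dH/Tm and dG(T_ref) = dH (1 - T_ref/Tm), taking dCp = 0 — the
    extrapolation the van't Hoff model itself supports.
    """
    from .synthetic import excess_cp  # model shared with the generator

    t = scan.temperature
    y = scan.excess_cp
    i_peak = int(np.argmax(y))
    if i_peak in (0, len(y) - 1):
        raise ValueError("scan does not bracket the transition peak")
    tm0 = float(t[i_peak])
    base0 = float(np.median(y[: max(3, len(y) // 20)]))
    cp_max = float(y[i_peak] - base0)
    dh0 = float(np.sqrt(max(cp_max, 1e-6) * 4.0 * R_KCAL * tm0**2))

    def resid(p):
        tm, dh, scale, b0, b1 = p
        return excess_cp(t, tm, dh, scale) + b0 + b1 * t - y

    x0 = np.array([tm0, dh0, 1.0, base0, 0.0])
    lo = [t[0], 1.0, 1e-6, -np.inf, -np.inf]
    hi = [t[-1], 5000.0, 1e6, np.inf, np.inf]
    sol = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise RuntimeError(f"DSC fit failed: {sol.message}")
    tm, dh, scale, b0, b1 = sol.x
    cov = None
    if sol.jac.shape[0] > sol.jac.shape[1]:
        try:
            cov = (
                2.0
                * sol.cost
                / (sol.jac.shape[0] - sol.jac.shape[1])
                * np.linalg.inv(sol.jac.T @ sol.jac)
            )
        except np.linalg.LinAlgError:
            cov = None
    return DSCFit(
        tm=float(tm),
        dh_vh=float(dh),
        ds_m=float(dh / tm),
        dg_ref=float(dh * (1.0 - reference_temperature / tm)),
        reference_temperature=reference_temperature,
        scale=float(scale),
        baseline=(float(b0), float(b1)),
        residual_norm=float(np.linalg.norm(sol.fun)),
        covariance=cov,
    )


def dg_thermal(fit: DSCFit, temperature: float, dcp: float = 0.0) -> float:
    """Unfolding free energy at an arbitrary temperature from a DSC fit.

    Gibbs-Helmholtz with an optional heat-capacity increment dCp
    (kcal/(mol K)); dcp = 0 reduces to dH (1 - T/Tm).
    """
    t, tm, dh = temperature, fit.tm, fit.dh_vh
    return dh * (1.0 - t / tm) + dcp * ((t - tm) - t * np.log(t / tm))


# --------------------------------------------------------------------------
# refolding and compensation


def refolding_efficiency(mre_refolded: float, mre_native: float) -> float:
    """Refolding efficiency: MRE of the refolded sample over the native MRE."""
    if mre_native == 0:
        raise ValueError("native MRE must be nonzero")
    if mre_refolded != 0 and np.sign(mre_refolded) != np.sign(mre_native):
        warnings.warn(
            "refolded and native MRE have opposite signs; ratio is physically suspect",
            RuntimeWarning,
        )
    return mre_refolded / mre_native


@dataclass
class CompensationFit:
    """Entropy-enthalpy compensation: OLS of dH on dS, slope in kelvin."""

    slope: float  # kelvin
    intercept: float  # kcal/mol
    r_squared: float

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


def compensation_regression(points) -> CompensationFit:
    """Regress unfolding enthalpies on entropies across protein variants.

    ``points`` is a sequence of (dH kcal/mol, dS kcal/(mol K)) pairs; the
    slope has units of temperature (the compensation temperature).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (dH, dS) pairs")
    dh, ds = pts[:, 0], pts[:, 1]
    res = linregress(ds, dh)
    return CompensationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
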