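"""ThT aggregation kinetics: sigmoidal fitting, lag times and seeding effects.

Amyloid formation monitored by Thioflavin-T fluorescence follows a sigmoidal
time course.  Traces are fitted with a four-parameter logistic
F(t) = f0 + A/(1 + exp(-k (t - t50))); the lag time uses the
tangent-at-inflection convention, lag = t50 - 2/k.  The aggregation index is
the pellet-to-supernatant protein ratio after ultracentrifugation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ThTTrace",
    "SigmoidalFit",
    "AggregationIndex",
    "fit_sigmoid",
    "fit_replicates",
    "normalize_trace",
    "aggregation_index",
    "seeding_effect",
    "is_flat",
]

FLAT_AMPLITUDE_FACTOR = 5.0  # amplitude below this multiple of baseline noise = flat


@dataclass
class ThTTrace:
    """A ThT fluorescence time course (hours, arbitrary units)."""

    time: np.ndarray
    fluorescence: np.ndarray
    replicate_id: str | None = None
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.size < 10:
            raise ValueError("trace needs at least 10 points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class SigmoidalFit:
    """Four-parameter logistic fit of a ThT trace."""

    f0: float
    amplitude: float
    t50: float  # hours
    rate_k: float  # 1/hours
    lag_time: float  # hours, = t50 - 2/rate_k
    residual_norm: float
    plateau_censored: bool = False
    covariance: np.ndarray | None = None

    def __post_init__(self):
        if self.rate_k <= 0:
            raise ValueError("rate_k must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if abs(self.lag_time - (self.t50 - 2.0 / self.rate_k)) > 1e-9:
            raise ValueError("lag_time must equal t50 - 2/rate_k")


def is_flat(trace: ThTTrace, factor: float = FLAT_AMPLITUDE_FACTOR) -> bool:
    """True when the trace shows no detectable aggregation signal.

    The rise (last-decile median minus first-decile median) is compared
    against ``factor`` times the baseline noise (std of the first decile).
    """
    n10 = max(3, trace.time.size // 10)
    base = trace.fluorescence[:n10]
    plateau = trace.fluorescence[-n10:]
    noise = max(float(np.std(base)), 1e-12)
    return float(np.median(plateau) - np.median(base)) < factor * noise


def fit_sigmoid(trace: ThTTrace) -> SigmoidalFit:
    """Fit a four-parameter logistic to one ThT trace.

    Monotone-decreasing traces are rejected; a trace that has not reached
    its plateau is fitted anyway but flagged ``plateau_censored``.
    """
    from .synthetic import logistic4  # shared model

    t, y = trace.time, trace.fluorescence
    n10 = max(3, t.size // 10)
    base = float(np.median(y[:n10]))
    top = float(np.median(y[-n10:]))
    if top < base:
        raise ValueError("monotone-decreasing trace; not a growth curve")
    amp0 = max(top - base, 1e-9 * max(abs(top), 1.0))
    t50_0 = float(t[np.argmin(np.abs(y - (base + amp0 / 2.0)))])
    dy = np.gradient(y, t)
    k0 = max(4.0 * float(np.max(dy)) / amp0, 1e-3)

    def resid(p):
        f0, amp, t50, k = p
        return logistic4(t, f0, amp, t50, k) - y

    lo = [-np.inf, 0.0, t[0] - (t[-1] - t[0]), 1e-6]
    hi = [np.inf, np.inf, t[-1] + (t[-1] - t[0]), np.inf]
    sol = least_squares(
        resid, [base, amp0, t50_0, k0], bounds=(lo, hi), xtol=1e-14, ftol=1e-14
    )
    if not sol.success:
        raise RuntimeError(f"sigmoid fit failed: {sol.message}")
    f0, amp, t50, k = sol.x

    # plateau censoring: the curve should be within 2% of its asymptote
    censored = logistic4(t[-1], 0.0, 1.0, t50, k) < 0.98
    if censored:
        warnings.warn("trace has not reached its plateau; fit flagged", RuntimeWarning)

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
    return SigmoidalFit(
        f0=float(f0),
        amplitude=float(amp),
        t50=float(t50),
        rate_k=float(k),
        lag_time=float(t50 - 2.0 / k),
        residual_norm=float(np.linalg.norm(sol.fun)),
        plateau_censored=bool(censored),
        covariance=cov,
    )


def fit_replicates(traces: list[ThTTrace]) -> tuple[list[SigmoidalFit], dict]:
    """Fit replicate traces independently and summarize parameters (mean ± sd)."""
    fits = [fit_sigmoid(tr) for tr in traces]
    summary = {}
    for name in ("f0", "amplitude", "t50", "rate_k", "lag_time"):
        vals = np.array([getattr(f, name) for f in fits])
        summary[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
    return fits, summary


def normalize_trace(trace: ThTTrace, mode: str = "minmax") -> ThTTrace:
    """Normalize a trace: 'minmax' maps [min, max] to [0, 1]; 'baseline'
    subtracts the median of the first decile (preserving amplitude)."""
    y = trace.fluorescence
    if np.ptp(y) == 0:
        raise ValueError("constant trace cannot be normalized")
    if mode == "minmax":
        out = (y - y.min()) / np.ptp(y)
    elif mode == "baseline":
        n10 = max(3, y.size // 10)
        out = y - np.median(y[:n10])
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    cond = dict(trace.condition)
    cond["normalization"] = mode
    return ThTTrace(
        time=trace.time, fluorescence=out, replicate_id=trace.replicate_id, condition=cond
    )


@dataclass
class AggregationIndex:
    """Pellet-to-supernatant protein ratio after ultracentrifugation."""

    pellet_amount: float
    supernatant_amount: float
    ai: float

    def __post_init__(self):
        if self.pellet_amount < 0 or self.supernatant_amount <= 0:
            raise ValueError("amounts must be >= 0 with supernatant > 0")


def aggregation_index(pellet: float, supernatant: float) -> AggregationIndex:
    """Aggregation index AI = pellet / supernatant."""
    if supernatant == 0:
        raise ZeroDivisionError("zero supernatant gives an infinite aggregation index")
    return AggregationIndex(
        pellet_amount=pellet, supernatant_amount=supernatant, ai=pellet / supernatant
    )


def seeding_effect(
    unseeded: SigmoidalFit, seeded: SigmoidalFit
) -> tuple[float, float]:
    """Lag-time reduction and amplitude gain caused by seeding.

    Returns (lag_shift hours, amplitude_ratio): lag(unseeded) - lag(seeded)
    and amp(seeded)/amp(unseeded).
    """
    if unseeded.plateau_censored or seeded.plateau_censored:
        warnings.warn(
            "one of the fits is plateau-censored; seeding metrics may be biased",
            RuntimeWarning,
        )
    return (
        unseeded.lag_time - seeded.lag_time,
        seeded.amplitude / unseeded.amplitude,
    )
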