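"""Impedance vector arithmetic and shared regression/correlation primitives.

In impedance flow cytometry each particle transit is summarised by a complex
impedance ``Z(ω)``: a real (resistive) part ``Zr`` and an imaginary
(capacitive-reactance) part ``Zi``, equivalently an amplitude ``|Z|`` and a
phase angle ``θ``.  Phase at high frequency (~8 MHz) reports membrane
integrity; amplitude at low frequency (~2 MHz) tracks particle volume.

Phase is handled in degrees throughout the public API — instrument scatter
plots, gates and population modes are all quoted in degrees — and amplitudes
stay in arbitrary instrument units (no calibration to ohms is attempted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ImpedanceVector",
    "RegressionFit",
    "polar_to_cartesian",
    "cartesian_to_polar",
    "fit_linear",
    "pearson",
]


@dataclass(frozen=True)
class ImpedanceVector:
    """One event's impedance at a single measurement frequency.

    Attributes
    ----------
    amplitude : float
        Impedance modulus ``|Z|`` in arbitrary instrument units (>= 0).
    phase_deg : float
        Phase angle θ in degrees, reported in [0, 360).
    frequency_mhz : float
        Measurement frequency in MHz.
    """

    amplitude: float
    phase_deg: float
    frequency_mhz: float = 8.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")

    @property
    def real(self) -> float:
        """Resistive component ``Zr = |Z| cos θ``."""
        return polar_to_cartesian(self.amplitude, self.phase_deg)[0]

    @property
    def imag(self) -> float:
        """Capacitive-reactance component ``Zi = |Z| sin θ``."""
        return polar_to_cartesian(self.amplitude, self.phase_deg)[1]

    @classmethod
    def from_cartesian(
        cls, real: float, imag: float, frequency_mhz: float = 8.0
    ) -> "ImpedanceVector":
        amp, phase = cartesian_to_polar(real, imag)
        if np.isnan(phase):
            phase = 0.0
        return cls(amplitude=amp, phase_deg=phase, frequency_mhz=frequency_mhz)


@dataclass(frozen=True)
class RegressionFit:
    """Simple (one-predictor) ordinary least squares fit summary."""

    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_value: float
    n: int


def polar_to_cartesian(amplitude, phase_deg):
    """Convert amplitude/phase to real/imaginary impedance components.

    ``Zr = |Z| cos θ`` and ``Zi = |Z| sin θ`` with θ given in degrees.
    Accepts scalars or arrays; negative amplitudes are rejected.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    if np.any(amplitude < 0):
        raise ValueError("amplitude must be non-negative")
    theta = np.deg2rad(np.asarray(phase_deg, dtype=float))
    zr = amplitude * np.cos(theta)
    zi = amplitude * np.sin(theta)
    if zr.ndim == 0:
        return float(zr), float(zi)
    return zr, zi


def cartesian_to_polar(real, imag):
    """Convert real/imaginary components to amplitude and phase in degrees.

    The phase uses full four-quadrant angle resolution (``arctan2``) and is
    reported in [0, 360).  The printed two-argument arctan form is
    quadrant-ambiguous, which matters here because pollen events sit around
    180–210 degrees.  A zero vector yields amplitude 0 with phase NaN
    (undefined direction).
    """
    zr = np.asarray(real, dtype=float)
    zi = np.asarray(imag, dtype=float)
    amp = np.hypot(zr, zi)
    phase = np.rad2deg(np.arctan2(zi, zr)) % 360.0
    phase = np.where(amp == 0.0, np.nan, phase)
    if amp.ndim == 0:
        return float(amp), float(phase)
    return amp, phase


def adjusted_r_squared(r_squared: float, n: int, n_predictors: int = 1) -> float:
    """Adjusted coefficient of determination for an OLS fit.

    ``Radj² = 1 − (1 − R²)(n − 1)/(n − p − 1)`` with ``p`` predictors; every
    regression in this package is simple linear (p = 1).
    """
    if n <= n_predictors + 1:
        raise ValueError(f"need n > {n_predictors + 1} points, got {n}")
    return 1.0 - (1.0 - r_squared) * (n - 1) / (n - n_predictors - 1)


def fit_linear(xs, ys) -> RegressionFit:
    """Ordinary least squares fit of ``ys`` on ``xs``.

    Returns slope, intercept, R², adjusted R² and the two-sided p-value of
    the slope t-test.  Requires at least 3 points and non-constant ``xs``.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise ValueError("xs and ys must have the same length")
    n = xs.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.ptp(xs) == 0:
        raise ValueError("xs are constant; slope undefined")
    if np.ptp(ys) == 0:
        # flat response: zero slope, no variance explained
        return RegressionFit(
            slope=0.0,
            intercept=float(ys[0]),
            r_squared=0.0,
            adj_r_squared=float(adjusted_r_squared(0.0, n)),
            p_value=1.0,
            n=int(n),
        )
    res = stats.linregress(xs, ys)
    r2 = res.rvalue**2
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(r2),
        adj_r_squared=float(adjusted_r_squared(r2, n)),
        p_value=float(res.pvalue),
        n=int(n),
    )


def pearson(xs, ys) -> float:
    """Pearson product-moment correlation R in [−1, 1].

    Both inputs must be non-constant with at least 3 paired values.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size:
        raise ValueError("xs and ys must have the same length")
    if xs.size < 3:
        raise ValueError(f"need at least 3 points, got {xs.size}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("constant input; correlation undefined")
    return float(stats.pearsonr(xs, ys).statistic)
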