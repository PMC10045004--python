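"""Moisture transport: dry-basis conversion, drying rate, diffusivity.

A drying run records the total wet mass of a thin product slab over
time.  Dividing out the dry-solid mass gives the dry-basis moisture
content ``M_t`` (kg water per kg dry matter); normalising by the initial
moisture gives the dimensionless moisture ratio

    MR = (M_t - M_e) / (M_0 - M_e)  ~=  M_t / M_0

(the equilibrium moisture ``M_e`` of fresh produce is small and defaults
to zero).  The falling-rate period of such runs is governed by internal
diffusion; for an infinite slab of half-thickness ``L`` the Fickian
series solution gives, after one-term linearisation,

    F0 = D_eff t / (4 L^2) = -0.101 ln(MR) - 0.0213

whose printed coefficients are ``1/pi^2`` and ``ln(8/pi^2)/pi^2`` at
that precision.  The effective moisture diffusivity ``D_eff`` (m^2/s)
follows from the least-squares slope of ``F0`` against time in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "DryingRun",
    "MoistureSeries",
    "to_dry_basis",
    "moisture_ratio",
    "drying_rate",
    "mean_drying_rate",
    "fourier_number",
    "estimate_deff",
    "F0_SLOPE",
    "F0_INTERCEPT",
]

#: One-term slab-linearisation coefficients, as conventionally printed.
#: Analytically they are 1/pi^2 = 0.10132 and ln(8/pi^2)/pi^2 = -0.02128.
F0_SLOPE = 0.101
F0_INTERCEPT = -0.0213

_BALANCE_RESOLUTION = 0.01  # g, typical analytical balance


@dataclass
class DryingRun:
    """Raw mass-vs-time record of one drying experiment.

    times are minutes starting at 0, masses are total wet mass in grams,
    ``dry_mass`` the dry-solid mass in grams.  ``method`` is ``"CD"``
    (convective) or ``"MD"`` (microwave), ``level`` the temperature in
    degC or the power in W.  ``thickness`` is the full slab thickness in
    metres; ``area`` (cm^2) is metadata only.
    """

    times: np.ndarray
    masses: np.ndarray
    dry_mass: float
    method: Literal["CD", "MD"] = "CD"
    level: float = 0.0
    thickness: float = 5e-4
    area: float | None = None
    balance_resolution: float = _BALANCE_RESOLUTION
    truth: object | None = None     # embedded generator truth, if synthetic
    stopped: bool = True            # constant-weight rule fired before max_time

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.masses.shape:
            raise ValueError("times and masses must be 1-D and equal length")
        if self.times.size < 3:
            raise ValueError("need at least 3 observations")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] != 0.0:
            raise ValueError("first observation must be at t = 0")
        if np.any(self.masses <= 0) or self.dry_mass <= 0:
            raise ValueError("masses and dry_mass must be positive")
        floor = self.dry_mass - 2.0 * self.balance_resolution
        if np.any(self.masses < floor - 1e-6):  # 1 ug slack for file round trips
            raise ValueError(
                "mass readings fall below dry mass beyond the balance-noise "
                f"allowance ({floor:.4g} g)"
            )
        if self.method not in ("CD", "MD"):
            raise ValueError("method must be 'CD' or 'MD'")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


@dataclass
class MoistureSeries:
    """Dry-basis moisture content and moisture ratio over time."""

    times: np.ndarray
    moisture_db: np.ndarray
    mr: np.ndarray
    m0: float
    me: float = 0.0
    n_clamped: int = 0  # readings below dry mass clamped to zero moisture

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.moisture_db = np.asarray(self.moisture_db, dtype=float)
        self.mr = np.asarray(self.mr, dtype=float)


def to_dry_basis(run: DryingRun, me: float = 0.0) -> MoistureSeries:
    """Convert a mass record to dry-basis moisture and moisture ratio.

    ``moisture_db[i] = (masses[i] - dry_mass) / dry_mass``; balance-noise
    readings below the dry mass are clamped to zero moisture and counted
    in ``n_clamped``.
    """
    if run.dry_mass >= run.masses[0]:
        raise ValueError("initial mass does not exceed dry mass: nothing to dry")
    m = (run.masses - run.dry_mass) / run.dry_mass
    n_clamped = int(np.sum(m < 0))
    m = np.clip(m, 0.0, None)
    m0 = float(m[0])
    mr = moisture_ratio(m, m0, me=me)
    return MoistureSeries(times=run.times, moisture_db=m, mr=mr, m0=m0,
                          me=me, n_clamped=n_clamped)


def moisture_ratio(moisture_db, m0: float, me: float = 0.0) -> np.ndarray:
    """``MR = (M_t - M_e)/(M_0 - M_e)``; reduces to ``M_t/M_0`` for M_e=0."""
    if m0 <= me:
        raise ValueError(f"need m0 > me (got m0={m0}, me={me})")
    m = np.asarray(moisture_db, dtype=float)
    return (m - me) / (m0 - me)


def drying_rate(series: MoistureSeries) -> np.ndarray:
    """Absolute moisture-loss rate per interval, kg water / (kg dw * min).

    ``DR[i] = |M[i+1] - M[i]| / (t[i+1] - t[i])``, length ``N - 1``.  The
    rate is reported as a magnitude: the raw finite difference is
    negative while the product dries, but drying rates are tabulated
    positive in this literature.
    """
    if series.times.size < 2:
        raise ValueError("need at least 2 observations")
    dt = np.diff(series.times)
    if np.any(dt == 0):
        raise ValueError("duplicate times")
    return np.abs(np.diff(series.moisture_db)) / dt


def mean_drying_rate(series: MoistureSeries) -> float:
    """Arithmetic mean of the interval drying rates.

    On a uniform time grid over a monotone series this equals
    ``(M_0 - M_end) / T``.
    """
    return float(drying_rate(series).mean())


def fourier_number(mr) -> np.ndarray | float:
    """Slab Fourier number from the one-term linearisation.

    ``F0 = -0.101 ln(MR) - 0.0213`` for ``0 < MR <= 1``, using the
    conventional printed coefficients (see module docstring).
    """
    mr_arr = np.asarray(mr, dtype=float)
    if np.any(mr_arr <= 0):
        raise ValueError("MR must be positive")
    out = -F0_SLOPE * np.log(mr_arr) + F0_INTERCEPT
    return float(out) if np.isscalar(mr) else out


def estimate_deff(series: MoistureSeries, thickness: float,
                  method: Literal["slope", "pointwise"] = "slope"
                  ) -> tuple[float, dict]:
    """Effective moisture diffusivity of a slab, m^2/s.

    Parameters
    ----------
    series : MoistureSeries
    thickness : float
        Full slab thickness in metres; the slab half-thickness
        ``L = thickness / 2`` enters as ``4 L^2``.
    method : {"slope", "pointwise"}
        ``"slope"`` (default) takes the OLS slope of ``F0(MR_i)``
        against time in seconds over the interior points with
        ``0 < MR < 1``; ``"pointwise"`` averages the per-point estimates
        ``F0_i * 4 L^2 / t_i`` (exposed for comparison).

    Returns
    -------
    (deff, info)
        ``info`` carries ``n_used``, ``slope`` (1/s) and a
        ``nonpositive_slope`` flag.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    L = thickness / 2.0
    mr = series.mr
    usable = (mr > 0) & (mr < 1) & (series.times > 0)
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable points with 0 < MR < 1")
    t_s = series.times[usable] * 60.0
    f0 = fourier_number(mr[usable])
    if method == "slope":
        slope = float(np.polyfit(t_s, f0, 1)[0])
        deff = slope * 4.0 * L * L
    elif method == "pointwise":
        per_point = f0 * 4.0 * L * L / t_s
        deff = float(np.mean(per_point))
        slope = deff / (4.0 * L * L)
    else:
        raise ValueError(f"unknown method {method!r}")
    info = {
        "n_used": int(usable.sum()),
        "slope_per_s": slope,
        "nonpositive_slope": bool(slope <= 0),
        "half_thickness_m": L,
        "method": method,
    }
    return deff, info


def analytic_f0_coefficients() -> tuple[float, float]:
    """Exact one-term coefficients ``(1/pi^2, ln(8/pi^2)/pi^2)``."""
    return 1.0 / math.pi**2, math.log(8.0 / math.pi**2) / math.pi**2
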