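"""Synthetic drying experiments and assay tables.

The generator emulates the bench protocol behind thin-layer drying
studies of fresh produce: ~10 g samples at 87% wet-basis moisture
spread 0.5 mm thick, weighed on a 0.01 g balance every 10 min
(convective drying, CD) or every 30 s (microwave drying, MD) until the
reading is constant.  A truth moisture-ratio curve (any catalog model,
or the exact Fickian slab series) is sampled on that grid, additive
normal noise is applied on the MR scale, the series is converted to
total mass, quantised to the balance resolution, and truncated when the
constant-weight rule fires.  The truth parameters ride along on the
returned run so that recovery can be checked end to end.

``preset_designs()`` provides nine ready-made designs — five CD
temperatures (40-120 degC) and four MD powers (200-800 W) — whose truth
curves are published Sledz-model fits for potato-peel drying at those
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .models import ParameterSet, eval_model
from .transport import DryingRun

__all__ = [
    "ExperimentDesign",
    "generate_drying_run",
    "generate_fickian_curve",
    "generate_assay_table",
    "preset_designs",
    "PRESET_TRUTHS",
]

_DEFAULT_INTERVAL = {"CD": 10.0, "MD": 0.5}   # min
_DEFAULT_MAX_TIME = {"CD": 1500.0, "MD": 120.0}  # min
_CD_RATED_POWER_W = 1500.0  # nominal convective-oven draw
_CD_DUTY_FACTOR = 0.4       # thermostat duty cycle (arbitrary, documented)


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of one synthetic drying run.

    ``truth_model`` is a :class:`ParameterSet` for any catalog model, or
    ``None`` with ``truth_deff`` set for an exact Fickian slab truth.
    ``noise_sd`` is additive normal noise on the MR scale (default 0.003,
    the magnitude of fit RMSEs typical of convective runs).  The
    constant-weight stopping rule fires at ``stop_rule`` consecutive
    identical quantised balance readings.
    """

    method: str = "CD"
    level: float = 40.0
    truth_model: ParameterSet | None = None
    truth_deff: float | None = None
    sampling_interval: float | None = None  # min; None -> 10 (CD) / 0.5 (MD)
    initial_mass: float = 10.0              # g
    wet_basis_moisture: float = 0.87
    thickness: float = 5e-4                 # m, full slab
    noise_sd: float = 0.003                 # MR units
    balance_resolution: float = 0.01        # g
    stop_rule: int = 3
    max_time: float | None = None           # min; None -> 1500 (CD) / 120 (MD)
    rated_power_w: float | None = None      # None -> level (MD) / oven nominal (CD)
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("CD", "MD"):
            raise ValueError("method must be 'CD' or 'MD'")
        if self.sampling_interval is not None and self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if not 0.0 < self.wet_basis_moisture < 1.0:
            raise ValueError("wet_basis_moisture must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if (self.truth_model is None) == (self.truth_deff is None):
            raise ValueError("give exactly one of truth_model or truth_deff")
        if self.stop_rule < 2:
            raise ValueError("stop_rule must be >= 2")

    @property
    def interval(self) -> float:
        return self.sampling_interval or _DEFAULT_INTERVAL[self.method]

    @property
    def horizon(self) -> float:
        return self.max_time or _DEFAULT_MAX_TIME[self.method]

    @property
    def dry_mass(self) -> float:
        return self.initial_mass * (1.0 - self.wet_basis_moisture)

    @property
    def m0_dry_basis(self) -> float:
        w = self.wet_basis_moisture
        return w / (1.0 - w)

    def energy_kwh(self, elapsed_min: float) -> float:
        """Synthesised electric energy for the run's duration.

        MD draws the rated (set) power continuously; a convective oven
        cycles its heater, modelled by a constant duty factor.
        """
        if self.method == "MD":
            power = self.rated_power_w if self.rated_power_w else self.level
            return power * (elapsed_min / 60.0) / 1000.0
        power = self.rated_power_w if self.rated_power_w else _CD_RATED_POWER_W
        return power * _CD_DUTY_FACTOR * (elapsed_min / 60.0) / 1000.0


def generate_fickian_curve(deff: float, thickness: float, times,
                           n_terms: int = 50) -> np.ndarray:
    """Exact slab-diffusion MR series (odd-term Fourier sum).

    ``MR(t) = (8/pi^2) sum_{odd n} n^-2 exp(-n^2 pi^2 D t / (4 L^2))``
    with ``L = thickness/2`` and t in minutes.  For t > 0 the truncation
    error at the default 50 terms is far below floating precision; at
    t = 0 the partial sum is 1 up to the series tail.
    """
    if deff <= 0 or thickness <= 0:
        raise ValueError("deff and thickness must be positive")
    L = thickness / 2.0
    t_s = np.asarray(times, dtype=float) * 60.0
    n = (2 * np.arange(n_terms) + 1)[:, None].astype(float)
    with np.errstate(under="ignore"):
        terms = np.exp(-(n**2) * np.pi**2 * deff * t_s[None, :] / (4 * L * L)) / n**2
    return (8.0 / np.pi**2) * terms.sum(axis=0)


def _truth_curve(design: ExperimentDesign, t: np.ndarray) -> np.ndarray:
    if design.truth_model is not None:
        L = design.thickness / 2.0
        return np.asarray(eval_model(design.truth_model, t, thickness_L=L))
    return generate_fickian_curve(design.truth_deff, design.thickness, t)


def generate_drying_run(design: ExperimentDesign,
                        seed: int | None = None) -> DryingRun:
    """Simulate one drying run; deterministic for a fixed seed.

    The truth MR curve is evaluated on the sampling grid up to the
    horizon, noise is added on the MR scale, masses are formed as
    ``dry_mass * (1 + M0 * MR)``, quantised to the balance resolution
    (and floored at the dry mass minus twice the resolution, the
    physical balance-noise allowance), and the run is truncated at the
    first time the constant-weight rule fires.  If the rule never fires
    within the horizon the full record is returned with
    ``stopped=False``.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    step = design.interval
    t = np.arange(0.0, design.horizon + step / 2.0, step)
    mr_truth = _truth_curve(design, t)
    if np.any(np.diff(mr_truth) > 1e-12):
        raise ValueError("truth curve is not non-increasing on the grid")
    mr_noisy = mr_truth + rng.normal(0.0, design.noise_sd, t.size)
    dry = design.dry_mass
    mass = dry * (1.0 + design.m0_dry_basis * mr_noisy)
    res = design.balance_resolution
    mass_q = np.round(mass / res) * res
    floor = np.round((dry - 2.0 * res) / res) * res
    mass_q = np.maximum(mass_q, floor)

    k = design.stop_rule
    stop_idx = None
    for i in range(k - 1, t.size):
        window = mass_q[i - k + 1: i + 1]
        if np.all(window == window[0]):
            stop_idx = i
            break
    if stop_idx is not None:
        end = stop_idx + 1
        stopped = True
    else:
        end = t.size
        stopped = False

    return DryingRun(
        times=t[:end],
        masses=mass_q[:end],
        dry_mass=dry,
        method=design.method,
        level=design.level,
        thickness=design.thickness,
        balance_resolution=res,
        truth=design.truth_model if design.truth_model is not None
        else {"deff": design.truth_deff},
        stopped=stopped,
    )


def generate_assay_table(n_conditions: int, n_replicates: int,
                         means, sd: float, seed: int = 0,
                         labels=None) -> dict[str, np.ndarray]:
    """Seeded normal replicates per condition, for the LSD machinery."""
    means = np.asarray(means, dtype=float)
    if means.size != n_conditions:
        raise ValueError("means length must equal n_conditions")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"g{i}" for i in range(n_conditions)]
    return {
        lab: mu + rng.normal(0.0, sd, n_replicates)
        for lab, mu in zip(labels, means)
    }


#: Sledz-model truth constants for nine potato-peel drying conditions
#: (b, k, a, k1), reference fits by condition.
PRESET_TRUTHS: dict[str, dict] = {
    "CD-40": dict(b=3.6874, k=0.0217, a=2.7143, k1=-0.0191),
    "CD-60": dict(b=1.1901, k=0.0304, a=0.1909, k1=-0.1269),
    "CD-80": dict(b=1.4528, k=0.0409, a=0.4552, k1=-0.0653),
    "CD-100": dict(b=11.9400, k=0.0875, a=10.9565, k1=-0.0680),
    "CD-120": dict(b=1.5087, k=0.0902, a=0.5087, k1=-2.6579),
    "MD-200": dict(b=1.5210, k=0.0818, a=0.5130, k1=-0.1405),
    "MD-400": dict(b=1.0637, k=0.1419, a=0.0767, k1=-0.7370),
    "MD-600": dict(b=1.0101, k=0.1535, a=0.0000, k1=0.8702),
    "MD-800": dict(b=0.9573, k=0.2044, a=0.0000, k1=0.5734),
}


def preset_designs() -> list[ExperimentDesign]:
    """The nine reference designs: 5 CD temperatures, 4 MD powers."""
    out = []
    for name, truth in PRESET_TRUTHS.items():
        method, level = name.split("-")
        out.append(
            ExperimentDesign(
                method=method,
                level=float(level),
                truth_model=ParameterSet("Sledz et al.", truth),
            )
        )
    return out


def preset_design(name: str) -> ExperimentDesign:
    """Look up one preset by name, e.g. ``"CD-40"`` or ``"MD-600"``."""
    try:
        truth = PRESET_TRUTHS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(PRESET_TRUTHS)}"
        ) from None
    method, level = name.split("-")
    return ExperimentDesign(method=method, level=float(level),
                            truth_model=ParameterSet("Sledz et al.", truth))
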