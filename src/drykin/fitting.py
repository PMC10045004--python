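"""Nonlinear least-squares fitting and ranking of thin-layer drying models.

The central objects follow the statsmodels convention: a
:class:`ThinLayerModel` is built from data (a moisture-ratio time series)
and ``fit()`` returns a :class:`ThinLayerFit` results object carrying the
estimated constants, goodness-of-fit statistics and a ``summary()``
table.  :func:`fit_catalog` fits every catalog model (or a subset) and
returns a :class:`SelectionTable` ranked by the usual selection rule of
this literature: highest R^2, then lowest RMSE, then fewest parameters.

Goodness of fit uses the three statistics customary for drying curves::

    RMSE  = sqrt(SSE / N)
    chi^2 = SSE / (N - z)          (z = number of fitted constants)
    R^2   = 1 - SSE / SS_tot       (SS_tot about the observed mean)

which are linked by the identity ``chi^2 = N * RMSE^2 / (N - z)``.

Initialisation is deterministic: decay rates start from the slope of a
log-linear regression of ln(MR) on t, amplitudes from endpoint values,
shape exponents at 1; the three models that are linear in their
constants are started from an exact linear least-squares solve.  An
optional seeded multistart perturbs that start for ill-conditioned
forms.  A fit that fails to converge is recorded (``converged=False``,
infinite-SSE sentinel statistics), never raised, so ranking a batch
cannot abort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import (
    ModelSpec,
    ParameterSet,
    _eval_raw,
    get_model,
    model_catalog,
)

__all__ = [
    "goodness_of_fit",
    "ThinLayerModel",
    "ThinLayerFit",
    "SelectionTable",
    "fit_model",
    "fit_catalog",
    "fit_all",
    "select_best",
]

_PENALTY = 1.0e3  # residual assigned where a model is undefined


def goodness_of_fit(observed, predicted, z: int) -> tuple[float, float, float]:
    """Return ``(r_squared, chi_squared, rmse)`` for a fitted MR series.

    Parameters
    ----------
    observed, predicted : array-like
        Experimental and model moisture ratios, equal length ``N >= 2``.
    z : int
        Number of fitted model constants; ``N > z`` is required for
        chi-squared.

    Raises
    ------
    ValueError
        On length mismatch, ``N <= z``, or constant observations (which
        leave R^2 undefined).
    """
    obs = np.asarray(observed, dtype=float)
    pre = np.asarray(predicted, dtype=float)
    if obs.shape != pre.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pre.shape}")
    n = obs.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if n <= z:
        raise ValueError(f"chi-squared undefined: N={n} <= z={z}")
    sse = float(np.sum((pre - obs) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant observations: R^2 undefined")
    rmse = float(np.sqrt(sse / n))
    chi2 = sse / (n - z)
    r2 = 1.0 - sse / ss_tot
    return r2, chi2, rmse


# --------------------------------------------------------------------------
# deterministic initialisation policy

def _log_slope_rate(t: np.ndarray, mr: np.ndarray) -> float:
    """|slope| of ln(MR) against t over the clearly-positive points."""
    mask = mr > 0.01
    if mask.sum() >= 2 and np.ptp(t[mask]) > 0:
        slope = np.polyfit(t[mask], np.log(mr[mask]), 1)[0]
        k = abs(float(slope))
    else:
        k = 0.01
    return float(np.clip(k, 1e-4, 5.0))


def _linear_lstsq(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def _default_init(spec: ModelSpec, t: np.ndarray, mr: np.ndarray) -> dict:
    """Documented deterministic starting values for every catalog model."""
    k = _log_slope_rate(t, mr)
    mr0 = float(mr[0])
    mr_end = float(mr[-1])
    name = spec.name
    if name == "Newton":
        return {"k": k}
    if name == "Henderson and Pabis":
        return {"a": max(mr0, 1e-3), "k": k}
    if name == "Logarithmic":
        c = min(mr_end, 0.5)
        return {"a": max(mr0 - c, 1e-3), "k": k, "c": c}
    if name in ("Page", "Modified Page 1", "Modified Page 2"):
        return {"k": k, "n": 1.0}
    if name == "Midilli et al.":
        return {"a": max(mr0, 1e-3), "k": k, "n": 1.0, "b": 0.0}
    if name == "Two terms":
        return {"a": 0.5 * mr0, "k": k, "b": 0.5 * mr0, "k1": max(0.5 * k, 1e-4)}
    if name == "Two-term exponential":
        return {"a": 1.2, "k": k}
    if name == "Approximation of diffusion":
        return {"a": 1.2, "k": k, "b": 0.5}
    if name == "Verma et al.":
        return {"a": 0.5, "k": k, "k1": max(0.5 * k, 1e-4)}
    if name == "Modified Henderson and Pabis":
        third = mr0 / 3.0
        return {"a": third, "k": k, "b": third,
                "k1": max(0.5 * k, 1e-4), "c": third, "k2": min(2.0 * k, 9.0)}
    if name == "Parabolic":
        c2, c1, c0 = np.polyfit(t, mr, 2)
        return {"a": float(c0), "b": float(c1), "c": float(c2)}
    if name == "Wang and Singh":
        X = np.column_stack([t, t * t])
        a_, b_ = _linear_lstsq(X, mr - 1.0)
        return {"a": float(a_), "b": float(b_)}
    if name == "Chavez-Mendez et al.":
        return {"L1": k, "L2": 0.9}
    if name == "Logistic":
        return {"b": 2.0 * max(mr0, 1e-3), "a": 1.0, "k": k}
    if name == "Sledz et al.":
        return {"b": 2.0 * max(mr0, 1e-3), "k": k, "a": 1.0, "k1": -k}
    if name == "Simplified Fick's diffusion equation":
        return {"a": max(mr0, 1e-3), "k": k}  # k rescaled by L^2 by the caller
    if name == "Weibull":
        return {"a": 1.0 / k, "b": 1.0}
    if name == "Demir et al.":
        return {"a": max(mr0, 1e-3), "k": k, "n": 1.0, "b": 0.0}
    if name == "Taghian Dinani et al.":
        # centre the Gaussian left of t=0 so that MR(0) ~= 1 and the curve
        # decays over the observed window
        a = max(2.0 * float(t[-1]) / 3.0, 1.5)
        return {"a": a, "b": -a * float(np.sqrt(max(np.log(a), 0.0)))}
    if name == "Fernando and Amarasinghe":
        # MR - 1 = a t + b t^2 - c MR t is linear in (a, b, c)
        X = np.column_stack([t, t * t, -mr * t])
        a_, b_, c_ = _linear_lstsq(X, mr - 1.0)
        return {"a": float(a_), "b": float(b_), "c": float(c_)}
    raise KeyError(name)


def _clip_to_bounds(values: dict, spec: ModelSpec) -> dict:
    out = {}
    for p in spec.parameter_names:
        lo, hi = spec.default_bounds[p]
        out[p] = float(np.clip(values[p], lo, hi))
    return out


# --------------------------------------------------------------------------
# results object

@dataclass
class ThinLayerFit:
    """Results of fitting one drying model to one MR series."""

    model_name: str
    params: ParameterSet | None
    n_obs: int
    n_params: int
    r_squared: float
    chi_squared: float
    rmse: float
    residuals: np.ndarray | None
    converged: bool
    init_used: Mapping[str, float]
    thickness_L: float | None = None

    @property
    def sse(self) -> float:
        if self.residuals is None:
            return float("inf")
        return float(np.sum(self.residuals**2))

    def predict(self, times) -> np.ndarray:
        if self.params is None:
            raise ValueError("fit failed; no parameters to predict with")
        from .models import eval_model

        return eval_model(self.params, times, thickness_L=self.thickness_L)

    def as_dict(self) -> dict:
        return {
            "model": self.model_name,
            "params": dict(self.params.values) if self.params else None,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "r_squared": self.r_squared,
            "chi_squared": self.chi_squared,
            "rmse": self.rmse,
            "converged": self.converged,
        }

    def plot(self, times, observed=None, ax=None):
        """Quick-look plot of the fitted MR curve (requires matplotlib).

        ``observed`` values, if given, are overlaid as points.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.asarray(times, dtype=float)
        ax.plot(t, self.predict(t), "-", label=f"{self.model_name} fit")
        if observed is not None:
            ax.plot(t, np.asarray(observed, dtype=float), "o", ms=3,
                    label="observed")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("moisture ratio")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            f"Thin-layer drying fit: {self.model_name}",
            "=" * 46,
            f"{'No. observations:':<26}{self.n_obs}",
            f"{'No. constants (z):':<26}{self.n_params}",
            f"{'Converged:':<26}{self.converged}",
            f"{'R-squared:':<26}{self.r_squared:.6f}",
            f"{'Chi-squared:':<26}{self.chi_squared:.6f}",
            f"{'RMSE:':<26}{self.rmse:.6f}",
            "-" * 46,
        ]
        if self.params is not None:
            for p, v in self.params.values.items():
                lines.append(f"{p:<10}{v: .6g}")
        lines.append("=" * 46)
        return "\n".join(lines)


def _failed_fit(spec: ModelSpec, n: int, init: Mapping[str, float]) -> ThinLayerFit:
    return ThinLayerFit(
        model_name=spec.name,
        params=None,
        n_obs=n,
        n_params=spec.n_params,
        r_squared=-np.inf,
        chi_squared=np.inf,
        rmse=np.inf,
        residuals=None,
        converged=False,
        init_used=dict(init),
    )


# --------------------------------------------------------------------------
# model object

class ThinLayerModel:
    """A drying-model curve fit, statsmodels style.

    Parameters
    ----------
    times : array-like
        Strictly increasing observation times in minutes.
    mr : array-like
        Observed moisture ratios, finite.
    model : str or ModelSpec
        Which catalog model to fit.
    thickness : float, optional
        Full slab thickness in metres.  Needed by the simplified Fickian
        form (whose argument is ``t / L**2`` with L the half-thickness);
        when absent that form is fitted with ``L = 1`` so its rate
        constant lumps the geometry.
    """

    def __init__(self, times, mr, model: str | ModelSpec,
                 thickness: float | None = None):
        t = np.asarray(times, dtype=float)
        y = np.asarray(mr, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("times and mr must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite moisture-ratio values")
        self.spec = model if isinstance(model, ModelSpec) else get_model(model)
        if t.size <= self.spec.n_params:
            raise ValueError(
                f"need N > z: N={t.size}, z={self.spec.n_params} "
                f"for {self.spec.name!r}"
            )
        self.times = t
        self.mr = y
        self.thickness = thickness
        self.half_thickness = None if thickness is None else thickness / 2.0

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model: str | ModelSpec,
                       time_col: str = "time_min", mr_col: str = "mr",
                       thickness: float | None = None) -> "ThinLayerModel":
        return cls(df[time_col].to_numpy(), df[mr_col].to_numpy(), model,
                   thickness=thickness)

    # -- fitting ----------------------------------------------------------

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        values = dict(zip(self.spec.parameter_names, x))
        L = self.half_thickness if self.spec.requires_thickness else None
        if self.spec.requires_thickness and L is None:
            L = 1.0
        pred = _eval_raw(self.spec.name, values, self.times, L)
        res = pred - self.mr
        bad = ~np.isfinite(res)
        if bad.any():
            res = np.where(bad, _PENALTY, res)
        return res

    def fit(self, init: ParameterSet | Mapping[str, float] | None = None,
            bounds: Mapping[str, tuple[float, float]] | None = None,
            multistart: int = 0, seed: int | None = None) -> ThinLayerFit:
        """Least-squares fit; returns a results object, never raises on
        non-convergence (``converged=False`` is preserved with the best
        found parameters or sentinel statistics).

        ``multistart > 0`` adds that many seeded log-normal perturbations
        of the deterministic start and keeps the lowest-SSE solution.
        """
        spec = self.spec
        if init is None:
            init_vals = _default_init(spec, self.times, self.mr)
            if spec.requires_thickness and self.half_thickness is not None:
                init_vals["k"] *= self.half_thickness**2
        elif isinstance(init, ParameterSet):
            init_vals = dict(init.values)
        else:
            init_vals = dict(init)
        init_vals = _clip_to_bounds(init_vals, spec)

        if bounds is None:
            lo, hi = spec.bounds_arrays()
        else:
            merged = dict(spec.default_bounds)
            merged.update(bounds)
            lo = np.array([merged[p][0] for p in spec.parameter_names])
            hi = np.array([merged[p][1] for p in spec.parameter_names])

        # the simplified Fickian rate constant k is O(L^2) ~ 1e-7 smaller
        # than the other constants; optimise it as k/L^2 for conditioning
        scale = np.ones(spec.n_params)
        if spec.requires_thickness and self.half_thickness is not None:
            scale[spec.parameter_names.index("k")] = self.half_thickness**2

        starts = [np.array([init_vals[p] for p in spec.parameter_names], float)]
        if multistart > 0:
            rng = np.random.default_rng(seed)
            for _ in range(multistart):
                factor = rng.lognormal(0.0, 0.7, size=len(starts[0]))
                shift = rng.normal(0.0, 0.1, size=len(starts[0]))
                starts.append(np.clip(starts[0] * factor + shift, lo, hi))

        best = None
        for x0 in starts:
            y0 = np.clip(x0, lo, hi) / scale
            try:
                sol = least_squares(
                    lambda y: self._residuals(y * scale), y0,
                    bounds=(lo / scale, hi / scale), method="trf",
                    x_scale="jac", ftol=1e-14, xtol=1e-14, gtol=1e-14,
                    max_nfev=5000,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol

        n = self.times.size
        if best is None or not np.all(np.isfinite(best.x)):
            return _failed_fit(spec, n, init_vals)

        values = dict(zip(spec.parameter_names,
                          (float(v) for v in best.x * scale)))
        params = ParameterSet(spec.name, values)
        L = self.half_thickness if spec.requires_thickness else None
        if spec.requires_thickness and L is None:
            L = 1.0
        pred = _eval_raw(spec.name, values, self.times, L)
        if not np.all(np.isfinite(pred)):
            return _failed_fit(spec, n, init_vals)
        try:
            r2, chi2, rmse = goodness_of_fit(self.mr, pred, spec.n_params)
        except ValueError:
            return _failed_fit(spec, n, init_vals)
        return ThinLayerFit(
            model_name=spec.name,
            params=params,
            n_obs=n,
            n_params=spec.n_params,
            r_squared=r2,
            chi_squared=chi2,
            rmse=rmse,
            residuals=self.mr - pred,
            converged=bool(best.success),
            init_used=init_vals,
            thickness_L=L,
        )


# --------------------------------------------------------------------------
# catalog-wide fitting and selection

@dataclass
class SelectionTable:
    """Ranked fits of several models to one drying condition."""

    label: str
    results: list[ThinLayerFit] = field(default_factory=list)

    def __post_init__(self):
        self.results = sorted(self.results, key=_rank_key)

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def best(self) -> ThinLayerFit:
        if not self.results:
            raise ValueError("empty selection table")
        top = self.results[0]
        if not np.isfinite(top.rmse):
            raise ValueError("all fits failed; no best model")
        return top

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, r in enumerate(self.results, start=1):
            row = {"rank": rank, "model": r.model_name,
                   "r_squared": r.r_squared, "chi_squared": r.chi_squared,
                   "rmse": r.rmse, "n_params": r.n_params,
                   "converged": r.converged}
            if r.params is not None:
                row["constants"] = "; ".join(
                    f"{p}={v:.6g}" for p, v in r.params.values.items()
                )
            else:
                row["constants"] = ""
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {"label": self.label, "results": [r.as_dict() for r in self.results]},
            indent=2, allow_nan=True,
        )

    def summary(self) -> str:
        df = self.to_frame()
        return f"Model selection — {self.label}\n" + df.to_string(index=False)


def _rank_key(r: ThinLayerFit):
    # highest R^2, then lowest RMSE, then fewest constants, then name
    r2 = r.r_squared if np.isfinite(r.r_squared) else -np.inf
    rmse = r.rmse if np.isfinite(r.rmse) else np.inf
    return (-r2, rmse, r.n_params, r.model_name)


def fit_model(times, mr, model: str | ModelSpec,
              init=None, bounds=None, thickness: float | None = None,
              multistart: int = 0, seed: int | None = None) -> ThinLayerFit:
    """Functional wrapper around :meth:`ThinLayerModel.fit`."""
    return ThinLayerModel(times, mr, model, thickness=thickness).fit(
        init=init, bounds=bounds, multistart=multistart, seed=seed
    )


def fit_catalog(times, mr, models: Iterable[str | ModelSpec] | None = None,
                label: str = "", thickness: float | None = None,
                multistart: int = 0, seed: int | None = None) -> SelectionTable:
    """Fit every requested catalog model and rank the results.

    A model whose fit fails (optimizer breakdown, undefined statistics,
    or N <= z) is recorded with ``converged=False`` and infinite-SSE
    sentinel statistics rather than raised.
    """
    specs = [m if isinstance(m, ModelSpec) else get_model(m)
             for m in (models if models is not None else model_catalog())]
    if not specs:
        raise ValueError("empty model list")
    results = []
    for spec in specs:
        try:
            fit = fit_model(times, mr, spec, thickness=thickness,
                            multistart=multistart, seed=seed)
        except ValueError:
            n = np.asarray(times).size
            fit = _failed_fit(spec, n, {})
        results.append(fit)
    return SelectionTable(label=label, results=results)


#: alias matching the vocabulary of batch fitting over all 22 forms
fit_all = fit_catalog


def select_best(table: SelectionTable) -> ThinLayerFit:
    """Rank-1 entry of a selection table (highest R^2 / lowest RMSE)."""
    return table.best()
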