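"""Catalog of thin-layer drying models.

Thin-layer drying experiments record the dimensionless moisture ratio
``MR(t)`` of a product dried in a single layer.  Decades of food-process
literature describe these curves with a small zoo of empirical closed
forms (Newton, Page, Henderson and Pabis, Midilli, logistic-type models,
...).  This module defines the catalog of 22 such models, each with named
constants drawn from ``{a, b, c, k, k1, k2, n, L1, L2}``, and evaluates
any of them on a time grid.

Time is in minutes throughout model space.  The "Simplified Fick's
diffusion equation" additionally needs the slab half-thickness ``L`` in
metres; it is the only catalog entry with a geometric argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "DomainError",
    "ModelSpec",
    "ParameterSet",
    "model_catalog",
    "get_model",
    "model_names",
    "eval_model",
    "nested_reduction",
    "catalog_as_json",
]


class DomainError(ValueError):
    """A model expression is mathematically undefined at the requested point."""


@dataclass(frozen=True)
class ModelSpec:
    """One drying-model equation.

    Attributes
    ----------
    name : str
        Model identifier as used in the drying literature.
    parameter_names : tuple of str
        Ordered constant names, unique within the spec.
    expression : str
        Human-readable closed form (documentation / JSON export only;
        evaluation is hand-coded).
    anchored_at_one : bool
        True when the expression forces ``MR(0) = 1`` for every
        admissible parameter set.
    default_bounds : mapping
        Per-parameter ``(lower, upper)`` fitting bounds.  Rate constants
        are kept positive, shape exponents positive, amplitudes wide, so
        that large degenerate optima (e.g. logistic ``b ~ 7.6e5``)
        remain representable.
    requires_thickness : bool
        True only for the simplified Fickian form, whose argument is
        ``t / L**2``.
    """

    name: str
    parameter_names: tuple[str, ...]
    expression: str
    anchored_at_one: bool
    default_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    requires_thickness: bool = False

    def __post_init__(self) -> None:
        if len(set(self.parameter_names)) != len(self.parameter_names):
            raise ValueError(f"duplicate parameter names in {self.name!r}")

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.default_bounds[p][0] for p in self.parameter_names])
        hi = np.array([self.default_bounds[p][1] for p in self.parameter_names])
        return lo, hi


@dataclass(frozen=True)
class ParameterSet:
    """Named constants for one catalog model."""

    model_name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        spec = get_model(self.model_name)
        if set(self.values) != set(spec.parameter_names):
            raise ValueError(
                f"{self.model_name!r} expects parameters {spec.parameter_names}, "
                f"got {tuple(self.values)}"
            )
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite value for {name!r}: {v}")

    def as_array(self) -> np.ndarray:
        spec = get_model(self.model_name)
        return np.array([self.values[p] for p in spec.parameter_names], float)

    def __getitem__(self, key: str) -> float:
        return float(self.values[key])


# --------------------------------------------------------------------------
# closed forms
#
# Each evaluator takes (t, p, L) with t an ndarray of minutes, p a dict of
# constants, L the slab half-thickness in metres (ignored except by the
# simplified Fickian form).  Evaluators return raw floats; undefined points
# come back as nan/inf and are turned into DomainError by eval_model.

_EVALUATORS: dict[str, Callable[..., np.ndarray]] = {}


def _evaluator(name: str):
    def deco(fn):
        _EVALUATORS[name] = fn
        return fn

    return deco


@_evaluator("Newton")
def _newton(t, p, L=None):
    return np.exp(-p["k"] * t)


@_evaluator("Henderson and Pabis")
def _henderson_pabis(t, p, L=None):
    return p["a"] * np.exp(-p["k"] * t)


@_evaluator("Logarithmic")
def _logarithmic(t, p, L=None):
    return p["a"] * np.exp(-p["k"] * t) + p["c"]


@_evaluator("Page")
def _page(t, p, L=None):
    return np.exp(-p["k"] * np.power(t, p["n"]))


@_evaluator("Modified Page 1")
def _modified_page_1(t, p, L=None):
    return np.exp(-np.power(p["k"] * t, p["n"]))


@_evaluator("Modified Page 2")
def _modified_page_2(t, p, L=None):
    # exp(-kt)^n == exp(-k n t); k and n are not separately identifiable.
    return np.exp(-p["k"] * t) ** p["n"]


@_evaluator("Midilli et al.")
def _midilli(t, p, L=None):
    return p["a"] * np.exp(-p["k"] * np.power(t, p["n"])) + p["b"] * t


@_evaluator("Two terms")
def _two_terms(t, p, L=None):
    return p["a"] * np.exp(-p["k"] * t) + p["b"] * np.exp(-p["k1"] * t)


@_evaluator("Two-term exponential")
def _two_term_exponential(t, p, L=None):
    a, k = p["a"], p["k"]
    return a * np.exp(-k * t) + (1.0 - a) * np.exp(-k * a * t)


@_evaluator("Approximation of diffusion")
def _approximation_of_diffusion(t, p, L=None):
    a, k, b = p["a"], p["k"], p["b"]
    return a * np.exp(-k * t) + (1.0 - a) * np.exp(-k * b * t)


@_evaluator("Verma et al.")
def _verma(t, p, L=None):
    a, k, k1 = p["a"], p["k"], p["k1"]
    return a * np.exp(-k * t) + (1.0 - a) * np.exp(-k1 * t)


@_evaluator("Modified Henderson and Pabis")
def _modified_henderson_pabis(t, p, L=None):
    return (
        p["a"] * np.exp(-p["k"] * t)
        + p["b"] * np.exp(-p["k1"] * t)
        + p["c"] * np.exp(-p["k2"] * t)
    )


@_evaluator("Parabolic")
def _parabolic(t, p, L=None):
    return p["a"] + p["b"] * t + p["c"] * t * t


@_evaluator("Wang and Singh")
def _wang_singh(t, p, L=None):
    return 1.0 + p["a"] * t + p["b"] * t * t


@_evaluator("Chavez-Mendez et al.")
def _chavez_mendez(t, p, L=None):
    # MR = (1 - (1 - L2) L1 t) ** (1 / (1 - L2)); undefined for negative
    # base with non-integer exponent, or L2 == 1.
    L1, L2 = p["L1"], p["L2"]
    if L2 == 1.0:
        return np.full_like(np.asarray(t, float), np.nan)
    base = 1.0 - (1.0 - L2) * L1 * np.asarray(t, float)
    with np.errstate(invalid="ignore"):
        return np.power(base, 1.0 / (1.0 - L2))


@_evaluator("Logistic")
def _logistic(t, p, L=None):
    with np.errstate(over="ignore"):
        return p["b"] / (1.0 + p["a"] * np.exp(p["k"] * t))


@_evaluator("Sledz et al.")
def _sledz(t, p, L=None):
    with np.errstate(over="ignore"):
        return p["b"] * np.exp(-p["k"] * t) / (1.0 + p["a"] * np.exp(p["k1"] * t))


@_evaluator("Simplified Fick's diffusion equation")
def _simplified_fick(t, p, L=None):
    if L is None:
        raise DomainError(
            "the simplified Fickian form needs the slab half-thickness L (m)"
        )
    return p["a"] * np.exp(-p["k"] * np.asarray(t, float) / (L * L))


@_evaluator("Weibull")
def _weibull(t, p, L=None):
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.exp(-np.power(np.asarray(t, float) / p["a"], p["b"]))


@_evaluator("Demir et al.")
def _demir(t, p, L=None):
    return p["a"] * np.exp(-p["k"] * t) ** p["n"] + p["b"]


@_evaluator("Taghian Dinani et al.")
def _taghian_dinani(t, p, L=None):
    # The literature prints the prefactor and the Gaussian width as the
    # same constant a; implemented literally with the single shared a.
    a, b = p["a"], p["b"]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.asarray(t, float) - b) / a
    return a * np.exp(-z * z)


@_evaluator("Fernando and Amarasinghe")
def _fernando_amarasinghe(t, p, L=None):
    t = np.asarray(t, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (1.0 + p["a"] * t + p["b"] * t * t) / (1.0 + p["c"] * t)


# --------------------------------------------------------------------------
# catalog

_RATE = (1e-8, 10.0)          # 1/min, strictly positive rate constants
_RATE_SIGNED = (-10.0, 10.0)  # logistic-type denominators admit negative rates
_AMP = (0.0, 1e7)             # non-negative amplitudes (logistic b, a)
_AMP_SIGNED = (-1e7, 1e7)
_SHAPE = (1e-3, 10.0)         # exponents n, Weibull shape
_POLY = (-10.0, 10.0)         # polynomial / rational coefficients on a minutes grid


def _spec(name, params, expr, anchored, bounds, requires_thickness=False):
    return ModelSpec(
        name=name,
        parameter_names=tuple(params),
        expression=expr,
        anchored_at_one=anchored,
        default_bounds=dict(bounds),
        requires_thickness=requires_thickness,
    )


_CATALOG: tuple[ModelSpec, ...] = (
    _spec("Newton", ("k",), "MR = exp(-k t)", True, {"k": _RATE}),
    _spec("Henderson and Pabis", ("a", "k"), "MR = a exp(-k t)", False,
          {"a": (0.0, 1e7), "k": _RATE}),
    _spec("Logarithmic", ("a", "k", "c"), "MR = a exp(-k t) + c", False,
          {"a": _AMP_SIGNED, "k": _RATE, "c": _AMP_SIGNED}),
    _spec("Page", ("k", "n"), "MR = exp(-k t^n)", True,
          {"k": _RATE, "n": _SHAPE}),
    _spec("Modified Page 1", ("k", "n"), "MR = exp(-(k t)^n)", True,
          {"k": _RATE, "n": _SHAPE}),
    _spec("Modified Page 2", ("k", "n"), "MR = exp(-k t)^n", True,
          {"k": _RATE, "n": _SHAPE}),
    _spec("Midilli et al.", ("a", "k", "n", "b"), "MR = a exp(-k t^n) + b t", False,
          {"a": _AMP_SIGNED, "k": _RATE, "n": _SHAPE, "b": (-1.0, 1.0)}),
    _spec("Two terms", ("a", "k", "b", "k1"),
          "MR = a exp(-k t) + b exp(-k1 t)", False,
          {"a": _AMP_SIGNED, "k": _RATE, "b": _AMP_SIGNED, "k1": _RATE}),
    _spec("Two-term exponential", ("a", "k"),
          "MR = a exp(-k t) + (1 - a) exp(-k a t)", True,
          {"a": (1e-6, 5.0), "k": _RATE}),
    _spec("Approximation of diffusion", ("a", "k", "b"),
          "MR = a exp(-k t) + (1 - a) exp(-k b t)", True,
          {"a": (-10.0, 10.0), "k": _RATE, "b": (1e-6, 10.0)}),
    _spec("Verma et al.", ("a", "k", "k1"),
          "MR = a exp(-k t) + (1 - a) exp(-k1 t)", True,
          {"a": (-10.0, 10.0), "k": _RATE, "k1": _RATE}),
    _spec("Modified Henderson and Pabis", ("a", "k", "b", "k1", "c", "k2"),
          "MR = a exp(-k t) + b exp(-k1 t) + c exp(-k2 t)", False,
          {"a": _AMP_SIGNED, "k": _RATE, "b": _AMP_SIGNED, "k1": _RATE,
           "c": _AMP_SIGNED, "k2": _RATE}),
    _spec("Parabolic", ("a", "b", "c"), "MR = a + b t + c t^2", False,
          {"a": _POLY, "b": _POLY, "c": _POLY}),
    _spec("Wang and Singh", ("a", "b"), "MR = 1 + a t + b t^2", True,
          {"a": _POLY, "b": _POLY}),
    _spec("Chavez-Mendez et al.", ("L1", "L2"),
          "MR = (1 - (1 - L2) L1 t)^(1/(1 - L2))", True,
          {"L1": (1e-8, 10.0), "L2": (-100.0, 1.0 - 1e-6)}),
    _spec("Logistic", ("b", "a", "k"), "MR = b / (1 + a exp(k t))", False,
          {"b": _AMP, "a": _AMP, "k": _RATE}),
    _spec("Sledz et al.", ("b", "k", "a", "k1"),
          "MR = b exp(-k t) / (1 + a exp(k1 t))", False,
          {"b": _AMP, "k": (0.0, 10.0), "a": _AMP, "k1": _RATE_SIGNED}),
    _spec("Simplified Fick's diffusion equation", ("a", "k"),
          "MR = a exp(-k t / L^2)", False,
          {"a": (0.0, 1e7), "k": (0.0, 1e7)}, requires_thickness=True),
    _spec("Weibull", ("a", "b"), "MR = exp(-(t/a)^b)", True,
          {"a": (1e-6, 1e7), "b": _SHAPE}),
    _spec("Demir et al.", ("a", "k", "n", "b"), "MR = a exp(-k t)^n + b", False,
          {"a": _AMP_SIGNED, "k": _RATE, "n": _SHAPE, "b": _AMP_SIGNED}),
    _spec("Taghian Dinani et al.", ("a", "b"), "MR = a exp(-((t - b)/a)^2)", False,
          {"a": (1e-6, 1e7), "b": (-1e7, 1e7)}),
    _spec("Fernando and Amarasinghe", ("a", "b", "c"),
          "MR = (1 + a t + b t^2) / (1 + c t)", True,
          {"a": _POLY, "b": _POLY, "c": _POLY}),
)

_BY_NAME = {s.name: s for s in _CATALOG}
assert len(_CATALOG) == 22


def model_catalog() -> list[ModelSpec]:
    """Return the 22 catalog models in their canonical order."""
    return list(_CATALOG)


def model_names() -> list[str]:
    return [s.name for s in _CATALOG]


def get_model(name: str) -> ModelSpec:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown drying model {name!r}; see model_names() for the catalog"
        ) from None


def _eval_raw(name: str, values: Mapping[str, float], times,
              thickness_L: float | None = None) -> np.ndarray:
    """Evaluate a model leaving undefined points as nan/inf (fitter path)."""
    t = np.asarray(times, dtype=float)
    return np.asarray(_EVALUATORS[name](t, values, thickness_L), dtype=float)


def eval_model(params: ParameterSet, times: Sequence[float],
               thickness_L: float | None = None) -> np.ndarray:
    """Evaluate a catalog model at the given times (minutes).

    Parameters
    ----------
    params : ParameterSet
        Model name plus a full set of named constants.
    times : array-like
        Non-negative times in minutes.
    thickness_L : float, optional
        Slab half-thickness in metres; required only by the simplified
        Fickian form.

    Returns
    -------
    ndarray
        Moisture-ratio values, finite wherever the expression is defined.

    Raises
    ------
    DomainError
        If the expression is undefined at any requested point (negative
        base under a non-integer power, division by zero, ...).
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    spec = get_model(params.model_name)
    if spec.requires_thickness and thickness_L is None:
        raise DomainError(f"{spec.name!r} requires thickness_L")
    out = _eval_raw(spec.name, params.values, t, thickness_L)
    if not np.all(np.isfinite(out)):
        raise DomainError(
            f"{spec.name!r} is undefined at some of the requested times "
            f"for the given parameters"
        )
    return out


# --------------------------------------------------------------------------
# documented algebraic nestings (used by model selection and its tests)

def _map_sledz_a0(v):
    return {"a": v["b"], "k": v["k"]}


def _map_sledz_k0(v):
    return {"b": v["b"], "a": v["a"], "k": v["k1"]}


def _map_page_n1(v):
    return {"k": v["k"]}


def _map_hp_a1(v):
    return {"k": v["k"]}


_NESTINGS: dict[tuple[str, tuple[tuple[str, float], ...]], tuple[str, Callable]] = {
    ("Sledz et al.", (("a", 0.0),)): ("Henderson and Pabis", _map_sledz_a0),
    ("Sledz et al.", (("k", 0.0),)): ("Logistic", _map_sledz_k0),
    ("Page", (("n", 1.0),)): ("Newton", _map_page_n1),
    ("Henderson and Pabis", (("a", 1.0),)): ("Newton", _map_hp_a1),
}


def nested_reduction(parent: str, constraint: Mapping[str, float]
                     ) -> tuple[str, Callable[[Mapping[str, float]], dict]]:
    """Resolve a documented algebraic nesting.

    Given a parent model and a pinning constraint (e.g. Sledz with
    ``a = 0``), return the equivalent child model name and a function
    mapping full parent parameter values to child values.  The parent
    under the constraint and the mapped child agree at every time.
    """
    key = (parent, tuple(sorted(constraint.items())))
    try:
        child, mapper = _NESTINGS[key]
    except KeyError:
        raise KeyError(
            f"no documented nesting for {parent!r} under {dict(constraint)!r}"
        ) from None
    return child, mapper


#: Models algebraically reachable from the Sledz form by pinning constants
#: (used when judging whether a selection landed in the Sledz family).
SLEDZ_FAMILY = frozenset(
    {"Sledz et al.", "Logistic", "Henderson and Pabis", "Newton"}
)


def catalog_as_json() -> list[dict]:
    """Catalog as plain dicts (name, parameters, expression) for export."""
    return [
        {
            "name": s.name,
            "parameters": list(s.parameter_names),
            "expression": s.expression,
            "anchored_at_one": s.anchored_at_one,
            "requires_thickness": s.requires_thickness,
        }
        for s in _CATALOG
    ]
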