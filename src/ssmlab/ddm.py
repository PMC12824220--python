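"""Drift diffusion model zoo with trial-level regression on value regressors.

Each model maps value regressors onto DDM parameters through linear
formulas (Wilkinson-style term lists), simulates by Euler-Maruyama with
unit diffusion, and supports either a static bound or a linearly
collapsing ("angle") bound B(t) = max(0, a - theta * t) with symmetric
absorbing barriers at +/-B(t).

Response coding maps the upper bound to the *left* option; accuracy
coding maps it to the objectively better bundle.  Regression-driven
threshold and collapse parameters pass through a softplus link to stay
positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .task import REGRESSOR_COLUMNS

INTERCEPT = "Intercept"

#: regressors whose sign flips when left and right are swapped; these are
#: scaled but never centred when standardising for fitting
SIGNED_REGRESSORS = {"signVD", "maxVD", "minVD"}


@dataclass(frozen=True)
class ModelSpec:
    """One row of the model zoo: bound type plus per-parameter formulas.

    ``formulas`` maps 'v', 'a' (and 'theta' for angle models) to ordered
    term lists; an ``Intercept`` entry plays the role of the ``1`` in
    ``a ~ 1 + absVD``.  ``extra_params`` are additional scalar free
    parameters (starting point ``z``, lapse rate ``p_outlier``, drift
    variability ``sv``).  Non-decision time ``t0`` is always estimated
    but, by the conventional count, not a "free parameter" of the model
    comparison.
    """

    name: str
    bound_type: str  # "static" | "angle"
    formulas: Mapping[str, tuple[str, ...]]
    extra_params: frozenset[str] = frozenset()
    coding: str = "response"  # "response" | "accuracy"

    def __post_init__(self) -> None:
        if self.bound_type not in ("static", "angle"):
            raise ValueError(f"unknown bound_type {self.bound_type!r}")
        if ("theta" in self.formulas) != (self.bound_type == "angle"):
            raise ValueError("theta formula present iff bound_type is 'angle'")
        for par, terms in self.formulas.items():
            for term in terms:
                if term not in REGRESSOR_COLUMNS and term not in (INTERCEPT, "hard", "easy"):
                    raise ValueError(f"unknown regressor {term!r} in formula for {par!r}")
        if not self.extra_params <= {"z", "p_outlier", "sv"}:
            raise ValueError("extra_params must be a subset of {z, p_outlier, sv}")

    @property
    def coefficient_names(self) -> tuple[str, ...]:
        names = []
        for par in ("v", "a", "theta", "z"):
            for term in self.formulas.get(par, ()):
                names.append(f"{par}_{term}")
        return tuple(names)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        """All fitted quantities, non-decision time included."""
        return self.coefficient_names + tuple(sorted(self.extra_params)) + ("t0",)


def _spec(name, bound, v, a, theta=None, extras=("z", "p_outlier"), coding="response"):
    formulas = {"v": tuple(v), "a": tuple(a)}
    if theta is not None:
        formulas["theta"] = tuple(theta)
    return ModelSpec(name, bound, formulas, frozenset(extras), coding)


_VD_A = (INTERCEPT, "absMaxVD", "absMinVD")
_OV_A = (INTERCEPT, "maxOV", "minOV")
_VDOV_A = (INTERCEPT, "absMaxVD", "absMinVD", "maxOV", "minOV")
_MAXMIN_V = ("maxVD", "minVD")

_REGISTRY: dict[str, ModelSpec] = {}
for spec in [
    # The original study's specification: difficulty as a median split,
    # accuracy-coded, per-condition drift/threshold/start point.
    ModelSpec("Original", "static",
              {"v": ("hard", "easy"), "a": ("hard", "easy"), "z": ("hard", "easy")},
              frozenset(), "accuracy"),
    _spec("Original*", "static", ("signVD",), (INTERCEPT, "absVD")),
    _spec("VD", "static", _MAXMIN_V, _VD_A),
    _spec("OV", "static", _MAXMIN_V, _OV_A),
    _spec("VDOV", "static", _MAXMIN_V, _VDOV_A),
    _spec("VD both", "angle", _MAXMIN_V, _VD_A, _VD_A),
    _spec("VD init", "angle", _MAXMIN_V, _VD_A, (INTERCEPT,)),
    _spec("VD rate", "angle", _MAXMIN_V, (INTERCEPT,), _VD_A),
    _spec("OV both", "angle", _MAXMIN_V, _OV_A, _OV_A),
    _spec("OV init", "angle", _MAXMIN_V, _OV_A, (INTERCEPT,)),
    _spec("OV rate", "angle", _MAXMIN_V, (INTERCEPT,), _OV_A),
    _spec("VDOV both", "angle", _MAXMIN_V, _VDOV_A, _VDOV_A),
    _spec("VDOV init", "angle", _MAXMIN_V, _VDOV_A, (INTERCEPT,)),
    _spec("VDOV rate", "angle", _MAXMIN_V, (INTERCEPT,), _VDOV_A),
]:
    _REGISTRY[spec.name] = spec


def model_registry(name: str) -> ModelSpec:
    """Look up a model by name; raises with the list of valid names."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; valid names: {sorted(_REGISTRY)}"
        ) from None


def model_names() -> tuple[str, ...]:
    return tuple(_REGISTRY)


def count_free_params(spec: ModelSpec) -> int:
    """Free-parameter count for model comparison.

    All formula coefficients (intercepts included) plus the scalar extras
    in {z, p_outlier, sv}; non-decision time is excluded by convention.
    """
    n = sum(len(terms) for terms in spec.formulas.values())
    return n + len(spec.extra_params & {"z", "p_outlier", "sv"})


def softplus(x):
    """Numerically stable log(1 + exp(x)); positivity link for a and theta."""
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def _design_matrix(terms: Sequence[str], regressors: pd.DataFrame) -> np.ndarray:
    cols = []
    n = len(regressors)
    for term in terms:
        if term == INTERCEPT:
            cols.append(np.ones(n))
        elif term in ("hard", "easy"):
            median = regressors["absVD"].median()
            hard = regressors["absVD"].to_numpy() <= median
            cols.append(hard.astype(float) if term == "hard" else (~hard).astype(float))
        else:
            cols.append(regressors[term].to_numpy(float))
    return np.column_stack(cols) if cols else np.zeros((n, 0))


def trial_params(
    spec: ModelSpec,
    coefs: Mapping[str, float],
    regressors: pd.DataFrame,
) -> dict[str, np.ndarray]:
    """Per-trial DDM parameters from a coefficient record.

    Drift is the raw linear combination; threshold and collapse pass
    through softplus; z, t0 and p_outlier are broadcast (z defaults to an
    unbiased 0.5, p_outlier to 0 when the spec does not free them).
    Returns arrays keyed v, a, theta, z, t0, p_outlier (and sv).
    """
    missing = [c for c in spec.coefficient_names if c not in coefs]
    if missing:
        raise ValueError(f"missing coefficients for {spec.name}: {missing}")
    n = len(regressors)
    out: dict[str, np.ndarray] = {}
    for par in ("v", "a", "theta"):
        terms = spec.formulas.get(par, ())
        if not terms:
            out[par] = np.zeros(n)
            continue
        x = _design_matrix(terms, regressors)
        beta = np.array([coefs[f"{par}_{t}"] for t in terms], dtype=float)
        lin = x @ beta
        out[par] = lin if par == "v" else softplus(lin)
    if spec.bound_type == "static":
        out["theta"] = np.zeros(n)
    if "z" in spec.formulas:  # condition-dependent start point (Original)
        x = _design_matrix(spec.formulas["z"], regressors)
        beta = np.array([coefs[f"z_{t}"] for t in spec.formulas["z"]], dtype=float)
        out["z"] = 1.0 / (1.0 + np.exp(-(x @ beta)))
    else:
        out["z"] = np.full(n, float(coefs.get("z", 0.5)))
    out["t0"] = np.full(n, float(coefs.get("t0", 0.0)))
    out["p_outlier"] = np.full(n, float(coefs.get("p_outlier", 0.0)))
    sv = float(coefs.get("sv", 0.0))
    out["sv"] = np.full(n, sv)
    if np.any(out["z"] <= 0) or np.any(out["z"] >= 1):
        raise ValueError("start point z must lie strictly in (0, 1)")
    return out


def simulate_trials(
    params: Mapping[str, np.ndarray],
    dt: float = 0.001,
    deadline: float = 0.75,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one outcome per trial.

    Returns (choices, rts) with choice +1 for the upper bound, -1 for the
    lower bound and 0 for an omission (no crossing before the deadline);
    omitted trials carry NaN RT.  With probability ``p_outlier`` a trial
    is replaced by a lapse: random response, RT uniform on (0, deadline).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if deadline <= 0:
        raise ValueError("deadline must be positive")
    v = np.ascontiguousarray(params["v"], dtype=float)
    sv = np.asarray(params.get("sv", np.zeros_like(v)), dtype=float)
    if np.any(sv > 0):
        rng = np.random.default_rng(seed ^ 0x5F5F5F)
        v = v + rng.standard_normal(v.shape) * sv
    return _kernels.ddm_batch(
        v,
        np.ascontiguousarray(params["a"], dtype=float),
        np.ascontiguousarray(params["theta"], dtype=float),
        np.ascontiguousarray(params["z"], dtype=float),
        np.ascontiguousarray(params["t0"], dtype=float),
        np.ascontiguousarray(params["p_outlier"], dtype=float),
        float(dt),
        float(deadline),
        int(seed) % 2**31,
    )


def simulate_ddm_trial(
    v: float,
    a: float,
    theta: float = 0.0,
    z: float = 0.5,
    t0: float = 0.0,
    p_outlier: float = 0.0,
    dt: float = 0.001,
    deadline: float = 0.75,
    seed: int = 0,
) -> tuple[int, float]:
    """One first-passage outcome: (+1 upper, -1 lower, 0 omission; rt)."""
    ch, rt = simulate_trials(
        {k: np.array([val]) for k, val in
         dict(v=v, a=a, theta=theta, z=z, t0=t0, p_outlier=p_outlier).items()},
        dt=dt, deadline=deadline, seed=seed,
    )
    return int(ch[0]), float(rt[0])


# ---------------------------------------------------------------------------
# Closed-form oracle for the static two-barrier diffusion
# ---------------------------------------------------------------------------


def static_absorption_probability(v: float, a: float, z: float) -> float:
    """P(upper barrier first) for a static-bound diffusion, unit noise.

    Classical two-barrier result for a Wiener process on [0, A] with
    A = 2a, start x0 = 2az and drift v:
    P = (1 - exp(-2 v x0)) / (1 - exp(-2 v A)); P = z when v = 0.
    """
    if a <= 0:
        raise ValueError("a must be positive")
    if not 0 < z < 1:
        raise ValueError("z must lie strictly in (0, 1)")
    if v == 0:
        return float(z)
    big_a = 2.0 * a
    x0 = big_a * z
    with np.errstate(over="ignore"):
        num = -np.expm1(-2.0 * v * x0)
        den = -np.expm1(-2.0 * v * big_a)
    return float(num / den)


def static_first_passage_density(
    v: float, a: float, z: float, t_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """First-passage densities at the upper and lower barrier on a grid.

    Uses the large-time eigenfunction series for absorption of a Wiener
    process on [0, A], truncated adaptively (terms added until the decay
    factor is negligible at the smallest grid time).  Returns
    (f_upper(t), f_lower(t)); each integrates to the corresponding
    absorption probability.
    """
    if a <= 0 or not 0 < z < 1:
        raise ValueError("require a > 0 and 0 < z < 1")
    t = np.asarray(t_grid, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time grid must be strictly positive")
    big_a = 2.0 * a

    def lower_density(drift: float, x0: float) -> np.ndarray:
        t_min = t.min()
        # need k^2 pi^2 t_min / (2 A^2) ~ 46 for double-precision underflow
        k_max = int(np.ceil(np.sqrt(92.0) * big_a / (math.pi * math.sqrt(t_min)))) + 1
        k = np.arange(1, k_max + 1)
        lam = (k * math.pi / big_a) ** 2 / 2.0
        series = (k * np.sin(k * math.pi * x0 / big_a))[None, :] * np.exp(
            -lam[None, :] * t[:, None]
        )
        pref = (math.pi / big_a**2) * np.exp(-drift * x0 - 0.5 * drift**2 * t)
        return pref * series.sum(axis=1)

    x0 = big_a * z
    f_lower = lower_density(v, x0)
    f_upper = lower_density(-v, big_a - x0)
    return np.maximum(f_upper, 0.0), np.maximum(f_lower, 0.0)
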