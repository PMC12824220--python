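"""Group-level maximum-likelihood fitting via IBS and differential evolution.

The objective for a candidate parameter vector is the negative IBS
estimate of the categorical log-likelihood (stratified RT-decile
categories, overall-value median split, omissions as their own
categories), averaged over a small number of independent repeats to tame
estimator noise.  Optimization uses bounded differential evolution — a
population-based, derivative-free method that tolerates noisy
objectives — optionally restarted from independent populations.

Value regressors are standardised before fitting (sign-symmetric
regressors are scaled but not centred, so a zero regressor still means a
balanced trial); the scaling is stored on the result so fitted
coefficients can be mapped back to the raw euro scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize
from scipy.stats import qmc

from . import _kernels
from . import ddm as _ddm
from .binning import BinningScheme, build_bins, harmonic_table, normalize_rt
from .lca import LCAParams, trial_drives
from .task import correct_side

FIT_DT = 0.005  # simulation step during fitting
SAMPLE_DT = 0.001  # simulation step when sampling from a fitted model


@dataclass(frozen=True)
class OptimizerConfig:
    """Budget and noise-handling knobs for the derivative-free search."""

    popsize: int = 5  # DE population multiplier (individuals = popsize * n_params)
    maxiter: int = 30  # DE generations
    repeats: int = 1  # IBS repeats averaged per objective evaluation
    k_max: int = 48  # IBS draw cap during optimization
    n_restarts: int = 1  # independent DE runs; best result kept
    polish_maxfev: int = 60  # Nelder-Mead refinement evaluations (0 disables)
    polish_repeats: int = 4  # IBS repeats during refinement
    final_repeats: int = 8  # IBS repeats for the reported log-likelihood
    final_k_max: int = 1000
    abort_margin: float = 150.0  # early-abort when this far below best-so-far
    stagewise_threshold: int = 10  # above this many parameters, fit in two stages


@dataclass
class FitResult:
    """A fitted model: parameters, likelihood estimate, and provenance."""

    model: str
    params: dict[str, float]  # natural-scale record (DDM coefs on z-scored regressors)
    scaling: dict[str, tuple[float, float]]  # regressor -> (center, scale)
    loglik: float
    loglik_se: float
    n_trials: int
    n_free_params: int
    seed: int
    bounds: dict[str, tuple[float, float]]
    trace: list[tuple[int, float]]  # (evaluation index, best-so-far objective)
    n_evals: int
    converged: bool
    binning: dict = field(default_factory=dict)

    def params_natural(self) -> dict[str, float]:
        """Coefficients mapped back to the raw (euro) regressor scale."""
        out = dict(self.params)
        if self.model == "lca" or not self.scaling:
            return out
        spec = _ddm.model_registry(self.model)
        for par, terms in spec.formulas.items():
            intercept_shift = 0.0
            for term in terms:
                if term == _ddm.INTERCEPT or term in ("hard", "easy"):
                    continue
                center, scale = self.scaling[term]
                name = f"{par}_{term}"
                raw = out[name] / scale
                intercept_shift += raw * center
                out[name] = raw
            iname = f"{par}_{_ddm.INTERCEPT}"
            if iname in out:
                out[iname] = out[iname] - intercept_shift
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params_natural"] = self.params_natural()
        return d


def standardize_regressors(
    trials: pd.DataFrame, terms: set[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Z-score regressor columns; signed regressors are scaled, not centred."""
    out = trials.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for term in sorted(terms):
        if term in (_ddm.INTERCEPT, "hard", "easy"):
            continue
        x = out[term].to_numpy(float)
        center = 0.0 if term in _ddm.SIGNED_REGRESSORS else float(x.mean())
        scale = float(x.std(ddof=0))
        if scale == 0:
            scale = 1.0
        out[term] = (x - center) / scale
        scaling[term] = (center, scale)
    return out, scaling


def default_bounds(model: str) -> dict[str, tuple[float, float]]:
    """Plausible box constraints per free parameter (documented defaults).

    DDM coefficient bounds are on the standardised-regressor scale.
    """
    if model == "lca":
        return {
            "t0": (0.05, 0.35),
            "b": (1.0, 25.0),
            "m": (0.5, 1.0),
            "k": (0.3, 15.0),
            "w": (0.1, 15.0),
            "a0": (0.2, 2.5),
            "c": (0.05, 4.0),
            "sigma": (0.1, 1.6),
        }
    spec = _ddm.model_registry(model)
    bounds: dict[str, tuple[float, float]] = {}
    for par, terms in spec.formulas.items():
        for term in terms:
            name = f"{par}_{term}"
            if par == "v":
                bounds[name] = (-6.0, 6.0)
            elif term == _ddm.INTERCEPT or term in ("hard", "easy"):
                bounds[name] = (-2.5, 1.5)
            else:
                bounds[name] = (-1.5, 1.5)
    if "z" in spec.extra_params:
        bounds["z"] = (0.25, 0.75)
    if "p_outlier" in spec.extra_params:
        bounds["p_outlier"] = (0.0, 0.1)
    if "sv" in spec.extra_params:
        bounds["sv"] = (0.0, 3.0)
    bounds["t0"] = (0.05, 0.35)
    return bounds


def _heuristic_x0(model: str, trials: pd.DataFrame, names: list[str],
                  box: list[tuple[float, float]]) -> np.ndarray:
    """Moment-based starting point, clipped into the box.

    For DDMs, inverts the static two-barrier relations at the dataset
    level: accuracy ~ 1/(1+exp(-2 v a)) and mean decision time
    ~ (a/v) tanh(v a) give a drift magnitude and threshold; drift
    coefficients then scale by the mean magnitude of their (signed)
    regressor.  For the LCA the documented default parameter set is the
    guess.  Crude on purpose — it only needs to land in the right basin.
    """
    responded = trials[trials["response"].isin(("left", "right"))]
    rt_mean = float(responded["rt"].mean())
    t0_hat = max(0.06, 0.85 * float(responded["rt"].min()))
    acc = float(np.clip(responded["correct"].mean(), 0.55, 0.95))
    x0 = {}
    if model == "lca":
        x0 = LCAParams().as_dict()
        x0["t0"] = t0_hat
    else:
        spec = _ddm.model_registry(model)
        dec_time = max(0.05, rt_mean - t0_hat)
        # solve acc/dec_time for (v, a) via the static closed forms
        va = 0.5 * math.log(acc / (1.0 - acc))  # v*a from accuracy
        a_hat = math.sqrt(max(1e-4, dec_time * va / math.tanh(va))) if va > 0 else 0.3
        v_hat = va / a_hat if a_hat > 0 else 1.0
        for par, terms in spec.formulas.items():
            for term in terms:
                name = f"{par}_{term}"
                if par == "v":
                    if term in ("hard", "easy"):
                        x0[name] = v_hat
                    else:
                        mag = float(np.abs(trials[term]).mean()) or 1.0
                        x0[name] = v_hat / mag / max(1, len(terms))
                elif term == _ddm.INTERCEPT or term in ("hard", "easy"):
                    # softplus^-1(a_hat) for a; mild collapse for theta
                    target = a_hat if par == "a" else (0.0 if par != "z" else 0.0)
                    x0[name] = (
                        math.log(math.expm1(max(target, 1e-3))) if par in ("a", "theta")
                        else 0.0
                    )
                else:
                    x0[name] = 0.0
        x0["z"] = 0.5
        x0["p_outlier"] = 0.02
        x0["sv"] = 0.5
        x0["t0"] = t0_hat
    vec = np.array([x0.get(n, 0.0) for n in names], dtype=float)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    return np.clip(vec, lo + 1e-9, hi - 1e-9)


class _Objective:
    """Negative IBS log-likelihood over the pooled table, with trace."""

    def __init__(self, model, trials, scheme, config, deadline, seed):
        self.model = model
        self.scheme = scheme
        self.config = config
        self.deadline = float(deadline)
        self.seed = int(seed) % 2**31
        self.harm = harmonic_table(max(config.k_max, config.final_k_max))
        self.obs_cat = np.ascontiguousarray(scheme.categorize(trials))
        self.flags = np.ascontiguousarray(scheme.flags(trials))
        self.cs = np.ascontiguousarray(correct_side(trials))
        self.trials = trials
        self.n_evals = 0
        self.best = math.inf
        self.trace: list[tuple[int, float]] = []
        if model != "lca":
            self.spec = _ddm.model_registry(model)
            self.names = list(self.spec.parameter_names)
        else:
            self.names = list(LCAParams.param_names())

    def _loglik_once(self, x: np.ndarray, k_max: int, seed: int, ll_floor: float) -> float:
        if self.model == "lca":
            rec = dict(zip(self.names, x))
            params = LCAParams(**rec)
            i1, i2 = trial_drives(params, self.trials)
            ones = np.ones(len(self.trials), dtype=np.int64)
            ll, _ = _kernels.ibs_lca(
                self.obs_cat, i1, i2, params.k, params.w, params.a0, params.c,
                params.sigma, params.t0, ones, self.flags, self.scheme.edges,
                self.scheme.n_bins, FIT_DT, self.deadline, k_max, self.harm, seed, False,
                ll_floor,
            )
            return ll
        rec = dict(zip(self.names, x))
        p = _ddm.trial_params(self.spec, rec, self.trials)
        cs = self.cs if self.spec.coding == "response" else np.ones_like(self.cs)
        ll, _ = _kernels.ibs_ddm(
            self.obs_cat, np.ascontiguousarray(p["v"]), np.ascontiguousarray(p["a"]),
            np.ascontiguousarray(p["theta"]), np.ascontiguousarray(p["z"]),
            np.ascontiguousarray(p["t0"]), np.ascontiguousarray(p["p_outlier"]),
            cs, self.flags, self.scheme.edges, self.scheme.n_bins,
            FIT_DT, self.deadline, k_max, self.harm, seed, ll_floor,
        )
        return ll

    def loglik(
        self, x: np.ndarray, repeats: int, k_max: int, use_floor: bool = False
    ) -> tuple[float, float]:
        if k_max >= self.harm.size:
            raise ValueError(f"k_max={k_max} exceeds the harmonic table ({self.harm.size - 1})")
        floor = -(self.best + self.config.abort_margin) if use_floor else -math.inf
        vals = []
        for r in range(repeats):
            s = (self.seed + 1_000_003 * (self.n_evals + 1) + 7919 * r + 1) % 2**31
            vals.append(self._loglik_once(np.asarray(x, float), k_max, s, floor))
        vals = np.asarray(vals)
        se = float(vals.std(ddof=1) / np.sqrt(repeats)) if repeats > 1 else float("nan")
        return float(vals.mean()), se

    def __call__(self, x: np.ndarray) -> float:
        ll, _ = self.loglik(x, self.config.repeats, self.config.k_max, use_floor=True)
        self.n_evals += 1
        obj = -ll
        if obj < self.best:
            self.best = obj
            self.trace.append((self.n_evals, obj))
        return obj


def fit_model(
    trials: pd.DataFrame,
    model: str,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    config: OptimizerConfig | None = None,
    seed: int = 0,
    deadline: float = 0.75,
    strata: str = "OV",
    n_quantiles: int = 10,
    normalize: bool = True,
) -> FitResult:
    """Fit a DDM from the registry (by name) or the LCA ("lca") at group level.

    The trial table must carry design, regressor and outcome columns.
    RTs are between-subject normalised, the stratified decile scheme is
    built from the observed data, and the model's simulator is matched
    to the observed categories through IBS.  Fully reproducible given
    ``seed``.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    config = config or OptimizerConfig()
    if normalize:
        trials = normalize_rt(trials)
    scheme = build_bins(trials, strata=strata, n_quantiles=n_quantiles)

    scaling: dict[str, tuple[float, float]] = {}
    if model != "lca":
        spec = _ddm.model_registry(model)
        used = {t for terms in spec.formulas.values() for t in terms}
        trials, scaling = standardize_regressors(trials, used)
        names = list(spec.parameter_names)
        n_free = _ddm.count_free_params(spec)
    else:
        names = list(LCAParams.param_names())
        n_free = 8

    user_bounds = dict(default_bounds(model))
    if bounds:
        user_bounds.update(bounds)
    missing = [n for n in names if n not in user_bounds]
    if missing:
        raise ValueError(f"no bounds for parameters: {missing}")
    for n in names:
        lo, hi = user_bounds[n]
        if lo > hi:
            raise ValueError(f"lower bound exceeds upper bound for {n!r}")
    box = [tuple(map(float, user_bounds[n])) for n in names]

    objective = _Objective(model, trials, scheme, config, deadline, seed)
    x0 = _heuristic_x0(model, trials, names, box)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])

    def _run_de(func, de_box, init_pop, de_seed, maxiter):
        return differential_evolution(
            func, de_box, seed=de_seed, maxiter=maxiter, popsize=config.popsize,
            tol=0.0, polish=False, init=init_pop, updating="immediate",
        )

    def _lhs_pop(de_lo, de_hi, n_pop, lhs_seed):
        sampler = qmc.LatinHypercube(d=len(de_lo), seed=lhs_seed)
        return qmc.scale(sampler.random(max(5, n_pop)), de_lo, de_hi)

    # Regression slopes on threshold/collapse make the search space large;
    # for big specs, stage 1 fits drift + intercepts with slopes frozen at
    # zero, stage 2 relaxes everything from a population centred there.
    slope_idx = [
        i for i, n in enumerate(names)
        if n.split("_", 1)[0] in ("a", "theta")
        and n.split("_", 1)[1] not in (_ddm.INTERCEPT, "hard", "easy")
    ] if model != "lca" else []
    stagewise = len(names) > config.stagewise_threshold and bool(slope_idx)

    candidates = []
    if stagewise:
        core_idx = np.array([i for i in range(len(names)) if i not in slope_idx])
        full0 = x0.copy()
        full0[slope_idx] = 0.0

        def embed(x_sub):
            full = full0.copy()
            full[core_idx] = x_sub
            return full

        sub_box = [box[i] for i in core_idx]
        sub_lo, sub_hi = lo[core_idx], hi[core_idx]
        init_sub = _lhs_pop(sub_lo, sub_hi, config.popsize * len(core_idx), seed)
        init_sub[0] = x0[core_idx]
        stage1 = _run_de(lambda xs: objective(embed(xs)), sub_box, init_sub,
                         seed % 2**31, config.maxiter)
        center = embed(stage1.x)
        for restart in range(config.n_restarts):
            rst_seed = (seed + 7_331 * restart + 13) % 2**31
            rng_pop = np.random.default_rng(rst_seed)
            n_pop = max(5, config.popsize * len(names))
            init_pop = _lhs_pop(lo, hi, n_pop, rst_seed)
            # half the population hugs the stage-1 solution
            n_near = n_pop // 2
            jitter = rng_pop.standard_normal((n_near, len(names))) * 0.08 * (hi - lo)
            init_pop[:n_near] = np.clip(center[None, :] + jitter, lo, hi)
            init_pop[0] = center
            result = _run_de(objective, box, init_pop, rst_seed,
                             max(4, config.maxiter // 2))
            candidates.append(np.asarray(result.x))
    else:
        for restart in range(config.n_restarts):
            rst_seed = (seed + 7_331 * restart) % 2**31
            init_pop = _lhs_pop(lo, hi, config.popsize * len(names), rst_seed)
            init_pop[0] = x0  # moment-based guess joins the population
            result = _run_de(objective, box, init_pop, rst_seed, config.maxiter)
            candidates.append(np.asarray(result.x))
    # head-to-head on fresh IBS draws (restart-internal values are noisy
    # single-repeat estimates and not comparable across runs)
    best_x, best_ll = None, -math.inf
    for cand in candidates:
        ll_c, _ = objective.loglik(cand, config.polish_repeats, config.k_max)
        objective.n_evals += 1
        if ll_c > best_ll:
            best_x, best_ll = cand, ll_c
    if best_x is None or not math.isfinite(best_ll):
        raise RuntimeError("optimizer budget exhausted without a valid evaluation")

    if config.polish_maxfev > 0:
        lo = np.array([b[0] for b in box])
        hi = np.array([b[1] for b in box])

        def polish_obj(x):
            xc = np.clip(x, lo, hi)
            penalty = 1e3 * float(np.sum((np.asarray(x) - xc) ** 2))
            ll_p, _ = objective.loglik(xc, config.polish_repeats, config.k_max, use_floor=True)
            objective.n_evals += 1
            val = -ll_p + penalty
            if val < objective.best:
                objective.best = val
                objective.trace.append((objective.n_evals, val))
            return val

        res = minimize(
            polish_obj,
            best_x,
            method="Nelder-Mead",
            options={"maxfev": config.polish_maxfev, "xatol": 1e-3, "fatol": 0.5,
                     "adaptive": True},
        )
        cand = np.clip(res.x, lo, hi)
        # head-to-head under matched repeats before accepting the refinement
        ll_de, _ = objective.loglik(best_x, config.polish_repeats, config.k_max)
        objective.n_evals += 1
        ll_nm, _ = objective.loglik(cand, config.polish_repeats, config.k_max)
        objective.n_evals += 1
        if ll_nm > ll_de:
            best_x = cand

    ll, se = objective.loglik(best_x, config.final_repeats, config.final_k_max)
    return FitResult(
        model=model,
        params={n: float(v) for n, v in zip(names, best_x)},
        scaling=scaling,
        loglik=ll,
        loglik_se=se,
        n_trials=len(trials),
        n_free_params=n_free,
        seed=seed,
        bounds={n: tuple(b) for n, b in zip(names, box)},
        trace=objective.trace,
        n_evals=objective.n_evals,
        converged=True,
        binning={
            "strata": strata,
            "n_quantiles": n_quantiles,
            "split_value": scheme.split_value,
        },
    )


def simulate_fitted(
    fit: FitResult,
    trials: pd.DataFrame,
    seed: int = 0,
    deadline: float = 0.75,
    dt: float = SAMPLE_DT,
) -> pd.DataFrame:
    """Simulate one dataset from a fitted model on the given trial design.

    Applies the stored regressor scaling for DDM fits so the fitted
    coefficients see the regressors exactly as during fitting.
    """
    out = trials.copy()
    if fit.model == "lca":
        params = LCAParams(**{k: fit.params[k] for k in LCAParams.param_names()})
        i1, i2 = trial_drives(params, out)
        ch, rt = _kernels.lca_batch(
            i1, i2, params.k, params.w, params.a0, params.c, params.sigma,
            params.t0, float(dt), float(deadline), int(seed) % 2**31, False,
        )
        cs = correct_side(out)
        resp = np.where(ch == 0, 0, np.where(ch == 1, cs, -cs))
    else:
        spec = _ddm.model_registry(fit.model)
        scaled = out.copy()
        for term, (center, scale) in fit.scaling.items():
            scaled[term] = (scaled[term].to_numpy(float) - center) / scale
        p = _ddm.trial_params(spec, fit.params, scaled)
        ch, rt = _ddm.simulate_trials(p, dt=dt, deadline=deadline, seed=seed)
        cs = correct_side(out)
        if spec.coding == "accuracy":
            resp = np.where(ch == 0, 0, ch * cs)
        else:
            resp = ch
    out["response"] = np.select([resp == 1, resp == -1], ["left", "right"], default="omitted")
    out["rt"] = rt
    out["correct"] = np.where(resp == 0, np.nan, (resp == cs).astype(float))
    return out
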