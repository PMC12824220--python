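"""Stratified RT-decile categories and the inverse-binomial-sampling estimator.

Observed and simulated trials are reduced to discrete outcome categories:
within each stratum (a median split on a design covariate crossed with
correct/error), responded trials fall into empirical RT-quantile bins,
and deadline misses get their own omission category per split level.
The IBS estimator then turns any black-box trial simulator into an
unbiased estimate of the categorical log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernels

RESPONDED = ("left", "right")


def normalize_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Remove between-subject RT variance.

    Subtracts each subject's mean RT and re-adds the grand mean (pooled
    over all non-omitted trials), so that every subject's mean equals the
    grand mean and the grand mean is unchanged.  Omitted trials are left
    untouched.  Idempotent.
    """
    out = trials.copy()
    responded = out["response"].isin(RESPONDED) & out["rt"].notna()
    counts = responded.groupby(out["subject_id"]).sum()
    empty = counts[counts == 0].index.tolist()
    if empty:
        raise ValueError(f"subjects with no non-omitted trials: {empty}")
    grand = out.loc[responded, "rt"].mean()
    subj_means = out.loc[responded].groupby("subject_id")["rt"].transform("mean")
    out.loc[responded, "rt"] = out.loc[responded, "rt"] - subj_means + grand
    return out


@dataclass(frozen=True)
class BinningScheme:
    """Stratified RT-quantile category definitions.

    Strata are ``(split flag) x (correct/error)`` with the flag a median
    split on ``strata_by`` (e.g. overall value ``OV`` for fitting, or
    equal-weight difficulty ``absVD`` for the quantile-BIC comparison).
    Category ids: ``stratum * n_bins + bin`` for responded trials with
    ``stratum = 2 * flag + is_correct``, and one omission category per
    flag level appended after all responded categories.
    """

    strata_by: str
    n_bins: int
    split_value: float
    edges: np.ndarray  # shape (4, n_bins - 1), right-closed, strictly increasing

    @property
    def n_strata(self) -> int:
        return self.edges.shape[0]

    @property
    def n_categories(self) -> int:
        return self.n_strata * self.n_bins + 2

    def flags(self, trials: pd.DataFrame) -> np.ndarray:
        """Median-split flag per trial (1 = above the split value)."""
        return (trials[self.strata_by].to_numpy(float) > self.split_value).astype(np.int64)

    def categorize(self, trials: pd.DataFrame) -> np.ndarray:
        """Category id per trial of a trial table.

        RT-bin edges are right-closed: an RT exactly equal to an edge
        falls in the lower bin.
        """
        omitted = ~trials["response"].isin(RESPONDED).to_numpy()
        correct = trials["correct"].to_numpy(float)
        choices = np.where(omitted, 0, np.where(correct == 1.0, 1, -1)).astype(np.int64)
        rts = trials["rt"].to_numpy(float)
        flags = self.flags(trials)
        ones = np.ones(len(trials), dtype=np.int64)
        return _kernels.categorize_batch(choices, rts, ones, flags, self.edges, self.n_bins)

    def counts(self, trials: pd.DataFrame) -> np.ndarray:
        """Per-category trial counts (length ``n_categories``)."""
        return np.bincount(self.categorize(trials), minlength=self.n_categories)


def categorize_trial(
    response: str, rt: float, correct: float, flag: int, scheme: BinningScheme
) -> int:
    """Category id for a single outcome (see ``BinningScheme.categorize``)."""
    if flag not in (0, 1):
        raise ValueError("flag must be 0 or 1")
    choice = 0 if response not in RESPONDED else (1 if correct else -1)
    return int(
        _kernels.categorize_batch(
            np.array([choice], dtype=np.int64),
            np.array([rt], dtype=float),
            np.array([1], dtype=np.int64),
            np.array([flag], dtype=np.int64),
            scheme.edges,
            scheme.n_bins,
        )[0]
    )


def build_bins(
    trials: pd.DataFrame, strata: str = "OV", n_quantiles: int = 10
) -> BinningScheme:
    """Empirical RT-quantile edges per stratum.

    ``strata`` names the design covariate for the median split ("OV" for
    the fitting scheme, "absVD" for the BIC scheme).  Raises if any
    stratum holds fewer than ``n_quantiles`` responded trials, naming it.
    """
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    if strata not in trials.columns:
        raise ValueError(f"stratum covariate {strata!r} not in trial table")
    responded = trials[trials["response"].isin(RESPONDED) & trials["rt"].notna()]
    split_value = float(trials[strata].median())
    flags = (responded[strata].to_numpy(float) > split_value).astype(int)
    correct = responded["correct"].to_numpy(float).astype(int)
    qs = np.arange(1, n_quantiles) / n_quantiles
    edges = np.empty((4, n_quantiles - 1))
    for flag in (0, 1):
        for corr in (0, 1):
            mask = (flags == flag) & (correct == corr)
            rts = responded.loc[mask, "rt"].to_numpy(float)
            label = f"{strata}{'>' if flag else '<='}{split_value:g} x {'correct' if corr else 'error'}"
            if rts.size < n_quantiles:
                raise ValueError(
                    f"stratum '{label}' has only {rts.size} responded trials "
                    f"(need >= {n_quantiles})"
                )
            e = np.quantile(rts, qs)
            # enforce strictly increasing edges even on a discrete RT lattice
            for i in range(1, e.size):
                if e[i] <= e[i - 1]:
                    e[i] = np.nextafter(e[i - 1], np.inf)
            edges[2 * flag + corr] = e
    return BinningScheme(strata, n_quantiles, split_value, edges)


def harmonic_table(k_max: int) -> np.ndarray:
    """harmonic[k] = sum_{j=1}^{k} 1/j, harmonic[0] = 0."""
    return np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, k_max + 1))])


def ibs_loglik(
    observed: Sequence[int],
    simulator: Callable[[np.ndarray, int], np.ndarray],
    k_max: int = 10_000,
    repeats: int = 1,
    seed: int = 0,
) -> tuple[float, float]:
    """Inverse-binomial-sampling estimate of the summed log-likelihood.

    For each trial the simulator is drawn until it first reproduces the
    observed category at draw K; that trial contributes
    ``-sum_{j=1}^{K-1} 1/j``, an unbiased estimate of ``ln p`` whenever
    the cap never binds.  Trials still unmatched at ``k_max`` draws are
    floored at ``-sum_{j=1}^{k_max-1} 1/j``.  Contributions are summed
    over trials and averaged over ``repeats`` independent estimates.

    ``simulator(indices, seed)`` must return one simulated category per
    requested trial index.  Returns ``(estimate, standard error)``; the
    SE is the between-repeat standard error (NaN for a single repeat).
    """
    obs = np.asarray(observed, dtype=np.int64)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    harm = harmonic_table(k_max)
    estimates = np.empty(repeats)
    rng = np.random.default_rng(seed)
    for r in range(repeats):
        total = 0.0
        active = np.arange(obs.size)
        k = 0
        while active.size and k < k_max:
            k += 1
            sim = np.asarray(
                simulator(active, int(rng.integers(2**31))), dtype=np.int64
            )
            matched = sim == obs[active]
            total += -harm[k - 1] * int(matched.sum())
            active = active[~matched]
        total += -harm[k_max - 1] * active.size
        estimates[r] = total
    se = float(np.std(estimates, ddof=1) / np.sqrt(repeats)) if repeats > 1 else float("nan")
    return float(estimates.mean()), se
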