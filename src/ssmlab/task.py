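"""Synthetic deadlined two-bundle choice task.

Generates trial designs that emulate the study this package reanalyses:
each trial offers a left and a right bundle of two "fractals", every
fractal worth EUR 0.10-0.80 on a 0.10 grid, choices must land within a
750 ms deadline, and the 160 trials per subject are balanced with respect
to the total value of the four fractals and the (equal-weight) value
difference between the bundles.

The design is built factorially: a grid of (total set value) x (bundle
value difference) cells, each cell filled with the same number of trials,
fractal quadruples drawn uniformly from the grid-compatible combinations
for that cell, and the higher-valued bundle assigned to the left or right
side at random.  This reproduces the stated balancing property and makes
equal-weight value difference and overall value orthogonal by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.10, 0.81, 0.10), 2))
DEFAULT_DEADLINE = 0.75

DESIGN_COLUMNS = [
    "subject_id",
    "trial",
    "v_left_high",
    "v_left_low",
    "v_right_high",
    "v_right_low",
]

REGRESSOR_COLUMNS = [
    "signVD",
    "absVD",
    "maxVD",
    "minVD",
    "absMaxVD",
    "absMinVD",
    "maxOV",
    "minOV",
    "OV",
]

OUTCOME_COLUMNS = ["response", "rt", "correct"]


@dataclass(frozen=True)
class Weighting:
    """Relative weight placed on the higher- vs lower-valued fractal.

    Normalised so that ``w_high + w_low == 1``.  Equal weighting is
    ``Weighting(0.5, 0.5)``; the study's behaviour implied roughly five
    times more weight on the higher fractal, i.e. ``Weighting.from_ratio(5)``.
    """

    w_high: float
    w_low: float

    def __post_init__(self) -> None:
        if self.w_high < 0 or self.w_low < 0:
            raise ValueError("weights must be nonnegative")
        total = self.w_high + self.w_low
        if total <= 0:
            raise ValueError("weights must not both be zero")
        object.__setattr__(self, "w_high", self.w_high / total)
        object.__setattr__(self, "w_low", self.w_low / total)

    @classmethod
    def from_ratio(cls, ratio: float) -> "Weighting":
        """Weighting with ``w_high / w_low == ratio``."""
        if ratio < 0:
            raise ValueError("ratio must be nonnegative")
        return cls(ratio / (1.0 + ratio), 1.0 / (1.0 + ratio))


EQUAL_WEIGHTING = Weighting(0.5, 0.5)
UNEQUAL_WEIGHTING = Weighting.from_ratio(5.0)


def _cell_levels(grid: np.ndarray, n_sum_levels: int, n_diff_levels: int):
    """Factorial levels of bundle-sum total S and bundle-sum difference D.

    A bundle sum lives on the grid-step lattice in [2*min, 2*max].  D
    levels are spaced two grid steps apart starting at 0 (so S +/- D stays
    on the lattice), and S levels are centred in the range where every D
    level is feasible.
    """
    step = float(np.round(np.min(np.diff(np.unique(grid))), 10)) if grid.size > 1 else 0.1
    lo, hi = 2 * grid.min(), 2 * grid.max()
    d_levels = np.round(np.arange(n_diff_levels) * 2 * step, 10)
    d_max = d_levels[-1]
    s_lo, s_hi = lo * 2 + d_max, hi * 2 - d_max  # S = s_A + s_B with s_B >= lo, s_A <= hi
    if s_hi - s_lo < (n_sum_levels - 1) * 2 * step:
        raise ValueError("value grid too small for the requested balance cells")
    # points of the even-parity lattice (so (S +/- D)/2 is a valid bundle
    # sum), spread as widely as the feasible range allows and centred in it
    if n_sum_levels > 1:
        spacing = max(1, int((s_hi - s_lo) / ((n_sum_levels - 1) * 2 * step))) * 2 * step
    else:
        spacing = 2 * step
    slack = (s_hi - s_lo) - (n_sum_levels - 1) * spacing
    start = s_lo + np.floor(slack / 2 / (2 * step)) * 2 * step
    s_levels = np.round(start + np.arange(n_sum_levels) * spacing, 10)
    if s_levels[0] < s_lo - 1e-9 or s_levels[-1] > s_hi + 1e-9:
        raise ValueError("value grid too small for the requested balance cells")
    return s_levels, d_levels


def _bundles_with_sum(grid: np.ndarray, total: float) -> list[tuple[float, float]]:
    """All (high, low) fractal pairs on the grid with high + low == total."""
    out = []
    gset = set(np.round(grid, 10))
    for high in grid:
        low = np.round(total - high, 10)
        if low <= high and low in gset:
            out.append((float(high), float(low)))
    return out


def build_design(
    n_subjects: int = 22,
    n_trials: int = 160,
    value_grid: Sequence[float] = DEFAULT_GRID,
    seed: int = 0,
    n_sum_levels: int = 4,
    n_diff_levels: int = 4,
) -> pd.DataFrame:
    """Build a balanced design table: one row per (subject, trial).

    Trials are spread exactly uniformly over the factorial balance cells
    (total set value level x equal-weight difference level); fractal
    quadruples are drawn uniformly from each cell's pool and the
    higher-valued bundle lands on a random side.

    Raises ``ValueError`` if the grid is empty or ``n_trials`` is not
    divisible by the number of balance cells.
    """
    grid = np.asarray(sorted(set(np.round(value_grid, 10))), dtype=float)
    if grid.size == 0:
        raise ValueError("value_grid must be nonempty")
    n_cells = n_sum_levels * n_diff_levels
    if n_trials % n_cells != 0:
        raise ValueError(
            f"n_trials={n_trials} is not divisible by the {n_cells} balance cells "
            f"({n_sum_levels} total-value x {n_diff_levels} difference levels)"
        )
    s_levels, d_levels = _cell_levels(grid, n_sum_levels, n_diff_levels)
    pools: dict[tuple[float, float], tuple[list, list]] = {}
    for s in s_levels:
        for d in d_levels:
            sum_a = np.round((s + d) / 2, 10)  # higher-valued bundle
            sum_b = np.round((s - d) / 2, 10)
            pool_a = _bundles_with_sum(grid, sum_a)
            pool_b = _bundles_with_sum(grid, sum_b)
            if not pool_a or not pool_b:
                raise ValueError(
                    f"no grid-compatible bundles for cell S={s}, D={d}; "
                    "choose fewer levels or a denser grid"
                )
            pools[(s, d)] = (pool_a, pool_b)

    rng = np.random.default_rng(seed)
    per_cell = n_trials // n_cells
    rows = []
    for subject in range(1, n_subjects + 1):
        trial_specs = []
        for s in s_levels:
            for d in d_levels:
                pool_a, pool_b = pools[(np.round(s, 10), np.round(d, 10))]
                for _ in range(per_cell):
                    ba = pool_a[rng.integers(len(pool_a))]
                    bb = pool_b[rng.integers(len(pool_b))]
                    a_left = bool(rng.integers(2))
                    left, right = (ba, bb) if a_left else (bb, ba)
                    trial_specs.append(left + right)
        order = rng.permutation(len(trial_specs))
        for t, idx in enumerate(order, start=1):
            lh, ll, rh, rl = trial_specs[idx]
            rows.append((subject, t, lh, ll, rh, rl))
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def compute_regressors(design: pd.DataFrame, weighting: Weighting = EQUAL_WEIGHTING) -> pd.DataFrame:
    """Trial-level value regressors.

    ``maxVD``/``minVD`` compare the higher-valued (resp. lower-valued)
    fractal of each bundle across sides, and ``maxOV``/``minOV`` sum them;
    these do not depend on the weighting.  ``signVD`` is the weighted
    bundle-value difference (left minus right), which reduces to
    ``(maxVD + minVD) / 2`` under equal weighting, and ``absVD`` is its
    magnitude.  ``OV`` is the total (unweighted) value of all four
    fractals.
    """
    lh = design["v_left_high"].to_numpy(float)
    ll = design["v_left_low"].to_numpy(float)
    rh = design["v_right_high"].to_numpy(float)
    rl = design["v_right_low"].to_numpy(float)
    max_vd = lh - rh
    min_vd = ll - rl
    sign_vd = weighting.w_high * max_vd + weighting.w_low * min_vd
    max_ov = lh + rh
    min_ov = ll + rl
    out = pd.DataFrame(
        {
            "signVD": sign_vd,
            "absVD": np.abs(sign_vd),
            "maxVD": max_vd,
            "minVD": min_vd,
            "absMaxVD": np.abs(max_vd),
            "absMinVD": np.abs(min_vd),
            "maxOV": max_ov,
            "minOV": min_ov,
            "OV": max_ov + min_ov,
        },
        index=design.index,
    )
    # grid values are exact decimals; rounding kills float dust so that
    # genuinely tied bundles get regressors of exactly 0
    return out.round(10)


def attach_regressors(design: pd.DataFrame, weighting: Weighting = EQUAL_WEIGHTING) -> pd.DataFrame:
    """Design table with regressor columns appended."""
    return pd.concat([design, compute_regressors(design, weighting)], axis=1)


def design_correlations(regressors: pd.DataFrame, weighting: Weighting = EQUAL_WEIGHTING) -> pd.DataFrame:
    """Correlation report between weighted value-difference magnitude and
    weighted overall value.

    Under equal weighting on a balanced design these are orthogonal; under
    unequal weighting (over-weighting each bundle's better fractal) they
    become correlated — the confound at the heart of the reanalysis.
    Constant columns are reported as NaN (undefined), never as 0.
    """
    if len(regressors) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    abs_vd_w = np.abs(
        weighting.w_high * regressors["maxVD"] + weighting.w_low * regressors["minVD"]
    )
    ov_w = weighting.w_high * regressors["maxOV"] + weighting.w_low * regressors["minOV"]
    frame = pd.DataFrame({"absVD_w": abs_vd_w, "OV_w": ov_w})
    stds = frame.std(ddof=1)
    corr = frame.corr()
    for col in frame.columns:
        if stds[col] == 0 or not np.isfinite(stds[col]):
            corr.loc[col, :] = np.nan
            corr.loc[:, col] = np.nan
    np.fill_diagonal(corr.values, np.where(stds.to_numpy() > 0, 1.0, np.nan))
    return corr


def correct_side(design: pd.DataFrame) -> np.ndarray:
    """Which response counts as correct: +1 left, -1 right.

    Correctness is defined by the equal-weight bundle sum; exact ties are
    credited to the left option (an arbitrary, documented convention —
    side assignment is randomised so no marginal bias results).
    """
    left = np.round(
        design["v_left_high"].to_numpy(float) + design["v_left_low"].to_numpy(float), 10
    )
    right = np.round(
        design["v_right_high"].to_numpy(float) + design["v_right_low"].to_numpy(float), 10
    )
    return np.where(left >= right, 1, -1)
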