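"""Rectified leaky competing accumulator with a collapsing bound.

Two accumulators race toward a shared, linearly collapsing threshold.
At each Euler step of size dt an accumulator's activation y integrates
its input drive I, leaks at rate k, is inhibited by the competing
accumulator at strength w, receives Gaussian noise of scale sigma, and is
rectified at zero (activations can never go negative).  The input drive
for an option with fractal values (v_max, v_min) is

    I = b * (m * v_max + (1 - m) * v_min)

with total drive b and max/min weighting ratio m.  The model is
accuracy-coded: accumulator 1 integrates the objectively better bundle.
There is no value-dependent threshold mechanism anywhere in the model —
the initial bound a0 and collapse rate c are constant across trials —
which is exactly what makes it the control-free generator in the
mimicry experiments.

As printed, the second accumulator's update applies the inhibition
weight to its *own* activation (redundant with leak); the field-standard
reading is mutual (cross) inhibition, which is the default here.  The
self-inhibition variant remains available via ``printed_inhibition=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import _kernels
from .task import attach_regressors, correct_side, Weighting, EQUAL_WEIGHTING


@dataclass(frozen=True)
class LCAParams:
    """The 8 free parameters (all strictly positive; m in [0, 1])."""

    t0: float = 0.15  # non-decision time, s
    b: float = 6.0  # total input drive, evidence/s per EUR
    m: float = 5.0 / 6.0  # max/min drive weighting ratio
    k: float = 2.0  # leak, 1/s
    w: float = 2.0  # mutual inhibition, 1/s
    a0: float = 1.1  # initial bound, evidence units
    c: float = 1.0  # bound collapse rate, evidence/s
    sigma: float = 0.5  # noise standard deviation

    def __post_init__(self) -> None:
        for name in ("t0", "b", "k", "w", "a0", "c", "sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("m must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def param_names(cls) -> tuple[str, ...]:
        return ("t0", "b", "m", "k", "w", "a0", "c", "sigma")


def input_drive(b: float, m: float, v_max: float, v_min: float):
    """Drive for one option: I = b * (m * v_max + (1 - m) * v_min)."""
    if np.any(np.asarray(m) < 0) or np.any(np.asarray(m) > 1):
        raise ValueError("m must lie in [0, 1]")
    return b * (m * np.asarray(v_max, float) + (1.0 - m) * np.asarray(v_min, float))


def trial_drives(params: LCAParams, design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial drives (I_correct, I_incorrect) from the design values."""
    cs = correct_side(design)
    lh = design["v_left_high"].to_numpy(float)
    ll = design["v_left_low"].to_numpy(float)
    rh = design["v_right_high"].to_numpy(float)
    rl = design["v_right_low"].to_numpy(float)
    i_left = input_drive(params.b, params.m, lh, ll)
    i_right = input_drive(params.b, params.m, rh, rl)
    i_corr = np.where(cs == 1, i_left, i_right)
    i_inc = np.where(cs == 1, i_right, i_left)
    return np.ascontiguousarray(i_corr), np.ascontiguousarray(i_inc)


def simulate_lca_trial(
    params: LCAParams,
    correct_values: tuple[float, float],
    incorrect_values: tuple[float, float],
    dt: float = 0.001,
    deadline: float = 0.75,
    seed: int = 0,
    printed_inhibition: bool = False,
) -> tuple[int, float]:
    """Simulate one trial.  Returns (winner, rt).

    winner is 1 if the correct-option accumulator crossed first, -1 for
    the incorrect one, 0 for an omission (no crossing before the
    deadline; NaN RT).  If the bound collapses to zero before a crossing,
    the accumulator with the larger activation wins at the
    floor-crossing time (exact tie: fair, seeded coin).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if deadline <= params.t0:
        raise ValueError("deadline must exceed non-decision time")
    i1 = input_drive(params.b, params.m, *correct_values)
    i2 = input_drive(params.b, params.m, *incorrect_values)
    ch, rt = _kernels.lca_batch(
        np.array([i1]), np.array([i2]),
        params.k, params.w, params.a0, params.c, params.sigma, params.t0,
        float(dt), float(deadline), int(seed) % 2**31, printed_inhibition,
    )
    return int(ch[0]), float(rt[0])


def simulate_lca_dataset(
    params: LCAParams,
    design: pd.DataFrame,
    dt: float = 0.001,
    deadline: float = 0.75,
    seed: int = 0,
    n_concat: int = 1,
    printed_inhibition: bool = False,
    weighting: Weighting = EQUAL_WEIGHTING,
    constant_drive: bool = False,
) -> pd.DataFrame:
    """Simulate a full trial table from the design.

    ``n_concat`` independently seeded passes over the design are
    concatenated (the study concatenated three ~3,500-trial passes to
    reach ~10,000 trials for the mimicry fits).  ``constant_drive``
    replaces each option's value-derived drive with the dataset-mean
    drive — the negative control in which no value signal reaches the
    accumulators.

    Output is a response-coded trial table (schema identical to the DDM
    generator's): accumulator 1 wins map to the objectively better side.
    """
    if n_concat < 1:
        raise ValueError("n_concat must be >= 1")
    if deadline <= params.t0:
        raise ValueError("deadline must exceed non-decision time")
    i_corr, i_inc = trial_drives(params, design)
    if constant_drive:
        mean_drive = float(np.mean(np.concatenate([i_corr, i_inc])))
        i_corr = np.full_like(i_corr, mean_drive)
        i_inc = np.full_like(i_inc, mean_drive)
    cs = correct_side(design)
    chunks = []
    for pass_idx in range(n_concat):
        ch, rt = _kernels.lca_batch(
            i_corr, i_inc,
            params.k, params.w, params.a0, params.c, params.sigma, params.t0,
            float(dt), float(deadline), (int(seed) + 7919 * pass_idx) % 2**31,
            printed_inhibition,
        )
        table = attach_regressors(design, weighting).copy()
        # winner 1 = correct side; map back to left/right response coding
        resp_sign = np.where(ch == 0, 0, np.where(ch == 1, cs, -cs))
        table["response"] = np.select(
            [resp_sign == 1, resp_sign == -1], ["left", "right"], default="omitted"
        )
        table["rt"] = rt
        table["correct"] = np.where(ch == 0, np.nan, (ch == 1).astype(float))
        if n_concat > 1:
            table["subject_id"] = table["subject_id"] + pass_idx * (
                design["subject_id"].max() + 1
            )
        chunks.append(table)
    return pd.concat(chunks, ignore_index=True)
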