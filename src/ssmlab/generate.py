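"""Subject-level parameter sampling and synthetic behaviour generation.

A generative model is either a DDM from the model zoo or the LCA.  Group
configurations give a location and scale per parameter; positivity-
constrained parameters are sampled on the log scale and unit-interval
parameters on the logit scale, so every draw respects its constraint.
Generation runs on the raw (euro) value regressors; the fitting module
standardises regressors internally and records the scaling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ddm as _ddm
from .lca import LCAParams, simulate_lca_dataset
from .task import attach_regressors, correct_side, EQUAL_WEIGHTING, Weighting

#: transform used when sampling each scalar parameter
_TRANSFORMS = {
    "t0": "log",
    "z": "logit",
    "p_outlier": "logit",
    "sv": "log",
    # LCA
    "b": "log",
    "m": "logit",
    "k": "log",
    "w": "log",
    "a0": "log",
    "c": "log",
    "sigma": "log",
}

#: group-level (location, scale) defaults for the generative models used in
#: the recovery experiments; locations chosen once to give behaviour in the
#: study's regime (accuracy well above chance, RTs inside the 750 ms
#: deadline with a small omission rate), scales wide enough that recovery
#: correlations are informative.
GROUP_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "Original*": {
        "v_signVD": (7.0, 1.5),
        "a_Intercept": (-0.5, 0.35),
        "a_absVD": (0.8, 0.4),
        "z": (0.5, 0.15),
        "p_outlier": (0.02, 0.3),
        "t0": (0.2, 0.1),
    },
    "VD": {
        "v_maxVD": (5.5, 1.2),
        "v_minVD": (1.5, 0.6),
        "a_Intercept": (-0.5, 0.35),
        "a_absMaxVD": (0.7, 0.35),
        "a_absMinVD": (0.3, 0.3),
        "z": (0.5, 0.15),
        "p_outlier": (0.02, 0.3),
        "t0": (0.2, 0.1),
    },
    "VD init": {
        "v_maxVD": (5.5, 1.2),
        "v_minVD": (1.5, 0.6),
        "a_Intercept": (0.2, 0.3),
        "a_absMaxVD": (0.7, 0.35),
        "a_absMinVD": (0.3, 0.3),
        "theta_Intercept": (0.5, 0.4),
        "z": (0.5, 0.15),
        "p_outlier": (0.02, 0.3),
        "t0": (0.2, 0.1),
    },
    "lca": {name: (getattr(LCAParams(), name), 0.15) for name in LCAParams.param_names()},
}


def _sample_one(loc: float, scale: float, transform: str, rng: np.random.Generator) -> float:
    if scale < 0:
        raise ValueError("scales must be nonnegative")
    if transform == "log":
        if loc <= 0:
            raise ValueError("log-scale parameters need a positive location")
        return float(np.exp(np.log(loc) + scale * rng.standard_normal()))
    if transform == "logit":
        if not 0 < loc < 1:
            raise ValueError("logit-scale parameters need a location in (0, 1)")
        eta = np.log(loc / (1 - loc)) + scale * rng.standard_normal()
        return float(1.0 / (1.0 + np.exp(-eta)))
    return float(loc + scale * rng.standard_normal())


def sample_subject_params(
    model_name: str,
    group_config: dict[str, tuple[float, float]] | None = None,
    n_subjects: int = 22,
    seed: int = 0,
) -> list[dict[str, float]]:
    """Draw one parameter record per subject from group location/scale.

    Positivity-constrained parameters (non-decision time, all LCA scale
    parameters) are log-normal across subjects; unit-interval parameters
    (z, p_outlier, m) are logit-normal; regression coefficients are
    normal.  With all scales zero every record equals the group location.
    """
    if model_name != "lca":
        _ddm.model_registry(model_name)  # validates the name
    if group_config is None:
        if model_name not in GROUP_DEFAULTS:
            raise KeyError(
                f"no default group config for {model_name!r}; pass group_config "
                f"(defaults exist for {sorted(GROUP_DEFAULTS)})"
            )
        group_config = GROUP_DEFAULTS[model_name]
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n_subjects):
        rec = {
            name: _sample_one(loc, scale, _TRANSFORMS.get(name, "identity"), rng)
            for name, (loc, scale) in group_config.items()
        }
        records.append(rec)
    return records


def generate_behavior(
    design: pd.DataFrame,
    subject_params: list[dict[str, float]],
    model_name: str,
    deadline: float = 0.75,
    dt: float = 0.001,
    seed: int = 0,
    weighting: Weighting = EQUAL_WEIGHTING,
) -> pd.DataFrame:
    """Simulate a full trial table from per-subject generative parameters.

    ``subject_params`` holds one record per subject (in subject-id order);
    a single record is broadcast to all subjects.  Output is a trial
    table: design + regressors + response/rt/correct, with response in
    {left, right, omitted} and omitted trials carrying NaN RT.
    """
    if deadline <= 0:
        raise ValueError("deadline must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    subjects = design["subject_id"].unique()
    if len(subject_params) == 1:
        subject_params = list(subject_params) * len(subjects)
    if len(subject_params) != len(subjects):
        raise ValueError(
            f"got {len(subject_params)} parameter records for {len(subjects)} subjects"
        )
    if model_name == "lca":
        chunks = []
        for subj, rec in zip(subjects, subject_params):
            sub = design[design["subject_id"] == subj]
            chunks.append(
                simulate_lca_dataset(
                    LCAParams(**rec), sub, dt=dt, deadline=deadline,
                    seed=(seed + 104729 * int(subj)) % 2**31, weighting=weighting,
                )
            )
        return pd.concat(chunks, ignore_index=True)

    spec = _ddm.model_registry(model_name)
    table = attach_regressors(design, weighting).copy()
    cs = correct_side(design)
    resp_sign = np.zeros(len(table), dtype=int)
    rts = np.full(len(table), np.nan)
    for subj, rec in zip(subjects, subject_params):
        mask = (design["subject_id"] == subj).to_numpy()
        params = _ddm.trial_params(spec, rec, table.loc[mask])
        choices, rt = _ddm.simulate_trials(
            params, dt=dt, deadline=deadline, seed=(seed + 104729 * int(subj)) % 2**31
        )
        if spec.coding == "accuracy":
            # upper bound = objectively better option
            resp_sign[mask] = np.where(choices == 0, 0, choices * cs[mask])
        else:
            resp_sign[mask] = choices  # upper bound = left
        rts[mask] = rt
    table["response"] = np.select(
        [resp_sign == 1, resp_sign == -1], ["left", "right"], default="omitted"
    )
    table["rt"] = rts
    table["correct"] = np.where(
        resp_sign == 0, np.nan, (resp_sign == cs).astype(float)
    )
    return table
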