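"""Goodness-of-fit statistics: RMSE, Willmott's index of agreement, and
matching of observations to a simulated trajectory on thermal time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "rmse",
    "willmott_d",
    "match_on_thermal_time",
    "MatchResult",
    "evaluate_trajectory",
    "EVALUATION_VARIABLES",
]

#: observation column -> trajectory column, the per-variable report shape
EVALUATION_VARIABLES = {
    "la": "la_bl",
    "tdw": "tdw",
    "ldw_bl": "ldw_bl",
    "ldw_fl": "ldw_fl",
    "dw_rest": "dw_rest",
    "qs_bl": "qs_bl",
    "qs_rest": "qs_rest",
    "qs_so4_bl": "qs_mobile_bl",
    "qs_so4_rest": "qs_mobile_rest",
    "qs_uptake_cum": "qs_uptake_cum",
    "par_abs_cum": "par_abs_cum",
}


def rmse(observed, simulated) -> float:
    """Root mean square error, in the units of the variable.

    ``sqrt(mean((S_i - O_i)^2))`` over paired series of equal length.
    """
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {sim.shape}")
    if obs.size == 0:
        raise ValueError("rmse needs at least one pair")
    return float(np.sqrt(np.mean((sim - obs) ** 2)))


def willmott_d(observed, simulated, variant: str = "standard") -> float:
    """Willmott's index of agreement, dimensionless in [0, 1].

    ``d = 1 - sum((S_i - O_i)^2) / sum((|S_i - Om| + |O_i - Om|)^2)`` with
    ``Om`` the observed mean.  ``d = 1`` iff the two series agree exactly.

    ``variant="printed"`` drops the absolute values in the denominator
    (``((S_i - Om) + (O_i - Om))^2``), a form that appears in some reports
    but whose terms can cancel; it is provided for comparison only and is
    not bounded below by 0.
    """
    obs = np.asarray(observed, dtype=float)
    sim = np.asarray(simulated, dtype=float)
    if obs.shape != sim.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {sim.shape}")
    if obs.size < 2:
        raise ValueError("willmott_d needs at least two pairs")
    om = obs.mean()
    num = float(np.sum((sim - obs) ** 2))
    if variant == "standard":
        den = float(np.sum((np.abs(sim - om) + np.abs(obs - om)) ** 2))
    elif variant == "printed":
        den = float(np.sum(((sim - om) + (obs - om)) ** 2))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if den == 0.0:
        raise ValueError(
            "index of agreement undefined: observed values are all equal "
            "and simulated equals their mean"
        )
    return 1.0 - num / den


@dataclass
class MatchResult:
    """Observation rows paired to trajectory rows on thermal time."""

    pairs: pd.DataFrame  # obs columns + matched trajectory columns
    unmatched: pd.DataFrame  # observation rows with no trajectory row in range


def match_on_thermal_time(
    obs: pd.DataFrame, traj: pd.DataFrame, tolerance: float = 10.0
) -> MatchResult:
    """Pair each observation with the nearest trajectory row in thermal time.

    Both frames need a ``tt_cum`` (trajectory) / ``tt`` (observations)
    column.  Rows farther than ``tolerance`` °Cd from any trajectory row are
    reported in ``unmatched``, never silently dropped.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if "tt" not in obs.columns:
        raise ValueError("observation table needs a 'tt' column")
    if "tt_cum" not in traj.columns:
        raise ValueError("trajectory table needs a 'tt_cum' column")
    traj_tt = traj["tt_cum"].to_numpy(dtype=float)
    matched_rows = []
    unmatched_rows = []
    for _, row in obs.iterrows():
        dist = np.abs(traj_tt - float(row["tt"]))
        j = int(np.argmin(dist))
        if dist[j] <= tolerance:
            combined = row.to_dict()
            combined.update(
                {f"sim_{c}": traj.iloc[j][c] for c in traj.columns}
            )
            combined["tt_distance"] = float(dist[j])
            matched_rows.append(combined)
        else:
            unmatched_rows.append(row.to_dict())
    return MatchResult(
        pairs=pd.DataFrame(matched_rows),
        unmatched=pd.DataFrame(unmatched_rows),
    )


def evaluate_trajectory(
    traj: pd.DataFrame,
    obs: pd.DataFrame,
    tolerance: float = 10.0,
    variables: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-variable RMSE and d of a trajectory against observations.

    Returns a report frame with columns ``variable, rmse, d, n``; variables
    with fewer than two matched pairs get ``n`` and blank statistics.  For
    leaf area, both the per-plant value and the per-area index (LAI =
    LA × density) share the same d, so only per-plant LA is reported.
    """
    variables = variables or EVALUATION_VARIABLES
    match = match_on_thermal_time(obs, traj, tolerance)
    rows = []
    for obs_col, sim_col in variables.items():
        sim_key = f"sim_{sim_col}"
        if (
            match.pairs.empty
            or obs_col not in match.pairs.columns
            or sim_key not in match.pairs.columns
        ):
            rows.append({"variable": obs_col, "rmse": np.nan, "d": np.nan, "n": 0})
            continue
        sub = match.pairs[[obs_col, sim_key]].dropna()
        n = len(sub)
        if n == 0:
            rows.append({"variable": obs_col, "rmse": np.nan, "d": np.nan, "n": 0})
            continue
        o = sub[obs_col].to_numpy(dtype=float)
        s = sub[sim_key].to_numpy(dtype=float)
        entry = {"variable": obs_col, "rmse": rmse(o, s), "d": np.nan, "n": n}
        if n >= 2 and not np.allclose(o, o[0]):
            entry["d"] = willmott_d(o, s)
        elif n >= 2 and np.allclose(s, o):
            entry["d"] = 1.0
        rows.append(entry)
    return pd.DataFrame(rows)
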