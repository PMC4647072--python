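"""Calibration: fit each sub-function of the simulator to observations.

Every time-course and allometric sub-function of the model is fitted
independently, as the model was parameterized: the potential leaf-area
sigmoid, the cumulative S-uptake and fallen-leaf dry-weight curves
(seeded multi-start nonlinear least squares), the radiation use efficiency
(ordinary least squares of per-area canopy dry weight on accumulated
absorbed PAR), the two critical-S dilution power laws (log–log least
squares of organic-S content on compartment dry weight) and the specific
leaf area (slope of produced leaf area on produced leaf dry weight).

The observation table is column-wise: any column may be missing and the
remaining sub-functions are still fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model_core import ModelParameters

__all__ = [
    "FitError",
    "FitResult",
    "OBSERVATION_COLUMNS",
    "validate_observations",
    "fit_rue",
    "fit_dilution_curve",
    "fit_time_course",
    "fit_sla",
    "estimate_sulfate_from_ratio",
    "calibrate",
    "TIME_COURSE_FORMS",
    "MULTISTART_SEED",
]

logger = logging.getLogger(__name__)

#: fixed seed for the jittered multi-start initializations
MULTISTART_SEED = 20151117

OBSERVATION_COLUMNS = (
    "tt",
    "la",
    "tdw",
    "ldw_bl",
    "ldw_fl",
    "dw_rest",
    "qs_bl",
    "qs_rest",
    "qs_so4_bl",
    "qs_so4_rest",
    "qs_uptake_cum",
    "par_abs_cum",
)


class FitError(RuntimeError):
    """A fit could not be performed or did not converge."""


@dataclass
class FitResult:
    """Outcome of one sub-function fit."""

    name: str
    estimates: dict[str, float]
    stderr: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    sse: float = float("nan")
    n: int = 0
    method: str = ""
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            for key, value in self.estimates.items():
                if not np.isfinite(value):
                    raise FitError(
                        f"{self.name}: non-finite estimate for {key} "
                        "reported as converged"
                    )


def validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Check an observation table: tt strictly increasing, values finite."""
    if "tt" not in obs.columns:
        raise ValueError("observation table needs a 'tt' column")
    if len(obs) == 0:
        raise ValueError("observation table is empty")
    tt = obs["tt"].to_numpy(dtype=float)
    if not np.all(np.diff(tt) > 0):
        raise ValueError("'tt' must be strictly increasing")
    unknown = [
        c
        for c in obs.columns
        if c not in OBSERVATION_COLUMNS
        and not c.endswith("_sd")
        and c not in ("la_produced", "lai")
    ]
    if unknown:
        logger.warning("ignoring unknown observation columns %s", unknown)
    return obs


# --------------------------------------------------------------------------
# fit primitives
# --------------------------------------------------------------------------


def fit_rue(obs: pd.DataFrame, ds: float = 1.0) -> FitResult:
    """Radiation use efficiency: OLS slope of per-area dry weight on
    accumulated absorbed PAR (g DW MJ⁻¹); the intercept absorbs initial
    biomass.

    ``tdw`` is per plant; ``ds`` converts it to canopy dry weight per m².
    """
    sub = obs[["par_abs_cum", "tdw"]].dropna()
    if len(sub) < 3:
        raise FitError("fit_rue needs at least 3 paired points")
    x = sub["par_abs_cum"].to_numpy(dtype=float)
    y = sub["tdw"].to_numpy(dtype=float) * ds
    if np.allclose(x, x[0]):
        raise FitError("fit_rue: absorbed-PAR values are all identical")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    return FitResult(
        name="rue",
        estimates={"rue": float(res.slope), "intercept": float(res.intercept)},
        stderr={"rue": float(res.stderr), "intercept": float(res.intercept_stderr)},
        sse=float(np.sum(resid**2)),
        n=len(sub),
        method="ols",
    )


def fit_dilution_curve(dw, s_org_content, name: str = "dilution") -> FitResult:
    """Critical-dilution power law ``[S] = alpha * DW ** beta``.

    Fitted by least squares in log–log space, which linearizes the power
    law; multiplicative observation noise becomes additive there.
    """
    dw = np.asarray(dw, dtype=float)
    content = np.asarray(s_org_content, dtype=float)
    if dw.shape != content.shape:
        raise ValueError("dw and content must have equal length")
    if np.any(dw <= 0) or np.any(content <= 0):
        raise ValueError("dilution-curve data must be strictly positive")
    if dw.size < 3:
        raise FitError(f"{name}: need at least 3 points")
    lx, ly = np.log(dw), np.log(content)
    if np.allclose(lx, lx[0]):
        raise FitError(f"{name}: dry weights are all identical")
    res = stats.linregress(lx, ly)
    alpha = float(np.exp(res.intercept))
    resid = ly - (res.intercept + res.slope * lx)
    return FitResult(
        name=name,
        estimates={"alpha": alpha, "beta": float(res.slope)},
        stderr={
            "alpha": alpha * float(res.intercept_stderr),
            "beta": float(res.stderr),
        },
        sse=float(np.sum(resid**2)),
        n=int(dw.size),
        method="loglog-ols",
    )


# -- nonlinear time courses -------------------------------------------------


def _form_sigmoid(tt, la0, la_max, k_half, n_shape):
    tt = np.asarray(tt, dtype=float)
    ratio = np.zeros_like(tt)
    pos = tt > 0
    ratio[pos] = (tt[pos] / k_half) ** n_shape
    return la0 + (la_max - la0) * ratio / (1.0 + ratio)


def _form_sigmoid_anchored(tt, la_max, k_half, n_shape, y0, la0, tt_offset):
    # observed produced leaf area = initial area + potential increments;
    # the sigmoid lives on the from-sowing scale, observations on the
    # simulation clock, and the measured initial area y0 anchors the curve
    tt = np.asarray(tt, dtype=float)
    return y0 + (
        _form_sigmoid(tt + tt_offset, la0, la_max, k_half, n_shape)
        - _form_sigmoid(np.asarray([tt_offset]), la0, la_max, k_half, n_shape)[0]
    )


def _form_uptake(tt, a_qs, b_qs):
    return a_qs * np.expm1(b_qs * np.asarray(tt, dtype=float))


def _form_leaf_fall_exp(tt, a_ldw_fl, b_ldw_fl, dw_fl_ini, tt_offset):
    tt = np.asarray(tt, dtype=float)
    return dw_fl_ini + a_ldw_fl * (
        np.exp(b_ldw_fl * (tt + tt_offset)) - np.exp(b_ldw_fl * tt_offset)
    )


def _form_leaf_fall_rate_integral(tt, a_ldw_fl, b_ldw_fl, dw_fl_ini):
    tt = np.asarray(tt, dtype=float)
    if abs(b_ldw_fl) < 1e-12:
        return dw_fl_ini + a_ldw_fl * tt
    return dw_fl_ini + a_ldw_fl * np.expm1(b_ldw_fl * tt) / b_ldw_fl


#: form name -> (callable, parameter names)
TIME_COURSE_FORMS = {
    "leaf_area": (_form_sigmoid, ("la0", "la_max", "k_half", "n_shape")),
    "leaf_area_anchored": (
        _form_sigmoid_anchored,
        ("la_max", "k_half", "n_shape", "y0", "la0", "tt_offset"),
    ),
    "uptake": (_form_uptake, ("a_qs", "b_qs")),
    "leaf_fall_exp": (
        _form_leaf_fall_exp,
        ("a_ldw_fl", "b_ldw_fl", "dw_fl_ini", "tt_offset"),
    ),
    "leaf_fall_rate_integral": (
        _form_leaf_fall_rate_integral,
        ("a_ldw_fl", "b_ldw_fl", "dw_fl_ini"),
    ),
}


def fit_time_course(
    tt,
    y,
    form: str,
    init: dict[str, float],
    fixed: dict[str, float] | None = None,
    n_starts: int = 5,
    seed: int = MULTISTART_SEED,
) -> FitResult:
    """Nonlinear least squares of a named time-course form.

    ``init`` gives starting values for the free parameters; ``fixed`` pins
    parameters (e.g. a known initial value).  Runs ``n_starts`` seeded,
    jittered initializations and keeps the best sum of squared residuals.
    """
    if form not in TIME_COURSE_FORMS:
        raise ValueError(
            f"unknown form {form!r}; available: {sorted(TIME_COURSE_FORMS)}"
        )
    func, param_names = TIME_COURSE_FORMS[form]
    fixed = dict(fixed or {})
    free = [n for n in param_names if n not in fixed]
    missing = set(free) - set(init)
    if missing:
        raise ValueError(f"missing initial guesses for {sorted(missing)}")
    tt = np.asarray(tt, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(tt) & np.isfinite(y)
    tt, y = tt[mask], y[mask]
    if tt.size < len(free) + 1:
        raise FitError(f"{form}: need at least {len(free) + 1} points")

    def residuals(theta):
        kwargs = dict(zip(free, theta))
        kwargs.update(fixed)
        return func(tt, **kwargs) - y

    rng = np.random.default_rng(seed)
    x0 = np.array([init[n] for n in free], dtype=float)
    best = None
    messages = []
    for start in range(n_starts):
        guess = x0 if start == 0 else x0 * rng.lognormal(0.0, 0.2, size=x0.size)
        try:
            sol = optimize.least_squares(residuals, guess, method="lm", max_nfev=10000)
        except Exception as exc:  # singular Jacobian etc.
            messages.append(str(exc))
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        sse = float(2.0 * sol.cost)
        if best is None or sse < best[1]:
            best = (sol, sse)
    if best is None:
        raise FitError(f"{form}: no start converged ({'; '.join(messages[:3])})")
    sol, sse = best
    stderr = _lsq_stderr(sol, tt.size, len(free))
    estimates = dict(zip(free, (float(v) for v in sol.x)))
    col_norms = np.linalg.norm(sol.jac, axis=0)
    max_norm = float(col_norms.max()) if col_norms.size else 0.0
    degenerate = [
        n
        for n, se, cn in zip(free, stderr, col_norms)
        if not np.isfinite(se)
        or se > 1e3 * max(abs(estimates[n]), 1e-12)
        or cn <= 1e-12 * max(max_norm, 1e-12)  # parameter has no leverage
    ]
    msg = ""
    if degenerate:
        msg = f"poorly constrained parameters: {degenerate}"
        logger.warning("%s: %s", form, msg)
    return FitResult(
        name=form,
        estimates=estimates,
        stderr=dict(zip(free, (float(s) for s in stderr))),
        converged=True,
        sse=sse,
        n=int(tt.size),
        method=f"least_squares(lm) x{n_starts} starts, seed {seed}",
        message=msg,
    )


def _lsq_stderr(sol, n: int, n_par: int) -> np.ndarray:
    dof = max(n - n_par, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
        return np.sqrt(np.clip(np.diag(jtj_inv) * s2, 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(n_par, np.nan)


def fit_sla(obs: pd.DataFrame) -> FitResult:
    """Specific leaf area: slope of produced leaf area on produced leaf DW.

    Uses the total produced leaf series (big leaf + fallen); both grow by
    the same daily increment converted through the SLA, so the slope is the
    SLA itself.
    """
    la_col = "la_produced" if "la_produced" in obs.columns else "la"
    needed = [la_col, "ldw_bl", "ldw_fl"]
    if any(c not in obs.columns for c in needed):
        raise FitError("fit_sla needs leaf area and leaf dry-weight columns")
    sub = obs[needed].dropna()
    if len(sub) < 3:
        raise FitError("fit_sla needs at least 3 points")
    x = (sub["ldw_bl"] + sub["ldw_fl"]).to_numpy(dtype=float)
    y = sub[la_col].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise FitError("fit_sla: leaf dry weights are all identical")
    res = stats.linregress(x, y)
    return FitResult(
        name="sla",
        estimates={"sla": float(res.slope), "intercept": float(res.intercept)},
        stderr={"sla": float(res.stderr)},
        n=len(sub),
        method="ols",
    )


def estimate_sulfate_from_ratio(
    tt, qs_total, anchor_tt, anchor_ratio
) -> np.ndarray:
    """Estimate sulfate-S from total S via an S:SO₄ ratio time course.

    The ratio is interpolated linearly in thermal time between anchor
    points; outside the anchors it is clamped to the nearest anchor (with a
    warning).  Sulfate = total / ratio.
    """
    tt = np.asarray(tt, dtype=float)
    qs_total = np.asarray(qs_total, dtype=float)
    anchor_tt = np.asarray(anchor_tt, dtype=float)
    anchor_ratio = np.asarray(anchor_ratio, dtype=float)
    if np.any(anchor_ratio <= 0):
        raise ValueError("ratio anchors must be positive")
    if np.any(tt < anchor_tt.min()) or np.any(tt > anchor_tt.max()):
        logger.warning(
            "sulfate estimation outside ratio anchors; clamping to nearest"
        )
    ratio = np.interp(tt, anchor_tt, anchor_ratio)
    return qs_total / ratio


# --------------------------------------------------------------------------
# whole-table calibration
# --------------------------------------------------------------------------


def calibrate(
    obs: pd.DataFrame,
    template: ModelParameters,
    seed: int = MULTISTART_SEED,
) -> tuple[ModelParameters, dict[str, FitResult]]:
    """Fit every fittable sub-function and return updated parameters.

    Columns absent from the table leave the template value in place; each
    failed fit is reported in the result dict (``converged=False``) while
    the remaining functions are still fitted.
    """
    validate_observations(obs)
    results: dict[str, FitResult] = {}
    updates: dict[str, float] = {}

    def attempt(name, fn):
        try:
            results[name] = fn()
        except (FitError, ValueError, KeyError) as exc:
            results[name] = FitResult(
                name=name, estimates={}, converged=False, message=str(exc)
            )
            logger.warning("calibration: %s failed: %s", name, exc)

    tt = obs["tt"].to_numpy(dtype=float)

    la_col = "la_produced" if "la_produced" in obs.columns else "la"
    if la_col in obs.columns:
        def fit_la():
            y = obs[la_col].to_numpy(dtype=float)
            r = fit_time_course(
                tt,
                y,
                "leaf_area_anchored",
                init={
                    "la_max": template.la_max,
                    "k_half": template.k_half,
                    "n_shape": template.n_shape,
                    "y0": float(y[np.isfinite(y)][0]),
                },
                fixed={"la0": template.la0, "tt_offset": template.tt_offset},
                seed=seed,
            )
            updates.update(
                {k: r.estimates[k] for k in ("la_max", "k_half", "n_shape")}
            )
            return r
        attempt("leaf_area", fit_la)

    if "qs_uptake_cum" in obs.columns:
        def fit_uptake():
            r = fit_time_course(
                tt,
                obs["qs_uptake_cum"].to_numpy(dtype=float),
                "uptake",
                init={"a_qs": template.a_qs, "b_qs": template.b_qs},
                seed=seed,
            )
            updates.update({k: r.estimates[k] for k in ("a_qs", "b_qs")})
            return r
        attempt("uptake", fit_uptake)

    if "ldw_fl" in obs.columns:
        def fit_fall():
            form = (
                "leaf_fall_exp"
                if template.leaf_fall_provider == "exp_amplitude"
                else "leaf_fall_rate_integral"
            )
            fixed = {"dw_fl_ini": template.dw_fl_ini}
            if form == "leaf_fall_exp":
                fixed["tt_offset"] = template.tt_offset
            r = fit_time_course(
                tt,
                obs["ldw_fl"].to_numpy(dtype=float),
                form,
                init={"a_ldw_fl": template.a_ldw_fl, "b_ldw_fl": template.b_ldw_fl},
                fixed=fixed,
                seed=seed,
            )
            updates.update({k: r.estimates[k] for k in ("a_ldw_fl", "b_ldw_fl")})
            return r
        attempt("leaf_fall", fit_fall)

    if {"par_abs_cum", "tdw"} <= set(obs.columns):
        def fit_rue_():
            r = fit_rue(obs, ds=template.ds)
            updates["rue"] = r.estimates["rue"]
            return r
        attempt("rue", fit_rue_)

    if {"qs_bl", "qs_so4_bl", "ldw_bl"} <= set(obs.columns):
        def fit_dil_bl():
            sub = obs[["qs_bl", "qs_so4_bl", "ldw_bl"]].dropna()
            content = (
                sub["qs_bl"].to_numpy(dtype=float)
                - sub["qs_so4_bl"].to_numpy(dtype=float)
            ) / sub["ldw_bl"].to_numpy(dtype=float)
            r = fit_dilution_curve(
                sub["ldw_bl"].to_numpy(dtype=float), content, name="dilution_bl"
            )
            updates["alpha_bl"] = r.estimates["alpha"]
            updates["beta_bl"] = r.estimates["beta"]
            return r
        attempt("dilution_bl", fit_dil_bl)

    if {"qs_rest", "qs_so4_rest", "dw_rest"} <= set(obs.columns):
        def fit_dil_rest():
            sub = obs[["qs_rest", "qs_so4_rest", "dw_rest"]].dropna()
            content = (
                sub["qs_rest"].to_numpy(dtype=float)
                - sub["qs_so4_rest"].to_numpy(dtype=float)
            ) / sub["dw_rest"].to_numpy(dtype=float)
            r = fit_dilution_curve(
                sub["dw_rest"].to_numpy(dtype=float), content, name="dilution_rest"
            )
            updates["alpha_rest"] = r.estimates["alpha"]
            updates["beta_rest"] = r.estimates["beta"]
            return r
        attempt("dilution_rest", fit_dil_rest)

    if {"ldw_bl", "ldw_fl"} <= set(obs.columns) and la_col in obs.columns:
        def fit_sla_():
            r = fit_sla(obs)
            updates["sla"] = r.estimates["sla"]
            return r
        attempt("sla", fit_sla_)

    fitted = replace(template, **updates)
    fitted.validate()
    return fitted, results
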