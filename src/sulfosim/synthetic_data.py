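"""Synthetic weather and model-consistent pseudo-observations.

No measured dataset accompanies the published parameter tables, so every
other module is exercised against (i) a seeded greenhouse-like weather
generator (slow seasonal sinusoid, fixed diurnal range, truncated-normal
PAR) and (ii) pseudo-observations sampled from a simulated trajectory at a
handful of thermal times — mimicking destructive harvests at successive
growth stages — with multiplicative log-normal replicate noise.

Pseudo-observed sulfate is derived so that organic-S content sits on the
critical dilution curve at the sampled dry weights ("critical-status"
mode): dilution curves are built from plants at critical S status, and this
is what makes the calibration round-trip exact on noise-free data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import WeatherRecord
from .model_core import ModelParameters, PlantState, Trajectory, simulate
from .sulfur import critical_s_content_bl, critical_s_content_rest

__all__ = [
    "WeatherGenSpec",
    "ObsGenSpec",
    "generate_weather",
    "generate_pseudo_observations",
    "generate_dilution_samples",
]

#: observation columns sampled from a trajectory (obs name -> state column)
_SAMPLED = {
    "la": "la_bl",
    "la_produced": None,  # la_bl + la_fl, handled specially
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


@dataclass
class WeatherGenSpec:
    """Greenhouse-like weather: seasonal sinusoid + diurnal range + noise.

    Defaults emulate a spring greenhouse: 15 °C mean drifting ±4 °C over
    the season, 10 °C day/night range, ~5 MJ m⁻² d⁻¹ PAR.
    """

    n_days: int = 60
    t_mean_base: float = 15.0
    t_amplitude: float = 4.0
    t_diurnal_range: float = 10.0
    t_noise_sd: float = 1.5
    par_mean: float = 5.0
    par_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be at least 1")
        if self.t_noise_sd < 0 or self.par_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.t_diurnal_range < 0:
            raise ValueError("diurnal range must be non-negative")


def generate_weather(spec: WeatherGenSpec) -> list[WeatherRecord]:
    """Deterministic-given-seed synthetic weather series.

    The daily mean follows ``t_mean_base + t_amplitude * sin(2π day/365)``
    plus Gaussian noise; min/max are the mean ∓/± half the diurnal range, so
    ``t_max >= t_min`` holds by construction.  PAR is Gaussian around
    ``par_mean``, truncated at 0.
    """
    rng = np.random.default_rng(spec.seed)
    days = np.arange(1, spec.n_days + 1)
    mean = (
        spec.t_mean_base
        + spec.t_amplitude * np.sin(2.0 * np.pi * days / 365.0)
        + rng.normal(0.0, spec.t_noise_sd, size=spec.n_days)
    )
    half = 0.5 * spec.t_diurnal_range
    par = np.maximum(
        rng.normal(spec.par_mean, spec.par_noise_sd, size=spec.n_days), 0.0
    )
    return [
        WeatherRecord(int(d), float(m - half), float(m + half), float(p))
        for d, m, p in zip(days, mean, par)
    ]


@dataclass
class ObsGenSpec:
    """Recipe for pseudo-observations from a source configuration.

    ``sample_tts`` defaults to five thermal times spanning the simulated
    window (the five destructive harvests, leaf development through early
    pod formation).  ``noise_sd`` is the log-scale standard deviation of the
    multiplicative replicate noise (0 gives exact trajectory values);
    ``n_replicates`` pseudo-plants are averaged per harvest.  With
    ``critical_status`` (default), sulfate columns place organic-S content
    on the critical dilution curves.
    """

    params: ModelParameters
    init: PlantState
    weather: list[WeatherRecord] = field(default_factory=list)
    sample_tts: list[float] | None = None
    noise_sd: float = 0.0
    n_replicates: int = 3
    seed: int = 0
    critical_status: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


def generate_pseudo_observations(
    spec: ObsGenSpec, return_trajectory: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, Trajectory]:
    """Simulate, sample at the requested thermal times, add replicate noise.

    Each requested thermal time is matched to the nearest simulated day;
    requests beyond the simulated range raise with the reachable range in
    the message.  Noise is mean-one log-normal
    (``exp(N(-sd²/2, sd))``), so replicate means converge to the trajectory
    values.  Returns the replicate-mean table with per-column ``*_sd``
    spread columns.
    """
    weather = spec.weather
    if not weather:
        weather = generate_weather(WeatherGenSpec(seed=spec.seed))
    traj = simulate(weather, spec.init, spec.params)
    states = traj.states()
    tts = np.array([s.tt_cum for s in states])
    sample_tts = spec.sample_tts
    if sample_tts is None:
        sample_tts = list(np.linspace(0.0, tts[-1], 5))
    rng = np.random.default_rng(spec.seed)
    rows = []
    for want in sample_tts:
        if want < tts[0] - 1e-9 or want > tts[-1] + 1e-9:
            raise ValueError(
                f"sampling thermal time {want} outside simulated range "
                f"[{tts[0]}, {tts[-1]}]"
            )
        state = states[int(np.argmin(np.abs(tts - want)))]
        row: dict[str, float] = {"tt": state.tt_cum}
        overrides = (
            _critical_status_pools(state, spec.params)
            if spec.critical_status
            else {}
        )
        for obs_name, attr in _SAMPLED.items():
            if obs_name in overrides:
                truth = overrides[obs_name]
            elif obs_name == "la_produced":
                truth = state.la_bl + state.la_fl
            else:
                truth = getattr(state, attr)
            if spec.noise_sd > 0:
                reps = truth * rng.lognormal(
                    -0.5 * spec.noise_sd**2, spec.noise_sd, size=spec.n_replicates
                )
                row[obs_name] = float(np.mean(reps))
                row[f"{obs_name}_sd"] = float(np.std(reps, ddof=1)) if spec.n_replicates > 1 else 0.0
            else:
                row[obs_name] = float(truth)
        rows.append(row)
    obs = pd.DataFrame(rows).sort_values("tt").reset_index(drop=True)
    obs = obs.loc[~obs["tt"].duplicated()].reset_index(drop=True)
    if return_trajectory:
        return obs, traj
    return obs


def _critical_status_pools(state: PlantState, p: ModelParameters) -> dict[str, float]:
    # a pseudo-plant at critical S status: organic pools sit exactly on the
    # (un-floored) dilution curves, sulfate is the simulated mobile pool
    out: dict[str, float] = {}
    if state.ldw_bl > 0:
        crit = critical_s_content_bl(state.ldw_bl, p, floor=False)
        out["qs_bl"] = crit * state.ldw_bl + state.qs_mobile_bl
        out["qs_so4_bl"] = state.qs_mobile_bl
    else:
        out["qs_bl"] = out["qs_so4_bl"] = 0.0
    if state.dw_rest > 0:
        crit = critical_s_content_rest(state.dw_rest, p)
        out["qs_rest"] = crit * state.dw_rest + state.qs_mobile_rest
        out["qs_so4_rest"] = state.qs_mobile_rest
    else:
        out["qs_rest"] = out["qs_so4_rest"] = 0.0
    return out


def generate_dilution_samples(
    p: ModelParameters,
    which: str = "bl",
    dw: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Organic-S content samples on a critical dilution curve.

    Returns a frame with ``dw`` and ``s_org_content`` columns; optional
    multiplicative log-normal noise on the content.
    """
    if dw is None:
        dw = np.geomspace(0.5, 30.0, 20)
    dw = np.asarray(dw, dtype=float)
    if which == "bl":
        content = p.alpha_bl * dw**p.beta_bl
    elif which == "rest":
        content = p.alpha_rest * dw**p.beta_rest
    else:
        raise ValueError("which must be 'bl' or 'rest'")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        content = content * rng.lognormal(0.0, noise_sd, size=dw.size)
    return pd.DataFrame({"dw": dw, "s_org_content": content})
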