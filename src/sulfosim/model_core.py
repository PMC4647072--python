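"""Core state container and the daily update of the crop simulator.

The plant is split into three compartments: a single "big leaf" (BL, all
in-planta leaves), fallen leaves (FL, abscised and lost), and the rest of the
plant (roots, taproot, stem, inflorescences, young pods).  Each day the
effective leaf-area increase is the minimum of three candidate increments —
what temperature permits (a sigmoid potential-area time course), what the
day's carbon gain permits (Beer–Monteith absorbed PAR × radiation use
efficiency × leaf allocation × specific leaf area), and what the day's sulfur
offer permits — von Liebig's law of minimum.  Biomass and sulfur pools are
then updated with strict conservation bookkeeping.

Time-course sub-functions (potential leaf area, cumulative S uptake,
cumulative fallen-leaf dry weight) are pluggable named providers so that
alternative fitted forms can be swapped in without touching the stepper.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .environment import WeatherRecord, daily_thermal_time, par_absorbed

__all__ = [
    "ModelParameters",
    "PlantState",
    "DailyFlux",
    "Trajectory",
    "potential_leaf_area",
    "potential_la_increment",
    "biomass_production",
    "carb_limited_la_increment",
    "fallen_leaf_dw",
    "step",
    "simulate",
    "SimulationError",
    "LA_PROVIDERS",
    "LEAF_FALL_PROVIDERS",
]

logger = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    """A daily update failed; the message carries the offending day index."""


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------


@dataclass
class ModelParameters:
    """Calibrated constants of the simulator.

    Units follow the field conventions: areas m² plant⁻¹, masses g DW
    plant⁻¹, sulfur mg S plant⁻¹, thermal time °Cd.

    Attributes
    ----------
    ds : plant density, plants m⁻² (converts per-plant to per-ground-area).
    k : PAR extinction coefficient of the canopy, dimensionless.
    t_base : base temperature of the degree-day clock, °C.
    la0, la_max, k_half, n_shape : potential leaf-area sigmoid — initial
        area, asymptote, half-saturation thermal time (°Cd) and Hill shape
        exponent.  The sigmoid is expressed on thermal time since sowing;
        ``tt_offset`` maps the simulation clock (which starts at 0 at the end
        of the vegetative rest) onto that scale.
    rue : radiation use efficiency, g DW MJ⁻¹ absorbed PAR; the only
        parameter that differs between sulfur treatments.
    sla : specific leaf area, m² g⁻¹ DW, held constant.
    beta_alloc : maximal fraction of daily biomass allocatable to leaves.
    qs_ini, a_qs, b_qs : initial whole-plant S (mg) and the exponential
        cumulative-uptake time course ``a_qs * (exp(b_qs * tt) - 1)``.
    dw_fl_ini, a_ldw_fl, b_ldw_fl : fallen-leaf dry-weight time course
        (see :func:`fallen_leaf_dw`); the fall is independent of S status.
    alpha_bl, beta_bl : big-leaf critical-S dilution curve
        ``[S]crit = alpha_bl * LDW_BL ** beta_bl`` (mg S g⁻¹ at 1 g; power).
    s_crit_floor, ldw_floor_threshold : below ``ldw_floor_threshold`` g the
        dilution curve is replaced by the constant floor (3 mg S g⁻¹).
    alpha_rest, beta_rest : dilution curve of the rest compartment.
    eps_pot : potential fraction of the daily mobile-S surplus routed to
        the big leaf.
    tt_offset : thermal time from sowing to simulation start, °Cd.
    """

    ds: float
    k: float
    la0: float
    la_max: float
    k_half: float
    n_shape: float
    rue: float
    sla: float
    beta_alloc: float
    qs_ini: float
    a_qs: float
    b_qs: float
    dw_fl_ini: float
    a_ldw_fl: float
    b_ldw_fl: float
    alpha_bl: float
    beta_bl: float
    alpha_rest: float
    beta_rest: float
    eps_pot: float
    t_base: float = 5.0
    s_crit_floor: float = 3.0
    ldw_floor_threshold: float = 3.0
    tt_offset: float = 0.0
    la_provider: str = "hill"
    leaf_fall_provider: str = "exp_amplitude"

    def validate(self) -> None:
        positive = (
            "ds k la_max k_half n_shape rue sla beta_alloc alpha_bl "
            "alpha_rest s_crit_floor ldw_floor_threshold"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")
        nonneg = "la0 qs_ini a_qs b_qs dw_fl_ini a_ldw_fl tt_offset".split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")
        if not 0.0 <= self.eps_pot <= 1.0:
            raise ValueError("eps_pot must lie in [0, 1]")
        if not 0.0 < self.beta_alloc <= 1.0:
            raise ValueError("beta_alloc must lie in (0, 1]")
        if self.la_provider not in LA_PROVIDERS:
            raise ValueError(f"unknown leaf-area provider {self.la_provider!r}")
        if self.leaf_fall_provider not in LEAF_FALL_PROVIDERS:
            raise ValueError(
                f"unknown leaf-fall provider {self.leaf_fall_provider!r}"
            )


# --------------------------------------------------------------------------
# state and fluxes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantState:
    """Per-plant compartment pools at the end of a day.

    ``tdw`` includes the fallen leaves; sulfur totals ``qs_bl``/``qs_rest``/
    ``qs_tot`` are derived properties (organic + mobile), ``qs_tot``
    excluding FL as in the variable inventory.
    """

    tt_cum: float = 0.0
    la_bl: float = 0.0
    la_fl: float = 0.0
    ldw_bl: float = 0.0
    ldw_fl: float = 0.0
    dw_rest: float = 0.0
    tdw: float = 0.0
    par_abs_cum: float = 0.0
    qs_org_bl: float = 0.0
    qs_mobile_bl: float = 0.0
    qs_org_rest: float = 0.0
    qs_mobile_rest: float = 0.0
    qs_fl: float = 0.0
    qs_uptake_cum: float = 0.0

    @property
    def qs_bl(self) -> float:
        return self.qs_org_bl + self.qs_mobile_bl

    @property
    def qs_rest(self) -> float:
        return self.qs_org_rest + self.qs_mobile_rest

    @property
    def qs_tot(self) -> float:
        """Whole-plant S excluding fallen leaves, mg S plant⁻¹."""
        return self.qs_bl + self.qs_rest

    def validate(self, rtol: float = 1e-9) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"state field {f.name} is non-finite")
            if v < 0:
                raise ValueError(f"state field {f.name} is negative ({v})")
        mass = self.ldw_bl + self.ldw_fl + self.dw_rest
        if abs(mass - self.tdw) > rtol * max(1.0, abs(self.tdw)):
            raise ValueError(
                f"dry-weight closure violated: compartments sum to {mass}, "
                f"tdw is {self.tdw}"
            )


@dataclass(frozen=True)
class DailyFlux:
    """Diagnostic record of every within-day flux of one update."""

    dtt: float
    par_abs: float
    d_tdw: float
    dla_tt: float
    dla_carb: float
    dla_s: float
    dla_eff: float
    d_ldw_fl: float
    d_la_fl: float
    fall_deficit: float
    dqs_uptake: float
    qs_fl_pot_remob: float
    dqs_offer: float
    dqs_org_bl: float
    dqs_org_rest: float
    dqs_mobile_bl: float
    dqs_mobile_rest: float
    dqs_fl_mobile: float
    dqs_fl_org: float
    limiting_factor: str


@dataclass
class Trajectory:
    """Time-indexed result of a simulation.

    ``initial_state`` is the day-0 state; ``records`` holds one
    (weather, state, flux) triple per simulated day.
    """

    initial_state: PlantState
    records: list[tuple[WeatherRecord, PlantState, DailyFlux]] = field(
        default_factory=list
    )

    def states(self) -> list[PlantState]:
        """All states, initial state first."""
        return [self.initial_state] + [s for _, s, _ in self.records]

    @property
    def final_state(self) -> PlantState:
        return self.records[-1][1] if self.records else self.initial_state

    def to_frame(self) -> pd.DataFrame:
        """One row per day (day 0 = initial state, flux columns NaN)."""
        rows = []
        state_names = [f.name for f in fields(PlantState)]
        flux_names = [f.name for f in fields(DailyFlux)]
        row0 = {"day": 0}
        row0.update({n: getattr(self.initial_state, n) for n in state_names})
        for n in ("qs_bl", "qs_rest", "qs_tot"):
            row0[n] = getattr(self.initial_state, n)
        rows.append(row0)
        for wrec, state, flux in self.records:
            row = {"day": wrec.day_index}
            row.update({n: getattr(state, n) for n in state_names})
            for n in ("qs_bl", "qs_rest", "qs_tot"):
                row[n] = getattr(state, n)
            row.update({n: getattr(flux, n) for n in flux_names})
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        frame = self.to_frame()
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(frame.columns)
            for _, row in frame.iterrows():
                writer.writerow(
                    [_format_cell(row[c]) for c in frame.columns]
                )


def _format_cell(value) -> str:
    if isinstance(value, str):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


# --------------------------------------------------------------------------
# time-course providers
# --------------------------------------------------------------------------


def _hill_leaf_area(tt_cum: float, p: ModelParameters) -> float:
    if tt_cum < 0:
        raise ValueError("thermal time must be non-negative")
    if tt_cum == 0.0:
        return p.la0
    ratio = (tt_cum / p.k_half) ** p.n_shape
    return p.la0 + (p.la_max - p.la0) * ratio / (1.0 + ratio)


LA_PROVIDERS: dict[str, Callable[[float, ModelParameters], float]] = {
    "hill": _hill_leaf_area,
}


def _fl_exp_amplitude(tt_cum: float, p: ModelParameters) -> float:
    # exponential on the from-sowing scale, anchored at dw_fl_ini at tt=0
    off = p.tt_offset
    return p.dw_fl_ini + p.a_ldw_fl * (
        math.exp(p.b_ldw_fl * (tt_cum + off)) - math.exp(p.b_ldw_fl * off)
    )


def _fl_rate_integral(tt_cum: float, p: ModelParameters) -> float:
    # integral of the rate a*exp(b*tt); linear limit as b -> 0
    a, b = p.a_ldw_fl, p.b_ldw_fl
    if abs(b) < 1e-12:
        return p.dw_fl_ini + a * tt_cum
    return p.dw_fl_ini + a * math.expm1(b * tt_cum) / b


LEAF_FALL_PROVIDERS: dict[str, Callable[[float, ModelParameters], float]] = {
    "exp_amplitude": _fl_exp_amplitude,
    "rate_integral": _fl_rate_integral,
}


# --------------------------------------------------------------------------
# elementary operations
# --------------------------------------------------------------------------


def potential_leaf_area(tt_cum: float, p: ModelParameters) -> float:
    """Temperature-driven potential leaf area (m² plant⁻¹) at ``tt_cum``.

    Sigmoid in thermal time: ``la0 + (la_max - la0) * tt^n / (K^n + tt^n)``.
    Monotone non-decreasing, equals ``la0`` at the origin and saturates at
    ``la_max``.  The argument is on the provider's own thermal-time scale;
    the stepper adds ``tt_offset`` before calling.
    """
    return LA_PROVIDERS[p.la_provider](tt_cum, p)


def potential_la_increment(tt_before: float, dtt: float, p: ModelParameters) -> float:
    """Potential leaf-area increase over one day, m² plant⁻¹."""
    if dtt < 0:
        raise ValueError("dtt must be non-negative")
    if dtt == 0.0:
        return 0.0
    return potential_leaf_area(tt_before + dtt, p) - potential_leaf_area(tt_before, p)


def biomass_production(par_abs: float, p: ModelParameters) -> float:
    """Daily per-plant dry-matter production, g DW plant⁻¹.

    ``rue * par_abs / ds``: absorbed PAR (per ground area) times radiation
    use efficiency, divided by plant density.  The whole-plant dry weight
    grows by exactly this amount each day, which makes the regression of
    per-area canopy dry weight on accumulated absorbed PAR return ``rue``
    exactly.
    """
    if par_abs < 0:
        raise ValueError("absorbed PAR must be non-negative")
    if p.ds <= 0:
        raise ValueError("plant density must be positive")
    return p.rue * par_abs / p.ds


def carb_limited_la_increment(d_tdw: float, p: ModelParameters) -> float:
    """Leaf-area increase the day's carbon gain can support, m² plant⁻¹.

    The leaf-allocatable fraction of production converted to area through
    the specific leaf area: ``beta_alloc * d_tdw * sla``.
    """
    if d_tdw < 0:
        raise ValueError("daily production must be non-negative")
    return p.beta_alloc * d_tdw * p.sla


def fallen_leaf_dw(tt_cum: float, p: ModelParameters) -> float:
    """Cumulative fallen-leaf dry weight at ``tt_cum``, g DW plant⁻¹.

    Monotone non-decreasing, equals ``dw_fl_ini`` at tt = 0; the fall is not
    dependent on plant S status.  The functional form is a named provider
    (``exp_amplitude`` by default, ``rate_integral`` available).
    """
    if tt_cum < 0:
        raise ValueError("thermal time must be non-negative")
    return LEAF_FALL_PROVIDERS[p.leaf_fall_provider](tt_cum, p)


# --------------------------------------------------------------------------
# the daily update
# --------------------------------------------------------------------------


def step(
    state: PlantState, weather: WeatherRecord, p: ModelParameters
) -> tuple[PlantState, DailyFlux]:
    """Advance the plant by one day; returns (new state, flux record).

    Fixed within-day order: thermal time; PAR absorption from the morning
    leaf area (explicit Euler); biomass production; the three candidate
    leaf-area increments; leaf fall with its sulfur withdrawals; the sulfur
    offer; the law-of-minimum effective increment; biomass bookkeeping; and
    the sulfur allocation/partitioning of the day's offer.
    """
    from . import sulfur  # local import to avoid a cycle at import time

    for name in ("t_min", "t_max", "par_incident"):
        if not math.isfinite(getattr(weather, name)):
            raise ValueError(f"non-finite weather input {name}")
    dtt = daily_thermal_time(weather.t_min, weather.t_max, p.t_base)
    tt0 = state.tt_cum
    tt1 = tt0 + dtt

    # carbon supply from the morning canopy
    par_abs = par_absorbed(weather.par_incident, state.la_bl * p.ds, p.k)
    d_tdw = biomass_production(par_abs, p)

    # candidate increments: temperature and carbon
    dla_tt = potential_la_increment(tt0 + p.tt_offset, dtt, p)
    dla_carb = carb_limited_la_increment(d_tdw, p)

    # leaf fall (S-independent time course); cannot drop more than exists
    d_ldw_fl_curve = fallen_leaf_dw(tt1, p) - fallen_leaf_dw(tt0, p)
    d_ldw_fl = min(d_ldw_fl_curve, state.ldw_bl)
    fall_deficit = d_ldw_fl_curve - d_ldw_fl
    if fall_deficit > 0:
        logger.warning(
            "day %d: leaf-fall curve exceeds remaining big-leaf biomass by "
            "%.6g g; fall truncated",
            weather.day_index,
            fall_deficit,
        )
    d_la_fl = min(d_ldw_fl * p.sla, state.la_bl)
    fall_frac = d_ldw_fl / state.ldw_bl if state.ldw_bl > 0 else 0.0
    qs_fl_org = state.qs_org_bl * fall_frac
    qs_fl_pot_remob = sulfur.fl_potential_remobilization(d_ldw_fl, state)

    # sulfur offer: uptake + remobilizable FL sulfate + whole mobile pool
    dqs_uptake = sulfur.s_uptake_cumulative(tt1, p) - sulfur.s_uptake_cumulative(
        tt0, p
    )
    mobile_pool = (state.qs_mobile_bl - qs_fl_pot_remob) + state.qs_mobile_rest
    dqs_offer = dqs_uptake + qs_fl_pot_remob + mobile_pool

    # sulfur-limited increment (full offer against the BL critical content)
    if state.ldw_bl >= p.ldw_floor_threshold:
        s_crit_bl = sulfur.critical_s_content_bl(state.ldw_bl, p)
    else:
        s_crit_bl = p.s_crit_floor
    dla_s = sulfur.s_limited_la_increment(dqs_offer, s_crit_bl, p)

    # law of minimum
    candidates = (
        ("temperature", dla_tt),
        ("carbon", dla_carb),
        ("sulfur", dla_s),
    )
    limiting_factor, dla_eff = min(candidates, key=lambda kv: kv[1])

    # biomass bookkeeping: leaves get dla_eff worth of mass, the remainder
    # of the day's production accrues to the rest compartment
    d_ldw_growth = dla_eff / p.sla
    d_dw_rest = d_tdw - d_ldw_growth
    new_ldw_bl = state.ldw_bl + d_ldw_growth - d_ldw_fl
    new_la_bl = state.la_bl + dla_eff - d_la_fl
    new_ldw_fl = state.ldw_fl + d_ldw_fl
    new_la_fl = state.la_fl + d_la_fl
    new_dw_rest = state.dw_rest + d_dw_rest
    new_tdw = state.tdw + d_tdw
    if new_ldw_bl < 0:  # only round-off can land here after the fall cap
        logger.warning("day %d: clamping ldw_bl deficit %.3g", weather.day_index, -new_ldw_bl)
        new_ldw_bl = 0.0
    if new_la_bl < 0:
        logger.warning("day %d: clamping la_bl deficit %.3g", weather.day_index, -new_la_bl)
        new_la_bl = 0.0

    # sulfur demand from the realized growth
    demand = sulfur.growth_s_requirements(
        dla_eff - d_la_fl, d_dw_rest, state, p, s_crit_bl=s_crit_bl
    )
    offer = sulfur.SulfurOffer(
        dqs_uptake=dqs_uptake,
        qs_fl_pot_remob=qs_fl_pot_remob,
        qs_mobile_pool=mobile_pool,
        dqs_offer=dqs_offer,
    )
    served_bl, served_rest, surplus, dqs_fl_mobile = sulfur.allocate_offer(
        offer, demand, p
    )
    dqs_mobile_bl, dqs_mobile_rest = sulfur.partition_mobile_s(
        surplus,
        dqs_uptake,
        max(demand.dqs_org_bl_req, 0.0) + demand.dqs_org_rest_req,
        demand.dqs_org_bl_req < 0.0,
        p,
    )

    new_state = PlantState(
        tt_cum=tt1,
        la_bl=new_la_bl,
        la_fl=new_la_fl,
        ldw_bl=new_ldw_bl,
        ldw_fl=new_ldw_fl,
        dw_rest=new_dw_rest,
        tdw=new_tdw,
        par_abs_cum=state.par_abs_cum + par_abs,
        qs_org_bl=state.qs_org_bl - qs_fl_org + served_bl,
        qs_mobile_bl=dqs_mobile_bl,
        qs_org_rest=state.qs_org_rest + served_rest,
        qs_mobile_rest=dqs_mobile_rest,
        qs_fl=state.qs_fl + qs_fl_org + dqs_fl_mobile,
        qs_uptake_cum=state.qs_uptake_cum + dqs_uptake,
    )
    flux = DailyFlux(
        dtt=dtt,
        par_abs=par_abs,
        d_tdw=d_tdw,
        dla_tt=dla_tt,
        dla_carb=dla_carb,
        dla_s=dla_s,
        dla_eff=dla_eff,
        d_ldw_fl=d_ldw_fl,
        d_la_fl=d_la_fl,
        fall_deficit=fall_deficit,
        dqs_uptake=dqs_uptake,
        qs_fl_pot_remob=qs_fl_pot_remob,
        dqs_offer=dqs_offer,
        dqs_org_bl=served_bl,
        dqs_org_rest=served_rest,
        dqs_mobile_bl=dqs_mobile_bl,
        dqs_mobile_rest=dqs_mobile_rest,
        dqs_fl_mobile=dqs_fl_mobile,
        dqs_fl_org=qs_fl_org,
        limiting_factor=limiting_factor,
    )
    return new_state, flux


def simulate(
    weather: Sequence[WeatherRecord],
    init: PlantState,
    p: ModelParameters,
) -> Trajectory:
    """Fold :func:`step` over a weather series.

    Deterministic: identical inputs give bit-identical trajectories.  An
    empty series returns a trajectory holding only the initial state.
    """
    p.validate()
    init.validate()
    traj = Trajectory(initial_state=init)
    state = init
    for wrec in weather:
        try:
            state, flux = step(state, wrec, p)
        except (ValueError, ArithmeticError) as exc:
            raise SimulationError(f"day {wrec.day_index}: {exc}") from exc
        traj.records.append((wrec, state, flux))
    return traj


def initial_state_from(p: ModelParameters, *, tdw_ini: float, ldw_bl_ini: float,
                       qs_bl_ini: float, qs_rest_ini: float) -> PlantState:
    """Build the day-0 state from the initial-condition table.

    The rest compartment is the residual ``tdw_ini - ldw_bl_ini - dw_fl_ini``;
    all initial sulfur is organic (mobile pools start empty).
    """
    dw_rest = tdw_ini - ldw_bl_ini - p.dw_fl_ini
    if dw_rest < 0:
        raise ValueError(
            "initial leaf + fallen-leaf dry weight exceeds initial total"
        )
    return PlantState(
        tt_cum=0.0,
        la_bl=p.la0,
        la_fl=0.0,
        ldw_bl=ldw_bl_ini,
        ldw_fl=p.dw_fl_ini,
        dw_rest=dw_rest,
        tdw=tdw_ini,
        par_abs_cum=0.0,
        qs_org_bl=qs_bl_ini,
        qs_mobile_bl=0.0,
        qs_org_rest=qs_rest_ini,
        qs_mobile_rest=0.0,
        qs_fl=0.0,
        qs_uptake_cum=0.0,
    )
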