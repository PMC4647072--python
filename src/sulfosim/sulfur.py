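"""Sulfur demand, offer, allocation and mobile-pool partitioning.

Growth sulfur requirements are set by critical dilution curves — the minimal
organic-S concentration that still permits maximal growth, declining as a
power law of compartment dry weight (the classical critical-N dilution
concept transposed to S).  The daily offer is uptake plus the sulfate
carried by today's falling leaves plus the whole-plant mobile (sulfate)
pool.  The offer serves the big leaf's organic demand first, then the rest
of the plant; what remains is stored as sulfate and re-partitioned between
leaf and rest, and any undrawn fallen-leaf sulfate is irreversibly lost
with the leaf.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .model_core import ModelParameters, PlantState

__all__ = [
    "SulfurDemand",
    "SulfurOffer",
    "s_uptake_cumulative",
    "critical_s_content_bl",
    "critical_s_content_rest",
    "growth_s_requirements",
    "fl_potential_remobilization",
    "allocate_offer",
    "s_limited_la_increment",
    "partition_mobile_s",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SulfurDemand:
    """Critical contents and the day's organic-S requirements.

    ``dqs_org_bl_req`` may be negative when the big leaf shrinks (leaf fall
    outpacing growth); allocation then treats it as zero.
    """

    s_crit_bl: float
    s_crit_rest: float
    dqs_org_bl_req: float
    dqs_org_rest_req: float


@dataclass(frozen=True)
class SulfurOffer:
    """Sources of the day's sulfur offer, mg S plant⁻¹.

    ``dqs_offer = dqs_uptake + qs_fl_pot_remob + qs_mobile_pool``; the
    mobile-pool term is the whole-plant sulfate pool at the start of the
    day net of the share leaving with today's falling tissue (counted in
    ``qs_fl_pot_remob``).
    """

    dqs_uptake: float
    qs_fl_pot_remob: float
    qs_mobile_pool: float
    dqs_offer: float

    def __post_init__(self) -> None:
        for name in ("dqs_uptake", "qs_fl_pot_remob", "qs_mobile_pool"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        total = self.dqs_uptake + self.qs_fl_pot_remob + self.qs_mobile_pool
        if not math.isclose(total, self.dqs_offer, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("dqs_offer does not equal the sum of its sources")


def s_uptake_cumulative(tt_cum: float, p: "ModelParameters") -> float:
    """Cumulative S taken up since simulation start, mg S plant⁻¹.

    Exponential time course ``a_qs * (exp(b_qs * tt) - 1)``: zero at the
    start, monotone non-decreasing for ``b_qs >= 0``.  The daily uptake is
    the difference of this curve over the day's thermal-time increment.
    """
    if tt_cum < 0:
        raise ValueError("thermal time must be non-negative")
    return p.a_qs * math.expm1(p.b_qs * tt_cum)


def critical_s_content_bl(ldw_bl: float, p: "ModelParameters", *,
                          floor: bool = True) -> float:
    """Critical (growth-required) S content of the big leaf, mg S g⁻¹ DW.

    Power-law dilution ``alpha_bl * ldw_bl ** beta_bl`` above the
    low-biomass threshold; below it the curve is replaced by the constant
    floor (the dilution law cannot be extrapolated to small canopies).
    Pass ``floor=False`` to evaluate the bare power law.
    """
    if ldw_bl <= 0:
        raise ValueError("big-leaf dry weight must be positive")
    if floor and ldw_bl < p.ldw_floor_threshold:
        return p.s_crit_floor
    return p.alpha_bl * ldw_bl ** p.beta_bl


def critical_s_content_rest(dw_rest: float, p: "ModelParameters") -> float:
    """Critical S content of the rest compartment, mg S g⁻¹ DW."""
    if dw_rest <= 0:
        raise ValueError("rest dry weight must be positive")
    return p.alpha_rest * dw_rest ** p.beta_rest


def growth_s_requirements(
    dla_candidate: float,
    d_dw_rest: float,
    state: "PlantState",
    p: "ModelParameters",
    *,
    s_crit_bl: float | None = None,
) -> SulfurDemand:
    """The day's organic-S requirements of both compartments.

    The big-leaf requirement is the critical content times the net leaf
    dry-weight change implied by ``dla_candidate`` (area / SLA); a shrinking
    leaf yields a negative requirement, reported as such but floored at zero
    by the allocator.  The rest requirement is its critical content times
    the day's rest-compartment growth.
    """
    if s_crit_bl is None:
        if state.ldw_bl >= p.ldw_floor_threshold:
            s_crit_bl = critical_s_content_bl(state.ldw_bl, p)
        else:
            s_crit_bl = p.s_crit_floor
    s_crit_rest = critical_s_content_rest(state.dw_rest, p) if state.dw_rest > 0 \
        else p.alpha_rest
    bl_req = s_crit_bl * dla_candidate / p.sla
    rest_req = s_crit_rest * max(d_dw_rest, 0.0)
    return SulfurDemand(
        s_crit_bl=s_crit_bl,
        s_crit_rest=s_crit_rest,
        dqs_org_bl_req=bl_req,
        dqs_org_rest_req=rest_req,
    )


def fl_potential_remobilization(d_ldw_fl: float, state: "PlantState") -> float:
    """Mobile S carried by today's falling tissue, mg S plant⁻¹.

    Falling tissue takes a biomass-proportional share of the leaf sulfate
    pool; that share enters the day's offer (it can be salvaged before the
    leaf drops).  Capped at the pool itself.
    """
    if d_ldw_fl < 0:
        raise ValueError("falling dry weight must be non-negative")
    if d_ldw_fl == 0.0:
        return 0.0
    if state.ldw_bl <= 0:
        logger.warning("falling tissue from an empty big leaf; no remobilization")
        return 0.0
    return min(state.qs_mobile_bl * d_ldw_fl / state.ldw_bl, state.qs_mobile_bl)


def allocate_offer(
    offer: SulfurOffer, demand: SulfurDemand, p: "ModelParameters"
) -> tuple[float, float, float, float]:
    """Serve the day's organic-S demands from the offer, in priority order.

    The big leaf is served first, then the rest of the plant.  Sources are
    drawn in the order uptake → mobile pool → fallen-leaf sulfate, so that
    sulfate about to leave with a falling leaf is salvaged only when
    actually needed.  Returns ``(dqs_org_bl, dqs_org_rest, surplus,
    dqs_fl_mobile)``: the served demands, the unspent uptake + mobile pool
    (credited back to the mobile pool), and the undrawn fallen-leaf sulfate
    (irreversibly lost with the leaf).  The four outputs sum exactly to the
    offer.
    """
    sources = [offer.dqs_uptake, offer.qs_mobile_pool, offer.qs_fl_pot_remob]

    def draw(amount: float) -> float:
        drawn = 0.0
        for i in range(len(sources)):
            if amount <= drawn:
                break
            take = min(sources[i], amount - drawn)
            sources[i] -= take
            drawn += take
        return drawn

    served_bl = draw(max(demand.dqs_org_bl_req, 0.0))
    served_rest = draw(demand.dqs_org_rest_req)
    surplus = sources[0] + sources[1]
    dqs_fl_mobile = sources[2]
    return served_bl, served_rest, surplus, dqs_fl_mobile


def s_limited_la_increment(
    dqs_offer: float, s_crit_bl: float, p: "ModelParameters"
) -> float:
    """Leaf-area increase the day's S offer can support, m² plant⁻¹.

    ``dqs_offer * sla / s_crit_bl``: the full offer converted to leaf mass
    at the critical content and then to area through the SLA.
    """
    if s_crit_bl <= 0:
        raise ValueError("critical S content must be positive")
    if dqs_offer < 0:
        raise ValueError("offer must be non-negative")
    return dqs_offer * p.sla / s_crit_bl


def partition_mobile_s(
    surplus: float,
    dqs_uptake: float,
    dqs_org_req_total: float,
    bl_req_negative: bool,
    p: "ModelParameters",
) -> tuple[float, float]:
    """Split the day's sulfate surplus between big leaf and rest.

    The leaf share is ``eps_pot`` when uptake covers the day's organic
    requirements, scaled down linearly by the uptake-to-requirement ratio
    otherwise, and forced to zero when the big-leaf requirement was negative
    (shrinking leaf: no sulfate is routed to a leaf that is losing mass).
    The two shares always sum to the surplus.
    """
    if surplus < 0:
        raise ValueError("surplus must be non-negative")
    if bl_req_negative:
        eps = 0.0
    elif dqs_org_req_total <= 0 or dqs_uptake >= dqs_org_req_total:
        eps = p.eps_pot
    else:
        eps = p.eps_pot * dqs_uptake / dqs_org_req_total
    eps = min(max(eps, 0.0), p.eps_pot)
    to_bl = eps * surplus
    return to_bl, surplus - to_bl
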