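"""Response to selection of a flux basis in a candidate evolution
environment.

All quantities are computed at the evolved state: growth fixed at
``growth_norm`` flux units, every environment component consumed, total
nutrient uptake held at its minimum.  Under those constraints:

* the *coupling* of an up-member is the smallest attainable ``|v|``
  (how much flux growth forces through it — the worst case for selection);
* the coupling of a down-member is the largest attainable ``|v|``
  (how little growth allows it to shrink — again the worst case);
* ``s_min`` is the joint worst-case total response, one MILP over all
  members simultaneously;
* ``b_min`` is the worst-case number of members whose response is
  stronger than in a reference condition.

Absolute values are linearized exactly: for minimized ``|v|`` two
inequalities suffice; for maximized ``|v|`` a big-M indicator binary
selects the sign branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import FluxBasis
from .lp import EvolvedState, FluxState, steady_state_problem
from .model import Environment, EvolveXConfig, StoichiometricModel, apply_environment
from .solver import LinearProblem


class BigMError(ValueError):
    """Flux bounds too large for the configured big-M constant."""


class ReferenceInfeasibleError(RuntimeError):
    """The reference environment cannot support the fixed growth flux."""


@dataclass
class SelectionResponse:
    """Per-member growth couplings and the worst-case total ``s_min``."""

    per_flux: dict[str, float]
    s_min: float
    tacking: frozenset[str]
    environment: Environment
    basis: FluxBasis
    linearization_gap: float = 0.0


@dataclass
class CoverageResult:
    """Worst-case count of members selected more strongly than reference."""

    b_min: int
    stronger_flags: dict[str, bool]
    gamma: float
    reference: dict[str, float]
    relaxed: bool = False


def _abs_cap(m_env: StoichiometricModel, rxn: str) -> float:
    j = m_env.index(rxn)
    return max(abs(m_env.v_lb[j]), abs(m_env.v_ub[j]))


def _check_big_m(m_env: StoichiometricModel, config: EvolveXConfig) -> None:
    worst = max(np.abs(m_env.v_lb).max(), np.abs(m_env.v_ub).max())
    if worst > config.big_M / 2:
        raise BigMError(
            f"big-M {config.big_M} too small for flux bound {worst}")


def _evolved_problem(model: StoichiometricModel, env: Environment,
                     evolved: EvolvedState, config: EvolveXConfig
                     ) -> tuple[LinearProblem, StoichiometricModel]:
    """Base LP of every selection computation: steady state in the applied
    environment, growth fixed, total uptake held at its optimum (or, under
    the literal rule, merely bounded below by it)."""
    m_env = apply_environment(model, env, forced_uptake=True,
                              uptake_bound=config.uptake_bound)
    lp = steady_state_problem(m_env)
    g = config.growth_norm
    lp.add_constraint({m_env.index(model.growth_id): 1.0}, lb=g, ub=g)
    uptake = {m_env.index(n): -1.0 for n in env.nutrient_ids}
    r_opt = evolved.r_uptake_opt
    if uptake:
        if config.uptake_rule == "bind":
            cap = r_opt * (1 + config.feasibility_tol) + config.feasibility_tol
            lp.add_constraint(uptake, ub=cap)
        else:  # literal printed direction: total uptake >= optimum
            lp.add_constraint(uptake, lb=r_opt)
    return lp, m_env


def _add_abs_min(lp: LinearProblem, j: int, cap: float) -> int:
    """t >= |v_j|; exact for minimized t."""
    t = lp.add_var(0.0, cap)
    lp.add_constraint({j: 1.0, t: -1.0}, ub=0.0)
    lp.add_constraint({j: -1.0, t: -1.0}, ub=0.0)
    return t


def _add_abs_max(lp: LinearProblem, j: int, cap: float, big_m: float) -> int:
    """t <= |v_j| via an indicator binary; exact for maximized t."""
    t = lp.add_var(0.0, cap)
    d = lp.add_var(0.0, 1.0, integer=True)
    # d = 0 branch: t <= v_j ; d = 1 branch: t <= -v_j
    lp.add_constraint({t: 1.0, j: -1.0, d: -big_m}, ub=0.0)
    lp.add_constraint({t: 1.0, j: 1.0, d: big_m}, ub=big_m)
    return t


def per_flux_coupling(model: StoichiometricModel, env: Environment,
                      evolved: EvolvedState, rxn: str, direction: str,
                      config: EvolveXConfig) -> float:
    """Growth coupling of one reaction in the evolved state.

    ``direction="up"``: minimum attainable ``|v|`` (LP); ``"down"``:
    maximum attainable ``|v|`` (MILP with one sign binary).
    """
    lp, m_env = _evolved_problem(model, env, evolved, config)
    _check_big_m(m_env, config)
    j = m_env.index(rxn)
    cap = _abs_cap(m_env, rxn)
    if direction == "up":
        t = _add_abs_min(lp, j, cap)
        lp.set_objective({t: 1.0}, sense="min")
    elif direction == "down":
        t = _add_abs_max(lp, j, cap, config.big_M)
        lp.set_objective({t: 1.0}, sense="max")
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    sol = lp.solve()
    if not sol.optimal:
        raise RuntimeError(
            f"coupling LP infeasible in environment {env.label!r}")
    return max(0.0, sol.objective)


def response_to_selection(model: StoichiometricModel, env: Environment,
                          basis: FluxBasis, evolved: EvolvedState,
                          config: EvolveXConfig) -> SelectionResponse:
    """Worst-case total response to selection of a basis (one joint MILP).

    Objective ``min sum_u |v_u| − sum_d |v_d|``: up-member fluxes at their
    joint minimum, down-member fluxes at their joint maximum.  Per-member
    couplings are re-computed by individual optimizations (the joint
    optimum need not be unique per coordinate); the tacking trait is the
    subset with coupling above ``coupling_tol``.
    """
    if not basis.members:
        return SelectionResponse({}, 0.0, frozenset(), env, basis)
    lp, m_env = _evolved_problem(model, env, evolved, config)
    _check_big_m(m_env, config)
    obj: dict[int, float] = {}
    t_vars: list[tuple[str, int, int]] = []  # (rxn, t index, v index)
    for rxn in sorted(basis.up_set):
        j = m_env.index(rxn)
        t = _add_abs_min(lp, j, _abs_cap(m_env, rxn))
        obj[t] = 1.0
        t_vars.append((rxn, t, j))
    for rxn in sorted(basis.down_set):
        j = m_env.index(rxn)
        t = _add_abs_max(lp, j, _abs_cap(m_env, rxn), config.big_M)
        obj[t] = -1.0
        t_vars.append((rxn, t, j))
    lp.set_objective(obj, sense="min")
    sol = lp.solve()
    if not sol.optimal:
        raise RuntimeError(
            f"response MILP infeasible in environment {env.label!r}")
    gap = max((abs(sol.x[t] - abs(sol.x[j])) for _, t, j in t_vars),
              default=0.0)
    per_flux = {}
    for rxn in sorted(basis.members):
        direction = "up" if rxn in basis.up_set else "down"
        per_flux[rxn] = per_flux_coupling(model, env, evolved, rxn,
                                          direction, config)
    tacking = frozenset(r for r, v in per_flux.items()
                        if v > config.coupling_tol)
    return SelectionResponse(per_flux, sol.objective, tacking, env, basis,
                             linearization_gap=gap)


def relative_response(flux_state: FluxState, growth: float) -> dict[str, float]:
    """Relative response to selection per flux: ``v / growth`` — the higher
    the flux per growth unit, the stronger the selection on it."""
    if growth <= 0:
        raise ValueError("zero growth")
    return {r: v / growth for r, v in flux_state.fluxes.items()}


def reference_couplings(model: StoichiometricModel, ref_env: Environment,
                        basis: FluxBasis,
                        config: EvolveXConfig) -> dict[str, float]:
    """Per-member couplings under the reference environment's evolved
    state — the yardstick for "stronger response than usual"."""
    from .lp import minimal_uptake_state
    evolved = minimal_uptake_state(model, ref_env, config)
    if not evolved.growth_supporting:
        raise ReferenceInfeasibleError(
            f"reference environment {ref_env.label!r} infeasible")
    out = {}
    for rxn in sorted(basis.members):
        direction = "up" if rxn in basis.up_set else "down"
        out[rxn] = per_flux_coupling(model, ref_env, evolved, rxn,
                                     direction, config)
    return out


def min_stronger_subset(model: StoichiometricModel, env: Environment,
                        basis: FluxBasis, evolved: EvolvedState, s_min: float,
                        reference: dict[str, float],
                        config: EvolveXConfig) -> CoverageResult:
    """Minimum number of basis members selected more strongly than in the
    reference condition, at the worst-case total response.

    One binary per member; a zero binary forces the member's coupling
    within ``(1+gamma)`` (up) or ``(1−gamma)`` (down) of its reference
    value while the total response is held at ``s_min``.
    """
    if not basis.members:
        return CoverageResult(0, {}, config.gamma, dict(reference))

    def attempt(slack: float):
        lp, m_env = _evolved_problem(model, env, evolved, config)
        _check_big_m(m_env, config)
        total: dict[int, float] = {}
        flags: list[tuple[str, int]] = []
        for rxn in sorted(basis.members):
            j = m_env.index(rxn)
            cap = _abs_cap(m_env, rxn)
            b = lp.add_var(0.0, 1.0, integer=True)
            flags.append((rxn, b))
            if rxn in basis.up_set:
                t = _add_abs_min(lp, j, cap)
                total[t] = 1.0
                # b = 0 -> |v| <= (1+gamma) * reference
                lp.add_constraint(
                    {t: 1.0, b: -config.big_M},
                    ub=(1 + config.gamma) * reference[rxn])
            else:
                t = _add_abs_max(lp, j, cap, config.big_M)
                total[t] = -1.0
                # b = 0 -> |v| >= (1-gamma) * reference
                lp.add_constraint(
                    {t: 1.0, b: config.big_M},
                    lb=(1 - config.gamma) * reference[rxn])
        lp.add_constraint(total, ub=s_min + slack)
        lp.set_objective({b: 1.0 for _, b in flags}, sense="min")
        return lp.solve(), flags

    slack = config.feasibility_tol * max(1.0, abs(s_min))
    sol, flags = attempt(slack)
    relaxed = False
    if not sol.optimal:
        sol, flags = attempt(10 * slack + config.feasibility_tol)
        relaxed = True
    if not sol.optimal:
        raise RuntimeError(
            f"coverage MILP infeasible in environment {env.label!r}")
    stronger = {rxn: bool(sol.x[b] > 0.5) for rxn, b in flags}
    return CoverageResult(round(sol.objective), stronger, config.gamma,
                          dict(reference), relaxed)
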