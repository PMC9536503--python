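"""Linear-programming primitives: FBA, FVA, wild-type flux ranges, and the
minimal-uptake evolved state.

The evolved state is the package's proxy for the endpoint of adaptive
laboratory evolution: the flux distribution that synthesizes a fixed
"arbitrary unit of growth" (``growth_norm``, default 10) from the minimum
total nutrient uptake, with every environment component forced to be
consumed at one flux unit or more.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Environment, EvolveXConfig, StoichiometricModel, apply_environment
from .solver import INFEASIBLE, OPTIMAL, LinearProblem


class InfeasibleError(RuntimeError):
    """An LP that the caller required to be feasible was not."""


@dataclass
class FluxState:
    """One flux distribution plus the objective that produced it."""

    fluxes: dict[str, float]
    objective_value: float | None
    status: str

    def __getitem__(self, rxn: str) -> float:
        return self.fluxes[rxn]

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL


@dataclass
class FluxRanges:
    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, rxn: str) -> tuple[float, float]:
        return self.ranges[rxn]

    def __contains__(self, rxn: str) -> bool:
        return rxn in self.ranges


@dataclass
class WildTypeRanges:
    """FVA ranges of the unevolved ("wild-type") phenotype plus the relaxed
    thresholds ``w_lb = w_min − delta*|w_min| − eps``,
    ``w_ub = w_max + delta*|w_max| + eps`` used by the flux-basis MILP."""

    ranges: FluxRanges
    w_lb: dict[str, float]
    w_ub: dict[str, float]
    delta: float
    epsilon: float


@dataclass
class EvolvedState:
    """Minimal-total-uptake flux state at fixed growth in one environment."""

    flux_state: FluxState
    r_uptake_opt: float | None
    environment: Environment
    growth_supporting: bool


def steady_state_problem(model: StoichiometricModel) -> LinearProblem:
    """LP skeleton shared by all operations: flux variables within bounds,
    S·v = 0 mass-balance rows."""
    lp = LinearProblem()
    lp.add_vars(model.v_lb, model.v_ub)
    lp.add_matrix_rows(model.S)
    return lp


def fba(model: StoichiometricModel, objective_rxn: str,
        sense: str = "max") -> FluxState:
    """Flux balance analysis: optimize one reaction flux at steady state."""
    j = model.index(objective_rxn)
    lp = steady_state_problem(model)
    lp.set_objective({j: 1.0}, sense=sense)
    sol = lp.solve()
    if not sol.optimal:
        return FluxState({}, None, sol.status)
    fluxes = dict(zip(model.reaction_ids, sol.x.tolist()))
    return FluxState(fluxes, sol.objective, OPTIMAL)


def fva(model: StoichiometricModel, reactions: list[str] | None = None,
        fixed: list[tuple[str, float, float]] = ()) -> FluxRanges:
    """Flux variability analysis: per-reaction min and max flux (2 LPs each),
    optionally with extra fixed constraints ``(rxn, lower, upper)``."""
    if reactions is None:
        reactions = list(model.reaction_ids)
    lp = steady_state_problem(model)
    for rxn, lo, hi in fixed:
        lp.add_constraint({model.index(rxn): 1.0}, lb=lo, ub=hi)
    ranges: dict[str, tuple[float, float]] = {}
    for rxn in reactions:
        j = model.index(rxn)
        lp.set_objective({j: 1.0}, sense="min")
        lo_sol = lp.solve()
        if lo_sol.status == INFEASIBLE:
            raise InfeasibleError(
                f"FVA infeasible under fixed constraints {list(fixed)!r}")
        lp.set_objective({j: 1.0}, sense="max")
        hi_sol = lp.solve()
        ranges[rxn] = (lo_sol.objective, hi_sol.objective)
    return FluxRanges(ranges)


def wild_type_ranges(model: StoichiometricModel, reference_env: Environment,
                     config: EvolveXConfig,
                     growth_fraction: float = 1.0) -> WildTypeRanges:
    """Wild-type flux ranges in a reference environment.

    FVA with growth fixed at ``growth_fraction`` of its maximum (plain
    uptake mode — nutrients available but not forced), then the
    delta/epsilon-relaxed thresholds.
    """
    m_env = apply_environment(model, reference_env, forced_uptake=False,
                              uptake_bound=config.uptake_bound)
    growth = fba(m_env, model.growth_id, "max")
    if not growth.optimal or growth.objective_value <= config.feasibility_tol:
        raise InfeasibleError("wild type does not grow in the reference environment")
    target = growth_fraction * growth.objective_value
    ranges = fva(m_env, fixed=[(model.growth_id, target, target)])
    w_lb, w_ub = {}, {}
    for rxn, (lo, hi) in ranges.ranges.items():
        w_lb[rxn] = lo - config.delta * abs(lo) - config.epsilon
        w_ub[rxn] = hi + config.delta * abs(hi) + config.epsilon
    return WildTypeRanges(ranges, w_lb, w_ub, config.delta, config.epsilon)


def minimal_uptake_state(model: StoichiometricModel, env: Environment,
                         config: EvolveXConfig) -> EvolvedState:
    """Evolved state: minimize total nutrient uptake at fixed growth.

    Minimizes ``sum_n (−v_n)`` over nutrients n subject to steady state,
    ``v_growth = growth_norm``, forced uptake of every nutrient and zeroed
    inhibited reactions.  An environment that cannot sustain the fixed
    growth flux is returned flagged non-growth-supporting, not raised.
    """
    m_env = apply_environment(model, env, forced_uptake=True,
                              uptake_bound=config.uptake_bound)
    lp = steady_state_problem(m_env)
    g = config.growth_norm
    lp.add_constraint({m_env.index(model.growth_id): 1.0}, lb=g, ub=g)
    lp.set_objective({m_env.index(n): -1.0 for n in env.nutrient_ids}, sense="min")
    sol = lp.solve()
    if not sol.optimal:
        return EvolvedState(FluxState({}, None, sol.status), None, env, False)
    fluxes = dict(zip(m_env.reaction_ids, sol.x.tolist()))
    return EvolvedState(FluxState(fluxes, sol.objective, OPTIMAL),
                        sol.objective, env, True)
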