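"""Minimal flux basis of a desired trait: the smallest set of fluxes that
must leave the wild-type flux ranges for the trait to reach a fraction
``alpha`` of its maximum in the application environment.

Solved as a MILP with one binary per candidate reaction that gates the
flux back into its wild-type thresholds when zero; alternative minimal
bases are enumerated with integer cuts; up/down directions are assigned
by one-sided feasibility probes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lp import FluxState, WildTypeRanges, fba, steady_state_problem
from .model import Environment, EvolveXConfig, StoichiometricModel, apply_environment
from .solver import OPTIMAL, LinearProblem


class TraitBlockedError(RuntimeError):
    """The trait flux cannot exceed zero in the application environment."""


class BasisError(RuntimeError):
    pass


@dataclass
class FluxBasis:
    """Result of one basis MILP solve: up-set H, down-set L, witness state."""

    up_set: frozenset[str]
    down_set: frozenset[str]
    trait_id: str
    alpha: float
    witness: FluxState
    ambiguous: frozenset[str] = frozenset()

    @property
    def k(self) -> int:
        return len(self.up_set)

    @property
    def l(self) -> int:
        return len(self.down_set)

    @property
    def members(self) -> frozenset[str]:
        return self.up_set | self.down_set

    @property
    def size(self) -> int:
        return self.k + self.l

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.up_set)), tuple(sorted(self.down_set)))


@dataclass
class BasisFamily:
    bases: list[FluxBasis]
    truncated: bool = False

    def __iter__(self):
        return iter(self.bases)

    def __len__(self) -> int:
        return len(self.bases)


def _trait_max(m_env: StoichiometricModel, trait_id: str) -> float:
    state = fba(m_env, trait_id, "max")
    if not state.optimal:
        raise BasisError("application environment infeasible")
    return state.objective_value


def _basis_milp(m_env: StoichiometricModel, trait_id: str, trait_floor: float,
                wt: WildTypeRanges, config: EvolveXConfig
                ) -> tuple[LinearProblem, dict[str, int]]:
    """Assemble the basis MILP; returns the problem and reaction -> binary
    variable index map (excluded reactions carry no binary: they may
    deviate freely at zero cost)."""
    lp = steady_state_problem(m_env)
    lp.add_constraint({m_env.index(trait_id): 1.0}, lb=trait_floor)
    y_index: dict[str, int] = {}
    for rxn in m_env.reaction_ids:
        if rxn in config.exclude_from_basis:
            continue
        j = m_env.index(rxn)
        lb_j, ub_j = m_env.v_lb[j], m_env.v_ub[j]
        w_lo, w_hi = wt.w_lb[rxn], wt.w_ub[rxn]
        if lb_j >= w_lo and ub_j <= w_hi:
            continue  # cannot leave the wild-type range at all
        y = lp.add_var(0.0, 1.0, integer=True)
        y_index[rxn] = y
        # y = 0 confines v_j to [w_lo, w_hi]; y = 1 relaxes to model bounds
        if ub_j > w_hi:
            lp.add_constraint({j: 1.0, y: -(ub_j - w_hi)}, ub=w_hi)
        if lb_j < w_lo:
            lp.add_constraint({j: 1.0, y: -(lb_j - w_lo)}, lb=w_lo)
    return lp, y_index


def _solve_members(lp: LinearProblem, y_index: dict[str, int],
                   m_env: StoichiometricModel
                   ) -> tuple[frozenset[str], FluxState, float] | None:
    lp.set_objective({y: 1.0 for y in y_index.values()}, sense="min")
    sol = lp.solve()
    if not sol.optimal:
        return None
    members = frozenset(r for r, y in y_index.items() if sol.x[y] > 0.5)
    fluxes = dict(zip(m_env.reaction_ids,
                      sol.x[:m_env.n_reactions].tolist()))
    return members, FluxState(fluxes, sol.objective, OPTIMAL), sol.objective


def assign_directions(model: StoichiometricModel, members: frozenset[str],
                      wt: WildTypeRanges, trait_id: str, alpha: float,
                      app_env: Environment, config: EvolveXConfig,
                      witness: FluxState | None = None
                      ) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Assign up/down to each basis member by one-sided feasibility probes.

    A member is *up* if the trait level is attainable only with its flux
    above the wild-type upper threshold, *down* if only below the lower
    one.  Members feasible on either side are resolved by the witness
    solution's side and reported in the ambiguous set.
    """
    m_env = apply_environment(model, app_env, forced_uptake=False,
                              uptake_bound=config.uptake_bound)
    trait_floor = alpha * _trait_max(m_env, trait_id)
    probe_tol = max(config.feasibility_tol, 1e-6)

    def probe(rxn: str, side: str) -> bool:
        lp = steady_state_problem(m_env)
        lp.add_constraint({m_env.index(trait_id): 1.0}, lb=trait_floor)
        # other members stay free; non-members confined to wild-type range
        for r in m_env.reaction_ids:
            if r in members or r in config.exclude_from_basis:
                continue
            lp.add_constraint({m_env.index(r): 1.0},
                              lb=wt.w_lb[r], ub=wt.w_ub[r])
        j = m_env.index(rxn)
        if side == "up":
            lp.add_constraint({j: 1.0}, lb=wt.w_ub[rxn] + probe_tol)
        else:
            lp.add_constraint({j: 1.0}, ub=wt.w_lb[rxn] - probe_tol)
        lp.set_objective({}, sense="min")
        return lp.solve().optimal

    up, down, ambiguous = set(), set(), set()
    for rxn in sorted(members):
        can_up = probe(rxn, "up")
        can_down = probe(rxn, "down")
        if can_up and not can_down:
            up.add(rxn)
        elif can_down and not can_up:
            down.add(rxn)
        elif can_up and can_down:
            ambiguous.add(rxn)
            w_val = witness[rxn] if witness is not None else 0.0
            (up if w_val > wt.w_ub[rxn] else down).add(rxn)
        else:
            raise BasisError(
                f"basis member {rxn!r} deviates on neither side — "
                "inconsistent MILP result")
    return frozenset(up), frozenset(down), frozenset(ambiguous)


def find_flux_basis(model: StoichiometricModel, app_env: Environment,
                    trait_id: str, wt: WildTypeRanges,
                    config: EvolveXConfig) -> FluxBasis:
    """Solve the minimal flux-basis MILP for one trait.

    Minimizes the number of reactions whose flux must leave the wild-type
    thresholds while the trait flux reaches ``alpha`` of its maximum in
    the application environment.
    """
    m_env = apply_environment(model, app_env, forced_uptake=False,
                              uptake_bound=config.uptake_bound)
    vmax = _trait_max(m_env, trait_id)
    if vmax <= config.feasibility_tol:
        raise TraitBlockedError(
            f"trait {trait_id!r} blocked in application environment")
    lp, y_index = _basis_milp(m_env, trait_id, config.alpha * vmax, wt, config)
    result = _solve_members(lp, y_index, m_env)
    if result is None:
        raise BasisError(f"basis MILP infeasible at alpha={config.alpha}")
    members, witness, _ = result
    up, down, ambiguous = assign_directions(
        model, members, wt, trait_id, config.alpha, app_env, config, witness)
    return FluxBasis(up, down, trait_id, config.alpha, witness, ambiguous)


def enumerate_flux_bases(model: StoichiometricModel, app_env: Environment,
                         trait_id: str, wt: WildTypeRanges,
                         config: EvolveXConfig) -> BasisFamily:
    """All alternative minimum-cardinality bases, via integer cuts.

    After each solution the cut ``sum_{j in solution} y_j <= n − 1`` is
    added and the MILP re-solved; enumeration stops when the objective
    exceeds the minimum, the problem turns infeasible, or
    ``enumeration_limit`` is reached.  Bases are returned in lexicographic
    member order.
    """
    m_env = apply_environment(model, app_env, forced_uptake=False,
                              uptake_bound=config.uptake_bound)
    vmax = _trait_max(m_env, trait_id)
    if vmax <= config.feasibility_tol:
        raise TraitBlockedError(
            f"trait {trait_id!r} blocked in application environment")
    lp, y_index = _basis_milp(m_env, trait_id, config.alpha * vmax, wt, config)
    first = _solve_members(lp, y_index, m_env)
    if first is None:
        raise BasisError(f"basis MILP infeasible at alpha={config.alpha}")
    n_min = round(first[2])
    found: list[tuple[frozenset[str], FluxState]] = []
    truncated = False
    current = first
    while True:
        members, witness, obj = current
        if round(obj) > n_min:
            break
        found.append((members, witness))
        if len(found) >= config.enumeration_limit:
            truncated = True
            break
        if n_min == 0:
            break  # the empty basis has no alternatives
        lp.add_constraint({y_index[r]: 1.0 for r in members}, ub=n_min - 1)
        current = _solve_members(lp, y_index, m_env)
        if current is None:
            break
    bases = []
    for members, witness in found:
        up, down, ambiguous = assign_directions(
            model, members, wt, trait_id, config.alpha, app_env, config, witness)
        bases.append(FluxBasis(up, down, trait_id, config.alpha,
                               witness, ambiguous))
    bases.sort(key=FluxBasis.sort_key)
    return BasisFamily(bases, truncated)


def write_basis_tsv(basis: FluxBasis, wt: WildTypeRanges, path) -> None:
    """Serialize a basis: one row per member with direction, witness flux
    and wild-type range."""
    lines = ["reaction\tdirection\twitness_flux\twt_min\twt_max\tambiguous"]
    for rxn in sorted(basis.members):
        direction = "up" if rxn in basis.up_set else "down"
        lo, hi = wt.ranges[rxn]
        lines.append(f"{rxn}\t{direction}\t{basis.witness[rxn]:.6g}"
                     f"\t{lo:.6g}\t{hi:.6g}\t{rxn in basis.ambiguous}")
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
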