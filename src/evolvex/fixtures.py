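"""Toy metabolic networks with analytically known couplings, plus
brute-force oracles that verify the MILP machinery independently.

The oracles deliberately assemble their LPs by hand with raw
``scipy.optimize.linprog`` calls — no code shared with the production
MILP builders — so that agreement between the two routes is a genuine
cross-check rather than a tautology.

Toy network TOY1 (the running example of the whole package)::

    EX_A:  A <-> out      [-1000, 0]     nutrient A
    EX_B:  B <-> out      [-1000, 0]     nutrient B
    R1:    A -> C         [0, 1000]
    R2:    B -> C + P     [0, 1000]      growth on B co-produces P
    R4:    C -> P         [0, 1000]
    R3:    C -> X         [0, 1000]
    EX_P:  P -> out       [0, 1000]      the desired trait (secretion)
    GROWTH:X -> out       [0, 1000]      fitness proxy

On nutrient A the product P can be bypassed entirely (trait uncoupled
from growth); on nutrient B every unit of growth forces one unit of P
secretion (trait growth-coupled) — the tacking-trait situation.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.optimize import linprog

from .model import Environment, EvolveXConfig, StoichiometricModel, apply_environment

ORACLE_SIZE_CAP = 12


class OracleSizeError(ValueError):
    """Network too large for exhaustive verification."""


# ---------------------------------------------------------------------------
# toy networks
# ---------------------------------------------------------------------------

def _build(name: str, mets: list[str], rxns: list[tuple[str, dict, float, float]],
           growth: str) -> StoichiometricModel:
    S = np.zeros((len(mets), len(rxns)))
    mi = {m: i for i, m in enumerate(mets)}
    ids, lb, ub = [], [], []
    for j, (rid, stoich, lo, hi) in enumerate(rxns):
        ids.append(rid)
        lb.append(lo)
        ub.append(hi)
        for m, c in stoich.items():
            S[mi[m], j] = c
    return StoichiometricModel(mets, ids, S, np.array(lb), np.array(ub),
                               growth, name=name)


def toy_network(name: str) -> StoichiometricModel:
    """Return one of the bundled toy networks: TOY1, TOY_FIG1, SERIES,
    PARALLEL (see module docstring for TOY1)."""
    if name == "TOY1":
        return _build("TOY1", ["A", "B", "C", "P", "X"], [
            ("EX_A", {"A": -1}, -1000, 0),
            ("EX_B", {"B": -1}, -1000, 0),
            ("R1", {"A": -1, "C": 1}, 0, 1000),
            ("R2", {"B": -1, "C": 1, "P": 1}, 0, 1000),
            ("R4", {"C": -1, "P": 1}, 0, 1000),
            ("R3", {"C": -1, "X": 1}, 0, 1000),
            ("EX_P", {"P": -1}, 0, 1000),
            ("GROWTH", {"X": -1}, 0, 1000),
        ], "GROWTH")
    if name == "TOY_FIG1":
        # two nutrient routes into one precursor pool E; nutrient S2
        # co-produces the secreted product P, nutrient S1 does not
        return _build("TOY_FIG1", ["S1", "S2", "E", "P", "X"], [
            ("EX_S1", {"S1": -1}, -1000, 0),
            ("EX_S2", {"S2": -1}, -1000, 0),
            ("CAT1", {"S1": -1, "E": 2}, 0, 1000),
            ("CAT2", {"S2": -1, "E": 1, "P": 1}, 0, 1000),
            ("PSYN", {"E": -1, "P": 1}, 0, 1000),
            ("BIO", {"E": -1, "X": 1}, 0, 1000),
            ("EX_P", {"P": -1}, 0, 1000),
            ("GROWTH", {"X": -1}, 0, 1000),
        ], "GROWTH")
    if name == "SERIES":
        # single linear path: every internal reaction fully coupled to growth
        return _build("SERIES", ["S", "M1", "M2"], [
            ("EX_S", {"S": -1}, -1000, 0),
            ("R1", {"S": -1, "M1": 1}, 0, 1000),
            ("R2", {"M1": -1, "M2": 1}, 0, 1000),
            ("GROWTH", {"M2": -1}, 0, 1000),
        ], "GROWTH")
    if name == "PARALLEL":
        # two redundant branches: neither coupled to growth, their sum is
        return _build("PARALLEL", ["S", "M"], [
            ("EX_S", {"S": -1}, -1000, 0),
            ("RA", {"S": -1, "M": 1}, 0, 1000),
            ("RB", {"S": -1, "M": 1}, 0, 1000),
            ("GROWTH", {"M": -1}, 0, 1000),
        ], "GROWTH")
    raise ValueError(f"unknown toy network {name!r}")


def random_network(seed: int) -> dict:
    """Seeded small random network, growth-feasible by construction.

    A nutrient-to-growth chain guarantees feasibility; a secreted product
    branch provides a trait; extra random internal reactions (possibly
    reversible) and an optional second nutrient create alternative routes.
    Returns the model plus suggested application/evolution environments
    and the trait id.
    """
    rng = np.random.default_rng(seed)
    n_chain = int(rng.integers(2, 4))  # chain metabolites M1..Mk
    mets = ["S"] + [f"M{i}" for i in range(1, n_chain + 1)] + ["P", "X"]
    rxns: list[tuple[str, dict, float, float]] = [
        ("EX_S", {"S": -1}, -1000, 0),
        ("T1", {"S": -1, "M1": 1}, 0, 1000),
    ]
    for i in range(1, n_chain):
        rxns.append((f"C{i}", {f"M{i}": -1, f"M{i+1}": 1}, 0, 1000))
    rxns.append(("BIO", {f"M{n_chain}": -1, "X": 1}, 0, 1000))
    branch_from = f"M{int(rng.integers(1, n_chain + 1))}"
    rxns.append(("PSYN", {branch_from: -1, "P": 1}, 0, 1000))
    rxns.append(("EX_P", {"P": -1}, 0, 1000))
    rxns.append(("GROWTH", {"X": -1}, 0, 1000))

    second_nutrient = bool(rng.random() < 0.5)
    if second_nutrient:
        mets.append("S2")
        target = f"M{int(rng.integers(1, n_chain + 1))}"
        stoich = {"S2": -1, target: 1}
        if rng.random() < 0.5:  # second nutrient may co-produce the product
            stoich["P"] = 1
        rxns.append(("EX_S2", {"S2": -1}, -1000, 0))
        rxns.append(("T2", stoich, 0, 1000))

    internal = [m for m in mets if m not in ("S", "S2")]
    n_extra = int(rng.integers(0, 3))
    for e in range(n_extra):
        if len(rxns) >= ORACLE_SIZE_CAP:
            break
        a, b = rng.choice(internal, size=2, replace=False)
        lo = -1000.0 if rng.random() < 0.3 else 0.0
        rxns.append((f"E{e}", {a: -1, b: 1}, lo, 1000))

    model = _build(f"RAND{seed}", mets, rxns, "GROWTH")
    app_env = Environment(frozenset({"EX_S"}), label="S")
    evo_env = (Environment(frozenset({"EX_S2"}), label="S2")
               if second_nutrient else app_env)
    return {"model": model, "app_env": app_env, "evo_env": evo_env,
            "trait_id": "EX_P"}


# ---------------------------------------------------------------------------
# raw-LP plumbing for the oracles (independent of evolvex.solver)
# ---------------------------------------------------------------------------

def _solve_raw(model: StoichiometricModel, c: np.ndarray,
               extra_rows: list[tuple[np.ndarray, float, float]] = (),
               var_bounds: dict[int, tuple[float, float]] | None = None):
    """linprog wrapper: min c·v s.t. S·v = 0, bounds, extra row constraints.
    Returns (feasible, objective, x)."""
    n = model.n_reactions
    bounds = list(zip(model.v_lb.tolist(), model.v_ub.tolist()))
    if var_bounds:
        for j, (lo, hi) in var_bounds.items():
            lo = max(lo, bounds[j][0])
            hi = min(hi, bounds[j][1])
            if lo > hi:
                return False, None, None
            bounds[j] = (lo, hi)
    A_ub, b_ub, A_eq, b_eq = [], [], [model.S], [np.zeros(model.n_metabolites)]
    for row, lo, hi in extra_rows:
        if lo == hi:
            A_eq.append(row.reshape(1, -1))
            b_eq.append(np.array([lo]))
        else:
            if np.isfinite(hi):
                A_ub.append(row)
                b_ub.append(hi)
            if np.isfinite(lo):
                A_ub.append(-row)
                b_ub.append(-lo)
    res = linprog(
        c,
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.vstack(A_eq), b_eq=np.concatenate(b_eq),
        bounds=bounds, method="highs",
    )
    if res.status != 0:
        return False, None, None
    return True, float(res.fun), res.x


def _unit_row(model: StoichiometricModel, rxn: str) -> np.ndarray:
    row = np.zeros(model.n_reactions)
    row[model.index(rxn)] = 1.0
    return row


def _uptake_row(model: StoichiometricModel, env: Environment) -> np.ndarray:
    row = np.zeros(model.n_reactions)
    for nut in env.nutrient_ids:
        row[model.index(nut)] = -1.0
    return row


def _evolved_rows(model: StoichiometricModel, env: Environment,
                  config: EvolveXConfig,
                  r_opt: float) -> list[tuple[np.ndarray, float, float]]:
    g = config.growth_norm
    cap = r_opt * (1 + config.feasibility_tol) + config.feasibility_tol
    return [
        (_unit_row(model, model.growth_id), g, g),
        (_uptake_row(model, env), -np.inf, cap),
    ]


def _min_uptake_raw(model: StoichiometricModel, env: Environment,
                    config: EvolveXConfig):
    """Oracle-side evolved state: (feasible, r_uptake_opt, applied model)."""
    m_env = apply_environment(model, env, forced_uptake=True,
                              uptake_bound=config.uptake_bound)
    g = config.growth_norm
    feas, obj, _ = _solve_raw(
        m_env, _uptake_row(m_env, env),
        extra_rows=[(_unit_row(m_env, m_env.growth_id), g, g)])
    return feas, obj, m_env


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def exhaustive_min_basis(model: StoichiometricModel, app_env: Environment,
                         trait_id: str, wt, alpha: float,
                         exclude: frozenset[str] = frozenset()) -> list[frozenset]:
    """All minimum-cardinality deviation sets, by brute-force subset sweep.

    A subset is feasible when the trait constraint can be met with every
    reaction outside the subset (and outside ``exclude``) confined to its
    wild-type thresholds.  Subsets are swept in increasing cardinality;
    the first feasible cardinality is enumerated completely.
    """
    if model.n_reactions > ORACLE_SIZE_CAP:
        raise OracleSizeError("oracle size cap exceeded "
                              f"({model.n_reactions} > {ORACLE_SIZE_CAP})")
    m_env = apply_environment(model, app_env, forced_uptake=False)
    tj = m_env.index(trait_id)
    c = np.zeros(m_env.n_reactions)
    c[tj] = -1.0
    feas, obj, _ = _solve_raw(m_env, c)
    if not feas:
        raise RuntimeError("trait LP infeasible in application environment")
    trait_max = -obj
    trait_row = (_unit_row(m_env, trait_id), alpha * trait_max, np.inf)
    candidates = [r for r in m_env.reaction_ids if r not in exclude]

    def subset_feasible(members: frozenset) -> bool:
        var_bounds = {
            m_env.index(r): (wt.w_lb[r], wt.w_ub[r])
            for r in candidates if r not in members
        }
        feas, _, _ = _solve_raw(m_env, np.zeros(m_env.n_reactions),
                                extra_rows=[trait_row], var_bounds=var_bounds)
        return feas

    for size in range(len(candidates) + 1):
        found = [frozenset(s) for s in combinations(candidates, size)
                 if subset_feasible(frozenset(s))]
        if found:
            return found
    return []  # unreachable: full set is always feasible


def fca_oracle(model: StoichiometricModel, env: Environment,
               config: EvolveXConfig | None = None) -> dict[str, bool]:
    """Directional growth-coupling classification by two sign-split LPs.

    For each reaction, minimize ``v`` on the ``v >= 0`` branch and ``−v``
    on the ``v <= 0`` branch under the evolved-state constraints; the
    reaction is coupled to growth iff the smallest attainable ``|v|``
    across feasible branches exceeds the coupling tolerance.  No big-M,
    no shared formulation with the selection module.
    """
    config = config or EvolveXConfig()
    feas, r_opt, m_env = _min_uptake_raw(model, env, config)
    if not feas:
        raise RuntimeError("environment does not support the fixed growth flux")
    rows = _evolved_rows(m_env, env, config, r_opt)
    out: dict[str, bool] = {}
    for rxn in m_env.reaction_ids:
        j = m_env.index(rxn)
        best = np.inf
        for sign in (1.0, -1.0):
            c = np.zeros(m_env.n_reactions)
            c[j] = sign
            vb = {j: (0.0, np.inf)} if sign > 0 else {j: (-np.inf, 0.0)}
            feas, obj, _ = _solve_raw(m_env, c, extra_rows=rows, var_bounds=vb)
            if feas:
                best = min(best, obj)
        out[rxn] = bool(np.isfinite(best) and best > config.coupling_tol)
    return out


def brute_force_b_min(model: StoichiometricModel, env: Environment,
                      up_set: frozenset[str], down_set: frozenset[str],
                      s_min: float, reference: dict[str, float],
                      config: EvolveXConfig | None = None) -> int:
    """Minimum stronger-than-reference subset size by enumerating every
    flag assignment (and every sign pattern of reversible members, which
    keeps absolute values linear within a branch)."""
    config = config or EvolveXConfig()
    members = sorted(up_set | down_set)
    p = len(members)
    if p > ORACLE_SIZE_CAP:
        raise OracleSizeError("basis too large for brute force")
    feas, r_opt, m_env = _min_uptake_raw(model, env, config)
    if not feas:
        raise RuntimeError("environment does not support the fixed growth flux")
    base_rows = _evolved_rows(m_env, env, config, r_opt)
    gamma = config.gamma
    tol = config.feasibility_tol * max(1.0, abs(s_min))
    reversible = [r for r in members
                  if m_env.v_lb[m_env.index(r)] < 0 < m_env.v_ub[m_env.index(r)]]

    def feasible_with_flags(strong: frozenset) -> bool:
        # sign s_r = +1 means v_r >= 0 on this branch, so |v_r| = s_r * v_r;
        # irreversible members keep the sign their bounds dictate
        for signs in product((1.0, -1.0), repeat=len(reversible)):
            sign = {r: (1.0 if m_env.v_ub[m_env.index(r)] > 0 else -1.0)
                    for r in members}
            sign.update(dict(zip(reversible, signs)))
            vb: dict[int, tuple[float, float]] = {}
            rows = list(base_rows)
            total = np.zeros(m_env.n_reactions)
            ok = True
            for r in members:
                j = m_env.index(r)
                s = sign[r]
                cur = vb.get(j, (-np.inf, np.inf))
                vb[j] = (max(cur[0], 0.0), cur[1]) if s > 0 else (cur[0], min(cur[1], 0.0))
                total[j] += s if r in up_set else -s
                if r not in strong:
                    thresh = reference[r]
                    if r in up_set:  # |v_r| <= (1+gamma)*ref
                        if s > 0:
                            vb[j] = (vb[j][0], min(vb[j][1], (1 + gamma) * thresh))
                        else:
                            vb[j] = (max(vb[j][0], -(1 + gamma) * thresh), vb[j][1])
                    else:  # |v_r| >= (1-gamma)*ref
                        lo = (1 - gamma) * thresh
                        if s > 0:
                            vb[j] = (max(vb[j][0], lo), vb[j][1])
                        else:
                            vb[j] = (vb[j][0], min(vb[j][1], -lo))
                if vb[j][0] > vb[j][1]:
                    ok = False
                    break
            if not ok:
                continue
            rows.append((total, -np.inf, s_min + tol))
            feas, _, _ = _solve_raw(m_env, np.zeros(m_env.n_reactions),
                                    extra_rows=rows, var_bounds=vb)
            if feas:
                return True
        return False

    best = p
    for size in range(p + 1):
        if any(feasible_with_flags(frozenset(s))
               for s in combinations(members, size)):
            best = size
            break
    return best
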