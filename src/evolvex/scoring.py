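"""Candidate-environment enumeration, suitability scoring and ranking.

The suitability score of an evolution environment is

    score = 1e3 * (k − s_min) / (k + l) + 1e3 * (k + l − b_min) / (k + l) + z

with k/l the up/down basis sizes, ``s_min`` the worst-case total response
to selection, ``b_min`` the worst-case stronger-than-reference subset
size and ``z`` the number of chemical components.  Lower is better: the
first term vanishes when every up-member is fully growth-coupled, the
second when every member responds more strongly than in the reference
condition, and the component count discounts for uncertain nutrient
preferences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

from .basis import BasisFamily, FluxBasis, enumerate_flux_bases
from .lp import minimal_uptake_state, wild_type_ranges
from .model import (Environment, EvolveXConfig, NutrientCatalogue,
                    StoichiometricModel)
from .selection import (min_stronger_subset, reference_couplings,
                        response_to_selection)

logger = logging.getLogger(__name__)


@dataclass
class EnvironmentScore:
    """Eq-by-eq ingredients and the final suitability score of one
    candidate environment (``score`` is None when not growth-supporting)."""

    environment: Environment
    k: int = 0
    l: int = 0
    s_min: float | None = None
    b_min: int | None = None
    z: int = 1
    term_selection: float | None = None
    term_coverage: float | None = None
    score: float | None = None
    growth_supporting: bool = False
    basis_used: FluxBasis | None = None
    basis_index: int | None = None
    tacking: frozenset[str] = frozenset()


def score_environment(k: int, l: int, s_min: float, b_min: int, z: int,
                      environment: Environment | None = None) -> EnvironmentScore:
    """Evaluate the suitability score formula (pure arithmetic, no
    clamping: a negative ``s_min`` legitimately raises the score)."""
    if k + l == 0:
        raise ValueError("empty basis not scoreable")
    if not 0 <= b_min <= k + l:
        raise ValueError("b_min outside [0, k + l]")
    if z < 1:
        raise ValueError("component count z must be >= 1")
    term_selection = 1e3 * (k - s_min) / (k + l)
    term_coverage = 1e3 * (k + l - b_min) / (k + l)
    return EnvironmentScore(
        environment=environment,
        k=k, l=l, s_min=s_min, b_min=b_min, z=z,
        term_selection=term_selection, term_coverage=term_coverage,
        score=term_selection + term_coverage + z,
        growth_supporting=True,
    )


def enumerate_environments(catalogue: NutrientCatalogue, max_size: int,
                           exact_size: bool = True,
                           inhibitors: bool = False) -> list[Environment]:
    """All nutrient combinations of size ``max_size`` (or 1..max_size),
    optionally crossed with each single inhibitor, in catalogue order."""
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if max_size > len(catalogue):
        raise ValueError(
            f"max_size {max_size} exceeds catalogue size {len(catalogue)}")
    sizes = [max_size] if exact_size else list(range(1, max_size + 1))
    envs: list[Environment] = []
    for size in sizes:
        for combo in combinations(catalogue.entries, size):
            label = "+".join(e.label for e in combo)
            nutrients = frozenset(e.exchange_id for e in combo)
            envs.append(Environment(nutrients, label=label))
            if inhibitors:
                for inh in catalogue.inhibitors:
                    envs.append(Environment(
                        nutrients, frozenset(inh.reaction_ids),
                        label=f"{label}+{inh.label}",
                        z_override=size + 1))
    return envs


def rank_environments(model: StoichiometricModel, app_env: Environment,
                      trait_id: str, catalogue: NutrientCatalogue,
                      reference_env: Environment, config: EvolveXConfig,
                      max_size: int = 3, exact_size: bool = True,
                      inhibitors: bool = False,
                      environments: list[Environment] | None = None,
                      growth_fraction: float = 1.0) -> list[EnvironmentScore]:
    """Full pipeline: basis in the application environment, then per
    candidate environment the evolved state, response to selection,
    coverage and score; sorted ascending by score (ties: fewer components,
    then label).  Non-growth-supporting candidates are listed last,
    unscored.  With several minimal bases, each is scored and the best
    score per environment is kept.
    """
    wt = wild_type_ranges(model, app_env, config, growth_fraction)
    family: BasisFamily = enumerate_flux_bases(model, app_env, trait_id,
                                               wt, config)
    refs = [reference_couplings(model, reference_env, b, config)
            for b in family]
    if environments is None:
        environments = enumerate_environments(catalogue, max_size,
                                              exact_size, inhibitors)
    scored: list[EnvironmentScore] = []
    unscored: list[EnvironmentScore] = []
    for env in environments:
        evolved = minimal_uptake_state(model, env, config)
        if not evolved.growth_supporting:
            unscored.append(EnvironmentScore(environment=env, z=env.z))
            continue
        best: EnvironmentScore | None = None
        for idx, (basis, ref) in enumerate(zip(family, refs)):
            resp = response_to_selection(model, env, basis, evolved, config)
            cov = min_stronger_subset(model, env, basis, evolved,
                                      resp.s_min, ref, config)
            es = score_environment(basis.k, basis.l, resp.s_min, cov.b_min,
                                   env.z, environment=env)
            es.basis_used = basis
            es.basis_index = idx
            es.tacking = resp.tacking
            if best is None or es.score < best.score:
                best = es
        logger.info("environment %s: score %.3f", env.label, best.score)
        scored.append(best)
    scored.sort(key=lambda e: (e.score, e.z, e.environment.label))
    return scored + unscored


def write_ranking(table: list[EnvironmentScore], path: str | Path) -> None:
    """Serialize a ranking to TSV (byte-identical across reruns for the
    same configuration and solver)."""
    cols = ["rank", "label", "nutrients", "inhibitors", "z", "k", "l",
            "s_min", "b_min", "score", "growth_supporting", "basis_index",
            "tacking"]
    lines = ["\t".join(cols)]

    def fmt(x) -> str:
        if x is None:
            return "NA"
        if isinstance(x, float):
            return f"{x:.6g}"
        return str(x)

    for rank, es in enumerate(table, start=1):
        env = es.environment
        lines.append("\t".join([
            fmt(rank if es.growth_supporting else None),
            env.label,
            ";".join(sorted(env.nutrient_ids)),
            ";".join(sorted(env.inhibited_ids)),
            fmt(es.z), fmt(es.k if es.growth_supporting else None),
            fmt(es.l if es.growth_supporting else None),
            fmt(es.s_min), fmt(es.b_min), fmt(es.score),
            str(es.growth_supporting), fmt(es.basis_index),
            ";".join(sorted(es.tacking)),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
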