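"""Stoichiometric models, environments, nutrient catalogues and configuration.

Conventions used throughout the package:

* Exchange reactions are written ``metabolite <-> (outside)`` with a single
  −1 stoichiometric entry, so *negative* exchange flux is uptake and
  positive flux is secretion.
* Flux bounds are clamped into a ±10,000 box on loading.  The big-M
  constant used by the selection MILPs (default 20,000) is double that box,
  which keeps every indicator constraint valid.
* Applying an :class:`Environment` blocks uptake of every exchange outside
  the nutrient set, zeroes inhibited reactions and, in *forced-uptake*
  mode, requires at least one flux unit of uptake for every nutrient
  (upper bound −1) — the convention under which evolved states and
  couplings are computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: default flux box half-width; bounds are clamped into it on load
FLUX_BOX = 10_000.0


class ModelValidationError(ValueError):
    """The model (or an environment applied to it) violates an invariant."""


class CatalogueError(ValueError):
    """A nutrient catalogue file is malformed."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass
class StoichiometricModel:
    """A stoichiometric network: S matrix, flux bounds, reaction identities.

    Rows of ``S`` follow ``metabolite_ids``, columns follow ``reaction_ids``.
    ``growth_id`` names the reaction whose flux serves as the fitness proxy.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    v_lb: np.ndarray
    v_ub: np.ndarray
    growth_id: str
    exchange_ids: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.v_lb = np.asarray(self.v_lb, dtype=float)
        self.v_ub = np.asarray(self.v_ub, dtype=float)
        if not self.exchange_ids:
            self.exchange_ids = tuple(self.detect_exchanges())
        self._index = {r: i for i, r in enumerate(self.reaction_ids)}
        self.validate()

    # -- bookkeeping -------------------------------------------------------
    def index(self, rxn: str) -> int:
        try:
            return self._index[rxn]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn!r}") from None

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def detect_exchanges(self) -> list[str]:
        """Exchanges are the columns with exactly one nonzero entry."""
        counts = np.count_nonzero(self.S, axis=0)
        return [r for r, c in zip(self.reaction_ids, counts) if c == 1]

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            v_lb=self.v_lb.copy(),
            v_ub=self.v_ub.copy(),
            growth_id=self.growth_id,
            exchange_ids=self.exchange_ids,
            name=self.name,
        )

    def validate(self) -> None:
        n = len(self.reaction_ids)
        if len(set(self.reaction_ids)) != n:
            raise ModelValidationError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise ModelValidationError("duplicate metabolite ids")
        if self.S.shape != (len(self.metabolite_ids), n):
            raise ModelValidationError(
                f"S shape {self.S.shape} does not match "
                f"{len(self.metabolite_ids)} metabolites x {n} reactions")
        if len(self.v_lb) != n or len(self.v_ub) != n:
            raise ModelValidationError("bounds length does not match reactions")
        bad = np.nonzero(self.v_lb > self.v_ub)[0]
        if bad.size:
            raise ModelValidationError(
                f"lower bound exceeds upper bound for reaction "
                f"{self.reaction_ids[bad[0]]!r}")
        if self.growth_id not in self._index:
            raise ModelValidationError(f"growth reaction {self.growth_id!r} unknown")
        for e in self.exchange_ids:
            if np.count_nonzero(self.S[:, self.index(e)]) != 1:
                raise ModelValidationError(
                    f"exchange {e!r} must touch exactly one metabolite")
        # big-M assumption: all bounds live inside the flux box
        np.clip(self.v_lb, -FLUX_BOX, FLUX_BOX, out=self.v_lb)
        np.clip(self.v_ub, -FLUX_BOX, FLUX_BOX, out=self.v_ub)


@dataclass(frozen=True)
class Environment:
    """A chemical environment: nutrient exchanges N plus inhibited reactions I.

    ``z`` is the chemical component count used by the suitability score;
    it defaults to ``|N| + |I|`` but may be overridden (e.g. when one
    inhibitor compound blocks several reactions).
    """

    nutrient_ids: frozenset[str]
    inhibited_ids: frozenset[str] = frozenset()
    label: str = ""
    z_override: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "nutrient_ids", frozenset(self.nutrient_ids))
        object.__setattr__(self, "inhibited_ids", frozenset(self.inhibited_ids))
        if self.nutrient_ids & self.inhibited_ids:
            raise ModelValidationError("nutrients and inhibited reactions overlap")
        if not self.label:
            object.__setattr__(self, "label", "+".join(sorted(self.nutrient_ids)))
        if self.z < 1:
            raise ModelValidationError("environment needs at least one component")

    @property
    def z(self) -> int:
        if self.z_override is not None:
            return self.z_override
        return len(self.nutrient_ids) + len(self.inhibited_ids)

    def validate_against(self, model: StoichiometricModel) -> None:
        exch = set(model.exchange_ids)
        for n in self.nutrient_ids:
            if n not in exch:
                raise ModelValidationError(
                    f"nutrient {n!r} is not an exchange reaction of the model")
        for i in self.inhibited_ids:
            if i not in model.reaction_ids:
                raise ModelValidationError(f"inhibited reaction {i!r} unknown")


@dataclass(frozen=True)
class CatalogueEntry:
    label: str
    exchange_id: str
    role: str  # carbon | nitrogen | both | other


@dataclass(frozen=True)
class InhibitorEntry:
    label: str
    reaction_ids: tuple[str, ...]


@dataclass
class NutrientCatalogue:
    """Ordered nutrient (and optional inhibitor) list for environment
    enumeration; the file order fixes the enumeration order."""

    entries: list[CatalogueEntry]
    inhibitors: list[InhibitorEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries] + [i.label for i in self.inhibitors]
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        if dupes:
            raise CatalogueError(f"duplicate catalogue labels: {dupes}")
        if not self.entries:
            raise CatalogueError("empty catalogue")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class EvolveXConfig:
    """Tunable parameters of the environment-design pipeline.

    alpha
        Required trait level as a fraction of its maximum in the
        application environment (trait constraint ``v_trait >= alpha*max``).
    delta, epsilon
        Multiplicative and absolute relaxation of the wild-type flux
        ranges: ``w_ub = w_max + delta*|w_max| + epsilon`` and symmetrically
        below.  epsilon keeps zero-flux ranges from being infinitely strict.
    gamma
        Stronger-than-reference threshold for the coverage MILP.
    big_M
        Indicator-constraint constant; must be at least double the flux box.
    growth_norm
        Fixed growth flux ("arbitrary unit of growth", default 10) at which
        evolved states and couplings are computed; normalizes scores across
        growth rates.
    uptake_rule
        "bind": hold total nutrient uptake at its optimum (default);
        "literal": the printed non-binding direction (uptake >= optimum).
    """

    alpha: float = 0.5
    delta: float = 0.03
    epsilon: float = 1e-6
    gamma: float = 0.0
    big_M: float = 20_000.0
    growth_norm: float = 10.0
    feasibility_tol: float = 1e-6
    coupling_tol: float = 1e-6
    exclude_from_basis: frozenset[str] = frozenset()
    enumeration_limit: int = 20
    uptake_bound: float = -1000.0
    uptake_rule: str = "bind"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.delta < 0 or self.epsilon < 0 or self.gamma < 0:
            raise ValueError("delta, epsilon, gamma must be nonnegative")
        if self.big_M < 2 * FLUX_BOX:
            raise ValueError(f"big_M must be >= {2 * FLUX_BOX}")
        if self.feasibility_tol <= 0 or self.coupling_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.uptake_rule not in ("bind", "literal"):
            raise ValueError("uptake_rule must be 'bind' or 'literal'")
        object.__setattr__(self, "exclude_from_basis",
                           frozenset(self.exclude_from_basis))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EvolveXConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

def read_model(path: str | Path, format: str | None = None,
               growth_id: str | None = None) -> StoichiometricModel:
    """Read a model from SBML (Level 3 + FBC, via cobrapy) or the repo JSON
    dialect; the format is inferred from the extension when not given."""
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        return _read_json(path, growth_id)
    if format == "sbml":
        return _read_sbml(path, growth_id)
    raise ValueError(f"unknown model format {format!r}")


def _read_json(path: Path, growth_id: str | None) -> StoichiometricModel:
    raw = json.loads(path.read_text())
    met_ids = list(raw["metabolites"])
    met_index = {m: i for i, m in enumerate(met_ids)}
    rxn_ids, lbs, ubs = [], [], []
    S = np.zeros((len(met_ids), len(raw["reactions"])))
    growth = growth_id
    for j, rxn in enumerate(raw["reactions"]):
        rxn_ids.append(rxn["id"])
        lbs.append(rxn.get("lb", -FLUX_BOX))
        ubs.append(rxn.get("ub", FLUX_BOX))
        for met, coef in rxn["metabolites"].items():
            S[met_index[met], j] = coef
        if rxn.get("growth") and growth_id is None:
            growth = rxn["id"]
    if growth is None:
        raise ModelValidationError("growth reaction unresolved")
    return StoichiometricModel(met_ids, rxn_ids, S, np.array(lbs),
                               np.array(ubs), growth, name=raw.get("name", ""))


def _read_sbml(path: Path, growth_id: str | None) -> StoichiometricModel:
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover - depends on install extras
        raise ImportError("SBML input requires the 'sbml' extra (cobrapy)") from exc
    cm = cobra.io.read_sbml_model(str(path))
    met_ids = [m.id for m in cm.metabolites]
    met_index = {m: i for i, m in enumerate(met_ids)}
    rxn_ids = [r.id for r in cm.reactions]
    S = np.zeros((len(met_ids), len(rxn_ids)))
    lbs, ubs = [], []
    for j, r in enumerate(cm.reactions):
        lbs.append(r.lower_bound)
        ubs.append(r.upper_bound)
        for met, coef in r.metabolites.items():
            S[met_index[met.id], j] = coef
    growth = growth_id
    if growth is None:
        obj = [r.id for r in cm.reactions if r.objective_coefficient]
        if len(obj) != 1:
            raise ModelValidationError("growth reaction unresolved")
        growth = obj[0]
    return StoichiometricModel(met_ids, rxn_ids, S, np.array(lbs),
                               np.array(ubs), growth, name=cm.id or "")


def write_json(model: StoichiometricModel, path: str | Path) -> None:
    """Serialize to the repo JSON dialect (round-trips exactly)."""
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        (nz,) = np.nonzero(model.S[:, j])
        rxns.append({
            "id": rid,
            "metabolites": {model.metabolite_ids[i]: model.S[i, j] for i in nz},
            "lb": model.v_lb[j],
            "ub": model.v_ub[j],
            "growth": rid == model.growth_id,
        })
    payload = {"name": model.name, "metabolites": model.metabolite_ids,
               "reactions": rxns}
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# environments
# ---------------------------------------------------------------------------

def apply_environment(model: StoichiometricModel, env: Environment, *,
                      forced_uptake: bool = True,
                      uptake_bound: float = -1000.0) -> StoichiometricModel:
    """Return a copy of ``model`` with bounds set for ``env``.

    Nutrient exchanges get uptake allowed down to ``uptake_bound``; with
    ``forced_uptake`` their upper bound becomes −1 so every environment
    component must be consumed (the evolved-state convention).  All other
    exchanges have uptake blocked; secretion bounds are never relaxed.
    Inhibited reactions are fixed to zero.
    """
    env.validate_against(model)
    out = model.copy()
    for e in out.exchange_ids:
        j = out.index(e)
        if e in env.nutrient_ids:
            out.v_lb[j] = min(out.v_lb[j], uptake_bound)
            if forced_uptake:
                out.v_ub[j] = min(out.v_ub[j], -1.0)
        else:
            out.v_lb[j] = max(out.v_lb[j], 0.0)
            out.v_ub[j] = max(out.v_ub[j], 0.0)
    for r in env.inhibited_ids:
        j = out.index(r)
        out.v_lb[j] = 0.0
        out.v_ub[j] = 0.0
    out.validate()
    return out


def load_environment(path: str | Path) -> Environment:
    """Read an environment from YAML: ``nutrients``, optional ``inhibited``,
    ``label`` and ``z`` keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return Environment(
        nutrient_ids=frozenset(raw.get("nutrients", ())),
        inhibited_ids=frozenset(raw.get("inhibited", ())),
        label=raw.get("label", ""),
        z_override=raw.get("z"),
    )


# ---------------------------------------------------------------------------
# catalogues
# ---------------------------------------------------------------------------

_ROLES = {"carbon", "nitrogen", "both", "other"}


def load_catalogue(path: str | Path) -> NutrientCatalogue:
    """Read a TSV nutrient catalogue.

    Header columns: ``label``, ``exchange_id``, ``role``.  Rows with
    ``role == "inhibitor"`` are inhibitor entries whose ``exchange_id``
    column holds semicolon-joined reaction ids.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise CatalogueError("empty catalogue")
    header = lines[0].rstrip("\n").split("\t")
    required = ["label", "exchange_id", "role"]
    if header[:3] != required:
        raise CatalogueError(f"catalogue header must start with {required}")
    entries: list[CatalogueEntry] = []
    inhibitors: list[InhibitorEntry] = []
    for ln_no, ln in enumerate(lines[1:], start=2):
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise CatalogueError(f"malformed row {ln_no}: {ln!r}")
        label, target, role = parts[0].strip(), parts[1].strip(), parts[2].strip()
        if role == "inhibitor":
            inhibitors.append(InhibitorEntry(label, tuple(target.split(";"))))
        elif role in _ROLES:
            entries.append(CatalogueEntry(label, target, role))
        else:
            raise CatalogueError(f"unknown role {role!r} in row {ln_no}")
    return NutrientCatalogue(entries, inhibitors)


def single_nutrient_env(exchange_id: str, label: str = "") -> Environment:
    """Convenience constructor for one-nutrient environments."""
    return Environment(frozenset({exchange_id}), label=label or exchange_id)
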