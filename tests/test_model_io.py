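import json

import numpy as np
import pytest

from evolvex.fixtures import toy_network
from evolvex.lp import fba
from evolvex.model import (CatalogueError, Environment, EvolveXConfig,
                           ModelValidationError, StoichiometricModel,
                           apply_environment, load_catalogue, read_model,
                           write_json)

CATALOGUE_22 = "label\texchange_id\trole\n" + "\n".join(
    f"nut{i:02d}\tEX_{i:02d}\t{'carbon' if i % 2 else 'nitrogen'}"
    for i in range(22)) + "\n"


def test_json_round_trip(tmp_path, toy1):
    path = tmp_path / "toy1.json"
    write_json(toy1, path)
    back = read_model(path)
    assert back.reaction_ids == toy1.reaction_ids
    assert back.metabolite_ids == toy1.metabolite_ids
    assert np.array_equal(back.S, toy1.S)
    assert np.array_equal(back.v_lb, toy1.v_lb)
    assert np.array_equal(back.v_ub, toy1.v_ub)
    assert back.growth_id == toy1.growth_id
    assert set(back.exchange_ids) >= {"EX_A", "EX_B", "EX_P"}


def test_read_model_without_growth_reaction_errors(tmp_path):
    payload = {"metabolites": ["A"],
               "reactions": [{"id": "EX_A", "metabolites": {"A": -1},
                              "lb": -10, "ub": 0}]}
    path = tmp_path / "m.json"
    path.write_text(json.dumps(payload))
    with pytest.raises(ModelValidationError, match="growth reaction unresolved"):
        read_model(path)


def test_inverted_bounds_name_the_reaction():
    with pytest.raises(ModelValidationError, match="R1"):
        StoichiometricModel(["A", "X"], ["EX_A", "R1", "GROWTH"],
                            np.array([[-1, -1, 0], [0, 1, -1]]),
                            np.array([-10.0, 5.0, 0.0]),
                            np.array([0.0, 1.0, 10.0]), "GROWTH")


def test_bounds_clamped_into_flux_box():
    m = StoichiometricModel(["A", "X"], ["EX_A", "R1", "GROWTH"],
                            np.array([[-1, -1, 0], [0, 1, -1]]),
                            np.array([-1e9, 0.0, 0.0]),
                            np.array([0.0, 1e9, 1e9]), "GROWTH")
    assert m.v_lb.min() >= -10_000 and m.v_ub.max() <= 10_000


class TestApplyEnvironment:
    def test_forced_uptake_bounds(self, toy1, env_b):
        m = apply_environment(toy1, env_b, forced_uptake=True)
        jb, ja = m.index("EX_B"), m.index("EX_A")
        assert (m.v_lb[jb], m.v_ub[jb]) == (-1000.0, -1.0)
        assert (m.v_lb[ja], m.v_ub[ja]) == (0.0, 0.0)
        # secretion exchange untouched
        jp = m.index("EX_P")
        assert (m.v_lb[jp], m.v_ub[jp]) == (0.0, 1000.0)

    def test_inhibited_reaction_zeroed(self, toy1):
        env = Environment(frozenset({"EX_A"}), frozenset({"R1"}))
        m = apply_environment(toy1, env)
        j = m.index("R1")
        assert (m.v_lb[j], m.v_ub[j]) == (0.0, 0.0)

    def test_internal_reaction_as_nutrient_rejected(self, toy1):
        env = Environment(frozenset({"R3"}))
        with pytest.raises(ModelValidationError, match="R3"):
            apply_environment(toy1, env)

    def test_idempotent(self, toy1, env_b):
        once = apply_environment(toy1, env_b)
        twice = apply_environment(once, env_b)
        assert np.array_equal(once.v_lb, twice.v_lb)
        assert np.array_equal(once.v_ub, twice.v_ub)

    def test_blocked_nutrient_has_zero_uptake_in_fba(self, toy1, env_b):
        m = apply_environment(toy1, env_b, forced_uptake=False)
        state = fba(m, "EX_A", "min")  # most-negative flux = max uptake
        assert state.objective_value == pytest.approx(0.0, abs=1e-9)


class TestCatalogue:
    def test_22_entry_catalogue(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text(CATALOGUE_22)
        cat = load_catalogue(path)
        assert len(cat) == 22
        assert cat.entries[0].label == "nut00"

    def test_empty_catalogue_errors(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(CatalogueError, match="empty"):
            load_catalogue(path)

    def test_duplicate_labels_listed(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("label\texchange_id\trole\n"
                        "glc\tEX_glc\tcarbon\nglc\tEX_glc2\tcarbon\n")
        with pytest.raises(CatalogueError, match="glc"):
            load_catalogue(path)

    def test_inhibitor_rows(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text("label\texchange_id\trole\n"
                        "glc\tEX_glc\tcarbon\n"
                        "2DG\tHEX1;HEX2\tinhibitor\n")
        cat = load_catalogue(path)
        assert cat.inhibitors[0].reaction_ids == ("HEX1", "HEX2")


def test_environment_invariants():
    with pytest.raises(ModelValidationError):
        Environment(frozenset({"EX_A"}), frozenset({"EX_A"}))
    env = Environment(frozenset({"EX_A", "EX_B"}), frozenset({"R9"}))
    assert env.z == 3
    assert Environment(frozenset({"EX_A"}), z_override=2).z == 2


def test_config_validation():
    with pytest.raises(ValueError):
        EvolveXConfig(alpha=0.0)
    with pytest.raises(ValueError):
        EvolveXConfig(big_M=100.0)
    with pytest.raises(ValueError):
        EvolveXConfig(feasibility_tol=0.0)


def test_config_from_yaml(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("alpha: 0.8\ngamma: 0.1\nexclude_from_basis: [GROWTH]\n")
    cfg = EvolveXConfig.from_yaml(path)
    assert cfg.alpha == 0.8 and cfg.gamma == 0.1
    assert cfg.exclude_from_basis == frozenset({"GROWTH"})


def test_sbml_round_trip_through_cobrapy(tmp_path):
    cobra = pytest.importorskip("cobra")
    from cobra import Metabolite, Model, Reaction
    cm = Model("tiny")
    a = Metabolite("A", compartment="e")
    x = Metabolite("X", compartment="c")
    ex = Reaction("EX_A")
    ex.add_metabolites({a: -1})
    ex.lower_bound, ex.upper_bound = -10, 0
    r1 = Reaction("R1")
    r1.add_metabolites({a: -1, x: 1})
    r1.upper_bound = 10
    gr = Reaction("GROWTH")
    gr.add_metabolites({x: -1})
    gr.upper_bound = 10
    cm.add_reactions([ex, r1, gr])
    cm.objective = "GROWTH"
    path = tmp_path / "tiny.xml"
    cobra.io.write_sbml_model(cm, str(path))
    m = read_model(path)
    assert m.growth_id == "GROWTH"
    assert fba(m, "GROWTH").objective_value == pytest.approx(10.0)
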