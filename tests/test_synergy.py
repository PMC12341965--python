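import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import synlogic as sl
from synlogic.synergy import Perturbation, ResponseEntry, score_all_pairs


@pytest.fixture
def panel():
    return sl.DrugPanel({
        "PI": ("inhibits", ("A",)),
        "AK": ("inhibits", ("B",)),
        "UP": ("activates", ("A", "B")),
    })


@pytest.fixture
def loop_model():
    net = sl.build_network([
        sl.SignedInteraction("A", "B", 1),
        sl.SignedInteraction("B", "A", 1),
    ])
    return sl.assemble_default_model(net)


@pytest.fixture
def outputs():
    return sl.OutputSpec({"A": 1.0, "B": -1.0})


class TestApplyPerturbation:
    def test_inhibitor_clamps_target_to_zero(self, loop_model, panel):
        perturbed = sl.apply_perturbation(loop_model, Perturbation(["PI"]), panel)
        assert perturbed.equation_for("A").fixed_value == 0
        assert perturbed.equation_for("B") == loop_model.equation_for("B")
        # value semantics
        assert loop_model.equation_for("A").fixed_value is None

    def test_activating_drug_clamps_to_one(self, loop_model, panel):
        perturbed = sl.apply_perturbation(loop_model, Perturbation(["UP"]), panel)
        assert perturbed.equation_for("A").fixed_value == 1
        assert perturbed.equation_for("B").fixed_value == 1

    def test_pair_order_irrelevant(self, loop_model, panel):
        ab = sl.apply_perturbation(loop_model, Perturbation(["PI", "AK"]), panel)
        ba = sl.apply_perturbation(loop_model, Perturbation(["AK", "PI"]), panel)
        assert ab.equations == ba.equations

    def test_unknown_drug_or_target_rejected(self, loop_model, panel):
        with pytest.raises(KeyError):
            sl.apply_perturbation(loop_model, Perturbation(["XX"]), panel)
        other = sl.DrugPanel({"ZZ": ("inhibits", ("Q",))})
        with pytest.raises(KeyError, match="'Q'"):
            sl.apply_perturbation(loop_model, Perturbation(["ZZ"]), other)


class TestModelGrowth:
    def test_worked_example_half_growth(self, loop_model, panel, outputs):
        """+1/-1 outputs both active: raw 0 in range [-1, 1] scales to 0.5."""
        perturbed = sl.apply_perturbation(loop_model, Perturbation(["UP"]), panel)
        assert sl.model_growth(perturbed, outputs) == pytest.approx(0.5)

    def test_max_case_scales_to_one(self, outputs):
        net = sl.build_network([
            sl.SignedInteraction("A", "A", 1),
            sl.SignedInteraction("A", "B", -1),
            sl.SignedInteraction("B", "B", 1),
        ])
        model = sl.assemble_default_model(net)
        clamped = model.with_equation(0, sl.LogicEquation("A", fixed_value=1))
        clamped = clamped.with_equation(
            clamped.node_index["B"], sl.LogicEquation("B", fixed_value=0))
        assert sl.model_growth(clamped, outputs) == pytest.approx(1.0)

    def test_no_fixed_point_is_undefined(self, outputs):
        net = sl.build_network([
            sl.SignedInteraction("A", "A", -1),
            sl.SignedInteraction("A", "B", 1),
            sl.SignedInteraction("B", "A", -1),
        ])
        model = sl.assemble_default_model(net)
        assert sl.model_growth(model, outputs) is None

    def test_multiple_fixed_points_average(self, loop_model, outputs):
        # fixed points (0,0) and (1,1) scale to 0.5 each
        assert sl.model_growth(loop_model, outputs) == pytest.approx(0.5)

    def test_scaling_commutes_with_averaging(self, small_system):
        """Affine scaling: mean(scaled) == scaled(mean raw)."""
        model = small_system.truth_model
        outputs = small_system.outputs
        attrs = sl.fixed_points(model)
        lo, hi = outputs.theoretical_min, outputs.theoretical_max
        idx = model.node_index
        raws = [sum(w * fp[idx[v]] for v, w in outputs.weights.items())
                for fp in attrs.fixed_points]
        expected = (np.mean(raws) - lo) / (hi - lo)
        assert sl.model_growth(model, outputs) == pytest.approx(expected)


class TestEnsembleGrowth:
    def test_mean_and_exclusion(self, panel, outputs):
        net = sl.build_network([
            sl.SignedInteraction("A", "B", 1),
            sl.SignedInteraction("B", "A", 1),
        ])
        stable = sl.assemble_default_model(net)
        # clamp-free model with no fixed point under PI (A:=0 forces B=0... still fixed)
        entry = sl.ensemble_growth([stable, stable], Perturbation(["UP"]),
                                   panel, outputs)
        assert entry.growth == pytest.approx(0.5)
        assert entry.models_used == 2
        assert entry.models_excluded == 0

    def test_all_models_excluded_gives_undefined(self, panel, outputs, caplog):
        net = sl.build_network([
            sl.SignedInteraction("A", "A", 1),
            sl.SignedInteraction("A", "B", -1),
            sl.SignedInteraction("B", "B", -1),
        ])
        model = sl.assemble_default_model(net)  # B self-inhibits: no fixed point
        entry = sl.ensemble_growth([model], Perturbation(["PI"]), panel, outputs)
        assert entry.growth is None
        assert entry.models_excluded == 1

    def test_no_path_no_effect(self, outputs):
        """Clamping a node with no path to any output leaves growth unchanged."""
        net = sl.build_network([
            sl.SignedInteraction("A", "B", 1),
            sl.SignedInteraction("B", "A", 1),
            sl.SignedInteraction("X", "X", 1),  # isolated switch
        ])
        model = sl.assemble_default_model(net)
        panel = sl.DrugPanel({"DX": ("inhibits", ("X",))})
        unperturbed = sl.model_growth(model, outputs)
        entry = sl.ensemble_growth([model], Perturbation(["DX"]), panel, outputs)
        assert entry.growth == pytest.approx(unperturbed)


class TestScoreSynergy:
    def test_worked_numbers(self):
        rec = sl.score_synergy(0.5, 0.5, 0.20, ("a", "b"))
        assert rec.expected == pytest.approx(0.25)
        assert rec.excess == pytest.approx(-0.05)
        assert rec.call == "synergy"

    def test_boundary_is_no_call(self):
        rec = sl.score_synergy(0.5, 0.5, 0.25, ("a", "b"))
        assert rec.excess == 0
        assert rec.call == "none"

    def test_symmetric_in_drug_order(self):
        a = sl.score_synergy(0.3, 0.8, 0.5, ("x", "y"))
        b = sl.score_synergy(0.8, 0.3, 0.5, ("y", "x"))
        assert a == b

    def test_undefined_input_flags_not_available(self):
        rec = sl.score_synergy(None, 0.5, 0.2, ("a", "b"))
        assert not rec.available
        assert rec.call == "not-available"

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_decomposition_exact(self, ga, gb, gab):
        rec = sl.score_synergy(ga, gb, gab, ("a", "b"))
        assert rec.observed == rec.expected + rec.excess  # E = A + S exactly


class TestNormalize:
    def test_equal_excess_maps_to_one(self):
        rec = sl.score_synergy(0.5, 0.5, 0.2, ("a", "b"))
        out = sl.normalize({("a", "b"): rec}, {("a", "b"): rec})
        assert out[("a", "b")].normalized == pytest.approx(1.0)

    def test_exponential_fold_change_values(self):
        x = sl.score_synergy(1.0, 1.0, 0.8, ("a", "b"))   # S = -0.2
        y = sl.score_synergy(1.0, 1.0, 0.9, ("a", "b"))   # S = -0.1
        assert sl.normalize({("a", "b"): x}, {("a", "b"): y})[
            ("a", "b")].normalized == pytest.approx(math.exp(-0.1))
        assert sl.normalize({("a", "b"): y}, {("a", "b"): x})[
            ("a", "b")].normalized == pytest.approx(math.exp(0.1))

    def test_unavailable_pairs_excluded(self):
        x = sl.score_synergy(0.5, 0.5, 0.2, ("a", "b"))
        missing = sl.score_synergy(None, 0.5, 0.2, ("a", "b"))
        assert sl.normalize({("a", "b"): x}, {("a", "b"): missing}) == {}
        assert sl.normalize({("a", "b"): missing}, {("a", "b"): x}) == {}


class TestProliferativeProfile:
    def test_rule_holds_over_many_draws(self, small_system):
        outputs = small_system.outputs
        rng = np.random.default_rng(0)
        for _ in range(200):
            prof = sl.sample_proliferative_profile(outputs, rng)
            assert all(prof.assignments[v] == 0 for v in outputs.negative_nodes)
            assert any(prof.assignments[v] == 1 for v in outputs.positive_nodes)
            assert set(prof.assignments) == set(outputs.weights)

    def test_fixed_seed_reproducible(self, small_system):
        a = sl.sample_proliferative_profile(small_system.outputs,
                                            np.random.default_rng(7))
        b = sl.sample_proliferative_profile(small_system.outputs,
                                            np.random.default_rng(7))
        assert a == b


class TestScoreAllPairs:
    def test_uses_single_and_pair_responses(self):
        responses = {
            "a": ResponseEntry(0.5, 1, 0),
            "b": ResponseEntry(0.5, 1, 0),
            "a+b": ResponseEntry(0.2, 1, 0),
        }
        perts = [Perturbation(["a"]), Perturbation(["b"]),
                 Perturbation(["a", "b"])]
        recs = score_all_pairs(responses, perts)
        assert recs[("a", "b")].excess == pytest.approx(-0.05)
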