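import collections

import numpy as np
import pytest

import synlogic as sl
from synlogic import io
from synlogic.logic import LinkOperator


class TestGeneratePlantedSystem:
    def test_artifacts_pass_reader_roundtrips(self, small_system, tmp_path):
        io.write_sif(small_system.network, tmp_path / "n.sif")
        assert io.read_sif(tmp_path / "n.sif") == small_system.network
        io.write_calibration(small_system.truth_profile, tmp_path / "ss.tab")
        assert io.read_calibration(
            tmp_path / "ss.tab", small_system.network
        ) == small_system.truth_profile
        io.write_drug_panel(small_system.panel, tmp_path / "p.tab")
        assert io.read_drug_panel(tmp_path / "p.tab") == small_system.panel
        io.write_output_spec(small_system.outputs, tmp_path / "o.tab")
        assert io.read_output_spec(tmp_path / "o.tab") == small_system.outputs
        io.write_gold_standard(small_system.gold, tmp_path / "g.tsv")
        assert io.read_gold_standard(tmp_path / "g.tsv") == small_system.gold

    def test_truth_profile_is_brute_force_fixed_point(self, small_system):
        attrs = sl.brute_force_fixed_points(small_system.truth_model)
        states = [dict(zip(attrs.nodes, fp)) for fp in attrs.fixed_points]
        spec = small_system.truth_profile.specified
        assert any(all(st[v] == s for v, s in spec.items()) for st in states)

    def test_fixed_seed_reproducible(self):
        a = sl.generate_planted_system(rng=np.random.default_rng(4))
        b = sl.generate_planted_system(rng=np.random.default_rng(4))
        assert a.network == b.network
        assert a.truth_model.equations == b.truth_model.equations
        assert a.truth_profile == b.truth_profile
        assert a.gold == b.gold

    def test_gold_has_both_classes_and_derives_from_truth(self, small_system):
        assert small_system.gold.n_pos >= 1
        assert small_system.gold.n_neg >= 1
        # recompute one labeled pair from the truth model
        from synlogic.synthetic import _gold_from_truth
        labels, _ = _gold_from_truth(small_system.truth_model,
                                     small_system.panel, small_system.outputs)
        assert labels == dict(small_system.gold.labels)

    def test_mask_fraction_reduces_m(self):
        full = sl.generate_planted_system(rng=np.random.default_rng(4))
        masked = sl.generate_planted_system(
            mask_fraction=0.4, rng=np.random.default_rng(4))
        assert masked.truth_profile.m == full.truth_profile.m - 6  # ceil(.4*15)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            sl.generate_planted_system(10, 5)
        with pytest.raises(ValueError):
            sl.generate_planted_system(n_outputs=1)


class TestCorruptProfile:
    @pytest.fixture
    def profile24(self):
        return sl.CalibrationProfile(
            {f"v{i:02d}": (i % 2) for i in range(24)} | {"u": sl.UNSPECIFIED}
        )

    def test_fraction_zero_is_identity(self, profile24, rng):
        assert sl.corrupt_profile(profile24, 0.0, rng) == profile24

    def test_fraction_one_flips_every_bit(self, profile24, rng):
        out = sl.corrupt_profile(profile24, 1.0, rng)
        for node, value in profile24.assignments.items():
            if value in (0, 1):
                assert out.assignments[node] == 1 - value
            else:
                assert out.assignments[node] == value

    def test_involution_at_fraction_one(self, profile24, rng):
        once = sl.corrupt_profile(profile24, 1.0, rng)
        twice = sl.corrupt_profile(once, 1.0, rng)
        assert twice == profile24

    def test_half_fraction_flips_exactly_half(self, profile24, rng):
        out = sl.corrupt_profile(profile24, 0.5, rng)
        flips = sum(out.assignments[v] != profile24.assignments[v]
                    for v in profile24.assignments)
        assert flips == 12


class TestScrambleTopology:
    @pytest.mark.parametrize("mode", ["source", "target", "sign", "all"])
    @pytest.mark.parametrize("fraction", [0.0, 0.3, 1.0])
    def test_counts_preserved(self, small_system, mode, fraction, rng):
        net = small_system.network
        out = sl.scramble_topology(net, mode, fraction, rng)
        assert out.nodes == net.nodes
        assert len(out.interactions) == len(net.interactions)
        out.validate_self_contained()

    def test_sign_mode_full_fraction_inverts_all(self, small_system, rng):
        net = small_system.network
        out = sl.scramble_topology(net, "sign", 1.0, rng)
        for before, after in zip(net.interactions, out.interactions):
            assert (before.source, before.target) == (after.source, after.target)
            assert after.sign == -before.sign

    def test_fraction_zero_is_identity(self, small_system, rng):
        net = small_system.network
        assert sl.scramble_topology(net, "source", 0.0, rng) == net

    def test_unknown_mode_rejected(self, small_system, rng):
        with pytest.raises(ValueError):
            sl.scramble_topology(small_system.network, "shuffle", 0.5, rng)


class TestParameterRecovery:
    def test_ga_recovers_planted_operators_on_identifiable_system(self):
        """On a system whose planted state pins every operator, calibrated
        models at the fitness threshold carry the planted operators."""
        system = sl.generate_planted_system(
            10, 18, rng=np.random.default_rng(6), unique_optimum=True)
        truth_ops = {
            eq.target: eq.link_operator
            for eq in system.truth_model.equations
            if eq.link_operator is not LinkOperator.NONE
        }
        # identifiability certificate by exhaustive enumeration
        optima = []
        for cand in sl.enumerate_parameterizations(
                sl.assemble_default_model(system.network)):
            attrs = sl.fixed_points(cand)
            if attrs.n and sl.compute_fitness(
                    attrs, system.truth_profile) == 1.0:
                optima.append(cand)
        assert len(optima) == 1

        ens = sl.evolve(system.network, system.truth_profile,
                        sl.GAConfig(evolutions=5, seed=3))
        hits = total = 0
        for model in ens.models:
            if model.fitness < 0.99:
                continue
            for eq in model.equations:
                if eq.target in truth_ops:
                    total += 1
                    hits += eq.link_operator is truth_ops[eq.target]
        assert total > 0
        assert hits / total >= 0.95


class TestDegradationExperiment:
    def test_fraction_zero_reproduces_clean_benchmark(self, small_system):
        config = sl.GAConfig(evolutions=3, generations_max=8)
        a = sl.degradation_experiment(small_system, [0.0], config,
                                      mode="profile", n_replicates=1, seed=21)
        b = sl.degradation_experiment(small_system, [0.0, 0.0], config,
                                      mode="profile", n_replicates=1, seed=21)
        cols = ["roc_auc", "pr_auc", "mean_fitness"]
        assert a[cols].iloc[0].tolist() == b[cols].iloc[0].tolist()
        assert a[cols].iloc[0].tolist() == b[cols].iloc[1].tolist()

    def test_table_schema_and_seed_recording(self, small_system):
        config = sl.GAConfig(evolutions=2, generations_max=5)
        table = sl.degradation_experiment(small_system, [0.0, 0.5], config,
                                          mode="sign", n_replicates=2, seed=8)
        assert list(table.columns) == [
            "experiment", "fraction", "replicate", "seed", "mean_fitness",
            "roc_auc", "pr_auc",
        ]
        assert len(table) == 4
        assert (table.experiment == "sign").all()
        # same replicate shares its GA seed across fractions
        by_rep = table.groupby("replicate")["seed"].nunique()
        assert (by_rep == 1).all()
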