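"""Evidence-amalgamation network: topology, inference, d-separation."""

import itertools

import networkx as nx
import numpy as np
import pytest

import esynthesis as es
from esynthesis.bayesnet import RCT_MODULATORS
from esynthesis.errors import ConfigError, DomainError, ValidationError


def random_binary_net(rng: np.random.Generator, n_nodes: int, edge_prob: float = 0.4):
    """Random binary DAG with random CPTs; edges go low index -> high index."""
    names = [f"N{i}" for i in range(n_nodes)]
    parents = {name: [] for name in names}
    for j in range(n_nodes):
        for i in range(j):
            if rng.random() < edge_prob:
                parents[names[j]].append(names[i])
    nodes = []
    for name in names:
        cpt = {}
        for key in itertools.product((1, 0), repeat=len(parents[name])):
            p = float(rng.uniform(0.05, 0.95))
            cpt[key] = (p, 1.0 - p)
        nodes.append(
            es.NetNode(name=name, states=(1, 0), parents=tuple(parents[name]), cpt=cpt)
        )
    return es.BayesNet(nodes)


def brute_force_conditional(net, query, state, evidence):
    """Oracle: explicit sum over the full joint table, no library inference."""
    names = list(net.nodes)
    numerator = denominator = 0.0
    for combo in itertools.product((1, 0), repeat=len(names)):
        assignment = dict(zip(names, combo))
        if any(assignment[k] != v for k, v in evidence.items()):
            continue
        prob = 1.0
        for name in names:
            node = net.nodes[name]
            key = tuple(assignment[p] for p in node.parents)
            prob *= node.cpt[key][node.states.index(assignment[name])]
        denominator += prob
        if assignment[query] == state:
            numerator += prob
    return numerator / denominator


class TestJointProbability:
    def test_two_node_deterministic_chain(self):
        a = es.NetNode("A", cpt={(): (0.5, 0.5)})
        b = es.NetNode("B", parents=("A",), cpt={(1,): (1.0, 0.0), (0,): (0.0, 1.0)})
        net = es.BayesNet([a, b])
        assert es.joint_probability(net, {"A": 1, "B": 1}) == 0.5
        assert es.joint_probability(net, {"A": 1, "B": 0}) == 0.0

    def test_joint_normalises(self, rng):
        net = random_binary_net(rng, 4)
        total = sum(
            es.joint_probability(net, dict(zip(net.nodes, combo)))
            for combo in itertools.product((1, 0), repeat=4)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_missing_node_rejected(self):
        net = es.BayesNet([es.NetNode("A", cpt={(): (0.5, 0.5)})])
        with pytest.raises(ValidationError):
            es.joint_probability(net, {})


class TestInfer:
    @pytest.mark.parametrize("n_nodes", [5, 8, 12])
    def test_matches_brute_force_on_random_nets(self, n_nodes, rng):
        for _ in range(3):
            net = random_binary_net(rng, n_nodes)
            names = list(net.nodes)
            evidence = {names[-1]: 1}
            expected = brute_force_conditional(net, names[0], 1, evidence)
            assert es.infer(net, names[0], evidence) == pytest.approx(expected, abs=1e-10)

    def test_marginal_sums_to_one(self, rng):
        net = random_binary_net(rng, 6)
        dist = es.marginal(net, "N3", {"N5": 0})
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_probability_evidence_rejected(self):
        a = es.NetNode("A", cpt={(): (1.0, 0.0)})
        net = es.BayesNet([a])
        with pytest.raises(DomainError):
            es.infer(net, "A", {"A": 0}, state=1)  # evidence A=0 has mass zero

    def test_report_cpt_diagnostic_rows(self):
        # the effect-size report is certain given dose-response plus the
        # right time course, and impossible given neither
        net = es.example_configuration()
        assert es.infer(net, "ES", {"DR": 1, "T": 1}) == pytest.approx(1.0, abs=1e-12)
        assert es.infer(net, "ES", {"DR": 0, "T": 0}) == pytest.approx(0.0, abs=1e-12)

    def test_report_evidence_raises_causal_hypothesis(self):
        net = es.example_configuration()
        assert es.infer(net, "C", {"ES": 1}) > es.infer(net, "C")

    def test_virtual_evidence_matches_analytic_update(self):
        # likelihood finding on a root: posterior odds = prior odds * ratio
        a = es.NetNode("A", cpt={(): (0.3, 0.7)})
        net = es.BayesNet([a])
        posterior = es.infer(net, "A", virtual_evidence={"A": {1: 0.9, 0: 0.1}})
        expected = 0.3 * 0.9 / (0.3 * 0.9 + 0.7 * 0.1)
        assert posterior == pytest.approx(expected, abs=1e-12)

    def test_diagnosticity_monotone_for_causal_posterior(self):
        # raising P(ES=1 | DR=1, T=1) while holding the false-positive rows
        # fixed never decreases P(C=1 | ES=1)
        previous = 0.0
        for hit in (0.6, 0.8, 1.0):
            cpt = {
                (1, 1): (hit, 1 - hit),
                (1, 0): (0.5, 0.5),
                (0, 1): (0.5, 0.5),
                (0, 0): (0.2, 0.8),
            }
            net = es.build_esynthesis_topology(
                reports=[{"name": "ES", "indicators": ["DR", "T"]}],
                cpts={"ES": cpt},
            )
            posterior = es.infer(net, "C", {"ES": 1})
            assert posterior >= previous - 1e-12
            previous = posterior


class TestDSeparation:
    @staticmethod
    def three_node(edges):
        nodes = {}
        for name in "ABC":
            parents = tuple(p for p, c in edges if c == name)
            cpt = {
                key: (0.7, 0.3) for key in itertools.product((1, 0), repeat=len(parents))
            }
            nodes[name] = es.NetNode(name, parents=parents, cpt=cpt)
        return es.BayesNet(nodes.values())

    def test_chain_blocked_by_middle(self):
        net = self.three_node([("A", "B"), ("B", "C")])
        assert es.d_separated(net, {"A"}, {"C"}, {"B"})
        assert not es.d_separated(net, {"A"}, {"C"}, set())

    def test_fork_blocked_by_root(self):
        net = self.three_node([("B", "A"), ("B", "C")])
        assert es.d_separated(net, {"A"}, {"C"}, {"B"})
        assert not es.d_separated(net, {"A"}, {"C"}, set())

    def test_collider_opens_when_conditioned(self):
        net = self.three_node([("A", "C"), ("B", "C")])
        assert es.d_separated(net, {"A"}, {"B"}, set())
        assert not es.d_separated(net, {"A"}, {"B"}, {"C"})

    def test_overlapping_sets_rejected(self):
        net = self.three_node([("A", "B"), ("B", "C")])
        with pytest.raises(ValidationError):
            es.d_separated(net, {"A"}, {"A"}, set())

    def test_symmetric_and_agrees_with_networkx(self, rng):
        for _ in range(20):
            net = random_binary_net(rng, 7, edge_prob=0.35)
            names = list(net.nodes)
            picks = rng.permutation(7)
            x, y = {names[picks[0]]}, {names[picks[1]]}
            z = {names[i] for i in picks[2 : 2 + rng.integers(0, 4)]}
            ours = es.d_separated(net, x, y, z)
            assert ours == es.d_separated(net, y, x, z)
            assert ours == nx.is_d_separator(net.graph, x, y, z)

    def test_soundness_against_enumerated_joint(self, rng):
        # d-separation must imply conditional independence in the joint
        for _ in range(15):
            net = random_binary_net(rng, 6, edge_prob=0.4)
            names = list(net.nodes)
            picks = rng.permutation(6)
            x, y = names[picks[0]], names[picks[1]]
            z_names = [names[i] for i in picks[2 : 2 + rng.integers(0, 3)]]
            if not es.d_separated(net, {x}, {y}, set(z_names)):
                continue
            for z_states in itertools.product((1, 0), repeat=len(z_names)):
                evidence = dict(zip(z_names, z_states))
                try:
                    p_joint = brute_force_conditional(net, x, 1, {**evidence, y: 1})
                except ZeroDivisionError:
                    continue
                p_marginal = brute_force_conditional(net, x, 1, evidence)
                assert p_joint == pytest.approx(p_marginal, abs=1e-10)


class TestTopology:
    def test_default_manifest_has_unique_non_modulator_root(self):
        net = es.build_esynthesis_topology()
        roots = [n for n in net.nodes if net.graph.in_degree(n) == 0]
        assert roots == ["C"]
        for indicator in ("Delta", "PD", "DR", "RoG", "M", "T"):
            assert ("C", indicator) in net.edges
        assert ("M", "T") in net.edges  # mechanism entails time course

    def test_single_rct_report_parent_set(self):
        net = es.build_esynthesis_topology(
            indicators=("Delta",),
            reports=[{"name": "REP1", "indicators": ["Delta"], "modulators": RCT_MODULATORS}],
        )
        assert set(net.node("REP1").parents) == {"Delta", *RCT_MODULATORS}

    def test_design_manifest_expands_indicators(self):
        net = es.build_esynthesis_topology(reports=[{"name": "R", "design": "cohort"}])
        assert set(net.node("R").parents) == {"T", "PD", "DR", "RoG"}

    def test_empty_manifest_yields_hypothesis_only(self):
        net = es.build_esynthesis_topology(indicators=())
        assert list(net.nodes) == ["C"]

    def test_unknown_indicator_rejected(self):
        with pytest.raises(ConfigError):
            es.build_esynthesis_topology(indicators=("Delta", "XYZ"))

    def test_cpt_rows_must_normalise(self):
        with pytest.raises(ConfigError, match="sums to"):
            es.NetNode("A", cpt={(): (0.6, 0.6)})

    def test_cycle_rejected(self):
        a = es.NetNode("A", parents=("B",), cpt={(1,): (0.5, 0.5), (0,): (0.5, 0.5)})
        b = es.NetNode("B", parents=("A",), cpt={(1,): (0.5, 0.5), (0,): (0.5, 0.5)})
        with pytest.raises(ConfigError, match="cycle"):
            es.BayesNet([a, b])


class TestEntailments:
    def test_example_configuration_is_faithful(self):
        assert es.validate_entailments(es.example_configuration()) == []

    def test_broken_time_course_entailment_reported(self):
        net = es.example_configuration()
        broken = dict(net.nodes)
        broken["T"] = es.NetNode(
            "T",
            parents=("C", "M"),
            cpt={(1, 1): (0.9, 0.1), (1, 0): (0.9, 0.1), (0, 1): (1.0, 0.0), (0, 0): (0.3, 0.7)},
        )
        violations = es.validate_entailments(es.BayesNet(broken.values()))
        assert any("C => T broken" in v for v in violations)

    def test_broken_dose_response_entailment_reported(self):
        net = es.example_configuration()
        broken = dict(net.nodes)
        broken["PD"] = es.NetNode("PD", parents=("C",), cpt={(1,): (0.8, 0.2), (0,): (0.1, 0.9)})
        violations = es.validate_entailments(es.BayesNet(broken.values()))
        assert any("DR => PD broken" in v for v in violations)

    def test_absent_mechanism_node_skipped_with_notice(self):
        net = es.build_esynthesis_topology(
            indicators=("T", "DR", "PD"),
            cpts={
                "C": {(): (0.5, 0.5)},
                "T": {(1,): (1.0, 0.0), (0,): (0.4, 0.6)},
                "DR": {(1,): (0.7, 0.3), (0,): (0.0, 1.0)},
                "PD": {(1,): (1.0, 0.0), (0,): (0.2, 0.8)},
            },
        )
        violations = es.validate_entailments(net)
        assert any(v.startswith("notice: node M absent") for v in violations)
        assert not any("broken" in v for v in violations)


class TestConfigIO:
    def test_yaml_round_trip_preserves_inference(self, tmp_path):
        net = es.example_configuration()
        path = tmp_path / "net.yaml"
        es.save_network(net, path)
        restored = es.load_network(path)
        assert es.infer(restored, "C", {"ES": 1}) == pytest.approx(
            es.infer(net, "C", {"ES": 1}), abs=1e-12
        )

    def test_schema_error_names_offending_entry(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("nodes:\n  - name: A\n    cpt:\n      - probs: [0.5, 0.6]\n")
        with pytest.raises(ConfigError, match="#1"):
            es.load_network(path)

    def test_unknown_given_parent_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "nodes:\n"
            "  - name: A\n"
            "    cpt:\n"
            "      - given: {Z: 1}\n"
            "        probs: [0.5, 0.5]\n"
        )
        with pytest.raises(ConfigError):
            es.load_network(path)
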