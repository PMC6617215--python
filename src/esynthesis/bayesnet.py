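"""Bayesian-network scaffold for amalgamating heterogeneous drug-safety evidence.

The network places the causal hypothesis node ``C`` ("drug D causes harm E
in population U") at the root.  Its children are causal indicators in the
Bradford-Hill tradition: difference-making ``Delta``, probabilistic
dependence ``PD``, dose-response ``DR``, rate of growth ``RoG``,
mechanistic knowledge ``M`` and time course ``T``.  Mechanism entails
time course, so an ``M -> T`` edge is present whenever both nodes are.
Study reports attach to the indicator(s) their design speaks to, and each
report is modulated by study-quality nodes (sample size, duration,
adjustment, randomisation, blinding, sponsorship bias).  The statistical
"black-box" indicators {PD, DR, RoG} are grouped under the label Sigma;
the group is a naming convention, not a probabilistic node.

Edges are epistemic: they encode probabilistic (in)dependence relations
among propositions, not causal mechanisms, and the module must not be
read as a causal-discovery tool.

Inference is exact enumeration over the joint (networks here stay small,
~20 nodes); d-separation uses the standard chain/fork/collider blocking
rules.  Conditional probability tables are user-supplied configuration:
the framework fixes the structure and a handful of entailment constraints
(C => T, C => M, DR => PD), not full parameterisations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import yaml

from .errors import ConfigError, DomainError, ValidationError

__all__ = [
    "NetNode",
    "BayesNet",
    "INDICATORS",
    "SIGMA_INDICATORS",
    "RCT_MODULATORS",
    "STUDY_DESIGN_INDICATORS",
    "build_esynthesis_topology",
    "example_configuration",
    "joint_probability",
    "infer",
    "marginal",
    "d_separated",
    "validate_entailments",
    "load_network",
    "save_network",
]

_CPT_ROW_TOL = 1e-12

State = Hashable

#: causal indicator vocabulary (children of the causal hypothesis C)
INDICATORS: tuple[str, ...] = ("Delta", "PD", "DR", "RoG", "M", "T")

#: the statistical "black-box" indicators grouped under the Sigma label
SIGMA_INDICATORS: tuple[str, ...] = ("PD", "DR", "RoG")

#: study-quality modulators of an RCT report: sample size, duration,
#: adjustment, randomisation, blinding, sponsorship bias
RCT_MODULATORS: tuple[str, ...] = ("SS", "DUR", "A", "R", "B", "SB")

#: which indicators each study design informs (Sigma expanded to its members)
STUDY_DESIGN_INDICATORS: dict[str, tuple[str, ...]] = {
    "rct": ("Delta", "T", "DR", "RoG"),
    "cohort": ("T",) + SIGMA_INDICATORS,
    "case_control": SIGMA_INDICATORS,
    "case_report": ("T", "Delta"),
    "basic_science": ("M",),
}


@dataclass(frozen=True)
class NetNode:
    """A network node: name, ordered finite states, parents, CPT.

    The CPT maps each combination of parent states (a tuple in parent
    order; the empty tuple for root nodes) to a probability row over this
    node's states.  Every row must sum to one within 1e-12.
    """

    name: str
    states: tuple[State, ...] = (1, 0)
    parents: tuple[str, ...] = ()
    cpt: Mapping[tuple[State, ...], tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.states)) != len(self.states) or not self.states:
            raise ConfigError(f"node {self.name}: states must be a non-empty distinct set")
        for key, row in self.cpt.items():
            if len(key) != len(self.parents):
                raise ConfigError(
                    f"node {self.name}: CPT key {key} does not match parents {self.parents}"
                )
            if len(row) != len(self.states):
                raise ConfigError(
                    f"node {self.name}: CPT row {row} does not match states {self.states}"
                )
            if any(p < 0 for p in row) or abs(sum(row) - 1.0) > _CPT_ROW_TOL:
                raise ConfigError(
                    f"node {self.name}: CPT row for parents={key} sums to {sum(row)!r}, not 1"
                )

    def prob(self, state: State, parent_states: tuple[State, ...]) -> float:
        try:
            row = self.cpt[parent_states]
        except KeyError:
            raise ConfigError(
                f"node {self.name}: no CPT row for parent states {parent_states}"
            ) from None
        return row[self.states.index(state)]


class BayesNet:
    """Directed acyclic graph of :class:`NetNode` with exact inference."""

    def __init__(self, nodes: Iterable[NetNode], label: str = ""):
        self.nodes: dict[str, NetNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise ConfigError(f"duplicate node name {node.name!r}")
            self.nodes[node.name] = node
        self.label = label
        graph = nx.DiGraph()
        graph.add_nodes_from(self.nodes)
        for node in self.nodes.values():
            for parent in node.parents:
                if parent not in self.nodes:
                    raise ConfigError(f"node {node.name}: unknown parent {parent!r}")
                graph.add_edge(parent, node.name)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ConfigError(f"network contains a cycle: {cycle}")
        self.graph = graph
        self._order = list(nx.topological_sort(graph))

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def node(self, name: str) -> NetNode:
        try:
            return self.nodes[name]
        except KeyError:
            raise ConfigError(f"no node named {name!r} in the network") from None

    def assignments(
        self, fixed: Mapping[str, State] | None = None
    ) -> Iterable[dict[str, State]]:
        """All full state maps consistent with ``fixed`` (evidence)."""
        fixed = dict(fixed or {})
        for name, state in fixed.items():
            node = self.node(name)
            if state not in node.states:
                raise ValidationError(f"{state!r} is not a state of node {name}")
        free = [n for n in self._order if n not in fixed]
        state_lists = [self.nodes[n].states for n in free]
        for combo in itertools.product(*state_lists):
            assignment = dict(fixed)
            assignment.update(zip(free, combo))
            yield assignment


def joint_probability(net: BayesNet, assignment: Mapping[str, State]) -> float:
    """Probability of one full assignment: the product of CPT entries."""
    missing = set(net.nodes) - set(assignment)
    if missing:
        raise ValidationError(f"assignment misses nodes {sorted(missing)}")
    prob = 1.0
    for name, node in net.nodes.items():
        parent_states = tuple(assignment[p] for p in node.parents)
        prob *= node.prob(assignment[name], parent_states)
        if prob == 0.0:
            return 0.0
    return prob


def _weighted_total(
    net: BayesNet,
    fixed: Mapping[str, State],
    virtual_evidence: Mapping[str, Mapping[State, float]] | None,
) -> float:
    total = 0.0
    for assignment in net.assignments(fixed):
        w = joint_probability(net, assignment)
        if virtual_evidence:
            for name, weights in virtual_evidence.items():
                w *= weights.get(assignment[name], 0.0)
        total += w
    return total


def infer(
    net: BayesNet,
    query: str,
    evidence: Mapping[str, State] | None = None,
    state: State | None = None,
    virtual_evidence: Mapping[str, Mapping[State, float]] | None = None,
) -> float:
    """Exact conditional probability P(query = state | evidence) by enumeration.

    ``state`` defaults to the query node's first state (1 for binary
    nodes).  ``virtual_evidence`` injects likelihood findings: a map
    node -> {state: weight} multiplied into the joint, the standard way
    to feed a likelihood ratio (e.g. a dose-response posterior from the
    grouped-binomial analysis) into the network without asserting a hard
    state.
    """
    evidence = dict(evidence or {})
    node = net.node(query)
    if state is None:
        state = node.states[0]
    if state not in node.states:
        raise ValidationError(f"{state!r} is not a state of node {query}")
    denominator = _weighted_total(net, evidence, virtual_evidence)
    if denominator <= 0.0:
        raise DomainError("evidence has probability zero: cannot condition on it")
    if query in evidence:
        return 1.0 if evidence[query] == state else 0.0
    numerator = _weighted_total(net, {**evidence, query: state}, virtual_evidence)
    return numerator / denominator


def marginal(
    net: BayesNet, query: str, evidence: Mapping[str, State] | None = None
) -> dict[State, float]:
    """Full conditional distribution of one node given evidence."""
    node = net.node(query)
    return {s: infer(net, query, evidence, state=s) for s in node.states}


def d_separated(
    net: BayesNet, x: Iterable[str], y: Iterable[str], z: Iterable[str] = ()
) -> bool:
    """True iff every path between X and Y is blocked by Z.

    Standard reachability ("Bayes ball"): traversal through a chain or
    fork is blocked at conditioned nodes; a collider passes only if the
    collider or one of its descendants is in Z.
    """
    x_set, y_set, z_set = set(x), set(y), set(z)
    for name in x_set | y_set | z_set:
        net.node(name)
    if (x_set & y_set) or (x_set & z_set) or (y_set & z_set):
        raise ValidationError("X, Y and Z must be pairwise disjoint")

    # ancestors of Z decide whether colliders are opened
    z_ancestors: set[str] = set(z_set)
    for name in z_set:
        z_ancestors |= nx.ancestors(net.graph, name)

    # states: (node, direction) with direction "up" = arrived from a child,
    # "down" = arrived from a parent
    visited: set[tuple[str, str]] = set()
    frontier = [(name, "up") for name in x_set]
    while frontier:
        name, direction = frontier.pop()
        if (name, direction) in visited:
            continue
        visited.add((name, direction))
        if name not in z_set and name in y_set:
            return False
        if direction == "up" and name not in z_set:
            frontier.extend((p, "up") for p in net.graph.predecessors(name))
            frontier.extend((c, "down") for c in net.graph.successors(name))
        elif direction == "down":
            if name not in z_set:
                frontier.extend((c, "down") for c in net.graph.successors(name))
            if name in z_ancestors:  # collider opened by Z or a descendant
                frontier.extend((p, "up") for p in net.graph.predecessors(name))
    return True


def _uniform_cpt(states: Sequence[State], parents: Sequence[NetNode]) -> dict:
    row = tuple(1.0 / len(states) for _ in states)
    keys = itertools.product(*[p.states for p in parents])
    return {key: row for key in keys}


def build_esynthesis_topology(
    indicators: Sequence[str] | None = None,
    reports: Sequence[Mapping] | None = None,
    cpts: Mapping[str, Mapping[tuple, Sequence[float]]] | None = None,
    label: str = "",
) -> BayesNet:
    """Assemble the evidence-amalgamation network from a manifest.

    Parameters
    ----------
    indicators
        Which causal indicators to instantiate (subset of
        :data:`INDICATORS`).  Defaults to all six; an empty sequence
        yields a network containing only the causal hypothesis ``C``.
    reports
        One manifest entry per report node, each a mapping with keys
        ``name``, and either ``design`` (a :data:`STUDY_DESIGN_INDICATORS`
        key, expanded to that design's indicator set) or ``indicators``
        (explicit parent indicators), plus optional ``modulators``
        (study-quality parent nodes, created as binary roots).
    cpts
        Optional CPT overrides keyed by node name; nodes without an
        entry get uniform rows (the structure is the framework's claim,
        the numbers are the analyst's).
    """
    indicators = tuple(INDICATORS if indicators is None else indicators)
    unknown = set(indicators) - set(INDICATORS)
    if unknown:
        raise ConfigError(f"unknown indicator(s) {sorted(unknown)}; known: {INDICATORS}")
    cpts = dict(cpts or {})

    parent_map: dict[str, list[str]] = {"C": []}
    for ind in indicators:
        parent_map[ind] = ["C"]
    if "M" in indicators and "T" in indicators:
        parent_map["T"].append("M")  # mechanism entails time course

    for entry in reports or []:
        name = entry.get("name")
        if not name:
            raise ConfigError(f"report manifest entry without a name: {entry!r}")
        if "design" in entry:
            design = entry["design"]
            if design not in STUDY_DESIGN_INDICATORS:
                raise ConfigError(
                    f"unknown study design {design!r}; known: {sorted(STUDY_DESIGN_INDICATORS)}"
                )
            report_indicators = [
                i for i in STUDY_DESIGN_INDICATORS[design] if i in indicators
            ]
        else:
            report_indicators = list(entry.get("indicators", ()))
            bad = set(report_indicators) - set(indicators)
            if bad:
                raise ConfigError(f"report {name}: indicators {sorted(bad)} not instantiated")
        modulators = list(entry.get("modulators", ()))
        for mod in modulators:
            parent_map.setdefault(mod, [])
        parent_map[name] = report_indicators + modulators

    # states default binary (1, 0); build nodes in dependency order
    nodes: dict[str, NetNode] = {}
    dag = nx.DiGraph()
    dag.add_nodes_from(parent_map)
    dag.add_edges_from(
        (p, child) for child, parents in parent_map.items() for p in parents
    )
    if not nx.is_directed_acyclic_graph(dag):
        raise ConfigError(f"manifest induces a cycle: {nx.find_cycle(dag)}")
    for name in nx.topological_sort(dag):
        parents = tuple(parent_map[name])
        parent_nodes = [nodes[p] for p in parents]
        cpt = cpts.get(name)
        if cpt is None:
            cpt = _uniform_cpt((1, 0), parent_nodes)
        nodes[name] = NetNode(name=name, states=(1, 0), parents=parents, cpt=dict(cpt))
    return BayesNet(nodes.values(), label=label or "evidence-amalgamation network")


def example_configuration() -> BayesNet:
    """A fully parameterised example network honouring the entailments.

    The numbers are illustrative, not estimates: they satisfy C => T,
    C => M and DR => PD, and give the effect-size report node ``ES`` the
    canonical diagnostic rows P(ES=1 | DR=1, T=1) = 1 and
    P(ES=1 | DR=0, T=0) = 0.
    """
    cpts = {
        "C": {(): (0.5, 0.5)},
        "Delta": {(1,): (0.9, 0.1), (0,): (0.1, 0.9)},
        # P(PD=1|C=1)=1 together with P(DR=1|C=0)=0 makes DR=1 & PD=0 impossible
        "PD": {(1,): (1.0, 0.0), (0,): (0.1, 0.9)},
        "DR": {(1,): (0.8, 0.2), (0,): (0.0, 1.0)},
        "RoG": {(1,): (0.5, 0.5), (0,): (0.05, 0.95)},
        "M": {(1,): (1.0, 0.0), (0,): (0.3, 0.7)},
        # parents (C, M): the causal hypothesis and mechanism each entail T
        "T": {
            (1, 1): (1.0, 0.0),
            (1, 0): (1.0, 0.0),
            (0, 1): (1.0, 0.0),
            (0, 0): (0.3, 0.7),
        },
        # parents (DR, T): effect-size report of the cohort study
        "ES": {
            (1, 1): (1.0, 0.0),
            (1, 0): (0.5, 0.5),
            (0, 1): (0.5, 0.5),
            (0, 0): (0.0, 1.0),
        },
    }
    net = build_esynthesis_topology(
        reports=[{"name": "ES", "indicators": ["DR", "T"]}],
        cpts=cpts,
        label="example configuration",
    )
    return net


def validate_entailments(net: BayesNet, tol: float = 1e-12) -> list[str]:
    """Check the framework's logical entailments against the CPTs.

    Verifies, where the relevant nodes exist: P(T=1 | C=1) = 1 (causation
    entails time course), P(M=1 | C=1) = 1 (causation entails a
    mechanism), and that no positive probability mass falls on DR=1 with
    PD=0 (dose-response entails probabilistic dependence).  Violations
    are returned, not raised; absent nodes skip their checks with a
    notice.
    """
    violations: list[str] = []
    names = set(net.nodes)
    if "C" not in names:
        return ["notice: node C absent, no entailment checks apply"]
    if infer(net, "C", state=1) <= 0:
        return ["notice: P(C=1) = 0, conditional entailments are vacuous"]
    for child, rule in (("T", "C => T broken"), ("M", "C => M broken")):
        if child not in names:
            violations.append(f"notice: node {child} absent, {child}-checks skipped")
            continue
        p = infer(net, child, {"C": 1}, state=1)
        if abs(p - 1.0) > tol:
            violations.append(f"{rule}: P({child}=1 | C=1) = {p:.6g}, expected 1")
    if {"DR", "PD"} <= names:
        mass = _weighted_total(net, {"DR": 1, "PD": 0}, None)
        if mass > tol:
            violations.append(
                f"DR => PD broken: P(DR=1, PD=0) = {mass:.6g}, expected 0"
            )
    else:
        violations.append("notice: DR or PD absent, DR => PD check skipped")
    return violations


# --- configuration I/O -----------------------------------------------------

def _state_from_yaml(value):
    return value  # YAML already distinguishes ints, bools and strings


def load_network(path: str | Path) -> BayesNet:
    """Load a network from a YAML/JSON configuration file.

    Schema: a mapping with optional ``label`` and a ``nodes`` list; each
    node has ``name``, optional ``states`` (default ``[1, 0]``),
    ``parents`` and a ``cpt`` list of rows ``{given: {parent: state},
    probs: [..]}`` (``given`` omitted for root nodes).
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, Mapping) or "nodes" not in raw:
        raise ConfigError(f"{path}: expected a mapping with a 'nodes' list")
    nodes = []
    for i, entry in enumerate(raw["nodes"]):
        try:
            name = entry["name"]
            states = tuple(entry.get("states", (1, 0)))
            parents = tuple(entry.get("parents", ()))
            cpt: dict[tuple, tuple[float, ...]] = {}
            for row in entry.get("cpt", ()):
                given = row.get("given", {})
                extra = set(given) - set(parents)
                if extra:
                    raise ConfigError(f"'given' names non-parents {sorted(extra)}")
                key = tuple(_state_from_yaml(given[p]) for p in parents)
                cpt[key] = tuple(float(v) for v in row["probs"])
            nodes.append(NetNode(name=name, states=states, parents=parents, cpt=cpt))
        except (KeyError, TypeError, ConfigError) as exc:
            raise ConfigError(f"{path}: node entry #{i + 1}: {exc}") from exc
    return BayesNet(nodes, label=raw.get("label", ""))


def save_network(net: BayesNet, path: str | Path) -> None:
    """Serialise a network to the YAML schema read by :func:`load_network`."""
    payload = {
        "label": net.label,
        "nodes": [
            {
                "name": node.name,
                "states": list(node.states),
                "parents": list(node.parents),
                "cpt": [
                    {"given": dict(zip(node.parents, key)), "probs": list(row)}
                    for key, row in node.cpt.items()
                ],
            }
            for node in net.nodes.values()
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")
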