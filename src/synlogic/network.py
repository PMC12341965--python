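"""Domain types for prior-knowledge networks and the files that accompany them.

A prior-knowledge network (PKN) is a signed, directed graph of causal
molecular interactions.  The topologies this package targets are
*self-contained*: every node is regulated by at least one other node, so
there are no free inputs whose state a user would have to clamp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: Sentinel for a calibration entry whose state is not determined.
UNSPECIFIED = "-"

ACTIVATION = 1
INHIBITION = -1


class NetworkError(ValueError):
    """Structural violation in a network or companion file."""


@dataclass(frozen=True)
class SignedInteraction:
    """One signed, directed causal interaction (edge) of a PKN."""

    source: str
    target: str
    sign: int  # +1 activation, -1 inhibition

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise NetworkError("interaction source and target must be non-empty")
        if self.sign not in (ACTIVATION, INHIBITION):
            raise NetworkError(f"sign must be +1 or -1, got {self.sign!r}")


@dataclass(frozen=True)
class PriorKnowledgeNetwork:
    """Signed digraph with deterministic (first-appearance) node order."""

    nodes: tuple[str, ...]
    interactions: tuple[SignedInteraction, ...]

    def __post_init__(self) -> None:
        seen = set()
        for ia in self.interactions:
            key = (ia.source, ia.target, ia.sign)
            if key in seen:
                raise NetworkError(f"duplicate interaction {key}")
            seen.add(key)
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise NetworkError("duplicate node identifiers")
        for ia in self.interactions:
            if ia.source not in node_set or ia.target not in node_set:
                raise NetworkError(f"interaction {ia} references unknown node")

    @property
    def node_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.nodes)}

    def regulators_of(self, node: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Return (activators, inhibitors) of ``node`` in interaction order."""
        acts = tuple(ia.source for ia in self.interactions
                     if ia.target == node and ia.sign == ACTIVATION)
        inhs = tuple(ia.source for ia in self.interactions
                     if ia.target == node and ia.sign == INHIBITION)
        return acts, inhs

    def validate_self_contained(self) -> None:
        """Every node must be the target of at least one interaction."""
        targeted = {ia.target for ia in self.interactions}
        for node in self.nodes:
            if node not in targeted:
                raise NetworkError(
                    f"network is not self-contained: node {node!r} has no regulator"
                )


def build_network(
    interactions: Iterable[SignedInteraction],
    *,
    auto_self_regulate: bool = False,
    require_self_contained: bool = True,
) -> PriorKnowledgeNetwork:
    """Assemble a network from interactions, deduplicating and ordering nodes.

    Node order is first appearance (source before target, line by line).
    Duplicate (source, target, sign) triples are dropped with a warning.
    With ``auto_self_regulate`` a positive self-loop is inserted on any node
    lacking a regulator instead of raising.
    """
    nodes: list[str] = []
    seen_nodes: set[str] = set()
    kept: list[SignedInteraction] = []
    seen_edges: set[tuple[str, str, int]] = set()
    for ia in interactions:
        for v in (ia.source, ia.target):
            if v not in seen_nodes:
                seen_nodes.add(v)
                nodes.append(v)
        key = (ia.source, ia.target, ia.sign)
        if key in seen_edges:
            logger.warning("dropping duplicate interaction %s", key)
            continue
        seen_edges.add(key)
        kept.append(ia)
    if not kept:
        raise NetworkError("network has no interactions")
    targeted = {ia.target for ia in kept}
    for node in nodes:
        if node not in targeted:
            if auto_self_regulate:
                logger.info("inserting positive self-loop on orphan node %r", node)
                kept.append(SignedInteraction(node, node, ACTIVATION))
            elif require_self_contained:
                raise NetworkError(
                    f"network is not self-contained: node {node!r} has no regulator"
                )
    return PriorKnowledgeNetwork(tuple(nodes), tuple(kept))


@dataclass(frozen=True)
class CalibrationProfile:
    """Partial node-activity observation vector used to score model fitness.

    ``assignments`` maps node name to 0, 1, or :data:`UNSPECIFIED`.  Nodes
    absent from the mapping are implicitly unspecified.  ``m`` counts the
    specified (0/1) entries — the denominator of the fitness formula.
    """

    assignments: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node, val in self.assignments.items():
            if val not in (0, 1, UNSPECIFIED):
                raise NetworkError(
                    f"calibration value for {node!r} must be 0, 1 or '-', got {val!r}"
                )

    @property
    def specified(self) -> dict[str, int]:
        return {v: s for v, s in self.assignments.items() if s in (0, 1)}

    @property
    def m(self) -> int:
        return len(self.specified)

    def restrict_to(self, nodes: Iterable[str]) -> "CalibrationProfile":
        keep = set(nodes)
        return CalibrationProfile(
            {v: s for v, s in self.assignments.items() if v in keep}
        )

    def validate_against(self, network: PriorKnowledgeNetwork) -> None:
        unknown = set(self.assignments) - set(network.nodes)
        if unknown:
            raise NetworkError(
                f"calibration profile references unknown node(s): {sorted(unknown)}"
            )


FIX_TO_0 = "inhibits"
FIX_TO_1 = "activates"


@dataclass(frozen=True)
class DrugPanel:
    """Drugs and the model nodes they clamp (to 0 for inhibitors, 1 for activators)."""

    entries: Mapping[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for drug, (effect, targets) in self.entries.items():
            if effect not in (FIX_TO_0, FIX_TO_1):
                raise NetworkError(
                    f"drug {drug!r}: effect must be '{FIX_TO_0}' or '{FIX_TO_1}'"
                )
            if not targets:
                raise NetworkError(f"drug {drug!r} has no targets")

    def targets_of(self, drug: str) -> tuple[str, ...]:
        return self.entries[drug][1]

    def fixed_value_of(self, drug: str) -> int:
        return 0 if self.entries[drug][0] == FIX_TO_0 else 1

    def validate_against(self, network: PriorKnowledgeNetwork) -> None:
        node_set = set(network.nodes)
        for drug, (_, targets) in self.entries.items():
            for t in targets:
                if t not in node_set:
                    raise NetworkError(
                        f"drug {drug!r} targets unknown node {t!r}"
                    )


@dataclass(frozen=True)
class OutputSpec:
    """Weighted output nodes defining the scaled global 'growth' read-out.

    The raw output of a stable state is the weighted sum of output-node
    states; it is scaled affinely to [0, 1] between the theoretical minimum
    (all negative-weight nodes active) and maximum (all positive-weight
    nodes active).
    """

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        pos = [w for w in self.weights.values() if w > 0]
        neg = [w for w in self.weights.values() if w < 0]
        if not pos or not neg:
            raise NetworkError(
                "output spec needs at least one positive and one negative weight"
            )

    @property
    def theoretical_min(self) -> float:
        return sum(w for w in self.weights.values() if w < 0)

    @property
    def theoretical_max(self) -> float:
        return sum(w for w in self.weights.values() if w > 0)

    @property
    def positive_nodes(self) -> tuple[str, ...]:
        return tuple(v for v, w in self.weights.items() if w > 0)

    @property
    def negative_nodes(self) -> tuple[str, ...]:
        return tuple(v for v, w in self.weights.items() if w < 0)
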