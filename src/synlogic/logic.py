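"""Link-operator logic equations and Boolean models.

Each node of a model carries one standardized update rule: its activating
regulators are OR-joined, its inhibiting regulators are OR-joined, and the
two groups are combined by a *link operator*,

    Act AND-NOT Inh  =  (a1 or a2 ...) and not (i1 or i2 ...)
    Act OR-NOT  Inh  =  (a1 or a2 ...) or  not (i1 or i2 ...)

AND-NOT requires both activation and absence of inhibition (less
permissive); OR-NOT requires either (more permissive).  The link operator
is the primary mutable parameter of the genetic algorithm; a model over n
link-operator equations spans a parameterization space of 2^n models.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .network import PriorKnowledgeNetwork

logger = logging.getLogger(__name__)


class LinkOperator(Enum):
    AND_NOT = "and not"
    OR_NOT = "or not"
    NONE = "none"

    def flipped(self) -> "LinkOperator":
        if self is LinkOperator.AND_NOT:
            return LinkOperator.OR_NOT
        if self is LinkOperator.OR_NOT:
            return LinkOperator.AND_NOT
        return self


class EquationError(ValueError):
    """Malformed logic equation (construction or text parsing)."""


_NAME_RE = re.compile(r"^[^\s()]+$")


@dataclass(frozen=True)
class LogicEquation:
    """One node's update rule.

    ``fixed_value`` overrides the rule with a constant — the representation
    of a drug-clamped node.  ``memo_operator`` remembers the last link
    operator used, so a topology mutation that empties one regulator class
    and later refills it restores the operator it had.
    """

    target: str
    activators: tuple[str, ...] = ()
    inhibitors: tuple[str, ...] = ()
    link_operator: LinkOperator = LinkOperator.NONE
    fixed_value: int | None = None
    memo_operator: LinkOperator = LinkOperator.AND_NOT

    def __post_init__(self) -> None:
        if self.fixed_value is not None:
            if self.fixed_value not in (0, 1):
                raise EquationError("fixed_value must be 0 or 1")
            return
        if not self.activators and not self.inhibitors:
            raise EquationError(f"equation for {self.target!r} has no regulators")
        both = bool(self.activators) and bool(self.inhibitors)
        if both and self.link_operator is LinkOperator.NONE:
            raise EquationError(
                f"{self.target!r}: both regulator classes present but no link operator"
            )
        if not both and self.link_operator is not LinkOperator.NONE:
            raise EquationError(
                f"{self.target!r}: link operator requires both regulator classes"
            )

    @property
    def regulators(self) -> tuple[str, ...]:
        return self.activators + self.inhibitors

    def evaluate(self, state: Mapping[str, int]) -> int:
        """Next state of the target under a full regulator assignment."""
        if self.fixed_value is not None:
            return self.fixed_value
        try:
            act = any(state[a] for a in self.activators) if self.activators else None
            inh = any(state[i] for i in self.inhibitors) if self.inhibitors else None
        except KeyError as exc:
            raise EquationError(
                f"state missing regulator {exc.args[0]!r} of {self.target!r}"
            ) from exc
        if act is None:
            return int(not inh)
        if inh is None:
            return int(act)
        if self.link_operator is LinkOperator.AND_NOT:
            return int(act and not inh)
        return int(act or not inh)

    # --- text dialect -----------------------------------------------------

    def to_text(self) -> str:
        """Serialize as e.g. ``B *= ((A) or (C)) and not ((D))``."""
        if self.fixed_value is not None:
            return f"{self.target} *= {self.fixed_value}"

        def group(names: Sequence[str]) -> str:
            return "(" + " or ".join(f"({n})" for n in names) + ")"

        if self.activators and self.inhibitors:
            return (
                f"{self.target} *= {group(self.activators)} "
                f"{self.link_operator.value} {group(self.inhibitors)}"
            )
        if self.activators:
            return f"{self.target} *= {group(self.activators)}"
        return f"{self.target} *= not {group(self.inhibitors)}"

    @classmethod
    def from_text(cls, line: str) -> "LogicEquation":
        try:
            lhs, rhs = line.split("*=", 1)
        except ValueError:
            raise EquationError(f"missing '*=' in equation: {line!r}") from None
        target = lhs.strip()
        if not _NAME_RE.match(target):
            raise EquationError(f"bad target identifier {target!r}")
        rhs = rhs.strip()
        if rhs in ("0", "1"):
            return cls(target, fixed_value=int(rhs))

        def ungroup(text: str) -> tuple[str, ...]:
            text = text.strip()
            if not (text.startswith("(") and text.endswith(")")):
                raise EquationError(f"malformed regulator group {text!r}")
            inner = text[1:-1].strip()
            names = []
            for part in inner.split(" or "):
                part = part.strip()
                if not (part.startswith("(") and part.endswith(")")):
                    raise EquationError(f"malformed regulator term {part!r}")
                name = part[1:-1].strip()
                if not _NAME_RE.match(name):
                    raise EquationError(f"bad regulator identifier {name!r}")
                names.append(name)
            if not names:
                raise EquationError(f"empty regulator group in {text!r}")
            return tuple(names)

        if rhs.startswith("not "):
            return cls(target, inhibitors=ungroup(rhs[4:]))
        for token, op in ((" and not ", LinkOperator.AND_NOT),
                          (" or not ", LinkOperator.OR_NOT)):
            if token in rhs:
                left, right = rhs.split(token, 1)
                return cls(
                    target,
                    activators=ungroup(left),
                    inhibitors=ungroup(right),
                    link_operator=op,
                    memo_operator=op,
                )
        return cls(target, activators=ungroup(rhs))


@dataclass(frozen=True)
class BooleanModel:
    """A full set of logic equations over a closed node universe.

    This is the genotype the genetic algorithm operates on.  Models use
    value semantics: mutation operators return new models, leaving their
    input (a GA parent kept by elitism) intact.
    """

    equations: tuple[LogicEquation, ...]
    provenance: str = ""
    fitness: float | None = None

    def __post_init__(self) -> None:
        targets = [eq.target for eq in self.equations]
        if len(set(targets)) != len(targets):
            raise EquationError("more than one equation for a node")
        universe = set(targets)
        for eq in self.equations:
            for reg in eq.regulators:
                if reg not in universe:
                    raise EquationError(
                        f"{eq.target!r} regulated by {reg!r}, which has no equation"
                    )

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(eq.target for eq in self.equations)

    @property
    def node_index(self) -> dict[str, int]:
        return {eq.target: i for i, eq in enumerate(self.equations)}

    def equation_for(self, node: str) -> LogicEquation:
        return self.equations[self.node_index[node]]

    def link_operator_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, eq in enumerate(self.equations)
            if eq.link_operator is not LinkOperator.NONE
        )

    def with_equation(self, idx: int, eq: LogicEquation) -> "BooleanModel":
        eqs = list(self.equations)
        eqs[idx] = eq
        return replace(self, equations=tuple(eqs))

    def with_fitness(self, fitness: float) -> "BooleanModel":
        return replace(self, fitness=fitness)


def assemble_default_model(network: PriorKnowledgeNetwork) -> BooleanModel:
    """Build the default model: OR-joined regulator groups linked by AND-NOT.

    A node with both activators and inhibitors gets the less permissive
    AND-NOT operator; single-class nodes need no link operator.
    """
    network.validate_self_contained()
    eqs = []
    for node in network.nodes:
        acts, inhs = network.regulators_of(node)
        op = LinkOperator.AND_NOT if acts and inhs else LinkOperator.NONE
        eqs.append(LogicEquation(node, acts, inhs, op))
    return BooleanModel(tuple(eqs), provenance="default assembly")


def evaluate_equation(eq: LogicEquation, state: Mapping[str, int]) -> int:
    return eq.evaluate(state)


def mutate_link_operators(
    model: BooleanModel, k: int, rng: np.random.Generator
) -> BooleanModel:
    """Flip link operators of k equations drawn uniformly with replacement.

    Drawing with replacement means a draw can hit the same equation twice,
    re-flipping it; only the flip parity per equation matters, so the k
    draws are made in one vectorized call.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return model
    eligible = model.link_operator_indices()
    if not eligible:
        logger.warning("mutate_link_operators: no link-operator equations; no-op")
        return model
    draws = rng.integers(0, len(eligible), size=k)
    flip_counts = np.bincount(draws, minlength=len(eligible))
    eqs = list(model.equations)
    for j, count in enumerate(flip_counts):
        if count % 2:
            idx = eligible[j]
            eq = eqs[idx]
            new_op = eq.link_operator.flipped()
            eqs[idx] = replace(eq, link_operator=new_op, memo_operator=new_op)
    return replace(model, equations=tuple(eqs))


def enumerate_parameterizations(model: BooleanModel):
    """Yield all 2^n link-operator assignments of a model (n = number of
    link-operator equations).  Intended for exhaustive analysis of small
    models; the count doubles per link-operator equation."""
    indices = model.link_operator_indices()
    for code in range(2 ** len(indices)):
        eqs = list(model.equations)
        for bit, idx in enumerate(indices):
            op = LinkOperator.OR_NOT if (code >> bit) & 1 else LinkOperator.AND_NOT
            eqs[idx] = replace(eqs[idx], link_operator=op, memo_operator=op)
        yield replace(model, equations=tuple(eqs))


def mutate_topology(
    model: BooleanModel,
    network: PriorKnowledgeNetwork,
    k: int,
    rng: np.random.Generator,
    max_redraws: int = 100,
) -> BooleanModel:
    """Apply k edge mutations: blacklist (remove) or whitelist (restore).

    Each mutation draws uniformly from the joint pool of removable present
    regulators and restorable absent regulators of the original network.  A
    removal that would leave its target with no regulator is rejected and
    redrawn, preserving self-containedness.  When a mutation empties one
    regulator class the link operator drops to NONE; when both classes are
    non-empty again the equation's remembered operator is restored.
    """
    eqs = list(model.equations)
    index = model.node_index
    original: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
        node: network.regulators_of(node) for node in network.nodes
    }

    def rebuild(eq: LogicEquation, acts: tuple[str, ...], inhs: tuple[str, ...]
                ) -> LogicEquation:
        if acts and inhs:
            op = eq.memo_operator
        else:
            op = LinkOperator.NONE
        return replace(eq, activators=acts, inhibitors=inhs, link_operator=op)

    applied = 0
    while applied < k:
        # candidate moves: ('rm'|'add', target, regulator, sign)
        moves: list[tuple[str, str, str, int]] = []
        for node, (o_acts, o_inhs) in original.items():
            eq = eqs[index[node]]
            for reg in eq.activators:
                moves.append(("rm", node, reg, 1))
            for reg in eq.inhibitors:
                moves.append(("rm", node, reg, -1))
            for reg in o_acts:
                if reg not in eq.activators:
                    moves.append(("add", node, reg, 1))
            for reg in o_inhs:
                if reg not in eq.inhibitors:
                    moves.append(("add", node, reg, -1))
        if not moves:
            logger.warning("mutate_topology: no candidate moves; stopping early")
            break
        ok = False
        for _ in range(max_redraws):
            kind, node, reg, sign = moves[rng.integers(0, len(moves))]
            eq = eqs[index[node]]
            acts, inhs = eq.activators, eq.inhibitors
            if kind == "rm":
                if len(acts) + len(inhs) <= 1:
                    continue  # would orphan the target; redraw
                if sign == 1:
                    acts = tuple(a for a in acts if a != reg)
                else:
                    inhs = tuple(i for i in inhs if i != reg)
            else:
                # restore in the original network's regulator order
                o_acts, o_inhs = original[node]
                if sign == 1:
                    acts = tuple(a for a in o_acts if a in acts or a == reg)
                else:
                    inhs = tuple(i for i in o_inhs if i in inhs or i == reg)
            eqs[index[node]] = rebuild(eq, acts, inhs)
            ok = True
            break
        if not ok:
            logger.warning("mutate_topology: redraw budget exhausted; stopping early")
            break
        applied += 1
    return replace(model, equations=tuple(eqs), provenance=model.provenance)
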