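"""Exact enumeration of the fixed points (stable states) of a Boolean model.

A fixed point is a full state x with f(x) = x under every node's update
rule; the set is independent of the update scheme (synchronous or
asynchronous), which is why it is the one attractor class this pipeline
relies on.  Models whose only attractors are complex (cyclic) simply have
no fixed point here (n = 0).

The solver is a DPLL-style backtracking search with tri-valued constraint
propagation over the link-operator circuit: whenever a node's update value
is already determined by the partial assignment, the constraint x_v =
f_v(x) forces x_v; conflicts prune the branch.  Exhaustive enumeration of
all solutions replaces the blocking-clause loop of a SAT formulation.  A
vectorized 2^N sweep is provided as an independent oracle for small N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .logic import BooleanModel, LinkOperator

UNKNOWN = -1


class CapacityError(RuntimeError):
    """Model too large for the configured node-count guard."""


class FixedPointOverflowError(RuntimeError):
    """More fixed points than the configured enumeration cap."""


@dataclass(frozen=True)
class AttractorSet:
    """All fixed points of a model, sorted lexicographically in node order."""

    nodes: tuple[str, ...]
    fixed_points: tuple[tuple[int, ...], ...]

    @property
    def n(self) -> int:
        return len(self.fixed_points)

    def as_dicts(self) -> list[dict[str, int]]:
        return [dict(zip(self.nodes, fp)) for fp in self.fixed_points]


def _compile(model: BooleanModel):
    """Precompile equations to index-based tuples for the solver."""
    index = model.node_index
    compiled = []
    for eq in model.equations:
        acts = tuple(index[a] for a in eq.activators)
        inhs = tuple(index[i] for i in eq.inhibitors)
        compiled.append((acts, inhs, eq.link_operator, eq.fixed_value))
    return compiled


def _tri_or(indices, state) -> int:
    """Tri-valued OR over state values: 1, 0, or UNKNOWN."""
    saw_unknown = False
    for i in indices:
        v = state[i]
        if v == 1:
            return 1
        if v == UNKNOWN:
            saw_unknown = True
    return UNKNOWN if saw_unknown else 0


def _tri_eval(compiled_eq, state) -> int:
    acts, inhs, op, fixed = compiled_eq
    if fixed is not None:
        return fixed
    if not inhs:
        return _tri_or(acts, state)
    if not acts:
        v = _tri_or(inhs, state)
        return UNKNOWN if v == UNKNOWN else 1 - v
    a = _tri_or(acts, state)
    b = _tri_or(inhs, state)
    if op is LinkOperator.AND_NOT:
        if a == 0 or b == 1:
            return 0
        if a == 1 and b == 0:
            return 1
        return UNKNOWN
    # OR_NOT
    if a == 1 or b == 0:
        return 1
    if a == 0 and b == 1:
        return 0
    return UNKNOWN


def fixed_points(
    model: BooleanModel,
    *,
    max_nodes: int = 4096,
    max_fixed_points: int = 64,
) -> AttractorSet:
    """Enumerate exactly the set {x : f(x) = x}.

    n = 0 is a legal result and means the model has only complex
    attractors.  Raises :class:`FixedPointOverflowError` beyond
    ``max_fixed_points`` solutions and :class:`CapacityError` beyond
    ``max_nodes`` nodes.
    """
    n_nodes = len(model.equations)
    if n_nodes > max_nodes:
        raise CapacityError(f"model has {n_nodes} nodes (> guard {max_nodes})")
    compiled = _compile(model)
    solutions: list[tuple[int, ...]] = []

    def propagate(state: list[int]) -> bool:
        """Force determined nodes; return False on conflict."""
        changed = True
        while changed:
            changed = False
            for v in range(n_nodes):
                val = _tri_eval(compiled[v], state)
                if val == UNKNOWN:
                    continue
                if state[v] == UNKNOWN:
                    state[v] = val
                    changed = True
                elif state[v] != val:
                    return False
        return True

    def search(state: list[int]) -> None:
        if not propagate(state):
            return
        try:
            branch = state.index(UNKNOWN)
        except ValueError:
            solutions.append(tuple(state))
            if len(solutions) > max_fixed_points:
                raise FixedPointOverflowError(
                    f"more than {max_fixed_points} fixed points"
                )
            return
        for bit in (0, 1):
            child = list(state)
            child[branch] = bit
            search(child)

    search([UNKNOWN] * n_nodes)
    solutions.sort()
    return AttractorSet(model.nodes, tuple(solutions))


def brute_force_fixed_points(model: BooleanModel, *, max_nodes: int = 20
                             ) -> AttractorSet:
    """Independent oracle: vectorized sweep of all 2^N states (N <= 20)."""
    n = len(model.equations)
    if n > max_nodes:
        raise CapacityError(f"brute force limited to {max_nodes} nodes")
    compiled = _compile(model)
    codes = np.arange(2 ** n, dtype=np.int64)
    # bit i of the code is node i's state
    states = (codes[:, None] >> np.arange(n)) & 1  # (2^n, n), 0/1
    states = states.astype(bool)
    nxt = np.empty_like(states)
    for v, (acts, inhs, op, fixed) in enumerate(compiled):
        if fixed is not None:
            nxt[:, v] = bool(fixed)
            continue
        act = states[:, list(acts)].any(axis=1) if acts else None
        inh = states[:, list(inhs)].any(axis=1) if inhs else None
        if act is None:
            nxt[:, v] = ~inh
        elif inh is None:
            nxt[:, v] = act
        elif op is LinkOperator.AND_NOT:
            nxt[:, v] = act & ~inh
        else:
            nxt[:, v] = act | ~inh
    stable = (nxt == states).all(axis=1)
    sols = sorted(tuple(int(b) for b in row) for row in states[stable])
    return AttractorSet(model.nodes, tuple(sols))
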