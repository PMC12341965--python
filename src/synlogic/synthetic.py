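"""Synthetic self-contained networks with planted ground truth.

The generator emulates the shape of curated signaling topologies — a
signed, directed, self-contained graph with designated positively and
negatively weighted output nodes, a partial steady-state profile and an
inhibitor panel — at sizes where every pipeline stage runs in seconds.
The planted truth is a specific link-operator assignment together with a
verified fixed point of it; gold-standard synergy labels are computed by
exhaustively simulating all drug pairs on that truth model.

Two degradation operators reproduce the robustness experiments: flipping
a controlled fraction of calibration bits, and scrambling interaction
sources, targets or signs (pairwise exchanges, so node and edge counts
are preserved).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .attractors import FixedPointOverflowError, fixed_points
from .evaluation import GoldStandard, benchmark
from .evolution import GAConfig, evolve
from .logic import BooleanModel, LinkOperator, assemble_default_model
from .network import (
    ACTIVATION,
    UNSPECIFIED,
    CalibrationProfile,
    DrugPanel,
    OutputSpec,
    PriorKnowledgeNetwork,
    SignedInteraction,
    build_network,
)
from .synergy import (
    Perturbation,
    all_perturbations,
    apply_perturbation,
    model_growth,
    normalize,
    sample_proliferative_profile,
    score_all_pairs,
    score_synergy,
    simulate_ensemble,
)

logger = logging.getLogger(__name__)

_MODE_CODES = {"profile": 0, "source": 1, "target": 2, "sign": 3, "all": 4}


@dataclass(frozen=True)
class PlantedSystem:
    """A complete synthetic study system with known ground truth."""

    network: PriorKnowledgeNetwork
    truth_model: BooleanModel
    truth_profile: CalibrationProfile
    outputs: OutputSpec
    panel: DrugPanel
    gold: GoldStandard
    flagged_pairs: tuple[tuple[str, str], ...] = ()


def _random_network(n_nodes: int, n_edges: int, rng: np.random.Generator
                    ) -> PriorKnowledgeNetwork:
    """Random signed digraph, every node regulated, no duplicate (s, t) pair."""
    names = [f"n{i:02d}" for i in range(n_nodes)]
    edges: list[SignedInteraction] = []
    used: set[tuple[str, str]] = set()
    # one incoming edge per node guarantees self-containedness
    for i, target in enumerate(names):
        source = names[int(rng.integers(0, n_nodes - 1))]
        if source == target:
            source = names[n_nodes - 1]
        sign = ACTIVATION if rng.random() < 0.7 else -1
        edges.append(SignedInteraction(source, target, sign))
        used.add((source, target))
    while len(edges) < n_edges:
        s = names[int(rng.integers(0, n_nodes))]
        t = names[int(rng.integers(0, n_nodes))]
        if s == t or (s, t) in used:
            continue
        sign = ACTIVATION if rng.random() < 0.7 else -1
        edges.append(SignedInteraction(s, t, sign))
        used.add((s, t))
    return build_network(edges)


def _random_parameterization(base: BooleanModel, rng: np.random.Generator
                             ) -> BooleanModel:
    eqs = list(base.equations)
    for i in base.link_operator_indices():
        op = LinkOperator.AND_NOT if rng.random() < 0.5 else LinkOperator.OR_NOT
        eqs[i] = dc_replace(eqs[i], link_operator=op, memo_operator=op)
    return dc_replace(base, equations=tuple(eqs), provenance="planted truth")


def generate_planted_system(
    n_nodes: int = 15,
    n_edges: int = 25,
    n_outputs: int = 4,
    n_drugs: int = 6,
    mask_fraction: float = 0.0,
    rng: np.random.Generator | int | None = None,
    *,
    require_unique_fixed_point: bool = False,
    unique_optimum: bool = False,
    min_positives: int = 1,
    max_retries: int = 200,
) -> PlantedSystem:
    """Draw a network, plant a truth parameterization and derive all inputs.

    The link-operator assignment is redrawn until it has at least one
    fixed point — exactly one with ``require_unique_fixed_point``.  With
    ``unique_optimum`` (which implies the former) all 2^n parameterizations
    are additionally enumerated and the draw is accepted only when the
    planted assignment is the *only* one achieving fitness 1 against the
    unmasked planted state — the condition under which calibration data can
    identify the planted truth, required by the recovery and degradation
    experiments.  The drug panel, and failing that the whole network, is
    redrawn until the truth model has a defined growth under every
    perturbation arm and the gold standard has at least one synergistic
    and one non-synergistic pair.
    """
    if n_edges < n_nodes:
        raise ValueError("n_edges >= n_nodes required for self-containedness")
    if n_outputs < 2:
        raise ValueError("n_outputs >= 2 required (positive and negative weights)")
    rng = np.random.default_rng(rng)

    for _ in range(max_retries):
        network = _random_network(n_nodes, n_edges, rng)
        truth = None
        for _ in range(25):
            candidate = _random_parameterization(
                assemble_default_model(network), rng
            )
            try:
                attrs = fixed_points(candidate)
            except FixedPointOverflowError:
                continue
            if attrs.n == 0:
                continue
            if (require_unique_fixed_point or unique_optimum) and attrs.n != 1:
                continue
            if unique_optimum and not _is_unique_optimum(candidate, attrs):
                continue
            truth, truth_attrs = candidate, attrs
            break
        if truth is None:
            continue

        out_nodes = [str(v) for v in
                     rng.choice(network.nodes, size=n_outputs, replace=False)]
        n_pos = max(1, n_outputs // 2)
        weights = {v: (1.0 if i < n_pos else -1.0)
                   for i, v in enumerate(out_nodes)}
        outputs = OutputSpec(weights)

        drawn = _draw_panel_with_gold(network, truth, outputs, n_drugs, rng,
                                      min_positives=min_positives)
        if drawn is None:
            continue
        panel, gold, flagged = drawn

        planted_state = dict(zip(truth_attrs.nodes, truth_attrs.fixed_points[0]))
        n_mask = math.ceil(mask_fraction * n_nodes)
        masked = set(
            str(v) for v in rng.choice(network.nodes, size=n_mask, replace=False)
        ) if n_mask else set()
        if len(masked) >= n_nodes:  # keep m >= 1
            masked.discard(sorted(masked)[0])
        profile = CalibrationProfile({
            v: (UNSPECIFIED if v in masked else planted_state[v])
            for v in network.nodes
        })
        return PlantedSystem(network, truth, profile, outputs, panel, gold,
                             tuple(flagged))
    raise RuntimeError(
        "no suitable planted system found within the retry budget; "
        "increase max_retries or change the generator seed"
    )


def _is_unique_optimum(truth: BooleanModel, truth_attrs) -> bool:
    """True iff no other link-operator assignment reproduces the planted
    state as its only stable behavior (fitness 1 on the unmasked profile)."""
    from .logic import enumerate_parameterizations

    indices = truth.link_operator_indices()
    if not indices or len(indices) > 14:
        return False
    planted = truth_attrs.fixed_points[0]
    optima = 0
    for candidate in enumerate_parameterizations(truth):
        try:
            attrs = fixed_points(candidate)
        except FixedPointOverflowError:
            continue
        if attrs.n >= 1 and all(fp == planted for fp in attrs.fixed_points):
            optima += 1
            if optima > 1:
                return False
    return optima == 1


def _draw_panel_with_gold(network, truth, outputs, n_drugs, rng,
                          n_attempts: int = 30, min_positives: int = 1):
    for _ in range(n_attempts):
        targets = rng.choice(network.nodes, size=n_drugs, replace=False)
        panel = DrugPanel({
            f"D{i:02d}": ("inhibits", (str(t),)) for i, t in enumerate(targets)
        })
        gold_labels, flagged = _gold_from_truth(truth, panel, outputs)
        values = list(gold_labels.values())
        if (sum(values) >= min_positives and not all(values)
                and not flagged):
            return panel, GoldStandard(gold_labels), flagged
    return None


def _gold_from_truth(truth: BooleanModel, panel: DrugPanel, outputs: OutputSpec):
    """Label every pair by exhaustive simulation of the truth model.

    Synergy is S < 0 strictly; pairs with undefined growth under any arm
    are labeled negative and flagged.
    """
    singles: dict[str, float | None] = {}
    for drug in panel.entries:
        singles[drug] = model_growth(
            apply_perturbation(truth, Perturbation([drug]), panel), outputs
        )
    labels: dict[tuple[str, str], bool] = {}
    flagged: list[tuple[str, str]] = []
    drugs = sorted(panel.entries)
    for i, a in enumerate(drugs):
        for b in drugs[i + 1:]:
            g_ab = model_growth(
                apply_perturbation(truth, Perturbation([a, b]), panel), outputs
            )
            rec = score_synergy(singles[a], singles[b], g_ab, (a, b))
            if not rec.available:
                labels[(a, b)] = False
                flagged.append((a, b))
            else:
                labels[(a, b)] = rec.excess < 0
    return labels, flagged


def corrupt_profile(
    profile: CalibrationProfile, fraction: float, rng: np.random.Generator
) -> CalibrationProfile:
    """Flip exactly round(fraction * m) specified bits, without replacement."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    specified = sorted(profile.specified)
    n_flips = int(round(fraction * len(specified)))
    if n_flips == 0:
        return CalibrationProfile(dict(profile.assignments))
    to_flip = set(rng.choice(specified, size=n_flips, replace=False))
    assignments = {
        node: (1 - value if node in to_flip and value in (0, 1) else value)
        for node, value in profile.assignments.items()
    }
    return CalibrationProfile(assignments)


def scramble_topology(
    network: PriorKnowledgeNetwork,
    mode: str,
    fraction: float,
    rng: np.random.Generator,
    *,
    max_redraws: int = 50,
) -> PriorKnowledgeNetwork:
    """Randomize round(fraction * E) interactions by pairwise exchange.

    ``source`` swaps the source of each selected interaction with that of a
    uniformly chosen partner; ``target`` likewise for targets; ``sign``
    inverts the annotation; ``all`` applies the three in sequence, each to
    its own sampled subset.  Exchange semantics preserve node and edge
    counts, and the target multiset, so self-containedness survives; an
    exchange that would duplicate an existing (source, target, sign) triple
    is redrawn.  Orphaned nodes (impossible under pure exchanges, kept as a
    safety net) get a positive self-loop.
    """
    if mode == "all":
        net = network
        for sub in ("source", "target", "sign"):
            net = scramble_topology(net, sub, fraction, rng,
                                    max_redraws=max_redraws)
        return net
    if mode not in ("source", "target", "sign"):
        raise ValueError(f"unknown scramble mode {mode!r}")
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    edges = [[ia.source, ia.target, ia.sign] for ia in network.interactions]
    n_edges = len(edges)
    k = int(round(fraction * n_edges))
    if k == 0:
        return network

    def triples() -> set[tuple[str, str, int]]:
        return {(s, t, g) for s, t, g in edges}

    selected = rng.choice(n_edges, size=k, replace=False)
    for i in selected:
        i = int(i)
        if mode == "sign":
            flipped = (edges[i][0], edges[i][1], -edges[i][2])
            if flipped in triples():
                logger.info("sign flip collides with existing edge; skipped")
                continue
            edges[i][2] = -edges[i][2]
            continue
        col = 0 if mode == "source" else 1
        done = False
        for _ in range(max_redraws):
            j = int(rng.integers(0, n_edges))
            if j == i:
                continue
            trial = [list(e) for e in edges]
            trial[i][col], trial[j][col] = trial[j][col], trial[i][col]
            seen = set()
            ok = True
            for s, t, g in trial:
                if (s, t, g) in seen:
                    ok = False
                    break
                seen.add((s, t, g))
            if ok:
                edges = trial
                done = True
                break
        if not done:
            logger.info("no duplicate-free %s exchange found; edge kept", mode)

    # safety net: exchanges preserve the target multiset, so this is a no-op
    targeted = {t for _, t, _ in edges}
    interactions = [SignedInteraction(s, t, g) for s, t, g in edges]
    for node in network.nodes:
        if node not in targeted:
            logger.warning("repairing orphaned node %r with a self-loop", node)
            interactions.append(SignedInteraction(node, node, ACTIVATION))
    return PriorKnowledgeNetwork(network.nodes, tuple(interactions))


def degradation_experiment(
    system: PlantedSystem,
    fractions,
    config: GAConfig,
    mode: str = "profile",
    n_replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Benchmark the full pipeline under controlled input degradation.

    For each fraction and replicate, the calibration profile is corrupted
    (``mode='profile'``) or the network is scrambled (other modes), a
    calibrated ensemble and a random-proliferative baseline ensemble are
    trained, all perturbations are simulated, normalized synergy scores
    are benchmarked against the planted gold standard, and one tidy row is
    recorded.  GA seeds depend only on (seed, mode, replicate), so fraction
    0 reproduces the clean-system benchmark exactly.
    """
    code = _MODE_CODES[mode]
    rows = []
    perts = all_perturbations(system.panel)
    for rep in range(n_replicates):
        ga_seed_cal = int(
            np.random.default_rng([seed, code, rep, 0]).integers(2 ** 31)
        )
        ga_seed_base = int(
            np.random.default_rng([seed, code, rep, 1]).integers(2 ** 31)
        )
        for f_idx, fraction in enumerate(fractions):
            rng_variant = np.random.default_rng([seed, code, rep, 2, f_idx])
            if mode == "profile":
                net = system.network
                train_profile = corrupt_profile(
                    system.truth_profile, fraction, rng_variant
                )
            else:
                net = scramble_topology(
                    system.network, mode, fraction, rng_variant
                )
                train_profile = system.truth_profile

            calibrated = evolve(
                net, train_profile, dc_replace(config, seed=ga_seed_cal)
            )

            def sampler(e: int) -> CalibrationProfile:
                return sample_proliferative_profile(
                    system.outputs,
                    np.random.default_rng([seed, code, rep, 3, e]),
                )

            baseline = evolve(
                net, sampler, dc_replace(config, seed=ga_seed_base)
            )
            resp_cal = simulate_ensemble(
                calibrated.models, perts, system.panel, system.outputs
            )
            resp_base = simulate_ensemble(
                baseline.models, perts, system.panel, system.outputs
            )
            scores = normalize(
                score_all_pairs(resp_cal, perts),
                score_all_pairs(resp_base, perts),
            )
            ranked = {p: r.normalized for p, r in scores.items()}
            try:
                result = benchmark(ranked, system.gold)
                roc_auc, pr_auc = result.roc_auc, result.pr_auc
            except ValueError as exc:
                logger.warning(
                    "benchmark unavailable (mode=%s fraction=%s rep=%d): %s",
                    mode, fraction, rep, exc,
                )
                roc_auc = pr_auc = float("nan")
            rows.append({
                "experiment": mode,
                "fraction": float(fraction),
                "replicate": rep,
                "seed": ga_seed_cal,
                "mean_fitness": calibrated.mean_fitness,
                "roc_auc": roc_auc,
                "pr_auc": pr_auc,
            })
    return pd.DataFrame(rows)
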