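"""Drug-perturbation simulation, growth read-out and Bliss-style synergy.

A drug clamps its target node(s) to 0 (inhibitor) or 1 (activator); the
perturbed model's stable states are enumerated and the global output
"growth" is the weighted sum of output-node states, scaled affinely to
[0, 1] between the theoretical minimum and maximum of the weighted sum,
averaged over the model's stable states and then over the ensemble.

Synergy follows the Bliss-independence decomposition E(a,b) = A(a,b) +
S(a,b) on the growth scale: the expected pair response A is the product
growth(a) * growth(b), and a pair whose observed growth falls short of it
(S < 0) is called synergistic.  Scores are normalized against a baseline
ensemble calibrated to random-yet-proliferative profiles via the
exponential fold change exp(S_calibrated - S_baseline); values below 1
lean synergistic, and ranking for benchmarking is ascending.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .attractors import fixed_points
from .logic import BooleanModel, LogicEquation
from .network import CalibrationProfile, DrugPanel, OutputSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Perturbation:
    """A single drug or an unordered pair of distinct drugs."""

    drugs: frozenset[str]

    def __init__(self, drugs) -> None:
        ds = frozenset(drugs)
        if len(ds) not in (1, 2):
            raise ValueError("perturbation must name 1 or 2 distinct drugs")
        object.__setattr__(self, "drugs", ds)

    @property
    def name(self) -> str:
        return "+".join(sorted(self.drugs))

    def __iter__(self):
        return iter(sorted(self.drugs))


@dataclass(frozen=True)
class ResponseEntry:
    """Ensemble-averaged scaled growth under one perturbation."""

    growth: float | None
    models_used: int
    models_excluded: int


@dataclass(frozen=True)
class SynergyRecord:
    """Bliss decomposition for one drug pair; E = A + S exactly."""

    pair: tuple[str, str]
    observed: float | None  # E(a,b)
    expected: float | None  # A(a,b) = growth(a) * growth(b)
    excess: float | None    # S(a,b) = E - A
    normalized: float | None = None
    available: bool = True

    @property
    def call(self) -> str:
        if not self.available:
            return "not-available"
        if self.excess < 0:
            return "synergy"
        if self.excess > 0:
            return "antagonism"
        return "none"


def apply_perturbation(
    model: BooleanModel, pert: Perturbation, panel: DrugPanel
) -> BooleanModel:
    """Clamp every targeted node to the drug's fixed value; value semantics."""
    clamp: dict[str, int] = {}
    nodes = set(model.nodes)
    for drug in pert:
        if drug not in panel.entries:
            raise KeyError(f"drug {drug!r} not in panel")
        value = panel.fixed_value_of(drug)
        for target in panel.targets_of(drug):
            if target not in nodes:
                raise KeyError(
                    f"drug {drug!r} targets node {target!r} absent from model"
                )
            clamp[target] = value
    eqs = tuple(
        LogicEquation(eq.target, fixed_value=clamp[eq.target])
        if eq.target in clamp else eq
        for eq in model.equations
    )
    return replace(model, equations=eqs, provenance=f"{pert.name} applied")


def model_growth(model: BooleanModel, outputs: OutputSpec) -> float | None:
    """Scaled global output averaged over stable states; None without any."""
    for node in outputs.weights:
        if node not in model.node_index:
            raise KeyError(f"output node {node!r} absent from model")
    attrs = fixed_points(model)
    if attrs.n == 0:
        return None
    lo, hi = outputs.theoretical_min, outputs.theoretical_max
    index = model.node_index
    scaled = []
    for fp in attrs.fixed_points:
        raw = sum(w * fp[index[v]] for v, w in outputs.weights.items())
        scaled.append((raw - lo) / (hi - lo))
    return float(np.mean(scaled))


def ensemble_growth(
    models: Sequence[BooleanModel],
    pert: Perturbation,
    panel: DrugPanel,
    outputs: OutputSpec,
) -> ResponseEntry:
    """Mean growth over models that retain a stable state under the drug(s).

    Models whose perturbed version has no fixed point are excluded from the
    mean (growth is undefined without an attractor) and counted.
    """
    if not models:
        raise ValueError("ensemble must be non-empty")
    growths = []
    excluded = 0
    for model in models:
        g = model_growth(apply_perturbation(model, pert, panel), outputs)
        if g is None:
            excluded += 1
        else:
            growths.append(g)
    if not growths:
        logger.warning("all %d models excluded under %s", len(models), pert.name)
        return ResponseEntry(None, 0, excluded)
    return ResponseEntry(float(np.mean(growths)), len(growths), excluded)


def simulate_ensemble(
    models: Sequence[BooleanModel],
    perturbations: Sequence[Perturbation],
    panel: DrugPanel,
    outputs: OutputSpec,
) -> dict[str, ResponseEntry]:
    """Responses for every perturbation, keyed by canonical name."""
    return {
        p.name: ensemble_growth(models, p, panel, outputs) for p in perturbations
    }


def score_synergy(
    g_a: float | None, g_b: float | None, g_ab: float | None,
    pair: tuple[str, str],
) -> SynergyRecord:
    """Bliss decomposition of one pair from its three growth values."""
    a, b = sorted(pair)
    if g_a is None or g_b is None or g_ab is None:
        return SynergyRecord((a, b), None, None, None, available=False)
    for g in (g_a, g_b, g_ab):
        if not (0.0 <= g <= 1.0):
            raise ValueError("growth values must lie in [0, 1]")
    expected = g_a * g_b
    excess = g_ab - expected
    # store observed as expected + excess so E = A + S holds bit-exactly
    return SynergyRecord((a, b), expected + excess, expected, excess)


def score_all_pairs(
    responses: Mapping[str, ResponseEntry],
    perturbations: Sequence[Perturbation],
) -> dict[tuple[str, str], SynergyRecord]:
    """Score every pair perturbation from an ensemble response table."""
    records = {}
    for pert in perturbations:
        drugs = sorted(pert.drugs)
        if len(drugs) != 2:
            continue
        a, b = drugs
        def g(name: str) -> float | None:
            entry = responses.get(name)
            return entry.growth if entry is not None else None
        records[(a, b)] = score_synergy(
            g(Perturbation([a]).name), g(Perturbation([b]).name),
            g(pert.name), (a, b),
        )
    return records


def normalize(
    calibrated: Mapping[tuple[str, str], SynergyRecord],
    baseline: Mapping[tuple[str, str], SynergyRecord],
) -> dict[tuple[str, str], SynergyRecord]:
    """Exponential fold change exp(S_calibrated - S_baseline) per pair.

    Pairs lacking either score are excluded from the result (and hence from
    any ranking) with a log message.
    """
    out = {}
    for pair, rec in calibrated.items():
        base = baseline.get(pair)
        if not rec.available or base is None or not base.available:
            logger.info("pair %s excluded from normalization", pair)
            continue
        out[pair] = replace(rec, normalized=math.exp(rec.excess - base.excess))
    return out


def sample_proliferative_profile(
    outputs: OutputSpec, rng: np.random.Generator
) -> CalibrationProfile:
    """Random proliferative phenotype: anti-survival outputs all inactive,
    pro-survival outputs random with at least one active; everything else
    unspecified."""
    neg = outputs.negative_nodes
    pos = outputs.positive_nodes
    while True:
        bits = rng.integers(0, 2, size=len(pos))
        if bits.any():
            break
    assignments: dict[str, object] = {v: 0 for v in neg}
    assignments.update({v: int(b) for v, b in zip(pos, bits)})
    return CalibrationProfile(assignments)


def all_perturbations(panel: DrugPanel) -> list[Perturbation]:
    """Every single drug and every unordered pair from a panel."""
    drugs = sorted(panel.entries)
    perts = [Perturbation([d]) for d in drugs]
    perts.extend(
        Perturbation([a, b])
        for i, a in enumerate(drugs) for b in drugs[i + 1:]
    )
    return perts
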