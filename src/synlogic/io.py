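"""Readers and writers for every file the pipeline touches.

Dialects:

* ``network.sif`` — tab-separated ``source<TAB>relation<TAB>target``
  (Cytoscape column order), relation ``->``/``activate(s)`` or
  ``-|``/``inhibit(s)``; ``#`` starts a comment.
* ``steadystate.tab`` — ``node<TAB>value`` with value 0, 1 or ``-``.
* ``drugpanel.tab`` — ``drug<TAB>effect<TAB>target1<TAB>target2...`` with
  effect ``inhibits`` (fix targets to 0) or ``activates`` (fix to 1).
* ``perturbations.tab`` — one perturbation per line: ``drugA`` or
  ``drugA<TAB>drugB``.
* ``modeloutputs.tab`` — ``node<TAB>signed real weight``.
* trained models — ``*.bnm`` text, one equation per line in the shared
  equation dialect, with optional ``# fitness:`` / ``# seed:`` headers.

All readers reject malformed rows (naming the line) rather than silently
repairing them.  Tabular outputs are TSV with a header row.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

from .logic import BooleanModel, EquationError, LogicEquation
from .network import (
    ACTIVATION,
    INHIBITION,
    UNSPECIFIED,
    CalibrationProfile,
    DrugPanel,
    NetworkError,
    OutputSpec,
    PriorKnowledgeNetwork,
    SignedInteraction,
    build_network,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


_RELATIONS = {
    "->": ACTIVATION,
    "activate": ACTIVATION,
    "activates": ACTIVATION,
    "-|": INHIBITION,
    "inhibit": INHIBITION,
    "inhibits": INHIBITION,
}


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if line.strip():
            yield lineno, line


def read_sif(path: str | Path, *, auto_self_regulate: bool = False
             ) -> PriorKnowledgeNetwork:
    """Read a signed, directed interaction network from SIF text."""
    path = Path(path)
    interactions = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
            )
        source, relation, target = (f.strip() for f in fields)
        sign = _RELATIONS.get(relation.lower())
        if sign is None:
            raise ParseError(
                f"{path}:{lineno}: unknown relation token {relation!r}"
            )
        interactions.append(SignedInteraction(source, target, sign))
    if not interactions:
        raise ParseError(f"{path}: empty network file")
    return build_network(interactions, auto_self_regulate=auto_self_regulate)


def write_sif(network: PriorKnowledgeNetwork, path: str | Path) -> None:
    lines = []
    for ia in network.interactions:
        rel = "->" if ia.sign == ACTIVATION else "-|"
        lines.append(f"{ia.source}\t{rel}\t{ia.target}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_calibration(path: str | Path, network: PriorKnowledgeNetwork
                     ) -> CalibrationProfile:
    """Read a partial steady-state observation (node -> 0/1/-)."""
    path = Path(path)
    node_set = set(network.nodes)
    assignments: dict[str, object] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 'node<TAB>value'")
        node, value = fields[0].strip(), fields[1].strip()
        if node not in node_set:
            raise ParseError(f"{path}:{lineno}: unknown node {node!r}")
        if value == UNSPECIFIED:
            assignments[node] = UNSPECIFIED
        elif value in ("0", "1"):
            assignments[node] = int(value)
        else:
            raise ParseError(
                f"{path}:{lineno}: value must be 0, 1 or '-', got {value!r}"
            )
    profile = CalibrationProfile(assignments)
    if profile.m < 1:
        raise ParseError(f"{path}: m >= 1 required (no specified 0/1 entries)")
    return profile


def write_calibration(profile: CalibrationProfile, path: str | Path) -> None:
    lines = [f"{node}\t{value}" for node, value in profile.assignments.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_drug_panel(path: str | Path) -> DrugPanel:
    path = Path(path)
    entries: dict[str, tuple[str, tuple[str, ...]]] = {}
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: expected 'drug<TAB>effect<TAB>target...'"
            )
        drug, effect, targets = fields[0], fields[1], tuple(fields[2:])
        if drug in entries:
            raise ParseError(f"{path}:{lineno}: duplicate drug {drug!r}")
        try:
            entries[drug] = (effect, targets)
            DrugPanel({drug: (effect, targets)})
        except NetworkError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not entries:
        raise ParseError(f"{path}: empty drug panel")
    return DrugPanel(entries)


def write_drug_panel(panel: DrugPanel, path: str | Path) -> None:
    lines = [
        "\t".join([drug, effect, *targets])
        for drug, (effect, targets) in panel.entries.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_perturbations(path: str | Path) -> list[tuple[str, ...]]:
    """One perturbation per line: a single drug or a tab-separated pair."""
    path = Path(path)
    perts = []
    for lineno, line in _data_lines(path):
        drugs = tuple(f.strip() for f in line.split("\t") if f.strip())
        if len(drugs) not in (1, 2):
            raise ParseError(f"{path}:{lineno}: expected 1 or 2 drug names")
        if len(drugs) == 2 and drugs[0] == drugs[1]:
            raise ParseError(f"{path}:{lineno}: pair members must be distinct")
        perts.append(drugs)
    if not perts:
        raise ParseError(f"{path}: empty perturbation list")
    return perts


def write_perturbations(perts: Sequence[tuple[str, ...]], path: str | Path) -> None:
    Path(path).write_text("\n".join("\t".join(p) for p in perts) + "\n")


def read_output_spec(path: str | Path) -> OutputSpec:
    path = Path(path)
    weights: dict[str, float] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 'node<TAB>weight'")
        node = fields[0].strip()
        try:
            weight = float(fields[1])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: weight must be a real number"
            ) from None
        if node in weights:
            raise ParseError(f"{path}:{lineno}: duplicate output node {node!r}")
        weights[node] = weight
    try:
        return OutputSpec(weights)
    except NetworkError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_output_spec(outputs: OutputSpec, path: str | Path) -> None:
    lines = [f"{node}\t{weight:g}" for node, weight in outputs.weights.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gold_standard(path: str | Path):
    """Read pair labels: ``drugA<TAB>drugB<TAB>0|1`` (1 = observed synergy)."""
    from .evaluation import GoldStandard

    path = Path(path)
    labels: dict[tuple[str, str], bool] = {}
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 3 or fields[2] not in ("0", "1"):
            raise ParseError(
                f"{path}:{lineno}: expected 'drugA<TAB>drugB<TAB>0|1'"
            )
        a, b = sorted(fields[:2])
        if a == b:
            raise ParseError(f"{path}:{lineno}: pair members must be distinct")
        labels[(a, b)] = fields[2] == "1"
    if not labels:
        raise ParseError(f"{path}: empty gold standard")
    return GoldStandard(labels)


def write_gold_standard(gold, path: str | Path) -> None:
    lines = [
        f"{a}\t{b}\t{int(bool(v))}"
        for (a, b), v in sorted(gold.labels.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# --- trained-model persistence (*.bnm) -----------------------------------


def write_model(model: BooleanModel, path: str | Path, *, seed: int | None = None
                ) -> None:
    lines = []
    if model.fitness is not None:
        lines.append(f"# fitness: {model.fitness!r}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines.extend(eq.to_text() for eq in model.equations)
    Path(path).write_text("\n".join(lines) + "\n")


def read_model(path: str | Path) -> BooleanModel:
    path = Path(path)
    fitness: float | None = None
    equations = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("fitness:"):
                fitness = float(body.split(":", 1)[1])
            continue
        try:
            equations.append(LogicEquation.from_text(line))
        except EquationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not equations:
        raise ParseError(f"{path}: no equations")
    model = BooleanModel(tuple(equations), provenance=f"read from {path.name}")
    return model if fitness is None else model.with_fitness(fitness)


def write_ensemble(models: Sequence[BooleanModel], directory: str | Path,
                   *, seed: int | None = None) -> list[Path]:
    """Write one ``model_<i>.bnm`` per model; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(models))))
    paths = []
    for i, model in enumerate(models):
        p = directory / f"model_{i:0{width}d}.bnm"
        write_model(model, p, seed=seed)
        paths.append(p)
    return paths


def read_ensemble(directory: str | Path) -> list[BooleanModel]:
    directory = Path(directory)
    paths = sorted(directory.glob("*.bnm"))
    if not paths:
        raise ParseError(f"{directory}: no *.bnm model files")
    return [read_model(p) for p in paths]
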