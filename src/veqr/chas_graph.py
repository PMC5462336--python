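"""Module dependency graph and grade-gated biomarker eligibility.

A multi-organ analysis pipeline labels regions in a divide-and-conquer
order: robust modules (image quality, airway) run first and later modules
build on the regions they establish (lungs from the airway, cardiac
structures from lungs and bone, breast from the sternum).  When a module's
input region is graded below the minimum it needs, the module -- and
everything downstream of it -- must not run: a failed lung segmentation
blocks nodule analysis rather than silently producing wrong biomarkers.

Quantitative biomarkers are gated the same way: each biomarker names the
graded regions it needs and the minimum grade per region (acceptable by
default; whole-lung measures such as the emphysema index require good).
The shipped graph and biomarker table are editable JSON documents, not
code, because the label inventory grows as new algorithms are added.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .label_store import Grade

__all__ = [
    "ModuleNode",
    "BiomarkerSpec",
    "execution_order",
    "blocked_modules",
    "evaluable_biomarkers",
    "load_chas_graph",
    "load_biomarkers",
    "GraphCycleError",
]


class GraphCycleError(ValueError):
    """The module graph contains a dependency cycle."""


@dataclass(frozen=True)
class ModuleNode:
    """One pipeline module: what it produces and what it needs.

    ``depends`` maps each prerequisite module name to the minimum grade its
    produced regions must hold for this module to run.
    """

    name: str
    produces: tuple[str, ...] = ()
    depends: Mapping[str, Grade] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "produces", tuple(self.produces))
        object.__setattr__(
            self,
            "depends",
            {d: Grade.parse(g) for d, g in dict(self.depends).items()},
        )


@dataclass(frozen=True)
class BiomarkerSpec:
    """A quantitative biomarker and the region grades it requires."""

    name: str
    requires: Mapping[str, Grade] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "requires",
            {r: Grade.parse(g) for r, g in dict(self.requires).items()},
        )


def execution_order(graph: Sequence[ModuleNode]) -> list[str]:
    """Deterministic topological order (lexicographic among ready modules).

    Raises :class:`GraphCycleError` naming the offending modules when the
    graph is cyclic, and ``ValueError`` when a dependency names a module
    that does not exist.
    """
    nodes = {n.name: n for n in graph}
    for n in graph:
        for dep in n.depends:
            if dep not in nodes:
                raise ValueError(
                    f"module {n.name!r} depends on unknown module {dep!r}"
                )
    indeg = {name: len(n.depends) for name, n in nodes.items()}
    dependents: dict[str, list[str]] = {name: [] for name in nodes}
    for n in graph:
        for dep in n.depends:
            dependents[dep].append(n.name)
    ready = [name for name, d in indeg.items() if d == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        name = heapq.heappop(ready)
        order.append(name)
        for child in dependents[name]:
            indeg[child] -= 1
            if indeg[child] == 0:
                heapq.heappush(ready, child)
    if len(order) != len(nodes):
        cycle = sorted(name for name, d in indeg.items() if d > 0)
        raise GraphCycleError(f"dependency cycle among modules: {cycle}")
    return order


def blocked_modules(
    graph: Sequence[ModuleNode], assessments: Mapping[str, Grade | str]
) -> set[str]:
    """Modules that must not run given the current region grades.

    A module is directly blocked when any prerequisite produced a region
    whose grade falls below that prerequisite's minimum-input grade;
    blocking propagates transitively to all dependents.  Regions without a
    grade do not block (absence of evidence is not failure evidence).
    """
    nodes = {n.name: n for n in graph}
    grades = {r: Grade.parse(g) for r, g in assessments.items()}
    blocked: set[str] = set()
    for n in graph:
        for dep, min_grade in n.depends.items():
            for region in nodes[dep].produces:
                g = grades.get(region)
                if g is not None and g < min_grade:
                    blocked.add(n.name)
    # transitive closure over dependents
    changed = True
    while changed:
        changed = False
        for n in graph:
            if n.name not in blocked and any(d in blocked for d in n.depends):
                blocked.add(n.name)
                changed = True
    return blocked


def evaluable_biomarkers(
    specs: Sequence[BiomarkerSpec], assessments: Mapping[str, Grade | str]
) -> set[str]:
    """Biomarkers whose every required region meets its minimum grade."""
    grades = {r: Grade.parse(g) for r, g in assessments.items()}
    out: set[str] = set()
    for spec in specs:
        if all(
            region in grades and grades[region] >= min_grade
            for region, min_grade in spec.requires.items()
        ):
            out.add(spec.name)
    return out


# ---------------------------------------------------------------------------
# Shipped configuration (editable JSON documents)
# ---------------------------------------------------------------------------


def load_chas_graph(path: str | Path | None = None) -> list[ModuleNode]:
    """Load the shipped (or a user-supplied) chest-analysis module graph."""
    if path is None:
        with resources.files("veqr.data").joinpath("chas_graph.json").open() as fh:
            doc = json.load(fh)
    else:
        doc = json.loads(Path(path).read_text())
    return [
        ModuleNode(
            name=m["name"],
            produces=tuple(m.get("produces", ())),
            depends=m.get("depends", {}),
        )
        for m in doc["modules"]
    ]


def load_biomarkers(path: str | Path | None = None) -> list[BiomarkerSpec]:
    """Load the shipped (or a user-supplied) biomarker dependency table."""
    if path is None:
        with resources.files("veqr.data").joinpath("biomarkers.json").open() as fh:
            doc = json.load(fh)
    else:
        doc = json.loads(Path(path).read_text())
    return [
        BiomarkerSpec(name=b["name"], requires=b.get("requires", {}))
        for b in doc["biomarkers"]
    ]
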