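"""Three-level explanation ontology and upward label/probability remapping.

The ontology is a forest rooted at the Gleason patterns (GP3, GP4, GP5).
Each pattern owns a set of *explanations* (broad histological criteria such
as "poorly formed glands"), each explanation a set of *sub-explanations*
(the finest annotation granularity).  A ``benign`` class exists at every
level and is always the last channel of the class index.

Upward remapping is the concept-bottleneck mechanism: a model that predicts
a per-pixel distribution over explanations yields a Gleason-pattern
distribution by *summing* the probabilities of each pattern's descendant
explanations, so the pattern decision is derived solely from interpretable
concepts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

IGNORE_LABEL = 255
"""Reserved integer marking pixels without a valid label (8-bit palette max)."""

_PATTERN_IDS = ("GP3", "GP4", "GP5")


class Level(str, enum.Enum):
    """Granularity levels, ordered fine → coarse (benign sits outside)."""

    SUB_EXPLANATION = "sub_explanation"
    EXPLANATION = "explanation"
    PATTERN = "pattern"
    BENIGN = "benign"

    @property
    def rank(self) -> int:
        return {"sub_explanation": 0, "explanation": 1, "pattern": 2, "benign": 3}[self.value]


#: The three class-index levels, fine to coarse.
CLASS_LEVELS = (Level.SUB_EXPLANATION, Level.EXPLANATION, Level.PATTERN)


class OntologyError(ValueError):
    """Raised when an ontology file violates the structural invariants."""


@dataclass(frozen=True)
class OntologyNode:
    term_id: str
    level: Level
    short_name: str
    long_text: str
    parent_id: str | None = None
    color: tuple[int, int, int] = (128, 128, 128)


@dataclass
class ExplanationOntology:
    """Validated ontology with deterministic class indexing.

    ``class_index(level)`` orders classes as: patterns ascending
    (GP3 < GP4 < GP5), children of each parent in file order, benign last.
    The ordering is a pure function of the node list, so serialized channel
    semantics are stable across loads of the same file.
    """

    nodes: dict[str, OntologyNode]
    _file_order: dict[str, int] = field(default_factory=dict, repr=False)
    _index_cache: dict[Level, tuple[str, ...]] = field(default_factory=dict, repr=False)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_nodes(cls, nodes: Iterable[OntologyNode]) -> "ExplanationOntology":
        node_list = list(nodes)
        seen: dict[str, OntologyNode] = {}
        dupes = [n.term_id for n in node_list if n.term_id in seen or seen.setdefault(n.term_id, n) is None]
        if dupes:
            raise OntologyError(f"duplicate term_ids: {sorted(set(dupes))}")
        onto = cls(nodes=seen, _file_order={n.term_id: i for i, n in enumerate(node_list)})
        onto._validate()
        return onto

    def _validate(self) -> None:
        offenders: list[str] = []
        if "benign" not in self.nodes or self.nodes["benign"].level is not Level.BENIGN:
            raise OntologyError("ontology must contain a 'benign' node with level 'benign'")
        for n in self.nodes.values():
            if n.level is Level.PATTERN:
                if n.term_id not in _PATTERN_IDS:
                    offenders.append(f"pattern node {n.term_id!r} not in {_PATTERN_IDS}")
                if n.parent_id is not None:
                    offenders.append(f"pattern node {n.term_id!r} has a parent")
            elif n.level is Level.BENIGN:
                if n.parent_id is not None:
                    offenders.append(f"benign node {n.term_id!r} has a parent")
            else:
                want = Level.PATTERN if n.level is Level.EXPLANATION else Level.EXPLANATION
                parent = self.nodes.get(n.parent_id) if n.parent_id else None
                if parent is None:
                    offenders.append(f"orphan node {n.term_id!r} (parent {n.parent_id!r} missing)")
                elif parent.level is not want:
                    offenders.append(
                        f"node {n.term_id!r} ({n.level.value}) has parent of level {parent.level.value}"
                    )
        # cycle check (cannot normally occur with strict parent levels, but
        # guards hand-built node sets)
        for n in self.nodes.values():
            seen_ids = set()
            cur: OntologyNode | None = n
            while cur is not None and cur.parent_id is not None:
                if cur.term_id in seen_ids:
                    offenders.append(f"cycle through {n.term_id!r}")
                    break
                seen_ids.add(cur.term_id)
                cur = self.nodes.get(cur.parent_id)
        if offenders:
            raise OntologyError("invalid ontology: " + "; ".join(sorted(offenders)))

    # -- indexing --------------------------------------------------------
    def class_index(self, level: Level | str) -> tuple[str, ...]:
        level = Level(level)
        if level not in self._index_cache:
            if level is Level.BENIGN:
                raise OntologyError("benign is not an indexing level")
            patterns = sorted(
                (n.term_id for n in self.nodes.values() if n.level is Level.PATTERN),
                key=_PATTERN_IDS.index,
            )
            if level is Level.PATTERN:
                ordered = list(patterns)
            else:
                ordered = []
                for pat in patterns:
                    for exp in self._children(pat):
                        if level is Level.EXPLANATION:
                            ordered.append(exp)
                        else:
                            ordered.extend(self._children(exp))
            self._index_cache[level] = tuple(ordered) + ("benign",)
        return self._index_cache[level]

    def _children(self, term_id: str) -> list[str]:
        kids = [n.term_id for n in self.nodes.values() if n.parent_id == term_id]
        return sorted(kids, key=self._file_order.__getitem__)

    def n_classes(self, level: Level | str) -> int:
        return len(self.class_index(level))

    def index_of(self, term_id: str, level: Level | str) -> int:
        return self.class_index(level).index(term_id)

    def palette(self, level: Level | str) -> np.ndarray:
        """(C, 3) uint8 display colors in class-index order."""
        return np.array([self.nodes[t].color for t in self.class_index(level)], dtype=np.uint8)

    def short_names(self, level: Level | str) -> tuple[str, ...]:
        return tuple(self.nodes[t].short_name for t in self.class_index(level))

    def subset(self, terms: Iterable[str]) -> "ExplanationOntology":
        """Restrict the ontology to ``terms`` plus their ancestors and benign.

        Useful for cohorts that exercise only part of the class tree: class
        indices then cover exactly the classes in play.  Relative file order
        of the kept nodes is preserved, so indexing stays deterministic.
        """
        keep: set[str] = {"benign"}
        for t in terms:
            if t not in self.nodes:
                raise OntologyError(f"unknown term_id {t!r}")
            node = self.nodes[t]
            keep.add(t)
            while node.parent_id is not None:
                keep.add(node.parent_id)
                node = self.nodes[node.parent_id]
        kept = sorted(keep, key=self._file_order.__getitem__)
        return ExplanationOntology.from_nodes(self.nodes[t] for t in kept)

    # -- remapping -------------------------------------------------------
    def ancestor_at_level(self, term_id: str, level: Level | str) -> str:
        """Unique ancestor of ``term_id`` at ``level``; benign maps to benign."""
        level = Level(level)
        if term_id not in self.nodes:
            raise OntologyError(f"unknown term_id {term_id!r}")
        node = self.nodes[term_id]
        if node.level is Level.BENIGN:
            return "benign"
        if level is Level.BENIGN:
            raise OntologyError("cannot remap a tumor term to the benign level")
        if level.rank < node.level.rank:
            raise OntologyError(
                f"cannot map {term_id!r} ({node.level.value}) down to {level.value}"
            )
        while node.level is not level:
            node = self.nodes[node.parent_id]  # type: ignore[index]
        return node.term_id

    def remap_lookup(self, from_level: Level | str, to_level: Level | str) -> np.ndarray:
        """Integer lookup: class index at ``from_level`` → index at ``to_level``."""
        src = self.class_index(from_level)
        dst = self.class_index(to_level)
        return np.array(
            [dst.index(self.ancestor_at_level(t, to_level)) for t in src], dtype=np.int64
        )

    def remap_matrix(self, from_level: Level | str, to_level: Level | str) -> np.ndarray:
        """(C_from, C_to) 0/1 child-sum matrix for distribution remapping."""
        lut = self.remap_lookup(from_level, to_level)
        mat = np.zeros((len(lut), self.n_classes(to_level)), dtype=np.float64)
        mat[np.arange(len(lut)), lut] = 1.0
        return mat

    def remap_soft(
        self, dist: np.ndarray, from_level: Level | str, to_level: Level | str
    ) -> np.ndarray:
        """Sum descendant channels upward; per-pixel mass is conserved exactly.

        ``dist`` has channels last and must match ``class_index(from_level)``.
        """
        from_level, to_level = Level(from_level), Level(to_level)
        if dist.shape[-1] != self.n_classes(from_level):
            raise OntologyError(
                f"distribution has {dist.shape[-1]} channels, "
                f"class_index[{from_level.value}] has {self.n_classes(from_level)}"
            )
        if from_level is to_level:
            return dist.copy()
        if Level(to_level).rank < Level(from_level).rank:
            raise OntologyError("remap_soft only maps upward in the ontology")
        return dist @ self.remap_matrix(from_level, to_level)

    def remap_hard(
        self,
        labels: np.ndarray,
        from_level: Level | str,
        to_level: Level | str,
        ignore: int = IGNORE_LABEL,
    ) -> np.ndarray:
        """Replace each integer label by its ancestor's index; ignore stays ignore."""
        from_level, to_level = Level(from_level), Level(to_level)
        valid = labels != ignore
        if valid.any():
            bad = np.unique(labels[valid & (labels >= self.n_classes(from_level))])
            if bad.size:
                raise OntologyError(f"labels {bad.tolist()} out of range at {from_level.value}")
        lut = self.remap_lookup(from_level, to_level)
        out = np.full_like(labels, ignore)
        out[valid] = lut[labels[valid]]
        return out


def _parse_node(raw: Mapping, idx: int) -> OntologyNode:
    try:
        level = Level(raw["level"])
    except (KeyError, ValueError) as exc:
        raise OntologyError(f"node #{idx}: unknown or missing level {raw.get('level')!r}") from exc
    if "term_id" not in raw:
        raise OntologyError(f"node #{idx}: missing term_id")
    color = tuple(int(c) for c in raw.get("color", (128, 128, 128)))
    return OntologyNode(
        term_id=str(raw["term_id"]),
        level=level,
        short_name=str(raw.get("short_name", raw["term_id"])),
        long_text=str(raw.get("long_text", "")),
        parent_id=raw.get("parent"),
        color=color,  # type: ignore[arg-type]
    )


def load_ontology(path) -> ExplanationOntology:
    """Load and validate an ontology from a YAML file (see shipped instance)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "nodes" not in doc:
        raise OntologyError("ontology file must contain a top-level 'nodes' list")
    nodes = [_parse_node(raw, i) for i, raw in enumerate(doc["nodes"])]
    return ExplanationOntology.from_nodes(nodes)


def default_ontology() -> ExplanationOntology:
    """The shipped canonical ontology: 3 patterns, 9 explanations (+benign)."""
    ref = resources.files("softgleason").joinpath("data/ontology_synthetic.yaml")
    with resources.as_file(ref) as path:
        return load_ontology(path)
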