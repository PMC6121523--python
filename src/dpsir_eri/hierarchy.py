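"""DPSIR indicator hierarchies.

An indicator system is a forest of small trees rooted at the five DPSIR
indices (Driving forces, Pressure, State, Impacts, Response), conventionally
coded A1..A5.  Indicators below the index layer are coded B, C, D and E, one
letter per layer, and the tree may be ragged: a C-factor can be a leaf or
carry D-subordinates, a D-node can carry E-subordinates.  Every leaf is
tagged with a polarity — ``positive`` if growth of the raw series raises
risk, ``negative`` if growth lowers it (typical for response-side
indicators).

Hierarchies are read from and written to YAML/JSON documents with one record
per node (keys ``id``, ``label``, ``parent``, ``polarity``).  The packaged
default is the municipal-solid-waste system for Dar es Salaam with layer
sizes (5, 18, 61, 14, 2).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "IndicatorNode",
    "Hierarchy",
    "Violation",
    "HierarchyError",
    "load_hierarchy",
    "validate_hierarchy",
    "default_hierarchy",
]

LAYERS = "ABCDE"
_ID_RE = re.compile(r"^([A-E])([1-9][0-9]*)$")

POSITIVE = "positive"
NEGATIVE = "negative"


class HierarchyError(ValueError):
    """Raised when a hierarchy document cannot be loaded as a valid tree.

    Carries the list of :class:`Violation` records that caused the failure.
    """

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        super().__init__(
            "invalid hierarchy: " + "; ".join(str(v) for v in violations)
        )


@dataclass(frozen=True)
class Violation:
    """One structural defect, naming the offending node."""

    code: str  # e.g. "duplicate-id", "layer-order", "missing-parent"
    node_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.node_id}: {self.message}"


@dataclass(frozen=True)
class IndicatorNode:
    """One element of the A–E indicator tree."""

    id: str
    label: str = ""
    parent_id: str | None = None
    polarity: str | None = None

    @property
    def layer(self) -> str:
        return self.id[0] if self.id else "?"


@dataclass
class Hierarchy:
    """An ordered collection of :class:`IndicatorNode`.

    The node list may be structurally invalid (``validate`` reports defects);
    loaders reject invalid documents up front.
    """

    nodes: tuple[IndicatorNode, ...]
    name: str = ""
    _index: dict[str, IndicatorNode] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )
    _children: dict[str, list[str]] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        for node in self.nodes:
            self._index.setdefault(node.id, node)
            if node.parent_id is not None:
                self._children.setdefault(node.parent_id, []).append(node.id)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def __getitem__(self, node_id: str) -> IndicatorNode:
        return self._index[node_id]

    def __len__(self) -> int:
        return len(self.nodes)

    def children(self, node_id: str) -> list[str]:
        return list(self._children.get(node_id, []))

    def is_leaf(self, node_id: str) -> bool:
        return node_id not in self._children

    @property
    def roots(self) -> list[str]:
        return [n.id for n in self.nodes if n.parent_id is None]

    @property
    def leaves(self) -> list[str]:
        return [n.id for n in self.nodes if self.is_leaf(n.id)]

    def subtree_leaves(self, node_id: str) -> list[str]:
        """Leaf ids under ``node_id`` (the node itself if it is a leaf)."""
        if self.is_leaf(node_id):
            return [node_id]
        out: list[str] = []
        for child in self.children(node_id):
            out.extend(self.subtree_leaves(child))
        return out

    def root_of(self, node_id: str) -> str:
        """The A-layer index a node ultimately belongs to."""
        seen = set()
        current = node_id
        while True:
            node = self._index[current]
            if node.parent_id is None:
                return current
            if current in seen:  # cycle guard; validation reports it properly
                raise HierarchyError(
                    [Violation("cycle", node_id, "ancestry contains a cycle")]
                )
            seen.add(current)
            current = node.parent_id

    def layer_counts(self) -> dict[str, int]:
        counts = {layer: 0 for layer in LAYERS}
        for node in self.nodes:
            if node.layer in counts:
                counts[node.layer] += 1
        return counts

    # -- serialization ---------------------------------------------------

    def serialize(self) -> dict:
        """Canonical document form: nodes sorted by layer, then numeric id."""

        def key(node: IndicatorNode):
            m = _ID_RE.match(node.id)
            return (node.layer, int(m.group(2)) if m else 0)

        records = []
        for node in sorted(self.nodes, key=key):
            rec: dict[str, str] = {"id": node.id, "label": node.label}
            if node.parent_id is not None:
                rec["parent"] = node.parent_id
            if node.polarity is not None:
                rec["polarity"] = node.polarity
            records.append(rec)
        return {"name": self.name, "nodes": records}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.serialize(), sort_keys=False, allow_unicode=True)
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.serialize(), indent=2))


def _nodes_from_document(doc: Mapping | Iterable) -> tuple[str, list[IndicatorNode]]:
    if isinstance(doc, Mapping):
        name = str(doc.get("name", ""))
        records = doc.get("nodes", [])
    else:
        name, records = "", list(doc)
    nodes = []
    for rec in records:
        if not isinstance(rec, Mapping) or "id" not in rec:
            raise HierarchyError(
                [Violation("malformed-record", str(rec), "node record needs an 'id'")]
            )
        nodes.append(
            IndicatorNode(
                id=str(rec["id"]),
                label=str(rec.get("label", "")),
                parent_id=(None if rec.get("parent") in (None, "") else str(rec["parent"])),
                polarity=(None if rec.get("polarity") in (None, "") else str(rec["polarity"])),
            )
        )
    return name, nodes


def validate_hierarchy(h: Hierarchy) -> list[Violation]:
    """Check every structural invariant; return violations instead of raising.

    Checks, in order: id syntax, duplicate ids, parent existence, layer order
    (a parent's layer letter must immediately precede the child's), roots
    confined to the A layer, acyclicity, and polarity tagging (required on
    leaves, disallowed on internal nodes).
    """
    violations: list[Violation] = []
    seen: set[str] = set()
    for node in h.nodes:
        m = _ID_RE.match(node.id)
        if not m:
            violations.append(
                Violation("malformed-code", node.id, "expected letter A–E plus integer")
            )
            continue
        if node.id in seen:
            violations.append(Violation("duplicate-id", node.id, "id appears twice"))
            continue
        seen.add(node.id)
        if node.parent_id is None:
            if node.layer != "A":
                violations.append(
                    Violation("orphan", node.id, f"{node.layer}-layer node has no parent")
                )
        else:
            parent = h._index.get(node.parent_id)
            if parent is None:
                violations.append(
                    Violation("missing-parent", node.id, f"parent {node.parent_id} not defined")
                )
            else:
                expected = LAYERS.find(node.layer) - 1
                if expected < 0 or parent.layer != LAYERS[expected]:
                    violations.append(
                        Violation(
                            "layer-order",
                            node.id,
                            f"layer {node.layer} node must hang off a "
                            f"{LAYERS[max(expected, 0)]}-layer parent, got {parent.layer}",
                        )
                    )
        if node.polarity is not None and node.polarity not in (POSITIVE, NEGATIVE):
            violations.append(
                Violation("bad-polarity", node.id, f"polarity {node.polarity!r} unknown")
            )
    # cycle detection over the declared parent links
    valid_ids = {n.id for n in h.nodes}
    for node in h.nodes:
        trail = set()
        current: str | None = node.id
        while current is not None and current in valid_ids:
            if current in trail:
                violations.append(Violation("cycle", node.id, "ancestry contains a cycle"))
                break
            trail.add(current)
            current = h._index[current].parent_id
    # polarity placement needs the child map
    for node in h.nodes:
        if node.id not in valid_ids:
            continue
        if h.is_leaf(node.id):
            if node.polarity is None:
                violations.append(
                    Violation("missing-polarity", node.id, "leaf has no polarity tag")
                )
        elif node.polarity is not None:
            violations.append(
                Violation("polarity-on-internal", node.id, "internal node carries a polarity")
            )
    return violations


def load_hierarchy(source: str | Path | Mapping | Iterable) -> Hierarchy:
    """Load and validate a hierarchy from a YAML/JSON file, text, or mapping.

    Raises :class:`HierarchyError` (listing every violation) if the document
    is structurally invalid.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if isinstance(source, Path) or path.exists():
            text = path.read_text()
        else:
            text = str(source)
        doc = yaml.safe_load(text)  # YAML is a superset of JSON
    else:
        doc = source
    name, nodes = _nodes_from_document(doc)
    h = Hierarchy(nodes=tuple(nodes), name=name)
    violations = validate_hierarchy(h)
    if violations:
        raise HierarchyError(violations)
    return h


def default_hierarchy() -> Hierarchy:
    """The packaged Dar es Salaam municipal-solid-waste indicator system."""
    text = (
        resources.files("dpsir_eri")
        .joinpath("data/dar_es_salaam_msw.yaml")
        .read_text()
    )
    return load_hierarchy(yaml.safe_load(text))
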