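"""Symptom catalog: the ordered 24-node symptom space.

The default catalog covers 12 non-suicidal self-injury (NSSI) behaviour
items (N1-N12), 6 depression items (D1-D6) and 6 anxiety items (A1-A6),
all rated on a 0-4 ordinal frequency/severity scale.  Node order is fixed
and defines row/column indexing of every weight matrix downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import ValidationError

#: community labels
NSSI = "NSSI"
DEP = "DEP"
ANX = "ANX"
COMMUNITIES = (NSSI, DEP, ANX)

# Item labels that are fixed by the questionnaires; the remaining items
# get neutral placeholders and can be overridden via a catalog config.
_KNOWN_LABELS = {
    "N5": "self-hitting",
    "N6": "self-biting",
    "N9": "self-cutting",
    "N11": "rubbing skin",
    "N12": "carving",
    "D1": "indifference",
    "D2": "feeling blue",
    "D4": "loneliness",
    "D6": "worthlessness",
    "A4": "feeling scared",
    "A6": "feeling tension",
}


@dataclass(frozen=True)
class SymptomNode:
    """A single symptom item.

    Parameters
    ----------
    node_id
        Short code, e.g. ``"N9"`` or ``"D2"``.
    label
        Human-readable symptom name.
    community
        One of ``"NSSI"``, ``"DEP"``, ``"ANX"``.
    scale_min, scale_max
        Inclusive ordinal response range (default 0-4).
    """

    node_id: str
    label: str
    community: str
    scale_min: int = 0
    scale_max: int = 4

    def __post_init__(self):
        if self.community not in COMMUNITIES:
            raise ValidationError(
                f"node {self.node_id!r}: community must be one of "
                f"{COMMUNITIES}, got {self.community!r}"
            )
        if not (isinstance(self.scale_min, int) and isinstance(self.scale_max, int)):
            raise ValidationError(f"node {self.node_id!r}: scale bounds must be integers")
        if self.scale_min >= self.scale_max:
            raise ValidationError(
                f"node {self.node_id!r}: scale_min must be < scale_max"
            )


@dataclass(frozen=True)
class SymptomCatalog:
    """Ordered collection of symptom nodes.

    The node order is authoritative: matrices produced by the estimator,
    the simulator and the metrics all index rows/columns in this order.
    """

    nodes: tuple[SymptomNode, ...]

    def __post_init__(self):
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate node_id in catalog")
        if len(ids) == 0:
            raise ValidationError("catalog must contain at least one node")

    # -- basic accessors ---------------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    @property
    def communities(self) -> list[str]:
        return [n.community for n in self.nodes]

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    def index(self, node_id: str) -> int:
        for i, n in enumerate(self.nodes):
            if n.node_id == node_id:
                return i
        raise KeyError(node_id)

    def community_of(self, node_id: str) -> str:
        return self.nodes[self.index(node_id)].community

    def members(self, community: str) -> list[str]:
        return [n.node_id for n in self.nodes if n.community == community]

    # -- serialization -----------------------------------------------------
    def to_records(self) -> list[dict]:
        return [
            {
                "node_id": n.node_id,
                "label": n.label,
                "community": n.community,
                "scale_min": n.scale_min,
                "scale_max": n.scale_max,
            }
            for n in self.nodes
        ]

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "SymptomCatalog":
        nodes = tuple(
            SymptomNode(
                node_id=r["node_id"],
                label=r.get("label", r["node_id"]),
                community=r["community"],
                scale_min=int(r.get("scale_min", 0)),
                scale_max=int(r.get("scale_max", 4)),
            )
            for r in records
        )
        return cls(nodes)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        records = self.to_records()
        if path.suffix.lower() in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(records, sort_keys=False))
        else:
            path.write_text(json.dumps(records, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SymptomCatalog":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yml", ".yaml"):
            records = yaml.safe_load(text)
        else:
            records = json.loads(text)
        return cls.from_records(records)


def _default_nodes() -> tuple[SymptomNode, ...]:
    nodes: list[SymptomNode] = []
    specs: Sequence[tuple[str, int, str]] = [
        ("N", 12, NSSI),
        ("D", 6, DEP),
        ("A", 6, ANX),
    ]
    placeholder = {NSSI: "NSSI item", DEP: "Depression item", ANX: "Anxiety item"}
    for prefix, count, community in specs:
        for k in range(1, count + 1):
            nid = f"{prefix}{k}"
            label = _KNOWN_LABELS.get(nid, f"{placeholder[community]} {k}")
            nodes.append(SymptomNode(nid, label, community))
    return tuple(nodes)


def default_catalog() -> SymptomCatalog:
    """The standard 24-node catalog: N1-N12 (NSSI), D1-D6, A1-A6."""
    return SymptomCatalog(_default_nodes())
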