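"""Cell classes, the Hamming pseudo-metric, the asymmetric d*, and annotation.

A *cell class* is an equivalence class of cells under an arbitrary partition
(a cluster or a supervised label) together with its eigen-cascade set.  Two
structures are compared in two ways:

* ``hamming`` — the symmetric difference of cascade sets, the natural
  pseudo-metric between single-cell GRN structures;
* ``d_star`` — ``1 − |A ∩ B| / |A|``, an asymmetric score that is 0 exactly
  when the centered class's cascades are all contained in the other's.
  Because eigen-cascade sets can be nested, containment (not symmetric
  difference) is the meaningful relation between classes.

``compare`` runs the three annotation modes (inference, labeling,
estimation) and groups compared classes into rings by their d* value —
the data behind a "planet plot".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .cascades import CascadeSet, RestrictionSpec, restrict_induced

__all__ = [
    "CellClass",
    "Partition",
    "ComparisonResult",
    "hamming",
    "d_star",
    "compare",
]

#: d* values are rounded to this many decimals when grouping rings.
RING_DECIMALS = 4


@dataclass(frozen=True)
class CellClass:
    """A named set of cells with the eigen-cascade set characterizing it."""

    class_id: str
    dataset_id: str
    member_cells: frozenset
    eigen: CascadeSet

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_cells", frozenset(self.member_cells))

    @property
    def key(self) -> tuple:
        return (self.dataset_id, self.class_id)


@dataclass(frozen=True)
class Partition:
    """A total assignment of cells to class ids (equivalence classes)."""

    dataset_id: str
    assignment: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))
        if not self.assignment:
            raise ValueError("partition assigns no cells")

    @classmethod
    def from_labels(cls, dataset_id: str, labels) -> "Partition":
        return cls(dataset_id, {str(c): str(l) for c, l in dict(labels).items()})

    def class_ids(self) -> list:
        return sorted(set(self.assignment.values()))

    def members(self, class_id: str) -> frozenset:
        return frozenset(c for c, l in self.assignment.items() if l == class_id)

    def __len__(self) -> int:
        return len(self.assignment)


def hamming(a: CascadeSet, b: CascadeSet) -> int:
    """Symmetric-difference distance |A ∪ B| − |A ∩ B| between structures."""
    if frozenset(a.universe) != frozenset(b.universe):
        raise ValueError("cascade sets live over different universes")
    if a.oriented != b.oriented:
        raise ValueError("cannot mix oriented and unoriented cascade sets")
    return len(a.cascades ^ b.cascades)


def d_star(a: CascadeSet, b: CascadeSet) -> float:
    """Asymmetric class similarity 1 − |A ∩ B| / |A| (0 iff A ⊆ B)."""
    if frozenset(a.universe) != frozenset(b.universe):
        raise ValueError("cascade sets live over different universes")
    if a.oriented != b.oriented:
        raise ValueError("cannot mix oriented and unoriented cascade sets")
    if not a.cascades:
        raise ValueError("undefined denominator: the centered cascade set is empty")
    inter = len(a.cascades & b.cascades)
    return 1.0 - inter / len(a.cascades)


@dataclass(frozen=True)
class ComparisonResult:
    """One centered class with the other classes grouped on d* rings.

    ``rings`` is an ordered list of ``(d*, [class keys])`` with strictly
    increasing values; the innermost ring is the assignment.
    """

    center: tuple
    rings: tuple
    mode: str
    vertex_subset: frozenset | None

    @property
    def assignment(self) -> list:
        """Class keys on the innermost ring (ties all reported)."""
        return list(self.rings[0][1]) if self.rings else []

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "mode": self.mode,
            "vertex_subset": (sorted(self.vertex_subset)
                              if self.vertex_subset is not None else None),
            "rings": [
                {"d_star": value, "classes": [list(k) for k in keys]}
                for value, keys in self.rings
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonResult":
        rings = tuple(
            (ring["d_star"], tuple(tuple(k) for k in ring["classes"]))
            for ring in d["rings"]
        )
        subset = d.get("vertex_subset")
        return cls(tuple(d["center"]), rings, d["mode"],
                   frozenset(subset) if subset is not None else None)

    @classmethod
    def from_json(cls, text: str) -> "ComparisonResult":
        return cls.from_dict(json.loads(text))


def _restricted(cc: CellClass, subset) -> CascadeSet:
    if subset is None:
        return cc.eigen
    kept = frozenset(subset) & frozenset(cc.eigen.universe)
    if not kept:
        raise ValueError(
            f"vertex subset is disjoint from the universe of {cc.key}"
        )
    return restrict_induced(cc.eigen, RestrictionSpec(cc.eigen.universe, kept))


def compare(mode: str, centers, others, vertex_subset=None) -> list:
    """Run one annotation mode and return a ComparisonResult per center.

    * ``inference`` — similarities within one dataset (a center is never
      compared with itself);
    * ``labeling`` — centers are the reference classes, others the query;
    * ``estimation`` — centers are the query classes, others the reference.

    All eigen sets are restricted to ``vertex_subset`` (induced subgraph)
    before computing d*; classes at equal rounded d* share a ring and are
    ordered lexicographically within it.
    """
    if mode not in ("inference", "labeling", "estimation"):
        raise ValueError(f"unknown comparison mode {mode!r}")
    centers = sorted(centers, key=lambda c: c.key)
    others = sorted(others, key=lambda c: c.key)
    subset = frozenset(vertex_subset) if vertex_subset is not None else None
    results = []
    for center in centers:
        a = _restricted(center, subset)
        by_value: dict = {}
        for other in others:
            if mode == "inference" and other.key == center.key:
                continue
            b = _restricted(other, subset)
            value = round(d_star(a, b), RING_DECIMALS)
            by_value.setdefault(value, []).append(other.key)
        rings = tuple(
            (value, tuple(sorted(by_value[value]))) for value in sorted(by_value)
        )
        results.append(ComparisonResult(center.key, rings, mode, subset))
    return results
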