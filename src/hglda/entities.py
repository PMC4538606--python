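"""Entity identifiers and bipartite association sets.

All downstream computation (pair scoring, group similarities, cross
validation) operates on :class:`AssociationSet` objects: deduplicated
bipartite edge sets between two named entity classes (miRNA, lncRNA,
disease, MeSH term) with O(1) neighbor lookup in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

NAMESPACES = ("mirna", "lncrna", "disease", "mesh_term")


def normalize_label(label: str) -> str:
    """Trim, case-fold and collapse internal whitespace.

    Entity labels from different source databases rarely agree on
    capitalisation or spacing; equality is always on the normalized form.
    """
    return " ".join(str(label).strip().casefold().split())


@dataclass(frozen=True, order=True)
class EntityId:
    """A namespaced, normalized entity identifier.

    Two ``EntityId`` objects are equal iff both the namespace and the
    normalized label agree.
    """

    namespace: str
    label: str

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(
                f"unknown namespace {self.namespace!r}; expected one of {NAMESPACES}"
            )
        normalized = normalize_label(self.label)
        if not normalized:
            raise ValueError(f"empty label in namespace {self.namespace!r}")
        object.__setattr__(self, "label", normalized)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.namespace}:{self.label}"


class AssociationSet:
    """A deduplicated bipartite edge set with two-way neighbor lookup.

    Parameters
    ----------
    left_class, right_class
        Entity-class names (namespaces) of the two sides.
    edges
        Iterable of ``(EntityId, EntityId)`` pairs; duplicates collapse.
    provenance
        Free-text source tag carried through transformations.
    """

    def __init__(
        self,
        left_class: str,
        right_class: str,
        edges: Iterable[tuple[EntityId, EntityId]] = (),
        provenance: str = "",
    ) -> None:
        if left_class not in NAMESPACES or right_class not in NAMESPACES:
            raise ValueError(
                f"entity classes must be among {NAMESPACES}, "
                f"got ({left_class!r}, {right_class!r})"
            )
        self.left_class = left_class
        self.right_class = right_class
        self.provenance = provenance
        self._edges: set[tuple[EntityId, EntityId]] = set()
        self._left_neighbors: dict[EntityId, set[EntityId]] = {}
        self._right_neighbors: dict[EntityId, set[EntityId]] = {}
        for left, right in edges:
            self.add(left, right)

    def add(self, left: EntityId, right: EntityId) -> None:
        if left.namespace != self.left_class:
            raise ValueError(
                f"left endpoint {left} does not match class {self.left_class!r}"
            )
        if right.namespace != self.right_class:
            raise ValueError(
                f"right endpoint {right} does not match class {self.right_class!r}"
            )
        edge = (left, right)
        if edge in self._edges:
            return
        self._edges.add(edge)
        self._left_neighbors.setdefault(left, set()).add(right)
        self._right_neighbors.setdefault(right, set()).add(left)

    @property
    def edges(self) -> frozenset[tuple[EntityId, EntityId]]:
        return frozenset(self._edges)

    def left_entities(self) -> set[EntityId]:
        return set(self._left_neighbors)

    def right_entities(self) -> set[EntityId]:
        return set(self._right_neighbors)

    def neighbors_of_left(self, entity: EntityId) -> frozenset[EntityId]:
        """Right-side neighbors of a left-side entity (empty if unknown)."""
        return frozenset(self._left_neighbors.get(entity, ()))

    def neighbors_of_right(self, entity: EntityId) -> frozenset[EntityId]:
        """Left-side neighbors of a right-side entity (empty if unknown)."""
        return frozenset(self._right_neighbors.get(entity, ()))

    def left_groups(self) -> Mapping[EntityId, frozenset[EntityId]]:
        """Map every left entity to its full right-side neighbor set."""
        return {e: frozenset(n) for e, n in self._left_neighbors.items()}

    def right_groups(self) -> Mapping[EntityId, frozenset[EntityId]]:
        return {e: frozenset(n) for e, n in self._right_neighbors.items()}

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, edge: tuple[EntityId, EntityId]) -> bool:
        return edge in self._edges

    def __iter__(self) -> Iterator[tuple[EntityId, EntityId]]:
        return iter(sorted(self._edges))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssociationSet):
            return NotImplemented
        return (
            self.left_class == other.left_class
            and self.right_class == other.right_class
            and self._edges == other._edges
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"AssociationSet({self.left_class}-{self.right_class}, "
            f"{len(self)} edges, provenance={self.provenance!r})"
        )
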