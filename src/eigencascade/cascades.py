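"""Cascade algebra: the set-theoretic core of GRN-structure identity.

A *cascade* is a set of one or two genes with a distinguished *dependent*
gene: ``{x, y}_x`` records that ``x`` depends on ``y``, while the singleton
``{x}_x`` records the mere presence of ``x`` as a vertex.  A cell's possessed
cascades are the image of its pairwise dependency relation under the map
``fc``; the collection doubles as a graph (singletons are vertices, pairs are
edges), so ``|C| = |V| + |E|`` always holds.

Restricting the gene universe from ``G`` to a panel ``F`` can be done two
ways — keeping only cascades fully inside ``F`` (induced subgraph) or pushing
every cascade through the quotient of its tropical semiring by the ideal
generated by the removed genes (see :mod:`eigencascade.tropical`).  The two
agree on complete possessed-cascade sets, which is the formal licence for
ignoring off-panel genes: they behave exactly like exogenous environment
factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

import networkx as nx

__all__ = [
    "Cascade",
    "CascadeSet",
    "RestrictionSpec",
    "cascades_from_dependency",
    "restrict_induced",
    "restrict_quotient",
    "to_undirected",
    "vertexes",
    "edges",
]


def _check_symbol(symbol: str) -> str:
    if not isinstance(symbol, str) or not symbol:
        raise ValueError(f"gene symbol must be a non-empty string, got {symbol!r}")
    return symbol


@dataclass(frozen=True)
class Cascade:
    """A 1–2 gene set with an optional distinguished dependent gene.

    ``dependent is None`` marks an unoriented cascade (after conversion to an
    undirected graph); oriented singletons always have ``dependent`` equal to
    their only member.
    """

    members: frozenset
    dependent: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not 1 <= len(self.members) <= 2:
            raise ValueError(
                f"a cascade has 1 or 2 members, got {sorted(self.members)}"
            )
        for g in self.members:
            _check_symbol(g)
        if self.dependent is not None and self.dependent not in self.members:
            raise ValueError(
                f"dependent {self.dependent!r} not among members {sorted(self.members)}"
            )

    # ---- constructors -------------------------------------------------
    @classmethod
    def singleton(cls, gene: str) -> "Cascade":
        return cls(frozenset([gene]), gene)

    @classmethod
    def pair(cls, dependent: str, other: str) -> "Cascade":
        """``{dependent, other}_dependent``: *dependent* depends on *other*."""
        if dependent == other:
            raise ValueError("pair cascade needs two distinct genes")
        return cls(frozenset([dependent, other]), dependent)

    @classmethod
    def unoriented(cls, members: Iterable[str]) -> "Cascade":
        return cls(frozenset(members), None)

    # ---- structure ----------------------------------------------------
    @property
    def is_vertex(self) -> bool:
        return len(self.members) == 1

    @property
    def is_edge(self) -> bool:
        return len(self.members) == 2

    @property
    def oriented(self) -> bool:
        return self.dependent is not None

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.members)), self.dependent or "")

    def drop_orientation(self) -> "Cascade":
        return Cascade(self.members, None)

    def __repr__(self) -> str:  # {x,y}_x notation
        body = ",".join(sorted(self.members))
        tag = f"_{self.dependent}" if self.dependent is not None else ""
        return f"{{{body}}}{tag}"


@dataclass(frozen=True)
class CascadeSet:
    """A set of cascades over a fixed gene universe.

    ``oriented`` applies to the whole set: oriented sets may contain feedback
    pairs ``{x,y}_x`` and ``{x,y}_y`` simultaneously; unoriented sets hold at
    most one cascade per member set.
    """

    universe: frozenset
    cascades: frozenset = field(default_factory=frozenset)
    oriented: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "universe", frozenset(self.universe))
        object.__setattr__(self, "cascades", frozenset(self.cascades))
        for g in self.universe:
            _check_symbol(g)
        for c in self.cascades:
            if not c.members <= self.universe:
                raise ValueError(f"cascade {c} outside universe")
            if self.oriented and not c.oriented:
                raise ValueError(f"unoriented cascade {c} in an oriented set")
            if not self.oriented and c.oriented:
                raise ValueError(f"oriented cascade {c} in an unoriented set")

    # ---- basic views ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.cascades)

    def __iter__(self) -> Iterator[Cascade]:
        return iter(sorted(self.cascades, key=Cascade.sort_key))

    def __contains__(self, c: Cascade) -> bool:
        return c in self.cascades

    def vertexes(self) -> frozenset:
        return frozenset(c for c in self.cascades if c.is_vertex)

    def edges(self) -> frozenset:
        return frozenset(c for c in self.cascades if c.is_edge)

    # ---- algebraic operations ------------------------------------------
    def restrict_induced(self, kept: Iterable[str]) -> "CascadeSet":
        return restrict_induced(self, RestrictionSpec(self.universe, kept))

    def restrict_quotient(self, kept: Iterable[str]) -> "CascadeSet":
        return restrict_quotient(self, RestrictionSpec(self.universe, kept))

    def to_undirected(self) -> "CascadeSet":
        return to_undirected(self)

    # ---- graph form ----------------------------------------------------
    def to_networkx(self) -> "nx.Graph | nx.DiGraph":
        """Graph form: singletons are nodes, pair cascades are edges.

        Oriented sets map ``{x,y}_x`` to a directed edge ``y -> x`` (the
        regulator points at the dependent gene).
        """
        g: nx.Graph | nx.DiGraph = nx.DiGraph() if self.oriented else nx.Graph()
        for c in self:
            if c.is_vertex:
                g.add_node(next(iter(c.members)))
            elif self.oriented:
                (other,) = c.members - {c.dependent}
                g.add_edge(other, c.dependent)
            else:
                x, y = sorted(c.members)
                g.add_edge(x, y)
        return g

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    # ---- text serialization --------------------------------------------
    def to_text(self) -> str:
        lines = [
            f"# universe: {','.join(sorted(self.universe))}",
            f"# oriented: {str(self.oriented).lower()}",
        ]
        for c in self:
            if self.oriented:
                rest = sorted(c.members - {c.dependent})
                lines.append(f"{c.dependent}\t{rest[0] if rest else '-'}")
            else:
                lines.append("\t".join(sorted(c.members)))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CascadeSet":
        universe: frozenset = frozenset()
        oriented = True
        cascades = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                key = key.strip()
                if key == "universe":
                    universe = frozenset(s for s in val.strip().split(",") if s)
                elif key == "oriented":
                    oriented = val.strip().lower() == "true"
                continue
            fields = line.split("\t")
            if oriented:
                dep, other = fields[0], fields[1]
                if other == "-":
                    cascades.append(Cascade.singleton(dep))
                else:
                    cascades.append(Cascade.pair(dep, other))
            else:
                cascades.append(Cascade.unoriented(fields))
        if not universe:
            universe = frozenset(g for c in cascades for g in c.members)
        return cls(universe, cascades, oriented)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def read(cls, path) -> "CascadeSet":
        with open(path) as fh:
            return cls.from_text(fh.read())


@dataclass(frozen=True)
class RestrictionSpec:
    """A gene-universe restriction ``G -> F``; ``removed`` is ``H = G - F``."""

    universe: frozenset
    kept: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "universe", frozenset(self.universe))
        object.__setattr__(self, "kept", frozenset(self.kept))
        if not self.kept <= self.universe:
            raise ValueError(
                f"kept genes {sorted(self.kept - self.universe)} outside the universe"
            )

    @property
    def removed(self) -> frozenset:
        return self.universe - self.kept


def cascades_from_dependency(
    dep: Callable[[str, str], bool], genes: Iterable[str]
) -> CascadeSet:
    """Possessed cascades of a cell from its pairwise dependency oracle.

    ``dep(x, y)`` answers "is x dependent on y?".  Every gene contributes its
    singleton; each ordered pair of distinct genes with ``dep(x, y)`` true
    contributes the pair cascade ``{x, y}_x``.  The diagonal is forced to
    singletons regardless of the oracle.
    """
    genes = frozenset(genes)
    if not genes:
        raise ValueError("empty universe")
    cascades = [Cascade.singleton(g) for g in genes]
    for x in sorted(genes):
        for y in sorted(genes):
            if x != y and dep(x, y):
                cascades.append(Cascade.pair(x, y))
    return CascadeSet(genes, cascades, oriented=True)


def restrict_induced(cset: CascadeSet, spec: RestrictionSpec) -> CascadeSet:
    """Induced-subgraph restriction: keep cascades with all members in F."""
    if frozenset(cset.universe) != frozenset(spec.universe):
        raise ValueError("restriction spec universe differs from the cascade set's")
    kept = frozenset(c for c in cset.cascades if c.members <= spec.kept)
    return CascadeSet(spec.kept, kept, cset.oriented)


def restrict_quotient(cset: CascadeSet, spec: RestrictionSpec) -> CascadeSet:
    """Quotient restriction: push each cascade through its semiring quotient.

    Per cascade with dependent gene g: if g is removed the whole carrier
    collapses onto the class of the environment element and the cascade
    vanishes; if g is kept, removed members fall into the ideal's fiber and
    are deleted, possibly collapsing a pair to the singleton ``{g}_g``.
    Results are deduplicated.  On complete possessed-cascade sets this equals
    the induced-subgraph restriction.
    """
    if not cset.oriented:
        raise ValueError("quotient restriction requires an oriented cascade set")
    if frozenset(cset.universe) != frozenset(spec.universe):
        raise ValueError("restriction spec universe differs from the cascade set's")
    out = set()
    for c in cset.cascades:
        if c.dependent not in spec.kept:
            continue  # the whole fiber maps to the environment class
        surviving = c.members & spec.kept
        out.add(Cascade(surviving, c.dependent))
    return CascadeSet(spec.kept, out, oriented=True)


def to_undirected(cset: CascadeSet) -> CascadeSet:
    """Quotient by the relation ``{x,y}_x ~ {x,y}_y``; idempotent."""
    if not cset.oriented:
        return cset
    merged = frozenset(c.drop_orientation() for c in cset.cascades)
    return CascadeSet(cset.universe, merged, oriented=False)


def vertexes(cset: CascadeSet) -> frozenset:
    """Cascades of cardinality 1 (the graph's vertex set)."""
    return cset.vertexes()


def edges(cset: CascadeSet) -> frozenset:
    """Cascades of cardinality 2 (the graph's edge set)."""
    return cset.edges()
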