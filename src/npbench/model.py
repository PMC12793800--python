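"""Domain types shared by every analysis stage.

Entities are keyed by ``(namespace, value)`` pairs so that a herb accession
and a disease accession with the same string never collide.  Compounds are
PubChem CIDs and protein targets are Entrez Gene IDs, both rendered as
integer strings; herbs, diseases and biological functions carry opaque
accession strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

logger = logging.getLogger("npbench")

NAMESPACES = frozenset({"herb", "compound", "target", "disease", "function"})
_INTEGER_NAMESPACES = frozenset({"compound", "target"})


@dataclass(frozen=True, order=True)
class EntityId:
    """A namespaced, stable entity identifier.

    ``compound`` values are PubChem CIDs and ``target`` values are Entrez
    Gene IDs; both must parse as positive integers.  Other namespaces carry
    opaque non-empty accession strings.
    """

    namespace: str
    value: str

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r}")
        if not self.value:
            raise ValueError("entity value must be non-empty")
        if self.namespace in _INTEGER_NAMESPACES:
            try:
                ok = int(self.value) > 0
            except ValueError:
                ok = False
            if not ok:
                raise ValueError(
                    f"{self.namespace} id {self.value!r} must be a positive integer"
                )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.namespace}:{self.value}"


def herb(value: str) -> EntityId:
    return EntityId("herb", value)


def compound(value: "str | int") -> EntityId:
    return EntityId("compound", str(value))


def target(value: "str | int") -> EntityId:
    return EntityId("target", str(value))


def disease(value: str) -> EntityId:
    return EntityId("disease", value)


def function(value: str) -> EntityId:
    return EntityId("function", value)


@dataclass
class IdMappingTable:
    """Raw-label → EntityId mapping for one or more source databases.

    Unmapped rows are stored with ``None`` (an explicit absent marker),
    never an empty string.  ``(source_db, raw_label)`` pairs are unique.
    """

    rows: dict[tuple[str, str], Optional[EntityId]] = field(default_factory=dict)

    def add(self, source_db: str, raw_label: str, mapped: Optional[EntityId]) -> None:
        key = (source_db, raw_label)
        if key in self.rows and self.rows[key] != mapped:
            raise ValueError(f"conflicting mapping for {key}")
        self.rows[key] = mapped

    def lookup(self, source_db: str, raw_label: str) -> Optional[EntityId]:
        return self.rows.get((source_db, raw_label))

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class TripartiteNetwork:
    """One source database's herb→compound and compound→target edge sets.

    Edges are deduplicated sets; multiplicity carries no meaning in any of
    the downstream formulas.  ``compound_attrs`` optionally holds
    pre-supplied per-compound columns (e.g. oral bioavailability or
    drug-likeness scores); they are never computed here.
    """

    db_label: str
    hc_edges: set[tuple[EntityId, EntityId]] = field(default_factory=set)
    ct_edges: set[tuple[EntityId, EntityId]] = field(default_factory=set)
    compound_attrs: dict[EntityId, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for h, c in self.hc_edges:
            if h.namespace != "herb" or c.namespace != "compound":
                raise ValueError(f"bad HC edge ({h}, {c})")
        for c, t in self.ct_edges:
            if c.namespace != "compound" or t.namespace != "target":
                raise ValueError(f"bad CT edge ({c}, {t})")

    # ---- node views -------------------------------------------------
    @property
    def herbs(self) -> set[EntityId]:
        return {h for h, _ in self.hc_edges}

    @property
    def compounds(self) -> set[EntityId]:
        return {c for _, c in self.hc_edges} | {c for c, _ in self.ct_edges}

    @property
    def targets(self) -> set[EntityId]:
        return {t for _, t in self.ct_edges}

    def compounds_of(self, h: EntityId) -> set[EntityId]:
        return {c for hh, c in self.hc_edges if hh == h}

    def targets_of(self, c: EntityId) -> set[EntityId]:
        return {t for cc, t in self.ct_edges if cc == c}

    def herb_targets(self, h: EntityId) -> set[EntityId]:
        """Union of targets over the herb's compounds (default aggregation)."""
        out: set[EntityId] = set()
        for c in self.compounds_of(h):
            out |= self.targets_of(c)
        return out

    def filter_compounds(self, keep: Iterable[EntityId]) -> "TripartiteNetwork":
        """Restrict both layers to the given compounds (e.g. an OB/DL pre-filter)."""
        keep = set(keep)
        return TripartiteNetwork(
            db_label=self.db_label,
            hc_edges={(h, c) for h, c in self.hc_edges if c in keep},
            ct_edges={(c, t) for c, t in self.ct_edges if c in keep},
            compound_attrs={c: a for c, a in self.compound_attrs.items() if c in keep},
        )


class PpiGraph:
    """Undirected protein–protein interaction graph over target EntityIds.

    Edges are canonicalized smaller-id-first; self-loops are rejected at
    insertion with a logged count.  Backed by a networkx Graph.
    """

    def __init__(self, edges: Iterable[tuple[EntityId, EntityId]] = (),
                 nodes: Iterable[EntityId] = ()):
        import networkx as nx

        self._g = nx.Graph()
        self.n_self_loops_rejected = 0
        for n in nodes:
            self._g.add_node(n)
        for u, v in edges:
            self.add_edge(u, v)

    def add_edge(self, u: EntityId, v: EntityId) -> None:
        if u == v:
            self.n_self_loops_rejected += 1
            return
        a, b = sorted((u, v))
        self._g.add_edge(a, b)

    def add_node(self, u: EntityId) -> None:
        self._g.add_node(u)

    @property
    def nx(self):
        return self._g

    def nodes(self) -> set[EntityId]:
        return set(self._g.nodes)

    def edges(self) -> set[tuple[EntityId, EntityId]]:
        return {tuple(sorted(e)) for e in self._g.edges}

    def has_edge(self, u: EntityId, v: EntityId) -> bool:
        return self._g.has_edge(u, v)

    def degree(self, u: EntityId) -> int:
        return self._g.degree(u)

    def neighbors(self, u: EntityId) -> set[EntityId]:
        return set(self._g.neighbors(u))

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __eq__(self, other) -> bool:
        if not isinstance(other, PpiGraph):
            return NotImplemented
        return self.nodes() == other.nodes() and self.edges() == other.edges()


@dataclass
class KnownAssociations:
    """Gold-standard label sets used for evaluation."""

    herb_target: set[tuple[EntityId, EntityId]] = field(default_factory=set)
    compound_target: set[tuple[EntityId, EntityId]] = field(default_factory=set)
    disease_protein: dict[EntityId, set[EntityId]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def apply_id_mapping(
    raw_edges: list[tuple[str, str]],
    table: IdMappingTable,
    source_db: str,
) -> tuple[list[tuple[EntityId, EntityId]], list[tuple[str, str]]]:
    """Map raw edge labels through an IdMappingTable.

    Edges with any unmapped endpoint are dropped and enumerated in the
    returned report; this mirrors the convention of keeping only data
    successfully mapped to the common identifier system.  Unmapped edges
    are a reported outcome, never an error.
    """
    mapped: list[tuple[EntityId, EntityId]] = []
    report: list[tuple[str, str]] = []
    for a_raw, b_raw in raw_edges:
        a = table.lookup(source_db, a_raw)
        b = table.lookup(source_db, b_raw)
        if a is None or b is None:
            report.append((a_raw, b_raw))
        else:
            mapped.append((a, b))
    if report:
        logger.info("apply_id_mapping: dropped %d/%d edges with unmapped endpoints",
                    len(report), len(raw_edges))
    return mapped, report


def merge_databases(
    networks: list[TripartiteNetwork],
    mode: str = "union",
    layer: str = "both",
) -> TripartiteNetwork:
    """Combine databases by set union or intersection of an edge layer.

    Intersection is computed at the association level (exact edge match),
    not the entity level.  ``layer`` selects which layer(s) are combined;
    a layer not selected is taken as the union across inputs so the result
    remains a complete tripartite network.
    """
    if not networks:
        raise ValueError("merge_databases requires at least one network")
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown mode {mode!r}")
    if layer not in ("hc", "ct", "both"):
        raise ValueError(f"unknown layer {layer!r}")

    def combine(sets: list[set], active: bool) -> set:
        out = set(sets[0])
        for s in sets[1:]:
            if active and mode == "intersection":
                out &= s
            else:
                out |= s
        return out

    hc = combine([n.hc_edges for n in networks], layer in ("hc", "both"))
    ct = combine([n.ct_edges for n in networks], layer in ("ct", "both"))
    sep = "∩" if mode == "intersection" else "∪"
    label = sep.join(n.db_label for n in networks)
    return TripartiteNetwork(db_label=label, hc_edges=hc, ct_edges=ct)


def induce_ppi_subnetwork(targets: set[EntityId], ppi: PpiGraph) -> PpiGraph:
    """Induced PPI subgraph on the given targets.

    Targets absent from the PPI are dropped (count logged); targets present
    but with no retained interaction stay as degree-0 nodes.
    """
    present = targets & ppi.nodes()
    missing = len(targets) - len(present)
    if missing:
        logger.warning("induce_ppi_subnetwork: %d targets absent from PPI", missing)
    sub = PpiGraph(nodes=present)
    for u, v in ppi.edges():
        if u in present and v in present:
            sub.add_edge(u, v)
    return sub
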