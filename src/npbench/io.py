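"""TSV readers and writers for the edge-list dialects every stage shares.

All files are UTF-8, tab-separated, unquoted, with a single header row.
Writers emit rows in lexicographic order so outputs are diffable.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

from .model import (
    EntityId,
    IdMappingTable,
    KnownAssociations,
    PpiGraph,
    TripartiteNetwork,
    compound,
    disease,
    herb,
    target,
)

logger = logging.getLogger("npbench")


class ParseError(ValueError):
    """A malformed row; the message names the file and 1-based line number."""


def _read_rows(path, n_cols: int, optional_extra: int = 0):
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            return
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if not (n_cols <= len(parts) <= n_cols + optional_extra):
                raise ParseError(f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}")
            yield lineno, parts


def _int_id(path, lineno, kind, value) -> EntityId:
    try:
        return EntityId(kind, value)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None


def load_tripartite(hc_path, ct_path, db_label: str) -> TripartiteNetwork:
    """Load one database from its herb_compound and compound_target TSVs.

    Duplicate rows collapse silently (logged); malformed rows raise a
    :class:`ParseError` naming the file and line.
    """
    hc_edges: set[tuple[EntityId, EntityId]] = set()
    n_hc_rows = 0
    for lineno, parts in _read_rows(hc_path, 2):
        n_hc_rows += 1
        h = EntityId("herb", parts[0]) if parts[0] else None
        if h is None:
            raise ParseError(f"{hc_path}:{lineno}: empty herb id")
        c = _int_id(hc_path, lineno, "compound", parts[1])
        hc_edges.add((h, c))

    ct_edges: set[tuple[EntityId, EntityId]] = set()
    n_ct_rows = 0
    for lineno, parts in _read_rows(ct_path, 2, optional_extra=1):
        n_ct_rows += 1
        c = _int_id(ct_path, lineno, "compound", parts[0])
        t = _int_id(ct_path, lineno, "target", parts[1])
        if len(parts) == 3 and parts[2] not in ("known", "predicted"):
            raise ParseError(f"{ct_path}:{lineno}: bad evidence value {parts[2]!r}")
        ct_edges.add((c, t))

    logger.info(
        "load_tripartite[%s]: %d HC rows -> %d edges, %d CT rows -> %d edges",
        db_label, n_hc_rows, len(hc_edges), n_ct_rows, len(ct_edges),
    )
    return TripartiteNetwork(db_label=db_label, hc_edges=hc_edges, ct_edges=ct_edges)


def write_tripartite(net: TripartiteNetwork, hc_path, ct_path) -> None:
    with Path(hc_path).open("w", encoding="utf-8") as fh:
        fh.write("herb_id\tcompound_cid\n")
        for h, c in sorted(net.hc_edges):
            fh.write(f"{h.value}\t{c.value}\n")
    with Path(ct_path).open("w", encoding="utf-8") as fh:
        fh.write("compound_cid\tgene_id\n")
        for c, t in sorted(net.ct_edges):
            fh.write(f"{c.value}\t{t.value}\n")


def load_ppi(path) -> PpiGraph:
    g = PpiGraph()
    for lineno, parts in _read_rows(path, 2):
        u = _int_id(path, lineno, "target", parts[0])
        v = _int_id(path, lineno, "target", parts[1])
        g.add_edge(u, v)
    if g.n_self_loops_rejected:
        logger.warning("load_ppi: rejected %d self-loops", g.n_self_loops_rejected)
    return g


def write_ppi(g: PpiGraph, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene_id_a\tgene_id_b\n")
        for u, v in sorted(g.edges()):
            fh.write(f"{u.value}\t{v.value}\n")


def load_id_mapping(path) -> IdMappingTable:
    """Read id_mapping.tsv; an empty mapped_value column means unmapped."""
    table = IdMappingTable()
    for lineno, parts in _read_rows(path, 4):
        source_db, raw_label, namespace, mapped_value = parts
        if mapped_value == "":
            table.add(source_db, raw_label, None)
        else:
            table.add(source_db, raw_label, _int_id(path, lineno, namespace, mapped_value)
                      if namespace in ("compound", "target")
                      else EntityId(namespace, mapped_value))
    return table


def write_id_mapping(table: IdMappingTable, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("source_db\traw_label\tnamespace\tmapped_value\n")
        for (db, raw), mapped in sorted(table.rows.items()):
            if mapped is None:
                fh.write(f"{db}\t{raw}\t\t\n")
            else:
                fh.write(f"{db}\t{raw}\t{mapped.namespace}\t{mapped.value}\n")


def load_known_associations(ht_path=None, ct_path=None, dp_path=None) -> KnownAssociations:
    known = KnownAssociations()
    if ht_path is not None:
        for lineno, parts in _read_rows(ht_path, 2):
            known.herb_target.add(
                (EntityId("herb", parts[0]), _int_id(ht_path, lineno, "target", parts[1]))
            )
    if ct_path is not None:
        for lineno, parts in _read_rows(ct_path, 2):
            known.compound_target.add(
                (_int_id(ct_path, lineno, "compound", parts[0]),
                 _int_id(ct_path, lineno, "target", parts[1]))
            )
    if dp_path is not None:
        for lineno, parts in _read_rows(dp_path, 2):
            d = EntityId("disease", parts[0])
            known.disease_protein.setdefault(d, set()).add(
                _int_id(dp_path, lineno, "target", parts[1])
            )
    return known


def write_known_associations(known: KnownAssociations, ht_path=None, ct_path=None,
                             dp_path=None) -> None:
    if ht_path is not None:
        with Path(ht_path).open("w", encoding="utf-8") as fh:
            fh.write("herb_id\tgene_id\n")
            for h, t in sorted(known.herb_target):
                fh.write(f"{h.value}\t{t.value}\n")
    if ct_path is not None:
        with Path(ct_path).open("w", encoding="utf-8") as fh:
            fh.write("compound_cid\tgene_id\n")
            for c, t in sorted(known.compound_target):
                fh.write(f"{c.value}\t{t.value}\n")
    if dp_path is not None:
        with Path(dp_path).open("w", encoding="utf-8") as fh:
            fh.write("disease_id\tgene_id\n")
            for d in sorted(known.disease_protein):
                for t in sorted(known.disease_protein[d]):
                    fh.write(f"{d.value}\t{t.value}\n")
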