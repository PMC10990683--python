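"""Offline pathway index search and parent/child relation lookup.

Mirrors the ReactomePathways.txt (3-column TSV: id, name, organism) and
ReactomePathwaysRelation.txt (2-column TSV: parent, child) dialects.  Search
is token-AND substring matching over all three fields; multi-field hits rank
first so a query like "glycolysis homo sapiens" prioritizes the more specific
entry.  The ranking key — (distinct fields hit desc, name length asc,
model_id) — is a declared convention giving a deterministic total order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)


class IndexFormatError(ValueError):
    """No parseable lines in the index/relations file."""


@dataclass(frozen=True)
class PathwayIndexEntry:
    model_id: str
    name: str
    organism: str


@dataclass(frozen=True)
class RelationEdge:
    parent_id: str
    child_id: str


def load_index(tsv_text: str) -> list[PathwayIndexEntry]:
    """Parse a 3-column pathway index; malformed lines are skipped and counted."""
    entries: list[PathwayIndexEntry] = []
    skipped = 0
    for line in tsv_text.splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            skipped += 1
            continue
        entries.append(PathwayIndexEntry(parts[0].strip(), parts[1].strip(),
                                         parts[2].strip()))
    if skipped:
        logger.warning("pathway index: skipped %d malformed line(s)", skipped)
    if not entries:
        raise IndexFormatError("pathway index contains no parseable lines")
    return entries


def load_relations(tsv_text: str) -> list[RelationEdge]:
    """Parse a 2-column parent->child relations file; self-loops are dropped."""
    edges: list[RelationEdge] = []
    skipped = 0
    for line in tsv_text.splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            skipped += 1
            continue
        parent, child = parts[0].strip(), parts[1].strip()
        if parent == child:
            skipped += 1
            continue
        edges.append(RelationEdge(parent, child))
    if skipped:
        logger.warning("pathway relations: skipped %d line(s)", skipped)
    if not edges:
        raise IndexFormatError("pathway relations file contains no parseable lines")
    return edges


def search(index: list[PathwayIndexEntry], query: str) -> list[PathwayIndexEntry]:
    """Rank entries matching every whitespace-separated token of ``query``.

    An entry matches when each lowercased token is a substring of the
    concatenation of its three lowercased fields.  Entries hit in more
    distinct fields rank first; ties break by name length then model id.
    """
    tokens = query.lower().split()
    if not tokens:
        raise ValueError("empty search query")

    ranked: list[tuple[tuple, PathwayIndexEntry]] = []
    for entry in index:
        fields = (entry.model_id.lower(), entry.name.lower(), entry.organism.lower())
        blob = "".join(fields)
        if not all(tok in blob for tok in tokens):
            continue
        fields_hit = sum(1 for f in fields if any(tok in f for tok in tokens))
        ranked.append(((-fields_hit, len(entry.name), entry.model_id), entry))
    ranked.sort(key=lambda item: item[0])
    return [entry for _, entry in ranked]


def find_associated(relations: list[RelationEdge], model_id: str) -> dict[str, list[str]]:
    """Parents and children of ``model_id`` in the relation file, deduplicated."""
    parents = sorted({e.parent_id for e in relations if e.child_id == model_id})
    children = sorted({e.child_id for e in relations if e.parent_id == model_id})
    return {"parents": parents, "children": children}
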