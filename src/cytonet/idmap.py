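"""Offline gene-identifier mapping and SBO term labelling.

Gene identifiers are not used uniformly across resources: SBML annotations
carry UniProt accessions, expression tables carry Ensembl gene ids, and users
think in HGNC symbols.  :class:`HgncTable` loads the HGNC complete-set CSV
dump and provides case-insensitive mapping between the three namespaces.

SBO (Systems Biology Ontology) terms attached to SBML species are resolved to
human-readable labels from either a two-column TSV or a minimal OWL/XML label
harvest (rdfs:label per class).
"""

from __future__ import annotations

import csv
import io
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

SBO_PATTERN = re.compile(r"^SBO:\d{7}$")
NAMESPACES = ("symbol", "ensembl", "uniprot")
UNKNOWN_SBO = "unknown SBO term"


class IdmapFormatError(ValueError):
    """Input table missing a required column or violating uniqueness."""


@dataclass
class HgncRecord:
    symbol: str
    ensembl_gene_id: str = ""
    uniprot_ids: list[str] = field(default_factory=list)
    gene_name: str = ""
    locus_type: str = ""


def _split_uniprot(cell: str) -> list[str]:
    # HGNC dumps vary: multiple accessions separated by "|" or whitespace
    return [tok for tok in re.split(r"[|\s]+", cell.strip()) if tok]


class HgncTable:
    """Bidirectional symbol/Ensembl/UniProt lookup built from an HGNC CSV."""

    REQUIRED = ("symbol", "ensembl_gene_id", "uniprot_ids", "name")

    def __init__(self, records: list[HgncRecord]):
        self.records = records
        self._by_symbol: dict[str, HgncRecord] = {}
        self._by_ensembl: dict[str, list[str]] = {}
        self._by_uniprot: dict[str, list[str]] = {}
        for rec in records:
            key = rec.symbol.lower()
            if key in self._by_symbol:
                raise IdmapFormatError(f"duplicate HGNC symbol {rec.symbol!r}")
            self._by_symbol[key] = rec
            if rec.ensembl_gene_id:
                self._by_ensembl.setdefault(rec.ensembl_gene_id.lower(), []).append(rec.symbol)
            for acc in rec.uniprot_ids:
                self._by_uniprot.setdefault(acc.lower(), []).append(rec.symbol)

    def __len__(self) -> int:
        return len(self.records)

    def symbol_to_uniprot(self, symbol: str) -> list[str]:
        rec = self._by_symbol.get(symbol.lower())
        return list(rec.uniprot_ids) if rec else []

    def symbol_to_ensembl(self, symbol: str) -> list[str]:
        rec = self._by_symbol.get(symbol.lower())
        return [rec.ensembl_gene_id] if rec and rec.ensembl_gene_id else []

    def describe(self, symbol: str) -> str:
        rec = self._by_symbol.get(symbol.lower())
        return rec.gene_name if rec else ""

    def map_identifier(self, query: str, from_ns: str, to_ns: str) -> list[str]:
        """Map ``query`` between namespaces; returns all matches, maybe empty."""
        for ns in (from_ns, to_ns):
            if ns not in NAMESPACES:
                raise ValueError(f"unknown namespace {ns!r}; expected one of {NAMESPACES}")
        q = query.lower()
        if from_ns == "symbol":
            symbols = [self._by_symbol[q].symbol] if q in self._by_symbol else []
        elif from_ns == "ensembl":
            symbols = self._by_ensembl.get(q, [])
        else:
            symbols = self._by_uniprot.get(q, [])

        if to_ns == "symbol":
            return sorted(set(symbols))
        out: list[str] = []
        for sym in symbols:
            if to_ns == "ensembl":
                out.extend(self.symbol_to_ensembl(sym))
            else:
                out.extend(self.symbol_to_uniprot(sym))
        return sorted(set(out))


def load_hgnc(csv_text: str) -> HgncTable:
    """Load an HGNC complete-set CSV (comma-separated, quoted fields)."""
    reader = csv.DictReader(io.StringIO(csv_text))
    header = reader.fieldnames or []
    for column in HgncTable.REQUIRED:
        if column not in header:
            raise IdmapFormatError(f"HGNC table missing required column {column!r}")
    records: list[HgncRecord] = []
    for row in reader:
        symbol = (row.get("symbol") or "").strip()
        if not symbol:
            continue
        records.append(HgncRecord(
            symbol=symbol,
            ensembl_gene_id=(row.get("ensembl_gene_id") or "").strip(),
            uniprot_ids=_split_uniprot(row.get("uniprot_ids") or ""),
            gene_name=(row.get("name") or "").strip(),
            locus_type=(row.get("locus_type") or "").strip(),
        ))
    return HgncTable(records)


def map_identifier(table: HgncTable, query: str, from_ns: str, to_ns: str) -> list[str]:
    return table.map_identifier(query, from_ns, to_ns)


def extract_link_id(uri: str) -> str:
    """Final path segment of an annotation URI ("…/uniprot/P09016" -> "P09016")."""
    trimmed = uri.rstrip("/")
    return trimmed.rsplit("/", 1)[-1]


# ---------------------------------------------------------------------------
# SBO ontology
# ---------------------------------------------------------------------------

class SboOntology:
    """term -> label lookup, loadable from a two-column TSV or OWL/XML."""

    def __init__(self, labels: dict[str, str]):
        self.labels = dict(labels)

    @classmethod
    def from_tsv(cls, tsv_text: str) -> "SboOntology":
        labels: dict[str, str] = {}
        for line in tsv_text.splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            term = parts[0].strip()
            if SBO_PATTERN.match(term):
                labels[term] = parts[1].strip()
        return cls(labels)

    @classmethod
    def from_owl(cls, owl_text: str) -> "SboOntology":
        """Minimal label harvest: rdfs:label of every owl:Class with an SBO id."""
        root = ET.fromstring(owl_text)
        labels: dict[str, str] = {}
        for node in root.iter():
            if node.tag.rsplit("}", 1)[-1] != "Class":
                continue
            about = next(
                (v for k, v in node.attrib.items() if k.rsplit("}", 1)[-1] == "about"),
                "",
            )
            term = about.rsplit("/", 1)[-1].replace("_", ":")
            if not SBO_PATTERN.match(term):
                continue
            for child in node:
                if child.tag.rsplit("}", 1)[-1] == "label" and child.text:
                    labels[term] = child.text.strip()
                    break
        return cls(labels)

    def label(self, term: str) -> str:
        if not SBO_PATTERN.match(term):
            raise IdmapFormatError(f"malformed SBO term {term!r}")
        return self.labels.get(term, UNKNOWN_SBO)


def sbo_label(term: str, ontology: SboOntology) -> str:
    return ontology.label(term)
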