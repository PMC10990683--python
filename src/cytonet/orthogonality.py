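"""Cross-model species overlap and knowledge-gap detection over an SBML corpus.

Reactome species ids are model-scoped, so cross-model identity is established
through the external identifiers harvested from species annotation URIs
(final path segment, e.g. a UniProt accession), optionally widened to gene
symbols through an HGNC table.  Species without any identifier are excluded
from cross-model claims and counted in the report footer.

A *gap species* is one that a model only ever produces (product-only role)
and whose identifiers appear in no other model of the corpus — the pattern of
a transcription factor whose downstream actions are missing from the
database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .idmap import HgncTable, extract_link_id
from .netgraph import ROLE_OUTPUT, classify_species_roles
from .sbml_io import PathwayModel

logger = logging.getLogger(__name__)

GAP_REASON = "product-only, no external appearances"


class UnknownModelError(KeyError):
    """Model id absent from the corpus index."""


@dataclass
class GapReport:
    model_id: str
    species_id: str
    identifiers: list[str]
    reason: str = GAP_REASON


@dataclass
class CorpusIndex:
    models: dict[str, PathwayModel] = field(default_factory=dict)
    # normalized identifier -> set of model ids containing it
    identifier_models: dict[str, set[str]] = field(default_factory=dict)
    # model id -> species id -> normalized identifiers
    species_identifiers: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    unidentified_species: int = 0

    def model_identifiers(self, model_id: str) -> set[str]:
        if model_id not in self.models:
            raise UnknownModelError(model_id)
        out: set[str] = set()
        for idents in self.species_identifiers[model_id].values():
            out.update(idents)
        return out


def _normalize(identifier: str) -> str:
    return identifier.strip().lower()


def species_identifiers(model: PathwayModel, species_id: str,
                        hgnc: HgncTable | None = None) -> list[str]:
    """Identifiers of one species: extracted link ids plus mapped gene symbols."""
    idents: list[str] = []
    for uri in model.species[species_id].annotation_uris:
        link_id = extract_link_id(uri)
        if not link_id:
            continue
        if link_id not in idents:
            idents.append(link_id)
        if hgnc is not None:
            for symbol in hgnc.map_identifier(link_id, "uniprot", "symbol"):
                if symbol not in idents:
                    idents.append(symbol)
    return idents


def build_corpus_index(models: list[PathwayModel],
                       hgnc: HgncTable | None = None) -> CorpusIndex:
    """Index every model's species by their harvested external identifiers."""
    if not models:
        raise ValueError("corpus must contain at least one model")
    index = CorpusIndex()
    for model in models:
        index.models[model.model_id] = model
        per_species: dict[str, list[str]] = {}
        for sid in model.species:
            idents = [_normalize(i) for i in species_identifiers(model, sid, hgnc)]
            per_species[sid] = idents
            if not idents:
                index.unidentified_species += 1
            for ident in idents:
                index.identifier_models.setdefault(ident, set()).add(model.model_id)
        index.species_identifiers[model.model_id] = per_species
    return index


def models_for_species(index: CorpusIndex, identifier: str) -> list[str]:
    """Model ids containing the identifier (exact match, case-normalized)."""
    return sorted(index.identifier_models.get(_normalize(identifier), set()))


def species_overlap(index: CorpusIndex, model_a: str, model_b: str) -> dict:
    """Shared identifiers and Jaccard index between two models of the corpus."""
    ids_a = index.model_identifiers(model_a)
    ids_b = index.model_identifiers(model_b)
    shared = ids_a & ids_b
    union = ids_a | ids_b
    return {
        "shared_identifiers": sorted(shared),
        "jaccard": (len(shared) / len(union)) if union else 0.0,
    }


def find_gap_species(index: CorpusIndex) -> list[GapReport]:
    """Every (model, species) that is product-only and unseen elsewhere.

    A modifier or reactant appearance of the same identifier in any other
    model disqualifies the gap: that appearance is exactly the downstream
    action whose absence the gap flags.
    """
    reports: list[GapReport] = []
    for model_id, model in index.models.items():
        product_only = {
            sr.species_id
            for sr in classify_species_roles(model)
            if sr.role == ROLE_OUTPUT
        }
        for sid in sorted(product_only):
            idents = index.species_identifiers[model_id][sid]
            if not idents:
                continue  # no cross-model claim possible without an identifier
            elsewhere = set()
            for ident in idents:
                elsewhere |= index.identifier_models.get(ident, set()) - {model_id}
            if not elsewhere:
                reports.append(GapReport(model_id, sid, list(idents)))
    return reports


def gap_report_json(index: CorpusIndex) -> dict:
    """JSON-ready gap report with a footer on unidentifiable species."""
    return {
        "gaps": [
            {
                "model_id": r.model_id,
                "species_id": r.species_id,
                "identifiers": r.identifiers,
                "reason": r.reason,
            }
            for r in find_gap_species(index)
        ],
        "footer": {
            "species_without_identifiers": index.unidentified_species,
            "note": "species lacking annotation identifiers are excluded "
                    "from cross-model claims",
        },
    }
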