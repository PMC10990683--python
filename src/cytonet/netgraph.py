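"""Bipartite species-reaction graph analytics.

Species roles follow the system-theoretic reading of a reaction network: an
*input* is only ever consumed (reactant or modifier), an *output* only ever
produced, a *mediator* sits on both sides, and an *isolated* species is listed
in the model but referenced by no reaction.

Pruning is reaction-centred: two reactions are adjacent when they share at
least one participant species (any role), and depth counts BFS hops on that
projection graph, so depth 0 is the focus reaction alone and depth 1 adds its
immediate neighbours ("1 reaction distance").
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import networkx as nx

from .sbml_io import (
    PathwayModel,
    ROLE_MODIFIER,
    ROLE_PRODUCT,
    ROLE_REACTANT,
)

ROLE_INPUT = "input"
ROLE_OUTPUT = "output"
ROLE_MEDIATOR = "mediator"
ROLE_ISOLATED = "isolated"

# Fixed DOT styling so exported files are byte-stable across runs.
DOT_STYLES = {
    "species": 'shape=ellipse',
    "reaction": 'shape=box, style=filled, fillcolor=orange',
}


class UnknownReactionError(KeyError):
    """Focus reaction id absent from the model."""


@dataclass
class SubgraphSpec:
    focus_reaction_id: str
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass
class SpeciesRole:
    species_id: str
    role: str


def classify_species_roles(model: PathwayModel) -> list[SpeciesRole]:
    """Partition every species of the model into input/output/mediator/isolated."""
    consumed: set[str] = set()
    produced: set[str] = set()
    for rxn in model.reactions:
        for ref in rxn.reactants:
            consumed.add(ref.species_id)
        for ref in rxn.modifiers:
            consumed.add(ref.species_id)
        for ref in rxn.products:
            produced.add(ref.species_id)

    roles: list[SpeciesRole] = []
    for sid in model.species:
        if sid in consumed and sid in produced:
            role = ROLE_MEDIATOR
        elif sid in consumed:
            role = ROLE_INPUT
        elif sid in produced:
            role = ROLE_OUTPUT
        else:
            role = ROLE_ISOLATED
        roles.append(SpeciesRole(sid, role))
    return roles


def reaction_adjacency(model: PathwayModel) -> nx.Graph:
    """Projection graph: reactions adjacent iff they share >=1 participant species."""
    graph = nx.Graph()
    by_species: dict[str, list[str]] = {}
    for rxn in model.reactions:
        graph.add_node(rxn.reaction_id)
        for ref in rxn.participants():
            by_species.setdefault(ref.species_id, []).append(rxn.reaction_id)
    for rxn_ids in by_species.values():
        # clique closure: all reactions sharing this species are adjacent
        for i, a in enumerate(rxn_ids):
            for b in rxn_ids[i + 1:]:
                if a != b:
                    graph.add_edge(a, b)
    return graph


def prune_subgraph(model: PathwayModel, spec: SubgraphSpec) -> PathwayModel:
    """Return the submodel within ``spec.depth`` reaction-hops of the focus."""
    known = {rxn.reaction_id for rxn in model.reactions}
    if spec.focus_reaction_id not in known:
        raise UnknownReactionError(
            f"reaction {spec.focus_reaction_id!r} not in model {model.model_id!r}"
        )
    graph = reaction_adjacency(model)
    distances = nx.single_source_shortest_path_length(
        graph, spec.focus_reaction_id, cutoff=spec.depth
    )
    keep = set(distances)

    pruned = PathwayModel(
        model_id=model.model_id,
        model_name=model.model_name,
        compartments=list(model.compartments),
    )
    for rxn in model.reactions:
        if rxn.reaction_id in keep:
            pruned.reactions.append(copy.deepcopy(rxn))
    needed = {
        ref.species_id for rxn in pruned.reactions for ref in rxn.participants()
    }
    pruned.species = {
        sid: copy.deepcopy(model.species[sid])
        for sid in model.species
        if sid in needed
    }
    return pruned


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _node_labels(model: PathwayModel) -> dict[str, str]:
    """Species display names, disambiguated with the id when names collide."""
    labels: dict[str, str] = {}
    counts: dict[str, int] = {}
    for sp in model.species.values():
        name = sp.display_name or sp.species_id
        counts[name] = counts.get(name, 0) + 1
    for sp in model.species.values():
        name = sp.display_name or sp.species_id
        if counts[name] > 1 and name != sp.species_id:
            name = f"{name} [{sp.species_id}]"
        labels[sp.species_id] = name
    return labels


def iter_edges(model: PathwayModel):
    """Yield (source, role, target) for every participant edge.

    Reactants and modifiers point species -> reaction; products point
    reaction -> species.  The multiset of yielded roles equals the model's
    participant multiset.
    """
    for rxn in model.reactions:
        for ref in rxn.reactants:
            yield ref.species_id, ROLE_REACTANT, rxn.reaction_id
        for ref in rxn.modifiers:
            yield ref.species_id, ROLE_MODIFIER, rxn.reaction_id
        for ref in rxn.products:
            yield rxn.reaction_id, ROLE_PRODUCT, ref.species_id


def to_dot(model: PathwayModel) -> str:
    """Render the bipartite network as a GraphViz digraph."""
    labels = _node_labels(model)
    lines = [f'digraph "{_dot_escape(model.model_id or "pathway")}" {{']
    for sid in model.species:
        lines.append(
            f'  "{_dot_escape(sid)}" [label="{_dot_escape(labels[sid])}", '
            f'{DOT_STYLES["species"]}];'
        )
    for rxn in model.reactions:
        label = rxn.display_name or rxn.reaction_id
        lines.append(
            f'  "{_dot_escape(rxn.reaction_id)}" [label="{_dot_escape(label)}", '
            f'{DOT_STYLES["reaction"]}];'
        )
    for source, role, target in iter_edges(model):
        lines.append(
            f'  "{_dot_escape(source)}" -> "{_dot_escape(target)}" '
            f'[label="{role}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_sif(model: PathwayModel) -> str:
    """Render the network as SIF: one tab-separated edge line per participant."""
    lines = [f"{source}\t{role}\t{target}" for source, role, target in iter_edges(model)]
    return "\n".join(lines) + ("\n" if lines else "")
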