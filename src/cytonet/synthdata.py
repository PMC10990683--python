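"""Deterministic generators for HPA-like expression tables and SBML corpora.

Both generators emit exactly the dialects the readers consume and return a
ground-truth manifest, so every pipeline stage can be tested offline against
planted structure: lineage marker genes with a known effect multiplier and
cluster-replicate noise on the expression side; species roles, cross-model
shared identifiers and knowledge-gap species on the network side.

Randomness is a single named stream per generator seeded from one integer;
no global state is touched, so regeneration with the same seed is
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sbml_io import (
    ParticipantRef,
    PathwayModel,
    ReactionNode,
    SpeciesNode,
    write_sbml,
    ROLE_MODIFIER,
    ROLE_PRODUCT,
    ROLE_REACTANT,
)

URI_PREFIX = "https://identifiers.org/uniprot/"


class SynthConfigError(ValueError):
    """Generator parameters are inconsistent or infeasible."""


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

# tissue / cell-type vocabulary; the two smooth-muscle lineages form a natural
# related group used to emulate "similar lineages sit close" behaviour
_TISSUES = ("Adipose tissue", "Placenta", "Heart muscle", "Liver", "Lung",
            "Spleen", "Testis", "Brain")
_CELL_TYPES = ("smooth muscle cells", "smooth muscle cells", "cardiomyocytes",
               "hepatocytes", "macrophages", "plasma cells", "spermatocytes",
               "excitatory neurons")


@dataclass
class ExpressionGroundTruth:
    """Study conditions for the synthetic expression table.

    Baseline per-gene nTPM is log-normal (log-mean ``baseline_mu``, log-sd
    ``baseline_sigma``); each lineage's marker genes are scaled by
    ``marker_multiplier``; cluster replicates apply multiplicative log-normal
    noise of log-sd ``noise_sigma``.
    """

    n_lineages: int = 8
    n_clusters: int = 3
    n_genes: int = 300
    markers_per_lineage: int = 10
    marker_multiplier: float = 5.0
    baseline_mu: float = 1.0
    baseline_sigma: float = 1.0
    noise_sigma: float = 0.2
    seed: int = 0
    # group name -> lineage indices sharing an extra marker set
    shared_groups: dict[str, list[int]] = field(
        default_factory=lambda: {"smooth_muscle": [0, 1]}
    )

    def __post_init__(self) -> None:
        if self.n_lineages < 2:
            raise SynthConfigError("need at least 2 lineages")
        if self.marker_multiplier <= 0 or self.baseline_sigma <= 0:
            raise SynthConfigError("effect and scale parameters must be positive")
        if self.noise_sigma < 0:
            raise SynthConfigError("noise sigma must be non-negative")
        needed = self.markers_per_lineage * (self.n_lineages + len(self.shared_groups))
        if needed > self.n_genes:
            raise SynthConfigError(
                f"{self.n_genes} genes cannot host {needed} marker slots"
            )
        for group, members in self.shared_groups.items():
            if any(m >= self.n_lineages for m in members):
                raise SynthConfigError(f"group {group!r} names an unknown lineage")


def _lineage_names(n: int) -> list[tuple[str, str]]:
    pairs = []
    for i in range(n):
        tissue = _TISSUES[i % len(_TISSUES)]
        cell_type = _CELL_TYPES[i % len(_CELL_TYPES)]
        if i >= len(_TISSUES):
            tissue = f"{tissue} {i // len(_TISSUES) + 1}"
        pairs.append((tissue, cell_type))
    return pairs


def make_expression_table(truth: ExpressionGroundTruth,
                          n_genes: int | None = None,
                          n_lineages: int | None = None) -> tuple[str, dict]:
    """Emit the 7-column HPA dialect plus a ground-truth manifest."""
    if n_genes is not None or n_lineages is not None:
        truth = ExpressionGroundTruth(
            **{**truth.__dict__,
               "n_genes": n_genes or truth.n_genes,
               "n_lineages": n_lineages or truth.n_lineages},
        )
    rng = np.random.default_rng(truth.seed)

    genes = [f"GENE{i:04d}" for i in range(truth.n_genes)]
    ensembl = {g: f"ENSG{90000000 + i:011d}" for i, g in enumerate(genes)}
    lineages = _lineage_names(truth.n_lineages)
    keys = [f"{t} {c}" for t, c in lineages]

    # disjoint marker blocks: one per lineage, then one per shared group
    cursor = 0
    markers: dict[str, list[str]] = {}
    for key in keys:
        markers[key] = genes[cursor:cursor + truth.markers_per_lineage]
        cursor += truth.markers_per_lineage
    group_markers: dict[str, list[str]] = {}
    for group in truth.shared_groups:
        group_markers[group] = genes[cursor:cursor + truth.markers_per_lineage]
        cursor += truth.markers_per_lineage

    baseline = np.exp(rng.normal(truth.baseline_mu, truth.baseline_sigma,
                                 size=truth.n_genes))

    lines = ["Gene\tGene.name\tTissue\tCluster\tCell.type\tRead.count\tnTPM"]
    for li, (tissue, cell_type) in enumerate(lineages):
        key = keys[li]
        lineage_markers = set(markers[key])
        for group, members in truth.shared_groups.items():
            if li in members:
                lineage_markers.update(group_markers[group])
        expected = baseline * np.where(
            [g in lineage_markers for g in genes], truth.marker_multiplier, 1.0
        )
        for cluster in range(truth.n_clusters):
            noise = (np.exp(rng.normal(0.0, truth.noise_sigma, truth.n_genes))
                     if truth.noise_sigma > 0 else np.ones(truth.n_genes))
            values = expected * noise
            reads = np.exp(rng.normal(5.0, 1.0, truth.n_genes))  # deliberately
            # only weakly related to nTPM, as read counts are in real data
            for gi, gene in enumerate(genes):
                lines.append(
                    f"{ensembl[gene]}\t{gene}\t{tissue}\tc-{cluster}\t{cell_type}"
                    f"\t{reads[gi]:.1f}\t{values[gi]:.4f}"
                )

    manifest = {
        "seed": truth.seed,
        "n_lineages": truth.n_lineages,
        "n_clusters": truth.n_clusters,
        "n_genes": truth.n_genes,
        "marker_multiplier": truth.marker_multiplier,
        "noise_sigma": truth.noise_sigma,
        "lineages": keys,
        "markers": markers,
        "group_markers": {
            group: {"genes": group_markers[group],
                    "lineages": [keys[m] for m in members]}
            for group, members in truth.shared_groups.items()
        },
        "baseline_means": {g: float(b) for g, b in zip(genes, baseline)},
    }
    return "\n".join(lines) + "\n", manifest


# ---------------------------------------------------------------------------
# SBML corpora
# ---------------------------------------------------------------------------

@dataclass
class SbmlGroundTruth:
    """Planted structure for the synthetic Reactome-like corpus."""

    n_models: int = 6
    species_per_model: int = 25
    reactions_per_model: int = 8
    modifiers_per_model: int = 2
    # model index -> number of planted gap species (product-only, identifier
    # appearing nowhere else in the corpus)
    gaps_per_model: dict[int, int] = field(default_factory=lambda: {0: 1, 1: 1})
    # identifier -> model indices sharing it (placed on mediator species)
    shared_identifiers: dict[str, list[int]] = field(
        default_factory=lambda: {"P10000": [0, 1], "P10001": [1, 2, 3]}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.species_per_model, self.reactions_per_model) < 1:
            raise SynthConfigError("corpus sizes must be positive")
        if self.n_models < 2:
            raise SynthConfigError("cross-model analysis needs at least 2 models")
        chain = self.reactions_per_model + 1
        for m, count in self.gaps_per_model.items():
            if m >= self.n_models:
                raise SynthConfigError(f"gap model index {m} out of range")
            spare = self.species_per_model - chain - self.modifiers_per_model
            if count > spare:
                raise SynthConfigError(
                    f"model {m}: {count} gaps exceed {spare} spare species"
                )
        for ident, members in self.shared_identifiers.items():
            if any(m >= self.n_models for m in members):
                raise SynthConfigError(f"shared id {ident} names an unknown model")


def _build_model(truth: SbmlGroundTruth, m: int) -> tuple[PathwayModel, dict]:
    """One connected bipartite model: a reaction chain with planted extras."""
    model_id = f"SYN-{m:03d}"
    model = PathwayModel(model_id=model_id, model_name=f"synthetic pathway {m}",
                         compartments=["cytosol"])
    roles: dict[str, str] = {}
    n_rxn = truth.reactions_per_model
    chain = [f"S{m}_{i}" for i in range(n_rxn + 1)]
    gap_count = truth.gaps_per_model.get(m, 0)
    n_extra = truth.species_per_model - len(chain) - truth.modifiers_per_model
    if n_extra < gap_count:
        raise SynthConfigError(f"model {m}: infeasible species budget")

    def add_species(sid: str, uris: list[str]) -> None:
        model.species[sid] = SpeciesNode(
            species_id=sid,
            display_name=sid.replace("_", " "),
            compartment="cytosol",
            sbo_term="SBO:0000252",
            annotation_uris=uris,
        )

    shared_on_model = [ident for ident, members in truth.shared_identifiers.items()
                       if m in members]
    for i, sid in enumerate(chain):
        if i == len(chain) - 1:
            # terminal product: identifier common to all models so the chain
            # end never masquerades as a knowledge gap
            uris = [f"{URI_PREFIX}TERMINALX"]
        else:
            uris = [f"{URI_PREFIX}CHAIN{m}X{i}"]
        # shared identifiers ride on interior (mediator) chain species
        if 0 < i < len(chain) - 1 and shared_on_model:
            idx = i - 1
            if idx < len(shared_on_model):
                uris.append(f"{URI_PREFIX}{shared_on_model[idx]}")
        add_species(sid, uris)
    if len(shared_on_model) > len(chain) - 2:
        raise SynthConfigError(f"model {m}: not enough mediators for shared ids")

    modifiers = [f"M{m}_{j}" for j in range(truth.modifiers_per_model)]
    for j, sid in enumerate(modifiers):
        add_species(sid, [f"{URI_PREFIX}MOD{m}X{j}"])

    extras, gap_species = [], []
    for j in range(n_extra):
        sid = f"X{m}_{j}"
        if j < gap_count:
            uri = f"{URI_PREFIX}GAP{m}X{j}"
            gap_species.append((sid, f"GAP{m}X{j}"))
        else:
            # an identifier recurring across models, so never a gap candidate
            uri = f"{URI_PREFIX}XPRODX{j}"
        add_species(sid, [uri])
        extras.append(sid)

    for i in range(n_rxn):
        rxn = ReactionNode(
            reaction_id=f"R{m}_{i}",
            display_name=f"step {i}",
            reactants=[ParticipantRef(chain[i], 1.0, ROLE_REACTANT)],
            products=[ParticipantRef(chain[i + 1], 1.0, ROLE_PRODUCT)],
        )
        if i < len(modifiers):
            rxn.modifiers.append(ParticipantRef(modifiers[i], 1.0, ROLE_MODIFIER))
        model.reactions.append(rxn)
    for j, sid in enumerate(extras):
        model.reactions[j % n_rxn].products.append(
            ParticipantRef(sid, 1.0, ROLE_PRODUCT)
        )

    roles[chain[0]] = "input"
    for sid in chain[1:-1]:
        roles[sid] = "mediator"
    roles[chain[-1]] = "output"
    for sid in modifiers:
        roles[sid] = "input"
    for sid in extras:
        roles[sid] = "output"

    meta = {
        "roles": roles,
        "gaps": [{"species_id": sid, "identifier": ident}
                 for sid, ident in gap_species],
    }
    return model, meta


def make_sbml_corpus(truth: SbmlGroundTruth) -> tuple[dict[str, str], dict]:
    """Emit a corpus of SBML files keyed by filename plus its manifest."""
    files: dict[str, str] = {}
    manifest: dict = {
        "seed": truth.seed,
        "n_models": truth.n_models,
        "models": {},
        "gaps": [],
        "shared_identifiers": {
            ident: [f"SYN-{m:03d}" for m in members]
            for ident, members in truth.shared_identifiers.items()
        },
    }
    all_identifiers: set[str] = set()
    for m in range(truth.n_models):
        model, meta = _build_model(truth, m)
        files[f"{model.model_id}.sbml"] = write_sbml(model)
        manifest["models"][model.model_id] = meta
        for rep in meta["gaps"]:
            manifest["gaps"].append({"model_id": model.model_id, **rep})
        for sp in model.species.values():
            for uri in sp.annotation_uris:
                all_identifiers.add(uri.rsplit("/", 1)[-1].lower())
    manifest["n_distinct_identifiers"] = len(all_identifiers)
    _check_manifest(files, manifest)
    return files, manifest


def _check_manifest(files: dict[str, str], manifest: dict) -> None:
    """Post-generation consistency check: re-derive planted facts from files."""
    from .netgraph import classify_species_roles
    from .orthogonality import build_corpus_index, find_gap_species
    from .sbml_io import parse_sbml

    models = [parse_sbml(text) for text in files.values()]
    for model in models:
        derived = {sr.species_id: sr.role for sr in classify_species_roles(model)}
        if derived != manifest["models"][model.model_id]["roles"]:
            raise SynthConfigError(
                f"model {model.model_id}: derived roles disagree with manifest"
            )
    derived_gaps = {
        (r.model_id, r.species_id)
        for r in find_gap_species(build_corpus_index(models))
    }
    planted = {(g["model_id"], g["species_id"]) for g in manifest["gaps"]}
    if derived_gaps != planted:
        raise SynthConfigError(
            f"gap mismatch: derived {sorted(derived_gaps)} != planted {sorted(planted)}"
        )
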