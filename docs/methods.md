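# Methods

## Network model and parsing

An SBML pathway model is held as a bipartite graph: species nodes and
reaction nodes, with participant edges in three roles (reactant, product,
modifier). Parsing is namespace-agnostic (elements matched on local names)
so Reactome's level/version drift and embedded RDF annotation blocks do not
break loading; a real XML parser is used throughout rather than pattern
matching, which is strictly more robust on the same files. Absent
stoichiometry defaults to 1.0 and absent `reversible` to false. Species
annotation URIs are harvested in document order from any `rdf:resource`
attribute inside the species' annotation block; all are kept, in order.
Model-level annotation and layout blocks are not part of the network
structure and are dropped on read (a logged warning notes this).

Writing emits SBML Level 3 with one `kineticLaw` block per parameterized
reaction. Rate expressions live in memory as Python-syntax infix text and
are serialized as content MathML (`times`, `divide`, `plus`, `minus`,
`power`, `ci`, `cn`); the reader converts that operator subset back to a
canonical infix form, so write∘parse is the identity on the in-memory
representation. MathML outside this subset (e.g. `exp`) is preserved
verbatim as a `custom` law rather than mistranslated.

## Species roles, pruning, export

Roles partition the species set: consumed-only (reactant or modifier) →
input; produced-only → output; both → mediator; unreferenced → isolated.
Modifiers count as consumption because a catalytic engagement is a
functional dependence on the species.

Pruning is defined on the reaction-adjacency projection: two reactions are
adjacent iff they share at least one participant species, *including
modifiers* (they are participants; a configurable exclusion was considered
and rejected as it changes distances silently). Depth is the BFS hop count
from the focus reaction; depth 0 keeps the focus alone, and any depth at or
beyond the component diameter saturates to the focus's connected component.
Retained species are exactly the participants of retained reactions.

DOT export uses one fixed style table (species: ellipse; reactions: orange
filled boxes; every edge labelled with its role) so exported files are
byte-stable. Duplicate display names — common in Reactome, where one
molecule recurs across compartments — are disambiguated by appending the
species id. SIF export is one tab-separated `source role target` line per
participant edge; both exports carry the same edge multiset as the model.

## Identifier mapping and gap detection

Cross-model species identity cannot use SBML species ids (they are
model-scoped); it uses the final path segment of each annotation URI
(`…/uniprot/P09016` → `P09016`), optionally widened to HGNC gene symbols.
Mapping between symbol/Ensembl/UniProt namespaces is case-insensitive and
list-valued; multi-accession UniProt cells are split on `|` and whitespace
since HGNC dumps vary. Only protein/gene identifiers are mapped; other
ontology types (small molecules) surface their raw URIs.

A **gap species** is product-only in its own model with no identifier
appearance in any other model of the corpus, in any role — a modifier-only
appearance elsewhere disqualifies it, because that appearance is precisely
the downstream action whose absence the gap would flag. Species with no
identifiers are excluded from cross-model claims and counted in the report
footer. Overlap between two models is the Jaccard index of their identifier
sets (0 when both are empty).

## Pathway search

The local index search lowercases the query, splits on whitespace and
requires every token as a substring of the concatenated id/name/organism
fields. Ranking is a declared convention, not an inherited one: entries hit
in more distinct fields first, then shorter names, then id — a total,
deterministic order that puts `glycolysis homo sapiens` style queries'
species-specific entries on top.

## Kinetics

Injected laws use global uniform constants (defaults k_f = v_max = k_m =
1.0, dimensionless units) with optional per-reaction overrides. Mass action
raises each reactant to its stoichiometry; a reactant-free reaction becomes
a constant source at rate k_f. Michaelis–Menten takes the *first listed
reactant* as substrate — the files carry no enzyme/substrate distinction,
so this convention is explicit and logged; reactant-free reactions are
skipped and reported. Modifiers are ignored by both laws; this is a known
simplification, as is the single global parameter set.

The integrator is classical fixed-step RK4 on d[X]/dt = Σ_r (s_out −
s_in)·v_r, intended as a sanity harness (it reproduces the analytic
unimolecular decay to ~1e-15 at dt = 1e-3 and conserves closed-system mass
to the same order), not a production solver: no stiffness control, no
events, no adaptive stepping. Species without an initial amount start at
1.0. Non-finite states abort with the offending time point.

## Expression pipeline

Lineage keys concatenate the `Tissue` field verbatim with `Cell.type`,
separated by one space (`Placenta smooth muscle cells`); in
cluster-resolved mode ` c-<cluster>` is appended (a leading `c-` already on
the cluster label is not doubled). Per-(gene, lineage) dispersion uses the
sample standard deviation (n−1) — the convention pinned by reproducing the
reference DEFA5 value 541,585 from its three printed replicates, where the
population estimator gives ≈442,200 — and CV% = 100·sd/mean; singletons and
zero-mean groups yield NA and are excluded (with counts) from summary
means.

Aggregation takes the median per (gene, lineage) over cluster rows (merge
mode) or per (gene, lineage, cluster) (retain mode); collapsing the
retained table by median reproduces the merged one. The pivoted matrix
fills absent (gene, lineage) cells with 0 nTPM — absence of reads, not
missingness, which keeps feature vectors dense; the choice is logged.
Constant columns (including all-zero) are dropped and listed, since they
carry no contrast and would break Min–Max normalization.

Min–Max normalization rescales each gene column to [0, 1] and stores the
(min, max) pair for query projection. Queries are normalized with those
stored parameters and clamped to [0, 1] (new data may exceed the observed
range); matrix genes absent from a query are 0-filled, query genes absent
from the matrix are ignored with a warning — the asymmetry is deliberate:
the matrix defines the feature space. Classification returns the top-k
lineages by L1 distance, ties broken by key sort. L2 is available for the
all-pairs distance matrix; L1 is the default for its robustness on
heavy-tailed expression features.

Z-profiles standardize one gene across all lineages (sample sd; a
per-tissue restriction is possible by filtering rows first). Default tiers
|z| ≥ 2 / |z| ≥ 3 are conventional normal-quantile cutoffs and are
configurable; a constant gene yields all-zero z. Note that with n lineages
the largest attainable |z| is bounded near √n, so a single expressing
lineage among ten cannot exceed the "very significant" tier — thresholds
should be read relative to panel size.

Exports write one TSV per lineage (genes by descending nTPM), one per gene
(lineages by descending z) and the distance matrix — #lineages + #genes + 1
files, logged in a manifest — with fixed float formatting so re-export is
byte-identical.

## Synthetic data

The expression generator emulates the structure of HPA's single-cell
archive: per-gene log-normal baselines (log-mean 1.0, log-sd 1.0, i.e.
median ≈ 2.7 nTPM with a heavy right tail), disjoint 10-gene marker blocks
per lineage scaled by 5× in their home lineage, an extra marker block
shared by the two smooth-muscle lineages (so related lineages are mutually
proximal), multiplicative log-normal cluster noise with log-sd 0.2, and
read counts only weakly related to nTPM. Default scale is 8 lineages × 3
clusters × 300 genes — a desk-scale stand-in chosen so the full pipeline
runs in well under a second. What it does *not* emulate: dropout and
zero-inflation, correlated gene programs, batch structure, the true
lineage count (hundreds) or gene count (~20k). Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
structure, not classifier performance on real atlas data.

The SBML generator builds each model as a reaction chain (guaranteeing a
connected projection graph) with modifier species, extra product-only
species, and annotation URIs minted in identifiers.org style. Planted
facts: chain heads/modifiers are inputs, interiors mediators, chain tails
and extras outputs; declared identifiers are shared across declared model
sets; gap species are product-only with corpus-unique identifiers, while
every other product-only species carries an identifier recurring in other
models so it cannot masquerade as a gap. The generator re-derives all
planted facts from the emitted files through the public API after
generation and refuses to return an inconsistent manifest. At least two
models are required, since gap detection is a cross-model notion.

## Numerical conventions

Median of an even-sized list is the mean of the two central values. Ties
in search and classification break by lexicographic key. NA propagation
follows the NA-excluded-mean rule stated above. All generator and
acceptance randomness flows from a single integer seed through
`numpy.random.default_rng`; nothing reads global random state.

## Known limitations

No SBML validator compliance or MIRIAM checking; no stochastic simulation;
no species-centred pruning; live database fetches are out of scope by
design (all references are local files); supervised classification is
deliberately absent — with one median vector per lineage there is nothing
to train on, which is exactly why a distance-based classifier is used.
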