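# Methods

This note documents the models, rules and numerical choices behind
`seednet`, what the synthetic fixtures do and do not emulate, and the
design decisions taken where more than one reading was defensible.

## Identifier model

A gene record carries up to three identifiers — HUGO-style symbol, Entrez
integer ID, UniProt accession — with at least one present. The canonical
key is the upper-cased symbol when available, else `ENTREZ:<id>`, else the
accession. Matching is case-insensitive for symbols, numeric for Entrez,
and case-insensitive with isoform suffixes (`-2` etc.) stripped for
UniProt. Query tokens are tried namespace by namespace in the order
symbol → Entrez → UniProt (configurable per store); the first hit wins, so
a token that is simultaneously an Entrez ID of one gene and a symbol of
another resolves to the symbol owner under the default order. An
identifier value claimed by two records is *ambiguous*: it is removed from
the lookup index at load time (noted in the load report) and tokens
hitting it are rejected with reason `ambiguous` rather than silently
resolved. Total rejection of a query raises a distinct error from partial
rejection, which only logs.

## Interactome loading

Edge lists are TSV with a declared column dialect (two interactor columns,
optional interaction-type column, optional header). Presets cover a
generic two-column layout, an HPRD-style flat file (symbols at columns 0
and 3) and a BioGRID-style table (Entrez IDs at columns 1 and 2, type code
at column 11). When a type filter is supplied and the dialect carries a
type column, a row is kept iff its type cell contains one of the requested
codes; codes are extracted tolerantly (bare `0417`, `MI:0417`,
`psi-mi:"MI:0417"(...)` all match). Self-loops are dropped, duplicate
edges (in either orientation) collapsed, and unresolvable rows skipped;
every drop is tallied by reason in a retrievable load report. Genes
present in the ID table with zero edges stay in the store — they are legal
isolated inputs and are needed for disconnected-gene accounting. Merging
multiple source files is by union of their edge sets after
canonicalization; the package takes no position on cross-database conflict
resolution beyond the ID table it is given.

## Subnetwork recruitment

All shortest paths are computed on the **full interactome**, never on the
growing subnetwork. Candidate-only mode: for each candidate, all
candidates at minimal positive distance, and all distinct shortest paths
to each, are recruited; candidate interactors are always recruited.
Two-set mode: paths run only candidate → closest target(s); target
interactors are not recruited; unreachable targets remain as isolated
target-role nodes. A gene in both sets has role `both`, behaves as a
candidate for recruitment, and is excluded from its own target search
(distance-0 self-paths are degenerate).

Node roles follow the precedence both > candidate > target > intermediate
> interactor; in particular a direct interactor that also lies interior to
a logged path is reported as `intermediate`.

**Edge set.** The default subnetwork contains only candidate-incident
interactome edges plus edges lying on logged shortest paths — the
recruited network is a union of star neighborhoods and path trees, not the
induced subgraph. Whether edges between two recruited interactors should
be drawn is genuinely open; the induced-subgraph alternative is available
via `induced_edges=True` and changes nothing else.

A candidate with no path to any other seed recruits only its direct
interactors and persists in the network (and in the disconnected count).

## Connectivity statistics

Pairs are all unordered candidate pairs (one-set) or all candidate ×
target cross pairs excluding self-pairs (two-set). Each pair contributes
its interactome hop count exactly once — co-minimal path multiplicity
never inflates the average — or the sentinel when no path exists.
Defaults: sentinel 17 hops. That constant is tied to a particular human
interactome snapshot (five edges beyond its observed maximum distance),
so it is a config parameter, not a universal truth; raising it can only
raise min/avg (tested as a monotonicity property). Asymmetric exclusion
rule: targets unreachable from every candidate are removed from the pair
set before averaging, while disconnected candidates stay and contribute
the sentinel; only disconnected candidates are reported. Consequence: the
"targets = candidates equals candidate-only" symmetry holds exactly when
the seed set is mutually reachable, and is tested under that condition.
Degenerate case the source analyses never exercise: if *every* target is
unreachable the pair set is empty; we then report min = avg = sentinel
with `pair_count = 0`. One-set queries need ≥ 2 candidates; fewer is an
error, not a NaN.

## Random baselines

Null model: node resampling only (no degree-preserving rewiring). Random
sets are drawn uniformly without replacement from the store's full gene
universe — isolated genes included, overlap with the true sets allowed —
matching the cardinality of the set they replace. Five replicates by
default; per-scheme rows are arithmetic means over replicates of each
statistic, so fractional mean disconnected counts (e.g. 2.6) are expected,
and the baseline `min_spl` row is the mean of per-replicate minima (not
the minimum of means). Each scheme draws independently per replicate; the
RNG is numpy's default PCG64 `Generator` seeded explicitly, making runs
reproducible given (seed, replicates) on any platform with the same numpy
generator. Scheme names: `random` (one-set); `candidate_to_random` (real
candidates, random targets), `random_to_target` (random candidates, real
targets), `random_to_random` (two-set).

## Enrichment

`fisher_upper_tail(k, n, K, N)` = P(X ≥ k) for X ~ Hypergeom(N, n, K),
evaluated through scipy's hypergeometric survival function (log-space
internally; verified against exact arbitrary-precision tail sums to
< 1e-9 relative error on the exhaustive lattice of tables with N ≤ 60,
and stable in spot checks at N = 1e5). k = 0 returns exactly 1. The
tested gene set defaults to **all** subnetwork nodes, including recruited
interactors and intermediates (`gene_set="candidates"` restricts to the
query); the universe defaults to all store genes
(`universe="catalogs"` switches to the union of catalog genes). The test
is one-sided (over-representation only). No multiple-testing correction
by default — the headline use reports raw p-values — with per-category
Benjamini–Hochberg available on request. Terms overlapping fewer than
`min_overlap` (default 1) genes are omitted; results sort ascending by
p-value within category, ties broken by term name for determinism.

## Exports and the results document

SIF lines are `geneA<TAB>pp<TAB>geneB` in lexicographic order; nodes not
covered by any emitted edge are written as bare single-token lines so
isolated genes survive a round-trip. `shortest_paths_only` scope restricts
to edges on logged paths. Gene lists are one identifier per line in the
requested namespace, deduplicated and sorted; genes lacking that namespace
fall back to their canonical key with a logged warning. The results
document is JSON with a versioned schema (pydantic-validated, unknown
fields rejected), sorted keys and stable ordering: write → read → write is
byte-identical, and reloading reproduces every report without
recomputation. Timestamps live only in the metadata block and default to
empty, keeping content deterministic.

## Synthetic fixtures

Generators: Erdős–Rényi G(n, p) (sparse homogeneous baseline),
Barabási–Albert preferential attachment (hub-dominated degree structure,
the feature of real PPI networks most relevant to path statistics), and
`path_union`, which plants exact pairwise distances via fresh disjoint
intermediate chains for closed-form checks. ID triples follow distinct
per-namespace patterns (`SYM0001` / `9000001` / `Q900001`) so
namespace-confusion bugs fail loudly. Duplicate and self-loop rows can be
injected in known numbers to exercise loader accounting. Catalogs plant
terms with exact overlaps against a named gene set. Every planted fact is
recorded in a JSON manifest verifiable against the emitted files, and a
fixed seed yields byte-identical files.

What the fixtures do **not** emulate: the real human interactome's size
(~16k proteins), its precise degree distribution, literature bias,
database-specific identifier noise, or correlated annotation structure.
Passing tests therefore demonstrate algorithmic correctness of
recruitment, counting and tail computation — not that any biological
conclusion from a real dataset would replicate.

## Problem sizes used in verification

Exhaustive builder verification runs over all non-isomorphic connected
graphs on ≤ 8 nodes — the 995 atlas graphs up to 7 nodes plus all 11,117
8-node graphs generated by single-vertex extension of the 7-node set
(complete, since every connected graph has a non-cut vertex) with
isomorphism dedup — plus 100 seeded random fixtures up to 50 nodes.
Connectivity is cross-checked against a hand-rolled pairwise-BFS oracle on
100 seeded fixtures; null-model calibration compares a 500-replicate
baseline on a 12-gene store against exact enumeration of all C(12,3)
candidate subsets (within three standard errors). The acceptance script
uses a 500-gene preferential-attachment interactome with a planted
30-gene term sharing 10 genes with the analyzed network. These sizes were
chosen to make every check exact or statistically calibrated at desk
scale.

## Known limitations

* The null model resamples nodes only; degree-matched nulls would be
  stricter for hub-heavy queries and are deliberately out of scope.
* Shortest-path recruitment is unweighted; confidence-scored interactomes
  are treated as binary.
* Connectivity statistics are computed on the full interactome, not the
  constructed subnetwork (consistent with recruitment, where "nearest" is
  defined in the interactome); on the subnetwork itself the same pairs
  can only be equally or less connected.
* Gene Ontology enrichment, network visualization and any live database
  retrieval are out of scope.
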