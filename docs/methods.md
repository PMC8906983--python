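# Methods

## Scope and model

`herbnet` implements the standard herb-to-target inference chain of network
pharmacology as a deterministic, offline computation. The pipeline treats
the problem as four successive set/graph operations plus one statistical
test:

1. a **conjunctive ADME filter** on ingredient descriptors (OB, in percent,
   and DL, dimensionless in [0, 1]);
2. a **set intersection** of normalized gene-symbol sets;
3. **centrality analysis** of two undirected simple graphs — the
   protein-protein interaction (PPI) graph over the intersection genes and
   the heterogeneous drug–ingredient–disease–target graph;
4. **over-representation analysis** (ORA) of the intersection genes against
   user-supplied GMT collections.

No biological inference happens beyond these operations: the package makes
the bookkeeping exact and reproducible, it does not model pharmacology
mechanistically.

## Parameters that matter

| parameter | default | units / scale | rationale |
|---|---|---|---|
| `ob_min` | 30 | percent, same scale the source tables print | conventional TCMSP activity cut-off |
| `dl_min` | 0.18 | dimensionless | conventional drug-likeness cut-off |
| `inclusive` | true | — | thresholds read as ≥; strict `>` available for sensitivity analysis |
| `score_min` | 0.4 | STRING combined score in [0, 1] | STRING's "medium confidence 0.400"; inclusive by default, strict flag for the literal `> 0.4` reading; 0–1000 integer scores auto-detected and divided by 1000 |
| `p_max` | 0.05 (GO), 0.01 (pathway) | raw p | the two cut-offs conventional ORA reports use; filtering uses raw p, BH q is always reported alongside but not filtered on |
| `top_k` | 30 | count | hub-list length, the usual "top 30" histogram |

## Centrality definitions and numerical choices

- **Degree** is the raw neighbour count, not normalized.
- **Closeness** is the un-normalized reciprocal total distance
  `CC(v) = 1/Σ_u d(v,u)`. This variant (rather than `(n−1)/Σd`) is what the
  undirected cytoHubba output reports: a reference compound closeness of
  0.013157895 is exactly 1/76, an integer distance sum, which only the
  un-normalized form produces. The normalized form sits behind a flag.
  Distances are restricted to the node's connected component, so hidden-
  free-node graphs give finite values; singleton components score 0.
- **Betweenness** is un-normalized Brandes over unordered pairs, endpoints
  excluded, with fractional shortest-path-multiplicity weighting
  `σ_st(v)/σ_st` (non-integer published values require the fractional form).
  The implementation accumulates single-source dependencies and halves the
  ordered-pair total.
- **Ties** in every ranking break by ascending node id, making all outputs
  deterministic.
- **Graph invariants**: self-loops are rejected (input self-loops are
  skipped with a warning), parallel edges collapse keeping the maximum
  score, and every edge endpoint must be a declared typed node.
- **Display rounding**: all values are kept at full precision internally;
  the mean degree `2E/N` is *truncated* (not rounded) to one decimal in
  display contexts (11.65 → "11.6"), matching how interaction-database
  summaries print it.
- The heterogeneous graph gives every compound one drug edge in addition to
  its target edges, so its graph degree is the compound–target degree plus
  one; compound importance is computed on the full graph, where the constant
  +1 cannot change the ordering.

## ORA

The statistic is the one-sided hypergeometric upper tail (equivalent to
one-sided Fisher exact), evaluated through scipy's survival function
(log-space internally) so deep tails keep precision; `k = 0` returns
exactly 1. The universe defaults to the union of the loaded collection
(self-contained, no external gene catalogue) and can be overridden with an
explicit gene list. Query genes outside the universe are dropped with a
logged count. Every term is tested and enters the Benjamini–Hochberg family
(statsmodels step-up); zero-overlap terms are never *reported* but do count
toward `m`, since the correction must cover all tests performed.

## Synthetic data: what it emulates, what it does not

The generators in `herbnet.fixtures` stand in for the live databases the
workflow normally queries (ingredient tables, target lists, scored
interactome, annotation collections). They are built for **exact count
control**, not statistical realism:

- stratified assignment guarantees the headline counts exactly (pass
  counts, set sizes and overlaps, surviving-edge counts, planted-term
  overlaps) rather than in expectation;
- the interactome is a random spanning tree plus planted hubs wired to
  `h = ceil(hub_degree_factor · 2E/N)` neighbours and background edges
  capped below `h − 1`, so planted hubs provably out-rank all other nodes —
  the generator verifies this and fails loudly if a configuration cannot
  satisfy it. Degree correlations, clustering and evidence-channel structure
  of real interactomes are *not* emulated;
- OB/DL values are drawn from a shifted gamma / uniform scheme that respects
  the screen strata but has no chemical meaning;
- one annotation term is planted to overlap the query by a chosen count;
  background terms are uniform draws.

Passing tests on these inputs therefore demonstrates the *correctness of the
computations* (counts, centralities, tail probabilities, determinism), not
that the pipeline's biological conclusions transfer to real databases, whose
contents drift between versions.

The study preset (`--preset paper`, one integer seed) fixes the generator at
the reference conditions: 63 ingredients with 5 passing, 51 drug targets vs
5376 disease genes overlapping in the 41 packaged reference genes, a 40-node
/ 233-edge interactome with 6 planted hubs at `hub_degree_factor = 2.5`
(hub degree 30, the magnitude of the study's top hubs), and a planted
pathway term of 20 genes sharing 15 with the 41-gene query in a 2000-gene
universe. One `numpy.random.SeedSequence` spawns an independent child stream
per generator, so identical configs produce byte-identical files.

## Packaged reference tables

The five active compounds (with OB/DL values), the 41 intersection genes
(with Entrez ids), and the per-compound centralities are packaged verbatim
in `herbnet.tables`. The underlying compound–target edge list was never
published; `compound_target_map()` is therefore a **synthetic** assignment
constructed to reproduce the printed per-compound degrees (46 links total,
every target covered). Published compound closeness/betweenness values are
carried as reference data but are not reproduced, since they depend on that
unpublished edge list; the internal consistency 1/0.013157895 = 76 is noted
above.

## Design choices where the design was open

- **Symbol normalization** (the upstream "name correction" step is
  tool-specific and undocumented): trim → uppercase → strip internal
  whitespace, with an optional user-supplied alias TSV applied after
  casefolding. Deterministic and documented beats an opaque script.
  Duplicates after normalization merge silently but are logged.
- **Gene identity is by symbol**; Entrez ids are carried as annotation only,
  because every computation in the chain operates on symbols.
- **Synthetic runs route through files**: the pipeline writes the generated
  bundle to `<out>/inputs/` and loads it back through the ordinary loaders,
  so synthetic and user-supplied runs exercise identical code paths.
- **Failure policy**: malformed inputs fail at load with file/line context;
  a stage failure aborts the run naming the stage, keeping artifacts already
  written.

## Problem sizes

The test suite and acceptance script run at the preset sizes above plus:
200 random graphs of 5–25 nodes for the centrality/oracle equivalence
checks, exhaustive hypergeometric enumeration for all universes N ≤ 12,
200 null-query replicates for ORA calibration, and 50 seeds of a 50-node /
120-edge / 5-hub interactome for planted-hub recovery. The full suite
completes in a few seconds on one CPU.

## Known limitations

- No live database access by design; real TCMSP/GeneCards/STRING exports
  must be supplied as files in the documented dialects.
- Only DC/CC/BC are implemented (no MCC/MNC/EPC-style scores), shortest
  paths are unweighted, and no layout/visualization is produced — the
  SIF/GraphML exports are meant for Cytoscape.
- ORA is overlap-based only (no ranked GSEA), with no term-redundancy
  collapsing.
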