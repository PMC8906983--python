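"""Seeded synthetic-data generators emulating the upstream web resources.

The study's computational inputs (herb ingredient tables, drug and disease
target lists, a scored interactome, annotation gene sets) all came from live
databases that cannot be queried offline and whose contents drift.  This
module generates structurally equivalent inputs with *exact*, controllable
headline counts — how many ingredients pass the ADME screen, how large the
target sets and their overlap are, how many scored edges survive the
confidence threshold, which interactome nodes are planted hubs, and which
annotation term is planted as enriched — so that every pipeline stage runs,
and is testable, with zero downloads.

All generators are pure functions of a :class:`SyntheticConfig`: one integer
seed drives independent spawned random streams (one per generator), so the
same config always produces byte-identical output files.  Counts are built
by stratified assignment, not rejection sampling, so they hold exactly
rather than in expectation.  Synthetic gene symbols use reserved prefixes
(``SYN`` for the target universe, ``ANN`` for annotation filler, ``FREE``
for sub-threshold interactome decoys) that cannot collide with the packaged
reference gene symbols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import tables
from .enrichment import GeneSetCollection, GeneSetTerm, write_gmt
from .network import ScoredEdge, write_scored_edges
from .screening import IngredientRecord, write_ingredients
from .targetsets import TargetSet, write_symbols

__all__ = [
    "SyntheticConfig",
    "paper_preset",
    "gen_ingredient_table",
    "gen_target_sets",
    "gen_ppi",
    "gen_annotations",
    "gen_ingredient_targets",
    "write_bundle",
]

# fixed spawn keys: each generator owns one independent stream
_STREAM_INGREDIENTS = 0
_STREAM_TARGETS = 1
_STREAM_PPI = 2
_STREAM_ANNOTATIONS = 3
_STREAM_MAPPING = 4


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic-data generators.

    Defaults reproduce the study's headline counts: 63 candidate ingredients
    of which 5 pass the screen; 51 drug targets and 5376 disease targets
    overlapping in exactly the 41 packaged reference genes; a 40-node
    interactome with 233 above-threshold edges; and one annotation term of
    20 genes planted to share 15 genes with the 41-gene query inside a
    2000-gene universe.
    """

    seed: int = 7
    # ingredient table
    n_ingredients: int = 63
    pass_fraction: float = 5 / 63
    # target sets
    n_universe: int = 8000
    n_drug_targets: int = 51
    n_disease_targets: int = 5376
    n_overlap: int = 41
    inject_reference_targets: bool = True
    # interactome
    ppi_nodes: int = 40
    ppi_edges: int = 233
    ppi_planted_hubs: int = 6
    hub_degree_factor: float = 2.5
    # annotations
    n_terms: int = 60
    planted_term_size: int = 20
    planted_overlap: int = 15
    query_size: int = 41
    annotation_universe: int = 2000

    def __post_init__(self) -> None:
        counts = {
            "n_ingredients": self.n_ingredients,
            "n_universe": self.n_universe,
            "n_drug_targets": self.n_drug_targets,
            "n_disease_targets": self.n_disease_targets,
            "n_overlap": self.n_overlap,
            "ppi_nodes": self.ppi_nodes,
            "ppi_edges": self.ppi_edges,
            "ppi_planted_hubs": self.ppi_planted_hubs,
            "n_terms": self.n_terms,
            "planted_term_size": self.planted_term_size,
            "planted_overlap": self.planted_overlap,
            "query_size": self.query_size,
            "annotation_universe": self.annotation_universe,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if not (0 <= self.pass_fraction <= 1):
            raise ValueError(f"pass_fraction must be in [0, 1], got {self.pass_fraction}")
        if self.n_overlap > min(self.n_drug_targets, self.n_disease_targets):
            raise ValueError("n_overlap cannot exceed either target-set size")
        if self.planted_overlap > min(self.planted_term_size, self.query_size):
            raise ValueError("planted_overlap cannot exceed term or query size")
        if self.ppi_planted_hubs > self.ppi_nodes:
            raise ValueError("ppi_planted_hubs cannot exceed ppi_nodes")
        if self.hub_degree_factor <= 0:
            raise ValueError("hub_degree_factor must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(5)
        return np.random.default_rng(children[stream])


def paper_preset(seed: int = 7) -> SyntheticConfig:
    """The default study-condition configuration with a chosen seed."""
    return SyntheticConfig(seed=seed)


# ---------------------------------------------------------------------------
# ingredient table
# ---------------------------------------------------------------------------


def gen_ingredient_table(cfg: SyntheticConfig) -> list[IngredientRecord]:
    """Ingredient records of which exactly ``round(n * pass_fraction)`` pass
    the OB >= 30 / DL >= 0.18 screen.

    Passing rows draw OB from a right-skewed gamma shifted above 30 and DL
    uniformly above 0.18; failing rows fail OB, DL, or both, chosen at
    random.  Values are rounded to two decimals (the precision the source
    tables print) without crossing a threshold.
    """
    rng = cfg.rng(_STREAM_INGREDIENTS)
    n = cfg.n_ingredients
    n_pass = int(math.floor(n * cfg.pass_fraction + 0.5))
    passing = set(rng.choice(n, size=n_pass, replace=False).tolist())
    records: list[IngredientRecord] = []
    for i in range(n):
        mol_weight = round(float(rng.uniform(150, 650)), 2)
        if i in passing:
            ob = round(30.0 + float(rng.gamma(2.0, 15.0)), 2)
            dl = round(float(rng.uniform(0.18, 0.95)), 2)
        else:
            mode = int(rng.integers(3))  # 0: fail OB, 1: fail DL, 2: fail both
            if mode == 0:
                ob = round(float(rng.uniform(1.0, 29.5)), 2)
                dl = round(float(rng.uniform(0.18, 0.95)), 2)
            elif mode == 1:
                ob = round(30.0 + float(rng.gamma(2.0, 15.0)), 2)
                dl = round(float(rng.uniform(0.01, 0.17)), 2)
            else:
                ob = round(float(rng.uniform(1.0, 29.5)), 2)
                dl = round(float(rng.uniform(0.01, 0.17)), 2)
        records.append(
            IngredientRecord(
                molecule_id=f"SMOL{i + 1:04d}",
                name=f"synthetic compound {i + 1:02d}",
                mol_weight=mol_weight,
                ob=ob,
                dl=dl,
            )
        )
    return records


# ---------------------------------------------------------------------------
# target sets
# ---------------------------------------------------------------------------


def _universe_symbols(n: int, prefix: str = "SYN") -> list[str]:
    return [f"{prefix}{i + 1:05d}" for i in range(n)]


def gen_target_sets(cfg: SyntheticConfig) -> tuple[TargetSet, TargetSet]:
    """Drug and disease target sets with an exact intersection size.

    With ``inject_reference_targets`` the 41 packaged reference genes are
    placed in both sets (so ``n_overlap`` must be >= 41; any excess overlap
    is made up of shared synthetic symbols); the remaining members are
    disjoint draws from the synthetic universe, so the intersection holds
    exactly.
    """
    rng = cfg.rng(_STREAM_TARGETS)
    if cfg.inject_reference_targets:
        reference = tables.intersection_targets().sorted_members()
        if cfg.n_overlap < len(reference):
            raise ValueError(
                f"n_overlap={cfg.n_overlap} is smaller than the "
                f"{len(reference)} injected reference genes"
            )
        if cfg.n_drug_targets < cfg.n_overlap:
            raise ValueError("n_drug_targets smaller than n_overlap")
    else:
        reference = []
    n_shared_syn = cfg.n_overlap - len(reference)
    n_drug_only = cfg.n_drug_targets - cfg.n_overlap
    n_disease_only = cfg.n_disease_targets - cfg.n_overlap
    needed = n_shared_syn + n_drug_only + n_disease_only
    universe = _universe_symbols(cfg.n_universe)
    if needed > len(universe):
        raise ValueError(
            f"n_universe={cfg.n_universe} too small: need {needed} distinct symbols"
        )
    draw = rng.choice(len(universe), size=needed, replace=False)
    picked = [universe[i] for i in draw]
    shared = picked[:n_shared_syn]
    drug_only = picked[n_shared_syn:n_shared_syn + n_drug_only]
    disease_only = picked[n_shared_syn + n_drug_only:]
    drug = TargetSet.from_symbols("drug_targets", [*reference, *shared, *drug_only])
    disease = TargetSet.from_symbols(
        "disease_targets", [*reference, *shared, *disease_only]
    )
    assert len(drug) == cfg.n_drug_targets and len(disease) == cfg.n_disease_targets
    return drug, disease


# ---------------------------------------------------------------------------
# scored interactome
# ---------------------------------------------------------------------------


def gen_ppi(
    cfg: SyntheticConfig, return_hubs: bool = False
) -> list[ScoredEdge] | tuple[list[ScoredEdge], list[str]]:
    """A scored edge list whose above-threshold subgraph has exact shape.

    With ``return_hubs=True`` the planted hub node ids are returned alongside
    the edges, so recovery experiments can score themselves exactly.

    Construction (stratified, per seed):

    1. a random spanning tree over ``ppi_nodes`` real nodes (so none is
       isolated after thresholding);
    2. each of ``ppi_planted_hubs`` randomly chosen hub nodes is wired up to
       degree ``h = ceil(hub_degree_factor * 2 * ppi_edges / ppi_nodes)``;
    3. background edges between non-hub pairs fill the count to exactly
       ``ppi_edges``, capped so no non-hub reaches degree ``h - 1``; a final
       check verifies every hub out-ranks every non-hub by degree;
    4. surviving edges get scores in [0.401, 0.999]; decoy edges (scores in
       [0.05, 0.399]) are attached to extra ``FREE`` nodes and to random
       unused real pairs, exercising both the threshold and the hide-free-
       nodes behaviour downstream.

    Raises ``ValueError`` when the requested shape is infeasible.
    """
    rng = cfg.rng(_STREAM_PPI)
    n, m, n_hubs = cfg.ppi_nodes, cfg.ppi_edges, cfg.ppi_planted_hubs
    if n < 2:
        raise ValueError("ppi_nodes must be >= 2")
    if m < n - 1:
        raise ValueError("ppi_edges must be >= ppi_nodes - 1 (spanning tree)")
    if m > n * (n - 1) // 2:
        raise ValueError("ppi_edges exceeds the simple-graph maximum")
    nodes = [f"G{i + 1:03d}" for i in range(n)]
    hub_idx = set(rng.choice(n, size=n_hubs, replace=False).tolist()) if n_hubs else set()
    hubs = [nodes[i] for i in sorted(hub_idx)]

    adjacent: set[frozenset[str]] = set()
    degree = {v: 0 for v in nodes}

    def add(u: str, v: str) -> bool:
        key = frozenset((u, v))
        if u == v or key in adjacent:
            return False
        adjacent.add(key)
        degree[u] += 1
        degree[v] += 1
        return True

    order = list(rng.permutation(nodes))
    for i in range(1, n):
        add(order[i], order[int(rng.integers(i))])

    h = math.ceil(cfg.hub_degree_factor * 2 * m / n)
    if h > n - 1:
        raise ValueError(
            f"planted hub degree {h} exceeds the maximum {n - 1} for {n} nodes"
        )
    for hub in hubs:
        others = [v for v in nodes if v != hub and frozenset((hub, v)) not in adjacent]
        need = h - degree[hub]
        if need > len(others):
            raise ValueError("cannot wire hub to the requested degree")
        if need > 0:
            for j in rng.choice(len(others), size=need, replace=False):
                add(hub, others[j])
    if len(adjacent) > m:
        raise ValueError(
            f"hub wiring alone needs {len(adjacent)} edges but ppi_edges={m}"
        )

    non_hubs = [v for v in nodes if v not in set(hubs)]
    candidates = [
        (u, v)
        for i, u in enumerate(non_hubs)
        for v in non_hubs[i + 1:]
        if frozenset((u, v)) not in adjacent
    ]
    cap = h - 2 if hubs else n  # keep non-hubs strictly below hub degree
    for j in rng.permutation(len(candidates)):
        if len(adjacent) == m:
            break
        u, v = candidates[j]
        if degree[u] <= cap - 1 and degree[v] <= cap - 1:
            add(u, v)
    if len(adjacent) != m:
        raise ValueError(
            f"could not reach ppi_edges={m} under the degree constraints "
            f"(got {len(adjacent)})"
        )
    if hubs:
        min_hub = min(degree[v] for v in hubs)
        max_other = max((degree[v] for v in non_hubs), default=0)
        if min_hub <= max_other:
            raise ValueError("planted hubs do not dominate the degree distribution")

    surviving = sorted(tuple(sorted(e)) for e in adjacent)
    edges = [
        ScoredEdge(u, v, round(float(rng.uniform(0.401, 0.999)), 3))
        for u, v in surviving
    ]

    # decoys: sub-threshold edges, some dangling from extra FREE nodes
    n_free = max(2, n // 10)
    free_nodes = [f"FREE{i + 1:02d}" for i in range(n_free)]
    decoys: list[tuple[str, str]] = []
    for fnode in free_nodes:
        for j in rng.choice(n, size=int(rng.integers(1, 3)), replace=False):
            decoys.append((fnode, nodes[j]))
    unused = [
        (u, v)
        for i, u in enumerate(nodes)
        for v in nodes[i + 1:]
        if frozenset((u, v)) not in adjacent
    ]
    n_extra = min(len(unused), max(1, m // 10))
    if n_extra:
        for j in rng.choice(len(unused), size=n_extra, replace=False):
            decoys.append(unused[j])
    edges += [
        ScoredEdge(u, v, round(float(rng.uniform(0.05, 0.399)), 3))
        for u, v in decoys
    ]
    perm = rng.permutation(len(edges))
    shuffled = [edges[i] for i in perm]
    return (shuffled, hubs) if return_hubs else shuffled


# ---------------------------------------------------------------------------
# annotation collections
# ---------------------------------------------------------------------------


def gen_annotations(
    cfg: SyntheticConfig,
    query: TargetSet | None = None,
    category: str = "pathway",
) -> tuple[GeneSetCollection, TargetSet, TargetSet]:
    """An annotation collection with one planted enriched term.

    Returns ``(collection, query, universe)``.  The universe holds exactly
    ``annotation_universe`` genes: the query genes plus reserved ``ANN``
    filler symbols.  The planted term (id ``T_PLANTED``) contains exactly
    ``planted_overlap`` query genes plus filler to ``planted_term_size``;
    ``n_terms`` background terms draw members uniformly from the universe.
    When no query is supplied a ``query_size``-gene query is sampled from
    the universe first.
    """
    rng = cfg.rng(_STREAM_ANNOTATIONS)
    N = cfg.annotation_universe
    if query is None:
        universe_list = _universe_symbols(N, prefix="ANN")
        q_idx = rng.choice(N, size=cfg.query_size, replace=False)
        query = TargetSet.from_symbols(
            "synthetic_query", [universe_list[i] for i in q_idx]
        )
    else:
        n_fill = N - len(query)
        if n_fill < 0:
            raise ValueError(
                f"annotation_universe={N} smaller than the {len(query)}-gene query"
            )
        universe_list = sorted(query.members) + _universe_symbols(n_fill, prefix="ANN")
    universe = TargetSet.from_symbols("annotation_universe", universe_list)

    query_sorted = sorted(query.members)
    non_query = sorted(universe.members - query.members)
    if cfg.planted_overlap > len(query_sorted):
        raise ValueError("planted_overlap exceeds the query size")
    n_out = cfg.planted_term_size - cfg.planted_overlap
    if n_out > len(non_query):
        raise ValueError("planted term does not fit in the universe")
    in_q = [query_sorted[i] for i in rng.choice(len(query_sorted),
                                                size=cfg.planted_overlap,
                                                replace=False)]
    out_q = [non_query[i] for i in rng.choice(len(non_query), size=n_out,
                                              replace=False)]
    terms = [GeneSetTerm("T_PLANTED", "planted enriched process",
                         frozenset(in_q + out_q))]
    universe_sorted = sorted(universe.members)
    for t in range(cfg.n_terms):
        size = int(rng.integers(10, 51))
        members = [universe_sorted[i]
                   for i in rng.choice(N, size=size, replace=False)]
        terms.append(GeneSetTerm(f"T{t + 1:03d}",
                                 f"synthetic background term {t + 1}",
                                 frozenset(members)))
    collection = GeneSetCollection(category=category, terms=tuple(terms))
    return collection, query, universe


# ---------------------------------------------------------------------------
# ingredient -> target mapping
# ---------------------------------------------------------------------------


def gen_ingredient_targets(
    cfg: SyntheticConfig,
    ingredients: Sequence[str],
    targets: TargetSet,
) -> dict[str, frozenset[str]]:
    """Map each active ingredient to a subset of the intersection targets.

    The first ingredient is made dominant (about 70 % of the targets),
    mirroring how one compound typically carries most of a herb's predicted
    connectivity; the rest get small random subsets.  Deterministic per seed.
    """
    if not ingredients:
        raise ValueError("ingredients must be non-empty")
    rng = cfg.rng(_STREAM_MAPPING)
    pool = targets.sorted_members()
    mapping: dict[str, frozenset[str]] = {}
    for i, name in enumerate(ingredients):
        if i == 0:
            size = max(1, int(round(0.7 * len(pool))))
        else:
            hi = max(3, len(pool) // 5)
            size = int(rng.integers(1, hi))
        idx = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
        mapping[name] = frozenset(pool[j] for j in idx)
    return mapping


# ---------------------------------------------------------------------------
# full input bundle
# ---------------------------------------------------------------------------


def write_bundle(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write the complete synthetic input bundle.

    Files written: ``ingredients.tsv``, ``drug_targets.txt``,
    ``disease_targets.txt``, ``ppi_edges.tsv``, ``ingredient_targets.tsv``,
    ``annotations_GO.gmt``, ``annotations_pathway.gmt``,
    ``annotation_universe.txt`` and a ``config.yaml`` echo.  Returns the
    path of each artifact keyed by a short name.  Identical configs produce
    byte-identical bundles.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    records = gen_ingredient_table(cfg)
    paths["ingredients"] = out / "ingredients.tsv"
    write_ingredients(records, paths["ingredients"])

    drug, disease = gen_target_sets(cfg)
    paths["drug_targets"] = out / "drug_targets.txt"
    paths["disease_targets"] = out / "disease_targets.txt"
    write_symbols(drug, paths["drug_targets"])
    write_symbols(disease, paths["disease_targets"])

    edges = gen_ppi(cfg)
    paths["ppi_edges"] = out / "ppi_edges.tsv"
    write_scored_edges(edges, paths["ppi_edges"])

    # the mapping and annotations hinge on the screen survivors and the
    # drug/disease intersection, recomputed here exactly as the pipeline does
    from .screening import ScreenCriteria, screen_ingredients
    from .targetsets import intersect_targets

    survivors = screen_ingredients(records, ScreenCriteria())
    venn = intersect_targets(drug, disease)
    intersection = TargetSet.from_symbols("intersection", venn.intersection)
    mapping = gen_ingredient_targets(cfg, [r.name for r in survivors], intersection)
    paths["ingredient_targets"] = out / "ingredient_targets.tsv"
    lines = ["ingredient\ttarget"]
    for name in mapping:
        for target in sorted(mapping[name]):
            lines.append(f"{name}\t{target}")
    paths["ingredient_targets"].write_text("\n".join(lines) + "\n", encoding="utf-8")

    # distinct stream for the GO-flavoured collection so the two GMTs differ
    go_cfg = replace(cfg, seed=cfg.seed + 1_000_003,
                     n_terms=max(10, cfg.n_terms // 2))
    collection_go, _, universe = gen_annotations(go_cfg, query=intersection,
                                                 category="GO")
    collection_pw, _, _ = gen_annotations(cfg, query=intersection,
                                          category="pathway")
    paths["gmt_GO"] = out / "annotations_GO.gmt"
    paths["gmt_pathway"] = out / "annotations_pathway.gmt"
    write_gmt(collection_go, paths["gmt_GO"])
    write_gmt(collection_pw, paths["gmt_pathway"])
    paths["annotation_universe"] = out / "annotation_universe.txt"
    write_symbols(universe, paths["annotation_universe"])

    paths["config"] = out / "config.yaml"
    paths["config"].write_text(
        yaml.safe_dump(asdict(cfg), sort_keys=True), encoding="utf-8"
    )
    return paths
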