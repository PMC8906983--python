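"""End-to-end orchestration: screen -> intersect -> PPI/hubs -> het network -> ORA.

One :class:`PipelineConfig` drives the whole chain.  Every input path may be
the literal string ``"synthetic:"``, in which case the seeded generators in
:mod:`herbnet.fixtures` write the corresponding input file into
``<out_dir>/inputs/`` first and the pipeline then loads it back through the
ordinary file loaders — so a synthetic run exercises exactly the same code
path as a run on user-supplied files, and two runs with the same config are
byte-identical (timestamps in the report aside).

Stage order is fixed: ingredients, targets, ppi, didt, enrichment.  A stage
failure raises :class:`StageError` naming the stage; artifacts already
written stay on disk for debugging.
"""

from __future__ import annotations

import difflib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__, fixtures, tables
from .enrichment import load_gmt, ora, rows_to_frame
from .network import (
    build_didt_network,
    build_ppi,
    centrality_table,
    compound_importance,
    format_avg_degree,
    load_scored_edges,
    rank_nodes,
    summarize,
    write_centrality_table,
    write_graphml,
    write_sif,
)
from .screening import ScreenCriteria, load_ingredients, screen_ingredients, write_ingredients
from .targetsets import TargetSet, intersect_targets, load_symbols, normalize_symbol, write_symbols

__all__ = ["PipelineConfig", "StageError", "validate_config", "run"]

logger = logging.getLogger(__name__)

SYNTHETIC = "synthetic:"

_DEFAULT_P_MAX = {"GO": 0.05, "pathway": 0.01}


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All tunables of one pipeline run.

    Threshold defaults are the study settings: OB >= 30 %, DL >= 0.18,
    interaction confidence >= 0.4, raw-p cutoffs 0.05 (GO) / 0.01 (pathway),
    top 30 hubs.
    """

    out_dir: str = "herbnet_out"
    seed: int = 7
    # inputs ("synthetic:" generates them from the seed)
    ingredients: str = SYNTHETIC
    ingredient_targets: str = SYNTHETIC
    drug_targets: str = SYNTHETIC
    disease_targets: str = SYNTHETIC
    ppi_edges: str = SYNTHETIC
    gmt: list[dict] = field(default_factory=lambda: [
        {"path": SYNTHETIC, "category": "GO"},
        {"path": SYNTHETIC, "category": "pathway"},
    ])
    universe: str | None = None  # optional explicit ORA universe file
    # thresholds
    ob_min: float = 30.0
    dl_min: float = 0.18
    score_min: float = 0.4
    strict_score: bool = False
    p_max: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_P_MAX))
    top_k: int = 30
    drug_id: str = tables.DRUG_ID
    disease_id: str = tables.DISEASE_ID

    def __post_init__(self) -> None:
        if not (0 <= self.score_min <= 1):
            raise ValueError(f"score_min must be in [0, 1], got {self.score_min}")
        if self.ob_min < 0 or self.dl_min < 0:
            raise ValueError("ob_min and dl_min must be >= 0")
        for category, p in self.p_max.items():
            if not (0 < p <= 1):
                raise ValueError(f"p_max[{category!r}] must be in (0, 1], got {p}")
        if self.top_k < 1:
            raise ValueError(f"top_k must be >= 1, got {self.top_k}")


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML (or JSON) config file.

    Unknown keys are rejected with a close-match suggestion; omitted keys
    take the documented defaults.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"{path}: unknown config key {key!r}{suggestion}")
    return PipelineConfig(**raw)


# ---------------------------------------------------------------------------


def _load_ingredient_targets(path: Path) -> dict[str, set[str]]:
    """Two-column TSV ``ingredient TAB target`` (header tolerated)."""
    mapping: dict[str, set[str]] = {}
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines()):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}, line {i + 1}: expected two tab-separated columns")
        if i == 0 and fields[0].strip().lower() in ("ingredient", "compound"):
            continue
        mapping.setdefault(fields[0].strip(), set()).add(
            normalize_symbol(fields[1])
        )
    return mapping


def run(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns the run report (also written as JSON).

    Artifacts land in ``config.out_dir``: screen survivors, the Venn JSON and
    intersection list, SIF/GraphML graphs, centrality and enrichment TSVs,
    the hub list, and ``report.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "timings_s": {},
    }

    synth_paths: dict[str, Path] = {}
    needs_synth = any(
        p == SYNTHETIC
        for p in (config.ingredients, config.ingredient_targets,
                  config.drug_targets, config.disease_targets, config.ppi_edges)
    ) or any(entry.get("path") == SYNTHETIC for entry in config.gmt)
    if needs_synth:
        cfg = fixtures.paper_preset(seed=config.seed)
        synth_paths = fixtures.write_bundle(cfg, out / "inputs")

    def resolve(spec: str, key: str) -> Path:
        if spec == SYNTHETIC:
            return synth_paths[key]
        return Path(spec)

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                logger.info("=== stage %s ===", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                report["timings_s"][name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Timer()

    # -- screening ---------------------------------------------------------
    with stage("screening"):
        records = load_ingredients(resolve(config.ingredients, "ingredients"))
        survivors = screen_ingredients(
            records, ScreenCriteria(config.ob_min, config.dl_min)
        )
        write_ingredients(survivors, out / "active_ingredients.tsv")
        report["stages"]["screening"] = {
            "ingredients_in": len(records),
            "ingredients_passing": len(survivors),
        }
        logger.info("screen: %d -> %d compounds", len(records), len(survivors))

    # -- target intersection ----------------------------------------------
    with stage("targets"):
        drug = load_symbols(resolve(config.drug_targets, "drug_targets"),
                            label="drug_targets")
        disease = load_symbols(resolve(config.disease_targets, "disease_targets"),
                               label="disease_targets")
        venn = intersect_targets(drug, disease)
        venn.to_json(out / "venn.json")
        intersection = TargetSet.from_symbols("intersection", venn.intersection)
        write_symbols(intersection, out / "intersection_targets.txt")
        report["stages"]["targets"] = {
            "drug_targets": venn.size_a,
            "disease_targets": venn.size_b,
            "intersection": venn.size_intersection,
        }
        logger.info("targets: %d ∩ %d -> %d", venn.size_a, venn.size_b,
                    venn.size_intersection)

    # -- PPI ---------------------------------------------------------------
    with stage("ppi"):
        edges = load_scored_edges(resolve(config.ppi_edges, "ppi_edges"))
        ppi = build_ppi(edges, threshold=config.score_min,
                        drop_isolated=True, strict=config.strict_score)
        summary = summarize(ppi)
        table = centrality_table(ppi)
        hubs = rank_nodes(table, "degree", config.top_k)
        write_sif(ppi, out / "ppi.sif")
        write_graphml(ppi, out / "ppi.graphml")
        write_centrality_table(table, out / "ppi_centrality.tsv")
        (out / "ppi_hubs.txt").write_text("\n".join(hubs) + "\n", encoding="utf-8")
        (out / "ppi_summary.json").write_text(json.dumps({
            "n_nodes": summary.n_nodes,
            "n_edges": summary.n_edges,
            "avg_degree": summary.avg_degree,
            "avg_degree_display": format_avg_degree(summary.avg_degree),
        }, indent=2) + "\n", encoding="utf-8")
        report["stages"]["ppi"] = {
            "edges_in": len(edges),
            "n_nodes": summary.n_nodes,
            "n_edges": summary.n_edges,
            "avg_degree": summary.avg_degree,
            "avg_degree_display": format_avg_degree(summary.avg_degree),
            "hubs": hubs,
        }
        logger.info("ppi: %d nodes / %d edges, mean degree %s",
                    summary.n_nodes, summary.n_edges,
                    format_avg_degree(summary.avg_degree))

    # -- heterogeneous drug-ingredient-disease-target network -------------
    with stage("didt"):
        mapping_raw = _load_ingredient_targets(
            resolve(config.ingredient_targets, "ingredient_targets")
        )
        ingredient_names = [r.name for r in survivors]
        mapping = {k: v for k, v in mapping_raw.items() if k in set(ingredient_names)}
        didt = build_didt_network(
            config.drug_id, ingredient_names, mapping,
            config.disease_id, intersection,
        )
        compounds = compound_importance(didt)
        write_sif(didt, out / "didt.sif", interaction="assoc")
        write_graphml(didt, out / "didt.graphml")
        write_centrality_table(compounds, out / "compound_centrality.tsv")
        report["stages"]["didt"] = {
            "n_nodes": didt.n_nodes,
            "n_edges": didt.n_edges,
            "top_compound": str(compounds.iloc[0]["node"]),
            "top_compound_degree": int(compounds.iloc[0]["degree"]),
        }
        logger.info("didt: %d nodes / %d edges; top compound %s",
                    didt.n_nodes, didt.n_edges, compounds.iloc[0]["node"])

    # -- enrichment --------------------------------------------------------
    with stage("enrichment"):
        if not config.gmt:
            report["stages"]["enrichment"] = {"skipped": True}
            logger.info("enrichment: no GMT collections configured; skipped")
        else:
            universe: TargetSet | str = "collection-union"
            if config.universe is not None:
                universe = load_symbols(Path(config.universe), label="universe")
            elif needs_synth:
                universe = load_symbols(synth_paths["annotation_universe"],
                                        label="universe")
            enrich_counts: dict[str, int] = {}
            for entry in config.gmt:
                category = entry.get("category", "pathway")
                gmt_path = resolve(entry["path"], f"gmt_{category}")
                collection = load_gmt(gmt_path, category=category)
                p_cut = config.p_max.get(category, 0.05)
                rows = ora(intersection, collection, universe=universe, p_max=p_cut)
                rows_to_frame(rows).to_csv(
                    out / f"enrichment_{category}.tsv", sep="\t", index=False,
                    lineterminator="\n",
                )
                enrich_counts[category] = len(rows)
                logger.info("enrichment[%s]: %d term(s) at p <= %g",
                            category, len(rows), p_cut)
            report["stages"]["enrichment"] = {"significant_terms": enrich_counts}

    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n",
                                     encoding="utf-8")
    return report
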