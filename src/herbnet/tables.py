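"""Packaged reference tables for the tangerine-peel / myocardial-hypertrophy study.

Three small tables travel with the package so the pipeline and its tests run
with zero downloads:

* the five active compounds of Citri Reticulatae Pericarpium (CRP, dried
  tangerine peel) that survive the OB >= 30 % / DL >= 0.18 screen, with their
  ADME descriptors;
* the 41 genes shared by the herb's target list and the myocardial-
  hypertrophy disease gene list (symbol + Entrez id);
* the per-compound centralities (degree / closeness / betweenness, undirected
  un-normalized) in the drug-ingredient-disease-target network, on which
  naringenin ranks first by every metric.
"""

from __future__ import annotations

from dataclasses import dataclass

from .screening import IngredientRecord
from .targetsets import TargetSet

__all__ = [
    "active_compounds",
    "intersection_targets",
    "compound_centralities",
    "compound_target_map",
    "CompoundCentrality",
    "DRUG_ID",
    "DISEASE_ID",
]

DRUG_ID = "CRP"
DISEASE_ID = "myocardial_hypertrophy"

# molecule_id, name, mol_weight (g/mol), OB (%), DL
_ACTIVE_COMPOUNDS = (
    ("MOL000359", "Sitosterol", 414.79, 36.91, 0.75),
    ("MOL004328", "Naringenin", 272.27, 59.29, 0.21),
    ("MOL005100", "Hesperetin", 302.30, 47.74, 0.27),
    ("MOL005815", "Citromitin", 404.45, 86.90, 0.51),
    ("MOL005828", "Nobiletin", 402.43, 61.67, 0.52),
)

# (symbol, entrez_id) — the 41 drug/disease intersection genes
_INTERSECTION_TARGETS = (
    ("PGR", 5241), ("NCOA2", 10499), ("NR3C2", 4306), ("PTGS1", 5742),
    ("ESR1", 2099), ("PTGS2", 5743), ("HSP90AB1", 3326), ("MBLAC2", 153364),
    ("PRKACA", 5566), ("PIK3CG", 5294), ("RELA", 5970), ("AKT1", 207),
    ("BCL2", 596), ("MAPK3", 5595), ("MAPK1", 5594), ("CASP3", 836),
    ("FASN", 2194), ("LDLR", 3949), ("BAD", 572), ("SOD1", 6647),
    ("CAT", 847), ("PPARG", 5468), ("APOB", 338), ("HMGCR", 3156),
    ("CYP19A1", 1588), ("GSTP1", 2950), ("UGT1A1", 54658), ("PPARA", 5465),
    ("SREBF1", 6720), ("GSR", 2936), ("ADIPOQ", 9370), ("ABAT", 18),
    ("SOAT1", 6646), ("SCN5A", 6331), ("KCNH2", 3757), ("F7", 2155),
    ("KCNMA1", 3778), ("NOS2", 4843), ("AR", 367), ("ESR2", 2100),
    ("DPP4", 1803),
)


@dataclass(frozen=True)
class CompoundCentrality:
    """Printed per-compound centralities in the heterogeneous network."""

    name: str
    degree: int
    closeness: float
    betweenness: float


_COMPOUND_CENTRALITIES = (
    CompoundCentrality("Naringenin", 30, 0.013157895, 534.495935),
    CompoundCentrality("Citromitin", 6, 0.008064516, 30.08565434),
    CompoundCentrality("Nobiletin", 4, 0.0078125, 14.99268293),
    CompoundCentrality("Sitosterol", 4, 0.0078125, 13.7000562),
    CompoundCentrality("Hesperetin", 2, 0.007575758, 3.497560976),
)


def active_compounds() -> list[IngredientRecord]:
    """The five screened active compounds with their ADME descriptors."""
    return [
        IngredientRecord(molecule_id=m, name=n, mol_weight=w, ob=ob, dl=dl)
        for m, n, w, ob, dl in _ACTIVE_COMPOUNDS
    ]


def intersection_targets() -> TargetSet:
    """The 41 drug/disease intersection genes as a normalized target set."""
    return TargetSet.from_symbols(
        "crp_hypertrophy_intersection", [s for s, _ in _INTERSECTION_TARGETS]
    )


def intersection_entrez() -> dict[str, int]:
    """Entrez gene ids carried as optional annotation keyed by symbol."""
    return dict(_INTERSECTION_TARGETS)


def compound_centralities() -> list[CompoundCentrality]:
    """Printed compound centralities, ordered by degree rank."""
    return list(_COMPOUND_CENTRALITIES)


def compound_target_map() -> dict[str, frozenset[str]]:
    """A deterministic compound -> target assignment matching the printed degrees.

    The study's underlying compound-target edge list is not published, so
    this synthetic assignment distributes the 41 intersection genes over the
    five compounds such that each compound touches exactly as many targets
    as its printed degree (46 links in total) and every target is covered.
    """
    symbols = sorted(s for s, _ in _INTERSECTION_TARGETS)
    return {
        "Naringenin": frozenset(symbols[:30]),
        "Citromitin": frozenset(symbols[30:36]),
        "Nobiletin": frozenset(symbols[36:40]),
        "Sitosterol": frozenset([symbols[40], *symbols[:3]]),
        "Hesperetin": frozenset(symbols[3:5]),
    }
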