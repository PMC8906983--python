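"""Over-representation analysis (ORA) of a gene set against GMT collections.

Given a query gene set (here, the drug/disease intersection genes) and an
annotation collection (GO categories, pathway gene sets) supplied as a GMT
file, each term is tested for overlap enrichment with the one-sided
hypergeometric upper tail — the statistic behind the usual web ORA services.
With a universe of ``N`` genes, a term of size ``K``, a query of size ``n``
and an observed overlap of ``k`` genes,

    p = P(X >= k),   X ~ Hypergeometric(N, K, n)

Benjamini-Hochberg q-values are computed across *all* tested terms (zero
overlap terms count toward the family even though they are never reported).
Filtering uses the raw p threshold, as the conventional web workflow does;
q is reported alongside for modern practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .targetsets import TargetSet, normalize_symbol

__all__ = [
    "GeneSetTerm",
    "GeneSetCollection",
    "EnrichmentRow",
    "load_gmt",
    "write_gmt",
    "hypergeom_upper",
    "bh_adjust",
    "ora",
    "top_terms",
    "rows_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetTerm:
    """One annotation term: id, human-readable name, member symbols."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.term_id:
            raise ValueError("term_id must be non-empty")
        if not self.members:
            raise ValueError(f"term {self.term_id!r} has no members")


@dataclass(frozen=True)
class GeneSetCollection:
    """A category-labelled list of annotation terms with unique ids."""

    category: str
    terms: tuple[GeneSetTerm, ...]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate term_id in collection {self.category!r}")

    def __len__(self) -> int:
        return len(self.terms)

    def universe(self) -> frozenset[str]:
        """Union of all member genes across terms."""
        genes: set[str] = set()
        for term in self.terms:
            genes |= term.members
        return frozenset(genes)


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested term with its overlap counts and p/q values.

    ``k``/``K``/``n``/``N`` are overlap, term size, query size and universe
    size, all measured inside the universe.
    """

    term_id: str
    term_name: str
    category: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float
    overlap: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValueError(f"{self.term_id}: k={self.k} outside [0, min(K, n)]")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.term_id}: p_value {self.p_value} outside (0, 1]")
        if self.q_value < self.p_value - 1e-15 or self.q_value > 1:
            raise ValueError(f"{self.term_id}: q_value {self.q_value} inconsistent with p")


def load_gmt(path: str | Path, category: str | None = None) -> GeneSetCollection:
    """Read a GMT file (term, description, members... per tab-separated line).

    Member symbols are normalized with the same rule as target sets;
    duplicate members within a term merge to one.
    """
    path = Path(path)
    terms: list[GeneSetTerm] = []
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines()):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}, line {i + 1}: GMT lines need >= 3 tab-separated fields "
                f"(name, description, members...)"
            )
        members = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
        terms.append(GeneSetTerm(fields[0].strip(), fields[1].strip(), members))
    return GeneSetCollection(category=category or path.stem, terms=tuple(terms))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT; members sorted for byte-stable output."""
    lines = [
        "\t".join([t.term_id, t.term_name, *sorted(t.members)])
        for t in collection.terms
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``X`` counts query genes falling in a term of size ``K`` when ``n`` genes
    are drawn without replacement from a universe of ``N``.  Evaluated via
    the survival function (log-space internally), so deep tails keep
    precision; ``k = 0`` returns exactly 1.
    """
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at 1; with a single test
    q equals p.
    """
    for p in p_values:
        if not (0 < p <= 1):
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    if len(p_values) == 0:
        return []
    _, q, _, _ = multipletests(list(p_values), method="fdr_bh")
    return [float(x) for x in q]


def ora(
    query: TargetSet,
    collection: GeneSetCollection,
    universe: TargetSet | str = "collection-union",
    p_max: float | None = None,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``query`` in each term.

    The universe defaults to the union of all genes in the collection (so
    the analysis is self-contained); pass a :class:`TargetSet` to override.
    Query genes outside the universe are dropped (count logged).  All terms
    are tested and enter the BH family; rows with ``k >= 1`` and (when
    ``p_max`` is given) ``p <= p_max`` are returned, sorted by ascending p
    then term_id.
    """
    if len(query) == 0:
        raise ValueError("query gene set is empty")
    if isinstance(universe, str):
        if universe != "collection-union":
            raise ValueError(f"unknown universe spec {universe!r}")
        universe_genes = set(collection.universe())
    else:
        universe_genes = set(universe.members)
    effective_query = query.members & universe_genes
    dropped = len(query) - len(effective_query)
    if dropped:
        logger.info(
            "%s: dropped %d query gene(s) outside the %d-gene universe",
            query.label, dropped, len(universe_genes),
        )
    if not effective_query:
        raise ValueError("no query genes remain inside the universe")

    N = len(universe_genes)
    n = len(effective_query)
    tested: list[tuple[GeneSetTerm, int, int, float, tuple[str, ...]]] = []
    for term in collection.terms:
        members = term.members & universe_genes
        K = len(members)
        overlap = tuple(sorted(members & effective_query))
        k = len(overlap)
        p = hypergeom_upper(k, K, n, N)
        tested.append((term, k, K, p, overlap))

    q_values = bh_adjust([t[3] for t in tested])
    rows = [
        EnrichmentRow(
            term_id=term.term_id,
            term_name=term.term_name,
            category=collection.category,
            k=k, K=K, n=n, N=N,
            p_value=p,
            q_value=max(q, p),  # guard against float noise in the cap
            overlap=overlap,
        )
        for (term, k, K, p, overlap), q in zip(tested, q_values)
        if k >= 1 and (p_max is None or p <= p_max)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def top_terms(rows: Iterable[EnrichmentRow], per_category_n: int) -> list[EnrichmentRow]:
    """First ``per_category_n`` rows of each category, preserving input order."""
    if per_category_n < 0:
        raise ValueError("per_category_n must be >= 0")
    kept: list[EnrichmentRow] = []
    counts: dict[str, int] = {}
    for row in rows:
        c = counts.get(row.category, 0)
        if c < per_category_n:
            kept.append(row)
            counts[row.category] = c + 1
    return kept


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Tabulate enrichment rows for TSV export."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "category": r.category,
                "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "overlap": ";".join(r.overlap),
            }
            for r in rows
        ],
        columns=["term_id", "term_name", "category", "k", "K", "n", "N",
                 "p_value", "q_value", "overlap"],
    )
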