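"""Gene-symbol normalization, target sets, and Venn intersection.

Drug-target and disease-target lists scraped from different databases rarely
agree on symbol spelling (case, stray whitespace, legacy aliases).  All
downstream graph and enrichment computations here operate on *normalized*
HGNC-style symbols, so the normalization rule is deliberately simple and
deterministic: trim, uppercase, strip internal whitespace, then (optionally)
map through a user-supplied alias table.  Set intersection of the normalized
drug and disease target sets yields the "co-acting" genes the rest of the
pipeline analyses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "normalize_symbol",
    "TargetSet",
    "VennResult",
    "intersect_targets",
    "load_symbols",
    "load_alias_map",
]

logger = logging.getLogger(__name__)


def normalize_symbol(raw: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Normalize one gene symbol.

    Rule: strip leading/trailing whitespace, collapse internal whitespace to
    nothing, uppercase.  If ``alias_map`` is given it is consulted *after*
    casefolding (its keys and values are normalized with the same rule), so
    ``"erk1" -> "MAPK3"`` works regardless of input case.  The rule is
    idempotent: ``normalize(normalize(x)) == normalize(x)``.
    """
    symbol = "".join(raw.split()).upper()
    if not symbol:
        raise ValueError(f"empty gene symbol after normalization: {raw!r}")
    if alias_map is not None:
        folded = {"".join(k.split()).upper(): "".join(v.split()).upper()
                  for k, v in alias_map.items()}
        symbol = folded.get(symbol, symbol)
    return symbol


@dataclass(frozen=True)
class TargetSet:
    """A named set of normalized gene symbols (set semantics, no duplicates)."""

    label: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("TargetSet label must be non-empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members

    @classmethod
    def from_symbols(
        cls,
        label: str,
        symbols: Iterable[str],
        alias_map: Mapping[str, str] | None = None,
    ) -> "TargetSet":
        """Build a set from raw symbols, normalizing each one.

        Duplicates after normalization are merged silently (the counts the
        field reports are unique-gene counts) but the merge is logged.
        """
        normalized = [normalize_symbol(s, alias_map) for s in symbols]
        members = frozenset(normalized)
        n_dup = len(normalized) - len(members)
        if n_dup:
            logger.info("%s: merged %d duplicate symbol(s) after normalization",
                        label, n_dup)
        return cls(label=label, members=members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class VennResult:
    """Sizes and sorted intersection of two target sets."""

    label_a: str
    label_b: str
    size_a: int
    size_b: int
    size_intersection: int
    intersection: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.size_intersection != len(self.intersection):
            raise ValueError("size_intersection must equal len(intersection)")
        if self.size_intersection > min(self.size_a, self.size_b):
            raise ValueError("intersection cannot exceed either input set")

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "size_a": self.size_a,
            "size_b": self.size_b,
            "size_intersection": self.size_intersection,
            "intersection": list(self.intersection),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def intersect_targets(a: TargetSet, b: TargetSet) -> VennResult:
    """Exact set intersection with deterministic (lexicographic) ordering."""
    common = sorted(a.members & b.members)
    return VennResult(
        label_a=a.label,
        label_b=b.label,
        size_a=len(a),
        size_b=len(b),
        size_intersection=len(common),
        intersection=tuple(common),
    )


def load_symbols(
    path: str | Path,
    label: str | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> TargetSet:
    """Load a target set from a symbol-per-line file or a TSV with a ``symbol`` column.

    Lines starting with ``#`` and blank lines are skipped in the line-oriented
    form.  The TSV form is detected by a header row containing ``symbol``.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    symbols: list[str] = []
    if lines and "symbol" in [c.strip().lower() for c in lines[0].split("\t")]:
        header = [c.strip().lower() for c in lines[0].split("\t")]
        col = header.index("symbol")
        for line in lines[1:]:
            if not line.strip():
                continue
            fields = line.split("\t")
            if col < len(fields) and fields[col].strip():
                symbols.append(fields[col])
    else:
        for line in lines:
            s = line.strip()
            if s and not s.startswith("#"):
                symbols.append(s)
    return TargetSet.from_symbols(label or path.stem, symbols, alias_map)


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Load a two-column (alias TAB canonical) TSV into a mapping.

    A header row is permitted and detected by the literal column names
    ``alias``/``symbol`` (case-insensitive).
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines()):
        if not line.strip() or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 2:
            raise ValueError(f"{path}, line {i + 1}: expected two tab-separated columns")
        if i == 0 and fields[0].lower() in ("alias", "from") :
            continue
        mapping[fields[0]] = fields[1]
    return mapping


def write_symbols(target_set: TargetSet, path: str | Path) -> None:
    """Write a target set as sorted symbol-per-line text."""
    Path(path).write_text(
        "\n".join(target_set.sorted_members()) + "\n", encoding="utf-8"
    )
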