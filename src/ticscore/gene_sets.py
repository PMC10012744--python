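"""Gene-set signatures: GMT I/O, overlap statistics, universe reconciliation.

Gene symbols are case-normalized to upper case on read because public
signature files mix cases across platforms. Within-set duplicates are
dropped (first occurrence kept) with a warning rather than an error,
since they are common in published signature inventories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DegenerateDataError, ParseError

log = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "overlap_count",
    "restrict_to_universe",
]


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered list of unique gene symbols."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of gene sets with unique names."""

    sets: list[GeneSet]
    universe: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def _normalize(symbol: str) -> str:
    return symbol.strip().upper()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (tab-separated: name, description, genes...).

    Within-set duplicate symbols are removed preserving first occurrence;
    symbols are upper-cased. Lines with fewer than three fields raise
    :class:`ParseError` naming the line number; duplicate set names raise
    :class:`ParseError` as well.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name, description, *genes = fields
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            uniq: list[str] = []
            members: set[str] = set()
            n_dupes = 0
            for g in genes:
                sym = _normalize(g)
                if not sym:
                    continue
                if sym in members:
                    n_dupes += 1
                    continue
                members.add(sym)
                uniq.append(sym)
            if n_dupes:
                log.warning(
                    "%s:%d: dropped %d duplicate symbol(s) in set %s",
                    path, lineno, n_dupes, name,
                )
            if not uniq:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets.append(GeneSet(name=name, description=description, genes=tuple(uniq)))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection back out as GMT (UTF-8)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def overlap_count(a: GeneSet, b: GeneSet) -> int:
    """Number of shared symbols, |a ∩ b|, after case normalization."""
    return len({_normalize(g) for g in a.genes} & {_normalize(g) for g in b.genes})


def restrict_to_universe(
    collection: GeneSetCollection,
    universe: Sequence[str] | Iterable[str],
    min_size: int = 3,
) -> GeneSetCollection:
    """Intersect every set with the measured gene universe.

    Sets with fewer than ``min_size`` surviving genes are dropped and
    logged. The default floor of 3 reflects that an enrichment score over
    fewer genes is dominated by single-gene noise. Idempotent.

    Raises :class:`DegenerateDataError` if no set survives.
    """
    uni = {_normalize(g) for g in universe}
    if not uni:
        raise ValueError("universe must be non-empty")
    kept: list[GeneSet] = []
    for s in collection:
        genes = tuple(g for g in s.genes if _normalize(g) in uni)
        if len(genes) < min_size:
            log.warning(
                "dropping set %s: %d of %d genes in universe (< min_size=%d)",
                s.name, len(genes), len(s), min_size,
            )
            continue
        if len(genes) < len(s):
            log.info(
                "set %s restricted from %d to %d genes", s.name, len(s), len(genes)
            )
        kept.append(GeneSet(name=s.name, description=s.description, genes=genes))
    if not kept:
        raise DegenerateDataError(
            "no gene set retains >= min_size genes after universe restriction"
        )
    return GeneSetCollection(sets=kept, universe=sorted(uni))
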