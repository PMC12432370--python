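"""Gene sets and GMT input/output.

A :class:`GeneSet` is a named, ordered collection of unique gene identifiers
with an optional category label (how the set was curated: used in a published
response predictor, annotated as anti-/pro-tumor function, or marking a
tumor-infiltrating cell type). :class:`GeneSetCollection` holds uniquely named
sets and round-trips through the standard tab-separated GMT format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)


class Category(str, Enum):
    """Provenance category of a tumor-microenvironment gene set."""

    predictor = "predictor"
    function = "function"
    cell_type = "cell_type"
    unknown = "unknown"


@dataclass
class GeneSet:
    """A named gene set.

    Parameters
    ----------
    name : str
        Unique identifier within a collection.
    genes : list of str
        Ordered, unique gene identifiers (non-empty).
    category : Category
        Curation category; defaults to ``unknown``.
    description : str
        Free-text description (second GMT column).
    """

    name: str
    genes: list[str]
    category: Category = Category.unknown
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene set names in collection")

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self:
            raise ValueError(f"duplicate gene set name {gene_set.name!r}")
        self.sets.append(gene_set)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        wanted = list(names)
        return GeneSetCollection([self[n] for n in wanted])


def _dedupe(genes: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for g in genes:
        if g and g not in seen:
            seen.add(g)
            out.append(g)
    return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are dropped, keeping the first occurrence.

    Raises
    ------
    ValueError
        On a line with fewer than three tab-separated fields, or a duplicate
        set name.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description, *genes = fields
            deduped = _dedupe(genes)
            if len(deduped) < len([g for g in genes if g]):
                logger.warning(
                    "%s: line %d: duplicate genes in set %r de-duplicated",
                    path, lineno, name,
                )
            collection.add(GeneSet(name=name, genes=deduped, description=description))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection to GMT format (category is not serialized)."""
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")
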