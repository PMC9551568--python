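"""Named gene-set collections and the GMT exchange format.

A collection maps set names (e.g. pathway names) to sets of gene symbols.
GMT is the standard tab-separated format: name, description, then one gene
per remaining column.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping
from pathlib import Path


class GeneSetCollection(Mapping[str, frozenset]):
    """Immutable-ish mapping of set name -> frozenset of gene symbols."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self._sets: dict[str, frozenset] = {}
        for name, genes in sets.items():
            genes = frozenset(str(g) for g in genes)
            if any(not g for g in genes):
                raise ValueError(f"gene set {name!r} contains an empty gene symbol")
            if name in self._sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            self._sets[name] = genes
        self.descriptions = dict(descriptions or {})

    def __getitem__(self, name: str) -> frozenset:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneSetCollection({len(self)} sets)"

    def union(self) -> frozenset:
        out: set = set()
        for genes in self._sets.values():
            out |= genes
        return frozenset(out)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with *universe*; empty sets are retained."""
        universe = frozenset(universe)
        if not universe:
            raise ValueError("universe is empty")
        return GeneSetCollection(
            {name: genes & universe for name, genes in self._sets.items()},
            self.descriptions,
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} in GMT")
            sets[name] = [g for g in genes if g]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n" if genes else f"{name}\t{desc}\n")


def restrict_to_universe(
    sets: GeneSetCollection, universe: Iterable[str]
) -> GeneSetCollection:
    """Intersect every set in *sets* with *universe* (empty results kept)."""
    return sets.restrict(universe)
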