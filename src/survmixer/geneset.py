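"""Gene-set collections that define the pathway-image layout.

A :class:`PathwayCollection` is an *ordered* list of named gene sets. Order
matters twice over: the order of pathways fixes which grid slot each pathway
occupies in the image, and the order of genes within a pathway fixes which
pixel each gene occupies inside its patch. Both orders are preserved exactly
as read from the input file, and downstream results depend on them.

The canonical carrier is GMT (tab-separated: name, description, genes...).
A minimal two-column long-format table (pathway, gene) is accepted as an
alternate input and normalized to the same type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class GeneSetError(ValueError):
    """Raised for malformed or inconsistent gene-set input."""


@dataclass(frozen=True)
class Pathway:
    name: str
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PathwayCollection:
    """Ordered, validated collection of gene sets.

    Invariants enforced at construction: at least one pathway, unique
    pathway names, at least one gene per pathway. A gene symbol may appear
    in several pathways (KEGG pathways overlap).
    """

    pathways: tuple[Pathway, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.pathways:
            raise GeneSetError("no pathways in collection")
        names = [p.name for p in self.pathways]
        seen: set[str] = set()
        for name in names:
            if name in seen:
                raise GeneSetError(f"duplicate pathway name: {name!r}")
            seen.add(name)
        for p in self.pathways:
            if not p.genes:
                raise GeneSetError(f"pathway {p.name!r} has no genes")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pathways]

    def as_dict(self) -> dict[str, list[str]]:
        """Name → gene list mapping (insertion-ordered)."""
        return {p.name: list(p.genes) for p in self.pathways}

    @classmethod
    def from_lists(cls, items: Iterable[tuple[str, Sequence[str]]]) -> "PathwayCollection":
        return cls(tuple(Pathway(str(n), tuple(_clean(g) for g in genes)) for n, genes in items))


def _clean(symbol: str) -> str:
    # case-sensitive matching; only surrounding whitespace is stripped
    return str(symbol).strip()


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT file (name TAB description TAB gene TAB gene ...).

    Pathways are returned in file order with genes in line order; the
    description field is discarded. Empty lines are skipped.
    """
    path = Path(path)
    items: list[tuple[str, list[str]]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GeneSetError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name = fields[0].strip()
            genes = [_clean(g) for g in fields[2:] if g.strip()]
            if not genes:
                raise GeneSetError(f"{path}:{lineno}: pathway {name!r} lists no genes")
            items.append((name, genes))
    if not items:
        raise GeneSetError(f"{path}: no pathways")
    return PathwayCollection.from_lists(items)


def write_gmt(collection: PathwayCollection, path: str | Path, description: str = "na") -> None:
    """Write a collection back to GMT; ``read_gmt`` round-trips it."""
    path = Path(path)
    with path.open("w") as fh:
        for p in collection:
            fh.write("\t".join([p.name, description, *p.genes]) + "\n")


def read_pathway_table(path: str | Path, sep: str = "\t") -> PathwayCollection:
    """Read a two-column long-format table (pathway, gene), one pair per row.

    Rows are grouped by first occurrence of each pathway name; gene order
    within a pathway follows row order. A header row is detected if the
    first line's columns are 'pathway' and 'gene' (case-insensitive).
    """
    path = Path(path)
    order: list[str] = []
    genes_by_pw: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(sep)
            if len(fields) < 2:
                raise GeneSetError(f"{path}:{lineno}: expected 2 columns (pathway{sep}gene)")
            pw, gene = fields[0].strip(), _clean(fields[1])
            if lineno == 1 and pw.lower() == "pathway" and gene.lower() == "gene":
                continue
            if pw not in genes_by_pw:
                order.append(pw)
                genes_by_pw[pw] = []
            genes_by_pw[pw].append(gene)
    if not order:
        raise GeneSetError(f"{path}: no pathways")
    return PathwayCollection.from_lists((pw, genes_by_pw[pw]) for pw in order)


def max_pathway_size(collection: PathwayCollection) -> int:
    """Number of genes in the longest pathway."""
    return max(len(p) for p in collection)


def union_genes(collection: PathwayCollection) -> list[str]:
    """Deduplicated union of all member genes, in first-occurrence order."""
    seen: set[str] = set()
    out: list[str] = []
    for p in collection:
        for g in p.genes:
            if g not in seen:
                seen.add(g)
                out.append(g)
    return out
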