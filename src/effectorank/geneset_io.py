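"""Gene sets, gene-set libraries, and their plain-text file formats.

Two formats are supported:

* plain gene lists — one symbol per line, ``#`` comments and blank
  lines ignored;
* GMT libraries — the Broad/MSigDB tab-separated convention
  ``term<TAB>description<TAB>member1<TAB>member2...``; the description
  column is ignored on read and written back as ``na``.

Symbols are normalized by trimming whitespace and uppercasing only.
Identifier-system conversion (Entrez/Ensembl) and cross-species symbol
mapping are deliberately out of scope: the pipeline treats symbols as
opaque labels that must merely be consistent across its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

#: Fallback genome size used as the hypergeometric universe when a
#: library does not configure one.
DEFAULT_UNIVERSE_SIZE = 20_000


class ValidationError(ValueError):
    """An input violates a domain invariant (bad symbol, duplicate term...)."""


class GMTParseError(ValueError):
    """A GMT line could not be parsed; the message carries the line number."""


def normalize_symbol(raw: str, *, context: str = "") -> str:
    """Return the canonical form of a gene symbol: trimmed and uppercased.

    Normalization is idempotent.  Raises :class:`ValidationError` for
    empty/whitespace-only input or symbols containing tabs or newlines
    (which would corrupt the tab-separated output formats).
    """
    if raw is None:
        raise ValidationError(f"gene symbol is missing{context}")
    symbol = raw.strip().upper()
    if not symbol:
        raise ValidationError(f"empty or whitespace-only gene symbol{context}")
    if "\t" in symbol or "\n" in symbol or "\r" in symbol:
        raise ValidationError(f"gene symbol contains tab/newline: {symbol!r}{context}")
    return symbol


@dataclass(frozen=True)
class GeneSet:
    """A named, order-free collection of normalized gene symbols."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_iterable(cls, name: str, symbols: Iterable[str]) -> "GeneSet":
        """Build a set from raw symbols, normalizing and collapsing duplicates."""
        return cls(name=name, genes=frozenset(normalize_symbol(s) for s in symbols))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes

    def __iter__(self) -> Iterator[str]:
        # Deterministic iteration order for reproducible outputs.
        return iter(sorted(self.genes))

    def intersection(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}&{other.name}", self.genes & other.genes)

    def difference(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}-{other.name}", self.genes - other.genes)

    def union(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}|{other.name}", self.genes | other.genes)


@dataclass
class GeneSetLibrary:
    """A named mapping term -> :class:`GeneSet` with a universe size ``N``.

    ``universe_size`` is the genome-size denominator of the
    hypergeometric enrichment test; it defaults to 20,000 and must be
    at least as large as the union of all member sets.
    """

    name: str
    terms: dict[str, GeneSet]
    universe_size: int = DEFAULT_UNIVERSE_SIZE

    def __post_init__(self) -> None:
        for term, members in self.terms.items():
            if len(members) == 0:
                raise ValidationError(
                    f"library {self.name!r}: term {term!r} has no member genes"
                )
        n_union = len(self.all_genes())
        if self.universe_size < n_union:
            raise ValidationError(
                f"library {self.name!r}: universe_size {self.universe_size} is "
                f"smaller than the union of member sets ({n_union})"
            )

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.terms.values():
            out |= members.genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetLibrary):
            return NotImplemented
        return (
            self.name == other.name
            and self.universe_size == other.universe_size
            and self.terms.keys() == other.terms.keys()
            and all(self.terms[t].genes == other.terms[t].genes for t in self.terms)
        )


def parse_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list.

    Blank lines and lines starting with ``#`` are skipped; duplicate
    symbols are collapsed.  The input-line vs unique-symbol counts are
    logged.  Raises :class:`ValidationError` if no usable line remains.
    """
    path = Path(path)
    symbols: list[str] = []
    n_lines = 0
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            n_lines += 1
            symbols.append(normalize_symbol(stripped, context=f" ({path}:{lineno})"))
    if not symbols:
        raise ValidationError(f"{path}: no usable gene symbols found")
    gene_set = GeneSet(name or path.stem, frozenset(symbols))
    logger.info(
        "%s: %d input lines, %d unique symbols", path, n_lines, len(gene_set)
    )
    return gene_set


def write_gene_list(gene_set: GeneSet, path: str | Path) -> None:
    """Write a gene set one symbol per line (sorted, UTF-8, Unix newlines)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        for symbol in gene_set:
            handle.write(symbol + "\n")


def parse_gmt(
    path: str | Path,
    name: str | None = None,
    universe_size: int | None = None,
) -> GeneSetLibrary:
    """Read a GMT library (term, description, members...).

    Raises :class:`GMTParseError` for lines with fewer than three
    tab-separated fields and :class:`ValidationError` for duplicate
    term identifiers.  When ``universe_size`` is not given it defaults
    to ``max(DEFAULT_UNIVERSE_SIZE, |union of members|)``.
    """
    path = Path(path)
    terms: dict[str, GeneSet] = {}
    with path.open("r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            term = fields[0].strip()
            if not term:
                raise GMTParseError(f"{path}:{lineno}: empty term identifier")
            if term in terms:
                raise ValidationError(f"{path}:{lineno}: duplicate term {term!r}")
            members = frozenset(
                normalize_symbol(f, context=f" ({path}:{lineno})")
                for f in fields[2:]
                if f.strip()
            )
            if not members:
                raise ValidationError(f"{path}:{lineno}: term {term!r} has no members")
            terms[term] = GeneSet(term, members)
    library_name = name or path.stem
    if universe_size is None:
        n_union = len(frozenset().union(*(t.genes for t in terms.values())) if terms else frozenset())
        universe_size = max(DEFAULT_UNIVERSE_SIZE, n_union)
    return GeneSetLibrary(library_name, terms, universe_size)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    """Write a library in GMT format; description column emitted as ``na``."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        for term in sorted(library.terms):
            members = "\t".join(sorted(library.terms[term].genes))
            handle.write(f"{term}\tna\t{members}\n")
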