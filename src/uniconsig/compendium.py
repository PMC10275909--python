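"""Molecular-concept and pathway collections.

A *molecular concept* is any knowledge-derived gene set — an ontology term,
a curated pathway, an interaction neighborhood, a protein-domain family —
used as a unit of functional evidence.  Concept compendia and pathway
collections are both plain GMT files (tab-separated: id, description,
member genes) and both load into the same :class:`ConceptCompendium`
container.

Set similarity between concepts uses the Ochiai (cosine) coefficient
``|A∩B| / sqrt(|A|·|B|)``, which, unlike Jaccard, stays high when a small
concept is fully contained in a much larger one (for nested ``A ⊂ B`` it
equals ``sqrt(|A|/|B|)`` versus Jaccard's ``|A|/|B|``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger("uniconsig.compendium")

#: Default concept-size filter bounds applied when reading GMT files.
#: Tiny concepts make the Ochiai index unstable; huge ones are uninformative.
DEFAULT_MIN_CONCEPT_SIZE = 5
DEFAULT_MAX_CONCEPT_SIZE = 2500


class GmtParseError(ValueError):
    """A GMT line could not be parsed (fewer than 3 tab-separated fields)."""


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


@dataclass(frozen=True)
class Concept:
    """A named gene set from a knowledge source.

    Gene identifiers are opaque, case-sensitive strings; no symbol mapping
    is performed (identifier harmonization is upstream curation).
    """

    id: str
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"concept {self.id!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.genes)


class ConceptCompendium:
    """Ordered collection of :class:`Concept` with unique ids.

    The *universe* is the union of all member gene sets; it defines the
    scoring domain for genome-wide concept-signature scores.
    """

    def __init__(self, concepts: Iterable[Concept]):
        self._concepts: list[Concept] = list(concepts)
        by_id: dict[str, Concept] = {}
        for c in self._concepts:
            if c.id in by_id:
                raise ValidationError(f"duplicate concept id {c.id!r}")
            by_id[c.id] = c
        self._by_id = by_id
        self._universe: frozenset[str] | None = None

    @property
    def concepts(self) -> Sequence[Concept]:
        return tuple(self._concepts)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self._concepts)

    @property
    def universe(self) -> frozenset[str]:
        if self._universe is None:
            u: set[str] = set()
            for c in self._concepts:
                u |= c.genes
            self._universe = frozenset(u)
        return self._universe

    def __len__(self) -> int:
        return len(self._concepts)

    def __iter__(self) -> Iterator[Concept]:
        return iter(self._concepts)

    def __contains__(self, concept_id: object) -> bool:
        return concept_id in self._by_id

    def __getitem__(self, concept_id: str) -> Concept:
        return self._by_id[concept_id]

    def subset(self, ids: Iterable[str]) -> "ConceptCompendium":
        """New compendium restricted to ``ids``, in the given order."""
        return ConceptCompendium(self._by_id[i] for i in ids)

    def with_concepts(self, extra: Iterable[Concept]) -> "ConceptCompendium":
        """New compendium with ``extra`` concepts appended."""
        return ConceptCompendium(list(self._concepts) + list(extra))


def read_gmt(
    path,
    min_size: int = DEFAULT_MIN_CONCEPT_SIZE,
    max_size: int = DEFAULT_MAX_CONCEPT_SIZE,
    source: str = "",
) -> ConceptCompendium:
    """Load a GMT file, keeping concepts whose deduplicated size is in
    ``[min_size, max_size]``.

    Each line must carry at least 3 tab-separated fields
    (id, description, gene, ...).  Duplicate gene tokens within a line are
    silently deduplicated (logged at debug level); duplicate concept ids
    are a hard error.  LF and CRLF line endings are accepted; blank lines
    are ignored.
    """
    if min_size < 1 or max_size < 1:
        raise ValidationError("min_size and max_size must be positive")
    if min_size > max_size:
        raise ValidationError(f"min_size={min_size} exceeds max_size={max_size}")
    concepts: list[Concept] = []
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            cid, name, *tokens = fields
            tokens = [t for t in tokens if t]
            genes = frozenset(tokens)
            if len(genes) < len(tokens):
                logger.debug(
                    "%s: line %d: %d duplicate gene tokens deduplicated in %r",
                    path, lineno, len(tokens) - len(genes), cid,
                )
            if not genes:
                raise GmtParseError(f"{path}: line {lineno}: concept {cid!r} has no genes")
            if min_size <= len(genes) <= max_size:
                concepts.append(Concept(id=cid, name=name, genes=genes, source=source))
            else:
                logger.debug(
                    "%s: line %d: concept %r filtered (size %d outside [%d, %d])",
                    path, lineno, cid, len(genes), min_size, max_size,
                )
    return ConceptCompendium(concepts)


def write_gmt(compendium: ConceptCompendium, path) -> None:
    """Write a compendium as GMT (genes sorted for reproducible output)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for c in compendium:
            fh.write("\t".join([c.id, c.name, *sorted(c.genes)]) + "\n")


def ochiai(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Ochiai (cosine) similarity ``|A∩B| / sqrt(|A|·|B|)`` in [0, 1].

    Raises :class:`ValidationError` for empty sets (undefined denominator).
    """
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValidationError("Ochiai index is undefined for empty sets")
    return len(a & b) / math.sqrt(len(a) * len(b))


def ochiai_matrix(gene_sets: Sequence[frozenset[str]]) -> np.ndarray:
    """Pairwise Ochiai similarities among ``gene_sets`` as an (m, m) array.

    Vectorized via a boolean membership matrix; used for the per-gene
    concept-redundancy penalization where all pairwise similarities among a
    gene's concepts are needed.
    """
    m = len(gene_sets)
    if m == 0:
        return np.zeros((0, 0))
    gene_index: dict[str, int] = {}
    for s in gene_sets:
        for g in s:
            gene_index.setdefault(g, len(gene_index))
    member = np.zeros((m, len(gene_index)), dtype=np.float64)
    for i, s in enumerate(gene_sets):
        for g in s:
            member[i, gene_index[g]] = 1.0
    inter = member @ member.T
    sizes = np.diag(inter).copy()
    if np.any(sizes == 0):
        raise ValidationError("Ochiai index is undefined for empty sets")
    return inter / np.sqrt(np.outer(sizes, sizes))


@dataclass(frozen=True)
class GeneConceptIndex:
    """Mapping gene identifier → ids of concepts containing that gene.

    Genes absent from the universe map to an empty set (absent-key
    contract), so lookups never raise.
    """

    mapping: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def concepts_for(self, gene: str) -> frozenset[str]:
        return self.mapping.get(gene, frozenset())

    def __getitem__(self, gene: str) -> frozenset[str]:
        return self.concepts_for(gene)

    def __len__(self) -> int:
        return len(self.mapping)

    @property
    def total_entries(self) -> int:
        """Sum of concept sizes — one entry per (gene, concept) membership."""
        return sum(len(v) for v in self.mapping.values())


def build_index(compendium: ConceptCompendium) -> GeneConceptIndex:
    """Invert the compendium into a gene → concept-ids index."""
    mapping: dict[str, set[str]] = {}
    for c in compendium:
        for g in c.genes:
            mapping.setdefault(g, set()).add(c.id)
    return GeneConceptIndex({g: frozenset(s) for g, s in mapping.items()})
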