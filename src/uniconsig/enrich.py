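"""End-to-end CSEA / WCSEA pathway enrichment.

Pipeline: concept weights (Ochiai for a target list, floored WKS NES for
a weighted list) → redundancy-penalized uniConSig scores for every
universe gene → WKS of each pathway gene set on the uniConSig-sorted
genome → sign-matched permutation NES and p → BH q-values → ranking by
NES.  Up- and down-regulation are analyzed in separate runs; the down
run negates the input weights before ranking.

The enrichment genome is the concept universe plus any weighted-list
genes; genes with no concept evidence sit in the zero-score tail so
functional relevance, not list membership, drives pathway rank.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compendium import ConceptCompendium, ValidationError
from .scoring import (
    DEFAULT_CONCEPT_MIN_OVERLAP,
    UniConSigScores,
    csea_concept_weights,
    csea_uniconsig,
    uniconsig_scores,
    wcsea_concept_weights,
)
from .wks import (
    DEFAULT_EXPONENT,
    DEFAULT_N_PERM,
    RankedList,
    WksEngine,
    adjust_pvalues,
)

logger = logging.getLogger("uniconsig.enrich")

DEFAULT_MIN_PATHWAY_OVERLAP = 5

TOOL_VERSION = "uniconsig 1.0.0"


@dataclass(frozen=True)
class EnrichmentParams:
    """Knobs shared by the CSEA/WCSEA pipelines.

    seed is mandatory for every stochastic step; there is no hidden
    global randomness.
    """

    seed: int
    n_perm: int = DEFAULT_N_PERM
    exponent: float = DEFAULT_EXPONENT
    min_pathway_overlap: int = DEFAULT_MIN_PATHWAY_OVERLAP
    concept_min_overlap: int = DEFAULT_CONCEPT_MIN_OVERLAP
    adjust_method: str = "benjamini_hochberg"
    null_mode: str = "shared"
    leave_one_out: bool = False


def derive_seed(seed: int, tag: str) -> int:
    """Deterministic sub-stream seed (< 2^31) for a named pipeline stage."""
    token = int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "big")
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, token]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class PathwayResult:
    pathway_id: str
    es: float
    nes: float
    p_value: float
    q_value: float
    rank: int
    leading_edge: frozenset[str]
    n_overlap: int


@dataclass(frozen=True)
class PathwayTable:
    """Ranked enrichment results for one direction, with provenance
    sufficient to re-run bit-identically (seed, params, input hashes)."""

    direction: str
    results: tuple[PathwayResult, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.results)

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, pathway_id: str) -> PathwayResult:
        for r in self.results:
            if r.pathway_id == pathway_id:
                return r
        raise KeyError(pathway_id)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.pathway_id for r in self.results)

    def rank_of(self, pathway_id: str) -> int | None:
        for r in self.results:
            if r.pathway_id == pathway_id:
                return r.rank
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway": [r.pathway_id for r in self.results],
                "es": [r.es for r in self.results],
                "nes": [r.nes for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "q_value": [r.q_value for r in self.results],
                "rank": [r.rank for r in self.results],
                "n_overlap": [r.n_overlap for r in self.results],
                "leading_edge": [";".join(sorted(r.leading_edge)) for r in self.results],
            }
        )

    def to_tsv(self, path) -> None:
        header = provenance_header(self.provenance)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, sep="\t", index=False, lineterminator="\n")

    def to_json(self, path) -> None:
        payload = {
            "direction": self.direction,
            "provenance": dict(self.provenance),
            "results": [
                {
                    "pathway": r.pathway_id,
                    "es": r.es,
                    "nes": r.nes,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "rank": r.rank,
                    "n_overlap": r.n_overlap,
                    "leading_edge": sorted(r.leading_edge),
                }
                for r in self.results
            ],
        }
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def provenance_header(prov: Mapping[str, object]) -> str:
    """Comment header stamped on every TSV output (no timestamps, so
    identically-configured runs are byte-identical)."""
    items = json.dumps(dict(prov), sort_keys=True, default=str)
    return f"# {TOOL_VERSION}\n# provenance: {items}\n"


def hash_compendium(compendium: ConceptCompendium) -> str:
    h = hashlib.sha256()
    for c in compendium:
        h.update(c.id.encode())
        h.update(b"\x00")
        h.update("\t".join(sorted(c.genes)).encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


def hash_weights(weighted: Mapping[str, float]) -> str:
    h = hashlib.sha256()
    for g in sorted(weighted):
        h.update(f"{g}\t{weighted[g]!r}\n".encode())
    return h.hexdigest()[:16]


def _ranked_genome(scores: UniConSigScores, extra_genes: Sequence[str] = ()) -> RankedList:
    """uniConSig-sorted genome: universe genes by normalized score
    descending (ties by gene id), with concept-less extra genes padded at
    score 0."""
    w = dict(scores.normalized)
    for g in extra_genes:
        w.setdefault(g, 0.0)
    return RankedList.from_weights(w)


def enrich_ranked(
    ranked: RankedList,
    pathways: ConceptCompendium,
    params: EnrichmentParams,
    direction: str,
    provenance: Mapping[str, object],
) -> PathwayTable:
    """WKS-test every pathway against a ranked list and assemble a table.

    Pathways overlapping the ranked genome by fewer than
    ``min_pathway_overlap`` genes are skipped with a log entry.  Results
    are BH-adjusted (q), sorted by NES descending (ties by pathway id)
    and ranked 1..K.
    """
    engine = WksEngine(
        ranked,
        exponent=params.exponent,
        n_perm=params.n_perm,
        seed=derive_seed(params.seed, f"pathway-{direction}"),
        null_mode=params.null_mode,
    )
    listed = ranked.gene_set
    rows = []
    for pw in pathways:
        overlap = pw.genes & listed
        if len(overlap) < params.min_pathway_overlap:
            logger.info(
                "pathway %r skipped: overlap %d < %d",
                pw.id, len(overlap), params.min_pathway_overlap,
            )
            continue
        stat = engine.test(overlap)
        rows.append((pw.id, stat, len(overlap)))
    if not rows:
        return PathwayTable(direction=direction, results=(), provenance=dict(provenance))
    qs = adjust_pvalues([s.p_value for _, s, _ in rows], method=params.adjust_method)
    order = sorted(
        range(len(rows)), key=lambda i: (-(rows[i][1].nes or 0.0), rows[i][0])
    )
    results = tuple(
        PathwayResult(
            pathway_id=rows[i][0],
            es=rows[i][1].es,
            nes=float(rows[i][1].nes or 0.0),
            p_value=float(rows[i][1].p_value or 1.0),
            q_value=float(qs[i]),
            rank=rank,
            leading_edge=rows[i][1].leading_edge,
            n_overlap=rows[i][2],
        )
        for rank, i in enumerate(order, start=1)
    )
    return PathwayTable(direction=direction, results=results, provenance=dict(provenance))


def run_csea(
    target: set[str],
    compendium: ConceptCompendium,
    pathways: ConceptCompendium,
    params: EnrichmentParams,
    direction: str = "up",
) -> PathwayTable:
    """CSEA: unweighted target list → uniConSig genome → pathway WKS."""
    target = set(target)
    scores = csea_uniconsig(target, compendium, leave_one_out=params.leave_one_out)
    ranked = _ranked_genome(scores, extra_genes=sorted(target))
    prov = {
        "mode": "csea",
        "direction": direction,
        "seed": params.seed,
        "n_perm": params.n_perm,
        "exponent": params.exponent,
        "adjust_method": params.adjust_method,
        "compendium_hash": hash_compendium(compendium),
        "pathways_hash": hash_compendium(pathways),
        "input_hash": hashlib.sha256("\n".join(sorted(target)).encode()).hexdigest()[:16],
    }
    return enrich_ranked(ranked, pathways, params, direction, prov)


def run_wcsea(
    weighted: Mapping[str, float],
    compendium: ConceptCompendium,
    pathways: ConceptCompendium,
    params: EnrichmentParams,
    direction: str = "up",
) -> PathwayTable:
    """WCSEA: weighted gene list → WKS concept weights → uniConSig genome
    → pathway WKS.  ``direction="down"`` negates the weights first."""
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    weighted = dict(weighted)
    if not weighted:
        raise ValidationError("weighted gene list is empty")
    vals = np.array(list(weighted.values()), dtype=np.float64)
    if np.all(vals == vals[0]):
        warnings.warn(
            "all input weights are equal; ranking falls back to gene-id order"
        )
    if direction == "down":
        weighted = {g: -w for g, w in weighted.items()}
    cw = wcsea_concept_weights(
        weighted,
        compendium,
        n_perm=params.n_perm,
        seed=derive_seed(params.seed, "concept"),
        exponent=params.exponent,
        min_overlap=params.concept_min_overlap,
        null_mode=params.null_mode,
    )
    scores = uniconsig_scores(cw, compendium)
    ranked = _ranked_genome(scores, extra_genes=sorted(weighted))
    prov = {
        "mode": "wcsea",
        "direction": direction,
        "seed": params.seed,
        "n_perm": params.n_perm,
        "exponent": params.exponent,
        "adjust_method": params.adjust_method,
        "compendium_hash": hash_compendium(compendium),
        "pathways_hash": hash_compendium(pathways),
        "input_hash": hash_weights(weighted),
    }
    return enrich_ranked(ranked, pathways, params, direction, prov)


def significant_count(table: PathwayTable, q_cutoffs: Sequence[float]) -> list[int]:
    """Number of pathways with q ≤ cutoff, per cutoff (non-decreasing)."""
    if len(table) == 0:
        raise ValidationError("pathway table is empty")
    qs = np.array([r.q_value for r in table.results])
    return [int((qs <= c).sum()) for c in q_cutoffs]
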