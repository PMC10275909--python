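"""Pathway crosstalk disambiguation.

Enriched pathways overlap through shared genes, so a single underlying
signal can light up several pathways at once.  Disambiguation keeps only
pathways that remain enriched after deleting the genes shared with a
stronger competing pathway: for each ordered pair (stronger A, weaker B)
with appreciable overlap, the remainder B \\ A is re-tested by WKS on
the uniConSig-ranked genome; B is pruned when its adjusted remainder
p-value is not significant.  Pruning is greedy in descending-NES order
and removed pathways never trigger further tests, so the procedure is
deterministic and idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .compendium import ConceptCompendium, ValidationError, ochiai
from .enrich import EnrichmentParams, PathwayTable, _ranked_genome, derive_seed
from .scoring import UniConSigScores
from .wks import WksEngine, adjust_pvalues

logger = logging.getLogger("uniconsig.disambiguation")

DEFAULT_ALPHA = 0.01
DEFAULT_TOP_K = 30
#: A pair is tested when pathways share >= 3 genes or their Ochiai >= 0.05.
DEFAULT_OCHIAI_TRIGGER = 0.05
DEFAULT_SHARED_TRIGGER = 3
DEFAULT_MIN_REMAINDER = 5


@dataclass(frozen=True)
class DisambiguationRecord:
    pathway_id: str
    competitor_id: str
    remainder_size: int
    remainder_p: float
    adjusted_p: float
    verdict: str  # kept | removed | degenerate


def disambiguate(
    table: PathwayTable,
    pathways: ConceptCompendium,
    scores: UniConSigScores,
    params: EnrichmentParams,
    alpha: float = DEFAULT_ALPHA,
    method: str = "bonferroni",
    top_k: int = DEFAULT_TOP_K,
    min_remainder: int = DEFAULT_MIN_REMAINDER,
    ochiai_trigger: float = DEFAULT_OCHIAI_TRIGGER,
    shared_trigger: int = DEFAULT_SHARED_TRIGGER,
    extra_genes: Sequence[str] = (),
) -> tuple[PathwayTable, list[DisambiguationRecord]]:
    """Prune the top_k of ``table`` to independently enriched pathways.

    Processing order is descending NES (the table's rank order).  For a
    candidate B, every already-kept stronger pathway A with triggered
    overlap contributes one remainder test of B \\ A; B's batch of
    remainder p-values is adjusted by ``method`` (Bonferroni by default)
    and B is removed as soon as any adjusted p ≥ ``alpha``.  A remainder
    overlapping the ranked genome by fewer than ``min_remainder`` genes
    is degenerate — a nested or near-identical pathway cannot be
    independently enriched — and B is removed with that verdict.

    Returns the pruned table (ranks renumbered 1..K', original order
    preserved) and the full test log.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    if top_k > len(table):
        raise ValidationError(f"top_k={top_k} exceeds table size {len(table)}")
    candidates = list(table.results[:top_k])
    ranked = _ranked_genome(scores, extra_genes=extra_genes)
    engine = WksEngine(
        ranked,
        exponent=params.exponent,
        n_perm=params.n_perm,
        seed=derive_seed(params.seed, "disambiguation"),
        null_mode=params.null_mode,
    )
    listed = ranked.gene_set
    kept: list = []
    records: list[DisambiguationRecord] = []
    for cand in candidates:
        b_genes = pathways[cand.pathway_id].genes
        tests: list[tuple[str, frozenset[str], int]] = []
        degenerate_vs: str | None = None
        for stronger in kept:
            a_genes = pathways[stronger.pathway_id].genes
            shared = a_genes & b_genes
            if not shared:
                continue
            if len(shared) < shared_trigger and ochiai(a_genes, b_genes) < ochiai_trigger:
                continue
            remainder = frozenset(b_genes - a_genes)
            testable = remainder & listed
            if len(testable) < min_remainder:
                degenerate_vs = stronger.pathway_id
                records.append(
                    DisambiguationRecord(
                        pathway_id=cand.pathway_id,
                        competitor_id=stronger.pathway_id,
                        remainder_size=len(remainder),
                        remainder_p=1.0,
                        adjusted_p=1.0,
                        verdict="degenerate",
                    )
                )
                logger.info(
                    "pathway %r removed as degenerate vs %r (remainder %d < %d)",
                    cand.pathway_id, stronger.pathway_id, len(remainder), min_remainder,
                )
                break
            tests.append((stronger.pathway_id, testable, len(remainder)))
        if degenerate_vs is not None:
            continue
        if not tests:
            kept.append(cand)
            continue
        ps = [engine.test(t[1]).p_value for t in tests]
        adj = adjust_pvalues(ps, method=method)
        removed = False
        for (comp, _, rsize), p, ap in zip(tests, ps, adj):
            verdict = "removed" if ap >= alpha else "kept"
            if verdict == "removed":
                removed = True
            records.append(
                DisambiguationRecord(
                    pathway_id=cand.pathway_id,
                    competitor_id=comp,
                    remainder_size=rsize,
                    remainder_p=float(p),
                    adjusted_p=float(ap),
                    verdict=verdict,
                )
            )
        if removed:
            logger.info("pathway %r removed: not independently enriched", cand.pathway_id)
        else:
            kept.append(cand)
    results = tuple(replace(r, rank=i) for i, r in enumerate(kept, start=1))
    pruned = PathwayTable(
        direction=table.direction,
        results=results,
        provenance={**dict(table.provenance), "disambiguated": True, "alpha": alpha,
                    "adjust_method": method, "top_k": top_k},
    )
    return pruned, records


def records_to_frame(records: Sequence[DisambiguationRecord]):
    import pandas as pd

    return pd.DataFrame(
        {
            "pathway": [r.pathway_id for r in records],
            "competitor": [r.competitor_id for r in records],
            "remainder_size": [r.remainder_size for r in records],
            "remainder_p": [r.remainder_p for r in records],
            "adjusted_p": [r.adjusted_p for r in records],
            "verdict": [r.verdict for r in records],
        }
    )
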