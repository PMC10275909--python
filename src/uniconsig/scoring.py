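"""Genome-wide uniConSig (universal concept signature) scoring.

Each gene x accumulates evidence from the molecular concepts it belongs
to.  A concept's weight ω_i measures its enrichment in the input: the
Ochiai similarity to an unweighted target list (CSEA) or the
zero-floored WKS NES against a weighted gene list (WCSEA).  Redundant
concepts are discounted by a penalization factor

    ε_i = Σ_j O_ij   over the gene's concepts j (including j = i),

giving effective weights EW_i = ω_i / ε_i and an effective concept
number ECN = Σ_i 1/ε_i.  The raw score is

    uniConSig(x) = Σ_i EW_i / sqrt(ECN),

interpreted as a redundancy-adjusted average of the concept weights;
the square root compresses the effect of large concept counts.  Raw
scores are min–max normalized to [0, 1] across the scored genome.

Because ε includes the self term (O_ii = 1), ε ≥ 1 always and the
single-concept closed form is exact: a gene in one concept scores ω.
Concepts with identical gene sets are collapsed to a single
representative before ε/EW/ECN are computed, so duplicated concepts have
exactly the same effect as a single copy — the intended semantics of the
penalization, made exact.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .compendium import (
    Concept,
    ConceptCompendium,
    GeneConceptIndex,
    ValidationError,
    ochiai,
    ochiai_matrix,
)
from .wks import DEFAULT_EXPONENT, DEFAULT_N_PERM, RankedList, WksEngine

logger = logging.getLogger("uniconsig.scoring")

#: Minimum concept overlap with the weighted list for WCSEA concept testing.
DEFAULT_CONCEPT_MIN_OVERLAP = 3

ConceptWeightTable = dict[str, float]


@dataclass(frozen=True)
class PenalizationRecord:
    concept_id: str
    omega: float
    epsilon: float
    ew: float


@dataclass(frozen=True)
class GenePenalization:
    """Per-concept penalization breakdown behind one gene's raw score."""

    gene: str
    records: tuple[PenalizationRecord, ...]
    ecn: float


@dataclass(frozen=True)
class UniConSigScores:
    """Gene → raw cumulative score and its [0, 1] min–max normalization."""

    raw: Mapping[str, float]
    normalized: Mapping[str, float]

    def ranked_genes(self) -> list[str]:
        """Genes sorted by normalized score descending, ties by gene id."""
        return [g for g, _ in sorted(self.normalized.items(), key=lambda kv: (-kv[1], kv[0]))]


def csea_concept_weights(
    target: set[str], compendium: ConceptCompendium
) -> ConceptWeightTable:
    """CSEA concept weights: ω_i = Ochiai(target, concept_i).

    Concepts disjoint from the target get ω = 0.  Raises if the target
    shares no genes with the compendium universe (identifier mismatch).
    """
    target = set(target)
    if not target:
        raise ValidationError("target gene list is empty")
    if not (target & compendium.universe):
        raise ValidationError(
            "target shares no genes with the concept universe; "
            "harmonize gene identifiers between the list and the compendium"
        )
    nt = len(target)
    weights: ConceptWeightTable = {}
    for c in compendium:
        inter = len(target & c.genes)
        weights[c.id] = inter / math.sqrt(nt * len(c.genes)) if inter else 0.0
    return weights


def wcsea_concept_weights(
    weighted: Mapping[str, float],
    compendium: ConceptCompendium,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    exponent: float = DEFAULT_EXPONENT,
    min_overlap: int = DEFAULT_CONCEPT_MIN_OVERLAP,
    null_mode: str = "shared",
) -> ConceptWeightTable:
    """WCSEA concept weights: ω_i = max(0, NES) of each concept in the
    ranked weighted list.

    Concepts overlapping the list by fewer than ``min_overlap`` genes are
    skipped (absent from the table, logged).  Negative NES is floored at
    zero: a depleted concept carries no signature weight.
    """
    ranked = RankedList.from_weights(weighted)
    if len(set(ranked.genes) & set(compendium.universe)) < 2:
        raise ValidationError(
            "fewer than 2 weighted genes overlap the concept universe; "
            "harmonize gene identifiers between the list and the compendium"
        )
    engine = WksEngine(ranked, exponent=exponent, n_perm=n_perm, seed=seed, null_mode=null_mode)
    listed = ranked.gene_set
    weights: ConceptWeightTable = {}
    for c in compendium:
        overlap = c.genes & listed
        if len(overlap) < min_overlap:
            logger.debug(
                "concept %r skipped: overlap %d < min_overlap %d",
                c.id, len(overlap), min_overlap,
            )
            continue
        stat = engine.test(overlap)
        weights[c.id] = max(0.0, stat.nes or 0.0)
    return weights


def penalization_factors(
    gene: str, index: GeneConceptIndex, compendium: ConceptCompendium
) -> dict[str, float]:
    """Literal per-gene penalization: for every concept i containing the
    gene, ε_i = Σ_j O_ij over *all* of the gene's concepts j, self term
    included (so ε_i ≥ 1).

    Returns an empty mapping for a gene with no concepts (the caller
    assigns score 0).  Note the scoring pipeline applies the same formula
    after restricting to positive-weight concepts and collapsing
    duplicate gene sets; this function reports the unrestricted factors.
    """
    ids = sorted(index.concepts_for(gene))
    if not ids:
        return {}
    sets = [compendium[i].genes for i in ids]
    o = ochiai_matrix(sets)
    eps = o.sum(axis=1)
    return {cid: float(e) for cid, e in zip(ids, eps)}


def _active_sets(
    weights: ConceptWeightTable, compendium: ConceptCompendium
) -> tuple[list[frozenset[str]], np.ndarray, list[str]]:
    """Distinct positive-weight gene sets with one representative each.

    Exact-duplicate concepts share a gene set and necessarily the same
    weight (ω is a function of the gene set); if a user-supplied table
    disagrees, the maximum is kept and logged.
    """
    seen: dict[frozenset[str], int] = {}
    sets: list[frozenset[str]] = []
    omegas: list[float] = []
    reps: list[str] = []
    for c in compendium:
        w = float(weights.get(c.id, 0.0))
        if w <= 0.0:
            continue
        if c.genes in seen:
            k = seen[c.genes]
            if abs(omegas[k] - w) > 1e-12:
                logger.debug(
                    "duplicate gene set %r vs %r with differing weights; keeping max",
                    reps[k], c.id,
                )
                omegas[k] = max(omegas[k], w)
            continue
        seen[c.genes] = len(sets)
        sets.append(c.genes)
        omegas.append(w)
        reps.append(c.id)
    return sets, np.asarray(omegas, dtype=np.float64), reps


def _raw_from_active(omega: np.ndarray, o_sub: np.ndarray) -> float:
    eps = o_sub.sum(axis=1)
    ew = omega / eps
    ecn = float((1.0 / eps).sum())
    return float(ew.sum() / math.sqrt(ecn))


def uniconsig_scores(
    weights: ConceptWeightTable,
    compendium: ConceptCompendium,
    index: GeneConceptIndex | None = None,
) -> UniConSigScores:
    """Raw and normalized uniConSig scores for every universe gene.

    Only concepts with ω > 0 contribute to a gene's ΣEW and ECN — a
    non-enriched concept should neither add signal nor dilute the
    effective concept number.  Genes with no positive-weight concept
    score 0.  If all raw scores are equal the normalization is degenerate
    and every normalized score is 0 (warned).
    """
    sets, omega, _ = _active_sets(weights, compendium)
    raw: dict[str, float] = {g: 0.0 for g in compendium.universe}
    if sets:
        o_full = ochiai_matrix(sets)
        gene_to_idx: dict[str, list[int]] = {}
        for i, s in enumerate(sets):
            for g in s:
                gene_to_idx.setdefault(g, []).append(i)
        for g, idx in gene_to_idx.items():
            ix = np.asarray(idx)
            raw[g] = _raw_from_active(omega[ix], o_full[np.ix_(ix, ix)])
    vals = np.array(list(raw.values()))
    lo, hi = (float(vals.min()), float(vals.max())) if vals.size else (0.0, 0.0)
    if hi > lo:
        normalized = {g: (v - lo) / (hi - lo) for g, v in raw.items()}
    else:
        if raw:
            warnings.warn("all raw uniConSig scores are equal; normalized scores set to 0")
        normalized = {g: 0.0 for g in raw}
    return UniConSigScores(raw=raw, normalized=normalized)


def gene_penalization(
    gene: str,
    weights: ConceptWeightTable,
    compendium: ConceptCompendium,
) -> GenePenalization:
    """Penalization breakdown for one gene as used by the scoring pipeline
    (positive-weight concepts, duplicate gene sets collapsed)."""
    sets, omega, reps = _active_sets(weights, compendium)
    idx = [i for i, s in enumerate(sets) if gene in s]
    if not idx:
        return GenePenalization(gene=gene, records=(), ecn=0.0)
    ix = np.asarray(idx)
    o_sub = ochiai_matrix([sets[i] for i in idx])
    eps = o_sub.sum(axis=1)
    records = tuple(
        PenalizationRecord(concept_id=reps[i], omega=float(omega[i]), epsilon=float(e), ew=float(omega[i] / e))
        for i, e in zip(idx, eps)
    )
    ecn = float((1.0 / eps).sum())
    return GenePenalization(gene=gene, records=records, ecn=ecn)


def csea_uniconsig(
    target: set[str],
    compendium: ConceptCompendium,
    leave_one_out: bool = False,
) -> UniConSigScores:
    """CSEA scoring convenience: concept weights then uniConSig.

    With ``leave_one_out`` each target gene x is scored with concept
    weights recomputed against target \\ {x} (the closed form
    ``(|T∩C| − [x∈C]) / sqrt((|T|−1)·|C|)``), replicating the original
    leave-one-out training protocol; non-target genes use the full
    weights.  Default keeps target genes in their own scoring.
    """
    target = set(target)
    weights = csea_concept_weights(target, compendium)
    scores = uniconsig_scores(weights, compendium)
    if not leave_one_out:
        return scores
    if len(target) < 2:
        raise ValidationError("leave-one-out requires a target of at least 2 genes")
    raw = dict(scores.raw)
    nt = len(target)
    for x in target & compendium.universe:
        loo: ConceptWeightTable = {}
        for c in compendium:
            inter = len(target & c.genes) - (1 if x in c.genes else 0)
            loo[c.id] = inter / math.sqrt((nt - 1) * len(c.genes)) if inter > 0 else 0.0
        sets, omega, _ = _active_sets(loo, compendium)
        idx = [i for i, s in enumerate(sets) if x in s]
        if not idx:
            raw[x] = 0.0
            continue
        o_sub = ochiai_matrix([sets[i] for i in idx])
        raw[x] = _raw_from_active(omega[np.asarray(idx)], o_sub)
    vals = np.array(list(raw.values()))
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        normalized = {g: (v - lo) / (hi - lo) for g, v in raw.items()}
    else:
        warnings.warn("all raw uniConSig scores are equal; normalized scores set to 0")
        normalized = {g: 0.0 for g in raw}
    return UniConSigScores(raw=raw, normalized=normalized)
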