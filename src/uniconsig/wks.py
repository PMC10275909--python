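"""Weighted Kolmogorov–Smirnov (WKS) running-sum enrichment.

A GSEA-style weighted step-up random walk over a ranked gene list: hits
(genes in the tested set) step the running sum up in proportion to
``|w|^exponent``; misses step it down by ``1/(N - N_hit)``.  The
enrichment score (ES) is the signed extremum of the walk.  The normalized
enrichment score is ``NES = ES / mean(ES_random)`` where the null ES
distribution comes from uniformly random gene subsets of the same size,
normalized against sign-matched null samples.

The null is size-stratified: gene sets with equal overlap share one null
distribution per ranked list (the ES null depends on the ranked weights
and the subset size only).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .compendium import ValidationError

logger = logging.getLogger("uniconsig.wks")

DEFAULT_EXPONENT = 1.0
DEFAULT_N_PERM = 1000


class UntestableSetError(ValidationError):
    """The tested gene set does not intersect the ranked list."""


@dataclass(frozen=True)
class RankedList:
    """Ranked gene list: unique genes with parallel non-increasing weights.

    Ties in weight are broken by lexicographic gene id so ranking is
    deterministic for any input order.
    """

    genes: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.weights):
            raise ValidationError("genes and weights must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("ranked gene identifiers must be unique")
        w = np.asarray(self.weights, dtype=np.float64)
        if np.any(np.diff(w) > 0):
            raise ValidationError("weights must be non-increasing")
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_weights(cls, weighted: Mapping[str, float]) -> "RankedList":
        """Sort a gene → weight mapping descending, ties by gene id."""
        items = sorted(weighted.items(), key=lambda kv: (-kv[1], kv[0]))
        genes = tuple(g for g, _ in items)
        weights = np.array([w for _, w in items], dtype=np.float64)
        return cls(genes=genes, weights=weights)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    @property
    def positions(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class EnrichmentStat:
    """WKS result: signed extremum ES, the full running sum, the leading
    edge, and (once normalized) NES and permutation p-value."""

    es: float
    running_sum: np.ndarray
    leading_edge: frozenset[str]
    nes: float | None = None
    p_value: float | None = None


@dataclass(frozen=True)
class NullDistribution:
    """ES samples for random same-size gene subsets, with the seed used."""

    es_samples: np.ndarray
    seed: int
    set_size: int = 0


def _hit_increments(
    weights: np.ndarray, hit: np.ndarray, exponent: float
) -> tuple[np.ndarray, float]:
    """Per-position hit weights ``|w|^exponent`` and their total.

    If every hit carries zero weight (possible when scores pad a zero
    tail), fall back to uniform increments so the walk stays defined.
    """
    w = np.abs(weights[hit]) ** exponent
    denom = float(w.sum())
    if denom == 0.0:
        w = np.ones(int(hit.sum()))
        denom = float(w.sum())
        logger.debug("all hit weights are zero; using uniform hit increments")
    return w, denom


def running_sum_es(
    ranked: RankedList,
    gene_set: Iterable[str],
    exponent: float = DEFAULT_EXPONENT,
) -> EnrichmentStat:
    """Compute the WKS running sum and signed-extremum ES for ``gene_set``.

    The ES is the running-sum element of maximal absolute deviation from
    zero (first occurrence on exact ties).  The leading edge is the hit
    genes at or before the extremum for positive ES, at or after it for
    negative ES.
    """
    if exponent < 0:
        raise ValidationError("exponent must be non-negative")
    gs = frozenset(gene_set)
    n = len(ranked)
    hit = np.fromiter((g in gs for g in ranked.genes), dtype=bool, count=n)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise UntestableSetError("gene set does not intersect the ranked list")
    step = np.empty(n, dtype=np.float64)
    w, denom = _hit_increments(ranked.weights, hit, exponent)
    step[hit] = w / denom
    if n_hit == n:
        # No miss steps exist: the walk climbs monotonically to 1.
        logger.debug("gene set covers the entire ranked list; ES=1 by convention")
        run = np.cumsum(step)
        return EnrichmentStat(es=1.0, running_sum=run, leading_edge=gs & ranked.gene_set)
    step[~hit] = -1.0 / (n - n_hit)
    run = np.cumsum(step)
    i = int(np.argmax(np.abs(run)))
    es = float(run[i])
    if es > 0:
        lead = {g for k, g in enumerate(ranked.genes) if hit[k] and k <= i}
    elif es < 0:
        lead = {g for k, g in enumerate(ranked.genes) if hit[k] and k >= i}
    else:
        lead = set()
    return EnrichmentStat(es=es, running_sum=run, leading_edge=frozenset(lead))


def _es_from_positions(
    positions: np.ndarray, hit_weights: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many subsets given as sorted hit-position rows.

    ``positions``: (P, k) int array of sorted 0-based ranks per subset;
    ``hit_weights``: length-n array of ``|w|^exponent``.  The running-sum
    extrema occur only at hit positions (local maxima) or just before hits
    (local minima), so the full walk need not be materialized.
    """
    p, k = positions.shape
    h = hit_weights[positions]
    denom = h.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0.0
    if np.any(zero):
        h[zero] = 1.0
        denom[zero] = float(k)
    cumh = np.cumsum(h, axis=1) / denom
    d = 1.0 / (n - k)
    m = np.arange(1, k + 1)
    tops = cumh - (positions + 1 - m) * d
    bots = np.concatenate([np.zeros((p, 1)), cumh[:, :-1]], axis=1) - (positions - (m - 1)) * d
    tmax = tops.max(axis=1)
    bmin = bots.min(axis=1)
    return np.where(tmax >= -bmin, tmax, bmin)


def permutation_null(
    ranked: RankedList,
    set_size: int,
    exponent: float = DEFAULT_EXPONENT,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> NullDistribution:
    """ES null from ``n_perm`` uniformly random subsets of ``set_size``
    genes drawn without replacement; bit-reproducible for a fixed seed."""
    n = len(ranked)
    if set_size < 1:
        raise ValidationError("set_size must be positive")
    if set_size > n:
        raise ValidationError(f"set_size {set_size} exceeds ranked list length {n}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if set_size == n:
        # Only one subset exists; every sample is the all-hit ES of 1.
        return NullDistribution(np.ones(n_perm), seed=seed, set_size=set_size)
    rng = np.random.default_rng(seed)
    wabs = np.abs(ranked.weights) ** exponent
    positions = np.empty((n_perm, set_size), dtype=np.int64)
    for i in range(n_perm):
        positions[i] = np.sort(rng.choice(n, size=set_size, replace=False))
    samples = _es_from_positions(positions, wabs, n)
    return NullDistribution(samples, seed=seed, set_size=set_size)


def normalize_es(es: float, null: NullDistribution) -> tuple[float, float]:
    """Sign-matched normalization: ``NES = ES / mean(same-sign null ES)``.

    The p-value is the one-sided empirical frequency of null samples at
    least as extreme with the same sign, add-one smoothed as
    ``(k+1)/(n_same_sign+1)`` so permutation p-values are never zero.
    """
    samples = null.es_samples
    if samples.size == 0:
        raise ValidationError("null distribution is empty")
    if es == 0.0:
        return 0.0, 1.0
    if es > 0:
        pool = samples[samples >= 0]
        strict = samples[samples > 0]
        if strict.size == 0:
            warnings.warn("no positive null samples; NES undefined, returning 0")
            return 0.0, 1.0
        nes = es / float(strict.mean())
        k = int((pool >= es).sum())
        p = (k + 1) / (pool.size + 1)
    else:
        pool = samples[samples < 0]
        if pool.size == 0:
            warnings.warn("no negative null samples; NES undefined, returning 0")
            return 0.0, 1.0
        nes = -(abs(es) / float(np.abs(pool).mean()))
        k = int((pool <= es).sum())
        p = (k + 1) / (pool.size + 1)
    return float(nes), float(min(p, 1.0))


_ADJUST_METHODS = {"bonferroni": "bonferroni", "benjamini_hochberg": "fdr_bh"}


def adjust_pvalues(
    p_values: Sequence[float], method: str = "benjamini_hochberg"
) -> np.ndarray:
    """Bonferroni or Benjamini–Hochberg adjustment, clipped to [0, 1],
    returned in input order."""
    if method not in _ADJUST_METHODS:
        raise ValidationError(f"unknown adjustment method {method!r}")
    p = np.asarray(list(p_values), dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method=_ADJUST_METHODS[method])
    return np.clip(adj, 0.0, 1.0)


def _stable_set_seed(seed: int, gene_set: frozenset[str]) -> int:
    """Derive a sub-seed from a gene set's content (order-independent)."""
    h = hashlib.sha256(("\n".join(sorted(gene_set))).encode()).digest()
    token = int.from_bytes(h[:4], "big")
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, token]).generate_state(1)[0] % (2**31))


def _size_seed(seed: int, size: int) -> int:
    return int(
        np.random.SeedSequence([seed & 0x7FFFFFFF, size]).generate_state(1)[0] % (2**31)
    )


class WksEngine:
    """WKS tester bound to one ranked list, with cached size-stratified
    permutation nulls (``null_mode="shared"``) or per-set nulls seeded
    from the set's content (``null_mode="per_set"``)."""

    def __init__(
        self,
        ranked: RankedList,
        exponent: float = DEFAULT_EXPONENT,
        n_perm: int = DEFAULT_N_PERM,
        seed: int = 0,
        null_mode: str = "shared",
    ):
        if null_mode not in ("shared", "per_set"):
            raise ValidationError(f"unknown null_mode {null_mode!r}")
        self.ranked = ranked
        self.exponent = float(exponent)
        self.n_perm = int(n_perm)
        self.seed = int(seed)
        self.null_mode = null_mode
        self._null_cache: dict[int, NullDistribution] = {}

    def null_for(self, set_size: int, gene_set: frozenset[str] | None = None) -> NullDistribution:
        if self.null_mode == "per_set" and gene_set is not None:
            sub = _stable_set_seed(self.seed, gene_set)
            return permutation_null(self.ranked, set_size, self.exponent, self.n_perm, sub)
        if set_size not in self._null_cache:
            sub = _size_seed(self.seed, set_size)
            self._null_cache[set_size] = permutation_null(
                self.ranked, set_size, self.exponent, self.n_perm, sub
            )
        return self._null_cache[set_size]

    def test(self, gene_set: Iterable[str]) -> EnrichmentStat:
        """ES, NES and permutation p for ``gene_set`` on the bound list."""
        gs = frozenset(gene_set) & self.ranked.gene_set
        stat = running_sum_es(self.ranked, gs, self.exponent)
        null = self.null_for(len(gs), gs)
        stat.nes, stat.p_value = normalize_es(stat.es, null)
        return stat


def running_sum_table(ranked: RankedList, stat: EnrichmentStat):
    """Enrichment-curve rows (rank, gene, weight, running_sum) for export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked) + 1),
            "gene": ranked.genes,
            "weight": ranked.weights,
            "running_sum": stat.running_sum,
        }
    )


def export_enrichment_curve(ranked: RankedList, stat: EnrichmentStat, path) -> None:
    """Write the running-sum curve as TSV (the per-pathway enrichment plot)."""
    running_sum_table(ranked, stat).to_csv(path, sep="\t", index=False)
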