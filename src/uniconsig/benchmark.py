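"""Dropout simulation, rank-variation benchmarking and synthetic fixtures.

scRNA-seq dropouts are emulated by deleting a random fraction of genes
from the weighted gene list (what a differential-expression pipeline
would emit after dropout), re-running enrichment, and measuring how
much the top-K pathway ranks move.  Rank variation is
``original_rank − perturbed_rank`` with negative values indicating
reduced significance; a pathway absent from the perturbed table gets
``perturbed_rank = K_new + 1``.

The synthetic fixture generator builds a concept compendium, a pathway
collection and a weighted gene list with planted signal: planted
pathways' genes receive a mean weight shift over Gaussian background
noise, and "signature" concepts partially overlapping each planted
pathway are added so concept-signature scoring has stable evidence to
lean on when individual genes drop out.  A plain WKS run on the raw
weighted list serves as the GSEA-like baseline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .compendium import Concept, ConceptCompendium, ValidationError, write_gmt
from .enrich import (
    EnrichmentParams,
    PathwayTable,
    derive_seed,
    enrich_ranked,
    run_csea,
    run_wcsea,
)
from .wks import RankedList

logger = logging.getLogger("uniconsig.benchmark")

DEFAULT_N_REPS = 5  # five perturbation replicates per simulated condition
DEFAULT_TOP_K = 30
#: Fraction of the weighted list (by weight, descending) used as the CSEA
#: target when benchmarking the unweighted method on a weighted fixture.
DEFAULT_TARGET_FRACTION = 0.1


@dataclass(frozen=True)
class DropoutSpec:
    """Fraction of genes to delete (in [0, 1)) and the deletion seed."""

    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction < 1.0:
            raise ValidationError("dropout fraction must be in [0, 1)")


def simulate_dropout(weighted: Mapping[str, float], spec: DropoutSpec) -> dict[str, float]:
    """Delete exactly ``round(fraction·N)`` genes uniformly at random.

    Gene order is preserved; the same seed always removes the same genes.
    """
    genes = list(weighted)
    n = len(genes)
    if n == 0:
        raise ValidationError("weighted gene list is empty")
    n_remove = int(round(spec.fraction * n))
    if n_remove == 0:
        return dict(weighted)
    rng = np.random.default_rng(spec.seed)
    removed = set(rng.choice(n, size=n_remove, replace=False).tolist())
    return {g: w for i, (g, w) in enumerate(weighted.items()) if i not in removed}


@dataclass(frozen=True)
class RankVariationReport:
    """Per-pathway rank shifts for the original top-K, plus summaries."""

    variation: Mapping[str, int]
    top_k: int
    median: float
    iqr: float
    fraction_unchanged: float


def rank_variation(
    original: PathwayTable, perturbed: PathwayTable, top_k: int
) -> RankVariationReport:
    """Rank variation of the original top_k pathways after perturbation."""
    if top_k > len(original):
        raise ValidationError(f"top_k={top_k} exceeds original table size {len(original)}")
    absent_rank = len(perturbed) + 1
    variation: dict[str, int] = {}
    for r in original.results[:top_k]:
        new_rank = perturbed.rank_of(r.pathway_id)
        if new_rank is None:
            new_rank = absent_rank
        variation[r.pathway_id] = r.rank - new_rank
    vals = np.array(list(variation.values()), dtype=float)
    return RankVariationReport(
        variation=variation,
        top_k=top_k,
        median=float(np.median(vals)),
        iqr=float(np.percentile(vals, 75) - np.percentile(vals, 25)),
        fraction_unchanged=float((vals == 0).mean()),
    )


@dataclass(frozen=True)
class SyntheticFixture:
    """Self-contained test universe: concepts, pathways, weighted list and
    ground truth about planted pathways."""

    compendium: ConceptCompendium
    pathways: ConceptCompendium
    weights: Mapping[str, float]
    planted: Mapping[str, float]  # pathway id -> effect size
    seed: int
    noise_sd: float = 1.0

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "concepts": out / "concepts.gmt",
            "pathways": out / "pathways.gmt",
            "weights": out / "weights.tsv",
            "truth": out / "truth.json",
        }
        write_gmt(self.compendium, paths["concepts"])
        write_gmt(self.pathways, paths["pathways"])
        with open(paths["weights"], "w", encoding="utf-8", newline="\n") as fh:
            for g, w in self.weights.items():
                fh.write(f"{g}\t{w!r}\n")
        with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
            json.dump(
                {"planted": dict(self.planted), "seed": self.seed, "noise_sd": self.noise_sd},
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
        return paths

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for c in self.compendium:
            h.update(f"{c.id}:{','.join(sorted(c.genes))};".encode())
        for p in self.pathways:
            h.update(f"{p.id}:{','.join(sorted(p.genes))};".encode())
        for g in sorted(self.weights):
            h.update(f"{g}={self.weights[g]!r};".encode())
        return h.hexdigest()


def generate_fixture(
    n_genes: int,
    n_concepts: int,
    concept_size_range: tuple[int, int],
    n_pathways: int,
    planted: Sequence[tuple[int, float]] = (),
    noise_sd: float = 1.0,
    seed: int = 0,
    pathway_size_range: tuple[int, int] = (20, 40),
    n_signature_per_planted: int = 5,
    signature_core_fraction: tuple[float, float] = (0.5, 0.9),
) -> SyntheticFixture:
    """Generate a deterministic planted-signal fixture.

    ``planted`` lists (pathway index, effect size) pairs; the named
    pathways' genes get a ``+effect`` mean shift on Normal(0, noise_sd)
    background weights.  For each planted pathway with positive effect,
    ``n_signature_per_planted`` signature concepts are drawn that contain
    a random 50–90% core of the pathway's genes topped up with random
    background genes — these provide the concept-signature "buffer" the
    weighted method exploits.  The remaining concepts are uniformly
    random gene sets, as are all pathways.  With no planted effect the
    fixture is an honest null: no concept is coupled to any pathway.
    """
    if n_genes < 1 or n_concepts < 1 or n_pathways < 1:
        raise ValidationError("n_genes, n_concepts and n_pathways must be positive")
    lo, hi = concept_size_range
    plo, phi = pathway_size_range
    if not (1 <= lo <= hi):
        raise ValidationError("invalid concept_size_range")
    if hi > n_genes or phi > n_genes:
        raise ValidationError("size range infeasible for n_genes")
    for idx, _ in planted:
        if not 0 <= idx < n_pathways:
            raise ValidationError(f"planted pathway index {idx} out of range")
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:05d}" for i in range(n_genes)])

    pw_list: list[Concept] = []
    for i in range(n_pathways):
        size = int(rng.integers(plo, phi + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        pw_list.append(
            Concept(id=f"PW{i:03d}", name=f"synthetic pathway {i}", genes=frozenset(genes[members]))
        )
    pathways = ConceptCompendium(pw_list)

    planted_ids = {f"PW{i:03d}": float(e) for i, e in planted}
    effective = [(f"PW{i:03d}", e) for i, e in planted if e > 0]

    concepts: list[Concept] = []
    cidx = 0
    flo, fhi = signature_core_fraction
    for pid, _ in effective:
        pw_genes = np.array(sorted(pathways[pid].genes))
        for _ in range(n_signature_per_planted):
            if cidx >= n_concepts:
                break
            size = int(rng.integers(lo, hi + 1))
            frac = float(rng.uniform(flo, fhi))
            n_core = max(1, min(size, int(round(frac * len(pw_genes)))))
            core = rng.choice(pw_genes, size=n_core, replace=False)
            n_pad = size - n_core
            pad = genes[rng.choice(n_genes, size=n_pad, replace=False)] if n_pad else []
            members = frozenset(core) | frozenset(pad)
            concepts.append(
                Concept(id=f"CPT{cidx:04d}", name=f"signature concept for {pid}", genes=members)
            )
            cidx += 1
    while cidx < n_concepts:
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        concepts.append(
            Concept(id=f"CPT{cidx:04d}", name="random concept", genes=frozenset(genes[members]))
        )
        cidx += 1
    compendium = ConceptCompendium(concepts)

    w = rng.normal(0.0, noise_sd, size=n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for pid, eff in planted_ids.items():
        for g in pathways[pid].genes:
            w[gene_pos[g]] += eff
    weights = {g: float(w[i]) for i, g in enumerate(genes)}
    return SyntheticFixture(
        compendium=compendium,
        pathways=pathways,
        weights=weights,
        planted=planted_ids,
        seed=seed,
        noise_sd=noise_sd,
    )


def load_fixture(fixture_dir) -> SyntheticFixture:
    """Read a fixture previously written with :meth:`SyntheticFixture.write`."""
    from .compendium import read_gmt

    d = Path(fixture_dir)
    compendium = read_gmt(d / "concepts.gmt", min_size=1, max_size=10**6)
    pathways = read_gmt(d / "pathways.gmt", min_size=1, max_size=10**6)
    weights: dict[str, float] = {}
    with open(d / "weights.tsv", encoding="utf-8") as fh:
        for line in fh:
            g, v = line.rstrip("\n").split("\t")
            weights[g] = float(v)
    with open(d / "truth.json", encoding="utf-8") as fh:
        truth = json.load(fh)
    return SyntheticFixture(
        compendium=compendium,
        pathways=pathways,
        weights=weights,
        planted=truth["planted"],
        seed=truth["seed"],
        noise_sd=truth.get("noise_sd", 1.0),
    )


def target_from_weights(
    weighted: Mapping[str, float], top_fraction: float = DEFAULT_TARGET_FRACTION
) -> set[str]:
    """Unweighted target for CSEA: the top fraction of genes by weight."""
    if not 0.0 < top_fraction <= 1.0:
        raise ValidationError("top_fraction must be in (0, 1]")
    ranked = RankedList.from_weights(dict(weighted))
    k = max(1, int(round(top_fraction * len(ranked))))
    return set(ranked.genes[:k])


def run_plain_wks(
    weighted: Mapping[str, float],
    pathways: ConceptCompendium,
    params: EnrichmentParams,
    direction: str = "up",
) -> PathwayTable:
    """GSEA-like baseline: WKS of each pathway directly on the raw
    weighted list, skipping concept-signature scoring."""
    weighted = dict(weighted)
    if direction == "down":
        weighted = {g: -w for g, w in weighted.items()}
    ranked = RankedList.from_weights(weighted)
    prov = {"mode": "plain_wks", "direction": direction, "seed": params.seed}
    return enrich_ranked(ranked, pathways, params, direction, prov)


_METHODS = ("wcsea", "csea", "plain_wks")


def _run_method(
    method: str,
    weighted: Mapping[str, float],
    fixture: SyntheticFixture,
    params: EnrichmentParams,
    target_fraction: float,
) -> PathwayTable:
    if method == "wcsea":
        return run_wcsea(weighted, fixture.compendium, fixture.pathways, params)
    if method == "csea":
        target = target_from_weights(weighted, target_fraction)
        return run_csea(target, fixture.compendium, fixture.pathways, params)
    if method == "plain_wks":
        return run_plain_wks(weighted, fixture.pathways, params)
    raise ValidationError(f"unknown method {method!r}; expected one of {_METHODS}")


def dropout_benchmark(
    fixture: SyntheticFixture,
    methods: Sequence[str],
    fractions: Sequence[float],
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    params: EnrichmentParams | None = None,
    top_k: int | None = None,
    target_fraction: float = DEFAULT_TARGET_FRACTION,
) -> dict[str, dict[tuple[float, int], RankVariationReport]]:
    """Perturb–rerun–compare for each method × fraction × replicate.

    Every method is run once on the intact list to fix the original
    ranking, then re-run on each dropout replicate; reports are keyed by
    (fraction, replicate).  The dropout seed for each replicate is
    derived deterministically from ``seed``.
    """
    for m in methods:
        if m not in _METHODS:
            raise ValidationError(f"unknown method {m!r}; expected one of {_METHODS}")
    if params is None:
        params = EnrichmentParams(seed=seed)
    reports: dict[str, dict[tuple[float, int], RankVariationReport]] = {}
    for method in methods:
        original = _run_method(method, fixture.weights, fixture, params, target_fraction)
        k = min(top_k or DEFAULT_TOP_K, len(original))
        per_method: dict[tuple[float, int], RankVariationReport] = {}
        for fraction in fractions:
            for rep in range(n_reps):
                drop_seed = derive_seed(seed, f"dropout-{fraction}-{rep}")
                spec = DropoutSpec(fraction=fraction, seed=drop_seed)
                perturbed_weights = simulate_dropout(fixture.weights, spec)
                perturbed = _run_method(method, perturbed_weights, fixture, params, target_fraction)
                per_method[(fraction, rep)] = rank_variation(original, perturbed, k)
        reports[method] = per_method
    return reports


def planted_variation_summary(
    reports: dict[str, dict[tuple[float, int], RankVariationReport]],
    planted_ids: Sequence[str],
) -> dict[str, dict[float, float]]:
    """Median |rank variation| of the planted pathways per method and
    dropout fraction (the stability headline number)."""
    out: dict[str, dict[float, float]] = {}
    for method, per in reports.items():
        by_frac: dict[float, list[float]] = {}
        for (fraction, _), rep in per.items():
            for pid in planted_ids:
                if pid in rep.variation:
                    by_frac.setdefault(fraction, []).append(abs(rep.variation[pid]))
        out[method] = {f: float(np.median(v)) for f, v in sorted(by_frac.items())}
    return out
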