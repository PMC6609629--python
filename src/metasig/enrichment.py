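"""Gene-set enrichment: weighted-KS running-sum statistic with phenotype
permutation, and hypergeometric over-representation for user-supplied sets.

The enrichment score (ES) is the signed maximum deviation of a running sum
that steps up at gene-set hits (proportionally to |metric|^weight) and down
uniformly at misses, over a ranking of all genes by a class-contrast metric
(signal-to-noise). Normalization (NES) and nominal p-values come from
re-ranking under permuted phenotype labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats_core
from .data_model import ExpressionMatrix, SampleAnnotation
from .intersect import GeneList

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "read_gmt",
    "signal_to_noise_rank",
    "enrichment_score",
    "nes_permutation_test",
    "overrepresentation_test",
]


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by a descending real-valued ranking metric."""

    genes: tuple[str, ...]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if not np.all(np.isfinite(self.metric)):
            raise ValueError("non-finite ranking metric")


@dataclass(frozen=True)
class EnrichmentResult:
    es: float
    nes: float
    nominal_p: float
    n_permutations: int
    set_size: int


def read_gmt(path: str | Path) -> dict[str, GeneList]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, GeneList] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, members): {line!r}")
        name = parts[0]
        sets[name] = GeneList.from_iterable(name, parts[2:])
    return sets


# ---------------------------------------------------------------------------


def _snr_metric(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-gene signal-to-noise: (mean_a - mean_b)/(sd_a + sd_b), with each
    sd floored at 0.2*|its mean| (and a small absolute floor), the GSEA
    convention that keeps low-variance genes from dominating."""
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    sa = np.maximum(a.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(ma), 1e-8))
    sb = np.maximum(b.std(axis=1, ddof=1), np.maximum(0.2 * np.abs(mb), 1e-8))
    return (ma - mb) / (sa + sb)


def signal_to_noise_rank(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    class_a: str,
    class_b: str,
) -> RankedList:
    """Rank all genes by signal-to-noise between two classes, descending."""
    sa = [s for s in ann.samples_of(class_a) if s in set(m.sample_ids)]
    sb = [s for s in ann.samples_of(class_b) if s in set(m.sample_ids)]
    if len(sa) < 3 or len(sb) < 3:
        raise ValueError("signal-to-noise ranking needs >= 3 samples per class")
    metric = _snr_metric(m.values[sa].to_numpy(float), m.values[sb].to_numpy(float))
    order = np.argsort(-metric, kind="mergesort")
    genes = tuple(np.asarray(m.gene_ids)[order])
    return RankedList(genes=genes, metric=metric[order])


def enrichment_score(
    ranked: RankedList, gene_set: GeneList | set[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov enrichment score and its running profile.

    Hits step the running sum up by |metric|^weight (normalized to sum 1
    over hits); misses step down by 1/(n_misses). ES is the deviation of
    largest magnitude. Returns (es, profile); the profile has one value per
    ranked gene and starts/ends at 0 by construction.
    """
    members = gene_set.genes if isinstance(gene_set, GeneList) else {str(g).strip().upper() for g in gene_set}
    hit = np.array([g.upper() in members for g in ranked.genes])
    n_hits = int(hit.sum())
    n_miss = len(ranked.genes) - n_hits
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_miss == 0:
        return 0.0, np.zeros(len(ranked.genes))
    w = np.abs(ranked.metric) ** weight
    hit_sum = w[hit].sum()
    if hit_sum == 0:
        hit_inc = np.where(hit, 1.0 / n_hits, 0.0)
    else:
        hit_inc = np.where(hit, w / hit_sum, 0.0)
    steps = hit_inc - np.where(hit, 0.0, 1.0 / n_miss)
    profile = np.cumsum(steps)
    es = float(profile[np.argmax(np.abs(profile))])
    return es, profile


def nes_permutation_test(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    gene_set: GeneList | set[str],
    class_a: str,
    class_b: str,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Phenotype-permutation enrichment test.

    Class labels are permuted ``n_perm`` times; each permutation re-ranks
    all genes and recomputes the ES. NES = ES divided by the mean |ES| of
    same-sign permutations; nominal p = (# same-sign permutation ES at least
    as extreme + 1) / (# same-sign + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sa = [s for s in ann.samples_of(class_a) if s in set(m.sample_ids)]
    sb = [s for s in ann.samples_of(class_b) if s in set(m.sample_ids)]
    if len(sa) < 3 or len(sb) < 3:
        raise ValueError("needs >= 3 samples per class")
    members = gene_set.genes if isinstance(gene_set, GeneList) else {str(g).strip().upper() for g in gene_set}
    genes = np.asarray(m.gene_ids)
    arr = m.values[sa + sb].to_numpy(float)
    na = len(sa)

    def es_of(cols_a: np.ndarray) -> float:
        mask = np.zeros(arr.shape[1], bool)
        mask[cols_a] = True
        metric = _snr_metric(arr[:, mask], arr[:, ~mask])
        order = np.argsort(-metric, kind="mergesort")
        ranked = RankedList(tuple(genes[order]), metric[order])
        es, _ = enrichment_score(ranked, members, weight)
        return es

    es_obs = es_of(np.arange(na))
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(arr.shape[1])[:na]
        perm_es[i] = es_of(perm)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es_obs)] if es_obs != 0 else perm_es
    n_same = len(same_sign)
    if n_same == 0:
        import warnings

        warnings.warn("no same-sign permutations; p at resolution limit")
        return EnrichmentResult(es_obs, np.sign(es_obs) * np.inf, 1.0 / (n_perm + 1), n_perm, len(members))
    nes = es_obs / np.mean(np.abs(same_sign))
    p = (int(np.sum(np.abs(same_sign) >= abs(es_obs))) + 1) / (n_same + 1)
    return EnrichmentResult(float(es_obs), float(nes), float(p), n_perm, len(members))


def overrepresentation_test(
    hits: GeneList, gene_set: GeneList, universe_size: int
) -> stats_core.TestResult:
    """Hypergeometric upper-tail test for over-representation of a gene set
    among a hit list drawn from a universe of ``universe_size`` genes."""
    if universe_size < len(hits) or universe_size < len(gene_set):
        raise ValueError("universe smaller than a gene list")
    k = len(hits.genes & gene_set.genes)
    p = stats_core.hypergeom_upper_tail(k, len(hits), len(gene_set), universe_size)
    return stats_core.TestResult(statistic=float(k), p_value=min(p, 1.0), method="hypergeometric")
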