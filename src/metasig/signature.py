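"""PCA-loading gene-signature discovery.

The core algorithm of the package. Starting from a candidate gene panel on a
standardized expression matrix:

1. fit PCA (samples as observations, genes as variables),
2. find the component that best separates two disease classes,
3. pre-select the genes with the most extreme loadings on that component,
4. greedily remove the gene with the smallest absolute first-component
   loading, accepting each removal only if it does not reduce the fraction
   of variance explained by the first component ("first component value")
   nor the class separation of the first-component scores,
5. the surviving panel is the signature.

The intuition: genes that carry the class-separating axis load heavily on
the leading component of the reduced panel; noise genes dilute the leading
component's variance share, so their removal raises it and is accepted,
while removal of a signature gene degrades separation and is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import stats_core
from .classify import roc_auc
from .data_model import ExpressionMatrix, SampleAnnotation, Scale
from .intersect import GeneList

__all__ = [
    "PCAModel",
    "SeparationResult",
    "PruneStep",
    "PruneTrace",
    "Signature",
    "PruneConfig",
    "pca_fit",
    "separation_statistic",
    "select_separating_component",
    "select_extreme_loadings",
    "greedy_prune",
    "discover_signature",
]


@dataclass(frozen=True)
class PCAModel:
    """Loadings (genes x components), scores (samples x components) and
    per-component variance-explained fractions, components in decreasing
    variance order. Loadings columns are orthonormal; each component is
    oriented so its largest-|loading| gene loads positively."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    loadings: np.ndarray
    scores: np.ndarray
    variance_explained: np.ndarray


@dataclass(frozen=True)
class SeparationResult:
    """How well one component's scores separate two classes."""

    component_index: int
    statistic: float  # |Welch t| of scores between classes
    auc: float  # rank concordance, oriented >= 0.5
    class_a: str
    class_b: str


@dataclass(frozen=True)
class PruneStep:
    removed_gene: str
    abs_loading: float
    variance_explained_0: float
    separation_statistic: float
    separation_auc: float
    accepted: bool


@dataclass(frozen=True)
class PruneTrace:
    steps: tuple[PruneStep, ...]

    def accepted(self) -> list[PruneStep]:
        return [s for s in self.steps if s.accepted]


@dataclass(frozen=True)
class Signature:
    genes: tuple[str, ...]
    final_variance_explained: float
    final_separation: SeparationResult

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "final_variance_explained": self.final_variance_explained,
            "final_separation": {
                "component_index": self.final_separation.component_index,
                "statistic": self.final_separation.statistic,
                "auc": self.final_separation.auc,
                "class_a": self.final_separation.class_a,
                "class_b": self.final_separation.class_b,
            },
        }


@dataclass(frozen=True)
class PruneConfig:
    """Tunables of the greedy backward elimination.

    min_size: smallest panel size pruning may reach.
    epsilon: absolute slack on the variance-fraction (and AUC) non-decrease
      requirement.
    metric: separation gate metric. "t" (default) requires the |Welch t| of
      the first-component scores not to drop by more than the relative slack
      ``sep_rel_tol``; "auc" requires the score AUC not to drop by more than
      ``epsilon``. The |t| gate stays informative after the AUC saturates at
      1.0, which is what stops pruning from eating into a strongly
      separating signature.
    sep_rel_tol: relative slack of the |t| gate. Removing a gene that
      carries no class information perturbs |t| by a few percent at most
      (sampling noise of the refit scores), while removing a genuine
      signature gene from a near-minimal panel costs >= ~10%; 0.01 sits
      below the cost of losing signal while letting uninformative-gene
      fluctuations be absorbed over successive rounds.
    paper_strict: drop the separation gate entirely and constrain only the
      first-component variance fraction. Note that the variance-explained
      fraction of the leading component rises under almost any removal
      (the eigenvalue loses at most the gene's contribution while the
      denominator loses a whole gene), so this variant prunes all the way
      to ``min_size``.
    rerank_each_step: re-rank removal candidates after every accepted
      removal (default) or rank once on the initial panel.
    """

    min_size: int = 2
    epsilon: float = 1e-6
    metric: str = "t"
    sep_rel_tol: float = 0.01
    paper_strict: bool = False
    rerank_each_step: bool = True
    k_extreme: int | None = None  # pre-selection size; None = ceil(panel/2)
    k_max_components: int = 3
    class_a: str = "primary"
    class_b: str = "metastatic"
    include_normals_in_fit: bool = False  # restrict the PCA fit to the two classes


# ---------------------------------------------------------------------------


def pca_fit(m: ExpressionMatrix) -> PCAModel:
    """PCA of the standardized matrix via SVD, samples as observations.

    The decomposition is of the centered samples x genes matrix X = U S Vt;
    loadings are V's columns, scores are U S, and the variance-explained
    fractions are the squared singular values over their sum.
    """
    if m.scale is not Scale.GENE_STANDARDIZED:
        raise ValueError("pca_fit requires a gene-standardized matrix")
    if m.n_samples < 3 or m.n_genes < 2:
        raise ValueError("pca_fit needs >= 3 samples and >= 2 genes")
    x = m.values.to_numpy(float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if not np.any(s > 0):
        raise ValueError("rank-0 input: no variance to decompose")
    var = s**2
    ve = var / var.sum()
    loadings = vt.T  # genes x components
    scores = u * s  # samples x components
    # orient: largest-|loading| gene positive on each component
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    return PCAModel(
        gene_ids=tuple(m.gene_ids),
        sample_ids=tuple(m.sample_ids),
        loadings=loadings,
        scores=scores,
        variance_explained=ve,
    )


def separation_statistic(
    model: PCAModel,
    ann: SampleAnnotation,
    component_index: int,
    class_a: str = "primary",
    class_b: str = "metastatic",
) -> SeparationResult:
    """|Welch t| and score-AUC of one component between two classes."""
    if not (0 <= component_index < model.loadings.shape[1]):
        raise ValueError(f"component {component_index} out of range")
    classes = ann.classes().reindex(model.sample_ids)
    sa = np.asarray(classes == class_a)
    sb = np.asarray(classes == class_b)
    if sa.sum() < 2 or sb.sum() < 2:
        raise ValueError("each class needs >= 2 samples with scores")
    scores = model.scores[:, component_index]
    res = stats_core.welch_t(scores[sa], scores[sb])
    labels = np.concatenate([np.zeros(sa.sum()), np.ones(sb.sum())])
    auc = roc_auc(np.concatenate([scores[sa], scores[sb]]), labels).auc
    auc = max(auc, 1.0 - auc)  # orientation-free
    return SeparationResult(
        component_index=component_index,
        statistic=abs(res.statistic),
        auc=auc,
        class_a=class_a,
        class_b=class_b,
    )


def select_separating_component(
    model: PCAModel,
    ann: SampleAnnotation,
    k_max: int = 3,
    class_a: str = "primary",
    class_b: str = "metastatic",
) -> SeparationResult:
    """Best class-separating component among the first k_max, by |Welch t|."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k = min(k_max, model.loadings.shape[1])
    results = [
        separation_statistic(model, ann, i, class_a, class_b) for i in range(k)
    ]
    return max(results, key=lambda r: r.statistic)


def select_extreme_loadings(
    model: PCAModel, component_index: int, k: int
) -> GeneList:
    """The k genes with largest |loading| on the chosen component.

    Ties in |loading| are broken lexicographically by gene id so the
    selection is deterministic.
    """
    n = len(model.gene_ids)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    absl = np.abs(model.loadings[:, component_index])
    # quantize so that exact ties (up to float round-off) break by gene id
    order = sorted(range(n), key=lambda i: (-round(absl[i], 12), model.gene_ids[i]))
    chosen = [model.gene_ids[i] for i in order[:k]]
    return GeneList.from_iterable("extreme_loadings", chosen)


# ---------------------------------------------------------------------------


def _match_panel(m: ExpressionMatrix, panel: GeneList | Sequence[str]) -> list[str]:
    """Matrix gene ids belonging to the panel, in matrix order; matching is
    case-insensitive because GeneList normalizes identifiers to upper case."""
    if isinstance(panel, GeneList):
        wanted = panel.genes
    else:
        wanted = {str(g).strip().upper() for g in panel}
    return [g for g in m.gene_ids if str(g).strip().upper() in wanted]


def _fit_matrix(m: ExpressionMatrix, ann: SampleAnnotation, cfg: PruneConfig) -> ExpressionMatrix:
    if cfg.include_normals_in_fit:
        return m
    keep = [s for s in m.sample_ids if s in set(ann.samples_of(cfg.class_a, cfg.class_b))]
    return m.subset_samples(keep)


def _panel_state(
    fit_m: ExpressionMatrix, ann: SampleAnnotation, panel: Sequence[str], cfg: PruneConfig
):
    model = pca_fit(fit_m.subset_genes(panel))
    sep = separation_statistic(model, ann, 0, cfg.class_a, cfg.class_b)
    return model, sep


def _separation_ok(before: SeparationResult, after: SeparationResult, cfg: PruneConfig) -> bool:
    if cfg.paper_strict:
        return True
    if cfg.metric == "auc":
        return after.auc >= before.auc - cfg.epsilon
    if cfg.metric == "t":
        return after.statistic >= before.statistic * (1 - cfg.sep_rel_tol)
    raise ValueError(f"unknown separation metric {cfg.metric!r}")


def greedy_prune(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    panel: GeneList | Sequence[str],
    config: PruneConfig | None = None,
) -> tuple[Signature, PruneTrace]:
    """Backward elimination of low-|loading| genes under non-degradation gates.

    At each round the panel's PCA is refit, genes are ranked by |loading| on
    the first component, and the smallest is tentatively removed. The removal
    is accepted iff the first component's variance-explained fraction does
    not drop (beyond epsilon) and, unless ``paper_strict``, the class
    separation of the first-component scores does not drop either. On
    rejection the next-smallest candidate is tried; pruning stops when no
    candidate is removable or ``min_size`` is reached.
    """
    cfg = config or PruneConfig()
    genes = _match_panel(m, panel)
    if len(genes) < cfg.min_size:
        raise ValueError(f"panel smaller than min_size={cfg.min_size}")
    fit_m = _fit_matrix(m, ann, cfg)
    current = list(genes)
    model, sep = _panel_state(fit_m, ann, current, cfg)
    steps: list[PruneStep] = []
    ranked_once: list[str] | None = None
    if not cfg.rerank_each_step:
        absl = np.abs(model.loadings[:, 0])
        ranked_once = [
            g
            for _, g in sorted(
                zip(absl, current), key=lambda p: (round(p[0], 12), p[1])
            )
        ]
    while len(current) > cfg.min_size:
        if cfg.rerank_each_step:
            absl = np.abs(model.loadings[:, 0])
            candidates = [
                g
                for _, g in sorted(
                    zip(absl, current), key=lambda p: (round(p[0], 12), p[1])
                )
            ]
        else:
            candidates = [g for g in ranked_once if g in set(current)]
        abs_by_gene = dict(zip(model.gene_ids, np.abs(model.loadings[:, 0])))
        accepted_any = False
        for gene in candidates:
            trial = [g for g in current if g != gene]
            trial_model, trial_sep = _panel_state(fit_m, ann, trial, cfg)
            ve_ok = (
                trial_model.variance_explained[0]
                >= model.variance_explained[0] - cfg.epsilon
            )
            ok = ve_ok and _separation_ok(sep, trial_sep, cfg)
            steps.append(
                PruneStep(
                    removed_gene=gene,
                    abs_loading=float(abs_by_gene[gene]),
                    variance_explained_0=float(trial_model.variance_explained[0]),
                    separation_statistic=trial_sep.statistic,
                    separation_auc=trial_sep.auc,
                    accepted=ok,
                )
            )
            if ok:
                current, model, sep = trial, trial_model, trial_sep
                accepted_any = True
                break
            if len(trial) < cfg.min_size:
                break
        if not accepted_any:
            break
    signature = Signature(
        genes=tuple(current),
        final_variance_explained=float(model.variance_explained[0]),
        final_separation=sep,
    )
    return signature, PruneTrace(tuple(steps))


def discover_signature(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    panel: GeneList | Sequence[str],
    config: PruneConfig | None = None,
) -> tuple[Signature, dict]:
    """Full discovery: separating component -> extreme loadings -> greedy prune.

    Returns the signature plus a report of the intermediate artifacts
    (chosen component, pre-selected panel, prune trace).
    """
    cfg = config or PruneConfig()
    genes = _match_panel(m, panel)
    sub = _fit_matrix(m, ann, cfg).subset_genes(genes)
    model = pca_fit(sub)
    chosen = select_separating_component(
        model, ann, cfg.k_max_components, cfg.class_a, cfg.class_b
    )
    k = cfg.k_extreme or int(np.ceil(len(genes) / 2))
    preselected = select_extreme_loadings(model, chosen.component_index, k)
    signature, trace = greedy_prune(m, ann, preselected, cfg)
    report = {
        "panel_size": len(genes),
        "separating_component": chosen.component_index,
        "separating_statistic": chosen.statistic,
        "separating_auc": chosen.auc,
        "k_extreme": k,
        "preselected_genes": sorted(preselected.genes),
        "n_prune_steps": len(trace.steps),
        "n_accepted_removals": len(trace.accepted()),
    }
    return signature, report
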