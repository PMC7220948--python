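"""Gene ranking by linear-kernel SVM recursive feature elimination.

A linear soft-margin SVM is fitted on the per-gene-standardised expression
of the candidate genes; the gene(s) with the smallest squared weight w_i^2
are eliminated and the fit repeated until no genes remain.  The reverse
elimination order is the ranking: the last survivor matters most.

Genes are standardised (training mean/sd) before every fit so that |w| is
comparable across genes regardless of their raw intensity scale.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

from genesig.datasets import ExpressionDataset
from genesig.ranking import GeneRanking


def _standardised_matrix(ds: ExpressionDataset, genes: list[str]) -> np.ndarray:
    idx = ds.gene_index(genes)
    X = ds.values[idx].T  # samples x genes
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [genes[i] for i in np.flatnonzero(sd == 0)[:5]]
        raise ValueError(f"zero-variance genes cannot be ranked: {bad}")
    return (X - mean) / sd


def rfe_rank(
    ds: ExpressionDataset,
    genes: GeneRanking,
    step: int = 1,
    C: float = 1.0,
    seed: int = 0,
) -> GeneRanking:
    """Rank ``genes`` by recursive elimination of smallest-|w| features.

    ``step`` genes are removed per iteration (1 gives a total order).
    Within-batch ties in w^2 are broken by the incoming ranking order
    (screening p-value order), keeping the procedure deterministic.
    """
    gene_list = list(genes.ordered_genes)
    if len(gene_list) < 2:
        raise ValueError("RFE needs at least 2 genes")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    y = ds.outcome
    if len(np.unique(y)) < 2:
        raise ValueError("RFE needs both outcome classes present")

    X_all = _standardised_matrix(ds, gene_list)
    col = {g: i for i, g in enumerate(gene_list)}
    in_rank = {g: i for i, g in enumerate(gene_list)}  # tie-break key

    remaining = list(gene_list)
    eliminated: list[str] = []  # worst first
    elim_iter: dict[str, int] = {}
    elim_weight: dict[str, float] = {}
    iteration = 0
    while remaining:
        iteration += 1
        clf = SVC(kernel="linear", C=C, random_state=seed)
        clf.fit(X_all[:, [col[g] for g in remaining]], y)
        w2 = np.asarray(clf.coef_).ravel() ** 2
        # sort ascending w^2; ties broken by screening rank (later rank removed
        # first so the better-screened gene survives longer)
        order = sorted(
            range(len(remaining)),
            key=lambda i: (w2[i], -in_rank[remaining[i]]),
        )
        n_drop = len(remaining) if step >= len(remaining) else step
        drop = [remaining[i] for i in order[:n_drop]]
        for g, i in zip(drop, order[:n_drop]):
            elim_iter[g] = iteration
            elim_weight[g] = float(w2[i])
        eliminated.extend(drop)
        remaining = [g for g in remaining if g not in set(drop)]

    ordered = list(reversed(eliminated))
    stats = genes.stats.reindex(ordered) if genes.stats is not None else None
    return GeneRanking(
        ordered_genes=ordered,
        stats=stats,
        elimination_order=elim_iter,
        weights_at_removal=elim_weight,
    )


def truncate(ranking: GeneRanking, m: int) -> GeneRanking:
    """Keep the top ``min(m, len)`` genes in rank order."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    kept = ranking.ordered_genes[:m]
    return GeneRanking(
        ordered_genes=kept,
        stats=ranking.stats.reindex(kept) if ranking.stats is not None else None,
        elimination_order=ranking.elimination_order,
        weights_at_removal=ranking.weights_at_removal,
    )
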