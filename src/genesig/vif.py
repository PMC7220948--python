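"""Variance-inflation-factor computation and VIF-constrained selection.

The VIF of predictor j within a set is 1 / (1 - R²_j), where R²_j is the
coefficient of determination from regressing predictor j on all the others
plus an intercept.  VIF = 1 means j is orthogonal to the rest; large VIF
means near-linear dependence (multicollinearity), which inflates model
coefficient variance and hurts generalisation.

``select_by_vif`` walks the SVM-RFE ranking best-first and keeps a gene only
if, after adding it, *every* VIF in the tentative set stays below the
threshold (default 10, the conventional multicollinearity alarm level).
The full re-check is what guarantees the advertised final-set property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from genesig.datasets import ExpressionDataset
from genesig.ranking import GeneRanking

_COLLINEAR_TOL = 1e-12


def vif(matrix: np.ndarray, j: int) -> float:
    """VIF of feature ``j`` within ``matrix`` (n_samples x p_features).

    Returns ``inf`` when feature j is (numerically) an exact linear
    combination of the others.  Requires n > p so the auxiliary least-squares
    fit is determined; callers with too many candidates must reduce the set.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 features")
    if n <= p:
        raise ValueError(
            f"n_samples={n} <= n_features={p}: reduce the candidate set "
            "(the auxiliary regression is singular)"
        )
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(n), others])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError(f"feature {j} is constant; VIF undefined")
    one_minus_r2 = np.sum(resid**2) / ss_tot
    if one_minus_r2 < _COLLINEAR_TOL:
        return float("inf")
    value = 1.0 / one_minus_r2
    # VIF >= 1 by construction; snap roundoff so orthogonality is exactly 1
    return 1.0 if value < 1.0 + 1e-12 else float(value)


def _all_vifs(X: np.ndarray) -> np.ndarray:
    return np.array([vif(X, j) for j in range(X.shape[1])])


@dataclass
class VifReport:
    """Outcome of VIF-constrained forward selection."""

    selected_genes: list[str]
    vif_values: list[float]  # final VIFs within the selected set
    rejected: list[tuple[str, float]]  # (gene_id, max VIF had it been added)
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "status": "selected", "vif": v}
            for g, v in zip(self.selected_genes, self.vif_values)
        ] + [
            {"gene_id": g, "status": "rejected", "vif": v} for g, v in self.rejected
        ]
        return pd.DataFrame(rows, columns=["gene_id", "status", "vif"])


def _standardise(X: np.ndarray) -> np.ndarray:
    # VIF is scale-invariant; standardising is purely for conditioning
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - mean) / sd


def select_by_vif(
    ds: ExpressionDataset,
    ranking: GeneRanking,
    threshold: float = 10.0,
    mode: str = "forward",
) -> VifReport:
    """Select a minimal low-collinearity subset of ``ranking``.

    ``mode="forward"`` (default): greedy forward pass in rank order.  The
    first gene is always accepted; each later gene is tentatively added, all
    VIFs of the tentative set recomputed, and the gene kept only when every
    VIF is below ``threshold``.  One full pass; selection order preserves the
    ranking.

    ``mode="backward"``: start from the full ranking and repeatedly drop the
    gene with the largest VIF until all VIFs are below the threshold
    (comparison variant; may keep lower-ranked genes the forward pass drops).
    """
    if threshold <= 1:
        raise ValueError(f"threshold must be > 1, got {threshold}")
    if len(ranking) == 0:
        raise ValueError("ranking is empty")
    if mode not in ("forward", "backward"):
        raise ValueError(f"mode must be 'forward' or 'backward', got {mode!r}")

    genes = list(ranking.ordered_genes)
    idx = ds.gene_index(genes)
    X = _standardise(ds.values[idx].T)  # samples x genes
    col = {g: i for i, g in enumerate(genes)}

    if mode == "backward":
        if ds.n_samples <= len(genes):
            raise ValueError(
                f"n_samples={ds.n_samples} <= candidate genes={len(genes)}: "
                "reduce the candidate set before backward VIF elimination"
            )
        kept = list(genes)
        rejected: list[tuple[str, float]] = []
        while len(kept) >= 2:
            vifs = _all_vifs(X[:, [col[g] for g in kept]])
            worst = int(np.argmax(vifs))
            if vifs[worst] < threshold:
                break
            rejected.append((kept[worst], float(np.max(vifs))))
            kept.pop(worst)
        final = (
            _all_vifs(X[:, [col[g] for g in kept]]).tolist()
            if len(kept) >= 2
            else [1.0] * len(kept)
        )
        return VifReport(kept, final, rejected, threshold)

    selected = [genes[0]]
    rejected = []
    for g in genes[1:]:
        tentative = selected + [g]
        if ds.n_samples <= len(tentative):
            raise ValueError(
                f"n_samples={ds.n_samples} <= tentative set size {len(tentative)}: "
                "reduce the candidate set (truncate the ranking further)"
            )
        vifs = _all_vifs(X[:, [col[t] for t in tentative]])
        if np.all(vifs < threshold):
            selected = tentative
        else:
            rejected.append((g, float(np.max(vifs))))
    final = (
        _all_vifs(X[:, [col[g] for g in selected]]).tolist()
        if len(selected) >= 2
        else [1.0]
    )
    return VifReport(selected, final, rejected, threshold)
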