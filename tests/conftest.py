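import numpy as np
import pandas as pd
import pytest

from genesig.datasets import ExpressionDataset


def make_dataset(values, outcome, strata=None, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    ann = pd.DataFrame({"outcome": outcome}, index=pd.Index(sample_ids))
    if strata is not None:
        ann["strata"] = strata
    return ExpressionDataset(gene_ids, sample_ids, values, ann)


@pytest.fixture
def small_dataset():
    """3 genes x 4 samples with balanced outcomes."""
    rng = np.random.default_rng(0)
    return make_dataset(rng.normal(8, 1, size=(3, 4)), [0, 0, 1, 1])


# ---------------------------------------------------------------------------
# independent oracles (kept free of genesig internals)


def auc_pair_counting(labels, scores):
    """AUC by exhaustive positive/negative pair comparison, ties count 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def vif_normal_equations(X, j):
    """VIF via the explicit normal equations (X'X)^-1 X'y regression."""
    X = np.asarray(X, dtype=float)
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    D = np.column_stack([np.ones(len(X)), others])
    beta = np.linalg.pinv(D.T @ D) @ D.T @ y
    resid = y - D @ beta
    r2 = 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
    if 1.0 - r2 < 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def mannwhitney_exact_enumeration(x, y):
    """Two-sided exact Mann-Whitney p-value by enumerating group assignments."""
    from itertools import combinations

    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    nx = len(x)

    def u_stat(xs, ys):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys
        )

    u_obs = u_stat(x, y)
    mu = nx * len(y) / 2.0
    count = 0
    total = 0
    idx = range(len(pooled))
    for comb in combinations(idx, nx):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in set(comb)]
        u = u_stat(xs, ys)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total
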