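"""Gene-count optimisation from the cross-validated AUC-vs-count curve.

More genes always help on the training data but eventually overfit; the
operating gene count is therefore chosen from a k-fold cross-validated AUC
curve over increasing counts of top-ranked genes.  The selection rule works
on the first differences of that curve: sort the differences descending,
take the value at the top-quartile rank (default 25%) as a threshold, and
keep the largest count whose incoming difference still meets it -- the last
point at which the curve is gaining at a top-quartile rate, i.e. the elbow.

Precisely, with diffs d_1..d_m (d_i = AUC at count i+1 minus AUC at count i)
sorted descending, the threshold is the value at rank ceil(q*m); the chosen
count is the largest count whose incoming diff is >= threshold *and*
strictly positive (so a plateau of exact zeros can never be chosen past the
curve's maximum); if no diff qualifies the first count is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from genesig.datasets import ExpressionDataset
from genesig.evaluate import auc, fit, predict_proba
from genesig.ranking import GeneRanking


@dataclass
class CountCurve:
    """(gene count -> CV AUC) curve with differential values and the choice."""

    counts: list[int]
    cv_auc: list[float]
    diffs: list[float] | None = None
    chosen_count: int | None = None
    diff_threshold: float | None = None

    def __post_init__(self) -> None:
        if list(self.counts) != sorted(set(self.counts)):
            raise ValueError("counts must be strictly increasing")
        if len(self.cv_auc) != len(self.counts):
            raise ValueError("cv_auc and counts length mismatch")

    def to_frame(self) -> pd.DataFrame:
        diffs = self.diffs or list(np.diff(self.cv_auc))
        return pd.DataFrame(
            {
                "count": self.counts,
                "cv_auc": self.cv_auc,
                "diff_from_previous": [math.nan] + list(diffs),
                "chosen": [c == self.chosen_count for c in self.counts],
            }
        )


def cv_auc_curve(
    ds: ExpressionDataset,
    ranking: GeneRanking,
    counts: list[int],
    k: int = 10,
    model: str = "mlr",
    seed: int = 0,
) -> CountCurve:
    """Mean validation-fold AUC of the top-c ranked genes, per count c.

    One outcome-stratified k-fold partition (derived from ``seed``) is shared
    across all counts so the curve reflects the gene count alone.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    counts = sorted(set(int(c) for c in counts))
    if counts[0] < 1 or counts[-1] > len(ranking):
        raise ValueError(f"counts must lie in [1, {len(ranking)}], got {counts}")
    y = ds.outcome
    n1, n0 = int(np.sum(y == 1)), int(np.sum(y == 0))
    if min(n1, n0) < k:
        raise ValueError(
            f"each class needs >= k samples for stratified {k}-fold CV "
            f"(class sizes {n0} and {n1}); use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**31)
    folds = list(skf.split(np.zeros(len(y)), y))
    sample_ids = np.asarray(ds.sample_ids)
    mean_aucs = []
    for c in counts:
        genes = ranking.top(c)
        fold_aucs = []
        for tr_idx, va_idx in folds:
            if len(np.unique(y[va_idx])) < 2 or len(np.unique(y[tr_idx])) < 2:
                raise ValueError("a CV fold contains a single class; use a smaller k")
            ds_tr = ds.subset(gene_ids=genes, sample_ids=list(sample_ids[tr_idx]))
            ds_va = ds.subset(gene_ids=genes, sample_ids=list(sample_ids[va_idx]))
            m = fit(ds_tr, genes, model_kind=model, seed=seed)
            fold_aucs.append(auc(ds_va.outcome, predict_proba(m, ds_va)))
        mean_aucs.append(float(np.mean(fold_aucs)))
    return CountCurve(counts=counts, cv_auc=mean_aucs)


def choose_count(curve: CountCurve, quantile: float = 0.25) -> CountCurve:
    """Apply the top-quantile differential-AUC rule to a computed curve."""
    if not (0 < quantile <= 1):
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    if len(curve.counts) < 3:
        raise ValueError("need at least 3 counts to choose a gene count")
    diffs = np.diff(curve.cv_auc)
    m = len(diffs)
    rank = max(int(math.ceil(quantile * m)), 1)
    threshold = float(np.sort(diffs)[::-1][rank - 1])
    # tolerance absorbs float noise so nominally equal diffs tie correctly
    qualifying = [
        curve.counts[i + 1]
        for i, d in enumerate(diffs)
        if d >= threshold - 1e-12 and d > 0
    ]
    chosen = max(qualifying) if qualifying else curve.counts[0]
    return replace(
        curve,
        diffs=[float(d) for d in diffs],
        chosen_count=int(chosen),
        diff_threshold=threshold,
    )
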