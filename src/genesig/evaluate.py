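"""Prediction models, AUC, and repeated stratified-split evaluation.

The default predictor is multiple logistic regression (MLR) on the
training-standardised expression of a signature's genes; linear SVM and
random forest comparators are available.  Discrimination is measured by the
area under the ROC curve (AUC), identical to the normalised Mann-Whitney U
statistic with ties counted one half.

Evaluation follows a repeated random-split protocol: the cohort is split
into training and validation portions (default ratio 2:1) stratified by
outcome and, when present, by a clinical stratum such as ER status; the
model is refitted per split and the distribution of validation AUCs over
repeats (default 200) is summarised by median, quartiles and a percentile
95% interval.  Arms are compared by two-sided Mann-Whitney tests on their
validation-AUC lists.

External validation supports two designs:

* ``exp1`` -- signature transfer: the external cohort is itself repeatedly
  split; the model is refitted on its training portion with the fixed gene
  signature and scored on its validation portion.
* ``exp2`` -- full model transfer: both cohorts are Z-scored per gene
  (independently, whole-dataset), the model is fitted on training portions
  of the discovery cohort and scored on the *entire* external cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from genesig.datasets import ExpressionDataset

logger = logging.getLogger(__name__)

MODEL_KINDS = ("mlr", "linear_svm", "rf")


# ---------------------------------------------------------------------------
# models


@dataclass
class FittedModel:
    """A trained predictor bound to its gene list and training scaler."""

    model_kind: str
    gene_ids: list[str]
    scaler_mean: np.ndarray = field(repr=False)
    scaler_sd: np.ndarray = field(repr=False)
    estimator: object = field(repr=False)
    seed: int = 0

    @property
    def coefficients(self) -> np.ndarray | None:
        """Linear coefficients on the standardised scale (None for RF)."""
        if hasattr(self.estimator, "coef_"):
            return np.asarray(self.estimator.coef_).ravel()
        return None

    @property
    def intercept(self) -> float | None:
        if hasattr(self.estimator, "intercept_"):
            return float(np.ravel(self.estimator.intercept_)[0])
        return None


def _training_matrix(ds: ExpressionDataset, gene_ids: list[str]) -> np.ndarray:
    idx = ds.gene_index(gene_ids)
    return ds.values[idx].T  # samples x genes


def fit(
    ds_train: ExpressionDataset,
    gene_ids: list[str],
    model_kind: str = "mlr",
    seed: int = 0,
) -> FittedModel:
    """Standardise on training statistics and fit the chosen model.

    MLR is maximum-likelihood logistic regression with an intercept and no
    penalty; under complete separation (non-convergence) it falls back to a
    vanishingly small ridge penalty (lambda = 1e-6) with a logged warning.
    The linear SVM uses C = 1 and scores by signed margin; the random forest
    uses 500 trees with sqrt(p) features per node.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}, got {model_kind!r}")
    y = ds_train.outcome
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single outcome class")
    if min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("each outcome class needs >= 2 training samples")

    X = _training_matrix(ds_train, gene_ids)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [gene_ids[i] for i in np.flatnonzero(sd == 0)[:5]]
        raise ValueError(f"zero-variance genes in training data: {bad}")
    Xs = (X - mean) / sd

    if model_kind == "mlr":
        est = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(Xs, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            logger.warning(
                "MLR did not converge (likely complete separation); "
                "refitting with ridge penalty lambda=1e-6"
            )
            est = LogisticRegression(
                penalty="l2", C=1e6, solver="lbfgs", max_iter=1000
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(Xs, y)
    elif model_kind == "linear_svm":
        est = SVC(kernel="linear", C=1.0, random_state=seed)
        est.fit(Xs, y)
    else:  # rf
        est = RandomForestClassifier(
            n_estimators=500, max_features="sqrt", random_state=seed
        )
        est.fit(Xs, y)

    return FittedModel(
        model_kind=model_kind,
        gene_ids=list(gene_ids),
        scaler_mean=mean,
        scaler_sd=sd,
        estimator=est,
        seed=seed,
    )


def predict_proba(model: FittedModel, ds: ExpressionDataset) -> np.ndarray:
    """Probability of outcome 1 per sample of ``ds``.

    MLR and RF return model probabilities; the linear SVM's signed margin is
    squashed through the logistic function, preserving its ranking while
    staying in [0, 1].
    """
    X = _training_matrix(ds, model.gene_ids)
    Xs = (X - model.scaler_mean) / model.scaler_sd
    est = model.estimator
    if model.model_kind == "linear_svm":
        margin = est.decision_function(Xs)
        return 1.0 / (1.0 + np.exp(-margin))
    proba = est.predict_proba(Xs)
    return proba[:, list(est.classes_).index(1)]


# ---------------------------------------------------------------------------
# metrics


def auc(labels, scores) -> float:
    """AUC = P(score of a random positive > random negative), ties count 1/2.

    Equivalent to the Mann-Whitney statistic U / (n1 * n0).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def mannwhitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p-value).

    Exact null distribution when both groups have <= 8 observations and the
    data are tie-free; otherwise the normal approximation with tie
    correction (no continuity correction, so identical lists give p = 1
    exactly).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# splitting


@dataclass
class SplitSpec:
    """Repeated stratified train/validation split specification.

    ``ratio`` is (train_parts, valid_parts): (2, 1) trains on two thirds.
    Splits are stratified by outcome and, when the dataset carries one, the
    clinical stratum; per-repeat randomness derives deterministically from
    (master_seed, repeat_index) so every arm sees identical splits.
    """

    ratio: tuple[int, int] = (2, 1)
    n_repeats: int = 200
    use_strata: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        tr, va = self.ratio
        if tr <= 0 or va <= 0:
            raise ValueError(f"ratio parts must be positive, got {self.ratio}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @property
    def train_fraction(self) -> float:
        tr, va = self.ratio
        return tr / (tr + va)


def _strata_keys(ds: ExpressionDataset, use_strata: bool) -> np.ndarray:
    y = ds.outcome.astype(str)
    strata = ds.strata
    if use_strata and strata is not None:
        return np.char.add(np.char.add(y, "|"), strata.astype(str))
    return y


def stratified_split(
    ds: ExpressionDataset, spec: SplitSpec, repeat_index: int
) -> tuple[list[str], list[str]]:
    """One stratified split; returns (train sample ids, valid sample ids)."""
    keys = _strata_keys(ds, spec.use_strata)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.master_seed) % 2**31, int(repeat_index)])
    )
    sample_ids = np.asarray(ds.sample_ids)
    train: list[str] = []
    valid: list[str] = []
    for key in sorted(set(keys)):
        members = np.flatnonzero(keys == key)
        if members.size < 2:
            raise ValueError(
                f"stratum {key!r} has {members.size} sample(s); "
                "need >= 2 per stratum to split"
            )
        perm = rng.permutation(members)
        n_train = int(round(members.size * spec.train_fraction))
        n_train = min(max(n_train, 1), members.size - 1)
        train.extend(sample_ids[perm[:n_train]])
        valid.extend(sample_ids[perm[n_train:]])
    # restore dataset column order for reproducible downstream fits
    order = {s: i for i, s in enumerate(ds.sample_ids)}
    train.sort(key=order.__getitem__)
    valid.sort(key=order.__getitem__)
    return train, valid


# ---------------------------------------------------------------------------
# reports


@dataclass
class ArmSummary:
    name: str
    per_split_auc: list[float]
    median: float
    q1: float
    q3: float
    ci95: tuple[float, float]


@dataclass
class EvaluationReport:
    """Per-arm AUC distributions plus pairwise Mann-Whitney comparisons."""

    arms: dict[str, ArmSummary]
    comparisons: list[tuple[str, str, float, float]]  # (a, b, U, p)
    train_arms: dict[str, ArmSummary] | None = None

    def per_split_frame(self) -> pd.DataFrame:
        return pd.DataFrame({n: a.per_split_auc for n, a in self.arms.items()})

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "arm": a.name,
                "median": a.median,
                "q1": a.q1,
                "q3": a.q3,
                "ci95_lo": a.ci95[0],
                "ci95_hi": a.ci95[1],
            }
            for a in self.arms.values()
        ]
        return pd.DataFrame(rows)

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.comparisons, columns=["arm_a", "arm_b", "U", "p_value"]
        )


def _summarise(name: str, aucs: list[float]) -> ArmSummary:
    arr = np.asarray(aucs, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return ArmSummary(
        name=name,
        per_split_auc=[float(v) for v in arr],
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        ci95=(float(lo), float(hi)),
    )


def _compare_arms(per_arm: dict[str, list[float]]) -> list[tuple[str, str, float, float]]:
    names = list(per_arm)
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            u, p = mannwhitney_u(per_arm[a], per_arm[b])
            out.append((a, b, u, p))
    return out


def _repeat_seed(spec: SplitSpec, repeat_index: int) -> int:
    ss = np.random.SeedSequence([int(spec.master_seed) % 2**31, int(repeat_index), 1])
    return int(ss.generate_state(1)[0] % 2**31)


def evaluate_signatures(
    ds: ExpressionDataset,
    signatures: dict[str, list[str]],
    spec: SplitSpec,
    model_kind: str = "mlr",
) -> EvaluationReport:
    """Repeated-split evaluation of one or more signatures on one cohort.

    All arms share the same splits (paired design, variance-reducing); the
    Mann-Whitney comparison between arms treats the AUC lists as independent
    samples regardless.
    """
    valid_aucs: dict[str, list[float]] = {n: [] for n in signatures}
    train_aucs: dict[str, list[float]] = {n: [] for n in signatures}
    for r in range(spec.n_repeats):
        tr_ids, va_ids = stratified_split(ds, spec, r)
        ds_tr = ds.subset(sample_ids=tr_ids)
        ds_va = ds.subset(sample_ids=va_ids)
        seed = _repeat_seed(spec, r)
        for name, genes in signatures.items():
            model = fit(ds_tr, genes, model_kind=model_kind, seed=seed)
            train_aucs[name].append(auc(ds_tr.outcome, predict_proba(model, ds_tr)))
            valid_aucs[name].append(auc(ds_va.outcome, predict_proba(model, ds_va)))
    return EvaluationReport(
        arms={n: _summarise(n, v) for n, v in valid_aucs.items()},
        comparisons=_compare_arms(valid_aucs),
        train_arms={n: _summarise(n, v) for n, v in train_aucs.items()},
    )


def external_validate(
    selection_ds: ExpressionDataset,
    external_ds: ExpressionDataset,
    signature: list[str],
    mode: str = "exp1",
    spec: SplitSpec | None = None,
    model_kind: str = "mlr",
    zscore: bool = True,
    arm_name: str = "signature",
) -> EvaluationReport:
    """Validate a signature against an independent external cohort.

    ``mode="exp1"`` repeatedly splits the external cohort, refits the model
    on its training portion (signature fixed) and scores its validation
    portion.  ``mode="exp2"`` Z-scores both cohorts per gene (unless
    ``zscore=False``), repeatedly splits the discovery cohort, fits on its
    training portion and scores the whole external cohort.
    """
    if mode not in ("exp1", "exp2"):
        raise ValueError(f"mode must be 'exp1' or 'exp2', got {mode!r}")
    spec = spec or SplitSpec()
    missing = [g for g in signature if g not in set(external_ds.gene_ids)]
    if missing:
        raise KeyError(f"signature genes absent from external data: {missing}")

    if mode == "exp1":
        return evaluate_signatures(
            external_ds, {arm_name: list(signature)}, spec, model_kind
        )

    if zscore:
        selection_ds = selection_ds.zscore_by_gene()
        external_ds = external_ds.zscore_by_gene()
    aucs: list[float] = []
    for r in range(spec.n_repeats):
        tr_ids, _ = stratified_split(selection_ds, spec, r)
        ds_tr = selection_ds.subset(sample_ids=tr_ids)
        model = fit(ds_tr, list(signature), model_kind=model_kind,
                    seed=_repeat_seed(spec, r))
        aucs.append(auc(external_ds.outcome, predict_proba(model, external_ds)))
    return EvaluationReport(
        arms={arm_name: _summarise(arm_name, aucs)}, comparisons=[]
    )
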