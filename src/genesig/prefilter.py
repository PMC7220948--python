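"""Stage-1 gene screening: intensity filter plus two-sample t-test.

Genes whose median intensity falls below a floor (default 5 on the log2
intensity scale) are discarded as unexpressed; the remaining genes are
tested for a mean difference between the two outcome groups and kept when
the two-sided p-value is at most ``p_threshold`` (default 0.005).

The intensity rule is deliberately configurable because "median below 5 in a
group" admits two readings: ``both`` (default) eliminates a gene only when it
is low in *both* groups, preserving genes expressed in one group only -- a
differential pattern worth keeping; ``any`` eliminates a gene low in either
group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from genesig.datasets import ExpressionDataset
from genesig.ranking import GeneRanking


@dataclass
class ScreenResult:
    """Per-gene screening outcome."""

    gene_id: str
    t_stat: float
    p_value: float
    median_g0: float
    median_g1: float
    passed_intensity: bool
    passed_pvalue: bool


def screen_genes(
    ds: ExpressionDataset,
    p_threshold: float = 0.005,
    intensity_threshold: float = 5.0,
    intensity_rule: str = "both",
    t_variant: str = "student",
) -> list[ScreenResult]:
    """Screen every gene; intensity filter first, then the t-test.

    Genes failing the intensity filter are not tested (t and p are NaN,
    ``passed_pvalue`` False).  ``t_variant="student"`` uses the
    pooled-variance two-sample t-test; ``"welch"`` drops the equal-variance
    assumption.
    """
    if not (0 < p_threshold <= 1):
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    if intensity_rule not in ("both", "any"):
        raise ValueError(f"intensity_rule must be 'both' or 'any', got {intensity_rule!r}")
    if t_variant not in ("student", "welch"):
        raise ValueError(f"t_variant must be 'student' or 'welch', got {t_variant!r}")

    y = ds.outcome
    g0 = ds.values[:, y == 0]
    g1 = ds.values[:, y == 1]
    if g0.shape[1] < 2 or g1.shape[1] < 2:
        raise ValueError(
            f"both outcome groups need >= 2 samples "
            f"(got {g0.shape[1]} and {g1.shape[1]})"
        )

    med0 = np.median(g0, axis=1)
    med1 = np.median(g1, axis=1)
    if intensity_rule == "both":
        # eliminate only when low in both groups
        passed_int = ~((med0 < intensity_threshold) & (med1 < intensity_threshold))
    else:
        passed_int = (med0 >= intensity_threshold) & (med1 >= intensity_threshold)

    t = np.full(ds.n_genes, np.nan)
    p = np.full(ds.n_genes, np.nan)
    if passed_int.any():
        idx = np.flatnonzero(passed_int)
        res = stats.ttest_ind(
            g1[idx], g0[idx], axis=1, equal_var=(t_variant == "student")
        )
        t[idx] = res.statistic
        p[idx] = res.pvalue
        # identical groups give 0/0 -> NaN; no evidence of a difference
        nan_t = idx[~np.isfinite(res.statistic)]
        t[nan_t] = 0.0
        p[nan_t] = 1.0

    return [
        ScreenResult(
            gene_id=ds.gene_ids[i],
            t_stat=float(t[i]),
            p_value=float(p[i]),
            median_g0=float(med0[i]),
            median_g1=float(med1[i]),
            passed_intensity=bool(passed_int[i]),
            passed_pvalue=bool(passed_int[i] and p[i] <= p_threshold),
        )
        for i in range(ds.n_genes)
    ]


def passing_genes(results: list[ScreenResult]) -> GeneRanking:
    """Genes passing both filters, ordered by ascending p-value.

    Ties keep the input (matrix row) order, making the downstream pipeline
    deterministic.  An empty ranking is a legal result.
    """
    passed = [r for r in results if r.passed_intensity and r.passed_pvalue]
    passed.sort(key=lambda r: r.p_value)  # stable: ties keep input order
    stats_df = pd.DataFrame(
        {
            "t_stat": [r.t_stat for r in passed],
            "p_value": [r.p_value for r in passed],
        },
        index=pd.Index([r.gene_id for r in passed], name="gene_id"),
    )
    return GeneRanking(ordered_genes=[r.gene_id for r in passed], stats=stats_df)


def screen_table(results: list[ScreenResult]) -> pd.DataFrame:
    """Exportable screening table (one row per gene)."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "t_stat": [r.t_stat for r in results],
            "p_value": [r.p_value for r in results],
            "median_g0": [r.median_g0 for r in results],
            "median_g1": [r.median_g1 for r in results],
            "passed_intensity": [r.passed_intensity for r in results],
            "passed": [r.passed_intensity and r.passed_pvalue for r in results],
        }
    )
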