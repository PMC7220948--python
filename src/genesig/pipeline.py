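"""End-to-end signature selection and evaluation.

The full flow: intensity/t-test screening -> linear SVM-RFE ranking ->
truncation to a candidate count -> VIF-constrained forward selection ->
k-fold-CV gene-count optimisation -> final signature; then repeated-split
internal evaluation and, when an external cohort is supplied, the two
external-validation designs (signature transfer and full model transfer).

The programmatic entry point follows the Model/Results convention:
``SignatureModel(ds, config).fit()`` returns a :class:`SignatureResults`
carrying the signature, every intermediate table (screening statistics, RFE
ranking, VIF report, count curve, per-gene audit trail) and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from genesig.count_opt import CountCurve, choose_count, cv_auc_curve
from genesig.datasets import ExpressionDataset
from genesig.evaluate import (
    EvaluationReport,
    SplitSpec,
    evaluate_signatures,
    external_validate,
)
from genesig.prefilter import screen_genes, passing_genes, screen_table
from genesig.ranking import GeneRanking
from genesig.rfe import rfe_rank, truncate
from genesig.vif import VifReport, select_by_vif


class StageError(RuntimeError):
    """A pipeline stage produced an empty gene set."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' left no genes: {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their conventional defaults."""

    p_threshold: float = 0.005
    intensity_threshold: float = 5.0
    intensity_rule: str = "both"
    t_variant: str = "student"
    rfe_counts: tuple[int, ...] = (2, 7, 12, 102)
    rfe_step: int = 1
    svm_C: float = 1.0
    vif_threshold: float = 10.0
    vif_mode: str = "forward"
    cv_k: int = 10
    count_quantile: float = 0.25
    split_ratio: tuple[int, int] = (2, 1)
    n_repeats: int = 200
    model_kind: str = "mlr"
    master_seed: int = 0

    def split_spec(self, n_repeats: int | None = None) -> SplitSpec:
        return SplitSpec(
            ratio=tuple(self.split_ratio),
            n_repeats=self.n_repeats if n_repeats is None else n_repeats,
            master_seed=self.master_seed,
        )


@dataclass
class Signature:
    """The final gene set with per-gene selection provenance."""

    gene_ids: list[str]
    provenance: pd.DataFrame = field(repr=False)  # p_value, rfe_rank, final_vif
    chosen_count: int
    config_snapshot: PipelineConfig = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.gene_ids) != self.chosen_count:
            raise ValueError("signature length must equal chosen_count")


# stage-outcome categories; every input gene lands in exactly one
AUDIT_STAGES = (
    "filtered_low_intensity",
    "failed_t_test",
    "rfe_eliminated",
    "vif_rejected",
    "selected_beyond_count",
    "final_signature",
)


@dataclass
class SignatureResults:
    """Everything the selection run produced, for audit and plotting."""

    signature: Signature
    screen: pd.DataFrame = field(repr=False)
    ranking: GeneRanking = field(repr=False)
    truncated: GeneRanking = field(repr=False)
    vif_report: VifReport = field(repr=False)
    count_curve: CountCurve | None = field(repr=False, default=None)
    internal_report: EvaluationReport | None = None
    exp1_report: EvaluationReport | None = None
    exp2_report: EvaluationReport | None = None

    def audit_frame(self) -> pd.DataFrame:
        """One row per input gene with the stage that decided its fate."""
        stage = {}
        for _, row in self.screen.iterrows():
            g = row["gene_id"]
            if not row["passed_intensity"]:
                stage[g] = "filtered_low_intensity"
            elif not row["passed"]:
                stage[g] = "failed_t_test"
            else:
                stage[g] = "rfe_eliminated"
        for g, _ in self.vif_report.rejected:
            stage[g] = "vif_rejected"
        for g in self.vif_report.selected_genes:
            stage[g] = "selected_beyond_count"
        for g in self.signature.gene_ids:
            stage[g] = "final_signature"
        return pd.DataFrame(
            {"gene_id": list(stage), "stage": [stage[g] for g in stage]}
        )

    def summary(self) -> str:
        sig = self.signature
        cfg = sig.config_snapshot
        n_total = len(self.screen)
        n_pass = int(self.screen["passed"].sum())
        lines = [
            "Gene-signature selection summary",
            "=" * 48,
            f"genes screened:            {n_total}",
            f"passed intensity + t-test: {n_pass} "
            f"(P <= {cfg.p_threshold}, floor {cfg.intensity_threshold})",
            f"RFE candidates ranked:     {len(self.truncated)}",
            f"VIF-selected (<{cfg.vif_threshold:g}):       "
            f"{len(self.vif_report.selected_genes)}",
            f"chosen gene count:         {sig.chosen_count}",
            f"signature: {', '.join(sig.gene_ids)}",
        ]
        if self.count_curve is not None and self.count_curve.chosen_count:
            cc = self.count_curve
            idx = cc.counts.index(cc.chosen_count)
            lines.append(
                f"CV AUC at chosen count:    {cc.cv_auc[idx]:.3f} "
                f"({cfg.cv_k}-fold, diff threshold {cc.diff_threshold:.4f})"
            )
        for name, rep in (
            ("internal validation", self.internal_report),
            ("external (signature transfer)", self.exp1_report),
            ("external (model transfer)", self.exp2_report),
        ):
            if rep is not None:
                for arm in rep.arms.values():
                    lines.append(
                        f"{name} [{arm.name}]: median AUC {arm.median:.3f} "
                        f"(Q1 {arm.q1:.3f}, Q3 {arm.q3:.3f}, "
                        f"95% CI {arm.ci95[0]:.3f}-{arm.ci95[1]:.3f})"
                    )
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Persist every stage artifact as tab-delimited text."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.screen.to_csv(out / "screening.tsv", sep="\t", index=False)
        self.ranking.to_frame().to_csv(out / "rfe_ranking.tsv", sep="\t", index=False)
        self.vif_report.to_frame().to_csv(out / "vif_report.tsv", sep="\t", index=False)
        if self.count_curve is not None:
            self.count_curve.to_frame().to_csv(
                out / "count_curve.tsv", sep="\t", index=False
            )
        self.audit_frame().to_csv(out / "gene_audit.tsv", sep="\t", index=False)
        sig = pd.DataFrame({"gene_id": self.signature.gene_ids})
        sig.to_csv(out / "signature.tsv", sep="\t", index=False)
        self.signature.provenance.to_csv(out / "provenance.tsv", sep="\t")
        cfg = pd.Series(asdict(self.signature.config_snapshot), name="value")
        cfg.to_csv(out / "config_snapshot.tsv", sep="\t")
        for name, rep in (
            ("internal", self.internal_report),
            ("exp1", self.exp1_report),
            ("exp2", self.exp2_report),
        ):
            if rep is not None:
                rep.per_split_frame().to_csv(
                    out / f"{name}_per_split_auc.tsv", sep="\t", index=False
                )
                rep.summary_frame().to_csv(
                    out / f"{name}_summary.tsv", sep="\t", index=False
                )
                if rep.comparisons:
                    rep.comparisons_frame().to_csv(
                        out / f"{name}_comparisons.tsv", sep="\t", index=False
                    )


def run_selection(
    ds_train: ExpressionDataset, config: PipelineConfig | None = None
) -> SignatureResults:
    """Execute the selection flow and return the signature with its audit."""
    config = config or PipelineConfig()
    results = screen_genes(
        ds_train,
        p_threshold=config.p_threshold,
        intensity_threshold=config.intensity_threshold,
        intensity_rule=config.intensity_rule,
        t_variant=config.t_variant,
    )
    screen_df = screen_table(results)
    passing = passing_genes(results)
    if len(passing) == 0:
        raise StageError(
            "prefilter",
            f"no gene passed P <= {config.p_threshold} with intensity floor "
            f"{config.intensity_threshold}",
        )
    if len(passing) == 1:
        # RFE needs >= 2 genes; a single survivor is its own ranking
        ranking = passing
    else:
        ranking = rfe_rank(
            ds_train,
            passing,
            step=config.rfe_step,
            C=config.svm_C,
            seed=config.master_seed,
        )
    # largest configured candidate count, capped by the ranking length
    rfe_count = min(max(config.rfe_counts), len(ranking))
    # VIF's auxiliary regressions need fewer candidates than samples
    rfe_count = min(rfe_count, ds_train.n_samples - 2)
    truncated = truncate(ranking, rfe_count)

    report = select_by_vif(
        ds_train, truncated, threshold=config.vif_threshold, mode=config.vif_mode
    )
    selected = report.selected_genes
    if not selected:
        raise StageError("vif_select", f"threshold {config.vif_threshold}")

    sel_ranking = GeneRanking(
        ordered_genes=list(selected),
        stats=ranking.stats.reindex(selected) if ranking.stats is not None else None,
    )
    curve = None
    if len(selected) >= 3:
        curve = cv_auc_curve(
            ds_train,
            sel_ranking,
            counts=list(range(1, len(selected) + 1)),
            k=config.cv_k,
            model=config.model_kind,
            seed=config.master_seed,
        )
        curve = choose_count(curve, quantile=config.count_quantile)
        chosen = curve.chosen_count
    else:
        chosen = len(selected)  # too few counts for the differential rule

    final_genes = selected[:chosen]
    prov = pd.DataFrame(
        {
            "p_value": (
                ranking.stats["p_value"].reindex(final_genes)
                if ranking.stats is not None
                else np.nan
            ),
            "rfe_rank": [ranking.ordered_genes.index(g) + 1 for g in final_genes],
            "final_vif": [
                report.vif_values[report.selected_genes.index(g)] for g in final_genes
            ],
        },
        index=pd.Index(final_genes, name="gene_id"),
    )
    signature = Signature(
        gene_ids=list(final_genes),
        provenance=prov,
        chosen_count=int(chosen),
        config_snapshot=config,
    )
    return SignatureResults(
        signature=signature,
        screen=screen_df,
        ranking=ranking,
        truncated=truncated,
        vif_report=report,
        count_curve=curve,
    )


def run_full(
    ds_train: ExpressionDataset,
    ds_external: ExpressionDataset | None = None,
    config: PipelineConfig | None = None,
    comparison_signatures: dict[str, list[str]] | None = None,
) -> SignatureResults:
    """Selection plus internal and (optionally) external validation."""
    config = config or PipelineConfig()
    res = run_selection(ds_train, config)
    arms = {"signature": res.signature.gene_ids}
    if comparison_signatures:
        arms.update(comparison_signatures)
    spec = config.split_spec()
    res.internal_report = evaluate_signatures(
        ds_train, arms, spec, model_kind=config.model_kind
    )
    if ds_external is not None:
        res.exp1_report = external_validate(
            ds_train,
            ds_external,
            res.signature.gene_ids,
            mode="exp1",
            spec=spec,
            model_kind=config.model_kind,
        )
        res.exp2_report = external_validate(
            ds_train,
            ds_external,
            res.signature.gene_ids,
            mode="exp2",
            spec=spec,
            model_kind=config.model_kind,
        )
    return res


class SignatureModel:
    """Model-style front door: data plus configuration, ``fit()`` to run.

    Examples
    --------
    >>> from genesig import SignatureModel, PipelineConfig
    >>> model = SignatureModel(ds, PipelineConfig(master_seed=7))
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(
        self,
        ds: ExpressionDataset,
        config: PipelineConfig | None = None,
        external: ExpressionDataset | None = None,
    ):
        self.ds = ds
        self.config = config or PipelineConfig()
        self.external = external

    @classmethod
    def from_dataframe(
        cls,
        matrix: pd.DataFrame,
        annotations: pd.DataFrame,
        config: PipelineConfig | None = None,
    ) -> "SignatureModel":
        return cls(ExpressionDataset.from_dataframe(matrix, annotations), config)

    def fit(self, evaluate: bool = True) -> SignatureResults:
        if evaluate:
            return run_full(self.ds, self.external, self.config)
        return run_selection(self.ds, self.config)
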