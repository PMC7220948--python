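"""Ordered gene lists with per-gene selection statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class GeneRanking:
    """An ordered list of genes, best first.

    ``stats`` carries per-gene screening statistics forward (t statistic,
    p-value).  After recursive feature elimination, ``elimination_order``
    holds the 1-based iteration at which each gene was removed (0 for genes
    never eliminated) and ``weights_at_removal`` the squared-weight criterion
    |w|^2 at the time of removal.
    """

    ordered_genes: list[str]
    stats: pd.DataFrame | None = field(default=None, repr=False)
    elimination_order: dict[str, int] | None = None
    weights_at_removal: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.ordered_genes)) != len(self.ordered_genes):
            raise ValueError("ranking contains duplicate gene ids")

    def __len__(self) -> int:
        return len(self.ordered_genes)

    def __iter__(self):
        return iter(self.ordered_genes)

    def top(self, m: int) -> list[str]:
        return self.ordered_genes[: max(m, 0)]

    def to_frame(self) -> pd.DataFrame:
        """Tab-delimited-ready table: rank, gene_id, elimination data, stats."""
        df = pd.DataFrame(
            {
                "rank": range(1, len(self.ordered_genes) + 1),
                "gene_id": self.ordered_genes,
            }
        )
        if self.elimination_order is not None:
            df["elimination_iteration"] = [
                self.elimination_order.get(g, 0) for g in self.ordered_genes
            ]
        if self.weights_at_removal is not None:
            df["weight_at_removal"] = [
                self.weights_at_removal.get(g, float("nan"))
                for g in self.ordered_genes
            ]
        if self.stats is not None:
            df = df.join(self.stats.reindex(self.ordered_genes), on="gene_id")
        return df
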