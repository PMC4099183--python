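"""High-level modelling interface: build an ANNI model, fit, inspect results.

Usage mirrors the familiar model/results split::

    model = ANNI.from_dataframe(df, config=AnniConfig(rng_seed=1))
    res = model.fit(progress=True)
    print(res.summary())
    filtered = res.filter()          # Pearson |r| >= 0.7
    simplified = res.network()       # strongest edge per target gene

``ANNI`` holds the (auto-scaled) expression matrix and the algorithm
configuration; ``ANNIResults`` carries the fitted interaction-score
matrix, per-target validation errors, and helpers for filtering,
simplification and export.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import AnniConfig
from .data import ExpressionMatrix, minmax_scale
from .inference import InteractionScoreMatrix, infer_all, pearson_filter
from .network import NetworkMap, hubs, strongest_edge_per_gene

__all__ = ["ANNI", "ANNIResults"]


class ANNI:
    """Leave-one-gene-out interaction model over an expression panel.

    Parameters
    ----------
    expression : ExpressionMatrix or pandas.DataFrame
        Samples x genes table. Unscaled data are min-max scaled per gene
        on construction (the raw matrix is kept for correlation
        filtering, whose Pearson statistic is scale-invariant).
    config : AnniConfig, optional
        Algorithm parameters; defaults reproduce the published settings.
    """

    def __init__(self, expression, config: Optional[AnniConfig] = None) -> None:
        if isinstance(expression, pd.DataFrame):
            expression = ExpressionMatrix(expression.astype(float))
        if not isinstance(expression, ExpressionMatrix):
            raise TypeError("expression must be an ExpressionMatrix or DataFrame")
        self.raw = expression
        self.exog = expression if expression.scaled else minmax_scale(expression)
        self.config = config or AnniConfig()

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: Optional[AnniConfig] = None
    ) -> "ANNI":
        return cls(df, config=config)

    @property
    def gene_ids(self):
        return self.exog.gene_ids

    def fit(self, progress: bool = False) -> "ANNIResults":
        """Train all per-gene models and return the fitted results."""
        scores = infer_all(self.exog, self.config, progress=progress)
        return ANNIResults(self, scores)


class ANNIResults:
    """Fitted interaction scores plus diagnostics and derived networks."""

    def __init__(self, model: ANNI, scores: InteractionScoreMatrix) -> None:
        self.model = model
        self.config = model.config
        self.scores = scores
        self._filtered: Optional[InteractionScoreMatrix] = None

    @property
    def per_target_val_mse(self) -> pd.Series:
        """Mean validation-partition MSE of each target gene's models."""
        return self.scores.per_target_val_mse

    def filter(self, cutoff: Optional[float] = None) -> InteractionScoreMatrix:
        """Mask interactions below the expression-correlation cutoff."""
        cutoff = self.config.pearson_cutoff if cutoff is None else cutoff
        filtered = pearson_filter(self.scores, self.model.exog, cutoff)
        if cutoff == self.config.pearson_cutoff:
            self._filtered = filtered
        return filtered

    def network(
        self, simplify: bool = True, filtered: bool = False,
        cutoff: Optional[float] = None,
    ) -> NetworkMap:
        """Build the interactome map, optionally filtered and simplified."""
        source = self.filter(cutoff) if filtered else self.scores
        if simplify:
            return strongest_edge_per_gene(source)
        from .network import InteractionEdge  # local to avoid cycle at import

        edges = [
            InteractionEdge(s, t, float(source.scores.loc[s, t]))
            for s in source.gene_ids for t in source.gene_ids
            if s != t and np.isfinite(source.scores.loc[s, t])
        ]
        return NetworkMap(nodes=list(source.gene_ids), edges=edges)

    def summary(self, top: int = 10) -> str:
        """Plain-text overview: fit diagnostics and strongest associations."""
        g = len(self.scores.gene_ids)
        cfg = self.config
        long = self.scores.to_long_frame().dropna(subset=["score"])
        strongest = long.reindex(
            long.score.abs().sort_values(ascending=False).index
        ).head(top)
        mse = self.per_target_val_mse
        lines = [
            "ANNI interaction model",
            "=" * 58,
            f"Genes: {g}    defined interactions: {self.scores.n_defined}",
            f"Architecture: N-{cfg.n_hidden}-1  "
            f"(N = {g - 1} inputs per target)",
            f"MCCV: {cfg.n_reshuffles} reshuffles x {cfg.n_repeats} repeats, "
            f"split {cfg.split_ratios[0]:g}:{cfg.split_ratios[1]:g}:{cfg.split_ratios[2]:g}",
            f"Validation MSE: mean {mse.mean():.4f}  "
            f"min {mse.min():.4f}  max {mse.max():.4f}",
            "",
            f"Strongest {len(strongest)} associations (by |score|):",
            f"{'source':>12} {'target':>12} {'score':>10} sign",
        ]
        for row in strongest.itertuples():
            sign = "inhibitory" if row.score < 0 else "stimulatory"
            lines.append(f"{row.source:>12} {row.target:>12} {row.score:>10.4f} {sign}")
        return "\n".join(lines)

    def hubs(self, min_degree: int = 2):
        """Hub genes of the simplified map (degree >= min_degree)."""
        return hubs(self.network(simplify=True), min_degree=min_degree)
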