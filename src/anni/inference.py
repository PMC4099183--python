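"""Leave-one-gene-out interaction inference under Monte-Carlo cross-validation.

For every gene in the panel, that gene becomes the output node of an
N-H-1 perceptron and all remaining genes become inputs. Under each of
``n_reshuffles`` random 60:20:20 train/test/validation partitions the
model is retrained ``n_repeats`` times from fresh random weights; the
training partition updates the weights, the test partition drives early
stopping, and the validation partition is only scored. Each trained
model contributes one signed influence score per input gene — the
connection-weight product summed over hidden units — and the per-entry
mean over all ``n_reshuffles x n_repeats`` models fills one column of
the G x G interaction-score matrix.

Filtering applies the Pearson correlation of the raw expression profiles
of source and target: entries with ``|r|`` below the cutoff (0.7 by
default) are masked as least significant.
"""

from __future__ import annotations

import sys
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnniConfig
from .data import ExpressionMatrix
from .mlp import MLPModel, predict, train_mlp

__all__ = [
    "MccvPartition",
    "InteractionScoreMatrix",
    "mccv_split",
    "influence_scores",
    "infer_single_target",
    "infer_all",
    "pearson_r",
    "pearson_filter",
]


@dataclass(frozen=True)
class MccvPartition:
    """Disjoint train/test/validation sample indices for one reshuffle."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    val_idx: np.ndarray

    def __post_init__(self) -> None:
        parts = [self.train_idx, self.test_idx, self.val_idx]
        combined = np.concatenate(parts)
        if len(np.unique(combined)) != combined.size:
            raise ValueError("partitions overlap")

    @property
    def n_samples(self) -> int:
        return self.train_idx.size + self.test_idx.size + self.val_idx.size


def mccv_split(
    n_samples: int,
    ratios: Sequence[float] = (0.6, 0.2, 0.2),
    seed=0,
) -> MccvPartition:
    """Randomly partition ``n_samples`` into train/test/validation sets.

    Samples are drawn without replacement; the test and validation sets
    get ``floor(ratio * n)`` samples each and the remainder goes to
    training, so e.g. 100 samples at 0.6:0.2:0.2 split 60/20/20 and 88
    samples split 54/17/17.
    """
    if n_samples < 5:
        raise ValueError("mccv_split requires at least 5 samples")
    ratios = tuple(float(r) for r in ratios)
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    n_test = int(np.floor(ratios[1] * n_samples))
    n_val = int(np.floor(ratios[2] * n_samples))
    n_train = n_samples - n_test - n_val
    if min(n_train, n_test, n_val) < 1:
        raise ValueError("split produces an empty partition")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    return MccvPartition(
        train_idx=np.sort(perm[:n_train]),
        test_idx=np.sort(perm[n_train:n_train + n_test]),
        val_idx=np.sort(perm[n_train + n_test:]),
    )


def influence_scores(model: MLPModel) -> np.ndarray:
    """Signed influence of each input on the output, from trained weights.

    The score of input ``i`` is ``sum_h w_ih[i, h] * w_ho[h]`` (bias
    weights excluded): the product of the connection weights along every
    input -> hidden -> output path. A positive score marks a stimulatory
    influence, a negative one an inhibitory influence.
    """
    return model.w_ih[:-1] @ model.w_ho[:-1]


def _target_seed_sequence(master_seed: int, gene_key: str) -> np.random.SeedSequence:
    """Per-target seed: master seed plus a stable hash of the gene key.

    Adding or removing other genes therefore never perturbs a given
    target's partitions or weight draws.
    """
    key_hash = zlib.crc32(str(gene_key).encode("utf-8"))
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key_hash])


def infer_single_target(
    m: ExpressionMatrix,
    target: str,
    cfg: Optional[AnniConfig] = None,
) -> Tuple[pd.Series, float]:
    """Score the influence of every other gene on ``target``.

    Trains ``n_reshuffles x n_repeats`` models with ``target`` as the
    output node and all remaining genes (in lexicographic key order, so
    results are invariant to column permutation) as inputs. Returns the
    per-source mean influence scores and the mean validation MSE.
    """
    cfg = cfg or AnniConfig()
    if not m.scaled:
        raise ValueError("expression matrix must be scaled before inference")
    if target not in m.values.columns:
        raise KeyError(f"unknown target gene {target!r}")
    predictors = sorted(g for g in m.gene_ids if g != target)
    X_all = np.ascontiguousarray(m.values[predictors].to_numpy(dtype=float))
    d_all = np.ascontiguousarray(m.values[target].to_numpy(dtype=float))
    n = X_all.shape[0]

    root = _target_seed_sequence(cfg.rng_seed, target)
    reshuffle_seqs = root.spawn(cfg.n_reshuffles)

    score_sum = np.zeros(len(predictors))
    val_mse_sum = 0.0
    n_models = 0
    for seq in reshuffle_seqs:
        children = seq.spawn(cfg.n_repeats + 1)
        part = mccv_split(n, cfg.split_ratios, np.random.default_rng(children[0]))
        X_tr, d_tr = X_all[part.train_idx], d_all[part.train_idx]
        X_te, d_te = X_all[part.test_idx], d_all[part.test_idx]
        X_va, d_va = X_all[part.val_idx], d_all[part.val_idx]
        for child in children[1:]:
            model, _ = train_mlp(
                X_tr, d_tr, cfg, np.random.default_rng(child), monitor=(X_te, d_te)
            )
            score_sum += influence_scores(model)
            resid = d_va - predict(model, X_va)
            val_mse_sum += float(np.mean(resid * resid))
            n_models += 1
    scores = pd.Series(score_sum / n_models, index=predictors, name=target)
    return scores, val_mse_sum / n_models


@dataclass
class InteractionScoreMatrix:
    """G x G signed interaction scores with a masked diagonal.

    ``scores.loc[source, target]`` is the mean influence of ``source``
    on ``target`` over all trained models for that target; diagonal
    entries are NaN and never exported. After filtering,
    ``expression_r`` records the expression correlation of each pair
    and ``kept`` flags the entries that survived the cutoff (removed
    entries are masked in ``scores``).
    """

    scores: pd.DataFrame
    per_target_val_mse: pd.Series
    expression_r: Optional[pd.DataFrame] = None
    kept: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if not self.scores.index.equals(self.scores.columns):
            raise ValueError("score matrix must be square with matching labels")
        diag = np.diagonal(self.scores.to_numpy())
        if not np.isnan(diag).all():
            raise ValueError("diagonal entries must be masked (NaN)")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.scores.columns)

    @property
    def n_defined(self) -> int:
        """Number of unmasked off-diagonal entries."""
        return int(self.scores.notna().to_numpy().sum())

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format view: one row per ordered (source, target) pair."""
        rows = []
        expr = self.expression_r
        kept = self.kept
        base = self.scores if kept is None else self.scores.where(kept)
        for src in self.gene_ids:
            for tgt in self.gene_ids:
                if src == tgt:
                    continue
                rows.append({
                    "source": src,
                    "target": tgt,
                    "score": self.scores.loc[src, tgt] if kept is None
                    else base.loc[src, tgt],
                    "expression_r": np.nan if expr is None else expr.loc[src, tgt],
                    "kept": True if kept is None else bool(kept.loc[src, tgt]),
                })
        return pd.DataFrame(rows)

    def write_dense(self, path) -> None:
        """Dense TSV, sources as rows, targets as columns, masked cells empty."""
        self.scores.to_csv(path, sep="\t", index_label="source")

    def write_long(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_dense(cls, path) -> "InteractionScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        mse = pd.Series(np.nan, index=df.columns)
        return cls(df, mse)


def infer_all(
    m: ExpressionMatrix,
    cfg: Optional[AnniConfig] = None,
    progress: bool = False,
) -> InteractionScoreMatrix:
    """Run leave-one-gene-out inference for every gene in the panel.

    Fills all ``G * (G - 1)`` off-diagonal entries of the interaction-
    score matrix (9,120 for a 96-gene panel). Deterministic given the
    configuration: per-target seeds derive from ``cfg.rng_seed`` and the
    gene key only.
    """
    cfg = cfg or AnniConfig()
    genes = m.gene_ids
    if len(genes) < 3:
        raise ValueError("inference requires at least 3 genes")
    scores = pd.DataFrame(np.nan, index=genes, columns=genes, dtype=float)
    val_mse = pd.Series(np.nan, index=genes, dtype=float)
    for k, target in enumerate(genes):
        col, mse = infer_single_target(m, target, cfg)
        scores.loc[col.index, target] = col
        val_mse[target] = mse
        if progress:
            print(
                f"[anni] target {k + 1}/{len(genes)} {target}: "
                f"val MSE {mse:.5f}", file=sys.stderr, flush=True,
            )
    return InteractionScoreMatrix(scores, val_mse)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN flags a zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson_r requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def pearson_filter(
    s: InteractionScoreMatrix,
    m: ExpressionMatrix,
    cutoff: float = 0.7,
) -> InteractionScoreMatrix:
    """Mask interactions whose expression correlation falls below the cutoff.

    Entry (source, target) is retained only when the absolute Pearson
    correlation between the two genes' expression profiles reaches
    ``cutoff``; the correlation (and hence its sign) is recorded
    alongside every retained entry.
    """
    if list(s.gene_ids) != list(m.gene_ids):
        raise ValueError("score matrix and expression matrix gene ids differ")
    expr_r = m.values.corr(method="pearson")
    offdiag = ~np.eye(len(s.gene_ids), dtype=bool)
    kept = pd.DataFrame(
        (expr_r.abs().to_numpy() >= cutoff) & offdiag & s.scores.notna().to_numpy(),
        index=s.scores.index, columns=s.scores.columns,
    )
    masked = s.scores.where(kept)
    return InteractionScoreMatrix(
        masked, s.per_target_val_mse.copy(), expression_r=expr_r, kept=kept
    )
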