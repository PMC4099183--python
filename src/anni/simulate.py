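"""Synthetic expression benchmark with planted correlation structure.

The generator emulates the assessment design used to validate the
inference algorithm: 100 samples in 2 balanced classes carrying a panel
of 100 features, of which 32 form a highly correlated block (population
pairwise |r| = 0.9) and 29 of those additionally separate the classes by
a mean shift. The correlated block is driven by a single latent Gaussian
factor z per sample:

    feature_j = lambda_j * z + shift_j * c + eps_j

with loadings ``lambda_j = +/- noise_sd * sqrt(r / (1 - r))`` of
alternating sign (so the block contains both positive and negative
correlations), class code ``c = +/- 1/2`` and i.i.d. Gaussian noise. All
remaining features are pure noise. The population correlation matrix
implied by this design is known exactly and serves as the ground truth
for the three benchmark metrics: the Pearson correlation between
predicted interaction scores and true pairwise correlations, the
percentage of correctly assigned interaction signs, and the true
positive rate of the correlation filter.

An optional pre-selection helper mimics a preceding feature screen:
generate a wide panel, then keep the features with the largest absolute
two-class t statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix
from .inference import InteractionScoreMatrix

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "EvaluationReport",
    "generate_dataset",
    "preselect_features",
    "evaluate",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the synthetic generator (defaults = assessment design)."""

    n_samples: int = 100
    n_features: int = 100
    n_correlated: int = 32
    within_block_r: float = 0.9
    n_predictive: int = 29
    class_shift: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_features < 1:
            raise ValueError("n_samples and n_features must be positive")
        if not (0 <= self.n_correlated <= self.n_features):
            raise ValueError("n_correlated must not exceed n_features")
        if not (0 <= self.n_predictive <= self.n_correlated):
            raise ValueError("n_predictive must not exceed n_correlated")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ValueError("within_block_r must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset.

    Stores the generator's latent-factor loadings and class-shift
    vector, from which the exact population correlation of any feature
    pair follows in closed form: with covariance
    ``Sigma = lam lam^T + Var(c) shift shift^T + noise_sd^2 I``,
    ``r_jk = Sigma_jk / sqrt(Sigma_jj Sigma_kk)``.
    """

    feature_ids: List[str]
    lam: np.ndarray
    shift: np.ndarray
    noise_sd: float
    class_var: float
    correlated_set: Set[str]
    predictive_set: Set[str]
    class_labels: pd.Series

    def _cov(self) -> np.ndarray:
        lam = self.lam[:, None]
        shift = self.shift[:, None]
        return (
            lam @ lam.T
            + self.class_var * (shift @ shift.T)
            + self.noise_sd ** 2 * np.eye(len(self.feature_ids))
        )

    @property
    def actual_r(self) -> pd.DataFrame:
        """Full population correlation matrix as a labelled DataFrame."""
        cov = self._cov()
        sd = np.sqrt(np.diag(cov))
        r = cov / np.outer(sd, sd)
        return pd.DataFrame(r, index=self.feature_ids, columns=self.feature_ids)

    def pair_r(self, a: str, b: str) -> float:
        ia = self.feature_ids.index(a)
        ib = self.feature_ids.index(b)
        cov = (
            self.lam[ia] * self.lam[ib]
            + self.class_var * self.shift[ia] * self.shift[ib]
            + (self.noise_sd ** 2 if ia == ib else 0.0)
        )
        va = self.lam[ia] ** 2 + self.class_var * self.shift[ia] ** 2 + self.noise_sd ** 2
        vb = self.lam[ib] ** 2 + self.class_var * self.shift[ib] ** 2 + self.noise_sd ** 2
        return float(cov / np.sqrt(va * vb))


def _feature_names(n: int) -> List[str]:
    width = max(3, len(str(n)))
    return [f"F{i + 1:0{width}d}" for i in range(n)]


def generate_dataset(spec: SyntheticSpec) -> Tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one dataset and its exact ground truth.

    The first ``n_correlated`` features form the latent-factor block
    (alternating loading signs), the first ``n_predictive`` of those
    additionally carry the class-mean shift, and all remaining features
    are independent Gaussian noise. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    names = _feature_names(spec.n_features)

    lam_mag = spec.noise_sd * np.sqrt(spec.within_block_r / (1.0 - spec.within_block_r))
    signs = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(spec.n_features)])
    lam = np.zeros(spec.n_features)
    lam[: spec.n_correlated] = lam_mag * signs[: spec.n_correlated]
    shift = np.zeros(spec.n_features)
    shift[: spec.n_predictive] = spec.class_shift * signs[: spec.n_predictive]

    half = spec.n_samples // 2
    labels = np.array(["A"] * (spec.n_samples - half) + ["B"] * half)
    rng.shuffle(labels)
    c = np.where(labels == "A", 0.5, -0.5)

    z = rng.standard_normal(spec.n_samples)
    eps = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_features))
    values = z[:, None] * lam[None, :] + c[:, None] * shift[None, :] + eps

    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    df = pd.DataFrame(values, index=sample_ids, columns=names)
    label_series = pd.Series(labels, index=sample_ids, name="class")
    m = ExpressionMatrix(df, class_labels=label_series)
    truth = SyntheticTruth(
        feature_ids=names,
        lam=lam,
        shift=shift,
        noise_sd=spec.noise_sd,
        class_var=0.25,
        correlated_set=set(names[: spec.n_correlated]),
        predictive_set=set(names[: spec.n_predictive]),
        class_labels=label_series,
    )
    return m, truth


def preselect_features(
    m: ExpressionMatrix, k: int, labels: Optional[pd.Series] = None
) -> ExpressionMatrix:
    """Keep the ``k`` features best separating the two classes.

    Ranks features by the absolute two-sample t statistic between the
    two class groups and keeps the top ``k`` (original column order
    preserved; ties broken by column order). Stands in for the feature
    screen that precedes interaction inference on a wide panel.
    """
    labels = labels if labels is not None else m.class_labels
    if labels is None:
        raise ValueError("pre-selection requires class labels")
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError("pre-selection requires exactly 2 classes")
    a = m.values[labels == classes[0]].to_numpy()
    b = m.values[labels == classes[1]].to_numpy()
    t = stats.ttest_ind(a, b, axis=0).statistic
    t = np.nan_to_num(t, nan=0.0)
    order = np.argsort(-np.abs(t), kind="stable")[:k]
    keep = m.values.columns[np.sort(order)]
    return ExpressionMatrix(
        m.values[keep].copy(), class_labels=m.class_labels, scaled=m.scaled
    )


@dataclass
class EvaluationReport:
    """The three benchmark metrics for one evaluation scope."""

    pearson_coefficient: float
    sign_accuracy_pct: float
    tpr_pct: float
    n_features_evaluated: int
    n_hidden: int
    n_pairs: int = 0
    scope: str = ""

    def __post_init__(self) -> None:
        for v in (self.sign_accuracy_pct, self.tpr_pct):
            if np.isfinite(v) and not (0.0 <= v <= 100.0):
                raise ValueError("percentages must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n_hidden": self.n_hidden,
            "n_features": self.n_features_evaluated,
            "scope": self.scope,
            "pearson_coefficient": self.pearson_coefficient,
            "sign_accuracy_pct": self.sign_accuracy_pct,
            "tpr_pct": self.tpr_pct,
            "n_pairs": self.n_pairs,
        }])

    def __str__(self) -> str:
        return (
            f"Evaluation ({self.scope}, {self.n_features_evaluated} features, "
            f"{self.n_hidden} hidden nodes, {self.n_pairs} pairs)\n"
            f"  Pearson coefficient (score vs actual r): {self.pearson_coefficient:.3f}\n"
            f"  Correctly assigned signs:                {self.sign_accuracy_pct:.2f}%\n"
            f"  True positive rate:                      {self.tpr_pct:.2f}%"
        )


def evaluate(
    predicted: InteractionScoreMatrix,
    truth,
    m: ExpressionMatrix,
    scope: str = "correlated_only",
    cutoff: float = 0.7,
    n_hidden: int = 2,
) -> EvaluationReport:
    """Score predicted interactions against the planted ground truth.

    Metrics are pairwise: the two directed scores of each unordered
    feature pair are averaged. Over pairs in scope:

    - ``pearson_coefficient``: correlation between averaged predicted
      scores and true population correlations;
    - ``sign_accuracy_pct``: share of pairs with a nonzero true
      correlation whose predicted score has the matching sign;
    - ``tpr_pct``: share of truly correlated pairs (|true r| >= cutoff)
      whose edges survive the expression-correlation filter at the same
      cutoff.

    ``scope="correlated_only"`` restricts to pairs within the planted
    correlated block; ``"all_features"`` uses every pair of the panel.
    """
    if scope not in ("correlated_only", "all_features"):
        raise ValueError(f"unknown scope {scope!r}")
    actual = truth.actual_r
    features = [g for g in predicted.gene_ids if g in set(actual.columns)]
    if scope == "correlated_only":
        features = [g for g in features if g in truth.correlated_set]
    if len(features) < 2:
        raise ValueError("evaluation scope contains fewer than 2 features")

    emp_r = m.values[features].corr(method="pearson")
    pred = predicted.scores

    s_pairs, r_pairs, surv = [], [], []
    for a, b in itertools.combinations(features, 2):
        s_pairs.append(0.5 * (pred.loc[a, b] + pred.loc[b, a]))
        r_pairs.append(float(actual.loc[a, b]))
        surv.append(abs(float(emp_r.loc[a, b])) >= cutoff)
    s_arr = np.asarray(s_pairs)
    r_arr = np.asarray(r_pairs)
    surv = np.asarray(surv)

    if np.ptp(s_arr) == 0 or np.ptp(r_arr) == 0:
        coeff = float("nan")
    else:
        coeff = float(stats.pearsonr(s_arr, r_arr).statistic)

    nonzero = r_arr != 0
    if nonzero.any():
        sign_pct = 100.0 * float(
            np.mean(np.sign(s_arr[nonzero]) == np.sign(r_arr[nonzero]))
        )
    else:
        sign_pct = float("nan")

    positives = np.abs(r_arr) >= cutoff
    tpr_pct = (
        100.0 * float(np.mean(surv[positives])) if positives.any() else float("nan")
    )

    return EvaluationReport(
        pearson_coefficient=coeff,
        sign_accuracy_pct=sign_pct,
        tpr_pct=tpr_pct,
        n_features_evaluated=len(features),
        n_hidden=n_hidden,
        n_pairs=len(s_pairs),
        scope=scope,
    )


class TruthTable:
    """Minimal truth object reconstructed from a pairs TSV.

    Provides the ``actual_r`` / ``correlated_set`` interface that
    :func:`evaluate` needs, without the generator internals.
    """

    def __init__(self, actual_r: pd.DataFrame, correlated_set: Set[str],
                 predictive_set: Optional[Set[str]] = None) -> None:
        self.actual_r = actual_r
        self.correlated_set = set(correlated_set)
        self.predictive_set = set(predictive_set or ())

    def pair_r(self, a: str, b: str) -> float:
        return float(self.actual_r.loc[a, b])


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write ground truth as a long TSV of unordered feature pairs.

    Columns: feature_a, feature_b, actual_r, a_correlated, b_correlated,
    a_predictive, b_predictive.
    """
    actual = truth.actual_r
    rows = []
    for a, b in itertools.combinations(truth.feature_ids, 2):
        rows.append({
            "feature_a": a,
            "feature_b": b,
            "actual_r": float(actual.loc[a, b]),
            "a_correlated": int(a in truth.correlated_set),
            "b_correlated": int(b in truth.correlated_set),
            "a_predictive": int(a in truth.predictive_set),
            "b_predictive": int(b in truth.predictive_set),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path) -> TruthTable:
    """Rebuild a :class:`TruthTable` from :func:`write_truth` output."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_a": str, "feature_b": str})
    required = {"feature_a", "feature_b", "actual_r"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: not a truth pairs TSV")
    feats: List[str] = []
    seen = set()
    for name in pd.concat([df.feature_a, df.feature_b]):
        if name not in seen:
            seen.add(name)
            feats.append(name)
    r = pd.DataFrame(np.eye(len(feats)), index=feats, columns=feats)
    correlated: Set[str] = set()
    predictive: Set[str] = set()
    for row in df.itertuples():
        r.loc[row.feature_a, row.feature_b] = row.actual_r
        r.loc[row.feature_b, row.feature_a] = row.actual_r
        if "a_correlated" in df.columns:
            if row.a_correlated:
                correlated.add(row.feature_a)
            if row.b_correlated:
                correlated.add(row.feature_b)
        if "a_predictive" in df.columns:
            if row.a_predictive:
                predictive.add(row.feature_a)
            if row.b_predictive:
                predictive.add(row.feature_b)
    return TruthTable(r, correlated, predictive)
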