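"""Algorithm configuration for the interaction-inference pipeline.

The defaults reproduce the published parameterization of the algorithm:
an N-2-1 backpropagation perceptron (N = number of genes minus one),
sigmoid activation, 300 epochs with an MSE threshold of 0.01 and a
100-epoch MSE window, momentum 0.5, learning rate 0.1, a Pearson *r*
cutoff of 0.7, and Monte-Carlo cross-validation with 50 reshuffles of a
60:20:20 train:test:validation split repeated 10 times per gene.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

__all__ = ["AnniConfig", "read_config", "write_config"]

_SPLIT_TOL = 1e-9


@dataclass(frozen=True)
class AnniConfig:
    """All tunable parameters of the inference algorithm.

    Parameters
    ----------
    n_hidden : int
        Hidden units in each per-gene perceptron (the published
        architecture is N-2-1).
    epochs : int
        Maximum training epochs per model.
    mse_threshold : float
        Training stops early once the monitored per-epoch MSE falls
        below this value.
    mse_window : int
        Patience window: training also stops when the monitored MSE has
        failed to improve by more than ``mse_improve_tol`` over this
        many consecutive epochs.
    momentum : float
        Fraction of the previous weight update carried into the current
        one (``alpha``), in ``[0, 1)``.
    learning_rate : float
        Step size ``eta`` of the backpropagation update.
    sigmoid_slope : float
        Slope ``a`` of the logistic activation ``1 / (1 + exp(-a v))``.
    pearson_cutoff : float
        Minimum absolute expression correlation for an interaction to
        survive filtering.
    n_reshuffles : int
        Monte-Carlo cross-validation partitions drawn per target gene.
    split_ratios : tuple of float
        Train:test:validation proportions; must sum to 1.
    n_repeats : int
        Independent restarts (weight re-initializations) per partition.
    weight_init_range : tuple of float
        Uniform range for initial connection weights.
    rng_seed : int
        Master seed; all per-target randomness derives from it.
    """

    n_hidden: int = 2
    epochs: int = 300
    mse_threshold: float = 0.01
    mse_window: int = 100
    momentum: float = 0.5
    learning_rate: float = 0.1
    sigmoid_slope: float = 1.0
    pearson_cutoff: float = 0.7
    n_reshuffles: int = 50
    split_ratios: Tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_repeats: int = 10
    weight_init_range: Tuple[float, float] = (-1.0, 1.0)
    rng_seed: int = 0
    mse_improve_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be a positive integer")
        if self.epochs < 1:
            raise ValueError("epochs must be a positive integer")
        if self.mse_window < 1:
            raise ValueError("mse_window must be a positive integer")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.sigmoid_slope <= 0:
            raise ValueError("sigmoid_slope must be positive")
        if not (0.0 <= self.pearson_cutoff <= 1.0):
            raise ValueError("pearson_cutoff must lie in [0, 1]")
        if self.n_reshuffles < 1 or self.n_repeats < 1:
            raise ValueError("n_reshuffles and n_repeats must be positive")
        ratios = tuple(float(r) for r in self.split_ratios)
        if len(ratios) != 3 or any(r <= 0 for r in ratios):
            raise ValueError("split_ratios must be three positive reals")
        if abs(sum(ratios) - 1.0) > _SPLIT_TOL:
            raise ValueError("split_ratios must sum to 1")
        lo, hi = self.weight_init_range
        if not lo < hi:
            raise ValueError("weight_init_range must be an increasing pair")
        object.__setattr__(self, "split_ratios", ratios)
        object.__setattr__(self, "weight_init_range", (float(lo), float(hi)))

    def replace(self, **changes) -> "AnniConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_TUPLE_FIELDS = {"split_ratios", "weight_init_range"}
_INT_FIELDS = {
    "n_hidden", "epochs", "mse_window", "n_reshuffles", "n_repeats", "rng_seed",
}


def read_config(path: str | Path) -> AnniConfig:
    """Read a ``key = value`` (or ``key: value``) text file into an AnniConfig.

    Keys are the :class:`AnniConfig` field names; unknown keys raise.
    Tuple-valued fields take comma-separated numbers. Lines starting
    with ``#`` and blank lines are ignored.
    """
    known = {f.name for f in dataclasses.fields(AnniConfig)}
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, _, val = line.partition(sep)
                break
        else:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = key.strip(), val.strip()
        if key not in known:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        if key in _TUPLE_FIELDS:
            values[key] = tuple(float(v) for v in val.replace(",", " ").split())
        elif key in _INT_FIELDS:
            values[key] = int(val)
        else:
            values[key] = float(val)
    return AnniConfig(**values)


def write_config(cfg: AnniConfig, path: str | Path) -> None:
    """Write a config as a ``key = value`` text file readable by :func:`read_config`."""
    lines = []
    for f in dataclasses.fields(cfg):
        val = getattr(cfg, f.name)
        if f.name in _TUPLE_FIELDS:
            val = ", ".join(repr(v) for v in val)
        lines.append(f"{f.name} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")
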