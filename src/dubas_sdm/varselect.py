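"""Predictor screening: pairwise Pearson correlation and jackknife importance.

The screening mirrors the classic bioclim-variable reduction: compute the
pairwise Pearson matrix of candidate layers, measure each variable's
importance by jackknife (training AUC with the variable alone, and the AUC
loss when it is left out), then keep the more important member of every
correlated pair using the |r| < 0.7 rule — implemented as a greedy pass in
decreasing importance order with name-order tie-break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geodata import ClimateStack

logger = logging.getLogger(__name__)

DEFAULT_R_MAX = 0.7


@dataclass
class CorrelationMatrix:
    names: list[str]
    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        k = len(self.names)
        if self.R.shape != (k, k):
            raise ValueError("correlation matrix shape must match names")

    def r(self, a: str, b: str) -> float:
        return float(self.R[self.names.index(a), self.names.index(b)])


def pearson_matrix(stack: ClimateStack, sample_points=None) -> CorrelationMatrix:
    """Pairwise Pearson correlations between layers.

    Computed over all unmasked cells, or over the given (lon, lat) sample
    points. A zero-variance layer gets correlation 0 against everything
    (diagonal stays 1) with a warning.
    """
    names = stack.names
    if sample_points is None:
        mask = stack.geometry.nodata_mask
        if (~mask).sum() < 3:
            raise ValueError("need at least 3 unmasked cells")
        data = np.column_stack([stack[n].values[~mask] for n in names])
    else:
        from .geodata import extract_at

        df = extract_at(stack, sample_points)
        ok = df["in_bounds"] & ~df["masked"]
        data = df.loc[ok, names].to_numpy(float)
        if len(data) < 3:
            raise ValueError("need at least 3 valid sample points")
    sd = data.std(axis=0)
    zero = sd == 0
    if zero.any():
        logger.warning("pearson_matrix: zero-variance layers %s; correlations set to 0",
                       [n for n, z in zip(names, zero) if z])
    safe = data.copy()
    safe[:, zero] = np.random.default_rng(0).standard_normal((len(data), zero.sum()))
    R = np.corrcoef(safe, rowvar=False)
    R[zero, :] = 0.0
    R[:, zero] = 0.0
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(list(names), R)


@dataclass
class ImportanceTable:
    """Jackknife importance: training quality alone and loss when left out."""

    table: pd.DataFrame          # columns: variable, gain_alone, loss_when_left_out
    baseline: float              # quality with every variable

    def ranked(self) -> list[str]:
        """Variables in decreasing gain-alone order, name-order tie-break."""
        t = self.table.sort_values(["gain_alone", "variable"],
                                   ascending=[False, True], kind="stable")
        return list(t.variable)


Trainer = Callable[[np.ndarray, np.ndarray, np.ndarray | None], np.ndarray]


def _train_auc(trainer: Trainer, X, labels, weights) -> float:
    from .ensemble import auc

    scores = trainer(X, labels, weights)
    return auc(scores, labels)


def jackknife_importance(
    trainer: Trainer,
    X: np.ndarray,
    names: Sequence[str],
    labels: np.ndarray,
    weights: np.ndarray | None = None,
) -> ImportanceTable:
    """Per-variable jackknife importance against an all-variables baseline.

    ``trainer(X, labels, weights) -> scores`` fits a model on the given
    feature columns and returns its training scores; quality is training AUC.
    A trainer failure on any subset is recorded as a missing entry.
    """
    X = np.asarray(X, dtype=float)
    names = list(names)
    if X.shape[1] != len(names) or X.shape[1] < 1:
        raise ValueError("X columns must match names")
    baseline = _train_auc(trainer, X, labels, weights)
    rows = []
    for j, name in enumerate(names):
        try:
            alone = _train_auc(trainer, X[:, [j]], labels, weights)
        except Exception as e:                      # trainer contract: record, don't crash
            logger.warning("jackknife: trainer failed on %s alone: %s", name, e)
            alone = np.nan
        if len(names) == 1:
            loss = 0.0
        else:
            try:
                without = _train_auc(trainer, np.delete(X, j, axis=1), labels, weights)
                loss = baseline - without
            except Exception as e:
                logger.warning("jackknife: trainer failed without %s: %s", name, e)
                loss = np.nan
        rows.append({"variable": name, "gain_alone": alone, "loss_when_left_out": loss})
    return ImportanceTable(pd.DataFrame(rows), baseline)


def select_uncorrelated(
    corr: CorrelationMatrix,
    importance: ImportanceTable,
    r_max: float = DEFAULT_R_MAX,
) -> list[str]:
    """Greedy low-correlation subset in decreasing importance order.

    A variable is accepted iff |r| < r_max against every already-accepted
    variable, so of any correlated pair the more important member survives.
    The threshold applies to |r|: anti-correlated predictors are equally
    redundant.
    """
    order = [n for n in importance.ranked() if n in corr.names]
    selected: list[str] = []
    for name in order:
        if all(abs(corr.r(name, s)) < r_max for s in selected):
            selected.append(name)
    return selected
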