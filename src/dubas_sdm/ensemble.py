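"""Replicated multi-model consensus, ROC/AUC, TSS and thresholding.

Validation follows the presence–background convention: background points
stand in as pseudo-absences, AUC is the rank (Mann–Whitney) statistic with
ties counted 1/2, the operating threshold maximizes sensitivity +
specificity over the observed scores, and skill is the true skill statistic

    TSS = (ad - bc) / ((a + c)(b + d)) = sensitivity + specificity - 1

computed from the confusion counts a (true presences), b (false presences),
c (false absences), d (true absences).

The consensus raster is, by default, the cellwise median of the replicate
member predictions: the median is invariant to each member's output scale
in the low-suitability tail, where an averaged consensus inherits the rank
noise of whichever member has the largest absolute scores there. A
TSS-weighted mean (members with TSS <= 0 excluded) and a plain mean are
available by configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import FitError, GeometryError
from .geodata import ClimateStack, OccurrenceTable, RasterGrid
from .sdm import (
    FeatureTable,
    SdmFit,
    build_feature_table,
    fit_brt,
    fit_glm_stepwise,
    fit_maxent,
    kernel_weight_surface,
    predict_sdm,
    record_density,
    record_weights,
    sample_background,
)

logger = logging.getLogger(__name__)

DEFAULT_MODELS = ("maxent", "glm", "brt")
DEFAULT_REPLICATES = 30


@dataclass(frozen=True)
class ConfusionTable:
    """Presence/absence confusion counts."""

    a: int   # correctly predicted presence cells
    b: int   # absences incorrectly predicted as presence
    c: int   # presences incorrectly predicted as absence
    d: int   # correctly predicted absence cells

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def sensitivity(self) -> float:
        if self.a + self.c == 0:
            raise ValueError("no presence cells; sensitivity undefined")
        return self.a / (self.a + self.c)

    @property
    def specificity(self) -> float:
        if self.b + self.d == 0:
            raise ValueError("no absence cells; specificity undefined")
        return self.d / (self.b + self.d)


def tss(ct: ConfusionTable) -> float:
    """True skill statistic (ad - bc) / ((a + c)(b + d))."""
    if ct.a + ct.c == 0 or ct.b + ct.d == 0:
        raise ValueError("TSS undefined with an empty presence or absence class")
    return (ct.a * ct.d - ct.b * ct.c) / ((ct.a + ct.c) * (ct.b + ct.d))


def auc(scores, labels) -> float:
    """Rank-statistic AUC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class EvalReport:
    auc: float
    tss: float
    threshold: float
    sensitivity: float
    specificity: float
    confusion: ConfusionTable

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "tss": self.tss, "threshold": self.threshold,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "confusion": {"a": self.confusion.a, "b": self.confusion.b,
                          "c": self.confusion.c, "d": self.confusion.d},
        }


def confusion_at(scores, labels, threshold: float) -> ConfusionTable:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    return ConfusionTable(
        a=int((pred & (labels == 1)).sum()),
        b=int((pred & (labels == 0)).sum()),
        c=int((~pred & (labels == 1)).sum()),
        d=int((~pred & (labels == 0)).sum()),
    )


def max_ss_threshold(scores, labels) -> tuple[float, EvalReport]:
    """Threshold maximizing sensitivity + specificity over observed scores.

    A cell scoring at or above the threshold is classified presence; ties in
    the objective break toward the lowest threshold (maximizing sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    cands = np.unique(scores)
    sens = (len(pos) - np.searchsorted(pos, cands, side="left")) / len(pos)
    spec = np.searchsorted(neg, cands, side="left") / len(neg)
    obj = sens + spec
    best = int(np.argmax(obj))          # argmax returns the first (lowest) maximizer
    thr = float(cands[best])
    ct = confusion_at(scores, labels, thr)
    report = EvalReport(
        auc=auc(scores, labels), tss=tss(ct), threshold=thr,
        sensitivity=ct.sensitivity, specificity=ct.specificity, confusion=ct,
    )
    return thr, report


# ---------------------------------------------------------------------------
# Replicated ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleMember:
    kind: str
    replicate: int
    fit: SdmFit
    prediction: RasterGrid
    report: EvalReport


@dataclass
class EnsembleResult:
    members: list[EnsembleMember]
    consensus: RasterGrid
    weight_surface: RasterGrid
    consensus_rule: str = "median"
    consensus_report: EvalReport | None = None

    def member_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"kind": m.kind, "replicate": m.replicate,
             "auc": m.report.auc, "tss": m.report.tss}
            for m in self.members
        ])


def _member_seed(seed: int, replicate: int, model_index: int) -> int:
    """Documented counter scheme: any single replicate is reproducible alone."""
    return int(np.random.SeedSequence([seed, replicate, model_index]).generate_state(1)[0] % 2**31)


def _grid_scores_at(grid: RasterGrid, points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    row, col, inside = grid.index_of(pts[:, 0], pts[:, 1])
    out = np.full(len(pts), np.nan)
    out[inside] = grid.values[row[inside], col[inside]]
    return out


def run_ensemble(
    stack: ClimateStack,
    train: OccurrenceTable,
    models: Sequence[str] = DEFAULT_MODELS,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    n_background: int = 1000,
    quadratic: bool = True,
    kernel_sd: float | None = None,
    consensus_rule: str = "median",
    model_params: dict | None = None,
) -> EnsembleResult:
    """Replicated multi-model consensus fit.

    Per replicate the background is resampled (from the record kernel
    density, bias matching) with a sub-seed derived from the master seed,
    each model is refit, and its prediction raster is scored on the training
    presences vs that replicate's background. The consensus is the cellwise
    member median by default; ``consensus_rule`` also accepts
    ``"tss_weighted"`` (mean weighted by max(TSS, 0), members with TSS <= 0
    excluded) and ``"mean"``. Fully deterministic given ``seed``.
    """
    if len(train) < 20:
        raise FitError("ensemble calibration needs at least 20 presence records")
    unknown = [m for m in models if m not in DEFAULT_MODELS]
    if unknown:
        raise ValueError(f"unknown models: {unknown}")
    model_params = model_params or {}
    geom = stack.geometry
    density = record_density(train, geom, kernel_sd)
    wsurf = kernel_weight_surface(train, geom, kernel_sd)
    pweights = record_weights(wsurf, train)
    pres_pts = np.column_stack([train.lon, train.lat])

    members: list[EnsembleMember] = []
    fitters = {"maxent": fit_maxent, "glm": fit_glm_stepwise, "brt": fit_brt}
    for r in range(replicates):
        bg_rng = np.random.default_rng(np.random.SeedSequence([seed, r]))
        bg_pts = sample_background(density, n_background, bg_rng)
        features = build_feature_table(stack, pres_pts, bg_pts, pweights, quadratic)
        for mi, kind in enumerate(models):
            kwargs = dict(model_params.get(kind, {}))
            if kind == "brt":
                kwargs.setdefault("seed", _member_seed(seed, r, mi))
            try:
                fit = fitters[kind](features, **kwargs)
                grid = predict_sdm(fit, stack)
            except Exception as e:
                logger.warning("ensemble member %s/rep%d failed: %s", kind, r, e)
                continue
            scores = np.concatenate([
                _grid_scores_at(grid, pres_pts), _grid_scores_at(grid, bg_pts),
            ])
            labels = np.concatenate([np.ones(len(pres_pts)), np.zeros(len(bg_pts))])
            ok = np.isfinite(scores)
            _, report = max_ss_threshold(scores[ok], labels[ok])
            members.append(EnsembleMember(kind, r, fit, grid, report))
    if not members:
        raise FitError("every ensemble member failed")

    consensus = combine_members(
        np.stack([m.prediction.values for m in members]),
        [m.report.tss for m in members], consensus_rule)
    mask = geom.nodata_mask.copy()
    consensus[mask] = np.nan
    return EnsembleResult(members, geom.copy_with(consensus, mask), wsurf, consensus_rule)


def combine_members(values: np.ndarray, tss_values: Sequence[float], rule: str) -> np.ndarray:
    """Combine member prediction arrays (stacked on axis 0) into a consensus."""
    if rule == "median":
        return np.median(values, axis=0)
    if rule == "mean":
        weights = np.ones(len(values))
    elif rule == "tss_weighted":
        weights = np.array([max(t, 0.0) for t in tss_values])
        if weights.sum() <= 0:
            logger.warning("all members have TSS <= 0; falling back to unweighted mean")
            weights = np.ones(len(values))
    else:
        raise ValueError(f"unknown consensus rule {rule!r}")
    return np.tensordot(weights / weights.sum(), values, axes=1)


def evaluate_on_split(
    prediction: RasterGrid,
    test: OccurrenceTable,
    background_points,
) -> EvalReport:
    """AUC, max-SS threshold and TSS of a prediction raster on held-out data.

    Scores are read off the raster at the test presences and at the supplied
    background (pseudo-absence) points.
    """
    if len(test) == 0:
        raise ValueError("test set is empty")
    pres = _grid_scores_at(prediction, np.column_stack([test.lon, test.lat]))
    bg = _grid_scores_at(prediction, background_points)
    if not np.isfinite(pres).any():
        raise ValueError("all test presences fall on masked/out-of-bounds cells")
    scores = np.concatenate([pres, bg])
    labels = np.concatenate([np.ones(len(pres)), np.zeros(len(bg))])
    ok = np.isfinite(scores)
    _, report = max_ss_threshold(scores[ok], labels[ok])
    return report


# ---------------------------------------------------------------------------
# Suitability classification
# ---------------------------------------------------------------------------

CLASS_UNSUITABLE, CLASS_MARGINAL, CLASS_HIGH = 0, 1, 2
CLASS_LABELS = {0: "unsuitable", 1: "marginal", 2: "high"}


def classify_suitability(
    consensus: RasterGrid, threshold: float, marginal_fraction: float = 0.5
) -> tuple[RasterGrid, pd.DataFrame]:
    """Three-class suitability map and its area table.

    ``high`` at or above the threshold; ``marginal`` in
    ``[marginal_fraction * threshold, threshold)``; ``unsuitable`` below.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if not 0 < marginal_fraction < 1:
        raise ValueError("marginal_fraction must be in (0, 1)")
    v = consensus.values
    codes = np.full(consensus.shape, np.nan)
    unmasked = ~consensus.nodata_mask
    codes[unmasked] = CLASS_UNSUITABLE
    codes[unmasked & (v >= marginal_fraction * threshold)] = CLASS_MARGINAL
    codes[unmasked & (v >= threshold)] = CLASS_HIGH
    total = int(unmasked.sum())
    rows = []
    for code, label in CLASS_LABELS.items():
        n = int(np.nansum(codes == code))
        rows.append({"class": label, "cells": n,
                     "percent": 100.0 * n / total if total else np.nan})
    return consensus.copy_with(codes), pd.DataFrame(rows)
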