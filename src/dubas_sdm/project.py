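"""Scenario projection: re-predicting fitted members on future climate.

A scenario is a named, co-registered climate stack (one GCM x RCP x horizon
combination). Fitted ensemble members are applied to it without refitting
and without clamping; the consensus and suitability classes are formed
exactly as for the current climate, and changes are summarized by a 3x3
class transition matrix whose marginals reconcile with the class areas.

Synthetic future stacks are produced by additive per-layer offsets (e.g.
warming bands of +1.4 to +2.6 degrees C), so scenario ordering effects are
testable without any GCM download.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .ensemble import CLASS_LABELS, EnsembleResult, classify_suitability
from .errors import GeometryError
from .geodata import ClimateStack, RasterGrid
from .sdm import predict_sdm

VALID_RCPS = (2.6, 4.5, 6.0, 8.5)
VALID_HORIZONS = (2050, 2070)


@dataclass
class Scenario:
    name: str
    stack: ClimateStack
    horizon: int
    rcp: float

    def __post_init__(self) -> None:
        if self.horizon not in VALID_HORIZONS:
            raise ValueError(f"horizon must be one of {VALID_HORIZONS}")
        if self.rcp not in VALID_RCPS:
            raise ValueError(f"rcp must be one of {VALID_RCPS}")


def perturb_stack(stack: ClimateStack, offsets: Mapping[str, float]) -> ClimateStack:
    """Additive per-layer perturbation (layers absent from the map unchanged)."""
    unknown = [n for n in offsets if n not in stack.names]
    if unknown:
        raise KeyError(f"offsets name layers not in stack: {unknown}")
    layers = {}
    for name, grid in stack.layers.items():
        delta = offsets.get(name, 0.0)
        layers[name] = grid.copy_with(grid.values + delta)
    return ClimateStack(layers)


def project_scenario(
    ensemble: EnsembleResult,
    scenario: Scenario,
    threshold: float,
    marginal_fraction: float = 0.5,
) -> tuple[RasterGrid, RasterGrid, pd.DataFrame]:
    """Consensus, class raster and area table for one future scenario.

    Members are re-predicted on the scenario stack (no refitting, no
    clamping) and combined with the same TSS weights as the current-climate
    consensus.
    """
    if not ensemble.consensus.same_geometry(scenario.stack.geometry):
        raise GeometryError(f"scenario {scenario.name!r} geometry differs from the fitted stack")
    preds = []
    weights = []
    for m in ensemble.members:
        missing = [n for n in m.fit.layer_names if n not in scenario.stack.names]
        if missing:
            raise KeyError(
                f"scenario {scenario.name!r} is missing layers {missing} "
                f"required by member {m.kind}/rep{m.replicate}"
            )
        preds.append(predict_sdm(m.fit, scenario.stack).values)
        weights.append(m.report.tss)
    from .ensemble import combine_members

    consensus = combine_members(np.stack(preds), weights, ensemble.consensus_rule)
    geom = scenario.stack.geometry
    consensus[geom.nodata_mask] = np.nan
    cgrid = geom.copy_with(consensus)
    classes, areas = classify_suitability(cgrid, threshold, marginal_fraction)
    areas.insert(0, "scenario", scenario.name)
    return cgrid, classes, areas


def change_summary(
    current_classes: RasterGrid, future_classes: RasterGrid
) -> tuple[pd.DataFrame, RasterGrid, RasterGrid]:
    """3x3 class transition matrix plus gained/lost maps for the high class.

    Returns (transition, gained, lost); transition rows are current classes,
    columns future classes, so row sums equal current class areas and column
    sums future class areas.
    """
    if not current_classes.same_geometry(future_classes):
        raise GeometryError("class rasters have different geometry")
    cur = current_classes.values
    fut = future_classes.values
    valid = ~current_classes.nodata_mask & ~future_classes.nodata_mask
    k = len(CLASS_LABELS)
    counts = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            counts[i, j] = int(np.sum(valid & (cur == i) & (fut == j)))
    labels = [CLASS_LABELS[i] for i in range(k)]
    transition = pd.DataFrame(counts, index=labels, columns=labels)
    high = max(CLASS_LABELS)
    gained = np.where(valid, ((cur != high) & (fut == high)).astype(float), np.nan)
    lost = np.where(valid, ((cur == high) & (fut != high)).astype(float), np.nan)
    mask = ~valid
    return transition, current_classes.copy_with(gained, mask), current_classes.copy_with(lost, mask)
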