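"""Agreement between inferential significance maps and predictive weight maps.

Per metric the FWE-corrected p-value vector (the "normalized significance
map", already in [0, 1]) is compared with the [0, 1]-normalized SVM weight map
over the same skeleton voxels via

* the sample Pearson correlation (two-sided p from the t transform) — where a
  genuine group effect exists, informative voxels have low p and high weight,
  so r is expected to be negative; and
* the first-order (1-D) Wasserstein distance between the two value
  distributions, computed as the mean absolute difference of matched order
  statistics (the samples have equal size by construction).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ConcordanceRecord:
    metric: str
    pearson_r: float
    pearson_p: float
    wasserstein: float
    n_voxels: int


def wasserstein_1d(a: np.ndarray, b: np.ndarray) -> float:
    """First-order Wasserstein distance between equal-size empirical samples.

    Equals the mean absolute difference of matched order statistics, i.e. the
    integral of the absolute quantile-function difference.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("samples must have equal size")
    return float(np.mean(np.abs(a - b)))


def concordance(
    weight_map: np.ndarray, p_map: np.ndarray, metric: str = ""
) -> ConcordanceRecord:
    """Pearson r/p and Wasserstein distance between weight and p maps."""
    w = np.asarray(weight_map, dtype=float)
    p = np.asarray(p_map, dtype=float)
    if w.shape != p.shape or w.ndim != 1:
        raise ValueError("weight and p maps must be equal-length vectors")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p map values must lie in (0, 1]")
    if np.ptp(w) == 0 or np.ptp(p) == 0:
        raise ValueError(
            f"zero variance in {'weight' if np.ptp(w) == 0 else 'p'} map; "
            "correlation undefined"
        )
    r, pval = stats.pearsonr(w, p)
    return ConcordanceRecord(
        metric=metric,
        pearson_r=float(r),
        pearson_p=float(pval),
        wasserstein=wasserstein_1d(w, p),
        n_voxels=int(w.size),
    )


def concordance_table(
    weight_maps: Mapping[str, np.ndarray],
    p_maps: Mapping[str, np.ndarray],
) -> tuple[list[ConcordanceRecord], pd.DataFrame]:
    """One record per metric with both maps; missing metrics are skipped."""
    records: list[ConcordanceRecord] = []
    for metric in weight_maps:
        if metric not in p_maps:
            logger.warning("metric %s missing a p map; skipped", metric)
            continue
        records.append(concordance(weight_maps[metric], p_maps[metric], metric))
    for metric in p_maps:
        if metric not in weight_maps:
            logger.warning("metric %s missing a weight map; skipped", metric)
    frame = pd.DataFrame(
        {
            "metric": [r.metric for r in records],
            "pearson_r": [r.pearson_r for r in records],
            "p_value": [r.pearson_p for r in records],
            "wasserstein": [r.wasserstein for r in records],
            "n_voxels": [r.n_voxels for r in records],
        }
    )
    return records, frame
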