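"""Scoring rules for the 17-item PTSD Checklist, civilian version (PCL-C).

Each item is rated 1-5 over the past month, so totals span 17-85.
Severity bands: 17-37 no obvious symptoms, 38-49 some symptoms, >=50
strictly screen-positive.  An item is symptom-positive at a score of 3
or more; the three DSM-IV symptom clusters are positive at >=1
re-experiencing, >=3 avoidance/numbness, and >=2 hyperarousal positive
items respectively.  The screening cutoff used throughout the pipeline
is a total of 38 (the lowered reference value); the strict >=50 standard
is available by passing ``threshold=50``.

The checklist itself never states the item-to-cluster assignment; the
default here is the standard PCL-C structure (items 1-5 re-experiencing,
6-12 avoidance/numbness, 13-17 hyperarousal), which is consistent with
the 1/3/2 cluster minima, and it can be overridden via
:class:`ScaleDefinition`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScaleDefinition",
    "ScoredRecord",
    "total_score",
    "severity_band",
    "screen_positive",
    "cluster_positivity",
    "score_record",
    "score_frame",
]

N_ITEMS = 17
MIN_TOTAL, MAX_TOTAL = 17, 85

CLUSTER_NAMES = ("reexperiencing", "avoidance_numbness", "hyperarousal")


def _default_clusters() -> dict[str, tuple[int, ...]]:
    return {
        "reexperiencing": tuple(range(1, 6)),
        "avoidance_numbness": tuple(range(6, 13)),
        "hyperarousal": tuple(range(13, 18)),
    }


def _default_minima() -> dict[str, int]:
    return {"reexperiencing": 1, "avoidance_numbness": 3, "hyperarousal": 2}


def _default_bands() -> dict[str, tuple[int, int]]:
    return {"none": (17, 37), "some": (38, 49), "strict_positive": (50, 85)}


@dataclass(frozen=True)
class ScaleDefinition:
    """Item clusters, positivity rules, and severity bands of the scale.

    ``clusters`` maps cluster name to 1-based item indices and must
    partition 1..17; ``bands`` must be disjoint and cover 17..85.
    """

    clusters: dict[str, tuple[int, ...]] = field(default_factory=_default_clusters)
    cluster_positive_min: dict[str, int] = field(default_factory=_default_minima)
    item_positive_threshold: int = 3
    bands: dict[str, tuple[int, int]] = field(default_factory=_default_bands)
    screen_threshold: int = 38

    def __post_init__(self) -> None:
        indices = sorted(i for idx in self.clusters.values() for i in idx)
        if indices != list(range(1, N_ITEMS + 1)):
            raise ValueError("cluster index sets must partition 1..17")
        if set(self.cluster_positive_min) != set(self.clusters):
            raise ValueError("cluster_positive_min keys must match clusters")
        covered = sorted(t for lo, hi in self.bands.values() for t in range(lo, hi + 1))
        if covered != list(range(MIN_TOTAL, MAX_TOTAL + 1)):
            raise ValueError("bands must be disjoint and cover 17..85")


DEFAULT_SCALE = ScaleDefinition()


@dataclass(frozen=True)
class ScoredRecord:
    respondent_id: int
    total: int
    band: str
    item_positive: tuple[bool, ...]
    cluster_positive: tuple[bool, bool, bool]
    screen_positive: bool


def _validate_items(items: Sequence[int]) -> np.ndarray:
    arr = np.asarray(items)
    if arr.shape != (N_ITEMS,):
        raise ValueError(f"expected exactly {N_ITEMS} items, got {arr.shape}")
    for idx, v in enumerate(arr, start=1):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"item {idx} is missing")
        if int(v) != v or not 1 <= int(v) <= 5:
            raise ValueError(f"item {idx} out of range [1, 5]: {v!r}")
    return arr.astype(int)


def total_score(items: Sequence[int]) -> int:
    """Sum of the 17 item scores (range 17-85)."""
    return int(_validate_items(items).sum())


def severity_band(total: int, scale: ScaleDefinition = DEFAULT_SCALE) -> str:
    """Map a total score to its severity band name."""
    if not MIN_TOTAL <= total <= MAX_TOTAL:
        raise ValueError(f"total must be in [{MIN_TOTAL}, {MAX_TOTAL}], got {total}")
    for name, (lo, hi) in scale.bands.items():
        if lo <= total <= hi:
            return name
    raise AssertionError("bands cover 17..85 by construction")


def screen_positive(total: int, threshold: int = 38) -> bool:
    """True iff the total reaches the screening cutoff (default 38)."""
    if not MIN_TOTAL <= total <= MAX_TOTAL:
        raise ValueError(f"total must be in [{MIN_TOTAL}, {MAX_TOTAL}], got {total}")
    return total >= threshold


def cluster_positivity(
    items: Sequence[int], scale: ScaleDefinition = DEFAULT_SCALE
) -> tuple[bool, ...]:
    """Per-cluster positivity: count items scored at or above the item
    threshold and compare with that cluster's minimum count."""
    arr = _validate_items(items)
    out = []
    for name in scale.clusters:
        idx = np.asarray(scale.clusters[name]) - 1
        n_pos = int((arr[idx] >= scale.item_positive_threshold).sum())
        out.append(n_pos >= scale.cluster_positive_min[name])
    return tuple(out)


def score_record(
    respondent_id: int,
    items: Sequence[int],
    scale: ScaleDefinition = DEFAULT_SCALE,
    threshold: int | None = None,
) -> ScoredRecord:
    arr = _validate_items(items)
    total = int(arr.sum())
    thr = scale.screen_threshold if threshold is None else threshold
    return ScoredRecord(
        respondent_id=respondent_id,
        total=total,
        band=severity_band(total, scale),
        item_positive=tuple(bool(v) for v in arr >= scale.item_positive_threshold),
        cluster_positive=cluster_positivity(arr, scale),
        screen_positive=screen_positive(total, thr),
    )


def score_frame(
    cohort: pd.DataFrame,
    scale: ScaleDefinition = DEFAULT_SCALE,
    threshold: int | None = None,
) -> pd.DataFrame:
    """Score every complete record of a cohort frame.

    Returns the input restricted to rows with all 17 items present,
    with total, band, screen_positive and per-cluster columns appended.
    """
    item_cols = [f"item_{k:02d}" for k in range(1, N_ITEMS + 1)]
    complete = cohort.dropna(subset=item_cols)
    scored = complete.copy()
    totals, bands, screens, clusters = [], [], [], []
    for row in complete[item_cols].itertuples(index=False):
        rec_items = [int(v) for v in row]
        total = total_score(rec_items)
        totals.append(total)
        bands.append(severity_band(total, scale))
        thr = scale.screen_threshold if threshold is None else threshold
        screens.append(screen_positive(total, thr))
        clusters.append(cluster_positivity(rec_items, scale))
    scored["total"] = totals
    scored["band"] = bands
    scored["screen_positive"] = screens
    cl = np.asarray(clusters, dtype=bool).reshape(len(scored), 3)
    scored["cluster_re"] = cl[:, 0]
    scored["cluster_avoid"] = cl[:, 1]
    scored["cluster_hyper"] = cl[:, 2]
    return scored
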