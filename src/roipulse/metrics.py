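"""Signal-quality metrics, the composite rBS score, and region ranking.

MAE/RMSE/PCC compare an estimated series against ground truth.  Per group of
records sharing (dataset, method, video), each region's rBS is

    rBS = (ln(max(MAE) - MAE + e) + ln(max(RMSE) - RMSE + e)) * |PCC|

with maxima taken over the group and natural logarithms, so the region
attaining both maxima scores exactly 2|PCC|.  Regions are ranked by the
median rBS over all groups, descending, ties sharing the best rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from roipulse.anatomy import _round2

__all__ = [
    "MetricRecord",
    "mae",
    "rmse",
    "pcc",
    "rbs_scores",
    "build_rbs_table",
    "median_rank",
    "top_bottom",
    "thickness_pixel_correlation",
    "load_reference_scores",
    "MetricsError",
    "UndefinedCorrelationError",
]

RegionKey = Union[int, str]

GROUP_COLS = ("dataset", "method", "video")


class MetricsError(ValueError):
    pass


class UndefinedCorrelationError(MetricsError):
    """A zero-variance series has no Pearson correlation."""


class InsufficientDataError(MetricsError):
    pass


def _pair(reference, estimate) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(reference, dtype=float).ravel()
    e = np.asarray(estimate, dtype=float).ravel()
    if r.size != e.size:
        raise MetricsError(f"length mismatch: {r.size} vs {e.size}")
    if r.size < 2:
        raise MetricsError("need at least 2 samples")
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(e))):
        raise MetricsError("series must be finite")
    return r, e


def mae(reference, estimate) -> float:
    """Mean absolute error."""
    r, e = _pair(reference, estimate)
    return float(np.mean(np.abs(e - r)))


def rmse(reference, estimate) -> float:
    """Root mean square error."""
    r, e = _pair(reference, estimate)
    return float(np.sqrt(np.mean((e - r) ** 2)))


def pcc(reference, estimate) -> float:
    """Pearson correlation coefficient, clipped to [-1, 1]."""
    r, e = _pair(reference, estimate)
    rc, ec = r - r.mean(), e - e.mean()
    denom = np.sqrt((rc ** 2).sum() * (ec ** 2).sum())
    if denom <= 0:
        raise UndefinedCorrelationError("zero-variance series")
    return float(np.clip((rc * ec).sum() / denom, -1.0, 1.0))


@dataclass(frozen=True)
class MetricRecord:
    """Per-(dataset, method, video, region) accuracy record; pcc None if undefined."""

    dataset: str
    method: str
    video: str
    region: RegionKey
    mae: float
    rmse: float
    pcc: Optional[float]

    def __post_init__(self):
        if self.mae < 0 or self.rmse < 0:
            raise MetricsError("mae/rmse must be non-negative")
        if self.pcc is not None and abs(self.pcc) > 1 + 1e-12:
            raise MetricsError("|pcc| must be <= 1")


def rbs_scores(group: Sequence[MetricRecord]) -> tuple[dict[RegionKey, float], list[RegionKey]]:
    """rBS per region for one group of records sharing (dataset, method, video).

    Returns ``(scores, excluded)`` where ``excluded`` lists regions dropped
    for having an undefined PCC.
    """
    if not group:
        raise MetricsError("empty metric group")
    keys = {(r.dataset, r.method, r.video) for r in group}
    if len(keys) != 1:
        raise MetricsError(f"records span multiple groups: {sorted(keys)}")
    usable = [r for r in group if r.pcc is not None]
    excluded = [r.region for r in group if r.pcc is None]
    if not usable:
        return {}, excluded
    max_mae = max(r.mae for r in usable)
    max_rmse = max(r.rmse for r in usable)
    scores = {}
    for r in usable:
        scores[r.region] = (
            math.log(max_mae - r.mae + math.e) + math.log(max_rmse - r.rmse + math.e)
        ) * abs(r.pcc)
    return scores, excluded


def build_rbs_table(records: Sequence[MetricRecord]) -> pd.DataFrame:
    """Tidy rBS table: one row per (dataset, method, video, region)."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        raise MetricsError("no records")
    rows = []
    for (ds, m, v), grp in df.groupby(list(GROUP_COLS), sort=True):
        recs = []
        for row in grp.to_dict("records"):
            if row["pcc"] is not None and pd.isna(row["pcc"]):
                row["pcc"] = None
            recs.append(MetricRecord(**row))
        scores, _ = rbs_scores(recs)
        for region, val in scores.items():
            rows.append({"dataset": ds, "method": m, "video": v,
                         "region": region, "rbs": val})
    return pd.DataFrame(rows)


def median_rank(rbs_table: pd.DataFrame) -> pd.DataFrame:
    """Median rBS per region with descending ranks; ties share the best rank."""
    if rbs_table.empty:
        raise MetricsError("empty rBS table")
    med = rbs_table.groupby("region")["rbs"].median()
    ranks = {reg: 1 + int((med > med[reg]).sum()) for reg in med.index}
    out = pd.DataFrame({
        "region": med.index,
        "median_rbs": med.values,
        "rank": [ranks[r] for r in med.index],
    }).sort_values(["rank", "region"], kind="stable").reset_index(drop=True)
    return out


def top_bottom(ranked: pd.DataFrame, k: int) -> tuple[list[RegionKey], list[RegionKey]]:
    """The k best and k worst regions by rank.

    Ties at the selection boundary are broken by region id: ascending for the
    top list, descending for the bottom list (a documented convention).
    """
    if k <= 0:
        raise MetricsError("k must be positive")
    if k > len(ranked):
        raise MetricsError(f"k={k} exceeds {len(ranked)} ranked regions")
    top = ranked.sort_values(["median_rbs", "region"], ascending=[False, True],
                             kind="stable")["region"].head(k).tolist()
    bot = ranked.sort_values(["median_rbs", "region"], ascending=[True, False],
                             kind="stable")["region"].head(k).tolist()
    return top, bot


def thickness_pixel_correlation(
    ranks: Mapping[RegionKey, int],
    thickness: Mapping[RegionKey, Optional[float]],
    pixel_counts: Mapping[RegionKey, int],
) -> tuple[float, float]:
    """Pearson r of (thickness, rank) and (pixel count, rank), 2-decimal half-up.

    Regions without thickness (the eye regions) enter only the pixel-count
    correlation.
    """
    th_regions = [r for r in ranks if thickness.get(r) is not None]
    px_regions = [r for r in ranks if r in pixel_counts]
    if len(th_regions) < 3 or len(px_regions) < 3:
        raise InsufficientDataError("need >= 3 usable regions per correlation")
    r_th = pcc([thickness[r] for r in th_regions], [ranks[r] for r in th_regions])
    r_px = pcc([pixel_counts[r] for r in px_regions], [ranks[r] for r in px_regions])
    return _round2(r_th), _round2(r_px)


def load_reference_scores() -> pd.DataFrame:
    """Published per-region benchmark: median rBS, rank and pixel count."""
    ref = resources.files("roipulse.data").joinpath("reference_region_scores.csv")
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh)
    if len(df) != 31:
        raise MetricsError("reference score table must have 31 regions")
    return df
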