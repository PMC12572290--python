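"""The Location Data Integrity Score (LDIS).

Ten binary indicators, equal weights: a site passes an indicator when the
corresponding diagnostic gives no reason to distrust its reported boundary,
and the score is simply the number of passes (0–10).  Indicators whose
inputs are unavailable are *missing* — by default neither pass nor fail,
with completeness reported alongside; a strict mode counts them as fails.

Threshold strictness follows the indicator definitions exactly: the
infrastructure rules fail on *more than* 10% coverage (strict ``>``), the
land-cover rules on *20% or more* (inclusive ``>=``).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig

#: canonical indicator names, in reporting order
INDICATORS = [
    "road_presence",
    "built_area_presence",
    "forest_at_planting_glad",
    "other_landcover_score",
    "nesting_polygon",
    "intersecting_polygon",
    "exact_admin_area",
    "perfect_circle_indicator",
    "geometry_validity",
    "stable_cropland_score",
]


class Outcome(str, enum.Enum):
    PASS = "pass"
    FAIL = "fail"
    MISSING = "missing"


def _binary(condition_fails, *inputs) -> Outcome:
    if any(x is None or (isinstance(x, float) and math.isnan(x)) for x in inputs):
        return Outcome.MISSING
    return Outcome.FAIL if condition_fails else Outcome.PASS


def binarize_indicators(
    flags: pd.Series | dict, metrics: pd.Series | dict, cfg: PipelineConfig | None = None
) -> dict[str, Outcome]:
    """Map one site's geometry flags + overlay metrics to the ten indicators."""
    cfg = cfg or PipelineConfig()
    f, m = dict(flags), dict(metrics)
    infra, lc = cfg.infra_cover_frac, cfg.landcover_cover_frac

    road = m.get("road_cover_fraction")
    built = m.get("built_fraction")
    tree = m.get("treecover_at_planting_fraction")
    other = m.get("other_landcover_fraction")
    water = m.get("permanent_water_fraction")
    crop = m.get("stable_cropland_fraction")
    # water bodies count toward whichever rule the config assigns
    if cfg.water_counts_as == "other_landcover":
        if other is not None and water is not None and not (
            math.isnan(other) or math.isnan(water)
        ):
            other = other + water
    else:
        if built is not None and water is not None and not (
            math.isnan(built) or math.isnan(water)
        ):
            built = built + water

    out = {
        "road_presence": _binary(road is not None and not math.isnan(road) and road > infra, road),
        "built_area_presence": _binary(
            built is not None and not math.isnan(built) and built > infra, built
        ),
        "forest_at_planting_glad": _binary(
            tree is not None and not math.isnan(tree) and tree >= lc, tree
        ),
        "other_landcover_score": _binary(
            other is not None and not math.isnan(other) and other >= lc, other
        ),
        "stable_cropland_score": _binary(
            crop is not None and not math.isnan(crop) and crop >= lc, crop
        ),
        "nesting_polygon": _binary(len(f.get("nested_in") or []) > 0, 0.0),
        "intersecting_polygon": _binary(len(f.get("intersecting_with") or []) > 0, 0.0),
        "exact_admin_area": _binary(bool(f.get("is_exact_administrative_area")), 0.0),
        "perfect_circle_indicator": _binary(bool(f.get("is_perfectly_circular")), 0.0),
        "geometry_validity": _binary(bool(f.get("project_geometries_invalid")), 0.0),
    }
    return {k: out[k] for k in INDICATORS}


@dataclass
class LDISRecord:
    site_id: str
    indicators: dict[str, Outcome]
    score: int
    n_evaluated: int
    completeness: float


def ldis(indicators: dict[str, Outcome], *, strict_missing: bool = False,
         site_id: str = "") -> LDISRecord:
    """Aggregate the ten indicator outcomes into the 0–10 score.

    ``strict_missing=True`` counts missing indicators as fails (they then
    enter ``n_evaluated``); by default missing indicators are excluded from
    the score and reflected only in ``completeness``.
    """
    unknown = set(indicators) - set(INDICATORS)
    if unknown or set(INDICATORS) - set(indicators):
        raise ValueError(
            f"indicator map must have exactly the ten canonical keys; "
            f"unknown={sorted(unknown)} missing={sorted(set(INDICATORS) - set(indicators))}"
        )
    vals = [Outcome(indicators[k]) for k in INDICATORS]
    if strict_missing:
        vals = [Outcome.FAIL if v is Outcome.MISSING else v for v in vals]
    n_pass = sum(v is Outcome.PASS for v in vals)
    n_eval = sum(v is not Outcome.MISSING for v in vals)
    return LDISRecord(
        site_id=site_id,
        indicators={k: v for k, v in zip(INDICATORS, vals)},
        score=n_pass,
        n_evaluated=n_eval,
        completeness=n_eval / len(INDICATORS),
    )


def score_table(
    sites: pd.DataFrame,
    flags: pd.DataFrame,
    metrics: pd.DataFrame,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Score every site and summarise the distribution.

    Returns (table, summary).  The summary holds the score histogram and the
    share of sites scoring 9 or less, split by geometry kind.
    """
    cfg = cfg or PipelineConfig()
    fl = flags.set_index("site_id")
    mt = metrics.set_index("site_id")
    site_ids = sites["site_id"].astype(str)
    orphans = (set(site_ids) - set(fl.index)) | (set(site_ids) - set(mt.index))
    if orphans:
        raise KeyError(f"sites without flags/metrics rows: {sorted(orphans)[:10]}")
    rows = []
    for _, site in sites.iterrows():
        sid = str(site["site_id"])
        ind = binarize_indicators(fl.loc[sid], mt.loc[sid], cfg)
        rec = ldis(ind, strict_missing=cfg.strict_missing, site_id=sid)
        rows.append({
            "site_id": sid,
            **{k: v.value for k, v in rec.indicators.items()},
            "ldis": rec.score,
            "n_evaluated": rec.n_evaluated,
            "completeness": rec.completeness,
            "geometry_kind": site.get("geometry_kind", "polygon"),
        })
    table = pd.DataFrame(rows)
    summary = {"by_geometry_kind": {}}
    for kind, grp in table.groupby("geometry_kind"):
        hist = grp["ldis"].value_counts().sort_index()
        summary["by_geometry_kind"][kind] = {
            "n_sites": int(len(grp)),
            "histogram": {int(k): int(v) for k, v in hist.items()},
            "share_score_le_9": float((grp["ldis"] <= 9).mean()),
            "share_perfect": float((grp["ldis"] == 10).mean()),
        }
    hist = table["ldis"].value_counts().sort_index()
    summary["all"] = {
        "n_sites": int(len(table)),
        "histogram": {int(k): int(v) for k, v in hist.items()},
        "share_score_le_9": float((table["ldis"] <= 9).mean()),
        "share_perfect": float((table["ldis"] == 10).mean()),
    }
    return table, summary


__all__ = ["INDICATORS", "Outcome", "LDISRecord", "binarize_indicators", "ldis", "score_table"]
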