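"""Planting-impact analysis: bootstrap mean changes, two-period
difference-in-differences, and a bucket-weighted synthetic control.

The DiD model is the saturated two-group / two-period regression

    Y_it = intercept + b1*g_i + b2*t_j + b3*(g_i x t_j) + e_it

with g the zone indicator (planting site = 1, surrounding annulus = 0) and
t the time indicator (comparison period = 1, baseline = 0).  b3 — the
interaction — is the DiD estimate of the planting effect.  Because the
design is saturated, OLS coefficients equal the classical cell-mean
contrasts, which the tests exploit.

The module follows the statsmodels idiom: build a :class:`DiDModel` from a
panel, call :meth:`~DiDModel.fit`, get a :class:`DiDResults` carrying
estimates, standard errors, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .veg_indices import PERIODS, ZONES

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiDSpec:
    """Which slice of the panel enters the 2x2 design."""

    outcome: str = "ndvi"
    period_after: str = "plus1"
    baseline_period: str = "at_planting"
    treatment_zone: str = "site"
    control_zone: str = "annulus"

    def __post_init__(self) -> None:
        if self.period_after == self.baseline_period:
            raise ValueError("period_after must differ from baseline_period")


def balance_panel(panel: pd.DataFrame, required_periods) -> pd.DataFrame:
    """Keep only sites with both zones present for every required period."""
    required = set(required_periods)
    sub = panel[panel["period"].isin(required)]
    cells = sub.drop_duplicates(["site_id", "zone", "period"])
    counts = cells.groupby("site_id").size()
    keep = counts.index[counts == len(ZONES) * len(required)]
    out = panel[panel["site_id"].isin(set(keep))].reset_index(drop=True)
    n_dropped = panel["site_id"].nunique() - len(keep)
    log.info("balanced panel: kept %d sites, dropped %d", len(keep), n_dropped)
    if out.empty:
        raise ValueError("balancing left an empty panel")
    return out


def mean_change_ci(
    panel: pd.DataFrame,
    zone: str,
    period: str,
    baseline: str = "at_planting",
    B: int = 1000,
    seed: int = 0,
    outcome: str = "ndvi",
) -> tuple[float, float, float]:
    """Mean outcome change vs baseline with a percentile bootstrap 95% CI.

    Sites are the resampling unit (drawn with replacement, seeded); the CI
    is the 2.5/97.5 percentile of the replicate means.
    """
    wide = (
        panel[(panel["zone"] == zone) & (panel["period"].isin([baseline, period]))]
        .pivot_table(index="site_id", columns="period", values=outcome)
        .dropna(subset=[baseline, period])
    )
    changes = (wide[period] - wide[baseline]).to_numpy()
    if len(changes) == 0:
        raise ValueError("no sites with both periods present")
    mean = float(changes.mean())
    if len(changes) < 2:
        log.warning("fewer than 2 sites; CI undefined")
        return mean, float("nan"), float("nan")
    if B == 1:
        log.warning("B=1 gives a degenerate CI equal to the single replicate")
    rng = np.random.default_rng(seed)
    reps = changes[rng.integers(0, len(changes), size=(B, len(changes)))].mean(axis=1)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return mean, float(lo), float(hi)


@dataclass
class DiDResults:
    """Fitted two-period DiD. Coefficient order: intercept, g, t, g x t."""

    params: np.ndarray
    bse: np.ndarray
    rsquared: float
    n_obs: int
    residual_sd: float
    cell_means: dict[str, float]  # keys: control_before, control_after, ...
    spec: DiDSpec

    _NAMES = ("intercept", "beta_g", "beta_t", "beta_gt")

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def beta_g(self) -> float:
        return float(self.params[1])

    @property
    def beta_t(self) -> float:
        return float(self.params[2])

    @property
    def beta_gt(self) -> float:
        """The DiD estimate of the planting effect."""
        return float(self.params[3])

    def counterfactual_series(self) -> dict[str, float]:
        """Model predictions per cell with the interaction removed.

        The treated-after entry is the no-effect counterfactual
        intercept + beta_g + beta_t; the other three cells coincide with
        the saturated fit.
        """
        b0, b1, b2, _ = self.params
        return {
            "control_before": float(b0),
            "control_after": float(b0 + b2),
            "treat_before": float(b0 + b1),
            "treat_after": float(b0 + b1 + b2),
        }

    def to_dict(self) -> dict:
        return {
            **{n: float(p) for n, p in zip(self._NAMES, self.params)},
            **{f"se_{s}": float(b) for s, b in zip(("intercept", "g", "t", "gt"), self.bse)},
            "r2": float(self.rsquared),
            "n_obs": int(self.n_obs),
            "residual_sd": float(self.residual_sd),
        }

    def summary(self) -> str:
        lines = [
            "Two-period difference-in-differences (OLS)",
            f"outcome: {self.spec.outcome}   baseline: {self.spec.baseline_period}"
            f"   after: {self.spec.period_after}",
            f"n_obs: {self.n_obs}   R2: {self.rsquared:.3f}"
            f"   resid. SD: {self.residual_sd:.3f}",
            f"{'term':<12}{'coef':>10}{'std err':>10}",
        ]
        for name, p, s in zip(self._NAMES, self.params, self.bse):
            lines.append(f"{name:<12}{p:>10.4f}{s:>10.4f}")
        return "\n".join(lines)


class DiDModel:
    """OLS on the saturated 2x2 zone-by-period design."""

    def __init__(self, y: np.ndarray, g: np.ndarray, t: np.ndarray,
                 spec: DiDSpec | None = None):
        y = np.asarray(y, dtype=float)
        g = np.asarray(g, dtype=float)
        t = np.asarray(t, dtype=float)
        if not (len(y) == len(g) == len(t)):
            raise ValueError("y, g, t must have equal length")
        for gv in (0, 1):
            for tv in (0, 1):
                if not np.any((g == gv) & (t == tv)):
                    raise ValueError(f"empty design cell g={gv}, t={tv}")
        self.y, self.g, self.t = y, g, t
        self.spec = spec or DiDSpec()

    @classmethod
    def from_panel(cls, panel: pd.DataFrame, spec: DiDSpec | None = None) -> "DiDModel":
        spec = spec or DiDSpec()
        sub = panel[panel["period"].isin([spec.baseline_period, spec.period_after])]
        sub = sub[sub["zone"].isin([spec.treatment_zone, spec.control_zone])]
        sub = balance_panel(sub, [spec.baseline_period, spec.period_after])
        y = sub[spec.outcome].to_numpy()
        g = (sub["zone"] == spec.treatment_zone).to_numpy()
        t = (sub["period"] == spec.period_after).to_numpy()
        return cls(y, g, t, spec)

    def fit(self) -> DiDResults:
        import statsmodels.api as sm

        X = np.column_stack([np.ones_like(self.y), self.g, self.t, self.g * self.t])
        res = sm.OLS(self.y, X).fit()
        cells = {
            "control_before": float(self.y[(self.g == 0) & (self.t == 0)].mean()),
            "control_after": float(self.y[(self.g == 0) & (self.t == 1)].mean()),
            "treat_before": float(self.y[(self.g == 1) & (self.t == 0)].mean()),
            "treat_after": float(self.y[(self.g == 1) & (self.t == 1)].mean()),
        }
        return DiDResults(
            params=np.asarray(res.params),
            bse=np.asarray(res.bse),
            rsquared=float(res.rsquared),
            n_obs=int(res.nobs),
            residual_sd=float(np.sqrt(res.mse_resid)),
            cell_means=cells,
            spec=self.spec,
        )


def fit_did(panel: pd.DataFrame, spec: DiDSpec | None = None) -> DiDResults:
    """Convenience wrapper: build the model from a panel and fit it."""
    return DiDModel.from_panel(panel, spec).fit()


def counterfactual_series(result: DiDResults) -> dict[str, float]:
    return result.counterfactual_series()


@dataclass
class SynthControlResult:
    bucket_edges: np.ndarray
    bucket_weights: np.ndarray
    control_means_by_period: dict[str, float]


def synthetic_control(
    control_ndvi_at_planting: np.ndarray,
    site_ndvi_at_planting: np.ndarray,
    control_panel: dict[str, np.ndarray],
    n_buckets: int = 10,
) -> SynthControlResult:
    """Bucket-weighted control trajectory matched to the sites' NDVI mix.

    Bucket edges are equal-probability quantile breaks of the sites'
    at-planting NDVI distribution; weights are the sites' share per bucket
    (equal up to ties).  Control points are assigned to buckets by their
    at-planting NDVI (end buckets are open, so every point lands
    somewhere), and each period's synthetic mean is the weight-averaged
    bucket mean of that period's control values.  Buckets without control
    points are dropped and the remaining weights renormalised, with a
    warning.
    """
    ctrl0 = np.asarray(control_ndvi_at_planting, dtype=float)
    site0 = np.asarray(site_ndvi_at_planting, dtype=float)
    ctrl0, site0 = ctrl0[np.isfinite(ctrl0)], site0[np.isfinite(site0)]
    if len(ctrl0) == 0 or len(site0) == 0:
        raise ValueError("both control and site NDVI sets must be non-empty")
    edges = np.quantile(site0, np.linspace(0, 1, n_buckets + 1))
    inner = np.unique(edges[1:-1])
    site_bucket = np.searchsorted(inner, site0, side="right")
    ctrl_bucket = np.searchsorted(inner, ctrl0, side="right")
    n_eff = len(inner) + 1
    weights = np.bincount(site_bucket, minlength=n_eff).astype(float)
    weights /= weights.sum()
    occupied = np.bincount(ctrl_bucket, minlength=n_eff) > 0
    if not occupied.any():
        raise ValueError("no control points fall into any bucket")
    if not occupied.all():
        log.warning("%d empty buckets re-weighted proportionally", int((~occupied).sum()))
        weights = np.where(occupied, weights, 0.0)
        weights /= weights.sum()
    means = {}
    for period, values in control_panel.items():
        values = np.asarray(values, dtype=float)
        if len(values) != len(np.asarray(control_ndvi_at_planting)):
            raise ValueError(f"period {period!r} values not aligned with control points")
        values = values[np.isfinite(np.asarray(control_ndvi_at_planting, dtype=float))]
        total = 0.0
        for b in range(n_eff):
            if weights[b] == 0:
                continue
            in_b = values[ctrl_bucket == b]
            in_b = in_b[np.isfinite(in_b)]
            if len(in_b):
                total += weights[b] * in_b.mean()
        means[period] = float(total)
    return SynthControlResult(
        bucket_edges=edges, bucket_weights=weights, control_means_by_period=means
    )


__all__ = [
    "DiDSpec", "DiDModel", "DiDResults", "SynthControlResult",
    "balance_panel", "mean_change_ci", "fit_did", "counterfactual_series",
    "synthetic_control",
]
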