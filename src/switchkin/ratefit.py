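"""Linear rate laws of photoswitching vs spot brightness.

Across ROIs of a gradient-illuminated acquisition, the off-switching rate
k_off = 1/τ_on grows linearly with the median spot brightness N_Det, and
the on-switching rate k_on = 1/τ_off is affine in N_Det with a nonzero
intercept.  The fits yield the physical parameters:

* ``N_tau_on``  — photon budget per on-event, the inverse gradient of the
  k_off fit: with k_off in s⁻¹ and N_Det in photons/frame,
  N_τon = 1 / (slope × frame_time).
* ``k_on0`` / ``tau_off0`` — thermal recovery rate and off-state lifetime,
  from the intercept of the k_on fit.
* ``beta_on`` — intensity response of k_on (the gradient), s⁻¹ per
  photon/frame.

Fits are weighted least squares with weights 1/SE² when rate standard
errors are available (ordinary least squares otherwise); standard errors
come from the fit covariance.  Outliers can be masked by studentized
residual before the final fit; masking is reported, never silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chemistry import BufferCondition

__all__ = [
    "RateFitResult",
    "rate_points_from_kinetics",
    "fit_rate_vs_brightness",
    "mask_outliers",
    "summarize_vs_thiolate",
]


@dataclass
class RateFitResult:
    which: str                      # "off" or "on"
    slope: float                    # s⁻¹ per (photon/frame)
    intercept: float                # s⁻¹
    slope_se: float
    intercept_se: float
    n_points_used: int
    frame_time_s: float
    masked_roi_ids: list = field(default_factory=list)
    N_tau_on_photons: float = math.nan
    k_on0_per_s: float = math.nan
    tau_off0_s: float = math.nan
    beta_on: float = math.nan

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "which", "slope", "intercept", "slope_se", "intercept_se",
            "n_points_used", "frame_time_s", "masked_roi_ids",
        )}
        if self.which == "off":
            d["N_tau_on_photons"] = self.N_tau_on_photons
            d["N_tau_on_se_photons"] = self.N_tau_on_se_photons
        else:
            d.update(
                k_on0_per_s=self.k_on0_per_s,
                tau_off0_s=self.tau_off0_s,
                beta_on=self.beta_on,
            )
        return d

    @property
    def N_tau_on_se_photons(self) -> float:
        """Delta-method SE of the photon budget (1/slope scaling)."""
        if self.which != "off" or not self.slope > 0:
            return math.nan
        return self.slope_se / (self.slope**2 * self.frame_time_s)

    @property
    def tau_off0_se_s(self) -> float:
        if self.which != "on" or not self.intercept > 0:
            return math.nan
        return self.intercept_se / self.intercept**2


def rate_points_from_kinetics(kin: pd.DataFrame) -> pd.DataFrame:
    """Per-ROI rate points (with propagated SEs) from a kinetics table.

    SE propagation: se(1/τ) = se(τ)/τ².  Invalid ROIs are dropped.
    """
    df = kin[kin["valid"]].copy()
    tau_on_s = df["tau_on_ms"] / 1e3
    df["k_off_se_per_s"] = (df["tau_on_se_ms"] / 1e3) / tau_on_s**2
    df["k_on_se_per_s"] = df["tau_off_se_s"] / df["tau_off_s"] ** 2
    df["masked"] = False
    return df[
        ["roi_id", "n_det_photons", "k_off_per_s", "k_off_se_per_s",
         "k_on_per_s", "k_on_se_per_s", "masked"]
    ].reset_index(drop=True)


def _design(points: pd.DataFrame, which: str) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    use = points[~points["masked"]]
    x = use["n_det_photons"].to_numpy(dtype=float)
    y = use[f"k_{which}_per_s"].to_numpy(dtype=float)
    se_col = f"k_{which}_se_per_s"
    se = use[se_col].to_numpy(dtype=float) if se_col in use else None
    if se is not None and not (np.all(np.isfinite(se)) and np.all(se > 0)):
        se = None
    return x, y, se


def fit_rate_vs_brightness(
    points: pd.DataFrame,
    which: str = "off",
    frame_time_s: float = 1.0,
    weighted: bool = True,
) -> RateFitResult:
    """Weighted linear fit of a switching rate against spot brightness.

    ``points`` needs columns ``roi_id``, ``n_det_photons``,
    ``k_{which}_per_s`` and optionally ``k_{which}_se_per_s`` and
    ``masked``.  Rates are s⁻¹; brightness photons/frame;
    ``frame_time_s`` converts the off-slope into the photon budget.
    """
    if which not in ("off", "on"):
        raise ValueError("which must be 'off' or 'on'")
    pts = points.copy()
    if "masked" not in pts:
        pts["masked"] = False
    x, y, se = _design(pts, which)
    if x.size < 3:
        raise ValueError(f"need >= 3 unmasked points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: brightness values all equal")
    X = sm.add_constant(x)
    if weighted and se is not None:
        model = sm.WLS(y, X, weights=1.0 / se**2)
    else:
        model = sm.OLS(y, X)
    res = model.fit()
    intercept, slope = res.params
    intercept_se, slope_se = res.bse

    out = RateFitResult(
        which=which,
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
        n_points_used=int(x.size),
        frame_time_s=frame_time_s,
        masked_roi_ids=pts.loc[pts["masked"], "roi_id"].tolist(),
    )
    if which == "off":
        out.N_tau_on_photons = (
            1.0 / (slope * frame_time_s) if slope > 0 else math.nan
        )
    else:
        out.k_on0_per_s = float(intercept)
        out.tau_off0_s = 1.0 / intercept if intercept > 0 else math.nan
        out.beta_on = float(slope)
    return out


def mask_outliers(
    points: pd.DataFrame,
    which: str = "off",
    residual_z_threshold: float = 3.0,
    max_iterations: int = 2,
    weighted: bool = True,
) -> pd.DataFrame:
    """Flag points with |studentized residual| above threshold.

    Iteratively refits (at most ``max_iterations`` times) and stops if
    masking would leave fewer than 3 points.  Returns a copy with the
    ``masked`` column updated.
    """
    pts = points.copy()
    if "masked" not in pts:
        pts["masked"] = False
    for _ in range(max_iterations):
        use = pts[~pts["masked"]]
        if len(use) < 3:
            break
        x, y, se = _design(pts, which)
        X = sm.add_constant(x)
        w = 1.0 / se**2 if (weighted and se is not None) else np.ones_like(y)
        res = sm.WLS(y, X, weights=w).fit()
        # internally studentized residuals of the (weighted) fit
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        hat = np.einsum(
            "ij,jk,ik->i", Xw, np.linalg.inv(Xw.T @ Xw), Xw
        )
        rw = sw * (y - res.fittedvalues)
        sigma = math.sqrt((rw**2).sum() / max(len(y) - 2, 1))
        if sigma <= 1e-10 * max(np.abs(sw * y).max(), 1e-300):
            break  # numerically exact fit: nothing to mask
        with np.errstate(divide="ignore", invalid="ignore"):
            stud = rw / (sigma * np.sqrt(1.0 - hat))
        stud = np.where(np.isfinite(stud), stud, 0.0)
        bad = np.abs(stud) > residual_z_threshold
        if not bad.any():
            break
        if len(use) - int(bad.sum()) < 3:
            import warnings

            warnings.warn("masking would leave < 3 points; stopping")
            break
        idx = use.index[bad]
        pts.loc[idx, "masked"] = True
    return pts


def summarize_vs_thiolate(
    entries: Iterable[tuple[BufferCondition, RateFitResult, RateFitResult, float]],
    equivalence_rtol: float = 0.15,
) -> pd.DataFrame:
    """Per-buffer summary of switching metrics against thiolate.

    ``entries`` are (buffer, off-fit, on-fit, max τ_off/τ_on of the
    central FOV).  Rows are sorted by thiolate concentration; buffers
    whose thiolate concentrations agree within ``equivalence_rtol`` are
    flagged as an equivalence pair (same chemistry reached via different
    pH/thiol combinations).
    """
    entries = list(entries)
    if len(entries) < 1:
        raise ValueError("need at least one buffer condition")
    rows = []
    for buf, fit_off, fit_on, max_ratio in entries:
        if fit_off.which != "off" or fit_on.which != "on":
            raise ValueError("pass (off-fit, on-fit) per buffer")
        rows.append(
            {
                "label": buf.label,
                "thiolate_mM": buf.thiolate_mM,
                "N_tau_on": fit_off.N_tau_on_photons,
                "tau_off0_s": fit_on.tau_off0_s,
                "beta_on": fit_on.beta_on,
                "max_ratio": max_ratio,
            }
        )
    df = pd.DataFrame(rows).sort_values("thiolate_mM").reset_index(drop=True)
    group = np.full(len(df), -1)
    gid = 0
    th = df["thiolate_mM"].to_numpy()
    for i in range(len(df) - 1):
        close = np.isclose(th[i], th[i + 1 :], rtol=equivalence_rtol)
        if close.any() and group[i] < 0:
            group[i] = gid
            group[i + 1 :][close] = gid
            gid += 1
    df["equivalent_group"] = group
    return df
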