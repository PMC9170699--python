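"""Acellular ROS (DCF) assay quantification.

Chemical enhancement is expressed as

    DEF_ROS = (FI_12Gy,NP - FI_0Gy,NP) / (FI_12Gy,blank - FI_0Gy,blank)

the ratio of the radiation-induced fluorescence gain with nanoparticles to
the gain of the nanoparticle-free blank, both measured on paired 0 Gy /
12 Gy plates. Enhancement efficiency per exposed surface area is the slope
of a linear regression of (DEF_ROS - 1) on the surface-area concentration
(cm^2/mL), with the intercept fixed at DEF_ROS = 1 (zero surface area can
produce no enhancement); a free-intercept variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssayError, DomainError, FitError

__all__ = ["def_ros", "RosSlope", "ros_slope", "analyze_ros_plate", "BLANK"]

BLANK = "none"

_ROS_COLS = ("material", "sa_conc_cm2_mL", "dose_Gy", "replicate", "fi")


def def_ros(fi_12_np, fi_0_np, fi_12_blank, fi_0_blank) -> float:
    """Chemical dose-enhancement factor from the four fluorescence readings."""
    denom = float(fi_12_blank) - float(fi_0_blank)
    if denom <= 0:
        raise AssayError(
            "no radiolysis signal in the blank (FI_12Gy <= FI_0Gy): assay failure"
        )
    return (float(fi_12_np) - float(fi_0_np)) / denom


@dataclass(frozen=True)
class RosSlope:
    material: str
    beam: str
    slope: float  # DEF_ROS excess per cm^2/mL
    ci95_lo: float
    ci95_hi: float
    n: int
    intercept: float = 1.0


def ros_slope(
    def_ros_values,
    sa_concs,
    material: str = "",
    beam: str = "",
    fix_intercept: bool = True,
) -> RosSlope:
    """Regression of DEF_ROS on surface-area concentration.

    With ``fix_intercept`` (default) the line is forced through DEF_ROS = 1
    at zero surface area and the 95% CI uses the t quantile with n - 1
    degrees of freedom; otherwise an ordinary free-intercept regression with
    n - 2 degrees of freedom is used.
    """
    y = np.asarray(def_ros_values, dtype=float)
    x = np.asarray(sa_concs, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("def_ros_values and sa_concs must be 1-D, equal length")
    if np.unique(x).size < (3 if fix_intercept else 2):
        raise FitError("degenerate design: need >= 3 distinct concentrations")
    if np.any(x < 0):
        raise DomainError("surface-area concentrations must be >= 0")
    n = y.size
    if fix_intercept:
        yy = y - 1.0
        sxx = float(np.sum(x * x))
        if sxx == 0:
            raise FitError("all concentrations are zero: degenerate design")
        slope = float(np.sum(x * yy) / sxx)
        rss = float(np.sum((yy - slope * x) ** 2))
        se = np.sqrt(rss / (n - 1) / sxx)
        half = float(stats.t.ppf(0.975, n - 1) * se)
        intercept = 1.0
    else:
        res = stats.linregress(x, y)
        slope = float(res.slope)
        half = float(stats.t.ppf(0.975, n - 2) * res.stderr)
        intercept = float(res.intercept)
    return RosSlope(
        material=material,
        beam=beam,
        slope=slope,
        ci95_lo=slope - half,
        ci95_hi=slope + half,
        n=n,
        intercept=intercept,
    )


def analyze_ros_plate(
    plate: pd.DataFrame, beam: str = "", fix_intercept: bool = True
) -> pd.DataFrame:
    """Per-material DEF_ROS regression from a tidy plate table.

    Expects columns ``material, sa_conc_cm2_mL, dose_Gy, replicate, fi`` with
    blank wells labelled material='none' at zero surface area. Per-replicate
    DEF_ROS uses the replicate 12 Gy reading minus the mean 0 Gy reading of
    the same condition, over the blank mean gain, so each material x
    concentration contributes one point per replicate to the regression.
    """
    missing = [c for c in _ROS_COLS if c not in plate.columns]
    if missing:
        raise DomainError(f"ROS table lacks required columns: {missing}")
    df = plate.copy()
    if "Au" in set(df["material"]):
        import warnings

        warnings.warn(
            "Au wells present: the DCF assay suffers strong interference with "
            "Au nanoparticles; interpret DEF_ROS for Au with caution",
            stacklevel=2,
        )
    blanks = df[df["material"] == BLANK]
    if blanks.empty:
        raise AssayError("no blank (material='none') wells present")
    b0 = blanks[blanks["dose_Gy"] == 0]["fi"]
    b12 = blanks[blanks["dose_Gy"] > 0]["fi"]
    denom = b12.mean() - b0.mean()
    if not denom > 0:
        raise AssayError("no radiolysis signal in the blanks: assay failure")
    # every DEF_ROS point shares the same blank net gain in its denominator;
    # this common multiplicative error is invisible to the regression
    # residuals, so its standard error is propagated into the slope CI
    var_denom = (
        (b12.var(ddof=1) / len(b12) if len(b12) > 1 else 0.0)
        + (b0.var(ddof=1) / len(b0) if len(b0) > 1 else 0.0)
    )
    rel_se_denom = np.sqrt(var_denom) / denom

    rows = []
    for mat, sub in df[df["material"] != BLANK].groupby("material"):
        xs, ys = [], []
        for sa, cond in sub.groupby("sa_conc_cm2_mL"):
            fi0 = cond[cond["dose_Gy"] == 0]["fi"].mean()
            reps = cond[cond["dose_Gy"] > 0]
            for _, r in reps.iterrows():
                xs.append(float(sa))
                ys.append((float(r["fi"]) - fi0) / denom)
        fit = ros_slope(
            np.asarray(ys), np.asarray(xs), material=str(mat), beam=beam,
            fix_intercept=fix_intercept,
        )
        t_q = stats.t.ppf(0.975, fit.n - (1 if fix_intercept else 2))
        x_arr = np.asarray(xs)
        y_arr = np.asarray(ys)
        # multiplicative plate noise makes the scatter grow with the fitted
        # mean; a heteroscedasticity-robust (HC1) slope standard error keeps
        # the CI honest where the homoscedastic residual formula undershoots
        resid = (y_arr - fit.intercept) - fit.slope * x_arr
        sxx = float(np.sum(x_arr**2))
        hc1 = np.sqrt(
            np.sum((x_arr * resid) ** 2) / sxx**2 * fit.n / (fit.n - 1)
        )
        half_reg = max(fit.ci95_hi - fit.slope, t_q * hc1)
        # a relative denominator error eps rescales the enhancement (slope
        # term) and, with the intercept pinned at 1, also shifts every point
        # by -eps, which the through-origin fit absorbs as Sum(x)/Sum(x^2)
        sens = abs(fit.slope) + (
            np.sum(x_arr) / np.sum(x_arr**2) if fix_intercept else 0.0
        )
        half = float(np.hypot(half_reg, t_q * sens * rel_se_denom))
        rows.append(
            {
                "material": mat,
                "beam": beam,
                "slope": fit.slope,
                "ci95_lo": fit.slope - half,
                "ci95_hi": fit.slope + half,
                "n": fit.n,
            }
        )
    return pd.DataFrame(rows)
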