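"""In-vitro survival analysis: luminescence -> cell counts -> SF -> LQ -> DMR.

The chain mirrors a CellTiter-Glo based clonogenic-surrogate assay:

1. luminescence is converted to cell number via a standard curve,
2. surviving fractions SF(D) = cells(D)/cells(0 Gy) are formed per condition,
3. SF is fitted to the linear-quadratic model SF(D) = exp(-(alpha*D + beta*D^2)),
4. the 50%-survival dose LD50 solves alpha*D + beta*D^2 = ln 2,
5. the dose-modifying ratio DMR50 = LD50(control) / LD50(nanoparticle),
6. sham (0 Gy) toxicity is summarized by a sigmoid with LC50 = ln(a)/b and a
   60% viability inclusion cutoff for the DMR analysis,
7. hydroxyl-radical quenching is quantified by the monodose enhancement ratio
   NER = SF(6 Gy, control)/SF(6 Gy, NP) and the degree of DMSO protection
   DoP = 1 - (NER_DMSO - 1)/(NER_noDMSO - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DomainError, FitError

__all__ = [
    "StandardCurve",
    "LQFit",
    "DMRResult",
    "ToxicityFit",
    "QuenchResult",
    "luminescence_to_cells",
    "surviving_fraction",
    "fit_lq",
    "ld50",
    "dmr50",
    "normalized_viability",
    "fit_toxicity",
    "ner",
    "dop",
    "run_survival_pipeline",
    "VIABILITY_CUTOFF",
]

VIABILITY_CUTOFF = 0.60
_LN2 = math.log(2.0)
_DMSO_TOL = 1e-9


# ---------------------------------------------------------------------------
# standard curve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardCurve:
    """Luminescence -> cell-count conversion.

    ``as_printed`` is the linear rule #cells = y*b/(a - b); ``saturation``
    inverts the saturating curve y = a*x/(b + x), i.e. #cells = y*b/(a - y).
    The defaults are the fitted plate-reader calibration constants.
    """

    a: float = 3.872e6
    b: float = 3.431e5
    form: str = "as_printed"

    def __post_init__(self):
        if self.form not in ("as_printed", "saturation"):
            raise DomainError("form must be 'as_printed' or 'saturation'")
        if not self.a > self.b > 0 and self.form == "as_printed":
            raise DomainError("as_printed form requires a > b > 0")
        if self.a <= 0 or self.b <= 0:
            raise DomainError("a and b must be > 0")

    def to_cells(self, y):
        return luminescence_to_cells(y, self)

    def to_luminescence(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise DomainError("cell count must be >= 0")
        if self.form == "as_printed":
            return x * (self.a - self.b) / self.b
        return self.a * x / (self.b + x)


def luminescence_to_cells(y, curve: StandardCurve | None = None):
    """Invert the standard curve; monotone and nonnegative in y."""
    curve = curve or StandardCurve()
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise DomainError("luminescence must be >= 0")
    if curve.form == "as_printed":
        out = y * curve.b / (curve.a - curve.b)
    else:
        if np.any(y >= curve.a):
            raise DomainError(
                "saturation form requires luminescence below the plateau a"
            )
        out = y * curve.b / (curve.a - y)
    return out if out.ndim else float(out)


def surviving_fraction(cells_dose, cells_0gy):
    """SF = cells(D)/cells(0 Gy); values > 1 are allowed (flag downstream)."""
    cells_0gy = np.asarray(cells_0gy, dtype=float)
    if np.any(cells_0gy <= 0):
        raise DomainError("0 Gy cell count must be > 0")
    out = np.asarray(cells_dose, dtype=float) / cells_0gy
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# linear-quadratic fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LQFit:
    alpha: float
    beta: float
    covariance: np.ndarray = field(compare=False)
    doses: tuple = ()
    residual_ss: float = 0.0

    @property
    def ld50(self) -> float:
        return ld50(self.alpha, self.beta)

    @property
    def extrapolated(self) -> bool:
        """True when LD50 lies beyond the fitted dose range."""
        d = self.ld50
        return (not np.isfinite(d)) or (bool(self.doses) and d > max(self.doses))

    def sf(self, dose):
        d = np.asarray(dose, dtype=float)
        return np.exp(-(self.alpha * d + self.beta * d * d))


def _lq_model(d, alpha, beta):
    return np.exp(-(alpha * d + beta * d * d))


def fit_lq(doses, sf, sf_sd=None) -> LQFit:
    """Constrained (alpha, beta >= 0) nonlinear least squares on the SF scale.

    Accepts replicate observations (doses repeated per replicate). Noise-free
    LQ data are recovered to machine precision; seeds come from a log-linear
    regression plus a fixed fallback.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(sf, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise FitError("doses and sf must be 1-D and equal length")
    if np.unique(d).size < 3 or 0.0 not in np.unique(d):
        raise FitError("need >= 3 dose levels including 0 Gy")
    if np.any(y <= 0):
        raise FitError("surviving fractions must be > 0 for the LQ fit")

    # log-linear seed: -ln SF = alpha d + beta d^2
    pos = d > 0
    seeds = [(0.1, 0.01)]
    if pos.sum() >= 2:
        A = np.stack([d[pos], d[pos] ** 2], axis=-1)
        try:
            coef, *_ = np.linalg.lstsq(A, -np.log(y[pos]), rcond=None)
            seeds.insert(0, (max(coef[0], 0.0), max(coef[1], 0.0)))
        except np.linalg.LinAlgError:
            pass
    best = None
    for p0 in seeds:
        try:
            popt, pcov = curve_fit(
                _lq_model,
                d,
                y,
                p0=p0,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                sigma=sf_sd,
                maxfev=20_000,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((y - _lq_model(d, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise FitError("LQ fit did not converge for any start point")
    popt, pcov, rss = best
    # flat survival: the exact boundary solution (0, 0) beats any interior
    # iterate the optimizer stops at
    rss_null = float(np.sum((y - 1.0) ** 2))
    if rss_null <= rss:
        popt, rss = np.zeros(2), rss_null
    return LQFit(
        alpha=float(popt[0]),
        beta=float(popt[1]),
        covariance=np.asarray(pcov),
        doses=tuple(sorted(set(d.tolist()))),
        residual_ss=rss,
    )


def ld50(alpha: float, beta: float) -> float:
    """Dose with 50% survival: solves alpha*D + beta*D^2 = ln 2.

    Uses the rationalized quadratic root 2 ln2 / (alpha + sqrt(alpha^2 +
    4 beta ln2)), continuous in beta at 0; infinite when alpha = beta = 0.
    """
    if alpha < 0 or beta < 0:
        raise DomainError("alpha and beta must be >= 0")
    if alpha == 0.0 and beta == 0.0:
        return math.inf
    return 2.0 * _LN2 / (alpha + math.sqrt(alpha * alpha + 4.0 * beta * _LN2))


@dataclass(frozen=True)
class DMRResult:
    material: str
    concentration_ug_mL: float
    dmr50: float
    sd: float
    included: bool
    n_batches: int = 1


def dmr50(lq_control: LQFit, lq_np: LQFit) -> float:
    """Dose-modifying ratio at 50% survival: LD50(control)/LD50(NP)."""
    num, den = lq_control.ld50, lq_np.ld50
    if not (np.isfinite(num) and np.isfinite(den)):
        raise FitError("DMR undefined: LD50 is infinite for a fit")
    return num / den


# ---------------------------------------------------------------------------
# toxicity
# ---------------------------------------------------------------------------


def normalized_viability(cells_np_0gy, cells_ctrl_0gy):
    """Sham-irradiation viability: NP-treated over untreated 0 Gy cell counts."""
    return surviving_fraction(cells_np_0gy, cells_ctrl_0gy)


@dataclass(frozen=True)
class ToxicityFit:
    a: float
    b: float
    lc50: float
    converged: bool
    included: dict = field(default_factory=dict, compare=False)


def _sigmoid(x, a, b):
    return 1.0 - 1.0 / (1.0 + a * np.exp(-b * x))


def fit_toxicity(concentrations, viability, cutoff: float = VIABILITY_CUTOFF):
    """Fit viability = 1 - 1/(1 + a e^{-b x}); LC50 = ln(a)/b.

    Returns a ToxicityFit whose ``included`` maps each concentration to the
    inclusion flag (measured viability >= cutoff). When the sigmoid does not
    converge or never crosses 50%, LC50 is inf and ``converged`` is False,
    but raw viabilities (and flags) are still reported.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(viability, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or np.unique(x).size < 3:
        raise FitError("need >= 3 concentration levels")
    if np.any(y <= 0) or np.any(y > 1.5):
        raise DomainError("viability must be in (0, 1.5]")
    included = {float(c): bool(v >= cutoff) for c, v in zip(x, y)}
    try:
        popt, _ = curve_fit(
            _sigmoid,
            x,
            y,
            p0=(50.0, 0.02),
            bounds=([1e-12, 1e-9], [np.inf, np.inf]),
            maxfev=20_000,
        )
        a, b = float(popt[0]), float(popt[1])
        lc50 = math.log(a) / b if a > 1.0 else math.inf
        # a fit extrapolating beyond the design while the data never fall
        # below 50% shows no observed crossing: flag LC50 as infinite
        if y.min() > 0.5 and lc50 > x.max():
            lc50 = math.inf
        return ToxicityFit(a=a, b=b, lc50=lc50, converged=True, included=included)
    except RuntimeError:
        return ToxicityFit(
            a=math.nan, b=math.nan, lc50=math.inf, converged=False, included=included
        )


# ---------------------------------------------------------------------------
# radical quenching
# ---------------------------------------------------------------------------


def ner(sf_ctrl, sf_np) -> float:
    """Monodose nanoparticle enhancement ratio SF(control)/SF(NP) at fixed dose."""
    sf_ctrl, sf_np = float(sf_ctrl), float(sf_np)
    if sf_ctrl <= 0 or sf_np <= 0:
        raise DomainError("surviving fractions must be > 0")
    return sf_ctrl / sf_np


def dop(sf_ctrl_dmso, sf_np_dmso, sf_ctrl_nodmso, sf_np_nodmso) -> float:
    """Degree of DMSO protection from the four 6 Gy surviving fractions.

    DoP = 1 - (NER_DMSO - 1)/(NER_noDMSO - 1); 0 when DMSO changes nothing,
    1 when it removes the whole nanoparticle enhancement. Undefined (error)
    when there is no enhancement to protect against (NER_noDMSO <= 1).
    """
    ner_dmso = ner(sf_ctrl_dmso, sf_np_dmso)
    ner_nodmso = ner(sf_ctrl_nodmso, sf_np_nodmso)
    if ner_nodmso <= 1.0:
        raise DomainError(
            "DoP undefined: no nanoparticle enhancement without DMSO "
            f"(NER = {ner_nodmso:.3g})"
        )
    return 1.0 - (ner_dmso - 1.0) / (ner_nodmso - 1.0)


@dataclass(frozen=True)
class QuenchResult:
    material: str
    dmso_M: float
    ner: float
    dop: float  # nan at the no-DMSO reference level or when undefined


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------

_REQUIRED_COLS = (
    "batch",
    "material",
    "conc_ug_mL",
    "dose_Gy",
    "dmso_M",
    "replicate",
    "luminescence",
)

_CONTROL = "none"


def run_survival_pipeline(
    plate: pd.DataFrame,
    curve: StandardCurve | None = None,
    cutoff: float = VIABILITY_CUTOFF,
    quench_dose_Gy: float = 6.0,
) -> dict[str, pd.DataFrame]:
    """Run the full chain on a tidy well table.

    Expects columns ``batch, material, conc_ug_mL, dose_Gy, dmso_M,
    replicate, luminescence`` with control wells labelled material='none'.
    Returns ``lq_fits``, ``dmr``, ``toxicity``, ``quench`` and ``qc`` tables.
    """
    curve = curve or StandardCurve()
    missing = [c for c in _REQUIRED_COLS if c not in plate.columns]
    if missing:
        raise DomainError(f"plate table lacks required columns: {missing}")
    df = plate.copy()
    df["cells"] = curve.to_cells(df["luminescence"].to_numpy(dtype=float))

    grp = (
        df.groupby(["batch", "material", "conc_ug_mL", "dmso_M", "dose_Gy"])["cells"]
        .mean()
        .rename("cells")
        .reset_index()
    )

    lq_rows, qc_rows = [], []
    fits: dict[tuple, LQFit] = {}
    viab: dict[tuple, float] = {}

    for (batch, dmso), sub in grp[np.isclose(grp["dmso_M"], 0.0)].groupby(
        ["batch", "dmso_M"]
    ):
        ctrl0 = sub[(sub["material"] == _CONTROL) & (sub["dose_Gy"] == 0)]["cells"]
        ctrl0 = float(ctrl0.iloc[0]) if len(ctrl0) else np.nan
        for (mat, conc), cond in sub.groupby(["material", "conc_ug_mL"]):
            cond = cond.sort_values("dose_Gy")
            cells0 = cond[cond["dose_Gy"] == 0]["cells"]
            if not len(cells0):
                continue
            cells0 = float(cells0.iloc[0])
            sf = surviving_fraction(cond["cells"].to_numpy(), cells0)
            if mat != _CONTROL and np.isfinite(ctrl0):
                viab[(batch, mat, conc)] = cells0 / ctrl0
            if np.any(sf > 1.0):
                qc_rows.append(
                    {
                        "batch": batch,
                        "material": mat,
                        "conc_ug_mL": conc,
                        "note": "SF > 1 retained (not clipped)",
                    }
                )
            try:
                fit = fit_lq(cond["dose_Gy"].to_numpy(dtype=float), sf)
            except FitError as exc:
                qc_rows.append(
                    {
                        "batch": batch,
                        "material": mat,
                        "conc_ug_mL": conc,
                        "note": f"LQ fit failed: {exc}",
                    }
                )
                continue
            fits[(batch, mat, conc)] = fit
            lq_rows.append(
                {
                    "batch": batch,
                    "material": mat,
                    "conc_ug_mL": conc,
                    "alpha": fit.alpha,
                    "beta": fit.beta,
                    "ld50_Gy": fit.ld50,
                    "extrapolated": fit.extrapolated,
                    "residual_ss": fit.residual_ss,
                }
            )

    # DMR per (material, concentration), batch repeats -> mean +- sd
    dmr_rows = []
    np_keys = sorted({(m, c) for (_, m, c) in fits if m != _CONTROL})
    for mat, conc in np_keys:
        per_batch = []
        for (batch, m, c), fit in fits.items():
            if m != mat or c != conc:
                continue
            ctrl = fits.get((batch, _CONTROL, 0.0))
            if ctrl is None:
                continue
            try:
                per_batch.append(dmr50(ctrl, fit))
            except FitError:
                qc_rows.append(
                    {
                        "batch": batch,
                        "material": mat,
                        "conc_ug_mL": conc,
                        "note": "DMR undefined (infinite LD50)",
                    }
                )
        if not per_batch:
            continue
        v = np.nanmean(
            [viab.get((b, mat, conc), np.nan) for b in {k[0] for k in fits}]
        )
        dmr_rows.append(
            {
                "material": mat,
                "conc_ug_mL": conc,
                "dmr50": float(np.mean(per_batch)),
                "sd": float(np.std(per_batch, ddof=1)) if len(per_batch) > 1 else 0.0,
                "viability": v,
                "included": bool(np.isnan(v) or v >= cutoff),
                "n_batches": len(per_batch),
            }
        )

    # toxicity per material, pooled over batches
    tox_rows = []
    for mat in sorted({m for (_, m, _) in viab}):
        pts = sorted(
            (c, v) for (b, m, c), v in viab.items() if m == mat
        )
        concs = np.array([p[0] for p in pts])
        vals = np.clip(np.array([p[1] for p in pts]), 1e-6, 1.5)
        if np.unique(concs).size >= 3:
            tox = fit_toxicity(concs, vals, cutoff)
            tox_rows.append(
                {
                    "material": mat,
                    "a": tox.a,
                    "b": tox.b,
                    "lc50_ug_mL": tox.lc50,
                    "converged": tox.converged,
                }
            )

    # quenching: per material, SF at the quench dose across the DMSO grid
    quench_rows = []
    has_dmso = grp[grp["dmso_M"] > _DMSO_TOL]
    if len(has_dmso):
        sf6 = {}
        for (batch, mat, conc, dmso), cond in grp.groupby(
            ["batch", "material", "conc_ug_mL", "dmso_M"]
        ):
            c0 = cond[cond["dose_Gy"] == 0]["cells"]
            c6 = cond[np.isclose(cond["dose_Gy"], quench_dose_Gy)]["cells"]
            if len(c0) and len(c6):
                sf6.setdefault((mat, conc, dmso), []).append(
                    float(c6.iloc[0]) / float(c0.iloc[0])
                )
        mats = sorted({(m, c) for (m, c, _) in sf6 if m != _CONTROL})
        for mat, conc in mats:
            levels = sorted({d for (m, c, d) in sf6 if m == mat and c == conc})
            base = None
            for dmso in levels:
                sf_np = float(np.mean(sf6[(mat, conc, dmso)]))
                ctrl_key = next(
                    (k for k in sf6 if k[0] == _CONTROL and np.isclose(k[2], dmso)),
                    None,
                )
                if ctrl_key is None:
                    continue
                sf_ctrl = float(np.mean(sf6[ctrl_key]))
                this_ner = ner(sf_ctrl, sf_np)
                if dmso <= _DMSO_TOL:
                    base = this_ner
                    d = np.nan
                elif base is None or base <= 1.0:
                    d = np.nan
                else:
                    d = 1.0 - (this_ner - 1.0) / (base - 1.0)
                quench_rows.append(
                    {
                        "material": mat,
                        "conc_ug_mL": conc,
                        "dmso_M": dmso,
                        "ner": this_ner,
                        "dop": d,
                    }
                )

    return {
        "lq_fits": pd.DataFrame(lq_rows),
        "dmr": pd.DataFrame(dmr_rows),
        "toxicity": pd.DataFrame(tox_rows),
        "quench": pd.DataFrame(quench_rows),
        "qc": pd.DataFrame(qc_rows),
    }
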