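"""Cellular nanoparticle uptake from ICP-MS elemental masses.

Per-cell metal mass as a function of nominal exposure concentration follows
a Hill-type saturation f(x) = A x^p / (B^p + x^p) (plateau A in ng/cell,
half-saturation B in ug/mL, cooperativity p). Per-cell metal mass converts
to an intracellular nanoparticle volume fraction via the material's metal
mass fraction and bulk density, a fixed cell volume (2800 um^3 for a
17.5 um diameter cell), and an optional sham-viability correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DomainError, FitError
from .materials import get_material

__all__ = [
    "UptakeFit",
    "hill_saturation",
    "fit_uptake",
    "mass_to_volume_fraction",
    "analyze_uptake_table",
    "DEFAULT_CELL_VOLUME_UM3",
]

DEFAULT_CELL_VOLUME_UM3 = 2800.0


def hill_saturation(x, a, b, p):
    """f(x) = A x^p / (B^p + x^p); f(0) = 0, f(B) = A/2, f(inf) = A."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        xp = np.where(x > 0, x**p, 0.0)
    return a * xp / (b**p + xp)


@dataclass(frozen=True)
class UptakeFit:
    a: float  # plateau, ng/cell
    b: float  # half-saturation, ug/mL
    p: float  # Hill exponent
    converged: bool
    residual_ss: float = 0.0
    degenerate: bool = False  # all-zero masses


def fit_uptake(concentrations, ng_per_cell) -> UptakeFit:
    """Least-squares fit of the saturation curve; exact on noise-free data."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(ng_per_cell, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("inputs must be 1-D and of equal length")
    if np.unique(x).size < 4:
        raise FitError("need >= 4 concentration levels")
    if np.any(y < 0) or np.any(x < 0):
        raise DomainError("concentrations and masses must be >= 0")
    if np.all(y == 0.0):
        return UptakeFit(0.0, np.nan, np.nan, converged=True, degenerate=True)
    p0 = (float(y.max()), float(np.median(x[x > 0])) or 1.0, 1.0)
    try:
        popt, _ = curve_fit(
            hill_saturation,
            x,
            y,
            p0=p0,
            bounds=([0.0, 1e-9, 0.05], [np.inf, np.inf, 20.0]),
            maxfev=40_000,
            xtol=1e-13,
            ftol=1e-13,
        )
    except RuntimeError:
        return UptakeFit(np.nan, np.nan, np.nan, converged=False)
    rss = float(np.sum((y - hill_saturation(x, *popt)) ** 2))
    return UptakeFit(
        float(popt[0]), float(popt[1]), float(popt[2]), converged=True,
        residual_ss=rss,
    )


def mass_to_volume_fraction(
    metal_ng_per_cell: float,
    material,
    cell_volume_um3: float = DEFAULT_CELL_VOLUME_UM3,
    sham_viability: float = 1.0,
) -> float:
    """Intracellular nanoparticle volume percent from per-cell metal mass.

    particle mass = metal mass / metal mass fraction; particle volume =
    particle mass / bulk density; vol% = 100 * volume / cell volume, divided
    by the sham viability (surviving cells carry the measured load). Pass
    sham_viability=1 to disable the correction.
    """
    if metal_ng_per_cell < 0:
        raise DomainError("metal mass must be >= 0")
    if cell_volume_um3 <= 0:
        raise DomainError("cell volume must be > 0")
    if not 0.0 < sham_viability <= 1.5:
        raise DomainError("sham viability must be in (0, 1.5]")
    mat = get_material(material)
    particle_g = metal_ng_per_cell * 1e-9 / mat.metal_mass_fraction
    volume_um3 = particle_g / mat.bulk_density * 1e12  # cm^3 -> um^3
    return 100.0 * volume_um3 / cell_volume_um3 / sham_viability


_UPTAKE_COLS = ("material", "conc_ug_mL", "replicate", "metal_ng_total", "cells_counted")


def analyze_uptake_table(
    table: pd.DataFrame,
    cell_volume_um3: float = DEFAULT_CELL_VOLUME_UM3,
    sham_viability: dict | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-material uptake summary and saturation fit from a tidy ICP table.

    Expects ``material, conc_ug_mL, replicate, metal_ng_total, cells_counted``;
    per-cell mass is metal_ng_total / cells_counted. ``sham_viability`` may map
    (material, conc) to the normalized viability used for the correction.
    """
    missing = [c for c in _UPTAKE_COLS if c not in table.columns]
    if missing:
        raise DomainError(f"uptake table lacks required columns: {missing}")
    df = table.copy()
    if np.any(df["cells_counted"].to_numpy(dtype=float) <= 0):
        raise DomainError("cells_counted must be > 0")
    df["ng_per_cell"] = df["metal_ng_total"].astype(float) / df[
        "cells_counted"
    ].astype(float)
    rows, fit_rows = [], []
    for mat, sub in df.groupby("material"):
        means = sub.groupby("conc_ug_mL")["ng_per_cell"].mean()
        fit = fit_uptake(means.index.to_numpy(dtype=float), means.to_numpy())
        fit_rows.append(
            {
                "material": mat,
                "A_ng_per_cell": fit.a,
                "B_ug_mL": fit.b,
                "p": fit.p,
                "converged": fit.converged,
            }
        )
        for conc, ng in means.items():
            viab = 1.0
            if sham_viability:
                viab = sham_viability.get((mat, float(conc)), 1.0)
            rows.append(
                {
                    "material": mat,
                    "conc_ug_mL": float(conc),
                    "ng_per_cell": float(ng),
                    "vol_percent": mass_to_volume_fraction(
                        float(ng), mat, cell_volume_um3, viab
                    ),
                }
            )
    return {"uptake": pd.DataFrame(rows), "fits": pd.DataFrame(fit_rows)}
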