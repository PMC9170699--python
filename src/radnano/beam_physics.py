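"""Photon spectra, coefficient tables, and the analytic macroscopic DEF.

The macroscopic dose-enhancement factor of a water system containing a mass
fraction f of nanoparticle material is

    as_printed:  DEF = 1 + f * <mu_en/rho>_NP / <mu_en/rho>_water
    mixture:     DEF = 1 + f * (<mu_en/rho>_NP / <mu_en/rho>_water - 1)

where <.> is the spectrum-weighted mean coefficient. ``as_printed`` is the
conventional additive form used in the radioenhancement literature and is the
default; ``mixture`` is the exact two-component kerma mixture rule (the form
the Monte-Carlo kerma limit reproduces). Spectrum weighting defaults to
energy fluence (weight * E * coefficient), since collision kerma is energy
fluence times mu_en/rho; plain fluence weighting is available.

The per-volume-fraction enhancement efficiency chi = (DEF - 1)/f_vol is
extracted by a through-origin least-squares fit in :func:`chi_fit`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import photon_data as phd
from .errors import DomainError, FitError, FormatError
from .materials import MaterialSpec, get_material

__all__ = [
    "PhotonSpectrum",
    "CoefficientTable",
    "EnhancementEfficiency",
    "load_spectrum",
    "builtin_spectrum_ids",
    "get_coefficient_table",
    "spectrum_mean_coefficient",
    "macroscopic_def",
    "chi_fit",
]

_E_MIN_KEV, _E_MAX_KEV = 1.0, 20000.0


@dataclass(frozen=True)
class PhotonSpectrum:
    """Relative photon fluence on a strictly increasing energy grid (keV)."""

    energies: np.ndarray
    weights: np.ndarray
    name: str = "custom"

    def __post_init__(self):
        e = np.atleast_1d(np.asarray(self.energies, dtype=float))
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if e.shape != w.shape or e.ndim != 1:
            raise FormatError("energies and weights must be 1-D and equal length")
        if np.any(np.diff(e) <= 0):
            raise FormatError("energies must be strictly increasing")
        if np.any(w < 0):
            raise FormatError("weights must be >= 0")
        if w.sum() <= 0:
            raise FormatError("spectrum has zero total weight")
        if e[0] <= _E_MIN_KEV or e[-1] >= _E_MAX_KEV:
            raise FormatError(
                f"energies must lie within ({_E_MIN_KEV}, {_E_MAX_KEV}) keV"
            )
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w / w.sum())

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.weights))


def _kv150() -> PhotonSpectrum:
    """Filtered-Kramers model of a 150 kV tungsten tube.

    Bremsstrahlung intensity ~ (E_max - E)/E, hardened by ~3 cm of
    PMMA-equivalent material (water attenuation scaled by the PMMA
    electron-density factor 0.965 and density 1.19); the thin beryllium
    window is negligible above 10 keV. Characteristic tungsten lines are not
    modelled: this is a coarse shape, adequate for coefficient weighting.
    """
    e = np.arange(12.5, 150.0 + 1e-9, 2.5)
    kramers = (150.0 - e) / e
    mu_pmma = phd.mu_rho_water(e) * 0.965 * 1.19  # cm^-1
    w = kramers * np.exp(-mu_pmma * 3.0)
    w[e >= 150.0] = 0.0
    keep = w > 0
    return PhotonSpectrum(e[keep], w[keep], name="kv150")


def _mv6() -> PhotonSpectrum:
    """Coarse tabulation of a generic 6 MV linac fluence spectrum in water."""
    e = np.array(
        [250, 500, 750, 1000, 1250, 1500, 2000, 2500, 3000,
         3500, 4000, 4500, 5000, 5500, 6000],
        dtype=float,
    )
    w = np.array(
        [0.35, 1.0, 0.95, 0.85, 0.75, 0.65, 0.50, 0.38, 0.28,
         0.20, 0.14, 0.09, 0.05, 0.02, 0.005]
    )
    return PhotonSpectrum(e, w, name="mv6")


_BUILTINS = {"kv150": _kv150, "mv6": _mv6}


def builtin_spectrum_ids() -> tuple[str, ...]:
    return tuple(sorted(_BUILTINS))


def load_spectrum(source) -> PhotonSpectrum:
    """Load a spectrum from a builtin id, a CSV path, or a file object.

    CSV schema: header ``energy_keV,weight``, one row per bin. The spectrum
    is normalized to unit total weight on load.
    """
    if isinstance(source, PhotonSpectrum):
        return source
    if isinstance(source, str) and source in _BUILTINS:
        return _BUILTINS[source]()
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        name = Path(source).stem
    elif isinstance(source, io.IOBase):
        text = source.read()
        name = "custom"
    else:
        raise FormatError(f"cannot load spectrum from {type(source).__name__}")
    rows = [r.strip() for r in text.splitlines() if r.strip()]
    if not rows:
        raise FormatError("empty spectrum file")
    start = 1 if rows[0].lower().replace(" ", "").startswith("energy") else 0
    try:
        data = np.array(
            [[float(x) for x in r.split(",")[:2]] for r in rows[start:]]
        )
    except ValueError as exc:
        raise FormatError(f"non-numeric spectrum row: {exc}") from None
    if data.ndim != 2 or data.shape[1] != 2:
        raise FormatError("spectrum file must have two numeric columns")
    return PhotonSpectrum(data[:, 0], data[:, 1], name=name)


# ---------------------------------------------------------------------------
# coefficient tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoefficientTable:
    """Log-log interpolable mass energy-absorption coefficient table."""

    material_id: str
    energies: np.ndarray
    mu_en_rho: np.ndarray
    mu_rho: np.ndarray | None = None

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        m = np.asarray(self.mu_en_rho, dtype=float)
        if np.any(np.diff(e) <= 0):
            raise FormatError("table energies must be strictly increasing")
        if np.any(m <= 0):
            raise FormatError("coefficients must be > 0")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_en_rho", m)

    def __call__(self, energy_kev) -> np.ndarray:
        e = np.asarray(energy_kev, dtype=float)
        if np.any(e < self.energies[0]) or np.any(e > self.energies[-1]):
            raise DomainError(
                f"energy outside table range for {self.material_id}: "
                f"[{self.energies[0]:.3g}, {self.energies[-1]:.3g}] keV"
            )
        return np.exp(
            np.interp(np.log(e), np.log(self.energies), np.log(self.mu_en_rho))
        )

    def interaction(self, energy_kev) -> np.ndarray:
        if self.mu_rho is None:
            raise DomainError(f"table {self.material_id} has no mu/rho column")
        e = np.asarray(energy_kev, dtype=float)
        return np.exp(
            np.interp(np.log(e), np.log(self.energies), np.log(self.mu_rho))
        )


def _water_table() -> CoefficientTable:
    ref = phd.WATER_REFERENCE
    return CoefficientTable(
        "water", ref["energy_keV"], ref["mu_en_rho"], ref["mu_rho"]
    )


def _material_table(material: MaterialSpec) -> CoefficientTable:
    fracs = material.mass_fractions
    grids = [phd.element_grid(s) for s in fracs]
    grid = np.unique(np.concatenate(grids))
    mu_en = phd.mu_en_rho_mixture(fracs, grid)
    mu = phd.mu_rho_mixture(fracs, grid)
    return CoefficientTable(material.coefficient_table_id, grid, mu_en, mu)


_TABLE_CACHE: dict[str, CoefficientTable] = {}


def get_coefficient_table(material) -> CoefficientTable:
    """Coefficient table for 'water', a registry name, or a MaterialSpec."""
    if isinstance(material, CoefficientTable):
        return material
    if isinstance(material, str) and material.lower() == "water":
        key = "water"
    else:
        material = get_material(material)
        key = material.coefficient_table_id
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = (
            _water_table() if key == "water" else _material_table(material)
        )
    return _TABLE_CACHE[key]


def spectrum_mean_coefficient(
    table, spectrum: PhotonSpectrum, weighting: str = "energy_fluence"
) -> float:
    """Spectrum-weighted mean mu_en/rho of a material."""
    table = get_coefficient_table(table)
    mu = table(spectrum.energies)
    if weighting == "energy_fluence":
        w = spectrum.weights * spectrum.energies
    elif weighting == "fluence":
        w = spectrum.weights
    else:
        raise DomainError("weighting must be 'energy_fluence' or 'fluence'")
    return float(np.sum(w * mu) / np.sum(w))


def macroscopic_def(
    material,
    f_mass: float,
    spectrum,
    mode: str = "as_printed",
    weighting: str = "energy_fluence",
) -> float:
    """Macroscopic dose-enhancement factor of a water/nanoparticle system."""
    if not 0.0 <= f_mass <= 1.0:
        raise DomainError("f_mass must be within [0, 1]")
    spectrum = load_spectrum(spectrum)
    ratio = spectrum_mean_coefficient(material, spectrum, weighting) / (
        spectrum_mean_coefficient("water", spectrum, weighting)
    )
    if mode == "as_printed":
        return 1.0 + f_mass * ratio
    if mode == "mixture":
        return 1.0 + f_mass * (ratio - 1.0)
    raise DomainError("mode must be 'as_printed' or 'mixture'")


# ---------------------------------------------------------------------------
# enhancement efficiency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnhancementEfficiency:
    """DEF excess per nanoparticle volume-fraction percent."""

    chi: float
    ci95: float
    compartment: str = "cytoplasm"
    n: int = 0
    residual_ss: float = field(default=0.0, compare=False)

    def __post_init__(self):
        if self.ci95 < 0:
            raise DomainError("ci95 must be >= 0")


def chi_fit(
    def_values, vol_fractions, compartment: str = "cytoplasm"
) -> EnhancementEfficiency:
    """Through-origin least squares of (DEF - 1) on volume fraction (vol%).

    chi is the fitted slope; the 95% confidence half-width comes from the
    t distribution with n - 1 degrees of freedom.
    """
    d = np.asarray(def_values, dtype=float)
    f = np.asarray(vol_fractions, dtype=float)
    if d.shape != f.shape or d.ndim != 1 or d.size < 2:
        raise FitError("need >= 2 paired (DEF, vol%) points")
    if np.any(f < 0):
        raise DomainError("volume fractions must be >= 0")
    sxx = float(np.sum(f * f))
    if sxx == 0.0:
        raise FitError("all volume fractions are zero: degenerate design")
    y = d - 1.0
    slope = float(np.sum(f * y) / sxx)
    resid = y - slope * f
    n = d.size
    rss = float(np.sum(resid**2))
    se = np.sqrt(rss / (n - 1) / sxx)
    ci95 = float(stats.t.ppf(0.975, n - 1) * se)
    return EnhancementEfficiency(
        chi=slope, ci95=ci95, compartment=compartment, n=n, residual_ss=rss
    )
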