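"""Nanoparticle material registry and the unit/fraction conversions built on it.

All downstream analyses (analytic dose-enhancement factors, Monte-Carlo
geometry, ICP-MS volume fractions) funnel their unit handling through this
module: BET-equivalent diameters from specific surface area, mass/volume/
surface-area concentration conversions, sphere packing fractions, and metal
mass fractions from stoichiometry.

Conventions: densities g/cm^3, SSA m^2/g, diameters nm (except cell-scale
volumes, um), mass concentrations ug/mL, surface-area concentrations cm^2/mL,
fractions dimensionless unless a function name says percent.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

from .errors import DomainError

__all__ = [
    "ATOMIC_WEIGHTS",
    "MaterialSpec",
    "ConcentrationRecord",
    "REGISTRY",
    "get_material",
    "parse_formula",
    "bet_diameter",
    "mass_frac_to_vol_frac",
    "vol_frac_to_mass_frac",
    "surface_conc_to_mass_conc",
    "vesicle_packing_fraction",
    "sphere_volume",
    "metal_mass_fraction",
]

# IUPAC 2021 standard atomic weights (conventional values), g/mol
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Si": 28.085,
    "Ti": 47.867,
    "Fe": 55.845,
    "Hf": 178.486,
    "W": 183.84,
    "Au": 196.967,
}

# elements counted as "metal" when deriving per-cell nanoparticle mass from
# ICP-MS elemental masses
_NONMETALS = frozenset({"H", "C", "N", "O"})

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

# random close packing of equal spheres; packings above get a hard error,
# approaching it gets a warning from vesicle geometry builders
RANDOM_CLOSE_PACK_VOL_PERCENT = 74.0


def parse_formula(formula: str | dict[str, float]) -> dict[str, float]:
    """Parse 'HfO2' / 'TiN' style formulas into element -> count."""
    if isinstance(formula, dict):
        counts = dict(formula)
    else:
        counts = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if m.start() != pos:
                raise DomainError(f"cannot parse formula {formula!r}")
            pos = m.end()
            sym, num = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0.0) + (float(num) if num else 1.0)
        if pos != len(formula) or not counts:
            raise DomainError(f"cannot parse formula {formula!r}")
    for sym, n in counts.items():
        if sym not in ATOMIC_WEIGHTS:
            raise KeyError(f"unknown element symbol {sym!r}")
        if n <= 0:
            raise DomainError(f"stoichiometric count for {sym} must be > 0")
    return counts


@dataclass(frozen=True)
class MaterialSpec:
    """A nanoparticle core material.

    Parameters
    ----------
    name : registry label, also the default coefficient-table id.
    formula : stoichiometric composition, e.g. ``"HfO2"`` or ``{"Hf":1,"O":2}``.
    bulk_density : bulk density in g/cm^3.
    ssa : specific surface area in m^2/g (optional; required for
        surface-area-based concentration conversions).
    metal_elements : elements quantified by elemental analysis; defaults to
        every non-{H,C,N,O} element in the formula.
    """

    name: str
    formula: dict[str, float] = field(hash=False)
    bulk_density: float
    ssa: float | None = None
    metal_elements: tuple[str, ...] = ()
    coefficient_table_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "formula", parse_formula(self.formula))
        if self.bulk_density <= 0:
            raise DomainError("bulk_density must be > 0")
        if self.ssa is not None and self.ssa <= 0:
            raise DomainError("ssa must be > 0 when given")
        if not self.metal_elements:
            metals = tuple(s for s in self.formula if s not in _NONMETALS)
            object.__setattr__(self, "metal_elements", metals)
        for sym in self.metal_elements:
            if sym not in self.formula:
                raise DomainError(f"metal element {sym} not in formula")
        if self.coefficient_table_id is None:
            object.__setattr__(self, "coefficient_table_id", self.name)
        mf = self.metal_mass_fraction
        if not (0.0 < mf <= 1.0):
            raise DomainError("metal mass fraction must be in (0, 1]")

    @property
    def molar_mass(self) -> float:
        return sum(ATOMIC_WEIGHTS[s] * n for s, n in self.formula.items())

    @property
    def metal_mass_fraction(self) -> float:
        metal = sum(ATOMIC_WEIGHTS[s] * self.formula[s] for s in self.metal_elements)
        return metal / self.molar_mass

    @property
    def mass_fractions(self) -> dict[str, float]:
        mm = self.molar_mass
        return {s: ATOMIC_WEIGHTS[s] * n / mm for s, n in self.formula.items()}

    @property
    def bet_diameter_nm(self) -> float:
        if self.ssa is None:
            raise DomainError(f"material {self.name} has no SSA")
        return bet_diameter(self.ssa, self.bulk_density)


def _default_registry() -> dict[str, MaterialSpec]:
    # densities: conventional bulk values that reproduce the printed BET
    # diameters where checkable; SSA: nitrogen-adsorption values per material
    table = [
        ("SiO2", "SiO2", 2.65, 343.6),
        ("TiO2", "TiO2", 4.3, 235.0),
        ("TiN", "TiN", 5.40, 62.7),
        ("WO3", "WO3", 7.16, 78.6),
        ("HfO2", "HfO2", 9.68, 114.0),
        ("Au", "Au", 19.3, 5.9),
    ]
    return {
        name: MaterialSpec(name=name, formula=f, bulk_density=rho, ssa=ssa)
        for name, f, rho, ssa in table
    }


REGISTRY: dict[str, MaterialSpec] = _default_registry()


def get_material(name: str | MaterialSpec) -> MaterialSpec:
    if isinstance(name, MaterialSpec):
        return name
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; registry has {sorted(REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------


def bet_diameter(ssa: float, density: float) -> float:
    """BET-equivalent sphere diameter in nm, d = 6000/(SSA * rho)."""
    if ssa <= 0 or density <= 0:
        raise DomainError("ssa and density must be > 0")
    return 6000.0 / (ssa * density)


def mass_frac_to_vol_frac(
    wt: float,
    rho_np: float,
    rho_medium: float = 1.0,
    mode: str = "dilute",
) -> float:
    """Convert a mass fraction of nanoparticles to a volume fraction.

    ``dilute`` (default) uses wt * rho_medium / rho_np, the approximation
    under which 5 wt% Au in water corresponds to 0.26 vol%; ``exact`` uses the
    full two-component mixture formula.
    """
    if not 0.0 <= wt <= 1.0:
        raise DomainError("mass fraction must be within [0, 1]")
    if rho_np <= 0 or rho_medium <= 0:
        raise DomainError("densities must be > 0")
    if mode == "dilute":
        return wt * rho_medium / rho_np
    if mode == "exact":
        if wt == 0.0:
            return 0.0
        v_np = wt / rho_np
        v_med = (1.0 - wt) / rho_medium
        return v_np / (v_np + v_med)
    raise DomainError(f"unknown mode {mode!r}")


def vol_frac_to_mass_frac(vol: float, rho_np: float, rho_medium: float = 1.0) -> float:
    """Exact inverse of mass_frac_to_vol_frac(..., mode='exact')."""
    if not 0.0 <= vol <= 1.0:
        raise DomainError("volume fraction must be within [0, 1]")
    if rho_np <= 0 or rho_medium <= 0:
        raise DomainError("densities must be > 0")
    m_np = vol * rho_np
    m_med = (1.0 - vol) * rho_medium
    return m_np / (m_np + m_med)


def surface_conc_to_mass_conc(sa_conc: float, ssa: float) -> float:
    """cm^2/mL exposed surface -> ug/mL mass concentration: 100 * sa / SSA."""
    if ssa <= 0:
        raise DomainError("ssa must be > 0")
    if sa_conc < 0:
        raise DomainError("surface-area concentration must be >= 0")
    # sa_conc [cm^2/mL] / (ssa [m^2/g] * 1e4 [cm^2/m^2]) = g/mL / 1e-6 -> ug/mL
    return 100.0 * sa_conc / ssa


def vesicle_packing_fraction(n_np: int, d_np: float, d_vesicle: float) -> float:
    """Volume percent of a vesicle occupied by n_np spheres of diameter d_np."""
    if d_np <= 0 or d_vesicle <= d_np:
        raise DomainError("need d_vesicle > d_np > 0")
    if n_np < 0:
        raise DomainError("n_np must be >= 0")
    pf = 100.0 * n_np * (d_np / d_vesicle) ** 3
    if pf > 100.0:
        raise DomainError(
            f"packing fraction {pf:.1f} vol% exceeds 100%: geometrically impossible"
        )
    return pf


def sphere_volume(diameter: float) -> float:
    """Volume of a sphere from its diameter (pi/6 * d^3); unit-cubed of input."""
    if diameter <= 0:
        raise DomainError("diameter must be > 0")
    return math.pi / 6.0 * diameter**3


def metal_mass_fraction(material: str | MaterialSpec) -> float:
    """Mass fraction of the quantified metal elements in the particle."""
    return get_material(material).metal_mass_fraction


# ---------------------------------------------------------------------------
# concentration record
# ---------------------------------------------------------------------------

_BASES = ("mass_ug_mL", "surface_cm2_mL", "wt_percent", "vol_percent")


@dataclass(frozen=True)
class ConcentrationRecord:
    """A nanoparticle concentration in one of four interchangeable bases.

    Conversions assume a dilute aqueous suspension (1 mL = 1 g of medium),
    the regime of every assay this package models; they round-trip to better
    than 1e-9 relative.
    """

    basis: str
    value: float
    material: MaterialSpec

    def __post_init__(self):
        if self.basis not in _BASES:
            raise DomainError(f"basis must be one of {_BASES}")
        if self.value < 0:
            raise DomainError("concentration must be >= 0")

    def as_mass_ug_mL(self) -> float:
        v, m = self.value, self.material
        if self.basis == "mass_ug_mL":
            return v
        if self.basis == "surface_cm2_mL":
            return surface_conc_to_mass_conc(v, m.ssa if m.ssa else -1.0)
        if self.basis == "wt_percent":
            return v * 1e4  # 1 wt% of 1 g/mL medium = 10 mg/mL
        return v / 100.0 * m.bulk_density * 1e6  # vol_percent

    def to(self, basis: str) -> "ConcentrationRecord":
        mass = self.as_mass_ug_mL()
        m = self.material
        if basis == "mass_ug_mL":
            value = mass
        elif basis == "surface_cm2_mL":
            if m.ssa is None:
                raise DomainError(f"material {m.name} has no SSA")
            value = mass * m.ssa / 100.0
        elif basis == "wt_percent":
            value = mass * 1e-4
        elif basis == "vol_percent":
            value = mass / (m.bulk_density * 1e6) * 100.0
        else:
            raise DomainError(f"basis must be one of {_BASES}")
        return ConcentrationRecord(basis=basis, value=value, material=m)
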