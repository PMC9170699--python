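"""Seeded generators emulating every experimental input of the pipeline.

Each generator is a pure function of its configuration (including the seed):
the same ``GeneratorConfig`` always produces the same tables. The emulated
design mirrors the in-vitro study conditions: 48-well plates with 2000 cells
seeded per well, nanoparticle conditions in triplicate and controls in
sextuplicate, doses {0, 2, 4, 6, 8} Gy, a DMSO grid {0, 0.11, 0.334, 0.667,
1} M in quadruplicate over two batches, an acellular ROS design with
constant exposed surface areas {36.8, 368, 1840} cm^2/mL in sextuplicate,
and saturating per-cell metal uptake.

Ground truths are explicit: a per-material dose-scaling factor k (the DMR
the pipeline should recover), an indirect-damage fraction phi (the share of
the nanoparticle enhancement quenchable by hydroxyl-radical scavenging), a
linear DEF_ROS slope per surface-area concentration, Hill-type uptake
parameters, and a sigmoid toxicity with a known LC50. Measurement noise is
multiplicative lognormal with a default 5% coefficient of variation, the
plate-reader repeatability achieved with the crosstalk adapter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError
from .survival import StandardCurve

__all__ = [
    "MaterialTruth",
    "GeneratorConfig",
    "dmso_protection",
    "gen_survival_plate",
    "gen_quench_plate",
    "gen_ros_plate",
    "gen_uptake_table",
    "gen_spectrum_fixture",
    "truth_for_ner_pair",
    "expected_ner",
    "expected_dop",
]


@dataclass(frozen=True)
class MaterialTruth:
    """Ground-truth behaviour of one nanoparticle material."""

    k_max: float = 1.5  # dose-scaling factor at the highest concentration
    phi: float = 0.5  # DMSO-quenchable fraction of the enhancement, [0, 1]
    lc50_ug_mL: float = 1.0e4  # sham-toxicity LC50
    tox_b: float = 0.03  # sigmoid steepness, 1/(ug/mL)
    ros_slope: float = 0.0  # DEF_ROS excess per cm^2/mL
    uptake_A: float = 1.0  # plateau ng metal per cell
    uptake_B: float = 60.0  # half-saturation ug/mL
    uptake_p: float = 1.5
    concentrations: tuple = (20.0, 40.0, 80.0, 160.0, 320.0)
    quench_conc: float = 160.0

    def __post_init__(self):
        if self.k_max < 1.0:
            raise DomainError("k_max must be >= 1")
        if not 0.0 <= self.phi <= 1.0:
            raise DomainError("phi must be within [0, 1]")

    def k_at(self, conc: float) -> float:
        """Dose-scaling factor at a nominal concentration (linear in conc)."""
        cmax = max(self.concentrations)
        return 1.0 + (self.k_max - 1.0) * conc / cmax

    def viability_at(self, conc: float) -> float:
        a = math.exp(self.tox_b * self.lc50_ug_mL)
        return 1.0 - 1.0 / (1.0 + a * math.exp(-self.tox_b * conc))


def _default_materials() -> dict[str, MaterialTruth]:
    # mirrors the observed kV trends: Au strongest DMR, then HfO2; ROS slopes
    # WO3 > TiO2 > HfO2; TiN toxic (LC50 157 ug/mL) and fully quenchable;
    # SiO2 inert negative control
    return {
        "SiO2": MaterialTruth(k_max=1.0, phi=0.0, ros_slope=0.0),
        "TiO2": MaterialTruth(k_max=1.5, phi=0.73, ros_slope=8.0e-4),
        "TiN": MaterialTruth(
            k_max=1.3, phi=1.0, lc50_ug_mL=157.0, ros_slope=0.0, quench_conc=80.0
        ),
        "WO3": MaterialTruth(k_max=1.45, phi=0.0, ros_slope=1.0e-3),
        "HfO2": MaterialTruth(k_max=2.0, phi=0.52, ros_slope=4.0e-4, quench_conc=320.0),
        "Au": MaterialTruth(
            k_max=3.0,
            phi=0.34,
            ros_slope=0.0,
            concentrations=(5.0, 10.0, 20.0, 40.0),
            quench_conc=40.0,
            uptake_A=1.2,
            uptake_B=20.0,
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """All ground truths and design constants for the synthetic study."""

    seed: int = 7
    alpha0: float = 0.03  # 1/Gy, control radiosensitivity
    beta0: float = 0.004  # 1/Gy^2
    cells0: float = 30_000.0  # 0 Gy control cell count at readout
    doses_Gy: tuple = (0.0, 2.0, 4.0, 6.0, 8.0)
    dmso_grid_M: tuple = (0.0, 0.11, 0.334, 0.667, 1.0)
    sa_grid_cm2_mL: tuple = (36.8, 368.0, 1840.0)
    n_replicates: int = 3
    n_control_replicates: int = 6
    n_quench_replicates: int = 4
    n_ros_replicates: int = 6
    n_uptake_replicates: int = 4
    n_batches: int = 2
    cv: float = 0.05  # plate-reader CV (with adapter)
    cv_uptake: float = 0.15
    ros_baseline_fi: float = 100.0
    ros_gain_fi: float = 200.0
    uptake_cells_counted: float = 3.0e5
    materials: dict[str, MaterialTruth] = field(default_factory=_default_materials)
    standard_curve: StandardCurve = field(default_factory=StandardCurve)

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def _rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([cfg.seed, stream])))


def _noise(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Mean-preserving multiplicative lognormal factors."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    s = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def dmso_protection(dmso_M: float) -> float:
    """Fraction of the quenchable effect realized at a DMSO concentration.

    Saturating-exponential shape reaching exactly 1 at >= 0.5 M, where the
    protective effect plateaus experimentally.
    """
    if dmso_M < 0:
        raise DomainError("DMSO concentration must be >= 0")
    return min(1.0, (1.0 - math.exp(-5.0 * dmso_M)) / (1.0 - math.exp(-2.5)))


def _sf(cfg: GeneratorConfig, dose: float, k: float) -> float:
    d = k * dose
    return math.exp(-(cfg.alpha0 * d + cfg.beta0 * d * d))


def _k_eff(truth: MaterialTruth, conc: float, dmso_M: float) -> float:
    k = truth.k_at(conc)
    return 1.0 + (k - 1.0) * (1.0 - truth.phi * dmso_protection(dmso_M))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_survival_plate(cfg: GeneratorConfig) -> pd.DataFrame:
    """Dose-response plate: luminescence per well for NP conditions + controls."""
    rng = _rng(cfg, 1)
    rows = []
    for batch in range(1, cfg.n_batches + 1):
        for dose in cfg.doses_Gy:
            sf = _sf(cfg, dose, 1.0)
            for rep in range(1, cfg.n_control_replicates + 1):
                cells = cfg.cells0 * sf * _noise(rng, cfg.cv, None)
                rows.append((batch, "none", 0.0, dose, 0.0, rep, cells))
        for mat, truth in cfg.materials.items():
            for conc in truth.concentrations:
                viab = truth.viability_at(conc)
                k = truth.k_at(conc)
                for dose in cfg.doses_Gy:
                    sf = _sf(cfg, dose, k)
                    for rep in range(1, cfg.n_replicates + 1):
                        cells = cfg.cells0 * viab * sf * _noise(rng, cfg.cv, None)
                        rows.append((batch, mat, conc, dose, 0.0, rep, cells))
    df = pd.DataFrame(
        rows,
        columns=[
            "batch", "material", "conc_ug_mL", "dose_Gy", "dmso_M",
            "replicate", "cells",
        ],
    )
    df["luminescence"] = cfg.standard_curve.to_luminescence(df.pop("cells").to_numpy())
    return df


def gen_quench_plate(cfg: GeneratorConfig, quench_dose_Gy: float = 6.0) -> pd.DataFrame:
    """Radical-quenching plate: 0/6 Gy across the DMSO grid, NP + control wells.

    Control wells keep k = 1 at every DMSO level; nanoparticle wells scale
    the NP-attributable dose enhancement by (1 - phi * protection(dmso)).
    """
    rng = _rng(cfg, 4)
    rows = []
    for batch in range(1, cfg.n_batches + 1):
        for dmso in cfg.dmso_grid_M:
            for dose in (0.0, quench_dose_Gy):
                sf = _sf(cfg, dose, 1.0)
                for rep in range(1, cfg.n_quench_replicates + 1):
                    cells = cfg.cells0 * sf * _noise(rng, cfg.cv, None)
                    rows.append((batch, "none", 0.0, dose, dmso, rep, cells))
            for mat, truth in cfg.materials.items():
                conc = truth.quench_conc
                viab = truth.viability_at(conc)
                k = _k_eff(truth, conc, dmso)
                for dose in (0.0, quench_dose_Gy):
                    sf = _sf(cfg, dose, k)
                    for rep in range(1, cfg.n_quench_replicates + 1):
                        cells = cfg.cells0 * viab * sf * _noise(rng, cfg.cv, None)
                        rows.append((batch, mat, conc, dose, dmso, rep, cells))
    df = pd.DataFrame(
        rows,
        columns=[
            "batch", "material", "conc_ug_mL", "dose_Gy", "dmso_M",
            "replicate", "cells",
        ],
    )
    df["luminescence"] = cfg.standard_curve.to_luminescence(df.pop("cells").to_numpy())
    return df


def gen_ros_plate(cfg: GeneratorConfig, dose_Gy: float = 12.0) -> pd.DataFrame:
    """Acellular DCF plate pair: 0 Gy reference and irradiated fluorescence."""
    rng = _rng(cfg, 2)
    rows = []
    base, gain = cfg.ros_baseline_fi, cfg.ros_gain_fi
    for rep in range(1, cfg.n_ros_replicates + 1):
        rows.append(("none", 0.0, 0.0, rep, base * _noise(rng, cfg.cv, None)))
        rows.append(
            ("none", 0.0, dose_Gy, rep, (base + gain) * _noise(rng, cfg.cv, None))
        )
    for mat, truth in cfg.materials.items():
        for sa in cfg.sa_grid_cm2_mL:
            enh = 1.0 + truth.ros_slope * sa
            for rep in range(1, cfg.n_ros_replicates + 1):
                rows.append((mat, sa, 0.0, rep, base * _noise(rng, cfg.cv, None)))
                rows.append(
                    (mat, sa, dose_Gy, rep,
                     (base + gain * enh) * _noise(rng, cfg.cv, None))
                )
    return pd.DataFrame(
        rows, columns=["material", "sa_conc_cm2_mL", "dose_Gy", "replicate", "fi"]
    )


def gen_uptake_table(cfg: GeneratorConfig) -> pd.DataFrame:
    """ICP-MS style table of total metal mass and pooled cell counts."""
    rng = _rng(cfg, 3)
    rows = []
    for mat, truth in cfg.materials.items():
        for conc in truth.concentrations:
            ng_cell = (
                truth.uptake_A
                * conc**truth.uptake_p
                / (truth.uptake_B**truth.uptake_p + conc**truth.uptake_p)
            )
            for rep in range(1, cfg.n_uptake_replicates + 1):
                total = ng_cell * cfg.uptake_cells_counted * _noise(
                    rng, cfg.cv_uptake, None
                )
                rows.append((mat, conc, rep, total, cfg.uptake_cells_counted))
    return pd.DataFrame(
        rows,
        columns=["material", "conc_ug_mL", "replicate", "metal_ng_total",
                 "cells_counted"],
    )


def gen_spectrum_fixture(n_lines: int = 2) -> "pd.DataFrame":
    """Tiny two-column spectrum table usable as a CSV fixture."""
    e = np.linspace(50.0, 100.0, n_lines)
    return pd.DataFrame({"energy_keV": e, "weight": np.ones_like(e)})


# ---------------------------------------------------------------------------
# closed-form expectations (oracles for round-trip tests)
# ---------------------------------------------------------------------------


def expected_ner(cfg: GeneratorConfig, material: str, dmso_M: float,
                 dose_Gy: float = 6.0) -> float:
    """Noise-free NER the quench plate encodes at one DMSO level."""
    truth = cfg.materials[material]
    k = _k_eff(truth, truth.quench_conc, dmso_M)
    return _sf(cfg, dose_Gy, 1.0) / _sf(cfg, dose_Gy, k)


def expected_dop(cfg: GeneratorConfig, material: str, dmso_M: float = 1.0,
                 dose_Gy: float = 6.0) -> float:
    """Noise-free DoP implied by the generator's k and phi."""
    n0 = expected_ner(cfg, material, 0.0, dose_Gy)
    n1 = expected_ner(cfg, material, dmso_M, dose_Gy)
    if n0 <= 1.0:
        raise DomainError("no enhancement without DMSO: DoP undefined")
    return 1.0 - (n1 - 1.0) / (n0 - 1.0)


def truth_for_ner_pair(
    ner_no_dmso: float,
    ner_full_dmso: float,
    alpha0: float = 0.03,
    beta0: float = 0.004,
    dose_Gy: float = 6.0,
) -> tuple[float, float]:
    """(k, phi) that reproduce a printed NER pair at full protection.

    Solves alpha*k*D + beta*(k*D)^2 = alpha*D + beta*D^2 + ln(NER) for each
    NER, then phi = 1 - (k_full - 1)/(k_no - 1).
    """
    if ner_full_dmso > ner_no_dmso or ner_no_dmso <= 1.0:
        raise DomainError("need NER_noDMSO > max(1, NER_DMSO)")

    def k_for(ner_val: float) -> float:
        target = alpha0 * dose_Gy + beta0 * dose_Gy**2 + math.log(ner_val)
        a, b = beta0 * dose_Gy**2, alpha0 * dose_Gy
        # a k^2 + b k - target = 0
        return (-b + math.sqrt(b * b + 4 * a * target)) / (2 * a)

    k = k_for(ner_no_dmso)
    k_full = k_for(ner_full_dmso)
    phi = 1.0 - (k_full - 1.0) / (k - 1.0)
    return k, min(max(phi, 0.0), 1.0)
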