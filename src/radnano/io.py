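"""Readers, writers and run configuration.

CSV conventions: comma separated, ``.`` decimal, mandatory header row, units
in the column names, unknown columns preserved. Parsing is header-keyed, so
column order is irrelevant; malformed rows are rejected with their line
numbers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import DomainError, FormatError

__all__ = [
    "SCHEMAS",
    "read_plate",
    "write_tables",
    "load_run_config",
    "config_hash",
]

SCHEMAS: dict[str, tuple[str, ...]] = {
    "survival": (
        "batch", "material", "conc_ug_mL", "dose_Gy", "dmso_M",
        "replicate", "luminescence",
    ),
    "ros": ("material", "sa_conc_cm2_mL", "dose_Gy", "replicate", "fi"),
    "uptake": (
        "material", "conc_ug_mL", "replicate", "metal_ng_total", "cells_counted",
    ),
    "spectrum": ("energy_keV", "weight"),
}

_STRING_COLS = {"material"}


def read_plate(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Numeric columns must parse as numbers in every row; offending rows are
    reported with their (1-based, header-inclusive) line numbers.
    """
    if schema not in SCHEMAS:
        raise DomainError(f"unknown schema {schema!r}; have {sorted(SCHEMAS)}")
    required = SCHEMAS[schema]
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse CSV {path}: {exc}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    out = df.copy()
    bad: list[int] = []
    for col in required:
        if col in _STRING_COLS:
            continue
        vals = pd.to_numeric(out[col], errors="coerce")
        bad.extend((out.index[vals.isna() & out[col].notna()] + 2).tolist())
        out[col] = vals
    if bad:
        raise FormatError(
            f"{path}: non-numeric values on line(s) {sorted(set(bad))[:20]}"
        )
    if out[list(required)].isna().any().any():
        rows = (out.index[out[list(required)].isna().any(axis=1)] + 2).tolist()
        raise FormatError(f"{path}: empty required cells on line(s) {rows[:20]}")
    # duplicate well keys are ambiguous measurements
    key_cols = [c for c in required if c not in ("luminescence", "fi",
                                                 "metal_ng_total",
                                                 "cells_counted", "weight")]
    if key_cols and out.duplicated(subset=key_cols).any():
        rows = (out.index[out.duplicated(subset=key_cols)] + 2).tolist()
        raise FormatError(f"{path}: duplicate well keys on line(s) {rows[:20]}")
    return out


def write_tables(tables: dict[str, pd.DataFrame], outdir, provenance: dict | None = None) -> list[Path]:
    """Write each table as <name>.csv plus a provenance JSON block."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    if provenance is not None:
        p = outdir / "provenance.json"
        p.write_text(json.dumps(provenance, indent=2, sort_keys=True, default=str))
        written.append(p)
    return written


def load_run_config(path) -> dict:
    """Load a YAML (or JSON) run configuration and validate its shape."""
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse config {path}: {exc}") from None
    if not isinstance(cfg, dict):
        raise FormatError("run configuration must be a mapping")
    materials = cfg.get("materials", {})
    if not isinstance(materials, dict):
        raise FormatError("'materials' section must map names to properties")
    for name, props in materials.items():
        if not isinstance(props, dict) or "formula" not in props or (
            "density_g_cm3" not in props
        ):
            raise FormatError(
                f"material {name!r} needs at least 'formula' and 'density_g_cm3'"
            )
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration for provenance blocks."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
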