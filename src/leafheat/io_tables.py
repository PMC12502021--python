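"""Read, validate and write the pipeline's tabular formats.

All interchange is plain CSV (RFC 4180, "." decimal separator) with a JSON
sidecar for run provenance.  Each reader validates its schema strictly by
default: rows violating an invariant are collected with their file line
numbers and the load aborts with a report; lenient mode drops violators with
a logged count instead.  Unrecognised columns are ignored with a notice.
"""

from __future__ import annotations

import datetime
import json
import logging
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LIPID_CLASSES = ("MGDG", "DGDG", "PG", "SQDG")

#: measured leaf temperatures must fall in this sanity window (degC)
TEMPERATURE_WINDOW = (10.0, 70.0)
LEAF_TEMP_WINDOW = (0.0, 70.0)


class SchemaError(ValueError):
    """A required column is missing or the file is empty."""


class ValidationError(ValueError):
    """One or more rows violate a table invariant (strict mode)."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        preview = "\n  ".join(violations[:20])
        more = "" if len(violations) <= 20 else f"\n  ... and {len(violations) - 20} more"
        super().__init__(f"{len(violations)} invalid row(s):\n  {preview}{more}")


def _load_csv(path, required: tuple[str, ...], optional: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in required + optional]
    if extra:
        logger.info("%s: ignoring unrecognised column(s): %s", path, ", ".join(extra))
        df = df.drop(columns=extra)
    return df


def _apply_checks(df: pd.DataFrame, checks, path, strict: bool) -> pd.DataFrame:
    """Run (mask, message) checks; report offenders by 1-based file line."""
    violations: list[str] = []
    bad = np.zeros(len(df), dtype=bool)
    for mask, message in checks:
        mask = np.asarray(mask, dtype=bool)
        for i in np.flatnonzero(mask):
            violations.append(f"line {i + 2}: {message}")
        bad |= mask
    if violations:
        if strict:
            raise ValidationError(violations)
        logger.warning("%s: dropping %d invalid row(s) (lenient mode)", path, int(bad.sum()))
        df = df.loc[~bad].reset_index(drop=True)
    return df


def read_fluorescence_table(path, strict: bool = True) -> pd.DataFrame:
    """Leaf-level Fv/Fm observations with per-leaf ambient controls."""
    df = _load_csv(
        path,
        required=("species", "site", "leaf_id", "temperature", "fvfm", "control_fvfm"),
        optional=("tree_id", "protocol", "recovery_hours"),
    )
    if "protocol" not in df.columns:
        df["protocol"] = "direct"
    lo, hi = TEMPERATURE_WINDOW
    checks = [
        (~df["fvfm"].between(0.0, 1.0), "fvfm outside [0, 1]"),
        (~(df["control_fvfm"].gt(0.0) & df["control_fvfm"].le(1.0)), "control_fvfm outside (0, 1]"),
        (~df["temperature"].between(lo, hi), f"temperature outside [{lo:g}, {hi:g}] degC"),
        (~df["protocol"].isin(["direct", "recovered"]), "protocol not in {direct, recovered}"),
    ]
    return _apply_checks(df, checks, path, strict)


def read_leaf_temperature_table(path, strict: bool = True) -> pd.DataFrame:
    """Midday leaf temperatures of sun-exposed leaves per species-site."""
    df = _load_csv(
        path, required=("species", "site", "leaf_temperature"), optional=("campaign",)
    )
    if "campaign" not in df.columns:
        df["campaign"] = "default"
    lo, hi = LEAF_TEMP_WINDOW
    checks = [
        (~df["leaf_temperature"].between(lo, hi), f"leaf_temperature outside [{lo:g}, {hi:g}] degC"),
    ]
    return _apply_checks(df, checks, path, strict)


def read_lipid_table(path, strict: bool = True) -> pd.DataFrame:
    """Lipid molecular-species abundances per class and species-site.

    Molecular species may arrive either as separate ``acyl_carbons`` /
    ``double_bonds`` columns or as a single ``lipid_species`` column in the
    conventional "carbons:double bonds" notation (e.g. ``36:6``).
    """
    df = _load_csv(
        path,
        required=("species", "site", "lipid_class", "abundance"),
        optional=("acyl_carbons", "double_bonds", "lipid_species"),
    )
    if "acyl_carbons" not in df.columns or "double_bonds" not in df.columns:
        if "lipid_species" not in df.columns:
            raise SchemaError(
                f"{path}: need either lipid_species or acyl_carbons + double_bonds columns"
            )
        parts = df["lipid_species"].astype(str).str.split(":", expand=True)
        if parts.shape[1] != 2:
            raise SchemaError(f"{path}: lipid_species must use 'carbons:double_bonds' notation")
        df["acyl_carbons"] = pd.to_numeric(parts[0], errors="coerce")
        df["double_bonds"] = pd.to_numeric(parts[1], errors="coerce")
    checks = [
        (
            ~df["lipid_class"].isin(LIPID_CLASSES),
            f"unknown lipid class (allowed: {', '.join(LIPID_CLASSES)})",
        ),
        (~(df["double_bonds"] >= 0), "double_bonds must be >= 0"),
        (~(df["acyl_carbons"] > 0), "acyl_carbons must be positive"),
        (~(df["abundance"] >= 0), "abundance must be non-negative"),
    ]
    return _apply_checks(df, checks, path, strict)


TRAIT_COLUMNS = (
    "leaf_area", "gs", "lma", "growth_temperature", "max_air_temperature",
    "osmolality",
)


def read_trait_table(path, strict: bool = True) -> pd.DataFrame:
    """Species-site trait means; trait columns are individually optional.

    Missing trait columns load fine — downstream regressions report the
    trait as not available.  Present values must be strictly positive.
    """
    df = _load_csv(path, required=("species", "site"), optional=TRAIT_COLUMNS)
    present = [c for c in TRAIT_COLUMNS if c in df.columns]
    absent = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if absent:
        logger.info("%s: trait column(s) not available: %s", path, ", ".join(absent))
    checks = [
        (df[c].notna() & ~(df[c] > 0), f"{c} must be strictly positive where present")
        for c in present
    ]
    return _apply_checks(df, checks, path, strict)


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a pipeline table as CSV (no index column)."""
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc
    return path


def write_run_metadata(path, config: dict, seed: int | None = None) -> Path:
    """JSON sidecar recording config, seed, software version and timestamp."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        version = metadata.version("leafheat")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    payload = {
        "config": config,
        "seed": seed,
        "software": {"name": "leafheat", "version": version},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return path


def write_results(results: dict[str, pd.DataFrame], outdir, config: dict | None = None,
                  seed: int | None = None) -> dict[str, Path]:
    """Write a named set of result tables plus the provenance sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in results.items():
        written[name] = write_table(df, outdir / f"{name}.csv")
    written["metadata"] = write_run_metadata(outdir / "run_metadata.json", config or {}, seed)
    return written
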