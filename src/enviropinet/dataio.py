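"""Reading, validation, harmonization and splitting of observation tables.

An observation table is a plain :class:`pandas.DataFrame` with one row per
(biofilter, time) sample: a ``study_id`` column, an optional
``sample_time`` column (days), and one column per configured physical
variable, stored in canonical units after ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .dimensions import DimensionalAnalysisError, VariableSpec

__all__ = [
    "META_COLUMNS",
    "load_units_config",
    "biofilter_specs",
    "biofilter_repeating",
    "read_observations",
    "write_observations",
    "drop_incomplete",
    "SplitSpec",
    "split_by_study",
    "Standardizer",
    "fit_standardizer",
    "apply_standardizer",
]

logger = logging.getLogger(__name__)

#: Non-physical columns an observation table may carry.
META_COLUMNS = ("study_id", "sample_time")


def _parse_fraction(x) -> Fraction:
    return Fraction(str(x))


def load_units_config(path: str | Path) -> tuple[list[VariableSpec], list[str]]:
    """Load variable specs from a YAML units/dimensions config.

    Returns ``(specs, repeating)`` where ``repeating`` lists the preferred
    pivot variables (may be empty).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _specs_from_mapping(raw)


def _specs_from_mapping(raw: dict) -> tuple[list[VariableSpec], list[str]]:
    if not isinstance(raw, dict) or "variables" not in raw:
        raise ValueError("units config must contain a 'variables' mapping")
    specs = []
    for sym, cfg in raw["variables"].items():
        cfg = cfg or {}
        dims = {d: _parse_fraction(e) for d, e in (cfg.get("dimensions") or {}).items()}
        specs.append(
            VariableSpec(
                symbol=str(sym),
                dimensions=dims,
                role=cfg.get("role", "independent"),
                unit=cfg.get("unit", ""),
                description=cfg.get("description", ""),
                scale=float(cfg.get("scale", 1.0)),
                offset=float(cfg.get("offset", 0.0)),
            )
        )
    repeating = [str(s) for s in (raw.get("repeating") or [])]
    return specs, repeating


def _default_config() -> dict:
    ref = resources.files("enviropinet.data") / "biofilter_units.yaml"
    return yaml.safe_load(ref.read_text())


def biofilter_specs() -> list[VariableSpec]:
    """The nine default biofilter variable specs (canonical units)."""
    return _specs_from_mapping(_default_config())[0]


def biofilter_repeating() -> list[str]:
    """Default repeating (pivot-preferred) variables for the biofilter system."""
    return _specs_from_mapping(_default_config())[1]


def read_observations(
    path: str | Path,
    specs: Sequence[VariableSpec] | None = None,
) -> pd.DataFrame:
    """Read a CSV of observations and convert values to canonical units.

    Every configured variable must appear as a column; unknown columns are
    rejected.  Unparseable cells become missing (NaN) and are handled later
    by :func:`drop_incomplete`.  Row order is preserved.
    """
    specs = list(specs) if specs is not None else biofilter_specs()
    df = pd.read_csv(path)
    symbols = [s.symbol for s in specs]
    unknown = [c for c in df.columns if c not in symbols and c not in META_COLUMNS]
    if unknown:
        raise ValueError(f"unknown column(s) in {path}: {unknown}")
    present = [s for s in symbols if s in df.columns]
    if not present:
        raise ValueError(f"no recognizable variable columns in {path}")
    missing = [s for s in symbols if s not in df.columns]
    if missing:
        raise ValueError(f"configured variable column(s) missing from {path}: {missing}")
    out = pd.DataFrame(index=df.index)
    out["study_id"] = (
        df["study_id"].astype(str) if "study_id" in df.columns else "study_1"
    )
    if "sample_time" in df.columns:
        out["sample_time"] = pd.to_numeric(df["sample_time"], errors="coerce")
    for s in specs:
        raw = pd.to_numeric(df[s.symbol], errors="coerce")
        out[s.symbol] = raw * s.scale + s.offset
    return out


def write_observations(
    table: pd.DataFrame,
    path: str | Path,
    specs: Sequence[VariableSpec] | None = None,
) -> None:
    """Write a table back to CSV in the configured *input* units, so that
    ``read_observations(write_observations(t))`` round-trips."""
    specs = list(specs) if specs is not None else biofilter_specs()
    out = pd.DataFrame(index=table.index)
    for c in META_COLUMNS:
        if c in table.columns:
            out[c] = table[c]
    for s in specs:
        out[s.symbol] = (table[s.symbol] - s.offset) / s.scale
    out.to_csv(path, index=False)


def drop_incomplete(
    table: pd.DataFrame,
    symbols: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Drop rows missing any variable, or with non-positive values.

    Positivity is required because every downstream transform (pi-group
    powers, log-space regression) is undefined at zero or below.  Returns
    the retained table and the number of rows removed.
    """
    if symbols is None:
        symbols = [s.symbol for s in biofilter_specs()]
    vals = table[list(symbols)].apply(pd.to_numeric, errors="coerce")
    keep = (np.isfinite(vals) & (vals > 0)).all(axis=1)
    dropped = int((~keep).sum())
    kept = table.loc[keep].copy()
    if len(kept) == 0:
        raise ValueError(
            f"all {len(table)} rows dropped as incomplete or non-positive"
        )
    if dropped:
        logger.info("dropped %d incomplete row(s), retained %d", dropped, len(kept))
    return kept, dropped


@dataclass(frozen=True)
class SplitSpec:
    """Study-based train/test split.

    All test rows come from ``holdout_study``; ``train_quota`` rows of that
    study are moved into training by a seeded random draw (mirroring a
    combined multi-study training set that includes part of the held-out
    study's time series).
    """

    holdout_study: str
    train_quota: int = 0
    seed: int = 0


def split_by_study(
    table: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition rows into train and test per a :class:`SplitSpec`."""
    studies = table["study_id"].astype(str)
    mask = studies == str(spec.holdout_study)
    n_holdout = int(mask.sum())
    if n_holdout == 0:
        raise ValueError(f"held-out study {spec.holdout_study!r} not present")
    if not 0 <= spec.train_quota <= n_holdout:
        raise ValueError(
            f"train_quota {spec.train_quota} exceeds held-out study size {n_holdout}"
        )
    rng = np.random.default_rng(spec.seed)
    holdout_idx = table.index[mask]
    promoted = rng.choice(holdout_idx, size=spec.train_quota, replace=False)
    promoted_set = set(promoted.tolist())
    test_set = {i for i in holdout_idx if i not in promoted_set}
    test_idx = [i for i in table.index if i in test_set]
    train_idx = [i for i in table.index if i not in test_set]
    train = table.loc[train_idx].copy()
    test = table.loc[test_idx].copy()
    return train, test


@dataclass(frozen=True)
class Standardizer:
    """Per-feature location/scale estimated on training data only.

    Uses the population standard deviation (``n`` divisor) so that the
    transformed training set has exactly unit variance.
    """

    mean: pd.Series
    sd: pd.Series

    @property
    def columns(self) -> list[str]:
        return list(self.mean.index)

    def inverse(self, z: pd.DataFrame) -> pd.DataFrame:
        return z[self.columns] * self.sd + self.mean


def fit_standardizer(features: pd.DataFrame) -> Standardizer:
    """Estimate per-column mean and population SD; reject degenerate columns."""
    if len(features) < 2:
        raise ValueError("standardizer needs at least 2 rows")
    x = features.apply(pd.to_numeric)
    mean = x.mean()
    sd = x.std(ddof=0)
    zero = [c for c in x.columns if sd[c] == 0 or not np.isfinite(sd[c])]
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    return Standardizer(mean=mean, sd=sd)


def apply_standardizer(std: Standardizer, features: pd.DataFrame) -> pd.DataFrame:
    """Apply fitted parameters; never re-estimates on the given data."""
    missing = [c for c in std.columns if c not in features.columns]
    if missing:
        raise ValueError(f"features missing column(s) {missing}")
    return (features[std.columns] - std.mean) / std.sd
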