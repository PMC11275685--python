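"""Readers and writers for the cohort-table dialect and model containers.

The table dialect is comma-separated UTF-8 with a header row and a fixed
column order: SampleID, Sex (F/M), Race (White/Black/Asian), Age
(floating-point years), optional Group (CN/MCI/AD) and Cognition (0-30),
then the 145 ROI volume columns in dictionary order.  A fitted model
directory holds one JSON container per stratum plus a manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import (
    AGE_COLUMN,
    COGNITION_COLUMN,
    GROUP_COLUMN,
    GROUPS,
    ID_COLUMN,
    RACE_COLUMN,
    RACES,
    ROI_NAMES,
    SEX_COLUMN,
    SEXES,
    STRATA,
)
from .kde import StratumKernelDensity

logger = logging.getLogger(__name__)

_DEMOGRAPHIC = [ID_COLUMN, SEX_COLUMN, RACE_COLUMN, AGE_COLUMN]
_OPTIONAL = [GROUP_COLUMN, COGNITION_COLUMN]


class SchemaError(ValueError):
    """A cohort file violates the table dialect."""


def read_cohort(path, rename: dict | None = None,
                roi_names: list | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    ``rename`` maps the file's column labels onto the packaged dictionary
    names (for users whose atlas export labels differ); ``roi_names``
    overrides the expected ROI set (reduced-dimension tables).
    Raises :class:`SchemaError` naming the offending column or data row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if rename:
        df = df.rename(columns=rename)
    expected_roi = list(roi_names) if roi_names is not None else list(ROI_NAMES)

    missing = [c for c in _DEMOGRAPHIC + expected_roi if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing[:5]}")
    extra = [c for c in df.columns
             if c not in _DEMOGRAPHIC + _OPTIONAL + expected_roi]
    if extra:
        raise SchemaError(f"{path.name}: unexpected column(s) {extra[:5]}")

    def bad_rows(mask) -> str:
        # +2: header line and 1-based numbering
        lines = [str(i + 2) for i in df.index[mask][:5]]
        return ", ".join(lines)

    for col, domain in ((SEX_COLUMN, SEXES), (RACE_COLUMN, RACES)):
        bad = ~df[col].isin(domain)
        if bad.any():
            raise SchemaError(
                f"{path.name}: invalid {col} value(s) "
                f"{sorted(df.loc[bad, col].unique())[:3]} at line(s) {bad_rows(bad)}"
            )
    if GROUP_COLUMN in df.columns:
        bad = ~df[GROUP_COLUMN].isin(GROUPS)
        if bad.any():
            raise SchemaError(f"{path.name}: invalid Group value(s) at "
                              f"line(s) {bad_rows(bad)}")

    numeric = [AGE_COLUMN] + expected_roi
    if COGNITION_COLUMN in df.columns:
        numeric.append(COGNITION_COLUMN)
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | np.isinf(vals)
        if bad.any():
            raise SchemaError(f"{path.name}: non-numeric or non-finite "
                              f"{col!r} at line(s) {bad_rows(bad)}")
        df[col] = vals
    if df[ID_COLUMN].duplicated().any():
        raise SchemaError(f"{path.name}: duplicate SampleID values")

    order = _DEMOGRAPHIC + [c for c in _OPTIONAL if c in df.columns] + expected_roi
    df = df[order]
    logger.info("read %s: %d rows, %d columns", path.name, *df.shape)
    return df


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as comma-separated UTF-8 with a header row,
    fixed column order and full floating-point precision."""
    path = Path(path)
    order = [c for c in _DEMOGRAPHIC + _OPTIONAL if c in table.columns]
    order += [c for c in table.columns if c not in order]
    table[order].to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    logger.info("wrote %s: %d rows", path.name, len(table))


# -- model directories ------------------------------------------------------

def _stratum_filename(stratum: tuple[str, str]) -> str:
    sex, race = stratum
    return f"kde_{sex}_{race}.json".lower()


def save_models(models: dict, directory) -> None:
    """Serialize ``{(sex, race): StratumKernelDensity}`` to a directory of
    JSON containers plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"format_version": 1, "strata": [], "files": []}
    for stratum, model in models.items():
        fname = _stratum_filename(stratum)
        with open(directory / fname, "w", encoding="utf-8") as fh:
            json.dump(model.to_dict(), fh)
        manifest["strata"].append(list(stratum))
        manifest["files"].append(fname)
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)


def load_models(directory) -> dict:
    """Load a model directory written by :func:`save_models`."""
    directory = Path(directory)
    with open(directory / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != 1:
        raise ValueError("unsupported model directory format")
    models = {}
    for stratum, fname in zip(manifest["strata"], manifest["files"]):
        with open(directory / fname, encoding="utf-8") as fh:
            models[tuple(stratum)] = StratumKernelDensity.from_dict(json.load(fh))
    missing = [s for s in STRATA if s not in models]
    if missing:
        logger.warning("model directory lacks strata: %s", missing)
    return models


# -- configuration ----------------------------------------------------------

def read_config(path) -> dict:
    """Load a YAML run configuration (flat keys plus optional per-ROI
    arrays); returns a plain dict for :func:`neurokde.simulate.default_config`
    style overrides."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
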