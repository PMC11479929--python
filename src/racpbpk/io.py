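"""CSV readers/writers and run-metadata capture.

Every numeric output file written by the CLI gets a JSON sidecar
(``<name>.meta.json``) recording the configuration hash, seeds, solver
settings, package version, timestamp and every defaulted parameter — enough
to reproduce the run bit-for-bit on the same platform.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .parameters import DrugParams, PhysioProfile

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("animal_id", "time_h", "matrix", "concentration", "unit")
#: accepted unit spellings, normalised to μg/L-equivalents (×1 throughout:
#: ng/mL ≡ μg/L and ng/g ≡ μg/kg)
UNIT_FACTORS = {
    "ug/L": 1.0, "ng/mL": 1.0, "ug/kg": 1.0, "ng/g": 1.0, "ug": 1.0,
}


class ObservedDataError(ValueError):
    pass


def read_observed(path: str | Path) -> pd.DataFrame:
    """Read an observed concentration table and normalise units.

    Required columns: animal_id, time_h, matrix, concentration, unit;
    optional status (``ok`` / ``<LOQ``).  Rows are validated individually and
    errors name the offending row number (1-based, excluding the header).
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ObservedDataError(f"{path}: missing columns {missing}")
    if "status" not in frame.columns:
        frame["status"] = "ok"
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        if row.unit not in UNIT_FACTORS:
            raise ObservedDataError(
                f"{path} row {i}: unknown unit {row.unit!r}")
        if not row.concentration >= 0:
            raise ObservedDataError(
                f"{path} row {i}: negative or missing concentration "
                f"{row.concentration!r}")
        if not row.time_h >= 0:
            raise ObservedDataError(f"{path} row {i}: bad time {row.time_h!r}")
    frame["concentration"] = frame["concentration"] * frame["unit"].map(
        UNIT_FACTORS)
    frame["unit"] = frame["unit"].map(
        lambda u: {"ng/mL": "ug/L", "ng/g": "ug/kg"}.get(u, u))
    return frame


def config_hash(profile: PhysioProfile, drug: DrugParams) -> str:
    payload = json.dumps(
        {"physiology": _plain(profile), "drug": _plain(drug)},
        sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _plain(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        value = getattr(obj, f.name)
        out[f.name] = dict(value) if isinstance(value, Mapping) else value
    return out


def write_with_metadata(frame: pd.DataFrame, path: str | Path,
                        metadata: Mapping[str, object]) -> None:
    """Write a CSV plus its reproducibility sidecar."""
    path = Path(path)
    frame.to_csv(path, index=False)
    sidecar = dict(metadata)
    sidecar.setdefault("software_version", __version__)
    sidecar.setdefault("timestamp_utc",
                       datetime.now(timezone.utc).isoformat())
    meta_path = path.with_suffix(path.suffix + ".meta.json") \
        if path.suffix != ".json" else path.with_name(path.stem + ".meta.json")
    meta_path.write_text(json.dumps(sidecar, indent=2, default=str) + "\n")
    log.info("wrote %s (+ %s)", path, meta_path.name)
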