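"""CSV / JSON / YAML input and output.

The study CSV dialect is long-form, one row per time point:

    sample_id,bmd_g_cm3,frequency_hz,time_s,storage_modulus_mpa,loss_modulus_mpa

comma-separated, '.' decimal, UTF-8.  Study metadata (tooth region, root
depth, trabecular number, protocol constants) travels separately as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .synthetic import (
    DMASweep,
    RootDepth,
    SampleRecord,
    StudyConfig,
    ToothRegion,
)

__all__ = [
    "STUDY_CSV_COLUMNS",
    "write_study_csv",
    "read_study_csv",
    "write_study_metadata",
    "read_study_metadata",
    "load_study_config",
]

STUDY_CSV_COLUMNS = (
    "sample_id",
    "bmd_g_cm3",
    "frequency_hz",
    "time_s",
    "storage_modulus_mpa",
    "loss_modulus_mpa",
)


def write_study_csv(
    samples: Sequence[SampleRecord],
    sweeps: Sequence[DMASweep],
    path: str | Path,
) -> None:
    """Write all sweeps of a study as one long-form CSV."""
    bmd_by_id = {s.sample_id: s.bmd for s in samples}
    frames = []
    for sw in sweeps:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sw.sample_id,
                    "bmd_g_cm3": bmd_by_id[sw.sample_id],
                    "frequency_hz": sw.frequency,
                    "time_s": sw.times,
                    "storage_modulus_mpa": sw.storage_series,
                    "loss_modulus_mpa": sw.loss_series,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_study_csv(path: str | Path) -> tuple[dict[str, float], list[DMASweep]]:
    """Read a study CSV.

    Returns ``(bmd_by_sample_id, sweeps)``.  Raises ``ValueError`` naming
    any missing required columns.
    """
    df = pd.read_csv(path)
    missing = [c for c in STUDY_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"study CSV {path} is missing required columns: {', '.join(missing)}"
        )
    if df.empty:
        raise ValueError(f"study CSV {path} contains no data rows")
    bmd_by_id: dict[str, float] = {}
    sweeps: list[DMASweep] = []
    for (sid, freq), grp in df.groupby(["sample_id", "frequency_hz"], sort=True):
        grp = grp.sort_values("time_s")
        bmds = grp["bmd_g_cm3"].unique()
        if len(bmds) != 1:
            raise ValueError(f"sample {sid!r} has inconsistent BMD values {bmds}")
        bmd_by_id[str(sid)] = float(bmds[0])
        sweeps.append(
            DMASweep(
                sample_id=str(sid),
                frequency=float(freq),
                times=grp["time_s"].to_numpy(dtype=float),
                storage_series=grp["storage_modulus_mpa"].to_numpy(dtype=float),
                loss_series=grp["loss_modulus_mpa"].to_numpy(dtype=float),
            )
        )
    return bmd_by_id, sweeps


def write_study_metadata(
    samples: Sequence[SampleRecord], path: str | Path
) -> None:
    payload = [
        {
            "sample_id": s.sample_id,
            "tooth_region": s.tooth_region.value,
            "root_depth": s.root_depth.value,
            "bmd_g_cm3": s.bmd,
            "trabecular_number_per_pixel": s.trabecular_number,
        }
        for s in samples
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_study_metadata(path: str | Path) -> list[SampleRecord]:
    payload = json.loads(Path(path).read_text())
    return [
        SampleRecord(
            sample_id=d["sample_id"],
            tooth_region=ToothRegion(d["tooth_region"]),
            root_depth=RootDepth(d["root_depth"]),
            bmd=d["bmd_g_cm3"],
            trabecular_number=d["trabecular_number_per_pixel"],
        )
        for d in payload
    ]


def load_study_config(path: str | Path) -> StudyConfig:
    """Load a :class:`StudyConfig` from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    valid = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "bmds" in data:
        data["bmds"] = tuple(data["bmds"])
    if "frequencies" in data:
        data["frequencies"] = tuple(data["frequencies"])
    return StudyConfig(**data)
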