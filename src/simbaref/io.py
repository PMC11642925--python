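"""Tabular TAC data: containers, validation, and TSV/JSON round-tripping.

The on-disk format is a long TSV with one row per subject x measurement x
region x frame (columns ``subject_id, measurement_id, centre, region,
frame_start, frame_duration, activity``; times in minutes) plus a JSON
sidecar holding per-measurement metadata (injected dose, age, group,
condition, per-region volumes). The reference-region TAC is stored as an
ordinary region row under a reserved label (default ``"cerebellum"``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import FrameSchedule

REFERENCE_REGION = "cerebellum"

REQUIRED_COLUMNS = [
    "subject_id",
    "measurement_id",
    "centre",
    "region",
    "frame_start",
    "frame_duration",
    "activity",
]


class SchemaError(ValueError):
    """The table is missing required columns or violates validation rules."""


@dataclass
class TAC:
    """A single time-activity curve with its identifying keys and metadata."""

    subject_id: str
    measurement_id: str
    region: str
    frames: FrameSchedule
    activity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if len(self.activity) != self.frames.n_frames:
            raise SchemaError("activity length does not match frame schedule")


@dataclass
class TACTable:
    """A validated long-format TAC table plus per-measurement metadata.

    ``frames`` holds one row per frame; ``meta`` one row per measurement with
    columns ``subject_id, measurement_id, centre, injected_dose, age, group,
    condition`` and a ``region_volumes`` dict column.
    """

    frames: pd.DataFrame
    meta: pd.DataFrame
    reference_region: str = REFERENCE_REGION

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frames.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        bad = self.frames["frame_duration"] <= 0
        if bad.any():
            raise SchemaError(
                f"non-positive frame_duration in rows {list(self.frames.index[bad][:10])}"
            )
        key = ["subject_id", "measurement_id", "region", "frame_start"]
        if self.frames.duplicated(subset=key).any():
            raise SchemaError("duplicate (subject, measurement, region, frame_start) rows")
        self.frames = self.frames.sort_values(
            ["subject_id", "measurement_id", "region", "frame_start"], kind="mergesort"
        ).reset_index(drop=True)
        refs = self.frames[self.frames["region"] == self.reference_region]
        meas = self.frames[["subject_id", "measurement_id"]].drop_duplicates()
        ref_meas = refs[["subject_id", "measurement_id"]].drop_duplicates()
        if len(ref_meas) != len(meas):
            raise SchemaError(
                f"every measurement needs a '{self.reference_region}' reference region TAC"
            )

    # ------------------------------------------------------------------ access
    def measurements(self) -> pd.DataFrame:
        return self.frames[["subject_id", "measurement_id"]].drop_duplicates().reset_index(
            drop=True
        )

    def _meta_for(self, subject_id: str, measurement_id: str) -> dict:
        m = self.meta[
            (self.meta["subject_id"] == subject_id)
            & (self.meta["measurement_id"] == measurement_id)
        ]
        if len(m) == 0:
            return {}
        row = m.iloc[0].to_dict()
        vols = row.pop("region_volumes", {}) or {}
        row["region_volumes"] = vols
        return row

    def _tac_from_rows(self, rows: pd.DataFrame, meta: dict) -> TAC:
        region = rows["region"].iloc[0]
        md = {k: v for k, v in meta.items() if k != "region_volumes"}
        md["region_volume"] = meta.get("region_volumes", {}).get(region)
        return TAC(
            subject_id=rows["subject_id"].iloc[0],
            measurement_id=rows["measurement_id"].iloc[0],
            region=region,
            frames=FrameSchedule(
                rows["frame_start"].to_numpy(), rows["frame_duration"].to_numpy()
            ),
            activity=rows["activity"].to_numpy(),
            metadata=md,
        )

    def iter_tacs(self, include_reference: bool = False):
        """Yield target-region TACs (and optionally the reference TACs)."""
        for (sid, mid, region), rows in self.frames.groupby(
            ["subject_id", "measurement_id", "region"], sort=True
        ):
            if region == self.reference_region and not include_reference:
                continue
            yield self._tac_from_rows(rows, self._meta_for(sid, mid))

    def reference_tac(self, subject_id: str, measurement_id: str) -> TAC:
        rows = self.frames[
            (self.frames["subject_id"] == subject_id)
            & (self.frames["measurement_id"] == measurement_id)
            & (self.frames["region"] == self.reference_region)
        ]
        if len(rows) == 0:
            raise KeyError(f"no reference TAC for {subject_id}/{measurement_id}")
        return self._tac_from_rows(rows, self._meta_for(subject_id, measurement_id))

    @property
    def regions(self) -> list[str]:
        return sorted(r for r in self.frames["region"].unique() if r != self.reference_region)


# ----------------------------------------------------------------------- files
def write_tac_table(table: TACTable, path: str | Path) -> None:
    """Write the frame table as TSV and the metadata as a ``.json`` sidecar."""
    path = Path(path)
    table.frames.to_csv(path, sep="\t", index=False)
    meta = table.meta.to_dict(orient="records")
    sidecar = {"reference_region": table.reference_region, "measurements": meta}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, default=float))


def read_tac_table(path: str | Path, reference_region: str | None = None) -> TACTable:
    """Read a TSV/CSV TAC table (and its JSON sidecar, if present)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frames = pd.read_csv(path, sep=sep, dtype={"subject_id": str, "measurement_id": str})
    sidecar_path = path.with_suffix(".json")
    ref = reference_region or REFERENCE_REGION
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        meta = pd.DataFrame(sidecar.get("measurements", []))
        if reference_region is None:
            ref = sidecar.get("reference_region", REFERENCE_REGION)
    else:
        meta = pd.DataFrame(columns=["subject_id", "measurement_id"])
    return TACTable(frames=frames, meta=meta, reference_region=ref)
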