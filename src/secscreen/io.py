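"""File schemas, packaged fixtures and atomic CSV output.

All files are plain comma-separated UTF-8 with "." decimals and a mandatory
header; every numeric column name carries an explicit unit suffix.  Writers
follow a write-then-rename contract so a crashed run never leaves a
half-written table behind.

Two fixtures ship with the package:

* ``campaign_activity_table.csv`` — transcription of the published per-SP cutinase
  activity table for *C. glutamicum* and *B. subtilis* (absolute U/mL and
  percent-of-maximum relatives, repeated isolates kept as separate rows).
  See :data:`CAMPAIGN_TABLE_CAVEAT` for known transcription limitations.
* ``reference_panel_synthetic.csv`` — a *synthetic* reference panel shaped
  like the published known-insert control experiment (NprE well separated,
  AmyE/YwmC overlapping, empty-vector near zero).  The publication prints no
  numeric panel values, so these are constructed, not transcribed.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .assay import KineticTrace
from .phenotype import ReferencePanel, SPRecord

__all__ = [
    "HOST_CG",
    "HOST_BS",
    "CAMPAIGN_TABLE_CAVEAT",
    "CampaignTableFixture",
    "load_campaign_table",
    "campaign_sp_records",
    "campaign_multiplicity_census",
    "load_reference_panel",
    "read_activity_table",
    "read_traces",
    "write_csv_atomic",
    "convert_units",
]

HOST_CG = "C_glutamicum"
HOST_BS = "B_subtilis"

#: Units accepted for activity columns.  1 U/mL = 1000 U/L = 1 kU/L, so the
#: two are numerically identical; the canonical internal unit is U/mL.
_UNIT_FACTORS = {"U/mL": 1.0, "kU/L": 1.0}

CAMPAIGN_TABLE_CAVEAT = (
    "Transcribed table lists 64 C. glutamicum rows although 66 clones were "
    "sequenced in the campaign; its multiplicity census (24/9/6/1 members "
    "seen 1/2/3/4 times) matches the published relative occurrences only at "
    "m=2. Shipped as transcribed; do not force agreement at m in {1, 3, 4}."
)


@dataclass(frozen=True)
class CampaignTableFixture:
    """The transcribed activity table plus its provenance caveat."""

    frame: pd.DataFrame  # long format, one row per (table row, host)
    caveat: str = CAMPAIGN_TABLE_CAVEAT


def _data_path(name: str):
    return resources.files("secscreen.data").joinpath(name)


def load_campaign_table() -> CampaignTableFixture:
    """Load the packaged per-SP activity table in long format.

    Columns: ``row`` (printed table row, preserving repeated isolates),
    ``sp_id``, ``host``, ``activity_U_per_mL``, ``sd_U_per_mL`` (NaN for the
    *B. subtilis* series, whose published errors are a flat 25%),
    ``relative_pct``, ``relative_sd_pct``.
    """
    with resources.as_file(_data_path("campaign_activity_table.csv")) as p:
        wide = pd.read_csv(p)
    rows = []
    for _, r in wide.iterrows():
        rows.append(
            {
                "row": int(r["row"]),
                "sp_id": r["sp_id"],
                "host": HOST_CG,
                "activity_U_per_mL": r["cg_activity_U_per_mL"],
                "sd_U_per_mL": r["cg_sd_U_per_mL"],
                "relative_pct": r["cg_relative_pct"],
                "relative_sd_pct": r["cg_relative_sd_pct"],
            }
        )
        rows.append(
            {
                "row": int(r["row"]),
                "sp_id": r["sp_id"],
                "host": HOST_BS,
                "activity_U_per_mL": r["bs_activity_U_per_mL"],
                "sd_U_per_mL": float("nan"),
                "relative_pct": r["bs_relative_pct"],
                "relative_sd_pct": float("nan"),
            }
        )
    return CampaignTableFixture(frame=pd.DataFrame(rows))


def campaign_sp_records(host: str) -> list[SPRecord]:
    """The fixture's series for one host as raw (un-normalized) SPRecords."""
    if host not in (HOST_CG, HOST_BS):
        raise ValueError(f"unknown host {host!r}; expected {HOST_CG} or {HOST_BS}")
    frame = load_campaign_table().frame
    sub = frame[frame["host"] == host]
    return [
        SPRecord(
            sp_id=r["sp_id"],
            host=host,
            mean_activity=float(r["activity_U_per_mL"]),
            sd_activity=0.0 if pd.isna(r["sd_U_per_mL"]) else float(r["sd_U_per_mL"]),
        )
        for _, r in sub.iterrows()
    ]


def campaign_multiplicity_census() -> dict[int, int]:
    """How many SPs the transcribed table lists exactly m times (m -> count)."""
    frame = load_campaign_table().frame
    per_sp = frame[frame["host"] == HOST_CG]["sp_id"].value_counts()
    census: dict[int, int] = {}
    for m in per_sp.values:
        census[int(m)] = census.get(int(m), 0) + 1
    return dict(sorted(census.items()))


def load_reference_panel(path: str | Path | None = None) -> ReferencePanel:
    """Load a reference panel CSV (defaults to the packaged synthetic panel)."""
    if path is None:
        with resources.as_file(_data_path("reference_panel_synthetic.csv")) as p:
            frame = pd.read_csv(p)
    else:
        frame = pd.read_csv(path)
    required = {"sp_id", "mean_activity_U_per_mL", "sd_activity_U_per_mL"}
    if not required.issubset(frame.columns):
        raise ValueError(f"reference panel must have columns {sorted(required)}")
    return ReferencePanel(
        entries=tuple(
            (str(r["sp_id"]), float(r["mean_activity_U_per_mL"]), float(r["sd_activity_U_per_mL"]))
            for _, r in frame.iterrows()
        )
    )


def convert_units(value: float, units: str) -> float:
    """Convert an activity to the canonical U/mL (kU/L is the identity)."""
    if units not in _UNIT_FACTORS:
        raise ValueError(f"unknown activity unit {units!r}; accepted: {sorted(_UNIT_FACTORS)}")
    return value * _UNIT_FACTORS[units]


def read_activity_table(path: str | Path) -> pd.DataFrame:
    """Read a clone activity table (clone_id, sp_id, host, replicate, activity, units).

    ``sp_id`` may be empty (unknown insert).  Activities are converted to the
    canonical U/mL column ``activity_U_per_mL``.  Malformed rows raise errors
    naming the offending row and column.
    """
    frame = pd.read_csv(path, dtype={"clone_id": str, "sp_id": str, "host": str, "units": str})
    required = ["clone_id", "host", "replicate", "activity", "units"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "sp_id" not in frame.columns:
        frame["sp_id"] = ""
    frame["sp_id"] = frame["sp_id"].fillna("")
    activities = []
    for idx, r in frame.iterrows():
        rowno = idx + 2  # header is line 1
        try:
            value = float(r["activity"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}: row {rowno}, column 'activity': not a number: {r['activity']!r}")
        if value < 0:
            raise ValueError(f"{path}: row {rowno}, column 'activity': negative activity {value}")
        try:
            activities.append(convert_units(value, str(r["units"])))
        except ValueError as e:
            raise ValueError(f"{path}: row {rowno}, column 'units': {e}") from None
    frame["activity_U_per_mL"] = activities
    return frame


def read_traces(path: str | Path) -> list[KineticTrace]:
    """Read long-format kinetic traces (well_id, role, time_s, A410, dilution_factor)."""
    frame = pd.read_csv(path, dtype={"well_id": str, "role": str})
    required = ["well_id", "role", "time_s", "A410", "dilution_factor"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    traces = []
    for well_id, grp in frame.groupby("well_id", sort=True):
        roles = set(grp["role"])
        if len(roles) != 1:
            raise ValueError(f"{path}: well {well_id!r} mixes roles {sorted(roles)}")
        dilutions = set(grp["dilution_factor"].astype(float))
        if len(dilutions) != 1:
            raise ValueError(f"{path}: well {well_id!r} has inconsistent dilution factors")
        grp = grp.sort_values("time_s")
        traces.append(
            KineticTrace(
                well_id=str(well_id),
                role=roles.pop(),
                times_s=grp["time_s"].to_numpy(dtype=float),
                absorbances=grp["A410"].to_numpy(dtype=float),
                dilution_factor=dilutions.pop(),
            )
        )
    return traces


def write_csv_atomic(frame: pd.DataFrame, path: str | Path, *, index: bool = False) -> Path:
    """Write a CSV via a temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            frame.to_csv(fh, index=index)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path
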