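"""Reading, validating, synchronizing and writing the study tables.

The working container for epoch data is a pandas DataFrame wrapped in
:class:`EpochTable`, with one row per synchronized 60 s epoch: participant id,
minute-aligned timestamp, activity label, METs from indirect calorimetry, and
counts per minute from the wrist device on the stroke-affected and
non-affected sides.  Participant metadata (demographics and Fugl-Meyer motor
scores) are parsed into :class:`ParticipantProfile` records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConsistencyError,
    DomainError,
    FormatError,
    RangeError,
    RowError,
)

ACTIVITY_LABELS = frozenset(
    {
        "leisurely_walk",
        "comfortable_walk",
        "moderate_walk",
        "brisk_walk",
        "sitting",
        "cleaning",
        "bicep_curls",
        "chair_squats",
        "lying",
        "standing",
        "recovery",
        "other",
    }
)

EPOCH_COLUMNS = (
    "participant_id",
    "timestamp",
    "activity",
    "mets",
    "cpm_affected",
    "cpm_nonaffected",
)

PARTICIPANT_COLUMNS = (
    "participant_id",
    "age_years",
    "sex",
    "weight_kg",
    "height_cm",
    "fm_upper",
    "fm_lower",
    "fm_total",
    "affected_side",
)


@dataclass(frozen=True)
class EpochRecord:
    """One synchronized 60 s measurement unit."""

    participant_id: str
    timestamp: pd.Timestamp
    activity_label: str
    cpm_affected: float | None
    cpm_nonaffected: float | None
    mets: float | None
    intensity_class: object = None


@dataclass
class EpochTable:
    """Ordered epoch rows plus a free-text provenance note.

    ``df`` columns follow :data:`EPOCH_COLUMNS` (plus, after classification,
    ``intensity``).  Timestamps are minute-truncated and unique within each
    participant.
    """

    df: pd.DataFrame
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[EpochRecord]:
        for row in self.df.itertuples(index=False):
            yield EpochRecord(
                participant_id=row.participant_id,
                timestamp=row.timestamp,
                activity_label=row.activity,
                cpm_affected=None if pd.isna(row.cpm_affected) else float(row.cpm_affected),
                cpm_nonaffected=None if pd.isna(row.cpm_nonaffected) else float(row.cpm_nonaffected),
                mets=None if pd.isna(row.mets) else float(row.mets),
                intensity_class=getattr(row, "intensity", None),
            )


@dataclass(frozen=True)
class ParticipantProfile:
    """Demographics and motor-impairment scores for one participant.

    Fugl-Meyer motor scores: upper body 0-66, lower body 0-34, total 0-100
    (total = upper + lower).  ``affected_side`` is the hemiparetic body side.
    """

    participant_id: str
    age: float
    sex: str
    weight: float
    fugl_meyer_upper: int
    fugl_meyer_lower: int
    fugl_meyer_total: int
    affected_side: str
    height: float | None = None

    def __post_init__(self):
        if not 0 <= self.fugl_meyer_upper <= 66:
            raise RangeError(
                f"{self.participant_id}: FM upper {self.fugl_meyer_upper} outside 0-66"
            )
        if not 0 <= self.fugl_meyer_lower <= 34:
            raise RangeError(
                f"{self.participant_id}: FM lower {self.fugl_meyer_lower} outside 0-34"
            )
        if self.fugl_meyer_total != self.fugl_meyer_upper + self.fugl_meyer_lower:
            raise ConsistencyError(
                f"{self.participant_id}: FM total {self.fugl_meyer_total} != "
                f"{self.fugl_meyer_upper} + {self.fugl_meyer_lower}"
            )
        if self.weight <= 0:
            raise DomainError(f"{self.participant_id}: weight must be positive")
        if self.affected_side not in ("left", "right"):
            raise FormatError(
                f"{self.participant_id}: affected_side must be 'left' or 'right'"
            )
        if self.sex not in ("female", "male"):
            raise FormatError(f"{self.participant_id}: sex must be 'female' or 'male'")


def _truncate_minute(ts: pd.Series) -> pd.Series:
    # epoch-start convention: truncate, never round, to the containing minute
    return ts.dt.floor("min")


def read_epoch_table(source, dialect: dict | None = None, policy: str = "strict") -> EpochTable:
    """Parse an epoch CSV into a validated :class:`EpochTable`.

    ``dialect`` maps canonical column names to the file's column names.
    Rows violating record invariants (unparsable timestamp, negative counts or
    METs, duplicate minute within a participant) are collected as row-indexed
    diagnostics; under ``policy="skip"`` they are dropped, under ``"strict"``
    (default) any diagnostic is fatal.
    """
    if policy not in ("strict", "skip"):
        raise ValueError("policy must be 'strict' or 'skip'")
    dialect = dialect or {}
    raw = pd.read_csv(source, dtype={dialect.get("participant_id", "participant_id"): str})
    rename = {v: k for k, v in dialect.items() if v in raw.columns}
    raw = raw.rename(columns=rename)
    for col in ("participant_id", "timestamp"):
        if col not in raw.columns:
            raise FormatError(f"mandatory column {col!r} missing")
    if not any(c in raw.columns for c in ("cpm_affected", "cpm_nonaffected", "mets")):
        raise FormatError("need at least one of cpm_affected, cpm_nonaffected, mets")
    for col in ("activity", "mets", "cpm_affected", "cpm_nonaffected"):
        if col not in raw.columns:
            raw[col] = np.nan
    raw["activity"] = raw["activity"].fillna("other")

    diagnostics: list[tuple[int, str]] = []
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna()
    for i in raw.index[bad]:
        diagnostics.append((int(i), f"unparsable timestamp {raw.loc[i, 'timestamp']!r}"))
    for col in ("cpm_affected", "cpm_nonaffected"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        neg = vals < 0
        for i in raw.index[neg]:
            diagnostics.append((int(i), f"negative {col} {raw.loc[i, col]!r}"))
        bad |= neg
        raw[col] = vals
    mets = pd.to_numeric(raw["mets"], errors="coerce")
    neg_mets = mets < 0
    for i in raw.index[neg_mets]:
        diagnostics.append((int(i), f"negative mets {raw.loc[i, 'mets']!r}"))
    bad |= neg_mets
    raw["mets"] = mets
    unknown = ~raw["activity"].isin(ACTIVITY_LABELS)
    for i in raw.index[unknown]:
        diagnostics.append((int(i), f"unknown activity label {raw.loc[i, 'activity']!r}"))
    bad |= unknown

    raw = raw.assign(timestamp=_truncate_minute(ts))
    dup = raw["timestamp"].notna() & raw.duplicated(["participant_id", "timestamp"], keep="first")
    for i in raw.index[dup]:
        diagnostics.append((int(i), "duplicate minute within participant"))
    bad |= dup

    if diagnostics and policy == "strict":
        raise RowError(f"{len(diagnostics)} invalid row(s)", diagnostics)
    kept = raw.loc[~bad, list(EPOCH_COLUMNS)].reset_index(drop=True)
    note = f"read_epoch_table: {len(kept)} rows kept, {int(bad.sum())} dropped"
    table = EpochTable(df=kept, provenance=note)
    table.diagnostics = diagnostics
    return table


def read_participants(source) -> list[ParticipantProfile]:
    """Parse the participant-metadata CSV.

    The Fugl-Meyer total is filled as upper + lower when absent; a supplied
    total inconsistent with the subscales is a :class:`ConsistencyError`.
    """
    raw = pd.read_csv(source, dtype={"participant_id": str})
    for col in ("participant_id", "age_years", "sex", "weight_kg", "fm_upper", "fm_lower", "affected_side"):
        if col not in raw.columns:
            raise FormatError(f"mandatory column {col!r} missing")
    profiles = []
    for row in raw.itertuples(index=False):
        upper, lower = int(row.fm_upper), int(row.fm_lower)
        total = getattr(row, "fm_total", None)
        total = upper + lower if total is None or pd.isna(total) else int(total)
        height = getattr(row, "height_cm", None)
        profiles.append(
            ParticipantProfile(
                participant_id=str(row.participant_id),
                age=float(row.age_years),
                sex=str(row.sex),
                weight=float(row.weight_kg),
                height=None if height is None or pd.isna(height) else float(height),
                fugl_meyer_upper=upper,
                fugl_meyer_lower=lower,
                fugl_meyer_total=total,
                affected_side=str(row.affected_side),
            )
        )
    return profiles


def write_participants(profiles: Iterable[ParticipantProfile], sink) -> None:
    """Write profiles back to the participants CSV schema."""
    rows = [
        {
            "participant_id": p.participant_id,
            "age_years": p.age,
            "sex": p.sex,
            "weight_kg": p.weight,
            "height_cm": p.height,
            "fm_upper": p.fugl_meyer_upper,
            "fm_lower": p.fugl_meyer_lower,
            "fm_total": p.fugl_meyer_total,
            "affected_side": p.affected_side,
        }
        for p in profiles
    ]
    pd.DataFrame(rows, columns=list(PARTICIPANT_COLUMNS)).to_csv(sink, index=False)


def write_epoch_table(table: EpochTable, sink) -> None:
    """Write the epoch table to its CSV schema (ISO 8601 timestamps)."""
    out = table.df.copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    out[list(EPOCH_COLUMNS)].to_csv(sink, index=False)


def align_streams(
    actigraphy_a: pd.Series,
    actigraphy_b: pd.Series,
    calorimetry: pd.Series,
    activity_log: Iterable[tuple],
    participant_id: str = "",
) -> EpochTable:
    """Synchronize one participant's three instrument streams on the minute grid.

    All series must carry datetime indexes; timestamps are truncated to the
    containing minute and only minutes present in *all three* streams are
    kept.  ``activity_log`` is an iterable of ``(start, end, label)`` half-open
    intervals; a kept minute covered by no interval is labeled ``"other"``.
    The count of dropped minutes per stream is recorded in the provenance note.
    """
    def prep(s: pd.Series, name: str) -> pd.Series:
        if not isinstance(s.index, pd.DatetimeIndex):
            raise FormatError(f"{name} must have a datetime index")
        s = s.copy()
        s.index = s.index.floor("min")
        if s.index.has_duplicates:
            raise FormatError(f"{name} has duplicate minutes")
        return s

    a = prep(actigraphy_a, "actigraphy_a")
    b = prep(actigraphy_b, "actigraphy_b")
    m = prep(calorimetry, "calorimetry")
    common = a.index.intersection(b.index).intersection(m.index).sort_values()
    if len(common) == 0:
        raise AlignmentError("instrument streams share no common minutes")

    labels = pd.Series("other", index=common, dtype=object)
    for start, end, label in activity_log:
        start = pd.Timestamp(start).floor("min")
        end = pd.Timestamp(end).floor("min")
        labels.loc[(common >= start) & (common < end)] = label

    df = pd.DataFrame(
        {
            "participant_id": participant_id,
            "timestamp": common,
            "activity": labels.values,
            "mets": m.loc[common].values,
            "cpm_affected": a.loc[common].values,
            "cpm_nonaffected": b.loc[common].values,
        }
    )
    note = (
        f"align_streams[{participant_id}]: kept {len(common)} minutes; dropped "
        f"a={len(a) - len(common)}, b={len(b) - len(common)}, calorimetry={len(m) - len(common)}"
    )
    return EpochTable(df=df.reset_index(drop=True), provenance=note)


def write_cutpoints(sets, sink) -> None:
    """Serialize calibrated cut-point sets to JSON (see pipeline.CutPointSet)."""
    sets = list(sets)
    if not sets:
        raise DomainError("cut-point collection is empty")
    payload = [s.to_dict() for s in sets]
    if hasattr(sink, "write"):
        json.dump(payload, sink, indent=2)
    else:
        with open(sink, "w") as fh:
            json.dump(payload, fh, indent=2)


def read_cutpoints(source):
    """Read cut-point sets back from JSON, checking boundary ordering."""
    from .pipeline import CutPointSet  # local import avoids a module cycle

    try:
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed cut-point JSON: {exc}") from exc
    if not isinstance(payload, list):
        raise FormatError("cut-point JSON must be a list of objects")
    return [CutPointSet.from_dict(obj) for obj in payload]
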