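"""Apply a calibrated cut-point set to a free-living count stream.

Each epoch's counts per minute map to an intensity class: SB at or below the
sedentary bound, MVPA at or above the MVPA bound (both bounds inclusive, as
calibrated), and LPA in the open band between.  Every epoch is scored; no
non-wear detection is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import Intensity
from .errors import DomainError
from .pipeline import CutPointSet


@dataclass
class ScoredSeries:
    """Per-epoch intensity labels plus cut-point provenance."""

    labels: np.ndarray  # Intensity per epoch
    timestamps: pd.DatetimeIndex | None = None
    stratum: str = ""
    side: str = ""
    config_fingerprint: str = ""

    def __len__(self) -> int:
        return len(self.labels)


def score_epochs(cpm, cutpoints: CutPointSet, timestamps=None) -> ScoredSeries:
    """Classify each epoch's CPM with the given cut-point set."""
    c = np.asarray(cpm, dtype=float)
    if np.any(c < 0):
        raise DomainError("counts must be non-negative")
    codes = np.full(c.shape, Intensity.LPA, dtype=int)
    codes[c <= cutpoints.sb_upper] = Intensity.SB
    codes[c >= cutpoints.mvpa_lower] = Intensity.MVPA
    labels = np.array([Intensity(int(v)) for v in codes], dtype=object)
    ts = pd.DatetimeIndex(timestamps) if timestamps is not None else None
    if ts is not None and len(ts) != len(c):
        raise ValueError("timestamps and cpm must be equal length")
    return ScoredSeries(
        labels=labels,
        timestamps=ts,
        stratum=cutpoints.stratum,
        side=cutpoints.side,
        config_fingerprint=cutpoints.config_fingerprint,
    )


def summarize_time(scored: ScoredSeries, epoch_seconds: int = 60) -> dict:
    """Minutes per intensity class; per calendar day as well when the
    timestamps span more than one day.  Total time is conserved exactly."""
    per_epoch_min = epoch_seconds / 60.0
    out = {cls.name: 0.0 for cls in Intensity}
    for lab in scored.labels:
        out[Intensity(lab).name] += per_epoch_min
    result = {"minutes": out, "total_minutes": per_epoch_min * len(scored.labels)}
    if scored.timestamps is not None and len(scored.timestamps) > 0:
        days = scored.timestamps.normalize()
        if days.nunique() > 1:
            per_day: dict = {}
            for day in sorted(days.unique()):
                mask = days == day
                day_out = {cls.name: 0.0 for cls in Intensity}
                for lab in np.asarray(scored.labels)[np.asarray(mask)]:
                    day_out[Intensity(lab).name] += per_epoch_min
                per_day[str(pd.Timestamp(day).date())] = day_out
            result["per_day"] = per_day
    return result


def scored_frame(scored: ScoredSeries, cpm) -> pd.DataFrame:
    """Tabular view of a scored stream for CSV export."""
    data = {"cpm": np.asarray(cpm, dtype=float), "intensity": [Intensity(l).name for l in scored.labels]}
    if scored.timestamps is not None:
        data = {"timestamp": [t.isoformat() for t in scored.timestamps], **data}
    return pd.DataFrame(data)
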