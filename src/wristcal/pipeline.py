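"""Full calibration analysis: stratify the cohort by stroke severity, derive
per-(side, stratum) cut-points, compare the two wrists' diagnostic accuracy,
and assemble agreement reports.

Six cut-point sets are produced — {all, mild, moderate_severe} x
{affected, non_affected} — alongside one between-wrist agreement report per
stratum slice.  Sedentary-behavior (SB) bounds are found by unconstrained
Youden maximization in the low-count direction; moderate-to-vigorous (MVPA)
bounds by Youden maximization subject to a false-positive-ratio ceiling
(default 0.10), which keeps MVPA estimates conservative.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import roc
from .agreement import AUC_CATEGORIES, ICC_CATEGORIES, AgreementReport, agreement_report
from .energy import Intensity, IntensityThresholds, classify_intensity
from .errors import (
    CalibrationInconsistencyError,
    ConsistencyError,
    FormatError,
    InsufficientDataError,
)
from .io import EpochTable, ParticipantProfile
from .roc import (
    POSITIVE_IF_GE,
    POSITIVE_IF_LE,
    AucResult,
    DeLongResult,
    ThresholdMetrics,
)

logger = logging.getLogger("wristcal")

STRATA = ("all", "mild", "moderate_severe")
SIDES = ("affected", "non_affected")


@dataclass(frozen=True)
class CalibrationConfig:
    """Tunable analysis parameters with the study defaults.

    ``fm_mild_min`` is the Fugl-Meyer total (0-100) at or above which a
    participant counts as mild stroke; ``max_fpr`` caps the MVPA cut-point's
    false-positive ratio.
    """

    sb_met_upper: float = 1.5
    mvpa_met_lower: float = 3.0
    max_fpr: float = 0.10
    fm_mild_min: int = 79
    epoch_seconds: int = 60
    ci_level: float = 0.95
    fpr_boundary: str = "le"  # "le" (fpr <= max_fpr) or "lt"
    failure_policy: str = "strict"  # or "permissive": skip unfillable cells
    icc_categories: tuple = ICC_CATEGORIES
    auc_categories: tuple = AUC_CATEGORIES

    def __post_init__(self):
        if not 0 < self.max_fpr < 1:
            raise ValueError("max_fpr must be in (0, 1)")
        if not 0 <= self.fm_mild_min <= 100:
            raise ValueError("fm_mild_min must be in [0, 100]")

    @property
    def met_thresholds(self) -> IntensityThresholds:
        return IntensityThresholds(self.sb_met_upper, self.mvpa_met_lower)

    def fingerprint(self) -> str:
        """Short provenance hash of the resolved scalar configuration."""
        payload = {
            "sb_met_upper": self.sb_met_upper,
            "mvpa_met_lower": self.mvpa_met_lower,
            "max_fpr": self.max_fpr,
            "fm_mild_min": self.fm_mild_min,
            "epoch_seconds": self.epoch_seconds,
            "ci_level": self.ci_level,
            "fpr_boundary": self.fpr_boundary,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class CutPointSet:
    """Calibrated SB/LPA/MVPA boundaries for one (stratum, side) cell.

    ``sb_upper`` is the inclusive upper CPM bound of sedentary behavior
    (SB <= sb_upper); ``mvpa_lower`` the inclusive lower bound of MVPA
    (MVPA >= mvpa_lower); light activity is the open band between them.
    """

    stratum: str
    side: str
    sb_upper: float
    mvpa_lower: float
    sb_metrics: ThresholdMetrics
    mvpa_metrics: ThresholdMetrics
    sb_auc: AucResult | None = None
    mvpa_auc: AucResult | None = None
    n_epochs: int = 0
    config_fingerprint: str = ""

    def __post_init__(self):
        if not self.sb_upper < self.mvpa_lower:
            raise CalibrationInconsistencyError(
                f"sb_upper ({self.sb_upper}) must be < mvpa_lower ({self.mvpa_lower})"
            )

    @property
    def lpa_band(self) -> tuple[float, float]:
        return (self.sb_upper, self.mvpa_lower)

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "side": self.side,
            "sb_le": self.sb_upper,
            "mvpa_ge": self.mvpa_lower,
            "n_epochs": self.n_epochs,
            "metrics": {
                "sb": self.sb_metrics.to_dict(),
                "mvpa": self.mvpa_metrics.to_dict(),
            },
            "auc": {
                "sb": self.sb_auc.to_dict() if self.sb_auc else None,
                "mvpa": self.mvpa_auc.to_dict() if self.mvpa_auc else None,
            },
            "config_fingerprint": self.config_fingerprint,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "CutPointSet":
        try:
            sb_le, mvpa_ge = obj["sb_le"], obj["mvpa_ge"]
            metrics = obj["metrics"]
        except (KeyError, TypeError) as exc:
            raise FormatError(f"cut-point object missing field: {exc}") from exc
        if not sb_le < mvpa_ge:
            raise ConsistencyError(f"sb_le ({sb_le}) must be < mvpa_ge ({mvpa_ge})")
        aucs = obj.get("auc") or {}

        def mk_auc(d):
            return AucResult(**d) if d else None

        return cls(
            stratum=obj.get("stratum", "all"),
            side=obj.get("side", "affected"),
            sb_upper=sb_le,
            mvpa_lower=mvpa_ge,
            sb_metrics=ThresholdMetrics(**metrics["sb"]),
            mvpa_metrics=ThresholdMetrics(**metrics["mvpa"]),
            sb_auc=mk_auc(aucs.get("sb")),
            mvpa_auc=mk_auc(aucs.get("mvpa")),
            n_epochs=obj.get("n_epochs", 0),
            config_fingerprint=obj.get("config_fingerprint", ""),
        )


@dataclass
class CalibrationResult:
    """Everything one full run produces."""

    cutpoints: list
    agreement: dict
    config_fingerprint: str
    failures: dict = field(default_factory=dict)

    def cell(self, stratum: str, side: str) -> CutPointSet:
        for s in self.cutpoints:
            if s.stratum == stratum and s.side == side:
                return s
        raise KeyError((stratum, side))

    def to_dict(self) -> dict:
        return {
            "cutpoints": [s.to_dict() for s in self.cutpoints],
            "agreement": {k: v.to_dict() for k, v in self.agreement.items()},
            "config_fingerprint": self.config_fingerprint,
            "failures": self.failures,
        }


def stratify(profiles, config: CalibrationConfig | None = None) -> dict:
    """Map each participant to 'mild' (FM total >= fm_mild_min) or
    'moderate_severe'."""
    config = config or CalibrationConfig()
    out = {}
    for p in profiles:
        if p.fugl_meyer_total is None:
            raise FormatError(f"{p.participant_id}: missing Fugl-Meyer total")
        out[p.participant_id] = (
            "mild" if p.fugl_meyer_total >= config.fm_mild_min else "moderate_severe"
        )
    return out


def annotate_intensity(epochs: EpochTable, config: CalibrationConfig | None = None) -> EpochTable:
    """Attach the criterion intensity class derived from measured METs.

    Epochs without a MET value get a missing intensity and are excluded from
    calibration downstream.
    """
    config = config or CalibrationConfig()
    df = epochs.df.copy()
    mets = df["mets"].to_numpy(dtype=float)
    intensity = np.array([None] * len(df), dtype=object)
    ok = ~np.isnan(mets)
    if ok.any():
        intensity[ok] = classify_intensity(mets[ok], config.met_thresholds)
    df["intensity"] = intensity
    return EpochTable(df=df, provenance=epochs.provenance)


def _side_column(df: pd.DataFrame, profiles, side: str) -> pd.Series:
    """Resolve the requested anatomical side to a CPM column.

    Tables that carry side-resolved columns (cpm_affected/cpm_nonaffected) are
    used directly; tables with raw left/right wrist columns are resolved via
    each profile's affected_side.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    if "cpm_affected" in df.columns and "cpm_nonaffected" in df.columns:
        return df["cpm_affected" if side == "affected" else "cpm_nonaffected"]
    if "cpm_left" in df.columns and "cpm_right" in df.columns:
        side_of = {}
        for p in profiles:
            if p.affected_side not in ("left", "right"):
                raise FormatError(f"{p.participant_id}: unknown affected_side")
            side_of[p.participant_id] = p.affected_side
        missing = set(df["participant_id"]) - set(side_of)
        if missing:
            raise FormatError(f"profiles missing for participants: {sorted(missing)}")
        affected = df["participant_id"].map(side_of)
        want_left = (affected == "left") == (side == "affected")
        return df["cpm_left"].where(want_left, df["cpm_right"])
    raise FormatError("epoch table has neither side-resolved nor left/right CPM columns")


def select_side_scores(
    epochs: EpochTable,
    profiles,
    side: str,
    target: Intensity,
    config: CalibrationConfig | None = None,
):
    """Paired (CPM scores, 0/1 labels) for one anatomical side and one target
    intensity, restricted to epochs with both a count and a MET-derived class."""
    config = config or CalibrationConfig()
    df = epochs.df
    if "intensity" not in df.columns:
        df = annotate_intensity(epochs, config).df
    cpm = _side_column(df, profiles, side)
    keep = cpm.notna() & df["intensity"].notna()
    scores = cpm[keep].to_numpy(dtype=float)
    labels = np.fromiter((1 if c == target else 0 for c in df.loc[keep, "intensity"]), dtype=int)
    return scores, labels


def _stratum_slice(epochs: EpochTable, profiles, stratum: str, config) -> EpochTable:
    if stratum == "all":
        return epochs
    strata = stratify(profiles, config)
    keep = epochs.df["participant_id"].map(strata) == stratum
    return EpochTable(df=epochs.df.loc[keep].reset_index(drop=True), provenance=epochs.provenance)


def calibrate_cell(
    epochs: EpochTable,
    profiles,
    stratum: str,
    side: str,
    config: CalibrationConfig | None = None,
) -> CutPointSet:
    """Derive one (stratum, side) cut-point set.

    SB bound: unconstrained Youden optimum in the ``positive_if_le``
    direction.  MVPA bound: Youden optimum subject to fpr <= max_fpr in the
    ``positive_if_ge`` direction.  AUCs carry DeLong variances and normal CIs.
    """
    config = config or CalibrationConfig()
    annotated = annotate_intensity(epochs, config)
    cell = _stratum_slice(annotated, profiles, stratum, config)
    present = {c for c in cell.df["intensity"] if c is not None}
    missing = {Intensity.SB, Intensity.LPA, Intensity.MVPA} - present
    if missing:
        raise InsufficientDataError(
            f"stratum {stratum!r}: no epochs of class(es) {sorted(m.name for m in missing)}"
        )

    sb_scores, sb_labels = select_side_scores(cell, profiles, side, Intensity.SB, config)
    sb_curve = roc.roc_curve(sb_scores, sb_labels, POSITIVE_IF_LE)
    sb_best = roc.youden_cutpoint(sb_curve)
    sb_auc = roc.auc_with_ci(sb_scores, sb_labels, POSITIVE_IF_LE, config.ci_level)

    mv_scores, mv_labels = select_side_scores(cell, profiles, side, Intensity.MVPA, config)
    mv_curve = roc.roc_curve(mv_scores, mv_labels, POSITIVE_IF_GE)
    mv_best = roc.constrained_cutpoint(mv_curve, config.max_fpr, config.fpr_boundary)
    mv_auc = roc.auc_with_ci(mv_scores, mv_labels, POSITIVE_IF_GE, config.ci_level)

    roc.lpa_band(sb_best, mv_best)  # raises if the boundaries cross
    logger.info(
        "cell stratum=%s side=%s n=%d sb<=%g mvpa>=%g",
        stratum, side, len(sb_scores), sb_best.threshold, mv_best.threshold,
    )
    return CutPointSet(
        stratum=stratum,
        side=side,
        sb_upper=sb_best.threshold,
        mvpa_lower=mv_best.threshold,
        sb_metrics=sb_best,
        mvpa_metrics=mv_best,
        sb_auc=sb_auc,
        mvpa_auc=mv_auc,
        n_epochs=int(len(sb_scores)),
        config_fingerprint=config.fingerprint(),
    )


def _complete_pairs(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["cpm_affected"].notna() & df["cpm_nonaffected"].notna()]


def calibrate_all(
    epochs: EpochTable,
    profiles,
    config: CalibrationConfig | None = None,
) -> CalibrationResult:
    """Run the whole analysis: six cut-point cells and three agreement reports.

    Under ``failure_policy="permissive"`` a cell whose stratum slice lacks an
    intensity class is recorded under ``failures`` instead of aborting.
    """
    config = config or CalibrationConfig()
    cutpoints, failures = [], {}
    for stratum in STRATA:
        for side in SIDES:
            try:
                cutpoints.append(calibrate_cell(epochs, profiles, stratum, side, config))
            except InsufficientDataError as exc:
                if config.failure_policy != "permissive":
                    raise
                failures[f"{stratum}/{side}"] = str(exc)

    agreement = {}
    annotated = annotate_intensity(epochs, config)
    for stratum in STRATA:
        cell = _stratum_slice(annotated, profiles, stratum, config)
        pairs = _complete_pairs(cell.df)
        if len(pairs) == 0:
            if config.failure_policy != "permissive":
                raise InsufficientDataError(f"stratum {stratum!r}: no complete-pair epochs")
            failures[f"agreement/{stratum}"] = "no complete-pair epochs"
            continue
        agreement[stratum] = agreement_report(
            pairs["cpm_affected"].to_numpy(float),
            pairs["cpm_nonaffected"].to_numpy(float),
            pairs["participant_id"].to_numpy(),
            level=config.ci_level,
            icc_table=config.icc_categories,
        )
    return CalibrationResult(
        cutpoints=cutpoints,
        agreement=agreement,
        config_fingerprint=config.fingerprint(),
        failures=failures,
    )


def compare_sides(
    epochs: EpochTable,
    profiles,
    stratum: str,
    intensity: Intensity,
    config: CalibrationConfig | None = None,
) -> DeLongResult:
    """DeLong test of affected- vs non-affected-side diagnostic accuracy for
    one target intensity within one stratum, on paired complete-wrist epochs."""
    config = config or CalibrationConfig()
    annotated = annotate_intensity(epochs, config)
    cell = _stratum_slice(annotated, profiles, stratum, config)
    pairs = _complete_pairs(cell.df)
    pairs = pairs[pairs["intensity"].notna()]
    if len(pairs) == 0:
        raise InsufficientDataError(f"stratum {stratum!r}: no paired epochs")
    labels = np.fromiter((1 if c == intensity else 0 for c in pairs["intensity"]), dtype=int)
    direction = POSITIVE_IF_LE if intensity == Intensity.SB else POSITIVE_IF_GE
    return roc.delong_test(
        pairs["cpm_affected"].to_numpy(float),
        pairs["cpm_nonaffected"].to_numpy(float),
        labels,
        directions=direction,
    )
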