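"""Synthetic laboratory-session cohort with known ground truth.

The generator emulates a calibration study in adults with chronic stroke:
each participant wears one count-accumulating device per wrist while
performing a scripted hour of activities of daily living — four paced walks
(each followed by a 2 min seated recovery), sitting, cleaning, two resistance
exercises, lying and standing, 5 min each — with concurrent indirect
calorimetry.  METs are drawn per activity from log-normal distributions;
expected counts follow a strictly increasing piecewise-linear link f(METs);
the two wrists share a fraction rho of multiplicative log-normal count noise;
and the affected side is attenuated by a per-participant factor lambda drawn
around a stratum mean (lower in moderate-to-severe stroke).  The planted CPM
boundaries f(1.5) and f(3.0) are returned as ground truth so that cut-point
recovery can be tested.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ProvenanceError, WristcalError
from .io import EpochTable, ParticipantProfile
from .pipeline import CutPointSet

# Measurement protocol: 10 activities x 5 min, a 2 min recovery after each walk.
DEFAULT_SCHEDULE = (
    ("leisurely_walk", 5),
    ("recovery", 2),
    ("comfortable_walk", 5),
    ("recovery", 2),
    ("moderate_walk", 5),
    ("recovery", 2),
    ("brisk_walk", 5),
    ("recovery", 2),
    ("sitting", 5),
    ("cleaning", 5),
    ("bicep_curls", 5),
    ("chair_squats", 5),
    ("lying", 5),
    ("standing", 5),
)

# Median METs per activity (log-normal location).  The values straddle the
# 1.5 and 3.0 MET class boundaries; they are free parameters of the
# simulator, not estimates of any particular cohort.
DEFAULT_MET_MEDIANS = {
    "lying": 1.0,
    "sitting": 1.2,
    "recovery": 1.3,
    "standing": 1.6,
    "leisurely_walk": 2.2,
    "cleaning": 2.3,
    "comfortable_walk": 2.8,
    "bicep_curls": 3.2,
    "moderate_walk": 3.3,
    "chair_squats": 3.8,
    "brisk_walk": 4.3,
}

# Strictly increasing METs -> expected CPM link (piecewise linear between
# knots, last slope extrapolated).  f(1.5) = 150 and f(3.0) = 650 are the
# planted class boundaries on the count scale.
DEFAULT_LINK_KNOTS = ((0.0, 0.0), (1.5, 150.0), (3.0, 650.0), (6.0, 2600.0))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated calibration session."""

    n_participants: int = 43
    mild_fraction: float = 29 / 43
    seed: int = 7
    schedule: tuple = DEFAULT_SCHEDULE
    met_medians: dict = field(default_factory=lambda: dict(DEFAULT_MET_MEDIANS))
    met_log_sd: float = 0.12
    link_knots: tuple = DEFAULT_LINK_KNOTS
    count_log_sd: float = 0.80
    rho: float = 0.30  # between-wrist shared noise fraction
    lambda_mild: float = 0.95  # affected-side attenuation, mild stratum
    lambda_modsev: float = 0.70  # ... moderate-to-severe stratum
    lambda_concentration: float = 50.0  # Beta concentration of per-person lambda
    dropout: float = 0.09  # per-epoch probability a minute is lost

    def __post_init__(self):
        if not 0 < self.lambda_mild <= 1 or not 0 < self.lambda_modsev <= 1:
            raise WristcalError("lambda values must lie in (0, 1]")
        if not 0 <= self.rho <= 1:
            raise WristcalError("rho must lie in [0, 1]")
        if not 0 <= self.dropout < 1:
            raise WristcalError("dropout must lie in [0, 1)")
        if self.met_log_sd < 0 or self.count_log_sd < 0:
            raise WristcalError("dispersions must be non-negative")
        mets = [m for m, _ in self.link_knots]
        cpm = [c for _, c in self.link_knots]
        if any(b <= a for a, b in zip(mets, mets[1:])) or any(
            b <= a for a, b in zip(cpm, cpm[1:])
        ):
            raise WristcalError("link knots must be strictly increasing in both axes")

    def link(self, mets) -> np.ndarray:
        """Expected CPM at the given METs (strictly increasing)."""
        xs = np.array([m for m, _ in self.link_knots])
        ys = np.array([c for _, c in self.link_knots])
        m = np.asarray(mets, dtype=float)
        out = np.interp(m, xs, ys)
        # extrapolate with the terminal slopes to keep strict monotonicity
        lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        out = np.where(m < xs[0], ys[0] + (m - xs[0]) * lo_slope, out)
        out = np.where(m > xs[-1], ys[-1] + (m - xs[-1]) * hi_slope, out)
        return out

    def fingerprint(self) -> str:
        payload = {
            k: (sorted(v.items()) if isinstance(v, dict) else v)
            for k, v in self.__dict__.items()
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimulationTruth:
    """Planted quantities a recovery test can compare against."""

    sb_boundary_cpm: float  # f(1.5)
    mvpa_boundary_cpm: float  # f(3.0)
    lambdas: dict  # participant -> affected-side attenuation
    rho: float
    seed: int
    config_fingerprint: str

    def __post_init__(self):
        if not self.sb_boundary_cpm < self.mvpa_boundary_cpm:
            raise WristcalError("planted boundaries must satisfy f(1.5) < f(3.0)")


def _draw_lambda(rng, mean: float, conc: float) -> float:
    if mean >= 1.0:
        return 1.0
    a, b = mean * conc, (1.0 - mean) * conc
    return float(np.clip(rng.beta(a, b), 1e-6, 1.0))


def simulate_cohort(config: SimulationConfig | None = None):
    """Generate (profiles, epoch table, truth) for one simulated session.

    Identical config (including its seed) gives bit-identical output.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    n_mild = int(round(config.mild_fraction * n))
    is_mild = np.zeros(n, dtype=bool)
    is_mild[rng.permutation(n)[:n_mild]] = True

    profiles: list[ParticipantProfile] = []
    lambdas: dict = {}
    rows = []
    start = pd.Timestamp("2019-01-01 08:00:00")
    for i in range(n):
        pid = f"P{i + 1:02d}"
        mild = bool(is_mild[i])
        total = int(rng.integers(79, 99)) if mild else int(rng.integers(8, 79))
        lo_min, lo_max = max(0, total - 66), min(34, total)
        lower = int(rng.integers(lo_min, lo_max + 1))
        upper = total - lower
        age = float(np.clip(round(rng.normal(67, 7)), 55, 87))
        sex = "female" if rng.random() < 0.35 else "male"
        weight = float(np.clip(np.round(rng.normal(78, 14), 1), 45, 130))
        height = float(np.clip(np.round(rng.normal(170, 10), 1), 145, 200))
        side = "left" if rng.random() < 0.5 else "right"
        profiles.append(
            ParticipantProfile(
                participant_id=pid,
                age=age,
                sex=sex,
                weight=weight,
                height=height,
                fugl_meyer_upper=upper,
                fugl_meyer_lower=lower,
                fugl_meyer_total=total,
                affected_side=side,
            )
        )
        lam_mean = config.lambda_mild if mild else config.lambda_modsev
        lam = _draw_lambda(rng, lam_mean, config.lambda_concentration)
        lambdas[pid] = lam

        minute = 0
        for label, dur in config.schedule:
            median = config.met_medians[label]
            for _ in range(dur):
                ts = start + pd.Timedelta(minutes=minute)
                minute += 1
                mets = median * float(np.exp(rng.normal(0.0, config.met_log_sd))) if config.met_log_sd > 0 else median
                base = float(config.link(mets))
                z_shared, z_a, z_b = rng.normal(size=3)
                sr, si = np.sqrt(config.rho), np.sqrt(1.0 - config.rho)
                # mean-corrected multiplicative noise, deviates clipped at
                # 2.5 sd (wrist count accumulators saturate; unbounded
                # log-normal tails would exceed observed device ranges)
                sd = config.count_log_sd
                eps_aff = sd * np.clip(sr * z_shared + si * z_a, -2.5, 2.5) - sd**2 / 2
                eps_non = sd * np.clip(sr * z_shared + si * z_b, -2.5, 2.5) - sd**2 / 2
                cpm_aff = max(0, int(round(lam * base * np.exp(eps_aff))))
                cpm_non = max(0, int(round(base * np.exp(eps_non))))
                if rng.random() < config.dropout:
                    continue
                rows.append(
                    {
                        "participant_id": pid,
                        "timestamp": ts,
                        "activity": label,
                        "mets": mets,
                        "cpm_affected": cpm_aff,
                        "cpm_nonaffected": cpm_non,
                    }
                )

    df = pd.DataFrame(rows)
    truth = SimulationTruth(
        sb_boundary_cpm=float(config.link(1.5)),
        mvpa_boundary_cpm=float(config.link(3.0)),
        lambdas=lambdas,
        rho=config.rho,
        seed=config.seed,
        config_fingerprint=config.fingerprint(),
    )
    table = EpochTable(
        df=df,
        provenance=f"simulate_cohort seed={config.seed} fp={truth.config_fingerprint}",
    )
    return profiles, table, truth


def planted_recovery_error(
    truth: SimulationTruth, derived: CutPointSet, epochs: EpochTable | None = None
) -> dict:
    """Signed CPM error of the derived bounds against the planted boundaries.

    If the epoch table the cut-points were derived from is supplied, its
    provenance stamp must match the truth's config fingerprint.
    """
    if epochs is not None and truth.config_fingerprint not in (epochs.provenance or ""):
        raise ProvenanceError("epoch table does not stem from this simulation run")
    return {
        "sb": float(derived.sb_upper) - truth.sb_boundary_cpm,
        "mvpa": float(derived.mvpa_lower) - truth.mvpa_boundary_cpm,
    }
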