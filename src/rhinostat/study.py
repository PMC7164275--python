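"""Synthetic rhinomanometry study generator.

Emulates the design of a paediatric anterior active rhinomanometry (AAR)
repeatability study: five diagnosis groups (healthy controls HC,
non-allergic rhinitis NAR, perennial allergic rhinitis PAR, seasonal
allergic rhinitis outside/during the pollen season SAR-O/SAR-D) of 10
children each; four resistance parameters (Broms R2 and the resistances at
75, 100 and 150 Pa) per nostril (R/L, with TOT = R + L) and breathing
phase (inspiratory/expiratory); five within-day replicates at the baseline
visit and one measurement at follow-up visits on days 14 and 28; a binary
current-rhinitis-symptoms outcome and a total five-symptom score (T5SS).

The generative model per (subject, parameter, phase, side) is two-level:
a subject latent level around the group mean with between-subject variance
icc * total, and replicate noise with within variance (1 - icc) * total,
where the total variance is calibrated to published group-level means and
SDs of the combined (R + L) resistances.  The default noise family is
lognormal (resistances are positive and their SDs are of the order of the
means); a normal mode exists to match the simulation batches' assumptions
exactly for estimator-recovery tests, at the price of occasional
nonpositive values.

Follow-up visits add a day-level random effect (so between-day ICC falls
below within-day ICC) and an optional multiplicative drift per visit
(SAR-D defaults to a decreasing drift, mimicking regression of resistance
as the pollen season wanes).

Symptoms are Bernoulli with the group prevalence, optionally tilted by the
subject's latent resistance through a logistic link so that ROC analyses
have a tunable signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import ConfigError

__all__ = [
    "GroupProfile",
    "StudyConfig",
    "StudyDataset",
    "generate_study",
    "make_fixture",
    "default_groups",
    "PARAMETERS",
    "PHASES",
]

PARAMETERS = ("R2", "R75", "R100", "R150")
PHASES = ("inspiratory", "expiratory")
GROUPS = ("HC", "NAR", "PAR", "SAR-O", "SAR-D")

# Published group-level calibration: mean and SD of the combined (R + L)
# resistance, per (parameter, phase), units Pa.s/cm3.
_CALIBRATION = {
    "HC": {
        ("R2", "inspiratory"): (1.17, 0.52), ("R2", "expiratory"): (1.06, 0.50),
        ("R75", "inspiratory"): (1.09, 0.47), ("R75", "expiratory"): (0.93, 0.48),
        ("R100", "inspiratory"): (1.09, 0.47), ("R100", "expiratory"): (0.93, 0.51),
        ("R150", "inspiratory"): (1.10, 0.61), ("R150", "expiratory"): (0.64, 0.52),
    },
    "NAR": {
        ("R2", "inspiratory"): (1.18, 0.66), ("R2", "expiratory"): (1.20, 0.71),
        ("R75", "inspiratory"): (1.06, 0.66), ("R75", "expiratory"): (0.80, 0.88),
        ("R100", "inspiratory"): (1.03, 0.66), ("R100", "expiratory"): (0.68, 0.84),
        ("R150", "inspiratory"): (0.81, 0.80), ("R150", "expiratory"): (0.62, 0.89),
    },
    "PAR": {
        ("R2", "inspiratory"): (1.91, 1.69), ("R2", "expiratory"): (1.82, 1.52),
        ("R75", "inspiratory"): (1.85, 1.53), ("R75", "expiratory"): (1.85, 1.59),
        ("R100", "inspiratory"): (1.80, 1.52), ("R100", "expiratory"): (1.56, 1.47),
        ("R150", "inspiratory"): (1.88, 1.80), ("R150", "expiratory"): (1.47, 1.63),
    },
    "SAR-O": {
        ("R2", "inspiratory"): (2.56, 5.16), ("R2", "expiratory"): (1.86, 3.18),
        ("R75", "inspiratory"): (2.20, 2.40), ("R75", "expiratory"): (2.38, 2.41),
        ("R100", "inspiratory"): (1.99, 2.43), ("R100", "expiratory"): (1.90, 1.80),
        ("R150", "inspiratory"): (2.57, 5.15), ("R150", "expiratory"): (1.98, 3.28),
    },
    "SAR-D": {
        ("R2", "inspiratory"): (8.85, 11.77), ("R2", "expiratory"): (8.39, 10.69),
        ("R75", "inspiratory"): (8.48, 8.57), ("R75", "expiratory"): (8.87, 7.63),
        ("R100", "inspiratory"): (7.98, 8.75), ("R100", "expiratory"): (6.41, 4.74),
        ("R150", "inspiratory"): (8.88, 11.77), ("R150", "expiratory"): (8.41, 10.68),
    },
}

# Group prevalence of the current-rhinitis-symptoms outcome and rough
# anthropometric calibration (age years, weight kg, height cm) for the
# baseline descriptive table.
_SYMPTOM_PROB = {"HC": 0.60, "NAR": 0.80, "PAR": 0.90, "SAR-O": 1.00, "SAR-D": 1.00}
_FEMALE_PROB = {"HC": 0.60, "NAR": 0.50, "PAR": 0.40, "SAR-O": 0.40, "SAR-D": 0.50}
_AGE = {"HC": (11.3, 1.64), "NAR": (12.2, 1.14), "PAR": (12.0, 2.31),
        "SAR-O": (11.3, 1.49), "SAR-D": (12.0, 1.70)}
_WEIGHT = {"HC": (56.2, 28.67), "NAR": (52.1, 11.72), "PAR": (50.9, 12.71),
           "SAR-O": (44.9, 7.48), "SAR-D": (44.9, 7.94)}
_HEIGHT = {"HC": (155.2, 14.63), "NAR": (155.9, 9.62), "PAR": (154.5, 15.44),
           "SAR-O": (146.4, 7.90), "SAR-D": (151.5, 10.87)}

# Default within-day true ICCs per group, in the range of the observed
# within-day estimates (conveniences, not claims about the cohort).
_TRUE_ICC = {"HC": 0.50, "NAR": 0.55, "PAR": 0.85, "SAR-O": 0.80, "SAR-D": 0.75}


@dataclass(frozen=True)
class GroupProfile:
    """Ground truth for one diagnosis group.

    ``mean_resistance``/``sd_resistance`` map (parameter, phase) to the
    mean and SD of the *combined* (R + L) resistance; per-side values are
    generated with mean/2 and SD/sqrt(2) (symmetric nostrils, independent
    sides).  ``day_drift`` multiplies the latent level once per follow-up
    visit (drift at day 14, drift^2 at day 28).
    """

    label: str
    mean_resistance: dict
    sd_resistance: dict
    true_icc: float
    symptom_prob: float
    day_drift: float = 1.0

    def __post_init__(self):
        if not 0 < self.true_icc < 1:
            raise ConfigError(f"true_icc must lie in (0, 1), got {self.true_icc}")
        if not 0 <= self.symptom_prob <= 1:
            raise ConfigError("symptom_prob must lie in [0, 1]")
        if any(m <= 0 for m in self.mean_resistance.values()):
            raise ConfigError("mean resistances must be positive")
        if any(s <= 0 for s in self.sd_resistance.values()):
            raise ConfigError("resistance SDs must be positive")


def default_groups() -> list[GroupProfile]:
    """The five calibrated diagnosis groups; SAR-D carries a decreasing
    between-visit drift."""
    groups = []
    for label in GROUPS:
        cal = _CALIBRATION[label]
        groups.append(
            GroupProfile(
                label=label,
                mean_resistance={k: v[0] for k, v in cal.items()},
                sd_resistance={k: v[1] for k, v in cal.items()},
                true_icc=_TRUE_ICC[label],
                symptom_prob=_SYMPTOM_PROB[label],
                day_drift=0.80 if label == "SAR-D" else 1.0,
            )
        )
    return groups


@dataclass
class StudyConfig:
    """Design of a synthetic study.

    ``day_sigma_frac`` scales the day-level random effect as a fraction of
    the within-subject SD (0 disables it and makes between-day
    reproducibility perfect up to drift).  ``symptom_slope`` is the
    logistic slope linking symptoms to the standardised log latent
    resistance (0 = independent).
    """

    groups: list[GroupProfile] = field(default_factory=default_groups)
    n_per_group: int = 10
    replicates_visit1: int = 5
    followup_days: list[int] = field(default_factory=lambda: [14, 28])
    noise_family: str = "lognormal"
    day_sigma_frac: float = 0.5
    symptom_slope: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ConfigError("need n_per_group >= 2")
        if self.replicates_visit1 < 2:
            raise ConfigError("need replicates_visit1 >= 2")
        if self.noise_family not in ("normal", "lognormal"):
            raise ConfigError(f"unknown noise_family {self.noise_family!r}")
        if self.day_sigma_frac < 0:
            raise ConfigError("day_sigma_frac must be >= 0")


@dataclass
class StudyDataset:
    """Long-format records plus per-subject outcomes.

    ``records`` columns: subject_id, group, day (0/14/28), parameter
    (R2/R75/R100/R150), phase (inspiratory/expiratory), side (R/L/TOT),
    replicate (1..5 at day 0, 1 at follow-ups), value.  TOT = R + L holds
    record-wise by construction.  ``subjects`` columns: subject_id, group,
    symptoms (bool), t5ss (0-15), sex, age, weight, height, bmi.
    """

    records: pd.DataFrame
    subjects: pd.DataFrame
    config: StudyConfig | None = None


def _side_params(mean_tot: float, sd_tot: float, icc: float, family: str):
    """Per-side two-level parameters from the combined-total calibration.

    Normal family: latent ~ N(m, sb), value ~ N(latent, sw) with
    sb^2 = icc * s^2, sw^2 = (1 - icc) * s^2, m = mean_tot / 2,
    s = sd_tot / sqrt(2).  Lognormal family: the same split applied on the
    log scale after moment matching, so the marginal per-side mean and SD
    still match m and s.
    """
    m = mean_tot / 2.0
    s = sd_tot / np.sqrt(2.0)
    if family == "normal":
        return m, np.sqrt(icc) * s, np.sqrt(1.0 - icc) * s
    s2log = np.log1p((s / m) ** 2)
    mlog = np.log(m) - s2log / 2.0
    slog = np.sqrt(s2log)
    return mlog, np.sqrt(icc) * slog, np.sqrt(1.0 - icc) * slog


def generate_study(cfg: StudyConfig | None = None, **kwargs) -> StudyDataset:
    """Draw one synthetic study dataset; identical seed + config gives an
    identical dataset."""
    if cfg is None:
        cfg = StudyConfig(**kwargs)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    days = [0] + list(cfg.followup_days)
    k1 = cfg.replicates_visit1
    rec_frames = []
    subj_rows = []
    for g_idx, grp in enumerate(cfg.groups):
        n = cfg.n_per_group
        sids = [f"{grp.label}-{i + 1:03d}" for i in range(n)]
        # reference latent (log-)level of R2 TOT inspiratory, reused for the
        # symptom link
        ref_latent = None
        for param in PARAMETERS:
            for phase in PHASES:
                mean_tot = grp.mean_resistance[(param, phase)]
                sd_tot = grp.sd_resistance[(param, phase)]
                loc, sb, sw = _side_params(
                    mean_tot, sd_tot, grp.true_icc, cfg.noise_family
                )
                latent = loc + sb * rng.standard_normal((n, 2))  # (subject, side)
                if param == "R2" and phase == "inspiratory":
                    ref_latent = latent.sum(axis=1)
                sides = {}
                for d_idx, day in enumerate(days):
                    k = k1 if day == 0 else 1
                    if cfg.noise_family == "lognormal":
                        # multiplicative drift on the resistance scale
                        level = latent + d_idx * np.log(grp.day_drift)
                    else:
                        level = latent * grp.day_drift**d_idx
                    if d_idx > 0 and cfg.day_sigma_frac > 0:
                        level = level + cfg.day_sigma_frac * sw * rng.standard_normal(
                            (n, 2)
                        )
                    vals = level[:, :, None] + sw * rng.standard_normal((n, 2, k))
                    if cfg.noise_family == "lognormal":
                        vals = np.exp(vals)
                    sides[day] = vals
                for s_idx, side in enumerate(("R", "L")):
                    for day in days:
                        k = k1 if day == 0 else 1
                        v = sides[day][:, s_idx, :]
                        rec_frames.append(
                            pd.DataFrame(
                                {
                                    "subject_id": np.repeat(sids, k),
                                    "group": grp.label,
                                    "day": day,
                                    "parameter": param,
                                    "phase": phase,
                                    "side": side,
                                    "replicate": np.tile(np.arange(1, k + 1), n),
                                    "value": v.ravel(),
                                }
                            )
                        )
                for day in days:
                    k = k1 if day == 0 else 1
                    v = sides[day].sum(axis=1)  # TOT = R + L record-wise
                    rec_frames.append(
                        pd.DataFrame(
                            {
                                "subject_id": np.repeat(sids, k),
                                "group": grp.label,
                                "day": day,
                                "parameter": param,
                                "phase": phase,
                                "side": "TOT",
                                "replicate": np.tile(np.arange(1, k + 1), n),
                                "value": v.ravel(),
                            }
                        )
                    )
        # outcomes: logistic tilt of the group prevalence by the latent level
        z = (ref_latent - ref_latent.mean()) / (ref_latent.std(ddof=1) or 1.0)
        if 0.0 < grp.symptom_prob < 1.0 and cfg.symptom_slope != 0.0:
            p = expit(logit(grp.symptom_prob) + cfg.symptom_slope * z)
        else:
            p = np.full(n, grp.symptom_prob)
        symptoms = rng.random(n) < p
        t5ss = rng.binomial(15, np.where(symptoms, 0.45, 0.15))
        sex = np.where(rng.random(n) < _FEMALE_PROB[grp.label], "F", "M")
        age = np.clip(rng.normal(*_AGE[grp.label], n), 10, 16)
        weight = np.clip(rng.normal(*_WEIGHT[grp.label], n), 25, None)
        height = np.clip(rng.normal(*_HEIGHT[grp.label], n), 120, None)
        subj_rows.append(
            pd.DataFrame(
                {
                    "subject_id": sids,
                    "group": grp.label,
                    "symptoms": symptoms,
                    "t5ss": t5ss,
                    "sex": sex,
                    "age": age,
                    "weight": weight,
                    "height": height,
                    "bmi": weight / (height / 100.0) ** 2,
                }
            )
        )
    records = pd.concat(rec_frames, ignore_index=True)
    subjects = pd.concat(subj_rows, ignore_index=True)
    return StudyDataset(records=records, subjects=subjects, config=cfg)


def make_fixture(name: str, seed: int = 12345) -> StudyDataset:
    """Deterministic canned datasets.

    tiny: 2 groups x 3 subjects, 3 replicates — unit-test speed.
    paper_scale: the exact clinical design, 5 groups x 10 subjects, 5
    within-day replicates, follow-ups at days 14 and 28.
    recovery: 200 subjects per group in normal noise mode, for
    estimator-recovery tests against the configured true ICCs.
    """
    if name == "tiny":
        cfg = StudyConfig(
            groups=default_groups()[:2],
            n_per_group=3,
            replicates_visit1=3,
            seed=seed,
        )
    elif name == "paper_scale":
        cfg = StudyConfig(seed=seed)
    elif name == "recovery":
        cfg = StudyConfig(
            n_per_group=200,
            noise_family="normal",
            seed=seed,
        )
    else:
        raise ConfigError(f"unknown fixture {name!r}")
    return generate_study(cfg)
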