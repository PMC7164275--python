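"""Clinical-style analysis pipeline for a long-format AAR study dataset.

Stages mirror a repeatability/reproducibility study report:

* baseline descriptives with Kruskal-Wallis / chi-square group comparisons;
* within-day repeatability: one-way ICC (H0: ICC <= 0.20) and mean
  per-subject CV, per (group, parameter, phase, side) including the
  combined total (total inspiratory + total expiratory);
* between-day reproducibility: two-occasion ICC, two-point CV and
  nonparametric Bland-Altman between the day-0 summary and each follow-up;
* ROC analysis of AAR parameters against the current-symptoms outcome:
  Mann-Whitney AUC, DeLong variance/CI and stratified five-fold
  cross-validated AUC.

Every agreement number is produced by calling the corresponding
:mod:`rhinostat.agreement` operation on the extracted sub-table — there is
no pipeline-local arithmetic to drift out of sync.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .agreement import (
    BlandAltman,
    OneWayICC,
    RepeatedMeasures,
    cv_mean,
)
from .errors import DesignError, PositivityError
from .study import StudyDataset, PARAMETERS, PHASES

logger = logging.getLogger("rhinostat")

__all__ = [
    "RepeatabilityTable",
    "ReproducibilityTable",
    "ROCResult",
    "baseline_table",
    "with_combined_total",
    "within_day_repeatability",
    "between_day_reproducibility",
    "auc_mann_whitney",
    "delong_ci",
    "cross_validated_auc",
    "roc_table",
    "two_point_cv",
]


@dataclass
class RepeatabilityTable:
    """Within-day ICC/CV per (group, parameter, phase, side)."""

    table: pd.DataFrame
    rho0: float


@dataclass
class ReproducibilityTable:
    """Between-day CV/ICC/Bland-Altman per (group, parameter, day pair)."""

    table: pd.DataFrame
    agreements: dict  # (group, parameter, day) -> BlandAltmanResults
    day0_summary: str


@dataclass
class ROCResult:
    """Nonparametric AUC with DeLong inference and cross-validated AUC.

    ``auc`` equals the Mann-Whitney statistic of the scores against the
    binary outcome; ``ci95`` is the Wald interval on the AUC scale, clipped
    to [0, 1]; ``p_value`` tests AUC = 0.5.  ``cv_auc`` is the mean
    held-out-fold AUC of a stratified k-fold split of the raw scores.
    """

    auc: float
    delong_se: float
    ci95: tuple[float, float]
    p_value: float
    cv_auc: float | None = None
    folds: int | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def baseline_table(
    subjects: pd.DataFrame,
    quantitative: tuple[str, ...] = ("age", "weight", "height", "bmi"),
    categorical: tuple[str, ...] = ("sex", "symptoms"),
    group: str = "group",
) -> pd.DataFrame:
    """Per-group descriptives with group-comparison p-values.

    Quantitative covariates: mean +/- SD and a Kruskal-Wallis test across
    groups; categorical: count (%) of the modal/true level and a chi-square
    test.  With a single group the comparison column is omitted.
    """
    groups = sorted(subjects[group].unique())
    compare = len(groups) >= 2
    if not compare:
        warnings.warn("single group: comparison p-values omitted")
    rows = []
    for cov in quantitative:
        if cov not in subjects:
            continue
        cells = {
            g: f"{s.mean():.2f} ± {s.std(ddof=1):.2f}"
            for g, s in subjects.groupby(group)[cov]
        }
        p = None
        if compare:
            samples = [s.to_numpy() for _, s in subjects.groupby(group)[cov]]
            if np.ptp(subjects[cov].to_numpy()) == 0:
                warnings.warn(f"covariate {cov!r} is constant; test omitted")
            else:
                p = float(stats.kruskal(*samples).pvalue)
        rows.append({"covariate": cov, "type": "quantitative", **cells, "p_value": p})
    for cov in categorical:
        if cov not in subjects:
            continue
        col = subjects[cov]
        level = True if col.dtype == bool else sorted(col.unique())[0]
        cells = {}
        for g, s in subjects.groupby(group)[cov]:
            cnt = int((s == level).sum())
            cells[g] = f"{cnt} ({100.0 * cnt / len(s):.1f}%)"
        p = None
        if compare:
            ct = pd.crosstab(subjects[group], col)
            if ct.shape[1] < 2:
                warnings.warn(f"covariate {cov!r} is constant; test omitted")
            else:
                p = float(stats.chi2_contingency(ct.to_numpy()).pvalue)
        rows.append(
            {"covariate": f"{cov}={level}", "type": "categorical", **cells, "p_value": p}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeatability / reproducibility
# ---------------------------------------------------------------------------

def with_combined_total(records: pd.DataFrame) -> pd.DataFrame:
    """Append combined-total rows: phase "combined", side "TOT", value =
    total inspiratory + total expiratory per (subject, day, parameter,
    replicate)."""
    tot = records[records["side"] == "TOT"]
    keys = ["subject_id", "group", "day", "parameter", "replicate"]
    wide = tot.pivot_table(index=keys, columns="phase", values="value").reset_index()
    if not set(PHASES) <= set(wide.columns):
        return records
    wide["value"] = wide["inspiratory"] + wide["expiratory"]
    wide["phase"] = "combined"
    wide["side"] = "TOT"
    combined = wide[keys + ["phase", "side", "value"]]
    return pd.concat([records, combined], ignore_index=True)


def _pivot_visit1(sub: pd.DataFrame) -> RepeatedMeasures | None:
    """Subjects x replicates table from day-0 rows, dropping incomplete
    subjects."""
    k = int(sub["replicate"].max())
    wide = sub.pivot_table(
        index="subject_id", columns="replicate", values="value"
    )
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.info("dropped %d subjects with incomplete replicates", dropped)
    if len(complete) < 2 or complete.shape[1] < 2 or complete.shape[1] != k:
        return None
    return RepeatedMeasures(complete.to_numpy(), subject_ids=list(complete.index))


def within_day_repeatability(
    data: StudyDataset, rho0: float = 0.20
) -> RepeatabilityTable:
    """Within-day ICC and mean per-subject CV per (group, parameter, phase,
    side), from the five baseline replicates.

    Keys whose per-subject mean is nonpositive (possible in normal noise
    mode) get ``mean_cv = NaN`` — the CV is undefined there by its
    positivity requirement — while the ICC is still reported.
    """
    records = with_combined_total(data.records)
    day0 = records[records["day"] == 0]
    rows = []
    for (grp, param, phase, side), sub in day0.groupby(
        ["group", "parameter", "phase", "side"], sort=True
    ):
        rm = _pivot_visit1(sub)
        if rm is None:
            continue
        res = OneWayICC(rm, rho0=rho0).fit()
        try:
            cvr = cv_mean(rm)
            mean_cv, acceptable = cvr.mean_cv, cvr.acceptable
        except PositivityError as exc:
            logger.warning(
                "CV undefined for %s/%s/%s/%s: %s", grp, param, phase, side, exc
            )
            mean_cv, acceptable = float("nan"), None
        rows.append(
            {
                "group": grp,
                "parameter": param,
                "phase": phase,
                "side": side,
                "n_subjects": rm.n_subjects,
                "icc": res.estimate,
                "f_statistic": res.f_statistic,
                "p_value": res.p_value,
                "benchmark": res.benchmark,
                "mean_cv": mean_cv,
                "cv_acceptable": acceptable,
            }
        )
    return RepeatabilityTable(table=pd.DataFrame(rows), rho0=rho0)


def two_point_cv(a: float, b: float) -> float:
    """CV of a two-measurement pair: |a - b| / (sqrt(2) * mean(a, b))."""
    m = (a + b) / 2.0
    if m <= 0:
        raise PositivityError(f"pair mean must be positive, got {m}")
    return abs(a - b) / (np.sqrt(2.0) * m)


def between_day_reproducibility(
    data: StudyDataset,
    day0_summary: str = "mean",
    rho0: float = 0.20,
) -> ReproducibilityTable:
    """Between-day reproducibility of the combined total per parameter.

    For each (group, parameter, follow-up day): pair the day-0 summary
    (mean of the five baseline replicates, or the first replicate if
    ``day0_summary="first"``) with the follow-up measurement; report the
    two-occasion one-way ICC, the mean two-point CV, and the nonparametric
    Bland-Altman agreement (differences day0 - later).  When the
    heteroscedasticity test is significant and all values are positive,
    a log-scale Bland-Altman rerun is attached as well.
    """
    if day0_summary not in ("mean", "first"):
        raise DesignError("day0_summary must be 'mean' or 'first'")
    records = with_combined_total(data.records)
    comb = records[(records["phase"] == "combined") & (records["side"] == "TOT")]
    day0 = comb[comb["day"] == 0]
    if day0_summary == "first":
        day0 = day0[day0["replicate"] == 1]
    base = day0.groupby(["group", "parameter", "subject_id"])["value"].mean()
    followups = sorted(d for d in comb["day"].unique() if d != 0)
    if not followups:
        raise DesignError("no follow-up days present")
    rows, agreements = [], {}
    for day in followups:
        later = (
            comb[comb["day"] == day]
            .set_index(["group", "parameter", "subject_id"])["value"]
            .sort_index()
        )
        for (grp, param), sub in base.groupby(level=["group", "parameter"]):
            pair = pd.concat(
                [sub.droplevel([0, 1]), later.loc[grp, param]], axis=1,
                keys=["day0", "later"],
            )
            complete = pair.dropna()
            if len(complete) < len(pair):
                logger.info(
                    "dropped %d subjects without day-%s follow-up (%s/%s)",
                    len(pair) - len(complete), day, grp, param,
                )
            if len(complete) < 3:
                continue
            rm = RepeatedMeasures(
                complete.to_numpy(), subject_ids=list(complete.index)
            )
            icc = OneWayICC(rm, rho0=rho0).fit()
            try:
                cv = float(
                    np.mean(
                        [two_point_cv(a, b) for a, b in complete.to_numpy()]
                    )
                )
            except PositivityError:
                cv = float("nan")
            ba = BlandAltman(
                complete["day0"].to_numpy(), complete["later"].to_numpy()
            ).fit()
            agreements[(grp, param, day)] = ba
            if ba.heteroscedastic and (complete.to_numpy() > 0).all():
                agreements[(grp, param, day, "log")] = BlandAltman(
                    complete["day0"].to_numpy(),
                    complete["later"].to_numpy(),
                    log_scale=True,
                ).fit()
            rows.append(
                {
                    "group": grp,
                    "parameter": param,
                    "day_pair": f"(0, {day})",
                    "n_subjects": len(complete),
                    "cv": cv,
                    "icc": icc.estimate,
                    "p_value": icc.p_value,
                    "bias": ba.bias,
                    "loa_lower": ba.loa_lower,
                    "loa_upper": ba.loa_upper,
                    "hetero_rho": ba.hetero_rho,
                    "hetero_p": ba.hetero_p,
                }
            )
    return ReproducibilityTable(
        table=pd.DataFrame(rows), agreements=agreements, day0_summary=day0_summary
    )


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray):
    if labels.all() or not labels.any():
        raise DesignError("both outcome classes must be present")


def auc_mann_whitney(scores, labels) -> float:
    """Nonparametric AUC: fraction of case-control pairs ranked correctly,
    ties counted half (the Mann-Whitney U statistic normalised by
    n_case * n_control)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise DesignError("scores and labels must have equal length")
    _check_two_classes(y)
    ranks = stats.rankdata(s)
    n1 = int(y.sum())
    n0 = y.size - n1
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components: per-case placements V10 (fraction of
    controls below, ties half) and per-control placements V01."""
    cases = scores[labels]
    controls = scores[~labels]
    cmp = (cases[:, None] > controls[None, :]).astype(float)
    cmp += 0.5 * (cases[:, None] == controls[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def delong_ci(scores, labels, level: float = 0.95) -> ROCResult:
    """AUC with DeLong variance and Wald confidence interval.

    var = Var(V10)/m + Var(V01)/n (sample variances of the case and
    control placement values).  Perfect separation gives variance 0 and a
    point interval.  ``p_value`` is the two-sided z test of AUC = 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_classes(y)
    if y.sum() < 2 or (~y).sum() < 2:
        raise DesignError("need at least 2 cases and 2 controls")
    v10, v01 = _placements(s, y)
    # point estimate via the rank identity, so it is bit-identical to
    # auc_mann_whitney on every input
    auc = auc_mann_whitney(s, y)
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo = float(np.clip(auc - z * se, 0.0, 1.0))
    hi = float(np.clip(auc + z * se, 0.0, 1.0))
    if se == 0.0:
        logger.warning("degenerate DeLong variance (perfect separation)")
        p = 0.0 if auc != 0.5 else 1.0
    else:
        p = float(2.0 * stats.norm.sf(abs(auc - 0.5) / se))
    return ROCResult(auc=auc, delong_se=se, ci95=(lo, hi), p_value=p)


def cross_validated_auc(scores, labels, folds: int = 5, seed: int = 0) -> float:
    """Mean held-out-fold AUC of a stratified k-fold split.

    The raw parameter is the score (a single-variable threshold
    classifier); nothing is fitted, so cross-validation here only removes
    the optimism of evaluating fold composition, as a sanity companion to
    the full-sample AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_classes(y)
    n_min = int(min(y.sum(), (~y).sum()))
    if n_min < folds:
        raise DesignError(
            f"minority class has {n_min} members; cannot stratify {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = [auc_mann_whitney(s[test], y[test]) for _, test in skf.split(s, y)]
    return float(np.mean(aucs))


def roc_table(
    data: StudyDataset,
    parameters=PARAMETERS,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """AUC / DeLong CI / cross-validated AUC of each AAR parameter
    (baseline mean of the total per phase, plus the combined total) for
    predicting the current-symptoms outcome, over the whole cohort."""
    records = with_combined_total(data.records)
    day0 = records[(records["day"] == 0) & (records["side"] == "TOT")]
    outcome = data.subjects.set_index("subject_id")["symptoms"]
    rows = []
    for param in parameters:
        for phase in list(PHASES) + ["combined"]:
            sub = day0[(day0["parameter"] == param) & (day0["phase"] == phase)]
            if sub.empty:
                continue
            score = sub.groupby("subject_id")["value"].mean()
            y = outcome.loc[score.index].to_numpy()
            if y.all() or not y.any():
                logger.warning("single outcome class; ROC skipped for %s/%s",
                               param, phase)
                continue
            res = delong_ci(score.to_numpy(), y)
            try:
                cv_auc = cross_validated_auc(
                    score.to_numpy(), y, folds=folds, seed=seed
                )
            except DesignError:
                cv_auc = float("nan")
            rows.append(
                {
                    "parameter": param,
                    "phase": phase,
                    "auc": res.auc,
                    "delong_se": res.delong_se,
                    "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1],
                    "p_value": res.p_value,
                    "cv_auc": cv_auc,
                    "folds": folds,
                }
            )
    return pd.DataFrame(rows)
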