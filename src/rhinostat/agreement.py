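"""Agreement indices for repeated measurements.

Implements the three repeatability/reproducibility statistics compared in
this package: the one-way random-effects intraclass correlation coefficient
(ICC) with its F test against a null reliability threshold, the coefficient
of variation (per-subject and pooled), and Bland-Altman agreement between
two measurement occasions with nonparametric (percentile) limits.

The ICC used throughout is the single-measurement, one-way random-effects
form

    ICC = sigma_B^2 / (sigma_B^2 + sigma_W^2),

estimated by method of moments from the one-way ANOVA mean squares of an
n-subjects x k-replicates table.  The estimator may be negative; it is
reported unclamped so that simulation summaries remain unbiased, and the
qualitative benchmark maps any value <= 0.20 to "poor".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AgreementUndefinedError,
    DesignError,
    MissingDataError,
    PositivityError,
)

__all__ = [
    "RepeatedMeasures",
    "VarianceComponents",
    "OneWayICC",
    "ICCResults",
    "BlandAltman",
    "BlandAltmanResults",
    "CVResult",
    "anova_oneway",
    "icc_oneway",
    "icc_benchmark",
    "cv_per_subject",
    "cv_mean",
    "cv_pooled",
    "bland_altman",
    "percentile",
]

BENCHMARKS = ("poor", "fair", "moderate", "substantial", "excellent")


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

class RepeatedMeasures:
    """An n-subjects x k-replicates table of measurements.

    Rows are subjects, columns replicates.  The one-way analysis treats the
    columns as exchangeable: there is no replicate (rater/occasion) effect,
    only a subject effect plus measurement error.

    Parameters
    ----------
    values : array-like, shape (n, k)
        Measurements; no missing entries allowed (drop incomplete subjects
        before constructing).
    subject_ids : sequence of hashable, optional
        Row labels; defaults to 0..n-1.
    """

    def __init__(self, values, subject_ids: Sequence | None = None):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise DesignError("values must be a 2-D (subjects x replicates) table")
        n, k = arr.shape
        if n < 2 or k < 2:
            raise DesignError(
                f"need at least 2 subjects and 2 replicates, got {n} x {k}"
            )
        if not np.all(np.isfinite(arr)):
            raise MissingDataError(
                "missing or non-finite entries; drop incomplete subjects first"
            )
        if subject_ids is None:
            subject_ids = list(range(n))
        if len(subject_ids) != n:
            raise DesignError("subject_ids length does not match number of rows")
        self.values = arr
        self.subject_ids = list(subject_ids)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        subject: str = "subject_id",
        value: str = "value",
        replicate: str | None = None,
    ) -> "RepeatedMeasures":
        """Pivot a long-format frame into a rectangular table.

        Subjects with an incomplete set of replicates are dropped (the
        one-way analysis here is balanced-only).
        """
        if replicate is None:
            wide = df.groupby(subject)[value].apply(lambda s: s.to_numpy())
        else:
            wide = (
                df.sort_values(replicate)
                .groupby(subject)[value]
                .apply(lambda s: s.to_numpy())
            )
        k = int(max(len(v) for v in wide))
        keep = wide[wide.apply(len) == k]
        return cls(np.vstack(keep.to_numpy()), subject_ids=list(keep.index))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RepeatedMeasures(n={self.n_subjects}, k={self.n_replicates})"


def _as_rm(data) -> RepeatedMeasures:
    if isinstance(data, RepeatedMeasures):
        return data
    return RepeatedMeasures(data)


# ---------------------------------------------------------------------------
# one-way ANOVA and ICC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceComponents:
    """Mean squares and method-of-moments variance components of a balanced
    one-way random-effects ANOVA.

    ``sigma2_between`` may be negative (when MS_between < MS_within); it is
    reported as computed.
    """

    ms_between: float
    ms_within: float
    sigma2_between: float
    sigma2_within: float
    df_between: int
    df_within: int


def anova_oneway(data) -> VarianceComponents:
    """Balanced one-way random-effects ANOVA of a subjects x replicates table.

    MS_between = k * Var(row means), MS_within = mean of row variances
    (sample variances, denominator k - 1).
    """
    rm = _as_rm(data)
    x = rm.values
    n, k = x.shape
    row_means = x.mean(axis=1)
    ms_between = k * float(np.var(row_means, ddof=1))
    ms_within = float(np.mean(np.var(x, axis=1, ddof=1)))
    return VarianceComponents(
        ms_between=ms_between,
        ms_within=ms_within,
        sigma2_between=(ms_between - ms_within) / k,
        sigma2_within=ms_within,
        df_between=n - 1,
        df_within=n * (k - 1),
    )


def icc_benchmark(icc: float) -> str:
    """Qualitative agreement label for an ICC value.

    poor (<= 0.20), fair (0.20, 0.40], moderate (0.40, 0.60],
    substantial (0.60, 0.80], excellent (> 0.80).  Negative estimates are
    "poor".
    """
    if icc > 0.80:
        return "excellent"
    if icc > 0.60:
        return "substantial"
    if icc > 0.40:
        return "moderate"
    if icc > 0.20:
        return "fair"
    return "poor"


@dataclass
class ICCResults:
    """Fitted one-way random-effects ICC.

    Attributes
    ----------
    estimate : float
        Method-of-moments ICC, (MSB - MSW) / (MSB + (k-1) MSW); can be
        negative, at most 1.
    components : VarianceComponents
    rho0 : float
        Null reliability threshold of the significance test
        H0: ICC <= rho0 vs H1: ICC > rho0.
    f_statistic : float
        (MSB/MSW) * (1 - rho0) / (1 + (k-1) rho0), referred to
        F(n-1, n(k-1)); +inf when MSW = 0 and MSB > 0.
    p_value : float
        One-sided upper tail probability.
    conf_int : (float, float)
        Exact F-pivot confidence interval for the ICC (Searle), at
        ``conf_level``.
    """

    estimate: float
    components: VarianceComponents
    rho0: float
    f_statistic: float
    p_value: float
    benchmark: str
    conf_int: tuple[float, float]
    conf_level: float
    n_subjects: int
    n_replicates: int
    model: "OneWayICC | None" = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def summary(self) -> str:
        vc = self.components
        lines = [
            "One-way random-effects ICC (single measurement)",
            "=" * 55,
            f"subjects: {self.n_subjects:<6d} replicates: {self.n_replicates}",
            f"MS between: {vc.ms_between:12.6g}   MS within: {vc.ms_within:12.6g}",
            f"sigma2_B:   {vc.sigma2_between:12.6g}   sigma2_W:  {vc.sigma2_within:12.6g}",
            "-" * 55,
            f"ICC estimate: {self.estimate:8.4f}   [{self.benchmark}]",
            f"{self.conf_level:.0%} CI: ({self.conf_int[0]:.4f}, {self.conf_int[1]:.4f})",
            f"H0: ICC <= {self.rho0:.2f}   F({vc.df_between}, {vc.df_within}) "
            f"= {self.f_statistic:.4f}   p = {self.p_value:.4g}",
            "=" * 55,
        ]
        return "\n".join(lines)


class OneWayICC:
    """One-way random-effects ICC model for a repeated-measures table.

    The model is X_ij = mu + b_i + e_ij with b_i ~ N(0, sigma_B^2) and
    e_ij ~ N(0, sigma_W^2); the ICC is the intra-subject correlation
    sigma_B^2 / (sigma_B^2 + sigma_W^2).  ``fit`` estimates it by method of
    moments and tests H0: ICC <= rho0 with the scaled F statistic.

    Parameters
    ----------
    data : RepeatedMeasures or array-like (n, k)
    rho0 : float in [0, 1)
        Null threshold; 0.20 separates "poor" from "fair" agreement.
    """

    def __init__(self, data, rho0: float = 0.20):
        self.data = _as_rm(data)
        if not 0 <= rho0 < 1:
            raise DesignError(f"rho0 must be in [0, 1), got {rho0}")
        self.rho0 = float(rho0)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        subject: str = "subject_id",
        value: str = "value",
        rho0: float = 0.20,
    ) -> "OneWayICC":
        return cls(RepeatedMeasures.from_long(df, subject=subject, value=value), rho0=rho0)

    def fit(self, conf_level: float = 0.95) -> ICCResults:
        vc = anova_oneway(self.data)
        n, k = self.data.n_subjects, self.data.n_replicates
        msb, msw = vc.ms_between, vc.ms_within
        if msw == 0.0 and msb == 0.0:
            raise AgreementUndefinedError(
                "all values identical: ICC is undefined (0/0)"
            )
        scale = (1.0 - self.rho0) / (1.0 + (k - 1) * self.rho0)
        if msw == 0.0:
            estimate, f_stat, p = 1.0, math.inf, 0.0
        else:
            estimate = (msb - msw) / (msb + (k - 1) * msw)
            f_stat = (msb / msw) * scale
            p = float(stats.f.sf(f_stat, vc.df_between, vc.df_within))
        ci = self._conf_int(msb, msw, n, k, conf_level)
        return ICCResults(
            estimate=estimate,
            components=vc,
            rho0=self.rho0,
            f_statistic=f_stat,
            p_value=p,
            benchmark=icc_benchmark(estimate),
            conf_int=ci,
            conf_level=conf_level,
            n_subjects=n,
            n_replicates=k,
            model=self,
        )

    @staticmethod
    def _conf_int(msb, msw, n, k, level) -> tuple[float, float]:
        # Exact interval from the F pivot of the one-way model.
        if msw == 0.0:
            return (1.0, 1.0)
        alpha = 1.0 - level
        fobs = msb / msw
        fl = fobs / stats.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
        fu = fobs * stats.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
        lo = (fl - 1.0) / (fl + k - 1.0)
        hi = (fu - 1.0) / (fu + k - 1.0)
        return (lo, hi)


def icc_oneway(data, rho0: float = 0.20) -> ICCResults:
    """Functional shorthand for ``OneWayICC(data, rho0).fit()``."""
    return OneWayICC(data, rho0=rho0).fit()


# ---------------------------------------------------------------------------
# coefficients of variation
# ---------------------------------------------------------------------------

def cv_per_subject(values) -> float:
    """Per-subject CV: sample SD (denominator length-1) over sample mean.

    Only meaningful on a ratio scale; the mean must be strictly positive.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise DesignError("need a 1-D series of length >= 2")
    m = float(arr.mean())
    if m <= 0:
        raise PositivityError(f"mean must be positive to form a CV, got {m}")
    return float(arr.std(ddof=1)) / m


@dataclass(frozen=True)
class CVResult:
    """Row-wise CVs of a repeated-measures table and their mean.

    ``acceptable`` applies the conventional strict CV < 15% rule to the
    mean CV; exactly 0.15 is not acceptable.
    """

    per_subject: tuple[float, ...]
    mean_cv: float
    acceptable: bool
    threshold: float = 0.15


def cv_mean(data, threshold: float = 0.15) -> CVResult:
    """Mean of the per-subject CVs across the rows of a table."""
    rm = _as_rm(data)
    cvs = []
    for sid, row in zip(rm.subject_ids, rm.values):
        try:
            cvs.append(cv_per_subject(row))
        except PositivityError as exc:
            raise PositivityError(
                f"subject {sid!r}: {exc}", subject_id=sid
            ) from exc
    mean_cv = float(np.mean(cvs))
    return CVResult(
        per_subject=tuple(cvs),
        mean_cv=mean_cv,
        acceptable=mean_cv < threshold,
        threshold=threshold,
    )


def cv_pooled(data) -> float:
    """Pooled CV: sample SD of all n*k values over their grand mean.

    This treats the whole table as one sample, so between-subject spread
    inflates it relative to the per-subject CV — which is exactly the
    behaviour the simulation study quantifies.
    """
    arr = np.asarray(getattr(data, "values", data), dtype=float).ravel()
    if arr.size < 2:
        raise DesignError("need at least 2 values")
    m = float(arr.mean())
    if m <= 0:
        raise PositivityError(f"grand mean must be positive, got {m}")
    return float(arr.std(ddof=1)) / m


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def percentile(values, p: float) -> float:
    """Percentile with linear interpolation between order statistics.

    Uses the endpoint-inclusive convention where percentile ``p`` (in
    [0, 100]) of m sorted values interpolates at rank 1 + (p/100)*(m-1).
    This single dialect is used everywhere in the package (it coincides
    with numpy's default "linear" method).
    """
    return float(np.percentile(np.asarray(values, dtype=float), p, method="linear"))


@dataclass
class BlandAltmanResults:
    """Pairwise agreement between two measurement occasions.

    ``differences`` are first - second; ``loa_lower``/``loa_upper`` are the
    5th/95th percentiles of the differences in nonparametric mode, or
    bias +/- 1.96 SD in parametric mode.  ``hetero_rho``/``hetero_p`` give a
    Spearman rank-correlation test of |difference| against the pairwise
    mean: a small p flags heteroscedasticity, for which a log-scale rerun
    is the usual remedy.
    """

    differences: np.ndarray
    means: np.ndarray
    bias: float
    loa_lower: float
    loa_upper: float
    hetero_rho: float
    hetero_p: float
    log_transformed: bool
    mode: str

    @property
    def heteroscedastic(self) -> bool:
        return self.hetero_p < 0.05

    def summary(self) -> str:
        scale = "log scale" if self.log_transformed else "original scale"
        lines = [
            f"Bland-Altman agreement ({self.mode}, {scale})",
            "=" * 55,
            f"pairs: {len(self.differences)}",
            f"bias (first - second): {self.bias: .4f}",
            f"limits of agreement: ({self.loa_lower:.4f}, {self.loa_upper:.4f})",
            f"heteroscedasticity: Spearman rho = {self.hetero_rho:.3f}, "
            f"p = {self.hetero_p:.3g}",
            "=" * 55,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Difference-vs-mean plot with bias and agreement limits."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.means, self.differences, s=18, alpha=0.8)
        ax.axhline(self.bias, color="k", lw=1)
        for y in (self.loa_lower, self.loa_upper):
            ax.axhline(y, color="k", lw=1, ls="--")
        ax.set_xlabel("mean of pair")
        ax.set_ylabel("difference (first - second)")
        return ax


class BlandAltman:
    """Bland-Altman agreement model for two paired measurement series.

    Parameters
    ----------
    first, second : array-like, equal length >= 3
        Paired measurements (e.g. baseline summary vs follow-up visit).
        Differences are taken first - second.
    mode : {"nonparametric", "parametric"}
        Nonparametric limits are the 5th and 95th percentiles of the
        differences (recommended when differences are not normal);
        parametric limits are bias +/- 1.96 SD.
    log_scale : bool
        Analyse log-transformed values (requires positive data); used when
        the spread of differences grows with the mean.
    """

    def __init__(self, first, second, mode: str = "nonparametric",
                 log_scale: bool = False):
        a = np.asarray(first, dtype=float)
        b = np.asarray(second, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise DesignError("first and second must be 1-D of equal length")
        if a.size < 3:
            raise DesignError("need at least 3 pairs")
        if mode not in ("nonparametric", "parametric"):
            raise DesignError(f"unknown mode {mode!r}")
        if log_scale and (np.any(a <= 0) or np.any(b <= 0)):
            raise PositivityError("log_scale requires strictly positive values")
        self.first, self.second = a, b
        self.mode = mode
        self.log_scale = log_scale

    def fit(self) -> BlandAltmanResults:
        a, b = self.first, self.second
        if self.log_scale:
            a, b = np.log(a), np.log(b)
        diff = a - b
        mean = (a + b) / 2.0
        bias = float(diff.mean())
        if self.mode == "nonparametric":
            lo, hi = percentile(diff, 5), percentile(diff, 95)
        else:
            sd = float(diff.std(ddof=1))
            lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
        absdiff = np.abs(diff)
        if np.ptp(absdiff) == 0 or np.ptp(mean) == 0:
            rho, p = 0.0, 1.0  # degenerate: no spread, nothing to correlate
        else:
            rho, p = stats.spearmanr(absdiff, mean)
            rho, p = float(rho), float(p)
        return BlandAltmanResults(
            differences=diff,
            means=mean,
            bias=bias,
            loa_lower=lo,
            loa_upper=hi,
            hetero_rho=rho,
            hetero_p=p,
            log_transformed=self.log_scale,
            mode=self.mode,
        )


def bland_altman(first, second, mode: str = "nonparametric",
                 log_scale: bool = False) -> BlandAltmanResults:
    """Functional shorthand for ``BlandAltman(...).fit()``."""
    return BlandAltman(first, second, mode=mode, log_scale=log_scale).fit()
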