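"""Sample-size determination for agreement studies.

Two planners:

* :func:`icc_sample_size` — Zou's subjects-per-group formula for testing
  H0: ICC <= rho0 against an expected ICC rho1 with k replicates per
  subject, based on the asymptotic normality of the log of the one-way
  F ratio.
* :func:`ba_sample_size` — number of subjects needed for a Bland-Altman
  agreement study so that, with the requested power, both 95% limits of
  agreement (with their confidence bounds) fall inside a symmetric
  +/- max_allowed_diff region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from scipy import stats

from .errors import InfeasibleDesignError, ConfigError

__all__ = [
    "IccSampleSizeRequest",
    "SampleSizeResult",
    "icc_sample_size",
    "ba_sample_size",
]


@dataclass(frozen=True)
class IccSampleSizeRequest:
    """Design of an ICC hypothesis test.

    rho1 is the ICC one expects to observe, rho0 the null threshold to
    reject (0.20 = upper edge of "poor agreement"), k the replicates per
    subject.  tails selects the critical value z_{1-alpha} (1) or
    z_{1-alpha/2} (2).
    """

    rho1: float
    rho0: float = 0.20
    k: int = 2
    alpha: float = 0.05
    power: float = 0.80
    tails: int = 2

    def __post_init__(self):
        if not (0 <= self.rho0 < 1 and self.rho1 < 1):
            raise ConfigError("ICCs must lie below 1 with rho0 in [0, 1)")
        if self.rho1 <= self.rho0:
            raise InfeasibleDesignError(
                f"expected ICC ({self.rho1}) must exceed the null ({self.rho0})"
            )
        if self.k < 2:
            raise ConfigError("need k >= 2 replicates per subject")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ConfigError("alpha and power must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ConfigError("tails must be 1 or 2")


@dataclass(frozen=True)
class SampleSizeResult:
    """Subjects per group: ``n`` is the ceiling of the real-valued solution
    ``n_raw``; ``request`` echoes the design."""

    n: int
    n_raw: float
    request: dict

    def to_dict(self) -> dict:
        return {"n": self.n, "n_raw": self.n_raw, "request": self.request}


def _zou_C(rho: float, k: int) -> float:
    return (1.0 + (k - 1) * rho) / (1.0 - rho)


def icc_sample_size(
    req: IccSampleSizeRequest | None = None, **kwargs
) -> SampleSizeResult:
    """Subjects per group for the one-way ICC test, by Zou's method.

    n_raw = 1 + 2 k (z_a + z_b)^2 / [ (k-1) (ln(C1/C0))^2 ] with
    C(rho) = (1 + (k-1) rho) / (1 - rho); the returned n is the ceiling.
    z_a is z_{1-alpha} or z_{1-alpha/2} according to ``tails``; z_b is
    z_{power}.
    """
    if req is None:
        req = IccSampleSizeRequest(**kwargs)
    za = stats.norm.ppf(1.0 - req.alpha / req.tails)
    zb = stats.norm.ppf(req.power)
    log_ratio = math.log(_zou_C(req.rho1, req.k) / _zou_C(req.rho0, req.k))
    n_raw = 1.0 + 2.0 * req.k * (za + zb) ** 2 / ((req.k - 1) * log_ratio**2)
    return SampleSizeResult(n=math.ceil(n_raw), n_raw=n_raw, request=asdict(req))


def _ba_power(n: int | float, mean_diff: float, sd_diff: float,
              max_allowed_diff: float, alpha: float) -> float:
    """Approximate probability that the one-sided confidence bound of the
    binding 95% limit of agreement falls inside +/- max_allowed_diff.

    Normal approximation: the estimated limit m_hat + 1.96 s_hat has
    standard error sd * sqrt(1/n + 1.96^2 / (2 (n-1))); the opposite limit
    is assumed non-binding (it is, whenever |mean_diff| > 0; for
    mean_diff = 0 the two tails are symmetric and the one-tailed result is
    mildly optimistic — the Monte-Carlo check in the tests bounds the
    error).
    """
    margin = max_allowed_diff - abs(mean_diff) - 1.96 * sd_diff
    se = sd_diff * math.sqrt(1.0 / n + 1.96**2 / (2.0 * (n - 1.0)))
    return float(stats.norm.cdf(margin / se - stats.norm.ppf(1.0 - alpha)))


def ba_sample_size(
    mean_diff: float,
    sd_diff: float,
    max_allowed_diff: float,
    alpha: float = 0.05,
    power: float = 0.80,
) -> SampleSizeResult:
    """Subjects needed for a Bland-Altman agreement study.

    Finds the smallest n such that, with probability ``power``, the
    estimated 95% limits of agreement together with their level-(1-alpha)
    one-sided confidence bounds lie within the symmetric agreement region
    +/- max_allowed_diff.

    Requires |mean_diff| + 1.96 sd_diff < max_allowed_diff; otherwise the
    true limits already violate the region and no n suffices.
    """
    if sd_diff <= 0 or max_allowed_diff <= 0:
        raise ConfigError("sd_diff and max_allowed_diff must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ConfigError("alpha and power must lie in (0, 1)")
    if abs(mean_diff) + 1.96 * sd_diff >= max_allowed_diff:
        raise InfeasibleDesignError(
            "true limits of agreement lie outside the allowed region; "
            "no sample size can demonstrate agreement"
        )
    n = 2
    while _ba_power(n, mean_diff, sd_diff, max_allowed_diff, alpha) < power:
        n += 1
        if n > 10**7:  # pragma: no cover - safeguarded by the precondition
            raise InfeasibleDesignError("no finite n reaches the requested power")
    # continuous solution for reporting
    from scipy.optimize import brentq

    f = lambda m: _ba_power(m, mean_diff, sd_diff, max_allowed_diff, alpha) - power
    n_raw = float(n) if f(2.0) >= 0 else brentq(f, 2.0, float(n))
    return SampleSizeResult(
        n=n,
        n_raw=n_raw,
        request={
            "mean_diff": mean_diff,
            "sd_diff": sd_diff,
            "max_allowed_diff": max_allowed_diff,
            "alpha": alpha,
            "power": power,
        },
    )
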