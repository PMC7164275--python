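"""Monte-Carlo study of the ICC/CV mismatch.

Two batches of simulations quantify how the coefficient of variation and
the intraclass correlation coefficient disagree as repeatability indices:

* **Batch 1** generates repeated measurements with a *known true CV* —
  subject i's k replicates are Normal(mu_i, mu_i * cv) around a fixed,
  equally spaced grid of subject means — and estimates the one-way ICC on
  each replicate dataset.  Summarised as a mean-ICC-vs-true-CV curve.
* **Batch 2** generates data from a two-level mixed model with a *known
  true ICC* — subject means Normal(gamma, sigma_B), replicates
  Normal(mean_i, sigma_W) with sigma_W = sigma_B sqrt((1-ICC)/ICC) — and
  estimates the pooled CV on each dataset.  Summarised as a
  (sigma_B, ICC) x gamma grid of mean CVs.

Randomness: a single root seed; each grid cell draws from its own
substream, ``SeedSequence(seed, spawn_key=(cell_index,))`` with cells
numbered in the row-major order of the configuration grids documented on
the config classes, so grids are bit-reproducible under partial or
parallel execution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "Batch1Config",
    "Batch2Config",
    "SimulationGrid",
    "simulate_batch1",
    "simulate_batch2",
    "derive_sigma_w",
    "grid_to_table",
]


def _default_mu_grid() -> list[float]:
    return list(np.linspace(5.0, 8.0, 10))


def _default_cv_grid() -> list[float]:
    return list(np.linspace(0.01, 0.99, 50))


@dataclass
class Batch1Config:
    """Fixed-CV normal generator (ICC estimated).

    Subject means are the *fixed* grid ``mu_grid`` (not redrawn per
    replicate): the between-subject spread is deterministic, and the true
    CV applies within subject via SD = mu_i * cv.  Cells are enumerated in
    the order of ``cv_grid``.
    """

    n_subjects: int = 10
    k_replicates: int = 5
    mu_grid: list[float] = field(default_factory=_default_mu_grid)
    cv_grid: list[float] = field(default_factory=_default_cv_grid)
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        mu = np.asarray(self.mu_grid, float)
        cv = np.asarray(self.cv_grid, float)
        if len(mu) != self.n_subjects:
            raise ConfigError("mu_grid length must equal n_subjects")
        if np.any(mu <= 0):
            raise ConfigError("all subject means must be positive")
        if np.any((cv <= 0) | (cv >= 1)):
            raise ConfigError("all cv_grid values must lie in (0, 1)")
        if self.k_replicates < 2 or self.n_subjects < 2 or self.replicates < 2:
            raise ConfigError("need n, k and replicates all >= 2")


@dataclass
class Batch2Config:
    """Two-level mixed-model generator (pooled CV estimated).

    Cells are enumerated row-major over (gamma, sigma_b, icc) in the order
    the three grids are given.
    """

    n_subjects: int = 10
    k_replicates: int = 5
    gamma_grid: list[float] = field(default_factory=lambda: list(range(1, 11)))
    sigma_b_grid: list[float] = field(default_factory=lambda: [1.0, 2.0, 3.0])
    icc_grid: list[float] = field(
        default_factory=lambda: [round(0.1 * i, 1) for i in range(1, 10)]
    )
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        icc = np.asarray(self.icc_grid, float)
        if np.any((icc <= 0) | (icc >= 1)):
            raise ConfigError("all icc_grid values must lie in (0, 1)")
        if np.any(np.asarray(self.sigma_b_grid, float) <= 0):
            raise ConfigError("sigma_b values must be positive")
        if self.k_replicates < 2 or self.n_subjects < 2 or self.replicates < 2:
            raise ConfigError("need n, k and replicates all >= 2")


@dataclass
class SimulationGrid:
    """Per-cell Monte-Carlo summaries.

    ``cells`` holds one row per configuration with its coordinates,
    ``mean_index`` (mean of the estimated index over replicates), ``mc_se``
    (SD of the per-replicate index / sqrt(replicates)) and
    ``n_replicates``.  ``index_name`` is "estimated_icc" (batch 1) or
    "estimated_cv" (batch 2).
    """

    cells: pd.DataFrame
    index_name: str
    config: object = None


def derive_sigma_w(sigma_b: float, icc: float) -> float:
    """Within-subject SD that yields a target true ICC at a given
    between-subject SD: sigma_B * sqrt((1 - ICC) / ICC)."""
    if not 0 < icc < 1:
        raise ConfigError(f"icc must lie in (0, 1), got {icc}")
    if sigma_b <= 0:
        raise ConfigError("sigma_b must be positive")
    return float(sigma_b) * float(np.sqrt((1.0 - icc) / icc))


def _icc_estimates(x: np.ndarray) -> np.ndarray:
    """Vectorised one-way ICC over the last two axes (subjects, replicates).

    Identical arithmetic to agreement.icc_oneway's estimator, applied to a
    stack of tables at once.
    """
    n, k = x.shape[-2], x.shape[-1]
    row_means = x.mean(axis=-1)
    msb = k * row_means.var(axis=-1, ddof=1)
    msw = x.var(axis=-1, ddof=1).mean(axis=-1)
    return (msb - msw) / (msb + (k - 1) * msw)


def _cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(cell_index,)))


def simulate_batch1(cfg: Batch1Config | None = None, **kwargs) -> SimulationGrid:
    """Estimate the one-way ICC on data generated with a known true CV.

    For each cv in the grid, draws ``replicates`` datasets of shape
    (n_subjects, k_replicates) with X_ij ~ Normal(mu_i, mu_i * cv) and
    records the mean and Monte-Carlo SE of the ICC estimates.  Negative
    estimates enter the mean unclamped.
    """
    if cfg is None:
        cfg = Batch1Config(**kwargs)
    mu = np.asarray(cfg.mu_grid, float)[:, None]  # (n, 1)
    rows = []
    for idx, cv in enumerate(cfg.cv_grid):
        rng = _cell_rng(cfg.seed, idx)
        z = rng.standard_normal((cfg.replicates, cfg.n_subjects, cfg.k_replicates))
        x = mu + mu * cv * z
        est = _icc_estimates(x)
        rows.append(
            {
                "true_cv": float(cv),
                "mean_index": float(est.mean()),
                "mc_se": float(est.std(ddof=1) / np.sqrt(cfg.replicates)),
                "n_replicates": cfg.replicates,
            }
        )
    return SimulationGrid(pd.DataFrame(rows), index_name="estimated_icc", config=cfg)


def simulate_batch2(
    cfg: Batch2Config | None = None, per_subject: bool = False, **kwargs
) -> SimulationGrid:
    """Estimate the CV on data generated with a known true ICC.

    For each (gamma, sigma_B, ICC): sigma_W = sigma_B sqrt((1-ICC)/ICC);
    per replicate, subject means mu_i ~ Normal(gamma, sigma_B) and values
    X_ij ~ Normal(mu_i, sigma_W); the pooled CV (SD of all n*k values over
    the grand mean) is recorded.  No truncation of negative draws or
    negative grand means: the ratio estimator is genuinely heavy-tailed at
    small gamma, as the summaries show.

    ``per_subject=True`` switches to the mean per-subject CV for
    sensitivity analysis (rows whose subject mean is nonpositive make that
    replicate's index undefined and it is recorded as NaN-excluded).
    """
    if cfg is None:
        cfg = Batch2Config(**kwargs)
    n, k = cfg.n_subjects, cfg.k_replicates
    rows = []
    idx = 0
    for gamma in cfg.gamma_grid:
        for sigma_b in cfg.sigma_b_grid:
            for icc in cfg.icc_grid:
                sigma_w = derive_sigma_w(sigma_b, icc)
                rng = _cell_rng(cfg.seed, idx)
                mu_i = gamma + sigma_b * rng.standard_normal((cfg.replicates, n, 1))
                x = mu_i + sigma_w * rng.standard_normal((cfg.replicates, n, k))
                if per_subject:
                    cvs = x.std(axis=-1, ddof=1) / x.mean(axis=-1)
                    est = cvs.mean(axis=-1)
                else:
                    flat = x.reshape(cfg.replicates, n * k)
                    est = flat.std(axis=-1, ddof=1) / flat.mean(axis=-1)
                rows.append(
                    {
                        "gamma": float(gamma),
                        "sigma_b": float(sigma_b),
                        "icc": float(icc),
                        "sigma_w": sigma_w,
                        "mean_index": float(est.mean()),
                        "mc_se": float(est.std(ddof=1) / np.sqrt(cfg.replicates)),
                        "n_replicates": cfg.replicates,
                    }
                )
                idx += 1
    return SimulationGrid(pd.DataFrame(rows), index_name="estimated_cv", config=cfg)


def grid_to_table(grid: SimulationGrid, layout: str) -> pd.DataFrame:
    """Export a simulation grid in a publication-shaped layout.

    ``fig1_curve``: two columns (true_cv, mean_estimated_icc) from a
    batch-1 grid.  ``table1_grid``: rows indexed by (sigma_b, sigma_w, icc)
    with one column per gamma, from a batch-2 grid.
    """
    if grid.cells.empty:
        raise ConfigError("empty simulation grid")
    if layout == "fig1_curve":
        if grid.index_name != "estimated_icc":
            raise ConfigError("fig1_curve layout requires a batch-1 grid")
        return grid.cells[["true_cv", "mean_index"]].rename(
            columns={"mean_index": "mean_estimated_icc"}
        )
    if layout == "table1_grid":
        if grid.index_name != "estimated_cv":
            raise ConfigError("table1_grid layout requires a batch-2 grid")
        wide = grid.cells.pivot_table(
            index=["sigma_b", "sigma_w", "icc"],
            columns="gamma",
            values="mean_index",
        ).sort_index(level=["sigma_b", "icc"])
        wide.columns = [f"mu={g:g}" for g in wide.columns]
        return wide.reset_index()
    raise ConfigError(f"unknown layout {layout!r}")
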