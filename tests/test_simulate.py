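"""Simulation engine: sigma_W derivation, reproducibility, layout exports
and reduced-size statistical properties (the full-default batches are
exercised in the acceptance tests)."""

import numpy as np
import pandas as pd
import pytest

import rhinostat as rs
from rhinostat.errors import ConfigError

# printed 2-dp sigma_W column of the mixed-model grid (sigma_b x icc)
SIGMA_W_TABLE = {
    1.0: [3.00, 2.00, 1.53, 1.22, 1.00, 0.82, 0.65, 0.50, 0.33],
    2.0: [6.00, 4.00, 3.06, 2.45, 2.00, 1.63, 1.31, 1.00, 0.67],
    3.0: [9.00, 6.00, 4.58, 3.67, 3.00, 2.45, 1.96, 1.50, 1.00],
}
ICCS = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]


@pytest.mark.parametrize("sigma_b", sorted(SIGMA_W_TABLE))
def test_derive_sigma_w_matches_published_column(sigma_b):
    got = [round(rs.derive_sigma_w(sigma_b, icc), 2) for icc in ICCS]
    assert got == SIGMA_W_TABLE[sigma_b]


def test_derive_sigma_w_round_trip_and_edges():
    for sigma_b in (0.5, 1.0, 2.7):
        for icc in (0.05, 0.3, 0.5, 0.95):
            sw = rs.derive_sigma_w(sigma_b, icc)
            back = sigma_b**2 / (sigma_b**2 + sw**2)
            assert back == pytest.approx(icc, rel=1e-12)
    assert rs.derive_sigma_w(1.7, 0.5) == pytest.approx(1.7)
    with pytest.raises(ConfigError):
        rs.derive_sigma_w(1.0, 0.0)
    with pytest.raises(ConfigError):
        rs.derive_sigma_w(1.0, 1.0)


def test_batch1_bit_reproducible_and_substream_stable():
    cfg = dict(cv_grid=[0.1, 0.3], replicates=50, seed=42)
    a = rs.simulate_batch1(**cfg)
    b = rs.simulate_batch1(**cfg)
    pd.testing.assert_frame_equal(a.cells, b.cells)
    # per-cell substreams: a partial grid reproduces the same first cell
    partial = rs.simulate_batch1(cv_grid=[0.1], replicates=50, seed=42)
    pd.testing.assert_frame_equal(partial.cells, a.cells.iloc[[0]])


def test_batch2_bit_reproducible():
    cfg = dict(gamma_grid=[5, 10], sigma_b_grid=[1.0], icc_grid=[0.5],
               replicates=50, seed=42)
    a = rs.simulate_batch2(**cfg)
    b = rs.simulate_batch2(**cfg)
    pd.testing.assert_frame_equal(a.cells, b.cells)


def test_batch1_low_cv_cell_near_design_icc():
    """At cv=0.01 the fixed spread of the subject means dominates: the mean
    estimated ICC is essentially 1."""
    grid = rs.simulate_batch1(cv_grid=[0.01], replicates=200, seed=3)
    assert grid.cells.mean_index.iloc[0] >= 0.95


def test_batch1_analytic_design_icc_check():
    """Cell means track the closed-form design ICC
    V_mu / (V_mu + cv^2 M_mu) for cv <= 0.5, up to MC noise plus the
    documented small-sample bias of the moment estimator (~ -0.008)."""
    cvs = [0.05, 0.15, 0.25, 0.35, 0.45]
    grid = rs.simulate_batch1(cv_grid=cvs, replicates=300, seed=4)
    mu = np.linspace(5, 8, 10)
    v_mu, m_mu = mu.var(ddof=1), (mu**2).mean()
    for _, row in grid.cells.iterrows():
        design = v_mu / (v_mu + row.true_cv**2 * m_mu)
        assert abs(row.mean_index - design) <= 3 * row.mc_se + 0.008


def test_batch2_per_subject_mode_smaller_than_pooled():
    """The per-subject CV ignores between-subject spread, so its mean falls
    well below the pooled CV under the same configuration."""
    cfg = dict(gamma_grid=[10], sigma_b_grid=[1.0], icc_grid=[0.5],
               replicates=300, seed=5)
    pooled = rs.simulate_batch2(**cfg).cells.mean_index.iloc[0]
    per_subj = rs.simulate_batch2(per_subject=True, **cfg).cells.mean_index.iloc[0]
    assert per_subj < pooled
    assert per_subj == pytest.approx(0.094, abs=0.01)  # ~ c4-adjusted sw/gamma
    assert pooled == pytest.approx(np.sqrt(2) / 10, abs=0.02)


def test_batch2_icc_parameter_recovery():
    """Data from the batch-2 model analysed with the one-way ICC recovers
    the true ICC within Monte-Carlo error at large n."""
    rng = np.random.default_rng(6)
    for true_icc in (0.3, 0.7):
        sw = rs.derive_sigma_w(1.0, true_icc)
        mu = rng.normal(10, 1.0, (400, 1))
        x = rng.normal(mu, sw, (400, 5))
        est = rs.icc_oneway(x).estimate
        assert est == pytest.approx(true_icc, abs=0.06)


def test_mc_se_scales_with_replicates():
    """mc_se shrinks like 1/sqrt(replicates): the 250 vs 1000 ratio lies in
    [1.8, 2.2]."""
    cell = dict(cv_grid=[0.35], seed=7)
    se_250 = rs.simulate_batch1(replicates=250, **cell).cells.mc_se.iloc[0]
    se_1000 = rs.simulate_batch1(replicates=1000, **cell).cells.mc_se.iloc[0]
    assert 1.8 <= se_250 / se_1000 <= 2.2


def test_grid_layouts_and_errors(batch1_default, batch2_default):
    curve = rs.grid_to_table(batch1_default, "fig1_curve")
    assert list(curve.columns) == ["true_cv", "mean_estimated_icc"]
    assert len(curve) == 50
    wide = rs.grid_to_table(batch2_default, "table1_grid")
    assert wide.shape == (27, 3 + 10)  # (sigma_b, sigma_w, icc) x 10 gammas
    with pytest.raises(ConfigError):
        rs.grid_to_table(batch1_default, "table1_grid")
    with pytest.raises(ConfigError):
        rs.grid_to_table(
            rs.SimulationGrid(pd.DataFrame(), "estimated_icc"), "fig1_curve"
        )


def test_config_validation():
    with pytest.raises(ConfigError):
        rs.Batch1Config(cv_grid=[0.0, 0.5])
    with pytest.raises(ConfigError):
        rs.Batch1Config(mu_grid=[1.0, 2.0])  # length != n_subjects
    with pytest.raises(ConfigError):
        rs.Batch2Config(icc_grid=[1.0])
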