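"""MR estimators and diagnostics: exact examples, invariants, calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from medmr import (
    MRData,
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    mr_presso,
    wald_ratio,
    weighted_median,
)
from medmr.estimators import Z95, _weighted_median_point
from medmr.exceptions import DegenerateDesignError, DomainError, InsufficientInstrumentsError


def _clean_data(n=10, beta=0.2, seed=0, sy=0.05, sx=0.02):
    rng = np.random.default_rng(seed)
    bx = np.abs(rng.normal(0.3, 0.05, n)) + 0.05
    by = beta * bx + rng.normal(0, sy, n)
    return MRData.from_arrays(bx, by, np.full(n, sy), sx=np.full(n, sx))


# -- Wald ratio -------------------------------------------------------------


def test_wald_ratio_exact():
    est = wald_ratio(0.5, 0.1, 0.05)
    assert est.beta == pytest.approx(0.2)
    assert est.se == pytest.approx(0.1)
    assert est.n_snps == 1


def test_wald_ratio_negative_bx_se_positive():
    est = wald_ratio(-0.5, 0.1, 0.05)
    assert est.beta == pytest.approx(-0.2)
    assert est.se == pytest.approx(0.1)


def test_wald_ratio_zero_bx_raises():
    with pytest.raises(DomainError):
        wald_ratio(0.0, 0.1, 0.05)


# -- IVW --------------------------------------------------------------------


def test_ivw_manual_formula():
    bx = np.array([1.0, 2.0])
    by = np.array([0.5, 0.8])
    sy = np.array([0.1, 0.2])
    w = 1 / sy**2
    expected = np.sum(w * bx * by) / np.sum(w * bx**2)
    est = ivw(MRData.from_arrays(bx, by, sy), random_effects=False)
    assert est.beta == pytest.approx(expected, rel=1e-12)
    assert est.se == pytest.approx(np.sqrt(1 / np.sum(w * bx**2)), rel=1e-12)


def test_ivw_two_identical_snps():
    est = ivw(MRData.from_arrays([1.0, 1.0], [0.5, 0.5], [0.1, 0.1]), random_effects=False)
    assert est.beta == pytest.approx(0.5, abs=1e-12)
    assert est.se == pytest.approx(0.1 / np.sqrt(2), rel=1e-12)


def test_ivw_single_snp_equals_wald():
    est = ivw(MRData.from_arrays([0.4], [0.1], [0.05]))
    w = wald_ratio(0.4, 0.1, 0.05)
    assert est.beta == pytest.approx(w.beta, rel=1e-12)
    assert est.se == pytest.approx(w.se, rel=1e-12)


def test_ivw_random_effects_never_smaller_se():
    data = _clean_data(15, seed=3)
    assert ivw(data, random_effects=True).se >= ivw(data, random_effects=False).se


def test_ivw_degenerate_and_empty():
    with pytest.raises(DegenerateDesignError):
        ivw(MRData.from_arrays([0.0, 0.0], [0.1, 0.1], [0.05, 0.05]))
    with pytest.raises(InsufficientInstrumentsError):
        ivw(MRData.from_arrays([], [], []))


# -- MR-Egger ---------------------------------------------------------------


def test_egger_exact_on_collinear_points():
    bx = np.array([0.1, 0.2, 0.3, 0.4])
    by = 0.1 + 0.2 * bx
    est, pleio = egger(MRData.from_arrays(bx, by, np.full(4, 0.05)))
    assert est.beta == pytest.approx(0.2, abs=1e-12)
    assert pleio.intercept == pytest.approx(0.1, abs=1e-12)


def test_egger_orientation_invariance():
    data = _clean_data(8, seed=1)
    flipped = MRData.from_arrays(
        data.bx * np.array([1, -1] * 4), data.by * np.array([1, -1] * 4), data.sy
    )
    e1, p1 = egger(data)
    e2, p2 = egger(flipped)
    assert e1.beta == pytest.approx(e2.beta, rel=1e-12)
    assert p1.intercept == pytest.approx(p2.intercept, rel=1e-12)


def test_egger_needs_three_instruments():
    with pytest.raises(InsufficientInstrumentsError):
        egger(MRData.from_arrays([0.1, 0.2], [0.02, 0.04], [0.05, 0.05]))


def test_egger_degenerate_constant_bx():
    with pytest.raises(DegenerateDesignError):
        egger(MRData.from_arrays([0.2, 0.2, 0.2], [0.04, 0.04, 0.04], [0.05, 0.05, 0.05]))


# -- weighted median --------------------------------------------------------


def test_weighted_median_interpolated_middle():
    # equal weights, ratios {0.1, 0.2, 0.3}: cumulative-weight midpoint sits on 0.2
    bx = np.array([1.0, 1.0, 1.0])
    by = np.array([0.1, 0.2, 0.3])
    est = weighted_median(MRData.from_arrays(bx, by, np.full(3, 0.05)), n_boot=50, seed=0)
    assert est.beta == pytest.approx(0.2, abs=1e-12)


def test_weighted_median_point_two_values():
    assert _weighted_median_point(np.array([0.1, 0.3]), np.array([1.0, 1.0])) == pytest.approx(0.2)


def test_weighted_median_robust_to_one_outlier():
    bx = np.ones(9)
    by = np.array([0.2] * 8 + [5.0])
    est = weighted_median(MRData.from_arrays(bx, by, np.full(9, 0.05)), n_boot=50, seed=0)
    assert est.beta == pytest.approx(0.2, abs=1e-9)


def test_weighted_median_seeded_deterministic():
    data = _clean_data(10, seed=4)
    a = weighted_median(data, n_boot=200, seed=11)
    b = weighted_median(data, n_boot=200, seed=11)
    assert a.beta == b.beta and a.se == b.se


# -- Cochran Q --------------------------------------------------------------


def test_q_zero_on_proportional_data():
    bx = np.array([0.1, 0.2, 0.3])
    data = MRData.from_arrays(bx, 0.5 * bx, np.full(3, 0.05))
    het = cochran_q(data, ivw(data, random_effects=False))
    assert het.q_stat == pytest.approx(0.0, abs=1e-20)
    assert het.df == 2
    assert het.pval == pytest.approx(1.0)


def test_q_minimized_at_ivw_slope():
    data = _clean_data(12, seed=5)
    b = ivw(data, random_effects=False).beta
    q0 = cochran_q(data, b).q_stat
    assert q0 <= cochran_q(data, b + 1e-3).q_stat
    assert q0 <= cochran_q(data, b - 1e-3).q_stat


def test_q_df_offset_for_egger():
    data = _clean_data(6, seed=6)
    assert cochran_q(data, 0.2, df_offset=2).df == 4


# -- leave-one-out ----------------------------------------------------------


def test_loo_row_per_variant_no_flags_on_clean_data():
    data = _clean_data(12, seed=7, sy=0.05)
    loo = leave_one_out(data)
    assert len(loo) == 12
    assert set(loo["variant_omitted"]) == set(data.variant_ids)
    assert not loo["influential"].any()


def test_loo_flags_gross_outlier():
    data = _clean_data(8, seed=8)
    by = data.by.copy()
    by[3] += 10 * data.sy[3]
    spiked = MRData.from_arrays(data.bx, by, data.sy, sx=data.sx, variant_ids=data.variant_ids)
    loo = leave_one_out(spiked)
    assert loo.loc[loo["variant_omitted"] == data.variant_ids[3], "influential"].item()


# -- MR-PRESSO --------------------------------------------------------------


def test_presso_clean_data_removes_nothing():
    data = _clean_data(12, seed=9)
    res, retained = mr_presso(data, n_simulations=500, seed=0)
    assert res.outliers == []
    assert retained is data
    assert res.global_pval > 0.05


def test_presso_detects_and_removes_implanted_outlier():
    data = _clean_data(12, seed=10)
    by = data.by.copy()
    by[5] += 10 * data.sy[5]
    spiked = MRData.from_arrays(data.bx, by, data.sy, sx=data.sx, variant_ids=data.variant_ids)
    res, retained = mr_presso(spiked, n_simulations=1000, seed=0)
    assert res.global_pval < 0.05
    assert data.variant_ids[5] in res.outliers
    assert data.variant_ids[5] not in retained.variant_ids
    assert np.isfinite(res.distortion_pval)


def test_presso_seeded_deterministic():
    data = _clean_data(10, seed=11)
    r1, _ = mr_presso(data, n_simulations=300, seed=42)
    r2, _ = mr_presso(data, n_simulations=300, seed=42)
    assert r1.global_pval == r2.global_pval
    assert (r1.outlier_pvals["pval_raw"] == r2.outlier_pvals["pval_raw"]).all()


def test_presso_needs_four_instruments():
    with pytest.raises(InsufficientInstrumentsError):
        mr_presso(_clean_data(3))


# -- equivariance properties -----------------------------------------------


@given(st.floats(0.2, 5.0), st.integers(0, 50))
def test_scaling_bx_divides_estimates(scale, seed):
    data = _clean_data(8, seed=seed)
    scaled = MRData.from_arrays(data.bx * scale, data.by, data.sy)
    assert ivw(scaled, random_effects=False).beta == pytest.approx(
        ivw(data, random_effects=False).beta / scale, rel=1e-9)
    assert egger(scaled)[0].beta == pytest.approx(egger(data)[0].beta / scale, rel=1e-9)


@given(st.integers(0, 50))
def test_negating_by_negates_estimates(seed):
    data = _clean_data(8, seed=seed)
    neg = MRData.from_arrays(data.bx, -data.by, data.sy)
    assert ivw(neg, random_effects=False).beta == pytest.approx(
        -ivw(data, random_effects=False).beta, rel=1e-9)
    wm_pos = weighted_median(data, n_boot=10, seed=0).beta
    wm_neg = weighted_median(neg, n_boot=10, seed=0).beta
    assert wm_neg == pytest.approx(-wm_pos, rel=1e-9)


# -- sampling-distribution checks ------------------------------------------


def test_ivw_fixed_ci_coverage():
    """Fixed-effect IVW 95% CI coverage under its own model, 1000 replicates."""
    rng = np.random.default_rng(2024)
    beta_true, n_snps, reps = 0.2, 30, 1000
    covered = 0
    bx = np.abs(rng.normal(0.3, 0.1, n_snps)) + 0.1
    sy = np.full(n_snps, 0.05)
    for _ in range(reps):
        by = beta_true * bx + rng.normal(0, sy)
        est = ivw(MRData.from_arrays(bx, by, sy), random_effects=False)
        covered += abs(est.beta - beta_true) <= Z95 * est.se
    assert 0.93 <= covered / reps <= 0.97


def test_egger_intercept_null_calibrated():
    """Without pleiotropy the intercept test rejects at most ~alpha."""
    rng = np.random.default_rng(2025)
    n_snps, reps = 50, 500
    rejections = 0
    bx = np.abs(rng.normal(0.3, 0.1, n_snps)) + 0.1
    sy = np.full(n_snps, 0.05)
    for _ in range(reps):
        by = 0.2 * bx + rng.normal(0, sy)
        _, pleio = egger(MRData.from_arrays(bx, by, sy))
        rejections += pleio.pval < 0.05
    assert rejections / reps <= 0.08


def test_or_scale_properties():
    est = ivw(MRData.from_arrays([1.0, 1.0], [0.5, 0.5], [0.1, 0.1]), random_effects=False)
    assert est.or_point == pytest.approx(np.exp(0.5))
    lo, hi = est.or_ci
    assert lo == pytest.approx(np.exp(est.beta - Z95 * est.se))
    assert hi == pytest.approx(np.exp(est.beta + Z95 * est.se))
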