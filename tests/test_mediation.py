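"""Two-step mediation: product of coefficients, screening gates, batch."""

import numpy as np
import pytest

from medmr import (
    MediationConfig,
    MediationModel,
    MREstimate,
    SimScenario,
    batch_screen,
    bidirectional_screen,
    mediated_effect_ci,
    simulate_summary,
)
from medmr.model import MRModel, MRResults
from medmr.estimators import MRData

CFG_FAST = MediationConfig(run_presso=False)


def _fitted_results(beta, se=0.01, n=5):
    """Minimal MRResults wrapper around arrays giving slope ``beta`` exactly."""
    bx = np.linspace(0.2, 0.6, n)
    data = MRData.from_arrays(bx, beta * bx, np.full(n, se))
    return MRModel(data).fit(method="ivw_fixed")


# -- mediated effect CI -----------------------------------------------------


def test_delta_method_exact():
    a = MREstimate("ivw_re", 0.3, 0.05, 1e-9, 10)
    b = MREstimate("ivw_re", 0.4, 0.05, 1e-9, 10)
    med = mediated_effect_ci(a, b)
    assert med.effect == pytest.approx(0.12, abs=1e-12)
    assert med.se == pytest.approx(np.sqrt(0.3**2 * 0.05**2 + 0.4**2 * 0.05**2), rel=1e-12)


def test_delta_method_zero_a():
    med = mediated_effect_ci(MREstimate("ivw_re", 0.0, 0.05, 0.9, 10),
                             MREstimate("ivw_re", 0.4, 0.05, 1e-9, 10))
    assert med.effect == 0.0
    assert med.se == pytest.approx(0.4 * 0.05, rel=1e-12)


def test_montecarlo_close_to_delta_and_deterministic():
    a = MREstimate("ivw_re", 0.3, 0.02, 1e-9, 10)
    b = MREstimate("ivw_re", 0.4, 0.02, 1e-9, 10)
    mc1 = mediated_effect_ci(a, b, method="montecarlo", n_draws=20000, seed=1)
    mc2 = mediated_effect_ci(a, b, method="montecarlo", n_draws=20000, seed=1)
    delta = mediated_effect_ci(a, b)
    assert mc1.ci == mc2.ci
    assert mc1.ci[0] == pytest.approx(delta.ci[0], abs=0.01)
    assert mc1.ci[1] == pytest.approx(delta.ci[1], abs=0.01)


def test_delta_ci_coverage():
    """Delta 95% CI for a*b covers the truth at nominal rate when both
    coefficients are well separated from zero (2000 replicates)."""
    rng = np.random.default_rng(77)
    a_true, b_true, sa, sb, reps = 0.3, 0.4, 0.03, 0.03, 2000
    covered = 0
    for _ in range(reps):
        a_hat = rng.normal(a_true, sa)
        b_hat = rng.normal(b_true, sb)
        med = mediated_effect_ci(MREstimate("ivw_re", a_hat, sa, 0.0, 5),
                                 MREstimate("ivw_re", b_hat, sb, 0.0, 5))
        covered += med.ci[0] <= a_true * b_true <= med.ci[1]
    assert 0.92 <= covered / reps <= 0.97


# -- decomposition algebra --------------------------------------------------


def test_c_prime_plus_mediated_equals_c(sim_world):
    cfg = MediationConfig(run_presso=False)
    res = MediationModel(sim_world.exposure_stats, sim_world.mediator_stats,
                         sim_world.outcome_stats, sim_world.ld, cfg).fit(force=True)
    assert res.mediated is not None and res.c is not None
    assert res.c_prime + res.mediated.effect == pytest.approx(res.c.beta, abs=1e-12)
    assert res.proportion == pytest.approx(res.mediated.effect / res.c.beta, rel=1e-12)


def test_proportion_withheld_on_sign_mismatch():
    from medmr.mediation import MediatedEffect, MediationResults, BidirectionalResult

    c = _fitted_results(-0.2)
    screen = BidirectionalResult(forward=c, reverse=None)
    res = MediationResults(exposure="e", mediator="m", outcome="o", screen=screen,
                           mediated=MediatedEffect(0.1, 0.02, (0.06, 0.14), 1e-6))
    assert res.proportion is None
    assert np.isnan(res.row()["proportion"])


# -- screening gates --------------------------------------------------------


def test_causal_world_passes_screen(sim_world):
    screen = bidirectional_screen(sim_world.exposure_stats, sim_world.outcome_stats,
                                  sim_world.ld, CFG_FAST)
    assert screen.forward is not None and screen.forward.pval < 0.05
    assert screen.passes(0.05)


def test_null_world_fails_forward_screen():
    sim = simulate_summary(SimScenario(a_true=0.0, b_true=0.0, c_prime_true=0.0, seed=123))
    res = MediationModel(sim.exposure_stats, sim.mediator_stats, sim.outcome_stats,
                         sim.ld, CFG_FAST).fit()
    assert res.rejection_stage == "screen_forward_not_significant"
    assert not res.passed
    assert res.mediated is None


def test_b_zero_world_rejected_at_b():
    """With no mediator->outcome effect the b gate should reject nearly always."""
    hits = 0
    reps = 30
    for s in range(reps):
        sim = simulate_summary(SimScenario(b_true=0.0, c_prime_true=0.25, seed=1000 + s))
        res = MediationModel(sim.exposure_stats, sim.mediator_stats, sim.outcome_stats,
                             sim.ld, CFG_FAST).fit()
        hits += res.rejection_stage == "b_not_significant"
    assert hits / reps >= 0.9


def test_force_fits_despite_failed_screen():
    sim = simulate_summary(SimScenario(a_true=0.0, b_true=0.0, c_prime_true=0.0, seed=123))
    res = MediationModel(sim.exposure_stats, sim.mediator_stats, sim.outcome_stats,
                         sim.ld, CFG_FAST).fit(force=True)
    assert res.rejection_stage is not None
    assert res.mediated is not None  # forced run still produces the decomposition


# -- batch ------------------------------------------------------------------


def test_batch_screen_reports_all_pathways(sim_world):
    batch = batch_screen([sim_world.exposure_stats], [sim_world.mediator_stats],
                         sim_world.outcome_stats, sim_world.ld, CFG_FAST)
    assert len(batch.pathways) == 1
    total = len(batch.report) + len(batch.rejections)
    assert total == 1
    if len(batch.report):
        row = batch.report.iloc[0]
        assert row["exposure"] == sim_world.exposure_stats.trait_name


def test_batch_bonferroni_never_passes_more():
    sim = simulate_summary(SimScenario(seed=10))
    mediators = []
    for k in range(3):
        m = sim.mediator_stats.copy()
        m.trait_name = f"mediator_{k}"
        mediators.append(m)
    plain = batch_screen([sim.exposure_stats], mediators, sim.outcome_stats, sim.ld, CFG_FAST)
    bonf = batch_screen([sim.exposure_stats], mediators, sim.outcome_stats, sim.ld,
                        MediationConfig(run_presso=False, multiple_testing="bonferroni"))
    assert len(bonf.report) <= len(plain.report)


def test_summary_renders(sim_world):
    res = MediationModel(sim_world.exposure_stats, sim_world.mediator_stats,
                         sim_world.outcome_stats, sim_world.ld, CFG_FAST).fit(force=True)
    text = res.summary()
    assert sim_world.exposure_stats.trait_name in text
    assert "mediated" in text.lower()
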