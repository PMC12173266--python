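"""Built-in validation experiments.

Each function re-derives a property of the pipeline from scratch at run
time: estimator equivalence against independent brute-force oracles,
closed-form spot values, type-I-error calibration of the tests under a
simulated global null, recovery of the mediation decomposition from the
synthetic DAG, detection of implanted pleiotropic outliers, exact
kept/dropped accounting of the selection funnel, and byte-level determinism
of pipeline outputs.  These back both the test suite and `medmr selftest`.
"""

from __future__ import annotations

import filecmp
import shutil
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimators as est
from .estimators import MRData
from .harmonize import harmonize
from .instruments import SelectionConfig, ZeroLD, MatrixLD, f_statistic, select_instruments
from .io import SummaryStatsTable, CANONICAL_COLUMNS
from .mediation import MediationConfig, MediationModel, mediated_effect_ci
from .model import MRModel
from .pipeline import RunConfig, TableSpec, LDSpec, run_phase1, run_phase2
from .simulate import SimScenario, LDBlocks, simulate, simulate_summary, write_fixtures


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------


def brute_force_ivw(bx, by, sy, n_iter: int = 3) -> float:
    """Minimize sum w (by - beta*bx)^2 by dense grid search with refinement
    and a final parabolic-vertex step (exact for a quadratic objective) —
    an oracle independent of the closed-form IVW solution."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    w = 1.0 / sy**2

    def rss(b):
        return float(np.sum(w * (by - b * bx) ** 2))

    ratios = by[bx != 0] / bx[bx != 0]
    lo, hi = float(np.min(ratios)) - 1.0, float(np.max(ratios)) + 1.0
    for _ in range(n_iter):
        grid = np.linspace(lo, hi, 401)
        vals = np.array([rss(b) for b in grid])
        i = int(np.argmin(vals))
        lo, hi = grid[max(i - 2, 0)], grid[min(i + 2, 400)]
    b = (lo + hi) / 2
    s = (hi - lo) / 4
    f_lo, f_mid, f_hi = rss(b - s), rss(b), rss(b + s)
    denom = f_lo - 2 * f_mid + f_hi
    if denom > 0:
        b = b + 0.5 * s * (f_lo - f_hi) / denom
    return float(b)


def oracle_wls_egger(bx, by, sy):
    """2-parameter weighted least squares via numpy lstsq on the
    sqrt(w)-scaled design — independent of the closed-form normal equations."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    sgn = np.where(bx < 0, -1.0, 1.0)
    x, y = bx * sgn, by * sgn
    sw = 1.0 / sy
    design = np.column_stack([sw, sw * x])
    coef, *_ = np.linalg.lstsq(design, sw * y, rcond=None)
    return float(coef[1]), float(coef[0])  # slope, intercept


def oracle_equivalence(n_instances: int = 100, seed: int = 0) -> dict:
    """Max |difference| between closed-form estimators and the oracles over
    random instances."""
    rng = np.random.default_rng(seed)
    max_ivw = 0.0
    max_egger = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(3, 40))
        bx = rng.normal(0.3, 0.6, n)
        bx[np.abs(bx) < 0.02] = 0.1  # keep ratios bounded for the grid oracle
        by = rng.normal(0.0, 0.5, n)
        sy = rng.uniform(0.05, 0.5, n)
        data = MRData.from_arrays(bx, by, sy)
        ivw_beta = est.ivw(data, random_effects=False).beta
        max_ivw = max(max_ivw, abs(ivw_beta - brute_force_ivw(bx, by, sy)))
        slope_o, int_o = oracle_wls_egger(bx, by, sy)
        e, p = est.egger(data)
        max_egger = max(max_egger, abs(e.beta - slope_o), abs(p.intercept - int_o))
    return {"ivw_max_abs_diff": max_ivw, "egger_max_abs_diff": max_egger, "n_instances": n_instances}


# ---------------------------------------------------------------------------
# analytic spot checks
# ---------------------------------------------------------------------------


def analytic_spot_checks() -> dict:
    two_snp = est.ivw(
        MRData.from_arrays(bx=[1.0, 1.0], by=[0.5, 0.5], sy=[0.1, 0.1]), random_effects=False
    )
    med = mediated_effect_ci(
        est.MREstimate("ivw_re", 0.3, 0.05, 1e-9, 10),
        est.MREstimate("ivw_re", 0.4, 0.05, 1e-9, 10),
    )
    return {
        "f_stat_unit_case": f_statistic(0.5, 3, 1),
        "f_stat_cohort_case": f_statistic(0.01, 7174, 1),
        "ivw_two_snp_beta": two_snp.beta,
        "ivw_two_snp_se": two_snp.se,
        "mediated_effect_example": med.effect,
        "mediated_se_example": med.se,
    }


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------


def null_scenario(seed: int = 0, **kwargs) -> SimScenario:
    """Default study conditions with all structural coefficients zero."""
    return SimScenario(
        a_true=0.0, b_true=0.0, c_prime_true=0.0, pleiotropy_mode="none", seed=seed, **kwargs
    )


def null_calibration(n_reps: int = 2000, seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error of the IVW test, Cochran Q and the Egger-intercept test
    under the simulated global null, through the full selection and
    harmonization funnel."""
    seeds = _child_seeds(seed, n_reps)
    rej_ivw = rej_q = rej_egger = used = 0
    for s in seeds:
        sim = simulate_summary(null_scenario(seed=int(s)))
        model = MRModel.from_tables(
            sim.exposure_stats, sim.outcome_stats, sim.ld, SelectionConfig(p_threshold=5e-5)
        )
        if model.n_snps < 3:
            continue
        res = model.fit(method="ivw_re")
        used += 1
        rej_ivw += res.pval < alpha
        rej_q += res.heterogeneity.pval < alpha
        rej_egger += res.pleiotropy.pval < alpha
    return {
        "n_reps": used,
        "ivw_rejection_rate": rej_ivw / used,
        "q_rejection_rate": rej_q / used,
        "egger_intercept_rejection_rate": rej_egger / used,
    }


# ---------------------------------------------------------------------------
# mediation parameter recovery
# ---------------------------------------------------------------------------


def recovery_scenario(seed: int = 0, **kwargs) -> SimScenario:
    """The canonical mediation world: a=0.3, b=0.4, c'=0.1 (the defaults),
    so c=0.22 and the true mediated proportion is 6/11."""
    return SimScenario(seed=seed, **kwargs)


def parameter_recovery(n_reps: int = 500, seed: int = 0) -> dict:
    """Run the full mediation pipeline on replicated synthetic worlds and
    summarize recovery of a, b, c and the mediated proportion."""
    seeds = _child_seeds(seed, n_reps)
    cfg = MediationConfig(run_presso=False)
    a_est, b_est, c_est, props, passed = [], [], [], [], 0
    for s in seeds:
        sim = simulate_summary(recovery_scenario(seed=int(s)))
        model = MediationModel(
            sim.exposure_stats, sim.mediator_stats, sim.outcome_stats, sim.ld, cfg
        )
        res = model.fit(force=True)
        if res.a is None or res.b is None or res.c is None:
            continue
        a_est.append(res.a.beta)
        b_est.append(res.b.beta)
        c_est.append(res.c.beta)
        if res.mediated is not None and res.c.beta != 0:
            props.append(res.mediated.effect / res.c.beta)
        passed += res.passed
    a_est, b_est, c_est = map(np.asarray, (a_est, b_est, c_est))
    sc = recovery_scenario()

    def mean_mcse(x):
        return float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(len(x)))

    mean_a, mcse_a = mean_mcse(a_est)
    mean_b, mcse_b = mean_mcse(b_est)
    mean_c, mcse_c = mean_mcse(c_est)
    return {
        "n_reps": len(a_est),
        "truth": {"a": sc.a_true, "b": sc.b_true, "c": sc.c_total,
                  "proportion": sc.a_true * sc.b_true / sc.c_total},
        "mean_a": mean_a, "mcse_a": mcse_a,
        "mean_b": mean_b, "mcse_b": mcse_b,
        "mean_c": mean_c, "mcse_c": mcse_c,
        "median_proportion": float(np.median(props)),
        "pathway_pass_rate": passed / len(a_est),
    }


# ---------------------------------------------------------------------------
# outlier machinery
# ---------------------------------------------------------------------------


def outlier_fixture(seed: int, n_snps: int = 12, displacement: float = 10.0) -> tuple[MRData, str]:
    """Instrument set with one variant's outcome effect displaced by
    ``displacement`` outcome standard errors; returns (data, outlier id)."""
    rng = np.random.default_rng(seed)
    beta_true = 0.2
    bx = rng.normal(0.3, 0.05, n_snps)
    bx = np.abs(bx) + 0.05
    sx = np.full(n_snps, 0.02)
    sy = np.full(n_snps, 0.05)
    by = beta_true * bx + rng.normal(0.0, sy)
    k = int(rng.integers(0, n_snps))
    by[k] += displacement * sy[k]
    data = MRData.from_arrays(bx, by, sy, sx=sx)
    return data, str(data.variant_ids[k])


def outlier_detection(n_reps: int = 200, seed: int = 0) -> dict:
    """Rate at which an implanted +10 SE outlier is flagged by MR-PRESSO and
    by the leave-one-out influence analysis."""
    seeds = _child_seeds(seed, n_reps)
    hit_presso = hit_loo = 0
    for s in seeds:
        data, outlier_id = outlier_fixture(int(s))
        presso, _ = est.mr_presso(data, n_simulations=1000, seed=int(s))
        hit_presso += outlier_id in presso.outliers
        loo = est.leave_one_out(data)
        flagged = set(loo.loc[loo["influential"], "variant_omitted"])
        hit_loo += outlier_id in flagged
    return {
        "n_reps": n_reps,
        "presso_detection_rate": hit_presso / n_reps,
        "loo_detection_rate": hit_loo / n_reps,
    }


# ---------------------------------------------------------------------------
# selection-funnel accounting
# ---------------------------------------------------------------------------


def funnel_fixture():
    """Ten variants with hand-constructed fates at every funnel stage.

    Returns (exposure table, outcome table, ld, expected) where ``expected``
    maps each stage to the exact variant-id sets.
    """
    n = 8000

    def row(vid, chrom, pos, ea, oa, eaf, beta, se, pval):
        return dict(variant_id=vid, chrom=chrom, pos=pos, effect_allele=ea,
                    other_allele=oa, eaf=eaf, beta=beta, se=se, pval=pval, n=n)

    strong = 0.12  # t = 8 at se 0.015 -> F = 64
    weak = 0.045  # t = 3 -> F = 9 < 10
    se0 = 0.015
    rows = [
        row("v01", "1", 1_000_000, "A", "G", 0.3, strong, se0, 0.5),    # fails p screen
        row("v02", "1", 2_000_000, "A", "G", 0.3, strong, se0, 1e-3),   # fails p screen
        row("v03", "2", 1_000_000, "A", "G", 0.3, strong, se0, 1e-6),   # index, kept
        row("v04", "2", 4_000_000, "A", "G", 0.3, strong, se0, 1e-5),   # clumped to v03 (r2=0.9)
        row("v05", "2", 6_000_000, "A", "G", 0.3, strong, se0, 1e-5),   # in window, r2 tiny: kept
        row("v06", "3", 1_000_000, "A", "G", 0.3, strong, se0, 1e-5),   # other chromosome: kept
        row("v07", "2", 30_000_000, "A", "G", 0.3, strong, se0, 1e-5),  # 29 Mb away: outside window
        row("v08", "4", 1_000_000, "A", "G", 0.3, weak, se0, 1e-5),     # F = 9: dropped
        row("v09", "5", 1_000_000, "A", "T", 0.5, strong, se0, 1e-5),   # palindromic, eaf 0.5: ambiguous
        row("v10", "6", 1_000_000, "A", "G", 0.3, strong, se0, 1e-5),   # incompatible outcome alleles
    ]
    exposure = SummaryStatsTable("exposure", "continuous", pd.DataFrame(rows, columns=CANONICAL_COLUMNS))

    out_rows = []
    for r in rows:
        r = dict(r)
        if r["variant_id"] == "v10":
            r["other_allele"] = "C"  # allele set mismatch
        r["beta"] = 0.05
        r["pval"] = 0.01
        out_rows.append(r)
    outcome = SummaryStatsTable("outcome", "binary", pd.DataFrame(out_rows, columns=CANONICAL_COLUMNS))

    ld = MatrixLD({("v03", "v04"): 0.9, ("v03", "v05"): 0.0005, ("v04", "v05"): 0.9,
                   ("v03", "v07"): 0.9}, default=0.0)
    expected = {
        "dropped_pvalue": {"v01", "v02"},
        "dropped_clump": {"v04"},
        "dropped_f_stat": {"v08"},
        "selected": {"v03", "v05", "v06", "v07", "v09", "v10"},
        "harmonization_ambiguous": {"v09"},
        "harmonization_incompatible": {"v10"},
        "final": {"v03", "v05", "v06", "v07"},
    }
    return exposure, outcome, ld, expected


def funnel_accounting() -> dict:
    """Exact-match check of the funnel against the constructed fixture."""
    exposure, outcome, ld, expected = funnel_fixture()
    sel = select_instruments(exposure, ld, SelectionConfig(p_threshold=5e-5))
    rep = sel.report
    got = {
        "dropped_pvalue": set(rep.loc[rep["drop_reason"] == "pvalue", "variant_id"]),
        "dropped_clump": set(rep.loc[rep["drop_reason"] == "clump", "variant_id"]),
        "dropped_f_stat": set(rep.loc[rep["drop_reason"] == "f_stat", "variant_id"]),
        "selected": set(sel.instruments.data["variant_id"]),
    }
    h = harmonize(sel.instruments, outcome.subset(sel.instruments.data["variant_id"]))
    excl = h.exclusions
    got["harmonization_ambiguous"] = set(excl.loc[excl["reason"] == "ambiguous", "variant_id"])
    got["harmonization_incompatible"] = set(excl.loc[excl["reason"] == "incompatible", "variant_id"])
    got["final"] = set(h.pairs["variant_id"])
    all_match = all(got[k] == expected[k] for k in expected)
    return {"exact_match": float(all_match), "stages": {k: sorted(v) for k, v in got.items()}}


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


def determinism_scenario(seed: int) -> SimScenario:
    """Small individual-level world with LD blocks, sized for quick runs."""
    return SimScenario(
        n_snps=60, n_exposure=1500, n_mediator=1500, n_outcome=2500,
        n_instruments_x=12, n_instruments_m=12, n_instruments_y=8,
        ld_blocks=LDBlocks(block_size=3, r=0.8), seed=seed,
    )


def determinism_check(workdir: str | Path, seed: int = 0) -> dict:
    """Run phase 1 + phase 2 twice from one manifest configuration and
    compare every output file byte-for-byte."""
    workdir = Path(workdir)
    fixtures = workdir / "fixtures"
    sim = simulate(determinism_scenario(seed))
    paths = write_fixtures(sim, fixtures)

    outdir = workdir / "run"
    snapshot = workdir / "snapshot"
    config = RunConfig(
        exposures=[TableSpec(path=str(paths["exposure"]), name="exposure")],
        mediators=[TableSpec(path=str(paths["mediator"]), name="mediator")],
        outcome=TableSpec(path=str(paths["outcome"]), name="outcome", trait_type="binary"),
        ld=LDSpec(mode="file", file=str(paths["ld"]), default_r2=0.0),
        seed=seed,
        n_presso_simulations=200,
        n_boot=200,
        output_dir=str(outdir),
    )
    # first run, then snapshot the outputs and rerun the identical config
    run_phase1(config)
    run_phase2(config)
    snapshot.mkdir(parents=True, exist_ok=True)
    first = sorted(p for p in outdir.iterdir() if p.is_file())
    for p in first:
        shutil.copy2(p, snapshot / p.name)
    run_phase1(config)
    run_phase2(config)
    second = sorted(p for p in outdir.iterdir() if p.is_file())

    names_a = sorted(p.name for p in first)
    names_b = sorted(p.name for p in second)
    identical = names_a == names_b and all(
        filecmp.cmp(snapshot / name, outdir / name, shallow=False) for name in names_a
    )
    return {"identical": float(identical), "n_files": len(names_a)}


# ---------------------------------------------------------------------------
# aggregate entry point
# ---------------------------------------------------------------------------


def run_all(seed: int = 1, fast: bool = True, workdir: str | Path | None = None) -> dict:
    import tempfile

    n_cal = 400 if fast else 2000
    n_rec = 100 if fast else 500
    n_out = 50 if fast else 200
    report = {
        "oracle": oracle_equivalence(100, seed=seed),
        "spot_checks": analytic_spot_checks(),
        "calibration": null_calibration(n_cal, seed=seed),
        "recovery": parameter_recovery(n_rec, seed=seed),
        "outliers": outlier_detection(n_out, seed=seed),
        "funnel": funnel_accounting(),
    }
    if workdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            report["determinism"] = determinism_check(tmp, seed=seed)
    else:
        report["determinism"] = determinism_check(workdir, seed=seed)
    return report
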