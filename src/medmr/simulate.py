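"""Synthetic GWAS summary statistics under an explicit mediation DAG.

Three non-overlapping cohorts (as two-sample MR assumes) are measured over a
shared variant panel.  The structural model is

    X = sum_j gamma_j G_j + eps_x                      (exposure, continuous)
    M = a X + sum_j alpha_j G_j + eps_m                (mediator, continuous)
    logit P(Y=1) = beta0 + b M + c' X + sum_j delta_j G_j   (binary outcome)

so the total exposure->outcome effect is c = c' + a*b and the mediated
proportion is a*b/c.  The panel contains exposure instruments (gamma != 0),
mediator-specific instruments, outcome-specific instruments (these make the
reverse direction of a bidirectional screen estimable), and null variants.
Horizontal pleiotropy attaches alpha/delta effects to the exposure's
instrument SNPs: zero ("none"), zero-mean normal ("balanced") or
shifted-mean normal ("directional").

Two fidelity levels share one panel/truth construction:

``simulate``            draws genotypes under Hardy-Weinberg (optionally with
                        block LD), generates phenotypes, and estimates each
                        per-variant association by OLS (continuous) or
                        per-variant logistic regression (binary), so outcome
                        betas are genuine log-odds ratios.
``simulate_summary``    draws the per-variant estimates directly from their
                        asymptotic sampling distributions — the fast mode for
                        large replicate grids (requires an LD-free panel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit

from .exceptions import ConfigError, DomainError
from .harmonize import PALINDROMIC_PAIRS
from .instruments import LDLookup, MatrixLD, ZeroLD
from .io import CANONICAL_COLUMNS, SummaryStatsTable, write_summary_stats

_BASES = np.array(list("ACGT"))


class LDBlocks(BaseModel):
    """Block-LD specification: consecutive SNPs grouped into blocks of
    ``block_size`` with within-block haplotype correlation ``r``."""

    block_size: int = Field(4, ge=2)
    r: float = Field(0.8, gt=0, lt=1)


class SimScenario(BaseModel):
    """Full parameterization of the synthetic causal world.

    Instrument effects have magnitudes uniform on [0.5, 1.5] x scale with a
    random sign: bounded away from zero, as in a genome-wide-significant
    instrument panel, which keeps every instrument's F statistic far above
    the weak-instrument range.  Default molecular-cohort sizes are chosen so
    that the IVW regression-dilution bias (of order se_x^2 / gamma^2 per
    instrument) is well below the Monte Carlo resolution of a
    several-hundred-replicate recovery study; the binary outcome cohort is
    disease-scale.
    """

    n_snps: int = Field(120, ge=1)
    n_exposure: int = Field(50_000, ge=10)
    n_mediator: int = Field(30_000, ge=10)
    n_outcome: int = Field(6000, ge=10)
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_instruments_x: int = Field(12, ge=0)
    n_instruments_m: int = Field(12, ge=0)
    n_instruments_y: int = Field(8, ge=0)
    gamma_scale: float = Field(0.6, gt=0)  # exposure-instrument effect magnitude scale
    alpha_scale: float = Field(0.6, gt=0)  # mediator-instrument effect magnitude scale
    delta_scale: float = Field(0.6, gt=0)  # outcome-instrument effect magnitude scale (log-odds)
    a_true: float = 0.3
    b_true: float = 0.4
    c_prime_true: float = 0.1
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = Field(0.08, ge=0)
    outcome_prevalence: float = Field(0.1, gt=0, lt=1)
    allele_scramble: float = Field(0.5, ge=0, le=1)  # fraction of non-exposure rows stored on the swapped allele
    ld_blocks: LDBlocks | None = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        n_special = self.n_instruments_x + self.n_instruments_m + self.n_instruments_y
        if n_special > self.n_snps:
            raise ValueError("instrument counts exceed n_snps")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy_mode must be none|balanced|directional")
        return self

    @property
    def c_total(self) -> float:
        return self.c_prime_true + self.a_true * self.b_true


@dataclass
class SimOutput:
    """Simulated cohorts plus the ground truth needed to check any estimate."""

    exposure_stats: SummaryStatsTable
    mediator_stats: SummaryStatsTable
    outcome_stats: SummaryStatsTable
    truth: dict = field(repr=False)
    ld: LDLookup = field(repr=False)
    ld_pairs: pd.DataFrame = field(repr=False)  # id_a, id_b, r2 (empty if independent panel)


# ---------------------------------------------------------------------------
# panel / truth construction (shared by both fidelity modes)
# ---------------------------------------------------------------------------


def _instrument_effects(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """Effect magnitudes uniform on [0.5, 1.5] * scale with random signs.

    Bounded away from zero: every instrument clears genome-wide selection
    decisively, so the default scenarios carry no winner's-curse or
    weak-instrument artefacts.
    """
    return rng.uniform(0.5 * scale, 1.5 * scale, size=n) * rng.choice([-1.0, 1.0], size=n)


def _build_panel(sc: SimScenario, rng: np.random.Generator) -> dict:
    n = sc.n_snps
    maf = rng.uniform(sc.maf_range[0], sc.maf_range[1], size=n)
    ea_idx = rng.integers(0, 4, size=n)
    # other allele: uniform over the remaining three bases
    oa_idx = (ea_idx + rng.integers(1, 4, size=n)) % 4
    effect_allele = _BASES[ea_idx]
    other_allele = _BASES[oa_idx]

    # genomic layout: each LD block occupies one compact region; regions are
    # far apart (> clumping window) and cycle through chromosomes
    block = sc.ld_blocks.block_size if sc.ld_blocks else 1
    region = np.arange(n) // block
    chrom = (region % 22 + 1).astype(str)
    pos = (region // 22) * 50_000_000 + 1_000_000 + (np.arange(n) % block) * 10_000

    gamma = np.zeros(n)
    alpha = np.zeros(n)
    delta = np.zeros(n)
    nx, nm, ny = sc.n_instruments_x, sc.n_instruments_m, sc.n_instruments_y
    ix = np.arange(0, nx)
    im = np.arange(nx, nx + nm)
    iy = np.arange(nx + nm, nx + nm + ny)
    gamma[ix] = _instrument_effects(rng, nx, sc.gamma_scale)
    alpha[im] = _instrument_effects(rng, nm, sc.alpha_scale)
    delta[iy] = _instrument_effects(rng, ny, sc.delta_scale)
    if sc.pleiotropy_mode == "balanced":
        alpha[ix] += rng.normal(0.0, sc.pleiotropy_sd, size=nx)
        delta[ix] += rng.normal(0.0, sc.pleiotropy_sd, size=nx)
    elif sc.pleiotropy_mode == "directional":
        alpha[ix] += rng.normal(sc.pleiotropy_sd, sc.pleiotropy_sd / 2, size=nx)
        delta[ix] += rng.normal(sc.pleiotropy_sd, sc.pleiotropy_sd / 2, size=nx)

    variant_id = np.array([f"rs{100000 + i}" for i in range(n)], dtype=object)
    return {
        "variant_id": variant_id,
        "chrom": chrom,
        "pos": pos.astype(int),
        "effect_allele": effect_allele,
        "other_allele": other_allele,
        "maf": maf,
        "gamma": gamma,
        "alpha": alpha,
        "delta": delta,
        "idx_x": ix,
        "idx_m": im,
        "idx_y": iy,
    }


def _marginal_effects(sc: SimScenario, panel: dict) -> dict:
    """True per-variant marginal effects on each trait (LD-free panel)."""
    g, al, de = panel["gamma"], panel["alpha"], panel["delta"]
    beta_x = g
    beta_m = sc.a_true * g + al
    beta_y = sc.b_true * (sc.a_true * g + al) + sc.c_prime_true * g + de
    return {"beta_x": beta_x, "beta_m": beta_m, "beta_y": beta_y}


def _table(panel, eaf, beta, se, pval, n, name, trait_type, scramble_mask=None) -> SummaryStatsTable:
    """Assemble a canonical table; rows in ``scramble_mask`` are stored on the
    swapped allele (beta negated, eaf complemented), emulating GWAS that
    report different effect alleles."""
    beta = beta.copy()
    eaf = eaf.copy()
    ea = panel["effect_allele"].copy()
    oa = panel["other_allele"].copy()
    if scramble_mask is not None and scramble_mask.any():
        m = scramble_mask
        beta[m] = -beta[m]
        eaf[m] = 1.0 - eaf[m]
        ea[m], oa[m] = oa[m].copy(), ea[m].copy()
    df = pd.DataFrame(
        {
            "variant_id": panel["variant_id"],
            "chrom": panel["chrom"],
            "pos": panel["pos"],
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": np.clip(pval, 5e-324, 1.0),
            "n": np.full(len(beta), n, dtype=int),
        },
        columns=CANONICAL_COLUMNS,
    )
    return SummaryStatsTable(name, trait_type, df)


# ---------------------------------------------------------------------------
# individual-level mode
# ---------------------------------------------------------------------------


def _genotypes(sc: SimScenario, maf: np.ndarray, n_ind: int, rng: np.random.Generator) -> np.ndarray:
    """Hardy-Weinberg genotypes; with ld_blocks, haplotypes share a latent
    Gaussian factor within each block (realized r2 is reported empirically)."""
    n_snps = len(maf)
    if sc.ld_blocks is None:
        return rng.binomial(2, maf, size=(n_ind, n_snps)).astype(np.float64)
    bs, r = sc.ld_blocks.block_size, sc.ld_blocks.r
    thr = stats.norm.ppf(maf)
    g = np.zeros((n_ind, n_snps))
    for _hap in range(2):
        n_blocks = (n_snps + bs - 1) // bs
        common = np.repeat(rng.normal(size=(n_ind, n_blocks)), bs, axis=1)[:, :n_snps]
        own = rng.normal(size=(n_ind, n_snps))
        z = np.sqrt(r) * common + np.sqrt(1 - r) * own
        g += (z < thr[None, :]).astype(np.float64)
    return g


def _ols_per_variant(g: np.ndarray, y: np.ndarray):
    """Simple-regression beta/se/p for every column of g at once."""
    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sgg = np.sum(gc**2, axis=0)
    if np.any(sgg == 0):
        raise DomainError("monomorphic variant in simulated genotypes; widen maf_range or increase n")
    beta = gc.T @ yc / sgg
    sse = np.sum(yc**2) - beta**2 * sgg
    sigma2 = sse / (n - 2)
    se = np.sqrt(sigma2 / sgg)
    pval = 2.0 * stats.t.sf(np.abs(beta / se), df=n - 2)
    return beta, se, pval


def _logistic_per_variant(g: np.ndarray, y: np.ndarray, max_iter: int = 25, tol: float = 1e-8):
    """Per-variant logistic regression (intercept + genotype) by vectorized
    Newton iterations; returns Wald beta/se/p per variant."""
    n, m = g.shape
    b0 = np.full(m, logit(max(min(y.mean(), 1 - 1e-9), 1e-9)))
    b1 = np.zeros(m)
    for _ in range(max_iter):
        eta = b0[None, :] + g * b1[None, :]
        p = expit(eta)
        wgt = p * (1 - p)
        r = y[:, None] - p
        g0 = r.sum(axis=0)
        g1 = (g * r).sum(axis=0)
        h00 = wgt.sum(axis=0)
        h01 = (wgt * g).sum(axis=0)
        h11 = (wgt * g * g).sum(axis=0)
        det = h00 * h11 - h01**2
        det = np.where(det <= 0, np.nan, det)
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        b0 += d0
        b1 += d1
        if np.nanmax(np.abs(np.concatenate([d0, d1]))) < tol:
            break
    eta = b0[None, :] + g * b1[None, :]
    p = expit(eta)
    wgt = p * (1 - p)
    h00 = wgt.sum(axis=0)
    h01 = (wgt * g).sum(axis=0)
    h11 = (wgt * g * g).sum(axis=0)
    det = h00 * h11 - h01**2
    se = np.sqrt(h00 / det)
    pval = 2.0 * stats.norm.sf(np.abs(b1 / se))
    return b1, se, pval


def _realized_ld(sc: SimScenario, g: np.ndarray, variant_id: np.ndarray) -> pd.DataFrame:
    """Empirical within-block r2 pairs from a genotype matrix."""
    rows = []
    if sc.ld_blocks is None:
        return pd.DataFrame(columns=["id_a", "id_b", "r2"])
    bs = sc.ld_blocks.block_size
    n_snps = g.shape[1]
    for start in range(0, n_snps, bs):
        idx = range(start, min(start + bs, n_snps))
        for i in idx:
            for j in idx:
                if j <= i:
                    continue
                r = np.corrcoef(g[:, i], g[:, j])[0, 1]
                rows.append((variant_id[i], variant_id[j], float(r**2)))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "r2"])


def simulate(scenario: SimScenario) -> SimOutput:
    """Individual-level simulation: genotypes, phenotypes, per-variant GWAS."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    panel = _build_panel(sc, rng)
    maf = panel["maf"]

    g_exp = _genotypes(sc, maf, sc.n_exposure, rng)
    g_med = _genotypes(sc, maf, sc.n_mediator, rng)
    g_out = _genotypes(sc, maf, sc.n_outcome, rng)

    def pheno(g):
        x = g @ panel["gamma"] + rng.normal(size=g.shape[0])
        m = sc.a_true * x + g @ panel["alpha"] + rng.normal(size=g.shape[0])
        return x, m

    x_e, _ = pheno(g_exp)
    _, m_m = pheno(g_med)
    x_o, m_o = pheno(g_out)
    eta0 = sc.b_true * m_o + sc.c_prime_true * x_o + g_out @ panel["delta"]
    try:
        beta0 = brentq(lambda b: expit(b + eta0).mean() - sc.outcome_prevalence, -30, 30)
    except ValueError as exc:
        raise DomainError(f"cannot achieve prevalence {sc.outcome_prevalence}: {exc}") from exc
    y = (rng.random(sc.n_outcome) < expit(beta0 + eta0)).astype(np.float64)
    if y.sum() == 0 or y.sum() == sc.n_outcome:
        raise DomainError(
            f"prevalence {sc.outcome_prevalence} incompatible with requested effects: "
            f"{int(y.sum())} cases of {sc.n_outcome} sampled"
        )

    bx, sx, px = _ols_per_variant(g_exp, x_e)
    bm, sm, pm = _ols_per_variant(g_med, m_m)
    by, sy, py = _logistic_per_variant(g_out, y)

    n_rest = sc.n_snps
    scr_m = rng.random(n_rest) < sc.allele_scramble
    scr_y = rng.random(n_rest) < sc.allele_scramble

    exposure = _table(panel, g_exp.mean(axis=0) / 2, bx, sx, px, sc.n_exposure, "exposure", "continuous")
    mediator = _table(panel, g_med.mean(axis=0) / 2, bm, sm, pm, sc.n_mediator, "mediator", "continuous", scr_m)
    outcome = _table(panel, g_out.mean(axis=0) / 2, by, sy, py, sc.n_outcome, "outcome", "binary", scr_y)

    ld_pairs = _realized_ld(sc, g_exp, panel["variant_id"])
    ld: LDLookup
    if len(ld_pairs):
        ld = MatrixLD({(r.id_a, r.id_b): r.r2 for r in ld_pairs.itertuples(index=False)}, default=0.0)
    else:
        ld = ZeroLD()

    truth = _truth_dict(sc, panel, beta0=beta0)
    return SimOutput(exposure, mediator, outcome, truth, ld, ld_pairs)


# ---------------------------------------------------------------------------
# summary-level mode
# ---------------------------------------------------------------------------


def simulate_summary(scenario: SimScenario) -> SimOutput:
    """Draw per-variant estimates from their asymptotic sampling
    distributions (LD-free panels only); orders of magnitude faster than the
    individual-level mode with the same panel/truth construction."""
    sc = scenario
    if sc.ld_blocks is not None:
        raise ConfigError("simulate_summary requires an LD-free panel (ld_blocks=None)")
    rng = np.random.default_rng(sc.seed)
    panel = _build_panel(sc, rng)
    maf = panel["maf"]
    v = 2.0 * maf * (1.0 - maf)
    marg = _marginal_effects(sc, panel)

    gamma, alpha = panel["gamma"], panel["alpha"]
    var_x = 1.0 + np.sum(gamma**2 * v)
    cov_x_galpha = np.sum(gamma * alpha * v)
    var_m = 1.0 + sc.a_true**2 * var_x + np.sum(alpha**2 * v) + 2 * sc.a_true * cov_x_galpha
    prev = sc.outcome_prevalence

    se_x = np.sqrt(var_x / (sc.n_exposure * v))
    se_m = np.sqrt(var_m / (sc.n_mediator * v))
    se_y = np.sqrt(1.0 / (sc.n_outcome * v * prev * (1 - prev)))

    bx = rng.normal(marg["beta_x"], se_x)
    bm = rng.normal(marg["beta_m"], se_m)
    by = rng.normal(marg["beta_y"], se_y)
    px = 2.0 * stats.norm.sf(np.abs(bx / se_x))
    pm = 2.0 * stats.norm.sf(np.abs(bm / se_m))
    py = 2.0 * stats.norm.sf(np.abs(by / se_y))

    def eaf_hat(n):
        return rng.binomial(2 * n, maf) / (2.0 * n)

    scr_m = rng.random(sc.n_snps) < sc.allele_scramble
    scr_y = rng.random(sc.n_snps) < sc.allele_scramble
    exposure = _table(panel, eaf_hat(sc.n_exposure), bx, se_x, px, sc.n_exposure, "exposure", "continuous")
    mediator = _table(panel, eaf_hat(sc.n_mediator), bm, se_m, pm, sc.n_mediator, "mediator", "continuous", scr_m)
    outcome = _table(panel, eaf_hat(sc.n_outcome), by, se_y, py, sc.n_outcome, "outcome", "binary", scr_y)

    truth = _truth_dict(sc, panel, beta0=float(logit(prev)))
    empty = pd.DataFrame(columns=["id_a", "id_b", "r2"])
    return SimOutput(exposure, mediator, outcome, truth, ZeroLD(), empty)


def _truth_dict(sc: SimScenario, panel: dict, beta0: float) -> dict:
    marg = _marginal_effects(sc, panel)
    return {
        "a_true": sc.a_true,
        "b_true": sc.b_true,
        "c_prime_true": sc.c_prime_true,
        "c_total_true": sc.c_total,
        "mediated_proportion_true": (sc.a_true * sc.b_true / sc.c_total) if sc.c_total != 0 else None,
        "beta0": beta0,
        "seed": sc.seed,
        "variant_id": panel["variant_id"].tolist(),
        "maf": panel["maf"].tolist(),
        "gamma": panel["gamma"].tolist(),
        "alpha": panel["alpha"].tolist(),
        "delta": panel["delta"].tolist(),
        "marginal_beta_x": marg["beta_x"].tolist(),
        "marginal_beta_m": marg["beta_m"].tolist(),
        "marginal_beta_y": marg["beta_y"].tolist(),
        "scenario": sc.model_dump(),
    }


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------


def write_fixtures(sim: SimOutput, directory: str | Path) -> dict[str, Path]:
    """Write the three cohort TSVs, the LD pair TSV and the truth JSON in the
    formats the IO and instrument-selection layers consume; reading the TSVs
    back reproduces the in-memory tables exactly."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": d / "exposure.tsv",
        "mediator": d / "mediator.tsv",
        "outcome": d / "outcome.tsv",
        "ld": d / "ld.tsv",
        "truth": d / "truth.json",
    }
    write_summary_stats(sim.exposure_stats, paths["exposure"])
    write_summary_stats(sim.mediator_stats, paths["mediator"])
    write_summary_stats(sim.outcome_stats, paths["outcome"])
    sim.ld_pairs.to_csv(paths["ld"], sep="\t", index=False, float_format="%.17g")
    with open(paths["truth"], "w") as fh:
        json.dump(sim.truth, fh, indent=1)
    return paths
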