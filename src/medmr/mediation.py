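"""Two-phase causal screen and two-step mediation decomposition.

Phase 1 is a bidirectional screen: the exposure must causally affect the
outcome (total effect c, p < alpha) with no evidence of reverse causation
(outcome->exposure effect d, p >= alpha).  Phase 2 estimates the
exposure->mediator effect a and the mediator->outcome effect b by separate
univariable MR runs; a pathway is emitted when both are significant.  The
mediated effect is the product a*b with a delta-method standard error, the
direct effect is c' = c - a*b, and the mediated proportion is (a*b)/c —
reported on the log-odds scale throughout and only when a*b and c agree in
sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats

from .estimators import Z95, MREstimate, ivw
from .exceptions import (
    DegenerateDesignError,
    InsufficientInstrumentsError,
    MedMRError,
    NoOverlapError,
)
from .harmonize import HarmonizeConfig
from .instruments import LDLookup, SelectionConfig
from .io import SummaryStatsTable
from .model import MRModel, MRResults


class MediationConfig(BaseModel):
    """Settings shared by the screen, the MR runs and the decomposition."""

    selection_molecular: SelectionConfig = SelectionConfig(p_threshold=5e-5)
    selection_outcome: SelectionConfig = SelectionConfig(p_threshold=5e-8)
    harmonization: HarmonizeConfig = HarmonizeConfig()
    method: str = "ivw_re"  # primary estimator reported by every run
    alpha: float = Field(0.05, gt=0, lt=1)
    n_boot: int = 1000
    n_presso_simulations: int = 1000
    run_presso: bool = False
    seed: int = 0
    mediated_ci_method: str = "delta"  # "delta" | "montecarlo"
    n_mediated_draws: int = 10000
    exclude_exposure_instruments: bool = True
    multiple_testing: str = "none"  # "none" | "bonferroni" | "fdr_bh"

    model_config = {"arbitrary_types_allowed": True}


@dataclass(frozen=True)
class MediatedEffect:
    effect: float
    se: float
    ci: tuple[float, float]
    pval: float


def mediated_effect_ci(
    a: MREstimate,
    b: MREstimate,
    method: str = "delta",
    n_draws: int = 10000,
    seed: int | None = 0,
) -> MediatedEffect:
    """Product-of-coefficients mediated effect a*b with uncertainty.

    ``delta``: se = sqrt(a^2 se_b^2 + b^2 se_a^2), symmetric normal CI —
    deterministic.  ``montecarlo``: seeded draws from the two normal sampling
    distributions give a percentile CI for the product (the product of two
    normals is skewed; the delta method is first-order).
    """
    effect = a.beta * b.beta
    se = float(np.sqrt(a.beta**2 * b.se**2 + b.beta**2 * a.se**2))
    if method == "delta":
        ci = (effect - Z95 * se, effect + Z95 * se)
        if se == 0.0:
            pval = 1.0 if effect == 0 else 5e-324
        else:
            pval = float(min(1.0, max(2.0 * stats.norm.sf(abs(effect / se)), 5e-324)))
        return MediatedEffect(effect, se, ci, pval)
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        prod = rng.normal(a.beta, a.se, n_draws) * rng.normal(b.beta, b.se, n_draws)
        lo, hi = np.quantile(prod, [0.025, 0.975])
        se_mc = float(np.std(prod, ddof=1))
        p = 2.0 * min(np.mean(prod <= 0.0), np.mean(prod >= 0.0))
        return MediatedEffect(effect, se_mc, (float(lo), float(hi)), float(max(p, 1.0 / n_draws)))
    raise MedMRError(f"unknown mediated-CI method {method!r}")


@dataclass
class BidirectionalResult:
    """Forward (exposure->outcome, c) and reverse (outcome->exposure, d) runs."""

    forward: MRResults | None
    reverse: MRResults | None
    failure_reason: str | None = None

    @property
    def passes_screen(self) -> bool:
        if self.forward is None or self.reverse is None:
            return False
        alpha = 0.05
        return bool(self.forward.pval < alpha and self.reverse.pval >= alpha)

    def passes(self, alpha: float) -> bool:
        if self.forward is None or self.reverse is None:
            return False
        return bool(self.forward.pval < alpha and self.reverse.pval >= alpha)


def _run_mr(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDLookup,
    selection: SelectionConfig,
    cfg: MediationConfig,
    exclude_ids: Sequence[str] | None = None,
) -> MRResults:
    """One full selection -> harmonization -> estimation run."""
    model = MRModel.from_tables(exposure, outcome, ld, selection, cfg.harmonization)
    if exclude_ids:
        drop = set(exclude_ids) & set(model.data.variant_ids)
        if drop:
            model = _drop_from_model(model, drop)
    if model.n_snps < 1:
        raise InsufficientInstrumentsError(
            f"no instruments survive for {exposure.trait_name} -> {outcome.trait_name}"
        )
    return model.fit(
        method=cfg.method,
        n_boot=cfg.n_boot,
        n_presso_simulations=cfg.n_presso_simulations,
        seed=cfg.seed,
        run_presso=cfg.run_presso,
    )


def _drop_from_model(model: MRModel, drop: set) -> MRModel:
    new = MRModel(model.data.drop(drop), exposure=model.exposure, outcome=model.outcome)
    new.selection = model.selection
    new.harmonized = model.harmonized
    return new


def bidirectional_screen(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDLookup,
    config: MediationConfig | None = None,
) -> BidirectionalResult:
    """Phase-1 screen: forward MR at the molecular threshold, reverse MR with
    outcome instruments selected at the stricter genome-wide threshold."""
    cfg = config or MediationConfig()
    try:
        forward = _run_mr(exposure, outcome, ld, cfg.selection_molecular, cfg)
    except (InsufficientInstrumentsError, DegenerateDesignError, NoOverlapError) as exc:
        return BidirectionalResult(None, None, failure_reason=f"forward: {exc}")
    try:
        reverse = _run_mr(outcome, exposure, ld, cfg.selection_outcome, cfg)
    except (InsufficientInstrumentsError, DegenerateDesignError, NoOverlapError) as exc:
        return BidirectionalResult(forward, None, failure_reason=f"reverse: {exc}")
    return BidirectionalResult(forward, reverse)


@dataclass
class MediationResults:
    """The a/b/c/c' decomposition for one exposure-mediator-outcome pathway."""

    exposure: str
    mediator: str
    outcome: str
    screen: BidirectionalResult
    a: MRResults | None = None
    b: MRResults | None = None
    mediated: MediatedEffect | None = None
    rejection_stage: str | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.rejection_stage is None

    @property
    def c(self) -> MRResults | None:
        return self.screen.forward

    @property
    def mediated_effect(self) -> float | None:
        return self.mediated.effect if self.mediated else None

    @property
    def c_prime(self) -> float | None:
        if self.mediated is None or self.c is None:
            return None
        return self.c.beta - self.mediated.effect

    @property
    def proportion(self) -> float | None:
        """Mediated proportion (a*b)/c; None when a*b and c disagree in sign."""
        if self.mediated is None or self.c is None:
            return None
        if np.sign(self.mediated.effect) != np.sign(self.c.beta):
            return None
        return self.mediated.effect / self.c.beta

    def row(self) -> dict:
        med = self.mediated
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "a_beta": self.a.beta if self.a else np.nan,
            "a_pval": self.a.pval if self.a else np.nan,
            "b_beta": self.b.beta if self.b else np.nan,
            "b_pval": self.b.pval if self.b else np.nan,
            "c_beta": self.c.beta if self.c else np.nan,
            "c_pval": self.c.pval if self.c else np.nan,
            "d_pval": self.screen.reverse.pval if self.screen.reverse else np.nan,
            "mediated_effect": med.effect if med else np.nan,
            "mediated_ci_low": med.ci[0] if med else np.nan,
            "mediated_ci_high": med.ci[1] if med else np.nan,
            "mediated_pval": med.pval if med else np.nan,
            "proportion": self.proportion if self.proportion is not None else np.nan,
            "c_prime": self.c_prime if self.c_prime is not None else np.nan,
            "flags": ";".join(self.flags),
            "rejection_stage": self.rejection_stage or "",
        }

    def summary(self) -> str:
        lines = [
            "Two-step MR mediation",
            "=" * 58,
            f"pathway: {self.exposure} -> {self.mediator} -> {self.outcome}",
        ]
        if self.rejection_stage:
            lines.append(f"REJECTED at stage: {self.rejection_stage}")
        for label, res in (("a (exposure->mediator)", self.a), ("b (mediator->outcome)", self.b), ("c (total effect)", self.c)):
            if res is not None:
                lines.append(
                    f"{label:>24}: beta {res.beta: .4f} (se {res.se:.4f}, p {res.pval:.3g}, n_snps {res.n_snps})"
                )
        if self.mediated is not None:
            m = self.mediated
            lines.append(
                f"      mediated effect a*b: {m.effect: .4f} (se {m.se:.4f}, "
                f"95% CI [{m.ci[0]: .4f}, {m.ci[1]: .4f}], p {m.pval:.3g})"
            )
            prop = self.proportion
            lines.append(
                f"      direct effect c':   {self.c_prime: .4f}    mediated proportion: "
                + (f"{100 * prop:.1f}%" if prop is not None else "inconsistent signs")
            )
        if self.flags:
            lines.append(f"flags: {', '.join(self.flags)}")
        lines.append("=" * 58)
        return "\n".join(lines)


class MediationModel:
    """Model object for one exposure - mediator - outcome pathway.

    ``fit()`` runs the bidirectional screen, the a and b MR analyses and the
    decomposition, returning :class:`MediationResults` whose
    ``rejection_stage`` records the first gate the pathway failed (or None).
    """

    def __init__(
        self,
        exposure: SummaryStatsTable,
        mediator: SummaryStatsTable,
        outcome: SummaryStatsTable,
        ld: LDLookup,
        config: MediationConfig | None = None,
    ):
        self.exposure = exposure
        self.mediator = mediator
        self.outcome = outcome
        self.ld = ld
        self.config = config or MediationConfig()

    def fit(self, screen: BidirectionalResult | None = None, force: bool = False) -> MediationResults:
        cfg = self.config
        if screen is None:
            screen = bidirectional_screen(self.exposure, self.outcome, self.ld, cfg)
        res = MediationResults(
            exposure=self.exposure.trait_name,
            mediator=self.mediator.trait_name,
            outcome=self.outcome.trait_name,
            screen=screen,
        )
        if screen.failure_reason is not None:
            res.rejection_stage = f"screen_error:{screen.failure_reason}"
            if not force:
                return res
        elif not screen.passes(cfg.alpha):
            if screen.forward is not None and screen.forward.pval >= cfg.alpha:
                res.rejection_stage = "screen_forward_not_significant"
            else:
                res.rejection_stage = "screen_reverse_causation"
            if not force:
                return res

        exposure_instrument_ids: list[str] = []
        if screen.forward is not None:
            exposure_instrument_ids = list(screen.forward.model.data.variant_ids)

        try:
            res.a = _run_mr(self.exposure, self.mediator, self.ld, cfg.selection_molecular, cfg)
        except (InsufficientInstrumentsError, DegenerateDesignError, NoOverlapError) as exc:
            res.rejection_stage = res.rejection_stage or f"a_error:{exc}"
            return res
        try:
            res.b = _run_mr(
                self.mediator,
                self.outcome,
                self.ld,
                cfg.selection_molecular,
                cfg,
                exclude_ids=exposure_instrument_ids if cfg.exclude_exposure_instruments else None,
            )
        except (InsufficientInstrumentsError, DegenerateDesignError, NoOverlapError) as exc:
            res.rejection_stage = res.rejection_stage or f"b_error:{exc}"
            return res

        if res.rejection_stage is None and res.a.pval >= cfg.alpha:
            res.rejection_stage = "a_not_significant"
        if res.rejection_stage is None and res.b.pval >= cfg.alpha:
            res.rejection_stage = "b_not_significant"
        if res.rejection_stage is not None and not force:
            return res

        res.mediated = mediated_effect_ci(
            res.a.estimate,
            res.b.estimate,
            method=cfg.mediated_ci_method,
            n_draws=cfg.n_mediated_draws,
            seed=cfg.seed,
        )
        if res.c is not None and np.sign(res.mediated.effect) != np.sign(res.c.beta):
            res.flags.append("inconsistent_sign")
        return res


def mediation_pipeline(
    exposure: SummaryStatsTable,
    mediator: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDLookup,
    config: MediationConfig | None = None,
) -> MediationResults:
    """Functional wrapper: build and fit a :class:`MediationModel`."""
    return MediationModel(exposure, mediator, outcome, ld, config).fit()


@dataclass
class BatchResult:
    pathways: list[MediationResults]
    report: pd.DataFrame = field(repr=False)
    rejections: pd.DataFrame = field(repr=False)


def batch_screen(
    exposures: Mapping[str, SummaryStatsTable] | Sequence[SummaryStatsTable],
    mediators: Mapping[str, SummaryStatsTable] | Sequence[SummaryStatsTable],
    outcome: SummaryStatsTable,
    ld: LDLookup,
    config: MediationConfig | None = None,
) -> BatchResult:
    """Evaluate every exposure x mediator pathway.

    Emits the passing pathways (ranked by mediated-effect p-value) plus a log
    of rejections by stage; per-pathway errors never abort the batch.  With
    ``multiple_testing`` set, the a/b gate p-values are adjusted across the
    batch (Bonferroni or Benjamini-Hochberg) before gating; the default is no
    correction.
    """
    cfg = config or MediationConfig()
    exp_list = list(exposures.values()) if isinstance(exposures, Mapping) else list(exposures)
    med_list = list(mediators.values()) if isinstance(mediators, Mapping) else list(mediators)

    screens: dict[str, BidirectionalResult] = {}
    results: list[MediationResults] = []
    for exp in exp_list:
        screens[exp.trait_name] = bidirectional_screen(exp, outcome, ld, cfg)
        for med in med_list:
            model = MediationModel(exp, med, outcome, ld, cfg)
            try:
                results.append(model.fit(screen=screens[exp.trait_name]))
            except MedMRError as exc:  # defensive: never abort the batch
                res = MediationResults(
                    exp.trait_name, med.trait_name, outcome.trait_name,
                    screens[exp.trait_name], rejection_stage=f"error:{exc}",
                )
                results.append(res)

    if cfg.multiple_testing != "none":
        _apply_multiplicity(results, cfg)

    passing = [r for r in results if r.passed]
    passing.sort(key=lambda r: (r.mediated.pval if r.mediated else 1.0))
    report = pd.DataFrame([r.row() for r in passing])
    rejections = pd.DataFrame(
        [
            {"exposure": r.exposure, "mediator": r.mediator, "stage": r.rejection_stage}
            for r in results
            if not r.passed
        ],
        columns=["exposure", "mediator", "stage"],
    )
    return BatchResult(results, report, rejections)


def _apply_multiplicity(results: list[MediationResults], cfg: MediationConfig) -> None:
    """Re-gate a/b significance using adjusted p-values across the batch."""
    testable = [r for r in results if r.passed or r.rejection_stage in ("a_not_significant", "b_not_significant")]
    if not testable:
        return
    for attr in ("a", "b"):
        pvals = np.array([getattr(r, attr).pval for r in testable if getattr(r, attr) is not None])
        rs = [r for r in testable if getattr(r, attr) is not None]
        if len(pvals) == 0:
            continue
        if cfg.multiple_testing == "bonferroni":
            adj = np.minimum(1.0, pvals * len(pvals))
        elif cfg.multiple_testing == "fdr_bh":
            adj = stats.false_discovery_control(pvals, method="bh")
        else:
            raise MedMRError(f"unknown multiple_testing mode {cfg.multiple_testing!r}")
        for r, p in zip(rs, adj):
            if p >= cfg.alpha and r.rejection_stage is None:
                r.rejection_stage = f"{attr}_not_significant_adjusted"
                r.mediated = None
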