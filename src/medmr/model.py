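"""Model/Results interface for a single two-sample MR analysis.

``MRModel`` holds one harmonized instrument set for an exposure/outcome pair
(either supplied directly or built from raw summary-statistics tables via
``MRModel.from_tables``, which runs the instrument-selection funnel and
harmonization).  ``fit()`` returns an ``MRResults`` carrying the causal
estimate, its uncertainty and the diagnostics (Egger intercept, Cochran Q,
leave-one-out, MR-PRESSO), with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimators as est
from .estimators import MRData, MREstimate, HeterogeneityTest, PleiotropyTest, PressoResult
from .exceptions import ConfigError
from .harmonize import HarmonizeConfig, HarmonizedData, harmonize
from .instruments import LDLookup, SelectionConfig, SelectionResult, select_instruments
from .io import SummaryStatsTable

_METHODS = ("ivw_re", "ivw_fixed", "egger", "weighted_median", "wald")


class MRModel:
    """Two-sample MR model over a harmonized instrument set.

    Parameters
    ----------
    data : MRData or HarmonizedData
        Harmonized per-variant exposure/outcome effects.
    exposure, outcome : str
        Trait labels used in summaries and report tables.
    """

    def __init__(self, data, exposure: str = "exposure", outcome: str = "outcome"):
        if isinstance(data, HarmonizedData):
            self.exposure = data.exposure_name
            self.outcome = data.outcome_name
            self.harmonized: HarmonizedData | None = data
            self.data = MRData.from_harmonized(data)
        elif isinstance(data, MRData):
            self.exposure = exposure
            self.outcome = outcome
            self.harmonized = None
            self.data = data
        else:
            raise ConfigError(f"unsupported data type for MRModel: {type(data)!r}")
        self.selection: SelectionResult | None = None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_tables(
        cls,
        exposure: SummaryStatsTable,
        outcome: SummaryStatsTable,
        ld: LDLookup,
        selection: SelectionConfig | None = None,
        harmonization: HarmonizeConfig | None = None,
    ) -> "MRModel":
        """Select instruments from the exposure GWAS, look them up in the
        outcome GWAS, and harmonize — the standard two-sample funnel."""
        sel = select_instruments(exposure, ld, selection)
        outcome_sub = outcome.subset(sel.instruments.data["variant_id"])
        harmonized = harmonize(sel.instruments, outcome_sub, harmonization)
        model = cls(harmonized)
        model.selection = sel
        return model

    @property
    def n_snps(self) -> int:
        return len(self.data)

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        method: str = "ivw_re",
        n_boot: int = 1000,
        n_presso_simulations: int = 1000,
        seed: int | None = 0,
        run_presso: bool = False,
        t_dist_egger: bool = False,
    ) -> "MRResults":
        """Fit the requested estimator plus the standard diagnostics.

        ``method`` is one of ivw_re (default), ivw_fixed, egger,
        weighted_median, wald.  Diagnostics (Egger intercept, Cochran Q,
        leave-one-out) are computed whenever enough instruments are
        available; MR-PRESSO runs only when ``run_presso`` is set (it is the
        expensive component).
        """
        if method not in _METHODS:
            raise ConfigError(f"unknown method {method!r}; expected one of {_METHODS}")
        d = self.data
        n = len(d)

        if method == "wald":
            if n != 1:
                raise ConfigError("wald method applies to a single instrument")
            estimate = est.wald_ratio(float(d.bx[0]), float(d.by[0]), float(d.sy[0]))
        elif method == "ivw_re":
            estimate = est.ivw(d, random_effects=True)
        elif method == "ivw_fixed":
            estimate = est.ivw(d, random_effects=False)
        elif method == "egger":
            estimate, _ = est.egger(d, t_dist=t_dist_egger)
        else:
            estimate = est.weighted_median(d, n_boot=n_boot, seed=seed)

        pleiotropy = heterogeneity = None
        loo = None
        if n >= 3:
            _egger_est, pleiotropy = est.egger(d, t_dist=t_dist_egger)
            loo = est.leave_one_out(d)
        if n >= 2:
            ref = estimate if method.startswith("ivw") else est.ivw(d)
            offset = 2 if method == "egger" else 1
            at = estimate if method == "egger" else ref
            heterogeneity = est.cochran_q(d, at, df_offset=offset)
        presso = None
        retained = None
        if run_presso and n >= 4:
            presso, retained_data = est.mr_presso(
                d, n_simulations=n_presso_simulations, seed=seed
            )
            retained = retained_data
        return MRResults(
            model=self,
            estimate=estimate,
            pleiotropy=pleiotropy,
            heterogeneity=heterogeneity,
            leave_one_out=loo,
            presso=presso,
            presso_retained=retained,
        )

    def fit_all(self, n_boot: int = 1000, seed: int | None = 0) -> pd.DataFrame:
        """Primary (IVW) plus secondary (weighted median, MR-Egger) estimates
        as one forest-plot-ready table."""
        rows = []
        methods = ["ivw_re", "ivw_fixed"]
        if self.n_snps >= 2:
            methods.append("weighted_median")
        if self.n_snps >= 3:
            methods.append("egger")
        for m in methods:
            res = self.fit(method=m, n_boot=n_boot, seed=seed)
            rows.append(res.row())
        return pd.DataFrame(rows)


@dataclass
class MRResults:
    """Fitted causal estimate with diagnostics for one exposure/outcome pair."""

    model: MRModel
    estimate: MREstimate
    pleiotropy: PleiotropyTest | None = None
    heterogeneity: HeterogeneityTest | None = None
    leave_one_out: pd.DataFrame | None = field(default=None, repr=False)
    presso: PressoResult | None = None
    presso_retained: MRData | None = field(default=None, repr=False)

    # convenience pass-throughs
    @property
    def beta(self) -> float:
        return self.estimate.beta

    @property
    def se(self) -> float:
        return self.estimate.se

    @property
    def pval(self) -> float:
        return self.estimate.pval

    @property
    def n_snps(self) -> int:
        return self.estimate.n_snps

    def conf_int(self) -> tuple[float, float]:
        return self.estimate.ci

    @property
    def odds_ratio(self) -> float:
        return self.estimate.or_point

    @property
    def or_conf_int(self) -> tuple[float, float]:
        return self.estimate.or_ci

    def no_pleiotropy(self, alpha: float = 0.05) -> bool | None:
        """True when the Egger intercept gives no evidence of directional
        pleiotropy (p >= alpha); None when untestable (< 3 instruments)."""
        if self.pleiotropy is None:
            return None
        return self.pleiotropy.pval >= alpha

    def row(self) -> dict:
        """One forest-plot row: exposure, outcome, method, estimate, OR, CI, p."""
        e = self.estimate
        lo, hi = e.or_ci
        return {
            "exposure": self.model.exposure,
            "outcome": self.model.outcome,
            "method": e.method,
            "n_snps": e.n_snps,
            "beta": e.beta,
            "se": e.se,
            "OR": e.or_point,
            "CI_low": lo,
            "CI_high": hi,
            "pval": e.pval,
        }

    def diagnostics_row(self) -> dict:
        return {
            "exposure": self.model.exposure,
            "outcome": self.model.outcome,
            "n_snps": self.n_snps,
            "egger_intercept": self.pleiotropy.intercept if self.pleiotropy else np.nan,
            "intercept_pval": self.pleiotropy.pval if self.pleiotropy else np.nan,
            "Q": self.heterogeneity.q_stat if self.heterogeneity else np.nan,
            "Q_df": self.heterogeneity.df if self.heterogeneity else np.nan,
            "Q_pval": self.heterogeneity.pval if self.heterogeneity else np.nan,
            "presso_global_pval": self.presso.global_pval if self.presso else np.nan,
            "n_outliers": len(self.presso.outliers) if self.presso else np.nan,
            "n_influential_loo": int(self.leave_one_out["influential"].sum())
            if self.leave_one_out is not None
            else np.nan,
        }

    def summary(self) -> str:
        e = self.estimate
        lo, hi = e.or_ci
        blo, bhi = e.ci
        lines = [
            "Two-sample MR results",
            "=" * 58,
            f"exposure:  {self.model.exposure}",
            f"outcome:   {self.model.outcome}",
            f"method:    {e.method}    instruments: {e.n_snps}",
            "-" * 58,
            f"beta {e.beta: .4f}  se {e.se:.4f}  95% CI [{blo: .4f}, {bhi: .4f}]  p {e.pval:.3g}",
            f"OR   {e.or_point: .4f}          95% CI [{lo: .4f}, {hi: .4f}]",
        ]
        if self.pleiotropy is not None:
            lines.append(
                f"Egger intercept {self.pleiotropy.intercept: .4f} "
                f"(se {self.pleiotropy.intercept_se:.4f}, p {self.pleiotropy.pval:.3g})"
            )
        if self.heterogeneity is not None:
            h = self.heterogeneity
            lines.append(f"Cochran Q {h.q_stat:.2f} on {h.df} df (p {h.pval:.3g})")
        if self.presso is not None:
            lines.append(
                f"MR-PRESSO global p {self.presso.global_pval:.3g}, "
                f"{len(self.presso.outliers)} outlier(s)"
            )
        if self.leave_one_out is not None:
            lines.append(
                f"leave-one-out: {int(self.leave_one_out['influential'].sum())} influential omission(s)"
            )
        lines.append("=" * 58)
        return "\n".join(lines)
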