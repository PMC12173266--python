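"""Selection of independent, strong genetic instruments.

The funnel is: p-value screen (genome-wide 5e-8 when the outcome is used as
an exposure, 5e-5 for molecular traits) -> greedy distance/r2 clumping ->
per-variant F-statistic filter (F > 10).  Every dropped variant is logged
with the stage that removed it, so stage counts always reconcile.

LD is supplied by the caller as a pairwise r2 lookup (precomputed matrix
file, simulation output, or a callback); computing LD from a genotype
reference panel is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .exceptions import DomainError, LDLookupError
from .io import SummaryStatsTable


class SelectionConfig(BaseModel):
    """Thresholds for instrument selection.

    Defaults follow the molecular-trait convention: p < 5e-5 screen, 10,000 kb
    clumping window at r2 < 0.001, and F > 10.  Use ``p_threshold=5e-8`` when
    a disease outcome serves as the exposure of a reverse-direction analysis.
    """

    p_threshold: float = Field(5e-5, gt=0)
    clump_kb: float = Field(10_000, gt=0)
    clump_r2: float = Field(0.001, ge=0, le=1)
    f_min: float = Field(10.0, ge=0)
    r2_estimator: str = "tstat"  # "tstat" | "eaf"


# ---------------------------------------------------------------------------
# LD lookups
# ---------------------------------------------------------------------------


class LDLookup:
    """Pairwise r2 lookup interface."""

    def r2(self, id_a: str, id_b: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class ZeroLD(LDLookup):
    """All pairs independent (r2 = 0); suitable for simulated independent panels."""

    def r2(self, id_a: str, id_b: str) -> float:
        return 0.0


class DistanceOnlyLD(LDLookup):
    """No-LD mode: treats every same-chromosome pair inside the clumping
    window as fully correlated, so clumping prunes by distance alone.
    This is an approximation for when no LD source is available."""

    def r2(self, id_a: str, id_b: str) -> float:
        return 1.0


class MatrixLD(LDLookup):
    """r2 from an explicit pair table; unlisted pairs raise :class:`LDLookupError`."""

    def __init__(self, pairs: dict[tuple[str, str], float], default: float | None = None):
        self._pairs = {}
        for (a, b), v in pairs.items():
            self._pairs[(a, b)] = float(v)
            self._pairs[(b, a)] = float(v)
        self.default = default

    @classmethod
    def from_tsv(cls, path: str | Path, default: float | None = None) -> "MatrixLD":
        df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
        return cls({(r.id_a, r.id_b): r.r2 for r in df.itertuples(index=False)}, default=default)

    def r2(self, id_a: str, id_b: str) -> float:
        if id_a == id_b:
            return 1.0
        try:
            return self._pairs[(id_a, id_b)]
        except KeyError:
            if self.default is not None:
                return self.default
            raise LDLookupError(id_a, id_b) from None


class CallbackLD(LDLookup):
    def __init__(self, fn: Callable[[str, str], float]):
        self._fn = fn

    def r2(self, id_a: str, id_b: str) -> float:
        return float(self._fn(id_a, id_b))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def pvalue_screen(table: SummaryStatsTable, p_threshold: float) -> SummaryStatsTable:
    """Keep records with pval < p_threshold, original order preserved."""
    kept = table.data.loc[table.data["pval"] < p_threshold].reset_index(drop=True)
    return SummaryStatsTable(table.trait_name, table.trait_type, kept)


def clump(
    table: SummaryStatsTable,
    ld: LDLookup,
    clump_kb: float = 10_000,
    clump_r2: float = 0.001,
) -> SummaryStatsTable:
    """Greedy LD clumping.

    Repeatedly take the remaining variant with the smallest p-value as an
    index variant and discard all remaining same-chromosome variants within
    ``clump_kb`` kilobases whose r2 with the index is >= ``clump_r2``.
    Ties in p-value are broken by (chrom, pos, variant_id) so the result does
    not depend on input row order.
    """
    df = table.data.reset_index(drop=True)
    order = df.sort_values(
        ["pval", "chrom", "pos", "variant_id"], kind="mergesort"
    ).index.to_list()
    window_bp = clump_kb * 1000.0

    alive = {i: True for i in order}
    kept_idx: list[int] = []
    chrom = df["chrom"]
    pos = df["pos"]
    vid = df["variant_id"]
    for i in order:
        if not alive[i]:
            continue
        kept_idx.append(i)
        alive[i] = False
        for j in order:
            if not alive[j]:
                continue
            if chrom[j] != chrom[i]:
                continue
            if abs(pos[j] - pos[i]) > window_bp:
                continue
            if ld.r2(vid[i], vid[j]) >= clump_r2:
                alive[j] = False
    kept_idx_sorted = sorted(kept_idx)  # original order
    kept = df.loc[kept_idx_sorted].reset_index(drop=True)
    return SummaryStatsTable(table.trait_name, table.trait_type, kept)


def f_statistic(r2: float, n_total: int, k_instruments: int) -> float:
    """Instrument-strength F = [R2/(1-R2)] * [(N-K-1)/K].

    N is the GWAS sample size and K the number of instruments (K = 1 for the
    per-variant filter).
    """
    if not (0.0 <= r2 < 1.0):
        raise DomainError(f"r2 must be in [0,1), got {r2}")
    if k_instruments < 1:
        raise DomainError(f"k_instruments must be >= 1, got {k_instruments}")
    if n_total <= k_instruments + 1:
        raise DomainError(f"need n_total > k_instruments + 1, got N={n_total}, K={k_instruments}")
    return (r2 / (1.0 - r2)) * ((n_total - k_instruments - 1) / k_instruments)


def estimate_r2(beta: float, se: float, n: int, eaf: float | None = None, method: str = "tstat") -> float:
    """Per-variant explained variance.

    ``tstat``: r2 = t^2 / (t^2 + n - 2) with t = beta/se — needs no allele
    frequency.  ``eaf``: 2*eaf*(1-eaf)*beta^2, valid for a standardized
    continuous trait.
    """
    if method == "tstat":
        if n <= 2:
            raise DomainError(f"need n > 2 for the t-statistic r2, got {n}")
        t2 = (beta / se) ** 2
        return t2 / (t2 + n - 2)
    if method == "eaf":
        if eaf is None or not np.isfinite(eaf):
            raise DomainError("eaf-based r2 requires a finite effect-allele frequency")
        return 2.0 * eaf * (1.0 - eaf) * beta**2
    raise DomainError(f"unknown r2 method {method!r}")


@dataclass
class SelectionResult:
    """Selected instruments plus the per-variant funnel report.

    ``report`` has one row per input variant: variant_id, pval, r2, f_stat,
    kept, drop_reason (one of "", "pvalue", "clump", "f_stat").
    """

    instruments: SummaryStatsTable
    report: pd.DataFrame = field(repr=False)

    def stage_counts(self) -> dict[str, int]:
        reasons = self.report["drop_reason"]
        return {
            "input": len(self.report),
            "dropped_pvalue": int((reasons == "pvalue").sum()),
            "dropped_clump": int((reasons == "clump").sum()),
            "dropped_f_stat": int((reasons == "f_stat").sum()),
            "kept": int(self.report["kept"].sum()),
        }


def select_instruments(
    table: SummaryStatsTable, ld: LDLookup, config: SelectionConfig | None = None
) -> SelectionResult:
    """p-value screen -> clump -> F filter, with a full accounting report."""
    cfg = config or SelectionConfig()
    df = table.data

    screened = pvalue_screen(table, cfg.p_threshold)
    after_screen = set(screened.data["variant_id"])

    clumped = clump(screened, ld, cfg.clump_kb, cfg.clump_r2)
    after_clump = set(clumped.data["variant_id"])

    # F filter on clumped set
    r2_vals: dict[str, float] = {}
    f_vals: dict[str, float] = {}
    keep_ids = []
    for rec in clumped.data.itertuples(index=False):
        r2 = estimate_r2(rec.beta, rec.se, rec.n, rec.eaf, method=cfg.r2_estimator)
        f = f_statistic(r2, rec.n, 1)
        r2_vals[rec.variant_id] = r2
        f_vals[rec.variant_id] = f
        if f > cfg.f_min:
            keep_ids.append(rec.variant_id)
    kept_set = set(keep_ids)

    report = pd.DataFrame(
        {
            "variant_id": df["variant_id"],
            "pval": df["pval"],
            "r2": [r2_vals.get(v, np.nan) for v in df["variant_id"]],
            "f_stat": [f_vals.get(v, np.nan) for v in df["variant_id"]],
            "kept": [v in kept_set for v in df["variant_id"]],
            "drop_reason": [
                ""
                if v in kept_set
                else "pvalue"
                if v not in after_screen
                else "clump"
                if v not in after_clump
                else "f_stat"
                for v in df["variant_id"]
            ],
        }
    )
    instruments = table.subset(keep_ids)
    return SelectionResult(instruments, report)


def write_selection_report(result: SelectionResult, path, delimiter: str = "\t") -> None:
    result.report.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
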