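"""Allele harmonization of exposure/outcome summary statistics.

Two-sample MR requires the per-variant exposure and outcome effects to refer
to the same effect allele.  Non-palindromic variants can be aligned from the
allele letters alone (swapping alleles negates the effect and complements the
frequency).  Palindromic variants (A/T, C/G) are strand-ambiguous: they are
aligned by effect-allele-frequency agreement when the exposure frequency is
away from 0.5, and excluded as "ambiguous" when it falls inside a window
around 0.5 (default [0.42, 0.58]) where frequency cannot resolve the strand.
A strict mode drops every palindromic variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import NoOverlapError
from .io import SummaryStatsTable

PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: columns of the harmonized table
HARMONIZED_COLUMNS = [
    "variant_id",
    "beta_exposure",
    "se_exposure",
    "pval_exposure",
    "beta_outcome",
    "se_outcome",
    "eaf_exposure",
    "eaf_outcome",
    "flipped",
    "palindromic",
]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is its own reverse complement (A/T or C/G)."""
    return (effect_allele.upper(), other_allele.upper()) in PALINDROMIC_PAIRS


@dataclass
class HarmonizeConfig:
    eaf_window: tuple[float, float] = (0.42, 0.58)
    drop_all_palindromic: bool = False


@dataclass
class HarmonizedData:
    """Harmonized exposure/outcome pairs plus the exclusion log.

    ``pairs`` has one row per retained variant (HARMONIZED_COLUMNS);
    ``exclusions`` has columns ``variant_id`` and ``reason`` with one row per
    excluded overlapping variant, so len(pairs) + len(exclusions) equals the
    size of the variant-ID intersection.
    """

    exposure_name: str
    outcome_name: str
    pairs: pd.DataFrame = field(repr=False)
    exclusions: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.pairs)


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    config: HarmonizeConfig | None = None,
) -> HarmonizedData:
    """Align outcome effects onto the exposure's effect-allele frame.

    Returns retained pairs and a per-variant exclusion log with reason codes
    ``ambiguous`` (palindromic, frequency uninformative or missing),
    ``palindromic`` (strict mode) and ``incompatible`` (allele sets that match
    neither directly nor by swap).
    """
    cfg = config or HarmonizeConfig()
    lo, hi = cfg.eaf_window

    exp = exposure.data
    out = outcome.data
    merged = exp.merge(out, on="variant_id", suffixes=("_exp", "_out"), how="inner")
    if len(merged) == 0:
        raise NoOverlapError(
            f"no overlapping variants between {exposure.trait_name!r} and {outcome.trait_name!r}"
        )

    rows = []
    excl = []
    for rec in merged.itertuples(index=False):
        vid = rec.variant_id
        ea_e, oa_e = rec.effect_allele_exp, rec.other_allele_exp
        ea_o, oa_o = rec.effect_allele_out, rec.other_allele_out
        pal = is_palindromic(ea_e, oa_e)

        same = (ea_o == ea_e) and (oa_o == oa_e)
        swapped = (ea_o == oa_e) and (oa_o == ea_e)
        if not same and not swapped:
            excl.append((vid, "incompatible"))
            continue

        if pal and cfg.drop_all_palindromic:
            excl.append((vid, "palindromic"))
            continue

        eaf_e = rec.eaf_exp
        eaf_o = rec.eaf_out
        if pal:
            # Allele letters cannot resolve strand for palindromic variants;
            # align by frequency agreement instead.
            if not np.isfinite(eaf_e) or not np.isfinite(eaf_o):
                excl.append((vid, "ambiguous"))
                continue
            if lo <= eaf_e <= hi:
                excl.append((vid, "ambiguous"))
                continue
            flip = (eaf_e - 0.5) * (eaf_o - 0.5) < 0  # opposite sides of 0.5
            beta_o = -rec.beta_out if flip else rec.beta_out
            eaf_o_al = 1.0 - eaf_o if flip else eaf_o
            rows.append(
                (vid, rec.beta_exp, rec.se_exp, rec.pval_exp, beta_o, rec.se_out, eaf_e, eaf_o_al, flip, True)
            )
        else:
            if same:
                rows.append(
                    (vid, rec.beta_exp, rec.se_exp, rec.pval_exp, rec.beta_out, rec.se_out, eaf_e, eaf_o, False, False)
                )
            else:  # swapped
                eaf_o_al = 1.0 - eaf_o if np.isfinite(eaf_o) else np.nan
                rows.append(
                    (vid, rec.beta_exp, rec.se_exp, rec.pval_exp, -rec.beta_out, rec.se_out, eaf_e, eaf_o_al, True, False)
                )

    pairs = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    exclusions = pd.DataFrame(excl, columns=["variant_id", "reason"])
    return HarmonizedData(exposure.trait_name, outcome.trait_name, pairs, exclusions)


def write_harmonized(data: HarmonizedData, pairs_path, exclusions_path=None, delimiter: str = "\t") -> None:
    data.pairs.to_csv(pairs_path, sep=delimiter, index=False, float_format="%.17g")
    if exclusions_path is not None:
        data.exclusions.to_csv(exclusions_path, sep=delimiter, index=False)
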