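"""Reading, validating and writing GWAS summary statistics.

A summary-statistics table holds one row per variant: identifier, position,
allele pair, effect-allele frequency, effect estimate (beta; log-odds for a
binary trait), its standard error, p-value and sample size.  Input is
header-labelled delimited text with a user-supplied column map, which covers
FinnGen-style and biobank-style exports alike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .exceptions import ConfigError, RowValidationError

VALID_BASES = frozenset("ACGT")

#: canonical column order used throughout the package
CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]


class ColumnMap(BaseModel):
    """Maps canonical field names to the column names of a source file.

    ``eaf`` may be ``None`` for files that do not report allele frequencies;
    the frequency is then recorded as missing for every variant.
    """

    variant_id: str = "variant_id"
    chrom: str = "chrom"
    pos: str = "pos"
    effect_allele: str = "effect_allele"
    other_allele: str = "other_allele"
    eaf: str | None = "eaf"
    beta: str = "beta"
    se: str = "se"
    pval: str = "pval"
    n: str = "n"


@dataclass
class SummaryStatsTable:
    """GWAS summary statistics for one trait.

    ``data`` uses the canonical columns; ``variant_id`` is unique.
    ``trait_type`` is ``"continuous"`` or ``"binary"`` (betas are log-odds
    ratios for binary traits).
    """

    trait_name: str
    trait_type: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ConfigError(f"summary table missing canonical columns: {missing}")
        if self.data["variant_id"].duplicated().any():
            dups = self.data.loc[self.data["variant_id"].duplicated(), "variant_id"]
            raise ConfigError(f"duplicate variant_id values: {sorted(set(dups))[:5]}")

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStatsTable":
        """Rows whose variant_id is in ``variant_ids``, original order preserved."""
        keep = self.data["variant_id"].isin(set(variant_ids))
        return SummaryStatsTable(self.trait_name, self.trait_type, self.data.loc[keep].reset_index(drop=True))

    def copy(self) -> "SummaryStatsTable":
        return SummaryStatsTable(self.trait_name, self.trait_type, self.data.copy())


def _validate_row(row: Mapping, line_no: int, errors: list[tuple[int, str]]) -> dict | None:
    """Normalize and validate one record; append to ``errors`` on failure."""
    out: dict = {}
    try:
        out["variant_id"] = str(row["variant_id"])
        out["chrom"] = str(row["chrom"])
        pos = int(row["pos"])
        if pos < 1:
            errors.append((line_no, f"pos must be >= 1, got {pos}"))
            return None
        out["pos"] = pos
        ea = str(row["effect_allele"]).upper()
        oa = str(row["other_allele"]).upper()
        if ea not in VALID_BASES or oa not in VALID_BASES:
            errors.append((line_no, f"alleles must be single bases A/C/G/T, got {ea!r}/{oa!r}"))
            return None
        if ea == oa:
            errors.append((line_no, f"effect_allele equals other_allele ({ea})"))
            return None
        out["effect_allele"], out["other_allele"] = ea, oa
        eaf = row.get("eaf", None)
        if eaf is None or (isinstance(eaf, float) and math.isnan(eaf)) or eaf == "":
            out["eaf"] = np.nan
        else:
            eaf = float(eaf)
            if not (0.0 <= eaf <= 1.0):
                errors.append((line_no, f"eaf outside [0,1]: {eaf}"))
                return None
            out["eaf"] = eaf
        beta = float(row["beta"])
        if not math.isfinite(beta):
            errors.append((line_no, f"non-finite beta: {beta}"))
            return None
        out["beta"] = beta
        se = float(row["se"])
        if not (se > 0) or not math.isfinite(se):
            errors.append((line_no, f"se must be > 0, got {se}"))
            return None
        out["se"] = se
        pval = float(row["pval"])
        if not (0.0 < pval <= 1.0):
            errors.append((line_no, f"pval must be in (0,1], got {pval}"))
            return None
        out["pval"] = pval
        n = int(row["n"])
        if n < 1:
            errors.append((line_no, f"n must be a positive integer, got {n}"))
            return None
        out["n"] = n
    except (KeyError, TypeError, ValueError) as exc:
        errors.append((line_no, f"unparseable row: {exc}"))
        return None
    return out


def table_from_records(
    records: Iterable[Mapping], trait_name: str, trait_type: str, *, first_line: int = 2
) -> SummaryStatsTable:
    """Build a validated table from dict-like records (line numbers for errors)."""
    errors: list[tuple[int, str]] = []
    rows = []
    for i, rec in enumerate(records):
        parsed = _validate_row(rec, first_line + i, errors)
        if parsed is not None:
            rows.append(parsed)
    if errors:
        raise RowValidationError(errors)
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    return SummaryStatsTable(trait_name, trait_type, df)


def read_summary_stats(
    path: str | Path,
    column_map: ColumnMap | Mapping[str, str | None] | None = None,
    trait_type: str = "continuous",
    trait_name: str | None = None,
    delimiter: str = "\t",
) -> SummaryStatsTable:
    """Read a delimited summary-statistics file into a validated table.

    Malformed rows are collected and reported together with their physical
    line numbers (header is line 1) in a :class:`RowValidationError`.
    """
    path = Path(path)
    if column_map is None:
        cmap = ColumnMap()
    elif isinstance(column_map, ColumnMap):
        cmap = column_map
    else:
        cmap = ColumnMap(**dict(column_map))

    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    mapping = cmap.model_dump()
    needed = {v for k, v in mapping.items() if v is not None}
    missing = needed - set(raw.columns)
    if missing:
        raise ConfigError(f"{path}: mapped columns not found in header: {sorted(missing)}")

    records = []
    for rec in raw.to_dict(orient="records"):
        canon = {k: rec[v] for k, v in mapping.items() if v is not None}
        if mapping["eaf"] is None:
            canon["eaf"] = np.nan
        records.append(canon)
    return table_from_records(
        records, trait_name or path.stem, trait_type, first_line=2
    )


def write_summary_stats(table: SummaryStatsTable, path: str | Path, delimiter: str = "\t") -> None:
    """Write a table with canonical headers; floats round-trip exactly."""
    table.data.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
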