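"""Instrument selection: screening, clumping, strength filter, LD lookups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from medmr import (
    DistanceOnlyLD,
    MatrixLD,
    SelectionConfig,
    ZeroLD,
    clump,
    estimate_r2,
    f_statistic,
    pvalue_screen,
    select_instruments,
)
from medmr.exceptions import DomainError, LDLookupError
from medmr.instruments import CallbackLD
from medmr.io import CANONICAL_COLUMNS, SummaryStatsTable
from medmr.validation import funnel_fixture


def _table(rows, name="t"):
    return SummaryStatsTable(name, "continuous", pd.DataFrame(rows, columns=CANONICAL_COLUMNS))


def _row(vid, chrom="1", pos=100, pval=1e-6, beta=0.12, se=0.015, eaf=0.3, n=8000):
    return dict(variant_id=vid, chrom=chrom, pos=pos, effect_allele="A", other_allele="G",
                eaf=eaf, beta=beta, se=se, pval=pval, n=n)


# -- LD lookups -------------------------------------------------------------


def test_zero_ld():
    assert ZeroLD().r2("a", "b") == 0.0


def test_distance_only_ld():
    assert DistanceOnlyLD().r2("a", "b") == 1.0


def test_matrix_ld_symmetric_and_self():
    ld = MatrixLD({("a", "b"): 0.7})
    assert ld.r2("a", "b") == 0.7
    assert ld.r2("b", "a") == 0.7
    assert ld.r2("a", "a") == 1.0


def test_matrix_ld_missing_pair_raises_without_default():
    ld = MatrixLD({("a", "b"): 0.7})
    with pytest.raises(LDLookupError):
        ld.r2("a", "c")
    assert MatrixLD({("a", "b"): 0.7}, default=0.0).r2("a", "c") == 0.0


def test_matrix_ld_from_tsv(tmp_path):
    path = tmp_path / "ld.tsv"
    pd.DataFrame({"id_a": ["a"], "id_b": ["b"], "r2": [0.5]}).to_csv(path, sep="\t", index=False)
    assert MatrixLD.from_tsv(path).r2("b", "a") == 0.5


def test_callback_ld():
    assert CallbackLD(lambda a, b: 0.25).r2("x", "y") == 0.25


# -- p-value screen ---------------------------------------------------------


def test_pvalue_screen_strict_inequality():
    t = _table([_row("a", pval=5e-5), _row("b", pval=4.9e-5, pos=200)])
    kept = pvalue_screen(t, 5e-5)
    assert list(kept.data["variant_id"]) == ["b"]


def test_pvalue_screen_preserves_order():
    t = _table([_row(f"v{i}", pval=1e-6, pos=100 * (i + 1)) for i in range(4)])
    assert list(pvalue_screen(t, 1e-3).data["variant_id"]) == ["v0", "v1", "v2", "v3"]


# -- clumping ---------------------------------------------------------------


def test_clump_prunes_by_ld_within_window():
    t = _table([
        _row("lead", pos=1_000_000, pval=1e-9),
        _row("near", pos=1_500_000, pval=1e-6),       # r2 0.9: pruned
        _row("indep", pos=2_000_000, pval=1e-6),      # r2 tiny: kept
        _row("far", pos=50_000_000, pval=1e-6),       # outside 10 Mb window: kept
    ])
    ld = MatrixLD({("lead", "near"): 0.9, ("lead", "indep"): 0.0005,
                   ("near", "indep"): 0.9}, default=0.0)
    kept = clump(t, ld, clump_kb=10_000, clump_r2=0.001)
    assert list(kept.data["variant_id"]) == ["lead", "indep", "far"]


def test_clump_different_chromosomes_independent():
    t = _table([_row("a", chrom="1", pval=1e-9), _row("b", chrom="2", pval=1e-6)])
    kept = clump(t, DistanceOnlyLD())
    assert list(kept.data["variant_id"]) == ["a", "b"]


def test_clump_row_order_invariance():
    rows = [_row("a", pos=1_000_000, pval=1e-9), _row("b", pos=1_100_000, pval=1e-6),
            _row("c", pos=9_000_000, pval=1e-7), _row("d", chrom="2", pval=1e-5)]
    ld = DistanceOnlyLD()
    ref = set(clump(_table(rows), ld).data["variant_id"])
    perm = set(clump(_table([rows[2], rows[0], rows[3], rows[1]]), ld).data["variant_id"])
    assert ref == perm == {"a", "d"}


def test_clump_pvalue_tie_broken_by_position():
    rows = [_row("late", pos=2_000_000, pval=1e-6), _row("early", pos=1_000_000, pval=1e-6)]
    kept = clump(_table(rows), DistanceOnlyLD())
    assert list(kept.data["variant_id"]) == ["early"]


@given(st.lists(
    st.tuples(st.integers(0, 50), st.integers(1, 10_000_000), st.floats(1e-12, 1.0)),
    min_size=1, max_size=15,
))
def test_clump_contraction_property(raw):
    rows, seen = [], set()
    for i, (vid_i, pos, pval) in enumerate(raw):
        vid = f"v{vid_i}"
        if vid in seen:
            continue
        seen.add(vid)
        rows.append(_row(vid, pos=pos, pval=pval))
    t = _table(rows)
    kept = set(clump(t, DistanceOnlyLD()).data["variant_id"])
    assert kept <= seen and len(kept) >= 1


# -- instrument strength ----------------------------------------------------


def test_f_statistic_exact_values():
    assert f_statistic(0.5, 3, 1) == pytest.approx(1.0, abs=1e-12)
    assert f_statistic(0.01, 7174, 1) == pytest.approx(7172 / 99, abs=1e-9)


def test_f_statistic_domain_errors():
    with pytest.raises(DomainError):
        f_statistic(1.0, 100, 1)
    with pytest.raises(DomainError):
        f_statistic(-0.1, 100, 1)
    with pytest.raises(DomainError):
        f_statistic(0.1, 2, 1)
    with pytest.raises(DomainError):
        f_statistic(0.1, 100, 0)


def test_estimate_r2_tstat_equals_f_identity():
    # with r2 = t^2/(t^2 + n - 2), F = [r2/(1-r2)]*(n-2) reduces exactly to t^2
    beta, se, n = 0.12, 0.015, 8000
    r2 = estimate_r2(beta, se, n)
    f = f_statistic(r2, n, 1)
    assert f == pytest.approx((beta / se) ** 2, rel=1e-9)


def test_estimate_r2_eaf_method():
    assert estimate_r2(0.2, 0.05, 1000, eaf=0.25, method="eaf") == pytest.approx(2 * 0.25 * 0.75 * 0.04)
    with pytest.raises(DomainError):
        estimate_r2(0.2, 0.05, 1000, eaf=None, method="eaf")
    with pytest.raises(DomainError):
        estimate_r2(0.2, 0.05, 1000, method="nope")


def test_f_monotone_in_r2():
    fs = [f_statistic(r2, 1000, 1) for r2 in (0.001, 0.01, 0.1, 0.5)]
    assert fs == sorted(fs)


# -- full funnel ------------------------------------------------------------


def test_select_instruments_funnel_fixture_exact():
    exposure, _, ld, expected = funnel_fixture()
    sel = select_instruments(exposure, ld, SelectionConfig(p_threshold=5e-5))
    rep = sel.report
    assert set(rep.loc[rep["drop_reason"] == "pvalue", "variant_id"]) == expected["dropped_pvalue"]
    assert set(rep.loc[rep["drop_reason"] == "clump", "variant_id"]) == expected["dropped_clump"]
    assert set(rep.loc[rep["drop_reason"] == "f_stat", "variant_id"]) == expected["dropped_f_stat"]
    assert set(sel.instruments.data["variant_id"]) == expected["selected"]


def test_stage_counts_reconcile():
    exposure, _, ld, _ = funnel_fixture()
    counts = select_instruments(exposure, ld, SelectionConfig(p_threshold=5e-5)).stage_counts()
    assert counts["input"] == (counts["dropped_pvalue"] + counts["dropped_clump"]
                               + counts["dropped_f_stat"] + counts["kept"])


def test_selection_tightening_threshold_contracts():
    exposure, _, ld, _ = funnel_fixture()
    loose = set(select_instruments(exposure, ld, SelectionConfig(p_threshold=5e-5)).instruments.data["variant_id"])
    tight = set(select_instruments(exposure, ld, SelectionConfig(p_threshold=1e-6)).instruments.data["variant_id"])
    assert tight <= loose
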