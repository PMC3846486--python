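"""Exact contingency tests and the incongruence tally."""

import numpy as np
import pytest

from wpiptyper.association import (
    ContingencyTable,
    SpecimenRecord,
    build_table,
    count_incongruent,
    enumerate_log_probs,
    fisher_exact,
    ld_test,
)
from wpiptyper.fixtures import make_cohort


def _ct(matrix):
    m = np.asarray(matrix)
    return ContingencyTable(
        tuple(f"r{i}" for i in range(m.shape[0])),
        tuple(f"c{j}" for j in range(m.shape[1])),
        m,
    )


# -- build_table -------------------------------------------------------------

def test_build_table_from_table3_cohort(scheme):
    records = make_cohort("table3", scheme, seed=2)
    t = build_table(records, "wpip_group", "taxon")
    assert t.total == 409
    i = t.row_labels.index("I")
    j = t.col_labels.index("quinquefasciatus")
    assert t.counts[i, j] == 133


def test_build_table_from_table2_cohort(scheme):
    t = build_table(make_cohort("table2", scheme, seed=2), "mtdna_group", "wpip_group")
    assert t.total == 184
    assert t.row_margins.tolist() == [72, 43, 46, 21, 2]  # mtDNA-1..5


def test_build_table_single_record():
    t = build_table(
        [SpecimenRecord("s", wpip_group="I", taxon="pipiens")], "wpip_group", "taxon"
    )
    assert t.counts.tolist() == [[1]]


def test_build_table_drop_missing():
    records = [
        SpecimenRecord("a", wpip_group="I", taxon="pipiens"),
        SpecimenRecord("b", wpip_group="I", taxon=None),
    ]
    assert build_table(records, "wpip_group", "taxon").total == 1
    assert build_table(records, "wpip_group", "taxon", drop_missing=False).total == 2
    with pytest.raises(ValueError):
        build_table([SpecimenRecord("c", ank2="a")], "wpip_group", "taxon")


# -- fisher_exact ------------------------------------------------------------

def test_2x2_matches_closed_form_hypergeometric():
    from scipy.stats import fisher_exact as scipy_fisher

    table = [[1, 9], [11, 3]]
    mine = fisher_exact(_ct(table))
    assert mine.method == "enumeration"
    assert mine.p_value == pytest.approx(scipy_fisher(table)[1], abs=1e-12)


def test_2x2_battery_matches_scipy():
    from scipy.stats import fisher_exact as scipy_fisher

    rng = np.random.default_rng(0)
    checked = 0
    while checked < 30:
        m = rng.integers(0, 12, size=(2, 2))
        if m.sum(axis=1).min() == 0 or m.sum(axis=0).min() == 0:
            continue
        mine = fisher_exact(_ct(m)).p_value
        ref = scipy_fisher(m)[1]
        assert mine == pytest.approx(ref, abs=1e-12), m
        checked += 1


def test_enumeration_probabilities_sum_to_one():
    for matrix in ([[1, 9], [11, 3]], [[5, 2, 1], [1, 6, 2], [2, 1, 7]], [[3, 3], [3, 3]]):
        lps = enumerate_log_probs(_ct(matrix))
        assert np.exp(lps).sum() == pytest.approx(1.0, abs=1e-9)


def test_monte_carlo_converges_to_enumeration():
    battery = [
        [[5, 2, 1], [1, 6, 2], [2, 1, 7]],
        [[4, 0, 2], [2, 5, 1], [0, 3, 6]],
        [[8, 1, 1], [1, 8, 1], [1, 1, 8]],
    ]
    for matrix in battery:
        exact = fisher_exact(_ct(matrix))
        mc = fisher_exact(_ct(matrix), enumeration_cap=10, mc_reps=100_000, seed=1)
        assert mc.method == "monte_carlo"
        assert mc.seed == 1
        assert abs(mc.p_value - exact.p_value) <= 3 * mc.mc_standard_error


def test_monte_carlo_is_seed_deterministic():
    m = _ct([[4, 0, 2], [2, 5, 1], [0, 3, 6]])
    r1 = fisher_exact(m, enumeration_cap=10, mc_reps=20_000, seed=9)
    r2 = fisher_exact(m, enumeration_cap=10, mc_reps=20_000, seed=9)
    assert r1.p_value == r2.p_value


def test_monte_carlo_requires_seed():
    with pytest.raises(ValueError, match="seed"):
        fisher_exact(_ct([[4, 0, 2], [2, 5, 1], [0, 3, 6]]), enumeration_cap=10)


def test_degenerate_single_row_is_p1():
    with pytest.warns(UserWarning, match="degenerate"):
        r = fisher_exact(_ct([[3, 4, 5]]))
    assert r.p_value == 1.0
    # an all-zero row is trimmed first
    with pytest.warns(UserWarning):
        r2 = fisher_exact(_ct([[3, 4, 5], [0, 0, 0]]))
    assert r2.p_value == 1.0


def test_enumeration_result_carries_no_seed():
    r = fisher_exact(_ct([[3, 3], [3, 3]]))
    assert r.seed is None and r.mc_standard_error is None


# -- ld_test -----------------------------------------------------------------

def test_perfect_linkage_is_extreme():
    records = [SpecimenRecord(f"a{i}", ank2="a", pk1="a") for i in range(50)] + [
        SpecimenRecord(f"b{i}", ank2="b", pk1="b") for i in range(50)
    ]
    r = ld_test(records)
    assert r.p_value < 1e-5


def test_single_shared_allele_degenerate():
    records = [SpecimenRecord(f"s{i}", ank2="a", pk1="a") for i in range(20)]
    with pytest.warns(UserWarning):
        r = ld_test(records)
    assert r.p_value == 1.0


def test_table1_cohort_ld_is_significant(scheme, table1_records):
    """ank2/pk1 are co-transmitted: the cohort shows extreme disequilibrium."""
    r = ld_test(table1_records, enumeration_cap=20_000, mc_reps=50_000, seed=3)
    assert r.p_value < 1e-4


# -- incongruence ------------------------------------------------------------

def test_incongruence_counts_on_wpip_mtdna_partition(scheme):
    t = build_table(make_cohort("table2", scheme, seed=4), "mtdna_group", "wpip_group")
    rows = {r["row"]: r for r in count_incongruent(t)}
    assert rows["mtDNA-1"]["off_modal"] == 7
    assert rows["mtDNA-1"]["off_modal_cells"] == {"V": 7}
    assert rows["mtDNA-2"]["off_modal"] == 4
    assert rows["mtDNA-2"]["off_modal_cells"] == {"III": 3, "undetermined": 1}
    assert rows["mtDNA-5"]["off_modal"] == 0


def test_incongruence_single_column_all_zero():
    t = _ct([[4], [7]])
    rows = count_incongruent(t)
    assert all(r["off_modal"] == 0 for r in rows)


def test_incongruence_tie_flagged():
    rows = count_incongruent(_ct([[3, 3, 1]]))
    assert rows[0]["tie"] is True
    assert sorted(rows[0]["modal"]) == ["c0", "c1"]
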