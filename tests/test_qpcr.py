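"""Comparative-C_T quantification: arithmetic, conventions, and table-level behavior."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aai_score import (
    CtRecord,
    InputValidationError,
    MissingDataError,
    delta_ct,
    delta_delta_ct,
    fold_change,
    mean_ct,
    quantify_table,
)

finite_cycles = st.floats(min_value=-50, max_value=50, allow_nan=False, allow_infinity=False)


@pytest.mark.parametrize(
    "replicates, expected",
    [
        ([20.0, 20.0, 20.0], 20.0),
        ([19.0, 21.0], 20.0),
        ([18.1, 18.4, 18.7], 18.4),  # checked against independent summation: 55.2 / 3
    ],
)
def test_mean_ct(replicates, expected):
    assert mean_ct(replicates) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("bad", [[], [float("nan")], [20.0, float("inf")]])
def test_mean_ct_rejects_empty_and_nonfinite(bad):
    with pytest.raises(InputValidationError):
        mean_ct(bad)


@pytest.mark.parametrize(
    "op, args, expected",
    [
        (delta_ct, (25.0, 20.0), 5.0),
        (delta_ct, (20.0, 20.0), 0.0),
        (delta_ct, (18.0, 20.5), -2.5),
        (delta_delta_ct, (5.0, 5.0), 0.0),
        (delta_delta_ct, (2.0, 5.0), -3.0),
        (delta_delta_ct, (6.5, 5.0), 1.5),
        (fold_change, (0.0,), 1.0),  # the calibrator itself: "PBS set to 1"
        (fold_change, (-3.0,), 8.0),
        (fold_change, (2.0,), 0.25),
    ],
)
def test_ct_arithmetic(op, args, expected):
    assert op(*args) == pytest.approx(expected, rel=1e-15)


@pytest.mark.parametrize("op", [delta_ct, delta_delta_ct])
def test_subtractions_reject_nonfinite(op):
    with pytest.raises(InputValidationError):
        op(float("nan"), 20.0)
    with pytest.raises(InputValidationError):
        op(20.0, float("inf"))


@given(x=finite_cycles)
def test_calibrator_against_itself_is_one(x):
    assert fold_change(delta_delta_ct(x, x)) == 1.0


@given(a=finite_cycles, b=finite_cycles)
def test_fold_change_is_multiplicative(a, b):
    assert fold_change(a + b) == pytest.approx(fold_change(a) * fold_change(b), rel=1e-12)


def _rec(sample, group, dose, gene, *cts):
    return CtRecord(sample_id=sample, group=group, dose=dose, gene=gene, ct_replicates=cts)


def test_single_calibrator_composition():
    """One group, calibrator dCt 5.0, test sample dCt 2.0 -> fold change 8."""
    records = [
        _rec("pbs1", "g", 0.0, "GAPDH", 20.0),
        _rec("pbs1", "g", 0.0, "IL-4", 25.0),  # dCt 5
        _rec("hdm1", "g", 100.0, "GAPDH", 19.0),
        _rec("hdm1", "g", 100.0, "IL-4", 21.0),  # dCt 2
    ]
    out = {r.sample_id: r for r in quantify_table(records)}
    assert out["pbs1"].fold_change == pytest.approx(1.0)
    assert out["hdm1"].delta_delta_ct == pytest.approx(-3.0)
    assert out["hdm1"].fold_change == pytest.approx(8.0)


def test_identical_cts_give_unit_fold_changes():
    records = [
        _rec(f"s{i}", "g", dose, gene, 21.5)
        for i, dose in enumerate([0.0, 0.0, 25.0, 100.0])
        for gene in ("GAPDH", "IL-4", "CCL7")
    ]
    for r in quantify_table(records):
        assert r.fold_change == pytest.approx(1.0)


def test_two_group_table_matches_spreadsheet_oracle():
    """Every ddCt recomputed independently with plain dict arithmetic."""
    table = {
        # sample: (group, dose, {gene: ct})
        "a-pbs1": ("A", 0.0, {"GAPDH": 20.0, "IL-4": 25.0, "IL-13": 26.0}),
        "a-pbs2": ("A", 0.0, {"GAPDH": 19.5, "IL-4": 24.9, "IL-13": 26.1}),
        "a-hdm1": ("A", 100.0, {"GAPDH": 20.2, "IL-4": 22.0, "IL-13": 24.0}),
        "a-hdm2": ("A", 100.0, {"GAPDH": 19.8, "IL-4": 22.5, "IL-13": 23.5}),
        "b-pbs1": ("B", 0.0, {"GAPDH": 21.0, "IL-4": 27.5, "IL-13": 28.0}),
        "b-pbs2": ("B", 0.0, {"GAPDH": 21.2, "IL-4": 27.3, "IL-13": 28.4}),
        "b-hdm1": ("B", 100.0, {"GAPDH": 21.1, "IL-4": 26.0, "IL-13": 27.2}),
    }
    records = [
        _rec(s, grp, dose, gene, ct)
        for s, (grp, dose, genes) in table.items()
        for gene, ct in genes.items()
    ]
    results = {(r.sample_id, r.analyte): r for r in quantify_table(records)}

    # independent recomputation, spreadsheet style
    for gene in ("IL-4", "IL-13"):
        for grp in ("A", "B"):
            pbs_dcts = [
                genes[gene] - genes["GAPDH"]
                for s, (g, dose, genes) in table.items()
                if g == grp and dose == 0.0
            ]
            calibrator = sum(pbs_dcts) / len(pbs_dcts)
            for s, (g, dose, genes) in table.items():
                if g != grp:
                    continue
                ddct = (genes[gene] - genes["GAPDH"]) - calibrator
                r = results[(s, gene)]
                assert r.delta_delta_ct == pytest.approx(ddct, abs=1e-12)
                assert r.fold_change == pytest.approx(2.0 ** -ddct, rel=1e-12)

    # calibrator-group mean fold change is 1 only in expectation, but the
    # mean of ddCt over the PBS samples is 0 by construction
    for grp in ("A", "B"):
        for gene in ("IL-4", "IL-13"):
            pbs = [
                results[(s, gene)].delta_delta_ct
                for s, (g, dose, _) in table.items()
                if g == grp and dose == 0.0
            ]
            assert sum(pbs) / len(pbs) == pytest.approx(0.0, abs=1e-12)


def test_constant_offset_target_gives_unit_folds():
    """Target C_T = reference C_T + const (any samples) -> fold change 1 everywhere."""
    records = []
    for i, (dose, ref) in enumerate([(0.0, 20.0), (0.0, 21.0), (25.0, 18.5), (100.0, 22.0)]):
        records.append(_rec(f"s{i}", "g", dose, "GAPDH", ref))
        records.append(_rec(f"s{i}", "g", dose, "CCL11", ref + 4.2))
    for r in quantify_table(records):
        assert r.fold_change == pytest.approx(1.0, rel=1e-12)


def test_missing_reference_gene_names_the_sample():
    records = [
        _rec("ok", "g", 0.0, "GAPDH", 20.0),
        _rec("ok", "g", 0.0, "IL-4", 25.0),
        _rec("broken", "g", 25.0, "IL-4", 23.0),
    ]
    with pytest.raises(MissingDataError, match="broken"):
        quantify_table(records)


def test_missing_calibrator_names_the_group():
    records = [
        _rec("s1", "noPBS", 25.0, "GAPDH", 20.0),
        _rec("s1", "noPBS", 25.0, "IL-4", 23.0),
    ]
    with pytest.raises(MissingDataError, match="noPBS"):
        quantify_table(records)


def test_replicate_rows_are_pooled_before_averaging():
    records = [
        _rec("s1", "g", 0.0, "GAPDH", 20.0, 20.4),
        _rec("s1", "g", 0.0, "GAPDH", 20.8),  # same well set, split across rows
        _rec("s1", "g", 0.0, "IL-4", 25.4),
    ]
    (r,) = quantify_table(records)
    assert r.delta_ct == pytest.approx(25.4 - 20.4)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(ct_replicates=()),
        dict(ct_replicates=(0.0,)),
        dict(ct_replicates=(float("nan"),)),
        dict(dose=-1.0),
    ],
)
def test_ct_record_validation(kwargs):
    base = dict(sample_id="s", group="g", dose=0.0, gene="IL-4", ct_replicates=(20.0,))
    with pytest.raises(InputValidationError):
        CtRecord(**{**base, **kwargs})
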