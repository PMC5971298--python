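"""Preparation chain: error labelling, filtering, imputation, encoding, screening."""

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from warfrev.cohort import CohortTable, VariableDef, default_spec_from_tables, generate_cohort
from warfrev import preprocessing as prep


# ---------------------------------------------------------------------------
# percentage error
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "idp, td, expected",
    [
        (5.0, 5.0, 0.0),
        (10.0, 8.0, 0.25),
        (16.0, 2.744, 4.831),  # the published extreme is attainable
        (2.0, 10.0, -0.8),
    ],
)
def test_percentage_error_therapeutic_denominator(idp, td, expected):
    assert prep.compute_percentage_error(idp, td) == pytest.approx(expected, abs=1e-3)


def test_percentage_error_idp_denominator_is_bounded_above_by_one():
    e = prep.compute_percentage_error(16.0, 2.744, denominator="idp")
    assert e == pytest.approx((16.0 - 2.744) / 16.0)
    assert e < 1.0


def test_percentage_error_rejects_nonpositive_doses():
    with pytest.raises(ValueError):
        prep.compute_percentage_error(0.0, 5.0)
    with pytest.raises(ValueError):
        prep.compute_percentage_error(5.0, -1.0)


# ---------------------------------------------------------------------------
# row filters
# ---------------------------------------------------------------------------

def _tiny_cohort(idps, tds=None):
    n = len(idps)
    tds = tds if tds is not None else [5.0] * n
    df = pd.DataFrame(
        {"idp": idps, "therapeutic_dose": tds},
        index=pd.Index([f"P{i}" for i in range(n)], name="id"),
    )
    schema = {
        "idp": VariableDef(kind="continuous", units="mg/day"),
        "therapeutic_dose": VariableDef(kind="continuous", units="mg/day"),
    }
    return CohortTable(df, schema)


def test_popular_filter_keeps_exact_grid_matches():
    cohort = _tiny_cohort([2.5, 3.0, 5.0, 9.0])
    kept = prep.filter_popular_doses(cohort, (2.5, 4, 5, 7.5, 10))
    assert list(kept.data.index) == ["P0", "P2"]


def test_popular_filter_with_full_grid_is_identity(cohort150):
    grid = sorted(cohort150.data["idp"].unique())
    kept = prep.filter_popular_doses(cohort150, grid)
    pd.testing.assert_frame_equal(kept.data, cohort150.data)


def test_popular_filter_retains_three_quarters_under_defaults():
    spec = default_spec_from_tables(n_patients=2000, seed=13)
    cohort = generate_cohort(spec)
    kept = prep.filter_popular_doses(cohort, spec.clinician_model.popular_grid)
    assert kept.n / cohort.n == pytest.approx(0.75, abs=0.03)


def test_drop_missing_label_counts_dropped_rows():
    cohort = _tiny_cohort([5.0] * 10)
    cohort.data.loc[["P1", "P4", "P7"], "therapeutic_dose"] = np.nan
    kept, dropped = prep.drop_missing_label(cohort)
    assert dropped == 3 and kept.n == 7
    full, dropped0 = prep.drop_missing_label(_tiny_cohort([5.0] * 4))
    assert dropped0 == 0 and full.n == 4
    allmiss = _tiny_cohort([5.0] * 3)
    allmiss.data["therapeutic_dose"] = np.nan
    empty, _ = prep.drop_missing_label(allmiss)
    assert empty.n == 0


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------

def _knn_fixture():
    """Six complete rows + the AST-missing row last; x/y place the target row
    near rows with AST 20..28 and far from the decoy."""
    df = pd.DataFrame(
        {
            "x": [0.0, 0.1, -0.1, 0.05, -0.05, 50.0, 0.0],
            "ast": [20.0, 22.0, 24.0, 26.0, 28.0, 500.0, np.nan],
            "smoke": ["No", "No", "No", "No", "No", "Yes", "No"],
        },
        index=pd.Index([f"P{i}" for i in range(7)], name="id"),
    )
    schema = {
        "x": VariableDef(kind="continuous"),
        "ast": VariableDef(kind="continuous", units="u/L"),
        "smoke": VariableDef(kind="categorical", levels=("Yes", "No"),
                             reference_level="No"),
    }
    return CohortTable(df, schema)


def test_knn_matches_brute_force_oracle_on_fixture():
    cohort = _knn_fixture()
    out = prep.impute_knn(cohort, k=5, exclude=())

    # independent brute-force: Gower-style distance over observed variables
    df = cohort.data
    sds = {c: df[c].std(ddof=0) for c in ("x", "ast")}
    dists = {}
    for rid in df.index[:-1]:
        d, cnt = 0.0, 0
        for c in ("x", "ast"):
            if not (pd.isna(df.at["P6", c]) or pd.isna(df.at[rid, c])):
                d += ((df.at["P6", c] - df.at[rid, c]) / sds[c]) ** 2
                cnt += 1
        d += float(df.at["P6", "smoke"] != df.at[rid, "smoke"])
        cnt += 1
        dists[rid] = d / cnt
    nearest = sorted(dists, key=lambda r: dists[r])[:5]
    oracle = df.loc[nearest, "ast"].mean()

    assert out.data.at["P6", "ast"] == pytest.approx(oracle)
    assert oracle == pytest.approx(24.0)  # the decoy row is excluded


def test_knn_identity_when_nothing_missing(cohort150):
    out = prep.impute_knn(cohort150, k=5)
    pd.testing.assert_frame_equal(out.data, cohort150.data)


def test_knn_k1_copies_the_exact_duplicate():
    cohort = _knn_fixture()
    df = cohort.data.copy()
    df.loc["P6", "x"] = 50.0
    df.loc["P6", "smoke"] = "Yes"  # now a duplicate of the decoy row P5
    dup = CohortTable(df, dict(cohort.schema))
    out = prep.impute_knn(dup, k=1, exclude=())
    assert out.data.at["P6", "ast"] == 500.0


def test_knn_warns_and_falls_back_with_few_neighbours():
    cohort = _tiny_cohort([5.0, 5.0])
    cohort.data.loc["P0", "idp"] = np.nan
    with pytest.warns(UserWarning):
        out = prep.impute_knn(cohort, k=5, exclude=("therapeutic_dose",))
    assert out.data.at["P0", "idp"] == 5.0


# ---------------------------------------------------------------------------
# imbalance exclusion
# ---------------------------------------------------------------------------

def _binary_cohort(n_yes, n_no, extra=None):
    n = n_yes + n_no
    data = {"flag": ["Yes"] * n_yes + ["No"] * n_no}
    schema = {"flag": VariableDef(kind="categorical", levels=("Yes", "No"),
                                  reference_level="No")}
    if extra:
        data.update(extra[0])
        schema.update(extra[1])
    df = pd.DataFrame(data, index=pd.Index([f"P{i}" for i in range(n)], name="id"))
    return CohortTable(df, schema)


@pytest.mark.parametrize(
    "n_yes, n_no, excluded",
    [
        (1, 99, True),     # 1%/99%, like the rarest published comorbidities
        (50, 50, False),
        (10, 90, False),   # exactly at the bound: the rule is strict "less than"
        (9, 91, True),
    ],
)
def test_imbalanced_binary_exclusion_rule(n_yes, n_no, excluded):
    cohort = _binary_cohort(n_yes, n_no)
    out, dropped = prep.exclude_imbalanced_binaries(cohort, min_fraction=0.10)
    assert (("flag" in dropped) == excluded)
    assert ("flag" in out.schema) != excluded


def test_multilevel_variables_not_touched_by_imbalance_rule():
    extra = (
        {"race": ["A"] * 98 + ["B", "C"]},
        {"race": VariableDef(kind="categorical", levels=("A", "B", "C"),
                             reference_level="A")},
    )
    cohort = _binary_cohort(50, 50, extra=extra)
    out, dropped = prep.exclude_imbalanced_binaries(cohort, min_fraction=0.10)
    assert "race" in out.schema and dropped == []


# ---------------------------------------------------------------------------
# encoding and standardization
# ---------------------------------------------------------------------------

def _cat_cohort():
    rng = np.random.default_rng(4)
    n = 40
    df = pd.DataFrame(
        {
            "age": rng.uniform(20, 80, n),
            "race": rng.choice(["A", "B", "C"], n),
            "idp": rng.choice([2.5, 5.0, 10.0], n),
            "therapeutic_dose": rng.uniform(2, 12, n),
        },
        index=pd.Index([f"P{i}" for i in range(n)], name="id"),
    )
    schema = {
        "age": VariableDef(kind="continuous", units="years"),
        "race": VariableDef(kind="categorical", levels=("A", "B", "C"),
                            reference_level="A"),
        "idp": VariableDef(kind="continuous", units="mg/day"),
        "therapeutic_dose": VariableDef(kind="continuous", units="mg/day"),
    }
    return CohortTable(df, schema)


def test_k_level_variable_yields_k_minus_1_dummies():
    mat = prep.encode_and_standardize(_cat_cohort())
    race_cols = [c for c in mat.columns if c.source == "race"]
    assert len(race_cols) == 2
    assert {c.level for c in race_cols} == {"B", "C"}
    j = [mat.column_names.index(c.name) for c in race_cols]
    sums = mat.values[:, j].sum(axis=1)
    assert set(np.unique(sums)) <= {0.0, 1.0}


def test_exclude_idp_drops_the_order_column():
    mat = prep.encode_and_standardize(_cat_cohort(), include_idp=False)
    assert "idp" not in mat.column_names


def test_standardization_round_trips_through_metadata():
    cohort = _cat_cohort()
    mat = prep.encode_and_standardize(cohort)
    enc = mat.meta["encoder"]
    back = enc.invert(mat)
    np.testing.assert_allclose(back["age"], cohort.data["age"], atol=1e-10)
    np.testing.assert_allclose(back["idp"], cohort.data["idp"], atol=1e-10)


def test_standardizer_fit_on_training_rows_only():
    cohort = _cat_cohort()
    fit_rows = list(cohort.data.index[:25])
    mat = prep.encode_and_standardize(cohort, fit_rows=fit_rows)
    age_info = next(c for c in mat.columns if c.name == "age")
    sub = cohort.data.loc[fit_rows, "age"]
    assert age_info.mean == pytest.approx(sub.mean())
    assert age_info.sd == pytest.approx(sub.std(ddof=0))
    j = mat.column_names.index("age")
    fit_idx = [mat.row_ids.index(r) for r in fit_rows]
    assert mat.values[fit_idx, j].mean() == pytest.approx(0.0, abs=1e-8)
    assert mat.values[fit_idx, j].std() == pytest.approx(1.0, abs=1e-8)


def test_unseen_level_encodes_as_reference_with_warning():
    cohort = _cat_cohort()
    enc = prep.ColumnEncoder().fit(cohort)
    other = _cat_cohort()
    other.data.loc[other.data.index[0], "race"] = "Z"
    with pytest.warns(UserWarning, match="unseen"):
        mat = enc.transform(other)
    j = [mat.column_names.index(c.name) for c in mat.columns if c.source == "race"]
    assert mat.values[0, j].sum() == 0.0


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

def test_duplicated_column_reduced_to_one(matrix_factory):
    rng = np.random.default_rng(0)
    x = rng.normal(size=200)
    X = np.column_stack([x, rng.normal(size=200), x])
    mat = matrix_factory(X, rng.normal(size=200), names=["a", "b", "a_copy"])
    out = prep.filter_correlated(mat, threshold=0.85)
    assert len(out.columns) == 2
    assert len(out.meta["dropped_correlated"]) == 1


def test_independent_columns_survive(matrix_factory):
    rng = np.random.default_rng(1)
    X = rng.normal(size=(1000, 2))
    out = prep.filter_correlated(matrix_factory(X, rng.normal(size=1000)), 0.85)
    assert len(out.columns) == 2


def test_pair_at_exactly_the_boundary_is_reduced(matrix_factory):
    rng = np.random.default_rng(2)
    n = 400
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    xs = (x - x.mean()) / x.std()
    resid = z - xs * (xs @ z) / n
    zs = resid / resid.std()
    y = 0.85 * xs + np.sqrt(1 - 0.85**2) * zs  # sample correlation exactly 0.85
    mat = matrix_factory(np.column_stack([xs, y]), rng.normal(size=n))
    out = prep.filter_correlated(mat, threshold=0.85)
    assert len(out.columns) == 1


def test_constant_column_dropped_with_warning(matrix_factory):
    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(50), rng.normal(size=50)])
    with pytest.warns(UserWarning, match="constant"):
        out = prep.filter_correlated(matrix_factory(X, rng.normal(size=50)), 0.85)
    assert [c.name for c in out.columns] == ["x1"]


def test_pipeline_idempotent_on_design(matrix_factory):
    rng = np.random.default_rng(5)
    X = rng.normal(size=(100, 4))
    mat = matrix_factory(X, rng.normal(size=100))
    once = prep.filter_correlated(mat, 0.85)
    twice = prep.filter_correlated(once, 0.85)
    assert once.column_names == twice.column_names
    np.testing.assert_array_equal(once.values, twice.values)
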