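"""Data preparation for the percentage-error model.

The chain mirrors the study protocol: label the percentage error of the
clinician's initial order, keep only patients ordered a popular dose, drop
rows without an observed therapeutic dose, impute remaining gaps with a
mixed-type K-nearest-neighbours rule, dummy-code categoricals against a
reference level, drop badly imbalanced binaries, standardize, and screen
highly correlated predictor columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import IDP_COL, LABEL_COL, TRUTH_COL, CohortTable

__all__ = [
    "ColumnInfo",
    "DesignMatrix",
    "compute_percentage_error",
    "filter_popular_doses",
    "drop_missing_label",
    "impute_knn",
    "exclude_imbalanced_binaries",
    "encode_and_standardize",
    "ColumnEncoder",
    "filter_correlated",
]


def compute_percentage_error(idp, therapeutic_dose, denominator: str = "therapeutic"):
    """Signed relative dosing error of the initial order, as a fraction.

    Positive values are overdoses, negative underdoses.  The denominator is
    the therapeutic dose by default (the only convention compatible with the
    observed error range, where errors well above +1 occur); ``"idp"`` is
    available as an alternative convention.
    """
    idp = np.asarray(idp, dtype=float)
    td = np.asarray(therapeutic_dose, dtype=float)
    if np.any(idp <= 0) or np.any(td <= 0):
        raise ValueError("doses must be positive")
    if denominator == "therapeutic":
        out = (idp - td) / td
    elif denominator == "idp":
        out = (idp - td) / idp
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return out if out.ndim else float(out)


def filter_popular_doses(cohort: CohortTable, grid: Sequence[float]) -> CohortTable:
    """Keep patients whose IDP sits on the popular dose grid (0.1 mg match)."""
    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    idp = cohort.data[IDP_COL]
    rounded = np.round(idp.astype(float) * 10) / 10
    keep = idp.notna() & rounded.isin([round(g, 1) for g in grid])
    return CohortTable(cohort.data.loc[keep].copy(), dict(cohort.schema))


def drop_missing_label(cohort: CohortTable) -> tuple[CohortTable, int]:
    """Remove rows without an observed therapeutic dose; report the count."""
    keep = cohort.data[LABEL_COL].notna()
    dropped = int((~keep).sum())
    return CohortTable(cohort.data.loc[keep].copy(), dict(cohort.schema)), dropped


# ---------------------------------------------------------------------------
# KNN imputation with a Gower-style mixed-type distance
# ---------------------------------------------------------------------------

def _pairwise_distances(
    target: pd.DataFrame,
    reference: pd.DataFrame,
    cont_cols: list[str],
    cat_cols: list[str],
    sds: dict[str, float],
) -> np.ndarray:
    """Mean per-variable dissimilarity over variables observed in both rows.

    Continuous: squared difference of sd-standardized values.  Categorical:
    simple matching (0 same / 1 different).  Pairs sharing no observed
    variable get distance +inf.
    """
    nt, nr = len(target), len(reference)
    num = np.zeros((nt, nr))
    cnt = np.zeros((nt, nr))
    for c in cont_cols:
        x = target[c].to_numpy(dtype=float)[:, None]
        y = reference[c].to_numpy(dtype=float)[None, :]
        ok = ~np.isnan(x) & ~np.isnan(y)
        d = np.where(ok, ((x - y) / sds[c]) ** 2, 0.0)
        num += d
        cnt += ok
    for c in cat_cols:
        xv = target[c].to_numpy(dtype=object)
        yv = reference[c].to_numpy(dtype=object)
        xna, yna = pd.isna(xv), pd.isna(yv)
        xv = np.where(xna, "\x00missing", xv)  # sentinel keeps != well-defined
        yv = np.where(yna, "\x00missing", yv)
        ok = ~xna[:, None] & ~yna[None, :]
        mismatch = xv[:, None] != yv[None, :]
        num += np.where(ok & mismatch, 1.0, 0.0)
        cnt += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(cnt > 0, num / np.maximum(cnt, 1), np.inf)
    return dist


def impute_knn(
    cohort: CohortTable,
    k: int = 5,
    reference: CohortTable | None = None,
    exclude: Sequence[str] = (LABEL_COL, TRUTH_COL),
) -> CohortTable:
    """Fill missing covariate cells from the k most similar reference rows.

    Distances use only variables observed in both rows; continuous cells are
    imputed with the neighbour mean, categorical with the neighbour mode
    (ties broken by level order).  ``reference`` defaults to the cohort
    itself; in a train/test protocol pass the training cohort so the test
    rows never inform each other.  Columns in ``exclude`` (the label and the
    synthetic ground truth) take no part in distances or imputation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ref = reference if reference is not None else cohort
    vars_ = [c for c in cohort.data.columns if c not in set(exclude)]
    cont = [c for c in vars_ if cohort.schema[c].kind == "continuous"]
    cat = [c for c in vars_ if cohort.schema[c].kind == "categorical"]

    sds = {}
    for c in cont:
        sd = float(ref.data[c].std(ddof=0))
        sds[c] = sd if sd > 0 else 1.0

    out = cohort.data.copy()
    need = cohort.data[vars_].isna()
    rows_with_missing = need.any(axis=1)
    if not rows_with_missing.any():
        return CohortTable(out, dict(cohort.schema))

    target = cohort.data.loc[rows_with_missing, vars_]
    dist = _pairwise_distances(target, ref.data[vars_], cont, cat, sds)
    # a row must not be its own neighbour when the cohort is its own reference
    if reference is None:
        tpos = {rid: i for i, rid in enumerate(cohort.data.index)}
        for i, rid in enumerate(target.index):
            dist[i, tpos[rid]] = np.inf
    ref_df = ref.data[vars_]

    for i, rid in enumerate(target.index):
        missing_here = [c for c in vars_ if need.at[rid, c]]
        for c in missing_here:
            observed = ref_df[c].notna().to_numpy()
            usable = observed & np.isfinite(dist[i])
            n_usable = int(usable.sum())
            if n_usable == 0:
                warnings.warn(
                    f"row {rid!r}: no usable neighbour for {c!r}; using reference marginal"
                )
                col = ref_df[c].dropna()
                if cohort.schema[c].kind == "continuous":
                    out.at[rid, c] = float(col.mean())
                else:
                    out.at[rid, c] = col.mode().iloc[0]
                continue
            kk = k
            if n_usable < k:
                warnings.warn(
                    f"row {rid!r}: only {n_usable} usable neighbours for {c!r} (k={k})"
                )
                kk = n_usable
            order = np.argsort(dist[i], kind="stable")
            neigh = [j for j in order if usable[j]][:kk]
            vals = ref_df[c].iloc[neigh]
            if cohort.schema[c].kind == "continuous":
                out.at[rid, c] = float(vals.astype(float).mean())
            else:
                counts = vals.value_counts()
                top = counts.max()
                levels = cohort.schema[c].levels or tuple(counts.index)
                winner = next(l for l in levels if counts.get(l, 0) == top)
                out.at[rid, c] = winner
    return CohortTable(out, dict(cohort.schema))


def exclude_imbalanced_binaries(
    cohort: CohortTable, min_fraction: float = 0.10
) -> tuple[CohortTable, list[str]]:
    """Drop two-level categoricals whose minority level is rarer than
    ``min_fraction`` of observed values (strict: exactly at the bound is
    kept).  Multi-level variables are untouched."""
    if not 0.0 < min_fraction < 0.5:
        raise ValueError("min_fraction must be in (0, 0.5)")
    dropped = []
    for name, d in cohort.schema.items():
        if d.kind != "categorical" or not d.levels or len(d.levels) != 2:
            continue
        col = cohort.data[name].dropna()
        if len(col) == 0:
            dropped.append(name)
            continue
        minority = min((col == lev).mean() for lev in d.levels)
        if minority < min_fraction:
            dropped.append(name)
    return cohort.drop_variables(dropped), dropped


# ---------------------------------------------------------------------------
# encoding / standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnInfo:
    """Metadata for one design-matrix column (enough to invert the encoding)."""

    name: str
    source: str
    level: str | None  # None for continuous columns
    reference_level: str | None
    mean: float | None  # standardization parameters; None for dummies
    sd: float | None


@dataclass
class DesignMatrix:
    """Fully numeric predictor matrix with label and column metadata."""

    values: np.ndarray
    columns: list[ColumnInfo]
    row_ids: list[str]
    label: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.label = np.asarray(self.label, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.columns)):
            raise ValueError("values shape does not match row/column metadata")
        if len(self.label) != len(self.row_ids):
            raise ValueError("label length does not match rows")
        if np.isnan(self.values).any():
            raise ValueError("design matrix contains missing entries")

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.column_names)

    def select_columns(self, names: Sequence[str]) -> "DesignMatrix":
        idx = [self.column_names.index(n) for n in names]
        return DesignMatrix(
            self.values[:, idx],
            [self.columns[i] for i in idx],
            list(self.row_ids),
            self.label.copy(),
            dict(self.meta),
        )


class ColumnEncoder:
    """Dummy coding + standardization fitted on one cohort, applicable to another.

    Categorical variables with k levels become k-1 indicators against the
    schema's reference level; continuous covariates (and IDP when included)
    are standardized with means/sds estimated on the fitting rows only.
    """

    def __init__(self, include_idp: bool = True, error_denominator: str = "therapeutic"):
        self.include_idp = include_idp
        self.error_denominator = error_denominator
        self.columns: list[ColumnInfo] = []

    def fit(self, cohort: CohortTable) -> "ColumnEncoder":
        cols: list[ColumnInfo] = []
        for name, d in cohort.schema.items():
            if name in (LABEL_COL, TRUTH_COL):
                continue
            if name == IDP_COL and not self.include_idp:
                continue
            if d.kind == "continuous":
                x = cohort.data[name].astype(float)
                if x.isna().any():
                    raise ValueError(f"continuous variable {name!r} has missing values")
                mean = float(x.mean())
                sd = float(x.std(ddof=0))
                cols.append(ColumnInfo(name, name, None, None, mean, sd if sd > 0 else 1.0))
            else:
                levels = list(d.levels or pd.unique(cohort.data[name].dropna()))
                ref = d.reference_level if d.reference_level is not None else levels[0]
                for lev in levels:
                    if lev == ref:
                        continue
                    cols.append(ColumnInfo(f"{name}={lev}", name, lev, ref, None, None))
        self.columns = cols
        return self

    def transform(self, cohort: CohortTable) -> DesignMatrix:
        if not self.columns:
            raise RuntimeError("encoder not fitted")
        n = cohort.n
        values = np.empty((n, len(self.columns)))
        seen_levels: dict[str, set] = {}
        for j, info in enumerate(self.columns):
            if info.level is None:
                x = cohort.data[info.source].astype(float).to_numpy()
                values[:, j] = (x - info.mean) / info.sd
            else:
                col = cohort.data[info.source]
                values[:, j] = (col == info.level).to_numpy(dtype=float)
                known = seen_levels.setdefault(info.source, {info.reference_level})
                known.add(info.level)
        for source, known in seen_levels.items():
            observed = set(cohort.data[source].dropna().unique())
            unseen = observed - known
            if unseen:
                warnings.warn(
                    f"{source!r}: unseen level(s) {sorted(map(str, unseen))} encoded as reference"
                )
        label = compute_percentage_error(
            cohort.data[IDP_COL].to_numpy(dtype=float),
            cohort.data[LABEL_COL].to_numpy(dtype=float),
            denominator=self.error_denominator,
        )
        return DesignMatrix(values, list(self.columns), list(cohort.data.index), label)

    def invert(self, matrix: DesignMatrix) -> pd.DataFrame:
        """Reverse standardization (continuous columns only) for inspection."""
        df = matrix.to_frame().copy()
        for info in matrix.columns:
            if info.level is None:
                df[info.name] = df[info.name] * info.sd + info.mean
        return df


def encode_and_standardize(
    cohort: CohortTable,
    include_idp: bool = True,
    fit_rows: Sequence | None = None,
    error_denominator: str = "therapeutic",
) -> DesignMatrix:
    """Encode the whole cohort, fitting standardizers on ``fit_rows`` only
    (default: all rows)."""
    enc = ColumnEncoder(include_idp=include_idp, error_denominator=error_denominator)
    fit_cohort = cohort if fit_rows is None else cohort.subset(fit_rows)
    enc.fit(fit_cohort)
    out = enc.transform(cohort)
    out.meta["encoder"] = enc
    return out


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

def filter_correlated(matrix: DesignMatrix, threshold: float = 0.85) -> DesignMatrix:
    """Greedy removal of collinear columns.

    While any pair of columns has |Pearson r| >= threshold, drop the member
    with the larger mean absolute correlation to the remaining columns (ties
    broken toward the later column).  Constant columns carry no information
    and are dropped first with a warning.  Dropped names are recorded in
    ``meta["dropped_correlated"]``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    names = matrix.column_names
    X = matrix.values
    keep = list(range(X.shape[1]))
    dropped: list[str] = []

    const = [j for j in keep if np.ptp(X[:, j]) == 0 or np.std(X[:, j]) == 0]
    for j in const:
        warnings.warn(f"dropping constant column {names[j]!r}")
        dropped.append(names[j])
    keep = [j for j in keep if j not in set(const)]

    while len(keep) >= 2:
        sub = X[:, keep]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        acorr = np.abs(corr)
        a, b = np.unravel_index(np.argmax(acorr), acorr.shape)
        if acorr[a, b] < threshold - 1e-12:
            break
        mean_a, mean_b = acorr[a].mean(), acorr[b].mean()
        if mean_a > mean_b:
            victim = a
        elif mean_b > mean_a:
            victim = b
        else:
            victim = max(a, b)  # tie -> later column
        dropped.append(names[keep[victim]])
        keep.pop(victim)

    out = matrix.select_columns([names[j] for j in keep])
    out.meta.update(matrix.meta)
    out.meta["dropped_correlated"] = dropped
    return out
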