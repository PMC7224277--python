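"""Data preparation for twin-pair variance-decomposition analyses.

The chain mirrors standard practice for pooled multi-cohort twin data:

1. map exact ages to single-year age groups (1–19) and one adult band (20–69),
   excluding ages below 0.5 or at/above 70 years;
2. keep one measurement per person per age group (the youngest);
3. remove within-group outliers by a symmetric z-score rule (a reproducible
   stand-in for manual inspection);
4. residualize height on exact age and cohort within each age × sex group;
5. residualize each parent's education on cohort and the twins' birth year,
   sum the two residuals and cut the standardized sum at ±0.5 SD into
   low / mid / high parental-education categories;
6. keep complete twin pairs only, producing one paired observation per pair
   per age group.

All steps operate on the long-format dataset of :mod:`twinmod.simulate` and
only add columns or drop rows, never reorder semantics: category is a
family-level attribute shared by co-twins, and the chain is idempotent.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

ADULT_GROUP = 20  # label of the 20–69 adult band


def assign_age_group(exact_age):
    """Map an exact age (years) to its age-group label, or None if excluded.

    Single-year groups use half-open bands: group ``k`` covers
    ``[k-0.5, k+0.5)`` for ``k = 1..19`` (so "age 1" is 0.5–1.5 years);
    ages in ``[19.5, 70)`` map to the adult band (label 20); ages below 0.5
    or at/above 70 are excluded (returned as ``None``).
    """
    age = float(exact_age)
    if age < 0:
        raise ValueError(f"exact_age must be >= 0, got {age}")
    if age < 0.5 or age >= 70.0:
        return None
    if age < 19.5:
        return int(np.floor(age + 0.5))
    return ADULT_GROUP


def assign_age_groups(exact_age: np.ndarray) -> np.ndarray:
    """Vectorized :func:`assign_age_group`; excluded ages become NaN."""
    age = np.asarray(exact_age, dtype=float)
    if (age < 0).any():
        raise ValueError("exact_age must be >= 0")
    grp = np.floor(age + 0.5)
    grp[age >= 19.5] = ADULT_GROUP
    grp[(age < 0.5) | (age >= 70.0)] = np.nan
    return grp


def dedup_youngest(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one measurement per person per age group: the one at the
    youngest exact age (ties broken by original row order)."""
    df = records.sort_values("exact_age", kind="stable")
    df = df.drop_duplicates(subset=["person_id", "age_group"], keep="first")
    return df.sort_index().reset_index(drop=True)


def filter_outliers(
    records: pd.DataFrame, z_limit: float = 4.0
) -> tuple[pd.DataFrame, float]:
    """Remove heights more than ``z_limit`` group SDs from the group mean.

    Group = age group × sex; the rule is applied once (not iterated).
    Groups with fewer than 3 records are left unfiltered with a warning.
    Returns the filtered records and the fraction removed.
    """
    if not z_limit > 0:
        raise ValueError("z_limit must be positive")
    if len(records) == 0:
        return records, 0.0
    grp = records.groupby(["age_group", "sex"])["height"]
    n = grp.transform("size")
    mean = grp.transform("mean")
    sd = grp.transform("std")
    small = n < 3
    if small.any():
        warnings.warn(
            f"{int(small.sum())} record(s) in age×sex groups with <3 observations "
            "were not outlier-filtered",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        z = (records["height"] - mean).abs() / sd
    keep = small | sd.isna() | (sd == 0) | (z <= z_limit)
    removed_fraction = 1.0 - keep.mean()
    return records.loc[keep].reset_index(drop=True), float(removed_fraction)


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares residuals; rank deficiency resolved by the minimum-norm
    solution (residuals are unaffected by which collinear column is dropped)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"design is rank deficient ({rank} < {X.shape[1]}); collinear "
            "columns effectively dropped",
            stacklevel=3,
        )
    return y - X @ beta


def _dummies(codes: pd.Series) -> np.ndarray:
    """Full indicator matrix for a categorical column (intercept handles the
    redundancy via the minimum-norm solve)."""
    cats = pd.Categorical(codes)
    return np.eye(len(cats.categories))[cats.codes]


def residualize_height(records: pd.DataFrame) -> pd.DataFrame:
    """Adjust height for exact age and cohort within each age × sex group.

    Within every age group × sex cell, height is regressed on exact age and
    cohort indicator variables (one dummy per cohort) by ordinary least
    squares; the residuals (column ``height_resid``) are the outcome used by
    all downstream modeling.  Residuals average zero within each cell.
    """
    df = records.copy()
    resid = np.full(len(df), np.nan)
    for _, idx in df.groupby(["age_group", "sex"]).indices.items():
        sub = df.iloc[idx]
        X = np.column_stack(
            [np.ones(len(sub)), sub["exact_age"].to_numpy(float), _dummies(sub["cohort_id"])]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # cohort dummies + intercept are always collinear
            resid[idx] = _ols_residuals(sub["height"].to_numpy(float), X)
    df["height_resid"] = resid
    return df


def residualize_education(records: pd.DataFrame) -> pd.DataFrame:
    """Adjust each parent's education for cohort and the twins' birth year.

    Education is a family-level variable: the regression runs on one row per
    pair (education years on cohort dummies and twin birth year), and the
    residuals — how much more or less educated the parent is than the average
    parent of a twin born that year in that cohort — are merged back onto all
    of the family's records as ``father_edu_resid`` / ``mother_edu_resid``.
    Education outside [0, 30] years is malformed input.
    """
    for col in ("father_edu", "mother_edu"):
        vals = records[col]
        bad = vals.notna() & ((vals < 0) | (vals > 30))
        if bad.any():
            raise ValueError(
                f"{col} outside the admissible 0–30 year range at row(s) "
                f"{list(records.index[bad][:5])}"
            )
    fam = records.drop_duplicates("pair_id")[
        ["pair_id", "cohort_id", "birth_year", "father_edu", "mother_edu"]
    ].reset_index(drop=True)
    X = np.column_stack(
        [np.ones(len(fam)), fam["birth_year"].to_numpy(float), _dummies(fam["cohort_id"])]
    )
    out = fam[["pair_id"]].copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["father_edu_resid"] = _ols_residuals(fam["father_edu"].to_numpy(float), X)
        out["mother_edu_resid"] = _ols_residuals(fam["mother_edu"].to_numpy(float), X)
    df = records.drop(columns=["father_edu_resid", "mother_edu_resid"], errors="ignore")
    return df.merge(out, on="pair_id", how="left")


def categorize_education(
    father_resid: np.ndarray,
    mother_resid: np.ndarray,
    sd: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sum the parental education residuals and cut into three SD categories.

    The residuals are summed to a combined family score, standardized by the
    sample SD of the sum (or ``sd`` if given, e.g. for per-region scoping),
    and cut at ±0.5: ``low`` below −0.5, ``mid`` in [−0.5, +0.5] (boundary
    points inclusive), ``high`` above +0.5.  Returns the standardized sums
    and the category labels.
    """
    total = np.asarray(father_resid, dtype=float) + np.asarray(mother_resid, dtype=float)
    if sd is None:
        sd = float(np.std(total[~np.isnan(total)], ddof=1))
    if not sd > 0:
        raise ValueError("summed education residuals have zero variance; cannot categorize")
    z = total / sd
    cat = np.where(z < -0.5, "low", np.where(z > 0.5, "high", "mid")).astype(object)
    cat[np.isnan(z)] = None
    return z, cat


def make_pairs(records: pd.DataFrame) -> pd.DataFrame:
    """Build complete-pair observations: one row per pair per age group.

    Twins without a co-twin measurement in the same age group are dropped.
    Member ordering is deterministic: for opposite-sex pairs the male twin is
    member 1; otherwise the lower ``person_id``.  Input must already be
    deduplicated within age group (at most one record per person per group).
    """
    df = records.copy()
    sizes = df.groupby(["pair_id", "age_group"])["person_id"].transform("size")
    df = df[sizes == 2]
    nuniq = df.groupby(["pair_id", "age_group"])["person_id"].transform("nunique")
    if (nuniq != 2).any():
        bad = df.loc[nuniq != 2, "pair_id"].iloc[0]
        raise ValueError(f"pair {bad!r} has duplicated person_ids within an age group")

    # deterministic member order: male first (OSDZ), then person_id
    sex_rank = (df["sex"] == "F").astype(int)
    df = df.assign(_rank=sex_rank).sort_values(
        ["pair_id", "age_group", "_rank", "person_id"], kind="stable"
    )
    member = df.groupby(["pair_id", "age_group"]).cumcount()
    first = df[member == 0].reset_index(drop=True)
    second = df[member == 1].reset_index(drop=True)

    pairs = pd.DataFrame(
        {
            "pair_id": first["pair_id"].to_numpy(),
            "age_group": first["age_group"].to_numpy(),
            "zygosity": first["zygosity"].to_numpy(),
            "cohort_id": first["cohort_id"].to_numpy(),
            "region": first["region"].to_numpy(),
            "sex1": first["sex"].to_numpy(),
            "sex2": second["sex"].to_numpy(),
            "height_resid1": first["height_resid"].to_numpy()
            if "height_resid" in first
            else first["height"].to_numpy(),
            "height_resid2": second["height_resid"].to_numpy()
            if "height_resid" in second
            else second["height"].to_numpy(),
        }
    )
    for col in ("edu_years_combined", "edu_category"):
        if col in first.columns:
            pairs[col] = first[col].to_numpy()
    return pairs.reset_index(drop=True)


class TwinPreprocessor(BaseEstimator, TransformerMixin):
    """Full preprocessing chain as a transformer.

    Parameters
    ----------
    z_limit : float, default 4.0
        Symmetric z-score limit of the outlier filter.
    sd_scope : {"global", "region"}, default "global"
        Whether the SD used for the education cut is computed over the whole
        dataset or within each region (for regional analyses).
    drop_incomplete_education : bool, default True
        Families missing either parent's education are excluded from
        categorized analyses (counted in ``n_missing_education_``).
    region_map : dict or None, default None
        Optional ``cohort_id -> region`` table overriding the dataset's
        region column; cohorts mapped to ``"excluded"`` (or absent from the
        table) get a missing region and drop out of region-stratified
        analyses while remaining in pooled ones.

    Attributes
    ----------
    pairs_ : DataFrame
        Complete paired observations with residualized heights and the
        education category, one row per pair per age group.
    records_ : DataFrame
        The individual-level records after all filters, with residual columns.
    removed_outlier_fraction_ : float
    n_excluded_age_ : int
    n_missing_education_ : int
        Individuals in families missing a parent's education.
    """

    def __init__(self, z_limit: float = 4.0, sd_scope: str = "global",
                 drop_incomplete_education: bool = True,
                 region_map: dict | None = None):
        self.z_limit = z_limit
        self.sd_scope = sd_scope
        self.drop_incomplete_education = drop_incomplete_education
        self.region_map = region_map

    def fit(self, X: pd.DataFrame, y=None) -> "TwinPreprocessor":
        if self.sd_scope not in ("global", "region"):
            raise ValueError("sd_scope must be 'global' or 'region'")
        df = X.copy()
        if self.region_map is not None:
            region = df["cohort_id"].map(self.region_map)
            df["region"] = region.where(region != "excluded")
        df["age_group"] = assign_age_groups(df["exact_age"].to_numpy())
        self.n_excluded_age_ = int(df["age_group"].isna().sum())
        df = df.dropna(subset=["age_group"]).reset_index(drop=True)
        df["age_group"] = df["age_group"].astype(int)

        df = dedup_youngest(df)
        df, self.removed_outlier_fraction_ = filter_outliers(df, self.z_limit)
        df = residualize_height(df)
        df = residualize_education(df)

        missing = df["father_edu_resid"].isna() | df["mother_edu_resid"].isna()
        self.n_missing_education_ = int(missing.sum())
        if self.drop_incomplete_education:
            df = df[~missing].reset_index(drop=True)

        if self.sd_scope == "region":
            z = np.full(len(df), np.nan)
            cat = np.empty(len(df), dtype=object)
            for _, idx in df.groupby("region").indices.items():
                zi, ci = categorize_education(
                    df["father_edu_resid"].to_numpy()[idx],
                    df["mother_edu_resid"].to_numpy()[idx],
                )
                z[idx], cat[idx] = zi, ci
        else:
            z, cat = categorize_education(
                df["father_edu_resid"].to_numpy(), df["mother_edu_resid"].to_numpy()
            )
        df["edu_years_combined"] = z
        df["edu_category"] = cat

        self.records_ = df
        self.pairs_ = make_pairs(df)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Run the chain on ``X`` and return the paired observations."""
        return TwinPreprocessor(**self.get_params()).fit(X).pairs_

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).pairs_


def preprocess(records: pd.DataFrame, **params) -> pd.DataFrame:
    """One-shot preprocessing: returns the paired observations."""
    return TwinPreprocessor(**params).fit(records).pairs_
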