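"""Synthetic multi-cohort twin data with known ACE variance structure.

The generator emulates the structure of a pooled multinational twin database:
several cohorts with distinct mean heights and birth-year ranges, repeated
height measurements across ages 1–69, a realistic zygosity mix (~38% MZ,
34% same-sex DZ, 28% opposite-sex DZ), parental education correlated with the
twins' birth year, and per-education-stratum additive-genetic (A), shared (C)
and unique (E) environmental variance components.

Latent twin deviations are constructed so the classical cross-twin
correlations hold exactly: the additive-genetic part of a DZ pair is built as
``sqrt(r)·shared + sqrt(1-r)·own`` with ``r = 0.5`` for same-sex DZ pairs and
``r = r_os ≤ 0.5`` for opposite-sex pairs, so the genetic correlation is exact
by construction rather than approximated.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ZYGOSITY_GROUPS = ("MZM", "MZF", "DZM", "DZF", "OSDZ")
#: approximate zygosity mix of pooled twin registries: 38% MZ / 34% SSDZ / 28% OSDZ
DEFAULT_GROUP_MIX = {"MZM": 0.19, "MZF": 0.19, "DZM": 0.17, "DZF": 0.17, "OSDZ": 0.28}

EDU_CATEGORIES = ("low", "mid", "high")

#: required columns of the long-format dataset, with dtypes enforced on read
DATASET_COLUMNS = {
    "person_id": "int64",
    "pair_id": "int64",
    "cohort_id": "object",
    "zygosity": "object",
    "sex": "object",
    "exact_age": "float64",
    "birth_year": "int64",
    "height": "float64",
    "father_edu": "float64",
    "mother_edu": "float64",
    "region": "object",
}

VALID_ZYGOSITY = ("MZ", "SSDZ", "OSDZ")

# Reference growth curve (cm): population-typical mean height at each age.
# Residualization removes means downstream, so only the shape matters.
_GROWTH_AGES = np.array(
    [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 25, 69],
    dtype=float,
)
_GROWTH_M = np.array(
    [75.0, 87.5, 96.8, 103.5, 110.5, 116.5, 122.5, 128.5, 134.0, 139.5,
     144.5, 151.5, 158.5, 165.5, 171.0, 174.5, 176.5, 177.5, 178.0, 178.4, 178.4]
)
_GROWTH_F = np.array(
    [73.5, 86.2, 95.8, 102.5, 109.5, 115.5, 121.5, 127.5, 133.5, 139.5,
     145.0, 152.5, 157.5, 161.5, 163.5, 164.5, 165.0, 165.5, 165.7, 165.7, 165.7]
)


def mean_height(exact_age, sex: str) -> np.ndarray:
    """Population-typical mean height (cm) at ``exact_age`` for ``sex`` ('M'/'F')."""
    curve = _GROWTH_M if sex == "M" else _GROWTH_F
    return np.interp(np.asarray(exact_age, dtype=float), _GROWTH_AGES, curve)


@dataclass(frozen=True)
class StratumSpec:
    """Variance structure of one parental-education stratum.

    Parameters
    ----------
    label : str
        Education-category token: ``low``, ``mid`` or ``high``.
    A_m, C_m, E_m, A_f, C_f, E_f : float
        Additive-genetic, shared-environmental and unique-environmental
        variance components (cm²), per sex.
    r_os : float
        Opposite-sex DZ additive-genetic correlation, in [0, 0.5].  Same-sex
        DZ pairs always use 0.5 and MZ pairs 1.0.
    mean_shift_m, mean_shift_f : float
        Additive mean offsets (cm) of this stratum relative to the cohort/age
        baseline, per sex.
    """

    label: str
    A_m: float
    C_m: float
    E_m: float
    A_f: float
    C_f: float
    E_f: float
    r_os: float = 0.5
    mean_shift_m: float = 0.0
    mean_shift_f: float = 0.0

    def __post_init__(self) -> None:
        for name in ("A_m", "C_m", "E_m", "A_f", "C_f", "E_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"variance component {name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.r_os <= 0.5:
            raise ValueError(f"r_os must lie in [0, 0.5], got {self.r_os}")

    def total_variance(self, sex: str) -> float:
        if sex == "M":
            return self.A_m + self.C_m + self.E_m
        return self.A_f + self.C_f + self.E_f

    def cross_covariance(self, zygosity: str) -> float:
        """Theoretical cross-twin covariance for a pair of the given zygosity."""
        if zygosity == "MZ":
            # both members share sex; caller picks the sex via components below
            raise ValueError("use cross_covariance_mz(sex) for MZ pairs")
        if zygosity == "SSDZ":
            raise ValueError("use cross_covariance_ssdz(sex) for SSDZ pairs")
        if zygosity == "OSDZ":
            return self.r_os * math.sqrt(self.A_m * self.A_f) + math.sqrt(self.C_m * self.C_f)
        raise ValueError(f"unknown zygosity {zygosity!r}")

    def cross_covariance_mz(self, sex: str) -> float:
        return (self.A_m + self.C_m) if sex == "M" else (self.A_f + self.C_f)

    def cross_covariance_ssdz(self, sex: str) -> float:
        return (0.5 * self.A_m + self.C_m) if sex == "M" else (0.5 * self.A_f + self.C_f)


@dataclass(frozen=True)
class CohortSpec:
    """One twin cohort: identity, region, birth years and mean offsets."""

    cohort_id: str
    region: str = "Europe"
    birth_year_range: tuple[int, int] = (1950, 1990)
    height_offset: float = 0.0  # cm added to the reference growth curve
    edu_offset: float = 0.0     # years added to the education model mean

    def __post_init__(self) -> None:
        lo, hi = self.birth_year_range
        if lo > hi:
            raise ValueError(f"birth_year_range must be (lo, hi) with lo <= hi, got {self.birth_year_range}")


@dataclass(frozen=True)
class EducationModel:
    """Parental education (years) as a function of the twins' birth year.

    Each parent's education is ``base_years + trend_per_decade·(birth_year −
    ref_year)/10 + cohort offset + family deviation``, clipped to [0, 30].
    The two parents' family-level deviations are bivariate normal with
    standard deviation ``family_sd`` and correlation ``couple_corr``
    (educational homogamy).
    """

    base_years: float = 11.0
    trend_per_decade: float = 0.8
    ref_year: int = 1950
    family_sd: float = 2.5
    couple_corr: float = 0.45

    def __post_init__(self) -> None:
        if self.family_sd <= 0:
            raise ValueError("family_sd must be positive")
        if not -1.0 < self.couple_corr < 1.0:
            raise ValueError("couple_corr must lie in (-1, 1)")

    @property
    def combined_sd(self) -> float:
        """SD of the summed parental deviations (the stratum-cut scale)."""
        return self.family_sd * math.sqrt(2.0 * (1.0 + self.couple_corr))


def _default_strata() -> dict[str, StratumSpec]:
    # identical variance structure across strata: the null of no moderation
    return {
        lab: StratumSpec(lab, A_m=33.0, C_m=6.0, E_m=9.0, A_f=28.0, C_f=6.0, E_f=8.0, r_os=0.45)
        for lab in EDU_CATEGORIES
    }


def _default_cohorts() -> list[CohortSpec]:
    return [
        CohortSpec("EU1", "Europe", (1940, 1985), height_offset=0.5, edu_offset=-0.5),
        CohortSpec("EU2", "Europe", (1960, 1995), height_offset=0.0, edu_offset=0.0),
        CohortSpec("NA1", "NorthAmericaAustralia", (1950, 1990), height_offset=-0.3, edu_offset=1.0),
        CohortSpec("EA1", "EastAsia", (1965, 2000), height_offset=-6.0, edu_offset=0.5),
    ]


@dataclass
class SimulationConfig:
    """Full specification of one synthetic twin dataset.

    Parameters
    ----------
    n_pairs_by_group : dict
        Number of twin pairs per zygosity-sex group
        (keys ``MZM, MZF, DZM, DZF, OSDZ``).  A family's education stratum is
        *not* fixed in advance: education is drawn first and the stratum
        follows from the same SD-based cut the preprocessing applies, so the
        generating label is recoverable downstream.
    strata : dict
        ``label -> StratumSpec`` for ``low``, ``mid``, ``high``.
    cohorts : list of CohortSpec
    age_grid : list of int
        Age-group labels (1–19, or 20 for the 20–69 adult band) at which every
        pair is measured; exact ages are jittered within the band.
    education : EducationModel
    dz_mean_delta : float
        Mean height of DZ minus MZ twins (cm); DZ twins run slightly taller.
    seed : int
    """

    n_pairs_by_group: dict[str, int] = field(
        default_factory=lambda: {g: int(round(2000 * DEFAULT_GROUP_MIX[g])) for g in ZYGOSITY_GROUPS}
    )
    strata: dict[str, StratumSpec] = field(default_factory=_default_strata)
    cohorts: list[CohortSpec] = field(default_factory=_default_cohorts)
    age_grid: list[int] = field(default_factory=lambda: [1, 5, 10, 15, 18, 20])
    education: EducationModel = field(default_factory=EducationModel)
    dz_mean_delta: float = 0.3
    seed: int = 0

    @classmethod
    def from_total(cls, total_pairs: int, mix: dict[str, float] | None = None, **kwargs) -> "SimulationConfig":
        mix = mix or DEFAULT_GROUP_MIX
        n = {g: int(round(total_pairs * mix[g])) for g in ZYGOSITY_GROUPS}
        return cls(n_pairs_by_group=n, **kwargs)

    def validate(self) -> None:
        for g, n in self.n_pairs_by_group.items():
            if g not in ZYGOSITY_GROUPS:
                raise ValueError(f"unknown zygosity-sex group {g!r}; expected one of {ZYGOSITY_GROUPS}")
            if n < 0:
                raise ValueError(f"pair count for {g} must be >= 0, got {n}")
        for lab in EDU_CATEGORIES:
            if lab not in self.strata:
                raise ValueError(f"missing StratumSpec for category {lab!r}")
        if not self.cohorts:
            raise ValueError("at least one cohort is required")
        for a in self.age_grid:
            if not 1 <= a <= 20:
                raise ValueError(f"age_grid entries must be age-group labels 1..20, got {a}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strata"] = {k: dataclasses.asdict(v) for k, v in self.strata.items()}
        d["cohorts"] = [dataclasses.asdict(c) for c in self.cohorts]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "strata" in d:
            d["strata"] = {k: StratumSpec(**v) for k, v in d["strata"].items()}
        if "cohorts" in d:
            d["cohorts"] = [
                CohortSpec(**{**c, "birth_year_range": tuple(c["birth_year_range"])})
                for c in d["cohorts"]
            ]
        if "education" in d and isinstance(d["education"], dict):
            d["education"] = EducationModel(**d["education"])
        return cls(**d)


def _group_sexes(group: str) -> tuple[str, str]:
    if group == "MZM" or group == "DZM":
        return ("M", "M")
    if group == "MZF" or group == "DZF":
        return ("F", "F")
    if group == "OSDZ":
        return ("M", "F")
    raise ValueError(f"unknown zygosity-sex group {group!r}")


def _group_zygosity(group: str) -> str:
    return {"MZM": "MZ", "MZF": "MZ", "DZM": "SSDZ", "DZF": "SSDZ", "OSDZ": "OSDZ"}[group]


def simulate_group(
    spec: StratumSpec, group: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` latent deviation pairs (cm) for one zygosity-sex group.

    Returns an ``(n, 2)`` array with twin 1 in column 0.  For OSDZ pairs the
    male twin is column 0.  The marginal variance of each column is
    ``A + C + E`` for the member's sex; the cross-twin covariance is
    ``A + C`` (MZ), ``0.5·A + C`` (same-sex DZ) or
    ``r_os·√(A_m·A_f) + √(C_m·C_f)`` (OSDZ).
    """
    sex1, sex2 = _group_sexes(group)
    zyg = _group_zygosity(group)
    A1, C1, E1 = ((spec.A_m, spec.C_m, spec.E_m) if sex1 == "M" else (spec.A_f, spec.C_f, spec.E_f))
    A2, C2, E2 = ((spec.A_m, spec.C_m, spec.E_m) if sex2 == "M" else (spec.A_f, spec.C_f, spec.E_f))

    if zyg == "MZ":
        r_a = 1.0
    elif zyg == "SSDZ":
        r_a = 0.5
    else:
        r_a = spec.r_os

    z_shared = rng.standard_normal(n)
    z_own1 = rng.standard_normal(n)
    z_own2 = rng.standard_normal(n)
    # additive-genetic part: exact correlation r_a by construction
    a1 = math.sqrt(A1) * (math.sqrt(r_a) * z_shared + math.sqrt(1.0 - r_a) * z_own1)
    a2 = math.sqrt(A2) * (math.sqrt(r_a) * z_shared + math.sqrt(1.0 - r_a) * z_own2)
    # shared environment: correlation 1 across co-twins (also cross-sex)
    z_c = rng.standard_normal(n)
    c1 = math.sqrt(C1) * z_c
    c2 = math.sqrt(C2) * z_c
    e1 = math.sqrt(E1) * rng.standard_normal(n)
    e2 = math.sqrt(E2) * rng.standard_normal(n)
    return np.column_stack([a1 + c1 + e1, a2 + c2 + e2])


def simulate_pair(
    spec: StratumSpec,
    zygosity: str,
    sexes: tuple[str, str],
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Draw the latent deviations (cm) of a single twin pair.

    ``zygosity`` is ``MZ``, ``SSDZ`` or ``OSDZ``; ``sexes`` the pair's sexes
    (MZ/SSDZ co-twins must match; OSDZ co-twins must differ).
    """
    if zygosity not in VALID_ZYGOSITY:
        raise ValueError(f"unknown zygosity token {zygosity!r}; expected one of {VALID_ZYGOSITY}")
    s1, s2 = sexes
    if zygosity in ("MZ", "SSDZ") and s1 != s2:
        raise ValueError(f"{zygosity} co-twins must share sex, got {sexes}")
    if zygosity == "OSDZ" and s1 == s2:
        raise ValueError(f"OSDZ co-twins must have opposite sexes, got {sexes}")
    if zygosity == "OSDZ":
        dev = simulate_group(spec, "OSDZ", 1, rng)[0]
        return (dev[0], dev[1]) if s1 == "M" else (dev[1], dev[0])
    group = ("MZ" if zygosity == "MZ" else "DZ") + s1
    dev = simulate_group(spec, group, 1, rng)[0]
    return dev[0], dev[1]


def simulate_cohorts(config: SimulationConfig) -> pd.DataFrame:
    """Generate a long-format twin dataset under ``config``.

    Each pair draws a cohort, a birth year, and family-level parental
    education; the education stratum follows from the SD-based cut of the
    summed family deviations (the same rule the preprocessing applies), and
    that stratum's variance structure generates the latent deviations.  The
    pair is then measured at every age-group label in ``config.age_grid``,
    with independent latent draws per age.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    total_pairs = sum(config.n_pairs_by_group.values())
    if total_pairs == 0:
        warnings.warn("empty simulation config: zero pairs requested", stacklevel=2)
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in DATASET_COLUMNS.items()})

    edu = config.education
    cut = 0.5 * edu.combined_sd  # cut on the raw summed deviations

    frames = []
    pair_base = 0
    for group in ZYGOSITY_GROUPS:
        n = config.n_pairs_by_group.get(group, 0)
        if n == 0:
            continue
        sex1, sex2 = _group_sexes(group)
        zyg = _group_zygosity(group)

        pair_ids = np.arange(pair_base, pair_base + n, dtype=np.int64)
        pair_base += n

        cohort_idx = rng.integers(0, len(config.cohorts), size=n)
        birth_year = np.empty(n, dtype=np.int64)
        cohort_id = np.empty(n, dtype=object)
        region = np.empty(n, dtype=object)
        edu_mean = np.empty(n)
        h_off = np.empty(n)
        for j, c in enumerate(config.cohorts):
            m = cohort_idx == j
            k = int(m.sum())
            if k == 0:
                continue
            lo, hi = c.birth_year_range
            birth_year[m] = rng.integers(lo, hi + 1, size=k)
            cohort_id[m] = c.cohort_id
            region[m] = c.region
            edu_mean[m] = edu.base_years + c.edu_offset
            h_off[m] = c.height_offset
        edu_mean = edu_mean + edu.trend_per_decade * (birth_year - edu.ref_year) / 10.0

        # family-level education deviations (educational homogamy)
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        fdev = edu.family_sd * z1
        mdev = edu.family_sd * (edu.couple_corr * z1 + math.sqrt(1 - edu.couple_corr**2) * z2)
        father_edu = np.clip(edu_mean + fdev, 0.0, 30.0)
        mother_edu = np.clip(edu_mean + mdev, 0.0, 30.0)

        sdev = fdev + mdev
        stratum = np.where(sdev < -cut, "low", np.where(sdev > cut, "high", "mid"))

        dz_delta = 0.0 if zyg == "MZ" else config.dz_mean_delta

        for age_label in config.age_grid:
            if age_label >= 20:
                exact_age = rng.uniform(19.5, 69.5, size=n)
            else:
                exact_age = rng.uniform(age_label - 0.5, age_label + 0.5, size=n)
            dev = np.empty((n, 2))
            shift1 = np.empty(n)
            shift2 = np.empty(n)
            for lab in EDU_CATEGORIES:
                m = stratum == lab
                k = int(m.sum())
                if k == 0:
                    continue
                spec = config.strata[lab]
                dev[m] = simulate_group(spec, group, k, rng)
                shift1[m] = spec.mean_shift_m if sex1 == "M" else spec.mean_shift_f
                shift2[m] = spec.mean_shift_m if sex2 == "M" else spec.mean_shift_f
            base1 = mean_height(exact_age, sex1) + h_off
            base2 = mean_height(exact_age, sex2) + h_off
            h1 = base1 + shift1 + dz_delta + dev[:, 0]
            h2 = base2 + shift2 + dz_delta + dev[:, 1]

            for member, (sex, h) in enumerate([(sex1, h1), (sex2, h2)]):
                frames.append(
                    pd.DataFrame(
                        {
                            "person_id": 2 * pair_ids + member,
                            "pair_id": pair_ids,
                            "cohort_id": cohort_id,
                            "zygosity": zyg,
                            "sex": sex,
                            "exact_age": np.round(exact_age, 3),
                            "birth_year": birth_year,
                            "height": np.round(h1 if member == 0 else h2, 2),
                            "father_edu": np.round(father_edu, 2),
                            "mother_edu": np.round(mother_edu, 2),
                            "region": region,
                        }
                    )
                )

    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["pair_id", "person_id", "exact_age"], kind="stable").reset_index(drop=True)
    return out


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a long-format twin dataset as UTF-8 CSV with a header row."""
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required column(s): {missing}")
    df.to_csv(path, index=False, columns=list(DATASET_COLUMNS))


def read_dataset(path) -> pd.DataFrame:
    """Read a long-format twin dataset CSV, validating schema and tokens."""
    df = pd.read_csv(path, dtype={"cohort_id": str, "region": str})
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset file {path} is missing required column(s): {missing}")
    if len(df):
        bad = ~df["zygosity"].isin(VALID_ZYGOSITY)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"unknown zygosity token {df['zygosity'].iloc[row]!r} at row {row} "
                f"(expected one of {VALID_ZYGOSITY})"
            )
        bad_sex = ~df["sex"].isin(("M", "F"))
        if bad_sex.any():
            row = int(np.flatnonzero(bad_sex.to_numpy())[0])
            raise ValueError(f"unknown sex token {df['sex'].iloc[row]!r} at row {row}")
    for c, t in DATASET_COLUMNS.items():
        df[c] = df[c].astype(t)
    return df[list(DATASET_COLUMNS)]
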