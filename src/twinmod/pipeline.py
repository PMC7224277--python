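"""End-to-end orchestration: simulate → preprocess → associate → decompose →
meta-regress, with full provenance and deterministic re-runs."""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from twinmod._version import __version__
from twinmod.ace import fit_by_stratum
from twinmod.association import association_by_group
from twinmod.metareg import (
    fit_meta_regression,
    render_markdown,
    summarize_table,
    warn_if_repeated_individuals,
)
from twinmod.preprocess import TwinPreprocessor
from twinmod.simulate import (
    DATASET_COLUMNS,
    SimulationConfig,
    VALID_ZYGOSITY,
    read_dataset,
    simulate_cohorts,
    write_dataset,
)

log = logging.getLogger("twinmod")


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Either ``input_path`` (an existing dataset CSV) or ``simulation``
    (a :class:`~twinmod.simulate.SimulationConfig`) supplies the data.  The
    top-level ``seed`` overrides the simulation seed so every stochastic
    step derives from one number.
    """

    output_dir: str = "twinmod_run"
    input_path: str | None = None
    simulation: SimulationConfig | None = None
    seed: int = 0
    by_region: bool = False
    z_limit: float = 4.0
    sd_scope: str = "global"
    region_map: dict | None = None
    min_pairs: int = 50
    min_n_association: int = 30
    variant: str = "ace"
    tau2_method: str = "mom"
    knapp_hartung: bool = False
    scales: tuple[str, ...] = ("raw", "standardized")
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulation"):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_dataset(path_or_df) -> pd.DataFrame:
    """Schema and integrity checks on a long-format dataset.

    Returns a report DataFrame with one row per violation (``row``,
    ``check``, ``detail``); empty means clean.  Checks: required columns,
    zygosity/sex tokens, co-twin consistency (shared pair metadata; MZ/SSDZ
    sexes equal, OSDZ opposite), age ≥ 0 and education within 0–30 years.
    """
    df = read_dataset(path_or_df) if not isinstance(path_or_df, pd.DataFrame) else path_or_df
    issues = []

    def flag(rows, check, detail):
        for r in np.atleast_1d(rows)[:50]:
            issues.append({"row": int(r), "check": check, "detail": detail})

    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        return pd.DataFrame([{"row": -1, "check": "schema", "detail": f"missing columns {missing}"}])
    bad = ~df["zygosity"].isin(VALID_ZYGOSITY)
    if bad.any():
        flag(np.flatnonzero(bad), "zygosity", "unknown zygosity token")
    bad = ~df["sex"].isin(("M", "F"))
    if bad.any():
        flag(np.flatnonzero(bad), "sex", "unknown sex token")
    bad = df["exact_age"] < 0
    if bad.any():
        flag(np.flatnonzero(bad), "age", "negative exact_age")
    for col in ("father_edu", "mother_edu"):
        bad = df[col].notna() & ((df[col] < 0) | (df[col] > 30))
        if bad.any():
            flag(np.flatnonzero(bad), "education", f"{col} outside 0–30 years")

    persons = df.drop_duplicates(["pair_id", "person_id"])
    for key in ("cohort_id", "birth_year", "father_edu", "mother_edu", "zygosity"):
        nun = persons.groupby("pair_id")[key].nunique(dropna=False)
        bad_pairs = nun[nun > 1].index
        if len(bad_pairs):
            rows = df.index[df["pair_id"].isin(bad_pairs)].to_numpy()
            flag(rows[:10], "pair", f"co-twins disagree on {key}")
    sexes = persons.groupby("pair_id").agg(zyg=("zygosity", "first"), ns=("sex", "nunique"))
    bad_pairs = sexes[(sexes["zyg"].isin(("MZ", "SSDZ")) & (sexes["ns"] > 1))
                      | ((sexes["zyg"] == "OSDZ") & (sexes["ns"] == 1))].index
    if len(bad_pairs):
        rows = df.index[df["pair_id"].isin(bad_pairs)].to_numpy()
        flag(rows[:10], "zygosity-sex", "sex composition inconsistent with zygosity")
    return pd.DataFrame(issues, columns=["row", "check", "detail"])


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write tables, figures, log and manifest.

    Returns a dict of the in-memory artifacts (``dataset``, ``pairs``,
    ``association``, ``strata``, ``metareg``, ``manifest``).  Re-running
    with the same config reproduces every numeric output exactly.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "load"
    artifacts: dict = {}
    try:
        if config.input_path is not None:
            dataset = read_dataset(config.input_path)
            log.info("loaded %d records from %s", len(dataset), config.input_path)
        else:
            sim = config.simulation or SimulationConfig()
            sim = dataclasses.replace(sim, seed=config.seed)
            dataset = simulate_cohorts(sim)
            log.info("simulated %d records (seed=%d)", len(dataset), config.seed)
        write_dataset(dataset, out / "dataset.csv")
        artifacts["dataset"] = dataset

        stage = "validate"
        report = validate_dataset(dataset)
        _write_csv(report, out / "validation.csv")
        if len(report):
            log.warning("validation found %d issue(s)", len(report))

        stage = "preprocess"
        prep = TwinPreprocessor(z_limit=config.z_limit, sd_scope=config.sd_scope,
                                region_map=config.region_map).fit(dataset)
        pairs = prep.pairs_
        _write_csv(pairs, out / "pairs.csv")
        artifacts["pairs"] = pairs
        log.info(
            "preprocess: %d pairs; outlier fraction %.2e; %d age-excluded; "
            "%d missing-education individuals",
            len(pairs), prep.removed_outlier_fraction_, prep.n_excluded_age_,
            prep.n_missing_education_,
        )

        stage = "mean_association"
        assoc = association_by_group(
            pairs, by_region=config.by_region, min_n=config.min_n_association
        )
        _write_csv(assoc, out / "association.csv")
        artifacts["association"] = assoc

        stage = "ace_model"
        by = ("age_group", "edu_category") + (("region",) if config.by_region else ())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strata = fit_by_stratum(
                pairs, by=by, variant=config.variant,
                min_pairs=config.min_pairs, random_state=config.seed,
            )
        _write_csv(strata, out / "strata.csv")
        artifacts["strata"] = strata

        stage = "meta_regression"
        warn_if_repeated_individuals(pairs)
        results = []
        for scale in config.scales:
            for comp in ("a2", "c2", "e2"):
                for sex in ("m", "f", "both"):
                    try:
                        res = fit_meta_regression(
                            strata, component=comp, scale=scale, sex=sex,
                            tau2_method=config.tau2_method,
                            knapp_hartung=config.knapp_hartung,
                        )
                    except ValueError as exc:
                        log.warning("metareg %s/%s/%s skipped: %s", scale, comp, sex, exc)
                        continue
                    res.insert(0, "scale_run", scale)
                    results.append(res)
        metareg = pd.concat(results, ignore_index=True) if results else pd.DataFrame()
        _write_csv(metareg, out / "metareg.csv")
        artifacts["metareg"] = metareg
        raw = metareg[metareg["scale"] == "raw"] if len(metareg) else metareg
        if len(raw):
            table = summarize_table(raw)
            (out / "metareg_table.md").write_text(render_markdown(table) + "\n")
            artifacts["metareg_table"] = table

        if config.make_figures:
            stage = "figures"
            from twinmod.plots import forest_plot, variance_bars

            if len(assoc):
                forest_plot(assoc, out / "association.png")
            if len(strata):
                variance_bars(strata, out / "variance_components.png")

        stage = "manifest"
        manifest = {
            "package": "twinmod",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "n_records": int(len(dataset)),
            "n_pairs": int(len(pairs)),
            "n_strata": int(len(strata)),
            "outputs": sorted(
                p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
            ),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        artifacts["manifest"] = manifest
        log.info("run complete")
        return artifacts
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
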