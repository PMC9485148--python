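"""End-to-end study orchestration.

:func:`run_study` reproduces the full comparison design on any cohort:

1. score-model estimation (builtin modified tables, user-supplied tables,
   and/or a fresh per-sex refit) with a method-comparison report computed
   on the full cohort (CA/DA/AD summaries, paired t-test, capped MAE);
2. a seeded 3:1 train/test split, native learner training on the training
   split only, and a learner report (MSE/RMSE/MAE/R² per learner, sex and
   split);
3. per-age-group MAE series for every method and learner.

One root seed fans out to stage-specific seeds through a named
SeedSequence derivation, so the split and each learner are independently
reproducible.  All tables are written as both CSV and JSON with stable
formatting; a manifest records config, seeds, timings and file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ensembles import (
    AdaBoostR2Config,
    ForestConfig,
    GBDTConfig,
    KNNConfig,
    KNNModel,
    fit_adaboost_r2,
    fit_forest,
    fit_gbdt,
)
from .metrics import (
    PairedAges,
    learner_metrics_row,
    method_comparison_row,
    per_group_mae,
)
from .refit import RefitConfig, refit
from .scores import ScoreTable, builtin_modified_tables, estimate_age_sum, load_score_table
from .staging import Cohort, Sex, age_distribution_table, read_staging_csv, split_train_test
from .trees import TreeConfig, encode_cohort, fit_tree
from .simulate import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

SCORE_METHODS = ("demirjian", "willems", "modified", "refit")
LEARNERS = ("decision_tree", "random_forest", "extra_trees", "adaboost_r2", "gbdt", "knn")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Study configuration: inputs, methods, learners, split, outputs."""

    input_csv: str | None = None  # None -> simulate the default cohort
    methods: tuple[str, ...] = ("modified", "refit")
    learners: tuple[str, ...] = LEARNERS
    ratio: float = 0.75
    seed: int = 0
    refit_strategy: str = "per_tooth"
    score_table_paths: dict[str, dict[str, str]] = field(default_factory=dict)
    # e.g. {"willems": {"female": "...json", "male": "...json"}}
    out_dir: str = "study_out"

    def validate(self) -> None:
        if not self.methods and not self.learners:
            raise PipelineError("config", "at least one method or learner required")
        bad = [m for m in self.methods if m not in SCORE_METHODS]
        if bad:
            raise PipelineError("config", f"unknown methods {bad}")
        bad = [l for l in self.learners if l not in LEARNERS]
        if bad:
            raise PipelineError("config", f"unknown learners {bad}")
        for m in self.methods:
            if m in ("demirjian", "willems") and m not in self.score_table_paths:
                raise PipelineError(
                    "config", f"method {m!r} needs score tables via score_table_paths"
                )


def derive_seeds(root_seed: int) -> dict[str, int]:
    """Named stage seeds derived from the root seed.

    Derivation: ``SeedSequence(root_seed).generate_state(n)``, one word per
    stage in a fixed order, reduced mod 2^31.
    """
    names = ["simulate", "split"] + [f"learner_{l}" for l in LEARNERS]
    state = np.random.SeedSequence(root_seed).generate_state(len(names))
    return {name: int(word % (2**31)) for name, word in zip(names, state)}


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    version: str
    timings: dict[str, float]
    files: dict[str, str]  # relative path -> sha256


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_report(df: pd.DataFrame, out_dir: Path, stem: str) -> list[Path]:
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"
    df.to_csv(csv_path, index=False)
    json_path.write_text(
        json.dumps(df.to_dict(orient="records"), indent=2, sort_keys=True) + "\n"
    )
    return [csv_path, json_path]


def _method_tables(config: RunConfig, cohort: Cohort) -> dict[str, dict[Sex, ScoreTable]]:
    """Resolve each requested score method to its per-sex tables."""
    out: dict[str, dict[Sex, ScoreTable]] = {}
    for method in config.methods:
        if method == "modified":
            female, male = builtin_modified_tables()
            out[method] = {Sex.FEMALE: female, Sex.MALE: male}
        elif method == "refit":
            tables = {}
            for sex in (Sex.FEMALE, Sex.MALE):
                base_f, base_m = builtin_modified_tables()
                base = base_f if sex is Sex.FEMALE else base_m
                sub = cohort.filter_sex(sex)
                if len(sub) == 0:
                    raise PipelineError("refit", f"no {sex.value} records to refit on")
                result = refit(sub, base, RefitConfig(config.refit_strategy, sex))
                tables[sex] = result.modified_table
            out[method] = tables
        else:  # demirjian / willems from user-supplied files
            paths = config.score_table_paths[method]
            out[method] = {
                Sex.FEMALE: load_score_table(paths["female"]),
                Sex.MALE: load_score_table(paths["male"]),
            }
    return out


def _paired_from_table(cohort: Cohort, table: ScoreTable) -> PairedAges:
    ids, ca, da, sexes = [], [], [], []
    for rec in cohort:
        est = estimate_age_sum(rec, table)
        ids.append(rec.subject_id)
        ca.append(rec.chronological_age)
        da.append(est.dental_age)
        sexes.append(rec.sex)
    return PairedAges(ids, np.array(ca), np.array(da), sexes)


_LEARNER_FITTERS = {
    "decision_tree": lambda X, y, seed: fit_tree(X, y, TreeConfig(min_samples_leaf=2)),
    "random_forest": lambda X, y, seed: fit_forest(X, y, ForestConfig(bootstrap=True), seed),
    "extra_trees": lambda X, y, seed: fit_forest(
        X, y, ForestConfig(bootstrap=False, randomize_splits=True), seed
    ),
    "adaboost_r2": lambda X, y, seed: fit_adaboost_r2(X, y, AdaBoostR2Config(), seed),
    "gbdt": lambda X, y, seed: fit_gbdt(X, y, GBDTConfig(), seed),
    "knn": lambda X, y, seed: KNNModel(X, y, KNNConfig()),
}


def train_learner(name: str, train: Cohort, seed: int):
    """Fit one named learner on a training cohort at the study defaults."""
    if name not in _LEARNER_FITTERS:
        raise PipelineError("train", f"unknown learner {name!r}")
    X, y = encode_cohort(train)
    return _LEARNER_FITTERS[name](X, y, seed)


def _paired_from_model(model, cohort: Cohort) -> PairedAges:
    X, _ = encode_cohort(cohort)
    da = model.predict(X)
    return PairedAges(
        [r.subject_id for r in cohort],
        cohort.ages(),
        np.asarray(da, dtype=float),
        [r.sex for r in cohort],
    )


def run_study(config: RunConfig) -> RunManifest:
    """Execute the full study; returns the manifest (also written to disk)."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)
    timings: dict[str, float] = {}
    files: list[Path] = []

    def stage(name):
        t0 = time.perf_counter()

        def done():
            timings[name] = round(time.perf_counter() - t0, 3)

        return done

    # ----- input -----
    done = stage("input")
    try:
        if config.input_csv is None:
            cohort, _truth = generate_cohort(CohortSpec(seed=seeds["simulate"]))
        else:
            cohort = read_staging_csv(config.input_csv)
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc
    done()

    files += _write_report(age_distribution_table(cohort), out_dir, "sample_distribution")

    # ----- score-model comparison (full cohort) -----
    method_rows, group_rows = [], []
    if config.methods:
        done = stage("score_models")
        try:
            tables = _method_tables(config, cohort)
            for method in config.methods:
                for sex in (Sex.FEMALE, Sex.MALE):
                    sub = cohort.filter_sex(sex)
                    if len(sub) == 0:
                        continue
                    pair = _paired_from_table(sub, tables[method][sex])
                    method_rows.append(method_comparison_row(method, sex, pair))
                    for b, v in per_group_mae(pair).items():
                        group_rows.append(
                            {"method": method, "sex": sex.value, "age_group": b.label, "MAE": v}
                        )
        except Exception as exc:
            raise PipelineError("score_models", str(exc)) from exc
        done()
        files += _write_report(pd.DataFrame(method_rows), out_dir, "method_comparison")

    # ----- split + learners -----
    learner_rows = []
    if config.learners:
        done = stage("split")
        train, test = split_train_test(cohort, config.ratio, seeds["split"])
        done()
        for name in config.learners:
            done = stage(f"learner_{name}")
            try:
                model = train_learner(name, train, seeds[f"learner_{name}"])
                for split_name, sub_cohort in (("training", train), ("testing", test)):
                    pair_all = _paired_from_model(model, sub_cohort)
                    for sex in (Sex.FEMALE, Sex.MALE):
                        mask = np.array([s is sex for s in pair_all.sex])
                        if not mask.any():
                            continue
                        pair = pair_all.subset(mask)
                        learner_rows.append(learner_metrics_row(name, sex, split_name, pair))
                        if split_name == "testing":
                            for b, v in per_group_mae(pair).items():
                                group_rows.append(
                                    {
                                        "method": name,
                                        "sex": sex.value,
                                        "age_group": b.label,
                                        "MAE": v,
                                    }
                                )
            except Exception as exc:
                raise PipelineError(f"learner_{name}", str(exc)) from exc
            done()
        files += _write_report(pd.DataFrame(learner_rows), out_dir, "learner_metrics")

    if group_rows:
        files += _write_report(pd.DataFrame(group_rows), out_dir, "per_age_group_mae")

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seeds=seeds,
        version=__version__,
        timings=timings,
        files={str(p.relative_to(out_dir)): _sha256(p) for p in files},
    )
    (out_dir / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True) + "\n"
    )
    return manifest


def compare_methods(report_a: pd.DataFrame, report_b: pd.DataFrame) -> pd.DataFrame:
    """Rank two reports' shared methods by test MAE, per sex, with deltas.

    Both inputs must carry matching ``attrs['cohort']`` provenance.  Rows
    are matched on (method, sex); the output adds the MAE delta (B − A) and
    a per-sex rank by the B-side MAE.
    """
    if report_a.attrs.get("cohort") != report_b.attrs.get("cohort"):
        raise PipelineError("compare", "reports computed on different cohorts")

    def norm(df):
        d = df.copy()
        if "learner" in d.columns:
            d["method"] = d.get("method", pd.Series(index=d.index, dtype=object)).fillna(
                d["learner"]
            ) if "method" in d.columns else d["learner"]
        if "split" in d.columns:
            d = d[d["split"].isna() | (d["split"] == "testing")]
        # score-method rows report capped MAE; learner rows plain MAE
        if "MAE" in d.columns and "MAE_under_18" in d.columns:
            d["MAE"] = d["MAE"].fillna(d["MAE_under_18"])
        elif "MAE_under_18" in d.columns:
            d["MAE"] = d["MAE_under_18"]
        return d[["method", "sex", "MAE"]]

    a, b = norm(report_a), norm(report_b)
    merged = a.merge(b, on=["method", "sex"], suffixes=("_a", "_b"))
    if merged.empty:
        raise PipelineError("compare", "no shared (method, sex) rows to compare")
    merged["delta"] = merged["MAE_b"] - merged["MAE_a"]
    merged["rank"] = merged.groupby("sex")["MAE_b"].rank(method="min")
    return merged.sort_values(["sex", "rank"]).reset_index(drop=True)
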