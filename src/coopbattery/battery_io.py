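"""Data contracts, configuration, and the end-to-end pipeline.

The single tabular interchange format is CSV with a header.  Trial data
travel in one long-format table (``participant_id, group, task, trial_index``
plus task-specific fields); every loader validates the rows of its task
against the documented scales and points at the offending row on failure.
Structured results are JSON; configuration is YAML.  Every output bundle
embeds the run configuration and seed for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import econ_models, inferential_stats, meta_analysis, mixed_models, model_selection
from . import svo_scoring, synthetic_cohort

logger = logging.getLogger("coopbattery")

__all__ = ["RunConfig", "load_trials", "write_trials", "run_pipeline", "TASK_SCHEMAS"]

# per-task required columns and inclusive value ranges
TASK_SCHEMAS: dict[str, dict] = {
    "svo": {"columns": {"item_id": (1, 15), "option_index": (1, 9)}},
    "dg": {"columns": {"allocation": (0, 10)}},
    "ug": {"columns": {"offer": (1, 6), "rejected": (0, 1)}},
    "minacc": {"columns": {"min_acceptance": (0, 10)}},
    "fairness": {"columns": {"offer": (0, 10), "rating": (1, 9)}},
    "jpe": {"columns": {"x_self": (-50, 50), "x_other": (-50, 50), "rating": (1, 8)}},
}
JPE_COMPLETE_TRIALS = 121


@dataclass
class RunConfig:
    """Run settings; serialised verbatim into every output for provenance."""

    seed: int = 0
    out_dir: str = "results"
    trials_path: Optional[str] = None        # if None, simulate
    summaries_path: Optional[str] = None     # printed-summary stats stage
    studies_path: Optional[str] = None       # meta-analysis study table
    stages: tuple[str, ...] = (
        "simulate", "score_svo", "fit_jpe", "bms", "stats", "glmm", "meta",
    )
    reverse_code_jpe: bool = False           # real data coded 1 = very good
    tau2_method: str = "REML"
    bms_n_samples: int = 100_000
    standardize_jpe: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _check_range(df: pd.DataFrame, task: str) -> None:
    schema = TASK_SCHEMAS[task]
    sub = df[df["task"] == task]
    for col, (lo, hi) in schema["columns"].items():
        if col not in sub.columns:
            raise ValueError(f"task {task!r}: missing column {col!r}")
        vals = pd.to_numeric(sub[col], errors="coerce")
        bad = sub.index[(vals < lo) | (vals > hi) | vals.isna()]
        if len(bad):
            raise ValueError(
                f"task {task!r}, column {col!r}: value out of range "
                f"[{lo}, {hi}] at row {int(bad[0])}"
            )


def load_trials(
    path: str | Path, *, reverse_code_jpe: bool = False
) -> pd.DataFrame:
    """Load and validate the long-format trials CSV.

    Unknown tasks are rejected; each task's fields are range-checked with
    the failing row named.  ``reverse_code_jpe`` flips raw 1 = very good
    ratings onto the analysis scale (larger = better).  Subjects with an
    incomplete 121-cell payoff grid are logged and flagged in the
    ``incomplete_jpe`` attribute, not dropped.
    """
    df = pd.read_csv(path)
    if "task" not in df.columns:
        raise ValueError("trials table has no 'task' column")
    unknown = set(df["task"].unique()) - set(TASK_SCHEMAS)
    if unknown:
        raise ValueError(f"unknown tasks in trials table: {sorted(unknown)}")
    for task in df["task"].unique():
        _check_range(df, task)
    if reverse_code_jpe:
        m = df["task"] == "jpe"
        df.loc[m, "rating"] = 9 - df.loc[m, "rating"]
    incomplete = []
    jpe = df[df["task"] == "jpe"]
    if len(jpe):
        counts = jpe.groupby("participant_id").size()
        incomplete = sorted(counts.index[counts != JPE_COMPLETE_TRIALS])
        for sid in incomplete:
            logger.warning(
                "subject %s has %d JPE trials (expected %d); flagged incomplete",
                sid, int(counts[sid]), JPE_COMPLETE_TRIALS,
            )
    df.attrs["incomplete_jpe"] = incomplete
    logger.info("loaded %d trial rows from %s", len(df), path)
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def score_svo_table(trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    svo = trials[trials["task"] == "svo"]
    for sid, sub in svo.groupby("participant_id"):
        choices = dict(zip(sub["item_id"].astype(int), sub["option_index"].astype(int)))
        res = svo_scoring.score_participant(choices)
        rows.append({
            "participant_id": sid,
            "group": sub["group"].iloc[0],
            "svo_angle": res.angle,
            "svo_category": res.category,
            "pm_index": res.pm_index,
            "pm_category": res.pm_category,
            "consistent_primary": res.consistent_primary,
            "consistent_secondary": res.consistent_secondary,
        })
    return pd.DataFrame(rows)


def fit_jpe_tables(trials: pd.DataFrame, standardize: bool) -> tuple[pd.DataFrame, pd.DataFrame]:
    registry = econ_models.model_registry()
    jpe = trials[trials["task"] == "jpe"]
    fits_rows, ev_rows = [], {}
    groups = {}
    for sid, sub in jpe.groupby("participant_id"):
        grid = sub[["x_self", "x_other"]].reset_index(drop=True)
        ratings = sub["rating"].to_numpy(dtype=float)
        groups[sid] = sub["group"].iloc[0]
        ev_rows[sid] = {}
        for name, spec in registry.items():
            fit = econ_models.fit_subject(spec, grid, ratings, standardize=standardize)
            ev_rows[sid][name] = fit.log_evidence
            fits_rows.append({
                "participant_id": sid, "group": groups[sid], "model": name,
                "r2": fit.r2, "log_evidence": fit.log_evidence,
                "alpha_hat": fit.alpha_hat, "beta_hat": fit.beta_hat,
                **{f"b_{k}": v for k, v in fit.coefs.items()},
            })
    ev = pd.DataFrame.from_dict(ev_rows, orient="index")
    ev.index.name = "participant_id"
    ev.attrs["groups"] = groups
    return pd.DataFrame(fits_rows), ev


def _stats_stage(trials: pd.DataFrame, svo_results: Optional[pd.DataFrame],
                 fits: Optional[pd.DataFrame]) -> pd.DataFrame:
    """Table of group comparisons mirroring the task-summary layout."""
    parts = trials.drop_duplicates("participant_id")[["participant_id", "group"]]
    groups = sorted(parts["group"].unique())
    if len(groups) != 2:
        raise ValueError("stats stage expects exactly two groups")
    g1, g2 = groups  # alphabetical; BPD before HC in the default labels
    rows = []

    def compare(measure: str, series: pd.Series, with_bf: bool = True) -> None:
        merged = parts.merge(series.rename("value"), on="participant_id")
        x = merged.loc[merged["group"] == g1, "value"].dropna().to_numpy()
        y = merged.loc[merged["group"] == g2, "value"].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            return
        wt = inferential_stats.welch_t(x, y)
        wx = inferential_stats.wilcoxon_ranksum(x, y)
        row = {
            "measure": measure, "group_1": g1, "group_2": g2,
            "m1": x.mean(), "sd1": x.std(ddof=1), "n1": len(x),
            "m2": y.mean(), "sd2": y.std(ddof=1), "n2": len(y),
            "t": wt.statistic, "df": wt.df, "ci_low": wt.ci_low,
            "ci_high": wt.ci_high, "p": wt.p, "d": wt.effect_size,
            "z": wx.statistic, "p_wilcoxon": wx.p, "r": wx.effect_size,
        }
        if with_bf:
            bf = inferential_stats.jzs_ttest_bf(
                a=inferential_stats.summarize(x), b=inferential_stats.summarize(y)
            )
            row["bf01"] = bf.bf01
        rows.append(row)

    if svo_results is not None and len(svo_results):
        sv = svo_results.set_index("participant_id")
        compare("svo_angle", sv["svo_angle"])
        consistent = sv[(sv["consistent_primary"]) & (sv["consistent_secondary"] == True)]  # noqa: E712
        if len(consistent):
            compare("pm_index", consistent["pm_index"])
    dg = trials[trials["task"] == "dg"].set_index("participant_id")["allocation"]
    if len(dg):
        compare("dg_allocation", dg)
    ug = trials[trials["task"] == "ug"]
    if len(ug):
        rates = ug.groupby("participant_id")["rejected"].mean() * 100.0
        compare("ug_rejection_rate", rates)
    ma = trials[trials["task"] == "minacc"].set_index("participant_id")["min_acceptance"]
    if len(ma):
        compare("min_acceptance", ma)
    if fits is not None and len(fits):
        fs = fits[fits["model"] == "fehr_schmidt"].set_index("participant_id")["alpha_hat"]
        compare("fs_alpha_hat", fs)
    if "dissociality" in trials.columns:
        dis = trials.drop_duplicates("participant_id").set_index("participant_id")["dissociality"]
        compare("dissociality", dis, with_bf=False)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages and write the report bundle.

    Returns the report dict; artifacts land under ``config.out_dir``.
    A stage failure raises after already-written outputs are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    trials = None
    if "simulate" in config.stages and config.trials_path is None:
        cfg = dataclasses.replace(synthetic_cohort.DEFAULT_CONFIG, seed=config.seed)
        cohort = synthetic_cohort.generate_cohort(cfg)
        trials = synthetic_cohort.trials_frame(cohort)
        synthetic_cohort.participants_frame(cohort).to_csv(out / "participants.csv", index=False)
        write_trials(trials, out / "trials.csv")
        logger.info("simulated cohort of %d participants (seed %d)", len(cohort), config.seed)
        report["n_participants"] = len(cohort)
    elif config.trials_path is not None:
        trials = load_trials(config.trials_path, reverse_code_jpe=config.reverse_code_jpe)

    svo_results = fits = evidence = None
    if trials is not None and "score_svo" in config.stages:
        svo_results = score_svo_table(trials)
        svo_results.to_csv(out / "svo_results.csv", index=False)

    if trials is not None and "fit_jpe" in config.stages:
        fits, evidence = fit_jpe_tables(trials, config.standardize_jpe)
        fits.to_csv(out / "subject_fits.csv", index=False)
        evidence.to_csv(out / "evidence_matrix.csv")

    if evidence is not None and "bms" in config.stages:
        groups = evidence.attrs["groups"]
        bms_report = {}
        for glabel in sorted(set(groups.values())):
            ids = [sid for sid, g in groups.items() if g == glabel]
            E = evidence.loc[ids]
            lgbf = model_selection.log_group_bf(E)
            bms = model_selection.rfx_bms(E, n_samples=config.bms_n_samples, seed=config.seed)
            lgbf.to_csv(out / f"lgbf_{glabel}.csv")
            bms_report[glabel] = {
                "bms": bms.as_dict(),
                "selection": model_selection.select_best(bms, lgbf),
            }
        with open(out / "bms_report.json", "w") as fh:
            json.dump(bms_report, fh, indent=2)
        report["bms"] = {
            g: r["selection"] for g, r in bms_report.items()
        }

    if trials is not None and "stats" in config.stages:
        stats_table = _stats_stage(trials, svo_results, fits)
        stats_table.to_csv(out / "group_stats.csv", index=False)
        report["group_stats_rows"] = len(stats_table)

    if trials is not None and "glmm" in config.stages:
        ug = trials[trials["task"] == "ug"].copy()
        fair = trials[trials["task"] == "fairness"].copy()
        glmm_report = {}
        if len(ug):
            res = mixed_models.fit_ug_glmm(ug, predictor="group")
            glmm_report["ug_group"] = _glmm_json(res)
            if "dissociality" in ug.columns and ug["dissociality"].notna().all():
                res_d = mixed_models.fit_ug_glmm(ug, predictor="dissociality")
                glmm_report["ug_dissociality"] = _glmm_json(res_d)
        if len(fair):
            res_f = mixed_models.fit_fairness_lmm(fair)
            glmm_report["fairness"] = _glmm_json(res_f)
        with open(out / "glmm_report.json", "w") as fh:
            json.dump(glmm_report, fh, indent=2)
        report["glmm"] = {k: v["fixed_effects"] for k, v in glmm_report.items()}

    if "meta" in config.stages and config.studies_path is not None:
        studies_df = pd.read_csv(config.studies_path)
        studies = []
        for _, r in studies_df.iterrows():
            if "d" in studies_df.columns and not pd.isna(r.get("d", np.nan)):
                d = float(r["d"])
                n1, n2 = int(r["n1"]), int(r["n2"])
                var_d = (n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2))
                studies.append(meta_analysis.StudyEffect(str(r["label"]), d, n1, n2, var_d))
            else:
                studies.append(meta_analysis.smd_from_summary(
                    str(r["label"]), r["m1"], r["s1"], int(r["n1"]),
                    r["m2"], r["s2"], int(r["n2"]),
                ))
        meta = meta_analysis.pool_random_effects(studies, config.tau2_method)
        forest = pd.DataFrame([
            {"label": s.label, "d": s.d, "se": np.sqrt(s.var_d),
             "ci_low": s.d - 1.959963984540054 * np.sqrt(s.var_d),
             "ci_high": s.d + 1.959963984540054 * np.sqrt(s.var_d),
             "weight": meta.weights[s.label]}
            for s in studies
        ])
        forest.to_csv(out / "forest_data.csv", index=False)
        funnel = pd.DataFrame({"d": [s.d for s in studies],
                               "se": [np.sqrt(s.var_d) for s in studies]})
        funnel.to_csv(out / "funnel_data.csv", index=False)
        with open(out / "meta_result.json", "w") as fh:
            json.dump(meta.as_dict(), fh, indent=2)
        report["meta"] = meta.as_dict()

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _glmm_json(res: mixed_models.GlmmResult) -> dict:
    return {
        "fixed_effects": {fe.name: {
            "b": fe.b, "se": fe.se, "t": fe.t, "df": fe.df, "p": fe.p,
            "ci": [fe.ci_low, fe.ci_high], "or": fe.odds_ratio,
        } for fe in res.fixed_effects},
        "random_intercept_sd": res.random_intercept_sd,
        "method": res.method,
        "n_obs": res.n_obs,
        "flags": list(res.flags),
    }


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
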