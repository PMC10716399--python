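"""End-to-end orchestration: generate -> score -> fit -> test.

Two modes: ``simulate`` generates a synthetic cohort and analyses it;
``analyze`` runs on existing tables.  All stages write delimited-text
outputs (scores.csv, tva_fits.csv, tva_changes.csv, sensory.csv,
stats_report.json, summary.tsv) plus a run manifest echoing the
configuration, the seed, per-stage row counts and any exclusions with
machine-readable reason codes.  Identical configuration and seed reproduce
byte-identical outputs: the generator is seeded and the fits are
deterministic (fixed grids, no stochastic restarts).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import somatosensory as soma
from . import tva
from .errors import EstimationFailureError, ValidationError
from .inference import StatResult, compare_groups, mixed_anova, paired_compare, subgroup_analyses
from .typing_scores import dictation_ccpm, score_table

logger = logging.getLogger("vismotor")

REQUIRED_COLUMNS = {
    "typing": ["subject_id", "group", "day", "session", "lesson_id", "entered", "errors", "duration_min"],
    "tva_trials": ["subject_id", "phase", "paradigm", "exposure_ms", "masked", "n_displayed", "layout", "reported"],
    "got": ["subject_id", "phase", "block_index", "spacing_mm", "n_trials", "n_correct"],
    "mdt": ["subject_id", "phase", "determination", "trial_index", "force_mN", "detected"],
    "subjects": ["subject_id", "group", "age", "gender", "consumption_h_week", "content_group"],
    "dictation": ["subject_id", "phase", "correct_chars", "minutes"],
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str  # "simulate" or "analyze"
    outdir: str | Path
    cohort: cohort_mod.CohortConfig | None = None
    tables: dict = field(default_factory=dict)  # name -> path, analyze mode
    seed: int = 0
    verbosity: str = "INFO"


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_tables(tables: dict[str, pd.DataFrame]) -> list[dict]:
    """Schema, range and referential-integrity checks; returns violations
    (empty list when pristine).  Never mutates its inputs."""
    violations: list[dict] = []

    def add(stage, code, detail):
        violations.append({"stage": stage, "code": code, "detail": detail})

    for name, df in tables.items():
        missing = [c for c in REQUIRED_COLUMNS.get(name, []) if c not in df.columns]
        if missing:
            add(name, "missing_columns", missing)

    typing = tables.get("typing")
    if typing is not None and not typing.empty and "entered" in typing:
        bad = typing[typing["errors"] > typing["entered"]]
        if len(bad):
            add("typing_performance", "errors_exceed_entered", bad.index.tolist())
        bad_day = typing[~typing["day"].isin(range(1, 6))]
        if len(bad_day):
            add("typing_performance", "day_out_of_range", bad_day.index.tolist())

    trials = tables.get("tva_trials")
    if trials is not None and not trials.empty and "exposure_ms" in trials:
        bad = trials[(trials["exposure_ms"] < 10) | (trials["exposure_ms"] > 200)]
        if len(bad):
            add("tva_attention", "exposure_out_of_range", bad.index.tolist())
        bad_rep = trials[trials["reported"] > trials["n_displayed"]]
        if len(bad_rep):
            add("tva_attention", "reported_exceeds_displayed", bad_rep.index.tolist())
        # referential integrity: subjects claiming both phases must have both
        phases = trials.groupby("subject_id")["phase"].agg(set)
        incomplete = [s for s, p in phases.items() if p != {"pre", "post"}]
        if incomplete:
            add("tva_attention", "missing_phase_warning", incomplete)

    got = tables.get("got")
    if got is not None and not got.empty and "n_correct" in got:
        bad = got[got["n_correct"] > got["n_trials"]]
        if len(bad):
            add("somatosensory", "correct_exceeds_trials", bad.index.tolist())
    return violations


def load_tables(paths: dict[str, str | Path]) -> dict[str, pd.DataFrame]:
    out = {}
    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"input table '{name}' not found at {path}")
        out[name] = pd.read_csv(path)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def tva_stage(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Fit whole- and partial-report parameters per subject x phase and
    derive change scores.  Subjects whose fit fails or does not converge in
    either phase are excluded from the change table with a reason code."""
    fit_rows, exclusions = [], []
    fits: dict[tuple, tva.TVAParams] = {}
    for (sid, phase), df in trials.groupby(["subject_id", "phase"], sort=True):
        whole = [
            tva.WholeReportTrial(
                exposure_ms=float(r.exposure_ms),
                masked=bool(r.masked),
                n_displayed=int(r.n_displayed),
                n_correct_reported=int(r.reported),
            )
            for r in df[df["paradigm"] == "whole"].itertuples()
        ]
        partial = [
            tva.PartialReportTrial(
                exposure_ms=float(r.exposure_ms),
                layout=cohort_mod.PARTIAL_LAYOUTS[str(r.layout)],
                reported_targets=int(r.reported),
            )
            for r in df[df["paradigm"] == "partial"].itertuples()
        ]
        try:
            params = tva.fit_whole_report(whole)
            if partial:
                params = tva.fit_partial_report(partial, params)
        except EstimationFailureError as exc:
            exclusions.append(
                {"subject_id": sid, "phase": phase, "reason": "fit_failure",
                 "detail": str(exc)}
            )
            continue
        fits[(sid, phase)] = params
        fit_rows.append(
            {
                "subject_id": sid,
                "phase": phase,
                "t0": params.t0,
                "C": params.C,
                "K": params.K,
                "mu": params.mu,
                "alpha": params.alpha,
                "w_lat": params.w_lat,
                "loglik": params.loglik,
                "converged": params.convergence.get("converged", False),
            }
        )

    change_rows = []
    for sid in sorted({s for s, _ in fits}):
        pre, post = fits.get((sid, "pre")), fits.get((sid, "post"))
        if pre is None or post is None:
            exclusions.append(
                {"subject_id": sid, "phase": "both", "reason": "missing_phase",
                 "detail": "pre or post fit unavailable"}
            )
            continue
        if not (pre.convergence.get("converged") and post.convergence.get("converged")):
            exclusions.append(
                {"subject_id": sid, "phase": "both", "reason": "non_converged_fit",
                 "detail": "boundary or non-converged estimate"}
            )
            continue
        cs = tva.change_scores(pre, post)
        change_rows.append(
            {
                "subject_id": sid,
                "C_pre": pre.C, "C_post": post.C,
                "K_pre": pre.K, "K_post": post.K,
                "C_change": cs.C_change, "C_rc": cs.C_rc,
                "K_change": cs.K_change, "K_rc": cs.K_rc,
            }
        )
    return pd.DataFrame(fit_rows), pd.DataFrame(change_rows), exclusions


def sensory_stage(
    got: pd.DataFrame, mdt: pd.DataFrame
) -> tuple[pd.DataFrame, list[dict]]:
    """g75 and MDT estimates per subject x phase with relative changes;
    censored estimates are flagged and excluded from change ratios."""
    rows: dict[tuple, dict] = {}
    exclusions: list[dict] = []
    for (sid, phase), df in got.groupby(["subject_id", "phase"], sort=True):
        df = df.sort_values("block_index")
        blocks = [
            soma.GOTBlock(float(r.spacing_mm), int(r.n_trials), int(r.n_correct))
            for r in df.itertuples()
        ]
        est = soma.g75(blocks)
        rows.setdefault((sid, phase), {"subject_id": sid, "phase": phase}).update(
            {"g75_mm": est.value, "g75_censored": est.censored or ""}
        )
    for (sid, phase), df in mdt.groupby(["subject_id", "phase"], sort=True):
        df = df.sort_values(["determination", "trial_index"])
        series = soma.MDTSeries(
            runs=tuple((float(r.force_mN), bool(r.detected)) for r in df.itertuples()),
            determination=tuple(int(r.determination) for r in df.itertuples()),
        )
        est = soma.mdt_threshold(series)
        rows.setdefault((sid, phase), {"subject_id": sid, "phase": phase}).update(
            {"mdt_mN": est.value, "mdt_se": est.se, "mdt_censored": est.censored or ""}
        )
    table = pd.DataFrame(list(rows.values()))
    if table.empty:
        return table, exclusions

    wide = table.pivot(index="subject_id", columns="phase")
    change_rows = []
    for sid in wide.index:
        row = {"subject_id": sid}
        for meas, cens in (("g75_mm", "g75_censored"), ("mdt_mN", "mdt_censored")):
            try:
                pre = wide.loc[sid, (meas, "pre")]
                post = wide.loc[sid, (meas, "post")]
                cens_pre = wide.loc[sid, (cens, "pre")]
                cens_post = wide.loc[sid, (cens, "post")]
            except KeyError:
                continue
            if cens_pre or cens_post or pd.isna(pre) or pd.isna(post):
                exclusions.append(
                    {"subject_id": sid, "measure": meas, "reason": "censored_threshold",
                     "detail": f"pre={cens_pre!r} post={cens_post!r}"}
                )
                row[f"{meas}_rc"] = np.nan
            else:
                row[f"{meas}_rc"] = soma.relative_change(float(pre), float(post))
        change_rows.append(row)
    changes = pd.DataFrame(change_rows)
    out = table.merge(changes, on="subject_id", how="left")
    return out, exclusions


def stats_stage(
    scores: pd.DataFrame,
    subjects: pd.DataFrame,
    typing: pd.DataFrame,
    tva_changes: pd.DataFrame | None,
    sensory: pd.DataFrame | None,
    dictation: pd.DataFrame | None,
) -> dict:
    """The trial's statistical battery on whatever stages are available."""
    report: dict = {"multiplicity": "none across behavioural endpoints"}
    merged = scores.merge(subjects, on=["subject_id", "group"], how="left")

    def put(key: str, result: StatResult):
        report[key] = result.to_dict()

    put("mle_group", compare_groups(merged, "mle"))
    for d in range(2, 6):
        put(f"gain_l3_d{d}_group", compare_groups(merged, f"gain_l3_d{d}"))
    for d in range(1, 6):
        put(f"di_d{d}_group", compare_groups(merged, f"di_d{d}"))

    long_gain = merged.melt(
        id_vars=["subject_id", "group"],
        value_vars=[f"gain_l3_d{d}" for d in range(1, 6)],
        var_name="day", value_name="gain",
    )
    long_gain["day"] = long_gain["day"].str[-1].astype(int)
    for key, res in mixed_anova(long_gain, dv="gain").items():
        put(f"gain_l3_anova_{key}", res)

    if {"age", "consumption_h_week", "gender", "content_group"} <= set(merged.columns):
        merged["content_group"] = merged["content_group"].fillna("")
        for key, res in subgroup_analyses(merged).items():
            put(f"subgroup_{key}", res)

    if dictation is not None and not dictation.empty:
        dic = dictation.merge(subjects[["subject_id", "group"]], on="subject_id")
        dic["ccpm"] = [
            dictation_ccpm(int(r.correct_chars), float(r.minutes))
            for r in dic.itertuples()
        ]
        pre = dic[dic["phase"] == "pre"]
        put("dictation_baseline_group", compare_groups(pre, "ccpm"))

    if tva_changes is not None and not tva_changes.empty:
        tc = tva_changes.merge(subjects[["subject_id", "group"]], on="subject_id")
        for meas in ("C_change", "C_rc", "K_change", "K_rc"):
            put(f"tva_{meas}_group", compare_groups(tc, meas))
        for grp in ("TV", "NOTV"):
            sub = tc[tc["group"] == grp]
            if len(sub) >= 3:
                put(f"tva_C_within_{grp}", paired_compare(sub["C_pre"], sub["C_post"]))
                put(f"tva_K_within_{grp}", paired_compare(sub["K_pre"], sub["K_post"]))

    if sensory is not None and not sensory.empty:
        sens = (
            sensory[sensory["phase"] == "pre"][
                ["subject_id", "g75_mm_rc", "mdt_mN_rc"]
            ]
            .merge(subjects[["subject_id", "group"]], on="subject_id")
        )
        for meas in ("g75_mm_rc", "mdt_mN_rc"):
            if sens[meas].notna().sum() >= 6:
                put(f"sensory_{meas}_group", compare_groups(sens.dropna(subset=[meas]), meas))
    return report


def _summary_tsv(report: dict) -> str:
    lines = ["endpoint\ttest\tstatistic\tdf\tp_value\teffect_size"]
    for key, val in report.items():
        if not isinstance(val, dict) or "test_name" not in val:
            continue
        df = val.get("df")
        df_s = ",".join(f"{x:g}" for x in df) if isinstance(df, list) else (
            "" if df is None else f"{df:g}"
        )
        stat = val.get("statistic")
        p = val.get("p_value")
        es = val.get("effect_size")
        fmt = lambda x: "" if x is None else format(x, ".4g")
        lines.append(
            f"{key}\t{val['test_name']}\t{fmt(stat)}\t{df_s}\t{fmt(p)}\t{fmt(es)}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"mode": config.mode, "seed": config.seed, "stages": {}, "exclusions": []}

    if config.mode == "simulate":
        cc = config.cohort or cohort_mod.CohortConfig(seed=config.seed)
        logger.info("simulating cohort: %d subjects", 2 * cc.n_per_group)
        dataset = cohort_mod.generate_cohort(cc)
        cohort_manifest = cohort_mod.write_cohort(dataset, outdir)
        manifest["cohort"] = {k: cohort_manifest[k] for k in ("seed", "n_per_group", "n_subjects")}
        tables = {
            "subjects": dataset.subjects,
            "typing": dataset.typing,
            "tva_trials": dataset.tva_trials,
            "got": dataset.got,
            "mdt": dataset.mdt,
            "dictation": dataset.dictation,
        }
    elif config.mode == "analyze":
        tables = load_tables(config.tables)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    violations = validate_tables(tables)
    hard = [v for v in violations if not v["code"].endswith("_warning")]
    if hard:
        raise ValidationError(hard[0]["stage"], hard)
    manifest["validation_warnings"] = violations

    scores = score_table(tables["typing"])
    scores.to_csv(outdir / "scores.csv", index=False)
    manifest["stages"]["scores"] = {"rows": int(len(scores))}

    tva_fits = tva_changes = None
    if not tables["tva_trials"].empty:
        logger.info("fitting TVA parameters for %d subject-phases",
                    tables["tva_trials"].groupby(["subject_id", "phase"]).ngroups)
        tva_fits, tva_changes, excl = tva_stage(tables["tva_trials"])
        tva_fits.to_csv(outdir / "tva_fits.csv", index=False)
        tva_changes.to_csv(outdir / "tva_changes.csv", index=False)
        manifest["stages"]["tva"] = {
            "fits": int(len(tva_fits)), "changes": int(len(tva_changes))
        }
        manifest["exclusions"].extend(excl)

    sensory = None
    if not tables["got"].empty or not tables["mdt"].empty:
        sensory, excl = sensory_stage(tables["got"], tables["mdt"])
        sensory.to_csv(outdir / "sensory.csv", index=False)
        manifest["stages"]["sensory"] = {"rows": int(len(sensory))}
        manifest["exclusions"].extend(excl)

    report = stats_stage(
        scores, tables["subjects"], tables["typing"],
        tva_changes, sensory, tables.get("dictation"),
    )
    (outdir / "stats_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "summary.tsv").write_text(_summary_tsv(report))
    manifest["stages"]["stats"] = {"endpoints": len(report)}

    if config.mode == "simulate" and config.cohort is not None:
        manifest["cohort_config"] = cohort_mod._config_dict(config.cohort)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
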