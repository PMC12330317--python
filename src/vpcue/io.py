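"""Configuration, file formats, and the end-to-end pipeline.

All tabular artifacts are UTF-8 CSV with a header row and '.' decimals; run
summaries are JSON.  A run is fully reproducible from its config and master
seed, and every run directory contains a log echoing both.

Trial tables carry one row per trial with the columns::

    participant, group, session, block, trial_index, target_type,
    start_x, start_y, p_target_x, p_target_y, visual_offset,
    v_cue_x, v_cue_y, endpoint_x, endpoint_y

MEP trace tables carry one row per trace: metadata columns (participant,
session, timepoint, condition, rate) followed by the samples s0..sN in mV.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimators, inference, sai as sai_mod
from .observer import (
    CohortConfig,
    CohortResult,
    GroupEffect,
    ParamDistributions,
    SaiCoupling,
    simulate_cohort,
)
from .schedule import BLOCK_LABELS, TARGET_TYPES

TRIAL_COLUMNS = [
    "participant", "group", "session", "block", "trial_index", "target_type",
    "start_x", "start_y", "p_target_x", "p_target_y", "visual_offset",
    "v_cue_x", "v_cue_y", "endpoint_x", "endpoint_y",
]
_NUMERIC_TRIAL_COLUMNS = [
    "trial_index", "start_x", "start_y", "p_target_x", "p_target_y",
    "visual_offset", "v_cue_x", "v_cue_y", "endpoint_x", "endpoint_y",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and participant."""


class ParseError(ValueError):
    """Raised for malformed input tables, naming the offending column/row."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisOptions:
    """Tunable analysis conventions (all with task-standard defaults)."""

    variance_ddof: int = 1  # sample (n-1) endpoint-variance denominator
    wv_min_valid: int = 3  # weights needed before a block mean is defined
    wv_sd_criterion: float = 0.5  # centroid-overlap exclusion threshold
    mep_window_ms: tuple[float, float] = sai_mod.DEFAULT_MEP_WINDOW_MS


@dataclass
class RunConfig:
    """Everything needed to reproduce a full simulate->analyze run."""

    experiment: str = "expt1"
    seed: int = 0
    n_per_group: int = 22
    group_effects: dict[str, GroupEffect] = field(
        default_factory=lambda: {
            "S1": GroupEffect(sigma_p_mult=1.3, eta_mult=1.4),
            "M1": GroupEffect(),
            "Sham": GroupEffect(),
        }
    )
    sai_coupling: SaiCoupling = field(default_factory=SaiCoupling)
    param_dist: ParamDistributions = field(default_factory=ParamDistributions)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        """Build a config from nested plain dicts, rejecting unknown keys."""
        def build(klass, payload, label):
            if not isinstance(payload, dict):
                raise ParseError(f"{label} must be a mapping")
            known = {f.name for f in fields(klass)}
            if unknown := set(payload) - known:
                raise ParseError(f"unknown {label} key(s): {sorted(unknown)}")
            return klass(**payload)

        known = {f.name for f in fields(cls)}
        if unknown := set(raw) - known:
            raise ParseError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        if "group_effects" in kwargs:
            kwargs["group_effects"] = {
                g: build(GroupEffect, v, f"group_effects[{g}]")
                for g, v in kwargs["group_effects"].items()
            }
        for key, klass in (
            ("sai_coupling", SaiCoupling),
            ("param_dist", ParamDistributions),
            ("analysis", AnalysisOptions),
        ):
            if key in kwargs:
                payload = dict(kwargs[key])
                for tup_key in ("eta_bounds", "mep_window_ms"):
                    if tup_key in payload:
                        payload[tup_key] = tuple(payload[tup_key])
                kwargs[key] = build(klass, payload, key)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            experiment=self.experiment,
            n_per_group=self.n_per_group,
            group_effects=dict(self.group_effects),
            sai_coupling=self.sai_coupling,
            param_dist=self.param_dist,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# Trial-table IO
# ---------------------------------------------------------------------------

def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    out = trials.reindex(columns=TRIAL_COLUMNS)
    out.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial table; errors name the column and row."""
    table = pd.read_csv(path)
    for col in TRIAL_COLUMNS:
        if col not in table.columns:
            raise ParseError(f"missing column {col!r}")
    for col in _NUMERIC_TRIAL_COLUMNS:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ParseError(f"non-numeric value in column {col!r} at row {row}")
        table[col] = coerced
    for col, allowed in (("target_type", TARGET_TYPES), ("block", BLOCK_LABELS)):
        bad = ~table[col].isin(allowed)
        if bad.any():
            row = int(bad.idxmax()) + 2
            raise ParseError(
                f"invalid {col} {table[col][bad].iloc[0]!r} at row {row}"
            )
    key = ["participant", "session", "block", "trial_index"]
    dup = table.duplicated(subset=key)
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise ParseError(f"duplicate (participant, session, block, trial_index) at row {row}")
    order_ok = (
        table.sort_values(key).groupby(["participant", "session", "block"])
        ["trial_index"].apply(lambda s: (np.diff(s) > 0).all() if len(s) > 1 else True)
    )
    if not order_ok.all():  # pragma: no cover - duplicates already rejected
        raise ParseError("trial indices are not strictly increasing within a block")
    return table


def write_traces(traces: dict[tuple[int, str], list], path: str | Path) -> None:
    """Serialise MEP traces, one row per trace (metadata then samples)."""
    rows = []
    for (pid, session), trace_list in traces.items():
        for tr in trace_list:
            row = {
                "participant": pid,
                "session": session,
                "timepoint": tr.timepoint,
                "condition": tr.condition,
                "rate": tr.rate,
            }
            row.update({f"s{i}": v for i, v in enumerate(tr.samples)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces(path: str | Path) -> dict[tuple[int, str], list]:
    table = pd.read_csv(path)
    meta = ["participant", "session", "timepoint", "condition", "rate"]
    for col in meta:
        if col not in table.columns:
            raise ParseError(f"missing column {col!r}")
    sample_cols = [c for c in table.columns if c not in meta]
    out: dict[tuple[int, str], list] = {}
    for _, row in table.iterrows():
        tr = sai_mod.MepTrace(
            samples=row[sample_cols].to_numpy(dtype=float),
            rate=float(row["rate"]),
            condition=row["condition"],
            timepoint=row["timepoint"],
        )
        out.setdefault((int(row["participant"]), row["session"]), []).append(tr)
    return out


# ---------------------------------------------------------------------------
# Estimation stage
# ---------------------------------------------------------------------------

def estimate_block(
    block: pd.DataFrame, options: AnalysisOptions | None = None
) -> dict:
    """All estimators applicable to one block of one participant's trials."""
    opts = options or AnalysisOptions()
    total_shift = float(block["visual_offset"].max())
    out: dict = estimators.block_recalibration(block, total_shift)
    if np.isfinite(out["recal_p_y"]) and np.isfinite(out["recal_v_y"]):
        out["recal_total_y"] = out["recal_p_y"] + out["recal_v_y"]

    # variance and weighting work on target-relative endpoints, since start
    # and target positions vary trial to trial by design
    rel = (
        estimators.target_relative(block)
        .drop(columns=["endpoint_x", "endpoint_y"])
        .rename(columns={"rel_x": "endpoint_x", "rel_y": "endpoint_y"})
    )[["target_type", "trial_index", "endpoint_x", "endpoint_y"]]
    p_trials = rel[rel.target_type == "P"]
    v_trials = rel[rel.target_type == "V"]
    vp_trials = rel[rel.target_type == "VP"]

    if len(p_trials) >= 3 and len(v_trials) >= 3:
        raw_p = estimators.endpoint_variance_2d(
            p_trials[["endpoint_x", "endpoint_y"]].to_numpy()
        )
        raw_v = estimators.endpoint_variance_2d(
            v_trials[["endpoint_x", "endpoint_y"]].to_numpy()
        )
        est = estimators.corrected_variances(raw_p, raw_v)
        out.update(
            var_p_raw=est.raw_p, var_v_raw=est.raw_v,
            var_p_corrected=est.corrected_p, var_v_corrected=est.corrected_v,
            var_negative_flag=est.negative_flag,
        )

    # weighting only on veridical (zero-offset) blocks, as in the task design
    if total_shift == 0 and len(vp_trials) >= 1 and len(v_trials) >= 4 and len(p_trials) >= 4:
        wv = estimators.block_wv(
            rel, sd_criterion=opts.wv_sd_criterion, min_valid=opts.wv_min_valid
        )
        out["wv_mean"] = np.nan if wv.block_mean is None else wv.block_mean
        out["wv_n_valid"] = wv.n_valid
    return out


def estimate_all(
    trials: pd.DataFrame, options: AnalysisOptions | None = None
) -> pd.DataFrame:
    """One estimate row per participant x session x block."""
    rows = []
    for (pid, session, block_label), block in trials.groupby(
        ["participant", "session", "block"], sort=True
    ):
        try:
            est = estimate_block(block.sort_values("trial_index"), options)
        except estimators.InsufficientDataError as exc:
            raise PipelineError(
                f"estimate stage failed for participant {pid}, block {block_label}: {exc}"
            ) from exc
        rows.append(
            {"participant": pid, "session": session, "block": block_label, **est}
        )
    return pd.DataFrame(rows)


def sai_table(
    traces: dict[tuple[int, str], list], options: AnalysisOptions | None = None
) -> pd.DataFrame:
    """One SAI measure row per participant x session from raw MEP traces."""
    opts = options or AnalysisOptions()
    rows = []
    for (pid, session), trace_list in sorted(traces.items()):
        m = sai_mod.sai_from_traces(trace_list, tuple(opts.mep_window_ms))
        rows.append(
            {
                "participant": pid, "session": session,
                "sai_pre": m.sai_pre, "sai_post": m.sai_post,
                "delta_sai": m.delta_sai,
                "n_cond_pre": m.n_cond_pre, "n_uncond_pre": m.n_uncond_pre,
                "n_cond_post": m.n_cond_post, "n_uncond_post": m.n_uncond_post,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Analysis stage
# ---------------------------------------------------------------------------

def _test_to_dict(res: inference.TestResult) -> dict:
    out = {
        "statistic": res.statistic,
        "df": list(res.df) if isinstance(res.df, tuple) else res.df,
        "p": res.p,
        "method": res.method,
    }
    if res.effect_size is not None:
        out["effect_size"] = res.effect_size
    if res.pairwise is not None:
        out["pairwise"] = res.pairwise.to_dict(orient="records")
    return out


def _model_to_dict(fit: inference.ModelFit) -> dict:
    return {
        "terms": [dataclasses.asdict(t) for t in fit.terms],
        "vif": fit.vif,
        "n_participants": fit.n_participants,
        "n_observations": fit.n_observations,
        "converged": fit.converged,
        "random_intercept_sd": fit.random_intercept_sd,
    }


def sai_model_table(estimates: pd.DataFrame, sai_df: pd.DataFrame) -> pd.DataFrame:
    """Join per-session recalibration with delta-SAI for the multilevel model."""
    second = estimates[estimates.block.isin(["conflict", "veridical2"])]
    recal = second[["participant", "session", "recal_p_y", "recal_v_y"]].rename(
        columns={"recal_p_y": "recal_p", "recal_v_y": "recal_v"}
    )
    return recal.merge(
        sai_df[["participant", "session", "delta_sai"]], on=["participant", "session"]
    )


def analyze_expt1(estimates: pd.DataFrame, sai_df: pd.DataFrame) -> dict:
    table = sai_model_table(estimates, sai_df)
    fit = inference.fit_sai_recalibration_model(table)

    sai_long = sai_df.melt(
        id_vars=["participant", "session"], value_vars=["sai_pre", "sai_post"],
        var_name="time", value_name="sai",
    )
    anova = inference.rm_anova_2x2(sai_long, "participant", "session", "time", "sai")

    conflict = table[table.session == "conflict"]
    recal_corr = inference.pearson_r(conflict["recal_v"], conflict["recal_p"])

    residuals = {}
    for target, other in (("recal_p", "recal_v"), ("recal_v", "recal_p")):
        for session in ("conflict", "veridical"):
            sub = table[table.session == session].reset_index(drop=True)
            residuals[f"{session}_{target}"] = inference.predictor_residuals(
                sub, target, other
            )

    return {
        "summary": {
            "sai_recalibration_model": _model_to_dict(fit),
            "sai_session_by_time_anova": {k: _test_to_dict(v) for k, v in anova.items()},
            "recal_v_vs_recal_p_conflict": _test_to_dict(recal_corr),
            "mean_recal_p_conflict": float(conflict["recal_p"].mean()),
            "mean_recal_v_conflict": float(conflict["recal_v"].mean()),
        },
        "model_table": table,
        "residuals": residuals,
    }


def analyze_expt2(estimates: pd.DataFrame) -> dict:
    wide = estimates.pivot_table(
        index="participant", columns="block",
        values=["var_p_raw", "var_v_raw", "wv_mean", "recal_p_y", "recal_v_y",
                "recal_total_y"],
        aggfunc="first",
    )
    groups = (
        estimates.groupby("participant")["group"].first()
        if "group" in estimates.columns else None
    )
    if groups is None:
        raise PipelineError("analyze stage: expt2 estimates need a 'group' column")

    d_var_p = (wide[("var_p_raw", "veridical2")] - wide[("var_p_raw", "veridical1")])
    d_var_v = (wide[("var_v_raw", "veridical2")] - wide[("var_v_raw", "veridical1")])
    g = groups.loc[d_var_p.index].to_numpy()

    out: dict = {}
    out["delta_p_variance_group"] = _test_to_dict(
        inference.group_comparison(d_var_p.to_numpy(), g, "anova_tukey")
    )
    out["delta_v_variance_group"] = _test_to_dict(
        inference.group_comparison(d_var_v.to_numpy(), g, "kruskal_wallis")
    )
    for name in ("recal_p_y", "recal_v_y", "recal_total_y"):
        vals = wide[(name, "conflict")]
        out[f"{name}_group"] = _test_to_dict(
            inference.group_comparison(vals.to_numpy(), groups.loc[vals.index], "anova_tukey")
        )
    corr = {}
    conflict_p = wide[("recal_p_y", "conflict")]
    conflict_v = wide[("recal_v_y", "conflict")]
    for label in pd.unique(g):
        mask = groups.loc[conflict_p.index] == label
        corr[label] = _test_to_dict(
            inference.pearson_r(conflict_v[mask], conflict_p[mask])
        )
    out["recal_v_vs_recal_p_by_group"] = corr
    return {"summary": out}


def analyze_control(estimates: pd.DataFrame) -> dict:
    vshift = estimates[estimates.block == "vshift_control"]
    res = inference.one_sample_t(vshift["recal_v_y"].to_numpy(), 0.0)
    return {
        "summary": {
            "visual_recalibration_t": _test_to_dict(res),
            "mean_recal_v": float(vshift["recal_v_y"].mean()),
        }
    }


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """simulate -> estimate -> sai -> analyze, writing all artifacts.

    Returns the output directory.  All outputs are reproducible bit-for-bit
    from (config, seed); ``log.txt`` echoes both so any run can be replayed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = simulate_cohort(config.cohort_config())
    write_trials(cohort.trials, out / "trials.csv")
    cohort.truth.to_csv(out / "ground_truth.csv", index=False)

    estimates = estimate_all(cohort.trials, config.analysis)
    estimates.to_csv(out / "estimates.csv", index=False)

    sai_df = None
    if cohort.traces:
        write_traces(cohort.traces, out / "traces.csv")
        sai_df = sai_table(cohort.traces, config.analysis)
        sai_df.to_csv(out / "sai.csv", index=False)

    if config.experiment == "expt1":
        if sai_df is None:
            raise PipelineError("analyze stage: expt1 requires SAI traces")
        analysis = analyze_expt1(estimates, sai_df)
        analysis["model_table"].to_csv(out / "sai_model_table.csv", index=False)
        for name, frame in analysis["residuals"].items():
            frame.to_csv(out / f"residuals_{name}.csv", index=False)
    elif config.experiment == "expt2":
        analysis = analyze_expt2(
            estimates.merge(
                cohort.truth[["participant", "group"]], on="participant", how="left"
            )
        )
    else:
        analysis = analyze_control(estimates)

    summary = {
        "experiment": config.experiment,
        "seed": config.seed,
        "n_participants": int(cohort.truth["participant"].nunique()),
        "results": analysis["summary"],
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "log.txt", "w", encoding="utf-8") as fh:
        fh.write(f"master_seed: {config.seed}\n")
        fh.write("config:\n")
        fh.write(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return out
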