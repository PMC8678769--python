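"""End-to-end orchestration: simulate/load -> fit & select -> summarise -> associate."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort as cohort_mod
from .association import roc_auc, trajectory_association
from .gbtm import select_model
from .io import frame_from_series, series_from_frame, write_report_json
from .summary import ClockContext, summarize_patients

log = logging.getLogger("bptraj")

REFERENCE_GROUPS = {"SBP": 3, "DBP": 2}
OUTCOME_COLUMNS = ("end_24h", "eni_24h", "mrs_unfavorable")


@dataclass
class RunConfig:
    """Configuration for one full analysis run."""

    output_dir: str = "bptraj_out"
    bp_path: str | None = None
    covariates_path: str | None = None
    outcomes_path: str | None = None
    simulate: bool = True
    n_patients: int = 353
    channels: tuple = ("SBP", "DBP")
    j_range: tuple = (2, 6)
    order_policy: str = "full-quartic"
    orders: int = 4
    min_share: float = 0.05
    min_appa: float = 0.7
    reference_groups: dict = field(default_factory=lambda: dict(REFERENCE_GROUPS))
    screen_threshold: float = 0.1
    n_starts: int = 4
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.j_range
        if not (1 <= lo <= hi <= 10):
            raise ValueError("j_range must lie within [1, 10]")
        for thr in (self.min_share, self.min_appa, self.screen_threshold):
            if not 0.0 < thr < 1.0:
                raise ValueError("thresholds must be in (0, 1)")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write every artifact under output_dir.

    Stages: obtain data (simulate or load) -> per-channel group-count
    selection -> modal group assignment -> classic BP parameter table ->
    trajectory-group associations (models 1-3) and per-parameter AUCs ->
    report JSON with the config, seed, selection traces and stage timings.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings, report = {}, {"config": config.__dict__.copy(), "seed": config.seed}

    t0 = time.perf_counter()
    if config.simulate:
        cc = cohort_mod.CohortConfig(n_patients=config.n_patients)
        cohort = cohort_mod.simulate_cohort(cc, seed=config.seed)
        bp_long, covariates, outcomes = cohort.bp_long, cohort.covariates, cohort.outcomes
        bp_long.to_csv(out / "bp_long.csv", index=False)
        covariates.to_csv(out / "covariates.csv", index=False)
        outcomes.to_csv(out / "outcomes.csv", index=False)
        cohort.truth.to_csv(out / "truth.csv", index=False)
    else:
        bp_long = pd.read_csv(config.bp_path, dtype={"patient_id": str})
        covariates = pd.read_csv(config.covariates_path, dtype={"patient_id": str})
        outcomes = pd.read_csv(config.outcomes_path, dtype={"patient_id": str})
    timings["data"] = time.perf_counter() - t0

    assignments = {}
    report["channels"] = {}
    for channel in config.channels:
        t0 = time.perf_counter()
        series = series_from_frame(bp_long, channel=channel)
        sel = select_model(
            series, j_range=range(config.j_range[0], config.j_range[1] + 1),
            orders=config.orders, order_policy=config.order_policy,
            min_share=config.min_share, min_appa=config.min_appa,
            n_starts=config.n_starts, seed=config.seed,
        )
        res = sel.result
        res.coefficients_frame().to_csv(out / f"trajectories_{channel}.csv", index=False)
        assignments[channel] = pd.DataFrame({
            "patient_id": res.posterior.patient_ids,
            f"{channel.lower()}_group": res.posterior.assignments,
        })
        report["channels"][channel] = {
            "selection_trace": sel.trace.to_dict(orient="records"),
            "chosen_n_groups": sel.chosen,
            "adequate": sel.adequate,
            "fit": res.to_json_dict(),
        }
        timings[f"gbtm_{channel}"] = time.perf_counter() - t0
        log.info("channel %s: chose J=%d", channel, sel.chosen)

    t0 = time.perf_counter()
    all_series = series_from_frame(bp_long)
    summaries = summarize_patients(all_series, ClockContext())
    summaries.to_csv(out / "bp_parameters.csv", index=False)
    timings["summaries"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    assoc_rows, auc_rows = [], []
    merged = outcomes.merge(covariates, on="patient_id")
    for channel in config.channels:
        merged_ch = merged.merge(assignments[channel], on="patient_id")
        groups = merged_ch[f"{channel.lower()}_group"]
        ref = config.reference_groups.get(channel, 1)
        ref = ref if (groups == ref).any() else int(groups.mode()[0])
        for outcome in OUTCOME_COLUMNS:
            if outcome not in merged_ch.columns or merged_ch[outcome].nunique() < 2:
                continue
            tab = trajectory_association(
                groups, merged_ch[outcome],
                covariates=merged_ch[["age", "sex", "glucose"]],
                reference=ref, screen_threshold=config.screen_threshold,
            )
            tab.insert(0, "outcome", outcome)
            tab.insert(1, "channel", channel)
            assoc_rows.append(tab)
            auc = roc_auc(groups.to_numpy(), merged_ch[outcome].to_numpy(),
                          predictor=f"{channel} trajectory group")
            auc_rows.append({"predictor": auc.predictor, "outcome": outcome,
                             "auc": auc.auc, "ci_low": auc.ci_low,
                             "ci_high": auc.ci_high, "p": auc.p_value})
    # per-parameter AUCs over the 24-h window
    wide = summaries[summaries["window"] == "h24"]
    for channel in config.channels:
        ws = wide[wide["channel"] == channel].merge(outcomes, on="patient_id")
        for param in ("mean", "max", "min", "range", "sd", "sv"):
            for outcome in OUTCOME_COLUMNS:
                if outcome not in ws.columns or ws[outcome].nunique() < 2:
                    continue
                auc = roc_auc(ws[param].to_numpy(), ws[outcome].to_numpy(),
                              predictor=f"24h {channel} {param}")
                auc_rows.append({"predictor": auc.predictor, "outcome": outcome,
                                 "auc": auc.auc, "ci_low": auc.ci_low,
                                 "ci_high": auc.ci_high, "p": auc.p_value})
    if assoc_rows:
        pd.concat(assoc_rows, ignore_index=True).to_csv(out / "associations.csv", index=False)
    pd.DataFrame(auc_rows).to_csv(out / "auc.csv", index=False)
    timings["associations"] = time.perf_counter() - t0

    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    write_report_json(out / "report.json", report)
    return report
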