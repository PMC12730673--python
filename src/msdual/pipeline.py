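"""End-to-end study replica on synthetic data.

Orchestrates: simulate cohort -> preprocess -> build rest/task global
templates -> model-order selection -> backfit -> parameters and fit
metrics -> template comparison -> group statistics -> report bundle.
Every artifact embeds the configuration hash and seed so a run is fully
reproducible from its output directory.
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
import yaml

from . import simulate as sim
from .backfit import backfit, fit_metrics, microstate_parameters, smooth_segmentation, tidy_parameters
from .clustering import pool_global_template, select_k, extract_peak_maps
from .compare import (correlation_matrix, dual_template_comparison,
                      matched_pair_correlations, subject_class_mean_maps, tanova)
from .io import average_reference, bandpass_filter
from .stats import (anova_from_summary, anova_oneway, assumption_gate,
                    bonferroni_pairwise, GroupSummary, kruskal_wallis,
                    lmm_task_model)

log = logging.getLogger("msdual.pipeline")


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run (strict keys)."""

    # simulation
    group_sizes: dict = field(default_factory=lambda: dict(sim.GROUP_SIZES))
    rest_duration_s: float = 300.0
    fs: float = 250.0
    noise_level: float = 0.25
    conditions: tuple = ("V-O",)
    rest_s: float = 120.0
    task_s: float = 80.0
    post_rest_s: float = 120.0
    seed: int = 0
    # clustering
    n_classes: int = 4
    k_range: tuple | None = None  # e.g. (2, 7) to run model-order selection
    n_init: int = 10
    max_iter: int = 500
    tol: float = 1e-5
    peak_separation_ms: float = 10.0
    # backfit
    min_duration_ms: float = 30.0
    # statistics
    alpha: float = 0.05
    n_perm: int = 5000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["k_range"] = list(self.k_range) if self.k_range else None
        return d

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> dict:
    return {"config_hash": config.hash, "seed": config.seed,
            "config": config.to_dict()}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full study replica; write the report bundle to ``outdir``.

    Returns the statistics report as a dict (also written as JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings = {}

    def stage(name):
        log.info("stage=%s t=%.1fs", name, time.time() - t_start)
        timings[name] = time.time() - t_start

    rng_root = np.random.SeedSequence(config.seed)
    profiles = sim.doc_group_profiles()
    templates_true = sim.make_canonical_templates()
    scfg = sim.SimulationConfig(fs=config.fs, noise_level=config.noise_level,
                                rest_s=config.rest_s, task_s=config.task_s,
                                post_rest_s=config.post_rest_s, seed=config.seed)

    # --- simulate ------------------------------------------------------
    stage("simulate")
    cohort = sim.simulate_cohort(profiles, config.group_sizes, scfg,
                                 templates_true, config.rest_duration_s)
    task_sessions = {}
    task_seeds = rng_root.spawn(1)[0].spawn(
        sum(config.group_sizes.values()) * len(config.conditions))
    i = 0
    for group, n in config.group_sizes.items():
        for subj in range(n):
            for cond in config.conditions:
                rec, truth = sim.simulate_task_session(
                    profiles[group], cond, scfg, templates_true,
                    seed=task_seeds[i])
                task_sessions[(group, subj, cond)] = (rec, truth)
                i += 1
    pd.DataFrame(
        [{"group": g, "index": i} for i, (_, _, g) in enumerate(cohort)]
    ).to_csv(outdir / "cohort_manifest.csv", index=False)

    # --- preprocess (recordings are synthesized average-referenced) ----
    stage("preprocess")
    rest_recs = [average_reference(rec) for rec, _, _ in cohort]

    # --- templates -----------------------------------------------------
    stage("templates")
    tmpl_seed = int(rng_root.spawn(2)[1].generate_state(1)[0] % (2**31 - 1))
    rest_template = pool_global_template(
        rest_recs, K=config.n_classes,
        min_separation_ms=config.peak_separation_ms, n_init=config.n_init,
        max_iter=config.max_iter, tol=config.tol, seed=tmpl_seed,
        provenance="resting-global")
    # task template: task windows of all sessions pooled
    task_windows = []
    for (group, subj, cond), (rec, _) in task_sessions.items():
        win = rec.sample_window(config.rest_s, config.task_s)
        task_windows.append(dataclasses.replace(
            rec, data=win.copy(), annotations=[]))
    task_template = pool_global_template(
        task_windows, K=config.n_classes,
        min_separation_ms=config.peak_separation_ms, n_init=config.n_init,
        max_iter=config.max_iter, tol=config.tol, seed=tmpl_seed + 1,
        provenance="task-global")
    rest_template.to_frame().to_csv(outdir / "rest_template.csv")
    task_template.to_frame().to_csv(outdir / "task_template.csv")

    cv_curve = None
    if config.k_range:
        stage("model-order")
        pooled = np.vstack([extract_peak_maps(r, config.peak_separation_ms)
                            for r in rest_recs[:4]])
        k_star, cv_curve = select_k(pooled, range(config.k_range[0],
                                                  config.k_range[1] + 1),
                                    n_init=config.n_init, seed=tmpl_seed)
        cv_curve.to_csv(outdir / "cv_curve.csv")
    else:
        k_star = config.n_classes

    # --- backfit rest --------------------------------------------------
    stage("backfit-rest")
    tidy_frames = []
    for idx, ((rec, truth, group), prec) in enumerate(zip(cohort, rest_recs)):
        seg = backfit(prec, rest_template)
        seg = smooth_segmentation(seg, prec, rest_template, config.min_duration_ms)
        params = microstate_parameters(seg, prec)
        fm = fit_metrics(seg, prec, rest_template)
        tf = tidy_parameters(params, labels=list(rest_template.labels),
                             subject=f"{group}-{idx}", group=group,
                             condition="rest", template="rest")
        tidy_frames.append(tf)
        tidy_frames.append(pd.DataFrame([
            {"class": "all", "metric": "r2", "value": fm.r2,
             "subject": f"{group}-{idx}", "group": group,
             "condition": "rest", "template": "rest"},
            {"class": "all", "metric": "residual_sd", "value": fm.residual_sd,
             "subject": f"{group}-{idx}", "group": group,
             "condition": "rest", "template": "rest"},
        ]))
    tidy = pd.concat(tidy_frames, ignore_index=True)

    # --- backfit task sessions against the resting template ------------
    stage("backfit-task")
    task_rows = []
    for (group, subj, cond), (rec, _) in task_sessions.items():
        prec = average_reference(rec)
        seg = backfit(prec, rest_template)
        seg = smooth_segmentation(seg, prec, rest_template, config.min_duration_ms)
        d_idx = list(rest_template.labels).index("D") if "D" in rest_template.labels else 3
        fs = prec.fs
        lab = seg.labels
        def window_cov(onset, dur):
            i0, i1 = int(onset * fs), int((onset + dur) * fs)
            w = lab[i0:i1]
            assigned = w >= 0
            return 100.0 * np.mean(w[assigned] == d_idx) if assigned.any() else np.nan
        rest_cov = window_cov(0, config.rest_s)
        task_cov = window_cov(config.rest_s, config.task_s)
        post_cov = window_cov(config.rest_s + config.task_s, config.post_rest_s)
        task_rows.append({"group": group, "subject": f"{group}-{subj}",
                          "condition": cond, "rest_coverage_D": rest_cov,
                          "task_coverage_D": task_cov,
                          "post_coverage_D": post_cov,
                          "value": task_cov - rest_cov})
    task_table = pd.DataFrame(task_rows)
    task_table.to_csv(outdir / "task_modulation.csv", index=False)
    tidy.to_csv(outdir / "parameters_tidy.csv", index=False)

    # --- template comparison -------------------------------------------
    stage("compare")
    corr = correlation_matrix(rest_template, task_template)
    corr.to_csv(outdir / "template_correlations.csv")
    matched = matched_pair_correlations(rest_template, task_template)
    mean_maps = subject_class_mean_maps(
        [(average_reference(rec), group)
         for (group, subj, cond), (rec, _) in task_sessions.items()],
        rest_template, config.min_duration_ms)
    tanova_results = {}
    tan_seed = int(rng_root.spawn(3)[2].generate_state(1)[0] % (2**31 - 1))
    for label in rest_template.labels:
        cls_maps = mean_maps[mean_maps["class"] == label]
        hc = np.vstack(cls_maps[cls_maps["group"] == "HC"]["map"].to_numpy()) \
            if (cls_maps["group"] == "HC").sum() >= 2 else None
        doc = np.vstack(cls_maps[cls_maps["group"] != "HC"]["map"].to_numpy()) \
            if (cls_maps["group"] != "HC").sum() >= 2 else None
        if hc is not None and doc is not None:
            tanova_results[label] = tanova(hc, doc, n_perm=config.n_perm,
                                           seed=tan_seed)
    vo_recs = {}
    for (group, subj, cond), (rec, _) in task_sessions.items():
        if cond == "V-O":
            vo_recs.setdefault(group, []).append(average_reference(rec))
    dual_tidy, dual_tests = (pd.DataFrame(), pd.DataFrame())
    if vo_recs and all(len(v) >= 2 for v in vo_recs.values()):
        dual_tidy, dual_tests = dual_template_comparison(
            vo_recs, rest_template, task_template, config.min_duration_ms,
            config.alpha)
        dual_tidy.to_csv(outdir / "dual_template_tidy.csv", index=False)
        dual_tests.to_csv(outdir / "dual_template_tests.csv", index=False)

    # --- group statistics ----------------------------------------------
    stage("stats")
    stats_report = {}
    for (label, metric), cell in tidy[tidy["class"] != "all"].groupby(
            ["class", "metric"]):
        samples = {g: grp["value"].to_numpy()
                   for g, grp in cell.groupby("group")}
        if len(samples) < 2 or any(len(v) < 2 for v in samples.values()):
            continue
        route = assumption_gate(samples, config.alpha)
        if route == "parametric":
            res = anova_oneway(samples)
            posthoc = (bonferroni_pairwise(samples, "t")
                       if res.p < config.alpha else None)
        else:
            res = kruskal_wallis(samples, config.alpha)
            posthoc = res.posthoc
        stats_report[f"{label}/{metric}"] = {
            "route": route, "test": res.name, "statistic": res.statistic,
            "df": list(res.df), "p": res.p, res.effect_name: res.effect,
            "posthoc": posthoc.to_dict("records") if posthoc is not None else None,
        }

    lmm_report = None
    if task_table["condition"].nunique() >= 2:
        try:
            lmm = lmm_task_model(task_table)
            lmm_report = {
                "interaction_F": lmm["interaction"].statistic,
                "interaction_df": list(lmm["interaction"].df),
                "interaction_p": lmm["interaction"].p,
                "contrasts": lmm["contrasts"].to_dict("records"),
            }
        except ValueError as exc:
            lmm_report = {"error": str(exc)}

    # group summaries of Microstate-D coverage (ordering check)
    d_cov = tidy[(tidy["class"] == "D") & (tidy["metric"] == "coverage")]
    group_means = d_cov.groupby("group")["value"].mean().to_dict()

    report = {
        "provenance": _provenance(config),
        "k_selected": int(k_star),
        "template_match": {
            "rest": rest_template.match_scores,
            "task": task_template.match_scores,
            "rest_vs_task_matched_abs_r": matched.to_dict(),
        },
        "tanova": tanova_results,
        "rest_statistics": stats_report,
        "task_lmm": lmm_report,
        "task_modulation_means": task_table.groupby(
            ["group", "condition"])["value"].mean().unstack().to_dict(),
        "microstate_D_coverage_group_means": group_means,
    }
    with open(outdir / "statistics.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    stage("done")
    # timings go in a separate run log so statistics.json stays
    # byte-reproducible for a given config + seed
    with open(outdir / "run_log.json", "w") as fh:
        json.dump({"provenance": _provenance(config),
                   "stage_start_s": {k: round(v, 3) for k, v in timings.items()}},
                  fh, indent=2)
    return report
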