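"""End-to-end pipeline orchestration.

Runs gate -> select -> permute -> stratify -> ebm-fit -> ebm-stage -> report
on either a simulated cohort or a cohort CSV, logging every stage's seed and
writing all artifacts plus a deterministic report hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import ebm as ebm_mod
from .cohort import (
    GROUP_AD,
    GROUP_ASYMAD,
    GROUP_CONTROL,
    SUBTYPE_AD_LIKE,
    SUBTYPE_CONTROL_LIKE,
    CohortError,
    CohortTable,
    read_cohort,
    write_cohort,
)
from .gating import assign_groups, fit_ratio_mixture
from .metrics import percent
from .panel import SelectionConfig, permutation_test, select_panel
from .stratify import (
    EmbeddingConfig,
    apoe_enrichment,
    stability_stratify,
)
from .synthetic import default_config, generate_cohort

log = logging.getLogger(__name__)


DEFAULT_PIPELINE_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {"n_control": 134, "n_asymad": 134, "n_ad": 134},
    "input_csv": None,
    "selection": {"train_fraction": 0.8, "rfe_stop_size": 14},
    "n_permutations": 200,
    "embedding": {"n_repeats": 10, "k_neighbors": 5, "tsne_max_iter": 250},
    "ebm": {"fast": True},
    "out_dir": None,
}


def _config_hash(config: Mapping[str, Any]) -> str:
    # out_dir is location metadata, not analysis configuration
    hashable = {k: v for k, v in config.items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(hashable, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Execute the full analysis; returns the artifact bundle.

    Every stage is seeded from the master seed and logs its configuration
    hash. Failures halt with the stage name attached.
    """
    cfg: dict[str, Any] = {**DEFAULT_PIPELINE_CONFIG, **(config or {})}
    seed = int(cfg["seed"])
    out_dir = Path(cfg["out_dir"]) if cfg["out_dir"] else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start seed=%d config=%s", seed, _config_hash(cfg))
    artifacts: dict[str, Any] = {"config": cfg, "config_hash": _config_hash(cfg)}

    def stage(name):
        def wrap(fn):
            try:
                log.info("stage %s (seed=%d)", name, seed)
                return fn()
            except Exception as exc:
                raise CohortError(f"pipeline stage {name!r} failed: {exc}") \
                    from exc
        return wrap

    # -- input ------------------------------------------------------------
    if cfg["input_csv"]:
        table = read_cohort(cfg["input_csv"])
    else:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", seed)
        table, truth = generate_cohort(default_config(**sim))
        artifacts["ground_truth"] = truth
    if out_dir:
        write_cohort(table, out_dir / "cohort.csv")

    # -- gate -------------------------------------------------------------
    @stage("gate")
    def gated():
        ratios = table.ratio()
        cutoff = fit_ratio_mixture(ratios, seed=seed)
        status = np.where(table.data["group_label"] == GROUP_AD,
                          "symptomatic", "CN")
        labels = assign_groups(table, status, ratio_cutoff=cutoff)
        return cutoff, labels

    cutoff, labels = gated
    artifacts["ratio_cutoff"] = cutoff
    keep = labels["assignment"].isin([GROUP_CONTROL, GROUP_ASYMAD, GROUP_AD])
    gated_table = table.subset(keep.to_numpy())
    gated_table.data["group_label"] = labels.loc[keep, "assignment"].to_numpy()
    gated_table = CohortTable(gated_table.data, gated_table.peptide_columns)
    artifacts["gate_labels"] = labels
    if out_dir:
        labels.to_csv(out_dir / "labels.csv", index=False)
        (out_dir / "cutoff.json").write_text(cutoff.to_json())

    # -- select -----------------------------------------------------------
    @stage("select")
    def panel_result():
        sel = SelectionConfig(seed=seed, **{
            k: v for k, v in cfg["selection"].items()})
        return select_panel(gated_table, sel)

    artifacts["panel"] = panel_result
    if out_dir:
        panel_result.to_json(out_dir / "panel.json")

    # -- permute ----------------------------------------------------------
    @stage("permute")
    def null():
        sel = SelectionConfig(seed=seed, **{
            k: v for k, v in cfg["selection"].items()})
        from .panel import split_train_test
        train_ids, test_ids = split_train_test(gated_table, sel)
        return permutation_test(
            panel_result.final_panel, gated_table, train_ids, test_ids,
            panel_result.scaler, n_draws=int(cfg["n_permutations"]), seed=seed)

    artifacts["permutation"] = null
    if out_dir:
        pd.DataFrame(null.distributions).to_csv(
            out_dir / "permutation_null.csv", index=False)
        (out_dir / "permutation.json").write_text(json.dumps(
            {"p_values": null.p_values, "observed": null.observed,
             "n_draws": null.n_draws}, indent=2))

    # -- stratify ---------------------------------------------------------
    @stage("stratify")
    def strat():
        emb = EmbeddingConfig(seed=seed, **{
            k: v for k, v in cfg["embedding"].items()})
        return stability_stratify(gated_table, panel_result.final_panel,
                                  panel_result.scaler, emb)

    artifacts["stratification"] = strat
    if out_dir:
        strat.to_frame().to_csv(out_dir / "strat.csv", index=False)

    @stage("apoe")
    def apoe():
        asym = gated_table.by_group(GROUP_ASYMAD)
        geno = asym.data.set_index(
            asym.data["subject_id"].astype(str)).loc[strat.subject_ids, "apoe"]
        return apoe_enrichment(strat.consensus, geno.tolist())

    artifacts["apoe"] = apoe

    # -- ebm fit + stage --------------------------------------------------
    @stage("ebm-fit")
    def fit():
        ebm_cfg_in = dict(cfg["ebm"])
        fast = ebm_cfg_in.pop("fast", False)
        n_bio = len(panel_result.final_panel)
        size = 2 if n_bio % 2 == 0 else 1
        ebm_cfg_in.setdefault("n_clusters", n_bio // size)
        ebm_cfg_in.setdefault("cluster_size", size)
        ebm_cfg_in.setdefault("seed", seed)
        ebm_cfg = (ebm_mod.fast_config(**ebm_cfg_in) if fast
                   else ebm_mod.EbmConfig(**ebm_cfg_in))
        train = gated_table.by_group(GROUP_CONTROL, GROUP_AD)
        idx = [panel_result.scaler.columns.index(p)
               for p in panel_result.final_panel]
        from .panel import _rows
        X = panel_result.scaler.transform(
            _rows(train, train.subject_ids))[:, idx]
        return ebm_mod.fit_ebm(X, train.group_labels, ebm_cfg,
                               panel_result.final_panel)

    artifacts["ebm_fit"] = fit
    if out_dir:
        np.savetxt(out_dir / "positional_variance.csv",
                   fit.positional_variance, delimiter=",")

    @stage("ebm-stage")
    def staged():
        from .panel import _rows
        idx = [panel_result.scaler.columns.index(p)
               for p in panel_result.final_panel]
        X = panel_result.scaler.transform(
            _rows(gated_table, gated_table.subject_ids))[:, idx]
        return ebm_mod.stage_subjects(fit, X)

    artifacts["stages"] = staged

    @stage("report")
    def report():
        subtype = dict(zip(strat.subject_ids, strat.consensus))
        fine = [subtype.get(sid, g) for sid, g in
                zip(gated_table.subject_ids, gated_table.group_labels)]
        stages = staged.ml_stage
        chi2, p = ebm_mod.stage_distribution_test(stages, fine)
        frac_rows = []
        n_stages = staged.probabilities.shape[1]
        for g in sorted(set(fine)):
            mask = np.array([f == g for f in fine])
            total = int(mask.sum())
            for s in range(n_stages):
                cnt = int((stages[mask] == s).sum())
                frac_rows.append({"group": g, "stage": s, "count": cnt,
                                  "fraction": cnt / total if total else 0.0,
                                  "percent": percent(cnt, total)
                                  if total else 0.0})
        mean_stage = {g: float(stages[[f == g for f in fine]].mean())
                      for g in sorted(set(fine))}
        rep = {
            "seed": seed,
            "config_hash": artifacts["config_hash"],
            "ratio_cutoff": cutoff.cutoff,
            "panel": panel_result.final_panel,
            "heldout_metrics": {
                **panel_result.heldout_metrics.rates,
                "roc_auc": panel_result.heldout_metrics.roc_auc},
            "permutation_p": null.p_values,
            "apoe_p_allele": apoe["p_allele"],
            "stage_chi2": chi2, "stage_p": p,
            "mean_stage_by_group": mean_stage,
            "stage_fractions": frac_rows,
        }
        return rep

    artifacts["report"] = report
    payload = json.dumps(report, sort_keys=True, default=float)
    artifacts["report_hash"] = hashlib.sha256(payload.encode()).hexdigest()
    if out_dir:
        (out_dir / "report.json").write_text(payload)
        pd.DataFrame(report["stage_fractions"]).to_csv(
            out_dir / "stage_fractions.csv", index=False)
        (out_dir / "report_hash.txt").write_text(artifacts["report_hash"])
    log.info("pipeline done; report hash %s", artifacts["report_hash"])
    return artifacts
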