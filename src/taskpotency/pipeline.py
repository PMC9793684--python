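"""Pipeline orchestration: simulate -> connectome -> harmonize -> normative
-> cross-task -> CCA -> report.

Each stage reads its inputs from, and writes its outputs to, a working
directory, so any stage can be re-run from saved intermediates and the CLI
verbs map one-to-one onto stage functions.  Subjects missing a condition's
time series are excluded from that task only (logged).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate as sim
from .behavior import impute_behavior_rf, BEHAVIOR_SCALES
from .cca import BrainBehaviorCCA
from .config import PipelineConfig, stage_seed
from .connectome import (EdgeTable, normalized_connectivity, task_potency,
                         vectorize_edges)
from .crosstask import compare_similarity, group_mean_pattern, task_similarity_matrix
from .harmonize import combat_harmonize
from .normative import (NormativePotencyModel, DevianceTable,
                        atypicality_percentages, bh_fdr, compare_groups,
                        td_crossval_deviations)
from .regions import Atlas, region_scores, top_regions

logger = logging.getLogger(__name__)


def _workdir(config: PipelineConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(config: PipelineConfig) -> None:
    """Generate and write the synthetic cohort, behavior, atlas and time series."""
    wd = _workdir(config)
    cfg = config.sim
    seed = stage_seed(config.master_seed, "simulate")
    cohort = sim.generate_cohort(cfg, seed)
    gt = sim.generate_ground_truth(cfg, seed)
    behavior, truth = sim.generate_behavior(cohort, cfg, seed)
    cohort.to_csv(wd / "cohort.csv", index=False)
    behavior.to_csv(wd / "behavior.csv")
    truth.to_csv(wd / "behavior_truth.csv")
    Atlas.synthetic(cfg.n_regions, cfg.n_networks).to_tsv(wd / "atlas.tsv")
    sim.write_ground_truth(gt, cfg, wd / "ground_truth")
    ts_dir = wd / "timeseries"
    for condition in cfg.conditions:
        cdir = ts_dir / condition
        cdir.mkdir(parents=True, exist_ok=True)
        for _, row in cohort.iterrows():
            ts = sim.simulate_condition_timeseries(row, condition, gt, cfg, seed)
            sim.write_timeseries(ts, cdir / f"{row['subject_id']}.tsv")
    logger.info("simulated %d subjects x %d conditions", len(cohort),
                len(cfg.conditions))


def stage_connectome(config: PipelineConfig) -> None:
    """Time series -> normalized connectivity -> task potency edge tables."""
    wd = _workdir(config)
    cohort = pd.read_csv(wd / "cohort.csv")
    conditions = list(config.sim.conditions)
    tasks = [c for c in conditions if c != "rest"]
    ts_dir = wd / "timeseries"

    normalized = {}
    fits = {}
    for condition in conditions:
        for sid in cohort["subject_id"]:
            path = ts_dir / condition / f"{sid}.tsv"
            if not path.exists():
                logger.info("missing %s time series for %s; excluded from that task",
                            condition, sid)
                continue
            ts = pd.read_csv(path, sep="\t").to_numpy(float)
            m, fit, shrink = normalized_connectivity(ts, sid, condition)
            normalized[(condition, sid)] = m
            fits[f"{sid}/{condition}"] = {**fit.to_dict(), "shrinkage": shrink}
    (wd / "mixture_fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))

    for task in tasks:
        mats = []
        for sid in cohort["subject_id"]:
            tm = normalized.get((task, sid))
            rm = normalized.get(("rest", sid))
            if tm is None or rm is None:
                continue
            mats.append(task_potency(tm, rm))
        vectorize_edges(mats, task=task).to_tsv(wd / f"edges_{task}.tsv")
    logger.info("potency edge tables written for %d tasks", len(tasks))


def stage_harmonize(config: PipelineConfig) -> None:
    """ComBat site harmonization of each task's potency edge table."""
    wd = _workdir(config)
    cohort = pd.read_csv(wd / "cohort.csv").set_index("subject_id")
    models = {}
    for path in sorted(wd.glob("edges_*.tsv")):
        task = path.stem.replace("edges_", "")
        edges = EdgeTable.from_tsv(path, task)
        meta = cohort.loc[edges.subject_ids]
        harmonized, model = combat_harmonize(
            edges, meta["site"].to_numpy(),
            meta[["age", "sex", "group"]].reset_index(drop=True),
            return_model=True)
        harmonized.to_tsv(wd / f"edges_harmonized_{task}.tsv")
        models[task] = model
    (wd / "harmonization.json").write_text(json.dumps(models, indent=2,
                                                      sort_keys=True))


def _load_harmonized(wd: Path) -> dict:
    out = {}
    for path in sorted(wd.glob("edges_harmonized_*.tsv")):
        task = path.stem.replace("edges_harmonized_", "")
        out[task] = EdgeTable.from_tsv(path, task)
    return out


def stage_normative(config: PipelineConfig) -> None:
    """Per-task normative deviation Z-scores and case-control comparison."""
    wd = _workdir(config)
    cohort = pd.read_csv(wd / "cohort.csv").set_index("subject_id")
    seed = stage_seed(config.master_seed, "normative")
    comparisons = []
    for task, edges in sorted(_load_harmonized(wd).items()):
        meta = cohort.loc[edges.subject_ids].reset_index()
        is_td = (meta["group"] == "td").to_numpy()
        td_rows = np.flatnonzero(is_td)
        aut_rows = np.flatnonzero(~is_td)
        td_tab = EdgeTable(task, [edges.subject_ids[i] for i in td_rows],
                           edges.edge_index, edges.values[td_rows])
        td_dev = td_crossval_deviations(
            td_tab, meta.loc[td_rows, ["age", "sex"]],
            k=min(config.normative_folds, len(td_rows)), seed=seed,
            basis=config.normative_basis)
        full = NormativePotencyModel(td_tab.values,
                                     meta.loc[td_rows, ["age", "sex"]]
                                     .reset_index(drop=True),
                                     basis=config.normative_basis).fit()
        full.dump(wd / f"normative_model_{task}.tsv",
                  wd / f"normative_model_{task}.json")
        aut_dev = full.deviation_scores(
            edges.values[aut_rows],
            meta.loc[aut_rows, ["age", "sex"]].reset_index(drop=True))
        aut_dev = DevianceTable(task, [edges.subject_ids[i] for i in aut_rows],
                                aut_dev.z, aut_dev.provenance)
        dev = DevianceTable(task, aut_dev.subject_ids + td_dev.subject_ids,
                            np.vstack([aut_dev.z, td_dev.z]),
                            aut_dev.provenance + td_dev.provenance)
        dev.to_tsv(wd / f"deviations_{task}.tsv")
        perc_a = atypicality_percentages(aut_dev, config.z_threshold)
        perc_t = atypicality_percentages(td_dev, config.z_threshold)
        comparisons.append(compare_groups(perc_a, perc_t, task=task,
                                          welch=config.welch))
        pd.DataFrame({"subject_id": dev.subject_ids,
                      "percent_atypical":
                          np.concatenate([perc_a, perc_t])}).to_csv(
            wd / f"percent_atypical_{task}.csv", index=False)
    qs = bh_fdr([c.p for c in comparisons])
    rows = []
    for c, q in zip(comparisons, qs):
        c.q = float(q)
        rows.append(c.to_dict())
    (wd / "group_comparisons.json").write_text(json.dumps(rows, indent=2,
                                                          sort_keys=True))


def _load_deviations(wd: Path) -> dict:
    out = {}
    for path in sorted(wd.glob("deviations_*.tsv")):
        task = path.stem.replace("deviations_", "")
        df = pd.read_csv(path, sep="\t", index_col=0)
        out[task] = DevianceTable(task, list(df.index.astype(str)),
                                  df.to_numpy(float))
    return out


def stage_crosstask(config: PipelineConfig) -> None:
    """Cross-task similarity matrices per group and their Wilcoxon comparison."""
    wd = _workdir(config)
    cohort = pd.read_csv(wd / "cohort.csv").set_index("subject_id")
    devs = _load_deviations(wd)
    sims = {}
    for group in ("autism", "td"):
        members = set(cohort.index[cohort["group"] == group])
        patterns = {}
        for task, dev in sorted(devs.items()):
            subs = [s for s in dev.subject_ids if s in members]
            patterns[task] = group_mean_pattern(dev, subs,
                                                signed=config.signed_pattern)
        sims[group] = task_similarity_matrix(patterns, group=group)
        sims[group].to_frame().to_csv(wd / f"similarity_{group}.csv")
    wil = compare_similarity(sims["autism"], sims["td"])
    out = {"statistic": wil.statistic, "p": wil.p, "n_pairs": wil.n_pairs,
           "differences": wil.differences.tolist(),
           "mean_offdiag_autism": sims["autism"].mean_off_diagonal(),
           "mean_offdiag_td": sims["td"].mean_off_diagonal()}
    (wd / "crosstask.json").write_text(json.dumps(out, indent=2, sort_keys=True))


def stage_cca(config: PipelineConfig) -> None:
    """Per-task out-of-sample CCA between autism deviations and behavior."""
    wd = _workdir(config)
    cohort = pd.read_csv(wd / "cohort.csv").set_index("subject_id")
    behavior = pd.read_csv(wd / "behavior.csv", index_col=0)[list(BEHAVIOR_SCALES)]
    seed = stage_seed(config.master_seed, "cca")
    imputed = impute_behavior_rf(behavior, seed=stage_seed(config.master_seed,
                                                           "behavior"))
    results = {}
    for task, dev in sorted(_load_deviations(wd).items()):
        aut = [s for s in dev.subject_ids
               if cohort.loc[s, "group"] == "autism" and s in imputed.index]
        idx = [dev.subject_ids.index(s) for s in aut]
        model = BrainBehaviorCCA(
            dev.z[idx], imputed.loc[aut], site=cohort.loc[aut, "site"].to_numpy(),
            k=config.pca_components, n_splits=config.cv_splits,
            k_folds=config.cv_folds, n_permutations=config.permutations,
            percentile=config.significance_percentile,
            global_pca=config.global_pca, task=task)
        res = model.fit(seed=seed)
        d = res.to_dict()
        np.savetxt(wd / f"cca_edge_weights_{task}.tsv", res.edge_weights,
                   delimiter="\t")
        results[task] = d
    (wd / "cca_results.json").write_text(json.dumps(results, indent=2,
                                                    sort_keys=True))


def stage_report(config: PipelineConfig) -> dict:
    """Aggregate stage outputs into one machine-readable report."""
    wd = _workdir(config)
    atlas = Atlas.from_tsv(wd / "atlas.tsv")
    cohort = pd.read_csv(wd / "cohort.csv").set_index("subject_id")
    devs = _load_deviations(wd)
    report = {"config": {"z_threshold": config.z_threshold,
                         "pca_components": config.pca_components,
                         "master_seed": config.master_seed},
              "tasks": {}}
    comparisons = json.loads((wd / "group_comparisons.json").read_text())
    cca = json.loads((wd / "cca_results.json").read_text()) \
        if (wd / "cca_results.json").exists() else {}
    for task, dev in sorted(devs.items()):
        aut = [s for s in dev.subject_ids if cohort.loc[s, "group"] == "autism"]
        pattern = group_mean_pattern(dev, aut)
        scores = region_scores(pattern, atlas)
        top = top_regions(scores, config.top_region_fraction)
        entry = {
            "n_autism": len(aut),
            "n_td": len(dev.subject_ids) - len(aut),
            "top_regions": [atlas.names[i] for i in top],
            "region_scores": np.round(scores, 10).tolist(),
        }
        comp = [c for c in comparisons if c["task"] == task]
        if comp:
            entry["group_comparison"] = comp[0]
        if task in cca:
            entry["cca"] = {k: cca[task][k] for k in
                            ("canonical_corrs", "behavior_weights",
                             "behavioral_loadings", "test_mean", "null_95",
                             "significant", "weight_stability_mean")}
        report["tasks"][task] = entry
    if (wd / "crosstask.json").exists():
        report["crosstask"] = json.loads((wd / "crosstask.json").read_text())
    (wd / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


STAGES = {
    "simulate": stage_simulate,
    "connectome": stage_connectome,
    "harmonize": stage_harmonize,
    "normative": stage_normative,
    "crosstask": stage_crosstask,
    "cca": stage_cca,
    "report": stage_report,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the final report dictionary."""
    for name, fn in STAGES.items():
        logger.info("stage %s", name)
        try:
            out = fn(config)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
    return out
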