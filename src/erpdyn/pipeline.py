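"""Declarative run configuration and the end-to-end pipeline driver.

Stage order: simulate (optional) -> preprocess -> ERP components -> windowed
topographies -> trajectory state space (+ bootstrap) -> dominant states ->
state sequences/transitions -> classification -> group statistics.  All
randomness derives from the single master seed: the generator uses ``seed``,
the bootstrap ``seed + 1`` and the classifier ``seed + 2``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import io as eio
from . import sequences as seqmod
from . import states as dsmod
from . import state_space as ssmod
from . import stats as gst
from . import topo as topomod
from .components import N200, P300, component_amplitude, component_latency, \
    intertrial_topographic_similarity
from .containers import CONDITIONS, GROUPS, EpochSet
from .errors import InvalidArgumentError
from .preprocess import condition_average, preprocess_epochs, window_means
from .synthetic import GeneratorConfig, simulate_cohort


@dataclass
class RunConfig:
    """All stage parameters in one declarative object."""

    simulate: bool = True
    input_dir: Optional[str] = None
    generator: Dict = field(default_factory=dict)
    filter_band: Optional[Tuple[float, float]] = None
    baseline_ms: Tuple[float, float] = (-200.0, 0.0)
    reject_uv: float = 500.0
    k_states: int = 4
    alpha: float = 0.05
    fdr_q: float = 0.05
    folds: int = 10
    cv_repeats: int = 50
    feature_windows: bool = False
    bootstrap_iterations: int = 200
    n_per_group: int = 15
    seed: int = 0

    _FIELDS = None  # filled below

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        if doc is None:
            doc = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        if "filter_band" in doc and doc["filter_band"] is not None:
            doc["filter_band"] = tuple(doc["filter_band"])
        if "baseline_ms" in doc:
            doc["baseline_ms"] = tuple(doc["baseline_ms"])
        return cls(**doc)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d.pop("_FIELDS", None)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def _matrix_csv(mat: np.ndarray, rows, cols, path: Path) -> None:
    df = pd.DataFrame(mat, index=rows, columns=cols)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format="%.10g")


def run_pipeline(config: RunConfig, out_dir: Union[str, Path]) -> Dict:
    """Execute every stage; returns the summary dict (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: Dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    # wall-clock timings go to a separate file so summary.json stays
    # deterministic across reruns
    timings: Dict[str, float] = {}

    def stage(name):
        rec = summary["stages"].setdefault(name, {})
        rec["_name"] = name
        timings[name] = time.time()
        return rec

    def done(rec, **counts):
        name = rec.pop("_name")
        timings[name] = round(time.time() - timings[name], 3)
        rec.update(counts)

    # --- input -----------------------------------------------------------
    rec = stage("input")
    if config.simulate:
        gen = GeneratorConfig(**{**config.generator, "seed": config.seed})
        epochsets, clinical, truth = simulate_cohort(gen)
        eio.write_clinical(out / "clinical.csv", clinical)
        eio.write_ground_truth(out / "ground_truth.json", truth)
    else:
        if not config.input_dir:
            raise InvalidArgumentError("input_dir required when simulate is false")
        epochsets = eio.read_cohort(config.input_dir)
        clin_path = Path(config.input_dir) / "clinical.csv"
        clinical = eio.read_clinical(clin_path) if clin_path.exists() else None
    done(rec, epochsets=len(epochsets))

    # --- preprocess + ERPs ----------------------------------------------
    rec = stage("preprocess")
    erps: Dict[Tuple[str, str], "object"] = {}
    groups_of: Dict[str, str] = {}
    n_rejected = 0
    epochs_by_key: Dict[Tuple[str, str], EpochSet] = {}
    for ep in epochsets:
        clean, rejected = preprocess_epochs(
            ep, filter_band=config.filter_band,
            baseline_window_ms=config.baseline_ms, reject_uv=config.reject_uv,
        )
        n_rejected += len(rejected)
        epochs_by_key[(ep.subject_id, ep.condition)] = clean
        erps[(ep.subject_id, ep.condition)] = condition_average(clean)
        groups_of[ep.subject_id] = ep.group
    # drop subjects missing a condition
    complete = [s for s in groups_of
                if all((s, c) in erps for c in CONDITIONS)]
    dropped = sorted(set(groups_of) - set(complete))
    if dropped:
        erps = {k: v for k, v in erps.items() if k[0] in complete}
        epochs_by_key = {k: v for k, v in epochs_by_key.items() if k[0] in complete}
    subjects = sorted(complete)
    done(rec, subjects=len(subjects), trials_rejected=n_rejected,
         subjects_dropped=len(dropped))

    # --- ERP components --------------------------------------------------
    rec = stage("components")
    comp_rows = []
    for sid in subjects:
        for spec in (N200, P300):
            erp = erps[(sid, spec.condition)]
            amp = component_amplitude(erp, spec)
            lat = component_latency(erp, spec)
            sim = intertrial_topographic_similarity(
                epochs_by_key[(sid, spec.condition)], spec
            )
            for ch, a, l in zip(erp.channel_names, amp, lat):
                comp_rows.append({
                    "subject": sid, "group": groups_of[sid],
                    "condition": spec.condition, "component": spec.name,
                    "channel": ch, "amplitude_uv": a, "latency_ms": l,
                    "similarity": sim,
                })
    _write_csv(pd.DataFrame(comp_rows), out / "components.csv")
    done(rec, rows=len(comp_rows))

    # --- windowed topographies ------------------------------------------
    rec = stage("topo")
    subj_seqs: Dict[str, Dict[str, "object"]] = {}
    for sid in subjects:
        subj_seqs[sid] = {c: window_means(erps[(sid, c)]) for c in CONDITIONS}
    group_seqs: Dict[Tuple[str, str], "object"] = {}
    for g in GROUPS:
        members = [s for s in subjects if groups_of[s] == g]
        if not members:
            continue
        for c in CONDITIONS:
            gm = topomod.group_mean_toposequence([subj_seqs[s][c] for s in members])
            gm.group, gm.condition = g, c
            group_seqs[(g, c)] = gm
    topo_dir = out / "topo"
    windows = [f"T{i}" for i in range(1, 7)]
    for c in CONDITIONS:
        for g in ("ADHD-I", "ADHD-C"):
            if (g, c) in group_seqs and ("TD", c) in group_seqs:
                cm = topomod.cross_corr_matrix(
                    group_seqs[(g, c)], group_seqs[("TD", c)], fdr_q=config.fdr_q
                )
                _matrix_csv(cm.r, windows, windows, topo_dir / f"corr_{g}_vs_TD_{c}.csv")
        for g in GROUPS:
            if (g, c) in group_seqs:
                cm = topomod.cross_corr_matrix(
                    group_seqs[(g, c)], group_seqs[(g, c)], fdr_q=config.fdr_q
                )
                _matrix_csv(cm.r, windows, windows, topo_dir / f"selfcorr_{g}_{c}.csv")
    done(rec, group_sequences=len(group_seqs))

    # --- trajectory state space -----------------------------------------
    rec = stage("trajectories")
    basis2d = ssmod.fit_basis(list(group_seqs.values()))
    traj_rows = []
    subj_metric_rows = []
    for g in GROUPS:
        if (g, "standard") not in group_seqs:
            continue
        tr_s = ssmod.project_trajectory(group_seqs[(g, "standard")], basis2d)
        tr_t = ssmod.project_trajectory(group_seqs[(g, "target")], basis2d)
        total, per_win = ssmod.trajectory_distance(tr_s, tr_t)
        angles = ssmod.angular_separation(tr_s, tr_t)
        len_s, _ = ssmod.trajectory_length(tr_s)
        len_t, _ = ssmod.trajectory_length(tr_t)
        traj_rows.append({
            "group": g, "intertrajectory_distance": total,
            "trajectory_length_standard": len_s,
            "trajectory_length_target": len_t,
            "mean_angular_separation_deg": float(np.nanmean(angles)),
        })
    for sid in subjects:
        tr_s = ssmod.project_trajectory(subj_seqs[sid]["standard"], basis2d)
        tr_t = ssmod.project_trajectory(subj_seqs[sid]["target"], basis2d)
        total, _ = ssmod.trajectory_distance(tr_s, tr_t)
        subj_metric_rows.append({
            "subject": sid, "group": groups_of[sid],
            "intertrajectory_distance": total,
        })
    _write_csv(pd.DataFrame(traj_rows), out / "traj" / "group_metrics.csv")
    subj_metrics = pd.DataFrame(subj_metric_rows)
    _write_csv(subj_metrics, out / "traj" / "subject_metrics.csv")

    boot_input = {
        g: [subj_seqs[s] for s in subjects if groups_of[s] == g] for g in GROUPS
    }
    boot_input = {g: v for g, v in boot_input.items() if v}
    boot = None
    if config.bootstrap_iterations > 0 and all(len(v) >= 2 for v in boot_input.values()):
        boot = ssmod.bootstrap_metrics(
            boot_input, n_per_group=config.n_per_group,
            iterations=config.bootstrap_iterations, seed=config.seed + 1,
        )
        boot_rows = []
        for metric, by_group in boot.items():
            for g, res in by_group.items():
                boot_rows.append({
                    "metric": metric, "group": g, "mean": res.mean, "sd": res.sd,
                    "iterations": res.iterations, "n_per_group": res.n_per_group,
                })
        _write_csv(pd.DataFrame(boot_rows), out / "traj" / "bootstrap_summary.csv")
    done(rec, groups=len(traj_rows))

    # --- dominant states -------------------------------------------------
    rec = stage("states")
    group_erps = []
    for g in GROUPS:
        members = [s for s in subjects if groups_of[s] == g]
        if not members:
            continue
        for c in CONDITIONS:
            stack = np.mean([erps[(s, c)].data for s in members], axis=0)
            ref = erps[(members[0], c)]
            group_erps.append(dataclasses.replace(
                ref, data=stack, subject_id=f"{g}-mean", group=g,
                n_trials_used=len(members),
            ))
    basis = dsmod.extract_states(group_erps, K=config.k_states)
    states_dir = out / "states"
    states_dir.mkdir(parents=True, exist_ok=True)
    _matrix_csv(basis.templates, list(basis.state_names), list(basis.channel_names),
                states_dir / "templates.csv")
    (states_dir / "basis.json").write_text(json.dumps({
        "explained_var": basis.explained_var.tolist(),
        "cumulative_explained_var": float(basis.explained_var.sum()),
        "K": basis.K,
        "provenance": basis.provenance,
    }, indent=1))

    differences: Dict[str, np.ndarray] = {}
    var_rows = []
    for sid in subjects:
        tc_s = dsmod.project_timecourse(erps[(sid, "standard")], basis)
        tc_t = dsmod.project_timecourse(erps[(sid, "target")], basis)
        differences[sid] = dsmod.projection_difference(tc_t, tc_s)
        for c in CONDITIONS:
            ve = dsmod.subject_variance_explained(erps[(sid, c)], basis)
            row = {"subject": sid, "group": groups_of[sid], "condition": c}
            row.update({f"PC{k + 1}": v for k, v in enumerate(ve)})
            var_rows.append(row)
    _write_csv(pd.DataFrame(var_rows), states_dir / "variance_explained.csv")
    done(rec, cumulative_explained_var=float(basis.explained_var.sum()))

    # --- state sequences -------------------------------------------------
    rec = stage("transitions")
    trans_dir = out / "trans"
    seq_rows = []
    for sid in subjects:
        for c in CONDITIONS:
            seq = seqmod.assign_states(erps[(sid, c)], basis, alpha=config.alpha)
            tm = seqmod.transition_matrix(seq)
            stab = seqmod.state_stability(tm)
            row = {
                "subject": sid, "group": groups_of[sid], "condition": c,
                "other_proportion": seqmod.other_proportion(seq),
            }
            for k, name in enumerate(tm.state_names):
                row[f"stability_{name}"] = stab[k]
            seq_rows.append(row)
    seq_df = pd.DataFrame(seq_rows)
    _write_csv(seq_df, trans_dir / "sequence_metrics.csv")
    done(rec, sequences=len(seq_rows))

    # --- classification --------------------------------------------------
    rec = stage("classification")
    clf_result = None
    sub_order, features = clf.build_features(
        differences, window_average=config.feature_windows
    )
    labels = np.array([groups_of[s] for s in sub_order])
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) >= 2 and counts.min() >= config.folds:
        clf_result = clf.classify_with_null(
            features, labels, folds=config.folds, repeats=config.cv_repeats,
            seed=config.seed + 2,
        )
        (out / "clf.json").write_text(json.dumps({
            "mean_accuracy": clf_result.mean_accuracy,
            "mean_shuffled_accuracy": clf_result.mean_shuffled_accuracy,
            "p_value": clf_result.p_value,
            "folds": clf_result.folds,
            "repeats": clf_result.repeats,
        }, indent=1))
        done(rec, mean_accuracy=clf_result.mean_accuracy)
    else:
        done(rec, skipped="too few subjects per group for stratified folds")

    # --- group statistics ------------------------------------------------
    rec = stage("stats")
    stat_rows = []

    def kw_row(metric: str, df: pd.DataFrame, col: str):
        by_group = [df.loc[df["group"] == g, col].to_numpy()
                    for g in GROUPS if (df["group"] == g).any()]
        if len(by_group) < 2 or any(len(v) < 1 for v in by_group):
            return
        res = gst.kw_dunn(by_group)
        stat_rows.append({"metric": metric, "test": "kruskal-wallis",
                          "statistic": res.statistic, "p": res.p, "pair": "",
                          "p_adjusted": ""})
        names = [g for g in GROUPS if (df["group"] == g).any()]
        for pw in res.pairwise:
            stat_rows.append({
                "metric": metric, "test": "dunn-sidak", "statistic": pw.z,
                "p": pw.p, "pair": f"{names[pw.pair[0]]}|{names[pw.pair[1]]}",
                "p_adjusted": pw.p_adjusted,
            })

    kw_row("intertrajectory_distance", subj_metrics, "intertrajectory_distance")
    for c in CONDITIONS:
        sub = seq_df[seq_df["condition"] == c]
        kw_row(f"other_proportion_{c}", sub, "other_proportion")

    if clinical is not None and "snap_attention" in getattr(clinical, "columns", ()):
        merged = subj_metrics.merge(clinical, on=["subject", "group"])
        if len(merged) >= 5:
            r, p = gst.pearson_corr(
                merged["intertrajectory_distance"], merged["snap_attention"]
            )
            stat_rows.append({"metric": "distance_vs_snap_attention",
                              "test": "pearson", "statistic": r, "p": p,
                              "pair": "", "p_adjusted": ""})
            if {"age", "iq"} <= set(merged.columns) and len(merged) >= 7:
                r, p = gst.partial_corr(
                    merged["intertrajectory_distance"], merged["snap_attention"],
                    merged[["age", "iq"]].to_numpy(),
                )
                stat_rows.append({"metric": "distance_vs_snap_attention",
                                  "test": "partial|age,iq", "statistic": r,
                                  "p": p, "pair": "", "p_adjusted": ""})
    _write_csv(pd.DataFrame(stat_rows), out / "stats.csv")
    done(rec, rows=len(stat_rows))

    summary["n_subjects"] = len(subjects)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (out / "timings.json").write_text(json.dumps(timings, indent=1, sort_keys=True))
    return summary
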