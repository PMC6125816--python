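"""End-to-end pipeline: simulate -> behavior -> ICA -> activity ->
connectivity -> prediction -> moderation, with persisted intermediates,
per-stage manifests and a markdown summary report.

Every stage derives its randomness from the single master seed in the
configuration, so rerunning with the same config reproduces every
output table byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import decomposition as dec
from . import activity as act
from . import connectivity as con
from . import prediction as pred
from .config import PipelineConfig
from .io import (
    write_bold_nifti,
    write_confounds_tsv,
    write_events_tsv,
)
from .simulate import (
    TaskDesign,
    generate_cohort,
    generate_task_design,
    simulate_subject_dataset,
)
from .simulate.bold import gaussian_blob_maps
from .simulate.cohort import default_ground_truth

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest(stage_dir: Path, params: dict, files: list[Path]):
    stage_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "parameters": params,
        "files": {f.name: _sha256(f) for f in files if f.exists()},
    }
    (stage_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _stage_simulate(cfg: PipelineConfig, out: Path):
    rng = np.random.default_rng(cfg.seed)
    design = generate_task_design(
        n_go=cfg.task.n_go,
        n_stop=cfg.task.n_stop,
        n_nogo=cfg.task.n_nogo,
        n_sessions=cfg.task.n_sessions,
        iti_s=cfg.task.iti_s,
        tr_s=cfg.task.tr_s,
        seed=int(rng.integers(2**31 - 1)),
    )
    truth = default_ground_truth(
        n_components=cfg.cohort.n_components,
        grid_shape=tuple(cfg.cohort.grid_shape),
        seed=int(rng.integers(2**31 - 1)),
    )
    cohort = generate_cohort(
        cfg.cohort.n_subjects,
        age_range=(cfg.cohort.age_min, cfg.cohort.age_max),
        truth=truth,
        seed=int(rng.integers(2**31 - 1)),
    )
    stage = out / "simulate"
    stage.mkdir(parents=True, exist_ok=True)
    files = []
    datasets = {}
    for s in cohort.subjects:
        ds = simulate_subject_dataset(s, design)
        datasets[s.subject_id] = ds
        sdir = stage / s.subject_id
        sdir.mkdir(exist_ok=True)
        for sess in range(1, design.n_sessions + 1):
            ev = sdir / f"ses-{sess}_events.tsv"
            write_events_tsv(ds["behavior"], ev, session=sess)
            cf = sdir / f"ses-{sess}_confounds.tsv"
            write_confounds_tsv(ds["motion"][sess], cf)
            ni = sdir / f"ses-{sess}_bold.nii.gz"
            write_bold_nifti(
                ds["bold"][sess], tuple(cfg.cohort.grid_shape), ni, cfg.task.tr_s, sess
            )
            files += [ev, cf, ni]
    cohort.table().to_csv(stage / "cohort_truth.csv", index=False)
    files.append(stage / "cohort_truth.csv")
    _manifest(stage, {"seed": cfg.seed, "task": cfg.task.__dict__}, files)
    return design, truth, cohort, datasets


def _stage_behavior(cfg: PipelineConfig, out: Path, cohort, datasets):
    rows = {}
    for s in cohort.subjects:
        ds = datasets[s.subject_id]
        summary = beh.summarize_performance(ds["behavior"])
        disp = [beh.rms_displacement(m)[1] for m in ds["motion"].values()]
        rows[s.subject_id] = {
            **{k: v for k, v in summary.items() if k != "flags"},
            "mean_displacement": float(np.mean(disp)),
            "age_years": s.age_years,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table, log = beh.apply_exclusions(table)
    stage = out / "behavior"
    stage.mkdir(parents=True, exist_ok=True)
    table.to_csv(stage / "behavior.csv", index_label="subject_id")
    (stage / "exclusions.json").write_text(json.dumps(log, indent=2))
    _manifest(stage, {}, [stage / "behavior.csv", stage / "exclusions.json"])
    return table, log


def _stage_ica(cfg: PipelineConfig, out: Path, design, truth, cohort, datasets, included):
    subject_data = {}
    for sid in included:
        ds = datasets[sid]
        cleaned = [
            dec.regress_confounds(ds["bold"][s], ds["motion"][s])
            for s in sorted(ds["bold"])
        ]
        subject_data[sid] = np.concatenate(cleaned, axis=0)
    concat = np.concatenate(list(subject_data.values()), axis=0)
    if cfg.ica.order == "auto":
        k = dec.select_model_order_mdl(concat, max_order=min(20, concat.shape[0] - 1))
        k = max(2, k)
    else:
        k = int(cfg.ica.order)
    comps = dec.group_ica(
        subject_data, k, n_runs=cfg.ica.n_runs, seed=cfg.seed + 17, tr_s=cfg.task.tr_s
    )
    # reference maps: ground-truth sources as signal templates plus a
    # synthetic uniform "CSF-like" map as a non-neuronal template
    refs = {
        f"truth_{i}": (truth.spatial_maps[i], "signal")
        for i in range(truth.n_components)
    }
    rng = np.random.default_rng(cfg.seed + 23)
    refs["csf_like"] = (
        gaussian_blob_maps(1, tuple(cfg.cohort.grid_shape), sigma_vox=4.0,
                           seed=rng)[0],
        "noise",
    )
    dec.classify_noise_components(comps, refs)
    matched, match_r = dec.match_components(truth.spatial_maps, comps.spatial_maps)
    stage = out / "ica"
    stage.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "stability": comps.stability_index,
            "label": comps.labels,
        }
    ).to_csv(stage / "components.csv", index_label="component")
    np.savetxt(stage / "spatial_maps.csv", comps.spatial_maps, delimiter=",")
    recov = pd.DataFrame({"matched_component": matched, "abs_r": match_r})
    recov.to_csv(stage / "truth_recovery.csv", index_label="truth_source")
    _manifest(stage, {"order": k, "n_runs": cfg.ica.n_runs},
              [stage / "components.csv", stage / "truth_recovery.csv"])
    return comps, recov


def _stage_activity(cfg: PipelineConfig, out: Path, design: TaskDesign, datasets,
                    comps: dec.ComponentSet, included, behavior_table):
    T = design.n_volumes_per_session
    session_lengths = [T] * design.n_sessions
    designs_per_subject = {
        sid: [
            act.build_design_matrix(
                datasets[sid]["behavior"], s, T, design.tr_s, datasets[sid]["motion"][s]
            )
            for s in range(1, design.n_sessions + 1)
        ]
        for sid in included
    }
    tcs = {sid: comps.subject_tcs[sid] for sid in included}
    resp = act.responsivity_table(tcs, designs_per_subject, session_lengths)
    ages = behavior_table.loc[included, "age_years"].to_numpy()
    group = act.group_responsivity_test(resp, alpha=cfg.stats.group_alpha)
    age_tab = act.age_effect_robust(resp, ages, alpha=cfg.stats.age_alpha)
    stage = out / "activity"
    stage.mkdir(parents=True, exist_ok=True)
    resp.to_csv(stage / "responsivity.csv", index_label="subject_id")
    group.to_csv(stage / "group_test.csv")
    age_tab.to_csv(stage / "age_test.csv")
    _manifest(stage, {"group_alpha": cfg.stats.group_alpha},
              [stage / "responsivity.csv", stage / "group_test.csv"])
    return resp, group, age_tab, designs_per_subject


def _stage_connectivity(cfg, out, design, datasets, comps, included,
                        designs_per_subject, behavior_table):
    T = design.n_volumes_per_session
    session_lengths = [T] * design.n_sessions
    tables = {}
    for kind in ("spontaneous", "cppi"):
        rows = {}
        for sid in included:
            cm = con.connectivity_matrix(
                comps.subject_tcs[sid],
                designs_per_subject[sid],
                datasets[sid]["behavior"],
                session_lengths,
                design.tr_s,
                kind=kind,
            )
            rows[sid] = cm.pairs()
        tables[kind] = pd.DataFrame.from_dict(rows, orient="index")
    ages = behavior_table.loc[included, "age_years"].to_numpy()
    tests = {
        kind: con.connectivity_group_tests(
            tables[kind], ages,
            group_alpha=cfg.stats.group_alpha, age_alpha=cfg.stats.age_alpha,
        )
        for kind in tables
    }
    stage = out / "connectivity"
    stage.mkdir(parents=True, exist_ok=True)
    files = []
    for kind, tab in tables.items():
        long = tab.stack().rename("value").reset_index()
        long.columns = ["subject_id", "pair", "value"]
        long["kind"] = kind
        f = stage / f"{kind}.csv"
        long.to_csv(f, index=False)
        files.append(f)
        tests[kind]["group"].to_csv(stage / f"{kind}_group_test.csv")
        tests[kind]["age"].to_csv(stage / f"{kind}_age_test.csv")
    _manifest(stage, {}, files)
    return tables, tests


def _stage_prediction(cfg, out, tables, resp, behavior_table, included):
    y = behavior_table.loc[included, "ssrt_ms"].to_numpy(dtype=float)
    age = behavior_table.loc[included, "age_years"].to_numpy(dtype=float)
    covars = behavior_table.loc[included, ["mean_displacement", "go_rt_mean_ms"]].to_numpy(
        dtype=float
    )
    feature_sets = {
        "model1_activity": resp.loc[included].to_numpy(dtype=float),
        "model2_spontaneous": tables["spontaneous"].loc[included].to_numpy(dtype=float),
        "model3_cppi": tables["cppi"].loc[included].to_numpy(dtype=float),
    }
    feature_sets["model4_joint"] = np.hstack(
        [feature_sets["model1_activity"], feature_sets["model3_cppi"]]
    )
    rng = np.random.default_rng(cfg.seed + 31)
    results = {}
    scores = {}
    k = cfg.cv.k
    for name, X in feature_sets.items():
        res = pred.cv_predict_scores(X, y, covars, k=k, seed=int(rng.integers(2**31 - 1)))
        p, _ = pred.permutation_pvalue(
            X, y, covars, n_perm=cfg.cv.n_perm, k=k,
            seed=int(rng.integers(2**31 - 1)), observed_r=res.observed_r,
        )
        repart = pred.repartition_distribution(
            X, y, covars, n_repart=cfg.cv.n_repart, k=k,
            seed=int(rng.integers(2**31 - 1)),
        )
        scores[name] = res.subject_scores
        results[name] = {
            "observed_r": res.observed_r,
            "permutation_p": p,
            "repartition_mean_r": float(repart.mean()),
            "repartition_sd_r": float(repart.std()),
            "mean_gamma": float(np.mean(res.gamma_per_fold)),
        }
    r_ind, p_ind = pred.independence_check(
        scores["model1_activity"], scores["model3_cppi"]
    )
    moderation = {}
    for name in ("model1_activity", "model3_cppi", "model4_joint"):
        m = pred.moderation_analysis(scores[name], age, y)
        moderation[name] = m.table
    stage = out / "prediction"
    stage.mkdir(parents=True, exist_ok=True)
    (stage / "models.json").write_text(json.dumps(results, indent=2))
    for name, tab in moderation.items():
        tab.to_csv(stage / f"moderation_{name}.csv")
    sc = pred.structure_coefficients(
        pd.DataFrame(feature_sets["model4_joint"]), scores["model4_joint"]
    )
    sc.to_csv(stage / "structure_coefficients_model4.csv")
    (stage / "independence.json").write_text(
        json.dumps({"r": r_ind, "p": p_ind}, indent=2)
    )
    _manifest(stage, {"k": k, "n_perm": cfg.cv.n_perm}, [stage / "models.json"])
    return results, moderation, (r_ind, p_ind)


def _write_report(out: Path, cfg, cohort, behavior_table, log, recov, comps,
                  group, age_tab, conn_tests, results, moderation, independence):
    lines = ["# stopnet pipeline report", ""]
    lines += [f"Master seed: {cfg.seed}; cohort n = {len(cohort.subjects)}", ""]
    lines += ["## Exclusions", ""]
    if log:
        for sid, reason in log.items():
            lines.append(f"- {sid}: {reason}")
    else:
        lines.append("- none")
    incl = behavior_table[~behavior_table["excluded"]]
    r_age_ssrt = np.corrcoef(incl["age_years"], incl["ssrt_ms"])[0, 1]
    r_age_gort = np.corrcoef(incl["age_years"], incl["go_rt_mean_ms"])[0, 1]
    lines += ["", "## Behavior", ""]
    lines.append(f"- mean SSRT {incl['ssrt_ms'].mean():.1f} ms; "
                 f"mean p(respond|signal) {incl['p_respond_signal'].mean():.3f}")
    lines.append(f"- r(age, SSRT) = {r_age_ssrt:.3f}; r(age, GoRT) = {r_age_gort:.3f}")
    lines += ["", "## Decomposition", ""]
    lines.append(f"- order k = {comps.order_k}; mean stability "
                 f"{comps.stability_index.mean():.3f}")
    lines.append(f"- ground-truth map recovery |r|: "
                 + ", ".join(f"{v:.3f}" for v in recov["abs_r"]))
    lines += ["", "## Responsivity", ""]
    lines.append(f"- group-significant components: "
                 f"{list(group.index[group['significant']])}")
    lines.append(f"- age-significant components: "
                 f"{list(age_tab.index[age_tab['significant']])}")
    lines += ["", "## Connectivity", ""]
    for kind, tests in conn_tests.items():
        g = tests["group"]
        a = tests["age"]
        lines.append(f"- {kind}: {int(g['significant'].sum())} group-significant, "
                     f"{int(a['significant'].sum())} age-significant connections")
    lines += ["", "## Prediction", ""]
    for name, res in results.items():
        lines.append(
            f"- {name}: r = {res['observed_r']:.3f} (perm p = {res['permutation_p']:.3f}, "
            f"repartition mean r = {res['repartition_mean_r']:.3f})"
        )
    lines.append(f"- score independence (model 1 vs 3): r = {independence[0]:.3f} "
                 f"(p = {independence[1]:.3f})")
    lines += ["", "## Moderation (scores x age -> SSRT)", ""]
    for name, tab in moderation.items():
        row = tab.loc["scores_x_age"]
        lines.append(f"- {name}: interaction r_partial = {row['r_partial']:.3f}, "
                     f"p = {row['p']:.4f}")
    (out / "report.md").write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns a bundle of in-memory results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        design, truth, cohort, datasets = _stage_simulate(cfg, out)
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e
    try:
        behavior_table, log = _stage_behavior(cfg, out, cohort, datasets)
    except Exception as e:
        raise RuntimeError(f"stage 'behavior' failed: {e}") from e
    included = [sid for sid in behavior_table.index
                if not behavior_table.loc[sid, "excluded"]
                and np.isfinite(behavior_table.loc[sid, "ssrt_ms"])]
    try:
        comps, recov = _stage_ica(cfg, out, design, truth, cohort, datasets, included)
    except Exception as e:
        raise RuntimeError(f"stage 'ica' failed: {e}") from e
    try:
        resp, group, age_tab, designs_per_subject = _stage_activity(
            cfg, out, design, datasets, comps, included, behavior_table
        )
    except Exception as e:
        raise RuntimeError(f"stage 'activity' failed: {e}") from e
    try:
        tables, conn_tests = _stage_connectivity(
            cfg, out, design, datasets, comps, included, designs_per_subject,
            behavior_table,
        )
    except Exception as e:
        raise RuntimeError(f"stage 'connectivity' failed: {e}") from e
    try:
        results, moderation, independence = _stage_prediction(
            cfg, out, tables, resp, behavior_table, included
        )
    except Exception as e:
        raise RuntimeError(f"stage 'prediction' failed: {e}") from e
    _write_report(out, cfg, cohort, behavior_table, log, recov, comps, group,
                  age_tab, conn_tests, results, moderation, independence)
    return {
        "design": design,
        "truth": truth,
        "cohort": cohort,
        "behavior": behavior_table,
        "exclusions": log,
        "components": comps,
        "recovery": recov,
        "responsivity": resp,
        "connectivity": tables,
        "connectivity_tests": conn_tests,
        "models": results,
        "moderation": moderation,
        "independence": independence,
    }
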