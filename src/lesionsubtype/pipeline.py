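"""End-to-end experiment orchestration from one configuration.

Stages: simulate -> preprocess -> plan -> train -> fuse -> evaluate ->
subtype -> decode -> summarize.  Every stage writes its outputs plus a
manifest recording a hash of the configuration slice it depends on; a rerun
with an unchanged configuration is a cache hit and recomputes nothing, while
a manifest whose declared outputs have gone missing raises a dependency
error rather than silently recomputing.

Two scale presets exist: ``full`` is the complete protocol
(231 subjects, 20 repeats of 6x8 nested folds, 800 epochs, 500 label
permutations -- cluster-scale compute) and ``smoke`` is a desk-scale run.
Any preset value can be overridden by an explicit configuration key.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnn as cnn_mod
from . import fusion, saliency, subtyping, decoding
from .errors import DependencyError, ReportError
from .evaluation import confusion_metrics, paired_compare, records_to_long_format
from .morphomap import preprocess_cohort, compose_ordinal_map, downsample_mode
from .partitions import build_cv_plan, categorize, CVPlan
from .svm import fit_svm, random_search_svm
from .synthetic import CohortSpec, generate_cohort

log = logging.getLogger(__name__)

PRESETS: dict[str, dict] = {
    "full": {
        "cohort": {"n_subjects": 231, "grid_shape": [48, 56, 48], "seed": 0},
        "preprocess": {"factor": 4},
        "plan": {"n_repeats": 20, "n_outer": 6, "n_inner": 8, "seed": 7},
        "cnn": {"complexity_levels": [1, 2, 3, 4],
                "dropout_rates": [0.6, 0.7, 0.8],
                "l2_penalties": [0.001, 0.01],
                "learning_rates": [0.1e-4, 0.8e-4, 1e-4],
                "epochs": 800, "batch_size": 128, "patience": 100},
        "svm": {"kernel": "linear", "reduction": "none", "n_candidates": 60},
        "subtype": {"k_min": 3, "k_max": 30, "n_runs": 1000,
                    "subsample_fraction": 0.6, "kmeans_replicates": 250,
                    "dip_boot": 1000},
        "decode": {"n_studies": 400, "n_topics": 200, "planted_odds_ratio": 8.0},
        "n_permutations": 500,
        "seed": 0,
    },
    "smoke": {
        "cohort": {"n_subjects": 60, "grid_shape": [48, 56, 48], "seed": 0},
        "preprocess": {"factor": 4},
        "plan": {"n_repeats": 2, "n_outer": 2, "n_inner": 2, "seed": 7},
        "cnn": {"complexity_levels": [1], "dropout_rates": [0.6],
                "l2_penalties": [0.001], "learning_rates": [1e-4],
                "epochs": 50, "batch_size": 128, "patience": 50},
        "svm": {"kernel": "linear", "reduction": "none", "n_candidates": 8},
        "subtype": {"k_min": 2, "k_max": 5, "n_runs": 60,
                    "subsample_fraction": 0.6, "kmeans_replicates": 8,
                    "dip_boot": 200},
        "decode": {"n_studies": 120, "n_topics": 25, "planted_odds_ratio": 8.0},
        "n_permutations": 0,
        "seed": 0,
    },
}


def load_config(path_or_dict) -> dict:
    """Merge a YAML config (or dict) over its scale preset."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    scale = user.get("scale", "smoke")
    if scale not in PRESETS:
        raise DependencyError(f"unknown scale preset {scale!r}")
    config = json.loads(json.dumps(PRESETS[scale]))  # deep copy
    for key, value in user.items():
        if key == "scale":
            continue
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    config["scale"] = scale
    return config


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


class _Stage:
    """Caching wrapper: skip when the manifest hash matches and outputs exist."""

    def __init__(self, out_dir: Path, name: str, config_slice, outputs: list[str]):
        self.dir = out_dir / name
        self.name = name
        self.hash = _hash(config_slice)
        self.outputs = [self.dir / o for o in outputs]
        self.manifest = self.dir / "manifest.json"

    def cached(self) -> bool:
        if not self.manifest.exists():
            return False
        meta = json.loads(self.manifest.read_text())
        if meta.get("hash") != self.hash:
            return False
        missing = [str(o) for o in self.outputs if not o.exists()]
        if missing:
            raise DependencyError(
                f"stage {self.name!r}: manifest present but outputs missing "
                f"({missing}); remove {self.dir} to recompute")
        log.info("stage %s: cache hit", self.name)
        return True

    def done(self):
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest.write_text(json.dumps({"hash": self.hash,
                                             "stage": self.name}))

    def require(self):
        if not self.manifest.exists():
            raise DependencyError(f"missing upstream stage {self.name!r}")
        for o in self.outputs:
            if not o.exists():
                raise DependencyError(
                    f"stage {self.name!r} output {o.name} missing or corrupted")


def _downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    omap = compose_ordinal_map({"csf": np.zeros_like(mask), "gm": mask,
                                "wm": np.zeros_like(mask)},
                               np.zeros_like(mask))
    return downsample_mode(omap, factor).values == omap.code_table["gm"]


def run_experiment(config, out_dir) -> Path:
    """Execute the full experiment; idempotent and resumable per stage."""
    config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "provenance.json").write_text(json.dumps(
        {"config": config, "config_hash": _hash(config)}, indent=2))
    seed = int(config["seed"])

    # ---------------- simulate ----------------
    sim = _Stage(out, "simulate", config["cohort"], ["cohort.npz", "cohort.csv"])
    if not sim.cached():
        spec = CohortSpec(**{**config["cohort"],
                             "grid_shape": tuple(config["cohort"]["grid_shape"])})
        cohort = generate_cohort(spec)
        sim.dir.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            sim.dir / "cohort.npz",
            csf=np.stack([s.tissue_masks["csf"] for s in cohort.subjects]),
            gm=np.stack([s.tissue_masks["gm"] for s in cohort.subjects]),
            wm=np.stack([s.tissue_masks["wm"] for s in cohort.subjects]),
            lesion=np.stack([s.lesion_mask for s in cohort.subjects]),
            brain=cohort.template.brain, left=cohort.template.left,
            patterns=cohort.subtype_patterns,
            wab=cohort.ground_truth["wab_aq"].to_numpy(),
            subtype=cohort.ground_truth["true_subtype"].to_numpy(),
        )
        cohort.ground_truth.to_csv(sim.dir / "cohort.csv", index=False)
        sim.done()
    sim.require()
    data = np.load(sim.dir / "cohort.npz")
    wab = data["wab"]
    _, y = categorize(wab)

    # ---------------- preprocess ----------------
    factor = int(config["preprocess"]["factor"])
    pre = _Stage(out, "preprocess", config["preprocess"], ["maps.npz"])
    if not pre.cached():
        tissue = [{"csf": data["csf"][i], "gm": data["gm"][i],
                   "wm": data["wm"][i]} for i in range(len(wab))]
        X, box, meta = preprocess_cohort(tissue, list(data["lesion"]),
                                         voxel_size_mm=2.0, factor=factor)
        box_sl = [[s.start, s.stop] for s in box]
        brain_ds = _downsample_mask(data["brain"], factor)
        left_ds = _downsample_mask(data["left"], factor)
        crop = tuple(slice(a, b) for a, b in box_sl)
        lesions_ds = np.stack([
            _downsample_mask(lm, factor)[crop] for lm in data["lesion"]])
        patterns_ds = np.stack([
            _downsample_pattern(p, factor)[crop] for p in data["patterns"]])
        pre.dir.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(pre.dir / "maps.npz", X=X, box=np.array(box_sl),
                            brain=brain_ds[crop], left=left_ds[crop],
                            lesions=lesions_ds, patterns=patterns_ds,
                            voxel_size_mm=meta.voxel_size_mm)
        pre.done()
    pre.require()
    maps = np.load(pre.dir / "maps.npz")
    X = maps["X"]

    # ---------------- plan ----------------
    plan_stage = _Stage(out, "plan", config["plan"], ["plan.json"])
    if not plan_stage.cached():
        cats, _ = categorize(wab)
        plan = build_cv_plan(cats, **config["plan"])
        plan_stage.dir.mkdir(parents=True, exist_ok=True)
        plan.to_json(plan_stage.dir / "plan.json")
        plan_stage.done()
    plan_stage.require()
    plan = CVPlan.from_json(plan_stage.dir / "plan.json")

    # ---------------- train ----------------
    train_cfg = {"cnn": config["cnn"], "svm": config["svm"]}
    train = _Stage(out, "train", train_cfg, ["predictions.npz"])
    if not train.cached():
        results = _train_all(X, y, plan, config, seed)
        train.dir.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(train.dir / "predictions.npz", **results)
        train.done()
    train.require()
    preds = dict(np.load(train.dir / "predictions.npz"))

    # ---------------- fuse ----------------
    fuse = _Stage(out, "fuse", train_cfg, ["fusion.npz"])
    if not fuse.cached():
        fusion_out = _fuse_all(preds, y, plan, seed)
        fuse.dir.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(fuse.dir / "fusion.npz", **fusion_out)
        fuse.done()
    fuse.require()
    fused = dict(np.load(fuse.dir / "fusion.npz"))

    # ---------------- evaluate ----------------
    ev = _Stage(out, "evaluate", train_cfg, ["performance.csv", "comparisons.json"])
    if not ev.cached():
        _evaluate_all(preds, fused, y, plan, ev.dir)
        ev.done()
    ev.require()

    # ---------------- subtype ----------------
    sub = _Stage(out, "subtype", config["subtype"], ["subtypes.json"])
    if not sub.cached():
        _subtype_all(preds, y, maps, config["subtype"], seed, sub.dir)
        sub.done()
    sub.require()

    # ---------------- decode ----------------
    dec = _Stage(out, "decode", config["decode"], ["decoding.json"])
    if not dec.cached():
        _decode_all(preds, maps, config["decode"], seed, sub.dir, dec.dir)
        dec.done()
    dec.require()

    summarize_results(out)
    return out


def _downsample_pattern(pattern: np.ndarray, factor: int) -> np.ndarray:
    s = pattern.shape
    pad = [(0, (-d) % factor) for d in s]
    pp = np.pad(pattern, pad)
    return pp.reshape(pp.shape[0] // factor, factor, pp.shape[1] // factor,
                      factor, pp.shape[2] // factor, factor).mean(axis=(1, 3, 5))


def _train_all(X, y, plan: CVPlan, config, seed) -> dict:
    ccfg = config["cnn"]
    schedule = cnn_mod.TrainingSchedule(
        total_epochs=int(ccfg["epochs"]), batch_size=int(ccfg["batch_size"]),
        early_stop_patience=int(ccfg["patience"]))
    grid = [cnn_mod.CNNConfig(complexity_level=c, dropout_rate=d, l2_penalty=l,
                              base_learning_rate=r, input_shape=X.shape[1:])
            for c in ccfg["complexity_levels"] for d in ccfg["dropout_rates"]
            for l in ccfg["l2_penalties"] for r in ccfg["learning_rates"]]
    scfg = config["svm"]
    n = len(y)
    R = plan.n_repeats
    grid_shape = X.shape[1:]
    out = {
        "cnn_proba": np.zeros((R, n, 2)), "svm_proba": np.zeros((R, n, 2)),
        "cnn_latent": np.zeros((R, n, grid[0].latent_width)),
        "gradcam": np.zeros((R, n) + grid_shape),
        "deep_attr": np.zeros((R, n) + grid_shape),
        "cnn_inner_proba": np.full((R, n, 2), np.nan),
        "svm_inner_proba": np.full((R, n, 2), np.nan),
    }
    background = np.full(grid_shape, -1.0)  # all-background reference
    for r in range(R):
        for f, test_idx in enumerate(plan.outer[r]):
            fold_seed = seed + 10000 * r + 100 * f
            trained, chosen, records = cnn_mod.tune_and_refit(
                X, y, plan, r, f, grid, schedule, seed=fold_seed)
            proba, latent = cnn_mod.predict_and_latent(trained, X[test_idx])
            out["cnn_proba"][r, test_idx] = proba
            out["cnn_latent"][r, test_idx] = latent
            for rec in records:
                if rec["config"] is chosen and "inner_proba" in rec:
                    for vidx, vproba in rec["inner_proba"]:
                        out["cnn_inner_proba"][r, vidx] = vproba
            for i in test_idx:
                cls = int(np.argmax(out["cnn_proba"][r, i]))
                out["gradcam"][r, i] = saliency.grad_cam_pp(
                    trained, X[i], cls).values
                out["deep_attr"][r, i] = saliency.deep_attribution(
                    trained, X[i], cls, background[None], n_steps=8).values

            train_idx = plan.outer_train(r, f)
            svm_config, _ = random_search_svm(
                X.reshape(n, -1), y, train_idx, plan.inner[r][f],
                kernel=scfg["kernel"], reduction=scfg["reduction"],
                n_candidates=int(scfg["n_candidates"]), seed=fold_seed)
            model = fit_svm(X[train_idx].reshape(len(train_idx), -1),
                            y[train_idx], svm_config, seed=fold_seed)
            out["svm_proba"][r, test_idx] = model.predict_proba(
                X[test_idx].reshape(len(test_idx), -1))
            # inner out-of-sample SVM probabilities for stacking
            for vidx in plan.inner[r][f]:
                vset = set(vidx.tolist())
                tr = np.array([i for i in train_idx if i not in vset])
                m = fit_svm(X[tr].reshape(len(tr), -1), y[tr], svm_config,
                            seed=fold_seed)
                out["svm_inner_proba"][r, vidx] = m.predict_proba(
                    X[vidx].reshape(len(vidx), -1))
    return out


def _fuse_all(preds, y, plan: CVPlan, seed) -> dict:
    R = plan.n_repeats
    n = len(y)
    curves, stack_pred = [], np.zeros((R, n), dtype=np.int64)
    latent_pred = np.zeros((R, n), dtype=np.int64)
    gradcam_pred = np.zeros((R, n), dtype=np.int64)
    attr_pred = np.zeros((R, n), dtype=np.int64)
    for r in range(R):
        ens = fusion.weighted_average_ensemble(
            preds["cnn_proba"][r], preds["svm_proba"][r], y)
        curves.append(ens["f1_curve"])
        for f, test_idx in enumerate(plan.outer[r]):
            train_idx = plan.outer_train(r, f)
            pc = preds["cnn_inner_proba"][r]
            ps = preds["svm_inner_proba"][r]
            ok = np.array([i for i in train_idx
                           if np.isfinite(pc[i]).all() and np.isfinite(ps[i]).all()])
            if len(ok) < 4 or len(np.unique(y[ok])) < 2:
                ok = train_idx  # fallback: refit-stage probabilities absent
                pc_fit, ps_fit = preds["cnn_proba"][r], preds["svm_proba"][r]
            else:
                pc_fit, ps_fit = pc, ps
            meta = fusion.stack_meta_learner(pc_fit[ok], ps_fit[ok], y[ok],
                                             indices=ok)
            stack_pred[r, test_idx] = meta.predict(
                preds["cnn_proba"][r][test_idx], preds["svm_proba"][r][test_idx])
        latent_pred[r] = fusion.downstream_svm(
            preds["cnn_latent"][r], y, plan, r, seed=seed + r)["predictions"]
        gradcam_pred[r] = fusion.downstream_svm(
            preds["gradcam"][r].reshape(n, -1), y, plan, r,
            seed=seed + r)["predictions"]
        attr_pred[r] = fusion.downstream_svm(
            preds["deep_attr"][r].reshape(n, -1), y, plan, r,
            seed=seed + r)["predictions"]
    return {"ensemble_f1_curves": np.array(curves), "stack_pred": stack_pred,
            "latent_svm_pred": latent_pred, "gradcam_svm_pred": gradcam_pred,
            "deep_attr_svm_pred": attr_pred}


def _evaluate_all(preds, fused, y, plan: CVPlan, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    models = {
        "cnn": lambda r: np.argmax(preds["cnn_proba"][r], axis=1),
        "svm": lambda r: np.argmax(preds["svm_proba"][r], axis=1),
        "stacked_lda": lambda r: fused["stack_pred"][r],
        "latent_svm": lambda r: fused["latent_svm_pred"][r],
        "gradcam_svm": lambda r: fused["gradcam_svm_pred"][r],
        "deep_attr_svm": lambda r: fused["deep_attr_svm_pred"][r],
    }
    per_model = {}
    for name, fn in models.items():
        recs = [confusion_metrics(y, fn(r), repeat_index=r)
                for r in range(plan.n_repeats)]
        per_model[name] = [rec.f1 for rec in recs]
        rows.extend(records_to_long_format(recs, name))
    pd.DataFrame(rows).to_csv(out_dir / "performance.csv", index=False)
    comparisons = {}
    if plan.n_repeats >= 2:
        for a, b in [("cnn", "svm"), ("cnn", "stacked_lda"),
                     ("gradcam_svm", "deep_attr_svm")]:
            try:
                comparisons[f"{a}_vs_{b}"] = paired_compare(per_model[a],
                                                            per_model[b])
            except Exception as exc:  # zero-variance diffs on tiny runs
                comparisons[f"{a}_vs_{b}"] = {"error": str(exc)}
    (out_dir / "comparisons.json").write_text(json.dumps(comparisons, indent=2))


def _subtype_all(preds, y, maps, cfg, seed, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    pred0 = np.argmax(preds["cnn_proba"][0], axis=1)
    gradcam0 = preds["gradcam"][0]
    result = {}
    for cls, cls_name in ((1, "severe"), (0, "nonsevere")):
        idx = np.flatnonzero(pred0 == cls)
        k_max = min(int(cfg["k_max"]), max(2, len(idx) - 1))
        k_min = min(int(cfg["k_min"]), k_max)
        if len(idx) < k_min + 2:
            result[cls_name] = {"skipped": f"only {len(idx)} subjects"}
            continue
        maps_cls = gradcam0[idx].reshape(len(idx), -1)
        consensus = {
            k: subtyping.consensus_matrix(
                maps_cls, k, n_runs=int(cfg["n_runs"]),
                subsample_fraction=float(cfg["subsample_fraction"]),
                seed=seed + 1000 + cls,
                kmeans_replicates=int(cfg["kmeans_replicates"]))
            for k in range(k_min, k_max + 1)
        }
        sel = subtyping.select_solution(consensus, n_boot=int(cfg["dip_boot"]),
                                        seed=seed + cls)
        k_sel = sel["k_selected"]
        solution = subtyping.affinity_propagation_consensus(
            consensus[k_sel], k_sel,
            pac=sel["diagnostics"][k_sel]["pac"],
            dip_p=sel["diagnostics"][k_sel]["dip_p"])
        summary = None
        if len(np.unique(solution.assignments)) > 1:
            s = subtyping.cluster_similarity_summary(maps_cls,
                                                     solution.assignments)
            summary = {"mean_within": s["mean_within"],
                       "mean_between": s["mean_between"]}
        result[cls_name] = {
            "subjects": idx.tolist(),
            "k_selected": int(k_sel),
            "assignments": solution.assignments.tolist(),
            "exemplars": [int(idx[e]) for e in solution.exemplars],
            "pac": float(solution.pac), "dip_p": float(solution.dip_p),
            "similarity": summary,
            "fallback": sel["fallback"],
        }
    (out_dir / "subtypes.json").write_text(json.dumps(result, indent=2))


def _decode_all(preds, maps, cfg, seed, subtype_dir: Path, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    subtypes = json.loads((subtype_dir / "subtypes.json").read_text())
    brain = maps["brain"]
    patterns = maps["patterns"]
    planted = {t: patterns[t] > 0.25 * max(patterns[t].max(), 1e-9)
               for t in range(len(patterns))}
    corpus = decoding.make_topic_corpus(
        brain.shape, n_studies=int(cfg["n_studies"]),
        n_topics=int(cfg["n_topics"]), planted=planted,
        odds_ratio=float(cfg["planted_odds_ratio"]), seed=seed + 5)
    topic_maps = [decoding.chi_square_meta_map(corpus, t)
                  for t in range(corpus.n_topics)]
    gradcam0 = preds["gradcam"][0]
    result = {}
    for cls_name, info in subtypes.items():
        if "skipped" in info:
            result[cls_name] = info
            continue
        per_cluster = {}
        for c, exemplar_subject in enumerate(info["exemplars"]):
            lesion = maps["lesions"][exemplar_subject]
            try:
                dec = decoding.decode_saliency(
                    gradcam0[exemplar_subject], lesion, topic_maps,
                    brain_mask=brain)
                per_cluster[str(c)] = {
                    "exemplar_subject": int(exemplar_subject),
                    "top_topics": [d["topic_id"] for d in dec["ranked"][:5]],
                    "retained": [d["topic_id"] for d in dec["retained"]],
                }
            except Exception as exc:
                per_cluster[str(c)] = {"error": str(exc)}
        result[cls_name] = per_cluster
    (out_dir / "decoding.json").write_text(json.dumps(result, indent=2))


def summarize_results(out_dir) -> Path:
    """Assemble the report tables from whatever stages have completed."""
    out = Path(out_dir)
    perf_path = out / "evaluate" / "performance.csv"
    if not perf_path.exists():
        raise ReportError(f"no evaluation outputs under {out}")
    perf = pd.read_csv(perf_path)
    summary = perf.groupby(["model", "metric"])["value"].agg(
        ["median", "mean", "std"]).reset_index()
    report_dir = out / "report"
    report_dir.mkdir(exist_ok=True)
    summary.to_csv(report_dir / "performance_summary.csv", index=False)

    lines = ["# Experiment summary", "", "## Model performance (across repeats)", ""]
    lines.append(summary.to_markdown(index=False))
    comp_path = out / "evaluate" / "comparisons.json"
    if comp_path.exists():
        lines += ["", "## Paired comparisons", "",
                  "```json", comp_path.read_text(), "```"]
    for optional, title in [("subtype/subtypes.json", "Subtyping"),
                            ("decode/decoding.json", "Decoding")]:
        p = out / optional
        if p.exists():
            lines += ["", f"## {title}", "", "```json", p.read_text(), "```"]
        else:
            lines += ["", f"## {title}", "", "_stage absent_"]
    (report_dir / "report.md").write_text("\n".join(lines))
    return report_dir
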