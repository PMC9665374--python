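"""End-to-end runner tying the stages into the two-phase study design.

Phase one (development): simulate a development cohort, gate signal
quality, extract features, exclude Isolation-Forest outliers, train the
13-model ensemble and choose the binary operating point — then freeze
the model (its serialized bytes are hashed into the manifest and any
retraining attempt on a frozen run directory raises).  Phase two
(validation): simulate a separate, blinded validation cohort with an
independent seed stream, score it with the frozen model only, and
compute the diagnostic statistics.  The BNP comparator simulation runs
alongside.  Every excluded subject is logged with the gate that
excluded it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import evaluation, features, modeling, quality
from .bnp import nri_vs_bnp, simulate_bnp_performance
from .config import RunConfig
from .errors import FrozenModelError
from .io import cohort_from_csv, cohort_to_csv, save_features
from .synthetic import generate_cohort, generate_cohort_signals

__all__ = ["run_pipeline", "freeze_hash", "score_cohort"]

log = logging.getLogger("pulsewave.pipeline")


def freeze_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _prepare_split(tag: str, n: int, config: RunConfig, seed: int, out: Path):
    """simulate -> qc -> featurize for one split; returns (subjects df,
    feature table restricted to QC-passing subjects, exclusion log)."""
    subjects = generate_cohort(n, config.cohort, seed=seed)
    records = generate_cohort_signals(subjects, config.signal, seed=seed + 1)
    cohort_to_csv(subjects, out / f"cohort_{tag}.csv")
    subj_df = cohort_from_csv(out / f"cohort_{tag}.csv")

    qc = quality.qc_cohort(records, config.quality)
    qc.to_csv(out / f"qc_{tag}.csv", index=False)
    excluded = []
    passing = []
    for rec, ok in zip(records, qc["overall_pass"]):
        if ok:
            passing.append(rec)
        else:
            excluded.append({"subject_id": rec.subject_id, "gate": "qc"})
            log.info("excluded %s at gate qc", rec.subject_id)
    feats = features.featurize_cohort(passing, config.features)
    save_features(feats, out / f"features_{tag}.csv")
    return subj_df, feats, excluded


def score_cohort(model: modeling.EnsembleModel, feats: pd.DataFrame) -> pd.Series:
    return model.predict(feats)


def run_pipeline(config: RunConfig, force: bool = False) -> dict:
    """Execute the full run; returns (and writes) the run manifest.

    Raises :class:`FrozenModelError` if the output directory already
    holds a frozen model and ``force`` is not set.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    bundle_path = out / "model.bundle"
    if bundle_path.exists() and not force:
        raise FrozenModelError(
            f"{bundle_path} exists: the model is frozen; refusing to retrain")

    manifest: dict = {"seed": config.seed, "stages": {}, "exclusions": []}
    ss = np.random.SeedSequence(config.seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]

    # ---- phase one: development ------------------------------------------
    log.info("stage simulate/qc/featurize: development (n=%d)", config.n_dev)
    dev_subj, dev_feats, excl = _prepare_split(
        "dev", config.n_dev, config, seeds[0], out)
    manifest["exclusions"].extend(excl)

    out_flags = modeling.detect_outliers(
        dev_feats, config.modeling.contamination, seed=seeds[1])
    for sid in dev_feats.index[out_flags]:
        manifest["exclusions"].append({"subject_id": sid, "gate": "isolation_forest"})
        log.info("excluded %s at gate isolation_forest", sid)
    dev_feats = dev_feats.loc[~out_flags]

    specs = modeling.default_model_specs(
        dev_feats.columns, seed=seeds[1], subset_range=config.modeling.subset_range)
    model = modeling.train_ensemble(dev_feats, dev_subj, specs, seed=seeds[1])
    joblib.dump(model, bundle_path)
    manifest["model_hash"] = freeze_hash(bundle_path)
    (out / "model.manifest.json").write_text(json.dumps({
        "n_constituents": len(model.constituents),
        "families": [c.spec.family for c in model.constituents],
        "seed": model.seed,
        "sha256": manifest["model_hash"],
    }, indent=2))

    dev_scores = score_cohort(model, dev_feats)
    dev_lv = dev_subj.loc[dev_feats.index, "lvedp"]
    ev = config.evaluation
    dev_mask = (dev_lv >= ev.elevated_def) | (dev_lv <= ev.nonelevated_def)
    dev_labels = (dev_lv[dev_mask] >= ev.elevated_def).astype(int)
    threshold = evaluation.sensitivity_operating_threshold(
        dev_scores[dev_mask], dev_labels, ev.target_sensitivity)
    manifest["stages"]["develop"] = {
        "n_subjects": int(config.n_dev),
        "n_trained": int(dev_feats.shape[0]),
        "operating_threshold": threshold,
    }

    # ---- phase two: blinded validation -----------------------------------
    log.info("stage simulate/qc/featurize: validation (n=%d)", config.n_val)
    val_subj, val_feats, excl = _prepare_split(
        "val", config.n_val, config, seeds[2], out)
    manifest["exclusions"].extend(excl)

    val_scores = score_cohort(model, val_feats)
    val_scores.rename("risk_score").to_csv(out / "scores_val.csv")
    val_lv = val_subj.loc[val_feats.index, "lvedp"]
    mask = (val_lv >= ev.elevated_def) | (val_lv <= ev.nonelevated_def)
    labels = (val_lv[mask] >= ev.elevated_def).astype(int)
    roc = evaluation.roc_auc(val_scores[mask], labels)
    tbl = evaluation.two_by_two(val_scores[mask], labels, threshold)
    metrics = {
        "auc": roc.auc, "auc_ci95": roc.ci95,
        "n_pos": roc.n_pos, "n_neg": roc.n_neg,
        "sens": tbl.sens, "sens_ci95": tbl.sens_ci95,
        "spec": tbl.spec, "spec_ci95": tbl.spec_ci95,
        "ppv": tbl.ppv, "npv": tbl.npv,
        "tp": tbl.tp, "fp": tbl.fp, "tn": tbl.tn, "fn": tbl.fn,
    }
    if ev.run_sweep:
        sweep = evaluation.threshold_sweep(
            val_scores[mask].to_numpy(), val_lv[mask].to_numpy(),
            elevated_defs=[ev.elevated_def],
            nonelevated_defs=list(range(12, 25)))
        sweep.to_csv(out / "sweep_val.csv")
        metrics["sweep_auc_range"] = (float(np.nanmin(sweep.to_numpy())),
                                      float(np.nanmax(sweep.to_numpy())))
    if ev.run_matching:
        pairs = evaluation.propensity_match(val_subj, seed=seeds[3])
        pairs.to_csv(out / "matched_pairs_val.csv", index=False)
        metrics["n_matched_pairs"] = int(pairs.shape[0])
    for col in ev.subgroups:
        rep = evaluation.subgroup_report(
            val_scores[mask].to_numpy(), labels.to_numpy(),
            val_subj.loc[labels.index], col)
        metrics[f"subgroup_{col}"] = {
            str(k): (None if v is None else {"auc": v.auc, "ci95": v.ci95})
            for k, v in rep["levels"].items()}
    manifest["stages"]["validate"] = metrics

    # ---- BNP comparator simulation ---------------------------------------
    bc = config.bnp
    bnp = simulate_bnp_performance(
        bc.non_elevated, bc.elevated, bc.n_non, bc.n_elev,
        bc.thresholds, bc.iterations, seed=seeds[3])
    agg = bnp.aggregate()
    nri = {str(t): {k: v for k, v in nri_vs_bnp(
        bc.ml_sens, bc.ml_spec, bnp, t).items() if k != "per_iteration"}
        for t in bc.thresholds}
    manifest["stages"]["bnpsim"] = {"aggregate": agg, "nri": nri}

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                        default=float))
    return manifest
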