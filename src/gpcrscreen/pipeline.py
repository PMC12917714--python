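"""End-to-end orchestration: featurize → score → train → evaluate →
attribute → screen → prioritize → correlate.

`run_full_pipeline` executes the whole workflow on synthetic or user data,
writes per-stage artifacts (CSV/JSON) under the output directory, and
emits a manifest sufficient to re-run the pipeline identically
(resolved configuration, seeds, input hashes, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .affinity_scoring import (
    AffinityRecord,
    apply_borderline_exclusion,
    build_offtarget_profiles,
    pair_docking_records,
    read_docking_csv,
    screen_affinity_filter,
    write_docking_csv,
)
from .attribution import explain_model, summarize, top_k_bits
from .chem_features import build_feature_matrix, read_ligand_table, write_feature_matrix
from .classifier import (
    DEFAULT_GRID,
    SplitSpec,
    fit_final,
    grid_search_cv,
    predict,
    save_model,
    stratified_split,
)
from .evaluation import (
    bootstrap_auc,
    confusion,
    metrics,
    permutation_test,
    precision_recall_f1,
    roc_auc,
)
from .screening import (
    ScreeningCandidate,
    bit_offtarget_correlation,
    percentile_select,
    prioritize,
    substructure_filter,
)
from .synthetic_data import GeneratorConfig, generate_screening_library, generate_training_set

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    """Declarative configuration of the full workflow.

    With no input paths, data come from the synthetic generator (seeded by
    ``seed``).  All counts/thresholds below default to the protocol the
    pipeline implements: 80/20 stratified split (split seed 42), 5-fold
    grid-search CV, 1000 permutations and bootstrap resamples, a K=10
    attribution background, top-5 driver bits, 90th-percentile confidence
    selection and a ±0.3 kcal/mol borderline window.
    """

    out_dir: str = "pipeline_out"
    seed: int = 42
    # input paths; None -> synthetic
    ligand_csv: str | None = None
    docking_csv: str | None = None
    library_docking_csv: str | None = None
    # synthetic generation
    n_ligands: int = 144
    library_size: int = 500
    nbits: int = 2048
    # split / training
    test_fraction: float = 0.2
    split_seed: int = 42
    cv_folds: int = 5
    # evaluation
    n_perm: int = 1000
    n_boot: int = 1000
    ci: float = 0.95
    # attribution
    background_k: int = 10
    n_explain: int = 50
    top_bits_k: int = 5
    # screening
    percentile: float = 90.0
    affinity_threshold: float = 0.3
    borderline_window: float = 0.3
    keep_ids: tuple[str, ...] = ()
    filter_mode: str = "any"
    bit_corr_top_n: int = 20
    target_receptor: str = "HCAR1"

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["keep_ids"] = list(self.keep_ids)
        return d

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "keep_ids" in data:
            data["keep_ids"] = tuple(data["keep_ids"])
        return cls(**data)


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _hash_df(df: pd.DataFrame) -> str:
    return _sha256(df.to_csv().encode())


def run_full_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and write artifacts + manifest under out_dir.

    Returns the run report (also written as ``report.json``).  Any stage
    failure propagates with the stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {}
    counts: dict[str, int] = {}
    stage = "setup"
    t0 = time.time()
    try:
        # ---- data -------------------------------------------------------
        stage = "data"
        gen_cfg = GeneratorConfig(
            n_ligands=config.n_ligands, nbits=config.nbits, seed=config.seed,
            target_receptor=config.target_receptor,
        )
        if config.ligand_csv:
            ligands = read_ligand_table(config.ligand_csv)
            docking = read_docking_csv(config.docking_csv)
        else:
            ligands, docking = generate_training_set(gen_cfg)
        counts["ligands_in"] = len(ligands)

        # ---- affinity scores -------------------------------------------
        stage = "affinity"
        affinities = pair_docking_records(docking)
        target_aff = [a for a in affinities if a.receptor_id == config.target_receptor]
        surviving = apply_borderline_exclusion(
            target_aff, window=config.borderline_window, keep_ids=config.keep_ids
        )
        surviving_ids = {a.ligand_id for a in surviving}
        ligands_kept = [l for l in ligands if l.ligand_id in surviving_ids]
        counts["after_borderline_exclusion"] = len(ligands_kept)
        pd.DataFrame(
            [(a.ligand_id, a.receptor_id, a.delta_affinity) for a in surviving],
            columns=["ligand_id", "receptor_id", "delta_affinity"],
        ).to_csv(out / "target_affinities.csv", index=False)

        # ---- features ---------------------------------------------------
        stage = "featurize"
        aff_map = {a.ligand_id: a.delta_affinity for a in surviving}
        matrix = build_feature_matrix(ligands_kept, aff_map, nbits=config.nbits)
        labels = np.array([l.label for l in ligands_kept])
        write_feature_matrix(matrix, out / "features.csv")

        # ---- split / train ---------------------------------------------
        stage = "train"
        split = SplitSpec(test_fraction=config.test_fraction, seed=config.split_seed)
        train_idx, test_idx = stratified_split(matrix, labels, split)
        counts["train"], counts["test"] = len(train_idx), len(test_idx)
        X_train, X_test = matrix.iloc[train_idx], matrix.iloc[test_idx]
        y_train, y_test = labels[train_idx], labels[test_idx]
        best, cv_acc = grid_search_cv(
            X_train, y_train, DEFAULT_GRID, k=config.cv_folds, seed=config.split_seed
        )
        model = fit_final(X_train, y_train, best, seed=config.split_seed)
        save_model(model, out / "model.bin")
        report["best_params"] = {"C": best.C, "gamma": best.gamma, "kernel": best.kernel}
        report["cv_accuracy"] = cv_acc

        # ---- evaluate ---------------------------------------------------
        stage = "evaluate"
        test_pred = predict(model, X_test)
        pred_classes = [p.predicted_class for p in test_pred]
        scores = [p.prob_antagonist for p in test_pred]
        cm = confusion(pred_classes, y_test, positive_class=1)
        m = metrics(cm)
        prec, rec, f1 = precision_recall_f1(cm)
        perm = permutation_test(
            X_train.to_numpy(float), y_train, best,
            n_perm=config.n_perm, k=config.cv_folds, seed=config.seed,
        )
        boot = bootstrap_auc(scores, y_test, n_boot=config.n_boot,
                             ci=config.ci, seed=config.seed)
        report["evaluation"] = {
            "confusion": {"tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn},
            "accuracy": m.accuracy, "sensitivity": m.sensitivity,
            "specificity": m.specificity,
            "precision": prec, "recall": rec, "f1": f1,
            "test_auc": roc_auc(scores, y_test),
            "permutation_p": perm.p_value,
            "permutation_observed_cv_accuracy": perm.observed_accuracy,
            "permutation_p_report": perm.p_report,
            "bootstrap_auc_mean": boot.mean_auc,
            "bootstrap_ci": [boot.ci_low, boot.ci_high],
            "bootstrap_skipped_resamples": boot.n_skipped,
        }

        # ---- attribution ------------------------------------------------
        stage = "attribute"
        attr = explain_model(
            model, X_train, n_explain=config.n_explain,
            background_k=config.background_k, seed=config.seed,
        )
        bits = top_k_bits(attr, k=config.top_bits_k)
        summarize(attr, "descriptors").to_csv(out / "shap_descriptors.csv", index=False)
        summarize(attr, "fingerprints").head(50).to_csv(
            out / "shap_fingerprints.csv", index=False
        )
        pd.DataFrame({"bit": bits.bits, "mean_abs_shap": bits.mean_abs_shap}).to_csv(
            out / "top_bits.csv", index=False
        )
        report["top_bits"] = list(bits.bits)

        # ---- screening funnel ------------------------------------------
        stage = "screen"
        library = generate_screening_library(gen_cfg, n=config.library_size)
        counts["library"] = len(library.ligands)
        lib_aff = pair_docking_records(library.docking)
        lib_target = {a.ligand_id: a.delta_affinity for a in lib_aff
                      if a.receptor_id == config.target_receptor}

        stage1 = substructure_filter(library.ligands, bits, mode=config.filter_mode)
        counts["after_bit_filter"] = len(stage1)
        stage1_aff = [AffinityRecord(l.ligand_id, config.target_receptor,
                                     lib_target[l.ligand_id]) for l in stage1]
        stage2_aff = screen_affinity_filter(stage1_aff, threshold=config.affinity_threshold)
        stage2_ids = {a.ligand_id for a in stage2_aff}
        stage2 = [l for l in stage1 if l.ligand_id in stage2_ids]
        counts["after_affinity_filter"] = len(stage2)

        if stage2:
            lib_matrix = build_feature_matrix(stage2, lib_target, nbits=config.nbits)
            lib_pred = predict(model, lib_matrix)
            antagonists = [p for p in lib_pred if p.predicted_class == 1]
            counts["predicted_antagonists"] = len(antagonists)
            selected = percentile_select(antagonists, pct=config.percentile)
        else:
            antagonists, selected = [], []
        counts["top_confidence"] = len(selected)
        sel_ids = [p.ligand_id for p in selected]
        pd.DataFrame(
            [(p.ligand_id, p.prob_antagonist, p.confidence_score, p.confidence_percentile)
             for p in selected],
            columns=["ligand_id", "prob_antagonist", "confidence", "percentile"],
        ).to_csv(out / "top_confidence.csv", index=False)

        # ---- off-target prioritization ---------------------------------
        stage = "prioritize"
        sel_panel = [a for a in lib_aff if a.ligand_id in sel_ids]
        profiles = {p.ligand_id: p for p in
                    build_offtarget_profiles(sel_panel, config.target_receptor)}
        lig_by_id = {l.ligand_id: l for l in library.ligands}
        pred_by_id = {p.ligand_id: p for p in selected}
        candidates = [
            ScreeningCandidate(
                ligand=lig_by_id[i], source_library="synthetic",
                target_delta_affinity=lib_target[i],
                prediction=pred_by_id[i], off_target=profiles[i],
            )
            for i in sel_ids
        ]
        ranked = prioritize(candidates) if candidates else []
        pd.DataFrame(
            [(c.ligand_id, c.target_delta_affinity, c.off_target.off_target_score)
             for c in ranked],
            columns=["ligand_id", "target_delta_affinity", "off_target_score"],
        ).to_csv(out / "prioritized.csv", index=False)

        # ---- bit / selectivity correlation ------------------------------
        stage = "correlate"
        correlations = []
        if len(ranked) >= 2:
            ot_scores = [c.off_target.off_target_score for c in ranked]
            if len(set(ot_scores)) > 1:
                correlations = bit_offtarget_correlation(
                    [c.ligand for c in ranked], ot_scores, top_n=config.bit_corr_top_n
                )
        pd.DataFrame(
            [(bc.bit, bc.spearman_r, bc.direction) for bc in correlations],
            columns=["bit", "spearman_r", "direction"],
        ).to_csv(out / "bit_correlations.csv", index=False)

        # ---- enrichment (synthetic truth available) ---------------------
        if config.ligand_csv is None and ranked:
            hidden = dict(zip((l.ligand_id for l in library.ligands),
                              library.hidden_labels))
            base_rate = float(np.mean(library.hidden_labels))
            hit_rate = float(np.mean([hidden[c.ligand_id] for c in ranked]))
            report["enrichment"] = {
                "library_base_rate": base_rate,
                "survivor_hit_rate": hit_rate,
                "enrichment_factor": hit_rate / base_rate if base_rate else float("nan"),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report["stage_counts"] = counts
    report["runtime_seconds"] = round(time.time() - t0, 2)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seeds": {"pipeline": config.seed, "split": config.split_seed},
        "input_hashes": {
            "features": _hash_df(matrix),
            "labels": _sha256(labels.tobytes()),
        },
        "stage_counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return report
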