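"""End-to-end experiment orchestration.

One config drives: cohort generation (or manifest loading), preprocessing,
hand-crafted + deep feature extraction, the model x feature-set grid under
patient-level repeated CV with bootstrap bias correction, pairwise tests,
and report serialization.  A single global seed deterministically derives
every per-stage, per-fold and per-bootstrap substream, so results never
depend on execution order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as nio
from .cohort import CohortConfig, PatientCase, generate_cohort
from .deep import (
    Backbone,
    BackboneConfig,
    build_backbone,
    deep_feature_maps,
    deep_feature_names,
    forward_all_pooled,
)
from .errors import NodalradError
from .evaluation import (
    ArmReport,
    compare_arms,
    cross_validate,
    evaluate_arm,
    make_patient_folds,
    patient_balance,
)
from .handcrafted import (
    DiscretizationConfig,
    assemble_handcrafted,
    compute_voxel_map,
)
from .models import FeatureSetSpec, assemble_feature_set, sample_hyperparameters
from .preprocessing import (
    DEFAULT_WINDOW,
    NodeVOI,
    preprocess_node,
    standardize_stack,
)

validate_manifest = nio.validate_manifest


@dataclass(frozen=True)
class PreprocessingConfig:
    target_spacing_mm: float = 1.0
    z_slices: int = 10
    xy_size: tuple[int, int] = (224, 224)
    window: tuple[float, float] = DEFAULT_WINDOW


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one run needs; sub-seeds derive from ``seed``."""

    cohort: CohortConfig = CohortConfig()
    manifest_path: str | None = None  # when set, read instead of simulate
    preprocessing: PreprocessingConfig = PreprocessingConfig()
    discretization: DiscretizationConfig = DiscretizationConfig()
    backbone: BackboneConfig = BackboneConfig()
    feature_sets: tuple[str, ...] = ("handcrafted", "deep", "hybrid")
    models: tuple[str, ...] = ("elastic_logit", "random_forest")
    n_configs_per_model: int = 10
    depth_k_choices: tuple[int, ...] = (1, 2, 3, 4)
    folds: int = 20
    repeats: int = 10
    bbc_bootstrap: int = 1000
    test_bootstrap: int = 1000
    seed: int = 0

    @staticmethod
    def from_dict(d: Mapping) -> "ExperimentConfig":
        d = dict(d)
        for key, cls in [
            ("cohort", CohortConfig),
            ("preprocessing", PreprocessingConfig),
            ("discretization", DiscretizationConfig),
            ("backbone", BackboneConfig),
        ]:
            if key in d and isinstance(d[key], Mapping):
                sub = dict(d[key])
                for f in dataclasses.fields(cls):
                    if f.name in sub and isinstance(sub[f.name], list):
                        sub[f.name] = tuple(sub[f.name])
                d[key] = cls(**sub)
        for f in dataclasses.fields(ExperimentConfig):
            if f.name in d and isinstance(d[f.name], list):
                d[f.name] = tuple(d[f.name])
        return ExperimentConfig(**d)

    @staticmethod
    def from_file(path: str | Path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return ExperimentConfig.from_dict(yaml.safe_load(fh))


def _stage_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % 2**31)


@dataclass
class FeatureBundle:
    """Aligned per-node feature tables and metadata."""

    handcrafted: pd.DataFrame            # indexed by node_id
    deep: dict[int, pd.DataFrame]        # depth_k -> table
    labels: np.ndarray
    patient_ids: list[str]
    node_ids: list[str]
    vois: list[NodeVOI] | None = None    # kept only when feature maps are wanted


def _iter_nodes(source):
    """Yield (node_id, patient_id, label, image, mask) from a cohort or handle."""
    if isinstance(source, nio.CohortHandle):
        for rec in source.records:
            image, mask = rec.load()
            yield rec.node_id, rec.patient_id, rec.label, image, mask
    else:
        for case in source:
            for i, node in enumerate(case.nodes):
                yield (f"{case.patient_id}_N{i:03d}", case.patient_id,
                       node.label, node.image, node.mask)


def extract_features(
    source: list[PatientCase] | nio.CohortHandle,
    preproc: PreprocessingConfig = PreprocessingConfig(),
    disc: DiscretizationConfig = DiscretizationConfig(),
    backbone: Backbone | BackboneConfig = BackboneConfig(),
    depth_ks: tuple[int, ...] = (1, 2, 3, 4),
    keep_vois: bool = False,
) -> FeatureBundle:
    """Run preprocessing + both extractors over every node of a cohort."""
    if isinstance(backbone, BackboneConfig):
        backbone = build_backbone(backbone)
    max_k = max(depth_ks)
    hand_rows, deep_rows = [], {k: [] for k in depth_ks}
    node_ids, patient_ids, labels, vois = [], [], [], []
    for node_id, pid, label, image, mask in _iter_nodes(source):
        voi = preprocess_node(image, mask, preproc.target_spacing_mm,
                              patient_id=pid, label=label)
        hand_rows.append(assemble_handcrafted(voi, disc))
        stack = standardize_stack(voi, preproc.z_slices, preproc.xy_size,
                                  preproc.window)
        pooled = forward_all_pooled(backbone, stack, max_k)
        for k in depth_ks:
            deep_rows[k].append(dict(zip(deep_feature_names(backbone.config, k),
                                         pooled[k])))
        node_ids.append(node_id)
        patient_ids.append(pid)
        labels.append(int(label))
        if keep_vois:
            vois.append(voi)
    hand_df = pd.DataFrame(hand_rows, index=node_ids)
    deep_dfs = {k: pd.DataFrame(deep_rows[k], index=node_ids) for k in depth_ks}
    return FeatureBundle(
        handcrafted=hand_df,
        deep=deep_dfs,
        labels=np.asarray(labels, dtype=int),
        patient_ids=patient_ids,
        node_ids=node_ids,
        vois=vois if keep_vois else None,
    )


def features_for_set(bundle: FeatureBundle, kind: str) -> pd.DataFrame | dict[int, pd.DataFrame]:
    """The design table(s) one feature set sees.

    Handcrafted is a single table; deep and hybrid are keyed by CNN depth
    because the deep block changes with the depth hyperparameter.
    """
    spec = FeatureSetSpec(kind)
    if kind == "handcrafted":
        any_k = next(iter(bundle.deep))
        return assemble_feature_set(bundle.handcrafted, bundle.deep[any_k], spec)
    return {
        k: assemble_feature_set(bundle.handcrafted, df, spec)
        for k, df in bundle.deep.items()
    }


def _arm_row(report: ArmReport) -> dict:
    return {
        "feature_set": report.feature_set,
        "model": report.model,
        "auc": round(report.auc, 6),
        "auc_ci_low": round(report.auc_ci[0], 6),
        "auc_ci_high": round(report.auc_ci[1], 6),
        "brier": round(report.brier, 6),
        "brier_ci_low": round(report.brier_ci[0], 6),
        "brier_ci_high": round(report.brier_ci[1], 6),
        "sbs_percent": round(report.sbs, 4),
        "sbs_ci_low": round(report.sbs_ci[0], 4),
        "sbs_ci_high": round(report.sbs_ci[1], 4),
        "sensitivity": round(report.sensitivity, 6),
        "specificity": round(report.specificity, 6),
        "cutoff": round(report.cutoff, 6),
        "selected_config": report.selected_config_id,
    }


def run_evaluation_grid(
    bundle: FeatureBundle,
    config: ExperimentConfig,
) -> tuple[dict[tuple[str, str], ArmReport], dict, "np.ndarray"]:
    """CV + BBC for every (feature set x model) arm, plus pairwise tests."""
    plan = make_patient_folds(
        list(dict.fromkeys(bundle.patient_ids)),
        config.folds,
        config.repeats,
        _stage_seed(config.seed, 1),
        balance=patient_balance(bundle.patient_ids, bundle.labels),
    )
    reports: dict[tuple[str, str], ArmReport] = {}
    # one config list per model family, shared by all feature sets, so the
    # arm comparison is not confounded by per-arm sampling luck
    model_configs = {
        model: sample_hyperparameters(
            None,
            config.n_configs_per_model,
            _stage_seed(config.seed, 2, mi),
            models=(model,),
            depth_k_choices=config.depth_k_choices,
        )
        for mi, model in enumerate(config.models)
    }
    for si, fs in enumerate(config.feature_sets):
        feats = features_for_set(bundle, fs)
        if fs == "handcrafted" and isinstance(feats, dict):  # pragma: no cover
            feats = next(iter(feats.values()))
        for mi, model in enumerate(config.models):
            configs = model_configs[model]
            matrix = cross_validate(
                feats, bundle.labels, bundle.patient_ids, configs, plan,
                seed=_stage_seed(config.seed, 3, si, mi),
            )
            reports[(fs, model)] = evaluate_arm(
                matrix, fs, model,
                B=config.bbc_bootstrap,
                seed=_stage_seed(config.seed, 4, si, mi),
            )
    tests = {}
    for mi, model in enumerate(config.models):
        if "hybrid" not in config.feature_sets:
            continue
        for oi, other in enumerate(("handcrafted", "deep")):
            if other not in config.feature_sets:
                continue
            res = compare_arms(
                bundle.labels,
                reports[("hybrid", model)],
                reports[(other, model)],
                B=config.test_bootstrap,
                seed=_stage_seed(config.seed, 5, mi, oi),
            )
            for metric, r in res.items():
                tests[f"{model}:hybrid_vs_{other}:{metric}"] = {
                    "difference": round(r.difference, 6),
                    "z": round(r.z, 4),
                    "p": float(r.p),
                }
    return reports, tests, plan


def _write_feature_maps(bundle: FeatureBundle, backbone: Backbone,
                        preproc: PreprocessingConfig, out: Path) -> list[str]:
    """Fig-3-style maps for one positive and one negative example node."""
    import nibabel as nib

    if bundle.vois is None:
        return []
    paths = []
    for wanted in (1, 0):
        idx = next((i for i, voi in enumerate(bundle.vois) if voi.label == wanted), None)
        if idx is None:
            continue
        voi = bundle.vois[idx]
        tag = "positive" if wanted else "negative"
        for feat in ("firstorder.mean", "glcm.contrast"):
            vmap = compute_voxel_map(voi, feat, kernel_radius=2)
            affine = np.diag(list(vmap.spacing) + [1.0])
            p = out / f"featuremap_{tag}_{feat.replace('.', '_')}.nii.gz"
            nib.save(nib.Nifti1Image(vmap.voxels.astype(np.float32), affine), p)
            paths.append(str(p))
        stack = standardize_stack(voi, preproc.z_slices, preproc.xy_size,
                                  preproc.window)
        maps = deep_feature_maps(backbone, stack, layer_index=min(3, backbone.n_stages))
        arr = np.stack(maps[:8], axis=0)
        p = out / f"featuremap_{tag}_deep_stage3.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.float32), np.eye(4)), p)
        paths.append(str(p))
    return paths


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict[str, str]:
    """Execute the full comparison and write the report files.

    Returns a mapping of artifact names to paths.  Reproducible bit-for-bit
    from (config, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        if config.manifest_path:
            source = validate_manifest(config.manifest_path)
        else:
            cohort_cfg = dataclasses.replace(
                config.cohort, seed=_stage_seed(config.seed, 0)
            )
            source = generate_cohort(cohort_cfg)
    except NodalradError as exc:
        raise NodalradError(f"stage=cohort: {exc}") from exc

    backbone = build_backbone(config.backbone)
    try:
        need_deep = {"deep", "hybrid"} & set(config.feature_sets)
        depth_ks = config.depth_k_choices if need_deep else (1,)
        bundle = extract_features(
            source, config.preprocessing, config.discretization, backbone,
            depth_ks=depth_ks, keep_vois=True,
        )
    except NodalradError as exc:
        raise NodalradError(f"stage=features: {exc}") from exc

    try:
        reports, tests, plan = run_evaluation_grid(bundle, config)
    except NodalradError as exc:
        raise NodalradError(f"stage=evaluation: {exc}") from exc

    rows = [_arm_row(r) for r in reports.values()]
    table = pd.DataFrame(rows)
    table_path = out / "report.csv"
    table.to_csv(table_path, index=False)

    curves = []
    for (fs, model), rep in reports.items():
        for pred, obs in rep.calibration_curve:
            curves.append({"feature_set": fs, "model": model, "kind": "calibration",
                           "x": float(pred), "y": float(obs)})
        from sklearn.metrics import roc_curve

        fpr, tpr, _ = roc_curve(bundle.labels, rep.pooled_predictions)
        for x, yv in zip(fpr, tpr):
            curves.append({"feature_set": fs, "model": model, "kind": "roc",
                           "x": float(x), "y": float(yv)})
    curves_path = out / "curves.csv"
    pd.DataFrame(curves).to_csv(curves_path, index=False)

    map_paths = _write_feature_maps(bundle, backbone, config.preprocessing, out)

    report = {
        "n_nodes": int(len(bundle.node_ids)),
        "n_patients": int(len(set(bundle.patient_ids))),
        "prevalence": round(float(bundle.labels.mean()), 6),
        "arms": rows,
        "pairwise_tests": tests,
        "seed": config.seed,
    }
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return {
        "report_json": str(report_path),
        "report_csv": str(table_path),
        "curves_csv": str(curves_path),
        "feature_maps": ",".join(map_paths),
    }
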