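"""End-to-end orchestration: cohort -> features -> selection -> model -> AUC.

All preprocessing (imputation, min-max scaling, instance-feature
standardization, feature selection) is fitted on training bags only and
frozen before it touches held-out bags; every fitted object records the
bag ids it saw so the leakage audit can assert an empty intersection with
the test fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import train_test_split

from .biomarkers import (
    MARKERS,
    ImputationModel,
    NormalizationParams,
    apply_minmax,
    fit_minmax,
    impute_mice_pmm,
)
from .features import BackboneSpec, FeatureBag, extract_features
from .model import ModelConfig
from .selection import SelectionResult, apply_selection, select_feature_dims
from .stats import EvalReport, evaluate_scores, roc_auc
from .synthetic import SyntheticConfig, SyntheticCohort, generate_cohort
from .training import TrainConfig, predict_scores, stratified_kfold, train

__all__ = [
    "FittedTransforms",
    "fit_transforms",
    "apply_transforms",
    "assert_no_leakage",
    "extract_cohort_features",
    "run_split_experiment",
    "fine_tune_experiment",
    "cross_validate",
    "shifted_cohort_config",
]


@dataclass
class FittedTransforms:
    imputation: ImputationModel
    norm: NormalizationParams
    selection: SelectionResult
    feat_mean: np.ndarray
    feat_std: np.ndarray
    seen_ids: tuple
    seed: int

    def fingerprint(self) -> dict:
        return {
            "n_keep": int(self.selection.n_keep),
            "kept_dims": self.selection.kept_dims.tolist(),
        }


def extract_cohort_features(cohort: SyntheticCohort, spec: BackboneSpec) -> list:
    return [extract_features(bag, spec) for bag in cohort.bags]


def _standardize(fb: FeatureBag, mean, std) -> FeatureBag:
    return FeatureBag(
        bag_id=fb.bag_id,
        matrix=(fb.matrix - mean) / std,
        label=fb.label,
        coords=fb.coords,
    )


def fit_transforms(
    train_bags: list,
    train_table,
    seed: int = 0,
    n_keep: int | None = None,
) -> FittedTransforms:
    """Fit imputation, min-max, feature standardization and selection on
    the training portion only."""
    completed, imp_model = impute_mice_pmm(train_table, seed=seed)
    norm = fit_minmax(completed)

    stacked = np.vstack([fb.matrix for fb in train_bags])
    mean = stacked.mean(axis=0)
    std = np.maximum(stacked.std(axis=0), 1e-8)

    std_bags = [_standardize(fb, mean, std) for fb in train_bags]
    pos = [fb for fb in std_bags if fb.label == 1]
    neg = [fb for fb in std_bags if fb.label == 0]
    selection = select_feature_dims(pos, neg, n_keep=n_keep)

    return FittedTransforms(
        imputation=imp_model,
        norm=norm,
        selection=selection,
        feat_mean=mean,
        feat_std=std,
        seen_ids=tuple(fb.bag_id for fb in train_bags),
        seed=seed,
    )


def apply_transforms(bags: list, table, t: FittedTransforms) -> tuple:
    """(selected FeatureBags, normalized biomarker matrix) for any cohort slice."""
    completed = t.imputation.apply(table, seed=t.seed)
    normed = apply_minmax(completed, t.norm)
    bio = normed[list(MARKERS)].to_numpy(dtype=float)
    out_bags = [
        apply_selection(_standardize(fb, t.feat_mean, t.feat_std), t.selection)
        for fb in bags
    ]
    return out_bags, bio


def assert_no_leakage(t: FittedTransforms, test_ids) -> None:
    """Every fitted transform must have been fitted without the test bags."""
    seen = set(t.seen_ids) | set(t.imputation.seen_ids) | set(t.norm.seen_ids)
    seen |= {b for b in t.selection.seen_bag_ids if b is not None}
    overlap = seen & set(test_ids)
    if overlap:
        raise AssertionError(f"transform fitted on test bags: {sorted(overlap)}")


def _table_rows(table, idx):
    return table.iloc[list(idx)].reset_index(drop=True)


def run_split_experiment(
    seed: int,
    modes: tuple = ("fused", "image", "biomarker"),
    cohort_config: SyntheticConfig | None = None,
    train_config: TrainConfig | None = None,
    backbone: BackboneSpec | None = None,
    n_keep: int = 16,
    test_fraction: float = 0.5,
) -> dict:
    """Generate a cohort, split it, train one model per modality, report AUCs.

    The default study conditions are the package defaults: 80 patients split
    40 train / 40 test, 20 tiles of 64 px per bag, the convolutional test
    backbone, and one model per requested mode trained under identical
    sampling and seeds.
    """
    cfg = cohort_config or SyntheticConfig(seed=seed)
    if cfg.seed != seed:
        cfg = replace(cfg, seed=seed)
    cohort = generate_cohort(cfg)
    spec = backbone or BackboneSpec(input_size=cfg.tile_size, seed=0)
    feature_bags = extract_cohort_features(cohort, spec)

    idx = np.arange(cfg.n_patients)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        stratify=cohort.labels,
        random_state=seed,
    )
    train_bags = [feature_bags[i] for i in train_idx]
    test_bags = [feature_bags[i] for i in test_idx]
    y_train = cohort.labels[train_idx]
    y_test = cohort.labels[test_idx]

    transforms = fit_transforms(
        train_bags, _table_rows(cohort.biomarkers, train_idx), seed=seed, n_keep=n_keep
    )
    assert_no_leakage(transforms, [feature_bags[i].bag_id for i in test_idx])

    tr_sel, tr_bio = apply_transforms(
        train_bags, _table_rows(cohort.biomarkers, train_idx), transforms
    )
    te_sel, te_bio = apply_transforms(
        test_bags, _table_rows(cohort.biomarkers, test_idx), transforms
    )

    tcfg = train_config or TrainConfig(seed=seed)
    results = {}
    for mode in modes:
        mcfg = ModelConfig(in_dim=transforms.selection.n_keep, mode=mode, seed=seed)
        model, log = train(tr_sel, tr_bio, y_train, mcfg, tcfg)
        scores = predict_scores(model, te_sel, te_bio)
        results[mode] = {
            "auc": roc_auc(scores, y_test),
            "scores": scores,
            "model": model,
            "log": log,
        }

    return {
        "cohort": cohort,
        "feature_bags": feature_bags,
        "backbone": spec,
        "transforms": transforms,
        "train_idx": train_idx,
        "test_idx": test_idx,
        "y_test": y_test,
        "test_bags_selected": te_sel,
        "test_bio": te_bio,
        "results": results,
    }


def shifted_cohort_config(
    base: SyntheticConfig,
    seed: int,
    marker_scale: float = 1.5,
    stain_offset: tuple = (-35, -20, 15),
) -> SyntheticConfig:
    """A domain-shifted copy of the study conditions: all biomarker medians
    multiplied by ``marker_scale`` (assay calibration gap) and every tile's
    RGB values offset by ``stain_offset`` (staining-protocol drift between
    centres)."""
    params = {
        m: {c: (mu + math.log(marker_scale), sd) for c, (mu, sd) in d.items()}
        for m, d in base.biomarker_params.items()
    }
    return replace(base, biomarker_params=params, stain_offset=stain_offset, seed=seed)


def fine_tune_experiment(
    seed: int,
    marker_scale: float = 1.5,
    stain_offset: tuple = (-35, -20, 15),
    ft_epochs: int = 5,
    cohort_config: SyntheticConfig | None = None,
    train_config: TrainConfig | None = None,
    n_keep: int = 16,
    base_experiment: dict | None = None,
) -> dict:
    """Train on cohort A, evaluate frozen vs fine-tuned on a shifted cohort B.

    Cohort B differs from A by a centre-style domain shift: a multiplicative
    rescaling of the biomarker medians (assay calibration gap) plus a stain
    offset on every tile (staining-protocol drift). Half of B is the
    fine-tuning set, the other half the test set. Transforms fitted on A are
    applied unchanged to B — the shift is exactly what the frozen model must
    cope with; fine-tuning runs a few low-learning-rate epochs from the
    frozen checkpoint.
    """
    base = base_experiment
    if base is None or "fused" not in base["results"]:
        base = run_split_experiment(
            seed,
            modes=("fused",),
            cohort_config=cohort_config,
            train_config=train_config,
            n_keep=n_keep,
        )
    cfg_a = base["cohort"].config
    tcfg = train_config or TrainConfig(seed=seed)

    cfg_b = shifted_cohort_config(
        cfg_a, seed + 100_000, marker_scale=marker_scale, stain_offset=stain_offset
    )
    cohort_b = generate_cohort(cfg_b)
    spec = base["backbone"]
    bags_b = extract_cohort_features(cohort_b, spec)

    idx = np.arange(cfg_b.n_patients)
    ft_idx, test_idx = train_test_split(
        idx, test_size=0.5, stratify=cohort_b.labels, random_state=seed + 1
    )
    transforms = base["transforms"]
    ft_sel, ft_bio = apply_transforms(
        [bags_b[i] for i in ft_idx], _table_rows(cohort_b.biomarkers, ft_idx), transforms
    )
    te_sel, te_bio = apply_transforms(
        [bags_b[i] for i in test_idx], _table_rows(cohort_b.biomarkers, test_idx), transforms
    )
    y_ft = cohort_b.labels[ft_idx]
    y_te = cohort_b.labels[test_idx]

    frozen_model = base["results"]["fused"]["model"]
    frozen_auc = roc_auc(predict_scores(frozen_model, te_sel, te_bio), y_te)

    ft_cfg = TrainConfig(
        learning_rate=tcfg.learning_rate * 0.3,
        epochs=ft_epochs,
        batch_size=tcfg.batch_size,
        seed=seed,
        fine_tune_from=frozen_model,
    )
    mcfg = ModelConfig(in_dim=n_keep, mode="fused", seed=seed)
    ft_model, _ = train(ft_sel, ft_bio, y_ft, mcfg, ft_cfg)
    ft_auc = roc_auc(predict_scores(ft_model, te_sel, te_bio), y_te)

    return {"frozen_auc": frozen_auc, "fine_tuned_auc": ft_auc, "seed": seed}


def cross_validate(
    cohort: SyntheticCohort,
    k: int = 6,
    seed: int = 0,
    mode: str = "fused",
    train_config: TrainConfig | None = None,
    backbone: BackboneSpec | None = None,
    n_keep: int = 16,
    bootstrap_B: int = 1000,
) -> EvalReport:
    """Stratified k-fold cross-validation on one cohort; pooled + per-fold AUC."""
    spec = backbone or BackboneSpec(input_size=cohort.config.tile_size, seed=0)
    feature_bags = extract_cohort_features(cohort, spec)
    bag_ids = [fb.bag_id for fb in feature_bags]
    plan = stratified_kfold(cohort.labels, k=k, seed=seed, bag_ids=bag_ids)
    tcfg = train_config or TrainConfig(seed=seed)

    n = len(feature_bags)
    pooled_scores = np.empty(n)
    per_fold_auc = []
    for fold in range(k):
        test_ids = set(plan.fold_ids(fold))
        te = [i for i in range(n) if bag_ids[i] in test_ids]
        tr = [i for i in range(n) if bag_ids[i] not in test_ids]
        transforms = fit_transforms(
            [feature_bags[i] for i in tr],
            _table_rows(cohort.biomarkers, tr),
            seed=seed,
            n_keep=n_keep,
        )
        assert_no_leakage(transforms, [bag_ids[i] for i in te])
        tr_sel, tr_bio = apply_transforms(
            [feature_bags[i] for i in tr], _table_rows(cohort.biomarkers, tr), transforms
        )
        te_sel, te_bio = apply_transforms(
            [feature_bags[i] for i in te], _table_rows(cohort.biomarkers, te), transforms
        )
        mcfg = ModelConfig(in_dim=transforms.selection.n_keep, mode=mode, seed=seed)
        model, _ = train(tr_sel, tr_bio, cohort.labels[tr], mcfg, tcfg)
        scores = predict_scores(model, te_sel, te_bio)
        pooled_scores[te] = scores
        if len(set(cohort.labels[te])) == 2:
            per_fold_auc.append(roc_auc(scores, cohort.labels[te]))

    return evaluate_scores(
        pooled_scores,
        cohort.labels,
        B=bootstrap_B,
        seed=seed,
        per_fold_auc=per_fold_auc,
    )
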