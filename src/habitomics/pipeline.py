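"""End-to-end orchestration: phantoms -> partition -> features -> selection
-> logistic model -> train/validation ROC summaries.

Every stage is seeded from a single pipeline seed (via numpy SeedSequence
spawning), so a fixed configuration reproduces byte-identical outputs.
Reproducibility (ICC) tables come from re-extracting all features under a
second observer's mask and under a repeat segmentation by the first
observer, both simulated by boundary perturbation; the habitat partition is
computed once on the primary masks and subregions are intersected with each
alternative mask.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from habitomics.deep import BackboneSpec, extract_cohort
from habitomics.features.extract import FeatureConfig, extract_all
from habitomics.habitat import build_partition
from habitomics.imaging_io import write_labelmap
from habitomics.models import linear_predictor, roc_auc, youden_threshold
from habitomics.phantom import PhantomSpec, generate_cohort, perturb_mask
from habitomics.selection import SelectionConfig, run_selection

log = logging.getLogger("habitomics")


@dataclass
class PipelineConfig:
    synthetic: bool = True
    n_cases: int = 40
    effect_size: float = 2.0
    seed: int = 0
    base_spec: PhantomSpec | None = None
    subregion: str = "S1"
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    train_fraction: float = 2.0 / 3.0
    ci_method: str = "delong"
    out_dir: str | None = None


def _stratified_split(case_ids, y, train_fraction, rng):
    train = []
    for cls in np.unique(y):
        idx = [cid for cid, yi in zip(case_ids, y) if yi == cls]
        n_train = int(round(train_fraction * len(idx)))
        picked = rng.choice(len(idx), size=n_train, replace=False)
        train += [idx[i] for i in picked]
    return sorted(train)


def _feature_table(cases, partition, subregion, config, masks=None) -> pd.DataFrame:
    rank = int(subregion[1:])
    rows = {}
    for case in cases:
        sub = partition.labels[case.case_id] == rank
        if masks is not None:
            sub = sub & (masks[case.case_id].data != 0)
        if not sub.any():
            warnings.warn(f"{case.case_id}: empty {subregion}, skipped", stacklevel=2)
            continue
        rows[case.case_id] = extract_all(case.volume, sub, config)
    return pd.DataFrame.from_dict(rows, orient="index")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic-cohort analysis; returns the result dict.

    The result carries the selected partition size, the per-stage feature
    counts, the fitted model, and train/validation performance summaries.
    With ``config.out_dir`` set, subregion label maps (NIfTI), feature tables
    and reports (CSV), and the performance JSON are also written there.
    """
    if not config.synthetic:
        raise NotImplementedError(
            "only synthetic cohorts are wired into run_pipeline; use the "
            "library functions directly for external data"
        )
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(5)]

    log.info("generating cohort: n=%d effect_size=%s", config.n_cases, config.effect_size)
    cohort = generate_cohort(
        config.n_cases, config.effect_size, base_spec=config.base_spec, seed=seeds[0]
    )
    case_ids = [c.case_id for c in cohort.cases]
    labels = pd.Series(cohort.outcome, index=case_ids)

    log.info("building habitat partition")
    partition = build_partition(cohort.cases, seed=seeds[1])

    masks_obs1 = {c.case_id: c.mask for c in cohort.cases}
    masks_obs2 = {c.case_id: c.mask_observer2 for c in cohort.cases}
    rng_rep = np.random.default_rng(seeds[2])
    masks_rep = {
        c.case_id: perturb_mask(c.mask, magnitude_vox=1, seed=int(rng_rep.integers(2**31 - 1)))
        for c in cohort.cases
    }

    log.info("extracting handcrafted features (3 segmentation sets)")
    fc = config.feature_config
    hand = _feature_table(cohort.cases, partition, config.subregion, fc, masks_obs1)
    hand2 = _feature_table(cohort.cases, partition, config.subregion, fc, masks_obs2)
    hand_rep = _feature_table(cohort.cases, partition, config.subregion, fc, masks_rep)

    log.info("extracting deep features (3 segmentation sets)")
    backbone = BackboneSpec(weights=("random", seeds[3]))
    deep = pd.DataFrame.from_dict(
        extract_cohort(cohort.cases, partition, config.subregion, backbone, masks_obs1),
        orient="index",
    )
    deep2 = pd.DataFrame.from_dict(
        extract_cohort(cohort.cases, partition, config.subregion, backbone, masks_obs2),
        orient="index",
    )
    deep_rep = pd.DataFrame.from_dict(
        extract_cohort(cohort.cases, partition, config.subregion, backbone, masks_rep),
        orient="index",
    )

    features = hand.join(deep, how="inner")
    features2 = hand2.join(deep2, how="inner")
    features_rep = hand_rep.join(deep_rep, how="inner")
    common = features.index.intersection(features2.index).intersection(features_rep.index)
    features, features2, features_rep = (
        features.loc[common],
        features2.loc[common],
        features_rep.loc[common],
    )
    labels = labels.loc[common]

    rng_split = np.random.default_rng(seeds[4])
    train_ids = _stratified_split(list(common), labels.to_numpy(), config.train_fraction, rng_split)
    val_ids = [c for c in common if c not in train_ids]

    log.info("running selection chain on %d features", features.shape[1])
    report, model = run_selection(
        features,
        labels,
        features2,
        features_rep,
        train_index=train_ids,
        config=config.selection,
        model_name="LR-synthetic",
    )

    # score every case with the final model on z-scored features
    if model.coefficients:
        mu = report.standardization["mean"]
        sd = report.standardization["sd"]
        Z = (features[report.standardization.index] - mu) / sd
        scores = pd.Series(
            [linear_predictor(model, Z.loc[cid].to_dict()) for cid in features.index],
            index=features.index,
        )
    else:
        scores = pd.Series(model.intercept, index=features.index)

    y = labels.to_numpy()
    s = scores.to_numpy()
    tr = labels.index.isin(train_ids)
    thr = youden_threshold(s[tr], y[tr])
    perf_train = roc_auc(s[tr], y[tr], ci_method=config.ci_method, threshold=thr)
    perf_val = roc_auc(s[~tr], y[~tr], ci_method=config.ci_method, threshold=thr)

    result = {
        "config": {
            "n_cases": config.n_cases,
            "effect_size": config.effect_size,
            "seed": config.seed,
            "subregion": config.subregion,
        },
        "k_subregions": int(partition.k),
        "ch_by_k": {str(k): v for k, v in partition.ch_by_k.items()},
        "stage_counts": report.stage_counts,
        "lambda_star": None if np.isnan(report.lambda_star) else report.lambda_star,
        "model": {
            "name": model.name,
            "intercept": model.intercept,
            "coefficients": model.coefficients,
        },
        "train": asdict(perf_train),
        "validation": asdict(perf_val),
        "train_ids": list(train_ids),
        "validation_ids": list(val_ids),
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for case in cohort.cases:
            write_labelmap(
                partition.labels[case.case_id],
                out / f"{case.case_id}_subregions.nii.gz",
                case.volume.spacing_mm,
                case.volume.affine,
            )
        pd.Series(partition.ch_by_k).rename("CH").to_csv(out / "ch_by_k.csv")
        features.to_csv(out / "features.csv")
        report.table.to_csv(out / "selection_report.csv")
        (out / "performance.json").write_text(json.dumps(result, indent=2, sort_keys=True))
        log.info("artifacts written to %s", out)

    return result
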