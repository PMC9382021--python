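"""Logistic models and ROC/AUC evaluation.

Houses the four published subregion-radiomics logistic models for brain
metastasis (primary-origin prediction LR-NSCLC / LR-BC, gene-status
prediction LR-EGFR / LR-HER2), transcribed with their intercepts and
per-feature coefficients; the linear predictor / probability evaluation; and
ROC summary statistics (AUC with DeLong or bootstrap confidence intervals,
accuracy/specificity/sensitivity at the Youden-optimal threshold).

The models' coefficients act on standardized (z-scored) feature values, so a
zero feature vector evaluates to the printed intercept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class MissingFeatureError(KeyError):
    """A model feature is absent from the supplied feature vector."""


@dataclass
class LrModel:
    """A fitted logistic regression model: intercept + named coefficients."""

    name: str
    intercept: float
    coefficients: dict  # feature name -> coefficient
    provenance: dict = field(default_factory=dict)  # canonical name -> source string

    @property
    def feature_names(self) -> list:
        return list(self.coefficients)

    @property
    def n_features(self) -> int:
        return len(self.coefficients)


_FILTERS = r"(?:original|wavelet-[LH]{3}|log-sigma-\d+(?:\.\d+)?-mm-3D|square|squareroot|lbp-3D-(?:m1|m2|k))"
_FAMILIES = r"(?:firstorder|glcm|glrlm|glszm|ngtdm)"
FEATURE_NAME_RE = re.compile(rf"^(?:{_FILTERS}_{_FAMILIES}_[A-Za-z0-9]+|DL_\d+)$")


def is_canonical_feature_name(name: str) -> bool:
    """True if a name follows the <filter>_<family>_<Statistic> or DL_<i> grammar."""
    return bool(FEATURE_NAME_RE.match(name))


# Coefficients transcribed from the published model formulas.  The literal
# formula term strings (with their stray spaces / truncations) are preserved
# as provenance next to each normalized canonical name.
_BUILTIN = {
    "LR-NSCLC": (
        -1.1569,
        [
            (0.2105, "wavelet-HLH_glrlm_LongRunEmphasis", "wavelet-HLH_glrlm_LongRunEmphasis"),
            (-1.4567, "wavelet-LHL_glszm_SmallAreaHighGrayLevelEmphasis", "wavelet-LHL_glszm_SmallAreaHighGrayLevelEmphasis"),
            (-1.2819, "wavelet-HHH_firstorder_RootMeanSquared", "wavelet-HHH_firstorder_RootMeanSquared"),
            (0.2768, "wavelet-HHH_glrlm_LongRunLowGrayLevelEmphasis", "wavelet-HHH_glrlm_LongRunLowGrayLevelEmphasis"),
            (0.9681, "lbp-3D-k_firstorder_Mean", "lbp-3D-k_firstorder_Mean"),
            (-0.5264, "DL_215", "DL_215"),
            (-0.8798, "DL_400", "DL_400"),
        ],
    ),
    "LR-BC": (
        -1.5412,
        [
            (1.9088, "wavelet-HHL_glcm_InverseVariance", "wavelet-HHL_ glcm_InverseVariance"),
            (1.9784, "wavelet-HHH_firstorder_InterquartileRange", "wavelet-HHH_ firstorder_InterquartileRange"),
            (-0.9107, "DL_317", "DL_317"),
            (-1.0072, "DL_144", "DL_144"),
            (-0.6121, "DL_122", "DL_122"),
        ],
    ),
    "LR-EGFR": (
        0.03461,
        [
            (1.8998, "squareroot_glszm_SmallAreaHighGrayLevelEmphasis", "squareroot_glszm_Small AreaHighGrayLevelEmphasi"),
            (-0.8220, "log-sigma-5-mm-3D_ngtdm_Contrast", "log-sigma-5-mm-3D_ngtdm_Contrast"),
            (1.6274, "wavelet-LHL_firstorder_Skewness", "wavelet-LHL_ firstorder_Skewness"),
            (0.9110, "lbp-3D-k_firstorder_MeanAbsoluteDeviation", "lbp-3D-k_firstorder_ MeanAbsoluteDeviation"),
            (1.1375, "lbp-3D-m2_glszm_GrayLevelVariance", "lbp-3D-m2_glszm_ GrayLevelVariance"),
            (0.0129, "DL_336", "DL_336"),
        ],
    ),
    "LR-HER2": (
        -0.2327,
        [
            (0.5867, "wavelet-LLH_firstorder_10Percentile", "wavelet-LLH_ firstorder_10Percentile"),
            (-5.5909, "square_ngtdm_Busyness", "square_ngtdm_Busyness"),
            (-1.5990, "DL_317", "DL_317"),
            (2.4984, "wavelet-HHL_glcm_Imc1", "wavelet-HHL_ glcm_Imc1"),
            (-0.2158, "log-sigma-3-mm-3D_glszm_LargeAreaHighGrayLevelEmphasis", "log-sigma-3-mm-3D_glszm _LargeAreaHighGrayLevelEmphasis"),
        ],
    ),
}


def builtin_models() -> dict:
    """The four published logistic models, keyed by name."""
    out = {}
    for name, (intercept, rows) in _BUILTIN.items():
        out[name] = LrModel(
            name=name,
            intercept=intercept,
            coefficients={canonical: coef for coef, canonical, _ in rows},
            provenance={canonical: literal for _, canonical, literal in rows},
        )
    return out


def linear_predictor(model: LrModel, feature_vector: dict) -> float:
    """intercept + sum(coef * value); raises naming any missing feature."""
    lp = model.intercept
    for fname, coef in model.coefficients.items():
        if fname not in feature_vector:
            raise MissingFeatureError(
                f"feature {fname!r} required by {model.name} is missing"
            )
        lp += coef * float(feature_vector[fname])
    return float(lp)


def predict_prob(model: LrModel, feature_vector: dict) -> float:
    """Logistic probability 1 / (1 + exp(-linear predictor))."""
    return float(1.0 / (1.0 + np.exp(-linear_predictor(model, feature_vector))))


# ----------------------------------------------------------------- metrics


@dataclass
class PerfSummary:
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    acc: float
    spe: float
    sen: float
    threshold: float


def _auc_concordance(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float, level=0.95):
    """DeLong variance of the AUC via placement values."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    v10 = ((pos[:, None] > neg[None, :]).mean(axis=1)
           + 0.5 * (pos[:, None] == neg[None, :]).mean(axis=1))
    v01 = ((pos[:, None] > neg[None, :]).mean(axis=0)
           + 0.5 * (pos[:, None] == neg[None, :]).mean(axis=0))
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def _bootstrap_ci(scores, labels, seed=0, n_boot=2000, level=0.95):
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([pi, ni])
        aucs[b] = _auc_concordance(scores[idx], labels[idx])
    alpha = (1 - level) / 2
    return float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1 - alpha))


def roc_auc(
    scores,
    labels,
    ci_method: str = "delong",
    threshold: float | None = None,
    seed: int = 0,
) -> PerfSummary:
    """ROC summary: concordance AUC, 95% CI, and ACC/SPE/SEN.

    AUC is the pairwise concordance probability (ties count 1/2), which
    equals the Mann-Whitney U statistic divided by n_pos * n_neg — both are
    computed and cross-checked on every call.  The operating point is the
    Youden-optimal threshold (maximizing sensitivity + specificity - 1) on
    these scores unless ``threshold`` is given (e.g. frozen from a training
    cohort).  CI via DeLong (default) or stratified bootstrap.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    auc = float(_auc_concordance(scores, labels))

    # internal cross-check against the rank-sum (Mann-Whitney) identity
    ranks = stats.rankdata(scores)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    assert abs(u / (n1 * n0) - auc) < 1e-10, "AUC/U-statistic mismatch"

    if ci_method == "delong":
        lo, hi = _delong_ci(scores, labels, auc)
    elif ci_method == "bootstrap":
        lo, hi = _bootstrap_ci(scores, labels, seed=seed)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    if threshold is None:
        threshold = youden_threshold(scores, labels)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    return PerfSummary(
        auc=auc,
        auc_ci_low=float(lo),
        auc_ci_high=float(hi),
        acc=(tp + tn) / len(labels),
        spe=tn / n0,
        sen=tp / n1,
        threshold=float(threshold),
    )


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the observed scores; ties resolve to the lowest threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    n1 = (labels == 1).sum()
    n0 = (labels == 0).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("Youden threshold requires both classes present")
    best_j, best_t = -np.inf, None
    for t in np.sort(np.unique(scores)):
        pred = scores >= t
        sen = (pred & (labels == 1)).sum() / n1
        spe = (~pred & (labels == 0)).sum() / n0
        j = sen + spe - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)
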