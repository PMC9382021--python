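"""Feature reproducibility filtering and model selection.

The selection chain mirrors standard radiomics practice and is applied
identically to handcrafted and deep features:

1. ICC filter: features must reach both inter-observer and intra-observer
   ICC(2,1) >= threshold (default 0.75, the usual "good reproducibility"
   cut) across repeated segmentations;
2. univariate screening: two-sided Mann-Whitney U-test, keep P < 0.05
   (no multiplicity correction — deliberate, matching common practice in
   radiomics signature construction, though statistically permissive);
3. standardization: z-score fitted on the training split only;
4. LASSO-logistic with stratified 10-fold cross-validation, keeping features
   with nonzero coefficients at the deviance-minimizing penalty;
5. bidirectional stepwise multivariate logistic regression on the surviving
   features (information-criterion driven), yielding the final model.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from habitomics.models import LrModel


# ------------------------------------------------------------------ ICC


def icc(ratings: np.ndarray) -> float:
    """Two-way random-effects, absolute-agreement, single-measurement ICC.

    ``ratings`` is (n_subjects, n_raters).  Computed from the two-way ANOVA
    decomposition (subjects x raters); the estimate is clipped to [-1, 1].
    Zero total variance is undefined and raises.
    """
    Y = np.asarray(ratings, dtype=np.float64)
    n, k = Y.shape
    if n < 3 or k < 2:
        raise ValueError("ICC requires at least 3 subjects and 2 raters")
    if np.ptp(Y) == 0:
        raise ValueError("ICC undefined: zero total variance")
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: zero denominator")
    return float(np.clip((msr - mse) / denom, -1.0, 1.0))


# --------------------------------------------------------- Mann-Whitney


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of sample x against y via midranks (tie-aware)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U-test p-value.

    Exact by full enumeration of group assignments when n_x + n_y <= 12
    (tie-aware: the two-sided p is the probability, over all C(n, n_x)
    assignments of the pooled values, of a U at least as far from its mean
    n_x*n_y/2 as observed); a tie-corrected normal approximation otherwise.
    All values tied gives p = 1.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    if n1 + n2 <= 12:
        pooled = np.concatenate([x, y])
        mean_u = n1 * n2 / 2.0
        obs_dev = abs(_u_statistic(x, y) - mean_u)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(combo)] = True
            u = _u_statistic(pooled[sel], pooled[~sel])
            # small epsilon guards midrank float ties
            if abs(u - mean_u) >= obs_dev - 1e-12:
                count += 1
            total += 1
        return count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# ----------------------------------------------------------------- LASSO


def fit_lasso_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """L1-penalized logistic coefficients at penalty ``lam``.

    Parameterized so the objective is mean deviance + lam * ||beta||_1
    (sklearn C = 1 / (lam * n)).
    """
    n = len(y)
    model = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (lam * n),
        solver="liblinear",
        max_iter=5000,
        tol=1e-8,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model.coef_[0]


def lasso_logistic_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """LASSO-logistic over a log-spaced penalty grid, lambda* by CV deviance.

    Stratified ``folds``-fold cross-validation; lambda* minimizes the mean
    held-out binomial deviance (ties resolve to the stronger penalty).
    Returns (coefficients at lambda*, lambda*).
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("LASSO-logistic requires both classes present")
    if lambda_grid is None:
        lambda_grid = np.logspace(-4, 0.5, 40)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=np.float64))
    folds = min(folds, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    deviance = np.zeros(len(lambda_grid))
    for train_idx, test_idx in skf.split(X, y):
        if len(np.unique(y[train_idx])) < 2:
            continue
        for j, lam in enumerate(lambda_grid):
            n_tr = len(train_idx)
            model = LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / (lam * n_tr),
                solver="liblinear",
                max_iter=2000,
                tol=1e-7,
                random_state=0,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(X[train_idx], y[train_idx])
            p = np.clip(model.predict_proba(X[test_idx])[:, 1], 1e-12, 1 - 1e-12)
            yt = y[test_idx]
            deviance[j] += -2.0 * (yt * np.log(p) + (1 - yt) * np.log(1 - p)).sum()

    best = int(np.flatnonzero(deviance == deviance.min())[-1])  # ties -> larger lambda
    lam_star = float(lambda_grid[best])
    return fit_lasso_logistic(X, y, lam_star), lam_star


# -------------------------------------------------------------- stepwise


def _fit_logit(X: np.ndarray, y: np.ndarray, names: list) -> tuple[float, np.ndarray, float]:
    """(information criterion penalty-free deviance handled by caller)
    Returns (-2 loglik, params, converged-flag) with a ridge fallback under
    perfect separation."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(res.params)) and np.abs(res.params).max() < 1e4:
                return float(-2 * res.llf), np.asarray(res.params), True
        except Exception:
            pass
    # perfect separation or non-convergence: small-ridge fallback
    warnings.warn("logistic fit unstable (separation?); using small-ridge fallback", stacklevel=2)
    model = LogisticRegression(l1_ratio=0.0, C=1e3, solver="lbfgs", max_iter=5000)
    model.fit(X, y) if X.shape[1] else model.fit(np.zeros((len(y), 1)), y)
    if X.shape[1]:
        params = np.concatenate([model.intercept_, model.coef_[0]])
        p = np.clip(model.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    else:
        params = np.array([model.intercept_[0]])
        p = np.clip(model.predict_proba(np.zeros((len(y), 1)))[:, 1], 1e-12, 1 - 1e-12)
    llf = float((y * np.log(p) + (1 - y) * np.log(1 - p)).sum())
    return -2 * llf, params, False


def stepwise_logistic(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list,
    criterion: str = "bic",
    name: str = "LR",
) -> LrModel:
    """Bidirectional stepwise multivariate logistic regression.

    Starting from the intercept-only model, forward steps add the candidate
    that most improves the information criterion and backward steps remove
    any term whose exclusion improves it, until no move helps.  BIC is the
    default criterion: with the modest cohorts this chain targets, AIC's
    2-point penalty admits too many chance features under the null, while
    BIC's log(n) penalty keeps the null model intercept-only.  Maximum
    likelihood via statsmodels (IRLS/Newton); perfect separation falls back
    to a lightly ridge-penalized fit with a warning.
    """
    y = np.asarray(y, dtype=int)
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] > len(y) / 5:
        warnings.warn(
            f"{X.shape[1]} candidate features for {len(y)} cases (> n/5)", stacklevel=2
        )
    pen = {"aic": 2.0, "bic": float(np.log(len(y)))}[criterion]

    def ic(subset: tuple) -> tuple[float, np.ndarray]:
        dev, params, _ = _fit_logit(X[:, list(subset)], y, None)
        return dev + pen * (len(subset) + 1), params

    current: tuple = ()
    best_ic, best_params = ic(current)
    improved = True
    while improved:
        improved = False
        # forward
        candidates = [j for j in range(X.shape[1]) if j not in current]
        moves = [(ic(current + (j,)), current + (j,)) for j in candidates]
        # backward
        moves += [
            (ic(tuple(c for c in current if c != j)), tuple(c for c in current if c != j))
            for j in current
        ]
        for (score, params), subset in moves:
            if score < best_ic - 1e-9:
                best_ic, best_params, current = score, params, subset
                improved = True
        # re-evaluate params for the chosen subset (moves kept the best)
    coefs = {feature_names[j]: float(b) for j, b in zip(current, best_params[1:])}
    return LrModel(name=name, intercept=float(best_params[0]), coefficients=coefs)


# ------------------------------------------------------------ full chain


@dataclass
class SelectionConfig:
    icc_threshold: float = 0.75
    mwu_alpha: float = 0.05
    lasso_folds: int = 10
    stepwise_criterion: str = "bic"
    seed: int = 0


@dataclass
class SelectionReport:
    """Per-feature audit of the selection chain plus global choices."""

    table: pd.DataFrame  # index = feature, columns: icc_inter, icc_intra, mwu_p, lasso_coef, kept, stage_dropped
    lambda_star: float
    standardization: pd.DataFrame  # index = feature (training means/sds)
    stage_counts: dict = field(default_factory=dict)


def run_selection(
    features: pd.DataFrame,
    labels: pd.Series,
    features_observer2: pd.DataFrame,
    features_repeat: pd.DataFrame,
    train_index,
    config: SelectionConfig | None = None,
    model_name: str = "LR",
) -> tuple[SelectionReport, LrModel]:
    """ICC -> Mann-Whitney -> z-score -> LASSO -> stepwise, on aligned tables.

    ``features`` are observer-1 values (rows = cases); ``features_observer2``
    the same features from a second observer's segmentation (inter-observer
    ICC); ``features_repeat`` a repeat segmentation by observer 1
    (intra-observer ICC).  Standardization and all model fitting use only
    ``train_index`` rows.  Returns the audit report and the final model whose
    coefficients act on z-scored features.
    """
    if config is None:
        config = SelectionConfig()
    cols = list(features.columns)
    features_observer2 = features_observer2.reindex(index=features.index, columns=cols)
    features_repeat = features_repeat.reindex(index=features.index, columns=cols)
    labels = labels.reindex(features.index)
    y = labels.to_numpy().astype(int)
    train_mask = features.index.isin(train_index)

    tbl = pd.DataFrame(
        index=cols,
        data={
            "icc_inter": np.nan,
            "icc_intra": np.nan,
            "mwu_p": np.nan,
            "lasso_coef": 0.0,
            "kept": False,
            "stage_dropped": "",
        },
    )

    # stage 1: reproducibility
    surviving = []
    for c in cols:
        try:
            tbl.loc[c, "icc_inter"] = icc(
                np.column_stack([features[c], features_observer2[c]])
            )
            tbl.loc[c, "icc_intra"] = icc(np.column_stack([features[c], features_repeat[c]]))
        except ValueError:
            tbl.loc[c, "stage_dropped"] = "icc"
            continue
        if (
            tbl.loc[c, "icc_inter"] >= config.icc_threshold
            and tbl.loc[c, "icc_intra"] >= config.icc_threshold
        ):
            surviving.append(c)
        else:
            tbl.loc[c, "stage_dropped"] = "icc"

    # stage 2: univariate screening (training split)
    stage2 = []
    for c in surviving:
        v = features.loc[train_mask, c].to_numpy()
        p = mann_whitney_p(v[y[train_mask] == 0], v[y[train_mask] == 1])
        tbl.loc[c, "mwu_p"] = p
        if p < config.mwu_alpha:
            stage2.append(c)
        else:
            tbl.loc[c, "stage_dropped"] = "mwu"

    report_kwargs = dict(lambda_star=np.nan, standardization=pd.DataFrame())
    stage_counts = {
        "input": len(cols),
        "after_icc": len(surviving),
        "after_mwu": len(stage2),
        "after_lasso": 0,
        "final_model": 0,
    }
    if not stage2:
        report = SelectionReport(table=tbl, stage_counts=stage_counts, **report_kwargs)
        return report, LrModel(name=model_name, intercept=0.0, coefficients={})

    # stage 3: standardization on the training split
    mu = features.loc[train_mask, stage2].mean()
    sd = features.loc[train_mask, stage2].std(ddof=0).replace(0.0, 1.0)
    Z = ((features[stage2] - mu) / sd).to_numpy()
    standardization = pd.DataFrame({"mean": mu, "sd": sd})

    # stage 4: LASSO with cross-validation
    coefs, lam = lasso_logistic_cv(
        Z[train_mask], y[train_mask], folds=config.lasso_folds, seed=config.seed
    )
    tbl.loc[stage2, "lasso_coef"] = coefs
    stage3 = [c for c, b in zip(stage2, coefs) if b != 0.0]
    for c in stage2:
        if c not in stage3:
            tbl.loc[c, "stage_dropped"] = "lasso"
    stage_counts["after_lasso"] = len(stage3)

    if not stage3:
        report = SelectionReport(
            table=tbl, lambda_star=lam, standardization=standardization, stage_counts=stage_counts
        )
        return report, LrModel(name=model_name, intercept=0.0, coefficients={})

    # stage 5: stepwise multivariate logistic
    sub = [stage2.index(c) for c in stage3]
    model = stepwise_logistic(
        Z[train_mask][:, sub],
        y[train_mask],
        stage3,
        criterion=config.stepwise_criterion,
        name=model_name,
    )
    final = set(model.coefficients)
    for c in stage3:
        if c not in final:
            tbl.loc[c, "stage_dropped"] = "stepwise"
    tbl.loc[list(final), "kept"] = True
    stage_counts["final_model"] = len(final)

    report = SelectionReport(
        table=tbl, lambda_star=lam, standardization=standardization, stage_counts=stage_counts
    )
    return report, model
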