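"""Association statistics: gene-property regression, tract variance
explained, and the class-imbalanced downsampled cross-validation harness.

Gene-property regression asks whether genes more expressed in a focal
tissue or cell type carry stronger association signal.  Gene p-values are
probit-transformed, Z_g = Phi^{-1}(1 - p_g), and regressed on the focal
expression E_t plus an average-expression baseline and optional covariates:

    Z_g = b0 + b1 E_{t,g} + b2 A_g + b3 C_g + e_g

with a one-sided test of b1 > 0 (higher expression -> stronger effects)
and Bonferroni correction across tested tissues/cell types.

The cross-validation harness reproduces the imbalanced-cohort protocol:
stratified k-fold, majority class downsampled (without replacement) to the
minority count inside each training fold only, test folds left at their
natural class ratio, AUC via the Mann-Whitney rank statistic, and
gain-based feature importances averaged over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "GenePropResult",
    "CVReport",
    "geneprop_regression",
    "tract_r2",
    "downsampled_cv",
    "auc_mannwhitney",
    "lightgbm_trainer",
    "logistic_trainer",
]

_P_CLAMP = 1e-12  # keeps the probit transform finite for p in {0, 1}


@dataclass
class GenePropResult:
    beta1: float
    se: float
    p_one_sided: float
    n_genes: int
    params: pd.Series

    def bonferroni(self, n_tissues: int) -> float:
        return min(1.0, n_tissues * self.p_one_sided)


def geneprop_regression(
    p_values,
    expression,
    avg_expression=None,
    covariates=None,
) -> GenePropResult:
    """OLS of probit-transformed gene p-values on focal-tissue expression."""
    p = np.asarray(p_values, dtype=np.float64)
    e = np.asarray(expression, dtype=np.float64)
    if p.shape != e.shape:
        raise ValueError("p-values and expression must align per gene")
    if np.isnan(p).any() or np.isnan(e).any():
        raise ValueError("missing values must be filtered before the regression")
    p = np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP)
    z = sps.norm.ppf(1.0 - p)

    cols = {"expr": e}
    if avg_expression is not None:
        cols["avg_expr"] = np.asarray(avg_expression, dtype=np.float64)
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if cov.shape[0] != p.size:
            cov = cov.T
        for j in range(cov.shape[1]):
            cols[f"cov_{j}"] = cov[:, j]
    X = sm.add_constant(pd.DataFrame(cols))
    if p.size <= X.shape[1] + 1:
        raise ValueError("too few genes for the number of predictors")
    fit = sm.OLS(z, X).fit()
    beta1 = float(fit.params["expr"])
    se = float(fit.bse["expr"])
    tval = float(fit.tvalues["expr"])
    if np.isfinite(tval):
        p_one = float(sps.t.sf(tval, fit.df_resid))  # H1: beta1 > 0
    else:
        # degenerate fit (e.g. all Z identical): se = 0; fall back to the
        # sign of the estimate, with the Z = 0 case giving the null p = 0.5
        p_one = 0.5 if beta1 == 0 else (0.0 if beta1 > 0 else 1.0)
    return GenePropResult(beta1=beta1, se=se, p_one_sided=p_one, n_genes=p.size, params=fit.params)


def tract_r2(latents, response) -> tuple[float, float, float]:
    """R^2, F and p for OLS of a per-subject tract value on all latent dims."""
    X = latents.to_numpy() if isinstance(latents, pd.DataFrame) else np.asarray(latents, dtype=np.float64)
    y = np.asarray(response, dtype=np.float64)
    if X.shape[0] != y.size:
        raise ValueError("latents and response differ in subject count")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("too few subjects for the latent dimensionality")
    if np.std(y) == 0:
        raise ValueError("constant response")
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    return float(fit.rsquared), float(fit.fvalue), float(fit.f_pvalue)


def auc_mannwhitney(y_true, scores) -> float:
    """AUC via the rank (Mann-Whitney) statistic; exact on small folds."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required to compute AUC")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def lightgbm_trainer(X, y, seed: int):
    """Default classifier: gradient-boosted trees with default hyperparameters."""
    import lightgbm as lgb

    clf = lgb.LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1)
    clf.fit(X, y)

    def score(Xt):
        return clf.predict_proba(Xt)[:, 1]

    importances = clf.booster_.feature_importance(importance_type="gain").astype(float)
    return score, importances


def logistic_trainer(X, y, seed: int):
    """Deterministic linear alternative for tests and quick runs."""
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(max_iter=1000)
    clf.fit(X, y)

    def score(Xt):
        return clf.decision_function(Xt)

    return score, np.abs(clf.coef_[0])


@dataclass
class CVReport:
    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    importances: np.ndarray | None
    fold_sizes: list[tuple[int, int]]  # (n_train_balanced, n_test)
    seed: int
    feature_names: list[str] = field(default_factory=list)


def downsampled_cv(
    features,
    labels,
    k: int = 5,
    trainer=lightgbm_trainer,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV with majority-class downsampling in training only."""
    if isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=np.float64)
        names = list(features.columns)
    else:
        X = np.asarray(features, dtype=np.float64)
        names = [f"f{j}" for j in range(X.shape[1])]
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or set(classes) != {0, 1}:
        raise ValueError(f"need binary 0/1 labels, got classes {classes}")
    minority = classes[np.argmin(counts)]
    if counts.min() < k:
        raise ValueError(f"minority class has {counts.min()} members; cannot stratify into {k} folds")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCF]))
    aucs: list[float] = []
    fold_sizes: list[tuple[int, int]] = []
    imp_sum = None
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        y_tr = y[tr]
        min_idx = tr[y_tr == minority]
        maj_idx = tr[y_tr != minority]
        keep = rng.choice(maj_idx, size=min_idx.size, replace=False)
        bal = np.concatenate([min_idx, keep])
        bal = bal[rng.permutation(bal.size)]
        if len(set(bal) & set(te)):
            raise AssertionError("train/test leakage")  # defensive; cannot happen
        if set(np.unique(y[te])) != {0, 1}:
            raise ValueError(f"fold {fold} test set lacks a class")
        score, importances = trainer(X[bal], y[bal], seed + fold)
        aucs.append(auc_mannwhitney(y[te], score(X[te])))
        fold_sizes.append((bal.size, te.size))
        if importances is not None:
            imp_sum = importances if imp_sum is None else imp_sum + importances
    return CVReport(
        fold_aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        sd_auc=float(np.std(aucs, ddof=1)),
        importances=None if imp_sum is None else imp_sum / k,
        fold_sizes=fold_sizes,
        seed=seed,
        feature_names=names,
    )
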