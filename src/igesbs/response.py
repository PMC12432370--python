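"""Elastic-net immunotherapy response model.

Signature scores from multiple cohorts are first harmonized (per-cohort
location/scale alignment to the pooled moments, a light-weight batch
correction), then an elastic-net logistic classifier is trained with nested
cross-validation: 5 stratified outer folds for performance assessment and a
10-fold inner grid search over the mixing parameter alpha (l1_ratio, 0.1 to
1.0 by 0.1) and the penalty strength. Out-of-fold predicted probabilities
are stacked across outer folds to give one overall AUC. The final model is
refit on all samples with inner-CV-selected hyperparameters; its per-
signature coefficients Coe_i feed the compound boosting score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .scoring import SignatureScoreMatrix

logger = logging.getLogger(__name__)

DEFAULT_L1_RATIOS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
DEFAULT_CS = tuple(np.logspace(-2, 2, 5))


@dataclass
class ResponseModel:
    """Fitted elastic-net response model.

    ``coefficients`` maps each signature to its Coe_i (zeros allowed);
    hyperparameters are the selected mixing alpha (l1_ratio) and inverse
    penalty C.
    """

    signature_ids: list[str]
    coefficients: dict[str, float]
    intercept: float
    l1_ratio: float
    C: float
    seed: int = 0
    cv_auc: float | None = None
    training_meta: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signature_ids": self.signature_ids,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "l1_ratio": self.l1_ratio,
            "C": self.C,
            "seed": self.seed,
            "cv_auc": self.cv_auc,
            "training_meta": self.training_meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ResponseModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


@dataclass
class CVReport:
    """Per-fold and overall (stacked out-of-fold) AUC."""

    fold_auc: list[float]
    fold_n: list[int]
    overall_auc: float


def harmonize_cohorts(
    scores: SignatureScoreMatrix | pd.DataFrame, cohort_labels: pd.Series
) -> pd.DataFrame:
    """Align each signature's per-cohort location/scale to the pooled moments.

    Within every cohort each signature row is z-transformed and rescaled to
    the pooled (all-sample) mean and sd, removing additive and
    multiplicative cohort batch effects. A signature constant within a
    cohort is left at the pooled mean there (warning).
    """
    vals = scores.values if isinstance(scores, SignatureScoreMatrix) else scores
    labels = cohort_labels.reindex(vals.columns)
    if labels.isna().any():
        raise ValueError("cohort label missing for some samples")
    pooled_mu = vals.mean(axis=1)
    pooled_sd = vals.std(axis=1, ddof=1)
    out = vals.copy().astype(float)
    for cohort, cols in vals.columns.groupby(labels).items():
        block = vals.loc[:, cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        constant = sd.fillna(0.0) == 0.0
        if constant.any():
            logger.warning("cohort %s: %d constant signatures left at pooled mean",
                           cohort, int(constant.sum()))
        safe_sd = sd.mask(constant, np.inf)
        z = block.sub(mu, axis=0).div(safe_sd, axis=0)
        out.loc[:, cols] = (
            z.mul(pooled_sd, axis=0).add(pooled_mu, axis=0).to_numpy()
        )
    return out


def evaluate_auc(probabilities, labels) -> float:
    """Rank-based AUC (Mann-Whitney normalization; ties count one half)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required to compute AUC")
    ranks = rankdata(p)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _inner_fit(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    l1_ratios,
    Cs,
    inner_folds: int,
    max_iter: int,
) -> LogisticRegressionCV:
    """Inner hyperparameter search; isolated so tests can instrument it."""
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    est = LogisticRegressionCV(
        Cs=list(Cs),
        l1_ratios=list(l1_ratios),
        solver="saga",
        scoring="roc_auc",
        cv=cv,
        max_iter=max_iter,
        tol=1e-2,
        random_state=seed,
        n_jobs=None,
        use_legacy_attributes=False,
    )
    est.fit(X, y)
    return est


def train_elastic_net(
    scores: SignatureScoreMatrix | pd.DataFrame,
    responses: pd.Series,
    cohort_labels: pd.Series | None = None,
    seed: int = 0,
    outer_folds: int = 5,
    inner_folds: int = 10,
    l1_ratios=DEFAULT_L1_RATIOS,
    Cs=DEFAULT_CS,
    max_iter: int = 2000,
) -> tuple[ResponseModel, CVReport]:
    """Nested-CV elastic net on signature scores.

    Parameters
    ----------
    scores : SignatureScoreMatrix or DataFrame
        Signatures x samples (standardized/harmonized upstream).
    responses : Series
        Binary response per sample.
    cohort_labels : Series, optional
        Recorded in training metadata only; harmonization is the caller's
        responsibility (see :func:`harmonize_cohorts`).
    seed : int
        Controls fold shuffling and the saga solver; the fit is
        deterministic given (data, seed).

    Returns
    -------
    (ResponseModel, CVReport)
        The model is refit on all samples with hyperparameters selected by
        inner CV on the full data; the report holds per-fold and stacked
        out-of-fold AUCs.
    """
    vals = scores.values if isinstance(scores, SignatureScoreMatrix) else scores
    y = responses.reindex(vals.columns)
    if y.isna().any():
        raise ValueError("response missing for some samples")
    y = y.to_numpy(dtype=int)
    X = vals.T.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 20:
        raise ValueError("insufficient for nested CV: need >=20 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate response: only one class present")

    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    oof = np.full(n, np.nan)
    fold_auc: list[float] = []
    fold_n: list[int] = []
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        est = _inner_fit(X[tr], y[tr], seed + fold + 1,
                         l1_ratios, Cs, inner_folds, max_iter)
        prob = est.predict_proba(X[te])[:, 1]
        oof[te] = prob
        fold_auc.append(evaluate_auc(prob, y[te]))
        fold_n.append(len(te))
    overall = evaluate_auc(oof, y)

    final = _inner_fit(X, y, seed, l1_ratios, Cs, inner_folds, max_iter)
    coef = final.coef_.ravel()
    model = ResponseModel(
        signature_ids=list(vals.index),
        coefficients={s: float(c) for s, c in zip(vals.index, coef)},
        intercept=float(final.intercept_[0]),
        l1_ratio=float(final.l1_ratio_),
        C=float(final.C_),
        seed=seed,
        cv_auc=overall,
        training_meta={
            "n_samples": int(n),
            "outer_folds": outer_folds,
            "inner_folds": inner_folds,
            "cohorts": sorted(set(cohort_labels)) if cohort_labels is not None else [],
        },
    )
    return model, CVReport(fold_auc=fold_auc, fold_n=fold_n, overall_auc=overall)


def predict_response(
    model: ResponseModel, scores: SignatureScoreMatrix | pd.DataFrame
) -> pd.Series:
    """Per-sample response probability: logistic(intercept + sum Coe_i s_i)."""
    vals = scores.values if isinstance(scores, SignatureScoreMatrix) else scores
    missing = [s for s in model.signature_ids if s not in vals.index]
    if missing:
        raise ValueError(f"scores missing model features: {missing[:5]}")
    X = vals.loc[model.signature_ids]
    mu = X.mean(axis=1).abs().max()
    sd = X.std(axis=1, ddof=1)
    if len(vals.columns) >= 10 and (mu > 1.0 or (sd > 3.0).any()):
        logger.warning("scores look unstandardized (|mean| or sd far from 0/1); "
                       "model was trained on standardized scores")
    coef = np.array([model.coefficients[s] for s in model.signature_ids])
    eta = model.intercept + coef @ X.to_numpy(dtype=float)
    return pd.Series(expit(eta), index=vals.columns, name="probability")
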