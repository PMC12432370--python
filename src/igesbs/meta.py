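"""Per-cohort logistic association and random-effects meta-analysis.

For every signature, the standardized score is regressed on the binary
immunotherapy response within each cohort (logistic regression; the slope is
the log-odds of response per 1-SD increase in signature score). Cohort slopes
are pooled with the classic DerSimonian-Laird random-effects estimator:

    w_i   = 1 / se_i^2                    (fixed-effect weights)
    Q     = sum w_i (b_i - b_FE)^2        (Cochran's Q)
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
    w*_i  = 1 / (se_i^2 + tau^2)
    b_RE  = sum w*_i b_i / sum w*_i,   se_RE = 1 / sqrt(sum w*_i)

with a Wald confidence interval and p-value, reported on the odds-ratio
scale. Signatures with pooled p < alpha are labelled sensitivity-associated
(sIGeS, OR > 1) or resistance-associated (rIGeS, OR < 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .genesets import GeneSetCollection
from .scoring import ExpressionMatrix, score_signatures, standardize_scores

logger = logging.getLogger(__name__)

#: slope magnitude at which the fit is declared separated and capped
MAX_ABS_BETA = 10.0


@dataclass
class CohortData:
    """Expression plus binary response for one cohort."""

    cohort_id: str
    expression: ExpressionMatrix
    response: pd.Series  # 0/1, indexed by sample id

    def __post_init__(self) -> None:
        self.response = self.response.reindex(self.expression.sample_ids)
        if self.response.isna().any():
            raise ValueError(f"cohort {self.cohort_id}: response missing for samples")


@dataclass
class CohortEffect:
    """Log-odds of response per 1-SD signature score in one cohort."""

    cohort_id: str
    beta: float
    se: float
    p: float
    n: int
    converged: bool = True


@dataclass
class MetaResult:
    """Pooled random-effects association for one signature."""

    signature_id: str
    beta_pooled: float
    or_pooled: float
    ci_low: float
    ci_high: float
    p: float
    tau2: float
    q_stat: float
    cohort_effects: list[CohortEffect] = field(default_factory=list)
    label: str = "none"


def fit_cohort_logistic(
    scores_z: np.ndarray | pd.Series,
    response: np.ndarray | pd.Series,
    cohort_id: str = "",
) -> CohortEffect:
    """Fit intercept + slope logistic regression by Newton-Raphson IRLS.

    Parameters
    ----------
    scores_z : array-like
        Standardized signature scores (one per sample).
    response : array-like
        Binary 0/1 response labels.

    Returns
    -------
    CohortEffect
        With Wald standard error and two-sided p. Under complete separation
        the slope is capped at +-10 and ``converged`` is False.
    """
    s = np.asarray(scores_z, dtype=float)
    y = np.asarray(response, dtype=float)
    n = s.size
    if n < 4:
        raise ValueError("need at least 4 samples for logistic fit")
    if y.min() == y.max():
        raise ValueError("degenerate response: only one class present")

    beta = np.zeros(2)
    converged = False
    for _ in range(100):
        eta = beta[0] + beta[1] * s
        p = expit(eta)
        w = p * (1.0 - p)
        # closed-form 2x2 Fisher information for [1, s]
        i00 = w.sum()
        i01 = (w * s).sum()
        i11 = (w * s * s).sum()
        det = i00 * i11 - i01 * i01
        g0 = (y - p).sum()
        g1 = ((y - p) * s).sum()
        if det <= 1e-12:
            break
        step0 = (i11 * g0 - i01 * g1) / det
        step1 = (i00 * g1 - i01 * g0) / det
        beta += np.array([step0, step1])
        if abs(beta[1]) > MAX_ABS_BETA:
            beta[1] = np.sign(beta[1]) * MAX_ABS_BETA
            break
        if max(abs(step0), abs(step1)) < 1e-10:
            converged = True
            break

    eta = beta[0] + beta[1] * s
    p_fit = expit(eta)
    w = p_fit * (1.0 - p_fit)
    i00 = w.sum()
    i01 = (w * s).sum()
    i11 = (w * s * s).sum()
    det = i00 * i11 - i01 * i01
    se = float(np.sqrt(i00 / det)) if det > 1e-12 else np.inf
    z = beta[1] / se if np.isfinite(se) and se > 0 else 0.0
    pval = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return CohortEffect(
        cohort_id=cohort_id,
        beta=float(beta[1]),
        se=se,
        p=max(pval, np.finfo(float).tiny),
        n=n,
        converged=converged,
    )


def pool_random_effects(
    effects: list[CohortEffect], signature_id: str = "", level: float = 0.95
) -> MetaResult:
    """Pool cohort effects with the DerSimonian-Laird estimator.

    Non-converged effects are excluded. With a single effect the pooled
    estimate equals that effect and tau^2 = 0.
    """
    usable = [e for e in effects if e.converged and np.isfinite(e.se) and e.se > 0]
    if not usable:
        raise ValueError("no converged cohort effects to pool")
    b = np.array([e.beta for e in usable])
    v = np.array([e.se**2 for e in usable])
    k = b.size
    w = 1.0 / v
    b_fe = float((w * b).sum() / w.sum())
    q = float((w * (b - b_fe) ** 2).sum())
    if k == 1:
        tau2 = 0.0
    else:
        c = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / c)
    w_star = 1.0 / (v + tau2)
    beta_pooled = float((w_star * b).sum() / w_star.sum())
    se_pooled = float(1.0 / np.sqrt(w_star.sum()))
    zcrit = norm.ppf(0.5 + level / 2.0)
    zstat = beta_pooled / se_pooled
    p = float(min(1.0, 2.0 * norm.sf(abs(zstat))))
    return MetaResult(
        signature_id=signature_id,
        beta_pooled=beta_pooled,
        or_pooled=float(np.exp(beta_pooled)),
        ci_low=float(np.exp(beta_pooled - zcrit * se_pooled)),
        ci_high=float(np.exp(beta_pooled + zcrit * se_pooled)),
        p=max(p, np.finfo(float).tiny),
        tau2=float(tau2),
        q_stat=q,
        cohort_effects=list(effects),
    )


def classify_iges(meta: MetaResult, alpha: float = 0.05) -> str:
    """Label a pooled result: sIGeS (p<alpha, OR>1), rIGeS (p<alpha, OR<1)."""
    if meta.p < alpha:
        if meta.or_pooled > 1.0:
            return "sIGeS"
        if meta.or_pooled < 1.0:
            return "rIGeS"
        logger.warning("signature %s: OR exactly 1 at p<alpha; labelled none",
                       meta.signature_id)
    return "none"


def run_discovery(
    cohorts: list[CohortData],
    sets: GeneSetCollection,
    method: str = "mean_z",
    alpha: float = 0.05,
) -> list[MetaResult]:
    """Full discovery chain: score, standardize per cohort, fit, pool, label.

    Signatures unscorable in a cohort (no member genes, or degenerate fit)
    are skipped for that cohort with a log message. Results are sorted by
    pooled p-value.
    """
    if len(cohorts) < 2:
        logger.warning("discovery with %d cohort(s); >=2 recommended", len(cohorts))
    per_cohort: dict[str, tuple[pd.DataFrame, pd.Series]] = {}
    for c in cohorts:
        raw = score_signatures(c.expression, sets, method=method)
        labels = pd.Series(c.cohort_id, index=c.expression.sample_ids)
        z = standardize_scores(raw, labels)
        per_cohort[c.cohort_id] = (z.values, c.response)

    results: list[MetaResult] = []
    for name in sets.names:
        effects: list[CohortEffect] = []
        for c in cohorts:
            z, y = per_cohort[c.cohort_id]
            row = z.loc[name]
            if row.isna().any():
                logger.warning("signature %s unscorable in cohort %s; skipped",
                               name, c.cohort_id)
                continue
            try:
                effects.append(
                    fit_cohort_logistic(row.to_numpy(), y.to_numpy(), c.cohort_id)
                )
            except ValueError as exc:
                logger.warning("signature %s, cohort %s: %s", name, c.cohort_id, exc)
        try:
            meta = pool_random_effects(effects, signature_id=name)
        except ValueError:
            logger.warning("signature %s: no poolable cohort effect", name)
            meta = MetaResult(
                signature_id=name, beta_pooled=np.nan, or_pooled=np.nan,
                ci_low=np.nan, ci_high=np.nan, p=np.nan, tau2=np.nan,
                q_stat=np.nan, cohort_effects=effects,
            )
            results.append(meta)
            continue
        meta.label = classify_iges(meta, alpha=alpha)
        results.append(meta)
    results.sort(key=lambda m: (np.isnan(m.p), m.p, m.signature_id))
    return results


def results_to_frame(results: list[MetaResult], bh_column: bool = True) -> pd.DataFrame:
    """Tabulate pooled results (one row per signature), optionally with a BH
    column for reporting; labels are based on the raw pooled p."""
    rows = []
    for m in results:
        rows.append({
            "signature": m.signature_id,
            "OR": m.or_pooled,
            "ci_low": m.ci_low,
            "ci_high": m.ci_high,
            "p": m.p,
            "tau2": m.tau2,
            "q_stat": m.q_stat,
            "n_cohorts": sum(e.converged for e in m.cohort_effects),
            "label": m.label,
        })
    frame = pd.DataFrame(rows)
    if bh_column and len(frame):
        from statsmodels.stats.multitest import multipletests

        ok = frame["p"].notna()
        adj = np.full(len(frame), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(frame.loc[ok, "p"], method="fdr_bh")[1]
        frame["p_bh"] = adj
    return frame
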