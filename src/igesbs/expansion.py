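"""Cancer-type-specific signature expansion.

Signatures discovered in patient cohorts are often small and partly
undetectable in cell lines, so each is expanded to the genes whose tissue
expression tracks the signature's activity score after adjusting for tumor
purity. For each gene x, signature score y and purity z, the first-order
partial Spearman correlation on ranks is

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

with a t-test on n-3 degrees of freedom. Genes pass with PSCC > 0.4,
Benjamini-Hochberg FDR < 0.05 and detectability proportion DP > 0.8 (strict
inequalities); survivors are ranked by PSCC descending and capped at 200.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, t as t_dist
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: default (pscc, fdr, dp) strict thresholds and gene cap
DEFAULT_THRESHOLDS = {"pscc": 0.4, "fdr": 0.05, "dp": 0.8, "max_genes": 200}


@dataclass
class PurityPanel:
    """Per-sample tumor purity (fraction in [0, 1]) for one cancer type."""

    purity: pd.Series  # indexed by sample id
    cancer_type: str = ""

    def __post_init__(self) -> None:
        vals = self.purity.to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any() or not np.all(np.isfinite(vals)):
            raise ValueError("purity values must lie in [0, 1]")


@dataclass
class ExpandedSignature:
    """Expansion output: genes ranked by PSCC, with filter provenance."""

    signature_id: str
    cancer_type: str
    genes: list[str]
    provenance: dict = field(default_factory=dict)


def _pearson_on(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def _partial_p(r: float, n: int, n_conf: int) -> float:
    """Two-sided t-test p for a (partial) correlation with n - 2 - n_conf df."""
    df = n - 2 - n_conf
    if not np.isfinite(r) or df <= 0:
        return np.nan
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    tval = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * t_dist.sf(abs(tval), df))


def partial_spearman(x, y, z) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given confounder z.

    A constant z carries no information: the plain Spearman correlation is
    returned (logged). If x or y is perfectly rank-correlated with z the
    partial correlation is undefined and ``(nan, nan)`` is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if not (y.size == n and z.size == n):
        raise ValueError("x, y, z must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    rx, ry, rz = rankdata(x), rankdata(y), rankdata(z)
    if np.ptp(rz) == 0:
        logger.info("constant confounder: falling back to plain Spearman")
        r = _pearson_on(rx, ry)
        return r, _partial_p(r, n, n_conf=0)
    r_xy = _pearson_on(rx, ry)
    r_xz = _pearson_on(rx, rz)
    r_yz = _pearson_on(ry, rz)
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        logger.warning("perfect rank correlation with confounder: "
                       "partial correlation undefined")
        return np.nan, np.nan
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    return float(r), _partial_p(r, n, n_conf=1)


def partial_spearman_screen(
    expr: pd.DataFrame, score: pd.Series, purity: pd.Series
) -> pd.DataFrame:
    """Vectorized partial Spearman of every gene row against one score.

    Returns a frame indexed by gene with columns ``pscc`` and ``p``.
    """
    samples = expr.columns
    y = score.reindex(samples).to_numpy(dtype=float)
    z = purity.reindex(samples).to_numpy(dtype=float)
    if np.isnan(y).any() or np.isnan(z).any():
        raise ValueError("score/purity missing for some samples")
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 samples")

    rx = np.apply_along_axis(rankdata, 1, expr.to_numpy(dtype=float))
    ry = rankdata(y)
    constant_z = np.ptp(z) == 0
    rz = rankdata(z)

    def _centered_unit(mat: np.ndarray) -> np.ndarray:
        mat = mat - mat.mean(axis=-1, keepdims=True)
        norm = np.sqrt((mat * mat).sum(axis=-1, keepdims=True))
        norm[norm == 0] = np.inf
        return mat / norm

    X = _centered_unit(rx)
    yv = _centered_unit(ry[None, :])[0]
    r_xy = X @ yv
    if constant_z:
        logger.info("constant purity: plain Spearman screen")
        pscc = r_xy
        pvals = np.array([_partial_p(r, n, 0) for r in pscc])
    else:
        zv = _centered_unit(rz[None, :])[0]
        r_xz = X @ zv
        r_yz = float(yv @ zv)
        denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        with np.errstate(divide="ignore", invalid="ignore"):
            pscc = (r_xy - r_xz * r_yz) / denom
        pscc[np.abs(r_xz) >= 1.0] = np.nan
        if abs(r_yz) >= 1.0:
            pscc[:] = np.nan
        pvals = np.array([_partial_p(r, n, 1) for r in pscc])
    return pd.DataFrame({"pscc": pscc, "p": pvals}, index=expr.index)


def detectability(cellline_counts: pd.DataFrame) -> pd.Series:
    """Fraction of cell lines in which a gene has at least one read."""
    if cellline_counts.shape[1] == 0:
        raise ValueError("no cell lines in count matrix")
    if (cellline_counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    dp = (cellline_counts >= 1).mean(axis=1)
    dp.name = "dp"
    return dp


def expand_signature(
    tissue: pd.DataFrame,
    score: pd.Series,
    purity: pd.Series,
    dp: pd.Series,
    signature_id: str,
    cancer_type: str = "",
    thresholds: dict | None = None,
    original_genes: list[str] | None = None,
    include_original: bool = False,
) -> tuple[ExpandedSignature, pd.DataFrame]:
    """Expand one signature to its cancer-type-specific gene list.

    Every gene in ``tissue`` is screened by purity-adjusted partial Spearman
    against the signature score; BH FDR is computed across all genes tested
    for this signature. Genes with PSCC > 0.4, FDR < 0.05 and DP > 0.8
    (strict) survive, ranked by PSCC descending (ties broken by gene id) and
    capped at 200.

    If nothing survives, the expansion falls back to the original member
    genes restricted to DP > 0.8 (logged loudly) so downstream models never
    silently lose a feature. ``include_original`` additionally unions in the
    detectable original members.

    Returns the expansion and a per-gene audit frame (pscc, p, fdr, dp).
    """
    th = dict(DEFAULT_THRESHOLDS)
    th.update(thresholds or {})
    screen = partial_spearman_screen(tissue, score, purity)
    ok = screen["p"].notna()
    fdr = np.full(len(screen), np.nan)
    if ok.any():
        fdr[ok.to_numpy()] = multipletests(screen.loc[ok, "p"], method="fdr_bh")[1]
    screen["fdr"] = fdr
    screen["dp"] = dp.reindex(screen.index)

    passed = screen[
        (screen["pscc"] > th["pscc"])
        & (screen["fdr"] < th["fdr"])
        & (screen["dp"] > th["dp"])
    ]
    # deterministic tie-break: pscc descending, then gene id ascending
    ordered = passed.iloc[
        np.lexsort((passed.index.to_numpy(dtype=str),
                    -passed["pscc"].to_numpy(dtype=float)))
    ]
    genes = list(ordered.index[: th["max_genes"]])

    fallback = False
    if not genes:
        fallback = True
        logger.warning(
            "signature %s (%s): no gene passed expansion filters; falling "
            "back to original members with DP > %.2f",
            signature_id, cancer_type, th["dp"],
        )
        if original_genes:
            dpo = screen["dp"].reindex(original_genes)
            genes = [g for g in original_genes if dpo.get(g, 0) > th["dp"]]
    elif include_original and original_genes:
        dpo = screen["dp"].reindex(original_genes)
        extra = [g for g in original_genes
                 if g not in set(genes) and dpo.get(g, 0) > th["dp"]]
        genes = genes + extra

    expansion = ExpandedSignature(
        signature_id=signature_id,
        cancer_type=cancer_type,
        genes=genes,
        provenance={**th, "fallback": fallback, "n_tested": int(ok.sum())},
    )
    return expansion, screen
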