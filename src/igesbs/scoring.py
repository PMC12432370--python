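"""Per-sample signature activity scores and cohort-wise standardization.

Expression matrices are genes x samples. Two single-sample scoring methods are
provided:

``mean_z``
    Each gene is z-scored across samples (sample sd, ddof=1); a signature's
    score in a sample is the mean z over its member genes present in the
    matrix. Zero-variance genes contribute z = 0.
``rank_enrichment``
    Within each sample, genes are ranked by expression (average ranks for
    ties); the score is the mean member-gene rank re-centred and rescaled to
    [-1, 1], an ssGSEA-like rank statistic.

Scores are standardized per cohort (mean 0, sd 1) before any downstream
association analysis, so one unit is one within-cohort standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection

logger = logging.getLogger(__name__)

SCORING_METHODS = ("mean_z", "rank_enrichment")


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix.

    ``values`` holds linear TPM-like abundances unless ``log_transformed`` is
    True, in which case they are log2(TPM + 1)-like. Scoring always works on
    the log scale; linear input is transformed internally.
    """

    values: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if not self.log_transformed and (arr < 0).any():
            raise ValueError("linear-scale expression must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def logged(self) -> pd.DataFrame:
        """Return the matrix on the log2(x + 1) scale."""
        if self.log_transformed:
            return self.values
        return np.log2(self.values + 1.0)


@dataclass
class SignatureScoreMatrix:
    """Signatures x samples activity scores."""

    values: pd.DataFrame
    standardized: bool = False
    method: str = "mean_z"


def _membership(sets: GeneSetCollection, genes: pd.Index, min_genes: int):
    """Yield (set, present-gene list) with logging for dropped genes."""
    gene_pos = pd.Index(genes)
    for s in sets:
        present = [g for g in s.genes if g in gene_pos]
        missing = len(s.genes) - len(present)
        if missing:
            logger.warning(
                "signature %s: %d/%d member genes absent from matrix, dropped",
                s.name, missing, len(s.genes),
            )
        if len(present) < min_genes:
            logger.warning(
                "signature %s: only %d member genes present (< %d); "
                "scores set to missing", s.name, len(present), min_genes,
            )
            yield s, None
        else:
            yield s, present


def score_signatures(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    method: str = "mean_z",
    min_genes: int = 1,
) -> SignatureScoreMatrix:
    """Compute per-sample activity scores for every signature.

    Parameters
    ----------
    expr : ExpressionMatrix
        Genes x samples.
    sets : GeneSetCollection
        Signatures to score; member genes absent from ``expr`` are dropped
        (logged). A set retaining fewer than ``min_genes`` genes scores as
        missing for all samples.
    method : {"mean_z", "rank_enrichment"}

    Returns
    -------
    SignatureScoreMatrix
        Unstandardized scores, one row per signature.
    """
    if method not in SCORING_METHODS:
        raise ValueError(f"unknown scoring method {method!r}")
    X = expr.logged()
    n_samples = X.shape[1]
    if method == "mean_z":
        if n_samples < 2:
            raise ValueError("mean_z requires >=2 samples")
        mu = X.mean(axis=1)
        sd = X.std(axis=1, ddof=1)
        safe_sd = sd.replace(0.0, np.inf)  # zero-variance gene -> z = 0
        Z = X.sub(mu, axis=0).div(safe_sd, axis=0)
        basis = Z
    else:
        G = X.shape[0]
        if G < 2:
            raise ValueError("rank_enrichment requires >=2 genes")
        ranks = X.rank(axis=0)  # average ranks, 1..G per sample
        basis = (ranks - (G + 1) / 2.0) * (2.0 / (G - 1))

    rows = {}
    for s, present in _membership(sets, X.index, min_genes):
        if present is None:
            rows[s.name] = pd.Series(np.nan, index=X.columns)
        else:
            rows[s.name] = basis.loc[present].mean(axis=0)
    scores = pd.DataFrame(rows).T
    scores.index.name = "signature"
    return SignatureScoreMatrix(values=scores, standardized=False, method=method)


def standardize_scores(
    scores: SignatureScoreMatrix, cohort_labels: pd.Series
) -> SignatureScoreMatrix:
    """Z-transform each signature within each cohort (mean 0, sd 1, ddof=1).

    A signature that is constant within a cohort is set to all zeros there
    (with a warning) rather than NaN.
    """
    vals = scores.values
    labels = cohort_labels.reindex(vals.columns)
    if labels.isna().any():
        raise ValueError("cohort label missing for some samples")
    out = vals.copy().astype(float)
    for cohort, cols in vals.columns.groupby(labels).items():
        block = vals.loc[:, cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        constant = sd.fillna(0.0) == 0.0
        if constant.any():
            logger.warning(
                "cohort %s: %d constant signature rows set to zero",
                cohort, int(constant.sum()),
            )
        safe_sd = sd.mask(constant, np.inf)
        out.loc[:, cols] = block.sub(mu, axis=0).div(safe_sd, axis=0).to_numpy()
    return SignatureScoreMatrix(values=out, standardized=True, method=scores.method)
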