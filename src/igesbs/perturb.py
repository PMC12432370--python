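"""Compound scoring: prerank GSEA, ACAT, PGES aggregation and boosting score.

A compound that significantly up-regulates sensitivity-associated signatures
(sIGeS) while down-regulating resistance-associated ones (rIGeS) is a
candidate immunotherapy booster. The chain per compound and cancer type:

1. For every perturbation condition (cell line, dose, time), genes are
   ranked by treated-minus-control expression difference.
2. Weighted-KS prerank GSEA (exponent 1 on |metric|) gives each signature an
   enrichment score ES, a permutation NES (ES divided by the mean |null ES|
   of matching sign), a permutation p and a BH FDR across signatures within
   the condition.
3. Per (signature, cancer type, compound), FDR-adjusted p-values across
   conditions are combined with the aggregated Cauchy association test
   (ACAT), and NES values are aggregated into a perturb gene expression
   score (PGES): each cell line contributes its reference-condition NES
   (10 uM / 24 h, or the nearest condition) plus an awarding term f, the
   mean NES difference of its non-reference conditions from the reference,
   weighted by a cell-line/tumor similarity weight W; PGES is the mean over
   cell lines.
4. The boosting score BS = sum over significantly perturbed signatures of
   Coe_i * PGES_i, with Coe_i the elastic-net coefficient; compounds are
   ranked by BS within each cancer type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet, GeneSetCollection
from .response import ResponseModel

logger = logging.getLogger(__name__)

REFERENCE_DOSE_UM = 10.0
REFERENCE_TIME_H = 24.0
P_CLIP = 1e-15


@dataclass
class PerturbationCondition:
    """One (compound, cell line, dose, time) profile with its plate-matched
    vehicle (DMSO) control."""

    compound_id: str
    cell_line: str
    cancer_type: str
    dose_um: float
    time_h: float
    treated: pd.Series  # gene -> log-scale expression
    control: pd.Series
    plate: str = ""

    def __post_init__(self) -> None:
        if self.dose_um <= 0 or self.time_h <= 0:
            raise ValueError("dose and time must be positive")


@dataclass
class EnrichmentResult:
    """Prerank GSEA result for one signature under one condition."""

    signature_id: str
    es: float
    nes: float
    p_perm: float
    fdr: float = np.nan
    condition: PerturbationCondition | None = None


@dataclass
class PGESRecord:
    """Aggregated perturbation effect for one (signature, cancer, compound)."""

    signature_id: str
    cancer_type: str
    compound_id: str
    pges: float
    p_combined: float
    n_conditions: int
    awarding: dict = field(default_factory=dict)  # cell line -> (f, m)


@dataclass
class BoostingScore:
    """Boosting score for one (compound, cancer type)."""

    compound_id: str
    cancer_type: str
    bs: float
    n_significant: int
    rank: int | None = None
    percentile: float | None = None


class CellWeightTable:
    """Cell-line weights W in (0, 1], normalized to max 1 per cancer type.

    W is the mean transcriptome correlation between a cell line and matched
    patient tumors, divided by the per-cancer-type maximum. Lookups fall
    back to the cancer-type mean, then to 1.0 (with a warning).
    """

    def __init__(self, table: pd.DataFrame, normalize: bool = True):
        required = {"cell_line", "cancer_type", "W"}
        if not required.issubset(table.columns):
            raise ValueError(f"weight table needs columns {sorted(required)}")
        table = table.copy()
        if (table["W"] <= 0).any():
            raise ValueError("weights must be positive")
        if normalize:
            table["W"] = table.groupby("cancer_type")["W"].transform(
                lambda w: w / w.max()
            )
        self.table = table

    def weight(self, cell_line: str, cancer_type: str) -> float:
        hit = self.table[
            (self.table["cell_line"] == cell_line)
            & (self.table["cancer_type"] == cancer_type)
        ]
        if len(hit):
            return float(hit["W"].iloc[0])
        same_type = self.table[self.table["cancer_type"] == cancer_type]
        if len(same_type):
            logger.warning("no weight for cell line %s in %s; using type mean",
                           cell_line, cancer_type)
            return float(same_type["W"].mean())
        logger.warning("no weights for cancer type %s; using 1.0", cancer_type)
        return 1.0


# ---------------------------------------------------------------------------
# gene ranking
# ---------------------------------------------------------------------------

def rank_genes(cond: PerturbationCondition) -> pd.Series:
    """Rank genes by treated - control difference, descending.

    Exact ties are broken lexicographically by gene id. Every treated gene
    must be present in the control profile.
    """
    missing = cond.treated.index.difference(cond.control.index)
    if len(missing):
        raise ValueError(f"genes missing in control profile: {list(missing[:5])}")
    diff = cond.treated - cond.control.reindex(cond.treated.index)
    genes = diff.index.to_numpy(dtype=str)
    order = np.lexsort((genes, -diff.to_numpy(dtype=float)))
    return diff.iloc[order]


# ---------------------------------------------------------------------------
# prerank GSEA with permutation NES
# ---------------------------------------------------------------------------

def _es_for_positions(pos: np.ndarray, w: np.ndarray, n_genes: int) -> np.ndarray:
    """Vectorized weighted-KS enrichment score for member-position sets.

    ``pos``: (n_rows, k) member positions in the ranked list, sorted
    ascending per row. ``w``: |metric| in rank order. Extremes of the
    running sum occur immediately before/after hits, so only 2k deviations
    per row are evaluated.
    """
    if pos.ndim == 1:
        pos = pos[None, :]
    k = pos.shape[1]
    hw = w[pos]
    cw = np.cumsum(hw, axis=1)
    total = cw[:, -1].copy()
    zero = total <= 0
    if zero.any():
        # all member metrics are zero: fall back to unweighted hit steps
        cw[zero] = np.arange(1, k + 1, dtype=float)
        total[zero] = k
    p_hit_after = cw / total[:, None]
    # P_hit just before hit j is the cumulative weight up to hit j-1
    prev = np.concatenate([np.zeros((cw.shape[0], 1)), cw[:, :-1]], axis=1)
    p_hit_before = prev / total[:, None]
    misses_before = pos - np.arange(k)[None, :]
    p_miss = misses_before / float(n_genes - k)
    dev_after = p_hit_after - p_miss
    dev_before = p_hit_before - p_miss
    max_pos = dev_after.max(axis=1)
    min_neg = dev_before.min(axis=1)
    # |max| vs |min| ties (within fp noise) resolve to the positive deviation
    return np.where(max_pos >= -min_neg - 1e-12, max_pos, min_neg)


def _brute_force_es(metric: np.ndarray, is_member: np.ndarray) -> float:
    """Reference running-sum ES; O(n) walk over the full ranked list."""
    w = np.abs(metric).astype(float)
    total = w[is_member].sum()
    n = metric.size
    k = int(is_member.sum())
    running = 0.0
    best = 0.0
    for i in range(n):
        if is_member[i]:
            running += (w[i] / total) if total > 0 else 1.0 / k
        else:
            running -= 1.0 / (n - k)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def _null_positions(rng: np.random.Generator, nperm: int, n: int, k: int) -> np.ndarray:
    mat = rng.random((nperm, n)).argpartition(k - 1, axis=1)[:, :k]
    mat.sort(axis=1)
    return mat


def _nes_p(es: float, null: np.ndarray) -> tuple[float, float]:
    """Sign-matched NES and permutation p for one observed ES."""
    if es == 0.0:
        return 0.0, 1.0
    if es > 0:
        pool = null[null > 0]
        extreme = int((pool >= es).sum())
    else:
        pool = null[null < 0]
        extreme = int((pool <= es).sum())
    if pool.size == 0:
        scale = np.abs(null).mean() if null.size else np.nan
    else:
        scale = np.abs(pool).mean()
    nes = es / scale if scale and np.isfinite(scale) and scale > 0 else np.nan
    p = (1.0 + extreme) / (1.0 + pool.size)
    return float(nes), float(min(p, 1.0))


def gsea_prerank_collection(
    ranked: pd.Series,
    sets: GeneSetCollection,
    nperm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Prerank GSEA of every signature against one ranked list.

    The gene-label permutation null is shared across signatures of equal
    member count, making large batches cheap. Returns a frame indexed by
    signature with columns es, nes, p_perm, fdr, n_members (BH FDR across
    the signatures of this condition).
    """
    if nperm < 100:
        raise ValueError("nperm must be >= 100")
    genes = ranked.index
    n = len(genes)
    gene_pos = pd.Series(np.arange(n), index=genes)
    w = np.abs(ranked.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)

    members: dict[str, np.ndarray] = {}
    for s in sets:
        pos = gene_pos.reindex(s.genes).dropna().to_numpy(dtype=int)
        if pos.size == 0:
            raise ValueError(f"signature {s.name}: no member genes in universe")
        if pos.size >= n:
            raise ValueError(f"signature {s.name}: degenerate set (covers universe)")
        pos.sort()
        members[s.name] = pos

    nulls: dict[int, np.ndarray] = {}
    for k in sorted({p.size for p in members.values()}):
        nulls[k] = _es_for_positions(_null_positions(rng, nperm, n, k), w, n)

    rows = []
    for name, pos in members.items():
        es = float(_es_for_positions(pos, w, n)[0])
        nes, p = _nes_p(es, nulls[pos.size])
        rows.append({"signature": name, "es": es, "nes": nes,
                     "p_perm": p, "n_members": pos.size})
    out = pd.DataFrame(rows).set_index("signature")
    out["fdr"] = multipletests(out["p_perm"], method="fdr_bh")[1]
    return out


def gsea_prerank(
    ranked: pd.Series, gene_set: GeneSet, nperm: int = 1000, seed: int = 0
) -> EnrichmentResult:
    """Prerank GSEA for a single signature (FDR left NaN: it is defined
    across the signatures of a condition)."""
    frame = gsea_prerank_collection(
        ranked, GeneSetCollection([gene_set]), nperm=nperm, seed=seed
    )
    row = frame.iloc[0]
    return EnrichmentResult(
        signature_id=gene_set.name,
        es=float(row["es"]),
        nes=float(row["nes"]),
        p_perm=float(row["p_perm"]),
    )


# ---------------------------------------------------------------------------
# ACAT
# ---------------------------------------------------------------------------

def acat_combine(pvals, weights=None) -> float:
    """Aggregated Cauchy association test.

    T = sum w_i tan((0.5 - p_i) pi) / sum w_i; combined p = 0.5 - atan(T)/pi.
    Valid under arbitrary dependence; p of exactly 0/1 is clipped to
    [1e-15, 1 - 1e-15] with a warning.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative, not all zero")
    if (p <= 0).any():
        logger.warning("p-values of 0 clipped to %g", P_CLIP)
    elif (p >= 1).any():
        # adjusted p-values of exactly 1 are routine; clip quietly
        logger.debug("p-values of 1 clipped to 1 - %g", P_CLIP)
    p = np.clip(p, P_CLIP, 1 - P_CLIP)
    t = float((w * np.tan((0.5 - p) * np.pi)).sum() / w.sum())
    return float(0.5 - np.arctan(t) / np.pi)


# ---------------------------------------------------------------------------
# reference selection and PGES
# ---------------------------------------------------------------------------

def is_reference(dose_um: float, time_h: float) -> bool:
    return dose_um == REFERENCE_DOSE_UM and time_h == REFERENCE_TIME_H


def select_reference(conditions: list[tuple[float, float]]) -> int:
    """Index of the reference condition among (dose_um, time_h) pairs.

    Exact (10 uM, 24 h) wins; otherwise the nearest condition in
    (log10 dose, log2 time) Euclidean distance, ties resolved toward lower
    dose then shorter time.
    """
    if not conditions:
        raise ValueError("no conditions")
    for i, (d, t) in enumerate(conditions):
        if is_reference(d, t):
            return i
    ref = (np.log10(REFERENCE_DOSE_UM), np.log2(REFERENCE_TIME_H))
    keyed = [
        (np.hypot(np.log10(d) - ref[0], np.log2(t) - ref[1]), d, t, i)
        for i, (d, t) in enumerate(conditions)
    ]
    keyed.sort()
    return keyed[0][3]


def compute_pges(
    results: list[EnrichmentResult],
    weights: CellWeightTable,
    signature_id: str | None = None,
) -> PGESRecord:
    """Aggregate per-condition enrichment into one PGES.

    ``results`` are the enrichment results of a single (signature, cancer
    type, compound) trio, one per perturbation condition, each carrying its
    condition and a condition-level FDR-adjusted p. With a single condition
    PGES reduces exactly to W * NES; with several, each cell line p
    contributes W_p * (NES_ref_p + f_p) where f_p is the mean NES excess of
    its non-reference conditions over the reference, and PGES is the mean
    over cell lines. The combined p is the ACAT of all per-condition FDRs.
    """
    if not results:
        raise ValueError("no enrichment results")
    for r in results:
        if r.condition is None:
            raise ValueError("enrichment results must carry their condition")
    sig = signature_id or results[0].signature_id
    cancer = results[0].condition.cancer_type
    compound = results[0].condition.compound_id

    by_cell: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_cell.setdefault(r.condition.cell_line, []).append(r)

    terms = []
    awarding: dict[str, tuple[float, int]] = {}
    for cell, rs in by_cell.items():
        ref_i = select_reference([(r.condition.dose_um, r.condition.time_h)
                                  for r in rs])
        nes_ref = rs[ref_i].nes
        others = [r.nes for j, r in enumerate(rs) if j != ref_i]
        f = float(np.mean([x - nes_ref for x in others])) if others else 0.0
        awarding[cell] = (f, len(others))
        w_cell = weights.weight(cell, cancer)
        terms.append(w_cell * (nes_ref + f))
    pges = float(np.mean(terms))
    p_combined = acat_combine([r.fdr for r in results])
    return PGESRecord(
        signature_id=sig,
        cancer_type=cancer,
        compound_id=compound,
        pges=pges,
        p_combined=p_combined,
        n_conditions=len(results),
        awarding=awarding,
    )


# ---------------------------------------------------------------------------
# boosting score and ranking
# ---------------------------------------------------------------------------

def compute_boosting_score(
    pges_records: list[PGESRecord],
    model: ResponseModel,
    fdr_threshold: float = 0.05,
) -> BoostingScore:
    """BS = sum over significant signatures of Coe_i * PGES_i.

    A signature is significant when its ACAT-combined p < ``fdr_threshold``;
    signatures without a model coefficient are skipped with a warning.
    BS = 0 when no signature is significant.
    """
    if not pges_records:
        raise ValueError("no PGES records")
    compound = pges_records[0].compound_id
    cancer = pges_records[0].cancer_type
    bs = 0.0
    n_sig = 0
    for rec in pges_records:
        if rec.p_combined >= fdr_threshold:
            continue
        coe = model.coefficients.get(rec.signature_id)
        if coe is None:
            logger.warning("signature %s has no model coefficient; skipped",
                           rec.signature_id)
            continue
        bs += coe * rec.pges
        n_sig += 1
    return BoostingScore(compound_id=compound, cancer_type=cancer,
                         bs=bs, n_significant=n_sig)


def rank_compounds(scores: list[BoostingScore]) -> pd.DataFrame:
    """Rank compounds by BS (descending) within one cancer type.

    Rank 1 is the highest BS; ties broken by compound id; percentile is
    rank / n (so the top compound of 1768 is at 1/1768).
    """
    if not scores:
        raise ValueError("no compounds to rank")
    frame = pd.DataFrame([
        {"compound": s.compound_id, "cancer_type": s.cancer_type,
         "bs": s.bs, "n_significant": s.n_significant}
        for s in scores
    ])
    frame = frame.sort_values(
        ["bs", "compound"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    frame["percentile"] = frame["rank"] / len(frame)
    for s in scores:
        row = frame.index[frame["compound"] == s.compound_id]
        if len(row):
            s.rank = int(frame.loc[row[0], "rank"])
            s.percentile = float(frame.loc[row[0], "percentile"])
    return frame


# ---------------------------------------------------------------------------
# validation statistics
# ---------------------------------------------------------------------------

@dataclass
class BoosterTest:
    effect_size: float
    p: float
    enriched: bool


def booster_enrichment_test(
    scores: pd.Series, known_labels: pd.Series
) -> BoosterTest:
    """Are compounds with supporting evidence scored higher?

    ``effect_size`` is mean(BS | known) - mean(BS | other); p is the
    one-sided (known > other) Wilcoxon rank-sum test. The enrichment flag
    applies the rule effect size > 1 and p < 0.05.
    """
    labels = known_labels.reindex(scores.index)
    if labels.isna().any():
        raise ValueError("label missing for some compounds")
    known = scores[labels.astype(bool)]
    other = scores[~labels.astype(bool)]
    if known.empty or other.empty:
        raise ValueError("both labelled groups must be non-empty")
    effect = float(known.mean() - other.mean())
    stat = mannwhitneyu(known, other, alternative="greater")
    return BoosterTest(effect_size=effect, p=float(stat.pvalue),
                       enriched=(effect > 1.0 and stat.pvalue < 0.05))


def direction_consistency(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, padj_cut: float = 0.1
) -> float:
    """Proportion of signatures regulated in A (p.adj < cut) whose NES sign
    matches in B. Returns NaN (with a warning) if nothing is regulated."""
    common = calls_a.index.intersection(calls_b.index)
    a = calls_a.loc[common]
    b = calls_b.loc[common]
    regulated = a[a["padj"] < padj_cut]
    if regulated.empty:
        logger.warning("no regulated signatures at p.adj < %g", padj_cut)
        return float("nan")
    same = np.sign(regulated["nes"]) == np.sign(b.loc[regulated.index, "nes"])
    return float(same.mean())


# ---------------------------------------------------------------------------
# end-to-end compound scoring
# ---------------------------------------------------------------------------

def score_compounds(
    conditions: list[PerturbationCondition],
    sets: GeneSetCollection,
    model: ResponseModel,
    weights: CellWeightTable,
    nperm: int = 1000,
    seed: int = 0,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score and rank every compound against every cancer type present.

    Returns (ranked BS table, per-signature PGES audit table).
    """
    by_condition: list[tuple[PerturbationCondition, pd.DataFrame]] = []
    for i, cond in enumerate(conditions):
        ranked = rank_genes(cond)
        enr = gsea_prerank_collection(ranked, sets, nperm=nperm,
                                      seed=seed + i)
        by_condition.append((cond, enr))

    trios: dict[tuple[str, str], dict[str, list[EnrichmentResult]]] = {}
    for cond, enr in by_condition:
        key = (cond.compound_id, cond.cancer_type)
        per_sig = trios.setdefault(key, {})
        for sig, row in enr.iterrows():
            per_sig.setdefault(sig, []).append(EnrichmentResult(
                signature_id=sig, es=row["es"], nes=row["nes"],
                p_perm=row["p_perm"], fdr=row["fdr"], condition=cond,
            ))

    audit_rows = []
    by_cancer: dict[str, list[BoostingScore]] = {}
    for (compound, cancer), per_sig in sorted(trios.items()):
        records = []
        for sig in sorted(per_sig):
            rec = compute_pges(per_sig[sig], weights, signature_id=sig)
            records.append(rec)
            audit_rows.append({
                "compound": compound, "cancer_type": cancer, "signature": sig,
                "pges": rec.pges, "p_combined": rec.p_combined,
                "n_conditions": rec.n_conditions,
            })
        bs = compute_boosting_score(records, model, fdr_threshold=fdr_threshold)
        by_cancer.setdefault(cancer, []).append(bs)

    ranked_frames = [rank_compounds(v) for _, v in sorted(by_cancer.items())]
    return pd.concat(ranked_frames, ignore_index=True), pd.DataFrame(audit_rows)
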