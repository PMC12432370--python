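"""Synthetic data with the statistical structure the pipeline assumes.

The generators emulate, at desk scale, the three data layers the framework
consumes:

* patient cohorts — latent per-sample signature activities drive both a
  logistic response model (planted log-odds per SD) and member-gene
  expression, with per-cohort batch shifts;
* a tumor tissue panel — Beta-distributed tumor purity, genes loaded on
  signature activity (true expansion targets), genes loaded on purity only
  (confounders that plain correlation would accept), plus a cell-line count
  matrix with configurable dropout for detectability filtering;
* compound perturbation profiles — plate-matched vehicle controls and
  treated profiles in which engineered compounds shift the genes of chosen
  signatures up or down (dose/time-scaled), while null compounds perturb
  random non-signature genes.

All generators are pure functions of (spec, seed): the same spec yields
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import logit, expit

from .genesets import GeneSet, GeneSetCollection
from .meta import CohortData
from .perturb import CellWeightTable, PerturbationCondition
from .scoring import ExpressionMatrix

BASELINE_LOG_EXPR = 5.0


@dataclass
class CohortSpec:
    n_samples: int = 100
    responder_fraction: float = 0.4

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not 0 < self.responder_fraction < 1:
            raise ValueError("responder_fraction must be in (0, 1)")


@dataclass
class CompoundSpec:
    """An engineered compound: shifts target-signature genes up or down."""

    compound_id: str
    targets: dict[str, int] = field(default_factory=dict)  # signature -> +1/-1
    magnitude: float = 1.0
    doses: tuple[float, ...] = (10.0,)
    times: tuple[float, ...] = (24.0,)


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic universe.

    Defaults are sized for sub-minute runs: 1000 genes, 40 signatures of 25
    genes, 5 cohorts of 100 samples at 40% responders, 3 cell lines and 60
    compounds (2 engineered + nulls).
    """

    seed: int = 0
    n_genes: int = 1000
    n_sets: int = 40
    genes_per_set: int = 25
    cohorts: list[CohortSpec] = field(
        default_factory=lambda: [CohortSpec() for _ in range(5)]
    )
    planted_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    batch_shift_sd: float = 0.5
    # tissue panel
    n_tissue_samples: int = 200
    purity_ab: tuple[float, float] = (5.0, 2.0)
    purity_score_corr: float = 0.6
    n_targets_per_signature: int = 3
    n_confounders_per_signature: int = 3
    target_noise_sd: float = 0.75
    confounder_noise_sd: float = 0.5
    n_cell_lines_panel: int = 10
    count_mean: float = 5.0
    dropout: dict[str, float] = field(default_factory=dict)
    # perturbations
    cell_lines: tuple[str, ...] = ("CL1", "CL2", "CL3")
    cancer_type: str = "SYNTH"
    n_null_compounds: int = 58
    compound_specs: list[CompoundSpec] = field(default_factory=list)
    perturb_noise_sd: float = 0.25
    null_magnitude: float = 1.0

    def __post_init__(self) -> None:
        for c in self.cohorts:
            if not isinstance(c, CohortSpec):
                raise TypeError("cohorts must be CohortSpec instances")
        if self.n_genes <= 0 or self.n_sets <= 0 or self.genes_per_set <= 0:
            raise ValueError("counts must be positive")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    def set_ids(self) -> list[str]:
        width = len(str(self.n_sets - 1))
        return [f"S{i:0{width}d}" for i in range(self.n_sets)]


def make_gene_sets(spec: SimulationSpec) -> GeneSetCollection:
    """Deterministic signature membership (disjoint blocks when they fit)."""
    genes = spec.gene_ids()
    rng = np.random.default_rng(spec.seed)
    sets = []
    if spec.n_sets * spec.genes_per_set <= spec.n_genes:
        perm = rng.permutation(spec.n_genes)
        for i, name in enumerate(spec.set_ids()):
            idx = perm[i * spec.genes_per_set:(i + 1) * spec.genes_per_set]
            sets.append(GeneSet(name=name, genes=[genes[j] for j in sorted(idx)]))
    else:
        for name in spec.set_ids():
            idx = rng.choice(spec.n_genes, size=spec.genes_per_set, replace=False)
            sets.append(GeneSet(name=name, genes=[genes[j] for j in sorted(idx)]))
    return GeneSetCollection(sets)


def generate_cohorts(
    spec: SimulationSpec,
) -> tuple[list[CohortData], GeneSetCollection, dict]:
    """Simulate response cohorts with planted signature-response effects.

    Per sample, latent activities A_s ~ N(0,1); response ~ Bernoulli with
    logit = logit(responder_fraction) + sum_s b_s A_s; member-gene
    expression = baseline + A_s + noise (+ per-cohort batch shift), clipped
    at zero on the log scale.
    """
    sets = make_gene_sets(spec)
    unknown = set(spec.planted_effects) - set(sets.names)
    if unknown:
        raise ValueError(f"planted effect on unknown signature(s): {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed + 1)
    genes = spec.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}
    membership = np.zeros((spec.n_sets, spec.n_genes))
    for si, s in enumerate(sets):
        for g in s.genes:
            membership[si, gene_index[g]] = 1.0
    b = np.array([spec.planted_effects.get(name, 0.0) for name in sets.names])

    cohorts = []
    for ci, cs in enumerate(spec.cohorts):
        n = cs.n_samples
        A = rng.standard_normal((spec.n_sets, n))
        eta = logit(cs.responder_fraction) + b @ A
        y = (rng.random(n) < expit(eta)).astype(int)
        noise = rng.standard_normal((spec.n_genes, n)) * spec.noise_sd
        shift = rng.standard_normal(spec.n_genes) * spec.batch_shift_sd
        expr = BASELINE_LOG_EXPR + membership.T @ A + noise + shift[:, None]
        np.clip(expr, 0.0, None, out=expr)
        cohort_id = f"cohort{ci}"
        samples = [f"{cohort_id}_s{j}" for j in range(n)]
        em = ExpressionMatrix(
            values=pd.DataFrame(expr, index=genes, columns=samples),
            log_transformed=True,
        )
        cohorts.append(CohortData(
            cohort_id=cohort_id,
            expression=em,
            response=pd.Series(y, index=samples),
        ))
    truth = {
        "planted_effects": dict(spec.planted_effects),
        "set_names": sets.names,
    }
    return cohorts, sets, truth


def generate_tissue_panel(
    spec: SimulationSpec, sets: GeneSetCollection | None = None
) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame, dict]:
    """Simulate a tissue panel with purity-confounded structure.

    Signature activities correlate with purity (loading
    ``purity_score_corr``). Target genes load on activity (detected by the
    purity-adjusted screen), confounder genes load on purity only (their
    marginal correlation with the score is spurious). Cell-line counts are
    Poisson with per-gene dropout probabilities.

    Returns (tissue expression, purity series, cell-line counts, truth).
    """
    sets = sets if sets is not None else make_gene_sets(spec)
    rng = np.random.default_rng(spec.seed + 2)
    genes = spec.gene_ids()
    n = spec.n_tissue_samples
    samples = [f"t{j:04d}" for j in range(n)]

    purity = rng.beta(*spec.purity_ab, size=n)
    purity_z = (purity - purity.mean()) / purity.std(ddof=1)
    lam = spec.purity_score_corr
    member_genes: set[str] = set()
    for s in sets:
        member_genes.update(s.genes)
    free = [g for g in genes if g not in member_genes]
    rng.shuffle(free)

    activities = {}
    targets: dict[str, list[str]] = {}
    confounders: dict[str, list[str]] = {}
    expr = pd.DataFrame(
        BASELINE_LOG_EXPR + rng.standard_normal((spec.n_genes, n)) * spec.noise_sd,
        index=genes, columns=samples,
    )
    cursor = 0
    gene_index = {g: i for i, g in enumerate(genes)}
    arr = expr.to_numpy()
    for s in sets:
        act = lam * purity_z + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        activities[s.name] = act
        for g in s.genes:  # member genes track activity so scoring recovers it
            arr[gene_index[g]] += act
        t_genes = free[cursor:cursor + spec.n_targets_per_signature]
        cursor += spec.n_targets_per_signature
        c_genes = free[cursor:cursor + spec.n_confounders_per_signature]
        cursor += spec.n_confounders_per_signature
        targets[s.name] = sorted(t_genes)
        confounders[s.name] = sorted(c_genes)
        for g in t_genes:
            arr[gene_index[g]] = (
                BASELINE_LOG_EXPR + act
                + rng.standard_normal(n) * spec.target_noise_sd
            )
        for g in c_genes:
            arr[gene_index[g]] = (
                BASELINE_LOG_EXPR + purity_z
                + rng.standard_normal(n) * spec.confounder_noise_sd
            )
    np.clip(arr, 0.0, None, out=arr)
    tissue = ExpressionMatrix(
        values=pd.DataFrame(arr, index=genes, columns=samples),
        log_transformed=True,
    )

    lines = [f"ccle{j}" for j in range(spec.n_cell_lines_panel)]
    counts = rng.poisson(spec.count_mean,
                         size=(spec.n_genes, len(lines))).astype(float)
    for g, rate in spec.dropout.items():
        if g in gene_index:
            drop = rng.random(len(lines)) < rate
            counts[gene_index[g], drop] = 0.0
    counts_df = pd.DataFrame(counts, index=genes, columns=lines)

    truth = {
        "targets": targets,
        "confounders": confounders,
        "activities": activities,
    }
    return tissue, pd.Series(purity, index=samples, name="purity"), counts_df, truth


def default_compound_specs(
    spec: SimulationSpec, orientation: dict[str, str]
) -> list[CompoundSpec]:
    """One booster (up-sIGeS / down-rIGeS), one inverted compound."""
    up = {s: +1 for s, lab in orientation.items() if lab == "sIGeS"}
    down = {s: -1 for s, lab in orientation.items() if lab == "rIGeS"}
    booster = {**up, **down}
    inverted = {s: -d for s, d in booster.items()}
    return [
        CompoundSpec(compound_id="booster", targets=booster),
        CompoundSpec(compound_id="inverted", targets=inverted),
    ]


def _dose_time_scale(dose: float, time: float) -> float:
    """Monotone-in-dose effect scale; 1 at the (10 uM, 24 h) reference."""
    d = max((np.log10(dose) + 1.0) / 2.0, 0.1)
    t = 1.0 if time == 24.0 else 0.8
    return d * t


def generate_perturbations(
    spec: SimulationSpec,
    sets: GeneSetCollection,
    orientation: dict[str, str] | None = None,
) -> tuple[list[PerturbationCondition], CellWeightTable, pd.Series, dict]:
    """Simulate perturbation profiles for engineered and null compounds.

    Engineered compounds (``spec.compound_specs``, or a default booster /
    inverted pair built from ``orientation``) shift the genes of their target
    signatures by +-magnitude x dose/time scale; null compounds shift a
    random draw of non-signature genes. Controls are plate-matched vehicle
    profiles.

    Returns (conditions, cell weights, known-booster labels, truth).
    """
    rng = np.random.default_rng(spec.seed + 3)
    genes = spec.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}
    member_genes: set[str] = set()
    for s in sets:
        member_genes.update(s.genes)
    non_members = [g for g in genes if g not in member_genes]

    compound_specs = list(spec.compound_specs)
    if not compound_specs:
        if orientation is None:
            raise ValueError("need orientation labels or explicit compound_specs")
        compound_specs = default_compound_specs(spec, orientation)
    null_ids = [f"null{j:03d}" for j in range(spec.n_null_compounds)]

    conditions: list[PerturbationCondition] = []
    labels = {}
    for cs in compound_specs:
        labels[cs.compound_id] = True
        for g_name in cs.targets:
            if g_name not in sets:
                raise ValueError(f"compound targets unknown signature {g_name}")
    for cid in null_ids:
        labels[cid] = False

    # one vehicle control per (cell line, plate), shared by its conditions
    controls = {
        cell: pd.Series(BASELINE_LOG_EXPR + rng.standard_normal(spec.n_genes),
                        index=genes)
        for cell in spec.cell_lines
    }

    def _make_condition(cid, cell, dose, time, delta):
        control = controls[cell]
        treated = (control.to_numpy() + delta
                   + rng.standard_normal(spec.n_genes) * spec.perturb_noise_sd)
        return PerturbationCondition(
            compound_id=cid, cell_line=cell, cancer_type=spec.cancer_type,
            dose_um=dose, time_h=time, plate=f"{cell}_plate0",
            treated=pd.Series(treated, index=genes),
            control=control,
        )

    for cs in compound_specs:
        delta_base = np.zeros(spec.n_genes)
        for sig, direction in cs.targets.items():
            for g in sets[sig].genes:
                delta_base[gene_index[g]] += direction * cs.magnitude
        for cell in spec.cell_lines:
            for dose in cs.doses:
                for time in cs.times:
                    scale = _dose_time_scale(dose, time)
                    conditions.append(_make_condition(
                        cs.compound_id, cell, dose, time, delta_base * scale))

    for cid in null_ids:
        picked = rng.choice(len(non_members),
                            size=min(spec.genes_per_set, len(non_members)),
                            replace=False)
        delta = np.zeros(spec.n_genes)
        sign = rng.choice([-1.0, 1.0])
        for j in picked:
            delta[gene_index[non_members[j]]] = sign * spec.null_magnitude
        for cell in spec.cell_lines:
            conditions.append(_make_condition(cid, cell, 10.0, 24.0, delta))

    w_raw = 0.7 + 0.3 * rng.random(len(spec.cell_lines))
    weights = CellWeightTable(pd.DataFrame({
        "cell_line": list(spec.cell_lines),
        "cancer_type": spec.cancer_type,
        "W": w_raw,
    }))
    truth = {
        "engineered": [cs.compound_id for cs in compound_specs],
        "null": null_ids,
        "orientation": dict(orientation or {}),
    }
    return conditions, weights, pd.Series(labels, name="known_booster"), truth


def spec_to_dict(spec: SimulationSpec) -> dict:
    """JSON/YAML-serializable view of a spec (for manifests)."""
    d = asdict(spec)
    d["cell_lines"] = list(spec.cell_lines)
    d["purity_ab"] = list(spec.purity_ab)
    for cs in d["compound_specs"]:
        cs["doses"] = list(cs["doses"])
        cs["times"] = list(cs["times"])
    return d


def spec_from_dict(payload: dict) -> SimulationSpec:
    """Build a spec from a plain dict (e.g. parsed YAML)."""
    payload = dict(payload)
    if "cohorts" in payload:
        payload["cohorts"] = [
            c if isinstance(c, CohortSpec) else CohortSpec(**c)
            for c in payload["cohorts"]
        ]
    if "compound_specs" in payload:
        payload["compound_specs"] = [
            c if isinstance(c, CompoundSpec) else CompoundSpec(
                **{**c, "doses": tuple(c.get("doses", (10.0,))),
                   "times": tuple(c.get("times", (24.0,)))}
            )
            for c in payload["compound_specs"]
        ]
    if "cell_lines" in payload:
        payload["cell_lines"] = tuple(payload["cell_lines"])
    if "purity_ab" in payload:
        payload["purity_ab"] = tuple(payload["purity_ab"])
    return SimulationSpec(**payload)
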