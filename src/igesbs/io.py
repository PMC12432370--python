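"""TSV input/output for the formats the pipeline exchanges.

All writers use a fixed float format so reruns with the same seed produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .perturb import PerturbationCondition
from .scoring import ExpressionMatrix

FLOAT_FORMAT = "%.10g"


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def read_expression_tsv(path: str | Path, log_transformed: bool = False) -> ExpressionMatrix:
    """Read a genes x samples matrix: first column gene id, header samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df, log_transformed=log_transformed)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    write_table(out, path)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata: sample_id, cohort_id, response in {0,1}."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort_id": str})
    required = {"sample_id", "cohort_id", "response"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    if not df["response"].isin([0, 1]).all():
        raise ValueError("response must be binary 0/1")
    return df.set_index("sample_id")


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    write_table(out, path)


def read_purity_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "purity"}.issubset(df.columns):
        raise ValueError("purity table needs columns sample_id, purity")
    return df.set_index("sample_id")["purity"]


def write_purity_tsv(purity: pd.Series, path: str | Path) -> None:
    out = purity.rename("purity").to_frame()
    out.index.name = "sample_id"
    write_table(out, path)


def read_cell_weights_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"cell_line", "cancer_type", "W"}.issubset(df.columns):
        raise ValueError("weight table needs columns cell_line, cancer_type, W")
    return df


# ---------------------------------------------------------------------------
# perturbation long format: one row per profile, metadata then gene columns
# ---------------------------------------------------------------------------

_PERTURB_META = ["compound_id", "cell_line", "cancer_type",
                 "dose_um", "time_h", "plate", "role"]


def write_perturbations_tsv(
    conditions: list[PerturbationCondition], path: str | Path
) -> None:
    """Write treated profiles plus one control row per (cell line, plate)."""
    if not conditions:
        raise ValueError("no conditions to write")
    genes = list(conditions[0].treated.index)
    rows = []
    seen_controls = set()
    for c in conditions:
        rows.append([c.compound_id, c.cell_line, c.cancer_type,
                     c.dose_um, c.time_h, c.plate, "treated",
                     *c.treated.reindex(genes).tolist()])
        key = (c.cell_line, c.plate)
        if key not in seen_controls:
            seen_controls.add(key)
            rows.append(["DMSO", c.cell_line, c.cancer_type,
                         0.0, 0.0, c.plate, "control",
                         *c.control.reindex(genes).tolist()])
    frame = pd.DataFrame(rows, columns=_PERTURB_META + genes)
    frame = frame.sort_values(
        ["cell_line", "plate", "role", "compound_id", "dose_um", "time_h"],
        kind="mergesort",
    ).reset_index(drop=True)
    write_table(frame, path, index=False)


def read_perturbations_tsv(path: str | Path) -> list[PerturbationCondition]:
    """Read the long format back, matching treated rows to their
    plate-matched control."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PERTURB_META if c not in df.columns]
    if missing:
        raise ValueError(f"perturbation table missing columns {missing}")
    genes = [c for c in df.columns if c not in _PERTURB_META]
    controls = {}
    for _, row in df[df["role"] == "control"].iterrows():
        controls[(row["cell_line"], row["plate"])] = pd.Series(
            row[genes].to_numpy(dtype=float), index=genes
        )
    conditions = []
    for _, row in df[df["role"] == "treated"].iterrows():
        key = (row["cell_line"], row["plate"])
        if key not in controls:
            raise ValueError(f"no control profile for plate {key}")
        conditions.append(PerturbationCondition(
            compound_id=row["compound_id"],
            cell_line=row["cell_line"],
            cancer_type=row["cancer_type"],
            dose_um=float(row["dose_um"]),
            time_h=float(row["time_h"]),
            plate=row["plate"],
            treated=pd.Series(row[genes].to_numpy(dtype=float), index=genes),
            control=controls[key],
        ))
    return conditions
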