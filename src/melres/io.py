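"""File formats: expression TSV, clinical CSV, signature TSV.

Plain text throughout — raw microarray processing (background correction,
RMA normalisation) is upstream of this pipeline, whose inputs are
already-normalised log-scale matrices.

* Expression: tab-separated, header row of sample ids, first column probe
  ids; numeric everywhere; duplicate probe ids rejected.
* Clinical: CSV with columns sample_id, pfs_months, pfs_event, os_months,
  os_event, age, sex (female/male), iss (I/II/III); times in months > 0,
  events 0/1.
* Signature: tab-separated with columns probe_id, gene_symbol, location,
  weight, new_weight (new_weight may be empty at the discovery stage).

The melphalan 19-probe resistance signature ships with the package and is
available through :func:`load_melphalan_signature`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .signature import COLUMNS as SIGNATURE_COLUMNS
from .signature import GeneSignature
from .simulate import CellLinePanel, PatientCohort

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_signature",
    "write_signature",
    "load_melphalan_signature",
    "read_cohort",
    "write_cohort",
    "read_panel",
    "write_panel",
]

CLINICAL_COLUMNS = ("sample_id", "pfs_months", "pfs_event", "os_months",
                    "os_event", "age", "sex", "iss")


def read_expression(path) -> pd.DataFrame:
    """Read a probes-by-samples expression matrix from TSV."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.index.name = "probe_id"
    if frame.index.duplicated().any():
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe id(s) in {path}: {dups}")
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric expression value at probe {row!r}, sample {col!r}"
            )
        if converted.isna().any():
            row = frame.index[converted.isna().to_numpy().argmax()]
            raise ValueError(f"missing expression value at probe {row!r}, sample {col!r}")
        frame[col] = converted
    return frame


def write_expression(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="probe_id")


def read_clinical(path) -> pd.DataFrame:
    """Read and validate a per-sample clinical table from CSV."""
    frame = pd.read_csv(path)
    missing = set(CLINICAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"clinical table missing column(s): {sorted(missing)}")
    frame["sample_id"] = frame["sample_id"].astype(str)
    if frame["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    frame = frame.set_index("sample_id")
    for col in ("pfs_months", "os_months", "age"):
        frame[col] = pd.to_numeric(frame[col], errors="raise")
    for col in ("pfs_months", "os_months"):
        if (frame[col] <= 0).any() or frame[col].isna().any():
            raise ValueError(f"{col} must be strictly positive months")
    for col in ("pfs_event", "os_event"):
        if not frame[col].isin([0, 1]).all():
            raise ValueError(f"{col} must be 0/1")
        frame[col] = frame[col].astype(int)
    bad_sex = ~frame["sex"].isin(["female", "male"])
    if bad_sex.any():
        raise ValueError(
            f"invalid sex level(s): {sorted(frame.loc[bad_sex, 'sex'].unique())}"
        )
    bad_iss = ~frame["iss"].isin(["I", "II", "III"])
    if bad_iss.any():
        raise ValueError(
            f"invalid ISS level(s): {sorted(frame.loc[bad_iss, 'iss'].unique())}"
        )
    return frame


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index_label="sample_id")


def read_signature(path) -> GeneSignature:
    """Read a signature TSV (probe_id, gene_symbol, location, weight, new_weight)."""
    frame = pd.read_csv(path, sep="\t")
    missing = {"probe_id", "weight"} - set(frame.columns)
    if missing:
        raise ValueError(f"signature file missing column(s): {sorted(missing)}")
    for col in ("gene_symbol", "location"):
        if col in frame.columns:
            frame[col] = frame[col].fillna("")
    return GeneSignature(frame)


def write_signature(signature: GeneSignature, path) -> None:
    frame = signature.to_frame().loc[:, list(SIGNATURE_COLUMNS)]
    frame.to_csv(path, sep="\t", index=False, na_rep="")


def load_melphalan_signature() -> GeneSignature:
    """The packaged 19-probe melphalan resistance signature.

    Weights are the cell-line discovery coefficients; new weights are the
    training-cohort Cox reweights, so the signature is ready for scoring.
    """
    ref = resources.files("melres.data") / "melphalan_signature.tsv"
    with resources.as_file(ref) as path:
        return read_signature(path)


# ---------------------------------------------------------------------------
# study bundles
# ---------------------------------------------------------------------------


def read_cohort(expression_path, clinical_path, label: str = "cohort") -> PatientCohort:
    """Assemble a cohort from its expression and clinical files.

    Sample ids in the clinical table must be exactly the expression column
    names (order follows the expression file).
    """
    expression = read_expression(expression_path)
    clinical = read_clinical(clinical_path)
    expr_samples = set(expression.columns)
    clin_samples = set(clinical.index)
    if expr_samples != clin_samples:
        only_e = sorted(expr_samples - clin_samples)[:5]
        only_c = sorted(clin_samples - expr_samples)[:5]
        raise ValueError(
            "expression and clinical sample ids differ "
            f"(expression-only: {only_e}, clinical-only: {only_c})"
        )
    clinical = clinical.loc[list(expression.columns)]
    return PatientCohort(expression=expression, clinical=clinical, label=label)


def write_cohort(cohort: PatientCohort, out_dir, prefix: str) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    expr_path = out_dir / f"{prefix}_expression.tsv"
    clin_path = out_dir / f"{prefix}_clinical.csv"
    write_expression(cohort.expression, expr_path)
    write_clinical(cohort.clinical, clin_path)
    return expr_path, clin_path


def read_panel(expression_path, gi50_path) -> CellLinePanel:
    """Assemble a cell-line panel from expression TSV and a GI50 CSV."""
    expression = read_expression(expression_path)
    gi = pd.read_csv(gi50_path, index_col=0)
    if "gi50" not in gi.columns:
        raise ValueError("GI50 file requires a 'gi50' column")
    gi.index = gi.index.astype(str)
    if set(gi.index) != set(expression.columns):
        raise ValueError("GI50 sample ids must match expression column names")
    gi50 = pd.to_numeric(gi.loc[list(expression.columns), "gi50"], errors="raise")
    zeros = pd.Series(np.zeros(expression.shape[0]), index=expression.index,
                      name="true_weight")
    return CellLinePanel(expression=expression, gi50=gi50, true_weights=zeros)


def write_panel(panel: CellLinePanel, out_dir, prefix: str = "panel") -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    expr_path = out_dir / f"{prefix}_expression.tsv"
    gi50_path = out_dir / f"{prefix}_gi50.csv"
    write_expression(panel.expression, expr_path)
    panel.gi50.rename("gi50").to_csv(gi50_path, index_label="line_id")
    return expr_path, gi50_path
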