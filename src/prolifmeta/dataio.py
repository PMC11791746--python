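"""Cohort data model and plain-text I/O.

A cohort is a log2 expression matrix (genes x samples) plus a clinical
annotation table aligned to the same samples.  Collections of cohorts are the
unit on which every pooled or meta-analytic operation in this package runs.

All files are tab-separated text.  Expression: first column the gene label,
one column per sample.  Clinical: one row per sample with the fixed column
set in :data:`CLINICAL_COLUMNS`; missing values are written as the literal
token ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: survival endpoint types, in fallback preference order: relapse-free,
#: distant-metastasis-free, disease-specific survival.
ENDPOINTS = ("RFS", "DMFS", "DSS")

#: fixed clinical column set (sample_id is the index when in memory).
CLINICAL_COLUMNS = (
    "er", "pr", "her2", "grade", "node", "size", "subtype",
    "time_months", "event", "endpoint", "treated",
)

#: default threshold above which a matrix is taken to be linear-scale
#: intensities rather than log2 values (log2 microarray data rarely
#: exceeds ~16).
LINEAR_SCALE_THRESHOLD = 50.0


class DataValidationError(ValueError):
    """Raised when an input file or assembled dataset violates an invariant."""


@dataclass
class ExpressionDataset:
    """One cohort: log2 expression values plus aligned clinical annotation.

    Parameters
    ----------
    cohort_id:
        Unique cohort label (e.g. a GEO accession).
    values:
        genes x samples DataFrame of finite log2 expression values.
    clinical:
        DataFrame indexed by sample id, columns from :data:`CLINICAL_COLUMNS`,
        in the same sample order as ``values``.
    platform:
        Free-text platform label.
    endpoint:
        Survival endpoint recorded for this cohort, one of :data:`ENDPOINTS`.
    truth:
        Optional simulation ground truth attached by the synthetic-data
        generator; never serialized.
    """

    cohort_id: str
    values: pd.DataFrame
    clinical: pd.DataFrame
    platform: str = "synthetic"
    endpoint: str = "RFS"
    truth: object | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise DataValidationError(
                f"endpoint must be one of {ENDPOINTS}, got {self.endpoint!r}"
            )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene labels: {dups}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DataValidationError("expression matrix contains non-finite values")
        if list(self.values.columns) != list(self.clinical.index):
            raise DataValidationError(
                "clinical rows must match expression columns in the same order"
            )
        validate_clinical(self.clinical)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_values(self, gene: str) -> pd.Series:
        if gene not in self.values.index:
            raise KeyError(f"gene {gene!r} not present in cohort {self.cohort_id}")
        return self.values.loc[gene]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionDataset":
        """Return a new dataset restricted to ``samples`` (order preserved)."""
        samples = [s for s in self.samples if s in set(samples)]
        return ExpressionDataset(
            cohort_id=self.cohort_id,
            values=self.values.loc[:, samples],
            clinical=self.clinical.loc[samples],
            platform=self.platform,
            endpoint=self.endpoint,
            truth=self.truth,
        )

    def survival(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (times, events, sample mask) for samples with follow-up."""
        t = pd.to_numeric(self.clinical["time_months"], errors="coerce")
        e = pd.to_numeric(self.clinical["event"], errors="coerce")
        mask = t.notna().to_numpy() & e.notna().to_numpy()
        return t.to_numpy(dtype=float)[mask], e.to_numpy(dtype=float)[mask], mask


def validate_clinical(clinical: pd.DataFrame) -> None:
    missing = [c for c in ("time_months", "event") if c not in clinical.columns]
    if missing:
        raise DataValidationError(f"clinical table lacks columns {missing}")
    t = pd.to_numeric(clinical["time_months"], errors="coerce")
    e = pd.to_numeric(clinical["event"], errors="coerce")
    if (t.dropna() < 0).any():
        raise DataValidationError("time_months contains negative values")
    if (t.notna() & e.isna()).any():
        bad = clinical.index[t.notna() & e.isna()].tolist()
        raise DataValidationError(f"event missing where time_months present: {bad}")
    bad_events = e.dropna()[~e.dropna().isin([0, 1])]
    if len(bad_events):
        raise DataValidationError(
            f"event must be 0/1, got {sorted(bad_events.unique())}"
        )


@dataclass
class CohortCollection:
    """Ordered list of cohorts with shared gene-universe views."""

    cohorts: list[ExpressionDataset] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.cohort_id for c in self.cohorts]
        if len(set(ids)) != len(ids):
            raise DataValidationError(f"cohort ids are not unique: {ids}")

    def __iter__(self) -> Iterator[ExpressionDataset]:
        return iter(self.cohorts)

    def __len__(self) -> int:
        return len(self.cohorts)

    def __getitem__(self, key: int | str) -> ExpressionDataset:
        if isinstance(key, str):
            for c in self.cohorts:
                if c.cohort_id == key:
                    return c
            raise KeyError(key)
        return self.cohorts[key]

    @property
    def cohort_ids(self) -> list[str]:
        return [c.cohort_id for c in self.cohorts]

    def gene_intersection(self) -> pd.Index:
        if not self.cohorts:
            return pd.Index([])
        common = self.cohorts[0].genes
        for c in self.cohorts[1:]:
            common = common.intersection(c.genes)
        return common

    def gene_union(self) -> pd.Index:
        union = pd.Index([])
        for c in self.cohorts:
            union = union.union(c.genes)
        return union


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV into a float DataFrame.

    Duplicate gene labels and non-numeric cells are rejected with the
    offending gene / line number in the error message.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise DataValidationError(
            f"{path}: duplicate gene label(s): {sorted(set(dup))}"
        )
    try:
        mat = raw.astype(float)
    except ValueError:
        for i, (gene, row) in enumerate(raw.iterrows()):
            for col, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    # +2: one header line, 1-based numbering
                    raise DataValidationError(
                        f"{path}:line {i + 2}: non-numeric value {cell!r} "
                        f"for gene {gene!r}, sample {col!r}"
                    ) from None
        raise
    mat.index = mat.index.astype(str)
    mat.index.name = "gene"
    return mat


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV (``NA`` = missing) indexed by sample_id."""
    clin = pd.read_csv(
        path, sep="\t", index_col="sample_id", dtype=str,
        na_values=["NA"], keep_default_na=False,
    )
    missing = [c for c in CLINICAL_COLUMNS if c not in clin.columns]
    if missing:
        raise DataValidationError(f"{path}: clinical table lacks columns {missing}")
    clin.index = clin.index.astype(str)
    for col in ("time_months", "event"):
        clin[col] = pd.to_numeric(clin[col], errors="coerce")
    return clin


def log2_transform_if_needed(
    matrix: pd.DataFrame, threshold: float = LINEAR_SCALE_THRESHOLD
) -> tuple[pd.DataFrame, bool]:
    """Log2-transform a matrix that looks like linear-scale intensities.

    If the maximum value strictly exceeds ``threshold`` the matrix is assumed
    to be on a linear scale and ``log2(x + 1)`` is returned with flag True;
    otherwise the matrix is returned unchanged with flag False.  The +1 offset
    keeps zeros finite.  Idempotent: a transformed matrix never re-triggers.
    """
    mx = matrix.to_numpy(dtype=float).max(initial=-np.inf)
    if mx > threshold:
        if (matrix.to_numpy(dtype=float) < 0).any():
            raise DataValidationError(
                "matrix has negative values but a maximum above the linear-scale "
                "threshold; cannot be linear intensities"
            )
        return np.log2(matrix + 1.0), True
    return matrix, False


def assemble_dataset(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    cohort_id: str,
    platform: str = "unknown",
    endpoint: str = "RFS",
) -> ExpressionDataset:
    """Join a matrix and clinical table into a validated dataset.

    Sample label sets must be equal; clinical rows are reordered to the
    matrix column order.
    """
    mat_samples = set(matrix.columns)
    clin_samples = set(clinical.index)
    if mat_samples != clin_samples:
        only_mat = sorted(mat_samples - clin_samples)
        only_clin = sorted(clin_samples - mat_samples)
        raise DataValidationError(
            f"sample labels differ between expression and clinical tables; "
            f"expression-only: {only_mat}, clinical-only: {only_clin}"
        )
    clinical = clinical.loc[matrix.columns]
    return ExpressionDataset(
        cohort_id=cohort_id, values=matrix, clinical=clinical,
        platform=platform, endpoint=endpoint,
    )


def write_dataset(dataset: ExpressionDataset, directory: str | Path) -> dict[str, Path]:
    """Write one cohort as expression + clinical TSVs; return the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    expr_path = directory / f"{dataset.cohort_id}_expression.tsv"
    clin_path = directory / f"{dataset.cohort_id}_clinical.tsv"
    values = dataset.values.copy()
    values.index.name = "gene"
    # default float formatting is shortest-repr, so values round-trip exactly
    values.to_csv(expr_path, sep="\t")
    clin = dataset.clinical.copy()
    clin.index.name = "sample_id"
    clin.to_csv(clin_path, sep="\t", na_rep="NA")
    return {"expression": expr_path, "clinical": clin_path}


def read_collection(manifest_path: str | Path) -> CohortCollection:
    """Read a cohort collection from a plain-text key=value manifest."""
    manifest_path = Path(manifest_path)
    kv: dict[str, str] = {}
    for line in manifest_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    n = int(kv["n_cohorts"])
    base = manifest_path.parent
    cohorts = []
    for i in range(n):
        expr = read_expression_matrix(base / kv[f"cohort.{i}.expression"])
        clin = read_clinical_table(base / kv[f"cohort.{i}.clinical"])
        ds = assemble_dataset(
            expr, clin,
            cohort_id=kv[f"cohort.{i}.id"],
            platform=kv.get(f"cohort.{i}.platform", "unknown"),
            endpoint=kv.get(f"cohort.{i}.endpoint", "RFS"),
        )
        cohorts.append(ds)
    return CohortCollection(cohorts)
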