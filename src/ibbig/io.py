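"""Readers, writers and discretization of upstream GSA outputs.

The canonical on-disk format is labelled TSV (CSV accepted on read);
ground truth, configs and run summaries are JSON.  Orientation is fixed
as rows = gene sets, columns = phenotypes; a transpose option handles
the other dialect.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AssociationMatrix, GAParams
from .simulate import GroundTruth

__all__ = [
    "RunConfig",
    "read_binary_matrix",
    "write_matrix",
    "discretize_pvalue_matrix",
    "discretize_enrichment_matrix",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; serialized into its summary."""

    input_path: str | None = None
    output_dir: str = "."
    params: GAParams = field(default_factory=GAParams)
    threshold: float = 0.05
    fdr: bool = True
    transpose: bool = False
    log_level: str = "INFO"

    def to_jsonable(self) -> dict:
        d = asdict(self)
        return d


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_binary_matrix(
    path, delimiter: str | None = None, transpose: bool = False
) -> AssociationMatrix:
    """Read a labelled 0/1 table; anything non-binary is rejected.

    The error for a non-binary cell names its row and column so the
    offending value can be located in the source file.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_delimiter(path, delimiter), index_col=0)
    if transpose:
        df = df.T
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate row or column labels")
    values = df.to_numpy()
    numeric = pd.to_numeric(pd.Series(values.ravel()), errors="coerce").to_numpy()
    bad = ~np.isin(numeric, (0.0, 1.0)) | np.isnan(numeric)
    if bad.any():
        flat = int(np.flatnonzero(bad)[0])
        r, c = divmod(flat, df.shape[1])
        raise ValueError(
            f"{path}: non-binary value {values.ravel()[flat]!r} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return AssociationMatrix(
        values=numeric.reshape(df.shape).astype(np.int8),
        row_ids=[str(x) for x in df.index],
        col_ids=[str(x) for x in df.columns],
    )


def write_matrix(matrix: AssociationMatrix, path, delimiter: str = "\t") -> None:
    matrix.to_dataframe().to_csv(path, sep=delimiter)


def discretize_pvalue_matrix(
    pvals: pd.DataFrame, threshold: float = 0.05, fdr: bool = True
) -> AssociationMatrix:
    """Threshold a gene-set x phenotype P-value matrix into associations.

    With ``fdr`` the Benjamini-Hochberg adjustment is applied per column
    (each phenotype is one independent GSA test family) before comparing
    against ``threshold``; an entry becomes 1 iff the (adjusted) P-value
    is below it.
    """
    values = pvals.to_numpy(dtype=float)
    if np.any((values < 0) | (values > 1) | ~np.isfinite(values)):
        raise ValueError("P-values must lie in [0, 1]")
    if fdr:
        from statsmodels.stats.multitest import multipletests

        adjusted = np.empty_like(values)
        for j in range(values.shape[1]):
            adjusted[:, j] = multipletests(values[:, j], method="fdr_bh")[1]
        values = adjusted
    binary = (values < threshold).astype(np.int8)
    return AssociationMatrix(
        values=binary,
        row_ids=[str(x) for x in pvals.index],
        col_ids=[str(x) for x in pvals.columns],
    )


def discretize_enrichment_matrix(
    scores: pd.DataFrame, cutoff: float = 0.3
) -> AssociationMatrix:
    """Split signed enrichment scores into up/down association rows.

    Each input gene set becomes two rows: ``<id>_up`` flags scores at or
    above ``+cutoff`` and ``<id>_dn`` scores at or below ``-cutoff``, so
    up- and down-regulation are tracked as separate associations.
    """
    values = scores.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("enrichment scores must be finite")
    up = (values >= cutoff).astype(np.int8)
    dn = (values <= -cutoff).astype(np.int8)
    stacked = np.empty((2 * values.shape[0], values.shape[1]), dtype=np.int8)
    stacked[0::2] = up
    stacked[1::2] = dn
    row_ids = []
    for rid in scores.index:
        row_ids.extend([f"{rid}_up", f"{rid}_dn"])
    return AssociationMatrix(
        values=stacked, row_ids=row_ids, col_ids=[str(x) for x in scores.columns]
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_jsonable(), indent=1))


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_jsonable(json.loads(Path(path).read_text()))
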