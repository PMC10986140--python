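"""Additive log-ratio transformation and transformation-quality checks.

The ALR reference is chosen as the feature whose relative abundance has the
lowest coefficient of variation across samples; the quality of the resulting
(j - 1)-dimensional log-ratio representation is verified by Procrustes
comparison against the centered log-ratio (CLR) configuration of the same
table, which preserves the full log-ratio geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import CountTable, TableValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ALRMatrix:
    """Samples x (j - 1) log-ratio values plus the reference identity."""

    values: pd.DataFrame  # samples x variables, natural-log ratios
    ref_id: str

    def __post_init__(self) -> None:
        if self.ref_id in self.values.columns:
            raise TableValidationError("reference feature among ALR variables")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise TableValidationError("non-finite ALR entries")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variable_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def select_variables(self, variable_ids) -> "ALRMatrix":
        return ALRMatrix(self.values.loc[:, list(variable_ids)], self.ref_id)


@dataclass(frozen=True)
class ProcrustesResult:
    correlation: float
    m2: float


def select_alr_reference(table: CountTable, on_proportions: bool = True) -> str:
    """Feature with the lowest coefficient of variation (SD / mean).

    By default the CV is computed on per-sample relative abundances so that
    library-size variation does not drive the choice; set
    ``on_proportions=False`` to use raw counts.  Exact ties are broken by
    lexicographic feature-ID order (logged).
    """
    values = table.matrix
    if np.any(values <= 0):
        raise TableValidationError(
            "zero or negative cells; run add_pseudocount before ALR steps"
        )
    if on_proportions:
        values = values / values.sum(axis=1, keepdims=True)
    cv = values.std(axis=0, ddof=1) / values.mean(axis=0)
    best = cv.min()
    tied = [fid for fid, c in zip(table.feature_ids, cv) if c == best]
    if len(tied) > 1:
        logger.info("select_alr_reference: %d tied minima, taking %s",
                    len(tied), min(tied))
    return min(tied)


def alr_transform(table: CountTable, ref: str) -> ALRMatrix:
    """ALR(j | ref) = ln(x_j) - ln(x_ref) for every feature j != ref."""
    if ref not in table.feature_ids:
        raise TableValidationError(f"reference {ref!r} not in table")
    values = table.matrix
    if np.any(values <= 0):
        raise TableValidationError("nonpositive cells; add a pseudocount first")
    logx = np.log(table.counts.to_numpy(dtype=float))
    df = pd.DataFrame(logx, index=table.sample_ids, columns=table.feature_ids)
    out = df.drop(columns=[ref]).sub(df[ref], axis=0)
    return ALRMatrix(out, ref)


def clr_transform(table: CountTable) -> pd.DataFrame:
    """Centered log-ratio: ln(x) minus the per-sample mean of ln(x)."""
    values = table.matrix
    if np.any(values <= 0):
        raise TableValidationError("nonpositive cells; add a pseudocount first")
    logx = np.log(values)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.sample_ids, columns=table.feature_ids)


def _procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    """Orthogonal Procrustes disparity between two centered configurations.

    Both configurations are translated to the origin and scaled to unit
    Frobenius norm; the optimal rotation (reflections allowed) then gives
    m2 = 1 - (sum of singular values)^2.
    """
    if x.shape[1] < y.shape[1]:
        x = np.pad(x, ((0, 0), (0, y.shape[1] - x.shape[1])))
    elif y.shape[1] < x.shape[1]:
        y = np.pad(y, ((0, 0), (0, x.shape[1] - y.shape[1])))
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise TableValidationError("degenerate (zero-spread) configuration")
    xc, yc = xc / nx, yc / ny
    s = np.linalg.svd(yc.T @ xc, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def procrustes_correlation(alr: ALRMatrix, table: CountTable) -> ProcrustesResult:
    """Procrustes fit of the ALR sample configuration onto the CLR one.

    correlation = sqrt(1 - m2), where m2 is the minimized normalized residual
    sum of squares after translation, scaling, and rotation.
    """
    if alr.sample_ids != table.sample_ids:
        raise TableValidationError("ALR and table sample sets differ")
    if len(alr.sample_ids) < 3:
        raise TableValidationError("Procrustes needs >= 3 samples")
    clr = clr_transform(table).to_numpy()
    m2 = _procrustes_m2(alr.matrix, clr)
    return ProcrustesResult(correlation=float(np.sqrt(1.0 - m2)), m2=m2)


def write_alr(alr: ALRMatrix, path: str | Path) -> None:
    """ALR TSV with a header comment recording the reference feature."""
    with open(path, "w") as fh:
        fh.write(f"# alr_reference={alr.ref_id}\n")
        alr.values.to_csv(fh, sep="\t", index_label="sample_id")


def read_alr(path: str | Path) -> ALRMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# alr_reference="):
            raise TableValidationError("missing alr_reference header comment")
        ref = first.split("=", 1)[1]
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return ALRMatrix(df, ref)
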