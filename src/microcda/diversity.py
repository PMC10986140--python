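"""Alpha/beta diversity with nonparametric and permutation tests.

Alpha indices are observed richness, Shannon entropy (base-2 by default) and
Pielou evenness; between-group differences are tested with Kruskal-Wallis.
Beta diversity supports Bray-Curtis and (presence/absence) Jaccard distances
with PERMANOVA for location and PERMDISP for dispersion, both using the
(r + 1)/(n + 1) permutation p-value estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .tables import CountTable, SampleMetadata, TableValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    sample_ids: tuple[str, ...]
    values: np.ndarray  # square, symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        d = self.values
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise TableValidationError("distance matrix shape mismatch")
        if not np.allclose(d, d.T, atol=1e-12):
            raise TableValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise TableValidationError("distance matrix diagonal not zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise TableValidationError("distances outside [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        ids = list(self.sample_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)


@dataclass(frozen=True)
class PermTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    method: str = ""


def alpha_indices(table: CountTable, base: float = 2.0) -> pd.DataFrame:
    """Per-sample observed richness, Shannon entropy, and Pielou evenness.

    Shannon uses log base ``base`` (default 2, i.e. bits); Pielou is
    H / log_base(S) and is reported as NaN when S = 1.
    """
    counts = table.matrix
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        empty = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise TableValidationError(f"empty samples: {empty}")
    records = []
    for sid, row in zip(table.sample_ids, counts):
        nz = row[row > 0]
        s = int(len(nz))
        h = float(stats.entropy(nz, base=base))
        j = h / (np.log(s) / np.log(base)) if s > 1 else np.nan
        records.append({"sample_id": sid, "observed": s, "shannon": h, "pielou": j})
    return pd.DataFrame(records).set_index("sample_id")


def kruskal_wallis(values, groups) -> PermTestResult:
    """Kruskal-Wallis H (tie-corrected) with the chi-square p approximation."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = sorted(set(groups.tolist()))
    if len(uniq) < 2:
        raise TableValidationError("Kruskal-Wallis needs >= 2 groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise TableValidationError("empty group in Kruskal-Wallis")
    if min(len(s) for s in samples) < 2:
        logger.warning("kruskal_wallis: a group has < 2 observations (low power)")
    if np.all(values == values[0]):
        return PermTestResult(0.0, 1.0, 0, method="kruskal-wallis")
    h, p = stats.kruskal(*samples)
    return PermTestResult(float(h), float(p), 0, method="kruskal-wallis")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """d(u, v) = 1 - 2 sum(min(u_i, v_i)) / (sum u + sum v)."""
    counts = table.matrix
    if np.any(counts.sum(axis=1) <= 0):
        raise TableValidationError("samples with zero total")
    d = squareform(pdist(counts, metric="braycurtis"))
    return DistanceMatrix(tuple(table.sample_ids), d)


def jaccard(table: CountTable) -> DistanceMatrix:
    """Unweighted Jaccard on presence/absence: 1 - |A & B| / |A | B|."""
    counts = table.matrix
    if np.any(counts.sum(axis=1) <= 0):
        raise TableValidationError("samples with zero total")
    d = squareform(pdist(counts > 0, metric="jaccard"))
    return DistanceMatrix(tuple(table.sample_ids), d)


def _group_masks(
    dm: DistanceMatrix, meta: SampleMetadata
) -> tuple[np.ndarray, list[str]]:
    labels = meta.labels_for(list(dm.sample_ids))
    uniq = sorted(set(labels.tolist()))
    if len(uniq) < 2:
        raise TableValidationError("permutation tests need >= 2 groups")
    for g in uniq:
        if (labels == g).sum() < 2:
            raise TableValidationError(f"group {g!r} has < 2 samples")
    return labels, uniq


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """PERMANOVA pseudo-F from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b, df_w = n_groups - 1, n - n_groups
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def permanova(
    dm: DistanceMatrix,
    meta: SampleMetadata,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermTestResult:
    """Permutational MANOVA on a distance matrix (label permutation)."""
    labels, uniq = _group_masks(dm, meta)
    codes = np.array([uniq.index(l) for l in labels])
    d2 = dm.values**2
    obs = _pseudo_f(d2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(uniq)) >= obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermTestResult(float(obs), float(p), n_perm, seed, "permanova")


def _pcoa_coords(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding of a (possibly non-Euclidean) matrix.

    Returns (real, imaginary) coordinate blocks for the positive- and
    negative-eigenvalue axes.  Non-Euclidean distances (e.g. Bray-Curtis)
    produce negative eigenvalues whose axes carry imaginary variance;
    dispersion statistics must subtract it or they are biased.
    """
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    evals, evecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals).max(), 1e-300) * 1e-10
    pos = evals > tol
    neg = evals < -tol
    real = (evecs[:, pos] * np.sqrt(evals[pos])
            if pos.any() else np.zeros((n, 1)))
    imag = (evecs[:, neg] * np.sqrt(-evals[neg])
            if neg.any() else np.zeros((n, 0)))
    return real, imag


def _dispersion_f(z: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way ANOVA F on distances-to-centroid z."""
    n = len(z)
    grand = z.mean()
    ss_b = sum(
        (codes == g).sum() * (z[codes == g].mean() - grand) ** 2
        for g in range(n_groups)
    )
    ss_w = sum(((z[codes == g] - z[codes == g].mean()) ** 2).sum()
               for g in range(n_groups))
    df_b, df_w = n_groups - 1, n - n_groups
    if ss_w <= 1e-300:
        return 0.0 if ss_b <= 1e-300 else np.inf
    return (ss_b / df_b) / (ss_w / df_w)


def permdisp(
    dm: DistanceMatrix,
    meta: SampleMetadata,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermTestResult:
    """Permutation test for homogeneity of group dispersions.

    Samples are embedded by PCoA (positive-eigenvalue axes); each sample's
    Euclidean distance to its group spatial centroid is the dispersion score,
    compared across groups with an ANOVA F.  The null permutes group labels
    and recomputes centroids and scores for each relabeling.
    """
    labels, uniq = _group_masks(dm, meta)
    codes = np.array([uniq.index(l) for l in labels])
    real, _imag = _pcoa_coords(dm.values)
    n_groups = len(uniq)

    def dispersion_f(cds: np.ndarray) -> float:
        z = np.empty(len(cds))
        for g in range(n_groups):
            idx = cds == g
            centroid = real[idx].mean(axis=0)
            z[idx] = np.linalg.norm(real[idx] - centroid, axis=1)
        if np.allclose(z, z.mean()):
            return 0.0
        return _dispersion_f(z, cds, n_groups)

    obs = dispersion_f(codes)
    if obs == 0.0:
        return PermTestResult(0.0, 1.0, n_perm, seed, "permdisp")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if dispersion_f(rng.permutation(codes)) >= obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermTestResult(float(obs), float(p), n_perm, seed, "permdisp")
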