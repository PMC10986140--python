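"""Count-table containers, TSV I/O, and table preparation steps.

The central substrate is :class:`CountTable`, a samples x features matrix of
non-negative abundances with aligned, unique identifiers.  Preparation
operations (prevalence filtering, pseudocount, genus collapsing, rarefaction,
PCA outlier screening) all consume and return :class:`CountTable` so they can
be chained in any pipeline order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
UNASSIGNED = "unassigned"

#: rank prefixes of QIIME2-style lineage strings, e.g. "g__Bacteroides"
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__")


class TableValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


@dataclass(frozen=True)
class CountTable:
    """Samples x features abundance matrix.

    Parameters
    ----------
    counts
        DataFrame with sample IDs as the index and feature IDs as columns.
        Entries must be non-negative and numeric.  Integer counts are the
        normal case; fractional values are tolerated so that pseudocounted
        tables remain first-class citizens.
    level
        Feature level, ``"asv"`` or ``"genus"``.
    """

    counts: pd.DataFrame
    level: str = "asv"

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample IDs: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate feature IDs: {dups}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableValidationError("non-numeric entries in count table")
        if np.any(values < 0):
            bad = np.argwhere(values < 0)[0]
            raise TableValidationError(
                f"negative count at sample {df.index[bad[0]]!r}, "
                f"feature {df.columns[bad[1]]!r}"
            )
        if self.level not in ("asv", "genus"):
            raise TableValidationError(f"unknown level {self.level!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def totals(self) -> pd.Series:
        """Per-sample read totals."""
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[list(sample_ids)], level=self.level)

    def select_features(self, feature_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[:, list(feature_ids)], level=self.level)

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to one)."""
        tot = self.counts.sum(axis=1)
        if (tot == 0).any():
            empty = tot.index[tot == 0].tolist()
            raise TableValidationError(f"samples with zero total: {empty}")
        return self.counts.div(tot, axis=0)


@dataclass(frozen=True)
class TaxonomyMap:
    """feature_id -> lineage of six ranks; unassigned ranks form a suffix."""

    lineages: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for fid, lin in self.lineages.items():
            if len(lin) != len(RANKS):
                raise TableValidationError(
                    f"lineage of {fid!r} has {len(lin)} ranks, expected {len(RANKS)}"
                )
            seen_unassigned = False
            for token in lin:
                if token == UNASSIGNED:
                    seen_unassigned = True
                elif seen_unassigned:
                    raise TableValidationError(
                        f"lineage of {fid!r} has an assigned rank below an "
                        f"unassigned one: {lin}"
                    )

    def lineage(self, feature_id: str) -> tuple[str, ...]:
        return tuple(self.lineages[feature_id])

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.lineages

    def deepest_assigned(self, feature_id: str) -> tuple[str, str]:
        """Return (rank name, token) of the deepest assigned rank."""
        lin = self.lineages[feature_id]
        for rank, token in zip(reversed(RANKS), reversed(lin)):
            if token != UNASSIGNED:
                return rank, token
        return RANKS[0], UNASSIGNED


@dataclass(frozen=True)
class SampleMetadata:
    """sample_id -> group label mapping for a two-level comparison."""

    groups: pd.Series

    def __post_init__(self) -> None:
        if self.groups.index.has_duplicates:
            raise TableValidationError("duplicate sample IDs in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    def labels(self) -> list[str]:
        """Distinct group labels in sorted order."""
        return sorted(self.groups.unique())

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.groups.index]
        if missing:
            raise TableValidationError(f"samples missing from metadata: {missing}")
        return self.groups.loc[list(sample_ids)].to_numpy()

    def require_two_groups(self, sample_ids: Sequence[str]) -> tuple[str, str]:
        labels = self.labels_for(sample_ids)
        uniq = sorted(set(labels))
        if len(uniq) != 2:
            raise TableValidationError(
                f"expected exactly two group labels, found {uniq}"
            )
        for lab in uniq:
            if (labels == lab).sum() == 0:
                raise TableValidationError(f"group {lab!r} has no samples")
        return uniq[0], uniq[1]


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_count_table(
    path: str | Path,
    orientation: str = "samples-as-rows",
    level: str = "asv",
) -> CountTable:
    """Read a TSV count table.

    ``orientation="samples-as-rows"`` expects sample IDs in the first column
    and feature IDs in the header; ``"features-as-rows"`` reads the transposed
    dialect and transposes it back.
    """
    if orientation not in ("samples-as-rows", "features-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if orientation == "features-as-rows":
        df = df.T
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna()][0]
            raise TableValidationError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            )
        df[col] = coerced
    values = df.to_numpy()
    if np.any(values != np.floor(values)):
        bad = np.argwhere(values != np.floor(values))[0]
        raise TableValidationError(
            f"non-integer count at sample {df.index[bad[0]]!r}, "
            f"feature {df.columns[bad[1]]!r}"
        )
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    return CountTable(df, level=level)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.counts
    if np.allclose(df.to_numpy(), np.round(df.to_numpy())):
        df = df.round().astype(np.int64)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV of feature ID and semicolon lineage string."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise TableValidationError("taxonomy TSV needs feature ID + lineage columns")
    lineages: dict[str, tuple[str, ...]] = {}
    for fid, lineage_str in zip(df.iloc[:, 0], df.iloc[:, 1]):
        lineages[str(fid)] = parse_lineage(lineage_str)
    return TaxonomyMap(lineages)


def parse_lineage(lineage_str: str) -> tuple[str, ...]:
    """Normalize a 'd__X;p__Y;...' string to a 6-tuple, unassigned-padded."""
    tokens = [t.strip() for t in str(lineage_str).split(";")]
    out: list[str] = []
    for i in range(len(RANKS)):
        token = tokens[i] if i < len(tokens) else ""
        # a bare prefix like "g__" means unassigned at that rank
        bare = token[3:] if token[:3] in _RANK_PREFIXES else token
        out.append(token if bare not in ("", "nan", UNASSIGNED) else UNASSIGNED)
    # enforce unassigned-as-suffix: once a rank is missing, deeper ones are too
    for i in range(1, len(out)):
        if out[i - 1] == UNASSIGNED:
            out[i] = UNASSIGNED
    return tuple(out)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    rows = [
        {"feature_id": fid, "lineage": ";".join(lin)}
        for fid, lin in tax.lineages.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise TableValidationError("metadata TSV needs sample_id and group columns")
    ser = pd.Series(df["group"].values, index=df["sample_id"].values, name="group")
    return SampleMetadata(ser)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": meta.groups.index, "group": meta.groups.values}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Preparation operations
# ---------------------------------------------------------------------------


def prevalence_filter(
    table: CountTable, meta: SampleMetadata, min_prev: float = 0.5
) -> CountTable:
    """Keep features with nonzero counts in >= ``min_prev`` of EACH group.

    The threshold is inclusive and evaluated in exact rational arithmetic:
    a feature present in 1 of 2 samples per group passes ``min_prev=0.5``.
    """
    g1, g2 = meta.require_two_groups(table.sample_ids)
    labels = meta.labels_for(table.sample_ids)
    thr = Fraction(min_prev)
    keep: list[str] = []
    for fid in table.feature_ids:
        col = table.counts[fid].to_numpy()
        ok = True
        for lab in (g1, g2):
            mask = labels == lab
            n = int(mask.sum())
            present = int(np.count_nonzero(col[mask]))
            if Fraction(present, n) < thr:
                ok = False
                break
        if ok:
            keep.append(fid)
    logger.info(
        "prevalence_filter: kept %d/%d features at min_prev=%s",
        len(keep), len(table.feature_ids), min_prev,
    )
    return table.select_features(keep)


def add_pseudocount(table: CountTable, value: float = 1) -> CountTable:
    """Add ``value`` (> 0) to every cell so that log-ratios are defined."""
    if value <= 0:
        raise ValueError(f"pseudocount must be positive, got {value}")
    return CountTable(table.counts + value, level=table.level)


def genus_labels(
    feature_ids: Iterable[str], tax: TaxonomyMap
) -> dict[str, str]:
    """Map each feature to its collapsed genus-level label.

    Features sharing an identical (normalized) lineage down to genus map to
    the same label.  Features unassigned at genus are labeled by their
    deepest assigned rank; when that short label would collide across
    distinct lineages the full truncated lineage is used instead.
    """
    feature_ids = list(feature_ids)
    missing = [fid for fid in feature_ids if fid not in tax]
    if missing:
        raise TableValidationError(f"ASV missing from taxonomy: {missing}")
    keys = {fid: tax.lineage(fid) for fid in feature_ids}

    def short_label(lin: tuple[str, ...]) -> str:
        for token in reversed(lin):
            if token != UNASSIGNED:
                return token
        return UNASSIGNED

    def long_label(lin: tuple[str, ...]) -> str:
        assigned = [t for t in lin if t != UNASSIGNED]
        return ";".join(assigned) if assigned else UNASSIGNED

    uniq_keys = sorted(set(keys.values()), key=long_label)
    shorts = [short_label(k) for k in uniq_keys]
    label_of: dict[tuple[str, ...], str] = {}
    for key, short in zip(uniq_keys, shorts):
        label_of[key] = short if shorts.count(short) == 1 else long_label(key)
    return {fid: label_of[keys[fid]] for fid in feature_ids}


def collapse_to_genus(table: CountTable, tax: TaxonomyMap) -> CountTable:
    """Sum ASV features sharing an identical lineage down to genus.

    Labeling follows :func:`genus_labels`.  Per-sample totals are conserved
    exactly.
    """
    if table.level != "asv":
        raise TableValidationError("collapse_to_genus requires an ASV-level table")
    label_of = genus_labels(table.feature_ids, tax)
    grouped = table.counts.T.groupby(
        [label_of[fid] for fid in table.feature_ids]
    ).sum().T
    grouped = grouped.loc[:, sorted(grouped.columns)]
    return CountTable(grouped, level="genus")


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample WITHOUT replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped (logged).  Draws use a
    multivariate hypergeometric, so each rarefied cell never exceeds the
    original count and repeat calls with the same seed are bit-identical.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    totals = table.totals()
    kept = [s for s in table.sample_ids if totals[s] >= depth]
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    if not kept:
        raise TableValidationError(
            f"rarefaction depth {depth} exceeds every sample total "
            f"(max {int(totals.max())})"
        )
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s",
                    len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    counts = table.counts.loc[kept].to_numpy(dtype=np.int64)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    df = pd.DataFrame(out, index=kept, columns=table.feature_ids)
    return CountTable(df, level=table.level)


def pca_outlier_screen(
    table: CountTable, k_sd: float = 3.0
) -> tuple[CountTable, list[str]]:
    """Remove samples far from the centroid in the first two PC scores.

    Counts are converted to relative abundances and column-centered before
    the decomposition.  A sample is removed when its Euclidean distance from
    the score centroid exceeds ``k_sd`` standard deviations of those
    distances.  ``k_sd=inf`` is the identity.
    """
    if table.shape[0] < 3:
        raise TableValidationError("PCA outlier screen needs >= 3 samples")
    rel = table.relative().to_numpy()
    centered = rel - rel.mean(axis=0)
    # scores on the first two PCs via SVD of the centered matrix
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = min(2, len(s))
    scores = u[:, :k] * s[:k]
    dist = np.linalg.norm(scores - scores.mean(axis=0), axis=1)
    sd = dist.std(ddof=1)
    if not np.isfinite(k_sd) or sd == 0:
        removed_mask = np.zeros(len(dist), dtype=bool)
    else:
        removed_mask = dist > k_sd * sd
    removed = [s_ for s_, bad in zip(table.sample_ids, removed_mask) if bad]
    if removed:
        logger.info("pca_outlier_screen: removed %d samples at k_sd=%s: %s",
                    len(removed), k_sd, removed)
    kept = [s_ for s_ in table.sample_ids if s_ not in set(removed)]
    return table.select_samples(kept), removed
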