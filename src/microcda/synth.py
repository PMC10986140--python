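"""Synthetic microbiome datasets with known group effects.

Counts are generated from a logistic-normal / multinomial model: per-feature
log-abundances are a fixed baseline plus a group shift (for designated
differential features) plus per-sample Gaussian noise; the softmax of those
log-abundances parameterizes a multinomial draw at a randomized depth.
Because additive log-ratios of the latent composition equal differences of
the log-abundances, effect sizes can be injected directly in units of the
ALR standard deviation — the scale on which the downstream analysis works.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .tables import (
    CountTable,
    SampleMetadata,
    TaxonomyMap,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator.

    The defaults mirror a two-line rabbit 16S study layout: two groups of a
    few dozen samples, read depths between ~11k and ~62k averaging ~29.5k,
    and a dominant phylum holding ~87% of the community.
    """

    n_per_group: tuple[int, int] = (31, 40)
    n_features: int = 300
    n_genera: int = 30
    depth_range: tuple[int, int] = (10_863, 62_439)
    depth_mean: float = 29_490.0
    dominant_fraction: float = 0.87
    diff_features: tuple[int, ...] = ()
    delta_sd: float = 0.0
    zero_inflation: float = 0.3
    group_labels: tuple[str, str] = ("A", "LP")
    noise_sd_range: tuple[float, float] = (0.3, 0.8)
    base_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.delta_sd < 0:
            raise ValueError("delta_sd must be >= 0")
        if any(i < 0 or i >= self.n_features for i in self.diff_features):
            raise ValueError("diff_features indices out of range")
        lo, hi = self.depth_range
        if not (lo <= self.depth_mean <= hi):
            raise ValueError("depth_mean must lie within depth_range")
        if self.n_genera < 2 or self.n_genera > self.n_features:
            raise ValueError("need 2 <= n_genera <= n_features")


def default_diff_features(spec: SyntheticSpec, n_diff: int) -> tuple[int, ...]:
    """Pick ``n_diff`` reasonably abundant feature indices (never the reference).

    Deterministic given the spec seed; spread across the mid-to-high abundance
    range so that injected effects survive multinomial sampling noise.
    """
    rng = np.random.default_rng(spec.seed + 7)
    base = _base_log_abundance(spec, rng)[0]
    order = np.argsort(base)[::-1]
    # skip index 0 (the designed ALR reference) and the very top of the ranking
    candidates = [int(i) for i in order if i != 0][2 : 2 + max(3 * n_diff, n_diff)]
    chosen = rng.choice(len(candidates), size=n_diff, replace=False)
    return tuple(sorted(candidates[int(c)] for c in chosen))


def _base_log_abundance(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline log-abundances and genus assignment, dominance-rescaled."""
    F, G = spec.n_features, spec.n_genera
    genus = np.arange(F) % G
    base = rng.normal(0.0, spec.base_log_sd, size=F)
    # feature 0: stable, abundant ALR reference candidate
    base[0] = np.quantile(base, 0.95)
    # genera in the first ~60% belong to the dominant phylum; rescale its mass
    n_dom_genera = max(1, int(round(G * 0.6)))
    dom = genus < n_dom_genera
    mass = np.exp(base)
    target = spec.dominant_fraction
    scale = (target / (1 - target)) * mass[~dom].sum() / mass[dom].sum()
    base[dom] += np.log(scale)
    return base, genus


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[CountTable, TaxonomyMap, SampleMetadata, pd.DataFrame]:
    """Generate (counts, taxonomy, metadata, truth).

    ``truth`` is a DataFrame with one row per feature: ``feature_id`` and
    ``delta_sd``, the designed between-group ALR shift (group 1 minus group 2,
    sorted label order) in units of the latent ALR standard deviation.
    """
    rng = np.random.default_rng(spec.seed)
    F = spec.n_features
    n1, n2 = spec.n_per_group
    N = n1 + n2

    base, genus = _base_log_abundance(spec, rng)
    noise_sd = rng.uniform(*spec.noise_sd_range, size=F)
    noise_sd[0] = 0.05  # designed low-CV ALR reference; carries no group shift

    # effect per feature, in ALR-SD units relative to the reference feature
    delta = np.zeros(F)
    alr_sd = np.sqrt(noise_sd**2 + noise_sd[0] ** 2)
    for i in spec.diff_features:
        if i == 0:
            raise ValueError("feature 0 is the reference and cannot carry an effect")
        delta[i] = spec.delta_sd * alr_sd[i]

    labels = np.array([spec.group_labels[0]] * n1 + [spec.group_labels[1]] * n2)
    order = sorted(set(spec.group_labels))
    in_group1 = labels == order[0]

    # log-abundance per sample: base (bias-corrected) + shift + noise
    loc = base - noise_sd**2 / 2.0
    z = loc[None, :] + rng.normal(0.0, 1.0, size=(N, F)) * noise_sd[None, :]
    z[in_group1] += delta[None, :]

    depths = _draw_depths(spec, rng, N)

    # zero-inflation mask applied to the composition before the multinomial
    # draw, so per-sample totals stay exactly at the drawn depth; reference
    # and differential features are exempt to keep the design calibrated
    eligible = np.ones(F, dtype=bool)
    eligible[0] = False
    eligible[list(spec.diff_features)] = False
    counts = np.zeros((N, F), dtype=np.int64)
    for s in range(N):
        mask = np.ones(F, dtype=bool)
        if spec.zero_inflation > 0:
            drop = rng.random(F) < spec.zero_inflation
            mask[eligible & drop] = False
        p = np.exp(z[s] - z[s].max())
        p[~mask] = 0.0
        p /= p.sum()
        counts[s] = rng.multinomial(depths[s], p)

    width = len(str(F - 1))
    feature_ids = [f"ASV{i:0{width}d}" for i in range(F)]
    sample_ids = [f"S{j:03d}" for j in range(N)]
    table = CountTable(
        pd.DataFrame(counts, index=sample_ids, columns=feature_ids), level="asv"
    )
    meta = SampleMetadata(pd.Series(labels, index=sample_ids, name="group"))
    tax = _make_taxonomy(spec, feature_ids, genus)
    truth = pd.DataFrame(
        {"feature_id": feature_ids, "delta_sd": np.where(delta != 0, spec.delta_sd, 0.0)}
    )
    return table, tax, meta, truth


def _draw_depths(
    spec: SyntheticSpec, rng: np.random.Generator, n: int
) -> np.ndarray:
    lo, hi = spec.depth_range
    sd = (hi - lo) / 6.0
    a, b = (lo - spec.depth_mean) / sd, (hi - spec.depth_mean) / sd
    draws = stats.truncnorm.rvs(
        a, b, loc=spec.depth_mean, scale=sd, size=n, random_state=rng
    )
    return np.round(draws).astype(np.int64)


def _make_taxonomy(
    spec: SyntheticSpec, feature_ids: list[str], genus: np.ndarray
) -> TaxonomyMap:
    G = spec.n_genera
    n_dom_genera = max(1, int(round(G * 0.6)))
    lineages: dict[str, tuple[str, ...]] = {}
    for fid, g in zip(feature_ids, genus):
        phylum = "p__Bacillota" if g < n_dom_genera else "p__Bacteroidota"
        lineages[fid] = (
            "d__Bacteria",
            phylum,
            f"c__Class{g % 5}",
            f"o__Order{g % 11}",
            f"f__Family{g}",
            f"g__Genus{g:03d}",
        )
    return TaxonomyMap(lineages)


def realized_effect(
    table: CountTable,
    meta: SampleMetadata,
    ref: str,
    feature: str,
    pseudocount: float = 1.0,
) -> float:
    """Empirical between-group ALR effect of one feature, in pooled-SD units.

    Returns (mean ALR in group 1 - mean ALR in group 2) divided by the pooled
    within-group standard deviation, where group 1 is the first label in
    sorted order.  Zero counts are handled by ``pseudocount`` (set it to 0 to
    require a strictly positive table).
    """
    if feature == ref:
        raise ValueError("feature must differ from the ALR reference")
    g1, g2 = meta.require_two_groups(table.sample_ids)
    x = table.counts[feature].to_numpy(dtype=float) + pseudocount
    r = table.counts[ref].to_numpy(dtype=float) + pseudocount
    if np.any(x <= 0) or np.any(r <= 0):
        raise ValueError("nonpositive values; supply a pseudocount")
    alr = np.log(x) - np.log(r)
    labels = meta.labels_for(table.sample_ids)
    a, b = alr[labels == g1], alr[labels == g2]
    n1, n2 = len(a), len(b)
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled variance for this ALR variable")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
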