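"""Two-class PLS-DA with Mahalanobis-centroid prediction and VIP selection.

Components are extracted by NIPALS with X-deflation on auto-scaled
predictors and a centered class-indicator response.  Prediction projects new
samples into score space and assigns the class whose training centroid is
nearest under the Mahalanobis metric of the pooled within-class score
covariance.  Model quality is the balanced error rate (BER) estimated by
repeated stratified k-fold cross-validation; variables are selected
iteratively by VIP > 1 until performance stops improving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compositional import ALRMatrix

logger = logging.getLogger(__name__)

_NIPALS_TOL = 1e-8
_NIPALS_MAX_ITER = 200
_RIDGE = 1e-8


class PLSDAError(ValueError):
    pass


def _as_xy(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, ALRMatrix):
        return X.matrix, X.variable_ids
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{i}" for i in range(arr.shape[1])]


@dataclass
class PLSDAModel:
    """Fitted model: scaling, weights/loadings, scores and class geometry."""

    variable_ids: list[str]
    classes: tuple[str, str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    weights: np.ndarray       # p x A, columns unit norm
    x_loadings: np.ndarray    # p x A
    y_loadings: np.ndarray    # A x 2
    scores: np.ndarray        # n x A training scores
    y_train: np.ndarray       # n training labels
    ncomp: int

    def rotations(self, ncomp: int | None = None) -> np.ndarray:
        """W* = W (P'W)^-1 mapping scaled X directly to scores."""
        a = self.ncomp if ncomp is None else min(ncomp, self.ncomp)
        w, p = self.weights[:, :a], self.x_loadings[:, :a]
        return w @ np.linalg.inv(p.T @ w)

    def transform(self, Xnew, ncomp: int | None = None) -> np.ndarray:
        x, _ = _as_xy(Xnew)
        xs = (x - self.x_mean) / self.x_scale
        return xs @ self.rotations(ncomp)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts for a designated positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise PLSDAError("negative confusion counts")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn, self.positive_class,
        )

    @classmethod
    def from_labels(cls, y_true, y_pred, positive_class) -> "ConfusionCounts":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        pos_t, pos_p = yt == positive_class, yp == positive_class
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            positive_class=str(positive_class),
        )


@dataclass(frozen=True)
class CVReport:
    mean_ber: np.ndarray   # indexed by component count - 1
    sd_ber: np.ndarray
    chosen_ncomp: int
    folds: int
    repeats: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ncomp": np.arange(1, len(self.mean_ber) + 1),
            "mean_ber": self.mean_ber,
            "sd_ber": self.sd_ber,
        })


@dataclass(frozen=True)
class PermutationReport:
    observed_rates: dict[str, float]
    null_rates: np.ndarray   # n_perm x 2, columns in sorted class order
    p_value: float
    n_permutations: int
    seed: int | None


# ---------------------------------------------------------------------------
# Fitting and prediction
# ---------------------------------------------------------------------------


def fit_plsda(X, y, ncomp: int) -> PLSDAModel:
    """Fit a two-class PLS-DA model by NIPALS.

    X columns are auto-scaled (centered, unit variance); y is encoded as a
    centered two-column indicator matrix.  Components are extracted with
    X-deflation; requested ``ncomp`` is clamped to min(n - 1, p) and to the
    numerical rank actually reached.
    """
    x, var_ids = _as_xy(X)
    y = np.asarray(y).astype(str)
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise PLSDAError(f"need exactly 2 classes, got {classes}")
    for c in classes:
        if (y == c).sum() < 2:
            raise PLSDAError(f"class {c!r} has < 2 samples")
    n, p = x.shape
    x_mean = x.mean(axis=0)
    x_scale = x.std(axis=0, ddof=1)
    if np.any(x_scale == 0):
        bad = [var_ids[i] for i in np.flatnonzero(x_scale == 0)]
        raise PLSDAError(f"zero-variance columns: {bad}")
    xs = (x - x_mean) / x_scale

    ymat = np.column_stack([(y == c).astype(float) for c in classes])
    yc = ymat - ymat.mean(axis=0)

    a_max = min(ncomp, n - 1, p)
    if a_max < 1:
        raise PLSDAError("cannot extract any component")

    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    C = np.zeros((a_max, 2))
    T = np.zeros((n, a_max))
    xres = xs.copy()
    fitted = 0
    for a in range(a_max):
        u = yc[:, 0]
        w_prev = None
        for _ in range(_NIPALS_MAX_ITER):
            w = xres.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-14:
                break
            w = w / nw
            t = xres @ w
            tt = t @ t
            if tt < 1e-14:
                break
            c = yc.T @ t / tt
            u = yc @ c / (c @ c)
            # direction is what matters; t and c flip sign together with w
            if w_prev is not None and min(
                np.linalg.norm(w - w_prev), np.linalg.norm(w + w_prev)
            ) < _NIPALS_TOL:
                break
            w_prev = w
        else:  # pragma: no cover - convergence is immediate for binary y
            logger.warning("NIPALS did not converge for component %d", a + 1)
        nw = np.linalg.norm(xres.T @ u)
        if nw < 1e-14:
            break
        t = xres @ w
        tt = t @ t
        if tt < 1e-12:
            break
        pvec = xres.T @ t / tt
        W[:, a], P[:, a], C[a] = w, pvec, yc.T @ t / tt
        T[:, a] = t
        xres = xres - np.outer(t, pvec)
        fitted = a + 1

    if fitted == 0:
        raise PLSDAError("no component could be extracted (degenerate X)")
    if fitted < ncomp:
        logger.info("fit_plsda: extracted %d of %d requested components",
                    fitted, ncomp)
    return PLSDAModel(
        variable_ids=var_ids,
        classes=(classes[0], classes[1]),
        x_mean=x_mean,
        x_scale=x_scale,
        weights=W[:, :fitted],
        x_loadings=P[:, :fitted],
        y_loadings=C[:fitted],
        scores=T[:, :fitted],
        y_train=y,
        ncomp=fitted,
    )


def _score_geometry(
    model: PLSDAModel, a: int
) -> tuple[np.ndarray, np.ndarray]:
    """Class centroids and pooled within-class covariance of training scores."""
    t = model.scores[:, :a]
    centroids = np.vstack([
        t[model.y_train == c].mean(axis=0) for c in model.classes
    ])
    n = t.shape[0]
    pooled = np.zeros((a, a))
    for c, m in zip(model.classes, centroids):
        resid = t[model.y_train == c] - m
        pooled += resid.T @ resid
    pooled /= max(n - 2, 1)
    if np.linalg.cond(pooled) > 1e8:
        ridge = _RIDGE * np.trace(pooled)
        logger.info("predict: near-singular score covariance, adding ridge %.3g",
                    ridge)
        pooled = pooled + ridge * np.eye(a)
    return centroids, pooled


def predict(model: PLSDAModel, Xnew, ncomp: int | None = None) -> np.ndarray:
    """Nearest-centroid labels under the pooled-covariance Mahalanobis metric.

    Exact ties go to the alphabetically first class.
    """
    a = model.ncomp if ncomp is None else min(ncomp, model.ncomp)
    t = model.transform(Xnew, a)
    centroids, pooled = _score_geometry(model, a)
    inv = np.linalg.inv(pooled)
    d2 = np.empty((t.shape[0], 2))
    for k in range(2):
        diff = t - centroids[k]
        d2[:, k] = np.einsum("ij,jk,ik->i", diff, inv, diff)
    # d2[:,0] <= d2[:,1] -> first (alphabetically first) class wins ties
    return np.where(d2[:, 0] <= d2[:, 1], model.classes[0], model.classes[1])


def balanced_error_rate(c: ConfusionCounts) -> float:
    """BER = 0.5 * (FP / (TN + FP) + FN / (FN + TP))."""
    if c.tn + c.fp == 0 or c.fn + c.tp == 0:
        raise PLSDAError("empty class in confusion counts")
    return 0.5 * (c.fp / (c.tn + c.fp) + c.fn / (c.fn + c.tp))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _stratified_folds(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold assignment preserving class proportions; classes must be >= folds."""
    assign = np.empty(len(y), dtype=int)
    for c in sorted(set(y.tolist())):
        idx = np.flatnonzero(y == c)
        if len(idx) < folds:
            raise PLSDAError(f"class {c!r} smaller than fold count {folds}")
        idx = rng.permutation(idx)
        for f, chunk in enumerate(np.array_split(idx, folds)):
            assign[chunk] = f
    return assign


def _cv_ber_matrix(
    x: np.ndarray,
    y: np.ndarray,
    max_ncomp: int,
    folds: int,
    repeats: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """BER per (component count, fold x repeat); also used by the null test."""
    bers = np.empty((max_ncomp, folds * repeats))
    df = pd.DataFrame(x)
    col = 0
    for _ in range(repeats):
        assign = _stratified_folds(y, folds, rng)
        for f in range(folds):
            test = assign == f
            model = fit_plsda(df[~test], y[~test], max_ncomp)
            for a in range(1, max_ncomp + 1):
                pred = predict(model, df[test], ncomp=a)
                conf = ConfusionCounts.from_labels(
                    y[test], pred, positive_class=model.classes[0]
                )
                bers[a - 1, col] = balanced_error_rate(conf)
            col += 1
    return bers


def cross_validate(
    X,
    y,
    max_ncomp: int = 10,
    folds: int = 4,
    repeats: int = 100,
    seed: int | None = None,
) -> CVReport:
    """Repeated stratified k-fold BER per candidate component count.

    The chosen component count is the smallest whose mean BER lies within one
    standard deviation of the global minimum (parsimony-directed one-SD rule).
    """
    x, _ = _as_xy(X)
    y = np.asarray(y).astype(str)
    max_ncomp = min(max_ncomp, x.shape[1],
                    min(np.bincount(_class_codes(y))) * (folds - 1))
    max_ncomp = max(max_ncomp, 1)
    rng = np.random.default_rng(seed)
    bers = _cv_ber_matrix(x, y, max_ncomp, folds, repeats, rng)
    mean = bers.mean(axis=1)
    sd = bers.std(axis=1, ddof=1)
    a_min = int(np.argmin(mean))
    chosen = int(np.flatnonzero(mean <= mean[a_min] + sd[a_min])[0]) + 1
    return CVReport(mean, sd, chosen, folds, repeats, seed)


def _class_codes(y: np.ndarray) -> np.ndarray:
    classes = sorted(set(y.tolist()))
    return np.array([classes.index(v) for v in y])


# ---------------------------------------------------------------------------
# VIP and iterative selection
# ---------------------------------------------------------------------------


def vip(model: PLSDAModel) -> pd.Series:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ), with SS_a
    the response variance explained by component a.  mean(VIP^2) = 1 exactly.
    """
    w = model.weights
    t = model.scores
    c = model.y_loadings
    ss = np.einsum("ia,ia->a", t, t) * np.einsum("ak,ak->a", c, c)
    wn2 = (w / np.linalg.norm(w, axis=0)) ** 2
    p = w.shape[0]
    v = np.sqrt(p * (wn2 @ ss) / ss.sum())
    return pd.Series(v, index=model.variable_ids, name="vip")


def iterative_vip_selection(
    X,
    y,
    max_ncomp: int = 10,
    folds: int = 4,
    repeats: int = 100,
    seed: int | None = None,
    max_rounds: int = 20,
    ber_floor: float = 0.05,
    vip_floor: float = 0.65,
) -> tuple[PLSDAModel, CVReport, list[str]]:
    """Iteratively retain VIP > 1 variables while CV performance holds.

    Each round CV-selects the component count, fits, keeps VIP > 1 variables,
    and re-runs CV on the reduced set; the round is accepted when the new
    mean BER (at its chosen component count) does not exceed the previous one
    by more than one standard deviation (the larger of the two rounds' SDs).
    The loop stops on rejection, a fixed point, or an empty selection.

    It also stops once the model has demonstrably reached its highest
    classification performance: mean BER at or below ``ber_floor`` AND the
    10th-percentile VIP at or above ``vip_floor``.  The second condition
    recognizes the fixed point where every remaining variable contributes
    comparably (all VIP ~ 1, since mean VIP^2 = 1 by construction) — further
    VIP > 1 thresholding there would merely split sampling noise, because a
    BER already at its floor cannot register the loss.
    """
    x, var_ids = _as_xy(X)
    y = np.asarray(y).astype(str)
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(x, columns=var_ids)

    current = list(var_ids)
    report = cross_validate(df[current], y, max_ncomp, folds, repeats,
                            seed=int(rng.integers(2**31)))
    model = fit_plsda(df[current], y, report.chosen_ncomp)
    for _ in range(max_rounds):
        scores = vip(model)
        cur_mean = report.mean_ber[report.chosen_ncomp - 1]
        if cur_mean <= ber_floor and scores.quantile(0.1) >= vip_floor:
            logger.info("iterative_vip_selection: performance saturated with "
                        "%d comparably important variables; stopping",
                        len(current))
            break
        selected = [v for v in current if scores[v] > 1.0]
        if not selected:
            logger.warning("iterative_vip_selection: VIP>1 empties the set; "
                           "keeping previous model")
            break
        if selected == current:
            break
        cand_report = cross_validate(df[selected], y, max_ncomp, folds, repeats,
                                     seed=int(rng.integers(2**31)))
        prev_sd = report.sd_ber[report.chosen_ncomp - 1]
        cand_mean = cand_report.mean_ber[cand_report.chosen_ncomp - 1]
        cand_sd = cand_report.sd_ber[cand_report.chosen_ncomp - 1]
        if cand_mean > cur_mean + max(prev_sd, cand_sd):
            logger.info("iterative_vip_selection: round rejected "
                        "(BER %.3f > %.3f + %.3f)",
                        cand_mean, cur_mean, max(prev_sd, cand_sd))
            break
        current, report = selected, cand_report
        model = fit_plsda(df[current], y, report.chosen_ncomp)
    return model, report, current


# ---------------------------------------------------------------------------
# Final performance and permutation test
# ---------------------------------------------------------------------------


def _cv_round_rates(
    df: pd.DataFrame,
    y: np.ndarray,
    ncomp: int,
    folds: int,
    rng: np.random.Generator,
) -> tuple[ConfusionCounts, dict[str, float]]:
    """One round of stratified CV: aggregated confusion + per-class rates."""
    classes = sorted(set(y.tolist()))
    assign = _stratified_folds(y, folds, rng)
    agg = ConfusionCounts(0, 0, 0, 0, classes[0])
    for f in range(folds):
        test = assign == f
        model = fit_plsda(df[~test], y[~test], ncomp)
        pred = predict(model, df[test])
        agg = agg + ConfusionCounts.from_labels(y[test], pred, classes[0])
    rates = {
        classes[0]: agg.tp / (agg.tp + agg.fn),
        classes[1]: agg.tn / (agg.tn + agg.fp),
    }
    return agg, rates


def final_performance(
    X,
    y,
    model: PLSDAModel,
    folds: int = 4,
    repeats: int = 10_000,
    seed: int | None = None,
) -> tuple[ConfusionCounts, dict[str, float]]:
    """Aggregate confusion counts and per-class true-positive rates.

    Runs repeated stratified CV on the model's selected variables at its
    fitted component count; counts are summed over every fold and repeat.
    """
    x, var_ids = _as_xy(X)
    df = pd.DataFrame(x, columns=var_ids)[model.variable_ids]
    y = np.asarray(y).astype(str)
    rng = np.random.default_rng(seed)
    agg = ConfusionCounts(0, 0, 0, 0, model.classes[0])
    for _ in range(repeats):
        conf, _rates = _cv_round_rates(df, y, model.ncomp, folds, rng)
        agg = agg + conf
    rates = {
        model.classes[0]: agg.tp / (agg.tp + agg.fn),
        model.classes[1]: agg.tn / (agg.tn + agg.fp),
    }
    return agg, rates


def permutation_test(
    X,
    y,
    ncomp: int,
    n_perm: int = 10_000,
    folds: int = 4,
    seed: int | None = None,
    observed_repeats: int = 10,
) -> PermutationReport:
    """Compare observed CV classification against label-permuted nulls.

    Every permutation preserves class sizes; the p-value uses the add-one
    estimator on the mean per-class true-positive rate.
    """
    x, var_ids = _as_xy(X)
    df = pd.DataFrame(x, columns=var_ids)
    y = np.asarray(y).astype(str)
    classes = sorted(set(y.tolist()))
    rng = np.random.default_rng(seed)

    obs_conf = ConfusionCounts(0, 0, 0, 0, classes[0])
    for _ in range(observed_repeats):
        conf, _ = _cv_round_rates(df, y, ncomp, folds, rng)
        obs_conf = obs_conf + conf
    observed = {
        classes[0]: obs_conf.tp / (obs_conf.tp + obs_conf.fn),
        classes[1]: obs_conf.tn / (obs_conf.tn + obs_conf.fp),
    }
    obs_mean = float(np.mean(list(observed.values())))

    null = np.empty((n_perm, 2))
    hits = 0
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        _, rates = _cv_round_rates(df, y_perm, ncomp, folds, rng)
        null[i] = [rates[classes[0]], rates[classes[1]]]
        if null[i].mean() >= obs_mean:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return PermutationReport(observed, null, float(p), n_perm, seed)
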