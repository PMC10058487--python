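"""Repeated stratified k-fold cross-validation and component selection.

The number of PLS components is a bias/variance dial: too few underfit,
too many chase noise.  It is tuned here the standard way for this kind of
model: repeated stratified k-fold cross-validation produces, for every
candidate component count, a cross-validated residual sum of squares
(PRESS); the one-standard-error rule then picks the most parsimonious
count whose mean PRESS is within one standard deviation (across the CV
repetitions) of the minimum.

The same CV machinery yields the quantity the method reports: the mean and
SD, over repetitions, of the cross-validated percentage of explained
variance (a Q²-type statistic) at a fixed component count.

Defaults follow the study design: k = 10 folds, 50 repetitions, folds
stratified on the binary outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pls import fit_pls, predict_components

__all__ = [
    "CVConfig",
    "CVCurve",
    "make_stratified_folds",
    "cv_curve",
    "one_se_select",
    "one_se_rule",
    "cv_explained_variance",
]


@dataclass(frozen=True)
class CVConfig:
    """Resampling plan for repeated stratified k-fold CV.

    ``strata`` are per-sample labels (typically the binary outcome); every
    stratum must have at least ``k`` members.  ``max_components`` defaults
    to min(n - 1, p, 10) at fold-construction time when left as None.
    ``scale_in_fold`` re-scales predictor columns to unit variance inside
    each training fold (off by default: scaling is normally a one-off
    global preprocessing step).  ``tss_full_data`` uses full-data response
    means in the explained-variance denominator so percentages are
    comparable across repeats; switching it off uses per-repeat pooled
    out-of-fold means.
    """

    seed: int
    k: int = 10
    repeats: int = 50
    strata: tuple | None = None
    max_components: int | None = None
    scale_in_fold: bool = False
    tss_full_data: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.strata is not None:
            object.__setattr__(self, "strata", tuple(self.strata))

    def with_strata(self, strata) -> "CVConfig":
        return replace(self, strata=tuple(strata))

    def resolved_max_components(self, n: int, p: int) -> int:
        cap = min(n - 1, p, 10)
        if self.max_components is None:
            return cap
        return min(self.max_components, n - 1, p)


@dataclass(frozen=True)
class CVCurve:
    """Per-repeat CV curves: rows are repetitions, columns component counts."""

    rss: np.ndarray
    per_repeat_evar: np.ndarray

    def __post_init__(self) -> None:
        rss = np.atleast_2d(np.asarray(self.rss, dtype=float))
        evar = np.atleast_2d(np.asarray(self.per_repeat_evar, dtype=float))
        if rss.shape != evar.shape:
            raise ValueError("rss and per_repeat_evar shapes differ")
        if np.any(rss < 0):
            raise ValueError("negative RSS")
        object.__setattr__(self, "rss", rss)
        object.__setattr__(self, "per_repeat_evar", evar)

    @property
    def n_repeats(self) -> int:
        return self.rss.shape[0]

    @property
    def max_components(self) -> int:
        return self.rss.shape[1]


def _repeat_seed(master_seed: int, repeat: int) -> np.random.Generator:
    """One master seed spawns an independent, reproducible stream per repeat."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, repeat]))


def make_stratified_folds(strata, k: int, seed) -> list[np.ndarray]:
    """Partition sample indices into ``k`` folds preserving class balance.

    Within each stratum, indices are shuffled and dealt into ``k`` chunks
    whose sizes differ by at most one; the chunk-to-fold assignment is
    itself shuffled so no fold is systematically larger.  Deterministic for
    a fixed seed.
    """
    strata = np.asarray(strata)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for label in np.unique(strata):
        idx = np.flatnonzero(strata == label)
        if idx.size < k:
            raise ValueError(
                f"stratum {label!r} has {idx.size} members, fewer than k={k}"
            )
        perm = rng.permutation(idx)
        chunks = np.array_split(perm, k)
        order = rng.permutation(k)
        for fold_i, chunk in zip(order, chunks):
            folds[fold_i].extend(chunk.tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _as_2d(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def cv_curve(X, Y, cv: CVConfig) -> CVCurve:
    """Cross-validated RSS and explained-variance curves over component counts.

    For each repetition, PLS models with 1..max_components components are
    fitted on every training fold (one nested NIPALS fit per fold) and the
    held-out rows are predicted; out-of-fold predictions are pooled before
    computing RSS.  Deterministic given the config seed.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d(Y)
    n, p = X.shape
    a_max = cv.resolved_max_components(n, p)
    strata = np.asarray(cv.strata) if cv.strata is not None else np.zeros(n)
    if strata.shape[0] != n:
        raise ValueError("strata length does not match X rows")

    y_full_means = Y.mean(axis=0)
    tss_full = float(np.sum((Y - y_full_means) ** 2))
    rss = np.zeros((cv.repeats, a_max))
    evar = np.zeros((cv.repeats, a_max))

    for r in range(cv.repeats):
        rng = _repeat_seed(cv.seed, r)
        folds = make_stratified_folds(strata, cv.k, rng)
        yhat = np.zeros((a_max, n, Y.shape[1]))
        tss_fold = 0.0  # per-training-fold-mean alternative denominator
        for test_idx in folds:
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            X_tr, Y_tr, X_te = X[mask], Y[mask], X[test_idx]
            tss_fold += float(np.sum((Y[test_idx] - Y_tr.mean(axis=0)) ** 2))
            if cv.scale_in_fold:
                sd = X_tr.std(axis=0, ddof=1)
                sd[sd == 0] = 1.0
                X_tr, X_te = X_tr / sd, X_te / sd
            if np.all(X_tr.std(axis=0) == 0):
                raise ValueError("training fold has a constant predictor block")
            a_fold = min(a_max, X_tr.shape[0] - 1, p)
            model = fit_pls(X_tr, Y_tr, a_fold)
            preds = predict_components(model, X_te)  # (realized, n_te, q)
            realized = preds.shape[0]
            yhat[:realized, test_idx, :] = preds
            if realized < a_max:  # degenerate fit: larger models coincide
                yhat[realized:, test_idx, :] = preds[-1]
        resid = Y[None, :, :] - yhat
        rss[r] = np.sum(resid**2, axis=(1, 2))
        tss_r = tss_full if cv.tss_full_data else tss_fold
        evar[r] = 1.0 - rss[r] / tss_r
    return CVCurve(rss=rss, per_repeat_evar=evar)


def one_se_rule(mean_rss, sd_at_min: float) -> int:
    """Most parsimonious count whose mean RSS is within one SD of the minimum.

    ``mean_rss[a-1]`` is the mean CV RSS with ``a`` components; returns the
    1-based component count.
    """
    m = np.asarray(mean_rss, dtype=float)
    if m.size == 0:
        raise ValueError("empty RSS curve")
    a_star = int(np.argmin(m))  # first index on ties = most parsimonious
    threshold = m[a_star] + float(sd_at_min)
    return int(np.flatnonzero(m <= threshold)[0]) + 1


def one_se_select(curve: CVCurve) -> int:
    """Apply the one-standard-error rule to a repeated-CV curve.

    The standard deviation is taken across repetitions at the minimizing
    component count (the repetition is the unit of replication).
    """
    m = curve.rss.mean(axis=0)
    a_star = int(np.argmin(m))
    if curve.n_repeats > 1:
        s = float(curve.rss[:, a_star].std(ddof=1))
    else:
        s = 0.0
    return one_se_rule(m, s)


def cv_explained_variance(
    X, Y, n_components: int, cv: CVConfig
) -> tuple[float, float]:
    """Mean and SD (percent) over repetitions of CV explained variance at a
    fixed component count — the number reported as an effect."""
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    curve = cv_curve(X, Y, replace(cv, max_components=n_components))
    return curve_evar_stats(curve, n_components)


def curve_evar_stats(curve: CVCurve, n_components: int) -> tuple[float, float]:
    """Percent mean/SD of per-repeat explained variance at a component count
    already present in ``curve`` (avoids recomputing the CV)."""
    col = curve.per_repeat_evar[:, n_components - 1]
    sd = float(col.std(ddof=1)) if col.size > 1 else 0.0
    return float(col.mean()) * 100.0, sd * 100.0
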