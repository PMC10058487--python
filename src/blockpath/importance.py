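"""Variable-importance reporting: bootstrap VIP and log2 fold-changes.

A variable's VIP (variable importance in the projection) from the selected
PLS model says how much it contributes to the model's predictive
components.  Because VIP values on ~100 samples are noisy, they are
stabilized by bootstrapping: rows are resampled with replacement
(stratified on the outcome so neither class can vanish), the model is
refitted at the *fixed* selected component count, and the per-variable
bootstrap mean and SD are reported.  A variable counts as important when
its bootstrap mean VIP exceeds an analyst-chosen threshold (typically 1,
the value at which all squared VIPs would be equal).

Log2 fold-changes complement the importance ranking with effect direction
and magnitude; they are computed on data neither mean-centered nor scaled
(for metabolomics: the log-transformed, zero-replaced intensities), and
never on residual blocks, where group means have no interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pls import fit_pls, vip
from .preprocess import DataBlock, Outcome

__all__ = ["VIPResult", "bootstrap_vip", "select_important", "log2_fold_change"]

#: how often a degenerate bootstrap resample (constant response or no
#: fittable component) may be redrawn before giving up
MAX_RESAMPLE_RETRIES = 100


@dataclass(frozen=True)
class VIPResult:
    """Observed and bootstrap VIP statistics for one fitted model."""

    variable_ids: tuple[str, ...]
    observed_vip: np.ndarray
    boot_mean: np.ndarray
    boot_sd: np.ndarray
    n_boot: int
    threshold: float
    n_components: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "variable_ids", tuple(self.variable_ids))
        for name in ("observed_vip", "boot_mean", "boot_sd"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float).ravel()
            )
        p = len(self.variable_ids)
        if not (self.observed_vip.size == self.boot_mean.size == self.boot_sd.size == p):
            raise ValueError("VIP vectors and variable ids disagree in length")
        if np.any(self.observed_vip < 0):
            raise ValueError("VIP values are non-negative by definition")

    @property
    def important(self) -> np.ndarray:
        return self.boot_mean > self.threshold

    def to_dict(self) -> dict:
        return {
            "variable_ids": list(self.variable_ids),
            "observed_vip": self.observed_vip.tolist(),
            "boot_mean": self.boot_mean.tolist(),
            "boot_sd": self.boot_sd.tolist(),
            "n_boot": self.n_boot,
            "threshold": self.threshold,
            "n_components": self.n_components,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VIPResult":
        return cls(
            variable_ids=tuple(d["variable_ids"]),
            observed_vip=np.asarray(d["observed_vip"]),
            boot_mean=np.asarray(d["boot_mean"]),
            boot_sd=np.asarray(d["boot_sd"]),
            n_boot=d["n_boot"],
            threshold=d["threshold"],
            n_components=d["n_components"],
        )


def _stratified_resample(rng: np.random.Generator, strata: np.ndarray) -> np.ndarray:
    """Row indices drawn with replacement within each stratum, preserving
    the stratum sizes."""
    out = []
    for label in np.unique(strata):
        idx = np.flatnonzero(strata == label)
        out.append(rng.choice(idx, size=idx.size, replace=True))
    return np.concatenate(out)


def bootstrap_vip(
    X,
    Y,
    n_components: int,
    n_boot: int = 500,
    strata=None,
    seed: int = 0,
    threshold: float = 1.0,
    variable_ids=None,
    stratified: bool = True,
) -> VIPResult:
    """Bootstrap mean and SD of VIP at a fixed component count.

    The component count is the one selected on the full data and is not
    re-tuned per resample; rank-deficient resamples may realize fewer
    components (early stop), which is accepted.  Resamples with a constant
    response are redrawn (bounded retries).  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if variable_ids is None:
        variable_ids = tuple(f"x{j + 1}" for j in range(p))
    strata_arr = (
        np.asarray(strata) if (strata is not None and stratified) else np.zeros(n)
    )

    observed = vip(fit_pls(X, Y, n_components))
    boots = np.empty((n_boot, p))
    n_redrawn = 0
    for b in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
        for attempt in range(MAX_RESAMPLE_RETRIES):
            rows = _stratified_resample(rng, strata_arr)
            Yb = Y[rows]
            if np.all(Yb.std(axis=0) == 0):
                n_redrawn += 1
                continue
            a_b = min(n_components, rows.size - 1, p)
            model = fit_pls(X[rows], Yb, a_b)
            if model.n_components >= 1:
                boots[b] = vip(model)
                break
            n_redrawn += 1
        else:
            raise RuntimeError(
                f"bootstrap resample {b} degenerate after "
                f"{MAX_RESAMPLE_RETRIES} redraws"
            )
    if n_redrawn:
        warnings.warn(
            f"{n_redrawn} degenerate bootstrap resamples were redrawn",
            stacklevel=2,
        )
    return VIPResult(
        variable_ids=tuple(variable_ids),
        observed_vip=observed,
        boot_mean=boots.mean(axis=0),
        boot_sd=boots.std(axis=0, ddof=1),
        n_boot=n_boot,
        threshold=threshold,
        n_components=n_components,
    )


def select_important(result: VIPResult, threshold: float | None = None) -> list[str]:
    """Variables whose bootstrap mean VIP strictly exceeds the threshold,
    ordered by decreasing bootstrap mean."""
    thr = result.threshold if threshold is None else threshold
    if thr < 0:
        raise ValueError("threshold must be >= 0")
    hits = np.flatnonzero(result.boot_mean > thr)
    order = hits[np.argsort(-result.boot_mean[hits], kind="stable")]
    return [result.variable_ids[i] for i in order]


def log2_fold_change(block_unscaled: DataBlock, outcome: Outcome) -> np.ndarray:
    """log2(mean over cases / mean over controls) per variable.

    Expects transformed-but-unscaled data (post log transform for
    metabolomics intensities, raw for clinical variables).  Variables with
    a non-positive group mean get NaN rather than raising.
    """
    if block_unscaled.sample_ids != outcome.sample_ids:
        raise ValueError("block and outcome sample ids differ")
    cases = outcome.coded == 1
    controls = outcome.coded == 0
    if not cases.any() or not controls.any():
        raise ValueError("both outcome classes must be non-empty")
    mean_case = block_unscaled.values[cases].mean(axis=0)
    mean_ctrl = block_unscaled.values[controls].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(mean_case / mean_ctrl)
    fc[(mean_case <= 0) | (mean_ctrl <= 0)] = np.nan
    return fc
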