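"""Global and partial block effects on a three-vertex path diagram.

Given an input block A, a mediating block B and an output C (a block or a
single binary outcome), the two quantities of interest are

* the **global effect** of A on C — the cross-validated percentage of C's
  variance explained by a PLS regression of C on A; and
* the **partial effect** of A on C given B — first the linear dependence
  of both C and A on B is removed (PLS regressions of C on B and of A on
  B, keeping the residual blocks E_BC and E_BA), then the cross-validated
  percentage of E_BC's variance explained by a PLS regression of E_BC on
  E_BA.

In the unidimensional Gaussian case these reduce exactly to the squared
correlation r²_AC and the squared partial correlation r²_AC·B, which is
what makes the construction a multidimensional generalization of classical
(partial-)correlation mediation analysis.

Component counts of every PLS model involved are selected independently by
repeated stratified k-fold CV with the one-standard-error rule.
Residualization is fitted once on the full data by default; CV randomness
applies to the final residual-on-residual regression.  A fully nested
variant (residualize inside every training fold) is available via
``nested=True`` for leakage-averse analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model_selection import (
    CVConfig,
    cv_curve,
    curve_evar_stats,
    make_stratified_folds,
    one_se_select,
)
from .pls import (
    PLSModel,
    explained_variance_fraction,
    fit_pls,
    predict,
    predict_components,
)
from .preprocess import DataBlock, Outcome

__all__ = [
    "PathDiagram",
    "EffectEstimate",
    "Residuals",
    "PathReport",
    "global_effect",
    "residualize",
    "partial_effect",
    "run_path",
    "training_global_effect",
    "training_partial_effect",
]

#: relative residual norm below which mediation is considered degenerate
#: (B reproduces the target exactly)
DEGENERATE_RESIDUAL_EPS = 1e-10


@dataclass(frozen=True)
class PathDiagram:
    """Role assignment of named blocks: A (input) -> C (output), mediated by B."""

    input_block: str
    mediator_block: str
    output: str
    name: str = "path"

    def __post_init__(self) -> None:
        roles = {self.input_block, self.mediator_block, self.output}
        if len(roles) != 3:
            raise ValueError("input, mediator and output must be distinct")


@dataclass(frozen=True)
class EffectEstimate:
    """A CV-estimated effect: mean ± SD percent of explained variance.

    ``n_components_main`` is the component count of the effect's own PLS
    model; for partial effects, ``n_components_CB`` / ``n_components_AB``
    record the counts of the two residualization models.
    """

    kind: str  # "global" | "partial"
    mean_percent: float
    sd_percent: float
    n_components_main: int
    n_components_CB: int | None = None
    n_components_AB: int | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("global", "partial"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.mean_percent > 100.0 + 1e-9:
            raise ValueError("explained variance cannot exceed 100%")
        if self.sd_percent < 0:
            raise ValueError("negative SD")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "mean_percent": self.mean_percent,
            "sd_percent": self.sd_percent,
            "n_components_main": self.n_components_main,
            "n_components_CB": self.n_components_CB,
            "n_components_AB": self.n_components_AB,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class Residuals:
    """Training residuals of a PLS regression, with their source model."""

    values: np.ndarray
    source_model: PLSModel
    n_components: int


def _matrix(block) -> np.ndarray:
    if isinstance(block, DataBlock):
        return block.values
    X = np.asarray(block, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def global_effect(
    A, C, cv: CVConfig, n_components: int | None = None
) -> EffectEstimate:
    """CV explained variance of C by A, with one-SE component selection.

    ``n_components`` overrides the selection (used by oracle tests and for
    sensitivity analyses); the CV estimate itself is always computed.
    """
    X, Y = _matrix(A), _matrix(C)
    curve = cv_curve(X, Y, cv)
    a = one_se_select(curve) if n_components is None else n_components
    if a <= curve.max_components:
        mean, sd = curve_evar_stats(curve, a)
    else:
        from .model_selection import cv_explained_variance

        mean, sd = cv_explained_variance(X, Y, a, cv)
    return EffectEstimate(
        kind="global",
        mean_percent=min(mean, 100.0),
        sd_percent=sd,
        n_components_main=a,
    )


def residualize(
    target, B, cv: CVConfig, n_components: int | None = None
) -> Residuals:
    """Remove the part of ``target`` linearly explained by block B.

    The PLS model of target on B is tuned by CV + one-SE rule (unless
    ``n_components`` forces a count) and fitted on the full data; the
    returned training residuals are column-centered by construction.
    """
    Xb, Y = _matrix(B), _matrix(target)
    if n_components is None:
        n_components = one_se_select(cv_curve(Xb, Y, cv))
    model = fit_pls(Xb, Y, n_components)
    resid = Y - predict(model, Xb)
    return Residuals(values=resid, source_model=model, n_components=model.n_components)


def partial_effect(
    A,
    C,
    B,
    cv: CVConfig,
    n_components: int | None = None,
    n_components_CB: int | None = None,
    n_components_AB: int | None = None,
    nested: bool = False,
) -> EffectEstimate:
    """CV explained variance of C's residuals (given B) by A's residuals.

    Percentages are of the *residual* variance ‖E_BC‖², not of C's original
    variance.  When B reproduces A exactly the effect is the degenerate
    limit 0 and is returned as such with a warning rather than an error.
    """
    Xa, Y, Xb = _matrix(A), _matrix(C), _matrix(B)
    ebc = residualize(Y, Xb, cv, n_components_CB)
    eba = residualize(Xa, Xb, cv, n_components_AB)
    a_scale = float(np.linalg.norm(Xa - Xa.mean(axis=0)))
    if np.linalg.norm(eba.values) <= DEGENERATE_RESIDUAL_EPS * max(a_scale, 1.0):
        warnings.warn(
            "mediator block reproduces the input block exactly; "
            "partial effect is the degenerate limit 0",
            stacklevel=2,
        )
        return EffectEstimate(
            kind="partial",
            mean_percent=0.0,
            sd_percent=0.0,
            n_components_main=1,
            n_components_CB=ebc.n_components,
            n_components_AB=eba.n_components,
            degenerate=True,
        )
    if nested:
        return _nested_partial(
            Xa, Y, Xb, cv, ebc.n_components, eba.n_components, n_components
        )
    curve = cv_curve(eba.values, ebc.values, cv)
    a = one_se_select(curve) if n_components is None else n_components
    mean, sd = curve_evar_stats(curve, min(a, curve.max_components))
    return EffectEstimate(
        kind="partial",
        mean_percent=min(mean, 100.0),
        sd_percent=sd,
        n_components_main=a,
        n_components_CB=ebc.n_components,
        n_components_AB=eba.n_components,
    )


def _nested_partial(
    Xa, Y, Xb, cv: CVConfig, a_cb: int, a_ab: int, a_main: int | None
) -> EffectEstimate:
    """Leakage-free variant: residualization models are refit on every
    training fold (component counts kept from the full-data selection)."""
    n = Xa.shape[0]
    strata = np.asarray(cv.strata) if cv.strata is not None else np.zeros(n)
    a_max = (
        a_main
        if a_main is not None
        else cv.resolved_max_components(n, Xa.shape[1])
    )
    evar = np.zeros((cv.repeats, a_max))
    q = Y.shape[1] if Y.ndim == 2 else 1
    for r in range(cv.repeats):
        rng = np.random.default_rng(np.random.SeedSequence([cv.seed, r]))
        folds = make_stratified_folds(strata, cv.k, rng)
        yhat = np.zeros((a_max, n, q))
        ebc_all = np.zeros((n, q))
        for test_idx in folds:
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            m_cb = fit_pls(Xb[mask], Y[mask], a_cb)
            m_ab = fit_pls(Xb[mask], Xa[mask], a_ab)
            ebc_tr = Y[mask] - predict(m_cb, Xb[mask])
            eba_tr = Xa[mask] - predict(m_ab, Xb[mask])
            ebc_te = Y[test_idx] - predict(m_cb, Xb[test_idx])
            eba_te = Xa[test_idx] - predict(m_ab, Xb[test_idx])
            ebc_all[test_idx] = ebc_te
            a_fold = min(a_max, ebc_tr.shape[0] - 1, eba_tr.shape[1])
            model = fit_pls(eba_tr, ebc_tr, a_fold)
            preds = predict_components(model, eba_te)
            realized = preds.shape[0]
            yhat[:realized, test_idx, :] = preds
            if realized < a_max:
                yhat[realized:, test_idx, :] = preds[-1]
        tss = float(np.sum(ebc_all**2))
        rss = np.sum((ebc_all[None] - yhat) ** 2, axis=(1, 2))
        evar[r] = 1.0 - rss / tss
    mean_curve = evar.mean(axis=0)
    a = a_main if a_main is not None else int(np.argmax(mean_curve)) + 1
    col = evar[:, a - 1]
    sd = float(col.std(ddof=1)) if col.size > 1 else 0.0
    return EffectEstimate(
        kind="partial",
        mean_percent=min(float(col.mean()) * 100.0, 100.0),
        sd_percent=sd * 100.0,
        n_components_main=a,
        n_components_CB=a_cb,
        n_components_AB=a_ab,
    )


def training_global_effect(A, C, n_components: int = 1) -> float:
    """Full-data (training) explained-variance fraction of C by A.

    With single standardized variables and one component this equals the
    squared correlation r²_AC.
    """
    X, Y = _matrix(A), _matrix(C)
    model = fit_pls(X, Y, n_components)
    return explained_variance_fraction(Y, predict(model, X), Y.mean(axis=0))


def training_partial_effect(
    A, C, B, n_components: int = 1, n_components_resid: int = 1
) -> float:
    """Full-data (training) partial explained-variance fraction.

    With single standardized variables and one component everywhere this
    equals the squared partial correlation r²_AC·B.
    """
    Xa, Y, Xb = _matrix(A), _matrix(C), _matrix(B)
    ebc = Y - predict(fit_pls(Xb, Y, n_components_resid), Xb)
    eba = Xa - predict(fit_pls(Xb, Xa, n_components_resid), Xb)
    model = fit_pls(eba, ebc, n_components)
    return explained_variance_fraction(
        ebc, predict(model, eba), ebc.mean(axis=0)
    )


@dataclass(frozen=True)
class PathReport:
    """Full result set for one path diagram: both effects, variable
    importance for both models, and input-variable log2 fold-changes
    (global model only; fold changes on residuals are not meaningful)."""

    diagram: PathDiagram
    global_estimate: EffectEstimate
    partial_estimate: EffectEstimate
    vip_global: "VIPResult"
    vip_partial: "VIPResult"
    log2_fc: dict[str, float] | None
    seed: int

    def to_dict(self) -> dict:
        return {
            "diagram": {
                "name": self.diagram.name,
                "input_block": self.diagram.input_block,
                "mediator_block": self.diagram.mediator_block,
                "output": self.diagram.output,
            },
            "global": self.global_estimate.to_dict(),
            "partial": self.partial_estimate.to_dict(),
            "vip_global": self.vip_global.to_dict(),
            "vip_partial": self.vip_partial.to_dict(),
            "log2_fc": self.log2_fc,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathReport":
        from .importance import VIPResult

        return cls(
            diagram=PathDiagram(
                input_block=d["diagram"]["input_block"],
                mediator_block=d["diagram"]["mediator_block"],
                output=d["diagram"]["output"],
                name=d["diagram"]["name"],
            ),
            global_estimate=EffectEstimate(**d["global"]),
            partial_estimate=EffectEstimate(**d["partial"]),
            vip_global=VIPResult.from_dict(d["vip_global"]),
            vip_partial=VIPResult.from_dict(d["vip_partial"]),
            log2_fc=d["log2_fc"],
            seed=d["seed"],
        )


def run_path(
    diagram: PathDiagram,
    blocks: dict[str, DataBlock],
    outcome: Outcome,
    cv: CVConfig,
    n_boot: int = 500,
    vip_threshold_global: float = 1.0,
    vip_threshold_partial: float = 1.0,
    unscaled_blocks: dict[str, DataBlock] | None = None,
    nested: bool = False,
) -> PathReport:
    """Estimate both effects of a path diagram plus variable importance.

    ``blocks`` hold the preprocessed (scaled) data; ``unscaled_blocks``
    optionally provide the transformed-but-unscaled input block on which
    log2 fold-changes are computed.  The outcome supplies the CV strata.
    """
    from .importance import bootstrap_vip, log2_fold_change

    if diagram.input_block not in blocks:
        raise KeyError(f"input block {diagram.input_block!r} not provided")
    if diagram.mediator_block not in blocks:
        raise KeyError(f"mediator block {diagram.mediator_block!r} not provided")
    A = blocks[diagram.input_block]
    B = blocks[diagram.mediator_block]
    if diagram.output in blocks:
        C = blocks[diagram.output].values
    else:
        C = outcome.coded
    cv = cv.with_strata(outcome.labels)

    g = global_effect(A, C, cv)
    p = partial_effect(A, C, B, cv, nested=nested)

    vip_g = bootstrap_vip(
        A.values,
        _matrix(C),
        n_components=g.n_components_main,
        n_boot=n_boot,
        strata=outcome.labels,
        seed=cv.seed,
        threshold=vip_threshold_global,
        variable_ids=A.variable_ids,
    )
    ebc = residualize(_matrix(C), B.values, cv, p.n_components_CB)
    eba = residualize(A.values, B.values, cv, p.n_components_AB)
    vip_p = bootstrap_vip(
        eba.values,
        ebc.values,
        n_components=p.n_components_main,
        n_boot=n_boot,
        strata=outcome.labels,
        seed=cv.seed,
        threshold=vip_threshold_partial,
        variable_ids=tuple(f"{v} residual" for v in A.variable_ids),
    )
    fc = None
    if unscaled_blocks is not None and diagram.input_block in unscaled_blocks:
        fc_vec = log2_fold_change(unscaled_blocks[diagram.input_block], outcome)
        fc = {
            v: (None if np.isnan(x) else float(x))
            for v, x in zip(A.variable_ids, fc_vec)
        }
    return PathReport(
        diagram=diagram,
        global_estimate=g,
        partial_estimate=p,
        vip_global=vip_g,
        vip_partial=vip_p,
        log2_fc=fc,
        seed=cv.seed,
    )
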