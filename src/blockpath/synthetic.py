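"""Synthetic multiblock data with known latent structure.

The case study this package is built around pairs a small clinical block
(6 variables) with a collinear metabolomic block (102 variables) measured
on 99 men, with a binary case/control outcome.  The generator emulates
that statistical shape with a latent-factor model:

    F  ~  N(0, I)               (n x L independent standard normal factors)
    A  =  F Λ_Aᵀ + ε_A          (low-dimensional, clinical-like)
    B  =  F Λ_Bᵀ + ε_B          (high-dimensional, collinear, metabolomics-like)
    s  =  F w                   (continuous risk score)
    y  =  1{s > median(s)}      (balanced classes; logistic draw optional)

Three named mediation scenarios control which latents the blocks and the
outcome share, and hence what the population global and partial effects of
A on y look like:

* ``full_mediation`` — every outcome-relevant latent loads on both A and
  B; B carries everything A knows about y, so the population partial
  effect is 0.
* ``independent_inputs`` — A and B load on disjoint latents and y depends
  only on A's; conditioning on B changes nothing, so partial ≈ global.
* ``shared_plus_unique`` — y depends on latents shared with B and on
  latents unique to A; the partial effect is positive but strictly below
  the global one.

For the unidimensional Gaussian case the population effects are available
in closed form (squared correlation and squared partial correlation),
which is what the trivariate generator and oracle below provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import DataBlock, Outcome, encode_outcome

__all__ = [
    "SyntheticSpec",
    "generate_multiblock",
    "generate_trivariate",
    "population_effects_unidimensional",
]

SCENARIOS = ("full_mediation", "independent_inputs", "shared_plus_unique")
OUTCOME_MODELS = ("threshold", "logistic")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the latent-factor multiblock generator.

    Defaults emulate the case study's dimensions (n=99, 6 clinical-like
    and 102 metabolomics-like variables) with moderate noise.  Loadings
    are drawn once from the seed unless given explicitly.
    """

    seed: int
    n_samples: int = 99
    p_A: int = 6
    p_B: int = 102
    n_latents: int = 4
    mediation_scenario: str = "full_mediation"
    loadings_A: np.ndarray | None = None
    loadings_B: np.ndarray | None = None
    latent_to_outcome: np.ndarray | None = None
    noise_sd_A: float = 0.5
    noise_sd_B: float = 0.5
    outcome_model: str = "threshold"

    def __post_init__(self) -> None:
        if self.mediation_scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.mediation_scenario!r}; "
                f"choose from {SCENARIOS}"
            )
        if self.outcome_model not in OUTCOME_MODELS:
            raise ValueError(f"unknown outcome model {self.outcome_model!r}")
        if self.noise_sd_A < 0 or self.noise_sd_B < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_latents < 1 or self.n_samples < 4:
            raise ValueError("need n_latents >= 1 and n_samples >= 4")


def _scenario_structure(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Loadings and outcome weights realizing the named scenario."""
    L = spec.n_latents

    def loadings(p: int, support: np.ndarray) -> np.ndarray:
        lam = rng.normal(0.0, 1.0, size=(p, L))
        lam[:, ~support] = 0.0
        # keep per-latent signal comparable across blocks
        norms = np.linalg.norm(lam, axis=0)
        norms[norms == 0] = 1.0
        return lam / norms * np.sqrt(p)

    if spec.mediation_scenario == "full_mediation":
        support_A = np.ones(L, dtype=bool)
        support_B = np.ones(L, dtype=bool)
        w = np.ones(L)
    elif spec.mediation_scenario == "independent_inputs":
        if L < 2:
            raise ValueError("independent_inputs needs >= 2 latents")
        half = L // 2
        support_A = np.arange(L) < half
        support_B = ~support_A
        w = support_A.astype(float)  # outcome depends only on A's latents
    else:  # shared_plus_unique
        if L < 2:
            raise ValueError("shared_plus_unique needs >= 2 latents")
        half = L // 2
        shared = np.arange(L) < half
        support_A = np.ones(L, dtype=bool)
        support_B = shared  # B sees only the shared latents
        w = np.ones(L)
    lam_A = spec.loadings_A if spec.loadings_A is not None else loadings(spec.p_A, support_A)
    lam_B = spec.loadings_B if spec.loadings_B is not None else loadings(spec.p_B, support_B)
    w = spec.latent_to_outcome if spec.latent_to_outcome is not None else w
    return np.asarray(lam_A, float), np.asarray(lam_B, float), np.asarray(w, float)


def generate_multiblock(
    spec: SyntheticSpec,
) -> tuple[DataBlock, DataBlock, Outcome, dict]:
    """Draw one dataset from the latent-factor model.

    Returns the two blocks, the encoded binary outcome and a ``truth``
    record holding the factors, the continuous score and the generating
    parameters.  Deterministic for a fixed spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    lam_A, lam_B, w = _scenario_structure(spec, rng)
    n = spec.n_samples
    F = rng.normal(size=(n, spec.n_latents))
    A = F @ lam_A.T + rng.normal(0.0, spec.noise_sd_A, size=(n, spec.p_A))
    B = F @ lam_B.T + rng.normal(0.0, spec.noise_sd_B, size=(n, spec.p_B))
    s = F @ w
    if spec.outcome_model == "threshold":
        labels = np.where(s > np.median(s), "case", "control")
    else:
        prob = 1.0 / (1.0 + np.exp(-s))
        labels = np.where(rng.random(n) < prob, "case", "control")
        if len(set(labels)) < 2:  # pathological draw; flip one sample
            labels[int(np.argmax(prob))] = "case"
            labels[int(np.argmin(prob))] = "control"
    sample_ids = tuple(f"S{i + 1:03d}" for i in range(n))
    block_A = DataBlock(
        values=A,
        sample_ids=sample_ids,
        variable_ids=tuple(f"A{j + 1}" for j in range(spec.p_A)),
        provenance=("synthetic",),
    )
    block_B = DataBlock(
        values=B,
        sample_ids=sample_ids,
        variable_ids=tuple(f"B{j + 1}" for j in range(spec.p_B)),
        provenance=("synthetic",),
    )
    outcome = encode_outcome(sample_ids, labels.tolist(), case_label="case")
    truth = {
        "factors": F,
        "score": s,
        "loadings_A": lam_A,
        "loadings_B": lam_B,
        "latent_to_outcome": w,
        "scenario": spec.mediation_scenario,
    }
    return block_A, block_B, outcome, truth


def _check_psd(r_ab: float, r_ac: float, r_bc: float) -> np.ndarray:
    corr = np.array(
        [[1.0, r_ab, r_ac], [r_ab, 1.0, r_bc], [r_ac, r_bc, 1.0]]
    )
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ValueError(
            f"correlations (r_AB={r_ab}, r_AC={r_ac}, r_BC={r_bc}) do not "
            "form a positive semi-definite matrix"
        )
    return corr


def generate_trivariate(
    correlations: tuple[float, float, float], n: int, seed: int
) -> tuple[DataBlock, DataBlock, DataBlock]:
    """n draws of (x_A, x_B, x_C) from a standard trivariate normal with the
    given (r_AB, r_AC, r_BC); returned as three single-column blocks."""
    r_ab, r_ac, r_bc = correlations
    corr = _check_psd(r_ab, r_ac, r_bc)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(np.zeros(3), corr, size=n, method="eigh")
    ids = tuple(f"S{i + 1:04d}" for i in range(n))
    return tuple(
        DataBlock(
            values=draws[:, [j]],
            sample_ids=ids,
            variable_ids=(name,),
            provenance=("synthetic",),
        )
        for j, name in enumerate(("xA", "xB", "xC"))
    )


def population_effects_unidimensional(
    correlations: tuple[float, float, float],
) -> tuple[float, float]:
    """Closed-form population effects for single standardized variables.

    global = r²_AC;  partial = [(r_AC − r_AB·r_BC) / √((1−r²_AB)(1−r²_BC))]²
    (the squared partial correlation of A and C given B).
    """
    r_ab, r_ac, r_bc = correlations
    _check_psd(r_ab, r_ac, r_bc)
    if abs(r_ab) >= 1.0 or abs(r_bc) >= 1.0:
        raise ValueError("|r_AB| = 1 or |r_BC| = 1: conditioning is degenerate")
    partial_r = (r_ac - r_ab * r_bc) / np.sqrt((1 - r_ab**2) * (1 - r_bc**2))
    return float(r_ac**2), float(partial_r**2)
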