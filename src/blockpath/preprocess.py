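"""Data preparation for multiblock path modeling.

Metabolomic intensity tables typically contain zeros (below-detection
signals) and right-skewed intensities.  The preparation pipeline used here
is the standard one for such data: replace zeros by a fraction of the
variable's smallest positive intensity, log-transform, and scale every
variable to unit variance.  Clinical variables are only scaled.  Samples
with any missing value in any block are dropped from every block
consistently (complete-case analysis).

Scaling is applied once, globally, before modeling; mean-centering is the
model's responsibility (each PLS fit centers with its own training means).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "DataBlock",
    "Outcome",
    "replace_zeros",
    "log_transform",
    "scale_unit_variance",
    "encode_outcome",
    "complete_cases",
]


@dataclass(frozen=True)
class DataBlock:
    """A samples x variables matrix with identifiers and provenance.

    ``provenance`` records the transformations applied so far, in order
    (e.g. ``["zeros_replaced", "log", "uv_scaled"]``).
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    variable_ids: tuple[str, ...]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("DataBlock values must be a 2-D matrix")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "variable_ids", tuple(str(v) for v in self.variable_ids))
        object.__setattr__(self, "provenance", tuple(self.provenance))
        n, p = values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.variable_ids) != p:
            raise ValueError(
                f"{len(self.variable_ids)} variable ids for {p} columns"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.variable_ids)) != p:
            raise ValueError("duplicate variable ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, tag: str) -> "DataBlock":
        """Return a copy with new values and ``tag`` appended to provenance."""
        return replace(self, values=values, provenance=self.provenance + (tag,))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.variable_ids)
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, provenance: tuple[str, ...] = ()
    ) -> "DataBlock":
        return cls(
            values=frame.to_numpy(dtype=float),
            sample_ids=tuple(str(i) for i in frame.index),
            variable_ids=tuple(str(c) for c in frame.columns),
            provenance=provenance,
        )


@dataclass(frozen=True)
class Outcome:
    """A binary per-sample outcome with its 0/1 coding.

    ``labels`` keeps the original category names; ``coded`` is the numeric
    vector entering the models (case -> 1, control -> 0).  Explained-variance
    results are invariant to swapping the coding.
    """

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    coded: np.ndarray
    case_label: str
    control_label: str

    def __post_init__(self) -> None:
        coded = np.asarray(self.coded, dtype=float).ravel()
        object.__setattr__(self, "coded", coded)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "labels", tuple(str(s) for s in self.labels))
        if not (len(self.sample_ids) == len(self.labels) == coded.size):
            raise ValueError("sample_ids, labels and coded must have equal length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in outcome")
        if np.unique(coded).size != 2:
            raise ValueError("coded outcome must take exactly two distinct values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def class_counts(self) -> dict[str, int]:
        return {
            self.case_label: int(np.sum(self.coded == 1)),
            self.control_label: int(np.sum(self.coded == 0)),
        }


def replace_zeros(block: DataBlock, fraction: float = 0.8) -> DataBlock:
    """Replace zero intensities by ``fraction`` of the variable's minimum
    positive intensity.

    Standard below-detection imputation for metabolomic intensity tables;
    the minimum is taken over the strictly positive entries of the variable
    (the zeros being replaced carry no intensity information).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    X = block.values
    if np.any(X < 0):
        raise ValueError("replace_zeros requires non-negative intensities")
    out = X.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        zeros = col == 0
        if not zeros.any():
            continue
        positive = col[col > 0]
        if positive.size == 0:
            raise ValueError(
                f"all-zero variable {block.variable_ids[j]!r}: "
                "no positive minimum exists"
            )
        out[zeros, j] = fraction * positive.min()
    return block.with_values(out, "zeros_replaced")


def log_transform(block: DataBlock, base: float = np.e) -> DataBlock:
    """Elementwise logarithm in ``base`` (> 1); requires positive entries."""
    if base <= 1:
        raise ValueError(f"log base must be > 1, got {base}")
    X = block.values
    bad = np.argwhere(X <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive entry at sample {block.sample_ids[i]!r}, "
            f"variable {block.variable_ids[j]!r}; run replace_zeros first"
        )
    out = np.log(X) / np.log(base)
    return block.with_values(out, "log")


def scale_unit_variance(block: DataBlock) -> DataBlock:
    """Divide each column by its sample standard deviation (n-1 denominator).

    Columns are *not* mean-centered here: centering is done per training set
    inside each model fit, so that cross-validation stays honest.
    Idempotent up to floating-point error.
    """
    X = block.values
    if X.shape[0] < 2:
        raise ValueError("unit-variance scaling needs at least 2 samples")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance variable {block.variable_ids[zero[0]]!r} "
            "cannot be scaled"
        )
    return block.with_values(X / sd, "uv_scaled")


def encode_outcome(
    sample_ids,
    labels,
    case_label: str | None = None,
) -> Outcome:
    """Code a two-class label vector as 0/1 with the case class mapped to 1.

    If ``case_label`` is not given, the lexicographically larger label is
    treated as the case so the coding is deterministic.  All downstream
    explained-variance results are invariant to swapping the coding.
    """
    labels = [str(s) for s in labels]
    distinct = sorted(set(labels))
    if len(distinct) != 2:
        raise ValueError(
            f"outcome must have exactly two distinct labels, got {distinct}"
        )
    if case_label is None:
        case_label = distinct[1]
    elif case_label not in distinct:
        raise ValueError(f"case label {case_label!r} not among {distinct}")
    control_label = next(d for d in distinct if d != case_label)
    coded = np.array([1.0 if s == case_label else 0.0 for s in labels])
    return Outcome(
        sample_ids=tuple(sample_ids),
        labels=tuple(labels),
        coded=coded,
        case_label=case_label,
        control_label=control_label,
    )


def complete_cases(
    blocks: list[DataBlock],
    outcome: Outcome,
    min_per_class: int = 1,
) -> tuple[list[DataBlock], Outcome, dict[str, int]]:
    """Drop samples with any missing value in any block, consistently.

    All blocks and the outcome must share the same sample ids in the same
    order.  Returns the filtered blocks, outcome and the per-class counts of
    the retained samples.  ``min_per_class`` guards downstream resampling:
    fewer retained samples than that in either class is an error.
    """
    ids = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ids:
            raise ValueError("blocks do not share sample ids (order included)")
    if outcome.sample_ids != ids:
        raise ValueError("outcome sample ids do not match the blocks")
    keep = np.ones(len(ids), dtype=bool)
    for b in blocks:
        keep &= np.isfinite(b.values).all(axis=1)
    keep &= np.isfinite(outcome.coded)
    if not keep.any():
        raise ValueError("no complete cases remain")
    idx = np.flatnonzero(keep)
    new_blocks = [
        replace(
            b,
            values=b.values[idx],
            sample_ids=tuple(b.sample_ids[i] for i in idx),
        )
        for b in blocks
    ]
    new_outcome = Outcome(
        sample_ids=tuple(ids[i] for i in idx),
        labels=tuple(outcome.labels[i] for i in idx),
        coded=outcome.coded[idx],
        case_label=outcome.case_label,
        control_label=outcome.control_label,
    )
    counts = new_outcome.class_counts()
    short = [lab for lab, c in counts.items() if c < min_per_class]
    if short:
        raise ValueError(
            f"class {short[0]!r} has fewer than {min_per_class} complete samples"
        )
    return new_blocks, new_outcome, counts
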