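"""Combining several markers into one analysis variable.

Four modes mirror common practice in expression studies: run each marker
separately (batch), a weighted signature mean with optional per-member
inversion, the ratio of two markers (e.g. normalization against a
housekeeping gene), and median stratification by one marker before
analysing another in the high or low arm only.  Each mode produces an
ordinary derived column that flows through cutoff selection and survival
analysis exactly like a raw marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sstats

from .exceptions import (
    CohortTooSmallError,
    ConstantVariableError,
    InvalidWeightsError,
    ZeroDenominatorError,
)
from .io import SurvivalDataset

MIN_ARM_SIZE = 4


@dataclass
class CombinationSpec:
    """Declarative description of a marker combination.

    mode is one of ``each_separately``, ``signature_mean``, ``ratio`` or
    ``stratified``.
    """

    mode: str
    members: list[str] = field(default_factory=list)
    weights: list[float] | None = None
    inverted: list[bool] | None = None
    numerator: str | None = None
    denominator: str | None = None
    stratifier: str | None = None
    arm: str | None = None            # "high" or "low"

    def __post_init__(self):
        if self.mode not in {"each_separately", "signature_mean", "ratio",
                             "stratified"}:
            raise ValueError(f"unknown combination mode {self.mode!r}")
        if self.mode == "ratio":
            if not self.numerator or not self.denominator or \
                    self.numerator == self.denominator:
                raise ValueError("ratio needs two distinct member markers")
        if self.mode == "stratified":
            if self.arm not in {"high", "low"}:
                raise ValueError("stratified arm must be 'high' or 'low'")
            if not self.stratifier:
                raise ValueError("stratified mode needs a stratifier marker")
        if self.mode == "signature_mean":
            k = len(self.members)
            if self.weights is not None and len(self.weights) != k:
                raise ValueError("weights length must match members")
            if self.inverted is not None and len(self.inverted) != k:
                raise ValueError("inverted length must match members")


def signature_mean(ds: SurvivalDataset, members: list[str],
                   weights=None, inverted=None,
                   zscore: bool = False) -> np.ndarray:
    """Weighted mean of a marker panel, with optional sign inversion.

    ``value_j = sum_i w_i * s_i * x_ij / sum_i w_i`` with ``s_i = -1`` for
    inverted members.  Weights must be positive (use the invert flags for
    sign changes); with ``zscore=True`` members are standardized before
    averaging, for panels on incompatible scales.
    """
    if len(members) < 1:
        raise ValueError("signature needs at least one member")
    k = len(members)
    w = np.ones(k) if weights is None else np.asarray(weights, dtype=float)
    s = np.ones(k) if inverted is None else \
        np.where(np.asarray(inverted, dtype=bool), -1.0, 1.0)
    if np.any(w < 0):
        raise InvalidWeightsError("weights must be nonnegative; use the "
                                  "invert flag to flip a member's sign")
    if w.sum() == 0:
        raise InvalidWeightsError("weights sum to zero")
    cols = np.column_stack([ds.marker(m) for m in members])
    if zscore:
        sd = cols.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ConstantVariableError("cannot z-score a constant member")
        cols = (cols - cols.mean(axis=0)) / sd
    return cols @ (w * s) / w.sum()


def gene_ratio(ds: SurvivalDataset, numerator: str,
               denominator: str) -> np.ndarray:
    """Per-sample ratio numerator/denominator of two markers."""
    num = ds.marker(numerator)
    den = ds.marker(denominator)
    zero = den == 0
    if zero.any():
        raise ZeroDenominatorError(
            f"denominator {denominator!r} is zero for "
            f"{int(zero.sum())} sample(s)",
            samples=list(np.asarray(ds.sample_ids)[zero]))
    return num / den


def stratified_subset(ds: SurvivalDataset, stratifier: str,
                      arm: str) -> SurvivalDataset:
    """Median-split the cohort on one marker and return the requested arm.

    Values <= median go to the low arm (the same boundary convention as
    dichotomization); the returned dataset is then analysed with another
    marker downstream.
    """
    vals = ds.marker(stratifier)
    if vals.min() == vals.max():
        raise ConstantVariableError(f"stratifier {stratifier!r} is constant")
    med = float(np.quantile(vals, 0.5))
    mask = vals <= med if arm == "low" else vals > med
    if arm not in {"low", "high"}:
        raise ValueError("arm must be 'low' or 'high'")
    if mask.sum() < MIN_ARM_SIZE:
        raise CohortTooSmallError(
            f"{arm} arm of {stratifier!r} has only {int(mask.sum())} samples "
            f"(minimum {MIN_ARM_SIZE})")
    return ds.subset(mask)


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("correlation needs at least 3 paired finite values")
    if x.std() == 0 or y.std() == 0:
        raise ConstantVariableError("correlation undefined for constant input")
    if method == "pearson":
        r = _sstats.pearsonr(x, y)
    elif method == "spearman":
        r = _sstats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r.statistic), float(r.pvalue)


def derive_column(ds: SurvivalDataset, spec: CombinationSpec):
    """Materialize a CombinationSpec into ``(dataset, derived marker name)``.

    ``each_separately`` and ``stratified`` do not create a column here:
    batch mode is orchestrated by the model layer, and stratification
    subsets the cohort instead.
    """
    if spec.mode == "signature_mean":
        name = "signature(" + " ".join(spec.members) + ")"
        vals = signature_mean(ds, spec.members, spec.weights, spec.inverted)
        return ds.with_marker(name, vals), name
    if spec.mode == "ratio":
        name = f"ratio({spec.numerator}/{spec.denominator})"
        vals = gene_ratio(ds, spec.numerator, spec.denominator)
        return ds.with_marker(name, vals), name
    raise ValueError(f"mode {spec.mode!r} does not derive a column")
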