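"""Multivariate Cox models mixing markers and clinical variables.

Markers enter continuously by default (dichotomization at a chosen
cutoff strategy is opt-in and computed on the complete-case cohort);
categorical clinical variables are dummy-coded against a reference
level.  Only samples with every selected variable observed are used
(complete-case analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cutoffs import best_cutoff_scan, dichotomize, quantile_cutoff
from .exceptions import (
    CollinearityError,
    ConfigError,
    InsufficientEventsError,
)
from .io import SurvivalDataset
from .survival import CoxResult, cox_fit, ph_assumption_test

VALID_TREATMENTS = {"continuous", "dichotomized", "categorical"}


@dataclass
class Variable:
    """One model term: a marker or clinical column plus how to encode it.

    treatment: ``continuous`` (raw numeric), ``dichotomized`` (split at a
    cutoff strategy: median, lower-quartile, upper-quartile, best, or a
    number), or ``categorical`` (dummy-coded, <= 10 levels).
    """

    name: str
    treatment: str = "continuous"
    cutoff: str | float = "median"
    reference: str | None = None   # categorical reference level

    def __post_init__(self):
        if self.treatment not in VALID_TREATMENTS:
            raise ConfigError(f"unknown treatment {self.treatment!r} for "
                              f"variable {self.name!r}")


@dataclass
class MultivariateSpec:
    variables: list[Variable] = field(default_factory=list)

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(self.variables) < 1:
            raise ConfigError("multivariate spec needs at least one variable")
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise CollinearityError(
                f"variable(s) entered more than once: {dup}", aliased=dup)

    @classmethod
    def parse(cls, text: str) -> "MultivariateSpec":
        """Parse ``"Gene_1:continuous,Filter_A:categorical"`` style strings."""
        variables = []
        for chunk in text.split(","):
            parts = chunk.strip().split(":")
            name = parts[0].strip()
            treatment = parts[1].strip() if len(parts) > 1 else "continuous"
            cutoff: str | float = "median"
            if len(parts) > 2:
                try:
                    cutoff = float(parts[2])
                except ValueError:
                    cutoff = parts[2].strip()
            variables.append(Variable(name, treatment, cutoff))
        return cls(variables)


def _column(ds: SurvivalDataset, name: str):
    """Fetch a raw column (marker first, then filter), as stored."""
    if name in ds.markers:
        return ds.markers[name], "marker"
    if name in ds.filters:
        return ds.filters[name], "filter"
    if name in ds.unusable_markers:
        raise ConfigError(f"variable {name!r} has missing cells and is not "
                          "usable as a model variable")
    raise KeyError(f"unknown variable {name!r}")


def complete_cases(ds: SurvivalDataset,
                   variables: list[str]) -> SurvivalDataset:
    """Rows where time, event and every listed variable are observed."""
    mask = np.isfinite(ds.time)
    for name in variables:
        col, kind = _column(ds, name)
        if kind == "marker":
            ok = np.isfinite(np.asarray(col, dtype=float))
        else:
            ok = np.array([str(v).strip().lower() not in
                           {"", "na", "nan", "null", "none", "n/a"}
                           for v in col])
        if not ok.any():
            raise ConfigError(f"variable {name!r} is missing in every row")
        mask &= ok
    excluded = int(ds.n - mask.sum())
    if excluded:
        warnings.warn(f"complete-case filtering excluded {excluded} sample(s)",
                      UserWarning, stacklevel=2)
    sub = ds.subset(mask)
    if sub.n_events < 2:
        raise InsufficientEventsError(
            f"only {sub.n_events} events remain after complete-case "
            "filtering")
    return sub


def _encode(ds: SurvivalDataset, spec: MultivariateSpec):
    """Build the design matrix: one column per continuous/dichotomized
    variable, one per non-reference level of each categorical."""
    columns: list[np.ndarray] = []
    names: list[str] = []
    notes: dict[str, str] = {}
    for var in spec.variables:
        col, kind = _column(ds, var.name)
        if var.treatment == "categorical":
            levels = sorted({str(v).strip() for v in col})
            if len(levels) < 2:
                raise ConfigError(f"categorical {var.name!r} has a single "
                                  "level")
            if len(levels) > 10:
                raise ConfigError(f"categorical {var.name!r} has "
                                  f"{len(levels)} levels (maximum 10)")
            ref = str(var.reference) if var.reference is not None else levels[0]
            if ref not in levels:
                raise ConfigError(f"reference level {ref!r} not among "
                                  f"{levels}")
            strcol = np.asarray([str(v).strip() for v in col])
            for lv in levels:
                if lv == ref:
                    continue
                columns.append((strcol == lv).astype(float))
                names.append(f"{var.name}={lv}")
            notes[var.name] = f"categorical (reference {ref})"
        else:
            vals = np.asarray(col, dtype=float)
            if var.treatment == "dichotomized":
                if isinstance(var.cutoff, (int, float)):
                    cut = float(var.cutoff)
                elif var.cutoff == "best":
                    cut = best_cutoff_scan(vals, ds.time, ds.event).best_cutoff
                else:
                    qmap = {"median": 0.5, "lower-quartile": 0.25,
                            "upper-quartile": 0.75}
                    if var.cutoff not in qmap:
                        raise ConfigError(f"unknown cutoff strategy "
                                          f"{var.cutoff!r}")
                    cut = quantile_cutoff(vals, qmap[var.cutoff])
                columns.append((dichotomize(vals, cut) == "high")
                               .astype(float))
                names.append(f"{var.name}>{cut:g}")
                notes[var.name] = f"dichotomized at {cut:g} ({var.cutoff})"
            else:
                columns.append(vals)
                names.append(var.name)
                notes[var.name] = "continuous"
    X = np.column_stack(columns)
    return X, names, notes


def _check_rank(X: np.ndarray, names: list[str]):
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR on the centered matrix
        _, r = np.linalg.qr(Xc)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [names[i] for i in range(X.shape[1])
                   if i < len(diag) and diag[i] <= tol] or names
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased: {aliased}", aliased=aliased)


@dataclass
class MultivariateCoxResults:
    """Fitted multivariate model: per-term table plus diagnostics."""

    fit: CoxResult
    table: pd.DataFrame
    encoding: dict[str, str]
    ph_test: object | None
    n: int
    n_events: int
    excluded: int

    @property
    def global_p(self) -> float:
        return self.fit.global_p

    def summary(self) -> str:
        lines = [f"Multivariate Cox model: n={self.n}, events={self.n_events}"
                 f" ({self.excluded} excluded as incomplete)"]
        for name, how in self.encoding.items():
            lines.append(f"  {name}: {how}")
        lines.append("")
        lines.append(self.table.to_string(index=False,
                                          float_format=lambda v: f"{v:.4g}"))
        lines.append(f"likelihood-ratio global p = {self.fit.global_p:.3g}")
        if self.ph_test is not None:
            lines.append(f"proportional-hazards global p = "
                         f"{self.ph_test.global_p:.3g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n": self.n, "n_events": self.n_events, "excluded": self.excluded,
            "global_p": self.fit.global_p,
            "encoding": self.encoding,
            "terms": self.table.to_dict(orient="records"),
            "ph_global_p": None if self.ph_test is None
            else self.ph_test.global_p,
        }


class MultivariateCoxModel:
    """Cox model over several encoded variables, statsmodels-style.

    Build from a dataset plus a :class:`MultivariateSpec` (or its string
    form), then call :meth:`fit`.
    """

    def __init__(self, dataset: SurvivalDataset,
                 spec: MultivariateSpec | str, ties: str = "efron"):
        self.dataset = dataset
        self.spec = (MultivariateSpec.parse(spec)
                     if isinstance(spec, str) else spec)
        self.ties = ties

    def fit(self, ph_test: bool = True) -> MultivariateCoxResults:
        names = [v.name for v in self.spec.variables]
        ds = complete_cases(self.dataset, names)
        excluded = self.dataset.n - ds.n
        X, colnames, notes = _encode(ds, self.spec)
        _check_rank(X, colnames)
        fit = cox_fit(ds.time, ds.event, X, ties=self.ties, names=colnames)
        table = fit.to_table()
        ph = None
        if ph_test:
            try:
                ph = ph_assumption_test(fit)
                table = table.assign(ph_p=ph.p)
            except Exception:
                ph = None
        return MultivariateCoxResults(
            fit=fit, table=table, encoding=notes, ph_test=ph,
            n=ds.n, n_events=ds.n_events, excluded=excluded)


def multivariate_cox(ds: SurvivalDataset, spec: MultivariateSpec | str,
                     ties: str = "efron") -> MultivariateCoxResults:
    """Functional entry point equivalent to MultivariateCoxModel(...).fit()."""
    return MultivariateCoxModel(ds, spec, ties=ties).fit()
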