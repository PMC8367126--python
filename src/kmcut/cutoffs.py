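"""Cutoff selection for dichotomizing continuous markers.

Three strategies are provided: a predefined quantile (median, lower or
upper quartile, or any custom quantile), trichotomization into tertiles
with the middle third omitted, and the best-cutoff scan.  The scan
iterates over every distinct observed marker value inside the
interquartile range, fits a univariate Cox model at each split, and
selects the cutoff with the smallest p-value (ties broken by the highest
hazard ratio after inversion).  Because the scan performs many tests on
one marker, Benjamini-Hochberg adjusted q-values are attached to every
candidate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sstats

from .exceptions import (
    AmbiguousCutoffWarning,
    ConstantVariableError,
    DegenerateTertilesError,
    NonConvergenceError,
    ScanFailedError,
)
from .survival import cox_fit, invert_hr, logrank_test

LOW, HIGH, OMITTED = "low", "high", "omitted"


def quantile_cutoff(values, q: float) -> float:
    """Type-7 (linear-interpolation) quantile of the marker values."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        raise ValueError("quantile cutoff needs at least 4 finite values")
    if values.min() == values.max():
        raise ConstantVariableError("cannot place a cutoff on a constant "
                                    "column")
    if not 0 < q < 1:
        raise ValueError("q must lie strictly between 0 and 1")
    return float(np.quantile(values, q))  # numpy default is type 7


def dichotomize(values, cutoff: float) -> np.ndarray:
    """Label each sample ``low`` (value <= cutoff) or ``high``."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return np.where(values <= cutoff, LOW, HIGH)


def trichotomize(values) -> tuple[np.ndarray, float, float]:
    """Tertile split; the middle third is flagged ``omitted``.

    Returns ``(labels, q_lower, q_upper)`` where labels are low for
    value <= 1/3-quantile, high for value > 2/3-quantile, omitted between.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 6:
        raise ValueError("trichotomization needs at least 6 values")
    if values.min() == values.max():
        raise ConstantVariableError("cannot trichotomize a constant column")
    q1 = float(np.quantile(values, 1 / 3))
    q2 = float(np.quantile(values, 2 / 3))
    labels = np.full(values.shape, OMITTED, dtype=object)
    labels[values <= q1] = LOW
    labels[values > q2] = HIGH
    if (labels == LOW).sum() == 0 or (labels == HIGH).sum() == 0:
        raise DegenerateTertilesError(
            "ties at the tertile boundaries emptied a cohort")
    return labels.astype(str), q1, q2


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1.

    NaN entries (failed fits) are passed through untouched and do not
    count toward the number of tests.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = _sstats.false_discovery_control(p[ok], method="bh")
    return out


@dataclass
class CutoffScanResult:
    """Per-candidate statistics of a best-cutoff scan."""

    candidates: np.ndarray   # sorted distinct values within [Q1, Q3]
    p: np.ndarray            # univariate Cox Wald p per candidate (NaN: failed)
    hr: np.ndarray           # HR per candidate, inverted to >= 1
    q: np.ndarray            # BH-adjusted p
    logrank_p: np.ndarray    # log-rank p recorded alongside
    n_low: np.ndarray
    n_high: np.ndarray
    best_cutoff: float
    best_index: int
    ambiguity_flag: bool
    q1: float                # scan bounds (lower/upper quartile)
    q3: float

    @property
    def best_p(self) -> float:
        return float(self.p[self.best_index])

    @property
    def best_q(self) -> float:
        return float(self.q[self.best_index])

    @property
    def min_q(self) -> float:
        return float(np.nanmin(self.q))

    def to_table(self):
        import pandas as pd
        return pd.DataFrame({
            "cutoff": self.candidates, "n_low": self.n_low,
            "n_high": self.n_high, "p": self.p, "HR": self.hr, "q": self.q,
            "logrank_p": self.logrank_p,
        })


def best_cutoff_scan(values, time, event, ties: str = "efron",
                     ambiguity_window: float | None = None,
                     rel_tol: float = 1e-9,
                     record_logrank: bool = False) -> CutoffScanResult:
    """Scan every distinct observed value in [Q1, Q3] as a cutoff.

    At each candidate the samples are split at ``value <= cutoff`` and a
    univariate Cox model of the high-vs-low indicator is fitted; the Wald
    p and the HR (inverted to >= 1) are recorded.  The best cutoff
    minimizes p; exact ties (relative tolerance ``rel_tol``, or any
    candidate with ``p <= ambiguity_window * min_p`` when a window is
    given) are broken by the highest HR and flagged as ambiguous.
    Candidates whose fit fails (e.g. perfect separation) carry NaN.
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = values.size
    if n < 8:
        raise ValueError("best-cutoff scan needs at least 8 samples")
    if event.sum() < 2:
        raise ScanFailedError("best-cutoff scan needs at least 2 events")
    if values.min() == values.max():
        raise ConstantVariableError("cannot scan a constant marker")

    q1 = float(np.quantile(values, 0.25))
    q3 = float(np.quantile(values, 0.75))
    candidates = np.unique(values)
    candidates = candidates[(candidates >= q1) & (candidates <= q3)]
    # a cutoff equal to the overall maximum would empty the high cohort
    candidates = candidates[candidates < values.max()]
    if candidates.size == 0:
        raise ScanFailedError("no candidate cutoffs inside the interquartile "
                              "range")

    m = candidates.size
    p = np.full(m, np.nan)
    hr = np.full(m, np.nan)
    lr_p = np.full(m, np.nan)
    n_low = np.zeros(m, dtype=int)
    n_high = np.zeros(m, dtype=int)
    for i, c in enumerate(candidates):
        grp = (values > c).astype(float)   # 1 = high cohort
        n_high[i] = int(grp.sum())
        n_low[i] = n - n_high[i]
        if n_high[i] == 0 or n_low[i] == 0:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = invert_hr(cox_fit(time, event, grp, ties=ties,
                                        names=["high"], warn_small=False))
            p[i] = fit.p[0]
            hr[i] = fit.hr[0]
            if record_logrank:
                _, lr_p[i] = logrank_test(time, event, grp)
        except NonConvergenceError:
            continue  # recorded as NaN for this candidate
        except Exception:
            continue

    if not np.isfinite(p).any():
        raise ScanFailedError("no candidate cutoff produced a convergent "
                              "two-cohort comparison")

    q = bh_adjust(p)
    min_p = np.nanmin(p)
    if ambiguity_window is not None:
        tied = np.nonzero(np.isfinite(p) & (p <= ambiguity_window * min_p))[0]
    else:
        tied = np.nonzero(np.isfinite(p) &
                          (p <= min_p * (1 + rel_tol) + 1e-300))[0]
    ambiguous = tied.size > 1
    best_index = int(tied[np.argmax(hr[tied])])
    if ambiguous:
        warnings.warn(
            f"{tied.size} cutoffs tie for the minimal p ({min_p:.3g}); "
            "selected the one with the highest HR",
            AmbiguousCutoffWarning, stacklevel=2)

    return CutoffScanResult(
        candidates=candidates, p=p, hr=hr, q=q, logrank_p=lr_p,
        n_low=n_low, n_high=n_high,
        best_cutoff=float(candidates[best_index]), best_index=best_index,
        ambiguity_flag=bool(ambiguous), q1=q1, q3=q3,
    )


def cutoff_plot_data(scan: CutoffScanResult) -> dict:
    """Aligned (cutoff -> p) and (cutoff -> HR) series plus the best-cutoff
    marker, ready for JSON/TSV serialization or plotting."""
    return {
        "cutoff": scan.candidates.tolist(),
        "p": scan.p.tolist(),
        "hr": scan.hr.tolist(),
        "q": scan.q.tolist(),
        "best": {"cutoff": scan.best_cutoff, "p": scan.best_p,
                 "hr": float(scan.hr[scan.best_index])},
    }


def plot_data_to_json(data: dict) -> str:
    return json.dumps(data, sort_keys=True)
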