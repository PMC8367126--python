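"""The statsmodels-style front door: MarkerSurvivalModel / Results.

A :class:`MarkerSurvivalModel` bundles a validated dataset, one analysis
variable (a raw marker or a combination of markers), optional filter
selections and a cutoff strategy.  :meth:`MarkerSurvivalModel.fit`
orchestrates the whole pipeline — filter, derive, dichotomize, estimate
the Kaplan-Meier curves per cohort, run the log-rank and univariate Cox
tests, test the proportional-hazards assumption — and returns a
:class:`MarkerSurvivalResults` carrying every number the analysis
produced, a ``summary()`` table, JSON/TSV exports and plotting helpers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import combine as _combine
from . import cutoffs as _cutoffs
from . import io as _io
from . import survival as _survival
from .exceptions import (
    ConfigError,
    EmptyCohortError,
    KMCutWarning,
    LowEventsWarning,
)

LOW_EVENT_FRACTION = 0.2
QUANTILE_STRATEGIES = {"median": 0.5, "lower-quartile": 0.25,
                       "upper-quartile": 0.75}


def _infinite_hr_result(exc, time, event, ties) -> _survival.CoxResult:
    """Degenerate CoxResult for a monotone partial likelihood."""
    sign = float(np.atleast_1d(exc.direction)[0]) if exc.direction is not None \
        else 1.0
    beta = np.array([np.inf if sign > 0 else -np.inf])
    return _survival.CoxResult(
        coefficients=beta, se=np.array([np.inf]), hr=np.exp(beta),
        ci_low=np.array([np.nan]), ci_high=np.array([np.nan]),
        p=np.array([np.nan]), global_p=np.nan, loglik=np.nan,
        loglik_null=np.nan, ties_method=ties, n=len(time),
        n_events=int(np.sum(event)), names=["high"],
        var=np.array([[np.inf]]))


@dataclass
class MarkerSurvivalResults:
    """Assembled outputs of one univariate marker analysis."""

    marker: str
    cutoff: float | None
    cutoff_strategy: str
    curves: dict[str, _survival.KMCurve]
    logrank_chi2: float
    logrank_p: float
    cox: _survival.CoxResult
    ph_test: _survival.PHTestResult | None
    scan: _cutoffs.CutoffScanResult | None
    median_survival: dict[str, tuple[float | None, str]]
    cohort_sizes: dict[str, int]
    cohort_values: dict[str, list[float]]   # per-cohort marker values
    n_omitted: int
    warnings: list[str] = field(default_factory=list)

    # -- readouts ---------------------------------------------------------
    @property
    def hr(self) -> float:
        return float(self.cox.hr[0])

    @property
    def hr_ci(self) -> tuple[float, float]:
        return float(self.cox.ci_low[0]), float(self.cox.ci_high[0])

    @property
    def cox_p(self) -> float:
        return float(self.cox.p[0])

    @property
    def fdr_q(self) -> float | None:
        """BH-adjusted q of the selected cutoff (best-cutoff runs only)."""
        return None if self.scan is None else self.scan.best_q

    def survival_at(self, t: float) -> dict[str, float]:
        return {name: curve.survival_at(t)
                for name, curve in self.curves.items()}

    # -- presentation -----------------------------------------------------
    def summary(self) -> str:
        lo, hi = self.hr_ci
        lines = [
            f"Survival analysis of {self.marker!r}",
            f"  cutoff: {self.cutoff:.6g} ({self.cutoff_strategy})"
            if self.cutoff is not None else
            f"  grouping: {self.cutoff_strategy}",
            "  cohorts: " + ", ".join(
                f"{k} n={v}" for k, v in self.cohort_sizes.items())
            + (f" ({self.n_omitted} omitted)" if self.n_omitted else ""),
        ]
        for name, (t, kind) in self.median_survival.items():
            if t is None:
                lines.append(f"  {name}: survival never reaches 0.75")
            elif kind == "median":
                lines.append(f"  {name}: median survival {t:g}")
            else:
                lines.append(f"  {name}: upper-quartile survival {t:g} "
                             "(median not reached)")
        lines += [
            f"  HR ({'low vs high' if self.cox.inverted else 'high vs low'})"
            f" = {self.hr:.4g}, 95% CI [{lo:.4g}, {hi:.4g}]",
            f"  Cox Wald p = {self.cox_p:.3g}   log-rank p = "
            f"{self.logrank_p:.3g}",
        ]
        if self.scan is not None:
            lines.append(f"  best-cutoff scan: {self.scan.candidates.size} "
                         f"candidates in [{self.scan.q1:.6g}, "
                         f"{self.scan.q3:.6g}], FDR q = {self.fdr_q:.3g}")
        if self.ph_test is not None:
            lines.append(f"  proportional hazards p = "
                         f"{self.ph_test.global_p:.3g}"
                         + ("  ** assumption violated"
                            if self.ph_test.global_p < 0.05 else ""))
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "marker": self.marker,
            "cutoff": self.cutoff,
            "cutoff_strategy": self.cutoff_strategy,
            "cohort_sizes": self.cohort_sizes,
            "n_omitted": self.n_omitted,
            "median_survival": {
                k: {"time": t, "kind": kind}
                for k, (t, kind) in self.median_survival.items()},
            "logrank": {"chi2": self.logrank_chi2, "p": self.logrank_p},
            "cox": {
                "hr": self.hr, "ci_low": self.hr_ci[0],
                "ci_high": self.hr_ci[1], "p": self.cox_p,
                "global_p": self.cox.global_p,
                "inverted": self.cox.inverted,
                "ties_method": self.cox.ties_method,
                "n": self.cox.n, "n_events": self.cox.n_events},
            "fdr_q": self.fdr_q,
            "ph_test": None if self.ph_test is None else {
                "global_p": self.ph_test.global_p,
                "transform": self.ph_test.transform},
            "km_curves": {k: c.to_plot_series()
                          for k, c in self.curves.items()},
            "cutoff_scan": None if self.scan is None
            else _cutoffs.cutoff_plot_data(self.scan),
            "cohort_values": self.cohort_values,
            "warnings": self.warnings,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    # -- file / figure output --------------------------------------------
    def export(self, out_dir) -> list[str]:
        """Write the report JSON, per-cohort KM tables, the results table
        and (for best-cutoff runs) the scan table; returns written paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []

        p = out / "report.json"
        p.write_text(self.to_json() + "\n")
        written.append(str(p))
        for name, curve in self.curves.items():
            p = out / f"km_curve_{name}.tsv"
            curve.to_table().to_csv(p, sep="\t", index=False)
            written.append(str(p))
        p = out / "results.tsv"
        self.cox.to_table().assign(
            logrank_p=self.logrank_p,
            fdr_q=np.nan if self.fdr_q is None else self.fdr_q,
        ).to_csv(p, sep="\t", index=False)
        written.append(str(p))
        if self.scan is not None:
            p = out / "cutoff_scan.tsv"
            self.scan.to_table().to_csv(p, sep="\t", index=False)
            written.append(str(p))
        # per-cohort marker values: the beeswarm plot's underlying data
        p = out / "cohort_values.tsv"
        with open(p, "w") as fh:
            fh.write("cohort\tvalue\n")
            for name, vals in self.cohort_values.items():
                for v in vals:
                    fh.write(f"{name}\t{v:g}\n")
        written.append(str(p))
        return written

    def plot_km(self, ax=None):
        """Kaplan-Meier step plot with censor ticks, one line per cohort."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4.5))
        for name, curve in self.curves.items():
            series = curve.to_plot_series()
            ax.step(series["time"], series["survival"], where="post",
                    label=f"{name} (n={self.cohort_sizes[name]})")
            if curve.event_times.size:
                cy = [curve.survival_at(t) for t in curve.censoring_times]
                ax.plot(curve.censoring_times, cy, "|", color=ax.lines[-1]
                        .get_color(), markersize=8)
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        ax.legend()
        ax.set_title(f"{self.marker}: HR={self.hr:.3g}, "
                     f"log-rank p={self.logrank_p:.3g}")
        return ax

    def plot_cutoff_scan(self, axes=None):
        """P-value and HR against the scanned cutoff values; the selected
        best cutoff is circled."""
        if self.scan is None:
            raise ConfigError("no scan available; run with cutoff='best'")
        import matplotlib.pyplot as plt
        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(10, 4))
        s = self.scan
        axes[0].plot(s.candidates, s.p, ".-")
        axes[0].scatter([s.best_cutoff], [s.best_p], s=120, facecolors="none",
                        edgecolors="red", zorder=3)
        axes[0].set_yscale("log")
        axes[0].set_xlabel("cutoff")
        axes[0].set_ylabel("Cox p-value")
        axes[1].plot(s.candidates, s.hr, ".-")
        axes[1].scatter([s.best_cutoff], [s.hr[s.best_index]], s=120,
                        facecolors="none", edgecolors="red", zorder=3)
        axes[1].set_xlabel("cutoff")
        axes[1].set_ylabel("hazard ratio")
        return axes

    def save_plots(self, out_dir) -> list[str]:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        ax = self.plot_km()
        p = out / "km_plot.png"
        ax.figure.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(str(p))
        if self.scan is not None:
            axes = self.plot_cutoff_scan()
            p = out / "cutoff_plot.png"
            axes[0].figure.savefig(p, dpi=150, bbox_inches="tight")
            plt.close(axes[0].figure)
            written.append(str(p))
        return written


class MarkerSurvivalModel:
    """Univariate marker survival analysis over a validated dataset.

    Parameters
    ----------
    dataset : SurvivalDataset (see :func:`kmcut.io.load_dataset`)
    marker : name of the analysis variable; omit when ``combination``
        derives one.
    cutoff : ``"median"``, ``"lower-quartile"``, ``"upper-quartile"``,
        ``"best"`` (interquartile scan), ``"trichotomize"``, or a number.
    filters : mapping filter-column -> allowed values, applied first.
    combination : optional :class:`kmcut.combine.CombinationSpec` deriving
        the analysis variable (signature mean or ratio) or stratifying the
        cohort before analysis.
    invert : report HRs below 1 as their reciprocal with swapped cohorts.
    """

    def __init__(self, dataset: _io.SurvivalDataset, marker: str | None = None,
                 cutoff: str | float = "median",
                 filters: dict | None = None,
                 combination: _combine.CombinationSpec | None = None,
                 invert: bool = False, ties: str = "efron",
                 ph_transform: str = "km",
                 low_event_fraction: float = LOW_EVENT_FRACTION,
                 ambiguity_window: float | None = None):
        if ties not in {"efron", "breslow"}:
            raise ConfigError(f"unknown ties method {ties!r}")
        self.dataset = dataset
        self.marker = marker
        self.cutoff = cutoff
        self.filters = filters or {}
        self.combination = combination
        self.invert = invert
        self.ties = ties
        self.ph_transform = ph_transform
        self.low_event_fraction = low_event_fraction
        self.ambiguity_window = ambiguity_window

    @classmethod
    def from_file(cls, path, **kwargs) -> "MarkerSurvivalModel":
        return cls(_io.load_dataset(path), **kwargs)

    # -- pipeline ---------------------------------------------------------
    def _prepare(self):
        """Filter, apply the combination, and resolve the analysis column."""
        ds = self.dataset
        if self.filters:
            ds = _io.apply_filters(ds, self.filters)
        marker = self.marker
        comb = self.combination
        if comb is not None:
            if comb.mode in {"signature_mean", "ratio"}:
                ds, marker = _combine.derive_column(ds, comb)
            elif comb.mode == "stratified":
                ds = _combine.stratified_subset(ds, comb.stratifier, comb.arm)
            elif comb.mode == "each_separately":
                raise ConfigError("batch mode: use run_batch() instead")
        if marker is None:
            raise ConfigError("no analysis marker given")
        if marker not in ds.markers:
            raise KeyError(f"unknown marker {marker!r}; available: "
                           f"{sorted(ds.markers)}")
        return ds, marker

    def _split(self, ds, values):
        """Resolve the cutoff strategy into cohort labels."""
        scan = None
        n_omitted = 0
        if isinstance(self.cutoff, (int, float)) and \
                not isinstance(self.cutoff, bool):
            cut = float(self.cutoff)
            strategy = "fixed"
            labels = _cutoffs.dichotomize(values, cut)
        elif self.cutoff in QUANTILE_STRATEGIES:
            cut = _cutoffs.quantile_cutoff(values,
                                           QUANTILE_STRATEGIES[self.cutoff])
            strategy = self.cutoff
            labels = _cutoffs.dichotomize(values, cut)
        elif self.cutoff == "best":
            scan = _cutoffs.best_cutoff_scan(
                values, ds.time, ds.event, ties=self.ties,
                ambiguity_window=self.ambiguity_window)
            cut = scan.best_cutoff
            strategy = "best"
            labels = _cutoffs.dichotomize(values, cut)
        elif self.cutoff == "trichotomize":
            labels, q1, q2 = _cutoffs.trichotomize(values)
            keep = labels != _cutoffs.OMITTED
            n_omitted = int((~keep).sum())
            return None, "trichotomize", labels, n_omitted, scan
        else:
            raise ConfigError(f"unknown cutoff strategy {self.cutoff!r}")
        if (labels == _cutoffs.LOW).sum() == 0 or \
                (labels == _cutoffs.HIGH).sum() == 0:
            raise EmptyCohortError(
                f"cutoff {cut:g} leaves an empty cohort")
        return cut, strategy, labels, n_omitted, scan

    def fit(self, ph_test: bool = True) -> MarkerSurvivalResults:
        ds, marker = self._prepare()
        values = ds.marker(marker)
        captured: list[str] = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cut, strategy, labels, n_omitted, scan = self._split(ds, values)

            keep = labels != _cutoffs.OMITTED
            time, event = ds.time[keep], ds.event[keep]
            vals_kept, labels_kept = values[keep], labels[keep]

            grp = (labels_kept == _cutoffs.HIGH).astype(float)
            curves = {}
            medians = {}
            sizes = {}
            cohort_values = {}
            for name in (_cutoffs.LOW, _cutoffs.HIGH):
                m = labels_kept == name
                sizes[name] = int(m.sum())
                cohort_values[name] = [float(v) for v in vals_kept[m]]
                curves[name] = _survival.km_estimate(time[m], event[m])
                medians[name] = curves[name].median_survival()

            chi2, lr_p = _survival.logrank_test(time, event, labels_kept)
            try:
                cox = _survival.cox_fit(time, event, grp, ties=self.ties,
                                        names=["high"])
            except _survival.NonConvergenceError as exc:
                # all events concentrated in one cohort: infinite HR; the
                # report keeps the curves and the log-rank test
                cox = _infinite_hr_result(exc, time, event, self.ties)
                captured.append(f"Cox fit did not converge: {exc}")
            if self.invert:
                cox = _survival.invert_hr(cox)
                if cox.inverted:
                    curves = {"low": curves["high"], "high": curves["low"]}
                    # label swap: the reported HR now compares low vs high

            ph = None
            if ph_test:
                try:
                    ph = _survival.ph_assumption_test(
                        cox, transform=self.ph_transform)
                except Exception as exc:
                    captured.append(f"proportional-hazards test skipped: "
                                    f"{exc}")

            n_used = len(time)
            ev_frac = event.mean() if n_used else 0.0
            if 0 < ev_frac < self.low_event_fraction:
                warnings.warn(
                    f"only {100 * ev_frac:.0f}% of samples have an event; "
                    "survival readouts are unstable", LowEventsWarning,
                    stacklevel=1)

        captured += [str(w.message) for w in caught
                     if issubclass(w.category, (KMCutWarning, UserWarning))]

        return MarkerSurvivalResults(
            marker=marker, cutoff=cut, cutoff_strategy=strategy,
            curves=curves, logrank_chi2=chi2, logrank_p=lr_p, cox=cox,
            ph_test=ph, scan=scan, median_survival=medians,
            cohort_sizes=sizes, cohort_values=cohort_values,
            n_omitted=n_omitted, warnings=captured,
        )


def run_batch(dataset: _io.SurvivalDataset, markers: list[str] | None = None,
              fdr_across_markers: bool = False, **model_kwargs):
    """Run the identical univariate analysis for each marker separately.

    Returns ``(results, errors)``: per-marker Results keyed by name, and a
    map of markers whose analysis failed (failures are isolated, not
    fatal).  With ``fdr_across_markers=True`` a second BH pass across the
    markers' p-values is attached as ``batch_q``.
    """
    markers = list(markers) if markers is not None \
        else sorted(dataset.markers)
    results: dict[str, MarkerSurvivalResults] = {}
    errors: dict[str, Exception] = {}
    for m in markers:
        try:
            results[m] = MarkerSurvivalModel(dataset, marker=m,
                                             **model_kwargs).fit()
        except Exception as exc:          # error isolation per marker
            errors[m] = exc
    if fdr_across_markers and results:
        names = list(results)
        q = _cutoffs.bh_adjust([results[m].cox_p for m in names])
        for m, qv in zip(names, q):
            results[m].__dict__["batch_q"] = float(qv)
    return results, errors


def run_analysis(config: dict) -> MarkerSurvivalResults:
    """Config-dict front end used by the CLI: one univariate analysis.

    Recognized keys: ``input`` (path) or ``dataset``, ``marker``,
    ``cutoff``, ``filters``, ``signature``/``ratio``/``stratify``,
    ``invert_hr``, ``ties``.  Deterministic given file plus config.
    """
    if "dataset" in config:
        ds = config["dataset"]
    else:
        ds = _io.load_dataset(config["input"])
    filters = config.get("filters") or {}
    if len(filters) > _io.MAX_FILTERS:
        raise ConfigError(f"a maximum of {_io.MAX_FILTERS} filters are "
                          "allowed")
    comb = None
    if config.get("signature"):
        sig = config["signature"]
        comb = _combine.CombinationSpec(
            mode="signature_mean", members=sig["members"],
            weights=sig.get("weights"), inverted=sig.get("inverted"))
    elif config.get("ratio"):
        num, den = config["ratio"]
        comb = _combine.CombinationSpec(mode="ratio", numerator=num,
                                        denominator=den,
                                        members=[num, den])
    elif config.get("stratify"):
        name, arm = config["stratify"]
        comb = _combine.CombinationSpec(mode="stratified", stratifier=name,
                                        arm=arm)
    model = MarkerSurvivalModel(
        ds, marker=config.get("marker"), cutoff=config.get("cutoff", "median"),
        filters=filters, combination=comb,
        invert=bool(config.get("invert_hr", False)),
        ties=config.get("ties", "efron"),
    )
    return model.fit(ph_test=config.get("ph_test", True))
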