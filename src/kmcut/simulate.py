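"""Synthetic survival cohorts with known ground truth.

The generator draws expression-like (log-normal) markers with an optional
marker-marker correlation, event times from an exponential or Weibull
baseline hazard scaled per sample by exp(sum_i log(HR_i) * z_i) — where
z_i is the standardized log-marker — and independent uniform censoring
calibrated to hit a requested censoring fraction.  Every dataset passes
table validation, so fixtures exercise the same code paths as user files.

A second fixture reproduces the documented 10-sample example table used
throughout the docs and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError
from .io import SurvivalDataset

_LOG_MU = 7.0    # typical log expression level (values around e^7 ~ 1100)
_LOG_SD = 1.0


@dataclass
class FixtureSpec:
    """Ground-truth configuration of a simulated cohort."""

    n: int = 200
    true_hr: tuple[float, ...] = (1.0,)
    baseline: str = "exponential"       # or "weibull"
    baseline_rate: float = 0.05         # lambda (per unit time)
    weibull_shape: float = 1.0          # k; 1 reduces to exponential
    censoring_fraction: float = 0.2
    n_markers: int | None = None
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 4:
            raise ConfigError("n must be at least 4")
        if self.baseline_rate <= 0 or self.weibull_shape <= 0:
            raise ConfigError("baseline parameters must be positive")
        if not 0 <= self.censoring_fraction < 1:
            raise ConfigError("censoring_fraction must lie in [0, 1)")
        if self.baseline not in {"exponential", "weibull"}:
            raise ConfigError(f"unknown baseline {self.baseline!r}")
        if self.n_markers is None:
            self.n_markers = len(self.true_hr)
        if len(self.true_hr) != self.n_markers:
            raise ConfigError("true_hr must list one HR per marker")
        if not -0.99 <= self.correlation <= 0.99:
            raise ConfigError("correlation must lie in (-1, 1)")
        if any(h <= 0 for h in self.true_hr):
            raise ConfigError("hazard ratios must be positive")


def generate(spec: FixtureSpec) -> tuple[SurvivalDataset, dict]:
    """Simulate a cohort; returns ``(dataset, ground_truth)``.

    Reproducible bit-for-bit from ``spec.seed`` (one named PCG64 stream).
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_markers

    cov = np.full((k, k), spec.correlation)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(k), cov, size=spec.n) if k > 1 \
        else rng.standard_normal((spec.n, 1))
    markers = np.exp(_LOG_MU + _LOG_SD * z)

    log_hr = np.log(np.asarray(spec.true_hr, dtype=float))
    mult = np.exp(z @ log_hr)           # per-sample hazard multiplier

    u = rng.uniform(size=spec.n)
    if spec.baseline == "exponential":
        t_event = -np.log(u) / (spec.baseline_rate * mult)
    else:
        t_event = (-np.log(u) / mult) ** (1.0 / spec.weibull_shape) \
            / spec.baseline_rate

    time, event, cmax = _apply_censoring(t_event, spec.censoring_fraction,
                                         rng)

    ds = SurvivalDataset(
        sample_ids=np.array([f"S{i + 1}" for i in range(spec.n)],
                            dtype=object),
        time=time, event=event, filters={},
        markers={f"Marker_{j + 1}": markers[:, j] for j in range(k)},
        id_name="Sample ID", time_name="Survival time",
        event_name="Survival event",
    )
    truth = {
        "true_hr": dict(zip([f"Marker_{j + 1}" for j in range(k)],
                            spec.true_hr)),
        "log_hr_per_sd": dict(zip([f"Marker_{j + 1}" for j in range(k)],
                                  log_hr)),
        "baseline": spec.baseline,
        "baseline_rate": spec.baseline_rate,
        "censoring_max": cmax,
        "achieved_censoring": float(1 - event.mean()),
        "standardized_markers": z,
    }
    return ds, truth


def _apply_censoring(t_event, fraction, rng):
    """Uniform(0, c) censoring with c calibrated by bisection so the
    realized censored fraction matches the request."""
    n = t_event.size
    if fraction == 0:
        return t_event.copy(), np.ones(n, dtype=int), np.inf
    v = rng.uniform(size=n)

    def censored_frac(cmax):
        return float((cmax * v < t_event).mean())

    lo, hi = 1e-12, float(t_event.max()) * 10
    # censored fraction decreases as cmax grows
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_frac(mid) > fraction:
            lo = mid
        else:
            hi = mid
    cmax = 0.5 * (lo + hi)
    achieved = censored_frac(cmax)
    if abs(achieved - fraction) > 0.05:
        raise ConfigError(
            f"could not reach censoring fraction {fraction} "
            f"(achieved {achieved:.3f})")
    c = cmax * v
    event = (t_event <= c).astype(int)
    time = np.minimum(t_event, c)
    return time, event, cmax


def generate_two_group(n: int, hr: float, censoring_fraction: float,
                       seed: int, baseline_rate: float = 0.05,
                       weibull_shapes: tuple[float, float] | None = None):
    """Balanced two-cohort fixture with a known group hazard ratio.

    The default draws exponential times with rate ``baseline_rate`` in
    group 0 and ``baseline_rate * hr`` in group 1.  Passing
    ``weibull_shapes=(k0, k1)`` instead draws Weibull times with those
    shapes (crossing hazards when the shapes straddle 1), which violates
    proportionality on purpose.  Returns ``(time, event, group)``.
    """
    rng = np.random.default_rng(seed)
    group = np.zeros(n, dtype=int)
    group[n // 2:] = 1
    u = rng.uniform(size=n)
    if weibull_shapes is None:
        rate = baseline_rate * np.where(group == 1, hr, 1.0)
        t_event = -np.log(u) / rate
    else:
        k = np.where(group == 1, weibull_shapes[1], weibull_shapes[0])
        mult = np.where(group == 1, hr, 1.0)
        t_event = (-np.log(u) / mult) ** (1.0 / k) / baseline_rate
    time, event, _ = _apply_censoring(t_event, censoring_fraction, rng)
    return time, event, group


# ---------------------------------------------------------------------------
# the documented 10-sample example table

_TABLE_HEADERS = ["Sample ID", "Survival time", "Survival event", "Filter_A",
                  "Filter_B", "Filter_C", "Gene_1", "ABC123", "DE45"]
_TABLE_ROWS = [
    ["Sample 1", 95, 1, 2, 2, 3, 1441, 4474, 1.13],
    ["Sample 2", 66, 0, 3, 3, 3, 3064, 421, 2.395],
    ["Sample 3", 70, 0, 3, 1, 1, 2529, 2974, 1.363],
    ["Sample 4", 26, 1, 3, 1, 3, 19, 3346, 4.818],
    ["Sample 5", 13, 0, 1, 2, 3, 3573, 1244, 2.058],
    ["Sample 6", 67, 0, 2, 3, 2, 2977, 962, 4.431],
    ["Sample 7", 96, 1, 3, 3, 3, 2777, 4367, 2.015],
    ["Sample 8", 67, 0, 3, 3, 1, 4606, 4190, 1.05],
    ["Sample 9", 95, 1, 3, 1, 2, 1209, 3930, 1.980],
    ["Sample 10", 1, 1, 2, 3, 2, 1894, 4897, 4.073],
]


def example_table_text(dialect: str = "tab") -> str:
    """The 10-sample example table as delimited text."""
    sep = {"tab": "\t", "semicolon": ";", "comma": ","}[dialect]
    lines = [sep.join(_TABLE_HEADERS)]
    for row in _TABLE_ROWS:
        lines.append(sep.join(str(c) for c in row))
    return "\n".join(lines) + "\n"


def example_fixture() -> SurvivalDataset:
    """The 10-sample example cohort, via the full parse/validate path."""
    from .io import parse_table, validate
    return validate(parse_table(example_table_text()))
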