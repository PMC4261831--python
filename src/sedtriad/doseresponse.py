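"""Log-logistic dose-response fitting for sediment-extract bioassays.

Two endpoints are supported:

* ``viability_pct`` -- neutral-red cytotoxicity, expressed as percent of
  the solvent-control absorbance (decreasing with dose);
* ``tail_pct`` -- comet-assay %DNA in tail, normalized to the highest
  mean %tail observed across the whole experiment set (the maximal
  effect; %DNA in tail never reaches 100%), hence increasing with dose
  on a 0-1 fraction-of-maximal-effect scale.

Both are fitted with a two-parameter log-logistic curve

    f(x) = lower + (upper - lower) / (1 + (x / EC50)^b)

with the asymptotes fixed by the normalization (lower = 0; upper = 100
for viability, 1.0 for the tail fraction) and the sign of the slope b
encoding the direction of response.  The fit is least squares on the raw
dose scale, parameterized in (log EC50, b) so that the asymptotic
standard error of log EC50 yields a delta-method 95% confidence interval
back-transformed to the concentration scale.

A series whose optimizer fails, whose EC50 falls outside the tenfold
extension of the tested dose range, or whose maximum observed normalized
effect stays below one half is flagged non-estimable rather than raising:
such an EC50 would be an extrapolation beyond the data and is rendered
"-" in output tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DegenerateControlError, InconsistentMaximumError

DIRECTION_DECREASING = "decreasing"
DIRECTION_INCREASING = "increasing"

#: relative tolerance when checking tail values against the study maximum
_MAX_TAIL_RTOL = 1e-9


@dataclass
class DoseResponseSeries:
    """One extract fraction's dose-response observations for one endpoint.

    ``observations`` is a DataFrame with columns ``concentration``
    (mg SEQ/mL), ``replicate`` and ``response``.
    """

    site: str
    fraction: int
    endpoint: str  # viability_pct | tail_pct
    fpg: bool
    observations: pd.DataFrame

    def __post_init__(self):
        required = {"concentration", "replicate", "response"}
        missing = required - set(self.observations.columns)
        if missing:
            raise ValueError(f"observations missing columns {sorted(missing)}")
        if (self.observations["concentration"] < 0).any():
            raise ValueError("concentrations must be non-negative")

    @property
    def doses(self) -> np.ndarray:
        return np.sort(self.observations["concentration"].unique())

    def mean_response(self) -> pd.Series:
        """Mean response per dose, sorted by dose."""
        return self.observations.groupby("concentration")["response"].mean().sort_index()


@dataclass
class LogLogisticModel:
    """Fitted two-parameter log-logistic curve with fixed asymptotes."""

    ec50: float
    slope: float
    lower: float
    upper: float
    log_ec50_se: float
    converged: bool
    estimable: bool
    reason: str = ""
    n_obs: int = 0

    def predict(self, x) -> np.ndarray:
        return log_logistic(np.asarray(x, dtype=float), self.ec50, self.slope,
                            self.lower, self.upper)


@dataclass
class Ec50Estimate:
    """Point estimate with 95% CI on the concentration scale; '-' when not estimable."""

    point: float | None
    ci95: tuple | None
    estimable: bool
    endpoint: str = ""
    fpg: bool = False
    reason: str = ""

    def render(self) -> str:
        if not self.estimable:
            return "-"
        lo, hi = self.ci95
        return f"{self.point:.1f} ({lo:.1f}-{hi:.1f})"


def log_logistic(x, ec50, b, lower=0.0, upper=1.0):
    """f(x) = lower + (upper - lower)/(1 + (x/ec50)^b), with f(0) the asymptote.

    At x = 0 the limit is ``upper`` for b > 0 (decreasing curve) and
    ``lower`` for b < 0 (increasing curve); the control anchors the
    asymptote rather than entering as log(0).
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, (x / ec50) ** b, 0.0)
    f = lower + (upper - lower) / (1.0 + ratio)
    zero_limit = upper if b > 0 else (lower if b < 0 else (lower + upper) / 2)
    return np.where(x > 0, f, zero_limit)


def normalize_viability(treated_absorbances, control_absorbances) -> float:
    """Percent viability: 100 x mean(treated) / mean(control)."""
    control_mean = float(np.mean(control_absorbances))
    if control_mean <= 0:
        raise DegenerateControlError(
            f"control mean absorbance must be positive, got {control_mean}")
    return 100.0 * float(np.mean(treated_absorbances)) / control_mean


def normalize_genotoxicity(tail_means, max_tail_study: float | None = None) -> np.ndarray:
    """%DNA-in-tail means as fractions of the study-wide maximal effect.

    When ``max_tail_study`` is None the maximum of the provided means is
    used (self-normalization over the experiment set).
    """
    tails = np.asarray(tail_means, dtype=float)
    if max_tail_study is None:
        max_tail_study = float(np.max(tails))
    if not max_tail_study > 0:
        raise InconsistentMaximumError(
            f"study maximum %tail must be positive, got {max_tail_study}")
    if np.any(tails > max_tail_study * (1 + _MAX_TAIL_RTOL)):
        raise InconsistentMaximumError(
            "a %tail value exceeds the declared study maximum "
            f"({np.max(tails)} > {max_tail_study})")
    return tails / max_tail_study


def _init_ec50(doses, responses, upper, direction):
    """Starting EC50: the dose bracketing half-maximal response by linear interpolation."""
    half = upper / 2.0
    order = np.argsort(doses)
    d, r = doses[order], responses[order]
    if direction == DIRECTION_DECREASING:
        crossing = r <= half
    else:
        crossing = r >= half
    idx = np.flatnonzero(crossing)
    pos = d[d > 0]
    if idx.size == 0 or idx[0] == 0:
        return float(np.sqrt(pos.min() * pos.max()))  # geometric mid-range fallback
    i = idx[0]
    d0, d1, r0, r1 = d[i - 1], d[i], r[i - 1], r[i]
    if r1 == r0:
        return float(d1)
    ec = d0 + (half - r0) * (d1 - d0) / (r1 - r0)
    if not ec > 0:
        ec = float(np.sqrt(pos.min() * pos.max()))
    return float(ec)


def fit_log_logistic(series: DoseResponseSeries,
                     direction: str | None = None) -> LogLogisticModel:
    """Least-squares log-logistic fit of a normalized dose-response series.

    Responses must already be normalized: percent-of-control for
    viability (upper = 100), fraction of maximal effect for %tail
    (upper = 1).  Direction defaults from the endpoint (viability
    decreases, tail effect increases).  Deterministic given the data:
    starting values come from a linear-interpolation bracket of the
    half-maximal response and a unit slope of the appropriate sign.
    """
    if direction is None:
        direction = (DIRECTION_DECREASING if series.endpoint == "viability_pct"
                     else DIRECTION_INCREASING)
    upper = 100.0 if series.endpoint == "viability_pct" else 1.0
    lower = 0.0

    obs = series.observations
    x = obs["concentration"].to_numpy(dtype=float)
    y = obs["response"].to_numpy(dtype=float)
    pos_doses = np.unique(x[x > 0])
    if pos_doses.size < 3:
        return LogLogisticModel(np.nan, np.nan, lower, upper, np.nan, False, False,
                                reason="fewer than 3 positive concentrations", n_obs=len(x))

    # maximum observed effect on the normalized scale
    dose_means = series.mean_response()
    if direction == DIRECTION_DECREASING:
        max_effect = (upper - dose_means.min()) / (upper - lower)
    else:
        max_effect = (dose_means.max() - lower) / (upper - lower)

    b0 = 1.0 if direction == DIRECTION_DECREASING else -1.0
    loge0 = np.log(_init_ec50(dose_means.index.to_numpy(), dose_means.to_numpy(),
                              upper, direction))

    def model(xx, loge, b):
        return log_logistic(xx, np.exp(loge), b, lower, upper)

    converged = True
    popt = pcov = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(model, x, y, p0=[loge0, b0], maxfev=10000)
    except (RuntimeError, ValueError):
        converged = False

    if not converged:
        return LogLogisticModel(np.nan, np.nan, lower, upper, np.nan, False, False,
                                reason="optimizer did not converge", n_obs=len(x))

    ec50 = float(np.exp(popt[0]))
    slope = float(popt[1])
    se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.nan

    lo_bound = pos_doses.min() / 10.0
    hi_bound = pos_doses.max() * 10.0
    estimable = True
    reason = ""
    if not (lo_bound <= ec50 <= hi_bound):
        estimable, reason = False, (
            f"EC50 {ec50:.3g} outside tenfold-extended dose range "
            f"[{lo_bound:.3g}, {hi_bound:.3g}]")
    elif max_effect < 0.5:
        estimable, reason = False, (
            f"maximum observed normalized effect {max_effect:.2f} < 0.5")
    # direction mismatch: fitted slope sign contradicts the requested direction
    elif (direction == DIRECTION_DECREASING and slope <= 0) or \
         (direction == DIRECTION_INCREASING and slope >= 0):
        estimable, reason = False, "fitted slope contradicts response direction"

    return LogLogisticModel(ec50, slope, lower, upper, se, True, estimable,
                            reason=reason, n_obs=len(x))


def ec50_with_ci(model: LogLogisticModel,
                 series: DoseResponseSeries | None = None,
                 level: float = 0.95) -> Ec50Estimate:
    """Delta-method CI on log(EC50), back-transformed to mg SEQ/mL."""
    endpoint = series.endpoint if series is not None else ""
    fpg = series.fpg if series is not None else False
    if not model.estimable:
        return Ec50Estimate(None, None, False, endpoint, fpg, reason=model.reason)
    if not np.isfinite(model.log_ec50_se):
        return Ec50Estimate(None, None, False, endpoint, fpg,
                            reason="singular information matrix")
    z = stats.norm.ppf(0.5 + level / 2.0)
    loge = np.log(model.ec50)
    lo = float(np.exp(loge - z * model.log_ec50_se))
    hi = float(np.exp(loge + z * model.log_ec50_se))
    return Ec50Estimate(model.ec50, (lo, hi), True, endpoint, fpg)


def estimate_ec50(series: DoseResponseSeries,
                  direction: str | None = None) -> Ec50Estimate:
    """Fit and summarize in one step: the common entry point."""
    model = fit_log_logistic(series, direction)
    return ec50_with_ci(model, series)


def fold_change_fpg(ec50_standard: Ec50Estimate, ec50_fpg: Ec50Estimate) -> float:
    """EC50 ratio standard/FPG: >1 means FPG treatment reveals extra (oxidative) damage."""
    if not (ec50_standard.estimable and ec50_fpg.estimable):
        raise ValueError("fold change undefined: at least one EC50 is non-estimable")
    return ec50_standard.point / ec50_fpg.point
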