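"""Incubation kinetics, control correction and stoichiometry tests.

Fits the two growth/consumption models used for anoxic batch incubations of
iron(III)-oxide-amended cultures:

* first-order decay of dissolved sulfide, C(t) = C0*exp(-k*t), by nonlinear
  least squares;
* specific growth rate k (per day) by ordinary least squares on
  ln(N_t / N_0) versus time over an exponential-phase window.

Product time series (sulfate, Fe(II)) are corrected against control
incubations point by point, and observed Fe(II):sulfate formation ratios are
compared with the ratio predicted from the electron balance of the assumed
reaction (8 for complete sulfide oxidation to sulfate, since Fe(III)->Fe(II)
takes one electron per iron).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .energetics import Reaction


@dataclass(frozen=True)
class TimeSeries:
    """One replicate measurement series (time strictly increasing)."""

    time: np.ndarray
    value: np.ndarray
    unit: str = ""
    analyte: str = ""
    condition: str = ""
    replicate: str = "1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "value", np.asarray(self.value, dtype=float))
        if self.time.shape != self.value.shape or self.time.ndim != 1:
            raise ValueError("time and value must be 1-D arrays of equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing within a replicate")
        if np.any(self.value < 0):
            raise ValueError("values must be non-negative")


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit C(t) = C0*exp(-k*t)."""

    c0: float
    k: float               # h^-1 (or 1/time-unit of the series)
    k_stderr: float
    c0_stderr: float
    rmse: float
    n: int

    def predict(self, t):
        return self.c0 * np.exp(-self.k * np.asarray(t, dtype=float))


def fit_first_order(ts: TimeSeries) -> DecayFit:
    """Nonlinear least-squares fit of the first-order decay model.

    The rate constant is constrained to k >= 0; a series that does not decay
    raises a warning and returns k ~ 0.  Starting values come from a
    log-linear regression when all values are positive, which makes the fit
    exact on noiseless exponential data.
    """
    t, v = ts.time, ts.value
    if len(t) < 3:
        raise ValueError("need at least 3 time points")
    if v[0] <= 0:
        raise ValueError("initial value must be positive")
    if v[-1] >= v[0]:
        warnings.warn("series does not decay; k will be ~0", stacklevel=2)
    if np.all(v > 0):
        slope, intercept = np.polyfit(t, np.log(v), 1)
        p0 = (float(np.exp(intercept)), float(max(-slope, 0.0)))
    else:
        p0 = (float(v[0]), 1.0 / (t[-1] - t[0]))

    def model(tt, c0, k):
        return c0 * np.exp(-k * tt)

    popt, pcov = optimize.curve_fit(model, t, v, p0=p0,
                                    bounds=([0.0, 0.0], [np.inf, np.inf]),
                                    maxfev=10000)
    c0, k = popt
    perr = np.sqrt(np.diag(pcov))
    resid = v - model(t, *popt)
    return DecayFit(c0=float(c0), k=float(k), k_stderr=float(perr[1]),
                    c0_stderr=float(perr[0]),
                    rmse=float(np.sqrt(np.mean(resid ** 2))), n=len(t))


@dataclass(frozen=True)
class GrowthFit:
    """Specific growth rate from ln(N_t/N_0) ~ time regression."""

    k: float          # day^-1 (or 1/time-unit of the series)
    k_stderr: float
    intercept: float
    r_squared: float
    window: tuple[float, float]
    n: int


def fit_growth_rate(ts: TimeSeries,
                    window: tuple[float, float] | None = None) -> GrowthFit:
    """OLS slope of ln(N_t/N_0) versus time; ``window`` restricts the fit to
    an apparent exponential phase (defaults to the full series)."""
    t, v = ts.time, ts.value
    if np.any(v <= 0):
        raise ValueError("cell densities must be positive")
    if window is not None:
        lo, hi = window
        if not (t[0] <= lo < hi <= t[-1]):
            raise ValueError("window must lie within the observed time span")
        mask = (t >= lo) & (t <= hi)
        t, v = t[mask], v[mask]
    if len(t) < 3:
        raise ValueError("need at least 3 time points in the fit window")
    y = np.log(v / ts.value[0])
    res = stats.linregress(t, y)
    return GrowthFit(k=float(res.slope), k_stderr=float(res.stderr),
                     intercept=float(res.intercept),
                     r_squared=float(res.rvalue ** 2),
                     window=(float(t[0]), float(t[-1])), n=len(t))


@dataclass(frozen=True)
class CorrectedDeltas:
    """Control-corrected concentration changes relative to t = 0."""

    time: np.ndarray
    delta: np.ndarray  # (treatment - treatment0) - (control - control0)


def control_correct(treatment: TimeSeries, control: TimeSeries,
                    interpolate: bool = False) -> CorrectedDeltas:
    """Subtract the control's change from the treatment's change per point.

    With ``interpolate=True`` the control is linearly interpolated onto the
    treatment time grid; the grids must then overlap the treatment span.
    Negative corrected deltas are preserved, not clipped.
    """
    t = treatment.time
    if np.array_equal(t, control.time):
        c = control.value
    elif interpolate:
        if t[0] < control.time[0] or t[-1] > control.time[-1]:
            raise ValueError("treatment times fall outside the control range")
        c = np.interp(t, control.time, control.value)
    else:
        raise ValueError("time grids differ; pass interpolate=True")
    delta = (treatment.value - treatment.value[0]) - (c - c[0])
    return CorrectedDeltas(time=t.copy(), delta=delta)


def predicted_ratio(reaction: Reaction, product: str | None = None) -> float:
    """Fe(II):product formation ratio implied by the reaction's electron
    balance (the coefficient ratio of the balanced reaction).

    The product defaults to the oxidized carbon/sulfur end product present in
    the stoichiometry (sulfate, then CO2, then elemental sulfur).
    """
    stoich = reaction.stoichiometry
    if "Fe2+" not in stoich or stoich["Fe2+"] <= 0:
        raise ValueError("reaction does not produce Fe2+")
    if product is None:
        for cand in ("SO4-2", "CO2", "S0"):
            if stoich.get(cand, 0) > 0:
                product = cand
                break
        else:
            raise ValueError("no recognised oxidized product in reaction")
    if stoich.get(product, 0) <= 0:
        raise ValueError(f"reaction does not produce {product!r}")
    return stoich["Fe2+"] / stoich[product]


@dataclass(frozen=True)
class StoichiometryResult:
    delta_product: float       # corrected product change, uM
    delta_fe2: float           # corrected Fe(II) change, uM
    observed_ratio: float      # Fe(II) : product
    predicted: float           # from the reaction electron balance
    per_cell_rate_fmol_h: float | None


def stoichiometric_ratio(product_treatment: TimeSeries,
                         product_control: TimeSeries,
                         fe2_treatment: TimeSeries,
                         fe2_control: TimeSeries,
                         reaction: Reaction,
                         product: str | None = None,
                         interpolate: bool = False,
                         cell_density: float | None = None,
                         ) -> StoichiometryResult:
    """Observed vs predicted Fe(II):product ratio at the final time point.

    Both analytes are control-corrected first.  When a cell density
    (cells/ml) is given, the per-cell product formation rate over the series
    span is reported as well.
    """
    dp = control_correct(product_treatment, product_control, interpolate)
    df = control_correct(fe2_treatment, fe2_control, interpolate)
    delta_p, delta_f = float(dp.delta[-1]), float(df.delta[-1])
    if delta_p <= 0:
        raise ValueError("corrected product change is not positive")
    rate = None
    if cell_density is not None:
        span = float(dp.time[-1] - dp.time[0])
        rate = per_cell_rate(delta_p, span, cell_density)
    return StoichiometryResult(delta_product=delta_p, delta_fe2=delta_f,
                               observed_ratio=delta_f / delta_p,
                               predicted=predicted_ratio(reaction, product),
                               per_cell_rate_fmol_h=rate)


def per_cell_rate(delta_umolar: float, delta_t_h: float,
                  cells_per_ml: float) -> float:
    """Per-cell formation rate in fmol cell^-1 h^-1.

    1 uM = 1 umol/L = 1e6 fmol/ml, hence
    rate = delta[uM] * 1e6 / (cells_per_ml * delta_t[h]).
    """
    if delta_t_h <= 0:
        raise ValueError("time interval must be positive")
    if cells_per_ml <= 0:
        raise ValueError("cell density must be positive")
    if delta_umolar < 0:
        raise ValueError("concentration change must be non-negative")
    return delta_umolar * 1e6 / (cells_per_ml * delta_t_h)


def summarize_rate_constants(fits: Sequence["DecayFit | GrowthFit"]) -> tuple[float, float]:
    """Mean and SD (n-1) of per-replicate rate constants."""
    ks = np.array([f.k for f in fits], dtype=float)
    if len(ks) == 0:
        raise ValueError("no fits supplied")
    sd = float(ks.std(ddof=1)) if len(ks) > 1 else 0.0
    return float(ks.mean()), sd
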