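"""Hill concentration-response fitting and functional-assay rate extraction.

Covers the three follow-up readouts of a lifetime-FRET screen:

* **Hill fits** of response vs compound concentration (EC50, molar) or vs
  pCa = -log10[Ca2+] (pCa50, the apparent calcium affinity), four-parameter
  by default (midpoint, Hill coefficient, both plateaus), with standard
  errors from the least-squares covariance;
* **pCa50 shifts** between two constructs, with SEs combined in quadrature —
  the statistic that quantifies phospholamban's inhibitory effect on the
  calcium pump's apparent affinity;
* **initial-rate extraction** from Ca-uptake fluorescence traces and from
  NADH-coupled ATPase A340 time courses (rate = -dA340/dt / (epsilon * l),
  NADH extinction 6220 /M/cm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import hill_curve

__all__ = [
    "HillFit",
    "UptakeRate",
    "hill_fit",
    "pca50_shift",
    "uptake_initial_rate",
    "atpase_rate_from_a340",
    "NADH_EXTINCTION_M_CM",
]

NADH_EXTINCTION_M_CM = 6220.0  # 340 nm molar extinction of NADH, /M/cm


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill model with standard errors.

    ``midpoint`` is pCa50 in pCa mode and EC50 (molar) in concentration
    mode.  ``saturated`` is False when the upper-plateau SE exceeds the
    plateau estimate itself — the response never levelled off, so the
    midpoint extrapolates beyond the data.
    """

    midpoint: float
    n_hill: float
    lower: float
    upper: float
    se_midpoint: float
    se_n_hill: float
    se_lower: float
    se_upper: float
    x_mode: str
    rss: float
    n_obs: int
    saturated: bool

    @property
    def pca50(self) -> float:
        if self.x_mode == "pCa":
            return self.midpoint
        return -np.log10(self.midpoint)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return hill_curve(x, self.midpoint, self.n_hill, self.lower, self.upper, self.x_mode)


@dataclass(frozen=True)
class UptakeRate:
    """Initial rate from a linear fit to the early part of a time course."""

    rate: float  # signal units / s, positive for uptake
    se_rate: float
    window_s: tuple[float, float]
    r_squared: float


def _as_xy(data: pd.DataFrame | tuple) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        return data["x_value"].to_numpy(float), data["response"].to_numpy(float)
    x, y = data
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def hill_fit(
    data: pd.DataFrame | tuple,
    x_mode: str = "pCa",
    fix_lower: float | None = None,
) -> HillFit:
    """Least-squares Hill fit.

    ``data`` is either the long-format table produced by the simulator
    (columns x_value, response; replicates as repeated x) or an ``(x, y)``
    pair.  In pCa mode the sigmoid falls with pCa and the midpoint is the
    pCa50; in concentration mode fitting is performed in log10(x) for
    stability and the midpoint is reported as EC50 in the original molar
    units.  ``fix_lower`` pins the lower plateau (three-parameter fit).

    A monotonicity violation beyond noise (e.g. a biphasic response) only
    warns — the Hill model is still fit, and the caller should inspect the
    residuals; biphasic/bell-shaped models are out of scope.
    """
    if x_mode not in ("pCa", "concentration"):
        raise ValueError("x_mode must be 'pCa' or 'concentration'")
    x, y = _as_xy(data)
    xs = np.unique(x)
    if xs.size < 5:
        raise ValueError(f"need at least 5 distinct x values, got {xs.size}")

    # crude monotonicity check on replicate means along the response axis
    means = np.array([y[x == xi].mean() for xi in xs])
    resid_sd = float(np.std(y - np.array([means[np.searchsorted(xs, xi)] for xi in x]))) or 1e-12
    diffs = np.diff(means)
    if diffs.size and np.any(diffs > 3 * resid_sd) and np.any(diffs < -3 * resid_sd):
        warnings.warn(
            "response is non-monotone beyond noise (biphasic?); "
            "a single Hill curve may fit poorly",
            stacklevel=2,
        )

    span = float(means.max() - means.min()) or 1.0
    if x_mode == "pCa":
        u = x
        mid0 = float(xs[np.argmin(np.abs(means - (means.max() + means.min()) / 2))])

        def model(u, mid, nh, lo, hi):
            return hill_curve(u, mid, nh, lo, hi, "pCa")

        bounds_mid = (u.min() - 5.0, u.max() + 5.0)
    else:
        if np.any(x <= 0):
            raise ValueError("concentrations must be > 0 in concentration mode")
        u = np.log10(x)
        mid0 = float(u[np.argmin(np.abs(y - (means.max() + means.min()) / 2))])

        def model(u, mid, nh, lo, hi):
            # Hill in log10 concentration: midpoint is log10(EC50)
            return lo + (hi - lo) / (1.0 + 10.0 ** (nh * (mid - u)))

        bounds_mid = (u.min() - 5.0, u.max() + 5.0)

    lo0 = float(means.min()) if fix_lower is None else fix_lower
    hi0 = float(means.max())
    p0 = [mid0, 1.5, lo0, hi0]
    lower_b = [bounds_mid[0], 0.05, -np.inf, -np.inf]
    upper_b = [bounds_mid[1], 20.0, np.inf, np.inf]
    if fix_lower is not None:
        def model3(u, mid, nh, hi, _m=model):
            return _m(u, mid, nh, fix_lower, hi)

        popt, pcov = optimize.curve_fit(
            model3, u, y, p0=[mid0, 1.5, hi0],
            bounds=([lower_b[0], 0.05, -np.inf], [upper_b[1], 20.0, np.inf]),
            maxfev=20000,
        )
        mid, nh, hi = popt
        lo, se_lo = fix_lower, 0.0
        perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
        se_mid, se_nh, se_hi = perr
    else:
        popt, pcov = optimize.curve_fit(
            model, u, y, p0=p0, bounds=(lower_b, upper_b), maxfev=20000
        )
        mid, nh, lo, hi = popt
        perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
        se_mid, se_nh, se_lo, se_hi = perr

    resid = y - model(u, mid, nh, lo, hi) if fix_lower is None else y - model3(u, mid, nh, hi)
    rss = float(resid @ resid)
    saturated = bool(se_hi <= abs(hi)) if abs(hi) > 0 else bool(se_hi <= span)

    if x_mode == "concentration":
        ec50 = 10.0 ** mid
        se_ec50 = float(ec50 * np.log(10.0) * se_mid)  # delta method
        midpoint, se_midpoint = float(ec50), se_ec50
    else:
        midpoint, se_midpoint = float(mid), float(se_mid)

    return HillFit(
        midpoint=midpoint,
        n_hill=float(nh),
        lower=float(lo),
        upper=float(hi),
        se_midpoint=se_midpoint,
        se_n_hill=float(se_nh),
        se_lower=float(se_lo),
        se_upper=float(se_hi),
        x_mode=x_mode,
        rss=rss,
        n_obs=int(y.size),
        saturated=saturated,
    )


def pca50_shift(fit_a: HillFit, fit_b: HillFit) -> tuple[float, float]:
    """pCa50 difference (a minus b) with SE combined in quadrature.

    Both fits must be in pCa mode; use ``HillFit.pca50`` conversions first
    if one was fit against molar concentration.
    """
    if fit_a.x_mode != "pCa" or fit_b.x_mode != "pCa":
        raise ValueError("both fits must be in pCa mode")
    shift = fit_a.midpoint - fit_b.midpoint
    se = float(np.hypot(fit_a.se_midpoint, fit_b.se_midpoint))
    return float(shift), se


def uptake_initial_rate(
    trace: pd.DataFrame,
    window_s: float | None = None,
) -> UptakeRate:
    """Initial Ca-uptake rate: minus the slope of a linear fit after ATP addition.

    ``trace`` has columns time_s, fluorescence, starting at reaction start.
    The default window is the first 20% of the trace.
    """
    t = trace["time_s"].to_numpy(float)
    y = trace["fluorescence"].to_numpy(float)
    total = t[-1] - t[0]
    if window_s is None:
        window_s = 0.2 * total
    if window_s > total:
        raise ValueError(f"window {window_s} s exceeds trace duration {total} s")
    sel = t <= t[0] + window_s
    if sel.sum() < 3:
        raise ValueError("window contains fewer than 3 samples")
    res = stats.linregress(t[sel], y[sel])
    return UptakeRate(
        rate=float(-res.slope),
        se_rate=float(res.stderr),
        window_s=(float(t[0]), float(t[0] + window_s)),
        r_squared=float(res.rvalue**2) if np.std(y[sel]) > 0 else 1.0,
    )


def atpase_rate_from_a340(
    trace: pd.DataFrame,
    window_s: float | None = None,
    extinction_m_cm: float = NADH_EXTINCTION_M_CM,
    path_cm: float = 0.55,
) -> UptakeRate:
    """ATP-hydrolysis rate from an NADH-coupled A340 time course.

    Each ATP hydrolysed regenerates one NADH oxidation, so the hydrolysis
    rate in molar/s is  -dA340/dt / (extinction * path length).  ``trace``
    has columns time_s, a340.  The default path length (0.55 cm) suits a
    200 uL well in a 96-well plate; warns if the windowed trace rises.
    """
    t = trace["time_s"].to_numpy(float)
    a = trace["a340"].to_numpy(float)
    total = t[-1] - t[0]
    if window_s is None:
        window_s = 0.5 * total
    if window_s > total:
        raise ValueError(f"window {window_s} s exceeds trace duration {total} s")
    sel = t <= t[0] + window_s
    res = stats.linregress(t[sel], a[sel])
    if res.slope > 0 and res.slope > 2 * (res.stderr or 0):
        warnings.warn("A340 rises in the fit window; NADH-coupled trace should fall",
                      stacklevel=2)
    rate_m_per_s = -res.slope / (extinction_m_cm * path_cm)
    se = (res.stderr or 0.0) / (extinction_m_cm * path_cm)
    return UptakeRate(
        rate=float(rate_m_per_s),
        se_rate=float(se),
        window_s=(float(t[0]), float(t[0] + window_s)),
        r_squared=float(res.rvalue**2) if np.std(a[sel]) > 0 else 1.0,
    )
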