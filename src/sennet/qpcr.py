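"""Cy0 quantification of qPCR amplification curves.

A 5-parameter Richards sigmoid

    F(x) = Fb + Fmax * (1 + exp(-(x - c)/b))**(-d)

is fitted to each fluorescence curve by nonlinear least squares; the Cy0
value is the cycle at which the tangent drawn at the curve's inflection
point crosses the baseline Fb. Unlike threshold-cycle methods, Cy0
depends on the curve's kinetics (shape), not on an arbitrary fluorescence
threshold, so differences in Cy0 across genotypes or time points reflect
differences in amplification kinetics.

For this parameterization the inflection point is ``x* = c + b*ln(d)``
and Cy0 has the closed form ``x* − b*(1 + 1/d)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .dataset import ValidationError
from .synthetic import richards


@dataclass
class RichardsFit:
    fmax: float
    b: float
    c: float
    d: float
    fb: float
    residual_rms: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.fmax, self.b, self.c, self.d, self.fb)


def fit_richards(cycles: np.ndarray, fluorescence: np.ndarray) -> RichardsFit:
    """Nonlinear least-squares fit of the Richards amplification model.

    Initialization from the data: Fb = min, Fmax = range, c = cycle at
    half-range, b = 2, d = 1. Flat curves (max/min ratio < 5 after
    baseline shift) are rejected as "no amplification".
    """
    x = np.asarray(cycles, dtype=float)
    y = np.asarray(fluorescence, dtype=float)
    if x.size < 15:
        raise ValidationError("need >= 15 cycles to fit")
    lo, hi = float(y.min()), float(y.max())
    # ratio guard on positive-shifted signal so negative baselines behave
    shift = -lo + 1.0 if lo <= 0 else 0.0
    if (hi + shift) / (lo + shift) < 5.0:
        raise ValidationError("no amplification: max/min fluorescence ratio < 5")
    half = lo + 0.5 * (hi - lo)
    c0 = float(x[np.argmin(np.abs(y - half))])
    p0 = [hi - lo, 2.0, c0, 1.0, lo]
    bounds = ([1e-9, 1e-3, x.min() - 10, 1e-3, -np.inf], [np.inf, 50.0, x.max() + 10, 50.0, np.inf])
    try:
        popt, _ = curve_fit(richards, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as err:  # pragma: no cover - scipy message passthrough
        raise ValidationError(f"fit did not converge: {err}") from err
    resid = y - richards(x, *popt)
    return RichardsFit(*map(float, popt), residual_rms=float(np.sqrt(np.mean(resid**2))))


def compute_cy0(fit: RichardsFit) -> float:
    """Tangent-intercept Cy0 of a fitted curve.

    The tangent at the inflection ``x* = c + b*ln(d)`` is extended to the
    baseline Fb; its crossing cycle is
    ``Cy0 = x* − (F(x*) − Fb)/F'(x*) = c + b*ln(d) − b*(1 + 1/d)``.
    """
    if fit.b <= 0 or fit.d <= 0 or fit.fmax <= 0:
        raise ValidationError("invalid fitted parameters (Fmax, b, d must be > 0)")
    return float(fit.c + fit.b * np.log(fit.d) - fit.b * (1.0 + 1.0 / fit.d))


def quantify_curves(table: pd.DataFrame) -> pd.DataFrame:
    """Fit every well in a long-format (well, cycle, fluorescence) table.

    Returns one row per well with fitted parameters, RMS residual and Cy0;
    wells that fail the amplification guard are reported with NaNs and an
    ``error`` message.
    """
    rows = []
    for well, sub in table.groupby("well", sort=True):
        sub = sub.sort_values("cycle")
        try:
            fit = fit_richards(sub["cycle"].to_numpy(), sub["fluorescence"].to_numpy())
            cy0 = compute_cy0(fit)
            in_range = sub["cycle"].min() <= cy0 <= sub["cycle"].max()
            rows.append(
                {
                    "well": well, "fmax": fit.fmax, "b": fit.b, "c": fit.c,
                    "d": fit.d, "fb": fit.fb, "residual_rms": fit.residual_rms,
                    "cy0": cy0, "cy0_in_range": in_range, "error": "",
                }
            )
        except ValidationError as err:
            rows.append(
                {
                    "well": well, "fmax": np.nan, "b": np.nan, "c": np.nan,
                    "d": np.nan, "fb": np.nan, "residual_rms": np.nan,
                    "cy0": np.nan, "cy0_in_range": False, "error": str(err),
                }
            )
    return pd.DataFrame(rows)
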