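"""Four-parameter-logistic (4PL) standard curves and inverse prediction.

ELISA optical densities follow the sigmoid
``OD = d + (a - d) / (1 + (x/c)^b)`` with lower asymptote ``d``, upper
asymptote ``a``, inflection concentration ``c`` and slope ``b``. Sample
concentrations are recovered by the analytic inverse
``x = c * ((a - d)/(OD - d) - 1)^(1/b)`` and multiplied by the dilution
factor. A dilution written "1:n" is read as (n+1)-fold by default (sample
plus n parts diluent), with a ``convention="n-fold"`` override; the parser
logs which reading it used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InvalidParameterError, OutOfRangeError

__all__ = ["Curve4PL", "four_pl", "fit_4pl", "concentration_from_od", "parse_dilution"]

logger = logging.getLogger(__name__)


def four_pl(x, a, d, c, b):
    """Evaluate the 4PL sigmoid at concentration(s) x.

    With b > 0 the response falls from a at x=0 toward d; with b < 0 it
    rises from d toward a (the usual ELISA orientation). x = 0 is handled
    as the appropriate limit.
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        t = np.where(x == 0, np.inf if b < 0 else 0.0, (x / c) ** b)
    return d + (a - d) / (1.0 + t)


@dataclass
class Curve4PL:
    """Fitted 4PL standard curve."""

    upper_asymptote: float  # a
    lower_asymptote: float  # d
    inflection: float       # c, concentration at the response midpoint
    slope: float            # b
    fit_stats: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.upper_asymptote == self.lower_asymptote:
            raise InvalidParameterError("asymptotes must differ")
        if not self.inflection > 0:
            raise InvalidParameterError("inflection concentration must be positive")

    def evaluate(self, x):
        return four_pl(x, self.upper_asymptote, self.lower_asymptote, self.inflection, self.slope)


def fit_4pl(standards) -> Curve4PL:
    """Least-squares 4PL fit to (concentration, OD) standards.

    Initialized from the data extremes (d = min OD, a = max OD, c =
    geometric mid-concentration, b = 1) with bounds keeping c > 0.
    """
    pts = [(float(x), float(y)) for x, y in standards]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if len(set(xs.tolist())) < 5:
        raise InvalidParameterError("need at least five distinct standard concentrations")
    if np.allclose(ys, ys[0]):
        raise FitFailureError("all ODs identical: the curve is degenerate")
    pos = xs[xs > 0]
    c0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    # slope sign from the observed trend: rising curves have b < 0 here
    trend = np.corrcoef(xs, ys)[0, 1]
    b0 = -1.0 if trend > 0 else 1.0
    p0 = [ys.max(), ys.min(), c0, b0]
    lo = [-np.inf, -np.inf, 1e-12, -np.inf]
    hi = [np.inf, np.inf, np.inf, np.inf]
    try:
        popt, pcov = curve_fit(four_pl, xs, ys, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError(f"4PL fit did not converge: {exc}") from exc
    if not np.all(np.isfinite(popt)):
        raise FitFailureError("4PL fit returned non-finite parameters")
    resid = ys - four_pl(xs, *popt)
    a, d, c, b = popt
    if a < d:  # canonical orientation: a = upper asymptote
        a, d, b = d, a, -b
    curve = Curve4PL(
        upper_asymptote=float(a),
        lower_asymptote=float(d),
        inflection=float(c),
        slope=float(b),
        fit_stats={
            "rss": float((resid**2).sum()),
            "rmse": float(np.sqrt((resid**2).mean())),
            "n": len(pts),
        },
    )
    fitted = curve.evaluate(np.sort(np.unique(xs[xs > 0])))
    diffs = np.diff(fitted)
    if np.any(diffs > 1e-9) and np.any(diffs < -1e-9):
        logger.warning("fitted 4PL is not monotone over the standards' range")
    return curve


def concentration_from_od(curve: Curve4PL, od: float, dilution_factor: float = 1.0) -> float:
    """Invert the standard curve at one OD and correct for dilution.

    Raises OutOfRangeError (side "below"/"above") for ODs outside the open
    interval between the asymptotes, i.e. outside the quantifiable range.
    """
    if dilution_factor < 1:
        raise InvalidParameterError("dilution_factor must be >= 1")
    a, d, c, b = curve.upper_asymptote, curve.lower_asymptote, curve.inflection, curve.slope
    lo, hi = (d, a) if a > d else (a, d)
    if od <= lo:
        raise OutOfRangeError(f"OD {od} at/below the lower asymptote {lo}", side="below")
    if od >= hi:
        raise OutOfRangeError(f"OD {od} at/above the upper asymptote {hi}", side="above")
    x = c * ((a - d) / (od - d) - 1.0) ** (1.0 / b)
    return float(x * dilution_factor)


def parse_dilution(text, convention: str = "plus-one") -> float:
    """Turn a dilution annotation like "1:4" into a numeric factor.

    convention="plus-one" (default): "1:n" means one part sample in n parts
    diluent, i.e. an (n+1)-fold dilution. convention="n-fold": "1:n" is an
    n-fold dilution. Plain numbers pass through unchanged.
    """
    if isinstance(text, (int, float)):
        return float(text)
    text = str(text).strip()
    if ":" in text:
        one, n = text.split(":")
        if float(one) != 1:
            raise InvalidParameterError(f"unsupported dilution notation {text!r}")
        n = float(n)
        factor = n + 1.0 if convention == "plus-one" else n
        logger.info("dilution %r read as %g-fold (%s convention)", text, factor, convention)
        return factor
    return float(text)
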