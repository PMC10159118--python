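"""Regression of proteome/protein quantities on GC content, significance codes,
and the biased-COG call.

Fits are ordinary least squares of a response (an amino-acid frequency,
a conformational parameter, a structure fraction, ...) on GC content
expressed as a fraction.  The slope p-value is the two-sided t-test on
the slope (degree 1) or on the highest-order coefficient (degree 2);
``degree="auto"`` keeps the quadratic term only when an F-test at 0.05
says it improves on the line.  p-values map to the R-style significance
codes ***, **, *, '.', ' ' at breakpoints 0.001 / 0.01 / 0.05 / 0.1
(left-open, right-closed).

A COG is called GC-biased when, regressing its members' helix, sheet and
coil fractions on their genes' GC content, at least two of the three
slope p-values fall below 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .structure import SSComposition

SIGNIF_BREAKS = (0.001, 0.01, 0.05, 0.1)
SIGNIF_CODES = ("***", "**", "*", ".", " ")

#: p-value threshold of the biased-COG rule.
COG_BIAS_ALPHA = 0.001
#: How many of the three structure fits must cross it.
COG_BIAS_MIN_SIGNIFICANT = 2
#: Minimum members required to fit a COG at all.
DEFAULT_MIN_MEMBERS = 10


class RegressionError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionResult:
    """An OLS fit of a response against GC content (as a fraction)."""

    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n: int
    degree: int
    signif: str
    coefficients: tuple[float, ...]  # ascending powers
    zero_variance: bool = False

    @property
    def slope_per_percent(self) -> float:
        """Slope per GC percentage point, the scale printed in output tables."""
        return self.slope / 100.0

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, float), self.coefficients)


@dataclass(frozen=True)
class COGBiasCall:
    """Per-COG structure-vs-GC regressions and the biased/unbiased verdict."""

    cog_id: str
    helix: RegressionResult
    sheet: RegressionResult
    coil: RegressionResult
    biased: bool

    @property
    def fits(self) -> dict[str, RegressionResult]:
        return {"helix": self.helix, "sheet": self.sheet, "coil": self.coil}


def signif_code(p: float) -> str:
    """R-style significance code for a p-value.

    p <= 0.001 -> '***', <= 0.01 -> '**', <= 0.05 -> '*', <= 0.1 -> '.',
    else ' '.
    """
    if not (0.0 <= p <= 1.0) or math.isnan(p):
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    for brk, code in zip(SIGNIF_BREAKS, SIGNIF_CODES):
        if p <= brk:
            return code
    return SIGNIF_CODES[-1]


def fit_linear(
    x: Sequence[float],
    y: Sequence[float],
    degree: Literal[1, 2, "auto"] = 1,
) -> RegressionResult:
    """OLS fit of y on x with degree 1 or 2 (or F-test-selected "auto").

    Degree 1 uses the closed-form simple regression; degree 2 regresses
    on (x, x^2) and tests the quadratic coefficient.  A response with
    zero variance returns slope 0 and p-value 1, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise RegressionError("x and y must be equal-length 1-D vectors")
    if degree == "auto":
        return _auto_fit(x, y)
    if degree not in (1, 2):
        raise RegressionError(f"degree must be 1, 2 or 'auto', got {degree!r}")
    n_min = degree + 2
    if x.size < n_min:
        raise RegressionError(f"need at least {n_min} points for degree {degree}")
    if np.ptp(x) == 0:
        raise RegressionError("x values are all identical")
    if np.ptp(y) == 0:
        coefs = (float(y[0]),) + (0.0,) * degree
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), p_value=1.0, r_squared=0.0,
            n=x.size, degree=degree, signif=signif_code(1.0),
            coefficients=coefs, zero_variance=True,
        )
    if degree == 1:
        res = stats.linregress(x, y)
        p = float(res.pvalue)
        return RegressionResult(
            slope=float(res.slope), intercept=float(res.intercept),
            p_value=p, r_squared=float(res.rvalue) ** 2, n=x.size, degree=1,
            signif=signif_code(p),
            coefficients=(float(res.intercept), float(res.slope)),
        )
    model = sm.OLS(y, sm.add_constant(np.column_stack([x, x**2]))).fit()
    p = float(model.pvalues[2])  # highest-order coefficient
    b0, b1, b2 = (float(c) for c in model.params)
    return RegressionResult(
        slope=b1, intercept=b0, p_value=p, r_squared=float(model.rsquared),
        n=x.size, degree=2, signif=signif_code(p), coefficients=(b0, b1, b2),
    )


def _auto_fit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Degree 1 unless the quadratic term survives an F-test at 0.05."""
    lin = fit_linear(x, y, degree=1)
    if x.size < 4 or lin.zero_variance:
        return lin
    quad = fit_linear(x, y, degree=2)
    rss1 = float(np.sum((y - lin.predict(x)) ** 2))
    rss2 = float(np.sum((y - quad.predict(x)) ** 2))
    df2 = x.size - 3
    if rss2 <= 0 or df2 <= 0:
        return quad if rss2 < rss1 else lin
    f = (rss1 - rss2) / (rss2 / df2)
    p_f = float(stats.f.sf(f, 1, df2))
    return quad if p_f < 0.05 else lin


def regression_table(
    fits: dict[str, RegressionResult], slope_per_percent: bool = True
) -> pd.DataFrame:
    """Summary table of named fits; slopes per GC percentage point by default."""
    rows = []
    for name, r in fits.items():
        rows.append(
            {
                "response_id": name,
                "n": r.n,
                "degree": r.degree,
                "slope": r.slope_per_percent if slope_per_percent else r.slope,
                "intercept": r.intercept,
                "p_value": r.p_value,
                "r2": r.r_squared,
                "signif_code": r.signif,
            }
        )
    return pd.DataFrame(rows).set_index("response_id")


def call_cog_bias(
    cog_id: str,
    members: Sequence[tuple[float, SSComposition]],
    min_members: int = DEFAULT_MIN_MEMBERS,
) -> COGBiasCall:
    """Classify one COG as GC-biased or not from (gene GC, composition) pairs.

    Three degree-1 fits (helix, sheet, coil fraction vs gene GC); biased
    iff at least two of the three slope p-values are below 0.001.
    """
    if len(members) < min_members:
        raise RegressionError(
            f"COG {cog_id}: {len(members)} members < floor {min_members}"
        )
    gc = np.array([m[0] for m in members], dtype=float)
    fits = {}
    for attr in ("frac_helix", "frac_sheet", "frac_coil"):
        y = np.array([getattr(m[1], attr) for m in members], dtype=float)
        fits[attr] = fit_linear(gc, y, degree=1)
    n_sig = sum(f.p_value < COG_BIAS_ALPHA for f in fits.values())
    return COGBiasCall(
        cog_id=cog_id,
        helix=fits["frac_helix"],
        sheet=fits["frac_sheet"],
        coil=fits["frac_coil"],
        biased=n_sig >= COG_BIAS_MIN_SIGNIFICANT,
    )


def cog_bias_table(calls: Sequence[COGBiasCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "cog_id": c.cog_id,
                "n_members": c.helix.n,
                "slope_helix": c.helix.slope_per_percent,
                "slope_sheet": c.sheet.slope_per_percent,
                "slope_coil": c.coil.slope_per_percent,
                "p_helix": c.helix.p_value,
                "p_sheet": c.sheet.p_value,
                "p_coil": c.coil.p_value,
                "biased": c.biased,
            }
        )
    return pd.DataFrame(rows).set_index("cog_id")
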