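"""Amplification-efficiency estimation from serial-dilution standard curves.

A template diluted 10-fold per step shifts Cp by log2(10) ~ 3.32 cycles when
amplification exactly doubles per cycle.  Regressing Cp on log10 template
amount therefore gives a slope near -3.32; efficiency follows from
E = 10^(-1/slope) - 1 (100% = perfect doubling).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DilutionSeries:
    """Mean Cp per point of a serial dilution of one gene's template."""

    gene: str
    dilution_factors: tuple[float, ...]
    cp: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.dilution_factors, float)
        c = np.asarray(self.cp, float)
        if d.size != c.size:
            raise ValueError("dilution_factors and cp differ in length")
        if d.size < 3:
            raise ValueError("a standard curve needs at least 3 points")
        if np.any(d <= 0):
            raise ValueError("dilution factors must be positive")
        if np.any(np.diff(d) <= 0):
            raise ValueError("dilution factors must be strictly increasing")
        if not np.all(np.isfinite(c)):
            raise ValueError("Cp values must be finite")


@dataclass(frozen=True)
class EfficiencyFit:
    """OLS standard-curve fit: slope/intercept in Cp per log10 template."""

    gene: str
    slope: float
    intercept: float
    e_percent: float
    r_squared: float
    valid: bool

    @property
    def e_fraction(self) -> float:
        return self.e_percent / 100.0


def fit_standard_curve(series: DilutionSeries,
                       x_is_log_template: bool = True) -> EfficiencyFit:
    """Fit Cp against log10 template amount by ordinary least squares.

    With ``x_is_log_template`` (default) x = -log10(dilution factor), so a
    valid curve has a negative slope and E% = (10^(-1/slope) - 1) * 100.
    The opposite sign convention (x = log10 dilution factor) is accepted via
    the flag; only |slope| enters E.  Fits with E% outside [90, 110] are
    logged as a warning; a slope of the wrong sign is flagged invalid.
    """
    x = np.log10(np.asarray(series.dilution_factors, float))
    if x_is_log_template:
        x = -x
    y = np.asarray(series.cp, float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10 dilution")
    res = stats.linregress(x, y)
    slope = res.slope if x_is_log_template else -res.slope
    valid = slope < 0
    if not valid:
        log.warning("%s: positive standard-curve slope %.3f (invalid fit)",
                    series.gene, slope)
        e_percent = float("nan")
    else:
        e_percent = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
        if not 90.0 <= e_percent <= 110.0:
            log.warning("%s: amplification efficiency %.2f%% outside [90, 110]",
                        series.gene, e_percent)
    return EfficiencyFit(
        gene=series.gene,
        slope=float(slope),
        intercept=float(res.intercept),
        e_percent=float(e_percent),
        r_squared=float(res.rvalue ** 2),
        valid=valid,
    )


def efficiency_report(fits: list[EfficiencyFit]) -> pd.DataFrame:
    """Tabulate fits, one row per gene (slope, E%, R^2, validity)."""
    return pd.DataFrame(
        [(f.gene, f.slope, f.intercept, f.e_percent, f.r_squared, f.valid)
         for f in fits],
        columns=["gene", "slope", "intercept", "e_percent", "r_squared",
                 "valid"],
    ).set_index("gene")
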