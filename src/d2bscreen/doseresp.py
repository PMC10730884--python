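"""Four-parameter logistic (4PL) dose-response fitting and CRBN dependence.

The same model serves viability curves (midpoint reported as EC50) and
immunoblot-quantified degradation curves (midpoint reported as DC50):

    response(c) = bottom + (top - bottom) / (1 + (c / ec50) ** hill)

Fitting is least squares on a log10(ec50) internal parameterization with
multi-start initialization across the dose range.  CRBN dependence of a
compound is tested by fitting wild-type and CRBN-knockout series on the
same dose grid: the knockout response is *abrogated* when its dynamic range
collapses (top - bottom < 0.2) or its midpoint shifts more than 100-fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DoseSeries",
    "FourPLFit",
    "CrbnDependence",
    "fit_4pl",
    "crbn_dependence",
    "four_pl",
]

RANGE_FLOOR = 0.2  # minimal top-bottom range for a meaningful midpoint
SHIFT_FOLD = 100.0  # ec50 fold-shift counting as abrogation


class DoseDataError(ValueError):
    pass


@dataclass(frozen=True)
class DoseSeries:
    compound_id: str
    cell_line: str
    concentrations: tuple[float, ...]  # mol/L, ascending
    responses: tuple[float, ...]  # viability fraction or normalized band intensity
    replicates: int = 1

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations)
        if len(c) != len(self.responses):
            raise DoseDataError("concentration/response length mismatch")
        if np.any(c <= 0):
            raise DoseDataError("concentrations must be strictly positive")
        if np.any(np.diff(c) < 0):
            raise DoseDataError("concentrations must be sorted ascending")
        if np.any(np.asarray(self.responses) < 0):
            raise DoseDataError("responses must be non-negative")


@dataclass(frozen=True)
class FourPLFit:
    top: float
    bottom: float
    ec50: float  # mol/L; reported as DC50 for degradation series
    hill: float
    rss: float
    converged: bool
    degenerate: bool = False
    extrapolated: bool = False


def four_pl(conc: np.ndarray, top: float, bottom: float, log10_ec50: float, hill: float) -> np.ndarray:
    """4PL response at the given concentrations (log10-midpoint parameterization)."""
    return bottom + (top - bottom) / (1.0 + (conc / 10.0 ** log10_ec50) ** hill)


def fit_4pl(series: DoseSeries) -> FourPLFit:
    """Least-squares 4PL fit with multi-start initialization.

    Requires at least four distinct concentrations.  A flat series (response
    range below 0.05) returns a degenerate fit whose midpoint is undefined
    (NaN).  The midpoint is flagged ``extrapolated`` when it falls outside
    [min dose / 10, max dose * 10].
    """
    conc = np.asarray(series.concentrations, dtype=float)
    resp = np.asarray(series.responses, dtype=float)
    if len(np.unique(conc)) < 4:
        raise DoseDataError("4PL fit needs >= 4 distinct concentrations")
    if resp.max() - resp.min() < 0.05:
        flat = float(resp.mean())
        return FourPLFit(
            top=flat, bottom=flat, ec50=float("nan"), hill=float("nan"),
            rss=float(np.sum((resp - flat) ** 2)), converged=True, degenerate=True,
        )

    lo, hi = np.log10(conc.min()), np.log10(conc.max())
    top0, bot0 = float(resp.max()), float(resp.min())
    starts = [
        (top0, bot0, mid, hill0)
        for mid in np.linspace(lo - 1, hi + 1, 7)
        for hill0 in (0.5, 1.0, 2.0)
    ]
    bounds = (
        [-0.5, -0.5, lo - 3, 0.05],
        [max(2.0, top0 * 2), max(2.0, top0 * 2), hi + 3, 20.0],
    )
    best: tuple[float, np.ndarray] | None = None
    converged = False
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                four_pl, conc, resp, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((four_pl(conc, *popt) - resp) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
            converged = True
    if best is None:
        flat = float(resp.mean())
        return FourPLFit(flat, flat, float("nan"), float("nan"),
                         float(np.sum((resp - flat) ** 2)), False, degenerate=True)
    rss, (top, bottom, log_ec50, hill) = best
    if bottom > top:  # canonical orientation: flip parameters, mirror slope
        top, bottom, hill = bottom, top, -hill
    ec50 = float(10.0 ** log_ec50)
    extrapolated = not (conc.min() / 10.0 <= ec50 <= conc.max() * 10.0)
    return FourPLFit(
        top=float(top), bottom=float(bottom), ec50=ec50, hill=float(hill),
        rss=rss, converged=converged, extrapolated=extrapolated,
    )


@dataclass(frozen=True)
class CrbnDependence:
    compound_id: str
    wt_fit: FourPLFit
    ko_fit: FourPLFit
    abrogated: bool


def crbn_dependence(wt: DoseSeries, ko: DoseSeries) -> CrbnDependence:
    """Fit wild-type and CRBN-knockout series and apply the abrogation rule.

    Both series must cover the same compound and dose grid.  Abrogation is
    declared when the knockout fit is degenerate, its response range is below
    0.2, or its midpoint is shifted more than 100-fold from wild type.
    """
    if wt.compound_id != ko.compound_id:
        raise DoseDataError("series compare different compounds")
    if tuple(wt.concentrations) != tuple(ko.concentrations):
        raise DoseDataError("dose grids differ between WT and KO series")
    wt_fit = fit_4pl(wt)
    ko_fit = fit_4pl(ko)
    if ko_fit.degenerate:
        abrogated = True
    elif (ko_fit.top - ko_fit.bottom) < RANGE_FLOOR:
        abrogated = True
    elif wt_fit.degenerate or np.isnan(wt_fit.ec50):
        abrogated = False
    else:
        abrogated = bool(ko_fit.ec50 / wt_fit.ec50 > SHIFT_FOLD)
    return CrbnDependence(wt.compound_id, wt_fit, ko_fit, abrogated)
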