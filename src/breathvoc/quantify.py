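"""Cross-platform quantitative intercomparison statistics.

Paired-response regression between two platforms (detector response on B
vs A across shared permeation loadings), replicate precision as relative
standard deviation, ICH-style detection limits from calibration slope and
blank noise, and per-sample chemical-class composition profiles of the
annotated VOCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, InputError, UndefinedStatisticError
from .records import CalibrationSeries

__all__ = [
    "fit_paired_response", "relative_sd", "lod_from_calibration",
    "class_composition", "CompositionProfile",
]


def fit_paired_response(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of platform-B responses on platform-A.

    Returns ``(slope, intercept, r_squared)``; this is the
    "correlation equation of intercomparison" between two instruments
    measuring the same loading series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise InputError("paired regression needs at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("non-finite responses in regression input")
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in x; fit is degenerate")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


def relative_sd(replicates) -> float:
    """Relative standard deviation (percent CV) of replicate responses."""
    r = np.asarray(replicates, dtype=float)
    if r.size < 2:
        raise InputError("RSD needs at least 2 replicates")
    mean = r.mean()
    if mean == 0:
        raise UndefinedStatisticError("mean response is zero; RSD undefined")
    return float(100.0 * r.std(ddof=1) / mean)


def lod_from_calibration(series: CalibrationSeries, blank_sd: float) -> float:
    """Limit of detection in ppbv from a calibration series.

    ``LOD = 3.3 * sigma_blank / slope`` on the loading axis (the
    ICH-style estimator), converted to a mixing ratio through the series'
    ``loading_to_ppbv`` factor. Strictly decreasing in slope, linear in
    blank noise.
    """
    if blank_sd < 0:
        raise InputError("blank standard deviation cannot be negative")
    slope, _, _ = fit_paired_response(series.loadings, series.responses)
    if slope <= 0:
        raise UndefinedStatisticError(
            f"calibration slope {slope:g} is not positive; LOD undefined"
        )
    return 3.3 * blank_sd / slope * series.loading_to_ppbv


@dataclass
class CompositionProfile:
    """Per-sample class percentages and their cohort summary.

    ``per_sample``: DataFrame indexed by sample, one column per class,
    rows summing to 100. ``cohort``: median/q1/q3 per class across
    samples (the Box-&-Whisker numbers).
    """

    per_sample: pd.DataFrame
    cohort: pd.DataFrame

    def median(self, chem_class: str) -> float:
        return float(self.cohort.loc[chem_class, "median"])


def class_composition(areas: pd.DataFrame) -> CompositionProfile:
    """Relative class abundance from annotated peak areas.

    Parameters
    ----------
    areas :
        Tidy table with columns ``sample``, ``chem_class``, ``area`` —
        one row per confirmed/probable annotation. Per sample, each
        class's percentage is 100 x (class area) / (total area).
    """
    required = {"sample", "chem_class", "area"}
    if not required.issubset(areas.columns):
        raise InputError(f"composition table needs columns {sorted(required)}")
    if (areas["area"] < 0).any():
        raise InputError("negative peak areas")
    totals = areas.groupby("sample")["area"].sum()
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise UndefinedStatisticError(
            f"all-zero areas for sample(s) {bad}; composition undefined"
        )
    wide = (areas.pivot_table(index="sample", columns="chem_class",
                              values="area", aggfunc="sum", fill_value=0.0))
    per_sample = wide.div(wide.sum(axis=1), axis=0) * 100.0
    cohort = pd.DataFrame({
        "median": per_sample.median(axis=0),
        "q1": per_sample.quantile(0.25, axis=0),
        "q3": per_sample.quantile(0.75, axis=0),
    })
    cohort.index.name = "chem_class"
    return CompositionProfile(per_sample=per_sample, cohort=cohort)
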