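"""Auxiliary estimators: qPCR quantification, DSB-formation rate, and
focus-loss interval statistics.

qPCR Ct values are converted to relative quantities through a per-primer
standard curve, ``2**((mean Ct - intercept) / slope)`` (technical
replicates averaged on the Ct scale first).  The DSB-formation rate is
the least-squares slope of a cut-fraction time course over its
approximately linear early region.  Focus-loss intervals summarise the
time between disappearance of two fluorescent loci flanking a break,
computed only over cells in which both losses were observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import FociEventTable
from .synth import CutFractionSeries


def quantity_from_ct(ct_values, slope: float, intercept: float) -> float:
    """Relative quantity from technical-replicate Ct values."""
    if slope == 0:
        raise ValueError("standard-curve slope must be nonzero")
    cts = np.asarray(ct_values, dtype=np.float64)
    if cts.size < 1:
        raise ValueError("need at least one Ct value")
    return float(2.0 ** ((cts.mean() - intercept) / slope))


@dataclass
class QpcrTable:
    """Long-format qPCR data plus per-locus standard curves.

    ``data``: columns locus, coordinate, condition, ct (one row per
    technical replicate).  ``curves``: columns locus, slope, intercept.
    """

    data: pd.DataFrame
    curves: pd.DataFrame

    REQUIRED = ("locus", "condition", "ct")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"qPCR table missing column {col!r}")
        for col in ("locus", "slope", "intercept"):
            if col not in self.curves.columns:
                raise ValueError(f"standard-curve table missing column {col!r}")
        if (self.curves["slope"] == 0).any():
            raise ValueError("standard-curve slope must be nonzero")

    @classmethod
    def from_tsv(cls, data_path, curves_path) -> "QpcrTable":
        return cls(pd.read_csv(data_path, sep="\t"), pd.read_csv(curves_path, sep="\t"))

    def quantity(self, locus: str, condition: str) -> float:
        rows = self.data[(self.data["locus"] == locus) & (self.data["condition"] == condition)]
        if rows.empty:
            raise ValueError(f"no rows for locus={locus!r}, condition={condition!r}")
        curve = self.curves[self.curves["locus"] == locus]
        if curve.empty:
            raise ValueError(f"no standard curve for locus {locus!r}")
        return quantity_from_ct(
            rows["ct"].to_numpy(), float(curve["slope"].iloc[0]),
            float(curve["intercept"].iloc[0]),
        )


def locus_ratio(
    table: QpcrTable,
    locus: str,
    control_locus: str = "rpoA",
    plus_condition: str = "+DSB",
    minus_condition: str = "-DSB",
) -> float:
    """Control-normalised +DSB/-DSB quantity ratio for one locus:
    (Q_locus/Q_control)_{+DSB} / (Q_locus/Q_control)_{-DSB}."""
    plus = table.quantity(locus, plus_condition) / table.quantity(control_locus, plus_condition)
    minus = table.quantity(locus, minus_condition) / table.quantity(control_locus, minus_condition)
    return plus / minus


def estimate_dsb_rate(
    series: CutFractionSeries,
    exclude_last: bool = True,
    saturation_cutoff: float = 0.5,
    method: str = "slope",
) -> float:
    """DSB-formation rate (per hour) from a cut-fraction time course.

    ``method="slope"`` fits an ordinary least-squares line (with
    intercept) to cut fraction vs time.  The final time point is excluded
    by default, and so are points past ``saturation_cutoff``: once an
    appreciable share of cells is cut, the curve bends away from its
    initial slope and a straight-line fit would underestimate the hazard
    (set the cutoff to 1 to disable).  ``method="hazard"`` instead fits
    -log(1 - fraction) vs time, which is exactly linear in time under a
    constant hazard and needs no cutoff.
    """
    t_h = series.time_min / 60.0
    f = series.fraction.copy()
    keep = np.ones(t_h.size, dtype=bool)
    if exclude_last and t_h.size:
        keep[-1] = False
    if method == "slope":
        keep &= f <= saturation_cutoff
        y = f
    elif method == "hazard":
        keep &= f < 1.0
        with np.errstate(divide="ignore"):
            y = -np.log1p(-np.clip(f, 0.0, 1.0 - 1e-12))
    else:
        raise ValueError(f"unknown method {method!r}")
    if keep.sum() < 3:
        raise ValueError("need at least 3 usable time points")
    A = np.vstack([t_h[keep], np.ones(int(keep.sum()))]).T
    slope = float(np.linalg.lstsq(A, y[keep], rcond=None)[0][0])
    return slope


@dataclass
class IntervalStats:
    """Summary of inter-focus loss intervals for one locus pair."""

    intervals_min: np.ndarray
    mean_min: float
    sd_min: float
    n_completers: int
    n_first_only: int
    n_neither: int
    frac_second_given_first: float


def interval_stats(
    events: FociEventTable,
    locus_pair: tuple[str, str],
    frame_period_min: float | None = None,
) -> IntervalStats:
    """Per-cell intervals between loss of the two named loci (minutes).

    Only cells losing both foci contribute to the interval mean; cells in
    which the second locus is censored (dissociation, movie end) are
    counted and reported separately, as is the fraction of first-locus
    losers that go on to lose the second (the loss-frequency readout).
    With ``frame_period_min`` the loss times are interpreted as frame
    counts and converted via the acquisition period.
    """
    first, second = locus_pair
    for name in locus_pair:
        if name not in events.events.columns:
            raise ValueError(f"locus {name!r} not present in the event table")
    a = events.events[first].to_numpy(float)
    b = events.events[second].to_numpy(float)
    if frame_period_min is not None:
        a = a * frame_period_min
        b = b * frame_period_min
    else:
        a = a / 60.0
        b = b / 60.0
    both = np.isfinite(a) & np.isfinite(b)
    first_only = np.isfinite(a) & ~np.isfinite(b)
    neither = ~np.isfinite(a)
    intervals = b[both] - a[both]
    n_first = int(both.sum() + first_only.sum())
    if both.sum() == 0:
        warnings.warn("no cells lost both foci; interval mean undefined", stacklevel=2)
        mean = sd = float("nan")
    else:
        mean = float(np.mean(intervals))
        sd = float(np.std(intervals, ddof=1)) if both.sum() > 1 else float("nan")
    return IntervalStats(
        intervals_min=intervals,
        mean_min=mean,
        sd_min=sd,
        n_completers=int(both.sum()),
        n_first_only=int(first_only.sum()),
        n_neither=int(neither.sum()),
        frac_second_given_first=float(both.sum() / n_first) if n_first else float("nan"),
    )
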