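"""Binned sequencing coverage and DSB processing profiles.

The readout of in vivo break processing is the ratio, per genomic bin, of
read counts in a DSB-induced sample to a control sample: territory that a
helicase-nuclease has degraded contributes no double-stranded template and
the ratio dips below one.  The pipeline is: bin read starts (default 4000
bins), rescale the experiment so both samples carry the same read total
inside a window far from the break, take per-bin ratios, and smooth with
lowess at a small bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess


def bin_edges(genome_length: int, n_bins: int) -> np.ndarray:
    """Equal-width half-open bins over [0, genome_length); the last bin
    absorbs any remainder."""
    if n_bins < 1:
        raise ValueError("need at least one bin")
    width = genome_length // n_bins
    if width < 1:
        raise ValueError("more bins than base pairs")
    edges = np.arange(n_bins + 1, dtype=np.int64) * width
    edges[-1] = genome_length
    return edges


@dataclass
class BinnedCoverage:
    """Per-bin read counts for one sample."""

    genome_length: int
    counts: np.ndarray
    sample_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def edges(self) -> np.ndarray:
        return bin_edges(self.genome_length, self.n_bins)

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.edges
        return (e[:-1] + e[1:]) / 2.0

    def to_bedgraph(self, path: str | Path, chrom: str = "chr") -> None:
        e = self.edges
        with open(path, "w") as fh:
            for s, t, c in zip(e[:-1], e[1:], self.counts):
                fh.write(f"{chrom}\t{s}\t{t}\t{c:g}\n")

    @classmethod
    def from_bedgraph(cls, path: str | Path, genome_length: int | None = None,
                      sample_label: str = "") -> "BinnedCoverage":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
        df = df.sort_values("start")
        if genome_length is None:
            genome_length = int(df["end"].max())
        return cls(genome_length, df["value"].to_numpy(float), sample_label)

    @classmethod
    def from_tsv(cls, path: str | Path, genome_length: int,
                 sample_label: str = "") -> "BinnedCoverage":
        """Two-column TSV (bin_start, count), header optional."""
        df = pd.read_csv(path, sep="\t", comment="#")
        if df.shape[1] < 2:
            raise ValueError("expected >= 2 columns (bin_start, count)")
        try:
            float(df.columns[0])
            df = pd.read_csv(path, sep="\t", comment="#", header=None)
        except ValueError:
            pass
        df = df.sort_values(df.columns[0])
        return cls(genome_length, df.iloc[:, 1].to_numpy(float), sample_label)


def bin_counts(
    read_starts,
    genome_length: int,
    n_bins: int = 4000,
    sample_label: str = "",
) -> BinnedCoverage:
    """Allocate read start positions to bins (each read increments one bin)."""
    pos = np.asarray(read_starts, dtype=np.float64)
    bad = int(np.sum((pos < 0) | (pos >= genome_length)))
    if bad:
        raise ValueError(f"{bad} read position(s) outside [0, {genome_length})")
    edges = bin_edges(genome_length, n_bins)
    counts, _ = np.histogram(pos, bins=edges)
    return BinnedCoverage(genome_length, counts.astype(np.float64), sample_label)


def normalize_pair(
    experiment: BinnedCoverage,
    control: BinnedCoverage,
    window: tuple[int, int],
) -> tuple[BinnedCoverage, float]:
    """Rescale the experiment so both samples have equal read totals inside
    ``window`` (bp, half-open).  Returns (scaled experiment, scalar)."""
    if experiment.n_bins != control.n_bins or experiment.genome_length != control.genome_length:
        raise ValueError("experiment and control must share a bin grid")
    centers = control.bin_centers
    sel = (centers >= window[0]) & (centers < window[1])
    if not sel.any():
        raise ValueError("normalization window contains no bins")
    ctrl_sum = control.counts[sel].sum()
    exp_sum = experiment.counts[sel].sum()
    if ctrl_sum <= 0 or exp_sum <= 0:
        raise ValueError("zero reads inside the normalization window")
    scalar = ctrl_sum / exp_sum
    scaled = replace(experiment, counts=experiment.counts * scalar)
    return scaled, scalar


@dataclass
class DegradationProfile:
    """Experiment/control ratio per bin, optionally lowess-smoothed.

    ``ratio`` is NaN where the control has zero reads; those bins are
    excluded from smoothing and from any downstream fit.
    """

    bin_centers: np.ndarray
    ratio: np.ndarray
    genome_length: int
    smoothed: np.ndarray | None = None
    normalization_window: tuple[int, int] | None = None
    smoothing_fraction: float | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=np.float64)
        self.ratio = np.asarray(self.ratio, dtype=np.float64)
        if self.bin_centers.shape != self.ratio.shape:
            raise ValueError("bin_centers and ratio must have equal length")

    @property
    def mask(self) -> np.ndarray:
        """True where the bin is usable (control had reads)."""
        return np.isfinite(self.ratio)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "bin_center": self.bin_centers.astype(np.int64),
                "raw_ratio": self.ratio,
                "smoothed_ratio": self.smoothed if self.smoothed is not None else np.nan,
                "mask": self.mask.astype(int),
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, genome_length: int) -> "DegradationProfile":
        df = pd.read_csv(path, sep="\t")
        smoothed = df["smoothed_ratio"].to_numpy(float)
        if np.all(np.isnan(smoothed)):
            smoothed = None
        return cls(
            bin_centers=df["bin_center"].to_numpy(float),
            ratio=df["raw_ratio"].to_numpy(float),
            genome_length=genome_length,
            smoothed=smoothed,
        )


def ratio_profile(
    experiment: BinnedCoverage,
    control: BinnedCoverage,
    normalization_window: tuple[int, int] | None = None,
) -> DegradationProfile:
    """Per-bin experiment/control ratio; zero-control bins are NaN-masked."""
    if experiment.n_bins != control.n_bins or experiment.genome_length != control.genome_length:
        raise ValueError("experiment and control must share a bin grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(control.counts > 0, experiment.counts / control.counts, np.nan)
    return DegradationProfile(
        bin_centers=control.bin_centers,
        ratio=r,
        genome_length=control.genome_length,
        normalization_window=normalization_window,
    )


def lowess_smooth(profile: DegradationProfile, fraction: float = 0.01) -> DegradationProfile:
    """Lowess (tricube local-linear, 0 robustness iterations) over unmasked
    bins; the bandwidth is a fraction of the unmasked bin count."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    ok = profile.mask
    if ok.sum() < 10:
        raise ValueError("too few unmasked bins to smooth")
    smoothed = np.full_like(profile.ratio, np.nan)
    smoothed[ok] = _sm_lowess(
        profile.ratio[ok], profile.bin_centers[ok],
        frac=fraction, it=0, delta=0.0, return_sorted=False,
    )
    return replace(profile, smoothed=smoothed, smoothing_fraction=fraction)


def build_profile(
    experiment: BinnedCoverage,
    control: BinnedCoverage,
    normalization_window: tuple[int, int],
    fraction: float = 0.01,
) -> DegradationProfile:
    """Full pipeline: window-normalise, ratio, smooth."""
    scaled, _ = normalize_pair(experiment, control, normalization_window)
    prof = ratio_profile(scaled, control, normalization_window)
    return lowess_smooth(prof, fraction)
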