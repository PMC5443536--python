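"""Synthetic inputs with known ground truth.

Generates every input the pipeline consumes: circular chromosomes with
controlled chi layouts (explicit coordinates, regular per-arm spacing, or
random per-arm densities), noisy binned coverage pairs drawn from a
survival profile, cut-fraction time courses under an exponential onset
model, and frame-quantised focus-loss tables.  Every generator is a pure
function of its arguments and a seed.

The default chromosome mimics the study system: 4.0 Mb, circular, break
at +780 kb, one chi-dense arm (5 kb spacing, toward the origin) and one
chi-poor arm (50 kb spacing, toward the terminus), all sites oriented to
attenuate the machine travelling away from the break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import BinnedCoverage, bin_edges
from .genome import CHI_MOTIF, GenomeModel, reverse_complement, scan_motif
from .simulate import Population, SurvivalProfile, FociEventTable, foci_loss_times

DEFAULT_LENGTH = 4_000_000
DEFAULT_DSB = 780_000
DEFAULT_DENSE_SPACING = 5_000
DEFAULT_SPARSE_SPACING = 50_000


def _arm_positions(dsb: int, length: int, spacing: int, side: str,
                   start_offset: int) -> np.ndarray:
    """Regularly spaced positions along one arm, up to half the chromosome."""
    half = length // 2
    dists = np.arange(start_offset, half + 1, spacing, dtype=np.int64)
    if side == "left":
        return (dsb - dists) % length
    return (dsb + dists) % length


def make_genome(
    length: int = DEFAULT_LENGTH,
    dsb: int = DEFAULT_DSB,
    ori: int = 0,
    chi_layout: dict | None = None,
    seed: int = 0,
    motif: str = CHI_MOTIF,
    with_sequence: bool = False,
    convention: str = "A",
) -> GenomeModel:
    """Build a circular genome with a controlled chi layout.

    ``chi_layout`` options (mutually exclusive keys):

    - ``{"forward": [...], "reverse": [...]}`` — explicit reference-strand
      coordinates.
    - ``{"left_spacing": bp, "right_spacing": bp, "offset": bp}`` — regular
      spacing along each arm (0/None disables an arm), sites oriented to
      attenuate the machine moving away from the DSB under ``convention``.
    - ``{"left_density": per bp, "right_density": per bp}`` — Poisson
      placement along each arm at the given densities, same orientation.

    Default: dense 5 kb spacing on the left arm, sparse 50 kb on the right.
    With ``with_sequence=True`` a background sequence free of spurious
    motif occurrences is generated and the motifs written in, so that
    :func:`~resectra.genome.scan_motif` recovers the layout exactly.
    """
    if chi_layout is None:
        chi_layout = {
            "left_spacing": DEFAULT_DENSE_SPACING,
            "right_spacing": DEFAULT_SPARSE_SPACING,
        }
    rng = np.random.default_rng(seed)
    if "forward" in chi_layout or "reverse" in chi_layout:
        fwd = np.asarray(chi_layout.get("forward", []), dtype=np.int64)
        rev = np.asarray(chi_layout.get("reverse", []), dtype=np.int64)
    else:
        if "left_spacing" in chi_layout or "right_spacing" in chi_layout:
            ls = chi_layout.get("left_spacing")
            rs = chi_layout.get("right_spacing")
            off_l = int(chi_layout.get("offset", ls or 0))
            off_r = int(chi_layout.get("offset", rs or 0))
            left = _arm_positions(dsb, length, ls, "left", off_l) if ls else np.array([], dtype=np.int64)
            right = _arm_positions(dsb, length, rs, "right", off_r) if rs else np.array([], dtype=np.int64)
        else:
            half = length // 2
            ld = chi_layout.get("left_density", 0.0)
            rd = chi_layout.get("right_density", 0.0)
            left = (dsb - rng.integers(1, half, rng.poisson(ld * half))) % length
            right = (dsb + rng.integers(1, half, rng.poisson(rd * half))) % length
        # active orientation: under convention A the left-moving machine
        # reads forward-strand chi, the right-moving machine reverse-strand
        if convention == "A":
            fwd, rev = left, right
        else:
            fwd, rev = right, left
    fwd = np.unique(fwd)
    rev = np.unique(rev)
    sequence = None
    if with_sequence:
        sequence = _sequence_for_layout(length, fwd, rev, motif, rng)
    return GenomeModel(
        length=length,
        dsb_position=dsb,
        ori_position=ori,
        chi_forward=fwd,
        chi_reverse=rev,
        sequence=sequence,
        motif=motif,
    )


def _sequence_for_layout(length: int, fwd: np.ndarray, rev: np.ndarray,
                         motif: str, rng: np.random.Generator) -> str:
    """Random background with no spurious motif, then motifs written in."""
    m = len(motif)
    occupied = []
    for p in np.concatenate([fwd, rev]):
        if p + m > length:
            raise ValueError("motif placement runs past the sequence end")
        occupied.append((int(p), int(p) + m))
    occupied.sort()
    for (s1, e1), (s2, e2) in zip(occupied, occupied[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping motif placements at {s1} and {s2}")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = rng.choice(bases, size=length).astype("U1")
    rc = reverse_complement(motif)
    # scrub spurious occurrences of motif/rc (circular) by resampling
    for _ in range(50):
        hits = scan_motif("".join(seq), motif, circular=True)
        spurious = [p for p in hits.forward_positions if p not in set(map(int, fwd))]
        spurious += [p for p in hits.reverse_positions if p not in set(map(int, rev))]
        if not spurious:
            break
        for p in spurious:
            idx = (int(p) + np.arange(m)) % length
            seq[idx] = rng.choice(bases, size=m)
    for p in fwd:
        seq[int(p):int(p) + m] = list(motif)
    for p in rev:
        seq[int(p):int(p) + m] = list(rc)
    out = "".join(seq)
    # writing the motifs in cannot create spurious hits only if their
    # flanks stay clean; verify the round trip outright
    final = scan_motif(out, motif, circular=True)
    if (list(final.forward_positions) != sorted(map(int, fwd))
            or list(final.reverse_positions) != sorted(map(int, rev))):
        raise RuntimeError("failed to realise the chi layout as a sequence")
    return out


def genome_to_fasta(genome: GenomeModel, path, name: str = "synthetic_chromosome") -> None:
    if genome.sequence is None:
        raise ValueError("genome has no sequence; build it with with_sequence=True")
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i:i + 70] + "\n")


def sample_coverage(
    survival: SurvivalProfile,
    mean_depth: float = 100.0,
    noise: str = "poisson",
    dispersion: float = 10.0,
    seed: int = 0,
    genome_length: int | None = None,
) -> tuple[BinnedCoverage, BinnedCoverage]:
    """Draw a (control, experiment) coverage pair from a survival profile.

    Control bins have mean ``mean_depth``; experiment bins have mean
    ``mean_depth * survival``.  ``noise`` is "poisson" or "nb" (negative
    binomial with the given dispersion: variance = mu + mu^2/dispersion).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    L = genome_length or int(round(survival.bin_centers[-1] + survival.bin_centers[0]))
    mu_ctrl = np.full(survival.bin_centers.size, float(mean_depth))
    mu_exp = mean_depth * survival.survival

    def _draw(mu: np.ndarray) -> np.ndarray:
        if noise == "poisson":
            return rng.poisson(mu).astype(np.float64)
        if noise == "nb":
            lam = rng.gamma(shape=dispersion, scale=np.maximum(mu, 1e-12) / dispersion)
            return rng.poisson(lam).astype(np.float64)
        raise ValueError(f"unknown noise model {noise!r}")

    control = BinnedCoverage(L, _draw(mu_ctrl), "control")
    experiment = BinnedCoverage(L, _draw(mu_exp), "experiment")
    return control, experiment


@dataclass
class CutFractionSeries:
    """Fraction of cells carrying a DSB at each sampled time."""

    time_min: np.ndarray
    fraction: np.ndarray
    genotype: str = ""
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=np.float64)
        self.fraction = np.asarray(self.fraction, dtype=np.float64)
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time points must be strictly increasing")

    def to_tsv(self, path) -> None:
        pd.DataFrame({"time_min": self.time_min, "cut_fraction": self.fraction}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, genotype: str = "") -> "CutFractionSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float), genotype)


DEFAULT_TIMEPOINTS_MIN = (0.0, 5.0, 10.0, 15.0, 30.0, 60.0, 120.0, 240.0)


def make_timecourse(
    onset_rate: float = 0.4,
    time_min=DEFAULT_TIMEPOINTS_MIN,
    noise_sd: float = 0.02,
    seed: int = 0,
    genotype: str = "synthetic",
) -> CutFractionSeries:
    """Cut-fraction series 1 - exp(-lambda t) with Gaussian noise, clipped
    to [0, 1] (clip count recorded on the series)."""
    rng = np.random.default_rng(seed)
    t = np.asarray(time_min, dtype=np.float64)
    f = 1.0 - np.exp(-onset_rate * t / 60.0)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=t.size)
    clipped = int(np.sum((f < 0) | (f > 1)))
    return CutFractionSeries(t, np.clip(f, 0.0, 1.0), genotype, n_clipped=clipped)


def make_foci_events(
    population: Population,
    locus_offsets: dict[str, float],
    frame_period_min: float = 4.0,
    detection_delay_min: float = 0.0,
    movie_length_min: float | None = None,
    t_total: float | None = None,
) -> FociEventTable:
    """Microscopy-like readout of simulated focus losses.

    Loss times are shifted by a fixed detection delay, then quantised up
    to the next frame boundary; losses after the movie ends are censored.
    ``frame_period_min=0`` disables quantisation.
    """
    t = population.params.t_total if t_total is None else t_total
    movie_s = t if movie_length_min is None else movie_length_min * 60.0
    table = foci_loss_times(population, locus_offsets, t_total=movie_s)
    ev = table.events.copy()
    frame_s = frame_period_min * 60.0
    for name in locus_offsets:
        x = ev[name] + detection_delay_min * 60.0
        if frame_s > 0:
            x = np.ceil(x / frame_s) * frame_s
        ev[name] = np.where(x <= movie_s, x, np.nan)
    return FociEventTable(ev, dict(locus_offsets), movie_s)
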