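"""Per-cell stochastic simulation of bidirectional DSB end processing.

Each simulated cell experiences a double-strand break at an exponentially
distributed onset time after induction (hazard ``onset_rate`` per hour).
From the break, two independent machines translocate away in opposite
directions at ``k_fast`` bp/s, each Bernoulli-testing every correctly
oriented chi site it reaches with probability ``p_chi``.  The first
recognised chi commits the machine irreversibly: it continues at
``k_slow`` bp/s, ignores further chi, and — if ``k_off`` > 0 — carries an
exponential dissociation clock started at commitment; dissociation freezes
that arm permanently.  Fronts are exact piecewise-linear functions of
time (event-driven; no time discretisation), capped at half the
chromosome so the two fronts of a circular chromosome never cross.

The population-level observables are the survival profile (fraction of
cells in which a genomic position is still double-stranded at a given
time) and per-cell focus-loss times for named loci.

Randomness: all draws are inverse-CDF transforms of a fixed-width block
of five uniforms per cell, taken row-major from a single counter-based
Philox stream keyed by ``seed``.  Cell ``i`` therefore consumes stream
positions ``5i..5i+4`` independently of the population size, so any
single cell is exactly reproducible without rerunning the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel, directional_chi

_U_PER_CELL = 5  # onset, commit-left, commit-right, dwell-left, dwell-right


@dataclass
class SimParams:
    """Parameters of the five-parameter resection model.

    onset_rate : DSB formation hazard, per hour per cell (lambda).
    k_fast     : pre-chi degradation speed, bp/s.
    p_chi      : per-site recognition probability for correctly oriented chi.
    k_slow     : post-chi processing speed, bp/s.
    k_off      : post-chi dissociation rate, per minute (0 = no dissociation).
    t_total    : induction horizon, seconds.
    model_variant : "no_dissociation" pins k_off to 0; "model1" pins
        k_slow to 0.85 * k_fast (the in vitro 15% slow-down) with k_off
        free; "model2"/"custom" leave both free.
    """

    onset_rate: float = 0.4
    k_fast: float = 400.0
    p_chi: float = 0.23
    k_slow: float = 340.0
    k_off: float = 0.0
    t_total: float = 3600.0
    n_cells: int = 10_000
    seed: int = 0
    model_variant: str = "custom"

    def __post_init__(self) -> None:
        if self.model_variant == "model1":
            self.k_slow = 0.85 * self.k_fast
        elif self.model_variant == "no_dissociation":
            self.k_off = 0.0
        for name in ("onset_rate", "k_fast", "k_slow", "k_off", "t_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.p_chi <= 1.0):
            raise ValueError("p_chi must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.k_slow > self.k_fast:
            warnings.warn(
                "k_slow exceeds k_fast: post-chi processing faster than "
                "pre-chi (allowed for grid exploration, but unphysical)",
                stacklevel=2,
            )


@dataclass
class MachineTrajectory:
    """One machine's piecewise-linear front, in bp from the DSB."""

    direction: str
    k_fast: float
    k_slow: float
    cap: float
    commit_distance: float | None  # None = never committed
    commit_time: float | None      # s after onset
    stop_time: float | None        # s after onset when it dissociated

    def extent(self, t) -> np.ndarray:
        """Distance degraded after ``t`` seconds of machine activity."""
        t = np.asarray(t, dtype=np.float64)
        e = self.k_fast * np.maximum(t, 0.0)
        if self.commit_distance is not None:
            ct = self.commit_time
            post = np.maximum(t - ct, 0.0)
            if self.stop_time is not None:
                post = np.minimum(post, self.stop_time - ct)
            e = np.where(t <= ct, e, self.commit_distance + self.k_slow * post)
        return np.minimum(e, self.cap)


def cell_uniforms(seed: int, index: int) -> np.ndarray:
    """The five-uniform block consumed by cell ``index`` under ``seed``."""
    gen = np.random.Generator(np.random.Philox(key=seed))
    return gen.random((index + 1, _U_PER_CELL))[index]


def _population_uniforms(seed: int, n_cells: int) -> np.ndarray:
    gen = np.random.Generator(np.random.Philox(key=seed))
    return gen.random((n_cells, _U_PER_CELL))


def _inv_exponential(u: np.ndarray, rate: float) -> np.ndarray:
    """Inverse-CDF exponential with given rate; rate 0 -> +inf."""
    if rate <= 0:
        return np.full_like(u, np.inf)
    return -np.log1p(-u) / rate


def _inv_geometric_index(u: np.ndarray, p: float) -> np.ndarray:
    """0-based index of the first Bernoulli(p) success; p=0 -> +inf."""
    if p <= 0:
        return np.full_like(u, np.inf)
    if p >= 1:
        return np.zeros_like(u)
    return np.floor(np.log1p(-u) / np.log1p(-p))


def sample_onsets(n_cells: int, onset_rate: float, t_total: float, seed: int) -> np.ndarray:
    """Exponential DSB onset times (s); values > t_total mean 'never cut'."""
    u = _population_uniforms(seed, n_cells)[:, 0]
    return _inv_exponential(u, onset_rate / 3600.0)


def simulate_machine(
    chi_distances: Sequence[float],
    params: SimParams,
    duration: float,
    rng: np.random.Generator,
    cap: float = np.inf,
    direction: str = "right",
) -> MachineTrajectory:
    """Simulate a single machine for ``duration`` seconds of activity.

    Chi sites are tested in order of distance; only sites actually reached
    within ``duration`` can commit the machine.
    """
    chi = np.asarray(sorted(chi_distances), dtype=np.float64)
    if duration < 0:
        raise ValueError("duration must be >= 0")
    commit_distance = commit_time = stop_time = None
    if params.k_fast > 0 and chi.size and params.p_chi > 0:
        idx = _inv_geometric_index(np.atleast_1d(rng.random()), params.p_chi)[0]
        if idx < chi.size:
            d = chi[int(idx)]
            t_reach = d / params.k_fast
            if t_reach <= duration and d <= cap:
                commit_distance = float(d)
                commit_time = float(t_reach)
                if params.k_off > 0:
                    dwell = _inv_exponential(
                        np.atleast_1d(rng.random()), params.k_off / 60.0
                    )[0]
                    stop_time = commit_time + float(dwell)
    return MachineTrajectory(
        direction=direction,
        k_fast=params.k_fast,
        k_slow=params.k_slow,
        cap=cap,
        commit_distance=commit_distance,
        commit_time=commit_time,
        stop_time=stop_time,
    )


@dataclass
class Population:
    """Vectorised per-cell state for both machines of every cell.

    Distances are bp from the DSB; ``commit_dist_*`` is +inf for a machine
    that never recognises any chi, ``dwell_*`` is +inf when k_off = 0.
    """

    genome: GenomeModel
    params: SimParams
    onset_s: np.ndarray
    commit_dist_left: np.ndarray
    commit_dist_right: np.ndarray
    dwell_left: np.ndarray
    dwell_right: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.onset_s.size

    @property
    def cap(self) -> float:
        return self.genome.length / 2.0

    def cut_mask(self, t_total: float | None = None) -> np.ndarray:
        t = self.params.t_total if t_total is None else t_total
        return self.onset_s <= t

    def _extent_one_side(self, elapsed: np.ndarray, commit_dist: np.ndarray,
                         dwell: np.ndarray) -> np.ndarray:
        p = self.params
        with np.errstate(divide="ignore", invalid="ignore"):
            commit_time = np.where(
                np.isfinite(commit_dist),
                commit_dist / p.k_fast if p.k_fast > 0 else np.inf,
                np.inf,
            )
        pre = p.k_fast * elapsed
        with np.errstate(invalid="ignore"):
            post = commit_dist + p.k_slow * np.minimum(elapsed - commit_time, dwell)
            ext = np.where(elapsed <= commit_time, pre, post)
        return np.minimum(ext, self.cap)

    def extents_at(self, t_total: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(left, right) degraded distances per cell at time ``t_total``."""
        t = self.params.t_total if t_total is None else t_total
        elapsed = np.maximum(t - self.onset_s, 0.0)
        left = self._extent_one_side(elapsed, self.commit_dist_left, self.dwell_left)
        right = self._extent_one_side(elapsed, self.commit_dist_right, self.dwell_right)
        return left, right

    def double_strand_ends(self, t_total: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(left, right) end of the fully degraded zone per cell.

        Pre-chi the machine degrades both strands; post-chi it resects a
        single strand, so the fully degraded zone stops at the chi
        commitment point (or at the front, if still pre-chi)."""
        left, right = self.extents_at(t_total)
        return (
            np.minimum(left, self.commit_dist_left),
            np.minimum(right, self.commit_dist_right),
        )

    def loss_times(self, offset_bp: float, t_total: float | None = None) -> np.ndarray:
        """Time (s after induction) at which the front passes a locus at a
        signed offset from the DSB (negative = left arm); NaN = censored."""
        t = self.params.t_total if t_total is None else t_total
        if offset_bp == 0:
            raise ValueError("locus offset must be nonzero")
        d = abs(float(offset_bp))
        if d > self.genome.length:
            raise ValueError("locus offset outside the chromosome")
        commit_dist = self.commit_dist_left if offset_bp < 0 else self.commit_dist_right
        dwell = self.dwell_left if offset_bp < 0 else self.dwell_right
        p = self.params
        with np.errstate(divide="ignore", invalid="ignore"):
            t_fast = d / p.k_fast if p.k_fast > 0 else np.inf
            commit_time = commit_dist / p.k_fast if p.k_fast > 0 else np.full_like(commit_dist, np.inf)
            t_post = commit_time + (d - commit_dist) / p.k_slow if p.k_slow > 0 else np.full_like(commit_dist, np.inf)
        reach = np.where(d <= commit_dist, t_fast, t_post)
        # dissociation before the locus, or locus beyond the front cap
        if p.k_slow > 0:
            with np.errstate(invalid="ignore"):
                reached_limit = np.where(
                    np.isfinite(dwell), commit_dist + p.k_slow * dwell, np.inf
                )
        else:
            reached_limit = commit_dist  # machine stalls at its chi
        reach = np.where(d <= np.maximum(reached_limit, commit_dist), reach, np.inf)
        if d > self.cap:
            reach = np.full_like(reach, np.inf)
        loss = self.onset_s + reach
        return np.where(loss <= t, loss, np.nan)


def simulate_population(genome: GenomeModel, params: SimParams,
                        convention: str = "A") -> Population:
    """Simulate ``params.n_cells`` independent cells.

    Chi lists for the two arms come from :func:`directional_chi` under the
    given orientation convention.
    """
    left_chi, right_chi = directional_chi(genome, convention=convention)
    u = _population_uniforms(params.seed, params.n_cells)
    onset = _inv_exponential(u[:, 0], params.onset_rate / 3600.0)
    k_off_s = params.k_off / 60.0

    def _side(chi: np.ndarray, u_commit: np.ndarray, u_dwell: np.ndarray):
        idx = _inv_geometric_index(u_commit, params.p_chi)
        dist = np.full(params.n_cells, np.inf)
        hit = idx < chi.size
        if chi.size and params.p_chi > 0:
            dist[hit] = chi[idx[hit].astype(np.int64)]
        # a chi beyond the front cap can never be reached
        dist[dist > genome.length / 2.0] = np.inf
        dwell = _inv_exponential(u_dwell, k_off_s)
        return dist, dwell

    dist_l, dwell_l = _side(np.asarray(left_chi, float), u[:, 1], u[:, 3])
    dist_r, dwell_r = _side(np.asarray(right_chi, float), u[:, 2], u[:, 4])
    return Population(
        genome=genome,
        params=params,
        onset_s=onset,
        commit_dist_left=dist_l,
        commit_dist_right=dist_r,
        dwell_left=dwell_l,
        dwell_right=dwell_r,
    )


def simulate_cell(genome: GenomeModel, params: SimParams, index: int,
                  convention: str = "A") -> dict:
    """Reconstruct cell ``index`` of :func:`simulate_population` exactly."""
    sub = replace(params, n_cells=index + 1)
    pop = simulate_population(genome, sub, convention)
    return {
        "onset_s": float(pop.onset_s[index]),
        "commit_dist_left": float(pop.commit_dist_left[index]),
        "commit_dist_right": float(pop.commit_dist_right[index]),
        "dwell_left": float(pop.dwell_left[index]),
        "dwell_right": float(pop.dwell_right[index]),
    }


@dataclass
class SurvivalProfile:
    """Fraction of cells in which each bin center is still double-stranded."""

    bin_centers: np.ndarray
    survival: np.ndarray
    n_cells: int
    t_total: float
    params: SimParams | None = None

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"bin_center": self.bin_centers.astype(np.int64), "survival": self.survival}
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _passed_fraction(extents: np.ndarray, dists: np.ndarray, n: int) -> np.ndarray:
    """Fraction of cells whose front strictly passed each distance."""
    s = np.sort(extents)
    return (n - np.searchsorted(s, dists, side="right")) / n


def survival_profile(
    population: Population,
    t_total: float | None = None,
    bin_centers: np.ndarray | None = None,
    n_bins: int = 4000,
    observable: str = "sequencing",
) -> SurvivalProfile:
    """Population survival at each bin center.

    With the default ``"sequencing"`` observable a position is lost once a
    front has passed it — single-stranded and degraded DNA alike
    contribute no double-stranded sequencing template.  The ``"qpcr"``
    observable retains weight 0.5 for single-strand-resected territory
    (between the chi commitment point and the front), where one template
    strand survives and still amplifies.  Uncut cells are intact
    everywhere.  Computed by rank counting over the sorted per-arm extent
    distributions, exact for non-crossing fronts.
    """
    if observable not in ("sequencing", "qpcr"):
        raise ValueError(f"unknown observable {observable!r}")
    g = population.genome
    t = population.params.t_total if t_total is None else t_total
    if bin_centers is None:
        from .coverage import bin_edges

        e = bin_edges(g.length, n_bins)
        bin_centers = (e[:-1] + e[1:]) / 2.0
    bin_centers = np.asarray(bin_centers, dtype=np.float64)
    left, right = population.extents_at(t)
    n = population.n_cells
    L = float(g.length)
    d_right = (bin_centers - g.dsb_position) % L
    d_left = (g.dsb_position - bin_centers) % L
    lost = _passed_fraction(right, d_right, n) + _passed_fraction(left, d_left, n)
    # the bin holding the DSB itself: covered from either side
    at_dsb = d_right == 0
    if at_dsb.any():
        lost_dsb = np.count_nonzero((right > 0) | (left > 0)) / n
        lost = np.where(at_dsb, lost_dsb, lost)
    if observable == "qpcr":
        ds_left, ds_right = population.double_strand_ends(t)
        lost_ds = _passed_fraction(ds_right, d_right, n) + _passed_fraction(ds_left, d_left, n)
        if at_dsb.any():
            lost_ds = np.where(
                at_dsb, np.count_nonzero((ds_right > 0) | (ds_left > 0)) / n, lost_ds
            )
        # half credit for territory that is resected but not fully degraded
        lost = 0.5 * lost + 0.5 * lost_ds
    surv = 1.0 - lost
    return SurvivalProfile(
        bin_centers=bin_centers,
        survival=np.clip(surv, 0.0, 1.0),
        n_cells=n,
        t_total=t,
        params=population.params,
    )


@dataclass
class FociEventTable:
    """Per-cell focus-loss times for named loci.

    ``events`` has one row per cell: column ``onset_s`` plus one column
    per locus holding the loss time in seconds after induction (NaN =
    censored: the focus survived to the end of the observation window).
    """

    events: pd.DataFrame
    locus_offsets: dict[str, float]
    t_total: float

    def to_tsv(self, path) -> None:
        self.events.to_csv(path, sep="\t", index_label="cell", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, locus_offsets=None, t_total=np.nan) -> "FociEventTable":
        df = pd.read_csv(path, sep="\t", index_col="cell")
        return cls(df, locus_offsets or {}, t_total)


def foci_loss_times(
    population: Population,
    locus_offsets: dict[str, float],
    t_total: float | None = None,
) -> FociEventTable:
    """Loss time of each named locus in every cell (NaN = censored)."""
    t = population.params.t_total if t_total is None else t_total
    data = {"onset_s": np.where(population.onset_s <= t, population.onset_s, np.nan)}
    for name, off in locus_offsets.items():
        data[name] = population.loss_times(off, t)
    return FociEventTable(pd.DataFrame(data), dict(locus_offsets), t)
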