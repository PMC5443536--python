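"""Preset in-silico experiments: simulate-and-refit parameter recovery.

Each preset generates synthetic observed data under a stated ground-truth
parameter set (the study conditions), runs the estimator under test, and
reports what it recovered.  All presets are pure functions of a master
seed.

Ground-truth parameter sets (pre-chi speed bp/s, chi recognition
probability, post-chi speed bp/s, dissociation rate /min):

- ``delta_recA``: 400, 0.23, 340 (= 0.85 * 400), 0 — the RecA-free
  scenario in which in vitro rates describe the in vivo profile.
- ``model1``: 400, 0.23, 340 (pinned to 0.85 * k_fast), 0.102.
- ``model2``: 400, 0.23, 96, 0.021.
- ``wildtype4``: 400, 0.22, 51, 0 — the four-parameter fit without
  dissociation.

The DSB-formation (onset) rate is 0.4 per hour throughout.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .coverage import DegradationProfile, build_profile
from .fitting import grid_scan
from .genome import GenomeModel
from .qpcr import estimate_dsb_rate, interval_stats
from .simulate import SimParams, foci_loss_times, simulate_population, survival_profile
from .synth import make_genome, make_timecourse, sample_coverage

NORM_WINDOW = (2_800_000, 3_400_000)
MEAN_DEPTH = 100.0
LOWESS_FRACTION = 0.01
N_BINS = 4000

TRUTH = {
    "delta_recA": SimParams(onset_rate=0.4, k_fast=400.0, p_chi=0.23,
                            k_slow=340.0, k_off=0.0),
    "model1": SimParams(onset_rate=0.4, k_fast=400.0, p_chi=0.23,
                        k_slow=340.0, k_off=0.102),
    "model2": SimParams(onset_rate=0.4, k_fast=400.0, p_chi=0.23,
                        k_slow=96.0, k_off=0.021),
    "wildtype4": SimParams(onset_rate=0.4, k_fast=400.0, p_chi=0.22,
                           k_slow=51.0, k_off=0.0),
}

HOUR = 3600.0


def _seeds(master: int, *tags: int) -> int:
    return int(np.random.SeedSequence([master, *tags]).generate_state(1)[0] % (2**31))


def synthetic_observed(
    genome: GenomeModel,
    truth: SimParams,
    times_s: list[float],
    seed: int,
    mean_depth: float = MEAN_DEPTH,
    n_cells: int = 10_000,
    n_bins: int = N_BINS,
) -> list[tuple[float, DegradationProfile]]:
    """Simulate the truth, sample Poisson coverage, build smoothed profiles.

    Each time point is an independent population: experimental time
    courses sacrifice a separate aliquot of cells per sample.
    """
    out = []
    for i, t in enumerate(times_s):
        pop = simulate_population(
            genome, replace(truth, n_cells=n_cells, t_total=t,
                            seed=_seeds(seed, 0, i)),
        )
        surv = survival_profile(pop, t_total=t, n_bins=n_bins)
        control, experiment = sample_coverage(
            surv, mean_depth=mean_depth, seed=_seeds(seed, 1, i),
            genome_length=genome.length,
        )
        out.append((t, build_profile(experiment, control, NORM_WINDOW, LOWESS_FRACTION)))
    return out


def recover_k_fast(seed: int = 0, n_cells: int = 10_000,
                   replicates: int = 1) -> dict:
    """Delta-recA scenario: 1 h profile, scan the pre-chi speed 100-2000
    bp/s in 50 bp/s steps (post-chi speed riding at 85% of it)."""
    genome = make_genome()
    truth = TRUTH["delta_recA"]
    observed = synthetic_observed(genome, truth, [HOUR], _seeds(seed, 10),
                                  n_cells=n_cells)
    fit = grid_scan(
        observed, genome, {"k_fast": np.arange(100.0, 2000.0 + 1, 50.0)},
        replace(truth, n_cells=n_cells), replicates=replicates,
        seed=_seeds(seed, 11), model1_constraint=True,
    )
    return {"value": fit.best["k_fast"], "truth": truth.k_fast, "fit": fit,
            "n": n_cells}


def recover_p_chi(seed: int = 0, n_cells: int = 10_000,
                  replicates: int = 1) -> dict:
    """Model 1 truth, 1 h + 2 h profiles, scan p_chi 0.05-0.50 step 0.01."""
    genome = make_genome()
    truth = TRUTH["model1"]
    observed = synthetic_observed(genome, truth, [HOUR, 2 * HOUR],
                                  _seeds(seed, 20), n_cells=n_cells)
    fit = grid_scan(
        observed, genome, {"p_chi": np.round(np.arange(0.05, 0.50 + 1e-9, 0.01), 10)},
        replace(truth, n_cells=n_cells), replicates=replicates,
        seed=_seeds(seed, 21),
    )
    return {"value": fit.best["p_chi"], "truth": truth.p_chi, "fit": fit,
            "n": n_cells}


def recover_model1(seed: int = 0, n_cells: int = 10_000,
                   replicates: int = 1) -> dict:
    """Model 1 truth, 1 h + 2 h profiles, scan k_off 0-0.3 step 0.006 under
    the Model 1 constraint (k_slow = 0.85 * k_fast)."""
    genome = make_genome()
    truth = TRUTH["model1"]
    observed = synthetic_observed(genome, truth, [HOUR, 2 * HOUR],
                                  _seeds(seed, 30), n_cells=n_cells)
    fit = grid_scan(
        observed, genome, {"k_off": np.round(np.arange(0.0, 0.30 + 1e-9, 0.006), 10)},
        replace(truth, n_cells=n_cells), replicates=replicates,
        seed=_seeds(seed, 31), model1_constraint=True,
    )
    return {"value": fit.best["k_off"], "truth": truth.k_off, "fit": fit,
            "n": n_cells}


def recover_model2(seed: int = 0, n_cells: int = 10_000,
                   replicates: int = 1) -> dict:
    """Model 2 truth, 1 h + 2 h profiles, joint scan of k_slow (8-400 bp/s
    step 8) and k_off (0-0.1 /min step 0.003)."""
    genome = make_genome()
    truth = TRUTH["model2"]
    observed = synthetic_observed(genome, truth, [HOUR, 2 * HOUR],
                                  _seeds(seed, 40), n_cells=n_cells)
    fit = grid_scan(
        observed, genome,
        {
            "k_slow": np.arange(8.0, 400.0 + 1, 8.0),
            "k_off": np.round(np.arange(0.0, 0.10 + 1e-9, 0.003), 10),
        },
        replace(truth, n_cells=n_cells), replicates=replicates,
        seed=_seeds(seed, 41),
    )
    return {
        "value_k_slow": fit.best["k_slow"],
        "value_k_off": fit.best["k_off"],
        "truth": (truth.k_slow, truth.k_off),
        "fit": fit,
        "n": n_cells,
    }


def recover_wildtype4(seed: int = 0, n_cells: int = 10_000,
                      replicates: int = 1) -> dict:
    """Four-parameter wild-type truth (no dissociation), 1 h + 2 h
    profiles, scan k_slow 10-200 bp/s step 5."""
    genome = make_genome()
    truth = TRUTH["wildtype4"]
    observed = synthetic_observed(genome, truth, [HOUR, 2 * HOUR],
                                  _seeds(seed, 50), n_cells=n_cells)
    fit = grid_scan(
        observed, genome, {"k_slow": np.arange(10.0, 200.0 + 1, 5.0)},
        replace(truth, n_cells=n_cells), replicates=replicates,
        seed=_seeds(seed, 51),
    )
    return {"value": fit.best["k_slow"], "truth": truth.k_slow, "fit": fit,
            "n": n_cells}


FOCI_GENOME_KW = dict(dsb=30_000)
FOCI_MOVIE_S = 4 * HOUR


def foci_interval(model: str, locus_far_bp: float, seed: int = 0,
                  n_cells: int = 10_000) -> dict:
    """Mean loss interval between loci at -38 kb and -``locus_far_bp``.

    The chromosome carries the break at +30 kb with chi every 5 kb on the
    arm holding the loci; the interval is averaged over cells that lose
    both foci within the observation window.
    """
    genome = make_genome(**FOCI_GENOME_KW)
    truth = TRUTH[model]
    pop = simulate_population(
        genome, replace(truth, n_cells=n_cells, t_total=FOCI_MOVIE_S,
                        seed=_seeds(seed, 60, int(locus_far_bp))),
    )
    events = foci_loss_times(pop, {"near": -38_000.0, "far": -float(locus_far_bp)})
    stats = interval_stats(events, ("near", "far"))
    return {"value": stats.mean_min, "stats": stats, "n": n_cells,
            "n_completers": stats.n_completers}


def recover_onset_rate(seed: int = 0, n_replicates: int = 3,
                       onset_rate: float = 0.4, noise_sd: float = 0.02) -> dict:
    """Slope estimate of the DSB-formation rate from synthetic cut-fraction
    series (mean over seeded replicates)."""
    estimates = [
        estimate_dsb_rate(
            make_timecourse(onset_rate=onset_rate, noise_sd=noise_sd,
                            seed=_seeds(seed, 70, r))
        )
        for r in range(n_replicates)
    ]
    return {"value": float(np.mean(estimates)), "estimates": estimates,
            "truth": onset_rate, "n": n_replicates}


def chi_array_comparison(seed: int = 0, n_cells: int = 5_000,
                         array_offset: int = 30_000, copies: int = 15) -> dict:
    """Effect of a tandem chi array inserted near the break.

    Simulates a chi-free chromosome with and without a ``copies``-strong
    array ``array_offset`` bp right of the DSB, in the attenuating
    orientation and flipped.  Returns the mean right-arm extent for each
    construct; the forward array should shorten it, the flipped array
    should not.
    """
    stride = 8
    positions = [array_offset + i * stride for i in range(copies)]
    truth = replace(TRUTH["delta_recA"], n_cells=n_cells,
                    seed=_seeds(seed, 80))
    out = {}
    for label, layout in (
        ("no_array", {"forward": [], "reverse": []}),
        ("chi_for", {"reverse": [780_000 + p for p in positions]}),
        ("chi_rev", {"forward": [780_000 + p for p in positions]}),
    ):
        genome = make_genome(chi_layout=layout)
        pop = simulate_population(genome, truth)
        _, right = pop.extents_at()
        out[label] = float(right[pop.cut_mask()].mean())
    return out
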