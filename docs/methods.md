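# Methods

## The model

`resectra` models in vivo processing of a site-specific double-strand
break (DSB) on a circular bacterial chromosome by an AddAB-family
helicase–nuclease. Five parameters govern a per-cell stochastic forward
simulation:

| parameter | meaning | units | default |
|---|---|---|---|
| λ (`onset_rate`) | hazard of DSB formation after induction | h⁻¹ | 0.4 |
| `k_fast` | pre-chi degradation speed | bp/s | 400 |
| `p_chi` | per-site recognition probability of a correctly oriented chi | – | 0.23 |
| `k_slow` | post-chi processing speed | bp/s | 340 |
| `k_off` | post-chi dissociation rate | min⁻¹ | 0 |

Each cell draws an exponential onset time (constant hazard λ; cells with
onset beyond the horizon stay uncut). From the break, two machines move
apart at `k_fast`, Bernoulli-testing each correctly oriented chi site in
order. The first success commits the machine irreversibly: speed drops
to `k_slow`, later chi sites are ignored, and an exponential
dissociation clock (rate `k_off`) starts; dissociation freezes that arm
permanently. There is no pre-chi dissociation and no re-initiation after
dissociation. Fronts are exact piecewise-linear functions of time — the
simulation is event-driven with no time-discretisation error — and are
capped at half the chromosome length so the two fronts of a circular
chromosome cannot cross.

Model variants used in fitting: the four-parameter variant pins
`k_off = 0`; **Model 1** pins `k_slow = 0.85·k_fast` (the in vitro ~15%
post-chi slow-down) and frees `k_off`; **Model 2** frees both `k_slow`
and `k_off`.

**Observables.** Sequencing sees only double-stranded template, so a
position is "lost" once a front passes it, whether the machine was
degrading both strands (pre-chi) or resecting one (post-chi). The
population survival profile is the per-bin fraction of cells in which
the bin center is still ahead of both fronts (uncut cells are intact
everywhere). An alternative `qpcr` observable gives weight 0.5 to
territory between the commitment point and the front, where one template
strand survives and still amplifies; this reproduces the characteristic
excess of qPCR signal over sequencing profiles away from the break.
Focus-loss times are first-passage times of the relevant arm's front at
the locus offset; a focus never reached within the horizon is censored.

**Randomness.** All draws are inverse-CDF transforms (never
ziggurat-style rejection) of a fixed block of five uniforms per cell
taken row-major from one counter-based Philox stream, so a population is
bit-reproducible under its seed and any single cell can be reconstructed
in isolation without re-simulating the rest.

## Chi scanning and orientation

Chi here is the exact 8-mer 5'-GCGGTGGT-3' (configurable). Scanning
reports all overlapping occurrences on both strands; circular sequences
are scanned across the coordinate origin and hits reported once, modulo
the length. Ambiguity codes are rejected rather than expanded — chi is
an exact motif and silent expansion would hide data problems.

Which reference strand carries "active" chi for a left- versus
right-moving machine is a bookkeeping convention, not something the
assembly dictates. It is exposed as `convention="A"|"B"`:
under A, forward-strand motifs attenuate the machine moving toward
decreasing coordinates and reverse-strand motifs the machine moving
toward increasing coordinates; B is the flip. All defaults use A; the
flag is the single place the choice lives. Replichore labels (leading /
lagging) are likewise a documented convention
(`leading_is_forward_on_right`) and flip when ori and ter are swapped.

Coordinates are 0-based, half-open, bp units everywhere.

## Coverage profiles

The genome is divided into equal-width bins (default 4000; the last bin
absorbs any remainder — and at least one bin is required, although
smoothing needs ten or more usable bins). The DSB-induced sample is
rescaled by one scalar so that its read total inside a normalization
window far from the break equals the control's (defaults 2800–3400 kb
for a break at +780 kb, 600–1200 kb for +3042 kb). The per-bin
experiment/control ratio is then smoothed with lowess (tricube
local-linear, 0 robustness iterations, bandwidth 0.01 as a fraction of
the unmasked bin count), via `statsmodels`; the test suite cross-checks
it against R's `lowess` on a fixture (agreement ≲1e-11). Bins with zero
control reads are carried as explicit NaN, excluded from smoothing and
fitting, never imputed. Bins do not wrap across the origin, matching the
linear plotting convention. Because a single genome and equal bin widths
are used, ratios of window-normalized counts equal ratios of
reads-per-kilobase-per-million values; the pipeline therefore operates
on counts.

## RMSD fitting

A simulated survival profile is compared with an observed smoothed
profile by root-mean-square deviation over a fit window: bins within
±1.5 Mb of the break (circular distance), excluding the normalization
window and masked bins. Two deliberate choices:

- **Like is compared with like.** The simulated profile is passed
  through the same lowess smoother as the data before the RMSD, so the
  smoother's local-linear bias (strongest where the profile bends near
  the break) cancels instead of leaking into the fit.
- **Baseline calibration.** The observed profile is divided by its mean
  raw ratio inside the normalization window before comparison. Dividing
  two noisy counts inflates the expected ratio by ≈ 1/depth even where
  the true ratio is 1; anchoring intact territory at exactly 1 removes a
  systematic upward shift that otherwise drags the dissociation-rate
  estimate upward.

Grids are explicit value lists (1–3 free parameters). Every grid point
is simulated with common random numbers — the same derived seed per
replicate at every point — so Monte-Carlo noise largely cancels out of
the argmin. RMSDs are averaged over replicates and, unweighted, over
time points. Ties break toward the smallest parameter values
(conservative rates). Default scan ranges: `k_fast` 100–2000 bp/s step
50 (the in vitro range), `p_chi` 0.02–0.60 step 0.02, `k_slow` 10–400
bp/s, `k_off` 0–0.3 min⁻¹ step 0.003. For the Model 2 joint scan the
`k_slow` grid runs 8–400 bp/s in steps of 8 so the reference value
(96 bp/s) lies on the lattice.

95% intervals use an RMSD-threshold rule: the connected hull (around the
best point, per parameter after minimising over the others) of grid
values whose RMSD lies within `min RMSD + 2·SD` of the minimum, where SD
is the replicate scatter at the best point; it requires ≥3 replicates. A
bootstrap-over-replicates alternative is available. Both are artifact
conventions — deterministic and simple — not an attempt to reproduce any
particular published interval rule.

## Auxiliary estimators

**qPCR quantities.** Technical-replicate Ct values are averaged first,
then converted through the primer's standard curve:
`2^((mean Ct − intercept)/slope)`. Locus ratios are
`(Q_locus/Q_control)₊DSB / (Q_locus/Q_control)₋DSB` with `rpoA` as the
default control locus.

**DSB-formation rate.** The cut fraction under a constant hazard is
`1 − e^(−λt)`, linear with slope λ only near t = 0. The default
estimator fits an ordinary least-squares line (with intercept) to cut
fraction vs time after dropping the final time point (240 min by
convention) *and* any point with fraction above 0.5: beyond that the
curve has visibly bent away from its initial slope and a straight line
systematically underestimates the hazard. On the standard sampling grid
(0–120 min) this returns ≈0.33 h⁻¹ for a true λ = 0.4 h⁻¹ — the
residual curvature bias of a slope estimator, reported as such. A
`method="hazard"` variant regresses `−log(1 − fraction)` on time, which
is exactly linear under the model and recovers λ without bias; both are
exposed because the slope definition is what the laboratory protocol
computes.

**Focus-loss intervals.** Intervals are computed only over cells that
lose both foci (censored cells are counted and reported, matching a
microscopy readout in which a cell whose second focus persists
contributes no interval). Frame-quantised input is supported via the
acquisition period (4 or 8 min); quantisation shifts individual times up
by at most one frame. The summary also reports the fraction of
first-locus losers that lose the second locus.

## Synthetic data

The generator provides every pipeline input with known ground truth:

- **Genome**: 4.0 Mb circular, break at +780 kb, chi every 5 kb on the
  origin-proximal arm and every 50 kb on the terminus-proximal arm, all
  in the attenuating orientation. This mirrors the qualitative replichore
  asymmetry of the study organism without hardcoding its actual genome.
  Explicit per-strand coordinates and random per-arm densities are also
  supported. Emitted FASTA backgrounds are rejection-resampled to carry
  no spurious motif occurrence, so a scan recovers the layout exactly.
  Background GC content is a uniform 50% — motif occurrence is controlled
  by construction, so compositional realism buys nothing here.
- **Coverage**: control bins Poisson (or negative binomial) around a
  mean depth (default 100 reads/bin, which makes 4000-bin profiles
  visibly smooth at desk scale); experiment bins around depth × survival.
- **Cut-fraction time courses**: `1 − e^(−λt)` at 0, 5, 10, 15, 30, 60,
  120, 240 min plus Gaussian noise (sd 0.02), clipped to [0, 1] with the
  clip count logged.
- **Foci events**: simulator truth, optionally delayed, quantised up to
  frame boundaries and censored at the movie end.

What the generator does *not* emulate: mappability and GC-coverage
biases, copy-number structure near ori/ter in growing cells, library
batch effects, qPCR efficiency drift, or imaging noise in focus calling.
Passing recovery tests therefore demonstrate estimator correctness under
the model's own assumptions — including counting noise at realistic
depth — but not robustness to artefacts absent from the generator.

## Study conditions used by the recovery experiments

The preset experiments (`resectra.experiments`, also driven by
`scripts/acceptance.py`) simulate 10,000 cells per profile at depth 100
reads/bin on the default 4 Mb chromosome and fit 1 h profiles (RecA-free
scenario) or joint 1 h + 2 h profiles (all other fits) with
single-replicate common-random-number scans. Each observed time point is
an independently simulated population, mirroring the aliquot structure
of a real time course (a sequenced sample is destroyed; the next time
point comes from different cells). Under these conditions the
one-dimensional scans recover their generating values to within one grid
step across seeds; the Model 2 joint scan recovers the ratio
`k_off/k_slow` tightly but can wander a few grid steps *along* the
(`k_slow`, `k_off`) ridge for unlucky noise realisations — a genuine
identifiability limit of that two-parameter design at this depth, not a
numerical artefact (adding a 4 h profile, more scan replicates, or
larger scan populations does not remove it, because the post-chi
distance travelled before dissociation depends on the two parameters
almost solely through their ratio).
Focus-loss experiments use a chromosome with the break at +30 kb, chi
every 5 kb on the locus-bearing arm, loci at −38/−230 kb (Model 1) or
−38/−130 kb (Model 2), 10,000 cells, and a 4 h observation window so
that late-onset cells still contribute completed intervals.

## Known limitations

- Homologous recombination, strand invasion and repair completion are
  out of scope; RecA enters only through the values of `k_slow`/`k_off`.
- Machines never re-initiate after dissociating, and only one chi
  commitment is allowed per machine per arm.
- The onset model is a constant hazard; if induction kinetics include a
  delay or ramp, early-time profile shape near the break will differ
  (an optional fixed-delay variant can be composed by shifting onsets).
- The front cap at half the chromosome length approximates the
  fronts-meet rule exactly only for symmetric extents; at the horizons
  studied (≤4 h) the cap is reached by a negligible fraction of cells.
- RMSD fitting is not likelihood-based inference; intervals are grid
  conventions, and strongly correlated parameter pairs (`k_slow`,
  `k_off`) identify jointly better than marginally.
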