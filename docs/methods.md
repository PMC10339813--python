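# Methods

This note documents the models, conventions and numerical choices behind
`psiselect`, in the order the pipeline applies them.

## Signal model and preprocessing

Input is a multichannel recording (channels x time) at a declared sampling
rate.  Analysis operates on fixed-length, non-overlapping epochs (default
10 s); a trailing remainder shorter than one epoch is discarded.  An
optional common-average re-reference (subtract the per-sample channel
mean) is available and off by default; it is a generic spatial reference,
not a volume-conduction correction.

Each epoch is decomposed into five canonical bands — delta 1–4, theta 4–8,
alpha 8–12, beta 12–30, gamma 30–60 Hz — with a windowed-sinc (Hamming)
FIR band-pass applied forward and backward for zero phase.  The tap count
is `max(odd(3·fs/f_low), 257)`, i.e. the impulse response spans roughly
three cycles of the slowest passband component, which keeps the delta
filter selective without becoming longer than an epoch.  Edges are handled
by reflection padding of one filter length; no samples are discarded.
Filtering is linear and phase-neutral, both of which are tested.

## Phase synchronization index

For band-limited signals x and y, instantaneous phases come from the
discrete analytic signal (FFT-based Hilbert transform, mean removed
first).  The synchrony measure is the resultant length of the phase
difference,

    PSI(x, y) = | (1/T) Σ_t exp(j(φ_x(t) − φ_y(t))) | ∈ [0, 1],

with 1:1 frequency locking (higher-order m:n locking is not implemented).
PSI is amplitude-invariant and symmetric.  A constant signal is a
documented degenerate case with phase defined as 0.

Two practical facts shape the tests and defaults:

* **Noise floor.** For independent signals PSI does not vanish at finite
  length: with roughly `N_eff ≈ bandwidth × duration` independent phase
  samples, PSI is Rayleigh-distributed with mean ≈ `0.5·sqrt(π/N_eff)`
  and 95th percentile ≈ `sqrt(ln 20 / N_eff)`.  For a 10-s epoch this is
  ≈ 0.25 in the 4-Hz-wide alpha band and ≈ 0.13 in the 18-Hz beta band.
  Tests assert these derived levels rather than a single universal cutoff.
* **Zero-lag coupling.** PSI as defined above is *sensitive* to zero-lag
  synchrony, and therefore to volume conduction.  A phase-lag-index mode
  (`method="pli"`, the resultant of `sign(Δφ)`) is provided for users who
  want the conduction-insensitive variant; the default remains PSI.

Per epoch and band, all channel pairs form a symmetric connectivity matrix
with zero diagonal (self-coupling excluded).  An undirected binary network
keeps an edge where PSI strictly exceeds the threshold τ (default 0.3).
Networks are built per epoch — that is what yields one feature sample per
epoch; a group-level network, when wanted for display, is the binarized
mean PSI matrix.

## Graph-topology features

Fourteen scalars per network, in a fixed order that also defines the
particle bit layout: DG, NB, CC, SPL, EB, GE, LE, TT, AC, SW, MD, MZ, HC,
GIC.  Conventions, chosen once and tested against brute-force enumeration:

* Node/edge-level quantities are reduced by an unweighted mean.
  Betweenness is *raw* (unnormalized, unordered pairs).  SPL averages
  geodesics over reachable ordered pairs only; GE averages 1/d over all
  ordered pairs with 1/∞ = 0, so disconnected epochs still yield finite
  features.
* CC is the mean local clustering with degree-<2 nodes contributing 0; TT
  is global transitivity.  LE is the mean global efficiency of
  neighbour-induced subgraphs.
* AC is the Pearson correlation of degrees over edge endpoints (both
  orientations); degree-regular graphs are a degenerate case → 0.
* MD is Newman modularity of a greedy (CNM) partition, which is
  deterministic here.
* HC is the exponent β of a least-squares fit of log C(k) = −β log k + c
  over nodes with degree ≥ 2 and positive clustering; fewer than two
  distinct qualifying degrees → 0.
* GIC is 4c(1−c) with c the adjacency spectral radius normalized between
  the path-graph and complete-graph extremes (clamped to [0, 1] so
  sub-path spectra of fragmented graphs give 0, not a negative value).
* SW and MZ are normalized against a Maslov–Sneppen degree-preserving
  rewired ensemble (default 100 graphs, 10 swaps per edge, seeded):
  SW = (CC/CC_rand)/(SPL/SPL_rand), MZ = the triangle-count z-score.
  The rewirer is an in-package numpy implementation (repeated double edge
  swaps with a consecutive-failure bail-out), because dense near-complete
  epoch networks freeze the swap space and make generic implementations
  pathologically slow.  A null ensemble with zero variance (unswappable
  graphs) gives MZ = 0; an unswappable graph self-normalizes to SW = 1.

Every degenerate case maps to 0 with a logged warning — never NaN — so
feature tables are always classifier-ready.  SW and MZ are the only
stochastic features; their ensemble seed is derived per (epoch, band) from
one table-level seed, making whole tables reproducible and independent of
processing order.  Node relabelling leaves the twelve deterministic
features exactly invariant; SW and MZ are invariant in distribution only,
since the rewiring trajectory depends on the labelling.

## Subset objectives

A candidate feature subset (binary mask) is scored by four minimized
objectives: the cross-validated error of an RBF-kernel SVM (C = 1,
gamma = 1/(D·var), i.e. sklearn's "scale"), Gaussian naive Bayes, and
linear discriminant analysis — each on the masked, z-scored columns, with
standardization statistics from the training folds only — plus a distance
objective

    F4 = 1 / (1 + exp(−(D_w − D_b)))

where D_b is the mean distance of each sample to its *nearest*
other-class sample and D_w the mean distance to its *farthest* same-class
sample (Euclidean, on the masked raw columns).  Compact, well-separated
classes drive F4 → 0.  The three classifiers share a single stratified
fold assignment per evaluation so their errors are comparable; 10 folds at
design scale, capped by the smallest class for tiny tables; leave-one-out
is available as an alternative scheme.  The empty mask receives the
penalty vector (1, 1, 1, 1).  Objective vectors are memoized by mask — the
search revisits subsets constantly — and the evaluator counts distinct
masks, which the run history exposes.

## The optimizers

All four algorithms minimize over the unit hypercube; problems map the
encoding to their native domain (affine for box bounds, threshold
decoding at 0.5 — strict — for masks).

**MOPSO** is inertia-weight PSO (w = 0.7, c1 = c2 = 2, velocity clamped to
±0.5 per dimension, positions clamped to [0, 1]) with a bounded external
archive (capacity 100) of mutually non-dominated solutions.  Leaders are
drawn by binary tournament on archive crowding distance; over-capacity
archives drop the most crowded entry.  Personal bests update on Pareto
dominance, with an unbiased coin flip for incomparable pairs.

**MOPSO-GDM** adds Gaussian differential mutation: each particle mutates
with probability 0.1 per iteration; a mutation draws two scalars
f1, f2 ~ N(0, 1) (shared across dimensions) and perturbs the position by

    Δ = 0.5·f1·(pbest − L) + 0.5·f2·(L_rand − L),

with L_rand the position of a random peer.  The default adds Δ to the
current position; a "literal" mode that *replaces* the position with Δ is
available behind a flag.  The perturbation scales with the swarm's spread,
so it is large early and vanishes at convergence.  With mutation rate 0
the hybrid consumes the identical random stream as plain MOPSO and
reproduces it bit for bit (tested).

**MOPSO-M** replaces GDM with Deb's polynomial mutation (η = 20, applied
at the same 0.1 particle rate, gene probability 1/D).  **NSGA-II** is the
textbook reference: binary tournament on (rank, crowding), SBX crossover
(η = 15, p = 0.9), polynomial mutation (η = 20, 1/D), elitist
environmental selection; it shares the same external archive bookkeeping
for reporting.

## Benchmarks and their honest limits

The ZDT suite (ZDT1–4, 6; ZDT5 is Boolean and excluded) with analytic
reference fronts sampled at 1,000 points; quality is measured by IGD
(mean distance from reference samples to the nearest obtained point), and
"front attained" is operationalized as median IGD < 0.1 over the trial
set.  The campaign default is 30 particles × 50 iterations × 20 trials at
D ∈ {10, 50}.

At that budget (1,530 evaluations) the swarm variants reliably attain
ZDT1, ZDT2, ZDT3 and ZDT6 at D = 10 (median IGD ≈ 0.004–0.007).  Two
things do *not* happen at that budget, and the package does not pretend
otherwise: NSGA-II needs roughly 100–150 generations at this population
size before its median IGD crosses 0.1 (verified by running it longer),
and ZDT4's Rastrigin-like g-function keeps every algorithm far from the
front (median IGD in the tens) — multimodal ZDT4 is routinely benchmarked
at ≥10k evaluations in the literature.  What survives at desk scale is the
*comparative* claim: Gaussian differential mutation keeps the hybrid's
median ZDT4 IGD at or below plain MOPSO's, at both D = 10 and D = 50.

## Synthetic data

`generate_coupled_epochs` emulates the statistical design of a two-group
resting-state study, not its physiology.  Per band, each channel mixes a
shared band-limited driver (weight c) with private band-limited noise
(weight 1 − c), plus broadband noise (sd 0.2); c is the group's coupling
for that band.  The default preset is 16 channels, 1024 Hz, 10-s epochs,
180 epochs per group, with group A ("patients") coupled more weakly than
group B, most distinctly in alpha/beta/gamma: delta/theta (0.40, 0.50),
alpha/beta/gamma (0.35, 0.65).  Couplings map monotonically to PSI
(tested), so the construction plants a known group contrast without
claiming anything about real pathology.  Randomness is split per
(group, epoch) by counter-keyed seed sequences: growing the epoch count
never reshuffles earlier epochs.  What this generator does **not**
reproduce: 1/f spectra, artifacts, volume conduction, within-subject
correlation.  Tests passing on it show the machinery is correct, not that
the pipeline separates real patient groups.

`generate_planted_features` builds classification tables directly:
informative columns carry a between-class mean shift of `effect_size`
standard deviations, the rest are N(0, 1) noise, labels balanced.

## Problem sizes used in the shipped test suite

Simulations in the test suite are sized for a desk machine: the graph
oracle suite enumerates 200 random graphs on ≤ 6 nodes; the PSI floor uses
100 pairs of 10,240-sample signals; the ZDT campaign runs the full
30 × 50 × 20-trial protocol at D = 10 (plus ZDT4 at D = 50); subset
recovery runs 30 particles × 25 iterations on 360 × 70 tables over 5
seeds; the end-to-end determinism check runs the whole pipeline twice at
8 channels, 256 Hz, 4-s epochs, 12 epochs per group, null ensembles of 20.
Larger runs are a matter of configuration, not code.

## Known limitations

* PSI is computed over whole epochs; no sub-windowing, no m:n locking.
* Only size-3 motifs (triangles) enter MZ; no weighted or directed
  variants of any metric.
* Cross-validation folds are epoch-wise by default; when multiple epochs
  come from one subject, subject-wise grouping (provided as the `loo`
  alternative and by external fold control) is the stricter choice, and
  epoch-wise errors should be read as optimistic for real data.
* The archive's crowding-based pruning bounds memory but can discard
  boundary-adjacent solutions on highly clustered fronts.
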