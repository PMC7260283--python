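# Methods

This note documents the models, estimators and numerical choices behind the
package, in the spirit of a methods appendix.

## Luminescence decay model and fitting

Gated detection of Tb³⁺ luminescence yields photon-count traces modeled as

    y(t) = B + Σₖ aₖ · exp(−t / τₖ),   k = 1..K

with non-negative amplitudes `aₖ` (counts), lifetimes `τₖ` (ms) and a constant
background `B`. Three components cover the practical cases: a fast instrument
artifact (sub-0.1 ms), an intermediate component attributed to protein
aggregation, and a slow component whose lifetime reports donor–acceptor
separation.

`fit_multi_exponential` minimizes the weighted least-squares objective with
weights `1/max(y, 1)` — the Poisson-motivated approximation to inverse-variance
weighting for counting data. The optimization uses variable projection: the
outer search (`scipy.optimize.least_squares`, Levenberg–Marquardt) runs over
log-lifetimes only, and at every step amplitudes and background are recovered
by non-negative weighted linear least squares (NNLS). This removes the linear
parameters from the nonlinear problem, which is otherwise badly conditioned.
Because multi-exponential objectives carry local minima, the free lifetimes
are started from a log-spaced grid spanning the acquisition window, repeated
at four multiplicative offsets (0.3×–3×); the best end point wins. Lifetimes
are re-sorted ascending after convergence (they may cross during
optimization). Lifetime standard errors come from the Gauss–Newton covariance
at the optimum via the delta method from log-lifetime; they are used only to
flag ambiguity, not as the quoted uncertainty.

Fixed lifetimes (e.g. a calibrated instrument-artifact value) are honored
exactly by excluding them from the outer search. Default settings: 3
components, all lifetimes free, artifact threshold 0.1 ms. The artifact
threshold is a classification default, chosen below the fastest physically
meaningful donor component at these time scales; it is configurable.

Recovery scale: at ~10⁴ peak counts, the slow 2.0 ms lifetime is recovered
with a median relative error well under 2 % (100 Poisson replicates); the
error grows monotonically as counts drop, checked at peak counts of 10⁴, 10³
and 2×10². Far below that (peak ≲ 10 counts) the weighted-LS approximation to
the Poisson likelihood breaks down and the ordering is no longer meaningful.

## Component classification

After sorting by lifetime: every component faster than the artifact threshold
is labeled `artifact`; the slowest component is the `reporter`; anything in
between is `aggregation`. If the two slowest lifetimes differ by less than the
sum of their standard errors the assignment is ambiguous — the fit is flagged
and no reporter label is given; replicate-level analyses exclude such fits
with a warning.

## Förster inversion and uncertainty

    R = R₀ · ( τ_DA / (τ_D − τ_DA) )^(1/6)

with `τ_D`/`τ_DA` the reporter lifetimes without/with acceptor and `R₀` the
pair's Förster distance (a required user input; it depends on the photophysics
of the donor/acceptor pair and is not computed here). The efficiency form
`R = R₀·((1−E)/E)^(1/6)` with `E = 1 − τ_DA/τ_D` is algebraically identical
and is used as a machine-precision cross-check. `τ_DA = τ_D/2` gives `R = R₀`
exactly; `τ_DA ≥ τ_D` (no detectable transfer) is an error.

`estimate_distance` averages reporter lifetimes over replicates within each
condition and applies the inversion to the means. The quoted spread is the
sample standard deviation of per-replicate distances, each donor–acceptor
replicate paired with the mean donor-only lifetime — uncertainty by replicate
spread rather than fit covariance, matching how ± values are conventionally
quoted for such measurements. With a single usable replicate the spread is
reported as 0.

## Stern–Volmer quenching

Emission spectra (550–650 nm, 1 nm grid) are read at a target wavelength
(572 nm for TMR) by nearest-neighbour lookup — interpolation would add nothing
on a 1 nm grid. Intensities are multiplied by the spectrum's cumulative
dilution factor, and F₀ is the zero-quencher point, so `F₀/F = 1` at `[Q] = 0`
by construction. The linear model

    F₀ / F = 1 + K_SV · [Q]

is fitted by ordinary least squares with a *free* intercept: the model implies
intercept 1, and leaving it free keeps deviations visible as a diagnostic.
`compare_accessibility` reports `K_SV ± se` per labeling site and pairwise
slope-difference z-scores `z = ΔK_SV / √(se₁² + se₂²)`; sites are called
"overlapping" (equally accessible) when every pairwise `|z| < 2`. The
threshold 2 is a documented default for a qualitative call, not a calibrated
test.

## Tethered-chain ensemble generator

The mobile N-terminus is modeled as a freely-jointed chain (FJC): `N` beads
connected by rigid virtual bonds of `b = 0.38 nm` (the Cα–Cα distance),
anchored at a fixed point that stands in for the folded transporter core. The
FJC is the minimal model of a disordered peptide and has closed-form
statistics — `⟨R²⟩ = N·b²` for the anchor-to-end vector — which serve as
Monte-Carlo oracles. Two static beads are appended to every ensemble: the
anchor itself and, optionally, a remote reference site, the analogue of the
anchor residues (A335 on EL4, H510 on TM12) that frame-wise distances are
measured to.

Two regimes:

* `inward_free` — bonds drawn independently and uniformly on the sphere
  (Gaussian draws, normalized); direct sampling, one independent draw per
  frame.
* `outward_locked` — the bead at `restraint_residue` (default 5, the
  salt-bridge position: in the folded outward state R5 pairs with D369) is
  harmonically restrained to `restraint_site` with force constant `k` in
  kT/nm², giving a thermal per-axis sd of `1/√k` nm. Sampling is Metropolis
  over bond vectors targeting (FJC prior) × exp(−k/2·|x_m − site|²): each move
  redraws one bond, either uniformly (probability 0.3) or by a small angular
  perturbation; both proposals are symmetric. Burn-in is 200·N moves and
  frames are collected every 10·N moves, so successive frames are effectively
  decorrelated rather than strictly independent — adequate for the ensemble
  statistics computed here, and verified against the pinned-bead sd oracle.

Environments are hard constraints: the membrane is the half-space `z <
slab_z` (an extended flat barrier the polar chain cannot enter — beads must
keep `z ≥ slab_z`), the micelle an excluded sphere. Free-mode sampling uses
rejection; if fewer than 1 in 10³ draws survive the walls, sampling falls back
to Metropolis with the walls as infinite-energy states. Restrained-mode
sampling treats walls inside the Metropolis acceptance. Infeasible geometry
(anchor inside the excluded region, restraint site beyond the chain's reach)
is an error, not a silent hang.

What the generator does **not** emulate: excluded volume within the chain,
secondary structure (TM1A's helicity), electrostatics, lipid/detergent
molecules, or solvent friction — there is no kinetics at all, only
configurational ensembles. Passing recovery tests therefore demonstrates that
the *analysis* is correct on ensembles with known statistics; it says nothing
about the biological magnitude of N-terminal mobility.

## Ensemble observables

All internal coordinates are nm; PDB I/O converts to/from Å. Residues are
identified by author numbers (1-based); insertion codes are rejected, and
alternate locations resolve to the highest occupancy.

* `ca_distance` — Euclidean Cα–Cα distance within one frame; symmetric and
  rigid-motion invariant.
* `distance_distributions` — per-target histogram of distance-to-anchor over
  frames. Default bin width 0.05 nm resolves ~0.1 nm features without
  empty-bin noise at a few thousand frames. Mean and sd are exact frame-wise
  statistics; the mode is the center of the maximal bin, ties broken toward
  the lowest distance. Bin edges are anchored at multiples of the bin width.
* `superpose` — Kabsch least-squares rigid superposition via
  `scipy.spatial.transform.Rotation.align_vectors`, which guarantees a proper
  rotation (det +1) even for reflection-dominated point sets; requires ≥ 3
  non-collinear points. The test suite checks it against an independent
  brute-force quaternion-grid minimizer.
* `rmsf` — every frame is superposed onto the first using a fit selection,
  then `RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩` per measured residue. When no fit
  selection is given, the residues outside the measured set are used (fit on
  the stable core, measure the mobile part); if fewer than 3 such residues
  exist the frames are taken as-is, which is the correct behavior for
  ensembles sampled in a fixed laboratory frame such as the anchored tether.
  For one residue jittered with isotropic per-axis Gaussian noise σ, RMSF
  converges to σ·√3.

## Synthetic-data defaults (the study conditions)

| Quantity | Default | Why |
|---|---|---|
| Decay lifetimes | 0.05 / 0.4 / 2.0 ms | artifact ≪ aggregation < reporter, on the ms scale of lanthanide donors |
| Decay amplitudes | 5000 / 2000 / 3000 counts | ~10⁴ peak counts, a realistic photon budget |
| Acquisition window | 0–10 ms, 5 µs step | ≥ 5 lifetimes of the slowest component |
| Titration noise | 1 % of F₀ | a clean fluorimeter reading |
| Quencher range | 0–0.5 M KI, 11 points | typical iodide titration |
| Bond length | 0.38 nm | Cα–Cα virtual bond |
| Tether length | 22 beads in regime tests | the first 22 residues form the mobile N-terminus/TM1A segment |
| Restraint | residue 5, k = 2000 kT/nm² | salt-bridge position; pins the bead to ~0.02 nm per axis |
| Frames | 3000–5000 | Monte-Carlo error ~1–2 % on second moments |

Seeds are explicit everywhere; no global random state is used or mutated.
Generators are bit-reproducible given (parameters, seed).

## Crystal-structure distances

`read_ensemble` + `ca_distance` reproduce published inter-residue distances
directly from deposited coordinates (for LeuT: Cα R11–A335 is 2.96 nm in the
inward-facing structure 3TT3 and 4.19 nm in the outward-occluded structure
2A56). The repository does not redistribute PDB data; the corresponding checks
in `tests/test_acceptance.py` expect one-time chain-A Cα extracts under
`data/` and report their absence otherwise.

## Known limitations

* The weighted-LS Poisson approximation biases lifetime estimates at very low
  counts (peak ≲ 10²); a full Poisson MLE is not implemented.
* Ambiguity detection relies on Gauss–Newton standard errors, which are
  optimistic for strongly correlated lifetime pairs (ratio ≲ 1.5).
* Metropolis frames in `outward_locked` mode are thinned, not independent;
  second-moment estimates are unaffected at the default thinning, but users
  computing rare-event statistics should increase it.
* The FJC ignores chain stiffness and excluded volume, so absolute widths of
  synthetic distance distributions are not comparable to those of real
  peptides; only relative (regime) comparisons are meaningful.
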