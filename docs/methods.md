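# Methods

This note documents the models, the synthetic study design, the numerical
choices, and what the tests do and do not establish about real data.

## The problem

A disordered protein is represented by an ensemble: conformers
`x_1 ... x_N` with weights `w_1 ... w_N` on the probability simplex.
Experiments measure ensemble averages of structural observables; an
optimizer adjusts the ensemble until the averages fit the data.  Because
many ensembles fit the same data, the outcome depends on the prior pool and
the optimizer.  The package implements both stages — pool construction and
optimization — plus the structural analytics used to compare outcomes, with
every input synthesized from a known ground truth so that correctness is
checkable.

## Synthetic conformers

Chains are grown residue by residue in internal coordinates (NeRF), with
ideal bond lengths/angles and a trans peptide; each residue carries N, H,
CA, C, O and (except glycine) CB.  Backbone dihedrals are drawn from a
three-basin library (helical (-62, -41); extended/PPII (-120, 130);
left-handed (60, 45); Gaussian widths 7/25/10 degrees).  The default coil
mixes the basins at (0.30, 0.62, 0.08), calibrated once so that the mean
radius of gyration of a 90-residue pool matches the excluded-volume scaling
prediction `Rg = 0.19 * L^0.588 nm` within a few percent.  Self-avoidance
is enforced as a hard 0.4 nm cutoff on nonadjacent CA pairs, with
per-residue resampling and whole-chain regrowth on failure.

Two style parameters create the contrasting pools:

* **Transient helices** are cooperative: each configured segment is switched
  on for a whole conformer with probability equal to its propensity, and
  switched-on residues sample the helical basin tightly.  Per-residue
  propensities measured by the DSSP-3 assignment then track the parameter.
* **Compaction** (`compaction_bias`) biases growth toward tertiary
  contacts: each placement is chosen among six clash-free candidates with
  Rosenbluth weights `exp(bias * n_contacts)`, a contact being a nonadjacent
  CA pair within 0.65 nm.  This collapses chains *through* contact
  formation, so compact pools carry genuine r^-6-visible close approaches
  and long-range hydrogen bonds anticorrelated with conformer size —
  qualitatively like force-field pools with attractive interactions.
  (Compacting by importance-resampling on Rg alone was tried first and
  rejected: it shrinks radii without creating contacts, which leaves the
  PRE observables uninformative at long range.)

Default styles: `coil` (no helices, no attraction), `matched` (two weak
segments, bias 0.3), `compact` (three stronger segments, bias 0.9).  Mean
Rg ordering compact < matched < coil holds with bootstrap confidence at
pool sizes of a few hundred.

## Ground truth and synthetic data

The ground truth is an exponential tilt of a pool's prior weights along a
scalar feature: `w*_i ∝ w0_i * exp(-c * f_i)` with `f` the conformer Rg (or
end-to-end distance).  A negative coefficient tilts toward expansion,
emulating the common situation that simulation pools are over-compact
relative to experiment.  Tilting keeps parameter recovery exact: every
observable's true value is the `w*`-weighted forward average.

Datasets are the truth averages plus Gaussian noise, with the noise level
recorded in the sigma column:

| observable | layout | noise (default) |
|---|---|---|
| SAXS `I(q)` | 40 points, q = 0.1–3.0 nm^-1 | 0.5% relative |
| chemical shifts | CA all residues, CB non-Gly (175 points) | 0.2 ppm |
| smFRET efficiency | one pair (residues 0, 89), R0 = 5.4 nm | 0.03 |
| PRE intensity ratios | 6 label sites (0, 20, 37, 63, 82, 89) x 89 residues | 0.05 |

These are realistic single-measurement precisions (sub-percent SAXS
statistics at low q; shift-predictor scatter; typical smFRET and PRE ratio
uncertainties).  The label sites place the construct's terminal and
internal spin labels on the 90-residue chain; the site-to-residue mapping is
configuration, not hard-coded.

## Forward models

All ensemble observables are weighted linear averages over conformers
except PRE, which averages `r^-6` before the rate is formed.

* **SAXS**: Debye sum over CA beads,
  `I(q) = f(q)^2 sum_ij sinc(q r_ij)` with a Gaussian bead form factor
  `f(q) = exp(-(q sigma_bead)^2 / 2)`, `sigma_bead = 0.31 nm`.  A scale and
  constant offset are re-fitted against the measured profile at every
  evaluation (closed-form weighted least squares), as measured intensities
  carry an arbitrary scale and background.  The bead-level model preserves
  the size/shape information the restraint carries; it is not an all-atom
  calculation with a hydration layer.
* **Chemical shifts**: residue-type random-coil reference values plus a
  secondary-structure offset driven by the conformer's DSSP-3 state
  (+0.7 ppm CA in helix, -0.7 ppm in extended; opposite sign on CB).  A
  deliberately transparent surrogate for a trained predictor: it makes CS
  data informative about exactly one thing (local secondary structure).
* **FRET**: `E = 1 / (1 + (r / R0)^6)` on the inter-site CA distance,
  averaged linearly over conformers.  No dye-linker cloud is modelled.
* **PRE**: the electron sits at the CB of the labelled residue (CA for
  glycine).  With `<r^-6>` the weighted ensemble average in nm^-6,

      Gamma_2 = K * <r^-6> * (4 tau_c + 3 tau_c / (1 + omega_H^2 tau_c^2))
      ratio   = R2 * exp(-Gamma_2 * t_d) / (R2 + Gamma_2)

  with defaults tau_c = 2 ns, t_d = 10 ms, R2 = 10 Hz,
  omega_H / 2 pi = 500 MHz, and the nitroxide point-dipole constant
  K = 1.23e-32 cm^6 s^-2.  A total correlation time tau_t = 0.5 ns is
  stored for completeness but unused by this simplified expression.  The
  model is inverted in closed form via the Lambert W function, which the
  subset selector uses to convert measured ratios into target distances.

## BME reweighting

The solver minimizes `L(w) = 1/2 chi2_total - theta * S_rel` in the logit
parametrization `w = softmax(z)` (L-BFGS, warm-startable), which enforces
positivity/normalization and the exponential posterior form by
construction; a damped fixed-point polish on the stationarity condition
sharpens the solution beyond the L-BFGS objective floor (the log-weights
then lie in the row space of the forward matrix to ~1e-6).  The SAXS
scale/offset is re-fitted inside every objective evaluation; its gradient
contribution vanishes at the inner optimum (envelope theorem).

`chi2_total = chi2_SAXS + chi2_CS + Omega * chi2_FRET` uses non-reduced
sums; `Omega` defaults to 75 and an `omega_scan` reports the trade-off
(chi2_FRET falls with Omega while chi2_SAXS is monitored).  The *reduced*
composite value reported in tables divides by the plain number of
datapoints.  CA and CB shifts enter chi2_CS with equal weight.

**Theta selection.**  A descending 12-point grid (3000 -> 1, geometric) is
solved with warm starts; chi2_total and N_eff are non-increasing along it.
The elbow is the maximum discrete (Menger) curvature of the
min-max-normalized **log** chi2_total vs **log** N_eff polyline — the
standard log-scale L-curve reading.  On linear scales the large-chi2 arm
dominates the normalization and the corner lands far too close to the
prior (measured: the recovered mean Rg was then biased by several times its
noise uncertainty).  Ties break toward larger theta (minimal perturbation).
A `validation-minimum` mode instead picks the theta minimizing the held-out
PRE score, which is the per-label-site RMSD of intensity ratios combined as
the root-mean-square over sites.

## Subset selection

The selector keeps an M-conformer subset (uniform weights), swapping one
member per trial against a uniformly drawn pool conformer, with Metropolis
acceptance on the weighted sum of target-normalized pseudo-energies and a
geometric annealing schedule (T0 = 1 in normalized units, alpha = 0.97, 300
trials per temperature, 60k-trial budget).  Restraints above target are
up-weighted by 1.2 every 100 trials (capped at 1e4).  Termination: all
normalized energies <= 1, or budget exhaustion (flagged, not raised).  The
proposal is symmetric, so at fixed temperature and fixed weights the chain
satisfies detailed balance; the test suite verifies the stationary
distribution on an enumerable 3-state toy.

**Targets.**  The default chi2 targets sit at an upper quantile,
`m + sqrt(2m)` (mean + 1 SD of a chi^2 with m degrees of freedom), because
a target at the mean is exceeded by the generating ensemble itself with
probability ~1/2 and "all restraints fit" would be a coin flip by
construction.  PRE pseudo-energies are harmonic in the effective distance
`d_eff = <r^-6>^(-1/6)` against targets obtained by inverting the
intensity-ratio model; points within one sigma of ratio = 1 are
statistically indistinguishable from "no enhancement" and carry zero
restraint.  Per-point distance tolerances are the larger of the
noise-propagated (delta-method) SD and a 0.5 nm floor — the conventional
generosity of PRE-derived distance bounds — summed into the target with the
same one-SD slack.  With materially tighter floors the measured behaviour
is pathological: finite subsets cannot reproduce heavy-tailed r^-6 averages
point-wise, runs cannot terminate, and the held-out FRET efficiency is
biased upward by about two experimental sigmas.

Five independent runs of M = 100 are concatenated into the 500-member
combined ensemble; terminal energies and trial counts are reported as
mean +- SD over runs.  The held-out FRET efficiency is scored as
`z_E = |E_ens - E_exp| / sigma` and never enters the energy.  Optional pool
replenishment replaces frequently-selected conformers (retention
probability ∝ 1/(1+count)) with freshly generated ones.

## Structural analytics

* **Rg**: CA point masses; ensemble `Rg^2 = sum_i w_i rg_i^2`, identical to
  the half-double-sum of mean square inter-residue distances (verified to
  1e-10).
* **Scaling maps**: weighted mean CA–CA distances normalized by a
  random-coil reference ensemble's own weighted means; posterior maps use
  the posterior weights.
* **DSSP-3**: Kabsch–Sander H-bond energies
  `E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)` kcal/mol
  (distances in Angstrom, bond if E < -0.5), n-turns (n = 3, 4, 5) with two
  consecutive turns making a helix, parallel/antiparallel bridge patterns
  making extended; helix takes precedence; everything else coil.  Bulge
  subtleties of the 8-state algorithm are omitted; the reduced assignment
  agrees with the reference DSSP implementation on the helix fixture.
  Missing amide hydrogens are rebuilt in the peptide plane.
* **H-bonds**: geometric criteria, H...O < 0.25 nm and N-H...O angle >
  120 degrees; tertiary-contact statistics use the |i-j| > 10 filter
  (0 disables it for secondary-structure work).  The per-conformer count
  PMF is weight-summed.
* **Pi-contacts**: planar groups (backbone amide planes always; side-chain
  planes when their atoms are present) with center distance <= 0.49 nm and
  normal angle <= 40 degrees, |i-j| > 10, classified bb-bb / sc-sc / sc-bb.
  This is a simplified center+normal test, not the full atom-overlap
  criterion; thresholds are configurable and the fixtures are defined
  relative to them.  Generated conformers carry only backbone + CB, so the
  sc classes are exercised with hand-built planar fixtures.
* **Weighted bootstrap**: resample N conformers with probabilities equal to
  the weights, evaluate the statistic on the resample with uniform weights,
  B = 1000 by default (the SD matches the closed-form SE of a weighted mean
  within a few percent at B = 2000).

## The study and its scale

`run_study` executes the whole design: three pools (default N = 250 each),
one dataset synthesized from an Rg-tilt (coefficient -1.0 nm^-1) of the
matched pool, BME (restrains SAXS+CS+FRET, validates PRE) and subset
selection (restrains SAXS+CS+PRE, validates FRET) on every pool, then the
weighted analytics and a six-row report.  The restraint/validation split is
fixed by construction.  Everything is deterministic given the master seed
(component seeds are spawned from it).  The between-prior spread of each
summary statistic is compared with the between-method spread; on the
default configuration the prior dominates every statistic, the helix
propensity most strongly.

The heavier validation scenario (`scenarios.recovery_scenario`) uses
N = 1000 compact-prior conformers and a -2.0 nm^-1 Rg tilt; pool sizes and
bootstrap depths throughout were chosen so the full test suite and the
acceptance script each complete in minutes on one CPU.

## What the synthetic study does not show

The generator emulates the statistical character of real pools — dimensions,
transient secondary structure, contact-driven compaction — but not their
physics: no side chains beyond CB, no solvent, no Boltzmann weighting, and
chemical shifts that respond to secondary structure only.  Passing tests
demonstrate that the optimizers and analytics behave correctly when their
assumptions hold (known truth inside the pool's span, calibrated noise).
They do not certify forward-model accuracy against real measurements, and
the quantitative results of the original integrative studies (which depend
on unpublished trajectories and experimental datasets) are out of scope.

## Known limitations

* The CS surrogate makes chemical shifts nearly redundant with the DSSP
  analytics; real shift predictors carry independent information and noise.
* PRE label placement ignores rotamer clouds; distances are CB-to-CB.
* Subset selection inherits the granularity of M = 100 averages: at data
  precisions far beyond the subset sampling scale its feasible set is a
  noise-cancelling family rather than truth-resembling subsets (the target
  calibration above accounts for this).
* The elbow detector assumes the scan brackets the trade-off corner; grids
  entirely inside the flat or steep regime yield a weak-elbow warning.
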