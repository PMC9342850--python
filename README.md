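# idpens — integrative conformational ensembles for disordered proteins

Intrinsically disordered proteins (IDPs) have no single native structure;
they are described by *conformational ensembles* — finite sets of 3D
structures with statistical weights.  Ensembles are usually obtained by
optimizing an initial conformer pool (a "prior") against ensemble-averaged
experimental data (SAXS, NMR chemical shifts, smFRET, PRE).  Because the
problem is badly underdetermined, the result depends both on the prior and
on the optimization method.  `idpens` implements, end to end and on fully
synthetic data, the machinery needed to study that dependence: it builds
contrasting prior pools for a 90-residue disordered chain, synthesizes
experimental datasets from a known ground truth, determines posterior
ensembles with two contrasting optimizers, and compares the posteriors
structurally.

It is written for structural-biology / biophysics researchers who want a
tested, reproducible sandbox for ensemble-optimization methodology.

## The two optimizers

**Bayesian Maximum Entropy (BME) reweighting.**  Posterior weights minimize

    L(w) = 1/2 * chi2_total(w) - theta * S_rel(w),
    chi2_total = chi2_SAXS + chi2_CS + Omega * chi2_FRET,
    S_rel = -sum_i w_i ln(w_i / w0_i) <= 0,     N_eff = exp(S_rel),

where the chi2 terms are non-reduced sums over datapoints, `theta > 0` sets
the confidence in the prior weights `w0`, and `Omega` (default 75)
compensates the single-datapoint FRET restraint for the hundreds of SAXS/CS
points.  `theta` is chosen by scanning a descending grid and locating the
L-curve elbow of the (chi2_total, N_eff) trade-off (or the minimum of a
held-out PRE validation score).  Six PRE intensity-ratio experiments are
never used as restraints; they validate the posterior.

**ENSEMBLE-style subset selection.**  A switching Monte-Carlo search under
simulated annealing selects fixed-size subsets of the pool, minimizing a
weighted sum of per-experiment pseudo-energies (chi2 for SAXS/CS, an
`<r^-6>^(-1/6)` distance harmonic for PRE), each normalized by a preset
target energy so that "below one" means fit.  Restraints above target are
periodically up-weighted; five independent 100-conformer runs are combined
into a 500-member posterior; the held-out smFRET efficiency is scored as
`z_E = |E_ens - E_exp| / sigma`.

## Worked example

```python
import numpy as np
from idpens import bme, scenarios

# compact prior pool (N=1000, 90 residues) with an expansion-tilted truth
scen = scenarios.recovery_scenario(n_conformers=1000, seed=7)

restraints  = {k: scen.forwards[k] for k in ("SAXS", "CS", "FRET")}
observables = {k: scen.datasets[k] for k in ("SAXS", "CS", "FRET")}
curve = bme.theta_scan(restraints, observables, scen.prior.prior_weights,
                       bme.ReweightConfig(), validation=scen.forwards["PRE"])
theta = bme.select_theta(curve, mode="elbow")
i = int(np.flatnonzero(curve.thetas == theta)[0])
res = curve.results[i]
print(f"theta* = {theta:.1f}")
print(f"N_eff = {res.diagnostics.neff:.2f}")
print(f"reduced chi2_total = {res.diagnostics.chi2_total_reduced:.2f}")
print(f"recovered mean Rg = {res.weights @ scen.truth.feature_values:.3f} nm")
print(f"truth mean Rg     = {scen.truth.mean_feature():.3f} nm")
```

prints

```
theta* = 38.1
N_eff = 0.64
reduced chi2_total = 0.92
recovered mean Rg = 2.507 nm
truth mean Rg     = 2.532 nm
```

i.e. the scan keeps 64% of the prior's effective conformers, fits the data
at about the noise level, and recovers the ground-truth mean radius of
gyration of the tilted ensemble to 0.025 nm — within the noise-replicate
uncertainty of the estimate.

## The study pipeline

The numbered drivers under `analysis/` run the full comparison as a
narrative (each stage writes TSV/PDB artifacts under `results/pipeline`):

```
python analysis/01_generate_priors.py     # coil / matched / compact pools
python analysis/02_synthesize_data.py     # SAXS, CS, FRET, PRE tables
python analysis/03_reweight_bme.py        # theta scans + posterior weights
python analysis/04_select_mc.py           # 5x100 subset selections + traces
python analysis/05_analyze_ensembles.py   # DSSP-3, H-bonds, pi, scaling maps
python analysis/06_compare.py             # prior vs method decomposition
```

The same study runs in one call as `idpens.study.run_study(RunConfig())`.
On the default configuration the between-prior spread of helix propensity
(~0.21) exceeds the between-method spread (~0.02) by an order of magnitude:
the prior pool shapes the posterior far more than the optimizer does.

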