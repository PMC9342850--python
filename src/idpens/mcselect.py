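"""Subset selection by switching Monte Carlo under simulated annealing.

The selector keeps a fixed-size subset of the conformer pool and, at each
trial, swaps one member for a pool conformer chosen uniformly at random.
The move is accepted if it lowers the total pseudo-energy, otherwise with
Metropolis probability ``exp(-dE/T)``; the temperature follows a geometric
annealing schedule.  Each restraint's pseudo-energy is normalized by a
preset target energy, so a normalized value below one means that restraint
is "fit"; optimization terminates when every restraint is fit (or the trial
budget runs out, which is flagged, not raised).  Restraints sitting above
their target are periodically up-weighted.

Restraint energies over a subset (uniform weights within the subset):

* SAXS / CS -- non-reduced chi^2 of the subset-average observables (with the
  usual scale/offset fit for SAXS);
* PRE -- a harmonic distance restraint on the effective distance
  ``d_eff = <r^-6>^(-1/6)`` against the target distance obtained by
  inverting the intensity-ratio forward model (points with ratio exactly 1
  carry no distance information and are excluded).

The protocol runs several independent selections and concatenates their
subsets into the combined posterior ensemble (five runs of 100 -> 500
members), reporting the mean and SD of terminal energies and trial counts
across runs.  A single held-out FRET efficiency is tracked as a z-score
``z_E = |E_subset - E_exp| / sigma`` and never enters the energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import Ensemble, ObservableSet, ValidationError
from .forward import (
    ForwardMatrix,
    PREParams,
    fit_scale_offset,
    r6_from_ratio,
)

__all__ = [
    "AnnealSchedule",
    "PseudoEnergySpec",
    "SelectionProblem",
    "SelectionResult",
    "CombinedSelection",
    "pseudo_energies",
    "anneal_select",
    "run_replicates",
    "replenish_pool",
    "z_test_fret",
]


@dataclass
class AnnealSchedule:
    """Geometric simulated-annealing schedule (energies are target-normalized)."""

    t0: float = 1.0
    alpha: float = 0.97
    trials_per_temperature: int = 300
    max_trials: int = 60_000

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("cooling factor alpha must be in (0, 1)")
        if self.t0 <= 0:
            raise ValidationError("T0 must be positive")


@dataclass
class PseudoEnergySpec:
    """Targets and adaptive weights of the restraint pseudo-energies.

    Default targets are upper chi^2 quantiles rather than the chi^2 mean:
    for SAXS/CS the target is ``m + k sqrt(2m)`` (the mean plus ``k``
    standard deviations of a chi^2 with m degrees of freedom), because a
    target at the mean is exceeded by the generating ensemble itself with
    probability ~1/2 and "all restraints fit" would be unattainable by
    construction.  The PRE harmonic target propagates the ratio noise into
    distance tolerances (floored at ``pre_tolerance_nm``) and takes the same
    ``k``-sigma slack.  All targets are configurable.
    """

    targets: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    gamma: float = 1.2          # up-weighting factor for unfit restraints
    adapt_every: int = 100      # trials between weight adaptations
    max_weight: float = 1e4     # cap on adapted restraint weights
    target_nsigma: float = 1.0  # chi^2 quantile slack of the default targets
    pre_tolerance_nm: float = 0.5
    pre_exclude_nsigma: float = 1.0  # drop PRE points with ratio >= 1 - n*sigma

    def __post_init__(self) -> None:
        if self.gamma <= 1.0:
            raise ValidationError("gamma must exceed 1")
        for t in self.targets.values():
            if t <= 0:
                raise ValidationError("target energies must be positive")
        for w in self.weights.values():
            if w <= 0:
                raise ValidationError("restraint weights must be positive")


class SelectionProblem:
    """Precomputed per-conformer data for fast subset energy evaluation."""

    def __init__(
        self,
        forwards: dict[str, ForwardMatrix],
        spec: PseudoEnergySpec | None = None,
        pre_params: PREParams | None = None,
        fit_saxs: bool = True,
    ) -> None:
        self.spec = spec or PseudoEnergySpec()
        self.pre_params = pre_params or PREParams()
        # SAXS intensities are compared after the usual scale/offset fit
        # (measured profiles carry an arbitrary scale and background)
        self.fit_saxs = fit_saxs
        self.kinds = list(forwards)
        self.forwards = forwards
        self.matrices: dict[str, np.ndarray] = {}
        self.obs: dict[str, ObservableSet] = {}
        self.pre_d_target: np.ndarray | None = None
        n_conf = None
        for kind, fm in forwards.items():
            if kind == "FRET":
                raise ValidationError(
                    "FRET is reserved for validation and cannot be a restraint"
                )
            self.matrices[kind] = fm.matrix
            self.obs[kind] = fm.observables
            n_conf = fm.matrix.shape[0] if n_conf is None else n_conf
            if fm.matrix.shape[0] != n_conf:
                raise ValidationError("forward matrices disagree on pool size")
        if n_conf is None:
            raise ValidationError("at least one restraint is required")
        self.n_conformers = n_conf
        if "PRE" in forwards:
            obs_pre = forwards["PRE"].observables
            ratios = obs_pre.values
            sig = obs_pre.sigmas
            # a ratio statistically indistinguishable from 1 carries no
            # distance information: the inverse model diverges there
            uninformative = ratios >= 1.0 - self.spec.pre_exclude_nsigma * sig
            r6 = r6_from_ratio(np.clip(ratios, 1e-9, 1.0 - 1e-12), self.pre_params)
            with np.errstate(divide="ignore"):
                d = np.where(r6 > 0, r6 ** (-1.0 / 6.0), np.inf)
            d[uninformative] = np.inf
            n_excluded = int(np.sum(~np.isfinite(d)))
            if n_excluded:
                warnings.warn(
                    f"{n_excluded} PRE datapoints are within "
                    f"{self.spec.pre_exclude_nsigma} sigma of ratio 1 (no "
                    "distance information) and carry zero restraint"
                )
            self.pre_d_target = d
        # fill default targets/weights
        k = self.spec.target_nsigma
        for kind in self.kinds:
            if kind not in self.spec.targets:
                if kind == "PRE":
                    self.spec.targets[kind] = self._pre_default_target()
                else:
                    m = float(len(self.obs[kind]))
                    self.spec.targets[kind] = m + k * np.sqrt(2.0 * m)
            self.spec.weights.setdefault(kind, 1.0)

    def _pre_default_target(self) -> float:
        """Noise-propagated harmonic target for the PRE distance restraints.

        Per retained point the tolerance is the larger of the configured
        floor and the delta-method SD of the target distance,
        ``|d d/d ratio| * sigma``; the target energy is the sum of squared
        tolerances, so the generating ensemble is expected to sit at a
        normalized energy of about one.
        """
        obs = self.obs["PRE"]
        valid = np.isfinite(self.pre_d_target)
        ratios = obs.values[valid]
        sig = obs.sigmas[valid]
        lo = np.clip(ratios - sig, 1e-9, 1.0 - 1e-12)
        hi = np.clip(ratios + sig, 1e-9, 1.0 - 1e-12)
        d_lo = r6_from_ratio(lo, self.pre_params) ** (-1.0 / 6.0)
        d_hi = r6_from_ratio(hi, self.pre_params) ** (-1.0 / 6.0)
        sd = 0.5 * np.abs(d_hi - d_lo)
        tol = np.maximum(sd, self.spec.pre_tolerance_nm)
        t2 = tol * tol
        return float(t2.sum() + self.spec.target_nsigma * np.sqrt(2.0 * np.sum(t2 * t2)))

    def column_sums(self, subset: np.ndarray) -> dict[str, np.ndarray]:
        return {k: self.matrices[k][subset].sum(axis=0) for k in self.kinds}

    def raw_energy(self, kind: str, mean_vec: np.ndarray) -> float:
        obs = self.obs[kind]
        if kind == "SAXS":
            if self.fit_saxs:
                _s, _c, mean_vec = fit_scale_offset(mean_vec, obs)
            r = (mean_vec - obs.values) / obs.sigmas
            return float(r @ r)
        if kind == "CS":
            r = (mean_vec - obs.values) / obs.sigmas
            return float(r @ r)
        if kind == "PRE":
            valid = np.isfinite(self.pre_d_target)
            d_eff = np.clip(mean_vec[valid], 1e-30, None) ** (-1.0 / 6.0)
            diff = d_eff - self.pre_d_target[valid]
            return float(diff @ diff)
        raise ValidationError(f"unknown restraint kind {kind!r}")

    def energies(self, subset: Sequence[int]) -> dict[str, tuple[float, float]]:
        subset = np.asarray(subset, dtype=int)
        sums = self.column_sums(subset)
        out = {}
        for k in self.kinds:
            raw = self.raw_energy(k, sums[k] / subset.size)
            out[k] = (raw, raw / self.spec.targets[k])
        return out


def pseudo_energies(
    subset: Sequence[int],
    forwards: dict[str, ForwardMatrix],
    spec: PseudoEnergySpec | None = None,
    pre_params: PREParams | None = None,
) -> dict[str, dict[str, float]]:
    """Raw and target-normalized pseudo-energies of a subset (uniform weights).

    Returns ``{kind: {"raw": ..., "normalized": ..., "fit": bool}}``.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValidationError("subset must be non-empty")
    problem = SelectionProblem(forwards, spec, pre_params)
    out = {}
    for kind, (raw, norm) in problem.energies(subset).items():
        out[kind] = {"raw": raw, "normalized": norm, "fit": bool(norm <= 1.0)}
    return out


@dataclass
class SelectionResult:
    """One annealing run: final subset, convergence flag and per-trial traces."""

    selected: np.ndarray
    converged: bool
    n_trials: int
    trace: pd.DataFrame
    final_energies: dict[str, tuple[float, float]]
    restraint_weights: dict[str, float]
    selection_counts: np.ndarray
    seed: int | None = None

    @property
    def total_energy(self) -> float:
        return float(sum(raw for raw, _n in self.final_energies.values()))


def anneal_select(
    problem: SelectionProblem,
    m_subset: int,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    fret_validation: ObservableSet | None = None,
    fret_matrix: np.ndarray | None = None,
    record_every: int = 10,
    adapt_weights: bool = True,
    stop_when_fit: bool = True,
    fixed_temperature: float | None = None,
) -> SelectionResult:
    """One switching-MC selection run under simulated annealing.

    Each trial swaps one subset member for a uniformly drawn pool conformer;
    acceptance is Metropolis on the weighted sum of target-normalized
    energies.  Every ``spec.adapt_every`` trials restraints with normalized
    energy above one are up-weighted by ``gamma``.  Terminates when all
    restraints are fit (normalized <= 1) or the budget is exhausted
    (``converged=False``).  Deterministic under a fixed seed.

    ``fixed_temperature`` (with ``adapt_weights=False``,
    ``stop_when_fit=False``) runs a plain Metropolis chain, e.g. for
    stationarity checks.
    """
    schedule = schedule or AnnealSchedule()
    spec = problem.spec
    n = problem.n_conformers
    if m_subset > n:
        raise ValidationError("subset size exceeds pool size")
    rng = np.random.default_rng(seed)
    subset = rng.choice(n, size=m_subset, replace=False)
    in_subset = np.zeros(n, dtype=bool)
    in_subset[subset] = True
    counts = np.zeros(n, dtype=int)
    counts[subset] += 1

    sums = problem.column_sums(subset)
    omega = dict(spec.weights)

    def normalized(sums_):
        return {
            k: problem.raw_energy(k, sums_[k] / m_subset) / spec.targets[k]
            for k in problem.kinds
        }

    def total(norm):
        return sum(omega[k] * norm[k] for k in problem.kinds)

    fret_e = None
    if fret_validation is not None:
        if fret_matrix is None:
            raise ValidationError("fret_matrix required with fret_validation")
        fret_e = np.asarray(fret_matrix, dtype=float).reshape(n)

    norm = normalized(sums)
    e_tot = total(norm)
    t = schedule.t0 if fixed_temperature is None else fixed_temperature

    rows = []

    def record(trial):
        row = {"trial": trial, "temperature": t}
        for k in problem.kinds:
            row[f"E_{k}"] = norm[k]
        if fret_e is not None:
            e_sub = fret_e[subset].mean()
            row["E_fret"] = e_sub
            row["z_E"] = abs(e_sub - fret_validation.values[0]) / fret_validation.sigmas[0]
        rows.append(row)

    record(0)
    converged = all(v <= 1.0 for v in norm.values())
    trial = 0
    while trial < schedule.max_trials and not (converged and stop_when_fit):
        trial += 1
        if fixed_temperature is None and trial % schedule.trials_per_temperature == 0:
            t = max(t * schedule.alpha, 1e-6)
        out_pos = rng.integers(m_subset)
        out_idx = subset[out_pos]
        in_idx = int(rng.integers(n))
        if in_subset[in_idx]:
            if record_every and trial % record_every == 0:
                record(trial)
            continue
        new_sums = {
            k: sums[k] + problem.matrices[k][in_idx] - problem.matrices[k][out_idx]
            for k in problem.kinds
        }
        new_norm = normalized(new_sums)
        new_tot = total(new_norm)
        de = new_tot - e_tot
        if de <= 0 or rng.random() < np.exp(-de / t):
            subset[out_pos] = in_idx
            in_subset[out_idx] = False
            in_subset[in_idx] = True
            counts[in_idx] += 1
            sums = new_sums
            norm = new_norm
            e_tot = new_tot
        if adapt_weights and trial % spec.adapt_every == 0:
            changed = False
            for k in problem.kinds:
                if norm[k] > 1.0 and omega[k] < spec.max_weight:
                    omega[k] = min(omega[k] * spec.gamma, spec.max_weight)
                    changed = True
            if changed:
                e_tot = total(norm)
        if record_every and trial % record_every == 0:
            record(trial)
        converged = all(v <= 1.0 for v in norm.values())

    record(trial)
    final = {k: (norm[k] * spec.targets[k], norm[k]) for k in problem.kinds}
    return SelectionResult(
        selected=np.sort(subset.copy()),
        converged=all(v <= 1.0 for v in norm.values()),
        n_trials=trial,
        trace=pd.DataFrame(rows),
        final_energies=final,
        restraint_weights=omega,
        selection_counts=counts,
        seed=seed,
    )


@dataclass
class CombinedSelection:
    """Multi-run selection: concatenated subset ensemble plus run statistics."""

    runs: list[SelectionResult]
    combined_indices: np.ndarray
    energy_mean: float
    energy_sd: float
    trials_mean: float
    trials_sd: float
    all_converged: bool
    z_fret: float | None = None


def run_replicates(
    problem: SelectionProblem,
    m_subset: int = 100,
    n_runs: int = 5,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    fret_validation: ObservableSet | None = None,
    fret_matrix: np.ndarray | None = None,
    record_every: int = 10,
) -> CombinedSelection:
    """Independent selection runs combined by concatenation (uniform weights).

    With the defaults this is the five-runs-of-100 protocol giving a
    500-conformer combined ensemble.  Terminal total energies and trial
    counts are summarized as mean +- SD across runs.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    runs = []
    for s in seeds:
        run_seed = int(s.generate_state(1)[0] % (2**31))
        runs.append(
            anneal_select(
                problem,
                m_subset,
                schedule=schedule,
                seed=run_seed,
                fret_validation=fret_validation,
                fret_matrix=fret_matrix,
                record_every=record_every,
            )
        )
    combined = np.concatenate([r.selected for r in runs])
    energies = np.array([r.total_energy for r in runs])
    trials = np.array([r.n_trials for r in runs], dtype=float)
    z = None
    if fret_validation is not None and fret_matrix is not None:
        e_comb = float(np.asarray(fret_matrix).reshape(-1)[combined].mean())
        z = abs(e_comb - fret_validation.values[0]) / float(fret_validation.sigmas[0])
    return CombinedSelection(
        runs=runs,
        combined_indices=combined,
        energy_mean=float(energies.mean()),
        energy_sd=float(energies.std(ddof=0)),
        trials_mean=float(trials.mean()),
        trials_sd=float(trials.std(ddof=0)),
        all_converged=all(r.converged for r in runs),
        z_fret=z,
    )


def replenish_pool(
    pool: Ensemble,
    generator: Callable[[int], "Ensemble"],
    selection_counts: np.ndarray,
    n_new: int | None = None,
    seed: int = 0,
) -> tuple[Ensemble, np.ndarray]:
    """Replace often-selected conformers with freshly generated ones.

    Retention is stochastic with probability proportional to
    ``1 / (1 + count)``, so the most-selected conformers are the most likely
    to be replaced; ``generator(n)`` must return ``n`` new conformers on the
    same topology.  Pool size is preserved and new members start with count 0.
    """
    counts = np.asarray(selection_counts, dtype=float)
    if counts.size != pool.n:
        raise ValidationError("selection_counts must match pool size")
    n_new = max(1, pool.n // 10) if n_new is None else int(n_new)
    if not (0 < n_new < pool.n):
        raise ValidationError("n_new must be in (0, pool size)")
    rng = np.random.default_rng(seed)
    p = 1.0 / (1.0 + counts)
    p = p / p.sum()
    keep = np.sort(rng.choice(pool.n, size=pool.n - n_new, replace=False, p=p))
    fresh = generator(n_new)
    if fresh.topology != pool.topology:
        raise ValidationError("generator returned conformers on another topology")
    new_conformers = [pool.conformers[i] for i in keep] + list(fresh.conformers)
    new_counts = np.concatenate([counts[keep].astype(int), np.zeros(n_new, dtype=int)])
    return Ensemble(new_conformers), new_counts


def z_test_fret(
    efficiencies: np.ndarray | float, fret_obs: ObservableSet
) -> float:
    """FRET validation z-score ``|E_ens - E_exp| / sigma``.

    ``efficiencies`` is either the per-conformer efficiency vector of a
    uniform-weight ensemble or an already-averaged scalar.
    """
    if fret_obs.kind != "FRET" or len(fret_obs) != 1:
        raise ValidationError("z-test needs a single-pair FRET observable")
    sigma = float(fret_obs.sigmas[0])
    if sigma <= 0:
        raise ValidationError("FRET sigma must be positive")
    e = float(np.mean(np.asarray(efficiencies, dtype=float)))
    return abs(e - float(fret_obs.values[0])) / sigma
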