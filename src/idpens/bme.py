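"""Bayesian Maximum Entropy reweighting with a composite, FRET-upweighted chi^2.

The posterior weights minimize

    L(w) = 1/2 * chi2_total(w) - theta * S_rel(w)

over the probability simplex, where ``chi2_total = chi2_SAXS + chi2_CS +
Omega * chi2_FRET`` is a sum of *non-reduced* chi^2 terms, ``S_rel =
-sum_i w_i ln(w_i / w0_i) <= 0`` is the relative entropy against the prior
weights, and ``theta > 0`` sets the confidence in the prior.  The scalar
``Omega`` compensates the single-datapoint FRET restraint for the many
SAXS/CS datapoints.  ``N_eff = exp(S_rel)`` is the effective fraction of
conformers retained.

The solver works in the mean-shifted logit parametrization
``w = softmax(z)`` with ``z`` initialized at ``ln w0``, which enforces
positivity and normalization by construction and is warm-startable across a
theta scan.  For SAXS, an overall scale and offset are re-fitted against the
weighted-average profile at every objective evaluation (the gradient through
the fit vanishes at the inner optimum, so the outer gradient treats the
fitted scale/offset as constants).

Hyperparameters are chosen the way such scans are usually read: a
descending theta grid is solved with warm starts, and theta* is taken either
at the elbow (maximum discrete curvature of the normalized chi2_total vs
N_eff polyline) or at the minimum of a held-out PRE validation score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .core import ObservableSet, ValidationError, validate_weights
from .forward import ForwardMatrix, PREParams, fit_scale_offset, ratio_from_r6

__all__ = [
    "ReweightConfig",
    "FitDiagnostics",
    "ReweightResult",
    "ScanCurve",
    "chi2",
    "srel",
    "bme_solve",
    "theta_scan",
    "select_theta",
    "omega_scan",
    "pre_validation_score",
]

RESTRAINT_KINDS = ("SAXS", "CS", "FRET")


@dataclass
class ReweightConfig:
    """BME hyperparameters and solver settings."""

    theta: float = 100.0
    omega: float = 75.0
    theta_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(3000.0, 1.0, 12)
    )
    omega_grid: tuple[float, ...] = (1.0, 5.0, 25.0, 75.0, 150.0)
    tol: float = 1e-12
    gtol: float = 1e-10
    max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.theta <= 0 or self.omega <= 0:
            raise ValidationError("theta and omega must be positive")
        self.theta_grid = np.asarray(self.theta_grid, dtype=float)
        if self.theta_grid.size and np.any(np.diff(self.theta_grid) > 0):
            raise ValidationError("theta grid must be sorted descending")


@dataclass
class FitDiagnostics:
    """Per-experiment and composite fit diagnostics at a weight vector."""

    chi2_by_kind: dict[str, float]
    n_points: dict[str, int]
    omega: float
    srel: float
    pre_score: float | None = None

    @property
    def chi2_total(self) -> float:
        """Omega-weighted sum of non-reduced chi^2 terms."""
        total = 0.0
        for kind, c in self.chi2_by_kind.items():
            total += (self.omega if kind == "FRET" else 1.0) * c
        return total

    @property
    def chi2_total_reduced(self) -> float:
        """chi2_total over the plain number of datapoints (all experiments)."""
        m = sum(self.n_points.values())
        return self.chi2_total / m if m else float("nan")

    def chi2_reduced(self, kind: str) -> float:
        return self.chi2_by_kind[kind] / self.n_points[kind]

    @property
    def neff(self) -> float:
        return float(np.exp(self.srel))


@dataclass
class ReweightResult:
    weights: np.ndarray
    theta: float
    omega: float
    diagnostics: FitDiagnostics
    converged: bool
    n_iter: int
    message: str = ""
    saxs_scale: tuple[float, float] | None = None


@dataclass
class ScanCurve:
    """Theta-scan diagnostics plus the selected theta."""

    thetas: np.ndarray
    diagnostics: list[FitDiagnostics]
    results: list[ReweightResult]
    chosen_theta: float | None = None
    selection_mode: str | None = None

    def column(self, name: str) -> np.ndarray:
        return np.array([getattr(d, name) for d in self.diagnostics])


def chi2(weights: np.ndarray, fm: ForwardMatrix, obs: ObservableSet) -> float:
    """Non-reduced chi^2 of the weighted ensemble average against the data.

    For SAXS the scale/offset fit is applied to the weighted-average curve
    before forming residuals.
    """
    if fm.matrix.shape[1] != len(obs):
        raise ValidationError("forward matrix and observables are misaligned")
    w = np.asarray(weights, dtype=float)
    avg = fm.average(w)
    if fm.kind == "SAXS":
        _s, _c, avg = fit_scale_offset(avg, obs)
    r = (avg - obs.values) / obs.sigmas
    return float(r @ r)


def srel(weights: np.ndarray, prior_weights: np.ndarray) -> float:
    """Relative entropy ``-sum_i w_i ln(w_i/w0_i)`` (<= 0, 0 iff w = w0).

    Zero posterior weights contribute 0 (x ln x -> 0); positive posterior
    weight on zero prior weight is a support violation.
    """
    w = validate_weights(weights)
    w0 = validate_weights(prior_weights, w.size)
    pos = w > 0
    if np.any(pos & (w0 == 0)):
        raise ValidationError("posterior support exceeds prior support")
    return float(-np.sum(w[pos] * np.log(w[pos] / w0[pos])))


def _check_datasets(
    forwards: dict[str, ForwardMatrix], observables: dict[str, ObservableSet]
) -> None:
    if not forwards:
        raise ValidationError("at least one restraint set is required")
    for kind, fm in forwards.items():
        if kind not in RESTRAINT_KINDS:
            raise ValidationError(f"{kind} cannot be used as a BME restraint here")
        if fm.kind != kind or observables[kind] is not fm.observables:
            if fm.kind != kind or len(observables[kind]) != fm.matrix.shape[1]:
                raise ValidationError(f"misaligned forward matrix for {kind}")


def bme_solve(
    forwards: dict[str, ForwardMatrix],
    observables: dict[str, ObservableSet],
    prior_weights: np.ndarray,
    config: ReweightConfig,
    z0: np.ndarray | None = None,
) -> ReweightResult:
    """Minimize ``1/2 chi2_total - theta * S_rel`` over the simplex.

    ``z0`` warm-starts the logit parameters (e.g. from the previous point of
    a theta scan).  The result carries per-experiment diagnostics; a
    non-converged optimizer is flagged, not raised.
    """
    _check_datasets(forwards, observables)
    w0 = validate_weights(prior_weights)
    n = w0.size
    theta, omega = config.theta, config.omega
    log_w0 = np.log(np.clip(w0, 1e-300, None))

    kinds = list(forwards)
    mats = {k: forwards[k].matrix for k in kinds}
    ys = {k: observables[k].values for k in kinds}
    sig = {k: observables[k].sigmas for k in kinds}
    weight_of = {k: (omega if k == "FRET" else 1.0) for k in kinds}

    def objective(z: np.ndarray):
        zs = z - z.max()
        e = np.exp(zs)
        w = e / e.sum()
        grad_w = theta * (np.log(np.clip(w, 1e-300, None)) - log_w0 + 1.0)
        f = 0.0
        for k in kinds:
            avg = w @ mats[k]
            if k == "SAXS":
                s, c, scaled = fit_scale_offset(avg, forwards[k].observables)
                r = (scaled - ys[k]) / sig[k]
                f += 0.5 * weight_of[k] * float(r @ r)
                grad_w += weight_of[k] * ((r / sig[k]) * s) @ mats[k].T
            else:
                r = (avg - ys[k]) / sig[k]
                f += 0.5 * weight_of[k] * float(r @ r)
                grad_w += weight_of[k] * (r / sig[k]) @ mats[k].T
        # entropy part of the objective
        f += theta * float(np.sum(w * (np.log(np.clip(w, 1e-300, None)) - log_w0)))
        grad_z = w * (grad_w - float(w @ grad_w))
        return f, grad_z

    z_init = log_w0.copy() if z0 is None else np.asarray(z0, dtype=float).copy()
    res = minimize(
        objective,
        z_init,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_iter,
            "ftol": config.tol,
            "gtol": config.gtol,
            "maxcor": 20,
        },
    )
    z = res.x - res.x.max()
    w = np.exp(z)
    w /= w.sum()

    # polish: damped fixed-point iteration on the stationarity condition
    # ln(w/w0) = -grad(1/2 chi2)/theta + const, which sharpens the
    # exponential form beyond the L-BFGS objective-difference floor
    def data_grad(w_):
        g = np.zeros_like(w_)
        for k in kinds:
            avg = w_ @ mats[k]
            if k == "SAXS":
                s, c, scaled = fit_scale_offset(avg, forwards[k].observables)
                r = (scaled - ys[k]) / sig[k]
                g += weight_of[k] * ((r / sig[k]) * s) @ mats[k].T
            else:
                r = (avg - ys[k]) / sig[k]
                g += weight_of[k] * (r / sig[k]) @ mats[k].T
        return g

    def objective_at(w_):
        f = 0.0
        for k in kinds:
            avg = w_ @ mats[k]
            if k == "SAXS":
                _s, _c, avg = fit_scale_offset(avg, forwards[k].observables)
            r = (avg - ys[k]) / sig[k]
            f += 0.5 * weight_of[k] * float(r @ r)
        f += theta * float(np.sum(w_ * (np.log(np.clip(w_, 1e-300, None)) - log_w0)))
        return f

    f_best = objective_at(w)
    z_cur = np.log(np.clip(w, 1e-300, None))
    for _ in range(100):
        z_new = log_w0 - data_grad(w) / theta
        z_cur = 0.5 * z_cur + 0.5 * z_new
        w_new = np.exp(z_cur - z_cur.max())
        w_new /= w_new.sum()
        f_new = objective_at(w_new)
        if f_new > f_best + 1e-12 * max(1.0, abs(f_best)):
            break
        w = w_new
        f_best = f_new

    diagnostics = evaluate_diagnostics(w, forwards, observables, w0, omega)
    saxs_scale = None
    if "SAXS" in forwards:
        s, c, _ = fit_scale_offset(w @ mats["SAXS"], forwards["SAXS"].observables)
        saxs_scale = (s, c)
    return ReweightResult(
        weights=w,
        theta=theta,
        omega=omega,
        diagnostics=diagnostics,
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
        saxs_scale=saxs_scale,
    )


def evaluate_diagnostics(
    weights: np.ndarray,
    forwards: dict[str, ForwardMatrix],
    observables: dict[str, ObservableSet],
    prior_weights: np.ndarray,
    omega: float,
    pre_score: float | None = None,
) -> FitDiagnostics:
    chis = {k: chi2(weights, forwards[k], observables[k]) for k in forwards}
    npts = {k: len(observables[k]) for k in forwards}
    return FitDiagnostics(
        chi2_by_kind=chis,
        n_points=npts,
        omega=omega,
        srel=srel(weights, prior_weights),
        pre_score=pre_score,
    )


def pre_validation_score(
    weights: np.ndarray,
    pre_forward: ForwardMatrix,
    params: PREParams | None = None,
) -> float:
    """Held-out PRE score: per-label-site RMSD of intensity ratios, then the
    root-mean-square of the site RMSDs."""
    params = params or PREParams()
    obs = pre_forward.observables
    if obs.kind != "PRE":
        raise ValidationError("pre_validation_score needs a PRE forward matrix")
    r6_mean = pre_forward.average(np.asarray(weights, dtype=float))
    calc = ratio_from_r6(r6_mean, params)
    sites = obs.meta["label_site"].to_numpy()
    rmsds = []
    for site in pd_unique(sites):
        m = sites == site
        if not np.any(m):
            warnings.warn(f"PRE label site {site} has no datapoints; skipped")
            continue
        d = calc[m] - obs.values[m]
        rmsds.append(np.sqrt(np.mean(d * d)))
    if not rmsds:
        raise ValidationError("no PRE datapoints")
    rmsds = np.asarray(rmsds)
    return float(np.sqrt(np.mean(rmsds * rmsds)))


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values preserving first appearance."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def theta_scan(
    forwards: dict[str, ForwardMatrix],
    observables: dict[str, ObservableSet],
    prior_weights: np.ndarray,
    config: ReweightConfig,
    validation: ForwardMatrix | None = None,
    pre_params: PREParams | None = None,
) -> ScanCurve:
    """Solve along the descending theta grid with warm starts.

    Per theta the scan records the full diagnostics and, when a held-out PRE
    forward matrix is given, the PRE validation score (never used as a
    restraint).  Failed points are flagged via ``converged`` and kept.
    """
    grid = np.asarray(config.theta_grid, dtype=float)
    if np.any(np.diff(grid) > 0):
        raise ValidationError("theta grid must be descending")
    results: list[ReweightResult] = []
    diags: list[FitDiagnostics] = []
    z0 = None
    for theta in grid:
        cfg = replace(config, theta=float(theta))
        res = bme_solve(forwards, observables, prior_weights, cfg, z0=z0)
        z0 = np.log(np.clip(res.weights, 1e-300, None))
        if validation is not None:
            res.diagnostics.pre_score = pre_validation_score(
                res.weights, validation, pre_params
            )
        results.append(res)
        diags.append(res.diagnostics)
    return ScanCurve(thetas=grid, diagnostics=diags, results=results)


def select_theta(curve: ScanCurve, mode: str = "elbow") -> float:
    """Choose theta* from a scan.

    ``elbow``: theta maximizing the discrete (Menger) curvature of the
    min-max-normalized (log chi2_total, log N_eff) polyline -- the corner is
    located on log scales, as is standard for L-curve analysis, because on
    linear scales the large-chi2 arm of the curve dominates the
    normalization and drags the corner toward the prior.
    ``validation-minimum``: theta minimizing the held-out PRE score.  Ties
    break toward larger theta (closer to the prior).
    """
    if curve.thetas.size < 4:
        raise ValidationError("theta selection needs at least 4 scan points")
    if mode == "validation-minimum":
        scores = curve.column("pre_score")
        if np.any([s is None for s in scores]):
            raise ValidationError("scan has no PRE validation scores")
        scores = scores.astype(float)
        best = np.flatnonzero(scores <= scores.min() + 1e-15)
        theta = float(curve.thetas[best[0]])  # grid descending: first = largest
    elif mode == "elbow":
        x = np.log(np.clip(curve.column("chi2_total"), 1e-300, None))
        y = np.log(np.clip([d.neff for d in curve.diagnostics], 1e-300, None))
        x = _minmax(x)
        y = _minmax(y)
        curv = np.zeros(curve.thetas.size)
        for i in range(1, curve.thetas.size - 1):
            curv[i] = _menger(x[i - 1 : i + 2], y[i - 1 : i + 2])
        if curv.max() - curv.min() < 1e-12:
            warnings.warn("weak elbow: trade-off curve is nearly straight")
        best = np.flatnonzero(curv >= curv.max() - 1e-15)
        theta = float(curve.thetas[best[0]])
    else:
        raise ValidationError(f"unknown selection mode {mode!r}")
    curve.chosen_theta = theta
    curve.selection_mode = mode
    return theta


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-300:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def _menger(x: np.ndarray, y: np.ndarray) -> float:
    """Curvature of the circumcircle through three points."""
    a = np.hypot(x[1] - x[0], y[1] - y[0])
    b = np.hypot(x[2] - x[1], y[2] - y[1])
    c = np.hypot(x[2] - x[0], y[2] - y[0])
    area2 = abs((x[1] - x[0]) * (y[2] - y[0]) - (x[2] - x[0]) * (y[1] - y[0]))
    if a * b * c == 0:
        return 0.0
    return 2.0 * area2 / (a * b * c)


@dataclass
class OmegaScanResult:
    omegas: np.ndarray
    diagnostics: list[FitDiagnostics]
    chosen_omega: float
    satisfied: bool


def omega_scan(
    forwards: dict[str, ForwardMatrix],
    observables: dict[str, ObservableSet],
    prior_weights: np.ndarray,
    config: ReweightConfig,
    validation: ForwardMatrix | None = None,
    fret_target: float = 1.0,
    saxs_tolerance: float = 0.1,
) -> OmegaScanResult:
    """Scan the FRET weighting factor Omega at fixed theta.

    Omega* is the smallest grid value whose FRET chi^2 (non-reduced, one
    datapoint) drops below ``fret_target`` while the SAXS chi^2 stays within
    a relative ``saxs_tolerance`` of its Omega = 1 value; if no Omega
    qualifies the largest grid value is returned with a warning.  Without a
    FRET restraint the scan is moot and returns Omega = 1.
    """
    omegas = np.asarray(sorted(config.omega_grid), dtype=float)
    if omegas.size < 2:
        raise ValidationError("omega grid needs at least 2 values")
    if "FRET" not in forwards:
        return OmegaScanResult(
            omegas=omegas, diagnostics=[], chosen_omega=1.0, satisfied=True
        )
    diags: list[FitDiagnostics] = []
    for om in omegas:
        cfg = replace(config, omega=float(om))
        res = bme_solve(forwards, observables, prior_weights, cfg)
        if validation is not None:
            res.diagnostics.pre_score = pre_validation_score(res.weights, validation)
        diags.append(res.diagnostics)
    saxs_ref = diags[0].chi2_by_kind.get("SAXS", 0.0) if omegas[0] == 1.0 else (
        diags[0].chi2_by_kind.get("SAXS", 0.0)
    )
    for om, d in zip(omegas, diags):
        ok_fret = d.chi2_by_kind["FRET"] <= fret_target
        ok_saxs = d.chi2_by_kind.get("SAXS", 0.0) <= saxs_ref * (1.0 + saxs_tolerance)
        if ok_fret and ok_saxs:
            return OmegaScanResult(
                omegas=omegas, diagnostics=diags, chosen_omega=float(om), satisfied=True
            )
    warnings.warn("no Omega met the FRET/SAXS criteria; returning the largest")
    return OmegaScanResult(
        omegas=omegas, diagnostics=diags, chosen_omega=float(omegas[-1]), satisfied=False
    )
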