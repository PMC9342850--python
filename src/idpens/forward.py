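"""Back-calculation of observables from conformers (forward models).

All ensemble observables are weighted linear averages of per-conformer
values, with two exceptions: SAXS, where an overall scale and constant
offset are re-fitted against the measured profile, and PRE, where the
ensemble averages the inverse sixth power of the label-nucleus distance
before the relaxation rate is formed (so compact conformers dominate).

The models are deliberately coarse-grained and self-contained:

* SAXS -- Debye sum over CA beads with a Gaussian bead form factor;
* chemical shifts -- random-coil reference values plus a secondary-structure
  offset driven by the 3-class DSSP assignment;
* FRET -- Forster efficiency ``E = 1/(1+(r/R0)^6)`` on the inter-site CA
  distance, averaged linearly over conformers;
* PRE -- Solomon-Bloembergen point-dipole intensity ratio with the electron
  placed at the CB atom of the labelled residue (CA for glycine):
  ``Gamma2 = K <r^-6> (4 tau_c + 3 tau_c / (1 + omega_H^2 tau_c^2))`` and
  ``ratio = R2 exp(-Gamma2 t_d) / (R2 + Gamma2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import lambertw

from .core import Conformer, Ensemble, ObservableSet, Topology, ValidationError

__all__ = [
    "PREParams",
    "ForwardMatrix",
    "ForwardConfig",
    "saxs_debye",
    "saxs_matrix",
    "fit_scale_offset",
    "fret_efficiency",
    "fret_matrix",
    "pre_r6_matrix",
    "ratio_from_r6",
    "gamma2_from_r6",
    "r6_from_ratio",
    "pre_intensity_ratio",
    "cs_predict",
    "cs_meta",
    "cs_matrix",
    "build_forward_matrix",
    "RANDOM_COIL_SHIFTS",
]


# ---------------------------------------------------------------------------
# SAXS: CA-bead Debye formula
# ---------------------------------------------------------------------------

DEFAULT_BEAD_SIGMA = 0.31  # nm, Gaussian bead form-factor width


def saxs_debye(
    conformer: Conformer | np.ndarray,
    q_grid: np.ndarray,
    bead_sigma: float = DEFAULT_BEAD_SIGMA,
) -> np.ndarray:
    """Scattering intensity I(q) of one conformer by the Debye sum over CA beads.

    ``I(q) = f(q)^2 sum_ij sinc(q r_ij)`` with ``f(q) = exp(-(q sigma)^2/2)``;
    the i = j and q -> 0 limits are the analytic ``sinc -> 1``.  ``q_grid``
    is in nm^-1 and must be non-negative.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValidationError("q values must be non-negative")
    ca = conformer.ca_coords() if isinstance(conformer, Conformer) else np.asarray(conformer)
    diff = ca[:, None, :] - ca[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    qr = q[:, None] * r.ravel()[None, :]
    s = np.sinc(qr / np.pi)  # np.sinc(x) = sin(pi x)/(pi x); sinc(0) = 1
    f2 = np.exp(-((q * bead_sigma) ** 2))
    return f2 * s.sum(axis=1)


def saxs_matrix(
    ensemble: Ensemble,
    q_grid: np.ndarray,
    bead_sigma: float = DEFAULT_BEAD_SIGMA,
    chunk: int = 64,
) -> np.ndarray:
    """Per-conformer Debye intensities, shape (n_conformers, n_q)."""
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValidationError("q values must be non-negative")
    ca = ensemble.ca_xyz()
    n, nres, _ = ca.shape
    out = np.empty((n, q.size))
    f2 = np.exp(-((q * bead_sigma) ** 2))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        diff = ca[lo:hi, :, None, :] - ca[lo:hi, None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=-1)).reshape(hi - lo, -1)
        s = np.sinc(r[:, None, :] * q[None, :, None] / np.pi)
        out[lo:hi] = f2[None, :] * s.sum(axis=2)
    return out


def fit_scale_offset(
    calc: np.ndarray, obs: ObservableSet
) -> tuple[float, float, np.ndarray]:
    """Weighted least-squares fit of ``s * calc + c`` to the observed profile.

    Returns ``(scale, offset, scaled)``; for a degenerate (constant)
    calculated curve the scale is fixed at 0 and only the offset is fitted.
    """
    calc = np.asarray(calc, dtype=float)
    if calc.size < 3:
        raise ValidationError("scale/offset fit needs at least 3 points")
    y = obs.values
    wgt = 1.0 / obs.sigmas**2
    sw = wgt.sum()
    mx = (wgt * calc).sum() / sw
    my = (wgt * y).sum() / sw
    vxx = (wgt * (calc - mx) ** 2).sum()
    if vxx <= 1e-30 * sw * max(1.0, mx * mx):
        return 0.0, float(my), np.full_like(calc, my)
    vxy = (wgt * (calc - mx) * (y - my)).sum()
    s = vxy / vxx
    c = my - s * mx
    return float(s), float(c), s * calc + c


# ---------------------------------------------------------------------------
# FRET
# ---------------------------------------------------------------------------

def fret_efficiency(
    conformer: Conformer, site_a: int, site_b: int, r0: float
) -> float:
    """Forster efficiency ``1/(1+(r/R0)^6)`` from the inter-site CA distance (nm)."""
    ra = conformer.atom(site_a, "CA")
    rb = conformer.atom(site_b, "CA")
    r = float(np.linalg.norm(ra - rb))
    if r == 0.0:
        return 1.0
    return 1.0 / (1.0 + (r / r0) ** 6)


def fret_matrix(
    ensemble: Ensemble, site_a: int, site_b: int, r0: float
) -> np.ndarray:
    """Per-conformer FRET efficiencies, shape (n_conformers, 1)."""
    ia = ensemble.topology.require(site_a, "CA")
    ib = ensemble.topology.require(site_b, "CA")
    r = np.linalg.norm(ensemble.xyz[:, ia, :] - ensemble.xyz[:, ib, :], axis=1)
    e = np.where(r == 0.0, 1.0, 1.0 / (1.0 + (r / r0) ** 6))
    return e[:, None]


# ---------------------------------------------------------------------------
# PRE: simplified Solomon-Bloembergen point-dipole intensity ratio
# ---------------------------------------------------------------------------

_NM6_TO_CM6 = 1e42  # r^-6 in nm^-6 -> cm^-6


@dataclass
class PREParams:
    """Spin-label relaxation parameters of the PRE intensity-ratio model.

    ``tau_t`` is carried for completeness but unused by the simplified
    expression, which depends on the label correlation time only.
    """

    tau_c: float = 2e-9          # s, effective spin-label correlation time
    tau_t: float = 0.5e-9        # s, total correlation time (stored, unused)
    t_d: float = 10e-3           # s, total INEPT time
    r2: float = 10.0             # Hz, reduced transverse relaxation rate
    omega_h: float = 2 * math.pi * 500e6  # rad/s, proton Larmor frequency
    k: float = 1.23e-32          # cm^6 s^-2, point-dipole constant

    def __post_init__(self) -> None:
        for name in ("tau_c", "tau_t", "t_d", "r2", "omega_h", "k"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"PRE parameter {name} must be positive")

    def spectral_factor(self) -> float:
        """``4 tau_c + 3 tau_c / (1 + omega_H^2 tau_c^2)`` in seconds."""
        return 4 * self.tau_c + 3 * self.tau_c / (1 + (self.omega_h * self.tau_c) ** 2)


def _label_atom_indices(top: Topology, residues) -> np.ndarray:
    """CB atom index per residue, falling back to CA for glycine."""
    idx = []
    for r in residues:
        i = top.index(r, "CB")
        if i is None:
            i = top.require(r, "CA")
        idx.append(i)
    return np.asarray(idx, dtype=int)


def pre_r6_matrix(ensemble: Ensemble, label_site: int, residues) -> np.ndarray:
    """Per-conformer ``r^-6`` (nm^-6) between the label-site CB and each residue CB.

    Shape (n_conformers, n_residues_requested).  The label site itself must
    not be in ``residues``.
    """
    residues = [int(r) for r in residues]
    if label_site in residues:
        raise ValidationError("label site must be excluded from PRE residues")
    top = ensemble.topology
    i_site = _label_atom_indices(top, [label_site])[0]
    i_res = _label_atom_indices(top, residues)
    d = np.linalg.norm(
        ensemble.xyz[:, i_res, :] - ensemble.xyz[:, [i_site], :], axis=2
    )
    return d**-6.0


def gamma2_from_r6(r6_mean: np.ndarray | float, params: PREParams) -> np.ndarray:
    """Transverse relaxation enhancement from the ensemble mean r^-6 (nm^-6)."""
    return params.k * np.asarray(r6_mean, float) * _NM6_TO_CM6 * params.spectral_factor()


def ratio_from_r6(r6_mean: np.ndarray | float, params: PREParams) -> np.ndarray:
    """Intensity ratio ``R2 exp(-Gamma2 t_d) / (R2 + Gamma2)`` in (0, 1]."""
    g2 = gamma2_from_r6(r6_mean, params)
    return params.r2 * np.exp(-g2 * params.t_d) / (params.r2 + g2)


def r6_from_ratio(ratio: np.ndarray | float, params: PREParams) -> np.ndarray:
    """Invert the intensity-ratio model back to the mean r^-6 (nm^-6).

    Closed form via the Lambert W function; ``ratio = 1`` maps to 0 (no
    enhancement, i.e. the restraint carries no distance information).
    """
    rho = np.asarray(ratio, dtype=float)
    if np.any(rho <= 0) or np.any(rho > 1):
        raise ValidationError("intensity ratios must lie in (0, 1]")
    td, r2 = params.t_d, params.r2
    arg = td * (r2 / rho) * np.exp(r2 * td)
    u = np.real(lambertw(arg)) / td  # u = R2 + Gamma2
    g2 = np.clip(u - r2, 0.0, None)
    return g2 / (params.k * _NM6_TO_CM6 * params.spectral_factor())


def pre_intensity_ratio(
    ensemble: Ensemble,
    weights: np.ndarray,
    label_site: int,
    residues,
    params: PREParams | None = None,
) -> np.ndarray:
    """Ensemble PRE intensity ratios for one label site.

    The ensemble averages ``r^-6`` over conformers with the given weights
    before forming ``Gamma2``; the label-site residue itself is excluded.
    """
    params = params or PREParams()
    residues = [r for r in residues if r != label_site]
    r6 = pre_r6_matrix(ensemble, label_site, residues)
    w = np.asarray(weights, dtype=float)
    return ratio_from_r6(w @ r6, params)


# ---------------------------------------------------------------------------
# chemical-shift surrogate: random-coil reference + secondary-shift offset
# ---------------------------------------------------------------------------

#: random-coil CA/CB chemical shifts (ppm) per residue type
RANDOM_COIL_SHIFTS: dict[str, tuple[float, float | None]] = {
    "A": (52.5, 19.1), "R": (56.0, 30.9), "N": (53.1, 38.9), "D": (54.2, 41.1),
    "C": (58.2, 28.0), "Q": (55.7, 29.4), "E": (56.6, 29.9), "G": (45.1, None),
    "H": (55.0, 29.0), "I": (61.1, 38.8), "L": (55.1, 42.4), "K": (56.2, 33.1),
    "M": (55.4, 32.9), "F": (57.7, 39.6), "P": (63.3, 32.1), "S": (58.3, 63.8),
    "T": (61.8, 69.8), "W": (57.5, 29.6), "Y": (57.9, 38.8), "V": (62.2, 32.9),
}

#: secondary-shift offsets (ppm): helix raises CA and lowers CB, extended the opposite
CS_DELTA_HELIX = {"CA": +0.7, "CB": -0.7}
CS_DELTA_EXT = {"CA": -0.7, "CB": +0.7}


def cs_meta(top: Topology) -> pd.DataFrame:
    """CS datapoint layout: CA for every residue, CB for non-glycine."""
    rows = []
    for r, aa in enumerate(top.sequence):
        rows.append((r, "CA"))
        if aa != "G":
            rows.append((r, "CB"))
    return pd.DataFrame(rows, columns=["resid", "atom"])


def cs_predict(
    conformer: Conformer,
    dssp: np.ndarray | None = None,
    meta: pd.DataFrame | None = None,
) -> np.ndarray:
    """Predicted CA/CB shifts (ppm) for the datapoints in ``meta``.

    The prediction is the residue-type random-coil value plus a
    secondary-shift offset set by the 3-class DSSP state (helix +, extended
    -, coil 0 on CA; opposite sign on CB).
    """
    from .analysis import dssp3

    if meta is None:
        meta = cs_meta(conformer.topology)
    if dssp is None:
        dssp = dssp3(conformer)
    seq = conformer.sequence
    out = np.empty(len(meta))
    for i, (resid, atom) in enumerate(zip(meta["resid"], meta["atom"])):
        aa = seq[int(resid)]
        if aa not in RANDOM_COIL_SHIFTS:
            raise ValidationError(f"unknown residue type {aa!r}")
        ca_ref, cb_ref = RANDOM_COIL_SHIFTS[aa]
        ref = ca_ref if atom == "CA" else cb_ref
        if ref is None:
            raise ValidationError(f"residue {resid} ({aa}) has no {atom} shift")
        state = dssp[int(resid)]
        if state == "H":
            ref = ref + CS_DELTA_HELIX[atom]
        elif state == "E":
            ref = ref + CS_DELTA_EXT[atom]
        out[i] = ref
    return out


def cs_matrix(ensemble: Ensemble, meta: pd.DataFrame | None = None) -> np.ndarray:
    """Per-conformer predicted shifts, shape (n_conformers, n_datapoints)."""
    from .analysis import dssp_states

    if meta is None:
        meta = cs_meta(ensemble.topology)
    seq = ensemble.sequence
    resid = meta["resid"].to_numpy(int)
    atoms = meta["atom"].to_numpy(object)
    ref = np.empty(len(meta))
    for i, (r, a) in enumerate(zip(resid, atoms)):
        ca_ref, cb_ref = RANDOM_COIL_SHIFTS[seq[r]]
        v = ca_ref if a == "CA" else cb_ref
        if v is None:
            raise ValidationError(f"residue {r} has no {a} shift")
        ref[i] = v
    d_h = np.where(atoms == "CA", CS_DELTA_HELIX["CA"], CS_DELTA_HELIX["CB"])
    d_e = np.where(atoms == "CA", CS_DELTA_EXT["CA"], CS_DELTA_EXT["CB"])
    states = dssp_states(ensemble)[:, resid]
    return (
        ref[None, :]
        + np.where(states == "H", d_h[None, :], 0.0)
        + np.where(states == "E", d_e[None, :], 0.0)
    )


# ---------------------------------------------------------------------------
# forward-matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class ForwardConfig:
    bead_sigma: float = DEFAULT_BEAD_SIGMA
    pre_params: PREParams | None = None


@dataclass
class ForwardMatrix:
    """Per-conformer back-calculated observables aligned to an ObservableSet.

    Rows are conformers, columns datapoints.  For PRE the matrix holds the
    per-conformer ``r^-6`` values (nm^-6): the ensemble intensity ratio is a
    nonlinear function of the weighted column means, so averaging must happen
    in r^-6 space.
    """

    kind: str
    matrix: np.ndarray
    observables: ObservableSet

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("forward matrix has non-finite entries")
        if self.matrix.shape[1] != len(self.observables):
            raise ValidationError("forward matrix does not align with observables")

    @property
    def n_conformers(self) -> int:
        return self.matrix.shape[0]

    def average(self, weights: np.ndarray) -> np.ndarray:
        """Weighted column average (in r^-6 space for PRE)."""
        return np.asarray(weights, dtype=float) @ self.matrix


def build_forward_matrix(
    ensemble: Ensemble,
    obs: ObservableSet,
    config: ForwardConfig | None = None,
) -> ForwardMatrix:
    """Back-calculate every conformer against the datapoints of ``obs``."""
    cfg = config or ForwardConfig()
    if obs.kind == "SAXS":
        F = saxs_matrix(ensemble, obs.meta["q_nm"].to_numpy(float), cfg.bead_sigma)
    elif obs.kind == "CS":
        F = cs_matrix(ensemble, obs.meta)
    elif obs.kind == "FRET":
        row = obs.meta.iloc[0]
        F = fret_matrix(
            ensemble, int(row["site_a"]), int(row["site_b"]), float(row["R0_nm"])
        )
    elif obs.kind == "PRE":
        group_ids = obs.meta.groupby("label_site", sort=False).ngroup().to_numpy()
        if np.any(np.diff(group_ids) < 0):
            raise ValidationError("PRE meta rows must be contiguous per label site")
        cols = []
        for site, grp in obs.meta.groupby("label_site", sort=False):
            cols.append(pre_r6_matrix(ensemble, int(site), grp["resid"].to_numpy(int)))
        F = np.concatenate(cols, axis=1)
    else:
        raise ValidationError(f"unknown observable kind {obs.kind!r}")
    return ForwardMatrix(kind=obs.kind, matrix=F, observables=obs)
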