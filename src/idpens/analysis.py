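"""Weighted structural analytics for comparing conformer ensembles.

Covers the quantities used to contrast posterior ensembles: 3-class
secondary structure (a minimal Kabsch-Sander assignment reduced to
helix/extended/coil), long-range backbone hydrogen bonds and their
per-conformer probability mass function, planar pi-contacts, CA-based radii
of gyration, inter-residue scaling maps against a reference ensemble, and
weighted-bootstrap uncertainties.

Ensemble averages are always weighted sums over conformers; bootstrap
uncertainties resample conformers with replacement with probabilities equal
to the ensemble weights, evaluating the statistic on the resample with
uniform weights.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import Conformer, Ensemble, ValidationError, validate_weights

__all__ = [
    "radius_of_gyration",
    "ensemble_rg",
    "ca_distance_matrix",
    "ScalingMap",
    "scaling_map",
    "amide_h_coords",
    "kabsch_sander_energy",
    "dssp3",
    "hbond_assign",
    "hbond_counts",
    "hbond_pmf",
    "Plane",
    "backbone_planes",
    "sidechain_planes",
    "plane_contacts",
    "pi_contacts",
    "ContactSummary",
    "contact_summary",
    "ss_propensity",
    "bootstrap_sd",
]


# ---------------------------------------------------------------------------
# global dimensions
# ---------------------------------------------------------------------------

def radius_of_gyration(conformer: Conformer) -> float:
    """Per-conformer radius of gyration over CA point masses (nm)."""
    ca = conformer.ca_coords()
    if len(ca) < 2:
        raise ValidationError("radius of gyration needs at least 2 residues")
    return float(np.sqrt(np.mean(np.sum((ca - ca.mean(axis=0)) ** 2, axis=1))))


def ensemble_rg(ensemble: Ensemble, weights: np.ndarray | None = None) -> float:
    """Ensemble radius of gyration: ``Rg^2 = sum_i w_i rg_i^2``.

    Equals ``(1/2n^2) sum_ij <r_ij^2>`` with the conformer-weighted mean
    square CA-CA distances (the pairwise identity for point masses).
    """
    w = _weights(ensemble, weights)
    rg2 = np.array([radius_of_gyration(c) ** 2 for c in ensemble.conformers])
    return float(np.sqrt(w @ rg2))


def _weights(ensemble: Ensemble, weights: np.ndarray | None) -> np.ndarray:
    if weights is None:
        return ensemble.prior_weights
    return validate_weights(weights, ensemble.n)


def ca_distance_matrix(conformer: Conformer) -> np.ndarray:
    ca = conformer.ca_coords()
    diff = ca[:, None, :] - ca[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


@dataclass
class ScalingMap:
    """Ratio of ensemble-mean CA-CA distances to a reference ensemble's.

    ``D[i, j] = <r_ij>_ens / <r_ij>_ref``; > 1 expanded, < 1 compact
    relative to the reference.  The diagonal is NaN.
    """

    D: np.ndarray

    def mean_offdiag(self, min_separation: int = 0) -> float:
        n = self.D.shape[0]
        i, j = np.triu_indices(n, k=max(1, min_separation + 1))
        return float(np.nanmean(self.D[i, j]))


def _mean_distance_matrix(ensemble: Ensemble, w: np.ndarray, chunk: int = 128) -> np.ndarray:
    ca = ensemble.ca_xyz()
    n_res = ca.shape[1]
    acc = np.zeros((n_res, n_res))
    for lo in range(0, ensemble.n, chunk):
        hi = min(lo + chunk, ensemble.n)
        diff = ca[lo:hi, :, None, :] - ca[lo:hi, None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1))
        acc += np.tensordot(w[lo:hi], d, axes=1)
    return acc


def scaling_map(
    ensemble: Ensemble,
    weights: np.ndarray | None,
    reference: Ensemble,
    reference_weights: np.ndarray | None = None,
) -> ScalingMap:
    """Weighted mean inter-residue distances normalized by a reference ensemble."""
    if ensemble.topology.n_residues != reference.topology.n_residues:
        raise ValidationError("ensemble and reference differ in sequence length")
    w = _weights(ensemble, weights)
    wr = _weights(reference, reference_weights)
    num = _mean_distance_matrix(ensemble, w)
    den = _mean_distance_matrix(reference, wr)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = num / den
    np.fill_diagonal(D, np.nan)
    return ScalingMap(D=D)


# ---------------------------------------------------------------------------
# backbone hydrogen bonds and DSSP-3
# ---------------------------------------------------------------------------

_NH_BOND = 0.1010  # nm


def amide_h_coords(conformer: Conformer) -> tuple[np.ndarray, np.ndarray]:
    """Amide H coordinates per residue and a validity mask.

    Uses explicit H atoms when present; otherwise reconstructs them in the
    peptide plane as the external bisector of the C(i-1)-N-CA angle.  The
    first residue has no reconstructable amide H unless one is present.
    """
    top = conformer.topology
    n = top.n_residues
    H = np.zeros((n, 3))
    ok = np.zeros(n, dtype=bool)
    for i in range(n):
        hi = top.index(i, "H")
        if hi is not None:
            H[i] = conformer.coords[hi]
            ok[i] = True
        elif i >= 1:
            c_prev = conformer.atom(i - 1, "C")
            ni = conformer.atom(i, "N")
            cai = conformer.atom(i, "CA")
            u = (c_prev - ni) / np.linalg.norm(c_prev - ni)
            v = (cai - ni) / np.linalg.norm(cai - ni)
            H[i] = ni - _NH_BOND * (u + v) / np.linalg.norm(u + v)
            ok[i] = True
    return H, ok


def _backbone_arrays(conformer: Conformer):
    top = conformer.topology
    n = top.n_residues
    def grab(name):
        return np.stack([conformer.coords[top.require(i, name)] for i in range(n)])
    return grab("N"), grab("CA"), grab("C"), grab("O")


def kabsch_sander_energy(conformer: Conformer) -> np.ndarray:
    """Kabsch-Sander electrostatic H-bond energy matrix (kcal/mol).

    ``E[i, j]`` is the energy of the bond donated by the NH of residue j to
    the CO of residue i:
    ``E = 0.084 (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332`` with distances
    in Angstrom.  Pairs with |i-j| < 2 or without an amide H are +inf.
    """
    N, _CA, C, O = _backbone_arrays(conformer)
    H, has_h = amide_h_coords(conformer)
    n = len(N)

    def dist(a, b):  # nm -> Angstrom
        return 10.0 * np.sqrt(
            np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
        )

    with np.errstate(divide="ignore"):
        E = 0.084 * 332.0 * (
            1.0 / dist(O, N) + 1.0 / dist(C, H) - 1.0 / dist(O, H) - 1.0 / dist(C, N)
        )
    idx = np.arange(n)
    near = np.abs(idx[:, None] - idx[None, :]) < 2
    E[near] = np.inf
    E[:, ~has_h] = np.inf
    return E


_KS_CUTOFF = -0.5  # kcal/mol


def _hbond_matrix(conformer: Conformer) -> np.ndarray:
    return kabsch_sander_energy(conformer) < _KS_CUTOFF


def dssp3(conformer: Conformer) -> np.ndarray:
    """Per-residue 3-class secondary structure: 'H', 'E' or 'C'.

    A reduced Kabsch-Sander assignment: n-turns (n = 3, 4, 5) from backbone
    H-bonds CO(i)...HN(i+n); two consecutive n-turns make a helix over
    residues i..i+n-1; parallel/antiparallel bridge patterns mark extended
    residues; everything else is coil.  Helix takes precedence over
    extended, matching the 8-to-3-state grouping (helical; strand/extended;
    loop/coil).
    """
    n = conformer.topology.n_residues
    out = np.full(n, "C", dtype="<U1")
    if n < 4:
        return out
    hb = _hbond_matrix(conformer)  # hb[i, j]: CO(i) <- NH(j)

    is_helix = np.zeros(n, dtype=bool)
    for turn in (4, 3, 5):
        t = np.zeros(n, dtype=bool)
        for i in range(n - turn):
            t[i] = hb[i, i + turn]
        for i in range(1, n - turn):
            if t[i - 1] and t[i]:
                is_helix[i : i + turn] = True

    is_ext = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if parallel or anti:
                is_ext[i] = is_ext[j] = True

    out[is_ext] = "E"
    out[is_helix] = "H"
    return out


def dssp_states(ensemble: Ensemble) -> np.ndarray:
    """DSSP-3 state matrix (n_conformers, n_residues), cached on the ensemble."""
    if "dssp3" not in ensemble.cache:
        ensemble.cache["dssp3"] = np.stack([dssp3(c) for c in ensemble.conformers])
    return ensemble.cache["dssp3"]


def hbond_assign(
    conformer: Conformer,
    min_separation: int = 10,
    dist_cutoff: float = 0.25,
    angle_cutoff_deg: float = 120.0,
) -> list[tuple[int, int]]:
    """Backbone H-bonds by geometric criteria: (donor residue, acceptor residue).

    A bond requires H...O distance < ``dist_cutoff`` (nm) and an N-H...O
    angle > ``angle_cutoff_deg``; only donor/acceptor pairs with
    ``|i - j| > min_separation`` are reported (0 disables the long-range
    filter, e.g. for secondary-structure work).
    """
    N, _CA, _C, O = _backbone_arrays(conformer)
    H, has_h = amide_h_coords(conformer)
    n = len(N)
    if not np.any(has_h):
        raise ValidationError("no amide hydrogens present or reconstructable")
    d_ho = np.sqrt(np.sum((H[:, None, :] - O[None, :, :]) ** 2, axis=-1))
    ho = O[None, :, :] - H[:, None, :]
    # donor-H...acceptor angle at the hydrogen, between H->N and H->O
    v1 = N - H
    ang = np.degrees(
        np.arccos(
            np.clip(
                np.sum(v1[:, None, :] * ho, axis=-1)
                / (
                    np.linalg.norm(v1, axis=-1)[:, None]
                    * np.clip(np.linalg.norm(ho, axis=-1), 1e-12, None)
                ),
                -1.0,
                1.0,
            )
        )
    )
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    mask = (
        has_h[:, None]
        & (d_ho < dist_cutoff)
        & (ang > angle_cutoff_deg)
        & (sep > min_separation)
    )
    donors, acceptors = np.nonzero(mask)
    return list(zip(donors.tolist(), acceptors.tolist()))


def hbond_counts(
    ensemble: Ensemble, min_separation: int = 10, **criteria
) -> np.ndarray:
    """Number of H-bonds per conformer."""
    return np.array(
        [len(hbond_assign(c, min_separation, **criteria)) for c in ensemble.conformers]
    )


def hbond_pmf(
    ensemble: Ensemble,
    weights: np.ndarray | None = None,
    min_separation: int = 10,
    counts: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Weighted PMF over per-conformer H-bond counts, plus the weighted mean.

    ``pmf[k] = sum_{i: count_i = k} w_i``.
    """
    w = _weights(ensemble, weights)
    if counts is None:
        counts = hbond_counts(ensemble, min_separation)
    kmax = int(counts.max())
    pmf = np.zeros(kmax + 1)
    np.add.at(pmf, counts, w)
    return pmf, float(w @ counts)


# ---------------------------------------------------------------------------
# planar pi-contacts
# ---------------------------------------------------------------------------

@dataclass
class Plane:
    """A planar group: its residue, provenance ('bb' or 'sc'), center and normal."""

    resid: int
    kind: str  # 'bb' | 'sc'
    center: np.ndarray
    normal: np.ndarray


#: side-chain planar groups by residue type (atoms must all be present)
SIDECHAIN_PLANE_ATOMS = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "ARG": ["NE", "CZ", "NH1", "NH2"],
    "ASN": ["CG", "OD1", "ND2"],
    "GLN": ["CD", "OE1", "NE2"],
    "ASP": ["CG", "OD1", "OD2"],
    "GLU": ["CD", "OE1", "OE2"],
}


def _fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    center = points.mean(axis=0)
    x = points - center
    _u, s, vt = np.linalg.svd(x, full_matrices=False)
    if s[1] < 1e-8:  # collinear points: no defined plane
        return None
    return center, vt[-1]


def backbone_planes(conformer: Conformer) -> list[Plane]:
    """Peptide amide planes (C_i, O_i, N_{i+1}), assigned to residue i."""
    planes = []
    for i in range(conformer.topology.n_residues - 1):
        pts = np.stack(
            [conformer.atom(i, "C"), conformer.atom(i, "O"), conformer.atom(i + 1, "N")]
        )
        fit = _fit_plane(pts)
        if fit is None:
            warnings.warn(f"degenerate peptide plane at residue {i}; skipped")
            continue
        planes.append(Plane(resid=i, kind="bb", center=fit[0], normal=fit[1]))
    return planes


def sidechain_planes(conformer: Conformer) -> list[Plane]:
    """Side-chain planar groups for residues whose plane atoms are all present."""
    top = conformer.topology
    planes = []
    for r, rname in enumerate(top.residue_names):
        atoms = SIDECHAIN_PLANE_ATOMS.get(rname)
        if atoms is None:
            continue
        idx = [top.index(r, a) for a in atoms]
        if any(i is None for i in idx):
            continue
        fit = _fit_plane(conformer.coords[np.array(idx)])
        if fit is None:
            warnings.warn(f"degenerate side-chain plane at residue {r}; skipped")
            continue
        planes.append(Plane(resid=r, kind="sc", center=fit[0], normal=fit[1]))
    return planes


def plane_contacts(
    planes: Sequence[Plane],
    d_max: float = 0.49,
    angle_max_deg: float = 40.0,
    min_separation: int = 10,
) -> list[tuple[Plane, Plane, str]]:
    """Pairwise planar contacts: center distance <= d_max (nm) and normal
    angle <= angle_max_deg (folded to [0, 90]); sequence separation
    ``|i - j| > min_separation``."""
    out = []
    for a_i in range(len(planes)):
        for b_i in range(a_i + 1, len(planes)):
            a, b = planes[a_i], planes[b_i]
            if abs(a.resid - b.resid) <= min_separation:
                continue
            if np.linalg.norm(a.center - b.center) > d_max:
                continue
            c = abs(float(np.dot(a.normal, b.normal)))
            ang = np.degrees(np.arccos(np.clip(c, 0.0, 1.0)))
            if ang > angle_max_deg:
                continue
            cls = {"bbbb": "bb-bb", "scsc": "sc-sc"}.get(a.kind + b.kind, "sc-bb")
            out.append((a, b, cls))
    return out


def pi_contacts(
    conformer: Conformer,
    d_max: float = 0.49,
    angle_max_deg: float = 40.0,
    min_separation: int = 10,
) -> Counter:
    """Counts of planar pi-contacts per class ('bb-bb', 'sc-sc', 'sc-bb')."""
    planes = backbone_planes(conformer) + sidechain_planes(conformer)
    contacts = plane_contacts(planes, d_max, angle_max_deg, min_separation)
    counts = Counter({"bb-bb": 0, "sc-sc": 0, "sc-bb": 0})
    for _a, _b, cls in contacts:
        counts[cls] += 1
    return counts


# ---------------------------------------------------------------------------
# propensities, contact summaries, bootstrap
# ---------------------------------------------------------------------------

def ss_propensity(
    ensemble: Ensemble,
    weights: np.ndarray | None = None,
    n_bootstrap: int = 0,
    seed: int = 0,
    states: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-residue helix/extended/coil propensities (weighted), with optional
    bootstrap standard deviations.

    The three propensities sum to 1 at every residue.  ``states`` may carry a
    precomputed (n_conformers, n_residues) DSSP-3 matrix.
    """
    w = _weights(ensemble, weights)
    if states is None:
        states = dssp_states(ensemble)
    cols = {}
    masks = {cls: states == cls for cls in ("H", "E", "C")}
    for cls, m in masks.items():
        cols[cls] = w @ m
    df = pd.DataFrame(
        {"resid": np.arange(states.shape[1]), "helix": cols["H"],
         "extended": cols["E"], "coil": cols["C"]}
    )
    if n_bootstrap >= 2:
        rng = np.random.default_rng(seed)
        boots = {cls: [] for cls in masks}
        for _ in range(n_bootstrap):
            idx = rng.choice(ensemble.n, size=ensemble.n, replace=True, p=w)
            for cls, m in masks.items():
                boots[cls].append(m[idx].mean(axis=0))
        for cls, name in (("H", "helix"), ("E", "extended"), ("C", "coil")):
            df[name + "_sd"] = np.std(np.stack(boots[cls]), axis=0)
    return df


@dataclass
class ContactSummary:
    """Weighted contact statistics of one ensemble."""

    hbond_pmf: np.ndarray
    n_hbonds: float
    n_hbonds_sd: float
    pi_means: dict[str, float]
    pi_sds: dict[str, float] = field(default_factory=dict)

    @property
    def n_pipi(self) -> float:
        return float(sum(self.pi_means.values()))


def contact_summary(
    ensemble: Ensemble,
    weights: np.ndarray | None = None,
    min_separation: int = 10,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> ContactSummary:
    """H-bond PMF and per-class pi-contact means with bootstrap SDs."""
    w = _weights(ensemble, weights)
    hb = hbond_counts(ensemble, min_separation)
    pmf, mean_hb = hbond_pmf(ensemble, w, min_separation, counts=hb)
    pi_rows = [pi_contacts(c, min_separation=min_separation) for c in ensemble.conformers]
    classes = ("bb-bb", "sc-sc", "sc-bb")
    pi_mat = np.array([[row[c] for c in classes] for row in pi_rows], dtype=float)
    pi_means = {c: float(w @ pi_mat[:, k]) for k, c in enumerate(classes)}
    pi_sds: dict[str, float] = {}
    hb_sd = 0.0
    if n_bootstrap >= 2:
        rng = np.random.default_rng(seed)
        idx = rng.choice(ensemble.n, size=(n_bootstrap, ensemble.n), replace=True, p=w)
        hb_sd = float(np.std(hb[idx].mean(axis=1)))
        for k, c in enumerate(classes):
            pi_sds[c] = float(np.std(pi_mat[idx, k].mean(axis=1)))
    return ContactSummary(
        hbond_pmf=pmf, n_hbonds=mean_hb, n_hbonds_sd=hb_sd,
        pi_means=pi_means, pi_sds=pi_sds,
    )


def bootstrap_sd(
    statistic: Callable[[Ensemble, np.ndarray], float],
    ensemble: Ensemble,
    weights: np.ndarray | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> float:
    """Weighted-bootstrap SD of a statistic.

    Draws ``n_bootstrap`` resamples of size N with replacement with
    probabilities equal to the weights and evaluates
    ``statistic(ensemble, resampled_indices)`` on each (the resample carries
    uniform weights; the weighting is encoded by the resampling itself).
    """
    if n_bootstrap < 2:
        raise ValidationError("need at least 2 bootstrap replicates")
    w = _weights(ensemble, weights)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.choice(ensemble.n, size=ensemble.n, replace=True, p=w)
        vals[b] = statistic(ensemble, idx)
    return float(np.std(vals))
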