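"""Synthetic prior ensembles and synthetic experimental datasets.

The study needs contrasting conformer pools for a 90-residue disordered
chain and "experimental" SAXS/CS/FRET/PRE tables generated from a known
ground truth, so that the whole optimization machinery can be exercised and
validated without any external data.

Chains are grown residue-by-residue from sampled backbone dihedrals with
ideal bond lengths and angles (trans peptide), with hard-sphere
self-avoidance on CA pairs.  Three prior styles mimic the qualitative
character of the pools such studies start from:

``coil``
    excluded-volume statistical coil, no residual structure;
``matched``
    coil plus mild transient helices and a mild compaction bias -- a prior
    already close to the synthetic truth;
``compact``
    stronger transient helices plus a strong compaction bias, emulating a
    pool that is over-compact relative to the data.

Compaction is implemented by importance resampling of an excluded-volume
pool with weights ``exp(-bias * Rg)``: it gives exact, analytically
controllable compaction without introducing attractive chain-growth moves.

The ground truth for data synthesis is an exponential tilt of an ensemble's
prior weights along a scalar feature (Rg or end-to-end distance), which
keeps parameter-recovery tests exact: the tilted ensemble average of any
observable is known, and noisy data are drawn around it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import (
    AA3,
    Conformer,
    Ensemble,
    EnsembleError,
    ObservableSet,
    Topology,
    validate_weights,
)
from .geometry import place_atom

__all__ = [
    "GenerationError",
    "PriorStyle",
    "GroundTruth",
    "NoiseConfig",
    "SynthConfig",
    "DEFAULT_SEQUENCE",
    "DEFAULT_STYLES",
    "RAMA_BASINS",
    "basin_sampler",
    "build_chain",
    "generate_prior",
    "make_ground_truth",
    "synthesize_experiments",
]


class GenerationError(EnsembleError):
    """Chain growth failed within the retry budget."""


# ideal backbone internal coordinates (nm / degrees), trans peptide
_B_N_CA = 0.1458
_B_CA_C = 0.1525
_B_C_N = 0.1329
_B_C_O = 0.1231
_B_N_H = 0.1010
_B_CA_CB = 0.1530
_A_N_CA_C = math.radians(111.2)
_A_CA_C_N = math.radians(116.2)
_A_C_N_CA = math.radians(121.7)
_A_CA_C_O = math.radians(120.5)
_A_C_CA_CB = math.radians(110.1)
_T_N_C_CA_CB = math.radians(-122.6)
_OMEGA = math.pi

#: (phi mean, psi mean, sigma) in degrees for the three dihedral basins.
RAMA_BASINS = {
    "helix": (-62.0, -41.0, 7.0),
    "extended": (-120.0, 130.0, 25.0),
    "left": (60.0, 45.0, 10.0),
}

#: default basin probabilities of the statistical coil (helix, extended, left)
COIL_BASIN_PROBS = (0.30, 0.62, 0.08)

#: default 90-residue disordered sequence: S/T/P-rich, Lys/Arg positive
#: charge, a few aromatics, no acidic residues (Sic1-like composition).
DEFAULT_SEQUENCE = (
    "MTPSTPPRSRGTSYLAQPSGNTSPSALMQGQKTPQKPSQNLVPVTPSTTKSFKNAPLLAP"
    "PNSNMGMTSPFNGLTSPQRSPFPKSSVKRT"
)


@dataclass
class PriorStyle:
    """Statistical character of a prior conformer pool."""

    name: str
    helix_segments: list[tuple[int, int, float]] = field(default_factory=list)
    compaction_bias: float = 0.0  # nm^-1, strength of exp(-bias*Rg) resampling
    basin_probs: tuple[float, float, float] = COIL_BASIN_PROBS

    def __post_init__(self) -> None:
        for start, end, p in self.helix_segments:
            if not (0 <= start < end):
                raise ValueError(f"bad helix segment ({start}, {end})")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"helix propensity {p} outside [0, 1]")
        if self.compaction_bias < 0:
            raise ValueError("compaction_bias must be >= 0")


@dataclass
class GroundTruth:
    """Known reweighting used to synthesize data: w_i ∝ w0_i exp(-c f_i)."""

    true_weights: np.ndarray
    tilt_feature: str
    coefficient: float
    feature_values: np.ndarray

    def __post_init__(self) -> None:
        self.true_weights = validate_weights(self.true_weights)

    def mean_feature(self) -> float:
        return float(self.true_weights @ self.feature_values)


def _sample_basin(name: str, rng: np.random.Generator, sigma_scale: float = 1.0):
    phi0, psi0, sig = RAMA_BASINS[name]
    sig = sig * sigma_scale
    phi = math.radians(rng.normal(phi0, sig))
    psi = math.radians(rng.normal(psi0, sig))
    return phi, psi


def basin_sampler(
    probs: Sequence[float] = COIL_BASIN_PROBS,
) -> Callable[[int, np.random.Generator], tuple[float, float]]:
    """Per-residue (phi, psi) sampler mixing the three dihedral basins."""
    names = list(RAMA_BASINS)
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()

    def sample(i: int, rng: np.random.Generator) -> tuple[float, float]:
        return _sample_basin(names[rng.choice(len(names), p=p)], rng)

    return sample


def fixed_sampler(phi_deg: float, psi_deg: float):
    """Sampler pinned at one (phi, psi) point, for geometric fixtures."""

    def sample(i: int, rng: np.random.Generator) -> tuple[float, float]:
        return math.radians(phi_deg), math.radians(psi_deg)

    return sample


CONTACT_RADIUS = 0.65  # nm, CA-CA distance counted as a nonlocal contact


def _grow_backbone(
    n_res: int,
    sampler: Callable[[int, np.random.Generator], tuple[float, float]],
    rng: np.random.Generator,
    clash_nm: float,
    per_residue_retries: int,
    attraction: float = 0.0,
    n_candidates: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[float, float]]] | None:
    """One growth attempt; returns (N, CA, C, phi_psi) or None on failure.

    With ``attraction > 0`` each residue placement is chosen among
    ``n_candidates`` clash-free candidates with Rosenbluth-style weights
    ``exp(attraction * n_contacts)``, where a contact is a nonadjacent CA
    within :data:`CONTACT_RADIUS`; this produces collapsed chains with
    genuine tertiary contacts rather than merely small radii.
    """
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    phi_psi = [sampler(0, rng)]
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    C[0] = CA[0] + _B_CA_C * np.array(
        [math.cos(math.pi - _A_N_CA_C), math.sin(math.pi - _A_N_CA_C), 0.0]
    )
    n_cand = max(1, n_candidates) if attraction > 0 else 1
    r_c2 = CONTACT_RADIUS * CONTACT_RADIUS
    for i in range(1, n_res):
        phi_psi.append(sampler(i, rng))
        candidates = []  # (n_contacts, pair_prev, pair_i, C_prev, N_i, CA_i, C_i)
        attempt = 0
        while len(candidates) < n_cand and attempt < per_residue_retries:
            if attempt > 0 or len(candidates) > 0:
                # redraw the dihedrals the placement depends on
                phi_psi[i - 1] = sampler(i - 1, rng)
                phi_psi[i] = sampler(i, rng)
                if i >= 2:
                    C[i - 1] = place_atom(
                        C[i - 2], N[i - 1], CA[i - 1],
                        _B_CA_C, _A_N_CA_C, phi_psi[i - 1][0],
                    )
            attempt += 1
            psi_prev = phi_psi[i - 1][1]
            Ni = place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi_prev)
            CAi = place_atom(CA[i - 1], C[i - 1], Ni, _B_N_CA, _A_C_N_CA, _OMEGA)
            Ci = place_atom(C[i - 1], Ni, CAi, _B_CA_C, _A_N_CA_C, phi_psi[i][0])
            n_contacts = 0
            if i >= 2:
                d2 = np.sum((CA[: i - 1] - CAi) ** 2, axis=1)
                if d2.min() < clash_nm * clash_nm:
                    continue
                n_contacts = int(np.sum(d2 < r_c2))
            candidates.append(
                (n_contacts, phi_psi[i - 1], phi_psi[i], C[i - 1].copy(), Ni, CAi, Ci)
            )
        if not candidates:
            return None
        if len(candidates) == 1:
            choice = candidates[0]
        else:
            logw = attraction * np.array([c[0] for c in candidates], dtype=float)
            w = np.exp(logw - logw.max())
            w /= w.sum()
            choice = candidates[rng.choice(len(candidates), p=w)]
        _nc, pair_prev, pair_i, C_prev, Ni, CAi, Ci = choice
        phi_psi[i - 1] = pair_prev
        phi_psi[i] = pair_i
        C[i - 1] = C_prev
        N[i], CA[i], C[i] = Ni, CAi, Ci
    return N, CA, C, phi_psi


def build_chain(
    sequence: str,
    phi_psi_sampler: Callable[[int, np.random.Generator], tuple[float, float]],
    seed: int | np.random.Generator = 0,
    clash_nm: float = 0.4,
    max_retries: int = 500,
    per_residue_retries: int = 60,
    attraction: float = 0.0,
    n_candidates: int = 6,
) -> Conformer:
    """Grow a self-avoiding backbone (N, H, CA, C, O, CB) from sampled dihedrals.

    Bond lengths/angles are ideal and the peptide bond is trans.  A placement
    that brings a CA within ``clash_nm`` of any non-adjacent CA is resampled;
    if a residue cannot be placed the chain is re-grown from scratch, up to
    ``max_retries`` times (then :class:`GenerationError`).  ``attraction``
    switches on contact-biased growth (see :func:`_grow_backbone`).
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have at least 2 residues")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_res = len(sequence)

    grown = None
    for _ in range(max_retries):
        grown = _grow_backbone(
            n_res, phi_psi_sampler, rng, clash_nm, per_residue_retries,
            attraction=attraction, n_candidates=n_candidates,
        )
        if grown is not None:
            break
    if grown is None:
        raise GenerationError(
            f"failed to grow a self-avoiding {n_res}-residue chain "
            f"in {max_retries} attempts"
        )
    N, CA, C, phi_psi = grown

    coords: list[np.ndarray] = []
    atom_resid: list[int] = []
    atom_names: list[str] = []
    residue_names = [AA3[a] for a in sequence]
    for i, aa in enumerate(sequence):
        psi_i = phi_psi[i][1]
        O = place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi_i + math.pi)
        if i == 0:
            H = place_atom(C[0], CA[0], N[0], _B_N_H, math.radians(119.0), math.pi)
        else:
            # in-plane external bisector of the C(i-1)-N-CA angle
            u = (C[i - 1] - N[i]) / np.linalg.norm(C[i - 1] - N[i])
            v = (CA[i] - N[i]) / np.linalg.norm(CA[i] - N[i])
            H = N[i] - _B_N_H * (u + v) / np.linalg.norm(u + v)
        for name, xyz in (("N", N[i]), ("H", H), ("CA", CA[i]), ("C", C[i]), ("O", O)):
            coords.append(xyz)
            atom_resid.append(i)
            atom_names.append(name)
        if aa != "G":
            CB = place_atom(N[i], C[i], CA[i], _B_CA_CB, _A_C_CA_CB, _T_N_C_CA_CB)
            coords.append(CB)
            atom_resid.append(i)
            atom_names.append("CB")
    top = Topology(atom_resid, atom_names, residue_names)
    return Conformer(np.array(coords), top)


def _style_sampler(style: PriorStyle, segment_on: np.ndarray):
    """Per-conformer sampler: helix basin inside switched-on segments, coil mix elsewhere."""
    base = basin_sampler(style.basin_probs)
    segs = [
        (start, end)
        for on, (start, end, _p) in zip(segment_on, style.helix_segments)
        if on
    ]

    def sample(i: int, rng: np.random.Generator) -> tuple[float, float]:
        for start, end in segs:
            if start <= i <= end:
                return _sample_basin("helix", rng, sigma_scale=0.6)
        return base(i, rng)

    return sample


def conformer_rg(conf: Conformer) -> float:
    """Radius of gyration over CA atoms (nm)."""
    ca = conf.ca_coords()
    return float(np.sqrt(np.mean(np.sum((ca - ca.mean(axis=0)) ** 2, axis=1))))


def generate_prior(
    style: PriorStyle,
    sequence: str = DEFAULT_SEQUENCE,
    n_conformers: int = 1000,
    seed: int = 0,
) -> Ensemble:
    """Generate an N-conformer prior pool of the given style (uniform weights).

    Transient helices are cooperative: each helix segment is switched on for
    a whole conformer with probability equal to its propensity parameter.
    ``compaction_bias`` is the pairwise-attraction strength of the
    contact-biased chain growth, producing collapsed conformers with real
    tertiary contacts (and hence r^-6-visible close approaches).
    """
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    rng = np.random.default_rng(seed)
    conformers = []
    for _ in range(n_conformers):
        seg_on = np.array(
            [rng.random() < p for (_s, _e, p) in style.helix_segments], dtype=bool
        )
        sampler = _style_sampler(style, seg_on)
        conformers.append(
            build_chain(sequence, sampler, rng, attraction=style.compaction_bias)
        )
    return Ensemble(conformers)


#: the three contrasting prior styles of the default synthetic study
DEFAULT_STYLES = {
    "coil": PriorStyle(name="coil"),
    "matched": PriorStyle(
        name="matched",
        helix_segments=[(22, 30, 0.20), (48, 56, 0.15)],
        compaction_bias=0.3,
    ),
    "compact": PriorStyle(
        name="compact",
        helix_segments=[(10, 18, 0.40), (22, 30, 0.50), (60, 68, 0.40)],
        compaction_bias=0.9,
    ),
}


def make_ground_truth(
    ensemble: Ensemble,
    tilt_feature: str = "rg",
    coefficient: float = 0.0,
) -> GroundTruth:
    """Exponentially tilt the prior weights along a per-conformer feature.

    ``true_weights ∝ prior_weights * exp(-coefficient * feature)``; a
    negative coefficient tilts toward larger feature values (e.g. expansion
    when the feature is Rg).
    """
    if tilt_feature in ("rg", "Rg"):
        f = np.array([conformer_rg(c) for c in ensemble.conformers])
    elif tilt_feature == "end_to_end":
        ca = ensemble.ca_xyz()
        f = np.linalg.norm(ca[:, -1, :] - ca[:, 0, :], axis=1)
    else:
        raise ValueError(f"unknown tilt feature {tilt_feature!r}")
    logw = np.log(np.clip(ensemble.prior_weights, 1e-300, None)) - coefficient * f
    logw -= logw.max()  # overflow guard
    w = np.exp(logw)
    w /= w.sum()
    return GroundTruth(
        true_weights=w,
        tilt_feature=tilt_feature,
        coefficient=coefficient,
        feature_values=f,
    )


@dataclass
class NoiseConfig:
    """Gaussian noise levels of the synthetic datasets (also the sigma columns)."""

    saxs_frac: float = 0.005     # relative, of the true intensity
    cs_sigma: float = 0.2        # ppm
    fret_sigma: float = 0.03     # efficiency units
    pre_sigma: float = 0.05      # intensity-ratio units


@dataclass
class SynthConfig:
    """Layout of the synthetic experiments (the study's measurement design)."""

    q_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.1, 3.0, 40)
    )  # nm^-1
    fret_pair: tuple[int, int] = (0, 89)   # 0-based residues, ~end-to-end
    fret_r0: float = 5.4                   # nm
    pre_label_sites: tuple[int, ...] = (0, 20, 37, 63, 82, 89)
    noise: NoiseConfig = field(default_factory=NoiseConfig)


def synthesize_experiments(
    ensemble: Ensemble,
    truth: GroundTruth,
    config: SynthConfig | None = None,
    seed: int = 0,
    forwards: dict[str, np.ndarray] | None = None,
) -> dict[str, ObservableSet]:
    """Create noisy SAXS/CS/FRET/PRE tables from the truth-weighted ensemble.

    For each kind the values are the ground-truth-weighted forward averages
    plus Gaussian noise of the configured sigma; the sigma column records the
    sigma actually used.  Setting all noise levels to zero reproduces the
    truth averages exactly.  Bitwise reproducible under a fixed seed.

    ``forwards`` may carry precomputed per-conformer matrices (as built by
    :func:`idpens.forward.build_forward_matrix` against this config's
    datapoint layout) to avoid recomputation across noise replicates.
    """
    import pandas as pd

    from . import forward

    cfg = config or SynthConfig()
    rng = np.random.default_rng(seed)
    w = truth.true_weights
    fwd = forwards or {}
    out: dict[str, ObservableSet] = {}

    # SAXS: truth-weighted average intensity on the q grid
    F_saxs = fwd.get("SAXS")
    if F_saxs is None:
        F_saxs = forward.saxs_matrix(ensemble, cfg.q_grid)
    I_true = w @ F_saxs
    sig_I = cfg.noise.saxs_frac * I_true
    noise = rng.normal(size=I_true.size) * sig_I if cfg.noise.saxs_frac > 0 else 0.0
    sig_col = sig_I if cfg.noise.saxs_frac > 0 else np.full(I_true.size, 1.0)
    out["SAXS"] = ObservableSet(
        kind="SAXS",
        values=I_true + noise,
        sigmas=np.where(sig_col > 0, sig_col, 1.0),
        meta=pd.DataFrame({"q_nm": cfg.q_grid}),
    )

    # chemical shifts: CA for every residue, CB for non-glycine
    meta_cs = forward.cs_meta(ensemble.topology)
    F_cs = fwd.get("CS")
    if F_cs is None:
        F_cs = forward.cs_matrix(ensemble, meta_cs)
    cs_true = w @ F_cs
    s = cfg.noise.cs_sigma
    vals = cs_true + (rng.normal(size=cs_true.size) * s if s > 0 else 0.0)
    out["CS"] = ObservableSet(
        kind="CS",
        values=vals,
        sigmas=np.full(cs_true.size, s if s > 0 else 1.0),
        meta=meta_cs,
    )

    # one FRET pair (~end-to-end)
    a, b = cfg.fret_pair
    F_fret = fwd.get("FRET")
    if F_fret is None:
        F_fret = forward.fret_matrix(ensemble, a, b, cfg.fret_r0)
    E_true = float(w @ F_fret[:, 0])
    s = cfg.noise.fret_sigma
    E_val = E_true + (float(rng.normal()) * s if s > 0 else 0.0)
    out["FRET"] = ObservableSet(
        kind="FRET",
        values=np.array([min(max(E_val, 0.0), 1.0)]),
        sigmas=np.array([s if s > 0 else 1.0]),
        meta=pd.DataFrame({"site_a": [a], "site_b": [b], "R0_nm": [cfg.fret_r0]}),
    )

    # PRE intensity ratios at the configured label sites
    params = forward.PREParams()
    rows_site, rows_res = [], []
    for site in cfg.pre_label_sites:
        residues = [r for r in range(ensemble.topology.n_residues) if r != site]
        rows_site.extend([site] * len(residues))
        rows_res.extend(residues)
    F_pre = fwd.get("PRE")
    if F_pre is None:
        cols = []
        for site in cfg.pre_label_sites:
            residues = [r for r in range(ensemble.topology.n_residues) if r != site]
            cols.append(forward.pre_r6_matrix(ensemble, site, residues))
        F_pre = np.concatenate(cols, axis=1)
    ratio_true = forward.ratio_from_r6(w @ F_pre, params)
    s = cfg.noise.pre_sigma
    vals = ratio_true + (rng.normal(size=ratio_true.size) * s if s > 0 else 0.0)
    out["PRE"] = ObservableSet(
        kind="PRE",
        values=np.clip(vals, 1e-6, 1.0),
        sigmas=np.full(ratio_true.size, s if s > 0 else 1.0),
        meta=pd.DataFrame({"label_site": rows_site, "resid": rows_res}),
    )
    return out
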