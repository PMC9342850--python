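"""Data model and I/O for conformer ensembles, weights and observable tables.

A :class:`Conformer` stores atomic coordinates in nanometres together with a
light-weight shared :class:`Topology`.  An :class:`Ensemble` is an ordered
collection of conformers over one topology with per-conformer prior weights
on the probability simplex.  Experimental data of one kind (SAXS, chemical
shifts, FRET or PRE intensity ratios) live in an :class:`ObservableSet`.

Exchange formats are deliberately plain text: multi-model PDB for ensembles
(read and written through :mod:`mdtraj`) and TSV tables for observables and
weights.  Coordinates are converted A <-> nm at the PDB boundary; internally
everything is nm.  Residues are indexed 0-based internally while PDB output
uses 1-based residue numbers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnsembleError",
    "FormatError",
    "TopologyError",
    "ValidationError",
    "Topology",
    "Conformer",
    "Ensemble",
    "WeightVector",
    "ObservableSet",
    "OBSERVABLE_KINDS",
    "validate_weights",
    "load_ensemble",
    "save_ensemble",
    "subsample_stride",
    "read_observables",
    "write_observables",
    "read_weights",
    "write_weights",
]


class EnsembleError(Exception):
    """Base error for ensemble handling."""


class FormatError(EnsembleError):
    """Malformed input file (inconsistent models, bad table)."""


class TopologyError(EnsembleError):
    """Missing or inconsistent atoms/residues."""


class ValidationError(EnsembleError):
    """Value-level invariant violated (weights, sigmas, ...)."""


AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA1 = {v: k for k, v in AA3.items()}

BACKBONE_REQUIRED = ("N", "CA", "C", "O")

# simplex tolerance shared by every weight check
SIMPLEX_TOL = 1e-9


def validate_weights(w: Iterable[float], n: int | None = None) -> np.ndarray:
    """Validate a probability vector and return it as a float array.

    Raises :class:`ValidationError` unless all entries are >= 0 and the sum
    is 1 within ``1e-9``.
    """
    arr = np.asarray(list(w) if not isinstance(w, np.ndarray) else w, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("weights must be one-dimensional")
    if n is not None and arr.size != n:
        raise ValidationError(f"expected {n} weights, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("weights must be finite")
    if np.any(arr < -SIMPLEX_TOL):
        raise ValidationError("weights must be non-negative")
    if abs(arr.sum() - 1.0) > SIMPLEX_TOL * max(1, arr.size):
        raise ValidationError(f"weights must sum to 1 (got {arr.sum()!r})")
    return np.clip(arr, 0.0, None)


@dataclass
class WeightVector:
    """Probability vector over conformers (simplex-validated on construction)."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = validate_weights(self.w)

    def __len__(self) -> int:
        return self.w.size

    def __array__(self, dtype=None) -> np.ndarray:
        return np.asarray(self.w, dtype=dtype)


class Topology:
    """Shared per-atom bookkeeping: residue index, residue name, atom name."""

    def __init__(
        self,
        atom_resid: Sequence[int],
        atom_names: Sequence[str],
        residue_names: Sequence[str],
    ) -> None:
        self.atom_resid = np.asarray(atom_resid, dtype=int)
        self.atom_names = list(atom_names)
        self.residue_names = list(residue_names)
        if len(self.atom_names) != self.atom_resid.size:
            raise TopologyError("atom_names and atom_resid length mismatch")
        self._index: dict[tuple[int, str], int] = {
            (int(r), a): i
            for i, (r, a) in enumerate(zip(self.atom_resid, self.atom_names))
        }
        self.sequence = "".join(AA1.get(rn, "X") for rn in self.residue_names)

    @property
    def n_atoms(self) -> int:
        return self.atom_resid.size

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def index(self, resid: int, atom_name: str) -> int | None:
        """Atom index of ``atom_name`` in residue ``resid`` (0-based), or None."""
        return self._index.get((resid, atom_name))

    def require(self, resid: int, atom_name: str) -> int:
        i = self.index(resid, atom_name)
        if i is None:
            raise TopologyError(
                f"residue {resid} ({self.residue_names[resid]}) lacks atom {atom_name}"
            )
        return i

    def select(self, atom_name: str) -> np.ndarray:
        """Indices of all atoms with the given name, in residue order."""
        return np.flatnonzero(np.array(self.atom_names, dtype=object) == atom_name)

    def validate(self) -> None:
        for r in range(self.n_residues):
            for name in BACKBONE_REQUIRED:
                self.require(r, name)
            if self.residue_names[r] != "GLY":
                self.require(r, "CB")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Topology)
            and self.atom_names == other.atom_names
            and self.residue_names == other.residue_names
            and np.array_equal(self.atom_resid, other.atom_resid)
        )


@dataclass
class Conformer:
    """One structure: coordinates (nm) plus a shared topology."""

    coords: np.ndarray
    topology: Topology

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise TopologyError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.topology.n_atoms} atoms"
            )

    @property
    def sequence(self) -> str:
        return self.topology.sequence

    @property
    def n_residues(self) -> int:
        return self.topology.n_residues

    def atom(self, resid: int, name: str) -> np.ndarray:
        return self.coords[self.topology.require(resid, name)]

    def ca_coords(self) -> np.ndarray:
        idx = self.topology.select("CA")
        return self.coords[idx]

    def validate(self, ca_bounds: tuple[float, float] = (0.2, 0.6)) -> None:
        """Enforce conformer invariants.

        Backbone completeness, CB for non-glycine, finite coordinates, and
        consecutive CA-CA distances inside ``ca_bounds`` (nm).
        """
        self.topology.validate()
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")
        ca = self.ca_coords()
        if len(ca) >= 2:
            d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
            lo, hi = ca_bounds
            if np.any(d <= lo) or np.any(d >= hi):
                raise ValidationError(
                    f"consecutive CA-CA distance outside ({lo}, {hi}) nm: "
                    f"range [{d.min():.3f}, {d.max():.3f}]"
                )


class Ensemble:
    """Ordered conformer set over one topology, with prior weights."""

    def __init__(
        self,
        conformers: Sequence[Conformer],
        prior_weights: Iterable[float] | None = None,
    ) -> None:
        if len(conformers) == 0:
            raise ValidationError("ensemble needs at least one conformer")
        top = conformers[0].topology
        for c in conformers[1:]:
            if c.topology is not top and c.topology != top:
                raise TopologyError("conformers do not share a topology")
            if c.coords.shape != conformers[0].coords.shape:
                raise TopologyError("conformers differ in atom count")
        self.conformers = list(conformers)
        self.topology = top
        n = len(self.conformers)
        if prior_weights is None:
            self.prior_weights = np.full(n, 1.0 / n)
        else:
            self.prior_weights = validate_weights(prior_weights, n)
        self._xyz: np.ndarray | None = None
        self.cache: dict = {}  # derived per-conformer quantities (e.g. DSSP states)

    @property
    def n(self) -> int:
        return len(self.conformers)

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> Conformer:
        return self.conformers[i]

    @property
    def sequence(self) -> str:
        return self.topology.sequence

    @property
    def xyz(self) -> np.ndarray:
        """Stacked coordinates, shape (n_conformers, n_atoms, 3), nm."""
        if self._xyz is None:
            self._xyz = np.stack([c.coords for c in self.conformers])
        return self._xyz

    def ca_xyz(self) -> np.ndarray:
        """CA coordinates, shape (n_conformers, n_residues, 3), nm."""
        return self.xyz[:, self.topology.select("CA"), :]

    def subset(self, indices: Iterable[int]) -> "Ensemble":
        idx = np.asarray(list(indices), dtype=int)
        return Ensemble([self.conformers[i] for i in idx])


def subsample_stride(ensemble: Ensemble, stride: int) -> Ensemble:
    """Keep conformers at indices 0, stride, 2*stride, ... with uniform weights."""
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    if stride >= ensemble.n:
        raise ValidationError(
            f"stride {stride} >= ensemble size {ensemble.n}: nothing left to keep"
        )
    return ensemble.subset(range(0, ensemble.n, stride))


# ---------------------------------------------------------------------------
# multi-model PDB I/O (via mdtraj)
# ---------------------------------------------------------------------------

def _mdtraj_topology(top: Topology):
    import mdtraj as md
    from mdtraj.core import element as elem

    elements = {"N": elem.nitrogen, "C": elem.carbon, "O": elem.oxygen,
                "H": elem.hydrogen, "S": elem.sulfur}
    mtop = md.Topology()
    chain = mtop.add_chain()
    residues = []
    for r, rname in enumerate(top.residue_names):
        residues.append(mtop.add_residue(rname, chain, resSeq=r + 1))
    for r, name in zip(top.atom_resid, top.atom_names):
        e = elements.get(name[0], elem.carbon)
        mtop.add_atom(name, e, residues[int(r)])
    return mtop


def save_ensemble(path: str | os.PathLike, ensemble: Ensemble) -> None:
    """Write a multi-model PDB (one MODEL per conformer), coordinates in A."""
    import mdtraj as md

    mtop = _mdtraj_topology(ensemble.topology)
    traj = md.Trajectory(xyz=ensemble.xyz.copy(), topology=mtop)
    traj.save_pdb(str(path))


def load_ensemble(path: str | os.PathLike) -> Ensemble:
    """Read a multi-model PDB into an Ensemble with uniform prior weights.

    Raises :class:`FormatError` for unreadable/inconsistent files and
    :class:`TopologyError` when required backbone atoms are missing.
    """
    import mdtraj as md

    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        traj = md.load_pdb(str(path), standard_names=False)
    except Exception as exc:  # mdtraj raises assorted errors on bad PDBs
        raise FormatError(f"could not parse multi-model PDB {path}: {exc}") from exc
    if traj.n_frames < 1:
        raise FormatError(f"{path} contains no MODEL")
    atom_resid = np.array([a.residue.index for a in traj.topology.atoms])
    atom_names = [a.name for a in traj.topology.atoms]
    residue_names = [r.name for r in traj.topology.residues]
    top = Topology(atom_resid, atom_names, residue_names)
    top.validate()
    conformers = [Conformer(traj.xyz[i].astype(float), top) for i in range(traj.n_frames)]
    return Ensemble(conformers)


# ---------------------------------------------------------------------------
# TSV observable tables
# ---------------------------------------------------------------------------

OBSERVABLE_KINDS = ("SAXS", "CS", "FRET", "PRE")

#: TSV column layout per kind: (meta columns, value column)
_TABLE_COLUMNS = {
    "SAXS": (["q_nm"], "I"),
    "CS": (["resid", "atom"], "shift_ppm"),
    "FRET": (["site_a", "site_b", "R0_nm"], "E"),
    "PRE": (["label_site", "resid"], "ratio"),
}


@dataclass
class ObservableSet:
    """One experiment type's values, uncertainties and metadata.

    ``meta`` is a DataFrame whose columns depend on ``kind``: q-grid (nm^-1)
    for SAXS; (resid, atom in {CA, CB}) for chemical shifts; (site_a, site_b,
    R0 in nm) for FRET; (label_site, resid) for PRE intensity ratios.
    """

    kind: str
    values: np.ndarray
    sigmas: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.kind not in OBSERVABLE_KINDS:
            raise ValidationError(f"unknown observable kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.values.shape != self.sigmas.shape or self.values.ndim != 1:
            raise ValidationError("values and sigmas must be 1-D and same length")
        if len(self.meta) != self.values.size:
            raise ValidationError("meta rows must match number of datapoints")
        if np.any(~np.isfinite(self.sigmas)) or np.any(self.sigmas <= 0):
            raise ValidationError("sigmas must be positive and finite")

    def __len__(self) -> int:
        return self.values.size


def write_observables(path: str | os.PathLike, obs: ObservableSet) -> None:
    meta_cols, value_col = _TABLE_COLUMNS[obs.kind]
    df = obs.meta[meta_cols].copy()
    df[value_col] = obs.values
    df["sigma"] = obs.sigmas
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_observables(path: str | os.PathLike, kind: str) -> ObservableSet:
    if kind not in OBSERVABLE_KINDS:
        raise ValidationError(f"unknown observable kind {kind!r}")
    meta_cols, value_col = _TABLE_COLUMNS[kind]
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"could not read table {path}: {exc}") from exc
    missing = [c for c in meta_cols + [value_col, "sigma"] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} for kind {kind}")
    return ObservableSet(
        kind=kind,
        values=df[value_col].to_numpy(float),
        sigmas=df["sigma"].to_numpy(float),
        meta=df[meta_cols].reset_index(drop=True),
    )


def write_weights(path: str | os.PathLike, weights: WeightVector | np.ndarray) -> None:
    w = np.asarray(weights, dtype=float)
    validate_weights(w)
    df = pd.DataFrame({"conformer_index": np.arange(w.size), "weight": w})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_weights(path: str | os.PathLike) -> WeightVector:
    df = pd.read_csv(path, sep="\t")
    if "weight" not in df.columns:
        raise FormatError(f"{path}: missing 'weight' column")
    order = np.argsort(df["conformer_index"].to_numpy())
    return WeightVector(df["weight"].to_numpy(float)[order])
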