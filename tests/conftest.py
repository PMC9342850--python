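"""Shared fixtures: small synthetic ensembles and geometric fixtures.

Everything is generated programmatically at session scope so the expensive
chain growth happens once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from idpens import synth
from idpens.core import Conformer, Ensemble, Topology

SEQ20 = "MTPSTPPRSRGTSYLAQPSG"


@pytest.fixture(scope="session")
def helix15() -> Conformer:
    """Ideal alpha-helix, 15 alanines at (phi, psi) = (-60, -45)."""
    return synth.build_chain("A" * 15, synth.fixed_sampler(-60.0, -45.0), seed=0)


@pytest.fixture(scope="session")
def strand15() -> Conformer:
    """Fully extended single strand (no bridge partner)."""
    return synth.build_chain("A" * 15, synth.fixed_sampler(-120.0, 120.0), seed=0)


@pytest.fixture(scope="session")
def coil60() -> Ensemble:
    """60 excluded-volume coils of a 20-residue chain."""
    return synth.generate_prior(
        synth.PriorStyle(name="coil"), SEQ20, n_conformers=60, seed=3
    )


@pytest.fixture(scope="session")
def coil90_small() -> Ensemble:
    """40 coils of the full 90-residue default sequence."""
    return synth.generate_prior(
        synth.PriorStyle(name="coil"), synth.DEFAULT_SEQUENCE, n_conformers=40, seed=5
    )


@pytest.fixture(scope="session")
def compact150() -> Ensemble:
    """150 conformers of the compact (attractive, transient-helix) style."""
    return synth.generate_prior(
        synth.DEFAULT_STYLES["compact"], synth.DEFAULT_SEQUENCE,
        n_conformers=150, seed=7,
    )


def make_conformer(atom_specs, residue_names) -> Conformer:
    """Build a Conformer from explicit (resid, atom_name, xyz) triples."""
    atom_resid = [a[0] for a in atom_specs]
    atom_names = [a[1] for a in atom_specs]
    coords = np.array([a[2] for a in atom_specs], dtype=float)
    top = Topology(atom_resid, atom_names, residue_names)
    return Conformer(coords, top)
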