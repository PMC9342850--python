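"""Canonical synthetic study scenarios.

These helpers bundle a prior pool, a known ground truth, the synthetic
datasets and the per-conformer forward matrices into one object, computing
the expensive matrices exactly once so that noise replicates and both
optimizers can reuse them.

* :func:`recovery_scenario` -- the compact-prior reweighting benchmark: an
  over-compact pool whose ground truth is an exponential tilt toward larger
  Rg, with SAXS/CS/FRET restraints and PRE held out.
* :func:`planted_scenario` -- a pool containing an exact planted subset
  whose uniform average generated the (noise-free) data; used to validate
  Monte-Carlo subset selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import forward, synth
from .core import Ensemble, ObservableSet

__all__ = ["Scenario", "recovery_scenario", "planted_scenario"]


@dataclass
class Scenario:
    """A prior pool with ground truth, datasets and aligned forward matrices."""

    prior: Ensemble
    truth: synth.GroundTruth
    config: synth.SynthConfig
    datasets: dict[str, ObservableSet]
    forwards: dict[str, forward.ForwardMatrix]
    planted_indices: np.ndarray | None = None

    @property
    def matrices(self) -> dict[str, np.ndarray]:
        return {k: fm.matrix for k, fm in self.forwards.items()}

    def replicate(self, seed: int) -> "Scenario":
        """Same truth and pool, fresh noise realization."""
        data = synth.synthesize_experiments(
            self.prior, self.truth, self.config, seed=seed, forwards=self.matrices
        )
        fwds = {
            k: forward.ForwardMatrix(k, self.forwards[k].matrix, data[k]) for k in data
        }
        return Scenario(
            prior=self.prior,
            truth=self.truth,
            config=self.config,
            datasets=data,
            forwards=fwds,
            planted_indices=self.planted_indices,
        )


def _matrices_for(prior: Ensemble, cfg: synth.SynthConfig) -> dict[str, np.ndarray]:
    a, b = cfg.fret_pair
    pre_cols = []
    for site in cfg.pre_label_sites:
        residues = [r for r in range(prior.topology.n_residues) if r != site]
        pre_cols.append(forward.pre_r6_matrix(prior, site, residues))
    return {
        "SAXS": forward.saxs_matrix(prior, cfg.q_grid),
        "CS": forward.cs_matrix(prior),
        "FRET": forward.fret_matrix(prior, a, b, cfg.fret_r0),
        "PRE": np.concatenate(pre_cols, axis=1),
    }


def _assemble(
    prior: Ensemble,
    truth: synth.GroundTruth,
    cfg: synth.SynthConfig,
    data_seed: int,
    planted: np.ndarray | None = None,
) -> Scenario:
    mats = _matrices_for(prior, cfg)
    data = synth.synthesize_experiments(prior, truth, cfg, seed=data_seed, forwards=mats)
    fwds = {k: forward.ForwardMatrix(k, mats[k], data[k]) for k in data}
    return Scenario(
        prior=prior, truth=truth, config=cfg, datasets=data, forwards=fwds,
        planted_indices=planted,
    )


def recovery_scenario(
    n_conformers: int = 1000,
    seed: int = 1,
    style: str | synth.PriorStyle = "compact",
    tilt_coefficient: float = -2.0,
    config: synth.SynthConfig | None = None,
) -> Scenario:
    """Compact prior + expansion-tilted ground truth + noisy datasets.

    The ground truth tilts the prior's weights by ``exp(+|c| Rg)`` (negative
    coefficient), emulating experimental data reporting a more expanded
    chain than the pool; recovering the truth's mean Rg by reweighting is
    then a well-posed parameter-recovery problem.
    """
    ss = np.random.SeedSequence(seed)
    s_prior, s_data = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    if isinstance(style, str):
        style = synth.DEFAULT_STYLES[style]
    cfg = config or synth.SynthConfig()
    prior = synth.generate_prior(
        style, synth.DEFAULT_SEQUENCE, n_conformers, seed=s_prior
    )
    truth = synth.make_ground_truth(prior, "rg", tilt_coefficient)
    return _assemble(prior, truth, cfg, s_data)


def planted_scenario(
    pool_size: int = 400,
    subset_size: int = 50,
    seed: int = 1,
    style: str | synth.PriorStyle = "coil",
    config: synth.SynthConfig | None = None,
) -> Scenario:
    """Pool with a planted subset whose exact averages are the data.

    The ground truth puts uniform weight on a random ``subset_size``-subset
    and the datasets are synthesized with zero noise (sigma columns keep the
    configured values), so the planted subset reproduces every observable
    exactly and Monte-Carlo selection has a verifiable solution.
    """
    ss = np.random.SeedSequence(seed)
    s_prior, s_pick = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    if isinstance(style, str):
        style = synth.DEFAULT_STYLES[style]
    base = config or synth.SynthConfig()
    noise_free = synth.SynthConfig(
        q_grid=base.q_grid,
        fret_pair=base.fret_pair,
        fret_r0=base.fret_r0,
        pre_label_sites=base.pre_label_sites,
        noise=synth.NoiseConfig(saxs_frac=0.0, cs_sigma=0.0, fret_sigma=0.0, pre_sigma=0.0),
    )
    prior = synth.generate_prior(style, synth.DEFAULT_SEQUENCE, pool_size, seed=s_prior)
    rng = np.random.default_rng(s_pick)
    planted = np.sort(rng.choice(pool_size, size=subset_size, replace=False))
    w = np.zeros(pool_size)
    w[planted] = 1.0 / subset_size
    rg = np.array([synth.conformer_rg(c) for c in prior.conformers])
    truth = synth.GroundTruth(
        true_weights=w, tilt_feature="planted", coefficient=0.0, feature_values=rg
    )
    scen = _assemble(prior, truth, noise_free, data_seed=0, planted=planted)
    # planted data are exact averages; restore realistic sigma columns so the
    # chi^2 targets are meaningful
    for kind, obs in scen.datasets.items():
        if kind == "SAXS":
            obs.sigmas = np.maximum(
                base.noise.saxs_frac * np.abs(obs.values), 1e-9
            )
        elif kind == "CS":
            obs.sigmas = np.full(len(obs), max(base.noise.cs_sigma, 1e-3))
        elif kind == "FRET":
            obs.sigmas = np.full(len(obs), max(base.noise.fret_sigma, 1e-3))
        elif kind == "PRE":
            obs.sigmas = np.full(len(obs), max(base.noise.pre_sigma, 1e-3))
    return scen
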