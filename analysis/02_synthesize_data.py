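#!/usr/bin/env python
"""Synthesize the "experimental" SAXS/CS/FRET/PRE tables.

The ground truth is an exponential tilt of the matched pool's weights toward
larger Rg, standing in for the real molecule being more expanded than the
simulation pools.  Noisy observables are drawn around the truth-weighted
forward averages and written as TSV tables; the sigma columns record the
noise actually used.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, DATA_DIR, PRIORS_DIR, ensure_dirs  # noqa: E402

from idpens import synth  # noqa: E402
from idpens.core import load_ensemble, write_observables, write_weights  # noqa: E402


def main() -> None:
    ensure_dirs()
    seeds = CONFIG.seeds()
    prior = load_ensemble(PRIORS_DIR / f"{CONFIG.truth_prior}.pdb")
    truth = synth.make_ground_truth(
        prior, CONFIG.truth_feature, CONFIG.truth_coefficient
    )
    datasets = synth.synthesize_experiments(prior, truth, CONFIG.synth, seed=seeds["data"])
    for kind, obs in datasets.items():
        write_observables(DATA_DIR / f"{kind.lower()}.tsv", obs)
        print(f"{kind}: {len(obs)} datapoints")
    write_weights(DATA_DIR / "true_weights.tsv", truth.true_weights)
    print(
        f"truth: {CONFIG.truth_feature} tilt {CONFIG.truth_coefficient} on "
        f"'{CONFIG.truth_prior}'; truth mean Rg = {truth.mean_feature():.3f} nm "
        f"(pool mean {truth.feature_values.mean():.3f} nm)"
    )


if __name__ == "__main__":
    main()
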