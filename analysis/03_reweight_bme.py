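#!/usr/bin/env python
"""Reweight every prior pool against the synthetic data by maximum entropy.

For each pool: build the forward matrices, scan theta downward over the
default grid (SAXS + CS + FRET restrained, Omega-weighted FRET), monitor the
held-out PRE score, select theta at the L-curve elbow and write the scan
table and posterior weights.  Watch the compact pool: its chi2 falls
steeply at first, and pushing theta below the elbow degrades the PRE
validation -- the overfitting signature.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import BME_DIR, CONFIG, DATA_DIR, PRIOR_NAMES, PRIORS_DIR, ensure_dirs  # noqa: E402

from idpens import bme, forward  # noqa: E402
from idpens.core import load_ensemble, read_observables, write_weights  # noqa: E402


def main() -> None:
    ensure_dirs()
    warnings.simplefilter("ignore")
    datasets = {
        kind: read_observables(DATA_DIR / f"{kind.lower()}.tsv", kind)
        for kind in ("SAXS", "CS", "FRET", "PRE")
    }
    for name in PRIOR_NAMES:
        prior = load_ensemble(PRIORS_DIR / f"{name}.pdb")
        fwd = {k: forward.build_forward_matrix(prior, datasets[k]) for k in datasets}
        curve = bme.theta_scan(
            {k: fwd[k] for k in ("SAXS", "CS", "FRET")},
            {k: datasets[k] for k in ("SAXS", "CS", "FRET")},
            prior.prior_weights,
            CONFIG.bme,
            validation=fwd["PRE"],
        )
        theta = bme.select_theta(curve, mode=CONFIG.theta_mode)
        i = int(np.flatnonzero(curve.thetas == theta)[0])
        res = curve.results[i]
        pd.DataFrame(
            {
                "theta": curve.thetas,
                "chi2_total": curve.column("chi2_total"),
                "chi2_total_reduced": curve.column("chi2_total_reduced"),
                "neff": [d.neff for d in curve.diagnostics],
                "pre_score": curve.column("pre_score"),
            }
        ).to_csv(BME_DIR / f"scan_{name}.tsv", sep="\t", index=False)
        write_weights(BME_DIR / f"weights_{name}.tsv", res.weights)
        d = res.diagnostics
        print(
            f"{name:8s} theta* = {theta:8.2f}  chi2_red = {d.chi2_total_reduced:.2f}  "
            f"N_eff = {d.neff:.2f}  PRE score = {d.pre_score:.3f}"
        )
    print(f"scan tables and weights under {BME_DIR}")


if __name__ == "__main__":
    main()
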