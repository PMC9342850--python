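#!/usr/bin/env python
"""Structural analytics of the six posterior ensembles (and the priors).

Per prior x method: weighted secondary-structure propensities with bootstrap
errors, the mean Rg, the long-range H-bond PMF, pi-contact class means, and
the scaling map against the coil pool as the random-coil reference.  The
analytics read the stage outputs of scripts 01-04 from disk.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import ANALYSIS_DIR, BME_DIR, CONFIG, MC_DIR, PRIOR_NAMES, PRIORS_DIR, ensure_dirs  # noqa: E402

from idpens import analysis  # noqa: E402
from idpens.core import load_ensemble, read_weights  # noqa: E402


def posterior_ensembles():
    """Yield (prior, method, ensemble, weights) for all six posteriors."""
    for name in PRIOR_NAMES:
        prior = load_ensemble(PRIORS_DIR / f"{name}.pdb")
        w_bme = read_weights(BME_DIR / f"weights_{name}.tsv").w
        yield name, "BME", prior, w_bme
        idx = np.loadtxt(MC_DIR / f"combined_{name}.tsv", skiprows=1, dtype=int)
        post = prior.subset(idx)
        yield name, "MC", post, np.full(post.n, 1.0 / post.n)


def main() -> None:
    ensure_dirs()
    warnings.simplefilter("ignore")
    seeds = CONFIG.seeds()
    reference = load_ensemble(PRIORS_DIR / "coil.pdb")  # random-coil reference
    rows = []
    for name, method, ens, w in posterior_ensembles():
        tag = f"{name}_{method.lower()}"
        ss = analysis.ss_propensity(ens, w, n_bootstrap=CONFIG.bootstrap, seed=seeds["analysis"])
        ss.to_csv(ANALYSIS_DIR / f"ss_{tag}.tsv", sep="\t", index=False)
        contacts = analysis.contact_summary(
            ens, w, n_bootstrap=CONFIG.bootstrap, seed=seeds["analysis"]
        )
        np.savetxt(
            ANALYSIS_DIR / f"hbond_pmf_{tag}.tsv", contacts.hbond_pmf,
            header="probability", comments="",
        )
        sm = analysis.scaling_map(ens, w, reference)
        np.savetxt(ANALYSIS_DIR / f"scaling_map_{tag}.tsv", sm.D, delimiter="\t")
        rows.append(
            {
                "prior": name,
                "method": method,
                "mean_rg": analysis.ensemble_rg(ens, w),
                "helix_mean": float(ss["helix"].mean()),
                "n_hbonds": contacts.n_hbonds,
                "n_hbonds_sd": contacts.n_hbonds_sd,
                "n_pipi": contacts.n_pipi,
                "scaling_vs_coil": sm.mean_offdiag(min_separation=10),
            }
        )
        print(
            f"{tag:16s} Rg = {rows[-1]['mean_rg']:.2f} nm  "
            f"helix = {rows[-1]['helix_mean']:.3f}  "
            f"nHB = {contacts.n_hbonds:.2f} +- {contacts.n_hbonds_sd:.2f}  "
            f"npi = {contacts.n_pipi:.2f}"
        )
    pd.DataFrame(rows).to_csv(ANALYSIS_DIR / "summary.tsv", sep="\t", index=False)
    print(f"analytics under {ANALYSIS_DIR}")


if __name__ == "__main__":
    main()
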