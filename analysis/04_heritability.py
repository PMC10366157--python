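#!/usr/bin/env python
"""Family-based heritability of the prepared intake traits.

Fits the kinship-covariance mixed model by Gibbs MCMC (two chains, split
Gelman-Rubin convergence check against the 1.03 rule) and by profile
maximum likelihood, and prints h2 in percent with its posterior SD — the
layout of a cohort-style heritability table.  The default Gibbs schedule
is scaled down; pass --preset reference for the full 400,000/200,000/40 run.
"""

import argparse
import json
from pathlib import Path

from famagg.heritability import (
    MCMCSettings,
    REFERENCE_PRESET,
    design_matrix,
    fit_gaussian_mcmc,
    fit_gaussian_ml,
)
from famagg.pedigree import kinship, read_pedigree
from famagg.phenotypes import read_phenotypes


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--iters", type=int, default=20_000)
    ap.add_argument("--burnin", type=int, default=10_000)
    ap.add_argument("--thin", type=int, default=10)
    ap.add_argument("--chains", type=int, default=2)
    ap.add_argument("--preset", choices=["reference", "none"], default="none")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    if args.preset == "reference":
        args.iters, args.burnin, args.thin = (
            REFERENCE_PRESET["n_iter"], REFERENCE_PRESET["n_burnin"], REFERENCE_PRESET["thin"]
        )

    ped = read_pedigree(args.cohort / "cohort.ped")
    table = read_phenotypes(args.cohort / "phenotypes_prepared.csv")
    km = kinship(ped)
    ids = [i for i in km.ids if i in table.data.index]
    sub = table.data.loc[ids]
    a_matrix = km.subset(ids).relationship()
    x, names = design_matrix(sub)
    settings = MCMCSettings(args.iters, args.burnin, args.thin, args.chains, args.seed)

    print(f"n={len(ids)} individuals; fixed effects: {names}")
    print(f"Gibbs: {settings.n_iter} sweeps, {settings.n_burnin} burn-in, "
          f"thin {settings.thin}, {settings.n_chains} chains "
          f"-> {(settings.n_iter - settings.n_burnin)//settings.thin} draws/chain")
    print(f"{'trait':10s} {'h2 (%)':>8s} {'post. SD':>9s} {'ML h2 (%)':>10s} {'R-hat':>7s}")
    for trait in table.traits:
        y = sub[trait].to_numpy(dtype=float)
        fit = fit_gaussian_mcmc(y, x, a_matrix, settings)
        ml = fit_gaussian_ml(y, x, a_matrix)
        summary = {"trait": trait, "n": len(y), **fit.summary()}
        summary["ml"] = {"h2": ml.h2, "loglik": ml.loglik,
                         "lrt_stat": ml.lrt_stat, "lrt_p": ml.lrt_p}
        (args.cohort / f"heritability_{trait}.json").write_text(
            json.dumps(summary, indent=2, default=float)
        )
        rhat = fit.rhat["h2"] if fit.rhat else float("nan")
        flag = "" if (fit.converged in (True, None)) else "  NOT CONVERGED"
        print(f"{trait:10s} {100*fit.h2_mean:8.2f} {fit.h2_sd:9.4f} "
              f"{100*ml.h2:10.2f} {rhat:7.4f}{flag}")
    print("\nwrote heritability_<trait>.json")


if __name__ == "__main__":
    main()
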