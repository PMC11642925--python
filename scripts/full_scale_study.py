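"""Opt-in full-scale simulation study (long-running; hours to days).

Reproduces the complete accuracy and inferential-efficiency grid — all nine
regions, sample sizes n in {10, 20, 40} per group, 500 mixed-model
replicates and (by default) 20 hierarchical-model replicates per condition
with power / false-positive rates from log-spline tail integration. The
desk-scale counterpart of this analysis is scripts/acceptance.py; this
script exists for full-magnitude comparisons (mean regional RMSE reductions,
power curves) and is NOT run by the test suite.

Usage::

    python scripts/full_scale_study.py --seed 1 --out scratch/full_scale \
        --n-simba-reps 20 --n-lme-reps 500
"""

from __future__ import annotations

import argparse
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--sample-sizes", type=int, nargs="+", default=[10, 20, 40])
    ap.add_argument("--n-simba-reps", type=int, default=20)
    ap.add_argument("--n-lme-reps", type=int, default=500)
    ap.add_argument("--chains", type=int, default=3)
    ap.add_argument("--warmup", type=int, default=1000)
    ap.add_argument("--samples", type=int, default=1000)
    args = ap.parse_args()
    seed = int(args.seed)
    args.out.mkdir(parents=True, exist_ok=True)

    from simbaref.design import MCMCOptions, Priors, SimbaSpec, build_design
    from simbaref.evaluation import (
        accuracy_metrics, lme_contrast, power_fpr, rmse_reduction,
    )
    from simbaref.model import SimbaModel, extract_contrast, sample_posterior
    from simbaref.nls import fit_dataset_nls
    from simbaref.simulate import (
        default_truth_parameters, make_reference_library, simulate_dataset,
    )

    library = make_reference_library(n=500, seed=seed * 13 + 1)
    base = default_truth_parameters()
    priors = Priors(
        intercept_mu={
            "logR1": float(np.log(0.95)),
            "logk2prime": float(np.log(0.09)),
            "logBPND": float(np.log(0.8)),
        }
    )
    power_rows, acc_tables = [], []
    for n in args.sample_sizes:
        # ---- LME comparator over many replicates (effect and null arms)
        for arm, effect in (("effect", 0.04), ("null", 0.0)):
            zs = []
            for rep in range(args.n_lme_reps):
                design = replace(
                    base, n_per_group=n, treatment_effect_logBPND=effect,
                    seed=(seed * 1_000_003 + 7919 * n + rep) % (2**31),
                )
                _, truth, ref_fits = simulate_dataset(design, library)
                res = lme_contrast(
                    truth.rename(columns={"true_logBPND": "logBPND"})
                )
                if res["converged"]:
                    zs.append(res["z"])
            pr = power_fpr(np.asarray(zs), seed=seed, method="lme-true",
                           n_per_group=n)
            power_rows.append({"arm": arm, **pr.as_dict()})

        # ---- hierarchical model over fewer replicates
        for arm, effect in (("effect", 0.04), ("null", 0.0)):
            zs = []
            for rep in range(args.n_simba_reps):
                design = replace(
                    base, n_per_group=n, treatment_effect_logBPND=effect,
                    seed=(seed * 2_000_003 + 104729 * n + rep) % (2**31),
                )
                table, truth, ref_fits = simulate_dataset(design, library)
                nls = fit_dataset_nls(table, ref_fits, seed=seed)
                spec = SimbaSpec(
                    covariates={"logBPND": ["group", "post", "group:post"]},
                    priors=priors,
                    mcmc=MCMCOptions(chains=args.chains, warmup=args.warmup,
                                     samples=args.samples, seed=seed + rep),
                )
                post = sample_posterior(
                    SimbaModel(build_design(table, ref_fits, spec)),
                    warm_start_estimates=nls,
                )
                zs.append(extract_contrast(post, "logBPND:group_patient:post")["z"])
                if arm == "effect" and rep == 0:
                    acc_s = accuracy_metrics(post.tac_estimates, truth)
                    acc_n = accuracy_metrics(nls, truth)
                    per_region, summary = rmse_reduction(acc_s, acc_n)
                    per_region.insert(0, "n_per_group", n)
                    acc_tables.append(per_region)
            pr = power_fpr(np.asarray(zs), seed=seed, method="simba",
                           n_per_group=n)
            power_rows.append({"arm": arm, **pr.as_dict()})
        pd.DataFrame(power_rows).to_csv(args.out / "power.csv", index=False)
        if acc_tables:
            pd.concat(acc_tables).to_csv(args.out / "rmse_reduction.csv", index=False)
        print(f"finished n={n}")

    (args.out / "config.json").write_text(json.dumps(vars(args), default=str, indent=1))


if __name__ == "__main__":
    main()
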