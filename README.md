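# simbaref

Simultaneous hierarchical Bayesian quantification and analysis of
reference-tissue PET time-activity-curve (TAC) data.

## The problem

Brain PET studies conventionally proceed in two stages: first each
time-activity curve — the radioactivity concentration of one brain region
of one scan, averaged over acquisition frames — is fit on its own with a
compartmental model to obtain pharmacokinetic (PK) parameters, and then the
binding estimates are carried into a separate statistical model. For
non-invasive quantification against a reference region (a region without
specific binding, classically cerebellum), the workhorse models are the
simplified reference tissue model (SRTM), with parameters R1 (relative
delivery), k2′ (reference-tissue clearance, 1/min) and BPND (non-displaceable
binding potential), and its four-parameter parent, the full reference tissue
model (FRTM, adding the dissociation rate k4). Per-TAC fitting is noisy in
small or low-binding regions, and two-stage analysis propagates that noise
poorly.

`simbaref` implements the simultaneous alternative, a SiMBA-style
(Simultaneous Multifactor Bayesian Analysis) model for reference-tissue
data: one hierarchical multivariate Bayesian model that performs
quantification *and* analysis for all regions of all individuals at once.
Each log PK parameter gets a linear predictor

    theta_ijk = alpha_i + X_ijk' beta_i + tau_ij + upsilon_ik + phi_ijk

with crossed, partially pooled subject (tau), region (upsilon) and TAC
(phi, subject x measurement x region) deviations drawn from estimated
multivariate normal distributions, covariates (age in centred decades,
diagnosis, treatment, centre and centre x region for multi-centre
harmonisation, region x age random slopes), and a structured
measurement-error model for log sigma (subject and region deviations,
centred log frame duration / region volume / injected dose, and a smooth
function of time). The measured activities are normal around the
closed-form SRTM/FRTM prediction evaluated at exp(theta).

Two ingredients make this tractable:

* **A parametric reference curve (Feng-1TC).** The reference TAC is
  described by a tri-exponential input shape with a linear rise convolved
  with a one-tissue impulse response plus an onset time — 9 purely
  descriptive parameters. Because this curve is a polynomial-exponential
  mixture, every convolution the reference-tissue models need has an exact
  closed form, so the MCMC never performs numerical convolution.
* **A blocked adaptive MCMC sampler** written for this posterior, which
  updates the conditionally independent TAC/subject/region blocks in
  parallel and mixes the intercepts and hierarchy scales through
  likelihood-invariant interweaving moves.

The package also ships the surrounding study machinery: bounded multi-start
Feng-1TC reference fitting with automated underfit detection, a
conventional per-TAC NLS comparator, a realistic synthetic-data generator
with ground truth (two groups, pre/post placebo or treatment design), and
the evaluation framework — regional RMSE / correlation against truth, a
univariate linear-mixed-model comparator on logBPND, and power /
false-positive-rate estimation via natural log-spline density tail
integration.

## Worked example

Simulate a small two-group pre/post study (10 subjects per group, three
regions including a small low-binding brain-stem region, "DBS"), quantify it
both ways, and compare accuracy against the known truth:

```python
import numpy as np
from dataclasses import replace

from simbaref import (
    MCMCOptions, Priors, SimbaSpec, build_design, default_truth_parameters,
    make_reference_library, simulate_dataset, fit_dataset_nls,
    accuracy_metrics, rmse_reduction, sample_posterior, extract_contrast,
)
from simbaref.model import SimbaModel

# 1. a reference-TAC library and a simulated two-group pre/post study
library = make_reference_library(n=30, seed=1)
base = default_truth_parameters()
design = replace(base, n_per_group=10,
                 regions=[r for r in base.regions if r.name in ("DBS", "FC", "OC")],
                 seed=42)
table, truth, ref_fits = simulate_dataset(design, library)

# 2. conventional two-stage quantification: per-TAC nonlinear least squares
nls = fit_dataset_nls(table, ref_fits, seed=0)

# 3. simultaneous hierarchical Bayesian fit (short chains for the example)
spec = SimbaSpec(
    covariates={"logBPND": ["group", "post", "group:post"]},
    priors=Priors(intercept_mu={"logR1": np.log(0.95).item(),
                                "logk2prime": np.log(0.09).item(),
                                "logBPND": np.log(0.8).item()}),
    mcmc=MCMCOptions(chains=2, warmup=600, samples=600, seed=7),
)
post = sample_posterior(SimbaModel(build_design(table, ref_fits, spec)),
                        warm_start_estimates=nls)

# 4. accuracy against the ground truth, and the treatment contrast
per_region, summary = rmse_reduction(
    accuracy_metrics(post.tac_estimates, truth), accuracy_metrics(nls, truth)
)
print(per_region[per_region.parameter == "BPND"].round(4).to_string(index=False))
c = extract_contrast(post, "logBPND:group_patient:post")
print(f"treatment - placebo contrast: {c['mean']:.3f} "
      f"(posterior SD {c['sd']:.3f}, 95% CI {c['ci95'][0]:.3f} to {c['ci95'][1]:.3f})")
```

Output (a couple of minutes on one core):

```
region parameter  rmse_a  rmse_b  reduction_pct
   DBS      BPND  0.0184  0.0465        60.4012
    FC      BPND  0.0188  0.0185        -1.4063
    OC      BPND  0.0307  0.0368        16.6379
treatment - placebo contrast: 0.026 (posterior SD 0.013, 95% CI 0.000 to 0.048)
```

`rmse_a` is the hierarchical model's BPND error against the simulated
truth, `rmse_b` the per-TAC NLS error, both over the baseline measurements
of the control group. The gain is largest (60%) in the noisy low-binding
DBS region, where per-TAC fitting struggles and partial pooling has the
most to offer; in the high-signal frontal cortex both methods are already
near the noise floor and the difference is marginal. The contrast is the
difference-in-differences treatment effect on logBPND (simulated truth
+0.04), recovered here with its full posterior uncertainty in the same
model that did the quantification.

The same pipeline is scriptable from the shell:

    simbaref simulate --out sim --seed 1
    simbaref fit-nls   --tacs sim/tacs.tsv --ref sim/ref_fits.json --out nls.csv
    simbaref fit-simba --tacs sim/tacs.tsv --ref sim/ref_fits.json \
        --out fit --config model.yaml --nls-init nls.csv
    simbaref evaluate  --estimates fit/tac_estimates.csv --truth sim/truth.csv \
        --out accuracy.csv --compare nls.csv

## Layout

* `simbaref.curves` / `simbaref.kinetics` — closed-form curve algebra and
  the Feng-1TC / SRTM / FRTM forward models (scalar and vectorised).
* `simbaref.reffit` — reference-curve fitting with underfit detection.
* `simbaref.nls` — the conventional per-TAC comparator.
* `simbaref.design` / `simbaref.model` — model specification, design
  matrices, the posterior, the sampler, and posterior summaries.
* `simbaref.simulate` — the synthetic-data generator and its defaults.
* `simbaref.evaluation` / `simbaref.logspline` — accuracy, LME comparator,
  power and false-positive rates.
* `simbaref.io` / `simbaref.cli` — TSV/JSON data formats and the CLI.

See `docs/methods.md` for the model, its assumptions, the simulation
design, and the numerical choices.
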