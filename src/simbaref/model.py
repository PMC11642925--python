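"""The simultaneous hierarchical multivariate Bayesian TAC model.

Every PK parameter of every TAC gets a log-scale linear predictor

    theta[i, tac] = alpha_i + X_i beta_i + tau_i[subject] + upsilon_i[region]
                    + phi_i[tac]

with the subject (tau), region (upsilon) and TAC (phi) deviation vectors
drawn from zero-mean multivariate normals whose covariances are estimated
(LKJ-prior correlations, half-normal SD priors). The measured activities are
normal around the closed-form SRTM (or FRTM) prediction evaluated at
exp(theta), with a structured log-sigma model (global level, subject and
region deviations, centred-log acquisition covariates, and a smooth function
of time). All deviation blocks are non-centred: the sampler works on
standard-normal z-scores scaled by the hierarchical SDs, which avoids the
funnel geometry that tightly regularised TAC deviations (prior SD 0.025)
would otherwise create.

Sampling uses a blocked adaptive Metropolis scheme written for this
posterior: TAC-, subject- and region-level blocks are conditionally
independent across their groups given the rest of the state, so each sweep
proposes and accepts them in parallel with a handful of vectorised
forward-model evaluations; global blocks (intercepts and fixed effects per
PK parameter, hierarchy scales, the sigma model) use multivariate proposals
with covariance adapted during warmup and frozen afterwards.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Design, SimbaSpec, build_design
from .io import TACTable
from .kinetics import frtm_predict_batch, srtm_predict_batch
from .reffit import RefFit

LOG2PI = float(np.log(2.0 * np.pi))


# ------------------------------------------------------------------- layout
class ParamLayout:
    """Maps named parameter blocks to slices of one flat state vector."""

    def __init__(self) -> None:
        self.shapes: dict[str, tuple[int, ...]] = {}
        self.slices: dict[str, slice] = {}
        self.size = 0

    def add(self, name: str, shape: tuple[int, ...]) -> None:
        n = int(np.prod(shape)) if shape else 1
        self.shapes[name] = shape
        self.slices[name] = slice(self.size, self.size + n)
        self.size += n

    def get(self, x: np.ndarray, name: str) -> np.ndarray:
        return x[self.slices[name]].reshape(self.shapes[name])

    def set(self, x: np.ndarray, name: str, value: np.ndarray) -> None:
        x[self.slices[name]] = np.asarray(value, float).ravel()

    def indices(self, name: str) -> np.ndarray:
        s = self.slices[name]
        return np.arange(s.start, s.stop)


# ------------------------------------------------- correlation parameterisation
def chol_from_cpc(z: np.ndarray, m: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from unconstrained partial correlations.

    ``z`` has length m(m-1)/2 in row-major lower-triangle order; each entry
    maps to a canonical partial correlation via tanh.
    """
    r = np.tanh(z)
    L = np.zeros((m, m))
    L[0, 0] = 1.0
    k = 0
    for i in range(1, m):
        rem = 1.0
        for j in range(i):
            L[i, j] = r[k] * np.sqrt(rem)
            rem -= L[i, j] ** 2
            k += 1
        L[i, i] = np.sqrt(max(rem, 1e-12))
    return L


def lkj_cpc_logprior(z: np.ndarray, m: int, eta: float) -> float:
    """LKJ(eta) prior on the correlation matrix, expressed on the unconstrained
    partial-correlation scale (includes the tanh Jacobian)."""
    total = 0.0
    k = 0
    for i in range(1, m):
        for j in range(i):
            beta = eta + 0.5 * (m - 2 - j)
            total += beta * np.log1p(-np.tanh(z[k]) ** 2)
            k += 1
    return float(total)


# ---------------------------------------------------------------------- model
class SimbaModel:
    """The posterior: parameter layout, log density, and cached forward passes."""

    def __init__(self, design: Design):
        self.design = design
        self.spec = design.spec
        spec, d = self.spec, design
        self.m = spec.m
        self.pooled_region_params = [
            p for p in spec.pk_parameters if p not in spec.region_dummies
        ]
        self.n_corr = self.m * (self.m - 1) // 2

        lay = ParamLayout()
        lay.add("alpha", (self.m,))
        for p in spec.pk_parameters:
            lay.add(f"beta_{p}", (d.fixed[p].X.shape[1],))
        lay.add("log_sd_subject", (self.m,))
        lay.add("log_sd_tac", (self.m,))
        lay.add("log_sd_region", (len(self.pooled_region_params),))
        lay.add("corr_subject", (self.n_corr,))
        lay.add("corr_tac", (self.n_corr,))
        lay.add("z_subject", (d.n_subjects, self.m))
        lay.add("z_tac", (d.n_tacs, self.m))
        lay.add("z_region", (d.n_regions, len(self.pooled_region_params)))
        lay.add("log_sd_slope", (len(spec.region_age_slopes),))
        lay.add("z_slope", (d.n_regions, len(spec.region_age_slopes)))
        lay.add("sigma_alpha", ())
        lay.add("sigma_coefs", (3,))  # clog duration, volume, dose
        lay.add("sigma_spline", (d.spline.shape[1],))
        lay.add("log_sd_sigma_subject", ())
        lay.add("log_sd_sigma_region", ())
        lay.add("z_sigma_subject", (d.n_subjects,))
        lay.add("z_sigma_region", (d.n_regions,))
        self.layout = lay

        pr = spec.priors
        self.sigma_mu = (
            pr.sigma_mu
            if pr.sigma_mu is not None
            else float(np.log(0.05 * np.mean(np.max(d.y, axis=1).clip(min=1e-6))))
        )
        self._i_k4 = (
            spec.pk_parameters.index("logk4") if spec.uses_frtm else None
        )
        self._i = {p: i for i, p in enumerate(spec.pk_parameters)}
        self.mu0 = np.array(
            [
                pr.intercept_mu.get(p, pr.logk4_mu if p == "logk4" else 0.0)
                for p in spec.pk_parameters
            ]
        )
        self.subject_sd_scales = np.array(
            [pr.subject_sd.get(p, 0.3) for p in spec.pk_parameters]
        )
        self.region_sd_scales = np.array(
            [pr.region_sd.get(p, 0.3) for p in self.pooled_region_params]
        )

    # ---------------------------------------------------------------- forward
    def theta(self, x: np.ndarray) -> np.ndarray:
        d, lay, spec = self.design, self.layout, self.spec
        th = np.tile(lay.get(x, "alpha"), (d.n_tacs, 1))
        for p in spec.pk_parameters:
            beta = lay.get(x, f"beta_{p}")
            if beta.size:
                th[:, self._i[p]] += d.fixed[p].X @ beta
        sd_s = np.exp(lay.get(x, "log_sd_subject"))
        L_s = chol_from_cpc(lay.get(x, "corr_subject"), self.m)
        dev_s = (lay.get(x, "z_subject") @ L_s.T) * sd_s[None, :]
        th += dev_s[d.subject_idx]
        sd_t = np.exp(lay.get(x, "log_sd_tac"))
        L_t = chol_from_cpc(lay.get(x, "corr_tac"), self.m)
        th += (lay.get(x, "z_tac") @ L_t.T) * sd_t[None, :]
        if self.pooled_region_params:
            sd_r = np.exp(lay.get(x, "log_sd_region"))
            dev_r = lay.get(x, "z_region") * sd_r[None, :]
            for j, p in enumerate(self.pooled_region_params):
                th[:, self._i[p]] += dev_r[d.region_idx, j]
        if spec.region_age_slopes:
            sd_sl = np.exp(lay.get(x, "log_sd_slope"))
            z_sl = lay.get(x, "z_slope")
            for j, p in enumerate(spec.region_age_slopes):
                th[:, self._i[p]] += sd_sl[j] * z_sl[d.region_idx, j] * d.age_decades
        return th

    def mu(self, theta: np.ndarray) -> np.ndarray:
        d = self.design
        # extreme proposals can overflow exp(); they yield non-finite rows and
        # are rejected by the sampler, so the warnings carry no information
        with np.errstate(over="ignore", invalid="ignore"):
            return self._mu_inner(np.exp(theta))

    def _mu_inner(self, pk: np.ndarray) -> np.ndarray:
        d = self.design
        i = self._i
        times = d.frames.midpoints
        if self.spec.uses_frtm:
            return frtm_predict_batch(
                pk[:, i["logR1"]], pk[:, i["logk2prime"]], pk[:, i["logBPND"]],
                pk[:, i["logk4"]], d.ref_batch, d.meas_idx, times,
            )
        return srtm_predict_batch(
            pk[:, i["logR1"]], pk[:, i["logk2prime"]], pk[:, i["logBPND"]],
            d.ref_batch, d.meas_idx, times,
        )

    def log_sigma(self, x: np.ndarray) -> np.ndarray:
        d, lay = self.design, self.layout
        base = (
            float(lay.get(x, "sigma_alpha"))
            + np.exp(float(lay.get(x, "log_sd_sigma_subject")))
            * lay.get(x, "z_sigma_subject")[d.subject_idx]
            + np.exp(float(lay.get(x, "log_sd_sigma_region")))
            * lay.get(x, "z_sigma_region")[d.region_idx]
            + lay.get(x, "sigma_coefs")[1] * d.clog_volume
            + lay.get(x, "sigma_coefs")[2] * d.clog_dose
        )
        per_frame = (
            lay.get(x, "sigma_coefs")[0] * d.clog_duration
            + d.spline @ lay.get(x, "sigma_spline")
        )
        return base[:, None] + per_frame[None, :]

    def loglik_pointwise(self, mu: np.ndarray, log_sigma: np.ndarray) -> np.ndarray:
        y = self.design.y
        z = (y - mu) * np.exp(-log_sigma)
        return -0.5 * LOG2PI - log_sigma - 0.5 * z * z

    def loglik_tac(self, mu: np.ndarray, log_sigma: np.ndarray) -> np.ndarray:
        ll = self.loglik_pointwise(mu, log_sigma)
        ll = np.where(np.isfinite(ll), ll, -np.inf)
        return ll.sum(axis=1)

    # ----------------------------------------------------------------- priors
    @staticmethod
    def _half_normal_on_log(log_sd: np.ndarray, scale: np.ndarray) -> float:
        sd = np.exp(log_sd)
        return float(np.sum(-0.5 * (sd / scale) ** 2 + log_sd))

    def log_prior(self, x: np.ndarray) -> float:
        lay, spec, pr = self.layout, self.spec, self.spec.priors
        lp = 0.0
        mu0 = np.array(
            [
                pr.intercept_mu.get(p, pr.logk4_mu if p == "logk4" else 0.0)
                for p in spec.pk_parameters
            ]
        )
        alpha = lay.get(x, "alpha")
        lp += float(np.sum(-0.5 * ((alpha - mu0) / pr.intercept_sd) ** 2))
        for p in spec.pk_parameters:
            beta = lay.get(x, f"beta_{p}")
            if beta.size:
                lp += float(np.sum(-0.5 * (beta / self.design.fixed[p].prior_sd) ** 2))
        sub_scales = np.array([pr.subject_sd.get(p, 0.3) for p in spec.pk_parameters])
        lp += self._half_normal_on_log(lay.get(x, "log_sd_subject"), sub_scales)
        lp += self._half_normal_on_log(
            lay.get(x, "log_sd_tac"), np.full(self.m, pr.tac_sd)
        )
        if self.pooled_region_params:
            reg_scales = np.array(
                [pr.region_sd.get(p, 0.3) for p in self.pooled_region_params]
            )
            lp += self._half_normal_on_log(lay.get(x, "log_sd_region"), reg_scales)
        lp += lkj_cpc_logprior(lay.get(x, "corr_subject"), self.m, pr.lkj_eta)
        lp += lkj_cpc_logprior(lay.get(x, "corr_tac"), self.m, pr.lkj_eta)
        for name in ("z_subject", "z_tac", "z_region", "z_slope",
                     "z_sigma_subject", "z_sigma_region"):
            z = lay.get(x, name)
            lp += float(-0.5 * np.sum(z * z))
        if spec.region_age_slopes:
            lp += self._half_normal_on_log(
                lay.get(x, "log_sd_slope"),
                np.full(len(spec.region_age_slopes), pr.slope_sd_scale),
            )
        lp += -0.5 * ((float(lay.get(x, "sigma_alpha")) - self.sigma_mu) / pr.sigma_mu_sd) ** 2
        lp += float(np.sum(-0.5 * (lay.get(x, "sigma_coefs") / pr.sigma_coef_sd) ** 2))
        lp += float(np.sum(-0.5 * (lay.get(x, "sigma_spline") / pr.sigma_spline_sd) ** 2))
        lp += self._half_normal_on_log(
            np.atleast_1d(lay.get(x, "log_sd_sigma_subject")), np.array([pr.sigma_dev_sd])
        )
        lp += self._half_normal_on_log(
            np.atleast_1d(lay.get(x, "log_sd_sigma_region")), np.array([pr.sigma_dev_sd])
        )
        return lp

    def log_density(self, x: np.ndarray) -> float:
        """Joint log posterior density (up to a constant) at a flat state vector."""
        th = self.theta(x)
        mu = self.mu(th)
        if not np.all(np.isfinite(mu)):
            return -np.inf
        ll = float(np.sum(self.loglik_tac(mu, self.log_sigma(x))))
        if not np.isfinite(ll):
            return -np.inf
        return ll + self.log_prior(x)

    # ------------------------------------------------------------------- init
    def initial_state(self, rng: np.random.Generator, jitter: float = 0.3) -> np.ndarray:
        """Start near the prior intercepts with data-scaled sigma and small z jitter."""
        lay, spec, pr = self.layout, self.spec, self.spec.priors
        x = np.zeros(lay.size)
        mu0 = np.array(
            [
                pr.intercept_mu.get(p, pr.logk4_mu if p == "logk4" else 0.0)
                for p in spec.pk_parameters
            ]
        )
        lay.set(x, "alpha", mu0 + 0.05 * rng.standard_normal(self.m))
        sub_scales = np.array([pr.subject_sd.get(p, 0.3) for p in spec.pk_parameters])
        lay.set(x, "log_sd_subject", np.log(0.5 * sub_scales))
        lay.set(x, "log_sd_tac", np.log(np.full(self.m, 0.5 * pr.tac_sd)))
        if self.pooled_region_params:
            reg_scales = np.array(
                [pr.region_sd.get(p, 0.3) for p in self.pooled_region_params]
            )
            lay.set(x, "log_sd_region", np.log(0.5 * reg_scales))
        for name in ("z_subject", "z_tac", "z_region", "z_sigma_subject", "z_sigma_region"):
            lay.set(x, name, jitter * rng.standard_normal(lay.shapes[name]))
        if spec.region_age_slopes:
            lay.set(
                x, "log_sd_slope",
                np.log(np.full(len(spec.region_age_slopes), 0.5 * pr.slope_sd_scale)),
            )
            lay.set(x, "z_slope", jitter * rng.standard_normal(lay.shapes["z_slope"]))
        lay.set(x, "log_sd_sigma_subject", np.log(0.5 * pr.sigma_dev_sd))
        lay.set(x, "log_sd_sigma_region", np.log(0.5 * pr.sigma_dev_sd))
        lay.set(x, "sigma_alpha", self.sigma_mu)
        return x

    def warm_start_from_estimates(self, x: np.ndarray, estimates: pd.DataFrame) -> None:
        """Overwrite intercepts and region dummies with medians of per-TAC estimates.

        ``estimates`` is a tidy NLS table (columns region, R1, k2prime, BPND).
        Mirrors the usual practice of initialising the chain in roughly the
        right neighbourhood; priors are untouched.
        """
        lay, spec, d = self.layout, self.spec, self.design
        logs = {
            "logR1": np.log(estimates["R1"].clip(lower=1e-3)),
            "logk2prime": np.log(estimates["k2prime"].clip(lower=1e-4)),
            "logBPND": np.log(estimates["BPND"].clip(lower=1e-3)),
        }
        alpha = lay.get(x, "alpha").copy()
        for p in spec.pk_parameters:
            if p not in logs:
                continue
            i = self._i[p]
            if p in spec.region_dummies:
                per_region = logs[p].groupby(estimates["region"]).median()
                base = per_region.get(d.regions[0], per_region.median())
                alpha[i] = base
                beta = lay.get(x, f"beta_{p}").copy()
                names = d.fixed[p].names
                for j, nm in enumerate(names):
                    if nm.startswith("region_"):
                        r = nm[len("region_"):]
                        if r in per_region.index:
                            beta[j] = per_region[r] - base
                lay.set(x, f"beta_{p}", beta)
            else:
                alpha[i] = float(logs[p].median())
        lay.set(x, "alpha", alpha)


# -------------------------------------------------------------------- sampler
@dataclass
class _BlockStats:
    proposals: int = 0
    accepts: float = 0.0

    @property
    def rate(self) -> float:
        return self.accepts / max(self.proposals, 1)


class _AdaptiveScale:
    """Robbins-Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, init: float, target: float):
        self.log_s = float(np.log(init))
        self.target = target

    def adapt(self, acc_rate: float, sweep: int) -> None:
        lr = 1.0 / (sweep + 10.0) ** 0.6
        self.log_s += lr * (acc_rate - self.target)
        self.log_s = float(np.clip(self.log_s, -12.0, 3.0))

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_s))


class _JointProposal:
    """Multivariate random-walk proposal with warmup covariance adaptation."""

    def __init__(self, dim: int, init_scale: float, target: float):
        self.dim = dim
        self.step = _AdaptiveScale(init_scale, target)
        self.mean = np.zeros(dim)
        self.cov = np.eye(dim)
        self.n = 0
        self.chol = np.eye(dim)

    def observe(self, value: np.ndarray) -> None:
        self.n += 1
        delta = value - self.mean
        self.mean += delta / self.n
        self.cov += (np.outer(delta, value - self.mean) - self.cov) / self.n
        if self.n >= 150 and self.n % 25 == 0:
            try:
                self.chol = np.linalg.cholesky(
                    self.cov + 1e-10 * np.eye(self.dim)
                )
            except np.linalg.LinAlgError:
                pass

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        return self.step.scale * (self.chol @ rng.standard_normal(self.dim))


class _Sampler:
    """One chain of the blocked adaptive Metropolis sampler."""

    def __init__(self, model: SimbaModel, rng: np.random.Generator):
        self.model = model
        self.rng = rng
        d, lay, spec = model.design, model.layout, model.spec
        self.x = model.initial_state(rng)
        self.stats: dict[str, _BlockStats] = {}

        # per-group z blocks: (name, group_of_tac or None, n_groups, sigma_only)
        self.group_blocks: list[tuple[str, np.ndarray, int, bool]] = [
            ("z_tac", np.arange(d.n_tacs), d.n_tacs, False),
            ("z_subject", d.subject_idx, d.n_subjects, False),
        ]
        if model.pooled_region_params:
            self.group_blocks.append(("z_region", d.region_idx, d.n_regions, False))
        if spec.region_age_slopes:
            self.group_blocks.append(("z_slope", d.region_idx, d.n_regions, False))
        self.group_blocks += [
            ("z_sigma_subject", d.subject_idx, d.n_subjects, True),
            ("z_sigma_region", d.region_idx, d.n_regions, True),
        ]
        self.group_scales = {
            name: _AdaptiveScale(0.3, spec.mcmc.target_accept_block)
            for name, _, _, _ in self.group_blocks
        }

        # joint blocks: (name, flat indices, sigma_only)
        self.joint_blocks: list[tuple[str, np.ndarray, bool]] = []
        for p in spec.pk_parameters:
            idx = np.r_[
                lay.indices("alpha")[model._i[p]], lay.indices(f"beta_{p}")
            ]
            self.joint_blocks.append((f"fixed_{p}", idx, False))
        self.joint_blocks.append(
            ("hier_subject",
             np.r_[lay.indices("log_sd_subject"), lay.indices("corr_subject")], False)
        )
        self.joint_blocks.append(
            ("hier_tac", np.r_[lay.indices("log_sd_tac"), lay.indices("corr_tac")], False)
        )
        reg_idx = np.r_[lay.indices("log_sd_region"), lay.indices("log_sd_slope")]
        if reg_idx.size:
            self.joint_blocks.append(("hier_region", reg_idx, False))
        self.joint_blocks.append(
            ("sigma_glob",
             np.r_[lay.indices("sigma_alpha"), lay.indices("sigma_coefs"),
                   lay.indices("sigma_spline"), lay.indices("log_sd_sigma_subject"),
                   lay.indices("log_sd_sigma_region")], True)
        )
        self.joint_proposals = {
            name: _JointProposal(len(idx), 0.05 / np.sqrt(len(idx)),
                                 spec.mcmc.target_accept_joint)
            for name, idx, _ in self.joint_blocks
        }
        for name, *_ in self.group_blocks:
            self.stats[name] = _BlockStats()
        for name, *_ in self.joint_blocks:
            self.stats[name] = _BlockStats()

        # recentering moves: translate a fixed effect while compensating in the
        # deviation z-scores so theta (hence the likelihood) is unchanged; the
        # Metropolis ratio involves only the priors. This decouples the
        # intercept/coefficient marginals from the strongly correlated
        # deviation blocks, which plain random-walk blocks mix through slowly.
        self.recenter_moves: list[dict] = []
        for p in spec.pk_parameters:
            i = model._i[p]
            cols: list[tuple[str, int, np.ndarray, float, float]] = [
                ("alpha", i, np.ones(d.n_tacs), model.mu0[i], spec.priors.intercept_sd)
            ]
            for c, nm in enumerate(d.fixed[p].names):
                cols.append(
                    (f"beta_{p}", c, d.fixed[p].X[:, c], 0.0, d.fixed[p].prior_sd[c])
                )
            for block, col, v_tac, c_mu, c_sd in cols:
                # a column constant within subject can be pushed through the
                # subject deviations; otherwise through the TAC deviations
                v_sub = np.full(d.n_subjects, np.nan)
                const_in_subject = True
                for s in range(d.n_subjects):
                    vals = v_tac[d.subject_idx == s]
                    if np.ptp(vals) > 0:
                        const_in_subject = False
                        break
                    v_sub[s] = vals[0]
                self.recenter_moves.append({
                    "stat": f"recenter_{p}",
                    "param_i": i,
                    "block": block,
                    "col": col,
                    "kind": "subject" if const_in_subject else "tac",
                    "v": v_sub if const_in_subject else v_tac,
                    "coef_mu": c_mu,
                    "coef_sd": c_sd,
                    "scale": _AdaptiveScale(0.05, 0.44),
                })
            # intercepts of pooled-region parameters also trade off against
            # the region deviations: add the region-direction translation too
            if p in model.pooled_region_params:
                self.recenter_moves.append({
                    "stat": f"recenter_{p}",
                    "param_i": model.pooled_region_params.index(p),
                    "block": "alpha", "col": i, "kind": "region",
                    "v": np.ones(d.n_regions),
                    "coef_mu": model.mu0[i], "coef_sd": spec.priors.intercept_sd,
                    "scale": _AdaptiveScale(0.05, 0.44),
                })
        # the sigma intercept trades off against the sigma deviation blocks
        for kind in ("sigma_subject", "sigma_region"):
            self.recenter_moves.append({
                "stat": "recenter_sigma",
                "param_i": None, "block": "sigma_alpha", "col": None, "kind": kind,
                "v": np.ones(d.n_subjects if kind == "sigma_subject" else d.n_regions),
                "coef_mu": model.sigma_mu, "coef_sd": spec.priors.sigma_mu_sd,
                "scale": _AdaptiveScale(0.05, 0.44),
            })
        for p in spec.pk_parameters:
            self.stats[f"recenter_{p}"] = _BlockStats()
        self.stats["recenter_sigma"] = _BlockStats()

        # rescaling moves: the complement of the non-centred updates. Propose
        # log_sd += delta while transforming the z-scores so the *deviations*
        # (hence theta and the likelihood) are unchanged; the Metropolis ratio
        # is the prior change plus the log-Jacobian -G*delta of the z
        # transformation (G = number of groups). Alternating centred-style and
        # non-centred-style updates lets the hierarchy scales mix even when
        # they are tightly coupled to hundreds of deviations.
        self.rescale_moves: list[dict] = []
        for i in range(model.m):
            self.rescale_moves.append({
                "stat": "rescale_sd", "sd_block": "log_sd_subject", "i": i,
                "z_block": "z_subject", "corr": "corr_subject",
                "half_scale": model.subject_sd_scales[i],
                "scale": _AdaptiveScale(0.1, 0.44),
            })
            self.rescale_moves.append({
                "stat": "rescale_sd", "sd_block": "log_sd_tac", "i": i,
                "z_block": "z_tac", "corr": "corr_tac",
                "half_scale": spec.priors.tac_sd,
                "scale": _AdaptiveScale(0.1, 0.44),
            })
        for j in range(len(model.pooled_region_params)):
            self.rescale_moves.append({
                "stat": "rescale_sd", "sd_block": "log_sd_region", "i": j,
                "z_block": "z_region", "corr": None,
                "half_scale": model.region_sd_scales[j],
                "scale": _AdaptiveScale(0.1, 0.44),
            })
        for j in range(len(spec.region_age_slopes)):
            self.rescale_moves.append({
                "stat": "rescale_sd", "sd_block": "log_sd_slope", "i": j,
                "z_block": "z_slope", "corr": None,
                "half_scale": spec.priors.slope_sd_scale,
                "scale": _AdaptiveScale(0.1, 0.44),
            })
        for sd_block, z_block in (
            ("log_sd_sigma_subject", "z_sigma_subject"),
            ("log_sd_sigma_region", "z_sigma_region"),
        ):
            self.rescale_moves.append({
                "stat": "rescale_sd", "sd_block": sd_block, "i": None,
                "z_block": z_block, "corr": None,
                "half_scale": spec.priors.sigma_dev_sd,
                "scale": _AdaptiveScale(0.1, 0.44),
            })
        self.stats["rescale_sd"] = _BlockStats()

        self.refresh_caches()

    def refresh_caches(self) -> None:
        m = self.model
        self.theta = m.theta(self.x)
        self.mu = m.mu(self.theta)
        self.logsig = m.log_sigma(self.x)
        self.ll_tac = m.loglik_tac(self.mu, self.logsig)
        self.lp = m.log_prior(self.x)

    # ------------------------------------------------------------- block moves
    def _update_group(self, name: str, group_of_tac: np.ndarray, n_groups: int,
                      sigma_only: bool, sweep: int, warm: bool) -> None:
        m, lay, rng = self.model, self.model.layout, self.rng
        scale = self.group_scales[name].scale
        z = lay.get(self.x, name).reshape(n_groups, -1)
        prop = z + scale * rng.standard_normal(z.shape)
        x_new = self.x.copy()
        lay.set(x_new, name, prop)
        if sigma_only:
            logsig_new = m.log_sigma(x_new)
            ll_new = m.loglik_tac(self.mu, logsig_new)
            theta_new, mu_new = self.theta, self.mu
        else:
            theta_new = m.theta(x_new)
            mu_new = m.mu(theta_new)
            ll_new = m.loglik_tac(mu_new, self.logsig)
            logsig_new = self.logsig
        d_ll = np.bincount(group_of_tac, weights=ll_new - self.ll_tac,
                           minlength=n_groups)
        d_lp = -0.5 * (np.sum(prop * prop, axis=1) - np.sum(z * z, axis=1))
        accept = np.log(rng.uniform(size=n_groups)) < d_ll + d_lp
        st = self.stats[name]
        st.proposals += 1
        st.accepts += float(np.mean(accept))
        if np.any(accept):
            rows = accept[group_of_tac]
            z[accept] = prop[accept]
            lay.set(self.x, name, z)
            if sigma_only:
                self.logsig[rows] = logsig_new[rows]
            else:
                self.theta[rows] = theta_new[rows]
                self.mu[rows] = mu_new[rows]
            self.ll_tac[rows] = ll_new[rows]
            self.lp = m.log_prior(self.x)
        if warm:
            self.group_scales[name].adapt(float(np.mean(accept)), sweep)

    def _update_joint(self, name: str, idx: np.ndarray, sigma_only: bool,
                      sweep: int, warm: bool) -> None:
        m, rng = self.model, self.rng
        jp = self.joint_proposals[name]
        x_new = self.x.copy()
        x_new[idx] += jp.draw(rng)
        if sigma_only:
            theta_new, mu_new = self.theta, self.mu
            logsig_new = m.log_sigma(x_new)
        else:
            theta_new = m.theta(x_new)
            mu_new = m.mu(theta_new)
            logsig_new = self.logsig
        ll_new = m.loglik_tac(mu_new, logsig_new)
        lp_new = m.log_prior(x_new)
        d = float(np.sum(ll_new) - np.sum(self.ll_tac)) + lp_new - self.lp
        accept = np.isfinite(d) and (np.log(rng.uniform()) < d)
        st = self.stats[name]
        st.proposals += 1
        st.accepts += float(accept)
        if accept:
            self.x = x_new
            self.theta, self.mu, self.logsig = theta_new, mu_new, logsig_new
            self.ll_tac, self.lp = ll_new, lp_new
        if warm:
            jp.step.adapt(float(accept), sweep)
            jp.observe(self.x[idx].copy())

    def _update_recenter(self, mv: dict, sweep: int, warm: bool) -> None:
        from scipy.linalg import solve_triangular

        m, lay, rng = self.model, self.model.layout, self.rng
        i = mv["param_i"]
        delta = mv["scale"].scale * rng.standard_normal()
        kind = mv["kind"]
        if kind in ("subject", "tac"):
            corr, sds, zname = (
                ("corr_subject", "log_sd_subject", "z_subject")
                if kind == "subject"
                else ("corr_tac", "log_sd_tac", "z_tac")
            )
            L = chol_from_cpc(lay.get(self.x, corr), m.m)
            sd_i = float(np.exp(lay.get(self.x, sds)[i]))
            e_i = np.zeros(m.m)
            e_i[i] = 1.0
            col = solve_triangular(L, e_i, lower=True)
            z = lay.get(self.x, zname)
            z_new = z - np.outer(mv["v"] * (delta / sd_i), col)
        elif kind == "region":
            sd_i = float(np.exp(lay.get(self.x, "log_sd_region")[i]))
            zname = "z_region"
            z = lay.get(self.x, zname)
            z_new = z.copy()
            z_new[:, i] = z[:, i] - delta / sd_i
        else:  # sigma_subject / sigma_region
            sds = "log_sd_" + kind
            zname = "z_" + kind
            sd_i = float(np.exp(np.atleast_1d(lay.get(self.x, sds))[0]))
            z = lay.get(self.x, zname)
            z_new = z - delta / sd_i
        c_old = np.atleast_1d(lay.get(self.x, mv["block"]))
        j = mv["col"] if mv["col"] is not None else 0
        d_coef = (
            -0.5 * ((c_old[j] + delta - mv["coef_mu"]) ** 2 - (c_old[j] - mv["coef_mu"]) ** 2)
            / mv["coef_sd"] ** 2
        )
        d_lp = -0.5 * float(np.sum(z_new * z_new) - np.sum(z * z)) + d_coef
        accept = np.isfinite(d_lp) and (np.log(rng.uniform()) < d_lp)
        st = self.stats[mv["stat"]]
        st.proposals += 1
        st.accepts += float(accept)
        if accept:  # theta, mu, sigma and the likelihood are untouched
            lay.set(self.x, zname, z_new)
            c_new = c_old.copy()
            c_new[j] += delta
            lay.set(self.x, mv["block"], c_new)
            self.lp += d_lp
        if warm:
            mv["scale"].adapt(float(accept), sweep)

    def _update_rescale(self, mv: dict, sweep: int, warm: bool) -> None:
        from scipy.linalg import solve_triangular

        m, lay, rng = self.model, self.model.layout, self.rng
        delta = mv["scale"].scale * rng.standard_normal()
        sds_old = np.atleast_1d(lay.get(self.x, mv["sd_block"]))
        i = mv["i"]
        j = 0 if i is None else i
        half_scale = mv["half_scale"]
        ls_old = sds_old[j]
        sd_old, sd_new = np.exp(ls_old), np.exp(ls_old + delta)
        z = lay.get(self.x, mv["z_block"])
        if mv["corr"] is None:
            # univariate deviations: dev = sd * z, so z' = z * exp(-delta)
            if z.ndim == 1:
                z_new = z * np.exp(-delta)
                n_groups = z.shape[0]
            else:
                z_new = z.copy()
                z_new[:, i] = z[:, i] * np.exp(-delta)
                n_groups = z.shape[0]
        else:
            L = chol_from_cpc(lay.get(self.x, mv["corr"]), m.m)
            w_i = z @ L[i, :]  # (G,), component i of L z per group
            e_i = np.zeros(m.m)
            e_i[i] = 1.0
            col = solve_triangular(L, e_i, lower=True)
            z_new = z + np.outer((np.exp(-delta) - 1.0) * w_i, col)
            n_groups = z.shape[0]
        # half-normal prior (with log-scale Jacobian) + z prior + transform Jacobian
        d_lp = (
            -0.5 * float(np.sum(z_new * z_new) - np.sum(z * z))
            - 0.5 * (sd_new**2 - sd_old**2) / half_scale**2
            + delta
        )
        log_jac = -n_groups * delta
        accept = np.isfinite(d_lp) and (np.log(rng.uniform()) < d_lp + log_jac)
        st = self.stats[mv["stat"]]
        st.proposals += 1
        st.accepts += float(accept)
        if accept:  # deviations, theta and the likelihood are unchanged
            sds_new = sds_old.copy()
            sds_new[j] += delta
            lay.set(self.x, mv["sd_block"], sds_new)
            lay.set(self.x, mv["z_block"], z_new)
            self.lp += d_lp
        if warm:
            mv["scale"].adapt(float(accept), sweep)

    def sweep(self, sweep: int, warm: bool) -> None:
        for name, group, n_groups, sigma_only in self.group_blocks:
            self._update_group(name, group, n_groups, sigma_only, sweep, warm)
        for name, idx, sigma_only in self.joint_blocks:
            self._update_joint(name, idx, sigma_only, sweep, warm)
        for _ in range(self.model.spec.mcmc.mix_reps):
            for mv in self.recenter_moves:
                self._update_recenter(mv, sweep, warm)
            for mv in self.rescale_moves:
                self._update_rescale(mv, sweep, warm)
        if (sweep + 1) % 200 == 0:  # guard against float drift in the caches
            self.refresh_caches()


# ------------------------------------------------------------------ posterior
@dataclass
class EffectiveParameters:
    """PSIS-LOO effective number of parameters for a fitted model."""

    total: float
    per_tac: float
    n_tacs: int
    unstable: bool  # any Pareto-k diagnostic above 0.7


class SimbaPosterior:
    """MCMC output: draws, per-TAC estimates, diagnostics, pointwise log-likelihood."""

    def __init__(self, model: SimbaModel, draws_x: np.ndarray,
                 log_likelihood: np.ndarray, tac_estimates: pd.DataFrame,
                 acceptance: dict[str, float]):
        self.model = model
        self.draws_x = draws_x  # (chains, draws, dim)
        self.log_likelihood = log_likelihood  # (chains, draws_thinned, T, F)
        self.tac_estimates = tac_estimates
        self.acceptance = acceptance
        self._diagnostics: dict | None = None

    # ------------------------------------------------------------ name access
    def _beta_name_index(self, name: str) -> tuple[str, int]:
        spec, d = self.model.spec, self.model.design
        for p in spec.pk_parameters:
            prefix = f"{p}:"
            if name.startswith(prefix):
                rest = name[len(prefix):]
                if rest == "intercept":
                    return "alpha", self.model._i[p]
                fe = d.fixed[p]
                if rest in fe.names:
                    return f"beta_{p}", fe.names.index(rest)
        raise KeyError(f"unknown coefficient '{name}'")

    def coef_draws(self, name: str) -> np.ndarray:
        """Draws of a named coefficient, e.g. ``"logBPND:group_patient:post"``."""
        block, j = self._beta_name_index(name)
        lay = self.model.layout
        s = lay.slices[block]
        flat = self.draws_x[:, :, s].reshape(self.draws_x.shape[0],
                                             self.draws_x.shape[1], -1)
        return flat[:, :, j]

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Key scalar draws (chains, draws): intercepts, fixed effects, SDs, sigma."""
        lay, spec, d = self.model.layout, self.model.spec, self.model.design
        out: dict[str, np.ndarray] = {}
        for p in spec.pk_parameters:
            out[f"{p}:intercept"] = self.coef_draws(f"{p}:intercept")
            for nm in d.fixed[p].names:
                out[f"{p}:{nm}"] = self.coef_draws(f"{p}:{nm}")
        for i, p in enumerate(spec.pk_parameters):
            s = lay.slices["log_sd_subject"]
            out[f"sd_subject:{p}"] = np.exp(self.draws_x[:, :, s.start + i])
            s = lay.slices["log_sd_tac"]
            out[f"sd_tac:{p}"] = np.exp(self.draws_x[:, :, s.start + i])
        for j, p in enumerate(self.model.pooled_region_params):
            s = lay.slices["log_sd_region"]
            out[f"sd_region:{p}"] = np.exp(self.draws_x[:, :, s.start + j])
        s = lay.slices["sigma_alpha"]
        out["sigma:intercept"] = self.draws_x[:, :, s.start]
        s = lay.slices["sigma_coefs"]
        for j, nm in enumerate(("clog_duration", "clog_volume", "clog_dose")):
            out[f"sigma:{nm}"] = self.draws_x[:, :, s.start + j]
        return out

    def correlation_draws(self, block: str = "subject") -> np.ndarray:
        """Correlation-matrix draws (chains, draws, m, m) for a deviation block."""
        lay, m = self.model.layout, self.model.m
        z = self.draws_x[:, :, lay.slices[f"corr_{block}"]]
        C, N, _ = z.shape
        out = np.empty((C, N, m, m))
        for c in range(C):
            for n in range(N):
                L = chol_from_cpc(z[c, n], m)
                out[c, n] = L @ L.T
        return out

    # ------------------------------------------------------------ diagnostics
    def diagnostics(self) -> dict:
        """Split-Rhat and bulk ESS for the key scalars, plus acceptance rates."""
        if self._diagnostics is not None:
            return self._diagnostics
        import arviz as az

        scal = self.scalar_draws()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idata = az.from_dict(posterior={k: v for k, v in scal.items()})
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        rhats = {k: float(rhat[k].values) for k in scal}
        esss = {k: float(ess[k].values) for k in scal}
        warn = [k for k, v in rhats.items() if np.isfinite(v) and v > 1.05]
        low_acc = [k for k, v in self.acceptance.items() if v < 0.05]
        self._diagnostics = {
            "rhat": rhats,
            "ess_bulk": esss,
            "acceptance": self.acceptance,
            "warnings": (
                [f"Rhat > 1.05 for: {', '.join(warn)}"] if warn else []
            ) + ([f"low acceptance for blocks: {', '.join(low_acc)}"] if low_acc else []),
        }
        return self._diagnostics

    def summary(self) -> pd.DataFrame:
        """Posterior mean/SD/intervals and diagnostics for the key scalars."""
        scal = self.scalar_draws()
        diag = self.diagnostics()
        rows = []
        for k, v in scal.items():
            flat = v.reshape(-1)
            rows.append({
                "parameter": k,
                "mean": float(np.mean(flat)),
                "sd": float(np.std(flat)),
                "q2.5": float(np.quantile(flat, 0.025)),
                "q97.5": float(np.quantile(flat, 0.975)),
                "rhat": diag["rhat"].get(k, np.nan),
                "ess_bulk": diag["ess_bulk"].get(k, np.nan),
            })
        return pd.DataFrame(rows)

    def to_draws_table(self) -> pd.DataFrame:
        """Tidy (chain, iteration, parameter, value) table of the key scalars."""
        recs = []
        for k, v in self.scalar_draws().items():
            C, N = v.shape
            for c in range(C):
                recs.append(pd.DataFrame({
                    "chain": c, "iteration": np.arange(N), "parameter": k,
                    "value": v[c],
                }))
        return pd.concat(recs, ignore_index=True)


def fit_simba(
    dataset: TACTable,
    ref_fits: dict[tuple[str, str], RefFit],
    spec: SimbaSpec,
    warm_start_estimates: pd.DataFrame | None = None,
) -> SimbaPosterior:
    """Fit the hierarchical model by MCMC and return the posterior.

    ``warm_start_estimates`` (a tidy per-TAC estimate table, e.g. from
    :func:`simbaref.nls.fit_dataset_nls`) initialises intercepts and region
    effects near the data; it does not alter priors. Deterministic given
    ``spec.mcmc.seed``.
    """
    design = build_design(dataset, ref_fits, spec)
    model = SimbaModel(design)
    return sample_posterior(model, warm_start_estimates)


def sample_posterior(
    model: SimbaModel, warm_start_estimates: pd.DataFrame | None = None
) -> SimbaPosterior:
    """Run the blocked adaptive Metropolis sampler on a built model."""
    spec = model.spec
    opts = spec.mcmc
    d = model.design
    thin = max(opts.loglik_thin, 1)
    n_keep_ll = (opts.samples + thin - 1) // thin
    draws = np.empty((opts.chains, opts.samples, model.layout.size))
    ll_store = np.empty((opts.chains, n_keep_ll, d.n_tacs, d.n_frames),
                        dtype=np.float32)
    pk_sum = np.zeros((d.n_tacs, model.m))
    pk_sumsq = np.zeros((d.n_tacs, model.m))
    acceptance: dict[str, list[float]] = {}
    for chain in range(opts.chains):
        rng = np.random.default_rng([opts.seed, chain])
        sampler = _Sampler(model, rng)
        if warm_start_estimates is not None:
            model.warm_start_from_estimates(sampler.x, warm_start_estimates)
            sampler.refresh_caches()
        for sweep in range(opts.warmup):
            sampler.sweep(sweep, warm=True)
        for stats in sampler.stats.values():  # report post-warmup rates only
            stats.proposals = 0
            stats.accepts = 0.0
        k = 0
        for sweep in range(opts.samples):
            sampler.sweep(opts.warmup + sweep, warm=False)
            draws[chain, sweep] = sampler.x
            pk = np.exp(sampler.theta)
            pk_sum += pk
            pk_sumsq += pk * pk
            if sweep % thin == 0:
                ll_store[chain, k] = model.loglik_pointwise(
                    sampler.mu, sampler.logsig
                ).astype(np.float32)
                k += 1
            if opts.progress and (sweep + 1) % 100 == 0:
                print(f"chain {chain}: {sweep + 1}/{opts.samples}")
        for name, st in sampler.stats.items():
            acceptance.setdefault(name, []).append(st.rate)

    n_draws_total = opts.chains * opts.samples
    mean_pk = pk_sum / n_draws_total
    sd_pk = np.sqrt(np.maximum(pk_sumsq / n_draws_total - mean_pk**2, 0.0))
    est = d.tac_keys.copy()
    for p, mcol in zip(spec.pk_parameters, range(model.m)):
        short = p[3:]  # strip "log": posterior summaries on the natural scale
        est[short] = mean_pk[:, mcol]
        est[f"sd_{short}"] = sd_pk[:, mcol]
    return SimbaPosterior(
        model=model,
        draws_x=draws,
        log_likelihood=ll_store,
        tac_estimates=est,
        acceptance={k: float(np.mean(v)) for k, v in acceptance.items()},
    )


# ------------------------------------------------------- derived quantities
def p_loo_pointwise(log_likelihood: np.ndarray) -> tuple[float, np.ndarray]:
    """PSIS-LOO effective number of parameters from pointwise log-likelihoods.

    ``log_likelihood`` has shape (chains, draws, observations). Returns the
    p_loo total and the per-observation Pareto-k diagnostics.
    """
    import arviz as az

    ll = np.asarray(log_likelihood, float)
    dummy = ll[:, :, 0]  # arviz requires a posterior group; content is unused
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior={"_lp": dummy}, log_likelihood={"y": ll})
        loo = az.loo(idata, pointwise=True)
    return float(loo.p_loo), np.asarray(loo.pareto_k)


def effective_parameters(post: SimbaPosterior) -> EffectiveParameters:
    """PSIS-LOO effective number of parameters (p_loo), total and per TAC.

    Pointwise predictive contributions are per frame of per TAC; the
    per-TAC figure is the total divided by the number of TACs.
    """
    C, N, T, F = post.log_likelihood.shape
    total, k = p_loo_pointwise(post.log_likelihood.reshape(C, N, T * F))
    return EffectiveParameters(
        total=total,
        per_tac=total / T,
        n_tacs=T,
        unstable=bool(np.any(k > 0.7)),
    )


def extract_contrast(
    post: SimbaPosterior,
    contrast: str | dict[str, float],
) -> dict:
    """Posterior summary of a named linear combination of fixed effects.

    ``contrast`` is either one coefficient name or a mapping name -> weight
    (e.g. ``{"logBPND:group_patient:post": 1.0}`` for a difference-in-
    differences treatment contrast). Returns mean, sd, 80% and 95% credible
    intervals and the decision statistic mean/sd (z).
    """
    if isinstance(contrast, str):
        contrast = {contrast: 1.0}
    total = None
    for name, w in contrast.items():
        v = w * post.coef_draws(name)
        total = v if total is None else total + v
    flat = total.reshape(-1)
    mean, sd = float(np.mean(flat)), float(np.std(flat))
    return {
        "mean": mean,
        "sd": sd,
        "ci80": (float(np.quantile(flat, 0.10)), float(np.quantile(flat, 0.90))),
        "ci95": (float(np.quantile(flat, 0.025)), float(np.quantile(flat, 0.975))),
        "z": mean / sd if sd > 0 else np.inf if mean != 0 else 0.0,
        "draws": total,
    }
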