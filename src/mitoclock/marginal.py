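"""Marginal likelihood by path sampling (PS) and stepping-stone (SS).

Both methods run a ladder of power posteriors p_beta ∝ prior * L^beta.
PS integrates E_beta[log L] over beta by the trapezoidal rule; SS sums
log-mean importance ratios between adjacent rungs.  A Bayes factor
between two models is the difference of their log marginal likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from mitoclock.diagnostics import effective_sample_size
from mitoclock.errors import ValidationError


def beta_schedule(n: int = 32, shape: float = 0.3) -> np.ndarray:
    """Rung values at quantiles of Beta(shape, 1): beta_k = (k/K)^(1/shape).

    The default concentrates rungs near 0 where the integrand changes
    fastest, the usual stepping-stone choice.
    """
    if n < 2:
        raise ValidationError("need at least 2 rungs")
    return (np.arange(n + 1) / n) ** (1.0 / shape)


@dataclass
class MarginalLikelihoodResult:
    log_ml_ps: float
    log_ml_ss: float
    betas: np.ndarray
    mc_error_ps: float
    mc_error_ss: float
    warnings: list

    def bayes_factor(self, other: "MarginalLikelihoodResult", method="ps") -> float:
        """log BF of this model over ``other``."""
        if method == "ps":
            return self.log_ml_ps - other.log_ml_ps
        return self.log_ml_ss - other.log_ml_ss


def marginal_likelihood(sample_loglik_at_beta, betas=None, seed=None,
                        ess_threshold: float = 50.0) -> MarginalLikelihoodResult:
    """Estimate log marginal likelihood from power-posterior log-likelihoods.

    ``sample_loglik_at_beta(beta, rng)`` must return a 1-D array of log L
    values sampled from the power posterior at ``beta`` (for beta = 0,
    from the prior).  Rungs with log-likelihood ESS below
    ``ess_threshold`` attach a warning to the result.
    """
    betas = beta_schedule() if betas is None else np.asarray(betas, float)
    if betas[0] != 0 or betas[-1] != 1 or np.any(np.diff(betas) <= 0):
        raise ValidationError("beta schedule must increase from 0 to 1")
    rng = np.random.default_rng(seed)
    warnings_ = []
    means = np.empty(len(betas))
    variances = np.empty(len(betas))
    ss_terms = []
    ss_vars = []
    for k, beta in enumerate(betas):
        ll = np.asarray(sample_loglik_at_beta(float(beta), rng), float)
        if ll.size < 10:
            raise ValidationError("need at least 10 samples per rung")
        ess = effective_sample_size(ll) if np.var(ll) > 0 else float(ll.size)
        if ess < ess_threshold:
            warnings_.append(f"rung beta={beta:.4g}: log-likelihood ESS {ess:.0f}")
        means[k] = ll.mean()
        variances[k] = np.var(ll) / max(ess, 1.0)
        if k + 1 < len(betas):
            db = betas[k + 1] - betas[k]
            w = db * ll
            ss_terms.append(logsumexp(w) - np.log(ll.size))
            # delta-method variance of the log-mean
            ratios = np.exp(w - logsumexp(w) + np.log(ll.size))
            ss_vars.append(np.var(ratios) / (max(ess, 1.0)))
    dbeta = np.diff(betas)
    log_ml_ps = float(np.sum(0.5 * (means[1:] + means[:-1]) * dbeta))
    err_ps = float(np.sqrt(np.sum(
        (0.5 * dbeta) ** 2 * (variances[1:] + variances[:-1]))))
    log_ml_ss = float(np.sum(ss_terms))
    err_ss = float(np.sqrt(np.sum(ss_vars)))
    return MarginalLikelihoodResult(log_ml_ps, log_ml_ss, betas,
                                    err_ps, err_ss, warnings_)


def phylo_power_posterior_sampler(alignment, annotation, samples, calibration,
                                  settings, **mcmc_kwargs):
    """Adapter: returns a ``sample_loglik_at_beta`` closure driving
    :func:`mitoclock.mcmc.mcmc_run` at each rung."""
    from dataclasses import replace as _replace

    from mitoclock.mcmc import mcmc_run

    def sample(beta, rng):
        s = _replace(settings, beta=float(beta), seed=int(rng.integers(2**31)),
                     sample_from_prior=False, store_trees=False, n_chains=1)
        res = mcmc_run(alignment, annotation, samples, calibration, s,
                       **mcmc_kwargs)
        return res.loglik_trace[0]

    return sample
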