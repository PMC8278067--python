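"""Self-contained MCMC machinery for the hierarchical models.

Gradient-free blocked Metropolis-within-Gibbs with Robbins-Monro scale
adaptation during warm-up:

* subject-level parameter blocks are proposed as random walks on the
  unconstrained scale and accepted independently per subject (subjects are
  conditionally independent given the population parameters, so the whole
  subject sweep is vectorized);
* population locations get exact conjugate Gibbs draws (normal-normal);
* population scales get an adaptive random-walk step on the log scale with a
  half-normal prior, interleaved with a non-centred rescaling move (sigma and
  all subject deviations updated jointly, offsets held fixed) that breaks the
  usual location-scale funnel.

Subject parameters relate to the population as
``theta_subject = mu + sigma * offset`` on the unconstrained scale, i.e. the
stored per-subject values are the centred version of a non-centred
standard-normal offset parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["PosteriorDraws", "sample_hierarchical", "RHAT_THRESHOLD"]

RHAT_THRESHOLD = 1.05
_ADAPT_TARGET = 0.3


@dataclass
class PosteriorDraws:
    """MCMC output: named draw arrays shaped (chain, draw, ...) + diagnostics."""

    draws: dict[str, np.ndarray]
    param_names: list[str]
    subject_ids: list[str] = field(default_factory=list)
    diagnostics: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for ``name`` with chain and draw axes flattened."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def compute_diagnostics(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        import arviz as az

        names = list(names) if names is not None else ["mu", "sigma"]
        rows = []
        for name in names:
            arr = self.draws[name]
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            for j in range(flat.shape[2]):
                label = (
                    f"{name}[{self.param_names[j]}]"
                    if flat.shape[2] == len(self.param_names)
                    else f"{name}[{j}]"
                )
                x = flat[:, :, j]
                rows.append(
                    {
                        "parameter": label,
                        "mean": float(x.mean()),
                        "sd": float(x.std(ddof=1)),
                        "q2.5": float(np.quantile(x, 0.025)),
                        "q97.5": float(np.quantile(x, 0.975)),
                        "rhat": float(az.rhat(az.convert_to_dataset(x))["x"].values),
                        "ess_bulk": float(az.ess(az.convert_to_dataset(x))["x"].values),
                    }
                )
        self.diagnostics = pd.DataFrame(rows)
        return self.diagnostics

    @property
    def converged(self) -> bool:
        if self.diagnostics is None:
            self.compute_diagnostics()
        return bool((self.diagnostics["rhat"] <= RHAT_THRESHOLD).all())

    def summary_dict(self) -> dict:
        if self.diagnostics is None:
            self.compute_diagnostics()
        return {
            "converged": self.converged,
            "n_chains": self.n_chains,
            "n_draws": self.n_draws,
            "parameters": self.diagnostics.to_dict(orient="records"),
            **{k: v for k, v in self.meta.items() if isinstance(v, (int, float, str, bool))},
        }


def sample_hierarchical(
    loglik_fn: Callable[[np.ndarray], np.ndarray],
    n_subjects: int,
    param_names: Sequence[str],
    seed: int,
    n_chains: int = 4,
    n_iter: int = 2000,
    n_warmup: int | None = None,
    thin: int = 1,
    sub_blocks: Sequence[Sequence[int]] | None = None,
    mu_prior_mean: float | np.ndarray = 0.0,
    mu_prior_sd: float | np.ndarray = 1.0,
    sigma_prior_sd: float | np.ndarray = 1.0,
    init_theta: np.ndarray | None = None,
    subject_ids: Sequence[str] | None = None,
) -> PosteriorDraws:
    """Sample the hierarchical posterior.

    Parameters
    ----------
    loglik_fn
        Vectorized data log-likelihood: maps unconstrained subject parameters
        (n_subjects, n_params) to one log-likelihood per subject.
    sub_blocks
        Index groups of subject parameters updated jointly (default: one
        block with all parameters).
    mu_prior_sd, sigma_prior_sd
        Std of the N(0, mu_prior_sd) prior on population locations and of the
        half-normal prior on population scales.
    init_theta
        Optional (n_subjects, n_params) starting values (jittered per chain).
    """
    param_names = list(param_names)
    P = len(param_names)
    S = n_subjects
    if n_warmup is None:
        n_warmup = n_iter // 2
    if not 0 < n_warmup < n_iter:
        raise ValueError("need 0 < n_warmup < n_iter")
    if sub_blocks is None:
        sub_blocks = [list(range(P))]
    sub_blocks = [np.asarray(b, dtype=int) for b in sub_blocks]
    mu_prior_mean = np.broadcast_to(np.asarray(mu_prior_mean, dtype=float), (P,))
    mu_prior_sd = np.broadcast_to(np.asarray(mu_prior_sd, dtype=float), (P,))
    sigma_prior_sd = np.broadcast_to(np.asarray(sigma_prior_sd, dtype=float), (P,))
    n_keep = (n_iter - n_warmup) // thin

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)

    mu_out = np.empty((n_chains, n_keep, P))
    sigma_out = np.empty((n_chains, n_keep, P))
    theta_out = np.empty((n_chains, n_keep, S, P))

    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        if init_theta is not None:
            theta = init_theta + 0.1 * rng.standard_normal((S, P))
        else:
            theta = 0.1 * rng.standard_normal((S, P))
        mu = theta.mean(axis=0)
        sigma = np.full(P, 0.5)
        curr_ll = loglik_fn(theta)
        if not np.all(np.isfinite(curr_ll)):
            raise RuntimeError("non-finite log-likelihood at initialization")

        # adaptive proposal scales (log-parameterized)
        log_s_theta = np.full((S, len(sub_blocks)), np.log(0.2))
        log_s_sigma = np.full(P, np.log(0.3))
        log_s_nc = np.full(len(sub_blocks), np.log(0.1))

        kept = 0
        for it in range(n_iter):
            adapt = it < n_warmup
            gamma = 1.0 / (1.0 + it) ** 0.6 if adapt else 0.0

            # --- subject blocks (vectorized over subjects) ---
            for bi, block in enumerate(sub_blocks):
                prop = theta.copy()
                step = np.exp(log_s_theta[:, bi])[:, None]
                prop[:, block] = theta[:, block] + step * rng.standard_normal(
                    (S, len(block))
                )
                prop_ll = loglik_fn(prop)
                d_prior = -0.5 * (
                    ((prop[:, block] - mu[block]) / sigma[block]) ** 2
                    - ((theta[:, block] - mu[block]) / sigma[block]) ** 2
                ).sum(axis=1)
                log_alpha = np.where(
                    np.isfinite(prop_ll), prop_ll - curr_ll + d_prior, -np.inf
                )
                accept = np.log(rng.random(S)) < log_alpha
                theta[accept] = prop[accept]
                curr_ll = np.where(accept, prop_ll, curr_ll)
                if adapt:
                    acc_prob = np.exp(np.minimum(log_alpha, 0.0))
                    acc_prob = np.where(np.isfinite(acc_prob), acc_prob, 0.0)
                    log_s_theta[:, bi] += gamma * (acc_prob - _ADAPT_TARGET)

            # --- population locations: conjugate normal draw ---
            prec = S / sigma**2 + 1.0 / mu_prior_sd**2
            mean = (theta.sum(axis=0) / sigma**2 + mu_prior_mean / mu_prior_sd**2) / prec
            mu = mean + rng.standard_normal(P) / np.sqrt(prec)

            # --- population scales: MH on log sigma, half-normal prior ---
            log_sig = np.log(sigma)
            prop_log_sig = log_sig + np.exp(log_s_sigma) * rng.standard_normal(P)
            prop_sig = np.exp(prop_log_sig)
            dev2 = ((theta - mu) ** 2).sum(axis=0)

            def _lp(sig, lsig):
                return (
                    -S * lsig
                    - 0.5 * dev2 / sig**2
                    - 0.5 * sig**2 / sigma_prior_sd**2
                    + lsig  # Jacobian of the log transform
                )

            log_alpha_s = _lp(prop_sig, prop_log_sig) - _lp(sigma, log_sig)
            accept_s = np.log(rng.random(P)) < log_alpha_s
            sigma = np.where(accept_s, prop_sig, sigma)
            if adapt:
                acc_prob_s = np.exp(np.minimum(log_alpha_s, 0.0))
                log_s_sigma += gamma * (acc_prob_s - _ADAPT_TARGET)

            # --- non-centred rescaling: (sigma, theta) jointly, offsets fixed ---
            for bi, block in enumerate(sub_blocks):
                d_lsig = np.exp(log_s_nc[bi]) * rng.standard_normal(len(block))
                new_sig = sigma[block] * np.exp(d_lsig)
                prop = theta.copy()
                prop[:, block] = mu[block] + (theta[:, block] - mu[block]) * (
                    new_sig / sigma[block]
                )
                prop_ll = loglik_fn(prop)
                # half-normal prior on sigma + log-scale Jacobian; the
                # standard-normal offset prior is invariant under this move
                d_logp = (
                    -0.5
                    * (new_sig**2 - sigma[block] ** 2)
                    / sigma_prior_sd[block] ** 2
                    + d_lsig
                ).sum()
                log_alpha_nc = np.where(
                    np.all(np.isfinite(prop_ll)),
                    (prop_ll - curr_ll).sum() + d_logp,
                    -np.inf,
                )
                if np.log(rng.random()) < log_alpha_nc:
                    theta = prop
                    curr_ll = prop_ll
                    sigma = sigma.copy()
                    sigma[block] = new_sig
                if adapt:
                    acc = float(np.exp(min(float(log_alpha_nc), 0.0)))
                    log_s_nc[bi] += gamma * (acc - _ADAPT_TARGET)

            if it >= n_warmup and (it - n_warmup) % thin == 0 and kept < n_keep:
                mu_out[c, kept] = mu
                sigma_out[c, kept] = sigma
                theta_out[c, kept] = theta
                kept += 1

    post = PosteriorDraws(
        draws={"mu": mu_out, "sigma": sigma_out, "theta": theta_out},
        param_names=param_names,
        subject_ids=list(subject_ids) if subject_ids else [f"s{i}" for i in range(S)],
        meta={
            "seed": seed,
            "n_iter": n_iter,
            "n_warmup": n_warmup,
            "thin": thin,
        },
    )
    post.compute_diagnostics()
    return post
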