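"""Bayesian mixture deconvolution of copying vectors (the SOURCEFIND model).

A recipient's copying vector ``l`` (total ``C`` cM over ``D`` donor
clusters) is modelled as multinomial with cell probabilities given by a
convex combination of surrogate-cluster profiles ``f^s``:

    l | beta  ~  Multinomial(C; sum_s beta_s f^s)
    beta | lambda ~ Dirichlet(lambda_1, ..., lambda_S)
    lambda_s ~ Uniform(0, 10)

The simplex weights ``beta`` are the ancestry proportions of interest; the
per-surrogate Dirichlet concentrations ``lambda`` are learned, which lets
the prior adapt towards sparsity when few surrogates contribute.  Inference
is by Metropolis-Hastings: a small random-walk proposal perturbs five
randomly chosen components of ``beta`` upward and five downward by the same
step and renormalises, and each ``lambda_s`` takes a bounded Gaussian
random-walk update.  Final estimates combine independent runs, weighting
each run's maximum-posterior draw by its posterior probability.

Chunk lengths are continuous cM, so the multinomial likelihood is evaluated
through its log-gamma generalisation on pseudo-counts ``f * effective_total``
(``f`` the normalised copying vector).  ``effective_total`` defaults to the
recipient's rounded total ``C`` and controls how concentrated the
likelihood is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln

from .copying import (
    AncestryEstimate,
    CopyingVector,
    SurrogateProfile,
    ValidationError,
    normalize,
)

__all__ = [
    "MCMCConfig",
    "MixtureState",
    "mixture_probs",
    "log_likelihood",
    "log_prior_beta",
    "propose_beta",
    "mh_accept",
    "update_lambda",
    "run_chain",
    "combine_runs",
    "estimate_ancestry",
]

# floor applied to mixture probabilities before logs, so donors the
# recipient copies from but no surrogate covers give a huge finite penalty
# rather than -inf
_PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    Defaults are the production settings (200,000 iterations thinned every
    1,000, combined over 50 independent runs); tests and simulations pass
    smaller values.

    Parameters
    ----------
    total_iterations
        MCMC iterations per run; must be a multiple of ``thinning``.
    thinning
        Keep every ``thinning``-th state.
    n_runs
        Independent chains combined into the final estimate.
    lambda_init
        Initial Dirichlet concentration (broadcast over surrogates); also
        the concentration of the distribution the initial ``beta`` is drawn
        from.
    lambda_bounds
        Support of the uniform hyperprior on each ``lambda_s``.
    lambda_proposal_sd
        Gaussian random-walk step for the ``lambda`` updates.
    beta_proposal_scale
        Upper bound of the uniform step size ``Y`` of the beta proposal.
    moves_per_direction
        How many components are pushed up (and down) by ``Y / moves``.
    clamp_eps
        Numerical-stability clamp keeping beta entries off the simplex
        boundary.
    effective_total
        Pseudo-count total for the likelihood; ``"use-C"`` means the
        recipient's own rounded total length.
    fix_lambda
        If set, ``lambda`` is held at this value and never updated.
    """

    total_iterations: int = 200_000
    thinning: int = 1_000
    n_runs: int = 50
    lambda_init: float = 0.5
    lambda_bounds: tuple[float, float] = (0.0, 10.0)
    lambda_proposal_sd: float = 0.2
    beta_proposal_scale: float = 0.1
    moves_per_direction: int = 5
    clamp_eps: float = 1e-7
    effective_total: float | Literal["use-C"] = "use-C"
    fix_lambda: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_iterations <= 0 or self.thinning <= 0:
            raise ValidationError("iteration counts must be positive")
        if self.total_iterations % self.thinning != 0:
            raise ValidationError("total_iterations must be a multiple of thinning")
        if self.n_runs < 1:
            raise ValidationError("n_runs must be >= 1")
        if self.beta_proposal_scale <= 0 or self.lambda_proposal_sd <= 0:
            raise ValidationError("proposal scales must be positive")
        if not self.lambda_bounds[0] < self.lambda_bounds[1]:
            raise ValidationError("lambda_bounds must be an increasing interval")

    def resolve_effective_total(self, cv: CopyingVector) -> float:
        if self.effective_total == "use-C":
            return float(round(cv.total_c))
        return float(self.effective_total)


@dataclass
class MixtureState:
    """One thinned MCMC state: simplex weights, concentrations, log posterior."""

    beta: np.ndarray
    lam: np.ndarray
    log_posterior: float


def mixture_probs(beta: np.ndarray, profiles: Sequence[SurrogateProfile]) -> np.ndarray:
    """Donor-cluster probabilities ``p_d = sum_s beta_s f^s_d``."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != len(profiles):
        raise ValidationError(
            f"beta has {beta.shape[0]} entries but there are {len(profiles)} profiles"
        )
    fmat = np.vstack([p.freqs for p in profiles])  # S x D
    return beta @ fmat


def log_likelihood(cv: CopyingVector, p: np.ndarray, effective_total: float) -> float:
    """Log-gamma generalisation of the multinomial log-pmf.

    Pseudo-counts are ``l~ = normalize(cv) * effective_total``; returns
    ``lgamma(N+1) - sum lgamma(l~+1) + sum l~ log p`` with ``N = sum l~``.
    Reduces to the exact multinomial log-pmf for integer pseudo-counts.
    """
    counts = normalize(cv) * effective_total
    p = np.maximum(np.asarray(p, dtype=float), _PROB_FLOOR)
    if np.any((p <= _PROB_FLOOR) & (counts > 0) & ~np.isfinite(np.log(p))):
        raise FloatingPointError("zero mixture probability with positive count")
    n = counts.sum()
    return float(
        gammaln(n + 1.0) - gammaln(counts + 1.0).sum() + counts @ np.log(p)
    )


def log_prior_beta(beta: np.ndarray, lam: np.ndarray) -> float:
    """Dirichlet(lambda) log density at beta."""
    beta = np.asarray(beta, dtype=float)
    lam = np.asarray(lam, dtype=float)
    return float(
        gammaln(lam.sum()) - gammaln(lam).sum() + ((lam - 1.0) @ np.log(beta))
    )


def propose_beta(
    beta: np.ndarray,
    rng: np.random.Generator,
    *,
    scale: float = 0.1,
    moves: int = 5,
    eps: float = 1e-7,
) -> np.ndarray:
    """Symmetric-treated random-walk proposal on the simplex.

    One step size ``Y ~ Uniform(0, scale)`` is drawn and reused: ``Y/moves``
    is added to ``moves`` components sampled with replacement, subtracted
    from ``moves`` components sampled with replacement, every touched entry
    is clamped into ``[eps, 1-eps]``, and the vector is renormalised.
    """
    s = beta.shape[0]
    out = beta.copy()
    y = rng.uniform(0.0, scale)
    step = y / moves
    idx = rng.integers(0, s, size=2 * moves)
    for j in idx[:moves]:
        v = out[j] + step
        out[j] = 1.0 - eps if v > 1.0 - eps else v
    for j in idx[moves:]:
        v = out[j] - step
        out[j] = eps if v < eps else v
    out /= out.sum()
    return out


def mh_accept(log_post_new: float, log_post_old: float, rng: np.random.Generator) -> bool:
    """Metropolis acceptance: probability ``min(exp(delta), 1)`` in log space."""
    if math.isnan(log_post_new) or math.isnan(log_post_old):
        raise FloatingPointError("NaN log posterior in acceptance step")
    delta = log_post_new - log_post_old
    if delta >= 0:
        return True
    return math.log(rng.uniform()) < delta


def update_lambda(
    lam: np.ndarray,
    beta: np.ndarray,
    rng: np.random.Generator,
    *,
    sd: float = 0.2,
    bounds: tuple[float, float] = (0.0, 10.0),
) -> np.ndarray:
    """One sweep of per-component Gaussian random-walk updates on lambda.

    Proposals outside ``bounds`` are rejected outright (the uniform
    hyperprior has bounded support); otherwise the acceptance ratio is the
    Dirichlet density ratio Pr(beta|lam') / Pr(beta|lam).
    """
    lam = lam.copy()
    log_beta = np.log(beta)
    lo, hi = bounds
    lam_sum = float(lam.sum())
    for s in range(lam.shape[0]):
        prop = rng.normal(lam[s], sd)
        if prop < lo or prop > hi:
            continue
        # only the s-th term of the Dirichlet log density changes
        delta = (
            math.lgamma(lam_sum - lam[s] + prop)
            - math.lgamma(lam_sum)
            - math.lgamma(prop)
            + math.lgamma(lam[s])
            + (prop - lam[s]) * log_beta[s]
        )
        if delta >= 0 or math.log(rng.uniform()) < delta:
            lam_sum += prop - lam[s]
            lam[s] = prop
    return lam


def _draw_initial_beta(
    s: int, lambda_init: float, eps: float, rng: np.random.Generator
) -> np.ndarray:
    beta = rng.dirichlet(np.full(s, lambda_init))
    beta = np.clip(beta, eps, 1.0 - eps)
    return beta / beta.sum()


def run_chain(
    cv: CopyingVector,
    profiles: Sequence[SurrogateProfile],
    config: MCMCConfig,
    rng: np.random.Generator,
    diagnostics: dict | None = None,
) -> list[MixtureState]:
    """Run one MCMC chain and return the thinned states.

    Each iteration performs the beta Metropolis-Hastings update followed by
    a lambda sweep (skipped when ``fix_lambda`` is set).  The initial beta
    is drawn from Dirichlet(lambda_init, ..., lambda_init).  When a
    ``diagnostics`` dict is supplied it is filled with the beta acceptance
    rate and the maximum log posterior seen among thinned states.
    """
    s = len(profiles)
    if s == 0:
        raise ValidationError("need at least one surrogate profile")
    eff_total = config.resolve_effective_total(cv)
    counts = normalize(cv) * eff_total
    fmat = np.vstack([p.freqs for p in profiles])  # S x D
    n = counts.sum()
    ll_const = float(gammaln(n + 1.0) - gammaln(counts + 1.0).sum())

    def loglik(beta: np.ndarray) -> float:
        p = np.maximum(beta @ fmat, _PROB_FLOOR)
        return ll_const + float(counts @ np.log(p))

    if config.fix_lambda is not None:
        lam = np.full(s, float(config.fix_lambda))
    else:
        lam = np.full(s, config.lambda_init)

    beta = _draw_initial_beta(s, config.lambda_init, config.clamp_eps, rng)
    cur_ll = loglik(beta)
    cur_lp = log_prior_beta(beta, lam)

    states: list[MixtureState] = []
    eps = config.clamp_eps
    scale = config.beta_proposal_scale
    moves = config.moves_per_direction
    n_accepted = 0
    for m in range(1, config.total_iterations + 1):
        cand = propose_beta(beta, rng, scale=scale, moves=moves, eps=eps)
        cand_ll = loglik(cand)
        cand_lp = log_prior_beta(cand, lam)
        if mh_accept(cand_ll + cand_lp, cur_ll + cur_lp, rng):
            beta, cur_ll, cur_lp = cand, cand_ll, cand_lp
            n_accepted += 1
        if config.fix_lambda is None:
            lam = update_lambda(
                lam,
                beta,
                rng,
                sd=config.lambda_proposal_sd,
                bounds=config.lambda_bounds,
            )
            cur_lp = log_prior_beta(beta, lam)
        if m % config.thinning == 0:
            states.append(MixtureState(beta.copy(), lam.copy(), cur_ll + cur_lp))
    if diagnostics is not None:
        diagnostics["beta_acceptance_rate"] = n_accepted / config.total_iterations
        diagnostics["max_log_posterior"] = max(st.log_posterior for st in states)
    return states


def combine_runs(
    per_run: Sequence[tuple[np.ndarray, float]],
    *,
    recipient_id: str = "",
    surrogate_ids: Sequence[str] | None = None,
) -> AncestryEstimate:
    """Posterior-probability-weighted average of per-run best draws.

    ``per_run`` holds each run's maximum-log-posterior thinned state.  The
    run weights are the softmax of the log posteriors (shifted by the max
    before exponentiating), so a run whose best draw dominates receives
    essentially all the weight.
    """
    if len(per_run) == 0:
        raise ValidationError("combine_runs needs at least one run")
    betas = np.vstack([b for b, _ in per_run])
    log_posts = np.array([lp for _, lp in per_run], dtype=float)
    shifted = log_posts - log_posts.max()
    weights = np.exp(shifted)
    weights /= weights.sum()
    combined = weights @ betas
    combined /= combined.sum()
    if surrogate_ids is None:
        surrogate_ids = [f"s{i}" for i in range(betas.shape[1])]
    return AncestryEstimate(
        recipient_id=recipient_id,
        proportions={sid: float(v) for sid, v in zip(surrogate_ids, combined)},
        per_run=[(b.copy(), float(lp)) for b, lp in per_run],
        combined_weights=weights,
    )


def estimate_ancestry(
    cv: CopyingVector,
    profiles: Sequence[SurrogateProfile],
    config: MCMCConfig,
) -> AncestryEstimate:
    """Full estimator: ``n_runs`` independent chains, combined.

    Run ``i`` is seeded with ``config.seed + i``, so identical configs give
    bit-identical estimates.
    """
    per_run: list[tuple[np.ndarray, float]] = []
    for i in range(config.n_runs):
        rng = np.random.default_rng(config.seed + i)
        states = run_chain(cv, profiles, config, rng)
        best = max(states, key=lambda st: st.log_posterior)
        per_run.append((best.beta, best.log_posterior))
    return combine_runs(
        per_run,
        recipient_id=cv.recipient_id,
        surrogate_ids=[p.surrogate_id for p in profiles],
    )


def threshold_proportions(
    est: AncestryEstimate, min_report: float
) -> AncestryEstimate:
    """Zero proportions below ``min_report`` and renormalise the rest."""
    kept = {s: v for s, v in est.proportions.items() if v >= min_report}
    if not kept:
        raise ValidationError("min_report removed every surrogate")
    total = sum(kept.values())
    props = {s: (kept[s] / total if s in kept else 0.0) for s in est.proportions}
    return AncestryEstimate(
        recipient_id=est.recipient_id,
        proportions=props,
        per_run=est.per_run,
        combined_weights=est.combined_weights,
    )
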