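"""Synthetic surrogate panels and recipients with known mixture proportions.

Real copying vectors come from chromosome painting of genotype panels that
are access-restricted; this module generates panels from the same
generative model the estimator assumes (multinomial draws around a convex
combination of surrogate profiles), so parameter recovery can be tested
end to end without any data download.  An optional over-dispersion knob
(Dirichlet-multinomial) stresses robustness to model misspecification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .copying import CopyingVector, SurrogateProfile, ValidationError
from .mcmc import MCMCConfig, estimate_ancestry
from .nnls import nnls_mixture

__all__ = [
    "SimulationSpec",
    "RecoveryReport",
    "make_profiles",
    "sample_copying_vector",
    "make_drifted_surrogate",
    "recovery_experiment",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of one simulated panel.

    ``separation`` in (0, 1] mixes each Dirichlet-drawn profile toward its
    own basis vector, so pairwise total-variation distance between
    profiles grows with it; ``drift_level`` >= 0 optionally concentrates a
    profile on a private self-copy column; ``overdispersion`` (if set)
    replaces the multinomial draw by a Dirichlet-multinomial with that
    concentration.
    """

    s: int
    d: int
    true_beta: tuple[float, ...]
    separation: float = 0.9
    effective_total: float = 20_000.0
    drift_level: float = 0.0
    overdispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < self.s:
            raise ValidationError("need at least as many donor columns as surrogates")
        beta = np.asarray(self.true_beta, dtype=float)
        if beta.shape[0] != self.s or np.any(beta < 0) or abs(beta.sum() - 1) > 1e-9:
            raise ValidationError("true_beta must be a length-S simplex vector")
        if not 0.0 <= self.separation <= 1.0:
            raise ValidationError("separation must lie in [0, 1]")


@dataclass
class RecoveryReport:
    """Per-component error summary of a simulate-estimate-compare cycle."""

    true_beta: np.ndarray
    mcmc_bias: np.ndarray
    mcmc_max_abs_error: float
    mcmc_rmse: float
    nnls_bias: np.ndarray
    nnls_max_abs_error: float
    nnls_rmse: float
    n_replicates: int


def make_profiles(spec: SimulationSpec, rng: np.random.Generator) -> list[SurrogateProfile]:
    """Draw S surrogate profiles over D donor columns.

    Each row is ``(1 - separation) * Dirichlet(1,...,1) + separation * e_i``
    with a distinct basis column ``e_i`` per surrogate: separation 0 gives
    exchangeable Dirichlet rows, separation 1 gives disjoint point masses.
    """
    profiles = []
    for i in range(spec.s):
        base = rng.dirichlet(np.ones(spec.d))
        basis = np.zeros(spec.d)
        basis[i] = 1.0
        freqs = (1.0 - spec.separation) * base + spec.separation * basis
        freqs /= freqs.sum()
        profiles.append(SurrogateProfile(f"s{i}", freqs))
    return profiles


def sample_copying_vector(
    true_beta: Sequence[float],
    profiles: Sequence[SurrogateProfile],
    effective_total: float,
    rng: np.random.Generator,
    *,
    recipient_id: str = "sim",
    overdispersion: float | None = None,
) -> CopyingVector:
    """Draw one recipient: Multinomial(effective_total, sum_s beta_s f^s).

    With ``overdispersion`` set, the cell probabilities are first
    perturbed as ``Dirichlet(p * overdispersion)`` (smaller values give
    noisier vectors than the multinomial alone).
    """
    beta = np.asarray(true_beta, dtype=float)
    fmat = np.vstack([p.freqs for p in profiles])
    p = beta @ fmat
    p = p / p.sum()
    if overdispersion is not None:
        # Dirichlet-multinomial: only perturb cells with support
        support = p > 0
        perturbed = np.zeros_like(p)
        perturbed[support] = rng.dirichlet(p[support] * overdispersion)
        p = perturbed
    counts = rng.multinomial(int(round(effective_total)), p).astype(float)
    return CopyingVector(recipient_id, counts, float(counts.sum()))


def make_drifted_surrogate(
    profile: SurrogateProfile,
    drift_level: float,
    self_column: int,
    *,
    rng: np.random.Generator | None = None,
) -> SurrogateProfile:
    """Concentrate a profile on a private self-copy column.

    Emulates a strongly drifted reference cluster whose members copy
    mostly from each other: mass ``drift_level / (1 + drift_level)`` moves
    onto ``self_column``.  At drift 0 the profile is unchanged; in the
    large-drift limit it approaches a point mass on the self column.
    """
    if drift_level < 0:
        raise ValidationError("drift_level must be >= 0")
    freqs = profile.freqs.copy()
    freqs[self_column] += drift_level
    freqs /= freqs.sum()
    return SurrogateProfile(profile.surrogate_id, freqs, profile.n_individuals)


def recovery_experiment(
    spec: SimulationSpec,
    *,
    n_replicates: int = 20,
    mcmc_config: MCMCConfig | None = None,
) -> RecoveryReport:
    """Simulate, estimate (Bayesian and NNLS), and compare to the truth.

    Each replicate draws a fresh recipient from fixed profiles; errors are
    averaged over replicates.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    profiles = make_profiles(spec, rng)
    if mcmc_config is None:
        mcmc_config = MCMCConfig(
            total_iterations=20_000, thinning=200, n_runs=4, seed=spec.seed
        )
    true_beta = np.asarray(spec.true_beta, dtype=float)
    mcmc_err = np.zeros((n_replicates, spec.s))
    nnls_err = np.zeros((n_replicates, spec.s))
    for rep in range(n_replicates):
        cv = sample_copying_vector(
            true_beta,
            profiles,
            spec.effective_total,
            rng,
            recipient_id=f"rep{rep}",
            overdispersion=spec.overdispersion,
        )
        cfg = replace(mcmc_config, seed=mcmc_config.seed + 1000 * rep)
        est = estimate_ancestry(cv, profiles, cfg)
        mcmc_err[rep] = est.as_vector([p.surrogate_id for p in profiles]) - true_beta
        sol = nnls_mixture(cv.lengths / cv.total_c, profiles)
        nnls_err[rep] = sol.weights - true_beta
    return RecoveryReport(
        true_beta=true_beta,
        mcmc_bias=mcmc_err.mean(axis=0),
        mcmc_max_abs_error=float(np.abs(mcmc_err).max()),
        mcmc_rmse=float(np.sqrt((mcmc_err**2).mean())),
        nnls_bias=nnls_err.mean(axis=0),
        nnls_max_abs_error=float(np.abs(nnls_err).max()),
        nnls_rmse=float(np.sqrt((nnls_err**2).mean())),
        n_replicates=n_replicates,
    )
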