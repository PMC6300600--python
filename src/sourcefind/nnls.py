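"""Non-negative least-squares mixture baseline.

Regresses a recipient's normalised copying vector on the surrogate
profiles under a non-negativity constraint, then rescales the weights to
sum to one (the sum-to-one condition is imposed post hoc, not in the
solver).  Fast and deterministic; the Bayesian sampler in
:mod:`sourcefind.mcmc` is its model-based refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .copying import SurrogateProfile, ValidationError

__all__ = ["NNLSSolution", "DegenerateFitWarning", "nnls_mixture"]


class DegenerateFitWarning(UserWarning):
    """All-zero NNLS solution; reported weights fall back to uniform."""


@dataclass(frozen=True)
class NNLSSolution:
    weights: np.ndarray          # length S, >= 0, rescaled to sum 1
    residual_norm: float         # ||F w - target|| before rescaling
    degenerate: bool = False


def nnls_mixture(
    target: np.ndarray, profiles: Sequence[SurrogateProfile]
) -> NNLSSolution:
    """Solve ``min ||F w - target||^2  s.t.  w >= 0`` and rescale to the simplex.

    ``F`` is the D x S matrix whose columns are the surrogate profiles and
    ``target`` a normalised copying vector.  The residual is reported for
    the raw (pre-rescale) solution.
    """
    if len(profiles) == 0:
        raise ValidationError("need at least one surrogate profile")
    target = np.asarray(target, dtype=float)
    if abs(target.sum() - 1.0) > 1e-6:
        raise ValidationError("target must be a normalised copying vector")
    fmat = np.column_stack([p.freqs for p in profiles])
    if fmat.shape[0] != target.shape[0]:
        raise ValidationError("target and profiles use different donor panels")
    weights, residual = _scipy_nnls(fmat, target)
    total = weights.sum()
    if total <= 0:
        warnings.warn(
            "NNLS returned the all-zero solution; weights undefined, "
            "reporting uniform",
            DegenerateFitWarning,
            stacklevel=2,
        )
        s = len(profiles)
        return NNLSSolution(np.full(s, 1.0 / s), float(residual), degenerate=True)
    return NNLSSolution(weights / total, float(residual))
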