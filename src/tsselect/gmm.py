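"""Generalized-method-of-moments (GMM) estimation of candidate-model rates.

Each candidate's free parameters are chosen to minimize a weighted sum of
squared differences between the first and second sample moments of the
observed time-t cells (the estimation split) and the same moments of the
candidate pool evolved to t under the trial parameters.  The moment vector
stacks means, variances and pairwise covariances (6 + 6 + 15 = 27 conditions
for six proteins); a means+variances-only mode is available via
``include_covariances=False``.

Weighting uses diagonal relative weights ``w_s = 1 / max(target_s^2, eps)``
by default so that moments on very different abundance scales contribute
comparably.  Optimization runs in log-parameter space (rates are positive and
span decades) with a seeded Latin-hypercube multi-start screen followed by
bounded quasi-Newton polishing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .errors import DataError, NumericalError
from .reaction_network import CandidateModel, evolve_cells, resolve_rates
from .tss_data import TSSDataset, child_seeds

__all__ = [
    "MomentSet",
    "GMMWeights",
    "EstimationResult",
    "compute_moments",
    "gmm_objective",
    "estimate_parameters",
    "DEFAULT_BOUNDS",
]

#: Bounds on each free rate during optimization (log-spaced search space).
DEFAULT_BOUNDS = (1e-8, 1e2)

_WEIGHT_EPS = 1e-12


@dataclass(frozen=True)
class MomentSet:
    """First and second sample moments of one snapshot.

    ``covariances`` holds the upper triangle (row-major, excluding the
    diagonal) of the covariance matrix.  ``timestamp`` records the snapshot
    time the moments were computed from, so an objective knows what time to
    evolve a candidate pool to.
    """

    means: np.ndarray
    variances: np.ndarray
    covariances: np.ndarray
    timestamp: float | None = None

    def __post_init__(self) -> None:
        n = len(self.means)
        if len(self.variances) != n or len(self.covariances) != n * (n - 1) // 2:
            raise DataError("inconsistent moment-vector lengths")

    def stacked(self, include_covariances: bool = True) -> np.ndarray:
        parts = [self.means, self.variances]
        if include_covariances:
            parts.append(self.covariances)
        return np.concatenate(parts)


@dataclass(frozen=True)
class GMMWeights:
    """Strictly positive diagonal weights aligned with the stacked moments."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v) & (v > 0)):
            raise DataError("GMM weights must be a 1-D strictly positive vector")
        object.__setattr__(self, "values", v)

    @classmethod
    def relative(cls, target: MomentSet, include_covariances: bool = True,
                 eps: float = _WEIGHT_EPS) -> "GMMWeights":
        """Relative squared-error weights ``1 / max(scale_s^2, eps)``.

        The scale of a mean or variance condition is the target itself; the
        scale of a covariance condition is ``sqrt(var_j * var_k)`` (so its
        error is measured on the correlation scale).  A covariance target can
        legitimately be near zero, and weighting it by its own inverse square
        would let pure sampling noise dominate the objective.
        """
        scale = [target.means, target.variances]
        if include_covariances:
            n = len(target.means)
            iu = np.triu_indices(n, k=1)
            v = np.asarray(target.variances, dtype=float)
            scale.append(np.sqrt(v[iu[0]] * v[iu[1]]))
        t = np.concatenate(scale)
        return cls(1.0 / np.maximum(t * t, eps))

    @classmethod
    def unit(cls, target: MomentSet, include_covariances: bool = True) -> "GMMWeights":
        return cls(np.ones_like(target.stacked(include_covariances)))

    @classmethod
    def inverse_variance(
        cls, estimation_data: "TSSDataset", include_covariances: bool = True,
    ) -> "GMMWeights":
        """Efficient diagonal weights: one over the sampling variance of each
        moment condition, estimated by plug-in from the estimation cells.

        ``Var(mean_j) = var_j/N``; ``Var(s2_j) ~ (m4_j - var_j^2)/N``;
        ``Var(cov_jk) ~ (var_j*var_k + cov_jk^2)/N``.  This is the standard
        first-step efficient choice for a diagonal GMM weighting matrix and
        weights the high signal-to-noise conditions (the means) accordingly.
        """
        X = estimation_data.abundances
        N = X.shape[0]
        if N < 4:
            raise DataError("inverse-variance weights need at least 4 cells")
        var = X.var(axis=0, ddof=1)
        centered = X - X.mean(axis=0)
        m4 = np.mean(centered**4, axis=0)
        parts = [var / N, np.maximum(m4 - var * var, var * var * 0.1) / N]
        if include_covariances:
            cov = np.cov(X, rowvar=False, ddof=1)
            iu = np.triu_indices(X.shape[1], k=1)
            parts.append((var[iu[0]] * var[iu[1]] + cov[iu] ** 2) / N)
        v = np.concatenate(parts)
        return cls(1.0 / np.maximum(v, np.finfo(float).tiny))


@dataclass(frozen=True)
class EstimationResult:
    """Outcome of one multi-start GMM fit."""

    model_id: int
    theta_tilde: np.ndarray
    objective_value: float
    converged: bool
    n_starts: int
    best_start_index: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.objective_value < 0:
            raise DataError("objective value must be >= 0")
        if not np.all(self.theta_tilde > 0):
            raise DataError("theta_tilde must be strictly positive")


def compute_moments(data: TSSDataset) -> MomentSet:
    """Sample means, variances and covariances (denominator N-1) of a snapshot.

    Invariant to row permutation; requires at least two cells.
    """
    X = data.abundances
    if X.shape[0] < 2:
        raise DataError("at least two cells are required to compute moments")
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    iu = np.triu_indices(X.shape[1], k=1)
    return MomentSet(
        means=X.mean(axis=0),
        variances=np.diag(cov).copy(),
        covariances=cov[iu],
        timestamp=data.timestamp,
    )


def gmm_objective(
    free_params: Sequence[float],
    model: CandidateModel,
    candidate_pool: TSSDataset,
    target: MomentSet,
    weights: GMMWeights | None = None,
    *,
    include_covariances: bool = True,
    max_rhs_evals: int | None = None,
) -> float:
    """Weighted sum of squared moment differences for one trial parameter.

    Evolves the candidate pool to the target's timestamp under the resolved
    rates, computes its moments and returns
    ``sum_s w_s * (m_s - target_s)^2`` (nonnegative; exactly zero iff every
    matched moment coincides).
    """
    if target.timestamp is None:
        raise DataError("target MomentSet must carry a timestamp")
    rates = resolve_rates(model, free_params)
    try:
        evolved = evolve_cells(
            model.network, rates, candidate_pool.abundances, target.timestamp,
            max_rhs_evals=max_rhs_evals,
            stiff_fallback=max_rhs_evals is None,
        )
    except NumericalError as exc:
        raise NumericalError(
            f"ODE evolution failed at free parameters {np.asarray(free_params)}: {exc}"
        ) from exc
    m = compute_moments(candidate_pool.with_abundances(np.maximum(evolved, 0.0),
                                                       target.timestamp))
    if weights is None:
        weights = GMMWeights.relative(target, include_covariances)
    diff = m.stacked(include_covariances) - target.stacked(include_covariances)
    return float(np.sum(weights.values * diff * diff))


def estimate_parameters(
    model: CandidateModel,
    candidate_pool: TSSDataset,
    target: MomentSet,
    weights: GMMWeights | None = None,
    n_starts: int = 8,
    seed: int = 0,
    *,
    include_covariances: bool = True,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    tol: float = 1e-10,
    n_polish: int = 2,
    extra_starts: Sequence[Sequence[float]] = (),
) -> EstimationResult:
    """Multi-start bounded minimization of the GMM objective in log-space.

    ``n_starts`` seeded Latin-hypercube points (plus any ``extra_starts``,
    e.g. an embedded solution of a nested sub-model) are screened by objective
    value; the best ``n_polish`` are refined with L-BFGS-B on log-parameters.
    ``converged`` reports whether the winning local search succeeded.
    """
    if n_starts < 1:
        raise DataError("n_starts must be >= 1")
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    d = model.n_free
    sampler = qmc.LatinHypercube(d=d, seed=child_seeds(seed, 1)[0])
    starts = [lo + (hi - lo) * row for row in sampler.random(n_starts)]
    starts += [np.log(np.asarray(s, dtype=float)) for s in extra_starts]

    cache: dict[tuple, float] = {}
    # finite penalty (not inf) keeps the bounded quasi-Newton line search
    # stable if a trial point is too stiff to integrate within budget
    penalty = 1e10

    def obj_log(logp: np.ndarray) -> float:
        key = tuple(np.round(logp, 12))
        if key not in cache:
            try:
                cache[key] = gmm_objective(
                    np.exp(logp), model, candidate_pool, target, weights,
                    include_covariances=include_covariances,
                    max_rhs_evals=5_000,
                )
            except NumericalError:
                cache[key] = penalty
        return cache[key]

    screened = [(obj_log(s), i, s) for i, s in enumerate(starts)]
    finite = [t for t in screened if t[0] < penalty]
    if not finite:
        raise NumericalError(
            f"GMM objective failed to evaluate at all {len(starts)} starts "
            f"for model {model.id}"
        )
    finite.sort(key=lambda t: (t[0], t[1]))

    best_val, best_idx, best_x, best_ok = finite[0][0], finite[0][1], finite[0][2], False
    for val, idx, s in finite[: max(1, n_polish)]:
        # FD step 1e-4 in log-space sits well above the integrator noise
        # floor (~rtol) while still resolving the smooth moment surface
        res = optimize.minimize(
            obj_log,
            s,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * d,
            options={"ftol": tol, "gtol": 1e-12, "maxiter": 200, "eps": 1e-4},
        )
        if res.fun < best_val or (res.fun == best_val and not best_ok):
            best_val, best_idx, best_x, best_ok = float(res.fun), idx, res.x, bool(res.success)
    return EstimationResult(
        model_id=model.id,
        theta_tilde=np.exp(np.asarray(best_x, dtype=float)),
        objective_value=max(best_val, 0.0),
        converged=best_ok,
        n_starts=len(starts),
        best_start_index=best_idx,
        seed=seed,
    )
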