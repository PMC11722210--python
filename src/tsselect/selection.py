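"""Model selection: approximate cross-entropy, approximate AICc, bootstrap.

For each candidate model the pipeline (i) estimates its free rates by GMM on
the 20% estimation split of the observed time-t cells, (ii) evolves the
candidate pool to t under the estimate, (iii) fits the copula-KDE predictive
density ``h_i``, and (iv) scores the candidate by its approximate
cross-entropy on the 80% evaluation split:

    ACE_i = (1/N) * sum_j  -log h_i(y_j | theta_i)        (nats)

The candidate with the smallest ACE is selected (ties break toward fewer free
parameters, then lower id).  Selecting the minimum-ACE candidate is
equivalent to minimum Kullback-Leibler divergence because the entropy of the
data-generating distribution is candidate-independent.

A complementary approximate AICc models the vector of observed-minus-
predicted mean abundances as independent zero-mean normals (diagonal
covariance); it requires more proteins than free parameters.  Bootstrap
resampling of the evaluation cells yields model-selection probabilities: the
fraction of resamples in which each candidate attains the minimum criterion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .density import DEFAULT_CDF_CLIP, JointDensityModel, fit_joint_density, joint_log_density
from .errors import DataError, NumericalError
from .gmm import EstimationResult, GMMWeights, compute_moments, estimate_parameters
from .reaction_network import CandidateModel, default_candidates, evolve_cells
from .tss_data import (
    ScenarioBundle,
    SimulatorConfig,
    TSSDataset,
    child_seeds,
    generate_scenario,
)

__all__ = [
    "SelectionSettings",
    "SelectionReport",
    "BootstrapReport",
    "approximate_cross_entropy",
    "approximate_aicc",
    "run_model_selection",
    "bootstrap_model_selection",
    "run_scenario_bootstrap",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionSettings:
    """Resolved design-decision switches for one selection run."""

    n_starts: int = 8
    n_polish: int = 2
    gmm_tol: float = 1e-10
    weights_mode: str = "relative"  # "relative" | "inverse_variance" | "unit"
    include_covariances: bool = True
    cdf_clip: float = DEFAULT_CDF_CLIP
    aicc_variance: str = "sem"  # "sem" | "pooled"
    chain_starts: bool = True  # seed each model's search with the nested fit

    def __post_init__(self) -> None:
        if self.weights_mode not in ("inverse_variance", "relative", "unit"):
            raise DataError(f"unknown weights_mode {self.weights_mode!r}")
        if self.aicc_variance not in ("sem", "pooled"):
            raise DataError(f"unknown aicc_variance {self.aicc_variance!r}")


def gmm_weights_for(
    settings: SelectionSettings, target, estimation_cells: TSSDataset
) -> GMMWeights:
    """Resolve the GMM weighting rule selected by ``settings``."""
    if settings.weights_mode == "inverse_variance":
        return GMMWeights.inverse_variance(
            estimation_cells, settings.include_covariances
        )
    if settings.weights_mode == "relative":
        return GMMWeights.relative(target, settings.include_covariances)
    return GMMWeights.unit(target, settings.include_covariances)


@dataclass(frozen=True)
class SelectionReport:
    """Per-candidate criteria and the selected model for one dataset."""

    candidate_ids: tuple[int, ...]
    n_free: tuple[int, ...]
    ace: np.ndarray
    aicc: np.ndarray  # NaN where unavailable
    theta_tilde: dict[int, np.ndarray]
    gmm_objective_values: dict[int, float]
    selected_by_ace: int
    selected_by_aicc: int | None
    ace_gap: float
    n_eval: int
    seed: int | None = None
    failed_candidates: tuple[int, ...] = ()


@dataclass(frozen=True)
class BootstrapReport:
    """Bootstrap model-selection probabilities and per-resample diagnostics."""

    B: int
    candidate_ids: tuple[int, ...]
    selection_counts: np.ndarray
    selection_probabilities: np.ndarray
    per_resample_ace: np.ndarray  # (B, n_candidates)
    per_resample_selected: np.ndarray  # (B,) candidate ids
    ace_gaps: np.ndarray  # (B,) |smallest - second smallest|
    correct: np.ndarray | None  # (B,) bool, when the truth is known
    concordance_with_aicc: float
    reestimate: bool
    seed: int | None = None


def approximate_cross_entropy(eval_cells: TSSDataset, model: JointDensityModel) -> float:
    """Sample-average cross-entropy ``(1/N) * sum_j -log h(y_j)`` in nats."""
    if eval_cells.n_proteins != len(model.marginals):
        raise DataError(
            f"evaluation data have {eval_cells.n_proteins} proteins but the "
            f"density model has {len(model.marginals)} marginals"
        )
    return float(np.mean(-joint_log_density(model, eval_cells.abundances)))


def _aicc_from_stats(
    delta: np.ndarray, s2: np.ndarray, k: int, n_proteins: int
) -> float:
    if n_proteins - k - 1 <= 0:
        raise DataError(
            f"approximate AICc needs more proteins than free parameters: with "
            f"n={n_proteins} proteins and k={k} the small-sample denominator "
            f"n-k-1={n_proteins - k - 1} is zero or negative"
        )
    log_l = float(np.sum(-0.5 * np.log(2.0 * np.pi * s2) - delta * delta / (2.0 * s2)))
    return -2.0 * log_l + 2.0 * k + 2.0 * k * (k + 1.0) / (n_proteins - k - 1.0)


def _mean_diff_stats(
    observed: np.ndarray, predicted: np.ndarray, variance_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    n_y, n_x = observed.shape[0], predicted.shape[0]
    delta = observed.mean(axis=0) - predicted.mean(axis=0)
    var_y = observed.var(axis=0, ddof=1)
    var_x = predicted.var(axis=0, ddof=1)
    if variance_mode == "sem":
        s2 = var_y / n_y + var_x / n_x
    else:  # pooled
        pooled = ((n_y - 1) * var_y + (n_x - 1) * var_x) / (n_y + n_x - 2)
        s2 = pooled * (1.0 / n_y + 1.0 / n_x)
    return delta, s2


def approximate_aicc(
    observed: TSSDataset,
    predicted: TSSDataset,
    k: int,
    *,
    variance_mode: str = "sem",
) -> float:
    """Approximate AICc on observed-minus-predicted mean abundances.

    ``delta_j = mean(observed_j) - mean(predicted_j)`` is modelled as
    ``Normal(0, s_j^2)`` independently across proteins, with ``s_j^2`` the
    variance of the mean difference (sum of squared standard errors; a pooled
    variant via ``variance_mode="pooled"``).  Returns
    ``-2 logL + 2k + 2k(k+1)/(n-k-1)`` and raises :class:`DataError` when
    ``n - k - 1 <= 0``.
    """
    if observed.protein_names != predicted.protein_names:
        raise DataError("observed and predicted datasets must share protein columns")
    if k < 1:
        raise DataError("k must be >= 1")
    delta, s2 = _mean_diff_stats(
        observed.abundances, predicted.abundances, variance_mode
    )
    return _aicc_from_stats(delta, s2, k, observed.n_proteins)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class _CandidateFit:
    """Internal per-candidate artifacts shared by selection and bootstrap."""

    model: CandidateModel
    estimate: EstimationResult
    evolved_pool: TSSDataset
    density: JointDensityModel
    eval_log_density: np.ndarray  # -log h at each evaluation cell (negated later)
    pred_means: np.ndarray
    pred_vars: np.ndarray


def _fit_candidates(
    bundle: ScenarioBundle,
    candidates: Sequence[CandidateModel],
    settings: SelectionSettings,
    seed: int,
    estimation_cells: TSSDataset | None = None,
) -> tuple[list[_CandidateFit], list[int]]:
    if estimation_cells is None:
        estimation_cells = bundle.estimation_cells
    target = compute_moments(estimation_cells)
    weights = gmm_weights_for(settings, target, estimation_cells)
    eval_cells = bundle.evaluation_cells
    ordered = sorted(candidates, key=lambda m: m.id)
    gmm_seeds = child_seeds(seed, len(ordered))
    fits: list[_CandidateFit] = []
    failed: list[int] = []
    prev_theta: np.ndarray | None = None
    prev_model: CandidateModel | None = None
    for model, gmm_seed in zip(ordered, gmm_seeds):
        extra: list[np.ndarray] = []
        if settings.chain_starts and prev_theta is not None:
            # warm start from the nested sub-model's solution, mapped through
            # its constraints into this model's free-parameter space
            full = prev_model.resolve_rates(prev_theta).as_array()
            extra.append(model.reduce_rates(full))
        try:
            est = estimate_parameters(
                model,
                bundle.candidate_pool,
                target,
                weights,
                n_starts=settings.n_starts,
                seed=gmm_seed,
                include_covariances=settings.include_covariances,
                tol=settings.gmm_tol,
                n_polish=settings.n_polish,
                extra_starts=extra,
            )
            rates = model.resolve_rates(est.theta_tilde)
            evolved = evolve_cells(
                model.network, rates, bundle.candidate_pool.abundances,
                bundle.observed.timestamp,
            )
            evolved = np.maximum(evolved, np.finfo(float).tiny)
            evolved_ds = bundle.candidate_pool.with_abundances(
                evolved, bundle.observed.timestamp
            )
            density = fit_joint_density(evolved_ds, cdf_clip=settings.cdf_clip)
            logdens = joint_log_density(density, eval_cells.abundances)
        except (NumericalError, DataError) as exc:
            warnings.warn(
                f"candidate model {model.id} failed and is excluded: {exc}",
                RuntimeWarning,
                stacklevel=2,
            )
            failed.append(model.id)
            continue
        fits.append(
            _CandidateFit(
                model=model,
                estimate=est,
                evolved_pool=evolved_ds,
                density=density,
                eval_log_density=logdens,
                pred_means=evolved.mean(axis=0),
                pred_vars=evolved.var(axis=0, ddof=1),
            )
        )
        prev_theta, prev_model = est.theta_tilde, model
    if not fits:
        raise NumericalError("every candidate model failed estimation")
    return fits, failed


def _argmin_with_parsimony(values: np.ndarray, fits: Sequence[_CandidateFit]) -> int:
    """Index of the minimum; exact ties break toward fewer free parameters,
    then lower candidate id."""
    order = sorted(
        range(len(values)),
        key=lambda i: (values[i], fits[i].model.n_free, fits[i].model.id),
    )
    return order[0]


def _gap(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    s = np.sort(values)
    return float(abs(s[1] - s[0]))


def run_model_selection(
    bundle: ScenarioBundle,
    candidates: Sequence[CandidateModel] | None = None,
    settings: SelectionSettings | None = None,
    seed: int | None = None,
) -> SelectionReport:
    """Run the full split-sample selection protocol on one scenario bundle."""
    candidates = list(candidates) if candidates is not None else default_candidates()
    settings = settings or SelectionSettings()
    seed = bundle.seed if seed is None else seed
    fits, failed = _fit_candidates(bundle, candidates, settings, seed)
    return _report_from_fits(bundle, fits, failed, settings, seed)


def _report_from_fits(
    bundle: ScenarioBundle,
    fits: list[_CandidateFit],
    failed: list[int],
    settings: SelectionSettings,
    seed: int,
) -> SelectionReport:
    eval_cells = bundle.evaluation_cells
    ace = np.array([float(np.mean(-f.eval_log_density)) for f in fits])
    obs = eval_cells.abundances
    aicc = np.full(len(fits), np.nan)
    for i, f in enumerate(fits):
        try:
            aicc[i] = approximate_aicc(
                eval_cells, f.evolved_pool, f.model.n_free,
                variance_mode=settings.aicc_variance,
            )
        except DataError:
            pass  # k >= n-1: AICc unavailable for this candidate
    i_ace = _argmin_with_parsimony(ace, fits)
    selected_by_aicc = None
    if np.all(np.isfinite(aicc)):
        selected_by_aicc = fits[_argmin_with_parsimony(aicc, fits)].model.id
    return SelectionReport(
        candidate_ids=tuple(f.model.id for f in fits),
        n_free=tuple(f.model.n_free for f in fits),
        ace=ace,
        aicc=aicc,
        theta_tilde={f.model.id: f.estimate.theta_tilde for f in fits},
        gmm_objective_values={f.model.id: f.estimate.objective_value for f in fits},
        selected_by_ace=fits[i_ace].model.id,
        selected_by_aicc=selected_by_aicc,
        ace_gap=_gap(ace),
        n_eval=obs.shape[0],
        seed=seed,
        failed_candidates=tuple(failed),
    )


def bootstrap_model_selection(
    bundle: ScenarioBundle,
    candidates: Sequence[CandidateModel] | None = None,
    B: int = 1000,
    seed: int | None = None,
    reestimate: bool = False,
    settings: SelectionSettings | None = None,
    _prefits: list[_CandidateFit] | None = None,
) -> BootstrapReport:
    """Bootstrap model-selection probabilities.

    Each resample draws evaluation cells with replacement and recomputes ACE
    and approximate AICc per candidate.  With ``reestimate=True`` the
    estimation cells are also resampled and the parameter estimates and
    densities refitted per resample (costly; default keeps them fixed).
    """
    if B < 1:
        raise DataError("B must be >= 1")
    candidates = list(candidates) if candidates is not None else default_candidates()
    settings = settings or SelectionSettings()
    seed = bundle.seed if seed is None else seed
    boot_seed, refit_seed = child_seeds(seed ^ 0x5EED, 2)
    rng = np.random.default_rng(boot_seed)
    eval_cells = bundle.evaluation_cells
    n_eval = eval_cells.n_cells
    obs = eval_cells.abundances

    if not reestimate:
        if _prefits is not None:
            fits = _prefits
        else:
            fits, _ = _fit_candidates(bundle, candidates, settings, seed)
        logdens = np.column_stack([f.eval_log_density for f in fits])  # (n_eval, C)

    C = len(candidates) if reestimate else logdens.shape[1]
    ids: tuple[int, ...] | None = None
    per_ace = np.empty((B, C))
    per_aicc = np.empty((B, C))
    selected = np.empty(B, dtype=int)
    selected_aicc = np.empty(B, dtype=object)
    gaps = np.empty(B)

    for b in range(B):
        idx = rng.integers(0, n_eval, size=n_eval)
        if reestimate:
            est_rows = bundle.estimation_idx[
                rng.integers(0, bundle.estimation_idx.size, size=bundle.estimation_idx.size)
            ]
            est_ds = TSSDataset(
                bundle.observed.abundances[est_rows],
                bundle.observed.timestamp,
                list(bundle.observed.protein_names),
                [f"resample{b}_{j}" for j in range(est_rows.size)],
            )
            fits_b, _ = _fit_candidates(
                bundle, candidates, settings, refit_seed + b,
                estimation_cells=est_ds,
            )
            logdens_b = np.column_stack([
                joint_log_density(f.density, obs[idx]) for f in fits_b
            ])
            fits_use = fits_b
        else:
            logdens_b = logdens[idx]
            fits_use = fits
        if ids is None:
            ids = tuple(f.model.id for f in fits_use)
        ace_b = -logdens_b.mean(axis=0)
        per_ace[b] = ace_b
        resampled = obs[idx]
        for i, f in enumerate(fits_use):
            try:
                delta = resampled.mean(axis=0) - f.pred_means
                s2 = (
                    resampled.var(axis=0, ddof=1) / n_eval
                    + f.pred_vars / f.evolved_pool.n_cells
                )
                per_aicc[b, i] = _aicc_from_stats(
                    delta, s2, f.model.n_free, eval_cells.n_proteins
                )
            except DataError:
                per_aicc[b, i] = np.nan
        i_sel = _argmin_with_parsimony(ace_b, fits_use)
        selected[b] = fits_use[i_sel].model.id
        if np.all(np.isfinite(per_aicc[b])):
            selected_aicc[b] = fits_use[
                _argmin_with_parsimony(per_aicc[b], fits_use)
            ].model.id
        else:
            selected_aicc[b] = None
        gaps[b] = _gap(ace_b)
        if (b + 1) % 50 == 0:
            logger.info("bootstrap resample %d/%d complete", b + 1, B)

    counts = np.array([int(np.sum(selected == cid)) for cid in ids])
    with_aicc = np.array([s is not None for s in selected_aicc])
    concordance = (
        float(np.mean(selected[with_aicc] == selected_aicc[with_aicc].astype(int)))
        if with_aicc.any()
        else float("nan")
    )
    correct = (
        selected == bundle.true_model_id if bundle.true_model_id is not None else None
    )
    return BootstrapReport(
        B=B,
        candidate_ids=ids,
        selection_counts=counts,
        selection_probabilities=counts / float(B),
        per_resample_ace=per_ace,
        per_resample_selected=selected,
        ace_gaps=gaps,
        correct=correct,
        concordance_with_aicc=concordance,
        reestimate=reestimate,
        seed=seed,
    )


def run_scenario_bootstrap(
    scenario: str,
    seed: int,
    B: int = 200,
    n_cells: int = 8000,
    t: float = 1.5,
    reestimate: bool = False,
    settings: SelectionSettings | None = None,
) -> tuple[ScenarioBundle, SelectionReport, BootstrapReport]:
    """Convenience end-to-end run of one scenario: simulate, select, bootstrap."""
    candidates = default_candidates()
    settings = settings or SelectionSettings()
    config = SimulatorConfig(scenario=scenario, n_cells=n_cells, t=t, seed=seed)
    bundle = generate_scenario(config, candidates)
    fits, failed = _fit_candidates(bundle, candidates, settings, bundle.seed)
    report = _report_from_fits(bundle, fits, failed, settings, bundle.seed)
    boot = bootstrap_model_selection(
        bundle, candidates, B=B, reestimate=reestimate, settings=settings,
        _prefits=None if reestimate else fits,
    )
    return bundle, report, boot
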