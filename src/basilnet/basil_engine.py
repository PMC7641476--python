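"""The batch screening iterative lasso (BASIL) outer loop.

The engine computes an exact penalized regression path on genotype data
that never has to fit in memory.  Each outer iteration performs exactly one
full-data scan (an inner-product pass of every candidate variant against a
small matrix of residual vectors) which simultaneously

* certifies, via the KKT stationarity condition, the candidate solutions
  fitted in the previous iteration — a variant left out of the strong set is
  genuinely inactive at lambda iff its gradient magnitude stays below
  lambda * alpha — and
* ranks the remaining variants by gradient magnitude to build the next
  strong set (the batch form of the strong screening rules).

Solutions are only ever reported for lambdas whose full-universe KKT check
passed, so the assembled path is exact: identical (to solver tolerance) to
fitting the full matrix in memory, for any batch size M and increment
delta-M.  When an entire batch fails certification the engine falls back to
the last certified lambda and enlarges the screening batch by delta-M,
which guarantees termination (the strong set grows monotonically toward the
full universe, where the check passes vacuously).

An optional validation split provides early stopping: the path is cut once
the validation metric has gone `early_stop_patience` certified lambdas
without improving on its running best.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from . import families as fam
from . import metrics as met
from .errors import AlignmentError, ConfigError, ConvergenceError
from .genotype_io import GenotypeStore, load_block, qc_filter, sparse_inner_products, variant_stats
from .lasso_core import FitResult, PenaltySpec, fit_path_on_strong_set, covariate_only_fit, relaxed_refit

__all__ = [
    "BasilConfig",
    "PathState",
    "PathSolution",
    "lambda_sequence",
    "screen",
    "kkt_check",
    "initial_batch_heuristic",
    "basil_run",
    "predict",
]


@dataclass(frozen=True)
class BasilConfig:
    """Tuning parameters of the outer loop.

    batch_m / delta_m default to a data-driven heuristic (see
    :func:`initial_batch_heuristic`) when left at None.  kkt_tolerance is
    relative to lambda * alpha.  lambda_min_ratio defaults to 0.01 when
    p > n and 1e-4 otherwise.
    """

    family: str = "gaussian"
    alpha_mix: float = 1.0
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    batch_m: int | None = None
    delta_m: int | None = None
    lambdas_per_iteration: int = 10
    min_pending: int = 5
    kkt_tolerance: float = 1e-6
    early_stop_patience: int = 2
    early_stopping: bool = True
    max_missing_rate: float = 0.10
    min_maf: float = 0.001
    min_batch: int = 1000
    relaxed: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.batch_m is not None and self.batch_m < 1:
            raise ConfigError("batch_m must be >= 1")
        if self.delta_m is not None and self.delta_m < 1:
            raise ConfigError("delta_m must be >= 1")
        if self.lambdas_per_iteration < 1:
            raise ConfigError("lambdas_per_iteration must be >= 1")
        if not 0.0 < self.alpha_mix <= 1.0:
            raise ConfigError("alpha_mix must lie in (0, 1]")
        if self.family not in fam.VALID_FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}")


@dataclass
class PathState:
    """Bookkeeping carried across outer iterations."""

    iteration: int = 0
    strong_set: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    ever_active: set = field(default_factory=set)
    screen_stats: np.ndarray | None = None
    warm_coef: dict = field(default_factory=dict)   # qc-local index -> coefficient
    warm_cov: np.ndarray | None = None
    warm_intercept: float = 0.0
    pending: list = field(default_factory=list)     # global lambda indices, ascending
    n_extended: int = 0                             # lambdas drawn into Λ so far
    batch_m: int = 0
    n_full_scans: int = 0


@dataclass
class PathSolution:
    """The certified path over the full variant universe.

    coefficients is a CSC matrix (n_variants x n_validated); entries outside
    each lambda's strong set are structurally zero.  validation_metric holds
    R^2 (gaussian), AUC (binomial), or minus the validation partial-likelihood
    deviance (cox); higher is better in all three cases.
    """

    lambda_values: np.ndarray
    lambda_indices: np.ndarray
    coefficients: sparse.csc_matrix
    covariate_coefficients: np.ndarray
    intercepts: np.ndarray
    train_metric: np.ndarray
    validation_metric: np.ndarray | None
    best_index: int | None
    qc_indices: np.ndarray
    impute_values: np.ndarray
    family: str
    alpha_mix: float
    n_full_scans: int
    n_iterations: int
    iteration_log: list
    relaxed_coefficients: sparse.csc_matrix | None = None
    relaxed_covariate_coefficients: np.ndarray | None = None

    @property
    def best_lambda(self) -> float | None:
        return None if self.best_index is None else float(self.lambda_values[self.best_index])


def lambda_sequence(max_abs_gradient: float, L: int, lambda_min_ratio: float) -> np.ndarray:
    """Log-equally-spaced decreasing grid from lambda_max down to its ratio."""
    if max_abs_gradient <= 0:
        raise ValueError("max_abs_gradient must be positive")
    if not 0 < lambda_min_ratio < 1:
        raise ValueError("lambda_min_ratio must lie in (0, 1)")
    return max_abs_gradient * np.logspace(0.0, np.log10(lambda_min_ratio), L)


def screen(gradients: np.ndarray, active_set, M: int) -> np.ndarray:
    """Strong set = active set union the top-M inactive gradient magnitudes.

    Ties in |gradient| break by ascending variant index for determinism.
    Returns sorted indices (positions into the gradient vector).
    """
    if M <= 0:
        raise ConfigError("screening batch size M must be positive")
    gradients = np.asarray(gradients, dtype=np.float64)
    p = gradients.shape[0]
    active = np.fromiter(active_set, dtype=np.int64) if len(active_set) else np.empty(0, np.int64)
    mask = np.ones(p, dtype=bool)
    mask[active] = False
    comp = np.nonzero(mask)[0]
    if comp.size > M:
        # sort by descending magnitude, ascending index on ties
        order = np.lexsort((comp, -gradients[comp]))
        comp = comp[order[:M]]
    return np.sort(np.concatenate([active, comp]))


def _kkt_from_stats(
    stats: np.ndarray, lambdas: np.ndarray, strong_mask: np.ndarray,
    alpha: float, tolerance: float,
):
    """Prefix KKT scan down a lambda batch on a precomputed statistic matrix.

    stats is (p x n_lambda) of per-variant gradient magnitudes (already
    divided by penalty factors).  Returns (index of smallest certified
    lambda or None, {lambda position: violating variant positions sorted by
    magnitude}).
    """
    n_lam = lambdas.shape[0]
    outside = ~strong_mask
    lam_bar = None
    violations: dict[int, np.ndarray] = {}
    for li in range(n_lam):
        thresh = lambdas[li] * alpha * (1.0 + tolerance)
        viol = np.nonzero(outside & (stats[:, li] >= thresh))[0]
        if viol.size:
            violations[li] = viol[np.argsort(-stats[viol, li], kind="stable")]
            break
        lam_bar = li
    return lam_bar, violations


def kkt_check(
    candidate_fits: FitResult,
    store: GenotypeStore,
    strong_set: np.ndarray,
    alpha_mix: float,
    tolerance: float,
    *,
    lambdas: np.ndarray,
    response,
    family: fam.FamilySpec,
    universe: np.ndarray,
    impute_values: np.ndarray,
    sample_indices: np.ndarray | None = None,
    penalty_factor: np.ndarray | None = None,
    chunk_size: int = 512,
):
    """Certify a batch of strong-set solutions against the full universe.

    Runs one inner-product pass of every universe variant against the
    family gradient vectors of the candidate solutions and applies the
    prefix rule: the result is the smallest lambda (position in the batch)
    whose excluded-variant gradients all stay below lambda * alpha, scanning
    down the batch until the first failure.
    """
    G = np.column_stack([
        fam.gradient_vector(family, response, candidate_fits.linear_predictor[:, li])
        for li in range(lambdas.shape[0])
    ])
    stats = np.abs(sparse_inner_products(
        store, G, universe, chunk_size=chunk_size,
        impute_values=impute_values, sample_indices=sample_indices,
    ))
    if penalty_factor is not None:
        pf = np.asarray(penalty_factor, dtype=np.float64)
        with np.errstate(divide="ignore"):
            stats = np.where(pf[:, None] > 0, stats / np.maximum(pf[:, None], 1e-300), 0.0)
    strong_mask = np.zeros(universe.shape[0], dtype=bool)
    pos = {int(v): i for i, v in enumerate(universe)}
    strong_mask[[pos[int(s)] for s in strong_set]] = True
    return _kkt_from_stats(stats, lambdas, strong_mask, alpha_mix, tolerance)


def initial_batch_heuristic(
    store: GenotypeStore,
    r0: np.ndarray,
    lambda_seq: np.ndarray,
    target_index: int = 10,
    *,
    universe: np.ndarray | None = None,
    impute_values: np.ndarray | None = None,
    sample_indices: np.ndarray | None = None,
    min_batch: int = 1000,
) -> int:
    """Strong-rule-guided initial batch size.

    Counts the variants whose screening statistic at the initial residual
    exceeds ``2*lambda_target - lambda_1`` — by the strong rules, roughly
    the set needed to certify the first ``target_index`` lambdas in one
    iteration — then floors the count at ``min_batch`` and caps it at the
    universe size.  ``target_index`` is 1-based along the lambda sequence.
    """
    if universe is None:
        universe = np.arange(store.n_variants)
    n = len(sample_indices) if sample_indices is not None else store.n_samples
    stats = np.abs(sparse_inner_products(
        store, np.asarray(r0, dtype=np.float64)[:, None], universe,
        impute_values=impute_values, sample_indices=sample_indices,
    ))[:, 0] / n
    return _batch_from_stats(stats, lambda_seq, target_index, min_batch)


def _batch_from_stats(stats, lambda_seq, target_index, min_batch) -> int:
    if target_index >= lambda_seq.shape[0]:
        raise ValueError("target_index must be below the sequence length")
    threshold = 2.0 * lambda_seq[target_index - 1] - lambda_seq[0]
    count = int(np.sum(stats > threshold))
    return min(max(count, min_batch), stats.shape[0])


def _slice_response(response, family: fam.FamilySpec, idx: np.ndarray):
    if family.name == "cox":
        return fam.SurvivalResponse(time=response.time[idx], event=response.event[idx])
    return np.asarray(response, dtype=np.float64)[idx]


def _validation_metric(family: fam.FamilySpec, response, eta: np.ndarray) -> float:
    """Higher-is-better model-selection metric on one split."""
    if family.name == "gaussian":
        return met.r_squared(response, eta)
    if family.name == "binomial":
        return met.auc(response, eta)
    return -fam.cox_neg_log_partial_likelihood(response, eta)


def basil_run(
    store: GenotypeStore,
    response,
    covariates: np.ndarray | None,
    config: BasilConfig,
    train_indices: np.ndarray | None = None,
    val_indices: np.ndarray | None = None,
) -> PathSolution:
    """Run the full BASIL loop and return the certified path.

    ``response`` (and ``covariates`` rows) are aligned with the store's
    samples; ``train_indices`` selects the fitting split (default: all
    samples) and ``val_indices`` an optional disjoint validation split used
    for the per-lambda metric and early stopping.  QC statistics and
    imputation means are computed on the training split only and reused for
    validation predictions.
    """
    family = fam.family_spec(config.family)
    n_total = store.n_samples
    if family.name == "cox":
        if len(response) != n_total:
            raise AlignmentError("response length does not match the genotype samples")
    else:
        if np.asarray(response).shape[0] != n_total:
            raise AlignmentError("response length does not match the genotype samples")
    if covariates is not None and np.asarray(covariates).shape[0] != n_total:
        raise AlignmentError("covariate rows do not match the genotype samples")

    if train_indices is None:
        train_idx = np.arange(n_total)
    else:
        train_idx = np.asarray(train_indices, dtype=np.int64)
    val_idx = None if val_indices is None else np.asarray(val_indices, dtype=np.int64)
    if val_idx is not None and np.intersect1d(train_idx, val_idx).size:
        raise AlignmentError("training and validation splits must be disjoint")

    n = train_idx.shape[0]
    y_train = _slice_response(response, family, train_idx)
    Z = None if covariates is None else np.asarray(covariates, dtype=np.float64)
    Z_train = None if Z is None else Z[train_idx]
    y_val = None if val_idx is None else _slice_response(response, family, val_idx)
    Z_val = None if (Z is None or val_idx is None) else Z[val_idx]

    # QC and imputation means on the training split only
    all_idx = np.arange(store.n_variants)
    stats_df = variant_stats(store, all_idx, sample_indices=train_idx)
    qc_idx = qc_filter(stats_df, config.max_missing_rate, config.min_maf)
    if qc_idx.size == 0:
        raise ConvergenceError("no variants pass QC")
    impute_all = stats_df["impute_value"].to_numpy()
    impute_qc = impute_all[qc_idx]
    p = qc_idx.size

    # initial residual from the unpenalized covariate-only model
    cov_fit = covariate_only_fit(Z_train, y_train, family)
    g0 = fam.gradient_vector(family, y_train, cov_fit.eta)

    state = PathState()
    state.warm_cov = cov_fit.coefficients.copy()
    state.warm_intercept = cov_fit.intercept
    iteration_log: list[dict] = []

    def one_pass(G: np.ndarray) -> np.ndarray:
        state.n_full_scans += 1
        return np.abs(sparse_inner_products(
            store, G, qc_idx, impute_values=impute_qc, sample_indices=train_idx,
        ))

    stats0 = one_pass(g0[:, None])[:, 0]
    state.iteration = 1
    lam_max = float(stats0.max()) / config.alpha_mix
    if lam_max <= 0:
        raise ConvergenceError("zero initial gradient; response carries no signal")
    ratio = config.lambda_min_ratio
    if ratio is None:
        if family.name == "cox":
            # the partial likelihood turns ill-conditioned near saturation;
            # survival paths default to a shorter lambda range
            ratio = 0.1
        else:
            ratio = 0.01 if p > n else 1e-4
    lams = lambda_sequence(lam_max, config.n_lambda, ratio)

    if config.batch_m is not None:
        state.batch_m = config.batch_m
    else:
        state.batch_m = _batch_from_stats(stats0, lams, min(10, config.n_lambda - 1),
                                          min(config.min_batch, p))
    delta_m = config.delta_m if config.delta_m is not None else max(state.batch_m // 2, 1)

    state.screen_stats = stats0
    n_first = min(config.lambdas_per_iteration, config.n_lambda)
    state.pending = list(range(n_first))
    state.n_extended = n_first

    # accumulators over certified lambdas
    val_lams: list[int] = []
    coef_cols: list[tuple[np.ndarray, np.ndarray]] = []   # (qc-local idx, values)
    cov_cols: list[np.ndarray] = []
    intercepts: list[float] = []
    train_metrics: list[float] = []
    val_metrics: list[float] = []
    relaxed_cols: list[tuple[np.ndarray, np.ndarray]] = []
    relaxed_cov_cols: list[np.ndarray] = []
    q = 0 if Z_train is None else Z_train.shape[1]

    pending_fit = None   # (FitResult, batch lambda positions, strong set, train block)
    stop = False

    while True:
        if pending_fit is None:
            # very first iteration: the r^(0) pass above was this iteration's scan
            pass
        else:
            fit, batch, S, X_S = pending_fit
            state.iteration += 1
            G = np.column_stack([
                fam.gradient_vector(family, y_train, fit.linear_predictor[:, li])
                for li in range(len(batch))
            ])
            stats = one_pass(G)
            strong_mask = np.zeros(p, dtype=bool)
            strong_mask[S] = True
            lam_bar, _viol = _kkt_from_stats(
                stats, lams[batch], strong_mask, config.alpha_mix, config.kkt_tolerance
            )
            if lam_bar is None:
                # total failure: fall back to the last certified lambda and
                # enlarge the batch; screen_stats still hold that residual
                state.batch_m = min(state.batch_m + delta_m, p)
                iteration_log.append({
                    "iteration": state.iteration, "strong_size": int(S.size),
                    "batch_lambdas": len(batch), "certified": 0,
                    "batch_m": state.batch_m, "fallback": True,
                })
                if state.batch_m >= p and S.size >= p:
                    raise ConvergenceError(
                        "KKT certification failed with the full variant universe "
                        "in the strong set"
                    )
            else:
                certified = batch[: lam_bar + 1]
                for bi, li in enumerate(certified):
                    beta = fit.coefficients[:, bi]
                    nz = np.nonzero(beta)[0]
                    val_lams.append(li)
                    coef_cols.append((S[nz], beta[nz]))
                    state.ever_active.update(int(v) for v in S[nz])
                    cov_cols.append(fit.covariate_coefficients[:, bi])
                    intercepts.append(float(fit.intercept[bi]))
                    train_metrics.append(
                        _validation_metric(family, y_train, fit.linear_predictor[:, bi])
                    )
                    if val_idx is not None:
                        Xv = load_block(store, qc_idx[S[nz]], impute_all[qc_idx[S[nz]]],
                                        val_idx).matrix
                        eta_v = intercepts[-1] + Xv @ beta[nz]
                        if q:
                            eta_v = eta_v + Z_val @ fit.covariate_coefficients[:, bi]
                        val_metrics.append(_validation_metric(family, y_val, eta_v))
                    if config.relaxed and family.name != "cox":
                        X_A = X_S[:, nz]
                        cov_r, act_r = relaxed_refit(X_A, Z_train, y_train, family)
                        relaxed_cols.append((S[nz], act_r))
                        relaxed_cov_cols.append(cov_r)
                bi = lam_bar
                state.screen_stats = stats[:, bi]
                state.warm_coef = {
                    int(j): float(v)
                    for j, v in zip(S, fit.coefficients[:, bi]) if v != 0.0
                }
                state.warm_cov = fit.covariate_coefficients[:, bi].copy()
                state.warm_intercept = float(fit.intercept[bi])
                state.pending = [li for li in state.pending if li not in set(certified)]
                iteration_log.append({
                    "iteration": state.iteration, "strong_size": int(S.size),
                    "batch_lambdas": len(batch), "certified": len(certified),
                    "batch_m": state.batch_m, "fallback": False,
                })
                # extension rule: top up the pending list when it runs short
                while (len(state.pending) < config.min_pending
                       and state.n_extended < config.n_lambda):
                    take = min(config.lambdas_per_iteration,
                               config.n_lambda - state.n_extended)
                    state.pending.extend(range(state.n_extended, state.n_extended + take))
                    state.n_extended += take
                # early stopping on the validation metric
                if (val_idx is not None and config.early_stopping
                        and len(val_metrics) > config.early_stop_patience):
                    best = int(np.argmax(val_metrics))
                    if len(val_metrics) - 1 - best >= config.early_stop_patience:
                        stop = True

        if stop or not state.pending:
            break

        S = screen(state.screen_stats, state.ever_active, state.batch_m)
        batch = sorted(state.pending)[: config.lambdas_per_iteration]
        X_S = load_block(store, qc_idx[S], impute_qc[S], train_idx).matrix
        warm = np.zeros(q + S.size)
        if state.warm_cov is not None:
            warm[:q] = state.warm_cov
        if state.warm_coef:
            pos_in_S = {int(j): i for i, j in enumerate(S)}
            for j, v in state.warm_coef.items():
                warm[q + pos_in_S[j]] = v
        penalty = PenaltySpec(lambda_values=lams[batch], alpha_mix=config.alpha_mix)
        fit = fit_path_on_strong_set(
            X_S, Z_train, y_train, family, penalty,
            warm_start=(warm, state.warm_intercept),
        )
        pending_fit = (fit, batch, S, X_S)

    # assemble the sparse full-universe path
    n_val_lams = len(val_lams)
    order = np.argsort(val_lams)
    rows, cols, vals = [], [], []
    for ci, oi in enumerate(order):
        loc, v = coef_cols[oi]
        rows.extend(qc_idx[loc])
        cols.extend([ci] * len(loc))
        vals.extend(v)
    coef_mat = sparse.csc_matrix(
        (vals, (rows, cols)), shape=(store.n_variants, n_val_lams)
    )
    relaxed_mat = None
    relaxed_cov = None
    if config.relaxed and relaxed_cols:
        r_rows, r_cols, r_vals = [], [], []
        for ci, oi in enumerate(order):
            loc, v = relaxed_cols[oi]
            r_rows.extend(qc_idx[loc])
            r_cols.extend([ci] * len(loc))
            r_vals.extend(v)
        relaxed_mat = sparse.csc_matrix(
            (r_vals, (r_rows, r_cols)), shape=(store.n_variants, n_val_lams)
        )
        relaxed_cov = np.column_stack([relaxed_cov_cols[oi] for oi in order]) \
            if relaxed_cov_cols else None

    vm = np.array([val_metrics[oi] for oi in order]) if val_idx is not None else None
    best = int(np.argmax(vm)) if vm is not None and vm.size else None
    return PathSolution(
        lambda_values=lams[np.array(val_lams)[order]] if n_val_lams else np.empty(0),
        lambda_indices=np.array(val_lams)[order] if n_val_lams else np.empty(0, int),
        coefficients=coef_mat,
        covariate_coefficients=(
            np.column_stack([cov_cols[oi] for oi in order]) if n_val_lams and q
            else np.zeros((q, n_val_lams))
        ),
        intercepts=np.array([intercepts[oi] for oi in order]),
        train_metric=np.array([train_metrics[oi] for oi in order]),
        validation_metric=vm,
        best_index=best,
        qc_indices=qc_idx,
        impute_values=impute_all,
        family=family.name,
        alpha_mix=config.alpha_mix,
        n_full_scans=state.n_full_scans,
        n_iterations=state.iteration,
        iteration_log=iteration_log,
        relaxed_coefficients=relaxed_mat,
        relaxed_covariate_coefficients=relaxed_cov,
    )


def predict(
    solution: PathSolution,
    store_or_block,
    covariates: np.ndarray | None = None,
    lam="best",
    sample_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample prediction at one certified lambda.

    Gaussian returns the linear predictor, binomial the probability, cox
    the relative risk exp(eta).  ``store_or_block`` may be a GenotypeStore
    (active columns are loaded with the training imputation means) or a
    dense matrix over the full variant universe.  ``lam`` is "best", an
    integer position into the certified path, or a lambda value.
    """
    if lam == "best":
        if solution.best_index is None:
            raise ValueError("no validation metric recorded; pass an explicit lambda")
        ci = solution.best_index
    elif isinstance(lam, (int, np.integer)):
        ci = int(lam)
    else:
        match = np.nonzero(np.isclose(solution.lambda_values, lam))[0]
        if match.size == 0:
            raise AlignmentError(f"lambda {lam} is not on the certified path")
        ci = int(match[0])

    beta = solution.coefficients[:, ci]
    active = beta.indices
    vals = beta.data
    if isinstance(store_or_block, GenotypeStore):
        if store_or_block.n_variants != solution.coefficients.shape[0]:
            raise AlignmentError(
                "store variant universe does not match the fitted solution"
            )
        if active.size:
            X = load_block(store_or_block, active, solution.impute_values[active],
                           sample_indices).matrix
        else:
            n_rows = (store_or_block.n_samples if sample_indices is None
                      else len(sample_indices))
            X = np.zeros((n_rows, 0))
    else:
        X = np.asarray(store_or_block, dtype=np.float64)
        if X.shape[1] != solution.coefficients.shape[0]:
            raise AlignmentError("matrix columns do not match the variant universe")
        X = X[:, active] if sample_indices is None else X[np.ix_(sample_indices, active)]
    eta = solution.intercepts[ci] + (X @ vals if active.size else 0.0)
    if covariates is not None and solution.covariate_coefficients.shape[0]:
        Zm = np.asarray(covariates, dtype=np.float64)
        if sample_indices is not None:
            Zm = Zm[sample_indices]
        eta = eta + Zm @ solution.covariate_coefficients[:, ci]
    eta = np.atleast_1d(np.asarray(eta, dtype=np.float64))
    if solution.family == "binomial":
        return 1.0 / (1.0 + np.exp(-eta))
    if solution.family == "cox":
        return np.exp(eta)
    return eta
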