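"""Joint MCMC over DBN parameters and missing values, plus test oracles.

The sampler is a blocked Gibbs scheme whose stationary distribution is
exactly ``exp(log_joint)`` over weights, biases, noise SDs, and the
standardized values of every missing entry (data augmentation — estimation
and imputation happen in one pass):

* weights + bias of each node: exact multivariate-Gaussian full conditional
  (conjugate Bayesian linear regression given the node's noise SD);
* each node's noise SD: univariate slice sampling on log σ, with the
  Exponential prior applied on the natural scale via change of variables;
* the missing entries of each variable: one joint Gaussian block draw.
  Their full-conditional precision couples only day-adjacent entries (the
  lag-1 chain), so the block is sampled exactly with a banded Cholesky.

Two independent oracles validate the sampler: the closed-form conjugate
posterior for fixed noise SDs, and a brute-force grid posterior (missing
entries marginalized by quadrature) for one- or two-parameter restrictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg as sla

from .daily_data import (
    DailySeries,
    STANDARDIZABLE,
    StandardizedSeries,
    check_eligibility,
    standardize,
    summarize_missingness,
)
from .dbn import (
    DBNStructure,
    ModelError,
    NodeSpec,
    PriorConfig,
    default_structure,
    log_joint,
    validate_structure,
    zero_params,
)


class InferenceError(RuntimeError):
    """Ineligible input or a degenerate sampling state."""


@dataclass
class McmcConfig:
    """Sampler settings: 1000 kept draws after 1000 discarded warmup sweeps,
    one chain, by default."""

    n_draws: int = 1000
    n_warmup: int = 1000
    n_chains: int = 1
    seed: int = 0
    sampler: str = "blocked-gibbs"

    def __post_init__(self) -> None:
        if self.n_draws < 1 or self.n_warmup < 0 or self.n_chains < 1:
            raise InferenceError("n_draws >= 1, n_warmup >= 0, n_chains >= 1 required")


@dataclass
class PosteriorDraws:
    """Draw matrix (n_draws × columns) over parameters and imputed values.

    Imputation columns are named ``imp_<var>_<day>`` and exist exactly for
    the missing entries of the fitted series, on the standardized scale.
    ``scales`` echoes the (mean, SD) registry used for internal
    standardization so effects can be mapped back to natural units.
    """

    draws: np.ndarray
    columns: list[str]
    config: McmcConfig
    scales: dict[str, tuple[float, float]]
    structure: DBNStructure
    missing_index: dict[str, np.ndarray]
    participant_id: str = ""
    group: str = ""
    _colmap: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._colmap = {name: i for i, name in enumerate(self.columns)}

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def col(self, name: str) -> np.ndarray:
        return self.draws[:, self._colmap[name]]

    def mean(self, name: str) -> float:
        return float(self.col(name).mean())

    def sd(self, name: str) -> float:
        return float(self.col(name).std(ddof=1))

    def ess(self, name: str) -> float:
        """Effective sample size (bulk ESS)."""
        import arviz as az

        x = self.col(name)
        if np.allclose(x, x[0]):
            return float(len(x))
        return float(az.ess(x.reshape(1, -1)))

    def mcse(self, name: str) -> float:
        """Monte-Carlo standard error of the posterior mean."""
        ess = max(self.ess(name), 1.0)
        return self.sd(name) / math.sqrt(ess)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.draws, columns=self.columns)


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------


def _slice_log_sigma(
    s0: float, n: int, ssr: float, rate: float, rng: np.random.Generator, width: float = 1.0
) -> float:
    """One slice-sampling update of s = log σ.

    Target: −n·s − SSR/(2e^{2s}) − rate·e^s + s (likelihood, Exponential
    prior on σ, and the log-scale Jacobian).
    """

    def logf(s: float) -> float:
        if abs(s) > 40.0:
            return -np.inf
        return -n * s - ssr / (2.0 * math.exp(2.0 * s)) - rate * math.exp(s) + s

    y = logf(s0) - rng.exponential()
    lo = s0 - width * rng.random()
    hi = lo + width
    for _ in range(100):
        if logf(lo) <= y:
            break
        lo -= width
    for _ in range(100):
        if logf(hi) <= y:
            break
        hi += width
    for _ in range(200):
        s1 = rng.uniform(lo, hi)
        if logf(s1) >= y:
            return s1
        if s1 < s0:
            lo = s1
        else:
            hi = s1
    return s0  # pathological shrinkage; keep current state


def _node_design(
    spec: NodeSpec, filled: Mapping[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix (parents + intercept) and response for k = 1..N−1."""
    cols = []
    for p, lag in spec.parents:
        arr = filled[p]
        cols.append(arr[1:] if lag == 0 else arr[:-1])
    cols.append(np.ones(len(filled[spec.name]) - 1))
    return np.column_stack(cols), filled[spec.name][1:]


def _sample_node_coeffs(
    spec: NodeSpec,
    filled: dict[str, np.ndarray],
    params: dict[str, float],
    priors: PriorConfig,
    fixed: Mapping[str, float],
    rng: np.random.Generator,
) -> None:
    names = list(spec.weight_names) + [spec.bias_name]
    X, y = _node_design(spec, filled)
    free = [i for i, nm in enumerate(names) if nm not in fixed]
    if not free:
        return
    fixed_idx = [i for i in range(len(names)) if i not in free]
    if fixed_idx:
        y = y - X[:, fixed_idx] @ np.array([params[names[i]] for i in fixed_idx])
        X = X[:, free]
    sigma2 = params[spec.noise_sd_name] ** 2
    mu0 = np.array([priors.normal(names[i])[0] for i in free])
    prec0 = np.array([1.0 / priors.normal(names[i])[1] ** 2 for i in free])
    A = (X.T @ X) / sigma2
    A[np.diag_indices_from(A)] += prec0
    rhs = prec0 * mu0 + (X.T @ y) / sigma2
    L = np.linalg.cholesky(A)
    mean = sla.cho_solve((L, True), rhs)
    beta = mean + sla.solve_triangular(L.T, rng.standard_normal(len(free)), lower=False)
    for i, val in zip(free, beta):
        params[names[i]] = float(val)


def _sample_noise_sd(
    spec: NodeSpec,
    filled: dict[str, np.ndarray],
    params: dict[str, float],
    priors: PriorConfig,
    rng: np.random.Generator,
) -> None:
    X, y = _node_design(spec, filled)
    coeffs = np.array([params[w] for w in spec.weight_names] + [params[spec.bias_name]])
    resid = y - X @ coeffs
    ssr = float(resid @ resid)
    s = _slice_log_sigma(
        math.log(params[spec.noise_sd_name]), len(y), ssr, priors.rate(spec.noise_sd_name), rng
    )
    params[spec.noise_sd_name] = math.exp(s)


def _missing_occurrences(
    structure: DBNStructure, var: str
) -> list[tuple[str, list[tuple[int, str | None]]]]:
    """For each node, where ``var`` enters its transition term.

    Each occurrence is (lag, weight_name) with weight_name None for the
    response itself (coefficient +1).  Bandwidth-1 structure is asserted:
    within any one node, occurrences of ``var`` may span at most one lag.
    """
    out = []
    for name, spec in structure.nodes.items():
        occ: list[tuple[int, str | None]] = []
        if name == var:
            occ.append((0, None))
        for (p, lag), wname in zip(spec.parents, spec.weight_names):
            if p == var:
                occ.append((lag, wname))
        if occ:
            lags = [l for l, _ in occ]
            if max(lags) - min(lags) > 1 or len(lags) != len(set(lags)) and name != var:
                raise ModelError(
                    f"{var} enters {name} at incompatible lags for block imputation"
                )
            out.append((name, occ))
    return out


def _sample_missing_block(
    var: str,
    miss: np.ndarray,
    occurrences: list[tuple[str, list[tuple[int, str | None]]]],
    filled: dict[str, np.ndarray],
    params: dict[str, float],
    structure: DBNStructure,
    rng: np.random.Generator,
) -> None:
    """Exact joint Gaussian draw of all missing entries of ``var``.

    Builds the full-vector canonical form (banded precision Q, linear term
    h) of the joint as a function of the variable's series, conditions on
    its observed entries, and samples the missing block via a tridiagonal
    Cholesky.  Day-0 entries carry the standard-normal initial prior.
    """
    n = len(filled[var])
    diag = np.zeros(n)
    off = np.zeros(n - 1)
    h = np.zeros(n)
    diag[0] += 1.0  # N(0,1) prior on a day-0 imputation (row unused when observed)

    for node_name, occ in occurrences:
        spec = structure.node(node_name)
        sig2 = params[spec.noise_sd_name] ** 2
        # rest of the residual, excluding every term that involves `var`
        rest = np.zeros(n - 1)
        if node_name != var:
            rest += filled[node_name][1:]
        rest -= params[spec.bias_name]
        for (p, lag), wname in zip(spec.parents, spec.weight_names):
            if p == var:
                continue
            arr = filled[p]
            rest -= params[wname] * (arr[1:] if lag == 0 else arr[:-1])
        rho = -rest
        coefs = [(lag, 1.0 if wname is None else -params[wname]) for lag, wname in occ]
        for i, (lag_i, a_i) in enumerate(coefs):
            sl_i = slice(1, n) if lag_i == 0 else slice(0, n - 1)
            h[sl_i] += a_i * rho / sig2
            for lag_j, a_j in coefs[i:]:
                w = a_i * a_j / sig2
                if lag_i == lag_j:
                    diag[sl_i] += w
                else:  # |Δlag| == 1 couples days (k, k−1)
                    off[: n - 1] += w
    x_obs = np.where(miss, 0.0, filled[var])
    qx = diag * x_obs
    qx[:-1] += off * x_obs[1:]
    qx[1:] += off * x_obs[:-1]
    r = h - qx

    idx = np.flatnonzero(miss)
    m = len(idx)
    dm = diag[idx]
    if np.any(dm <= 0):
        raise InferenceError(f"degenerate imputation precision for {var}")
    ab = np.zeros((2, m))
    ab[1] = dm
    if m > 1:
        adjacent = np.diff(idx) == 1
        ab[0, 1:] = np.where(adjacent, off[idx[:-1]], 0.0)
    cb = sla.cholesky_banded(ab, lower=False)
    mean = sla.cho_solve_banded((cb, False), r[idx])
    draw = mean + sla.solve_banded((0, 1), cb, rng.standard_normal(m))
    filled[var][idx] = draw


def fit_participant(
    series: DailySeries,
    structure: DBNStructure | None = None,
    priors: PriorConfig | None = None,
    cfg: McmcConfig | None = None,
    *,
    fixed_params: Mapping[str, float] | None = None,
    skip_eligibility: bool = False,
) -> PosteriorDraws:
    """Joint posterior over DBN parameters and missing standardized values.

    Standardizes the series internally (observed-data moments, recorded for
    back-transforms), then runs the blocked Gibbs sampler.  ``fixed_params``
    pins named parameters (including noise SDs) at given values — they are
    conditioned on rather than sampled, which is how the conjugate-oracle
    comparisons are run.  Deterministic for a given config seed.
    """
    structure = structure or default_structure()
    violations = validate_structure(structure)
    if violations:
        raise ModelError("; ".join(violations))
    priors = priors or PriorConfig()
    cfg = cfg or McmcConfig()
    fixed = dict(fixed_params or {})

    if not skip_eligibility:
        elig = check_eligibility(summarize_missingness(series))
        if not elig.eligible:
            raise InferenceError("ineligible series: " + "; ".join(elig.reasons))

    std = standardize(series)
    filled = {k: v.copy() for k, v in std.values.items()}
    missing_index: dict[str, np.ndarray] = {}
    for var in structure.nodes:
        mask = np.isnan(filled[var])
        if mask.any():
            missing_index[var] = np.flatnonzero(mask)
            filled[var][mask] = 0.0  # prior-typical initialization
    for var in structure.exogenous:
        if np.isnan(filled[var]).any():
            raise InferenceError(f"exogenous variable {var} has missing entries")

    params = zero_params(structure)
    params.update(fixed)
    masks = {var: np.isnan(std.values[var]) for var in missing_index}
    occurrences = {var: _missing_occurrences(structure, var) for var in missing_index}

    param_names = structure.parameter_names()
    imp_names = [f"imp_{var}_{k}" for var in missing_index for k in missing_index[var]]
    columns = param_names + imp_names
    out = np.empty((cfg.n_draws, len(columns)))

    rng = np.random.default_rng(cfg.seed)
    total_sweeps = cfg.n_warmup + cfg.n_draws
    specs = list(structure.nodes.values())
    for sweep in range(total_sweeps):
        for spec in specs:
            _sample_node_coeffs(spec, filled, params, priors, fixed, rng)
            if spec.noise_sd_name not in fixed:
                _sample_noise_sd(spec, filled, params, priors, rng)
        for var in missing_index:
            _sample_missing_block(
                var, masks[var], occurrences[var], filled, params, structure, rng
            )
        if sweep >= cfg.n_warmup:
            row = sweep - cfg.n_warmup
            out[row, : len(param_names)] = [params[nm] for nm in param_names]
            pos = len(param_names)
            for var in missing_index:
                idx = missing_index[var]
                out[row, pos : pos + len(idx)] = filled[var][idx]
                pos += len(idx)

    return PosteriorDraws(
        draws=out,
        columns=columns,
        config=cfg,
        scales=std.scales,
        structure=structure,
        missing_index=missing_index,
        participant_id=series.participant_id,
        group=series.group,
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def conjugate_posterior_oracle(
    design: np.ndarray,
    response: np.ndarray,
    noise_sd: float,
    prior_mean: np.ndarray | float = 0.0,
    prior_sd: np.ndarray | float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Gaussian posterior for linear regression with known noise SD.

    Posterior precision = prior precision + XᵀX/σ²; posterior mean =
    covariance × (prior precision·prior mean + Xᵀy/σ²).  Returns
    (mean vector, covariance matrix).
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(response, dtype=float)
    if noise_sd <= 0:
        raise InferenceError("noise_sd must be positive")
    p = X.shape[1] if X.size else len(np.atleast_1d(prior_mean))
    mu0 = np.broadcast_to(np.asarray(prior_mean, dtype=float), (p,)).copy()
    sd0 = np.broadcast_to(np.asarray(prior_sd, dtype=float), (p,)).copy()
    prec = np.diag(1.0 / sd0**2)
    if X.size:
        prec = prec + (X.T @ X) / noise_sd**2
        rhs = mu0 / sd0**2 + (X.T @ y) / noise_sd**2
    else:
        rhs = mu0 / sd0**2
    cov = np.linalg.inv(prec)
    return cov @ rhs, cov


@dataclass
class GridPosterior:
    """Normalized posterior over one or two parameters on a dense grid."""

    names: list[str]
    grids: list[np.ndarray]
    probs: np.ndarray  # 1-D or 2-D, sums to 1

    def marginal(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.names.index(name)
        if self.probs.ndim == 1:
            return self.grids[0], self.probs
        return self.grids[i], self.probs.sum(axis=1 - i)


def grid_posterior_oracle(
    series: DailySeries,
    structure: DBNStructure,
    priors: PriorConfig,
    free: Mapping[str, np.ndarray],
    fixed: Mapping[str, float],
    missing_grid: np.ndarray | None = None,
) -> GridPosterior:
    """Brute-force posterior on a grid, for sampler validation.

    At most two free parameters; every other parameter is pinned by
    ``fixed``.  Missing entries (at most two) are marginalized by quadrature
    over ``missing_grid`` (default: 161 points on [−6, 6] standardized).
    Evaluates ``log_joint`` pointwise — fully independent of the sampler.
    """
    if len(free) not in (1, 2):
        raise InferenceError("grid oracle supports 1 or 2 free parameters")
    std = standardize(series)
    data = std.values
    missing = [
        (var, int(k))
        for var in structure.nodes
        for k in np.flatnonzero(np.isnan(data[var]))
    ]
    if len(missing) > 2:
        raise InferenceError("grid oracle supports at most 2 missing entries")
    if missing_grid is None:
        missing_grid = np.linspace(-6.0, 6.0, 161)

    names = list(free)
    grids = [np.asarray(free[nm], dtype=float) for nm in names]
    shape = tuple(len(g) for g in grids)
    logp = np.empty(shape)

    miss_combos: list[dict[tuple[str, int], float]]
    if not missing:
        miss_combos = [{}]
    elif len(missing) == 1:
        miss_combos = [{missing[0]: v} for v in missing_grid]
    else:
        miss_combos = [
            {missing[0]: v0, missing[1]: v1} for v0 in missing_grid for v1 in missing_grid
        ]

    from scipy.special import logsumexp

    base = dict(fixed)
    for index in np.ndindex(*shape):
        for nm, g, i in zip(names, grids, index):
            base[nm] = float(g[i])
        vals = np.array(
            [log_joint(structure, priors, data, base, imputed=c) for c in miss_combos]
        )
        logp[index] = logsumexp(vals)
    logp -= logp.max()
    probs = np.exp(logp)
    total = probs.sum()
    if not np.isfinite(total) or total <= 0:
        raise InferenceError("grid too coarse to normalize")
    probs /= total
    return GridPosterior(names=names, grids=grids, probs=probs)


def grid_tv_distance(grid_post: GridPosterior, name: str, draws: np.ndarray) -> float:
    """Total variation distance between sampler draws (binned on the grid's
    cells) and the grid posterior's marginal."""
    grid, probs = grid_post.marginal(name)
    edges = np.concatenate(([-np.inf], 0.5 * (grid[1:] + grid[:-1]), [np.inf]))
    counts, _ = np.histogram(draws, bins=edges)
    q = counts / counts.sum()
    return 0.5 * float(np.abs(probs - q).sum())
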