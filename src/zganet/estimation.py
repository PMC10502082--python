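"""Maximum-likelihood fitting with multi-start optimization and profile likelihood.

All free parameters are optimized on the log10 scale, which enforces
positivity and lets a single box cover several orders of magnitude.  The data
term is a Gaussian -2 log-likelihood with an absolute (additive) error model
per observable; observation scales sigma can be fixed, estimated as free
parameters alongside the kinetics, or concentrated out analytically (the
closed-form joint-ML value per observable).  A weak L2 prior on the log10
parameters, (log10 theta / 3)^2 per parameter, discourages solutions more
than ~3 decades from 1 while leaving the data term dominant; profiles are
computed on the pure data objective so confidence intervals stay data-based.

Optimization runs a deterministic multi-start: starting points are sampled
uniformly in the log10 box from a seeded generator and each start is refined
with a bounded quasi-Newton optimizer (L-BFGS-B).  Converged objectives
sorted ascending form the waterfall; the size of the cluster within a small
tolerance of the best value indicates how reproducibly the optimum is found.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "ObjectiveSpec",
    "FitResult",
    "FitCollection",
    "ProfileResult",
    "neg2_loglik",
    "l2_prior_penalty",
    "multistart_fit",
    "profile_likelihood",
    "CHI2_95_1DF",
]

#: 95% chi-square threshold with one degree of freedom, used for profile CIs
CHI2_95_1DF = 3.841458820694124

LOG2PI = float(np.log(2.0 * np.pi))


def neg2_loglik(predictions, data, sigmas) -> float:
    """-2 log L of aligned predictions under the absolute Gaussian error model.

    ``sigmas`` is either a scalar or an array aligned with the data points
    (one value per point, typically constant within an observable).  Returns
    sum over points of (y - yhat)^2 / sigma^2 + log(2 pi sigma^2).
    """
    predictions = np.asarray(predictions, dtype=float)
    data = np.asarray(data, dtype=float)
    if predictions.shape != data.shape:
        raise ValueError("predictions and data are not aligned")
    sigmas = np.broadcast_to(np.asarray(sigmas, dtype=float), data.shape)
    if np.any(sigmas <= 0):
        raise ValueError("sigmas must be positive")
    r = (data - predictions) / sigmas
    return float(np.sum(r * r) + np.sum(LOG2PI + 2.0 * np.log(sigmas)))


def concentrated_neg2_loglik(predictions, data, groups, sigma_floor: float = 1e-8):
    """-2 log L with per-group sigma at its analytic joint-ML value.

    ``groups`` assigns each point to an observable; sigma_hat_o^2 is the mean
    squared residual of group o (floored to keep the objective finite on
    noise-free data).  Returns (value, {group: sigma_hat}).
    """
    predictions = np.asarray(predictions, dtype=float)
    data = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    value = 0.0
    sig = {}
    for g in np.unique(groups):
        m = groups == g
        res = data[m] - predictions[m]
        n = res.size
        s2 = max(float(np.mean(res * res)), sigma_floor**2)
        value += n * (np.log(2.0 * np.pi * s2) + float(np.sum(res * res)) / (n * s2))
        sig[g] = float(np.sqrt(s2))
    return float(value), sig


def l2_prior_penalty(params_log10, scale: float = 3.0) -> float:
    """Weak L2 prior on log10 parameters: sum of (log10 theta / scale)^2.

    A parameter three orders of magnitude from 1 contributes exactly one
    to the objective at the default scale of 3.
    """
    v = np.asarray(params_log10, dtype=float)
    return float(np.sum((v / scale) ** 2))


@dataclass
class ObjectiveSpec:
    """A -2 log L objective over named log10-transformed parameters.

    ``fn`` maps a log10 parameter vector to the data term (-2 log L).  When
    ``include_prior`` is set the L2 prior is added over the parameters
    selected by ``prior_mask`` (default: all).
    """

    fn: Callable[[np.ndarray], float]
    param_names: Sequence[str]
    include_prior: bool = True
    prior_scale: float = 3.0
    prior_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be positive")
        names = list(self.param_names)
        if len(set(names)) != len(names):
            raise ValueError("free parameters must appear exactly once")
        self.param_names = names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def prior(self, theta_log10: np.ndarray) -> float:
        v = np.asarray(theta_log10, dtype=float)
        if self.prior_mask is not None:
            v = v[np.asarray(self.prior_mask, dtype=bool)]
        return l2_prior_penalty(v, self.prior_scale)

    def value(self, theta_log10, with_prior: bool | None = None) -> float:
        theta_log10 = np.asarray(theta_log10, dtype=float)
        val = float(self.fn(theta_log10))
        use_prior = self.include_prior if with_prior is None else with_prior
        if use_prior:
            val += self.prior(theta_log10)
        return val


@dataclass
class FitResult:
    start_index: int
    start_log10: np.ndarray
    params_log10: np.ndarray
    objective: float
    converged: bool
    grad_norm: float
    n_evals: int

    @property
    def params(self) -> np.ndarray:
        return 10.0 ** np.asarray(self.params_log10)


@dataclass
class FitCollection:
    objective_spec: ObjectiveSpec
    results: list[FitResult]
    cluster_tol: float = 0.01
    bounds: list | None = None

    @property
    def finished(self) -> list[FitResult]:
        return [r for r in self.results if np.isfinite(r.objective)]

    @property
    def best(self) -> FitResult:
        finished = self.finished
        if not finished:
            raise RuntimeError("all optimization starts failed")
        return min(finished, key=lambda r: r.objective)

    @property
    def waterfall(self) -> np.ndarray:
        """Objectives of converged runs sorted ascending (all finished runs
        when no run passed the strict convergence check)."""
        conv = [r.objective for r in self.finished if r.converged]
        if not conv:
            conv = [r.objective for r in self.finished]
        return np.sort(np.asarray(conv, dtype=float))

    @property
    def cluster_size(self) -> int:
        w = self.waterfall
        return int(np.sum(w <= w[0] + self.cluster_tol))

    def to_frame(self):
        import pandas as pd

        rows = []
        for r in self.results:
            row = {"start": r.start_index, "objective": r.objective, "converged": r.converged, "grad_norm": r.grad_norm}
            for name, v in zip(self.objective_spec.param_names, r.params_log10):
                row[f"log10_{name}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def _safe_objective(f):
    def wrapped(x):
        try:
            v = f(x)
        except (FloatingPointError, OverflowError, ValueError, RuntimeError):
            return 1e12
        if not np.isfinite(v):
            return 1e12
        return v

    return wrapped


def multistart_fit(
    objective: ObjectiveSpec,
    n_starts: int,
    start_box=(-3.0, 3.0),
    seed: int = 0,
    bounds=None,
    grad_tol: float = 1e-4,
    cluster_tol: float = 0.01,
    maxiter: int = 300,
    fd_eps: float = 1e-6,
    extra_starts=None,
) -> FitCollection:
    """Deterministic multi-start local optimization in log10 parameter space.

    Start points are drawn uniformly inside ``start_box`` (scalar pair or
    per-parameter array of shape (n, 2)) by a generator seeded with ``seed``,
    so identical seeds give bit-identical starts and waterfalls.  ``bounds``
    defaults to the start box.  ``extra_starts`` prepends caller-chosen
    points (e.g. a previous optimum for warm starts).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    n = objective.n_params
    box = np.asarray(start_box, dtype=float)
    if box.ndim == 1:
        box = np.tile(box, (n, 1))
    if box.shape != (n, 2) or np.any(~np.isfinite(box)):
        raise ValueError("start_box must be finite and match the parameter count")
    rng = np.random.default_rng(seed)
    starts = rng.uniform(box[:, 0], box[:, 1], size=(n_starts, n))
    if extra_starts is not None:
        extra = np.atleast_2d(np.asarray(extra_starts, dtype=float))
        starts = np.vstack([extra, starts])
    if bounds is None:
        bounds = [tuple(b) for b in box]

    f = _safe_objective(lambda x: objective.value(x))
    results: list[FitResult] = []
    for i, x0 in enumerate(starts):
        res = minimize(
            f,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9, "eps": fd_eps},
        )
        grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.inf
        converged = bool(res.success) and np.isfinite(res.fun) and grad_norm < grad_tol
        results.append(
            FitResult(
                start_index=i,
                start_log10=np.asarray(x0, dtype=float),
                params_log10=np.asarray(res.x, dtype=float),
                objective=float(res.fun),
                converged=converged,
                grad_norm=grad_norm,
                n_evals=int(res.nfev),
            )
        )
    coll = FitCollection(objective, results, cluster_tol=cluster_tol, bounds=list(bounds))
    coll.best  # raises if everything failed
    return coll


@dataclass
class ProfileResult:
    param_name: str
    grid: np.ndarray
    profile: np.ndarray  # data-term objective re-optimized at each grid value
    mle_value: float  # log10 of the parameter at the best fit
    best_objective: float  # data-term objective at the best fit
    ci_lower: float  # log10 scale; -inf when the lower crossing was not found
    ci_upper: float
    threshold: float = CHI2_95_1DF
    failed_points: list[int] = field(default_factory=list)

    @property
    def identifiable(self) -> bool:
        return np.isfinite(self.ci_lower) and np.isfinite(self.ci_upper)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"param": self.param_name, "log10_value": self.grid, "objective": self.profile})


def _reoptimize_fixed(objective: ObjectiveSpec, fixed_index: int, fixed_value: float, x_init: np.ndarray, bounds, maxiter: int, fd_eps: float):
    """Minimize the pure data term over all parameters except one held fixed."""
    free_idx = [i for i in range(objective.n_params) if i != fixed_index]

    def assemble(xf):
        full = np.empty(objective.n_params)
        full[fixed_index] = fixed_value
        full[free_idx] = xf
        return full

    if not free_idx:
        return float(_safe_objective(lambda x: objective.value(x, with_prior=False))(np.array([fixed_value]))), x_init
    f = _safe_objective(lambda xf: objective.value(assemble(xf), with_prior=False))
    sub_bounds = [bounds[i] for i in free_idx] if bounds is not None else None
    res = minimize(
        f,
        x_init[free_idx],
        method="L-BFGS-B",
        bounds=sub_bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9, "eps": fd_eps},
    )
    return float(res.fun), assemble(res.x)


def profile_likelihood(
    fit: FitCollection,
    param: str,
    grid_spec=None,
    threshold: float = CHI2_95_1DF,
    maxiter: int = 200,
    fd_eps: float = 1e-6,
    flat_tol: float = 1e-6,
) -> ProfileResult:
    """Profile the data-term objective along one parameter.

    At each grid value the parameter is fixed and all others re-optimized
    (prior excluded); the 95% confidence interval collects the values where
    the profile stays within ``threshold`` (chi-square 3.84 by default) of
    its minimum.  Both crossings inside the scanned range make the parameter
    identifiable.  ``grid_spec`` is (lo, hi, n) on the log10 scale; by
    default the scan covers MLE +/- 2 decades with 41 points.
    """
    objective = fit.objective_spec
    names = list(objective.param_names)
    if param not in names:
        raise KeyError(f"unknown parameter {param!r}")
    j = names.index(param)
    best = fit.best
    x_best = np.asarray(best.params_log10, dtype=float)
    bounds = fit.bounds
    base = objective.value(x_best, with_prior=False)
    # re-polish the data-only objective around the (possibly prior-shifted) MLE
    base, x_base = _reoptimize_fixed(objective, j, x_best[j], x_best, bounds, maxiter, fd_eps)

    if grid_spec is None:
        lo, hi, npts = x_best[j] - 2.0, x_best[j] + 2.0, 41
    else:
        lo, hi, npts = grid_spec
    grid = np.linspace(float(lo), float(hi), int(npts))

    profile = np.empty_like(grid)
    failed: list[int] = []
    # scan outward from the closest grid point with warm starts
    j0 = int(np.argmin(np.abs(grid - x_best[j])))
    for order in (range(j0, grid.size), range(j0 - 1, -1, -1)):
        x_init = x_base.copy()
        for k in order:
            try:
                val, x_opt = _reoptimize_fixed(objective, j, grid[k], x_init, bounds, maxiter, fd_eps)
                profile[k] = val
                x_init = x_opt
            except Exception:
                profile[k] = np.nan
                failed.append(k)

    finite = np.isfinite(profile)
    pmin = float(np.nanmin(profile)) if finite.any() else base
    pmin = min(pmin, base)

    def crossing(side: int) -> float:
        """Interpolated log10 value where the profile crosses pmin+threshold."""
        ks = range(j0, grid.size) if side > 0 else range(j0, -1, -1)
        prev_k = None
        for k in ks:
            if not np.isfinite(profile[k]):
                continue
            if profile[k] > pmin + threshold:
                if prev_k is None:
                    return grid[k]
                # linear interpolation between prev_k and k
                y0, y1 = profile[prev_k] - pmin, profile[k] - pmin
                frac = (threshold - y0) / (y1 - y0)
                return float(grid[prev_k] + frac * (grid[k] - grid[prev_k]))
            prev_k = k
        return np.inf * side

    span = float(np.nanmax(profile) - pmin) if finite.any() else 0.0
    if span < flat_tol:
        # structurally flat direction: no information about this parameter
        return ProfileResult(param, grid, profile, x_best[j], base, -np.inf, np.inf, threshold, failed)
    return ProfileResult(param, grid, profile, x_best[j], pmin, crossing(-1), crossing(+1), threshold, failed)
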