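"""Builders turning a model + dataset into an ObjectiveSpec for fitting.

Datasets are tidy long-format tables: core data has columns
(observable, genotype, time, replicate, value); per-gene target data has
(condition, time, replicate, value).  Observation scales can be fixed,
estimated as extra free parameters (``sigma_<obs>``), or concentrated out
analytically per observable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_model import CoreModelSpec, GenotypeFlags, simulate_core
from .estimation import ObjectiveSpec, concentrated_neg2_loglik, neg2_loglik
from .mini_models import InputCurves, MiniModelParams, RegulationScenario

__all__ = ["build_core_objective", "build_mini_objective", "mini_param_names"]


def build_core_objective(
    model: CoreModelSpec,
    dataset: pd.DataFrame,
    free_params: list[str],
    sigma_mode: str = "concentrated",
    sigmas=1.0,
    include_prior: bool = True,
    prior_scale: float = 3.0,
    rtol: float = 1e-7,
    atol: float = 1e-9,
    sigma_floor: float = 1e-8,
) -> ObjectiveSpec:
    """-2 log L objective of the core model against a time-course table.

    ``free_params`` are optimized on the log10 scale; all other model
    parameters stay at their values in ``model.params``.  With
    ``sigma_mode="free"`` one ``sigma_<observable>`` parameter per observed
    transcript is appended to the search vector.
    """
    required = {"observable", "genotype", "time", "value"}
    if not required <= set(dataset.columns):
        raise ValueError(f"dataset must have columns {sorted(required)}")
    for p in free_params:
        if p not in model.params:
            raise KeyError(f"unknown model parameter {p!r}")
    if sigma_mode not in ("fixed", "free", "concentrated"):
        raise ValueError("sigma_mode must be fixed, free or concentrated")

    df = dataset.reset_index(drop=True)
    genotypes = [GenotypeFlags.from_label(g) for g in df["genotype"].unique()]
    times = np.sort(df["time"].unique())
    obs_names = list(df["observable"].unique())
    # index map row -> (genotype, observable, time)
    t_pos = {t: i for i, t in enumerate(times)}
    row_geno = df["genotype"].to_numpy()
    row_obs = df["observable"].to_numpy()
    row_t = np.array([t_pos[t] for t in df["time"]])
    values = df["value"].to_numpy(dtype=float)

    names = list(free_params)
    if sigma_mode == "free":
        names = names + [f"sigma_{o}" for o in obs_names]
    n_kin = len(free_params)

    if sigma_mode == "fixed":
        if np.isscalar(sigmas):
            sigma_by_obs = {o: float(sigmas) for o in obs_names}
        else:
            sigma_by_obs = {o: float(sigmas[o]) for o in obs_names}
        row_sigma = np.array([sigma_by_obs[o] for o in row_obs])

    def predict(theta_kin: np.ndarray) -> np.ndarray:
        m = model.with_params(**{p: 10.0**v for p, v in zip(free_params, theta_kin)})
        pred = np.empty(len(df))
        for g in genotypes:
            traj = simulate_core(m, g, times, rtol=rtol, atol=atol)
            mask = row_geno == g.label()
            for oi, oname in enumerate(traj.observable_names):
                sel = mask & (row_obs == oname)
                if sel.any():
                    pred[sel] = traj.observables[oi][row_t[sel]]
        return pred

    def fn(theta: np.ndarray) -> float:
        pred = predict(theta[:n_kin])
        if sigma_mode == "fixed":
            return neg2_loglik(pred, values, row_sigma)
        if sigma_mode == "free":
            sig = {o: 10.0 ** theta[n_kin + i] for i, o in enumerate(obs_names)}
            return neg2_loglik(pred, values, np.array([sig[o] for o in row_obs]))
        val, _ = concentrated_neg2_loglik(pred, values, row_obs, sigma_floor=sigma_floor)
        return val

    spec = ObjectiveSpec(fn=fn, param_names=names, include_prior=include_prior, prior_scale=prior_scale)
    spec.predict = predict  # type: ignore[attr-defined]
    return spec


def mini_param_names(scenario: RegulationScenario, sigma_mode: str = "concentrated") -> list[str]:
    names = ["v", *scenario.free_thresholds(), "d"]
    if sigma_mode == "free":
        names.append("sigma")
    return names


def _params_from_theta(scenario: RegulationScenario, theta: np.ndarray, h: float) -> MiniModelParams:
    ks = scenario.free_thresholds()
    kw = {}
    for i, name in enumerate(ks, start=1):
        kw[{"K_P": "K_P", "K_N": "K_N", "K_SOX": "K_S"}[name]] = 10.0 ** theta[i]
    return MiniModelParams(v=10.0 ** theta[0], d=10.0 ** theta[1 + len(ks)], h=h, **kw)


def build_mini_objective(
    scenario: RegulationScenario,
    inputs: InputCurves,
    gene_data: pd.DataFrame,
    sigma_mode: str = "concentrated",
    sigma: float = 1.0,
    include_prior: bool = True,
    prior_scale: float = 3.0,
    sigma_floor: float = 1e-8,
) -> ObjectiveSpec:
    """-2 log L objective of one regulatory scenario for one target gene.

    Free parameters: synthesis rate v, one Hill threshold per regulated
    factor, degradation rate d (and sigma when ``sigma_mode="free"``); the
    Hill coefficient is fixed at the input set's h.  The same ODE is used in
    every condition; conditions differ only through the input curves.
    """
    required = {"condition", "time", "value"}
    if not required <= set(gene_data.columns):
        raise ValueError(f"gene_data must have columns {sorted(required)}")
    missing = set(gene_data["condition"].unique()) - set(inputs.conditions)
    if missing:
        raise KeyError(f"no input curves for conditions {sorted(missing)}")

    df = gene_data.reset_index(drop=True)
    values = df["value"].to_numpy(dtype=float)
    conds = list(df["condition"].unique())
    cond_rows = {c: df.index[df["condition"] == c].to_numpy() for c in conds}
    cond_times = {c: df.loc[rows, "time"].to_numpy(dtype=float) for c, rows in cond_rows.items()}

    names = mini_param_names(scenario, sigma_mode)
    n_kin = len(names) - (1 if sigma_mode == "free" else 0)

    # stacked precomputations: x^h per factor over (condition, dense time),
    # plus linear-interpolation indices/weights from the dense grid to the
    # observed times -- the per-evaluation work is then a handful of
    # vectorized array operations and one IIR filter call
    from scipy.signal import lfilter

    t_dense = inputs.t_dense
    dt = float(t_dense[1] - t_dense[0])
    if not np.allclose(np.diff(t_dense), dt):
        raise ValueError("input curves must be on a uniform dense grid")
    h = inputs.h
    factors = [f for f, s in zip(("P", "N", "SOX"), scenario.signs) if s != 0]
    signs = {f: s for f, s in zip(("P", "N", "SOX"), scenario.signs)}
    xh = {f: np.stack([inputs._pow[c][f] for c in conds]) for f in factors}
    idx0, idx1, w1, row_of = [], [], [], []
    for ci, c in enumerate(conds):
        pos = np.clip(np.searchsorted(t_dense, cond_times[c], side="right") - 1, 0, t_dense.size - 2)
        frac = (cond_times[c] - t_dense[pos]) / dt
        idx0.append(pos)
        idx1.append(pos + 1)
        w1.append(frac)
        row_of.append(cond_rows[c])

    def predict(theta_kin: np.ndarray) -> np.ndarray:
        v = 10.0 ** theta_kin[0]
        d = max(10.0 ** theta_kin[1 + len(factors)], 1e-12)
        a = np.full((len(conds), t_dense.size), v)
        for i, f in enumerate(factors):
            Kh = (10.0 ** theta_kin[1 + i]) ** h
            if signs[f] > 0:
                a *= xh[f] / (Kh + xh[f])
            else:
                a *= Kh / (Kh + xh[f])
        e = np.exp(-d * dt)
        b = (0.5 * (a[:, 1:] + a[:, :-1]) / d) * (1.0 - e)
        T = np.empty_like(a)
        T[:, 0] = 0.0
        T[:, 1:] = lfilter([1.0], [1.0, -e], b, axis=1)
        pred = np.empty(len(df))
        for ci in range(len(conds)):
            Tc = T[ci]
            pred[row_of[ci]] = Tc[idx0[ci]] * (1.0 - w1[ci]) + Tc[idx1[ci]] * w1[ci]
        return pred

    def fn(theta: np.ndarray) -> float:
        pred = predict(theta[:n_kin])
        if sigma_mode == "fixed":
            return neg2_loglik(pred, values, sigma)
        if sigma_mode == "free":
            return neg2_loglik(pred, values, 10.0 ** theta[n_kin])
        val, _ = concentrated_neg2_loglik(pred, values, np.zeros(len(df), dtype=int), sigma_floor=sigma_floor)
        return val

    spec = ObjectiveSpec(fn=fn, param_names=names, include_prior=include_prior, prior_scale=prior_scale)
    spec.predict = predict  # type: ignore[attr-defined]
    spec.scenario = scenario  # type: ignore[attr-defined]
    return spec
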