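"""Single-ODE mini models of target-gene regulation by Pou5f3, Nanog and SOX.

Each zygotic target is described by one ODE,

    dT/dt = v * gate_P(P(t)) * gate_N(N(t)) * gate_S(SOX(t)) - d * T,   T(2 hpf) = 0,

where the protein inputs P, N and SOX come from the core model and each gate
is a Hill activation (sign +1), Hill repression (sign -1) or the neutral
factor 1 (sign 0).  Requiring at least one activator among the three signs
leaves 19 of the 27 sign triples; these are the regulatory scenarios a target
can follow.  The differential equation is identical across genotypes:
conditions differ only through the input curves.

Because the ODE is linear in T given the inputs, targets are integrated
exactly on a dense grid with an exponential (exact linear-ODE) stepper
rather than a generic stiff solver; this is what makes fitting thousands of
scenario/gene combinations cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import hill_activation, hill_repression

__all__ = [
    "RegulationScenario",
    "MiniModelParams",
    "InputCurves",
    "INPUT_OFFSET",
    "enumerate_scenarios",
    "regulation_gate",
    "simulate_target",
    "scenario_to_group",
    "GROUP_LABELS",
]

#: additive offset applied to inputs before gates; removes 0^h singularities
INPUT_OFFSET = 1e-4

#: the six merged regulatory groups, keyed by Pou5f3/Nanog action
GROUP_LABELS = ("P+N+", "P+", "P+N-", "P-N+", "N+", "SOX")

FACTORS = ("P", "N", "SOX")


@dataclass(frozen=True, order=True)
class RegulationScenario:
    """Sign triple (s_P, s_N, s_SOX), each in {+1, 0, -1}, with >= 1 activator."""

    s_P: int
    s_N: int
    s_SOX: int

    def __post_init__(self):
        for s in (self.s_P, self.s_N, self.s_SOX):
            if s not in (+1, 0, -1):
                raise ValueError("scenario signs must be +1, 0 or -1")
        if +1 not in (self.s_P, self.s_N, self.s_SOX):
            raise ValueError("a scenario needs at least one activating factor")

    @property
    def signs(self) -> tuple[int, int, int]:
        return (self.s_P, self.s_N, self.s_SOX)

    def free_thresholds(self) -> tuple[str, ...]:
        """Names of the Hill thresholds this scenario estimates (sign != 0)."""
        return tuple(f"K_{f}" for f, s in zip(FACTORS, self.signs) if s != 0)

    def label(self) -> str:
        sym = {+1: "+", 0: "0", -1: "-"}
        return f"P{sym[self.s_P]}N{sym[self.s_N]}S{sym[self.s_SOX]}"


# stable ordering of signs: activation first, then none, then repression
_SIGN_ORDER = (+1, 0, -1)


def enumerate_scenarios() -> list[RegulationScenario]:
    """All 19 sign triples with at least one activator, in stable
    lexicographic order over (s_P, s_N, s_SOX) with + < 0 < -."""
    out = []
    for sp in _SIGN_ORDER:
        for sn in _SIGN_ORDER:
            for ss in _SIGN_ORDER:
                if +1 in (sp, sn, ss):
                    out.append(RegulationScenario(sp, sn, ss))
    return out


def regulation_gate(sign: int, x, K: float, h: float = 5.0):
    """One regulator's multiplicative factor in (0, 1].

    sign +1: x^h/(K^h+x^h); sign -1: K^h/(K^h+x^h); sign 0: 1.
    """
    if sign == 0:
        return np.ones_like(np.asarray(x, dtype=float))
    if K <= 0:
        raise ValueError("Hill threshold K must be positive")
    if h <= 0:
        raise ValueError("Hill coefficient h must be positive")
    if np.any(np.asarray(x) < 0):
        raise ValueError("input level must be non-negative")
    if sign == +1:
        return hill_activation(x, K, h)
    if sign == -1:
        return hill_repression(x, K, h)
    raise ValueError("sign must be +1, 0 or -1")


@dataclass
class MiniModelParams:
    """Kinetic parameters of one target-gene mini model.

    Thresholds are supplied only for regulators with non-zero sign; ``sigma``
    is the absolute error scale of the observations (optional until fitted).
    """

    v: float
    d: float
    K_P: float | None = None
    K_N: float | None = None
    K_S: float | None = None
    h: float = 5.0
    sigma: float | None = None

    def threshold_for(self, factor: str) -> float | None:
        return {"P": self.K_P, "N": self.K_N, "SOX": self.K_S}[factor]

    def validate(self, scenario: RegulationScenario) -> None:
        if self.v < 0 or self.d < 0 or self.h <= 0:
            raise ValueError("v, d must be non-negative and h positive")
        for factor, sign in zip(FACTORS, scenario.signs):
            K = self.threshold_for(factor)
            if sign != 0 and (K is None or K <= 0):
                raise ValueError(f"scenario regulates {factor} but K_{factor} is missing or non-positive")


class InputCurves:
    """Per-condition protein input curves P(t), N(t), SOX(t) on [2, 6] hpf.

    Stores each condition on a shared dense grid; gate computations reuse the
    precomputed x^h arrays (h is fixed), so evaluating a new parameter set
    costs only scalar K^h operations.
    """

    def __init__(self, t_dense: np.ndarray, curves: dict[str, dict[str, np.ndarray]], h: float = 5.0):
        self.t_dense = np.asarray(t_dense, dtype=float)
        self.h = float(h)
        self.conditions = list(curves)
        self._curves = {}
        self._pow = {}
        for cond, d in curves.items():
            entry = {}
            powers = {}
            for f in FACTORS:
                x = np.asarray(d[f], dtype=float) + INPUT_OFFSET
                entry[f] = x
                powers[f] = x**self.h
            self._curves[cond] = entry
            self._pow[cond] = powers

    @staticmethod
    def from_core(model, genotypes, n_dense: int = 201, h: float | None = None) -> "InputCurves":
        """Simulate the core model for each genotype and collect P/N/SOX."""
        from .core_model import simulate_core

        t_dense = np.linspace(model.t0, 6.0, n_dense)
        curves = {}
        for g in genotypes:
            traj = simulate_core(model, g, t_dense)
            curves[g.label()] = {
                "P": traj.state("Pou5f3"),
                "N": traj.state("Nanog"),
                "SOX": traj.state("SOX"),
            }
        return InputCurves(t_dense, curves, h=h if h is not None else model.params["h"])

    def gate_product(self, condition: str, scenario: RegulationScenario, params: MiniModelParams) -> np.ndarray:
        if condition not in self._curves:
            raise KeyError(f"no input curves for condition {condition!r}")
        prod = np.ones_like(self.t_dense)
        for f, sign in zip(FACTORS, scenario.signs):
            if sign == 0:
                continue
            K = params.threshold_for(f)
            if K is None or K <= 0:
                raise ValueError(f"missing/invalid threshold K_{f}")
            Kh = K**self.h
            xh = self._pow[condition][f]
            if sign > 0:
                prod = prod * (xh / (Kh + xh))
            else:
                prod = prod * (Kh / (Kh + xh))
        return prod


def _integrate_linear(t: np.ndarray, a: np.ndarray, d: float) -> np.ndarray:
    """Exact stepping of dT/dt = a(t) - d T with a piecewise-linear a, T(t0)=0.

    Uses the closed-form update with the trapezoid of a over each step; for
    constant a this reproduces (a/d)(1 - e^{-d dt}) exactly.
    """
    T = np.zeros_like(t)
    dt = np.diff(t)
    if d <= 1e-12:
        # pure accumulation
        T[1:] = np.cumsum(0.5 * (a[1:] + a[:-1]) * dt)
        return T
    amid = 0.5 * (a[1:] + a[:-1])
    if np.allclose(dt, dt[0]):
        # uniform grid: the recurrence is a constant-coefficient IIR filter
        from scipy.signal import lfilter

        e = float(np.exp(-d * dt[0]))
        b = (amid / d) * (1.0 - e)
        T[1:] = lfilter([1.0], [1.0, -e], b)
        return T
    e = np.exp(-d * dt)
    for k in range(t.size - 1):
        T[k + 1] = T[k] * e[k] + (amid[k] / d) * (1.0 - e[k])
    return T


def simulate_target(
    scenario: RegulationScenario,
    params: MiniModelParams,
    inputs: InputCurves,
    condition: str,
    t_grid,
) -> np.ndarray:
    """Target mRNA curve for one condition, evaluated on ``t_grid``."""
    params.validate(scenario)
    t_grid = np.asarray(t_grid, dtype=float)
    a = params.v * inputs.gate_product(condition, scenario, params)
    T_dense = _integrate_linear(inputs.t_dense, a, params.d)
    return np.interp(t_grid, inputs.t_dense, T_dense)


def simulate_target_all(
    scenario: RegulationScenario,
    params: MiniModelParams,
    inputs: InputCurves,
    t_grid,
) -> dict[str, np.ndarray]:
    """Target curves for every condition in the input set."""
    return {c: simulate_target(scenario, params, inputs, c, t_grid) for c in inputs.conditions}


def scenario_to_group(scenario: RegulationScenario) -> str:
    """Merge the 19 scenarios into six groups keyed by Pou5f3/Nanog action.

    (+,+) -> "P+N+"; (+,0) -> "P+"; (+,-) -> "P+N-"; (-,+) -> "P-N+";
    (0,+) -> "N+"; all remaining scenarios (both s_P <= 0 and s_N <= 0,
    which forces s_SOX = +1) -> "SOX".
    """
    if not isinstance(scenario, RegulationScenario):
        raise TypeError("expected a RegulationScenario")
    sp, sn = scenario.s_P, scenario.s_N
    if sp == +1 and sn == +1:
        return "P+N+"
    if sp == +1 and sn == 0:
        return "P+"
    if sp == +1 and sn == -1:
        return "P+N-"
    if sp == -1 and sn == +1:
        return "P-N+"
    if sp == 0 and sn == +1:
        return "N+"
    return "SOX"
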