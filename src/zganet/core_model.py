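"""Core ODE network of the zebrafish genome activators Pou5f3, Nanog and SoxB1.

The model tracks, between 2 and 6 hours post fertilization (hpf), the mRNA
pools of the maternal genome activators (*pou5f3*, *nanog*, *sox19b*) and of
the early zygotic SoxB1 genes (*sox19a*, *sox3*, *sox2*), plus the three
proteins Pou5f3, Nanog and a pooled SOX activity (sum of all SoxB1 products).
Zygotic transcription is governed by Hill kinetics with steep thresholds
(Hill coefficient 5) combined multiplicatively (AND gates).  Maternal
*sox19b* is cleared by a switch-like, time-dependent degradation rate.

Maternal-zygotic null genotypes are encoded by three boolean flags; each flag
removes the corresponding maternal mRNA pool and the factor's contribution to
protein synthesis, so all eight single/double/triple combinations are
expressible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "GenotypeFlags",
    "Reaction",
    "CoreModelSpec",
    "TrajectorySet",
    "DEFAULT_TOPOLOGY",
    "DEFAULT_PARAMS",
    "build_core_model",
    "sox19b_clearance_rate",
    "simulate_core",
    "hill_activation",
    "hill_repression",
]

#: regulator proteins a topology may reference
REGULATORS = ("Pou5f3", "Nanog", "SOX")

#: genes with a zygotic transcription reaction in the full model
ZYGOTIC_GENES = ("pou5f3", "nanog", "sox19a", "sox3", "sox2")

#: transcripts observed in the RNA-seq time curves
OBSERVABLES = ("pou5f3", "nanog", "sox19b", "sox19a", "sox3", "sox2")

T0 = 2.0  # hpf; initial condition of the ODE system


class ConfigError(ValueError):
    """Invalid model topology or parameterization."""


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the last valid time reached."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class GenotypeFlags:
    """Maternal-zygotic loss-of-function flags.

    mz_spg removes Pou5f3 (null allele: no functional protein), mz_nanog
    removes Nanog, mz_sox removes maternal Sox19b only (zygotic SoxB1 genes
    remain intact).
    """

    mz_spg: bool = False
    mz_nanog: bool = False
    mz_sox: bool = False

    def label(self) -> str:
        if not (self.mz_spg or self.mz_nanog or self.mz_sox):
            return "WT"
        parts = []
        if self.mz_spg:
            parts.append("p")
        if self.mz_sox:
            parts.append("s")
        if self.mz_nanog:
            parts.append("n")
        return "MZ" + "".join(parts)

    @staticmethod
    def from_label(label: str) -> "GenotypeFlags":
        if label == "WT":
            return GenotypeFlags()
        if not label.startswith("MZ"):
            raise ConfigError(f"unknown genotype label {label!r}")
        tail = label[2:]
        if tail == "triple":
            tail = "psn"
        known = set("psn")
        if not tail or not set(tail) <= known:
            raise ConfigError(f"unknown genotype label {label!r}")
        return GenotypeFlags(mz_spg="p" in tail, mz_nanog="n" in tail, mz_sox="s" in tail)


#: the eight constructible genotypes, wild-type first
ALL_GENOTYPES = tuple(
    GenotypeFlags(mz_spg=p, mz_nanog=n, mz_sox=s)
    for p, n, s in [
        (False, False, False),
        (True, False, False),
        (False, False, True),
        (False, True, False),
        (True, False, True),
        (True, True, False),
        (False, True, True),
        (True, True, True),
    ]
)

#: seven conditions used for fitting: everything except the triple mutant,
#: in which all three inputs are absent and targets are uninformative
DEFAULT_FIT_GENOTYPES = ALL_GENOTYPES[:7]


@dataclass(frozen=True)
class Reaction:
    kind: str  # transcription | mrna_degradation | translation | protein_degradation
    substrate: str | None
    product: str | None
    rate_law: str


# Default regulatory topology: gene -> ((regulator, sign), ...); sign +1
# activation, -1 repression; multiple regulators combine as an AND gate.
DEFAULT_TOPOLOGY: dict[str, tuple[tuple[str, int], ...]] = {
    "pou5f3": (("Pou5f3", +1), ("SOX", +1)),
    "nanog": (("Nanog", +1),),
    "sox19a": (("Nanog", +1),),
    "sox3": (("SOX", +1), ("Pou5f3", -1)),
    "sox2": (("Pou5f3", +1), ("SOX", +1)),
}

# Generating parameters of the default model.  Units: expression in arbitrary
# normalized RNA-seq units, rates per hour, time in hpf.  Chosen so that
# maternal pools decay over 2-6 hpf while zygotic transcripts switch up after
# major ZGA (~3 hpf) and reach a few hundred units, matching the scale of
# normalized counts the transcript-classification thresholds assume.
DEFAULT_PARAMS: dict[str, float] = {
    # zygotic synthesis rates (units/h)
    "v_pou5f3": 150.0,
    "v_nanog": 120.0,
    "v_sox19a": 250.0,
    "v_sox3": 300.0,
    "v_sox2": 120.0,
    # Hill thresholds per regulatory edge (protein units)
    "K_pou5f3_Pou5f3": 150.0,
    "K_pou5f3_SOX": 300.0,
    "K_nanog_Nanog": 120.0,
    "K_sox19a_Nanog": 150.0,
    "K_sox3_SOX": 250.0,
    "K_sox3_Pou5f3": 400.0,
    "K_sox2_Pou5f3": 200.0,
    "K_sox2_SOX": 350.0,
    # Hill coefficient (strong threshold behaviour)
    "h": 5.0,
    # mRNA degradation rates (1/h); sox19b uses the clearance switch instead
    "d_pou5f3": 0.30,
    "d_nanog": 0.35,
    "d_sox19a": 0.25,
    "d_sox3": 0.25,
    "d_sox2": 0.25,
    # switch-like maternal sox19b clearance
    "sw_base": 0.10,
    "sw_max": 2.0,
    "sw_t": 4.5,
    "sw_steep": 10.0,
    # translation rates (protein units per mRNA unit per hour)
    "tl_pou5f3": 1.0,
    "tl_nanog": 1.0,
    "tl_sox": 1.0,
    # protein degradation rates (1/h)
    "dp_pou5f3": 0.35,
    "dp_nanog": 0.40,
    "dp_sox": 0.30,
    # maternal initial amounts at 2 hpf
    "x0_pou5f3": 250.0,
    "x0_sox19b": 400.0,
    "x0_nanog": 200.0,
}


@dataclass
class CoreModelSpec:
    """States, reactions, parameters and regulatory topology of the core model."""

    state_names: list[str]
    reaction_list: list[Reaction]
    params: dict[str, float]
    topology: dict[str, tuple[tuple[str, int], ...]]
    t0: float = T0

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_list)

    def with_params(self, **updates: float) -> "CoreModelSpec":
        merged = dict(self.params)
        merged.update(updates)
        _validate_params(merged, self.topology)
        return replace(self, params=merged)

    # --- YAML round trip -------------------------------------------------
    def to_yaml(self) -> str:
        payload = {
            "states": list(self.state_names),
            "reactions": [
                {
                    "kind": r.kind,
                    "substrate": r.substrate,
                    "product": r.product,
                    "rate_law": r.rate_law,
                }
                for r in self.reaction_list
            ],
            "params": {k: float(v) for k, v in self.params.items()},
            "topology": {g: [[reg, int(sign)] for reg, sign in edges] for g, edges in self.topology.items()},
            "t0": float(self.t0),
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @staticmethod
    def from_yaml(text: str) -> "CoreModelSpec":
        payload = yaml.safe_load(text)
        topology = {
            g: tuple((reg, int(sign)) for reg, sign in edges) for g, edges in payload["topology"].items()
        }
        spec = build_core_model(topology)
        spec = spec.with_params(**payload["params"])
        if payload["states"] != spec.state_names:
            raise ConfigError("state list in YAML does not match topology-derived states")
        return spec


@dataclass
class TrajectorySet:
    """Simulated state trajectories and the six observed transcripts."""

    time_grid: np.ndarray
    state_names: list[str]
    state_values: np.ndarray  # [state, time]
    observable_names: list[str]
    observables: np.ndarray  # [observable, time]
    genotype: GenotypeFlags

    def state(self, name: str) -> np.ndarray:
        return self.state_values[self.state_names.index(name)]

    def observable(self, name: str) -> np.ndarray:
        return self.observables[self.observable_names.index(name)]


def hill_activation(x, K, h):
    """Saturating activation x^h / (K^h + x^h)."""
    xh = np.asarray(x, dtype=float) ** h
    return xh / (K**h + xh)


def hill_repression(x, K, h):
    """Saturating repression K^h / (K^h + x^h); complements hill_activation."""
    Kh = K**h
    return Kh / (Kh + np.asarray(x, dtype=float) ** h)


def sox19b_clearance_rate(t, base: float, max_rate: float, t_sw: float, steepness: float):
    """Switch-like maternal sox19b mRNA clearance rate (1/h).

    rate(t) = base + (max - base) * t^s / (t_sw^s + t^s): the rate rises
    monotonically from ``base`` to ``max_rate`` with midpoint at ``t_sw``.
    """
    if base < 0 or max_rate < 0:
        raise ValueError("clearance rates must be non-negative")
    if base > max_rate:
        raise ValueError("base clearance rate must not exceed the maximal rate")
    if steepness <= 0:
        raise ValueError("steepness must be positive")
    t = np.asarray(t, dtype=float)
    ts = t**steepness
    return base + (max_rate - base) * ts / (t_sw**steepness + ts)


def _validate_topology(topology: dict) -> dict[str, tuple[tuple[str, int], ...]]:
    clean: dict[str, tuple[tuple[str, int], ...]] = {}
    for gene, edges in topology.items():
        if gene == "sox19b":
            raise ConfigError("sox19b is maternal-only and cannot be zygotically transcribed")
        if gene not in ZYGOTIC_GENES:
            raise ConfigError(f"unknown zygotic gene {gene!r}")
        tidy = []
        for reg, sign in edges:
            if reg not in REGULATORS:
                raise ConfigError(f"unknown regulator {reg!r}; expected one of {REGULATORS}")
            if sign not in (+1, -1):
                raise ConfigError(f"edge sign must be +1 or -1, got {sign!r}")
            tidy.append((reg, int(sign)))
        clean[gene] = tuple(tidy)
    return clean


def _validate_params(params: dict[str, float], topology: dict) -> None:
    for name, value in params.items():
        if name.startswith(("v_", "K_", "d_", "dp_", "tl_", "x0_", "sw_")) or name == "h":
            if value < 0:
                raise ConfigError(f"parameter {name} must be non-negative, got {value}")
    for gene, edges in topology.items():
        for reg, _sign in edges:
            key = f"K_{gene}_{reg}"
            if key not in params:
                raise ConfigError(f"missing Hill threshold parameter {key}")


def build_core_model(topology_config="default") -> CoreModelSpec:
    """Assemble the core model from a regulator map.

    The default build has 11 states (8 mRNA pools, 3 proteins) and 17
    reactions: 5 zygotic transcription, 6 per-gene mRNA degradation
    (maternal/zygotic pools of a gene share one degradation reaction),
    3 translation and 3 protein degradation.
    """
    if topology_config == "default":
        topology = dict(DEFAULT_TOPOLOGY)
    else:
        topology = _validate_topology(dict(topology_config))

    states: list[str] = []
    # maternal pools always present
    states.append("pou5f3_m")
    if "pou5f3" in topology:
        states.append("pou5f3_z")
    states.append("nanog_m")
    if "nanog" in topology:
        states.append("nanog_z")
    states.append("sox19b_m")
    for g in ("sox19a", "sox3", "sox2"):
        if g in topology:
            states.append(g)
    states += ["Pou5f3", "Nanog", "SOX"]

    reactions: list[Reaction] = []
    for gene in ZYGOTIC_GENES:
        if gene in topology:
            gate = " * ".join(
                f"H{'+' if sign > 0 else '-'}({reg}; K_{gene}_{reg}, h)" for reg, sign in topology[gene]
            ) or "1"
            target = f"{gene}_z" if gene in ("pou5f3", "nanog") else gene
            reactions.append(Reaction("transcription", None, target, f"v_{gene} * {gate}"))
    # one degradation reaction per gene; maternal and zygotic pools share it
    for gene, pools in (
        ("pou5f3", ("pou5f3_m", "pou5f3_z")),
        ("nanog", ("nanog_m", "nanog_z")),
        ("sox19b", ("sox19b_m",)),
        ("sox19a", ("sox19a",)),
        ("sox3", ("sox3",)),
        ("sox2", ("sox2",)),
    ):
        pools = tuple(p for p in pools if p in states)
        if not pools:
            continue
        law = "d_sw(t)" if gene == "sox19b" else f"d_{gene}"
        reactions.append(Reaction("mrna_degradation", "+".join(pools), None, f"{law} * ({'+'.join(pools)})"))
    reactions.append(Reaction("translation", "pou5f3_m+pou5f3_z", "Pou5f3", "tl_pou5f3 * pou5f3_mRNA"))
    reactions.append(Reaction("translation", "nanog_m+nanog_z", "Nanog", "tl_nanog * nanog_mRNA"))
    reactions.append(Reaction("translation", "soxB1_mRNA", "SOX", "tl_sox * soxB1_mRNA"))
    for prot, rate in (("Pou5f3", "dp_pou5f3"), ("Nanog", "dp_nanog"), ("SOX", "dp_sox")):
        reactions.append(Reaction("protein_degradation", prot, None, f"{rate} * {prot}"))

    params = dict(DEFAULT_PARAMS)
    # drop thresholds for edges not in this topology
    wanted = {f"K_{g}_{r}" for g, edges in topology.items() for r, _ in edges}
    params = {k: v for k, v in params.items() if not k.startswith("K_") or k in wanted}
    _validate_params(params, topology)
    return CoreModelSpec(states, reactions, params, topology)


def simulate_core(
    model: CoreModelSpec,
    genotype: GenotypeFlags,
    t_grid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    neg_tol: float = 1e-6,
) -> TrajectorySet:
    """Integrate the core ODE system from 2 hpf on the requested time grid.

    Null genotypes zero the corresponding maternal initial amount and the
    factor's protein-synthesis contribution.  Zygotic mRNA pools and zygotic
    protein amounts start at zero.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if t_grid.min() < model.t0 - 1e-12 or t_grid.max() > 6.0 + 1e-9:
        raise ValueError("t_grid must lie within [2, 6] hpf")
    p = model.params
    topo = model.topology
    names = model.state_names
    idx = {s: i for i, s in enumerate(names)}
    n = len(names)

    y0 = np.zeros(n)
    y0[idx["pou5f3_m"]] = 0.0 if genotype.mz_spg else p["x0_pou5f3"]
    y0[idx["nanog_m"]] = 0.0 if genotype.mz_nanog else p["x0_nanog"]
    y0[idx["sox19b_m"]] = 0.0 if genotype.mz_sox else p["x0_sox19b"]

    tl_p = 0.0 if genotype.mz_spg else p["tl_pou5f3"]
    tl_n = 0.0 if genotype.mz_nanog else p["tl_nanog"]
    sox19b_in_sox = 0.0 if genotype.mz_sox else 1.0

    has_pz = "pou5f3_z" in idx
    has_nz = "nanog_z" in idx

    # precompiled reaction structure: plain floats and integer indices so the
    # RHS avoids per-call dict lookups (it runs ~1e3 times per integration)
    i_pm, i_nm, i_sm = idx["pou5f3_m"], idx["nanog_m"], idx["sox19b_m"]
    i_P, i_N, i_S = idx["Pou5f3"], idx["Nanog"], idx["SOX"]
    prot_idx = {"Pou5f3": i_P, "Nanog": i_N, "SOX": i_S}
    h = p["h"]
    txn = []  # (target idx, v, d, ((protein idx, K^h, sign), ...))
    for gene, edges in topo.items():
        target = idx[f"{gene}_z" if gene in ("pou5f3", "nanog") else gene]
        gates = []
        for reg, sign in edges:
            K = p[f"K_{gene}_{reg}"]
            if K <= 0:
                raise ConfigError(f"Hill threshold K_{gene}_{reg} must be positive")
            gates.append((prot_idx[reg], K**h, sign))
        txn.append((target, p[f"v_{gene}"], p[f"d_{gene}"], tuple(gates)))
    d_pou, d_nan = p["d_pou5f3"], p["d_nanog"]
    dp_P, dp_N, dp_S = p["dp_pou5f3"], p["dp_nanog"], p["dp_sox"]
    tl_s = p["tl_sox"]
    sw_base, sw_max, sw_t, sw_s = p["sw_base"], p["sw_max"], p["sw_t"], p["sw_steep"]
    sox_zyg_idx = [idx[g] for g in ("sox19a", "sox3", "sox2") if g in idx]
    i_pz = idx.get("pou5f3_z")
    i_nz = idx.get("nanog_z")

    def rhs(t, y):
        dy = np.empty(n)
        ts = t**sw_s
        d_sw = sw_base + (sw_max - sw_base) * ts / (sw_t**sw_s + ts)
        dy[i_pm] = -d_pou * y[i_pm]
        dy[i_nm] = -d_nan * y[i_nm]
        dy[i_sm] = -d_sw * y[i_sm]
        for target, v, d, gates in txn:
            a = v
            for pi, Kh, sign in gates:
                x = y[pi]
                xh = x**h if x > 0.0 else 0.0
                a *= xh / (Kh + xh) if sign > 0 else Kh / (Kh + xh)
            dy[target] = a - d * y[target]
        pou_mrna = y[i_pm] + (y[i_pz] if i_pz is not None else 0.0)
        nan_mrna = y[i_nm] + (y[i_nz] if i_nz is not None else 0.0)
        sox_mrna = sox19b_in_sox * y[i_sm]
        for si in sox_zyg_idx:
            sox_mrna += y[si]
        dy[i_P] = tl_p * pou_mrna - dp_P * y[i_P]
        dy[i_N] = tl_n * nan_mrna - dp_N * y[i_N]
        dy[i_S] = tl_s * sox_mrna - dp_S * y[i_S]
        return dy

    t_eval = t_grid
    needs_t0 = t_grid[0] > model.t0 + 1e-12
    if needs_t0:
        t_eval = np.concatenate([[model.t0], t_grid])
    sol = solve_ivp(rhs, (model.t0, float(t_eval[-1])), y0, t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else model.t0
        raise IntegrationError(f"core model integration failed: {sol.message}", last_time=last)
    Y = sol.y[:, 1:] if needs_t0 else sol.y
    scale = max(1.0, float(np.max(np.abs(Y))))
    if Y.min() < -neg_tol * scale:
        raise IntegrationError(f"negative state beyond tolerance: min={Y.min():.3g}")
    Y = np.clip(Y, 0.0, None)

    obs = np.empty((len(OBSERVABLES), t_grid.size))
    obs[0] = Y[idx["pou5f3_m"]] + (Y[idx["pou5f3_z"]] if has_pz else 0.0)
    obs[1] = Y[idx["nanog_m"]] + (Y[idx["nanog_z"]] if has_nz else 0.0)
    obs[2] = Y[idx["sox19b_m"]]
    for k, g in enumerate(("sox19a", "sox3", "sox2"), start=3):
        obs[k] = Y[idx[g]] if g in idx else np.zeros(t_grid.size)
    return TrajectorySet(t_grid, list(names), Y, list(OBSERVABLES), obs, genotype)


def trajectories_to_frame(traj: TrajectorySet):
    """Tidy TSV-ready frame: time column + one column per state."""
    import pandas as pd

    data = {"time": traj.time_grid}
    for i, s in enumerate(traj.state_names):
        data[s] = traj.state_values[i]
    return pd.DataFrame(data)


def observables_to_frame(traj: TrajectorySet):
    import pandas as pd

    data = {"time": traj.time_grid}
    for i, s in enumerate(traj.observable_names):
        data[s] = traj.observables[i]
    return pd.DataFrame(data)
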