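"""Synthetic datasets with planted ground truth for every pipeline stage.

Three generators emulate the study's data layouts:

* ``generate_core_dataset`` - noisy time courses of the six observed
  transcripts across genotypes, simulated from the core model with additive
  Gaussian noise (the absolute error model used in fitting);
* ``generate_target_panel`` - per-gene target time courses simulated from
  randomly parameterized mini models driven by the core protein dynamics,
  with the generating scenario and merged group recorded per gene;
* ``generate_genomic_fixture`` - a toy genome of accessible regions whose
  per-contrast accessibility evidence, H3K27ac means, rescue signals, TF
  peaks, motif hits and region-gene couplings are all consistent with
  planted labels, with effect sizes expressed relative to the
  classification thresholds.

Every generator is deterministic given (seed, config) and returns the
generated tables together with a ``SyntheticTruth`` record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import (
    DEFAULT_FIT_GENOTYPES,
    CoreModelSpec,
    GenotypeFlags,
    build_core_model,
    simulate_core,
)
from .mini_models import (
    GROUP_LABELS,
    InputCurves,
    MiniModelParams,
    RegulationScenario,
    enumerate_scenarios,
    scenario_to_group,
    simulate_target,
)

__all__ = [
    "SyntheticTruth",
    "TIMEPOINTS",
    "generate_core_dataset",
    "generate_target_panel",
    "generate_genomic_fixture",
]

TIMEPOINTS = (2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0)


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized alongside every generated dataset."""

    seed: int
    config: dict = field(default_factory=dict)
    core_params: dict = field(default_factory=dict)
    gene_truth: dict = field(default_factory=dict)  # gene -> {scenario, group, params}
    region_truth: dict = field(default_factory=dict)  # region -> {group, statuses, rescue}
    coupling: dict = field(default_factory=dict)  # planted strong cells etc.

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(
            {
                "seed": self.seed,
                "config": self.config,
                "core_params": self.core_params,
                "gene_truth": self.gene_truth,
                "region_truth": self.region_truth,
                "coupling": self.coupling,
            },
            indent=2,
            sort_keys=True,
            default=default,
        )


def generate_core_dataset(
    model: CoreModelSpec | None = None,
    genotypes=None,
    timepoints=TIMEPOINTS,
    replicates: int = 3,
    sigma_obs: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Noisy transcript time courses simulated from the core model.

    ``sigma_obs`` is the absolute Gaussian noise scale (scalar or dict per
    observable); zero gives the noise-free limit, negative values raise.
    Negative noisy values are truncated at zero and flagged in the
    ``truncated`` column.
    """
    model = model if model is not None else build_core_model("default")
    genotypes = tuple(genotypes) if genotypes is not None else DEFAULT_FIT_GENOTYPES
    t = np.asarray(timepoints, dtype=float)
    if np.isscalar(sigma_obs):
        if sigma_obs < 0:
            raise ValueError("sigma_obs must be non-negative")
        sigma_by_obs = None
    else:
        sigma_by_obs = {k: float(v) for k, v in dict(sigma_obs).items()}
        if any(v < 0 for v in sigma_by_obs.values()):
            raise ValueError("sigma_obs must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for g in genotypes:
        traj = simulate_core(model, g, t)
        for oi, obs in enumerate(traj.observable_names):
            s = sigma_by_obs[obs] if sigma_by_obs is not None else float(sigma_obs)
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, s, size=t.size) if s > 0 else np.zeros(t.size)
                vals = traj.observables[oi] + noise
                truncated = vals < 0
                vals = np.clip(vals, 0.0, None)
                for k in range(t.size):
                    rows.append(
                        {
                            "observable": obs,
                            "genotype": g.label(),
                            "replicate": rep,
                            "time": t[k],
                            "value": vals[k],
                            "truncated": bool(truncated[k]),
                        }
                    )
    df = pd.DataFrame(rows)
    truth = SyntheticTruth(
        seed=seed,
        config={
            "genotypes": [g.label() for g in genotypes],
            "timepoints": list(map(float, t)),
            "replicates": replicates,
            "sigma_obs": sigma_by_obs if sigma_by_obs is not None else float(sigma_obs),
        },
        core_params={k: float(v) for k, v in model.params.items()},
    )
    return df, truth


# log10 ranges for per-gene mini-model parameters.  Thresholds are drawn
# within the dynamic range of the core protein inputs so every regulator's
# sign is informative; rates give curves that rise visibly within 2-6 hpf.
DEFAULT_PARAM_RANGES = {
    "v": (1.7, 2.3),  # 50 - 200 units/h
    "d": (-0.5, 0.3),  # 0.3 - 2 /h
    "K_frac": (0.25, 0.7),  # threshold as a fraction of the WT input maximum
}


def generate_target_panel(
    n_genes: int,
    scenario_mix=None,
    param_ranges: dict | None = None,
    noise_level: float = 0.05,
    replicates: int = 3,
    timepoints=TIMEPOINTS,
    inputs: InputCurves | None = None,
    model: CoreModelSpec | None = None,
    genotypes=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth, InputCurves]:
    """Target-gene time courses simulated from randomly drawn mini models.

    ``scenario_mix`` is a list of RegulationScenario cycled over genes
    (default: one representative per merged group, cycled), or "all19" to
    cycle through the full enumeration.  ``noise_level`` scales the additive
    Gaussian sigma as a fraction of each gene's curve maximum.  Returns the
    long-format panel, the truth record and the input curves used.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    if scenario_mix is None:
        # one representative scenario per merged group, in group order
        reps = {}
        for s in enumerate_scenarios():
            reps.setdefault(scenario_to_group(s), s)
        scenario_mix = [reps[g] for g in GROUP_LABELS]
    elif scenario_mix == "all19":
        scenario_mix = enumerate_scenarios()
    else:
        scenario_mix = list(scenario_mix)
    if not scenario_mix:
        raise ValueError("scenario_mix must not be empty")

    model = model if model is not None else build_core_model("default")
    genotypes = tuple(genotypes) if genotypes is not None else DEFAULT_FIT_GENOTYPES
    if inputs is None:
        inputs = InputCurves.from_core(model, genotypes)
    t = np.asarray(timepoints, dtype=float)
    rng = np.random.default_rng(seed)

    # dynamic range of each input in the conditions where the factor is present
    input_max = {}
    for f in ("P", "N", "SOX"):
        m = 0.0
        for c in inputs.conditions:
            m = max(m, float(np.max(inputs._curves[c][f])))
        input_max[f] = m

    rows = []
    gene_truth = {}
    for gi in range(n_genes):
        gene = f"g{gi:04d}"
        scenario = scenario_mix[gi % len(scenario_mix)]
        v = 10.0 ** rng.uniform(*ranges["v"])
        d = 10.0 ** rng.uniform(*ranges["d"])
        kw = {}
        for f, attr in (("P", "K_P"), ("N", "K_N"), ("SOX", "K_S")):
            sign = dict(zip(("P", "N", "SOX"), scenario.signs))[f]
            if sign != 0:
                frac = rng.uniform(*ranges["K_frac"])
                kw[attr] = frac * input_max[f]
        params = MiniModelParams(v=v, d=d, h=inputs.h, **kw)
        curves = {c: simulate_target(scenario, params, inputs, c, t) for c in inputs.conditions}
        curve_max = max(float(np.max(c)) for c in curves.values())
        sigma = noise_level * curve_max if curve_max > 0 else 0.0
        for c, vals in curves.items():
            for rep in range(1, replicates + 1):
                noisy = vals + (rng.normal(0.0, sigma, size=t.size) if sigma > 0 else 0.0)
                noisy = np.clip(noisy, 0.0, None)
                for k in range(t.size):
                    rows.append({"gene": gene, "condition": c, "replicate": rep, "time": t[k], "value": noisy[k]})
        gene_truth[gene] = {
            "scenario": list(scenario.signs),
            "group": scenario_to_group(scenario),
            "params": {"v": v, "d": d, **{k: float(x) for k, x in kw.items()}},
            "sigma": sigma,
            "curve_max": curve_max,
        }
    df = pd.DataFrame(rows)
    truth = SyntheticTruth(
        seed=seed,
        config={
            "n_genes": n_genes,
            "noise_level": noise_level,
            "replicates": replicates,
            "timepoints": list(map(float, t)),
            "conditions": list(inputs.conditions),
            "param_ranges": {k: list(v) for k, v in ranges.items()},
        },
        core_params={k: float(v) for k, v in model.params.items()},
        gene_truth=gene_truth,
    )
    return df, truth, inputs


# ---------------------------------------------------------------------------
# genomic fixture
# ---------------------------------------------------------------------------

#: planted transcript class per region group for the chi-square coupling
DEFAULT_GROUP_TO_CLASS = {"1.PN": "DOWN", "2.P": "DOWN", "3.N": "SAME", "4.-": "UP"}

TRANSCRIPT_CLASSES = ("DOWN", "SAME", "UP")

#: per-TF H3K27ac status planted per group (activator/blocker pattern:
#: synergistic 1.PN, antagonistic 2.P (p+n-) and 3.N (p-n+), redundant 4.-)
GROUP_TF_STATUS = {
    "1.PN": {"MZp": "+", "MZn": "+", "MZs": "0"},
    "2.P": {"MZp": "+", "MZn": "-", "MZs": "0"},
    "3.N": {"MZp": "-", "MZn": "+", "MZs": "0"},
    "4.-": {"MZp": "0", "MZn": "0", "MZs": "0"},
}

#: rescue by single-TF injection planted per group
GROUP_RESCUE = {
    "1.PN": {"P": False, "N": False, "S": False, "PN": True},
    "2.P": {"P": True, "N": False, "S": False, "PN": True},
    "3.N": {"P": False, "N": True, "S": False, "PN": True},
    "4.-": {"P": False, "N": True, "S": True, "PN": True},
}

#: motif hits planted per group (which motif is enriched at the summit)
GROUP_MOTIF = {"1.PN": "pou:sox", "2.P": "pou", "3.N": "nanog", "4.-": "sox"}


def generate_genomic_fixture(
    n_regions: int = 400,
    group_proportions=(0.25, 0.25, 0.25, 0.25),
    effect_factor: float = 2.0,
    coupling_strength: float = 0.75,
    n_genes: int | None = None,
    seed: int = 0,
    balanced: bool = True,
    spacing: int = 105_000,
    tss_offset: int = 25_000,
    thresholds: dict | None = None,
) -> tuple[dict, SyntheticTruth]:
    """A toy genome whose classification inputs encode planted labels.

    Regions sit ``spacing`` bp apart on one chromosome (auto-sized to at
    least 10 Mb) so that each region pairs with exactly one gene (TSS at
    ``tss_offset`` downstream; neighbour TSS distances exceed the 50 kb
    linking window).  ``effect_factor`` places every planted effect that
    factor beyond its classification threshold (H3K27ac deltas, acetylation
    level, FDR margin, rescue log-ratio).  ``coupling_strength`` is the
    probability that a gene's transcript class equals the class planted for
    its region's group (0 = independent null).

    Returns a dict of tables (regions, evidence, h3k27ac, rescue, tf_peaks,
    motif_hits, tss, transcript_status, peak_times) plus the truth record.
    """
    props = np.asarray(group_proportions, dtype=float)
    if props.size != 4 or np.any(props < 0) or not np.isclose(props.sum(), 1.0):
        raise ValueError("group_proportions must be four non-negative values summing to 1")
    if not (0.0 <= coupling_strength <= 1.0):
        raise ValueError("coupling_strength must be in [0, 1]")
    if effect_factor <= 1.0:
        raise ValueError("effect_factor must exceed 1 for planted labels to be recoverable")
    th = {"fdr": 0.05, "acetyl": 0.2, "delta": 0.7, "floor": 0.1}
    if thresholds:
        th.update(thresholds)
    n_genes = n_genes if n_genes is not None else n_regions
    rng = np.random.default_rng(seed)

    chrom = "chrS"
    chrom_len = max(10_000_000, n_regions * spacing + 2 * spacing)
    summits = 60_000 + spacing * np.arange(n_regions)

    groups = []
    if balanced:
        counts = np.floor(props * n_regions).astype(int)
        while counts.sum() < n_regions:
            counts[np.argmax(props * n_regions - counts)] += 1
        for g, c in zip(("1.PN", "2.P", "3.N", "4.-"), counts):
            groups += [g] * c
        groups = list(rng.permutation(groups))
    else:
        groups = list(rng.choice(["1.PN", "2.P", "3.N", "4.-"], size=n_regions, p=props))

    region_ids = [f"AR{i:05d}" for i in range(n_regions)]
    regions = pd.DataFrame(
        {
            "region_id": region_ids,
            "chrom": chrom,
            "start": summits - 55,
            "end": summits + 55,
            "summit": summits,
            "group_planted": groups,
        }
    )

    # --- differential accessibility evidence ------------------------------
    sig_fdr = th["fdr"] / effect_factor
    null_fdr = min(1.0, th["fdr"] * effect_factor * 4)
    down_fc = -1.0
    rows = []
    for rid, grp in zip(region_ids, groups):
        down_in = {"MZtriple": True, "MZp": grp in ("1.PN", "2.P"), "MZn": grp in ("1.PN", "3.N")}
        for contrast, is_down in down_in.items():
            for norm in range(1, 5):
                if is_down:
                    fc, q = down_fc, sig_fdr
                else:
                    fc, q = 0.1, null_fdr
                rows.append({"region_id": rid, "contrast": contrast, "normalization": norm, "log2fc": fc, "fdr": q})
    evidence = pd.DataFrame(rows)

    # --- H3K27ac means ----------------------------------------------------
    wt_level = th["acetyl"] * effect_factor  # acetylated with margin
    delta = th["delta"] * effect_factor
    rows = []
    region_truth = {}
    for rid, grp in zip(region_ids, groups):
        entry = {"WT": wt_level}
        statuses = GROUP_TF_STATUS[grp]
        for mut, st in statuses.items():
            if st == "+":
                entry[mut] = wt_level * 2.0 ** (-delta)
            elif st == "-":
                entry[mut] = wt_level * 2.0**delta
            else:
                entry[mut] = wt_level
        entry["MZtriple"] = wt_level * 2.0 ** (-delta)  # PSN jointly required
        rows.append({"region_id": rid, **entry})
        region_truth[rid] = {"group": grp, "h3k27ac_status": dict(statuses), "psn_status": "+"}
    h3k27ac = pd.DataFrame(rows)

    # --- rescue signals ---------------------------------------------------
    rows = []
    wt_sig, ctrl_sig = 8.0, 2.0
    geo = float(np.sqrt(wt_sig * ctrl_sig))
    for rid, grp in zip(region_ids, groups):
        flags = GROUP_RESCUE[grp]
        for combo, rescued in flags.items():
            inj = geo * (effect_factor if rescued else 1.0 / effect_factor)
            rows.append({"region_id": rid, "combo": combo, "wt": wt_sig, "control": ctrl_sig, "injected": inj, "rescued_planted": rescued})
        region_truth[rid]["rescue"] = dict(flags)
    rescue = pd.DataFrame(rows)

    # --- TF ChIP peaks (every region TF-bound -> all are TdARs) -----------
    tf_peaks = {
        tf: pd.DataFrame({"chrom": chrom, "start": summits - 20, "end": summits + 20})
        for tf in ("Pou5f3", "SoxB1", "Nanog")
    }

    # --- motif hits: 2 hits at target-group summits, 1 at every control ---
    rows = []
    motifs = sorted(set(GROUP_MOTIF.values()))
    for motif in motifs:
        for rid, grp, s in zip(region_ids, groups, summits):
            if GROUP_MOTIF[grp] == motif:
                rows.append({"motif": motif, "chrom": chrom, "start": s - 10, "end": s + 0})
                rows.append({"motif": motif, "chrom": chrom, "start": s + 5, "end": s + 15})
            rows.append({"motif": motif, "chrom": chrom, "start": s + 1000 - 5, "end": s + 1000 + 5})
    motif_hits = pd.DataFrame(rows)

    # --- genes, TSS, transcript classes ----------------------------------
    gene_ids = [f"t{i:05d}" for i in range(n_genes)]
    tss = pd.DataFrame(
        {
            "gene": gene_ids,
            "chrom": chrom,
            "tss": [summits[i % n_regions] + tss_offset for i in range(n_genes)],
        }
    )
    classes = []
    for i, gid in enumerate(gene_ids):
        grp = groups[i % n_regions]
        planted = DEFAULT_GROUP_TO_CLASS[grp]
        if rng.uniform() < coupling_strength:
            classes.append(planted)
        else:
            classes.append(TRANSCRIPT_CLASSES[rng.integers(len(TRANSCRIPT_CLASSES))])
    transcript_status = pd.DataFrame({"gene": gene_ids, "status": classes})

    # developmental peak-time annotation: prematurely expressed (UP) genes
    # peak late (~24 hpf), DOWN/SAME genes peak early (~8 hpf)
    peak = np.where(np.array(classes) == "UP", rng.normal(24.0, 3.0, n_genes), rng.normal(8.0, 2.0, n_genes))
    peak_times = pd.DataFrame({"gene": gene_ids, "peak_time_hpf": np.round(np.clip(peak, 3.0, 120.0), 2)})

    planted_cells = sorted({(g, c) for g, c in DEFAULT_GROUP_TO_CLASS.items()}) if coupling_strength > 0 else []
    truth = SyntheticTruth(
        seed=seed,
        config={
            "n_regions": n_regions,
            "n_genes": n_genes,
            "group_proportions": props.tolist(),
            "effect_factor": effect_factor,
            "coupling_strength": coupling_strength,
            "balanced": balanced,
            "chrom": chrom,
            "chrom_length": int(chrom_len),
            "spacing": spacing,
            "tss_offset": tss_offset,
            "thresholds": th,
        },
        region_truth=region_truth,
        coupling={
            "group_to_class": DEFAULT_GROUP_TO_CLASS,
            "planted_cells": [list(c) for c in planted_cells],
            "gene_class": dict(zip(gene_ids, classes)),
        },
    )
    tables = {
        "regions": regions,
        "evidence": evidence,
        "h3k27ac": h3k27ac,
        "rescue": rescue,
        "tf_peaks": tf_peaks,
        "motif_hits": motif_hits,
        "tss": tss,
        "transcript_status": transcript_status,
        "peak_times": peak_times,
    }
    return tables, truth
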