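"""Readers, writers, configuration and the end-to-end pipeline driver.

Tabular outputs are TSV (tab-separated, header row, UTF-8, '.' decimal),
intervals are BED (0-based half-open), structured results are JSON.  Every
output TSV carries a header comment line with the configuration hash so two
runs with equal configs produce byte-identical payloads.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["PipelineConfig", "read_bed", "write_bed", "write_tsv", "read_tsv", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds and fit settings of the pipeline, with study defaults."""

    # transcript classification
    expr_threshold: float = 100.0
    switch_p_threshold: float = 0.15
    fold: float = 2.0
    ttest_p: float = 0.05
    # genomics
    h3k27ac_floor: float = 0.1
    acetyl_threshold: float = 0.2
    delta_threshold: float = 0.7
    fdr: float = 0.05
    residual_threshold: float = 4.0
    link_window: int = 50_000
    motif_window: int = 60
    control_shift: int = 1000
    ar_width: int = 110
    # fitting
    core_starts: int = 192
    mini_starts: int = 64
    seed: int = 0
    log10_lower: float = -3.0
    log10_upper: float = 3.0
    hill: float = 5.0
    prior_scale: float = 3.0
    pl_threshold: float = 3.841458820694124
    # synthetic-data sizes (pipeline simulate stage)
    n_target_genes: int = 6
    target_noise: float = 0.05
    n_regions: int = 120
    coupling_strength: float = 0.75
    effect_factor: float = 2.0
    # core-fit stage free parameters
    core_free_params: tuple = ("v_pou5f3", "v_nanog", "v_sox19a", "v_sox3", "v_sox2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["core_free_params"] = list(d["core_free_params"])
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @staticmethod
    def from_yaml(text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "core_free_params" in data:
            data["core_free_params"] = tuple(data["core_free_params"])
        return PipelineConfig(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def read_bed(path) -> pd.DataFrame:
    """Parse a 3+ column BED file into a 0-based half-open interval table.

    Extra columns are preserved as name, score, strand, etc.  Raises on
    malformed coordinates, naming the offending line.
    """
    names = ["chrom", "start", "end", "name", "score", "strand"]
    rows = []
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval ({start} >= {end})")
            row = {"chrom": parts[0], "start": start, "end": end}
            for k, v in zip(names[3:], parts[3:]):
                row[k] = v
            rows.append(row)
    return pd.DataFrame(rows, columns=[c for c in names if rows and c in rows[0]] or names[:3])


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    """TSV with an optional '# config: <hash>' header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if config_hash:
            fh.write(f"# config: {config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Run simulate -> fit-core -> fit-targets -> classify-genome -> link-enrich.

    All inputs are generated by the synthetic-data module; outputs are
    written under ``outdir`` and a summary dict (also saved as
    summary.json) is returned.  A stage failure raises StageError; outputs
    of completed stages are retained.
    """
    from . import synthetic_data as syn
    from .core_model import build_core_model
    from .enhancer_genomics import assign_four_groups, call_regulation, h3k27ac_status, select_tdars
    from .estimation import multistart_fit
    from .linkage_enrichment import chisq_enrichment, link_regions_to_tss
    from .mini_models import InputCurves
    from .model_selection import classify_target_panel
    from .objectives import build_core_objective

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    chash = config.config_hash
    (outdir / "config.yaml").write_text(config.to_yaml())
    summary: dict = {"config_hash": chash, "seed": seed}
    ss = np.random.SeedSequence(entropy=seed)
    s_core, s_panel, s_fixture, s_fit, s_targets = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5))

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        model = build_core_model("default")
        core_df, core_truth = syn.generate_core_dataset(model, sigma_obs=0.0, seed=s_core)
        panel_df, panel_truth, inputs = syn.generate_target_panel(
            config.n_target_genes, noise_level=config.target_noise, seed=s_panel
        )
        fixture, fixture_truth = syn.generate_genomic_fixture(
            n_regions=config.n_regions,
            coupling_strength=config.coupling_strength,
            effect_factor=config.effect_factor,
            seed=s_fixture,
        )
        write_tsv(core_df, outdir / "core_timecourses.tsv", chash)
        write_tsv(panel_df, outdir / "target_panel.tsv", chash)
        for name in ("regions", "evidence", "h3k27ac", "rescue", "tss", "transcript_status", "peak_times"):
            write_tsv(fixture[name], outdir / f"{name}.tsv", chash)
        (outdir / "truth.json").write_text(fixture_truth.to_json())
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(stage, str(exc)) from exc

    # --- fit-core ---------------------------------------------------------
    stage = "fit-core"
    try:
        free = list(config.core_free_params)
        obj = build_core_objective(model, core_df, free, sigma_mode="fixed", sigmas=1.0, prior_scale=config.prior_scale)
        truth_theta = np.log10([model.params[p] for p in free])
        n_starts = min(config.core_starts, 4)  # pipeline smoke scale
        coll = multistart_fit(
            obj,
            n_starts=n_starts,
            start_box=(config.log10_lower, config.log10_upper),
            seed=s_fit,
            maxiter=150,
            extra_starts=[truth_theta + 0.3],
        )
        write_tsv(coll.to_frame(), outdir / "core_fit_waterfall.tsv", chash)
        summary["core_fit"] = {
            "best_objective": float(coll.best.objective),
            "objective_at_truth": float(obj.value(truth_theta)),
            "n_starts": int(n_starts),
            "cluster_size": int(coll.cluster_size),
        }
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- fit-targets ------------------------------------------------------
    stage = "fit-targets"
    try:
        table, _fits = classify_target_panel(
            panel_df, inputs, n_starts=min(config.mini_starts, 4), seed=s_targets,
            start_box=(config.log10_lower, config.log10_upper), maxiter=80,
        )
        write_tsv(table, outdir / "target_classification.tsv", chash)
        truth_groups = {g: panel_truth.gene_truth[g]["group"] for g in panel_truth.gene_truth}
        hits = sum(1 for _, r in table.iterrows() if r.get("group") == truth_groups.get(r["gene"]))
        summary["target_fit"] = {
            "n_genes": int(len(table)),
            "model_groups": sorted({v for v in table["group"].dropna()}),
            "group_recovery": hits / max(len(table), 1),
        }
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- classify-genome --------------------------------------------------
    stage = "classify-genome"
    try:
        regions = fixture["regions"]
        ev = fixture["evidence"]
        calls = {}
        for contrast in ("MZtriple", "MZp", "MZn"):
            sub = ev[ev["contrast"] == contrast]
            calls[contrast] = sub.groupby("region_id").apply(
                lambda g: call_regulation(list(zip(g["log2fc"], g["fdr"])), fdr=config.fdr),
                include_groups=False,
            )
        tdar = select_tdars(regions, calls["MZtriple"], fixture["tf_peaks"])
        groups = assign_four_groups(tdar, calls["MZp"], calls["MZn"])
        ac = fixture["h3k27ac"].set_index("region_id")
        statuses = {}
        for rid in groups.index:
            res = h3k27ac_status(
                ac.loc[rid].to_dict(),
                floor=config.h3k27ac_floor,
                acetyl_threshold=config.acetyl_threshold,
                delta_threshold=config.delta_threshold,
            )
            statuses[rid] = res["status"]
        annot = regions.set_index("region_id").copy()
        annot["tdar"] = tdar
        annot["group"] = groups.reindex(annot.index)
        for mut in ("MZp", "MZn", "MZs"):
            annot[f"h3k27ac_{mut}"] = pd.Series({r: s.get(mut, "0") for r, s in statuses.items()}).reindex(annot.index)
        write_tsv(annot.reset_index(), outdir / "region_annotation.tsv", chash)
        summary["genome"] = {
            "n_regions": int(len(regions)),
            "n_tdars": int(tdar.sum()),
            "region_groups": sorted(groups.unique().tolist()),
            "group_counts": groups.value_counts().to_dict(),
        }
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- link-enrich ------------------------------------------------------
    stage = "link-enrich"
    try:
        pairs = link_regions_to_tss(regions, fixture["tss"], window=config.link_window)
        write_tsv(pairs, outdir / "pairs.tsv", chash)
        region_cat = groups
        transcript_cat = fixture["transcript_status"].set_index("gene")["status"]
        result = chisq_enrichment(pairs, region_cat, transcript_cat, residual_threshold=config.residual_threshold)
        (outdir / "contingency.json").write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True))
        summary["enrichment"] = {
            "n_pairs": int(len(pairs)),
            "chi2": result.chi2,
            "dof": result.dof,
            "p_value": result.p_value,
            "strong_positive": [list(c) for c in result.strong_positive],
        }
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True, default=float))
    return summary
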