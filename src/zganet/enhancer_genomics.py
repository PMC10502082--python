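"""Rule-based classification of accessible chromatin regions and enhancers.

Accessible regions (ARs) are 110 bp windows centered on ATAC-seq peak
summits.  Per-mutant regulation calls use a consensus over four differential
-accessibility normalizations (all four significant with the same sign).
TdARs are ARs that lose accessibility in the triple Pou5f3/Sox19b/Nanog
mutant and overlap a TF ChIP-seq peak by at least 1 bp; they fall into four
groups by the non-redundant requirement for Pou5f3 and/or Nanog.  H3K27
acetylation assigns per-TF activator (+), neutral (0) or blocker (-) status
from floored mean log2 ChIP/input ratios; rescue by TF microinjection is a
log-ratio comparison; motif enrichment contrasts motif densities at summits
versus 1 kb-shifted controls.

All intervals are 0-based half-open (BED convention) and strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AR_WIDTH",
    "FOUR_GROUPS",
    "RegionRecord",
    "define_ars",
    "call_regulation",
    "select_tdars",
    "assign_four_groups",
    "h3k27ac_status",
    "score_rescue",
    "motif_enrichment",
    "gc_content",
]

AR_WIDTH = 110
FOUR_GROUPS = ("1.PN", "2.P", "3.N", "4.-")


@dataclass
class RegionRecord:
    region_id: str
    chrom: str
    start: int
    end: int
    summit: int
    clipped: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start


def define_ars(summits: pd.DataFrame, width: int = AR_WIDTH, chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """110 bp regions [summit - w/2, summit + w/2) around single-base summits.

    ``summits`` needs columns chrom and summit (absolute coordinate).
    Overlapping summits give overlapping regions (no merging).  Regions
    crossing a chromosome boundary are clipped and flagged.
    """
    if not {"chrom", "summit"} <= set(summits.columns):
        raise ValueError("summits table needs columns chrom, summit")
    half = width // 2
    rows = []
    for i, rec in enumerate(summits.itertuples(index=False)):
        chrom, summit = rec.chrom, int(rec.summit)
        size = chrom_sizes.get(chrom) if chrom_sizes else None
        if summit < 0 or (size is not None and summit >= size):
            raise ValueError(f"summit {summit} is off chromosome {chrom}")
        start, end = summit - half, summit + (width - half)
        clipped = False
        if start < 0:
            start, clipped = 0, True
        if size is not None and end > size:
            end, clipped = size, True
        region_id = getattr(rec, "region_id", None) or f"AR{i:06d}"
        rows.append({"region_id": region_id, "chrom": chrom, "start": start, "end": end, "summit": summit, "clipped": clipped})
    return pd.DataFrame(rows)


def call_regulation(evidence, fdr: float = 0.05) -> str:
    """Consensus regulation call from four (log2FC, FDR) normalization pairs.

    down iff all four fold changes are negative with FDR below threshold;
    up analogously with positive fold changes; anything else is same.
    """
    pairs = list(evidence)
    if len(pairs) != 4:
        raise ValueError(f"expected exactly four (log2FC, FDR) pairs, got {len(pairs)}")
    fcs = np.array([p[0] for p in pairs], dtype=float)
    fdrs = np.array([p[1] for p in pairs], dtype=float)
    if np.any(~np.isfinite(fcs)) or np.any(~np.isfinite(fdrs)):
        raise ValueError("evidence contains non-finite values")
    if np.all((fcs < 0) & (fdrs < fdr)):
        return "down"
    if np.all((fcs > 0) & (fdrs < fdr)):
        return "up"
    return "same"


def _overlaps_any(regions: pd.DataFrame, peaks: pd.DataFrame) -> pd.Series:
    """Boolean per region: >= 1 bp overlap with any peak (half-open)."""
    flags = np.zeros(len(regions), dtype=bool)
    for chrom, sub in regions.groupby("chrom"):
        p = peaks[peaks["chrom"] == chrom]
        if p.empty:
            continue
        starts = p["start"].to_numpy(int)
        ends = p["end"].to_numpy(int)
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        # running maximum of peak ends for peaks starting before the region end
        max_end = np.maximum.accumulate(ends)
        for i, (s, e) in zip(sub.index, zip(sub["start"].to_numpy(int), sub["end"].to_numpy(int))):
            j = np.searchsorted(starts, e, side="left")  # peaks with start < e
            if j > 0 and max_end[j - 1] > s:
                flags[regions.index.get_loc(i)] = True
    return pd.Series(flags, index=regions.index)


def select_tdars(ars: pd.DataFrame, triple_calls: pd.Series, tf_peaks: dict[str, pd.DataFrame]) -> pd.Series:
    """TdAR flag: down in the triple mutant AND >= 1 bp overlap with the
    union of the TF ChIP-seq peak sets."""
    calls = triple_calls.reindex(ars["region_id"])
    if calls.isna().any():
        missing = ars["region_id"][calls.isna().to_numpy()].tolist()[:3]
        raise KeyError(f"missing triple-mutant calls for regions {missing}...")
    union = pd.concat(list(tf_peaks.values()), ignore_index=True) if tf_peaks else pd.DataFrame(columns=["chrom", "start", "end"])
    bound = _overlaps_any(ars, union)
    tdar = (calls.to_numpy() == "down") & bound.to_numpy()
    return pd.Series(tdar, index=ars["region_id"].to_numpy(), name="tdar")


def assign_four_groups(tdar_flags: pd.Series, spg_calls: pd.Series, nanog_calls: pd.Series) -> pd.Series:
    """Four pioneer-requirement groups of TdARs.

    1.PN down in both MZspg and MZnanog; 2.P down in MZspg only; 3.N down in
    MZnanog only; 4.- down in neither.  Defined only for TdARs.
    """
    tdar_ids = tdar_flags.index[tdar_flags.astype(bool)]
    out = {}
    for rid in tdar_ids:
        if rid not in spg_calls.index or rid not in nanog_calls.index:
            raise KeyError(f"missing mutant calls for TdAR {rid}")
        p_down = spg_calls.loc[rid] == "down"
        n_down = nanog_calls.loc[rid] == "down"
        if p_down and n_down:
            out[rid] = "1.PN"
        elif p_down:
            out[rid] = "2.P"
        elif n_down:
            out[rid] = "3.N"
        else:
            out[rid] = "4.-"
    return pd.Series(out, name="group", dtype=object)


def h3k27ac_status(
    mean_log2_ratios: dict[str, float],
    floor: float = 0.1,
    acetyl_threshold: float = 0.2,
    delta_threshold: float = 0.7,
) -> dict:
    """Acetylation flag and per-TF activator/blocker status for one region.

    ``mean_log2_ratios`` maps genotype (WT plus mutants by TF, e.g. MZspg,
    MZs, MZn, optionally the triple) to the mean H3K27ac signal over 1 kb
    around the summit.  Values below ``floor`` are raised to it.  The region
    is acetylated when the floored WT mean exceeds ``acetyl_threshold``; a TF
    is an activator ("+") when removing it drops the signal by more than
    ``delta_threshold`` in log2, a blocker ("-") when the signal rises by
    more than that, else neutral ("0").
    """
    if "WT" not in mean_log2_ratios:
        raise KeyError("mean_log2_ratios must include a WT entry")
    floored = {}
    for g, v in mean_log2_ratios.items():
        v = float(v)
        if not np.isfinite(v):
            raise ValueError(f"non-finite H3K27ac mean for {g}")
        floored[g] = max(v, floor)
        if floored[g] <= 0:
            raise ValueError("floored H3K27ac means must be positive")
    wt = floored["WT"]
    acetylated = wt > acetyl_threshold
    statuses = {}
    for g, v in floored.items():
        if g == "WT":
            continue
        delta = float(np.log2(v / wt))
        statuses[g] = "+" if delta < -delta_threshold else ("-" if delta > delta_threshold else "0")
    return {"acetylated": bool(acetylated), "status": statuses, "floored": floored}


def score_rescue(wt_signal: float, control_signal: float, injected_signal: float) -> bool:
    """Rescue of accessibility by TF microinjection into the triple mutant.

    Rescued iff log2(injected/control) strictly exceeds log2(WT/injected);
    algebraically, injected > sqrt(WT * control).
    """
    for v in (wt_signal, control_signal, injected_signal):
        if v <= 0:
            raise ValueError("signals must be positive")
    return float(np.log2(injected_signal / control_signal)) > float(np.log2(wt_signal / injected_signal))


def motif_enrichment(
    motif_hits: pd.DataFrame,
    summits: pd.DataFrame,
    window: int = 60,
    control_shift: int = 1000,
) -> dict:
    """log2 ratio of motif density at AR summits versus shifted controls.

    Density is the mean number of motif hits overlapping [summit - w/2,
    summit + w/2) over all summits; controls shift every summit
    ``control_shift`` bp downstream (strandless: +shift in coordinates).
    Enrichment is undefined (NaN, flagged) when the control density is zero.
    """
    half = window // 2

    def density(shift: int) -> float:
        counts = np.zeros(len(summits))
        for k, rec in enumerate(summits.itertuples(index=False)):
            s = int(rec.summit) + shift
            lo, hi = s - half, s + (window - half)
            hits = motif_hits[motif_hits["chrom"] == rec.chrom]
            counts[k] = int(((hits["start"] < hi) & (hits["end"] > lo)).sum())
        return float(counts.mean()) if counts.size else 0.0

    d_ar = density(0)
    d_ctrl = density(control_shift)
    if d_ctrl == 0:
        return {"ar_density": d_ar, "control_density": d_ctrl, "enrichment": np.nan, "defined": False}
    return {"ar_density": d_ar, "control_density": d_ctrl, "enrichment": float(np.log2(d_ar / d_ctrl)) if d_ar > 0 else -np.inf, "defined": True}


def gc_content(sequence: str) -> float:
    """GC fraction of a 110 bp region sequence over {A,C,G,T,N}.

    N bases are excluded from the denominator; an all-N sequence gives NaN.
    """
    seq = sequence.upper()
    if len(seq) != AR_WIDTH:
        raise ValueError(f"expected a {AR_WIDTH} bp sequence, got {len(seq)}")
    counts = {b: seq.count(b) for b in "ACGTN"}
    if sum(counts.values()) != len(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"invalid characters in sequence: {bad}")
    denom = len(seq) - counts["N"]
    if denom == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / denom
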